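import numpy as np
import pytest

from portaldid.config import SimulationConfig
from portaldid.simulate import generate_cohort


def null_structure(**overrides) -> dict:
    """Config kwargs that switch off every nuisance component of the generator.

    Used by parameter-recovery tests so the only signal is what the test
    injects.
    """
    base = dict(
        consistent_user_frac=0.0,
        temporary_user_frac=0.0,
        dispersion=1.0,
        adoption_logit_coefs={"intercept": -1.0},
        apn_increment_rate_user=0.4,
        apn_increment_rate_nonuser=0.4,
        covariate_effects={},
        apn_effect={},
        time_effects=(0.0,) * 12,
        disease_effects=(0.0,) * 11,
        treatment_effects={
            "arrived": (0.0,) * 11,
            "no_show": (0.0,) * 11,
            "cancelled": (0.0,) * 11,
        },
        intercepts={
            "arrived": np.log(0.5),
            "no_show": np.log(0.08),
            "cancelled": np.log(0.08),
        },
    )
    base.update(overrides)
    return base


@pytest.fixture(scope="session")
def default_cohort():
    """Mid-size cohort under the study-condition defaults (selection, lags,
    overdispersion all active); shared across read-only tests."""
    config = SimulationConfig(n_patients=5000, seed=20260919)
    patients, quarters = generate_cohort(config)
    return config, patients, quarters


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
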