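"""Synthetic cohort generator: determinism, selection, APN process, counts."""

import math

import numpy as np
import pandas as pd
import pytest

from portaldid.config import ConfigError, SimulationConfig
from portaldid.prep import validate_observations
from portaldid.simulate import (
    assign_adoption,
    generate_cohort,
    patient_rng,
    read_cohort,
    simulate_apn_path,
    simulate_counts,
    write_cohort,
)
from conftest import null_structure


class TestGenerateCohort:
    def test_zero_patients_gives_empty_tables(self):
        patients, quarters = generate_cohort(SimulationConfig(n_patients=0, seed=1))
        assert len(patients) == 0 and len(quarters) == 0
        assert list(quarters.columns) == [
            "patient_id", "t", "apn", "arrived", "no_show", "cancelled"
        ]

    def test_same_seed_bit_identical(self):
        cfg = SimulationConfig(n_patients=300, seed=77)
        p1, q1 = generate_cohort(cfg)
        p2, q2 = generate_cohort(cfg)
        pd.testing.assert_frame_equal(p1, p2)
        pd.testing.assert_frame_equal(q1, q2)

    def test_different_seed_differs(self):
        p1, _ = generate_cohort(SimulationConfig(n_patients=300, seed=1))
        p2, _ = generate_cohort(SimulationConfig(n_patients=300, seed=2))
        assert not p1.equals(p2)

    def test_degenerate_selection_yields_no_adopters(self):
        cfg = SimulationConfig(
            n_patients=400, seed=3,
            adoption_logit_coefs={"intercept": -math.inf},
        )
        patients, _ = generate_cohort(cfg)
        assert (patients["status"] == "non-user").all()
        assert patients["adopt_index"].isna().all()

    def test_generated_users_adopt_at_or_after_new_visit(self, default_cohort):
        _, patients, _ = default_cohort
        users = patients[patients["status"].isin(["user", "temporary-user"])]
        assert (users["adopt_index"] >= users["new_index"]).all()
        assert (users["adopt_index"] <= 11).all()

    def test_nonusers_have_no_adoption_quarter(self, default_cohort):
        _, patients, _ = default_cohort
        assert patients.loc[patients["status"] == "non-user", "adopt_index"].isna().all()

    def test_emitted_observations_satisfy_invariants(self, default_cohort):
        _, _, quarters = default_cohort
        validate_observations(quarters)  # should not raise

    def test_window_runs_from_baseline_to_end(self, default_cohort):
        _, patients, quarters = default_cohort
        spans = quarters.groupby("patient_id")["t"].agg(["min", "max", "size"])
        assert (spans["max"] == 11).all()
        assert (spans["size"] == spans["max"] - spans["min"] + 1).all()
        regular = patients[patients["status"] != "consistent-user"]
        merged = regular.merge(spans, left_on="patient_id", right_index=True)
        assert (merged["min"] == merged["new_index"] - 1).all()

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigError, match="dispersion"):
            SimulationConfig(n_patients=10, dispersion=0.5)
        with pytest.raises(ConfigError, match="covariate_prevalences"):
            SimulationConfig(
                n_patients=10,
                covariate_prevalences={"sex": {"Female": 0.9, "Male": 0.3}},
            )
        with pytest.raises(ConfigError, match="time_effects"):
            SimulationConfig(n_patients=10, time_effects=(0.0,) * 3)

    def test_csv_round_trip(self, tmp_path):
        patients, quarters = generate_cohort(SimulationConfig(n_patients=50, seed=9))
        write_cohort(patients, quarters, tmp_path)
        p2, q2 = read_cohort(tmp_path)
        pd.testing.assert_frame_equal(patients, p2, check_dtype=False)
        pd.testing.assert_frame_equal(quarters, q2, check_dtype=False)


class TestAssignAdoption:
    def test_zero_probability_never_adopts(self, rng):
        for _ in range(50):
            flag, adopt = assign_adoption({}, {"intercept": -math.inf}, 3, rng)
            assert flag is False and math.isnan(adopt)

    def test_empirical_adoption_fraction_matches_binomial(self):
        # constant logistic mean p = 0.3; binomial MC band +-0.02 at n=10,000
        p = 0.3
        coefs = {"intercept": math.log(p / (1 - p))}
        rng = np.random.default_rng(4)
        flags = [assign_adoption({}, coefs, 2, rng)[0] for _ in range(10_000)]
        assert abs(np.mean(flags) - p) < 0.02

    def test_adoption_never_precedes_new_visit(self, rng):
        for new in (1, 5, 10):
            for _ in range(200):
                flag, adopt = assign_adoption({}, {"intercept": 50.0}, new, rng)
                assert flag and new <= adopt <= 11

    def test_zero_mean_lag_adopts_at_new_visit(self, rng):
        for _ in range(50):
            _, adopt = assign_adoption({}, {"intercept": 9.0}, 4, rng, mean_lag=0.0)
            assert adopt == 4


class TestApnPath:
    def test_zero_rate_constant_path(self, rng):
        path = simulate_apn_path(10, 0.0, 3, rng)
        assert (path == 3).all()

    def test_negative_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_apn_path(5, -0.1, 0, rng)

    def test_paths_nondecreasing(self, rng):
        for _ in range(200):
            path = simulate_apn_path(12, 0.7, 1, rng)
            assert (np.diff(path) >= 0).all()

    def test_mean_increment_matches_rate(self, rng):
        # law of large numbers: mean per-quarter increment within 3 SE of rate
        rate, n_paths, steps = 0.6, 10_000, 6
        total = sum(
            simulate_apn_path(steps + 1, rate, 0, rng)[-1] for _ in range(n_paths)
        )
        mean_inc = total / (n_paths * steps)
        se = math.sqrt(rate / (n_paths * steps))
        assert abs(mean_inc - rate) < 3 * se

    def test_user_group_accrues_more_problems(self, default_cohort):
        config, patients, quarters = default_cohort
        assert config.apn_increment_rate_user > config.apn_increment_rate_nonuser
        end = quarters[quarters["t"] == 11].merge(patients, on="patient_id")
        users = end.loc[end["status"] == "user", "apn"].mean()
        nonusers = end.loc[end["status"] == "non-user", "apn"].mean()
        assert users > nonusers


class TestSimulateCounts:
    def test_null_predictor_has_unit_mean(self, rng):
        draws = simulate_counts(np.zeros(10_000), 1.0, rng)
        assert abs(draws.mean() - 1.0) < 0.05

    def test_variance_to_mean_ratio_targets_dispersion(self, rng):
        mu, phi = 4.0, 2.0
        draws = simulate_counts(np.full(10_000, np.log(mu)), phi, rng)
        assert abs(draws.var() / draws.mean() - phi) < 0.2

    def test_unit_dispersion_is_poisson(self, rng):
        # chi-square goodness of fit against Poisson(2), alpha = 0.01
        from scipy import stats

        mu = 2.0
        draws = simulate_counts(np.full(20_000, np.log(mu)), 1.0, rng)
        kmax = 8
        observed = np.bincount(np.minimum(draws, kmax), minlength=kmax + 1)
        probs = stats.poisson.pmf(np.arange(kmax), mu)
        probs = np.append(probs, 1 - probs.sum())
        chi2 = ((observed - 20_000 * probs) ** 2 / (20_000 * probs)).sum()
        assert stats.chi2.sf(chi2, kmax) > 0.01

    def test_nonfinite_predictor_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_counts(np.array([0.0, np.inf]), 1.0, rng)

    def test_dispersion_below_one_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_counts(np.zeros(3), 0.9, rng)


class TestSubstreams:
    def test_substreams_keyed_by_patient(self):
        a = patient_rng(5, 3).random(4)
        b = patient_rng(5, 3).random(4)
        c = patient_rng(5, 4).random(4)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)


def test_adoption_quarter_rate_ratio_approaches_exp_beta0():
    """With only a lag-0 treatment effect, the user/non-user ratio of mean
    arrived counts at the adoption quarter estimates exp(beta0)."""
    beta0 = np.log(1.5)
    cfg = SimulationConfig(
        n_patients=10_000, seed=60,
        **null_structure(
            treatment_effects={
                "arrived": tuple([beta0] + [0.0] * 10),
                "no_show": (0.0,) * 11,
                "cancelled": (0.0,) * 11,
            },
            adoption_mean_lag=0.0,
        ),
    )
    patients, quarters = generate_cohort(cfg)
    merged = quarters.merge(patients, on="patient_id")
    at_adopt = merged[merged["t"] == merged["adopt_index"]]
    user_mean = at_adopt["arrived"].mean()
    nonuser_mean = merged.loc[merged["status"] == "non-user", "arrived"].mean()
    ratio = user_mean / nonuser_mean
    assert abs(np.log(ratio) - beta0) < 0.1
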