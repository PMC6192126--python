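"""Simulation configuration for the synthetic EHR cohort generator.

The defaults emulate the structure of a new-patient primary-care cohort in a
12-quarter window: demographic prevalences follow the published non-user
marginals of a large academic health system, roughly a quarter of patients
adopt the portal (with covariate-dependent selection), adoption happens at or
shortly after the new visit, disease burden (active problem number, APN)
rises faster for eventual adopters, and the three appointment outcomes
(arrived, no-show, cancelled) are overdispersed log-link counts with
time fixed effects, disease-process lags and treatment lags.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import log
from typing import Mapping, Sequence

from .prep import N_QUARTERS

OUTCOMES = ("arrived", "no_show", "cancelled")


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the offending field."""


def _default_prevalences() -> dict[str, dict[str, float]]:
    # Non-user demographic marginals of the study population (column
    # percentages of the published balance table), renormalized.
    return {
        "age_category": {
            "0-18": 0.124, "19-30": 0.276, "31-45": 0.240, "46-64": 0.240, "65+": 0.119,
        },
        "sex": {"Female": 0.556, "Male": 0.444},
        "race": {
            "Asian": 0.032, "Black": 0.264, "Hispanic": 0.004,
            "Other": 0.060, "Unknown": 0.051, "White": 0.588,
        },
        "marital_status": {
            "Divorced/Separated": 0.048, "Married": 0.302, "Other": 0.010,
            "Partner": 0.005, "Single": 0.525, "Unknown": 0.087, "Widowed": 0.024,
        },
        "insurance": {
            "Blue Cross Blue Shield": 0.394, "Commercial/Managed Care": 0.185,
            "Federal/Military": 0.006, "Medicaid": 0.227, "Medicare": 0.147,
            "No Record": 0.002, "Self-pay": 0.037, "Workers Compensation": 0.002,
        },
    }


def _default_adoption_coefs() -> dict:
    # Log-odds of portal adoption: direction and rough size of the published
    # selection pattern (middle-aged, female, married more likely; children,
    # Black race, Medicaid/Medicare less likely).  Intercept targets an
    # adopter share near 26%.
    return {
        "intercept": -1.05,
        "age_category": {"0-18": -1.3, "31-45": 0.45, "46-64": 0.35, "65+": -0.15},
        "sex": {"Female": 0.45},
        "race": {"Black": -0.85, "Asian": 0.3},
        "marital_status": {"Married": 0.55},
        "insurance": {"Medicaid": -0.9, "Medicare": -0.45},
    }


def _default_time_effects() -> tuple[float, ...]:
    # Mild secular drift in visit rates across the 12 quarters.
    return tuple(0.01 * t for t in range(N_QUARTERS))


def _default_disease_effects() -> tuple[float, ...]:
    # Natural course of the condition triggering the new visit: a strong
    # utilization spike at the new-visit quarter that decays over ~2 years.
    peaks = [1.4, 0.9, 0.7, 0.55, 0.45, 0.35, 0.3, 0.25, 0.2, 0.15, 0.1]
    return tuple(peaks)


def _zero_lags() -> tuple[float, ...]:
    return tuple(0.0 for _ in range(N_QUARTERS - 1))


def _default_treatment_effects() -> dict[str, tuple[float, ...]]:
    # Treatment scales all appointment-making by the published arrived-visit
    # trajectory (boost at adoption fading into a deficit) and additionally
    # shifts the per-appointment no-show odds by the published Omega
    # trajectory.  Because arrived and cancelled share one vector, the
    # complement count Z = arrived + cancelled is exactly log-linear and the
    # generated no-show Omega_k equals the stated odds ratios; the
    # cancellation rate is (nearly) unaffected, as the study found.
    volume = [log(x) for x in
              (1.330, 0.991, 0.950, 0.950, 0.941, 0.901, 0.920, 0.819, 0.804,
               0.911, 0.905)]
    noshow_omega = [log(x) for x in
                    (0.663, 0.827, 0.752, 0.806, 0.784, 0.685, 0.658, 0.932,
                     0.835, 0.603, 0.781)]
    no_show = [v + o for v, o in zip(volume, noshow_omega)]
    return {"arrived": tuple(volume), "no_show": tuple(no_show),
            "cancelled": tuple(volume)}


def _default_intercepts() -> dict[str, float]:
    # Log baseline quarterly rates: completed visits dominate; no-shows
    # around 0.04/quarter (0.14-0.20 per patient-year); cancellations similar.
    return {"arrived": log(0.18), "no_show": log(0.040), "cancelled": log(0.050)}


def _default_covariate_effects() -> dict[str, dict[str, float]]:
    # Small log-scale utilization shifts by demography.
    return {
        "age_category": {"46-64": 0.10, "65+": 0.20},
        "sex": {"Female": 0.05},
        "insurance": {"Medicare": 0.10},
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Lag-effect sequences are indexed k = 0..n_quarters-2 (quarters since the
    new visit for disease effects, since portal adoption for treatment
    effects); shorter sequences are padded with zeros.
    """

    n_patients: int = 2000
    n_quarters: int = N_QUARTERS
    seed: int = 0
    covariate_prevalences: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_prevalences
    )
    adoption_logit_coefs: Mapping = field(default_factory=_default_adoption_coefs)
    time_effects: Sequence[float] = field(default_factory=_default_time_effects)
    disease_effects: Sequence[float] = field(default_factory=_default_disease_effects)
    treatment_effects: Mapping[str, Sequence[float]] = field(
        default_factory=_default_treatment_effects
    )
    intercepts: Mapping[str, float] = field(default_factory=_default_intercepts)
    user_main_effect: float = 0.0
    apn_effect: Mapping[str, float] = field(
        default_factory=lambda: {"1-4": 0.25, "5+": 0.45}
    )
    covariate_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_covariate_effects
    )
    dispersion: float = 1.5
    apn_start_mean: float = 1.5
    apn_increment_rate_user: float = 0.55
    apn_increment_rate_nonuser: float = 0.40
    adoption_mean_lag: float = 0.5
    consistent_user_frac: float = 0.10
    temporary_user_frac: float = 0.05
    login_mean: float = 4.0
    full_window: bool = False

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be nonnegative")
        if self.n_quarters < 2:
            raise ConfigError("n_quarters must be at least 2")
        if self.dispersion < 1.0:
            raise ConfigError("dispersion must be >= 1")
        if self.apn_start_mean < 0:
            raise ConfigError("apn_start_mean must be nonnegative")
        for name in ("apn_increment_rate_user", "apn_increment_rate_nonuser"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.adoption_mean_lag < 0:
            raise ConfigError("adoption_mean_lag must be nonnegative")
        if not 0 <= self.consistent_user_frac + self.temporary_user_frac <= 1:
            raise ConfigError(
                "consistent_user_frac + temporary_user_frac must lie in [0, 1]"
            )
        if self.login_mean < 1:
            raise ConfigError("login_mean must be >= 1 (activation counts as a login)")
        for var, levels in self.covariate_prevalences.items():
            probs = list(levels.values())
            if any(p < 0 or p > 1 for p in probs):
                raise ConfigError(f"covariate_prevalences[{var!r}] outside [0, 1]")
            # printed column percentages round to ~0.1%; renormalize silently
            # inside that tolerance, reject anything further off
            if abs(sum(probs) - 1.0) > 1e-2:
                raise ConfigError(f"covariate_prevalences[{var!r}] must sum to 1")
        if len(self.time_effects) != self.n_quarters:
            raise ConfigError("time_effects must have length n_quarters")
        max_lags = self.n_quarters - 1
        if len(self.disease_effects) > max_lags:
            raise ConfigError("disease_effects longer than n_quarters - 1")
        for outcome in OUTCOMES:
            if outcome not in self.intercepts:
                raise ConfigError(f"intercepts missing outcome {outcome!r}")
            lags = self.treatment_effects.get(outcome, ())
            if len(lags) > max_lags:
                raise ConfigError(
                    f"treatment_effects[{outcome!r}] longer than n_quarters - 1"
                )

    # -- convenience -------------------------------------------------------

    def with_(self, **overrides) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **overrides)

    def padded_lags(self, values: Sequence[float]) -> "tuple[float, ...]":
        out = list(values) + [0.0] * (self.n_quarters - 1 - len(values))
        return tuple(out)
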