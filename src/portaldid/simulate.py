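"""Synthetic longitudinal EHR cohort generator.

Emulates the data structure the panel-DID analysis assumes: a 12-quarter
window, staggered new-visit quarters, covariate-dependent portal adoption at
or shortly after the new visit, a nondecreasing disease-burden (APN) process
that rises faster for adopters, and overdispersed log-link counts of
appointments arrived, no-shows and cancellations with time fixed effects,
disease-process lags and treatment lags.

All randomness flows from ``config.seed`` through per-patient Philox
substreams keyed by patient id, so cohorts are reproducible row-for-row and
invariant to patient reordering.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .config import OUTCOMES, SimulationConfig
from .prep import (
    STATUS_CONSISTENT,
    STATUS_NONUSER,
    STATUS_TEMPORARY,
    STATUS_USER,
    apn_category,
    classify_patient_status,
    compute_baseline_quarter,
)

PATIENT_COLUMNS = [
    "patient_id", "age_category", "sex", "race", "marital_status", "insurance",
    "status", "new_index", "adopt_index", "login_count",
]
QUARTER_COLUMNS = ["patient_id", "t", "apn", "arrived", "no_show", "cancelled"]


def patient_rng(seed: int, patient_id: int) -> np.random.Generator:
    """Counter-based substream for one patient, keyed by (seed, patient_id)."""
    return np.random.Generator(np.random.Philox(key=(int(seed) << 32) + int(patient_id)))


def _logistic(x: float) -> float:
    if x > 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def adoption_probability(covariates: dict, coefs: dict) -> float:
    """Logistic adoption probability from per-covariate log-odds."""
    lp = float(coefs.get("intercept", 0.0))
    for var, level in covariates.items():
        lp += float(coefs.get(var, {}).get(level, 0.0))
    return _logistic(lp)


def assign_adoption(
    covariates: dict,
    coefs: dict,
    new_index: int,
    rng: np.random.Generator,
    mean_lag: float = 0.5,
    t_max: int = 11,
) -> tuple[bool, float]:
    """Draw portal adoption and its timing for one patient.

    Adoption is Bernoulli with a logistic mean in the covariates.  Adopters
    activate the portal at the new visit or shortly after: the lag beyond the
    new-visit quarter is geometric with the configured mean, truncated at the
    end of the window.  Returns ``(user_flag, adopt_index)`` with NaN for
    non-adopters.
    """
    p = adoption_probability(covariates, coefs)
    if not (rng.random() < p):
        return False, math.nan
    if mean_lag <= 0:
        lag = 0
    else:
        lag = int(rng.geometric(1.0 / (1.0 + mean_lag))) - 1
    return True, float(min(new_index + lag, t_max))


def simulate_apn_path(
    n_quarters: int,
    increment_rate: float,
    start_value: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Nondecreasing active-problem-number path over ``n_quarters`` quarters.

    The path starts at ``start_value`` and accrues independent
    Poisson(``increment_rate``) increments each subsequent quarter.
    """
    if increment_rate < 0:
        raise ValueError("increment_rate must be nonnegative")
    if n_quarters < 1:
        return np.zeros(0, dtype=np.int64)
    increments = rng.poisson(increment_rate, size=n_quarters - 1) if n_quarters > 1 else []
    return int(start_value) + np.concatenate([[0], np.cumsum(increments, dtype=np.int64)])


def simulate_counts(
    lin_pred: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw counts with mean exp(lin_pred) and variance dispersion * mean.

    ``dispersion == 1`` gives plain Poisson draws; ``dispersion > 1`` uses a
    negative-binomial parameterization with size mu/(phi-1) and success
    probability 1/phi, whose variance/mean ratio is exactly phi.
    """
    lin_pred = np.asarray(lin_pred, dtype=float)
    if not np.all(np.isfinite(lin_pred)):
        raise ValueError("nonfinite linear predictor in count simulation")
    if dispersion < 1.0:
        raise ValueError("dispersion must be >= 1")
    mu = np.exp(lin_pred)
    if dispersion == 1.0:
        return rng.poisson(mu)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if np.any(pos):
        size = mu[pos] / (dispersion - 1.0)
        out[pos] = rng.negative_binomial(size, 1.0 / dispersion)
    return out


def generate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one synthetic cohort: (patients table, patient-quarter table)."""
    T = config.n_quarters - 1
    cov_order = list(config.covariate_prevalences)
    cov_levels = {v: list(lv) for v, lv in config.covariate_prevalences.items()}
    cov_cum = {}
    for v in cov_order:
        c = np.cumsum(list(config.covariate_prevalences[v].values()))
        cov_cum[v] = c / c[-1]
    time_eff = np.asarray(config.time_effects, dtype=float)
    disease_eff = np.asarray(config.padded_lags(config.disease_effects), dtype=float)
    treat_eff = {
        o: np.asarray(config.padded_lags(config.treatment_effects.get(o, ())), dtype=float)
        for o in OUTCOMES
    }
    adopter_split = (config.consistent_user_frac, config.temporary_user_frac)

    patient_rows: list[tuple] = []
    q_pid: list[np.ndarray] = []
    q_t: list[np.ndarray] = []
    q_apn: list[np.ndarray] = []
    q_counts: dict[str, list[np.ndarray]] = {o: [] for o in OUTCOMES}

    for pid in range(config.n_patients):
        rng = patient_rng(config.seed, pid)

        u = rng.random(len(cov_order))
        covs = {
            v: cov_levels[v][int(np.searchsorted(cov_cum[v], u[j], side="right"))]
            for j, v in enumerate(cov_order)
        }
        new_index = int(rng.integers(1, T)) if T > 1 else 1

        adopter, adopt_index = assign_adoption(
            covs, config.adoption_logit_coefs, new_index, rng,
            mean_lag=config.adoption_mean_lag, t_max=T,
        )
        active_at_end = True
        adopt_raw: float | None = None
        if adopter:
            roll = rng.random()
            if roll < adopter_split[0]:
                adopt_raw = -1.0  # pre-study activation
                adopt_index = math.nan
            elif roll < adopter_split[0] + adopter_split[1]:
                adopt_raw = adopt_index
                active_at_end = False
            else:
                adopt_raw = adopt_index
        else:
            active_at_end = False
        status = classify_patient_status(adopt_raw, active_at_end, (0, T))

        login_count = int(rng.geometric(1.0 / config.login_mean)) if adopter else 0

        in_window_adopt = adopt_index if not math.isnan(adopt_index) else None
        baseline_t = max(compute_baseline_quarter(new_index, in_window_adopt), 0)
        if status == STATUS_CONSISTENT:
            # portal active since before the window: observe from t = 0, the
            # floor used when this group joins the sensitivity user cohort
            baseline_t = 0
        t_start = 0 if config.full_window else baseline_t
        ts = np.arange(t_start, T + 1)
        window = ts >= baseline_t

        rate = (
            config.apn_increment_rate_user if adopter
            else config.apn_increment_rate_nonuser
        )
        start = int(rng.poisson(config.apn_start_mean))
        path = simulate_apn_path(int(np.sum(window)), rate, start, rng)
        apn = np.zeros(ts.shape, dtype=np.int64)
        apn[window] = path

        # effective treatment start: consistent-users are active from t = 0
        if status == STATUS_CONSISTENT:
            treat_start: float = 0.0
        elif adopter:
            treat_start = adopt_index
        else:
            treat_start = math.inf

        dlag = ts - new_index
        has_d = (dlag >= 0) & (dlag <= T - 1)
        tlag = ts - treat_start
        has_t = np.isfinite(tlag) & (tlag >= 0) & (tlag <= T - 1)
        apn_shift = np.array(
            [config.apn_effect.get(apn_category(int(a)), 0.0) for a in apn]
        )
        cov_shift = sum(
            float(config.covariate_effects.get(v, {}).get(covs[v], 0.0))
            for v in cov_order
        )
        base_lp = (
            time_eff[ts]
            + np.where(has_d, disease_eff[np.clip(dlag, 0, T - 1)], 0.0)
            + apn_shift
            + cov_shift
            + (config.user_main_effect if adopter else 0.0)
        )
        tl = np.clip(tlag, 0, T - 1).astype(int, copy=False) if adopter else None
        for o in OUTCOMES:
            lp = base_lp + config.intercepts[o]
            if adopter:
                lp = lp + np.where(has_t, treat_eff[o][tl], 0.0)
            lp = np.where(window, lp, -np.inf)
            counts = np.zeros(ts.shape, dtype=np.int64)
            if np.any(window):
                counts[window] = simulate_counts(lp[window], config.dispersion, rng)
            q_counts[o].append(counts)

        patient_rows.append(
            (pid, covs["age_category"], covs["sex"], covs["race"],
             covs["marital_status"], covs["insurance"], status, new_index,
             adopt_index if status in (STATUS_USER, STATUS_TEMPORARY) else math.nan,
             login_count)
        )
        q_pid.append(np.full(ts.shape, pid, dtype=np.int64))
        q_t.append(ts)
        q_apn.append(apn)

    patients = pd.DataFrame(patient_rows, columns=PATIENT_COLUMNS)
    if patient_rows:
        quarters = pd.DataFrame(
            {
                "patient_id": np.concatenate(q_pid),
                "t": np.concatenate(q_t),
                "apn": np.concatenate(q_apn),
                "arrived": np.concatenate(q_counts["arrived"]),
                "no_show": np.concatenate(q_counts["no_show"]),
                "cancelled": np.concatenate(q_counts["cancelled"]),
            }
        )
    else:
        quarters = pd.DataFrame(
            {c: pd.Series(dtype=np.int64) for c in QUARTER_COLUMNS}
        )
    return patients, quarters


def write_cohort(
    patients: pd.DataFrame, quarters: pd.DataFrame, outdir: str | Path
) -> tuple[Path, Path]:
    """Write `patients.csv` / `quarters.csv` (missing adopt_index as empty field)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p_path = outdir / "patients.csv"
    q_path = outdir / "quarters.csv"
    patients.to_csv(p_path, index=False)
    quarters.to_csv(q_path, index=False)
    return p_path, q_path


def read_cohort(outdir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the generator's CSV pair back into data frames."""
    outdir = Path(outdir)
    patients = pd.read_csv(outdir / "patients.csv")
    quarters = pd.read_csv(outdir / "quarters.csv")
    return patients, quarters
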