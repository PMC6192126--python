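"""Two-model rate-ratio (Omega) test for no-show and cancellation rates.

A per-appointment event rate (e.g. the no-show rate, no-shows over
appointments scheduled) is compared between users and non-users by fitting
the panel-DID count model twice: once with the event count Y as response and
once with the complementary count Z of scheduled appointments that were not
the event.  With lag-k treatment effects beta_k (Y model) and b_k (Z model),

    Omega_k = exp(beta_k - b_k) = rho1 / rho0,

where rho = E[Y]/E[Z] is the per-completed-appointment odds of the event and
rho/(1+rho) the event rate.  Omega_k < 1 if and only if the treated/control
event-rate ratio is below 1, so testing Omega_k = 1 tests the rate contrast.
The two fits share one design and are correlated; by default the contrast's
CI and p-value come from a nonparametric bootstrap that resamples matched
pairs (or patients) and refits both models, with a faster influence-function
(delta-method) approximation available.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .glm import FitError, QuasiPoissonFit, fit_quasi_poisson, irls_poisson
from .panel import design_matrix

log = logging.getLogger(__name__)

EVENTS = ("no_show", "cancelled")


def rate_from_rho(rho):
    """Event rate from per-completed-appointment odds: rho/(1+rho)."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0):
        raise ValueError("rho must be nonnegative")
    out = rho / (1.0 + rho)
    return float(out) if out.ndim == 0 else out


def rho_from_rate(rate):
    """Inverse of :func:`rate_from_rho`: rate/(1-rate)."""
    rate = np.asarray(rate, dtype=float)
    if np.any((rate < 0) | (rate >= 1)):
        raise ValueError("rate must lie in [0, 1)")
    out = rate / (1.0 - rate)
    return float(out) if out.ndim == 0 else out


def derive_paired_responses(
    observations: pd.DataFrame,
    event: str = "no_show",
    include_cancellations: bool = True,
) -> tuple[pd.Series, pd.Series]:
    """Split scheduled appointments into event and non-event counts.

    Scheduled = arrived + no_show + cancelled.  Y is the event count and
    Z = scheduled - Y, so Y + Z = scheduled row by row.  With
    ``include_cancellations=False`` (no-show analysis only) cancellations are
    excluded from the denominator: Z = arrived.
    """
    if event not in EVENTS:
        raise KeyError(f"event must be one of {EVENTS}")
    y = observations[event].astype(int)
    if include_cancellations or event == "cancelled":
        scheduled = (
            observations["arrived"] + observations["no_show"] + observations["cancelled"]
        )
        z = scheduled - y
    else:
        z = observations["arrived"].astype(int)
    if (z < 0).any():
        raise ValueError("negative complementary count; inconsistent appointment counts")
    return y, z


def fit_paired_outcome_models(
    panel: pd.DataFrame,
    event: str = "no_show",
    n_quarters: int = 12,
    include_cancellations: bool = True,
    X: pd.DataFrame | None = None,
) -> tuple[QuasiPoissonFit, QuasiPoissonFit]:
    """Fit the event-count and complement-count models on one shared design."""
    if X is None:
        X = design_matrix(panel, n_quarters=n_quarters)
    y, z = derive_paired_responses(panel, event, include_cancellations)
    try:
        fit_y = fit_quasi_poisson(X, y.to_numpy(float))
    except FitError as exc:
        raise FitError(f"event-count ({event}) model failed: {exc}") from exc
    try:
        fit_z = fit_quasi_poisson(X, z.to_numpy(float))
    except FitError as exc:
        raise FitError(f"complement-count model failed: {exc}") from exc
    return fit_y, fit_z


def _treatment_lags(fit_y: QuasiPoissonFit, fit_z: QuasiPoissonFit) -> list[int]:
    ks = []
    for name in fit_y.params.index:
        if name.startswith("tlag_") and name in fit_z.params.index:
            ks.append(int(name.split("_")[1]))
    return sorted(ks)


def _reference_row(columns: list[str], tau: int, dlag: int | None, T: int) -> np.ndarray:
    """Design row for a reference user (all covariates at reference levels)."""
    row = pd.Series(0.0, index=columns)
    if "const" in row.index:
        row["const"] = 1.0
    if "user" in row.index:
        row["user"] = 1.0
    if tau >= 1 and f"time_{tau}" in row.index:
        row[f"time_{tau}"] = 1.0
    if dlag is not None and 0 <= dlag <= T - 1 and f"dlag_{dlag}" in row.index:
        row[f"dlag_{dlag}"] = 1.0
    return row.to_numpy()


def implied_rates(
    fit_y: QuasiPoissonFit,
    fit_z: QuasiPoissonFit,
    panel: pd.DataFrame,
    k: int,
    n_quarters: int = 12,
) -> tuple[float, float, float, float]:
    """Implied (rho1, rho0, rate1, rate0) at reference covariates for lag k.

    The reference profile is a user with every categorical at its reference
    level, evaluated at the modal adoption and new-visit quarters of the
    user group, k quarters post adoption.
    """
    T = n_quarters - 1
    users = panel[(panel["user"] == 1) & panel["treatment_lag"].notna()]
    if len(users):
        adopt = (users["t"] - users["treatment_lag"]).mode().iloc[0]
        new = (users["t"] - users["disease_lag"]).dropna().mode()
        new = new.iloc[0] if len(new) else adopt
    else:
        adopt, new = 1, 1
    tau = int(min(adopt + k, T))
    dlag = int(tau - new) if 0 <= tau - new <= T - 1 else None
    ry = _reference_row(list(fit_y.params.index), tau, dlag, T)
    rz = _reference_row(list(fit_z.params.index), tau, dlag, T)
    lp_y0 = float(ry @ fit_y.params.to_numpy())
    lp_z0 = float(rz @ fit_z.params.to_numpy())
    beta = fit_y.params.get(f"tlag_{k}", np.nan)
    b = fit_z.params.get(f"tlag_{k}", np.nan)
    rho0 = np.exp(lp_y0 - lp_z0)
    rho1 = np.exp(lp_y0 + beta - (lp_z0 + b))
    return rho1, rho0, rate_from_rho(rho1), rate_from_rho(rho0)


def _bootstrap_contrasts(
    X: np.ndarray,
    columns: list[str],
    y: np.ndarray,
    z: np.ndarray,
    unit_rows: list[np.ndarray],
    start_y: np.ndarray,
    start_z: np.ndarray,
    lag_cols: dict[int, int],
    n_boot: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Resample units, refit both models, return (n_boot, n_lags) of beta_k - b_k."""
    n_units = len(unit_rows)
    lags = sorted(lag_cols)
    out = np.full((n_boot, len(lags)), np.nan)
    for b in range(n_boot):
        take = rng.integers(0, n_units, size=n_units)
        idx = np.concatenate([unit_rows[u] for u in take])
        Xb = X[idx]
        support = Xb.any(axis=0)
        cols = np.flatnonzero(support)
        try:
            by, *_ = irls_poisson(Xb[:, cols], y[idx], start=start_y[cols])
            bz, *_ = irls_poisson(Xb[:, cols], z[idx], start=start_z[cols])
        except (FitError, np.linalg.LinAlgError):
            continue
        pos = {c: i for i, c in enumerate(cols)}
        for j, k in enumerate(lags):
            c = lag_cols[k]
            if c in pos:
                out[b, j] = by[pos[c]] - bz[pos[c]]
    return out


def omega_test(
    fit_y: QuasiPoissonFit,
    fit_z: QuasiPoissonFit,
    panel: pd.DataFrame,
    pairs: pd.DataFrame | None = None,
    n_boot: int = 500,
    seed: int = 0,
    method: str = "bootstrap",
    min_success: float = 0.5,
    n_quarters: int = 12,
) -> pd.DataFrame:
    """Estimate and test Omega_k = exp(beta_k - b_k) for every available lag.

    ``method="bootstrap"`` (default) resamples matched pairs -- or patients,
    when no pair table is given -- with replacement, refits both models per
    replicate, and forms percentile CIs and a two-sided inversion p-value.
    ``method="delta"`` uses the joint influence-function covariance of the
    two fits (fast approximation).  Returns one row per lag with the implied
    reference no-show/cancellation rates.
    """
    if fit_y.X is None or fit_z.X is None:
        raise ValueError("fits must retain their design (keep_data=True)")
    lags = _treatment_lags(fit_y, fit_z)
    if not lags:
        raise ValueError("no treatment-lag coefficients shared by the two fits")
    # a lag cell with no events in either response has a divergent MLE; its
    # contrast is reported as absent rather than as a spurious 0 or inf
    cols = {k: list(fit_y.params.index).index(f"tlag_{k}") for k in lags}
    degenerate = {
        k for k in lags
        if fit_y.y[fit_y.X[:, cols[k]] == 1].sum() == 0
        or fit_z.y[fit_z.X[:, cols[k]] == 1].sum() == 0
    }
    lags = [k for k in lags if k not in degenerate]
    if degenerate:
        log.info("omega: lags %s have empty event cells; skipped", sorted(degenerate))
    if not lags:
        raise ValueError("every treatment-lag cell is empty of events")
    d_hat = {
        k: float(fit_y.params[f"tlag_{k}"] - fit_z.params[f"tlag_{k}"]) for k in lags
    }

    pid = panel["patient_id"].to_numpy()
    if pairs is not None and len(pairs):
        units = [
            np.flatnonzero((pid == u) | (pid == n))
            for u, n in zip(pairs["user_id"], pairs["nonuser_id"])
        ]
    else:
        units = [np.flatnonzero(pid == p) for p in np.unique(pid)]

    columns = list(fit_y.params.index)
    lag_cols = {k: columns.index(f"tlag_{k}") for k in lags}
    records = []
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        draws = _bootstrap_contrasts(
            fit_y.X, columns, fit_y.y, fit_z.y, units,
            fit_y.params.to_numpy(), fit_z.params.to_numpy(),
            lag_cols, n_boot, rng,
        )
        for j, k in enumerate(lags):
            d = draws[:, j]
            d = d[np.isfinite(d)]
            if len(d) < min_success * n_boot:
                raise FitError(
                    f"lag {k}: only {len(d)}/{n_boot} successful bootstrap refits"
                )
            lo, hi = np.percentile(d, [2.5, 97.5])
            n_eff = len(d)
            p_lo = (np.sum(d <= 0) + 1) / (n_eff + 1)
            p_hi = (np.sum(d >= 0) + 1) / (n_eff + 1)
            p = min(1.0, 2.0 * min(p_lo, p_hi))
            records.append((k, d_hat[k], np.exp(lo), np.exp(hi), p, n_eff))
    elif method == "delta":
        cov = _joint_contrast_se(fit_y, fit_z, units, lag_cols)
        z975 = stats.norm.ppf(0.975)
        for k in lags:
            se = cov[k]
            d = d_hat[k]
            p = 2.0 * stats.norm.sf(abs(d) / se) if se > 0 else np.nan
            records.append((k, d, np.exp(d - z975 * se), np.exp(d + z975 * se), p, 0))
    else:
        raise ValueError("method must be 'bootstrap' or 'delta'")

    rows = []
    for k, d, lo, hi, p, nb in records:
        rho1, rho0, r1, r0 = implied_rates(fit_y, fit_z, panel, k, n_quarters)
        rows.append(
            {
                "lag": k, "omega": float(np.exp(d)), "ci_low": lo, "ci_high": hi,
                "p": p, "rho_treated": rho1, "rho_control": rho0,
                "rate_treated": r1, "rate_control": r0, "n_boot": nb,
            }
        )
    return pd.DataFrame(rows)


def _joint_contrast_se(
    fit_y: QuasiPoissonFit,
    fit_z: QuasiPoissonFit,
    units: list[np.ndarray],
    lag_cols: dict[int, int],
) -> dict[int, float]:
    """SE of beta_k - b_k from stacked per-unit score influence functions."""
    X, yy, muy = fit_y.X, fit_y.y, fit_y.mu
    zz, muz = fit_z.y, fit_z.mu
    Ay = np.linalg.inv((X * muy[:, None]).T @ X)
    Az = np.linalg.inv((X * muz[:, None]).T @ X)
    ry = (yy - muy)[:, None] * X
    rz = (zz - muz)[:, None] * X
    p = X.shape[1]
    Myy = np.zeros((p, p))
    Mzz = np.zeros((p, p))
    Myz = np.zeros((p, p))
    for rows in units:
        sy = ry[rows].sum(axis=0)
        sz = rz[rows].sum(axis=0)
        Myy += np.outer(sy, sy)
        Mzz += np.outer(sz, sz)
        Myz += np.outer(sy, sz)
    Vy = Ay @ Myy @ Ay
    Vz = Az @ Mzz @ Az
    Cyz = Ay @ Myz @ Az
    out = {}
    for k, c in lag_cols.items():
        var = Vy[c, c] + Vz[c, c] - 2.0 * Cyz[c, c]
        out[k] = float(np.sqrt(max(var, 0.0)))
    return out
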