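"""Panel difference-in-differences design and overdispersed Poisson fit.

The design has one row per patient-quarter from the patient's baseline
quarter through the end of the window.  For patient i at quarter t the
log-link mean of a count outcome is

    gamma*User_i + sum_tau lambda_tau*Time_{i tau}(t)
      + sum_k theta_k*D_{ik}(t) + sum_k beta_k*P_{ik}(t)
      + alpha*APN_cat_{it} + eta*X_i

with Time_{i tau}(t)=1 iff tau=t, D_{ik}(t)=1 iff t-NewIndex_i=k (disease
process, both groups), and P_{ik}(t)=1 iff t-AdoptIndex_i=k and User_i=1
(lag-k treatment effect).  The tau=0 time dummy is absorbed into the
intercept; APN category "0" and the first level of each demographic are
reference levels.  Inference is quasi-Poisson: Wald tests with the Pearson
dispersion scaling the covariance.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd
from scipy import stats

from .glm import QuasiPoissonFit, fit_quasi_poisson
from .prep import DEMOGRAPHIC_COLUMNS, STATUS_USER, apn_category, compute_baseline_quarter

log = logging.getLogger(__name__)

RESPONSES = ("arrived", "no_show", "cancelled")

_ROLE_PATTERNS = {
    "time": re.compile(r"^time_(\d+)$"),
    "disease": re.compile(r"^dlag_(\d+)$"),
    "treatment": re.compile(r"^tlag_(\d+)$"),
}


class DesignError(ValueError):
    """Raised when the panel cannot be assembled (missing quarters, bad lags)."""


def build_panel(
    patients: pd.DataFrame,
    quarters: pd.DataFrame,
    n_quarters: int = 12,
    full_window: bool = False,
) -> pd.DataFrame:
    """Assemble one design row per patient-quarter.

    ``patients`` must already be the analysis cohort (users + comparison
    non-users), with ``status``, ``new_index`` and ``adopt_index``; rows are
    taken from each patient's baseline quarter (or t=0 when
    ``full_window``) through the end of the window, and every required
    quarter observation must exist.
    """
    T = n_quarters - 1
    pats = patients.set_index("patient_id")
    user = (pats["status"] == STATUS_USER).astype(int)
    baseline = pats.apply(
        lambda r: max(compute_baseline_quarter(r["new_index"], r.get("adopt_index")), 0),
        axis=1,
    )
    start = baseline * 0 if full_window else baseline

    merged = quarters.merge(
        pd.DataFrame(
            {
                "patient_id": pats.index,
                "user": user.to_numpy(),
                "new_index": pats["new_index"].to_numpy(),
                "adopt_index": pats["adopt_index"].to_numpy()
                if "adopt_index" in pats
                else np.nan,
                "window_start": start.to_numpy(),
            }
        ),
        on="patient_id",
        how="inner",
    )
    merged = merged[(merged["t"] >= merged["window_start"]) & (merged["t"] <= T)]

    # every quarter in the window must be observed
    counts = merged.groupby("patient_id")["t"].agg(["size", "min", "max"])
    missing_pat = counts.index[counts["size"] != T - counts["min"] + 1]
    if len(missing_pat):
        pid = missing_pat[0]
        have = set(merged.loc[merged["patient_id"] == pid, "t"])
        t_missing = sorted(set(range(int(counts.loc[pid, "min"]), T + 1)) - have)
        raise DesignError(f"patient {pid} missing quarter rows {t_missing}")
    absent = set(pats.index) - set(counts.index)
    if absent:
        raise DesignError(f"patients without any quarter rows: {sorted(absent)[:5]}")

    dlag = merged["t"] - merged["new_index"]
    has_d = (dlag >= 0) & (dlag <= T - 1)
    tlag = merged["t"] - merged["adopt_index"]
    has_t = (merged["user"] == 1) & tlag.notna() & (tlag >= 0) & (tlag <= T - 1)

    panel = pd.DataFrame(
        {
            "patient_id": merged["patient_id"].to_numpy(),
            "t": merged["t"].astype(int).to_numpy(),
            "user": merged["user"].to_numpy(),
            "disease_lag": dlag.where(has_d).to_numpy(),
            "treatment_lag": tlag.where(has_t).to_numpy(),
            "apn_cat": merged["apn"].astype(int).map(apn_category).to_numpy(),
            "arrived": merged["arrived"].astype(int).to_numpy(),
            "no_show": merged["no_show"].astype(int).to_numpy(),
            "cancelled": merged["cancelled"].astype(int).to_numpy(),
        }
    )
    demo = pats[list(DEMOGRAPHIC_COLUMNS)]
    panel = panel.merge(demo, left_on="patient_id", right_index=True, how="left")
    return panel.sort_values(["patient_id", "t"], ignore_index=True)


def design_matrix(panel: pd.DataFrame, n_quarters: int = 12) -> pd.DataFrame:
    """Encode the panel into the named dummy design (intercept included).

    Columns: const, user, time_1..time_T, dlag_0..dlag_{T-1},
    tlag_0..tlag_{T-1}, apn_<level> (reference "0"), and one dummy per
    non-reference demographic level.
    """
    T = n_quarters - 1
    n = len(panel)
    cols: dict[str, np.ndarray] = {"const": np.ones(n), "user": panel["user"].to_numpy(float)}
    t = panel["t"].to_numpy()
    for tau in range(1, T + 1):
        cols[f"time_{tau}"] = (t == tau).astype(float)
    dl = panel["disease_lag"].to_numpy(float)
    tl = panel["treatment_lag"].to_numpy(float)
    for k in range(T):
        cols[f"dlag_{k}"] = (dl == k).astype(float)
    for k in range(T):
        cols[f"tlag_{k}"] = (tl == k).astype(float)
    apn = panel["apn_cat"].astype(str)
    for level in ("1-4", "5+"):
        cols[f"apn_{level}"] = (apn == level).to_numpy(float)
    X = pd.DataFrame(cols, index=panel.index)
    demo = pd.get_dummies(
        panel[list(DEMOGRAPHIC_COLUMNS)].astype(str), drop_first=True, dtype=float
    )
    return pd.concat([X, demo], axis=1)


def fit_overdispersed_poisson(
    panel: pd.DataFrame,
    response: str = "arrived",
    n_quarters: int = 12,
    X: pd.DataFrame | None = None,
) -> QuasiPoissonFit:
    """Fit the panel-DID quasi-Poisson model for one count response.

    Point estimates are Poisson ML; the Pearson dispersion phi scales the
    covariance (quasi-likelihood).  Lag dummies with zero support are
    dropped and recorded on the fit.
    """
    if response not in panel.columns:
        raise KeyError(f"unknown response {response!r}")
    if X is None:
        X = design_matrix(panel, n_quarters=n_quarters)
    fit = fit_quasi_poisson(X, panel[response].to_numpy(float))
    if fit.dropped:
        log.info("dropped zero-support columns: %s", fit.dropped)
    return fit


def lag_effect_table(fit: QuasiPoissonFit, role: str = "treatment") -> pd.DataFrame:
    """Rate ratios exp(coef) with 95% Wald CIs per lag for one dummy role.

    Dropped (zero-support) lags are reported with NaN estimates.
    """
    if role not in _ROLE_PATTERNS:
        raise KeyError(f"role must be one of {sorted(_ROLE_PATTERNS)}")
    pat = _ROLE_PATTERNS[role]
    z = stats.norm.ppf(0.975)
    ks, rrs, lows, highs, ps = [], [], [], [], []
    names = list(fit.params.index) + fit.dropped
    for name in names:
        m = pat.match(name)
        if not m:
            continue
        k = int(m.group(1))
        ks.append(k)
        if name in fit.dropped:
            rrs.append(np.nan), lows.append(np.nan), highs.append(np.nan), ps.append(np.nan)
            continue
        b = fit.params[name]
        se = float(np.sqrt(fit.cov.loc[name, name]))
        rrs.append(np.exp(b))
        lows.append(np.exp(b - z * se))
        highs.append(np.exp(b + z * se))
        ps.append(2.0 * stats.norm.sf(abs(b) / se) if se > 0 else np.nan)
    out = pd.DataFrame(
        {"lag": ks, "rr": rrs, "ci_low": lows, "ci_high": highs, "p": ps}
    ).sort_values("lag", ignore_index=True)
    return out
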