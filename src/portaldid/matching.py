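"""Propensity-score estimation and 1:1 nearest-neighbor matching.

Non-users are matched to portal users on the probability of becoming a user,
estimated by logistic regression on the time-invariant demographics plus the
discretized baseline utilization profile.  By default matching is exact on
the new-visit quarter (stratified) with greedy nearest-neighbor selection on
the propensity score inside each stratum, without replacement and without a
caliper.  Balance is reported Table-1 style: per-level counts, column
percentages and Pearson chi-square p-values for the unmatched and matched
contrasts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2_contingency

from .prep import BASELINE_CATEGORY_COLUMNS, DEMOGRAPHIC_COLUMNS

log = logging.getLogger(__name__)

MATCHING_COVARIATES = tuple(DEMOGRAPHIC_COLUMNS) + tuple(BASELINE_CATEGORY_COLUMNS)


@dataclass
class PropensityModel:
    """Logistic propensity fit: coefficients, per-patient scores, model card."""

    params: pd.Series
    scores: pd.Series  # indexed by patient_id
    reference_levels: dict[str, str]
    penalized: bool = False


@dataclass
class MatchedCohort:
    pairs: pd.DataFrame  # columns: user_id, nonuser_id, stratum, score_user, score_nonuser
    unmatched_users: list = field(default_factory=list)
    propensity: PropensityModel | None = None

    @property
    def matched_ids(self) -> np.ndarray:
        return np.concatenate(
            [self.pairs["user_id"].to_numpy(), self.pairs["nonuser_id"].to_numpy()]
        )


def _design(covariates: pd.DataFrame, columns: list[str] | None = None):
    cats = covariates.astype("object")
    X = pd.get_dummies(cats, drop_first=True, dtype=float)
    refs = {
        c: sorted(cats[c].astype(str).unique())[0] for c in cats.columns
    }
    X.insert(0, "const", 1.0)
    if columns is not None:
        X = X.reindex(columns=columns, fill_value=0.0)
    return X, refs


def estimate_propensity(
    covariates: pd.DataFrame, user_flag: pd.Series | np.ndarray
) -> PropensityModel:
    """Estimate P(user | baseline covariates) by maximum-likelihood logit.

    On (quasi-)separation the fit falls back to a small ridge penalty and
    warns.  ``covariates`` must be indexed by patient_id and contain only
    categorical columns.
    """
    y = np.asarray(user_flag, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("propensity model needs both users and non-users")
    X, refs = _design(covariates)
    penalized = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
        params = res.params
        scores = np.asarray(res.fittedvalues)
        ok = res.converged and np.all(np.isfinite(params))
    except (sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning,
            np.linalg.LinAlgError):
        ok = False
    if not ok:
        warnings.warn(
            "propensity logit separated or failed to converge; "
            "refitting with a small ridge penalty"
        )
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(C=1e3, max_iter=2000)
        Xv = X.drop(columns="const").to_numpy()
        lr.fit(Xv, y)
        params = pd.Series(
            np.concatenate([lr.intercept_, lr.coef_[0]]), index=X.columns
        )
        scores = lr.predict_proba(Xv)[:, 1]
        penalized = True
    eps = np.finfo(float).tiny
    scores = np.clip(scores, eps, 1.0 - eps)
    return PropensityModel(
        params=pd.Series(params, index=X.columns),
        scores=pd.Series(scores, index=covariates.index),
        reference_levels=refs,
        penalized=penalized,
    )


def _greedy_match(
    user_ids: np.ndarray,
    user_scores: np.ndarray,
    nonuser_ids: np.ndarray,
    nonuser_scores: np.ndarray,
    caliper: float | None,
) -> tuple[list[tuple], list]:
    """Greedy 1:1 nearest neighbor without replacement.

    Users are processed in descending propensity score; distance ties break
    to the lowest non-user id.
    """
    order = np.lexsort((user_ids, -user_scores))
    # pool kept id-sorted so that np.argmin on equal distances lands on the
    # lowest remaining non-user id
    pool_order = np.argsort(nonuser_ids)
    pool_ids = nonuser_ids[pool_order]
    pool_scores = nonuser_scores[pool_order]
    alive = np.ones(len(pool_ids), dtype=bool)
    pairs: list[tuple] = []
    unmatched: list = []
    for idx in order:
        uid, us = user_ids[idx], user_scores[idx]
        if not alive.any():
            unmatched.append(uid)
            continue
        live = np.flatnonzero(alive)
        d = np.abs(pool_scores[live] - us)
        j = live[int(np.argmin(d))]
        if caliper is not None and abs(pool_scores[j] - us) > caliper:
            unmatched.append(uid)
            continue
        pairs.append((uid, pool_ids[j], us, pool_scores[j]))
        alive[j] = False
    return pairs, unmatched


def match_nearest(
    scores: pd.Series,
    user_ids: np.ndarray,
    nonuser_ids: np.ndarray,
    strata: pd.Series | None = None,
    caliper: float | None = None,
) -> MatchedCohort:
    """Match each user to its nearest-propensity non-user, 1:1 without replacement.

    When ``strata`` (e.g. the new-visit quarter) is given, matching is exact
    on the stratum and nearest-neighbor within it.  Users left without a
    candidate are reported in ``unmatched_users`` with a warning.
    """
    user_ids = np.asarray(user_ids)
    nonuser_ids = np.asarray(nonuser_ids)
    rows: list[tuple] = []
    unmatched: list = []
    if strata is None:
        groups = [(None, user_ids, nonuser_ids)]
    else:
        groups = []
        for key in np.unique(strata.loc[np.concatenate([user_ids, nonuser_ids])]):
            groups.append(
                (
                    key,
                    user_ids[strata.loc[user_ids].to_numpy() == key],
                    nonuser_ids[strata.loc[nonuser_ids].to_numpy() == key],
                )
            )
    for key, uids, nids in groups:
        if len(uids) == 0:
            continue
        if len(nids) < len(uids):
            warnings.warn(
                f"stratum {key!r}: only {len(nids)} non-users for {len(uids)} users; "
                "partial matching"
            )
        p, um = _greedy_match(
            uids,
            scores.loc[uids].to_numpy(),
            nids,
            scores.loc[nids].to_numpy(),
            caliper,
        )
        rows.extend([(u, n, key, su, sn) for (u, n, su, sn) in p])
        unmatched.extend(um)
    pairs = pd.DataFrame(
        rows, columns=["user_id", "nonuser_id", "stratum", "score_user", "score_nonuser"]
    )
    return MatchedCohort(pairs=pairs, unmatched_users=unmatched)


def balance_table(
    covariates: pd.DataFrame,
    user_flag: pd.Series,
    matched: MatchedCohort | None = None,
    variables: tuple[str, ...] = MATCHING_COVARIATES,
) -> pd.DataFrame:
    """Table-1-style balance diagnostics.

    For every categorical variable: level counts and column percentages for
    users vs non-users, with a Pearson chi-square p-value (no continuity
    correction), in the full cohort and -- when a matching is supplied -- in
    the matched cohort (users vs matched non-users).
    """
    user_flag = user_flag.astype(bool)
    cohorts = {"unmatched": (covariates, user_flag)}
    if matched is not None and len(matched.pairs):
        ids = np.concatenate(
            [matched.pairs["user_id"].to_numpy(), matched.pairs["nonuser_id"].to_numpy()]
        )
        cohorts["matched"] = (covariates.loc[ids], user_flag.loc[ids])
    records = []
    for cohort, (covs, flag) in cohorts.items():
        for var in variables:
            tab = pd.crosstab(covs[var].astype(str), flag)
            tab = tab.reindex(columns=[False, True], fill_value=0)
            tab = tab.loc[(tab.sum(axis=1) > 0)]
            if tab.shape[0] < 2 or (tab.sum(axis=0) == 0).any():
                pval = np.nan
                log.info("balance: %s/%s degenerate; chi-square skipped", cohort, var)
            else:
                _, pval, _, _ = chi2_contingency(tab.to_numpy(), correction=False)
            totals = tab.sum(axis=0)
            for level, row in tab.iterrows():
                records.append(
                    {
                        "cohort": cohort,
                        "variable": var,
                        "level": level,
                        "n_nonuser": int(row[False]),
                        "pct_nonuser": 100.0 * row[False] / max(totals[False], 1),
                        "n_user": int(row[True]),
                        "pct_user": 100.0 * row[True] / max(totals[True], 1),
                        "p_value": pval,
                    }
                )
    return pd.DataFrame.from_records(records)
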