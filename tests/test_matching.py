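"""Propensity estimation, greedy nearest-neighbor matching, balance tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from portaldid.matching import (
    balance_table,
    estimate_propensity,
    match_nearest,
)


def logit_ml_oracle(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Independent numeric maximizer of the Bernoulli log-likelihood."""

    def negll(beta):
        eta = X @ beta
        return float(np.sum(np.logaddexp(0.0, eta)) - y @ eta)

    def grad(beta):
        p = 1.0 / (1.0 + np.exp(-(X @ beta)))
        return X.T @ (p - y)

    res = optimize.minimize(
        negll, np.zeros(X.shape[1]), jac=grad, method="BFGS",
        options={"gtol": 1e-12, "maxiter": 1000},
    )
    return res.x


def greedy_oracle(users, nonusers):
    """Reference greedy matching: users by descending score, each taking the
    closest remaining non-user, distance ties to the lowest id."""
    pool = dict(nonusers)  # id -> score
    pairs = {}
    for uid, score in sorted(users, key=lambda kv: (-kv[1], kv[0])):
        if not pool:
            break
        best = min(pool.items(), key=lambda kv: (abs(kv[1] - score), kv[0]))
        pairs[uid] = best[0]
        del pool[best[0]]
    return pairs


class TestPropensity:
    def test_null_selection_gives_flat_scores(self, rng):
        n = 4000
        covs = pd.DataFrame(
            {
                "a": rng.choice(["x", "y"], n),
                "b": rng.choice(["p", "q", "r"], n),
            },
            index=pd.RangeIndex(n, name="patient_id"),
        )
        flags = rng.random(n) < 0.3  # independent of covariates
        model = estimate_propensity(covs, flags)
        slopes = model.params.drop("const")
        assert (slopes.abs() < 0.3).all()
        assert abs(model.scores.mean() - flags.mean()) < 0.02

    def test_matches_numeric_likelihood_oracle_on_toy(self):
        covs = pd.DataFrame(
            {
                "x1": ["a", "a", "b", "b", "a", "b", "a", "b"],
                "x2": ["u", "v", "u", "v", "v", "u", "v", "u"],
            },
            index=pd.RangeIndex(8, name="patient_id"),
        )
        y = np.array([0, 0, 0, 0, 0, 1, 1, 1], dtype=float)  # finite MLE (no separation)
        model = estimate_propensity(covs, y)
        X = np.column_stack(
            [
                np.ones(8),
                (covs["x1"] == "b").astype(float),
                (covs["x2"] == "v").astype(float),
            ]
        )
        oracle = logit_ml_oracle(X, y)
        np.testing.assert_allclose(model.params.to_numpy(), oracle, atol=1e-6)

    def test_scores_strictly_inside_unit_interval(self, default_cohort):
        _, patients, _ = default_cohort
        covs = patients.set_index("patient_id")[
            ["age_category", "sex", "race", "marital_status", "insurance"]
        ]
        flags = patients.set_index("patient_id")["status"].eq("user")
        model = estimate_propensity(covs, flags)
        assert (model.scores > 0).all() and (model.scores < 1).all()

    def test_single_class_rejected(self):
        covs = pd.DataFrame({"a": ["x", "y", "x"]})
        with pytest.raises(ValueError):
            estimate_propensity(covs, np.ones(3))


class TestNearestNeighbor:
    def test_worked_example_matches_enumeration_oracle(self):
        users = [(0, 0.2), (1, 0.5), (2, 0.9)]
        nonusers = [(10, 0.1), (11, 0.45), (12, 0.55), (13, 0.85), (14, 0.95)]
        scores = pd.Series(dict(users + nonusers))
        res = match_nearest(scores, np.array([0, 1, 2]), np.array([10, 11, 12, 13, 14]))
        got = dict(zip(res.pairs["user_id"], res.pairs["nonuser_id"]))
        assert got == greedy_oracle(users, nonusers)
        # frozen from the oracle: 0.95 is (in binary) minutely closer to 0.9
        # than 0.85 is, so the highest-score user takes id 14
        assert got == {2: 14, 1: 11, 0: 10}

    def test_exact_distance_tie_breaks_to_lowest_id(self):
        # binary-exact scores: both candidates at distance 0.25
        scores = pd.Series({0: 0.5, 7: 0.75, 3: 0.25})
        res = match_nearest(scores, np.array([0]), np.array([7, 3]))
        assert res.pairs["nonuser_id"].iloc[0] == 3

    def test_identical_score_multisets_match_exactly(self):
        scores = pd.Series({0: 0.3, 1: 0.6, 2: 0.8, 10: 0.3, 11: 0.6, 12: 0.8})
        res = match_nearest(scores, np.array([0, 1, 2]), np.array([10, 11, 12]))
        assert len(res.pairs) == 3 and not res.unmatched_users
        dist = (res.pairs["score_user"] - res.pairs["score_nonuser"]).abs()
        assert (dist == 0).all()

    def test_single_pair(self):
        scores = pd.Series({5: 0.4, 9: 0.9})
        res = match_nearest(scores, np.array([5]), np.array([9]))
        assert list(res.pairs[["user_id", "nonuser_id"]].iloc[0]) == [5, 9]

    def test_empty_user_set_is_empty_result(self):
        scores = pd.Series({1: 0.5})
        res = match_nearest(scores, np.array([], dtype=int), np.array([1]))
        assert len(res.pairs) == 0

    def test_no_nonuser_reused_and_pair_count(self, rng):
        n_u, n_n = 60, 100
        ids = np.arange(n_u + n_n)
        scores = pd.Series(rng.random(n_u + n_n), index=ids)
        res = match_nearest(scores, ids[:n_u], ids[n_u:])
        assert res.pairs["nonuser_id"].is_unique
        assert len(res.pairs) == min(n_u, n_n)

    def test_partial_matching_warns_and_reports_unmatched(self, rng):
        ids = np.arange(7)
        scores = pd.Series(rng.random(7), index=ids)
        with pytest.warns(UserWarning, match="partial"):
            res = match_nearest(scores, ids[:5], ids[5:])
        assert len(res.pairs) == 2 and len(res.unmatched_users) == 3

    def test_stratified_matching_respects_strata(self, rng):
        n = 40
        ids = np.arange(n)
        scores = pd.Series(rng.random(n), index=ids)
        strata = pd.Series(ids % 2, index=ids)
        res = match_nearest(scores, ids[: n // 2], ids[n // 2:], strata=strata)
        for _, row in res.pairs.iterrows():
            assert strata[row["user_id"]] == strata[row["nonuser_id"]] == row["stratum"]

    def test_caliper_excludes_distant_pairs(self):
        scores = pd.Series({0: 0.1, 1: 0.9, 10: 0.12, 11: 0.5})
        res = match_nearest(scores, np.array([0, 1]), np.array([10, 11]), caliper=0.05)
        assert list(res.pairs["user_id"]) == [0]
        assert res.unmatched_users == [1]


class TestBalanceTable:
    def _covs(self, rng, n=300):
        return pd.DataFrame(
            {
                "age_category": rng.choice(["young", "old"], n),
                "sex": rng.choice(["F", "M"], n),
            },
            index=pd.RangeIndex(n, name="patient_id"),
        )

    def test_identical_groups_have_p_one(self, rng):
        half = self._covs(rng, 200)
        covs = pd.concat([half, half], ignore_index=True)
        covs.index.name = "patient_id"
        flags = pd.Series([False] * 200 + [True] * 200, index=covs.index)
        table = balance_table(covs, flags, variables=("age_category", "sex"))
        np.testing.assert_allclose(table["p_value"].to_numpy(), 1.0)

    def test_two_by_two_matches_hand_computation(self):
        # users 10/90 vs non-users 30/70 on a binary covariate
        levels = ["a"] * 30 + ["b"] * 70 + ["a"] * 10 + ["b"] * 90
        covs = pd.DataFrame({"v": levels})
        covs.index.name = "patient_id"
        flags = pd.Series([False] * 100 + [True] * 100, index=covs.index)
        table = balance_table(covs, flags, variables=("v",))
        # hand chi-square: expected a = 20, b = 80 per group
        chi2_hand = sum(
            (obs - exp) ** 2 / exp
            for obs, exp in [(30, 20), (70, 80), (10, 20), (90, 80)]
        )
        from scipy.stats import chi2

        p_hand = chi2.sf(chi2_hand, 1)
        assert table["p_value"].iloc[0] == pytest.approx(p_hand, rel=1e-10)

    def test_percentages_sum_to_hundred(self, rng):
        covs = self._covs(rng)
        flags = pd.Series(rng.random(len(covs)) < 0.4, index=covs.index)
        table = balance_table(covs, flags, variables=("age_category", "sex"))
        sums = table.groupby(["cohort", "variable"])[["pct_user", "pct_nonuser"]].sum()
        assert np.allclose(sums, 100.0)

    def test_label_swap_leaves_balance_unchanged(self, rng):
        covs = self._covs(rng)
        flags = pd.Series(rng.random(len(covs)) < 0.5, index=covs.index)
        t1 = balance_table(covs, flags, variables=("age_category", "sex"))
        t2 = balance_table(covs, ~flags, variables=("age_category", "sex"))
        np.testing.assert_allclose(t1["p_value"], t2["p_value"])
        np.testing.assert_allclose(t1["n_user"], t2["n_nonuser"])
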