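"""Panel-DID design construction and lag-effect inference."""

import numpy as np
import pandas as pd
import pytest

from portaldid.config import SimulationConfig
from portaldid.glm import QuasiPoissonFit
from portaldid.panel import (
    DesignError,
    build_panel,
    design_matrix,
    fit_overdispersed_poisson,
    lag_effect_table,
)
from portaldid.prep import apply_inclusion_criteria
from portaldid.simulate import generate_cohort


@pytest.fixture(scope="module")
def included_panel(default_cohort):
    _, patients, quarters = default_cohort
    included, _ = apply_inclusion_criteria(patients)
    panel = build_panel(included, quarters)
    return included, panel


class TestDesignRules:
    def test_indicator_iff_rules_hold_row_by_row(self, included_panel):
        """Time, disease-lag, and treatment-lag indicators obey their iff
        definitions on every generated panel row."""
        included, panel = included_panel
        pats = included.set_index("patient_id")
        new = pats.loc[panel["patient_id"], "new_index"].to_numpy()
        adopt = pats.loc[panel["patient_id"], "adopt_index"].to_numpy()
        user = pats.loc[panel["patient_id"], "status"].eq("user").to_numpy()
        t = panel["t"].to_numpy()

        dlag_expect = np.where((t - new >= 0) & (t - new <= 10), t - new, np.nan)
        np.testing.assert_array_equal(panel["disease_lag"].to_numpy(), dlag_expect)

        tl = t - adopt
        tlag_expect = np.where(user & (tl >= 0) & (tl <= 10), tl, np.nan)
        np.testing.assert_array_equal(panel["treatment_lag"].to_numpy(), tlag_expect)

        X = design_matrix(panel)
        time_cols = X[[f"time_{tau}" for tau in range(1, 12)]].to_numpy()
        np.testing.assert_array_equal(time_cols.sum(axis=1), (t > 0).astype(float))
        active = time_cols.argmax(axis=1) + 1
        np.testing.assert_array_equal(active[t > 0], t[t > 0])

        dlag_cols = X[[f"dlag_{k}" for k in range(11)]].to_numpy()
        np.testing.assert_array_equal(
            dlag_cols.sum(axis=1), np.isfinite(dlag_expect).astype(float)
        )
        tlag_cols = X[[f"tlag_{k}" for k in range(11)]].to_numpy()
        np.testing.assert_array_equal(
            tlag_cols.sum(axis=1), np.isfinite(tlag_expect).astype(float)
        )

    def test_disease_lag_example(self):
        patients = pd.DataFrame(
            {
                "patient_id": [1], "status": ["non-user"], "new_index": [2],
                "adopt_index": [np.nan],
                "age_category": ["19-30"], "sex": ["F"], "race": ["White"],
                "marital_status": ["Single"], "insurance": ["Medicaid"],
            }
        )
        quarters = pd.DataFrame(
            {"patient_id": 1, "t": range(1, 12), "apn": 0,
             "arrived": 0, "no_show": 0, "cancelled": 0}
        )
        panel = build_panel(patients, quarters)
        row = panel[panel["t"] == 5].iloc[0]
        assert row["disease_lag"] == 3

    def test_nonusers_never_get_treatment_lags(self, included_panel):
        _, panel = included_panel
        assert panel.loc[panel["user"] == 0, "treatment_lag"].isna().all()

    def test_missing_quarter_row_is_an_error(self):
        patients = pd.DataFrame(
            {
                "patient_id": [1], "status": ["non-user"], "new_index": [2],
                "adopt_index": [np.nan],
                "age_category": ["19-30"], "sex": ["F"], "race": ["White"],
                "marital_status": ["Single"], "insurance": ["Medicaid"],
            }
        )
        quarters = pd.DataFrame(
            {"patient_id": 1, "t": [1, 2, 4, 5, 6, 7, 8, 9, 10, 11], "apn": 0,
             "arrived": 0, "no_show": 0, "cancelled": 0}
        )
        with pytest.raises(DesignError, match=r"patient 1 .*\[3\]"):
            build_panel(patients, quarters)

    def test_apn_categories_match_baseline_levels(self, included_panel):
        _, panel = included_panel
        assert set(panel["apn_cat"]) <= {"0", "1-4", "5+"}


class TestFit:
    def test_dispersion_recovered_from_generator(self, included_panel):
        _, panel = included_panel
        assert len(panel) >= 5000
        fit = fit_overdispersed_poisson(panel, "arrived")
        assert fit.scale == pytest.approx(1.5, rel=0.15)

    def test_unknown_response_rejected(self, included_panel):
        _, panel = included_panel
        with pytest.raises(KeyError):
            fit_overdispersed_poisson(panel, "imaginary")

    def test_empty_lag_cells_dropped_not_imputed(self, default_cohort):
        # keep only late adopters: treatment lags beyond 11 - min(adopt) are
        # unreachable and their dummies must be dropped, not imputed
        _, patients, quarters = default_cohort
        included, _ = apply_inclusion_criteria(patients)
        late = included[
            (included["status"] != "user") | (included["adopt_index"] >= 6)
        ]
        assert (late["status"] == "user").sum() > 20
        panel = build_panel(late, quarters)
        fit = fit_overdispersed_poisson(panel, "arrived")
        for k in range(6, 11):
            assert f"tlag_{k}" in fit.dropped
        table = lag_effect_table(fit, "treatment")
        assert np.isnan(table.loc[table["lag"] >= 6, "rr"]).all()
        assert np.isfinite(table.loc[table["lag"] == 0, "rr"]).all()


class TestLagEffectTable:
    def _fit_with(self, coef, se):
        params = pd.Series({"const": 0.0, "tlag_0": coef})
        cov = pd.DataFrame(
            [[1e-4, 0.0], [0.0, se ** 2]], index=params.index, columns=params.index
        )
        return QuasiPoissonFit(
            params=params, cov=cov, scale=1.0, n_obs=10, df_resid=8,
            converged=True, n_iter=3, pearson_chi2=8.0,
        )

    def test_zero_coefficient_gives_unit_rr_and_p_one(self):
        table = lag_effect_table(self._fit_with(0.0, 0.1), "treatment")
        row = table.iloc[0]
        assert row["rr"] == pytest.approx(1.0)
        assert row["p"] == pytest.approx(1.0)

    def test_closed_form_transform(self):
        coef, se = 0.2853, 0.0226
        row = lag_effect_table(self._fit_with(coef, se), "treatment").iloc[0]
        assert row["rr"] == pytest.approx(np.exp(coef), rel=1e-12)
        assert row["ci_low"] == pytest.approx(np.exp(coef - 1.959963985 * se), rel=1e-6)
        assert row["ci_high"] == pytest.approx(np.exp(coef + 1.959963985 * se), rel=1e-6)

    def test_interval_always_contains_estimate(self, included_panel):
        _, panel = included_panel
        fit = fit_overdispersed_poisson(panel, "arrived")
        for role in ("treatment", "disease"):
            table = lag_effect_table(fit, role).dropna()
            assert ((table["ci_low"] <= table["rr"]) & (table["rr"] <= table["ci_high"])).all()

    def test_unknown_role_rejected(self):
        with pytest.raises(KeyError):
            lag_effect_table(self._fit_with(0.0, 0.1), "weather")
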