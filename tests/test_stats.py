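"""Cohort transforms and standardized age regressions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bbbleak.simulate import CohortSpec, simulate_cohort
from bbbleak.stats import (RegressionResult, _standardized_ols, fit_age_model,
                           fit_interaction_model, transform_ki, transform_wmh)


class TestTransforms:
    @pytest.mark.parametrize("x,expect", [(8.0, 2.0), (-8.0, -2.0),
                                          (0.0, 0.0), (0.027, 0.3)])
    def test_signed_cube_root_values(self, x, expect):
        assert transform_ki(np.array([x]))[0] == pytest.approx(expect)

    def test_cube_root_preserves_order_and_sign(self, rng):
        x = rng.normal(0, 1e-6, 500)
        y = transform_ki(x)
        assert sps.spearmanr(x, y).statistic == 1.0
        assert np.all(np.sign(y) == np.sign(x))

    @pytest.mark.parametrize("x,expect", [(1.0, 0.0), (np.e, 1.0)])
    def test_log_wmh_values(self, x, expect):
        assert transform_wmh(np.array([x]))[0] == pytest.approx(expect)

    def test_log_wmh_zero_needs_offset(self):
        with pytest.raises(ValueError, match="positive"):
            transform_wmh(np.array([0.0, 1.0]))
        with pytest.warns(UserWarning, match="offset"):
            out = transform_wmh(np.array([0.0, 1.0]), offset=1e-3)
        assert out[0] == pytest.approx(np.log(1e-3))

    def test_nonfinite_ki_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            transform_ki(np.array([1.0, np.nan]))


def make_table(n, rng, y=None, **extra):
    age = rng.uniform(47, 91, n)
    table = pd.DataFrame({
        "age": age,
        "sex": rng.integers(0, 2, n),
        "sbp": rng.normal(140, 17, n),
        "bmi": rng.normal(28, 4, n),
        "diabetes": rng.integers(0, 2, n),
        "smoker": rng.integers(0, 2, n),
        "wmh_volume": np.exp(rng.normal(1, 0.8, n)),
        "cortical_thickness": rng.normal(2.5, 0.1, n),
        "hippocampal_volume": rng.normal(6.5, 0.7, n),
    })
    if y is None:
        y = rng.normal(1e-6, 3e-7, n)
    table["ki_white_matter"] = y
    for k, v in extra.items():
        table[k] = v
    return table


class TestStandardizedOls:
    def test_single_predictor_beta_equals_pearson_r(self, rng):
        x = rng.normal(0, 3, 200)
        y = 0.4 * x + rng.normal(0, 1, 200)
        beta, p, n = _standardized_ols(y, pd.DataFrame({"x": x}))
        r = sps.pearsonr(x, y)
        assert beta["x"] == pytest.approx(r.statistic, abs=1e-10)
        assert p["x"] == pytest.approx(r.pvalue, abs=1e-10)

    def test_matches_hand_rolled_normal_equations(self, rng):
        n = 120
        X = pd.DataFrame({"a": rng.normal(0, 2, n),
                          "b": rng.integers(0, 2, n).astype(float),
                          "c": rng.normal(5, 1, n)})
        y = 0.3 * X["a"] - 0.2 * X["b"] + rng.normal(0, 1, n)
        beta, p, _ = _standardized_ols(y.to_numpy(), X)
        # oracle: explicit (X'X)^-1 X'y with t-test p-values
        M = np.column_stack([np.ones(n), X.to_numpy()])
        XtX_inv = np.linalg.inv(M.T @ M)
        b = XtX_inv @ M.T @ y.to_numpy()
        resid = y.to_numpy() - M @ b
        s2 = resid @ resid / (n - M.shape[1])
        se = np.sqrt(s2 * np.diag(XtX_inv))
        tvals = b / se
        pvals = 2 * sps.t.sf(np.abs(tvals), n - M.shape[1])
        sdy = np.std(y, ddof=1)
        for j, col in enumerate(X.columns, start=1):
            expect_beta = b[j] * np.std(X[col], ddof=1) / sdy
            assert beta[col] == pytest.approx(expect_beta, abs=1e-10)
            assert p[col] == pytest.approx(pvals[j], abs=1e-10)

    def test_constant_predictor_rejected_by_name(self, rng):
        X = pd.DataFrame({"a": rng.normal(0, 1, 50), "flat": np.ones(50)})
        with pytest.raises(ValueError, match="flat"):
            _standardized_ols(rng.normal(0, 1, 50), X)


class TestFitAgeModel:
    def test_perfect_age_predictor(self, rng):
        n = 80
        table = make_table(n, rng)
        z = (table["age"] - table["age"].mean()) / table["age"].std()
        table["ki_white_matter"] = (z + rng.normal(0, 1e-9, n)) ** 3
        res = fit_age_model(table, "white_matter")
        assert res.beta["age"] == pytest.approx(1.0, abs=1e-4)
        assert res.p["age"] < 1e-20

    def test_row_order_invariance(self, rng):
        table = make_table(60, rng)
        a = fit_age_model(table, "white_matter")
        b = fit_age_model(table.sample(frac=1, random_state=0),
                          "white_matter")
        assert a.beta["age"] == pytest.approx(b.beta["age"], abs=1e-12)
        assert a.p["age"] == pytest.approx(b.p["age"], abs=1e-12)

    def test_affine_rescaling_of_predictor_leaves_beta_unchanged(self, rng):
        table = make_table(60, rng)
        a = fit_age_model(table, "white_matter")
        table2 = table.copy()
        table2["age"] = table2["age"] * 12.0 + 5.0   # months, shifted
        b = fit_age_model(table2, "white_matter")
        assert a.beta["age"] == pytest.approx(b.beta["age"], abs=1e-10)
        assert a.p["age"] == pytest.approx(b.p["age"], abs=1e-10)

    def test_confounder_model_includes_vascular_covariates(self, rng):
        res = fit_age_model(make_table(80, rng), "white_matter",
                            confounders=True)
        assert set(res.predictors) == {"age", "sex", "sbp", "bmi",
                                       "diabetes", "smoker"}

    def test_missing_rows_dropped_with_warning(self, rng):
        table = make_table(40, rng)
        table.loc[:4, "sbp"] = np.nan
        with pytest.warns(UserWarning, match="dropped 5 rows"):
            res = fit_age_model(table, "white_matter", confounders=True)
        assert res.n == 35

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError, match="complete rows"):
            fit_age_model(make_table(8, rng), "white_matter")

    def test_programmed_effect_recovered_from_generator(self):
        table, truth = simulate_cohort(CohortSpec(n_subjects=2000), seed=42)
        res = fit_age_model(table, "white_matter")
        assert res.beta["age"] == pytest.approx(
            truth["beta_age"]["white_matter"], abs=0.05)


class TestFitInteractionModel:
    def test_large_interaction_is_retained(self, rng):
        n = 300
        table = make_table(n, rng)
        age_c = table["age"] - table["age"].mean()
        m = table["cortical_thickness"]
        y = 0.05 * age_c * (m - m.mean()) + rng.normal(0, 0.05, n)
        table["ki_white_matter"] = y**3
        res = fit_interaction_model(table, "white_matter",
                                    "cortical_thickness")
        assert res.interaction_pruned is False
        assert "age_x_measure" in res.predictors

    def test_null_interaction_is_usually_pruned(self, rng):
        pruned = 0
        for seed in range(20):
            table, _ = simulate_cohort(CohortSpec(n_subjects=57), seed=seed)
            res = fit_interaction_model(table, "white_matter", "wmh_volume")
            pruned += res.interaction_pruned
        assert pruned >= 16   # ~95% expected under the null

    def test_mediation_attenuates_age_effect(self):
        spec = CohortSpec(n_subjects=400, mediator="wmh_volume")
        table, _ = simulate_cohort(spec, seed=7)
        marginal = fit_age_model(table, "white_matter")
        med = fit_interaction_model(table, "white_matter", "wmh_volume")
        assert abs(med.beta["age"]) < abs(marginal.beta["age"])
        # with the mediator in the model, age should lose significance
        assert med.p["age"] > 0.05 or abs(med.beta["age"]) < 0.1

    def test_unknown_measure_rejected(self, rng):
        with pytest.raises(ValueError, match="integrity_measure"):
            fit_interaction_model(make_table(40, rng), "white_matter",
                                  "ventricle_volume")

    def test_stage1_results_reported(self, rng):
        table, _ = simulate_cohort(CohortSpec(n_subjects=57), seed=0)
        res = fit_interaction_model(table, "white_matter", "wmh_volume")
        assert res.stage1_beta is not None
        assert "age_x_measure" in res.stage1_beta
        frame = res.to_frame()
        assert {"final", "with_interaction"} <= set(frame["model_stage"])
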