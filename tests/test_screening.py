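"""Logistic fitter and the per-medication screen."""

import numpy as np
import pandas as pd
import pytest

from medwas import ExposureMatrix, ModelSpec, MWASModel, fit_logistic, run_mwas
from medwas.screening import export_forest

from conftest import two_by_two_outcome_design


def design(y, x, *covs):
    return np.column_stack([np.ones(len(y)), x, *covs])


def make_matrix(cohort, columns):
    frame = pd.DataFrame(columns, index=pd.Index(cohort["delivery_id"], name="delivery_id"))
    patients = cohort.set_index("delivery_id")["patient_id"]
    return ExposureMatrix(frame.astype("int8"), patients)


def make_cohort(y, **covs):
    n = len(y)
    base = {"delivery_id": [f"d{i}" for i in range(n)],
            "patient_id": [f"p{i}" for i in range(n)],
            "maternal_age": np.full(n, 30.0), "art": np.zeros(n, dtype=int),
            "infertility": np.zeros(n, dtype=int), "mb": np.asarray(y, dtype=int)}
    base.update(covs)
    return pd.DataFrame(base)


class TestFitLogistic:
    def test_two_by_two_equals_cross_product_ratio(self):
        # exposed: 4 MB / 6 not; unexposed: 9 MB / 81 not -> OR (4*81)/(6*9) = 6
        y, x = two_by_two_outcome_design(4, 6, 9, 81)
        fit = fit_logistic(y, design(y, x))
        assert fit.converged
        assert np.exp(fit.params[1]) == pytest.approx(6.0, abs=1e-8)
        # Woolf SE of the log cross-product ratio
        assert fit.bse[1] == pytest.approx(np.sqrt(1/4 + 1/6 + 1/9 + 1/81), abs=1e-8)

    def test_balanced_outcome_gives_null_or(self):
        # identical outcome distribution in both exposure groups
        y, x = two_by_two_outcome_design(5, 45, 5, 45)
        fit = fit_logistic(y, design(y, x))
        assert fit.params[1] == pytest.approx(0.0, abs=1e-10)

    def test_complete_separation_flagged(self):
        y, x = two_by_two_outcome_design(20, 0, 0, 80)
        fit = fit_logistic(y, design(y, x))
        assert fit.diverged[1]

    def test_non_binary_outcome_rejected(self):
        y = np.array([0.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="binary"):
            fit_logistic(y, np.ones((3, 1)))

    def test_constant_covariate_dropped_without_changing_exposure_beta(self):
        rng = np.random.default_rng(7)
        x = rng.integers(0, 2, 400).astype(float)
        y = (rng.random(400) < 0.2 + 0.3 * x).astype(float)
        base = fit_logistic(y, design(y, x))
        with_const = fit_logistic(y, design(y, x, np.full(400, 2.0)))
        assert np.isnan(with_const.params[2])
        assert with_const.params[1] == pytest.approx(base.params[1], abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_statsmodels_oracle(self, seed):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(seed)
        n = 500
        X = design(np.zeros(n), rng.integers(0, 2, n), rng.normal(30, 6, n))
        beta_true = np.array([-2.0, 0.8, 0.02])
        y = (rng.random(n) < 1 / (1 + np.exp(-X @ beta_true))).astype(float)
        fit = fit_logistic(y, X)
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit(tol=1e-12, maxiter=200)
        np.testing.assert_allclose(fit.params, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.bse, ref.bse, atol=1e-6)


class TestModelSpec:
    def test_covariate_sets(self):
        assert ModelSpec("model1").covariates == ()
        assert ModelSpec("model2").covariates == ("maternal_age",)
        assert ModelSpec("model3").covariates == ("maternal_age", "art", "infertility")

    def test_invalid_label_and_alpha(self):
        with pytest.raises(ValueError):
            ModelSpec("model4")
        with pytest.raises(ValueError):
            ModelSpec("model1", alpha=1.5)


class TestRunMWAS:
    def _screen(self, tables, y, model="model1", alpha=0.05):
        cohort = make_cohort(y)
        matrix = make_matrix(cohort, tables)
        return run_mwas(cohort, matrix, spec=model, alpha=alpha)

    def test_single_medication_bonferroni_equals_nominal(self):
        y, x = two_by_two_outcome_design(4, 6, 9, 81)
        res = self._screen({"medA": x.astype(int)}, y)
        assert len(res) == 1
        assert res.loc[0, "p_bonf"] == pytest.approx(res.loc[0, "p"])

    def test_family_size_multiplies_p(self):
        y, x = two_by_two_outcome_design(4, 6, 9, 81)
        zero = np.zeros(len(y), dtype=int)
        cols = {"medA": x.astype(int)}
        cols.update({f"null{i}": np.roll(x.astype(int), 7 * (i + 1)) for i in range(3)})
        res = self._screen(cols, y).set_index("medication_id")
        assert res.loc["medA", "p_bonf"] == pytest.approx(min(1.0, 4 * res.loc["medA", "p"]))

    def test_bonferroni_calls_subset_of_nominal(self):
        rng = np.random.default_rng(11)
        n = 2000
        y = (rng.random(n) < 0.05).astype(int)
        cols = {f"m{i:02d}": (rng.random(n) < 0.05).astype(int) for i in range(20)}
        res = self._screen(cols, y)
        assert ((res["sig_bonf"] == 1) <= (res["sig_nominal"] == 1)).all()

    def test_results_sorted_and_counts_correct(self):
        y, x = two_by_two_outcome_design(4, 6, 9, 81)
        res = self._screen({"b_med": x.astype(int), "a_med": 1 - x.astype(int)}, y)
        assert list(res["medication_id"]) == ["a_med", "b_med"]
        assert res.set_index("medication_id").loc["b_med", "n_exposed"] == 10
        assert res.set_index("medication_id").loc["b_med", "n_exposed_mb"] == 4

    def test_separated_medication_flagged_not_fatal(self):
        rng = np.random.default_rng(3)
        n = 300
        y = np.zeros(n, dtype=int)
        y[:30] = 1
        sep = np.zeros(n, dtype=int)
        sep[:10] = 1  # all exposed have the outcome
        ok = (rng.random(n) < 0.1).astype(int)
        res = self._screen({"sep": sep, "fine": ok}, y).set_index("medication_id")
        assert res.loc["sep", "converged"] == 0
        assert np.isnan(res.loc["sep", "or_"])
        assert res.loc["sep", "sig_nominal"] == 0
        assert res.loc["fine", "converged"] == 1

    def test_or_equals_exp_beta_and_ci_ordering(self):
        y, x = two_by_two_outcome_design(12, 40, 30, 400)
        res = self._screen({"medA": x.astype(int)}, y, model="model1").iloc[0]
        assert res["or_"] == pytest.approx(np.exp(res["beta"]))
        assert res["ci_low"] <= res["or_"] <= res["ci_high"]
        assert res["ci_low"] == pytest.approx(np.exp(res["beta"] - 1.96 * res["se"]))


class TestForestExport:
    def _results(self, y, cols, model="model3"):
        cohort = make_cohort(y)
        rng = np.random.default_rng(5)
        cohort["maternal_age"] = rng.normal(30, 6, len(y)).round(1)
        cohort["art"] = (rng.random(len(y)) < 0.3).astype(int)
        cohort["infertility"] = (rng.random(len(y)) < 0.3).astype(int)
        matrix = make_matrix(cohort, cols)
        return MWASModel(cohort, matrix, model=model).fit()

    def test_rows_per_significant_medication_and_term(self):
        y, x = two_by_two_outcome_design(40, 60, 90, 810)
        results = self._results(y, {"medA": x.astype(int)})
        forest = export_forest(results, significant_only=True)
        if not forest.empty:
            assert set(forest["term"]) == {"exposure", "maternal_age", "art", "infertility"}
            assert len(forest) == 4 * forest["medication_id"].nunique()

    def test_no_significant_medications_gives_empty_table(self):
        rng = np.random.default_rng(9)
        y = (rng.random(500) < 0.2).astype(int)
        results = self._results(y, {"null": (rng.random(500) < 0.3).astype(int)},
                                model="model1")
        res = results.frame
        if res["sig_nominal"].sum() == 0:
            assert export_forest(results).empty

    def test_nonconverged_excluded_with_note(self):
        y = np.zeros(300, dtype=int)
        y[:30] = 1
        sep = np.zeros(300, dtype=int)
        sep[:10] = 1
        results = self._results(y, {"sep": sep}, model="model1")
        forest = export_forest(results, significant_only=False)
        assert "sep" in forest.attrs["excluded_nonconverged"]
        assert forest.empty
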