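"""Logistic fitting, screening, stepwise selection and model evaluation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from immunorecov.logistic import (
    auc_quality_label,
    backward_stepwise,
    classify_and_tabulate,
    compare_aic,
    evaluate_published_model,
    fit_logistic,
    hosmer_lemeshow,
    likelihood_ratio_test,
    load_published_models,
    roc_auc,
    univariable_screen,
)


def _sim_design(n, beta, rng, k_noise=0):
    X = pd.DataFrame({f"x{i}": rng.normal(size=n) for i in range(len(beta) + k_noise)})
    eta = sum(b * X[f"x{i}"] for i, b in enumerate(beta))
    y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float))
    return X, y


class TestFit:
    def test_intercept_only_closed_form(self):
        y = pd.Series([1.0] * 14 + [0.0] * 19)
        X = pd.DataFrame(index=y.index)
        m = fit_logistic(X, y)
        assert np.allclose(m.fitted, 14 / 33)

    def test_matches_brute_force_likelihood_grid(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0]})
        y = pd.Series([0.0, 1.0, 0.0, 1.0])  # not separable
        m = fit_logistic(X, y)

        def nll(par):
            eta = par[0] + par[1] * X["x"]
            p = 1 / (1 + np.exp(-eta))
            return -float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))

        res = optimize.minimize(nll, [0.0, 0.0], method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
        assert m.params["const"] == pytest.approx(res.x[0], abs=1e-3)
        assert m.params["x"] == pytest.approx(res.x[1], abs=1e-3)
        assert m.aic == pytest.approx(2 * 2 - 2 * (-res.fun), abs=1e-6)

    def test_separation_flagged(self):
        X = pd.DataFrame({"x": [-2.0, -1.0, 1.0, 2.0, 3.0, -3.0]})
        y = pd.Series([0.0, 0.0, 1.0, 1.0, 1.0, 0.0])
        m = fit_logistic(X, y)
        assert m.separation

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(pd.DataFrame({"x": [1.0, 2.0, 3.0]}), pd.Series([1.0, 1.0, 1.0]))

    def test_rank_deficient_design_rejected(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "x2": [2.0, 4.0, 6.0, 8.0]})
        with pytest.raises(ValueError):
            fit_logistic(X, pd.Series([0.0, 1.0, 0.0, 1.0]))

    def test_missing_rows_dropped_and_counted(self):
        X = pd.DataFrame({"x": [0.0, 1.0, np.nan, 3.0, 1.5, -1.0]})
        y = pd.Series([0.0, 1.0, 0.0, 1.0, 1.0, 0.0])
        m = fit_logistic(X, y)
        assert m.n == 5 and m.n_dropped == 1


class TestScreenAndStepwise:
    def test_strong_predictor_retained(self):
        rng = np.random.default_rng(0)
        X, y = _sim_design(300, [2.0], rng, k_noise=1)
        retained, pvals = univariable_screen(X, y)
        assert "x0" in retained and pvals["x0"] < 1e-6

    def test_noise_screen_type_one_rate(self):
        # a pure-noise candidate passes the p<0.20 screen ~20% of the time
        rng = np.random.default_rng(1)
        kept = 0
        reps = 200
        for _ in range(reps):
            X, y = _sim_design(200, [0.0], rng)
            retained, _ = univariable_screen(X, y)
            kept += "x0" in retained
        se = math.sqrt(0.2 * 0.8 / reps)
        assert abs(kept / reps - 0.20) < 4 * se

    def test_outcome_identical_candidate_flagged_retained(self):
        y = pd.Series([0.0, 1.0] * 10)
        X = pd.DataFrame({"dup": y * 2 - 1})
        retained, _ = univariable_screen(X, y)
        assert "dup" in retained

    def test_noise_predictor_removed_first(self):
        rng = np.random.default_rng(2)
        removed_first = 0
        reps = 50
        for _ in range(reps):
            X, y = _sim_design(500, [1.5], rng, k_noise=1)  # x0 signal, x1 noise
            model, trace = backward_stepwise(X, y)
            if trace and trace[0] == "x1":
                removed_first += 1
            elif not trace and "x1" in model.predictors:
                pass  # both kept: x1 happened to reach significance
        assert removed_first >= 0.9 * reps * 0.9  # >=90% removal, slack for kept-both runs

    def test_all_significant_model_unchanged(self):
        rng = np.random.default_rng(3)
        X, y = _sim_design(500, [1.5, -1.5], rng)
        model, trace = backward_stepwise(X, y)
        assert trace == [] and set(model.predictors) == {"x0", "x1"}

    def test_trace_length_identity(self):
        rng = np.random.default_rng(4)
        X, y = _sim_design(300, [2.0], rng, k_noise=3)
        model, trace = backward_stepwise(X, y)
        assert len(trace) == X.shape[1] - len(model.predictors)


class TestLRTAndAIC:
    def test_reduced_equals_full(self):
        rng = np.random.default_rng(5)
        X, y = _sim_design(100, [1.0], rng)
        m = fit_logistic(X, y)
        stat, df, p = likelihood_ratio_test(m, m)
        assert stat == pytest.approx(0.0, abs=1e-9) and p == 1.0

    def test_statistic_nonnegative_and_null_uniform(self):
        rng = np.random.default_rng(6)
        pvals = []
        for _ in range(200):
            X, y = _sim_design(200, [1.0], rng, k_noise=1)
            full = fit_logistic(X, y)
            red = fit_logistic(X[["x0"]], y)
            stat, df, p = likelihood_ratio_test(red, full)
            assert stat >= 0 and df == 1
            pvals.append(p)
        # noise column: LRT p approximately U(0,1)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(7)
        X, y = _sim_design(100, [1.0, 1.0], rng)
        m1 = fit_logistic(X[["x0"]], y)
        m2 = fit_logistic(X[["x1"]], y)
        with pytest.raises(ValueError):
            likelihood_ratio_test(m1, m2)

    def test_aic_same_model_identical_and_noise_raises_aic(self):
        rng = np.random.default_rng(8)
        X, y = _sim_design(150, [1.0], rng, k_noise=1)
        m1 = fit_logistic(X[["x0"]], y)
        m1b = fit_logistic(X[["x0"]], y)
        ranking = compare_aic([m1, m1b])
        assert ranking[0][1] == ranking[1][1]
        # adding pure noise raises AIC in expectation
        diffs = []
        for _ in range(100):
            X, y = _sim_design(150, [1.0], rng, k_noise=1)
            small = fit_logistic(X[["x0"]], y)
            big = fit_logistic(X, y)
            diffs.append(big.aic - small.aic)
        assert np.mean(diffs) > 0

    def test_aic_on_different_rows_rejected(self):
        rng = np.random.default_rng(9)
        X, y = _sim_design(100, [1.0], rng)
        m1 = fit_logistic(X, y)
        m2 = fit_logistic(X.iloc[:80], y.iloc[:80])
        with pytest.raises(ValueError):
            compare_aic([m1, m2])


class TestGoodnessOfFit:
    def test_perfectly_calibrated_bins_statistic_zero(self):
        # each probability stratum observes exactly its expected event count
        p = np.repeat([0.2, 0.4, 0.6, 0.8], 10)
        y = np.concatenate([
            np.r_[np.ones(2), np.zeros(8)],
            np.r_[np.ones(4), np.zeros(6)],
            np.r_[np.ones(6), np.zeros(4)],
            np.r_[np.ones(8), np.zeros(2)],
        ])
        stat, _ = hosmer_lemeshow(p, y, g=4)
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_null_p_roughly_uniform(self):
        # well-specified model: HL applied to fitted probabilities, chi2(g-2)
        rng = np.random.default_rng(10)
        pvals = []
        for _ in range(200):
            X, y = _sim_design(300, [1.0], rng)
            m = fit_logistic(X, y)
            _, pv = hosmer_lemeshow(m.fitted, y, g=10)
            pvals.append(pv)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.005

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow([0.5] * 5, [1, 0, 1, 0, 1], g=10)
        with pytest.raises(ValueError):
            hosmer_lemeshow([0.5] * 20, [1] * 20, g=1)


class TestROCAndClassification:
    def test_perfect_and_constant_scores(self):
        y = np.array([0, 0, 1, 1])
        auc, label, _ = roc_auc([0.1, 0.2, 0.8, 0.9], y)
        assert auc == 1.0 and label == "excellent"
        auc, label, _ = roc_auc([0.5, 0.5, 0.5, 0.5], y)
        assert auc == 0.5 and label == "poor"

    def test_auc_equals_mann_whitney_identity(self):
        from immunorecov.stats import mann_whitney

        rng = np.random.default_rng(11)
        scores = rng.permutation(40) / 40.0  # tie-free
        y = (rng.random(40) < 0.4).astype(int)
        if y.sum() in (0, 40):
            y[0] = 1 - y[0]
        auc, _, _ = roc_auc(scores, y)
        mw = mann_whitney(scores[y == 1], scores[y == 0])
        assert auc == pytest.approx(mw.extra["U_a"] / (y.sum() * (len(y) - y.sum())), abs=1e-12)

    @pytest.mark.parametrize("auc, label", [
        (0.55, "poor"), (0.75, "fair"), (0.85, "good"), (0.95, "excellent"),
    ])
    def test_quality_bins(self, auc, label):
        assert auc_quality_label(auc) == label

    def test_classification_rates(self):
        ev = classify_and_tabulate([1.0, 1.0, 0.0, 0.0], [True, True, False, False])
        assert (ev.sensitivity, ev.specificity, ev.accuracy) == (100.0, 100.0, 100.0)

    def test_boundary_half_is_probably_pir(self):
        ev = classify_and_tabulate([0.5], [True])
        assert ev.sensitivity == 100.0

    def test_accuracy_identity(self):
        rng = np.random.default_rng(12)
        p = rng.random(50)
        pir = rng.random(50) < 0.5
        ev = classify_and_tabulate(p, pir)
        tp = ((p >= 0.5) & pir).sum()
        tn = ((p < 0.5) & ~pir).sum()
        assert ev.accuracy == pytest.approx(100.0 * (tp + tn) / 50)


class TestPublishedModels:
    def test_resource_has_four_three_predictor_models(self):
        models = load_published_models()
        assert set(models) == {"1", "2", "3", "4"}
        assert all(len(m.predictors) == 3 for m in models.values())

    def test_model3_worked_example(self):
        m = load_published_models()["3"]
        cov = pd.DataFrame(
            {"age_years": [45.0], "log10_vl_baseline": [5.0], "cd4_count_6mo": [200.0]}
        )
        out = evaluate_published_model(m, cov)
        assert out.loc[0, "p_pir"] == pytest.approx(0.905, abs=5e-4)
        assert out.loc[0, "class"] == "probably PIR"

    def test_zero_coefficients_give_half(self):
        from immunorecov.logistic import PublishedLogisticModel

        m = PublishedLogisticModel("toy", 0, 0, 0, 0, ("a", "b", "c"), 1)
        assert m.p_pir(10.0, -3.0, 99.0) == 0.5

    def test_p_pir_decreases_in_cd4_under_model3(self):
        m = load_published_models()["3"]
        cov = pd.DataFrame({
            "age_years": [45.0] * 3,
            "log10_vl_baseline": [5.0] * 3,
            "cd4_count_6mo": [100.0, 200.0, 400.0],
        })
        p = evaluate_published_model(m, cov)["p_pir"]
        assert p.is_monotonic_decreasing and p.nunique() == 3

    def test_missing_predictor_rows_get_no_prediction(self):
        m = load_published_models()["4"]
        cov = pd.DataFrame({
            "age_years": [45.0, 50.0],
            "log10_vl_baseline": [5.0, np.nan],
            "cd4_count_2mo": [150.0, 200.0],
        })
        out = evaluate_published_model(m, cov)
        assert out.loc[1, "class"] == "no-prediction"
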