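"""Comparison tests, effect sizes, multiplicity/outlier policies, features."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immunorecov.cohort import VisitSeries
from immunorecov.stats import (
    bonferroni_flags,
    cd4_slope,
    cohens_d_pooled,
    cramers_v,
    derived_features,
    extreme_outlier_sensitivity,
    fisher_exact_2x2,
    flag_extreme_outliers,
    independent_t,
    independent_t_from_stats,
    magnitude_label,
    mann_whitney,
    paired_d,
    route_test,
    thymic_score,
)


def series(*pairs):
    t, v = zip(*pairs)
    return VisitSeries(np.array(t, float), np.array(v, float))


class TestRouting:
    def test_gaussian_samples_route_to_t(self):
        rng = np.random.default_rng(1)
        assert route_test(rng.normal(size=200), rng.normal(size=200)) == "t-test"

    def test_skewed_sample_routes_to_mann_whitney(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=200)
        b = np.exp(rng.normal(size=200) * 2)  # heavily skewed
        assert route_test(a, b) == "mann-whitney"

    def test_tiny_samples_nonparametric_with_warning(self):
        with pytest.warns(UserWarning):
            assert route_test([1, 2], [3, 4]) == "mann-whitney"


class TestTTest:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = independent_t(x, x)
        assert res.statistic == 0.0 and res.effect_size == 0.0

    def test_reported_age_comparison(self):
        # baseline age summaries of the two responder groups
        res = independent_t_from_stats(38.1, 8.6, 14, 45.3, 10.8, 19)
        assert res.df == 31
        assert res.effect_size == pytest.approx(0.72, abs=0.005)
        assert res.magnitude == "medium"

    def test_unit_shift_gives_d_one(self):
        rng = np.random.default_rng(3)
        # construct exactly: d from summary stats
        assert cohens_d_pooled(0.0, 1.0, 50, 1.0, 1.0, 50) == pytest.approx(1.0)

    def test_paired_d_and_degenerate_cases(self):
        assert paired_d([1.0, 2.0, 3.0]) == pytest.approx(2.0)
        with pytest.raises(ZeroDivisionError):
            paired_d([1.0, 1.0, 1.0])
        with pytest.raises(ZeroDivisionError):
            cohens_d_pooled(0.0, 0.0, 5, 1.0, 0.0, 5)


def _enumerated_mw_p(a, b):
    """Two-sided exact Mann-Whitney p by enumerating group assignments."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = None

    def u_of(idx):
        x = pooled[list(idx)]
        rest = pooled[[i for i in range(len(pooled)) if i not in idx]]
        wins = sum((xi > rest).sum() + 0.5 * (xi == rest).sum() for xi in x)
        return wins

    us = [u_of(c) for c in itertools.combinations(range(len(pooled)), n1)]
    u_obs = u_of(tuple(range(n1)))
    us = np.array(us)
    n1n2 = n1 * (len(pooled) - n1)
    lo = float(np.mean(us <= u_obs))
    hi = float(np.mean(us >= u_obs))
    return min(1.0, 2 * min(lo, hi))


class TestMannWhitney:
    def test_small_sample_exact_example(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.extra["U_a"] == 0.0
        assert res.p == pytest.approx(1 / 3)

    def test_identical_multisets_r_zero(self):
        res = mann_whitney([1, 2, 2, 5], [1, 2, 2, 5])
        assert res.effect_size == 0.0

    @given(
        st.lists(st.integers(0, 6), min_size=2, max_size=6),
        st.lists(st.integers(0, 6), min_size=2, max_size=6),
    )
    @settings(max_examples=60, deadline=None)
    def test_u_complementarity_with_ties(self, a, b):
        res = mann_whitney(a, b)
        assert res.extra["U_a"] + res.extra["U_b"] == pytest.approx(len(a) * len(b))

    def test_exact_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n1, n2 = rng.integers(2, 7), rng.integers(2, 7)
            vals = rng.permutation(20)[: n1 + n2].astype(float)  # tie-free
            a, b = vals[:n1], vals[n1:]
            assert mann_whitney(a, b).p == pytest.approx(_enumerated_mw_p(a, b), abs=1e-12)


def _enumerated_fisher_p(table):
    """Two-sided Fisher p by enumerating tables with fixed margins."""
    a, b, c, d = np.asarray(table).ravel()
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestFisherAndCramer:
    @pytest.mark.parametrize(
        "table, expected_or",
        [
            ([[7, 12], [2, 12]], 3.50),    # HCV co-infection counts
            ([[9, 5], [14, 5]], 0.64),     # gender counts
            ([[3, 11], [8, 10]], 0.34),    # drug-resistance counts
        ],
    )
    def test_reported_odds_ratios(self, table, expected_or):
        res = fisher_exact_2x2(table)
        assert res.effect_size == pytest.approx(expected_or, abs=0.005)

    def test_diagonal_table_p(self):
        assert fisher_exact_2x2([[2, 0], [0, 2]]).p == pytest.approx(1 / 3)

    def test_zero_cell_or(self):
        assert fisher_exact_2x2([[0, 13], [5, 10]]).effect_size == 0.0
        assert fisher_exact_2x2([[5, 0], [3, 10]]).effect_size == math.inf

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -2], [3, 4]])

    def test_cramers_v_extremes(self):
        assert cramers_v([[10, 0], [0, 10]]).effect_size == pytest.approx(1.0)
        outer = np.outer([10, 20], [6, 4])  # independent margins
        assert cramers_v(outer).effect_size == pytest.approx(0.0, abs=1e-12)

    def test_cramers_v_hand_computed_3x2(self):
        table = np.array([[10, 5], [4, 8], [6, 6]], float)
        n = table.sum()
        exp = np.outer(table.sum(1), table.sum(0)) / n
        chi2 = ((table - exp) ** 2 / exp).sum()
        v = math.sqrt(chi2 / (n * (2 - 1)))
        assert cramers_v(table).effect_size == pytest.approx(v, abs=1e-12)


class TestMagnitudeBins:
    @pytest.mark.parametrize(
        "kind, value, label",
        [
            ("cohens_d", 0.72, "medium"),
            ("cohens_d", 0.29, "small"),
            ("cohens_d", 0.3, "medium"),   # lower boundary closed
            ("cohens_d", 0.8, "large"),    # overlap resolves upward
            ("rank_r", -0.44, "medium"),
            ("rank_r", 0.5, "large"),
            ("cramers_v", 0.27, "small"),
            ("cramers_v", 0.7, "medium"),
            ("cramers_v", 0.71, "large"),
            ("correlation", 0.95, "very high"),
            ("correlation", 0.9, "very high"),
            ("correlation", 0.65, "moderate"),
            ("correlation", 0.1, "negligible"),
        ],
    )
    def test_bins(self, kind, value, label):
        assert magnitude_label(kind, value) == label

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            magnitude_label("eta_squared", 0.5)


class TestBonferroni:
    @pytest.mark.parametrize("m, expected", [(14, 0.004), (5, 0.010), (1, 0.05)])
    def test_thresholds(self, m, expected):
        _, threshold = bonferroni_flags([0.5], alpha=0.05, m=m)
        assert round(threshold, 3) == expected

    def test_flags(self):
        flags, thr = bonferroni_flags([0.001, 0.01, 0.2], alpha=0.05, m=14)
        assert list(flags) == [True, False, False]


class TestOutliers:
    def test_distant_point_flagged(self):
        x = list(range(1, 9)) + [1000]
        assert flag_extreme_outliers(x).tolist() == [False] * 8 + [True]

    def test_no_outliers_identical_results(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=30), rng.normal(1.0, 1.0, size=30)
        w, wo, agree = extreme_outlier_sensitivity(independent_t, a, b)
        assert w.p == wo.p and agree

    def test_outlier_removed_from_its_sample_only(self):
        a = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 1000.0])
        b = np.arange(10.0)
        w, wo, _ = extreme_outlier_sensitivity(mann_whitney, a, b)
        assert wo.extra["U_a"] + wo.extra["U_b"] == (len(a) - 1) * len(b)


class TestDerivedFeatures:
    def test_interval_slopes(self):
        assert cd4_slope(series((0, 100), (2, 200)), 0, 2) == pytest.approx(50.0)
        assert cd4_slope(series((0, 0), (6, 60), (12, 120)), 0, 12) == pytest.approx(10.0)
        s = series((2, 100), (6, 120), (12, 150))
        # independent closed-form check of the same OLS slope
        oracle = np.polyfit([2, 6, 12], [100, 120, 150], 1)[0]
        assert cd4_slope(s, 2, 12) == pytest.approx(oracle, abs=1e-12)
        assert cd4_slope(s, 2, 12) == pytest.approx(5.0)
        assert np.isnan(cd4_slope(s, 20, 30))

    def test_thymic_score(self):
        assert thymic_score([10, 14], [2, 3]) == pytest.approx(30.0)
        assert thymic_score([12], [3]) == pytest.approx(36.0)
        assert thymic_score([10, 14], [0, 0]) == 0.0
        with pytest.raises(ValueError):
            thymic_score([], [1])

    def test_feature_table(self):
        df = pd.DataFrame({
            "cd4_count": [400.0, 300.0],
            "cd8_count": [800.0, 0.0],
            "rte_pct": [20.0, 10.0],
            "naive_count": [50.0, 30.0],
            "memory_count": [25.0, 60.0],
            "sj_trec_per1e5": [3000.0, 500.0],
            "djb_trec_per1e5": [300.0, 0.0],
        })
        out = derived_features(df, pbmc_per_ml=1.5e6)
        assert out.loc[0, "rte_abs"] == pytest.approx(80.0)
        assert out.loc[0, "sj_beta_ratio"] == pytest.approx(10.0)
        assert out.loc[0, "cd4_cd8_ratio"] == pytest.approx(0.5)
        assert out.loc[0, "trec_per_ml"] == pytest.approx(3000.0 * 15)
        assert out.loc[0, "naive_memory_ratio"] == pytest.approx(2.0)
        # zero denominators are flagged, not propagated silently
        assert np.isnan(out.loc[1, "cd4_cd8_ratio"]) and out.loc[1, "cd4_cd8_ratio_undefined"]
        assert np.isnan(out.loc[1, "sj_beta_ratio"]) and out.loc[1, "sj_beta_ratio_undefined"]


class TestFisherEnumerationOracle:
    def test_exact_p_matches_enumeration_for_small_tables(self):
        # spot-check here; the exhaustive n<=12 sweep runs in the acceptance suite
        rng = np.random.default_rng(2)
        for _ in range(40):
            t = rng.integers(0, 5, size=(2, 2))
            if t.sum() == 0 or t.sum(0).min() == 0 or t.sum(1).min() == 0:
                continue
            assert fisher_exact_2x2(t).p == pytest.approx(
                _enumerated_fisher_p(t), abs=1e-10
            )
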