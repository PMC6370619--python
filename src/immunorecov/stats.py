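"""Group-comparison statistics, effect sizes, multiplicity and outlier
policies, and derived immunological features.

Test routing follows the study protocol: Shapiro-Wilk normality screening
decides between the pooled-variance independent t-test (with Cohen's d) and
the Mann-Whitney U test (with the rank effect size r = Z/√N); 2x2 categorical
comparisons use Fisher's exact test with the cross-product odds ratio; larger
contingency tables use Cramér's V. Bonferroni thresholds are α/m. Extreme
outliers are values outside [P25 - 3·IQR, P75 + 3·IQR] (linear-interpolation
quartiles), and every comparison can be re-run with them removed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import CohortTable, VisitSeries

__all__ = [
    "TestResult",
    "route_test",
    "independent_t",
    "independent_t_from_stats",
    "cohens_d_pooled",
    "paired_d",
    "mann_whitney",
    "fisher_exact_2x2",
    "cramers_v",
    "magnitude_label",
    "bonferroni_flags",
    "extreme_outlier_bounds",
    "flag_extreme_outliers",
    "extreme_outlier_sensitivity",
    "cd4_slope",
    "slope_table",
    "thymic_score",
    "derived_features",
    "compare_feature",
]


@dataclass
class TestResult:
    """One two-sided test with its effect size and magnitude label."""

    test: str
    statistic: float
    p: float
    effect_size: float
    effect_kind: str  # cohens_d | rank_r | odds_ratio | cramers_v | correlation
    magnitude: str = ""
    df: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.p) and not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p-value {self.p} outside [0, 1]")
        if not self.magnitude and np.isfinite(self.effect_size):
            self.magnitude = magnitude_label(self.effect_kind, self.effect_size)


# -- routing ----------------------------------------------------------------

def route_test(a, b, alpha: float = 0.05) -> str:
    """'t-test' if both samples pass Shapiro-Wilk at alpha, else 'mann-whitney'."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if min(a.size, b.size) < 3:
        warnings.warn("sample too small for a normality screen; using nonparametric test")
        return "mann-whitney"
    pa = sps.shapiro(a).pvalue
    pb = sps.shapiro(b).pvalue
    return "t-test" if (pa >= alpha and pb >= alpha) else "mann-whitney"


def route_correlation(x, y, alpha: float = 0.05) -> str:
    """'pearson' if both variables pass Shapiro-Wilk at alpha, else 'spearman'."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if min(x.size, y.size) < 3:
        warnings.warn("sample too small for a normality screen; using Spearman")
        return "spearman"
    ok = sps.shapiro(x).pvalue >= alpha and sps.shapiro(y).pvalue >= alpha
    return "pearson" if ok else "spearman"


# -- effect sizes -----------------------------------------------------------

def cohens_d_pooled(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> float:
    """|Δmean| over the pooled SD (Student's pooling, df = n_a+n_b-2)."""
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("SDs must be non-negative")
    sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2)
    if sp2 == 0:
        raise ZeroDivisionError("pooled SD is zero; Cohen's d undefined")
    return abs(mean_a - mean_b) / math.sqrt(sp2)


def paired_d(differences) -> float:
    """|mean of differences| over the SD of the differences (paired design)."""
    d = np.asarray(differences, float)
    if d.size < 2:
        raise ValueError("need at least 2 paired differences")
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        raise ZeroDivisionError("SD of the differences is zero; Cohen's d undefined")
    return abs(float(np.mean(d))) / sd


# -- tests ------------------------------------------------------------------

def independent_t(a, b) -> TestResult:
    """Pooled-variance Student's t (df = n_a + n_b - 2) with Cohen's d."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    res = sps.ttest_ind(a, b, equal_var=True)
    try:
        d = cohens_d_pooled(a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size)
    except ZeroDivisionError:
        if a.mean() == b.mean():
            d = 0.0
        else:
            raise
    stat = float(res.statistic)
    if not np.isfinite(stat):  # zero pooled variance, equal means
        stat = 0.0
    p = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    return TestResult("t-test", stat, p, d, "cohens_d", df=float(a.size + b.size - 2))


def independent_t_from_stats(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> TestResult:
    """Summary-statistic variant of the pooled t-test."""
    res = sps.ttest_ind_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=True)
    d = cohens_d_pooled(mean_a, sd_a, n_a, mean_b, sd_b, n_b)
    return TestResult(
        "t-test", float(res.statistic), float(res.pvalue), d, "cohens_d",
        df=float(n_a + n_b - 2),
    )


def mann_whitney(a, b) -> TestResult:
    """Mann-Whitney U for sample_a (pair wins + half ties).

    p is exact (enumeration) for small tie-free samples and uses the normal
    approximation with tie correction otherwise; the effect size is
    r = Z/√N, signed positive when sample_a tends larger.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = a.size, b.size
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    u_a = float(res.statistic)
    # tie-corrected normal approximation for Z (and hence r)
    n = n1 + n2
    pooled = np.concatenate([a, b])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1)) if n > 1 else 0.0
    var_u = n1 * n2 / 12.0 * (n + 1 - tie_term)
    z = (u_a - n1 * n2 / 2.0) / math.sqrt(var_u) if var_u > 0 else 0.0
    r = z / math.sqrt(n)
    return TestResult(
        "mann-whitney", u_a, float(res.pvalue), r, "rank_r",
        extra={"U_a": u_a, "U_b": n1 * n2 - u_a, "Z": z},
    )


def fisher_exact_2x2(table) -> TestResult:
    """Fisher's exact test with the cross-product (sample) odds ratio.

    The two-sided p sums hypergeometric probabilities ≤ the observed table's.
    OR = (a·d)/(b·c) for table [[a, b], [c, d]]; a zero cell yields 0 or inf.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t != np.floor(t)) or np.any(t < 0):
            raise ValueError("table must hold non-negative integer counts")
        t = t.astype(int)
    a, b, c, d = t.ravel()
    if b * c == 0:
        orat = math.inf if a * d > 0 else 0.0
    else:
        orat = (a * d) / (b * c)
    p = float(sps.fisher_exact(t, alternative="two-sided").pvalue)
    mag = magnitude_label("odds_ratio", orat) if np.isfinite(orat) else "large"
    return TestResult("fisher-exact", orat, p, orat, "odds_ratio", magnitude=mag)


def cramers_v(table) -> TestResult:
    """Cramér's V = sqrt(χ² / (n·(min(r,c)-1))) with the uncorrected χ²."""
    t = np.asarray(table, float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("table must have at least 2 rows and 2 columns")
    if np.any(t < 0) or t.sum() <= 0:
        raise ValueError("table must hold non-negative counts with a positive total")
    chi2, p, dof, _ = sps.chi2_contingency(t, correction=False)
    n = t.sum()
    v = math.sqrt(chi2 / (n * (min(t.shape) - 1)))
    return TestResult("chi-square", float(chi2), float(p), v, "cramers_v", df=float(dof))


# -- magnitude bins ---------------------------------------------------------

_CORR_BINS = ((0.3, "negligible"), (0.5, "low"), (0.7, "moderate"), (0.9, "high"))


def magnitude_label(kind: str, value: float) -> str:
    """Printed magnitude bins; the absolute value is binned.

    cohens_d: <0.3 small, [0.3, 0.8) medium, ≥0.8 large (the upper bin wins
    at the 0.8 overlap). rank_r: <0.3, [0.3, 0.5), ≥0.5. cramers_v: <0.3,
    [0.3, 0.7], >0.7. correlation: negligible/low/moderate/high/very high at
    0.3/0.5/0.7/0.9.
    """
    v = abs(value)
    if kind == "cohens_d":
        return "small" if v < 0.3 else ("medium" if v < 0.8 else "large")
    if kind == "rank_r":
        return "small" if v < 0.3 else ("medium" if v < 0.5 else "large")
    if kind == "cramers_v":
        return "small" if v < 0.3 else ("medium" if v <= 0.7 else "large")
    if kind == "correlation":
        for cut, lab in _CORR_BINS:
            if v < cut:
                return lab
        return "very high"
    if kind == "odds_ratio":
        # descriptive only; an OR near 1 is a weak association
        lor = abs(math.log(v)) if 0 < v < math.inf else math.inf
        return "small" if lor < math.log(1.5) else ("medium" if lor < math.log(3) else "large")
    raise ValueError(f"unknown effect-size kind {kind!r}")


# -- multiplicity and outliers ----------------------------------------------

def bonferroni_flags(p_values, alpha: float = 0.05, m: int | None = None):
    """Significance flags at the Bonferroni-adjusted threshold alpha/m."""
    p = np.asarray(p_values, float)
    m = p.size if m is None else int(m)
    if m < 1:
        raise ValueError("m must be >= 1")
    threshold = alpha / m
    return p < threshold, threshold


def extreme_outlier_bounds(x) -> tuple[float, float]:
    """[P25 - 3·IQR, P75 + 3·IQR] with linear-interpolation quartiles."""
    x = np.asarray(x, float)
    p25, p75 = np.percentile(x, [25, 75], method="linear")
    iqr = p75 - p25
    return p25 - 3 * iqr, p75 + 3 * iqr


def flag_extreme_outliers(x) -> np.ndarray:
    lo, hi = extreme_outlier_bounds(x)
    x = np.asarray(x, float)
    return (x < lo) | (x > hi)


def extreme_outlier_sensitivity(
    analysis: Callable[..., TestResult], *samples
) -> tuple[TestResult, TestResult, bool]:
    """Run ``analysis`` with and without extreme outliers (flagged per sample).

    Returns (with, without, agreement flag on significance at 0.05).
    """
    cleaned = []
    for s in samples:
        s = np.asarray(s, float)
        keep = ~flag_extreme_outliers(s)
        if not keep.any():
            raise ValueError("all points flagged as extreme outliers")
        cleaned.append(s[keep])
    with_out = analysis(*samples)
    without = analysis(*cleaned)
    agree = (with_out.p < 0.05) == (without.p < 0.05)
    return with_out, without, agree


# -- derived features -------------------------------------------------------

def cd4_slope(series: VisitSeries, t_i: float, t_f: float) -> float:
    """OLS slope (cells/μL/month) over all visits in the closed [t_i, t_f].

    Returns NaN when fewer than 2 visits fall in the interval.
    """
    s = series.window(t_i, t_f)
    if len(s) < 2:
        return np.nan
    tc = s.times - s.times.mean()
    return float(tc @ (s.values - s.values.mean()) / (tc @ tc))


def slope_table(
    cohort: CohortTable,
    intervals: Sequence[tuple[float, float]] = ((0, 2), (2, 12), (12, 24), (24, 36), (36, 48), (48, 60)),
    analyte: str = "cd4_count",
) -> pd.DataFrame:
    """Per-patient interval slopes (one column per interval)."""
    out = {}
    for pid in cohort.patient_ids:
        s = cohort.series(pid, analyte)
        out[pid] = {f"slope_{a}_{b}": cd4_slope(s, a, b) for a, b in intervals}
    return pd.DataFrame.from_dict(out, orient="index")


def thymic_score(volumes, indices) -> float:
    """Product of the mean thymic volume and the mean thymic index over the
    first year of therapy."""
    volumes = np.asarray(volumes, float)
    indices = np.asarray(indices, float)
    if volumes.size == 0 or indices.size == 0:
        raise ValueError("need at least one volume and one index")
    return float(np.mean(volumes) * np.mean(indices))


def derived_features(
    df: pd.DataFrame, pbmc_per_ml: float = 1.5e6
) -> pd.DataFrame:
    """Row-wise derived immunological features.

    Input columns (when present): ``cd4_count``, ``cd8_count``, ``rte_pct``,
    ``naive_count``, ``memory_count``, ``sj_trec_per1e5``, ``djb_trec_per1e5``
    (sum of the six DJβ1-TREC frequencies). Outputs: ``cd4_cd8_ratio``,
    ``rte_abs`` (cells/μL), ``naive_memory_ratio``, ``trec_per_ml``,
    ``sj_beta_ratio``. Zero denominators yield NaN plus a companion
    ``*_undefined`` flag column (no silent propagation).
    """
    out = pd.DataFrame(index=df.index)

    def ratio(num, den, name):
        und = (den == 0) | den.isna() | num.isna()
        vals = num.astype(float).where(~und) / den.astype(float).where(~und)
        out[name] = vals
        out[f"{name}_undefined"] = und.astype(bool)

    if {"cd4_count", "cd8_count"} <= set(df.columns):
        ratio(df["cd4_count"], df["cd8_count"], "cd4_cd8_ratio")
    if {"rte_pct", "cd4_count"} <= set(df.columns):
        out["rte_abs"] = df["rte_pct"] / 100.0 * df["cd4_count"]
    if {"naive_count", "memory_count"} <= set(df.columns):
        ratio(df["naive_count"], df["memory_count"], "naive_memory_ratio")
    if "sj_trec_per1e5" in df.columns:
        out["trec_per_ml"] = df["sj_trec_per1e5"] * pbmc_per_ml / 1e5
    if {"sj_trec_per1e5", "djb_trec_per1e5"} <= set(df.columns):
        ratio(df["sj_trec_per1e5"], df["djb_trec_per1e5"], "sj_beta_ratio")
    return out


def compare_feature(a, b, name: str = "") -> TestResult:
    """Route and run the two-group comparison for one quantitative feature."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    which = route_test(a, b)
    res = independent_t(a, b) if which == "t-test" else mann_whitney(a, b)
    if name:
        res.extra["feature"] = name
    return res
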