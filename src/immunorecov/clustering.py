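"""Three-step longitudinal clustering of CD4 trajectories.

Step 1 computes 24 per-patient summary measures of the CD4 trajectory over
the first 36 months of therapy; step 2 runs a PCA on the correlation matrix
of the standardized measures and keeps factors with eigenvalue > 1, selecting
for each retained factor the measure with the largest absolute loading;
step 3 partitions patients with k-means (k = 2, 50 seeded restarts) on the
standardized selected measures. Clusters are labelled a posteriori: the
cluster with the larger fraction of patients whose CD4 count exceeds
500 cells/μL at least once during the window is the adequate-responder (AIR)
cluster, the other the poor-responder (PIR) cluster.

First differences are raw successive differences of the observed values;
"per unit time" variants divide by the time gap. Second differences are
successive differences of the first differences. Measures whose denominator
is zero (e.g. slope ratios on a flat trajectory) are flagged undefined and
imputed with the cohort median before the PCA.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .cohort import CohortTable, VisitSeries

logger = logging.getLogger(__name__)

__all__ = [
    "MEASURE_NAMES",
    "FactorSelection",
    "ClusterAssignment",
    "compute_summary_measures",
    "measures_table",
    "select_measures_pca",
    "cluster_trajectories",
    "label_clusters",
    "classify_by_500_rule",
    "cluster_cohort",
]

#: canonical order of the 24 trajectory summary measures
MEASURE_NAMES: tuple[str, ...] = (
    "range",                       # m1  max - min
    "mean_over_time",              # m2
    "sd",                          # m3
    "cv",                          # m4  100*sd/mean
    "change",                      # m5  last - first
    "mean_change_per_unit_time",   # m6  m5 / elapsed time
    "change_rel_first",            # m7  m5 / first
    "change_rel_mean",             # m8  m5 / m2
    "slope",                       # m9  OLS slope on time
    "r_squared",                   # m10 R^2 of the linear fit
    "max_first_diff",              # m11
    "sd_first_diff",               # m12
    "sd_first_diff_per_time",      # m13 SD of per-month first differences
    "mean_abs_first_diff",         # m14
    "max_abs_first_diff",          # m15
    "max_abs_fd_rel_mean",         # m16 m15 / m2
    "max_abs_fd_rel_slope",        # m17 m15 / m9
    "sd_fd_rel_slope",             # m18 m12 / m9
    "mean_second_diff",            # m19
    "mean_abs_second_diff",        # m20
    "max_abs_second_diff",         # m21
    "max_abs_sd_rel_mean",         # m22 m21 / m2
    "max_abs_sd_rel_mean_abs_fd",  # m23 m21 / m14
    "mean_abs_sd_rel_mean_abs_fd", # m24 m20 / m14
)

CD4_THRESHOLD = 500.0  # cells/μL, strict ">" per the crossing rule
DEFAULT_WINDOW = (0.0, 36.0)


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else np.nan


def compute_summary_measures(series: VisitSeries) -> dict[str, float]:
    """The 24 trajectory summary measures; NaN marks an undefined measure.

    Requires at least 3 non-missing visits.
    """
    t, y = series.times, series.values
    if len(t) < 3:
        raise ValueError("at least 3 non-missing visits are required")
    m: dict[str, float] = {}
    m["range"] = float(np.max(y) - np.min(y))
    mean = float(np.mean(y))
    m["mean_over_time"] = mean
    sd = float(np.std(y, ddof=1))
    m["sd"] = sd
    m["cv"] = _safe_div(100.0 * sd, mean)
    change = float(y[-1] - y[0])
    m["change"] = change
    m["mean_change_per_unit_time"] = _safe_div(change, float(t[-1] - t[0]))
    m["change_rel_first"] = _safe_div(change, float(y[0]))
    m["change_rel_mean"] = _safe_div(change, mean)
    # least-squares linear fit
    tc = t - t.mean()
    sxx = float(tc @ tc)
    slope = float(tc @ (y - mean) / sxx)
    m["slope"] = slope
    sst = float(((y - mean) ** 2).sum())
    sse = float(((y - mean - slope * tc) ** 2).sum())
    m["r_squared"] = _safe_div(sst - sse, sst)
    fd = np.diff(y)
    fd_unit = fd / np.diff(t)
    m["max_first_diff"] = float(np.max(fd))
    m["sd_first_diff"] = float(np.std(fd, ddof=1))
    m["sd_first_diff_per_time"] = float(np.std(fd_unit, ddof=1))
    m["mean_abs_first_diff"] = float(np.mean(np.abs(fd)))
    m["max_abs_first_diff"] = float(np.max(np.abs(fd)))
    m["max_abs_fd_rel_mean"] = _safe_div(m["max_abs_first_diff"], mean)
    m["max_abs_fd_rel_slope"] = _safe_div(m["max_abs_first_diff"], slope)
    m["sd_fd_rel_slope"] = _safe_div(m["sd_first_diff"], slope)
    sdiff = np.diff(fd)
    if sdiff.size == 0:
        m.update({k: np.nan for k in MEASURE_NAMES[18:]})
        return m
    m["mean_second_diff"] = float(np.mean(sdiff))
    m["mean_abs_second_diff"] = float(np.mean(np.abs(sdiff)))
    m["max_abs_second_diff"] = float(np.max(np.abs(sdiff)))
    m["max_abs_sd_rel_mean"] = _safe_div(m["max_abs_second_diff"], mean)
    m["max_abs_sd_rel_mean_abs_fd"] = _safe_div(m["max_abs_second_diff"], m["mean_abs_first_diff"])
    m["mean_abs_sd_rel_mean_abs_fd"] = _safe_div(m["mean_abs_second_diff"], m["mean_abs_first_diff"])
    return m


def measures_table(
    cohort: CohortTable,
    analyte: str = "cd4_count",
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Per-patient measures over the clustering window; patients with fewer
    than 3 usable visits are excluded with a warning."""
    rows, index = [], []
    for pid in cohort.patient_ids:
        s = cohort.series(pid, analyte).window(*window)
        if len(s) < 3:
            warnings.warn(f"patient {pid!r} excluded: fewer than 3 visits in window")
            continue
        rows.append(compute_summary_measures(s))
        index.append(pid)
    return pd.DataFrame(rows, index=index, columns=list(MEASURE_NAMES))


@dataclass
class FactorSelection:
    """Retained PCA factors and their representative measures."""

    n_factors: int
    eigenvalues: np.ndarray
    selected_measures: list[str]
    loadings: pd.DataFrame  # measures x retained factors
    dropped_measures: list[str] = field(default_factory=list)
    imputed: dict[str, int] = field(default_factory=dict)


def _standardize(df: pd.DataFrame) -> pd.DataFrame:
    return (df - df.mean()) / df.std(ddof=1)


def _preprocess_measures(df: pd.DataFrame, cap_outliers: bool = True) -> tuple[pd.DataFrame, dict]:
    """Median-impute undefined measures and cap extreme values.

    Ratio-type measures (slope ratios, CV) are heavy-tailed on noisy
    trajectories; values outside the study's extreme-outlier fences
    [P25 - 3·IQR, P75 + 3·IQR] are winsorized to the fences so that a single
    aberrant trajectory cannot dominate the PCA or form a singleton cluster.
    """
    df = df.copy()
    imputed: dict[str, int] = {}
    for col in df.columns:
        n_nan = int(df[col].isna().sum())
        if n_nan and n_nan < len(df):
            df[col] = df[col].fillna(df[col].median())
            imputed[col] = n_nan
            logger.warning("measure %s: imputed %d undefined values with the median", col, n_nan)
    if cap_outliers:
        for col in df.columns:
            vals = df[col].dropna()
            if vals.empty:
                continue
            p25, p75 = np.percentile(vals, [25, 75])
            iqr = p75 - p25
            df[col] = df[col].clip(p25 - 3 * iqr, p75 + 3 * iqr)
    return df, imputed


def select_measures_pca(measures: pd.DataFrame) -> FactorSelection:
    """PCA on the correlation matrix of the measures; keep eigenvalues > 1.

    Constant or entirely-undefined measures are dropped; remaining undefined
    entries are imputed with the cohort median (logged). For each retained
    factor the measure with the largest absolute loading is selected,
    ties and repeats resolved by canonical measure order.
    """
    if len(measures) < 2:
        raise ValueError("PCA requires at least 2 patients")
    df, imputed = _preprocess_measures(measures)
    sds = df.std(ddof=1)
    dropped = [c for c in df.columns if df[c].isna().all() or sds[c] == 0 or not np.isfinite(sds[c])]
    df = df.drop(columns=dropped)
    if df.shape[1] == 0:
        raise ValueError("all measures are constant or undefined; nothing to select")
    corr = np.corrcoef(_standardize(df).to_numpy(), rowvar=False)
    corr = np.atleast_2d(corr)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    retained = np.flatnonzero(eigval > 1.0)
    if retained.size == 0:  # single dominant dimension: keep the first factor
        retained = np.array([0])
    loadings = pd.DataFrame(
        eigvec[:, retained] * np.sqrt(eigval[retained]),
        index=df.columns,
        columns=[f"factor_{i+1}" for i in range(retained.size)],
    )
    selected: list[str] = []
    canon = {name: i for i, name in enumerate(MEASURE_NAMES)}
    for col in loadings.columns:
        ranked = sorted(
            loadings.index,
            key=lambda mname: (-abs(loadings.loc[mname, col]), canon.get(mname, 99)),
        )
        pick = next(mname for mname in ranked if mname not in selected)
        selected.append(pick)
    return FactorSelection(
        n_factors=int(retained.size),
        eigenvalues=eigval,
        selected_measures=selected,
        loadings=loadings,
        dropped_measures=dropped,
        imputed=imputed,
    )


@dataclass
class ClusterAssignment:
    """Per-patient cluster ids (1/2) and a posteriori AIR/PIR labels."""

    assignments: pd.DataFrame  # index patient_id; columns cluster, label, crossed_500
    seed: int
    cluster_labels: dict[int, str] = field(default_factory=dict)
    crossing_counts: dict[int, int] = field(default_factory=dict)

    def labels_map(self) -> dict:
        return dict(self.assignments["label"])


def cluster_trajectories(
    selection: FactorSelection,
    measures: pd.DataFrame,
    k: int = 2,
    seed: int = 0,
    n_init: int = 50,
) -> ClusterAssignment:
    """k-means on the standardized selected measures (best of ``n_init``
    seeded restarts). Deterministic given the seed and invariant under
    patient reordering (rows are sorted by patient id internally)."""
    if k > len(measures):
        raise ValueError(f"k={k} exceeds the number of patients ({len(measures)})")
    df, _ = _preprocess_measures(measures)
    df = df.loc[:, selection.selected_measures].sort_index()
    X = _standardize(df).to_numpy()
    X = np.nan_to_num(X)  # a constant selected measure carries no information
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    ids = km.fit_predict(X)
    out = pd.DataFrame({"cluster": ids + 1}, index=df.index)
    return ClusterAssignment(assignments=out, seed=seed)


def classify_by_500_rule(series: VisitSeries, window: tuple[float, float] = DEFAULT_WINDOW) -> bool:
    """True iff the CD4 count strictly exceeds 500 cells/μL at least once in
    the window (baseline included)."""
    s = series.window(*window)
    if len(s) == 0:
        raise ValueError("series has no visits in the window")
    return bool(np.max(s.values) > CD4_THRESHOLD)


def label_clusters(
    assignment: ClusterAssignment,
    cohort: CohortTable,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> ClusterAssignment:
    """Attach AIR/PIR labels: the cluster with the larger fraction of patients
    crossing 500 cells/μL during the window is AIR. Ties fall back to the
    higher cluster-mean CD4 with a warning."""
    df = assignment.assignments.copy()
    clusters = sorted(df["cluster"].unique())
    if len(clusters) != 2:
        raise ValueError("labelling requires exactly 2 clusters")
    crossed = {}
    means = {}
    for pid in df.index:
        s = cohort.series(pid, "cd4_count").window(*window)
        crossed[pid] = classify_by_500_rule(s, window)
        means[pid] = float(np.mean(s.values))
    df["crossed_500"] = pd.Series(crossed)
    frac = df.groupby("cluster")["crossed_500"].mean()
    counts = df.groupby("cluster")["crossed_500"].sum().astype(int)
    if frac[clusters[0]] == frac[clusters[1]]:
        warnings.warn("crossing fractions tied; labelling by higher cluster-mean CD4")
        cmean = pd.Series(means).groupby(df["cluster"]).mean()
        air = int(cmean.idxmax())
    else:
        air = int(frac.idxmax())
    pir = next(c for c in clusters if c != air)
    labels = {air: "AIR", pir: "PIR"}
    df["label"] = df["cluster"].map(labels)
    return ClusterAssignment(
        assignments=df,
        seed=assignment.seed,
        cluster_labels=labels,
        crossing_counts={c: int(counts[c]) for c in clusters},
    )


def cluster_cohort(
    cohort: CohortTable,
    window: tuple[float, float] = DEFAULT_WINDOW,
    k: int = 2,
    seed: int = 0,
) -> tuple[pd.DataFrame, FactorSelection, ClusterAssignment]:
    """Convenience wrapper running the full 3-step procedure plus labelling."""
    mt = measures_table(cohort, "cd4_count", window)
    sel = select_measures_pca(mt)
    asg = cluster_trajectories(sel, mt, k=k, seed=seed)
    asg = label_clusters(asg, cohort, window)
    return mt, sel, asg
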