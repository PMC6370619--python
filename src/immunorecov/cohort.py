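"""Cohort containers and plain-text I/O.

A cohort is stored as two tables:

* **visits** — long format, one row per (patient, time, analyte):
  ``patient_id,time_months,analyte,value``.
* **covariates** — wide format, one row per patient, ``patient_id`` plus
  baseline covariates and (optionally) ``true_group`` / assigned labels.

The analyte vocabulary used throughout the package:
``cd4_count`` (cells/μL), ``cd8_count`` (cells/μL), ``cd4_cd8_ratio``,
``rte_pct`` (% recent thymic emigrants among CD4+ T cells),
``sj_trec_per1e5`` (sj-TRECs per 1e5 PBMC), ``sj_beta_ratio``,
``thymic_volume`` (cm³), ``thymic_index`` (ordinal 0–5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: months on ART at which the study cohort was sampled
DEFAULT_SCHEDULE: tuple[float, ...] = (0, 2, 6, 12, 16, 20, 24, 28, 32, 36, 42, 48, 54, 60)

VISIT_COLUMNS = ["patient_id", "time_months", "analyte", "value"]

KNOWN_ANALYTES = {
    "cd4_count",
    "cd8_count",
    "cd4_cd8_ratio",
    "rte_pct",
    "sj_trec_per1e5",
    "sj_beta_ratio",
    "thymic_volume",
    "thymic_index",
}


class CohortIOError(ValueError):
    """Raised for malformed cohort files; the message names the offending rows."""


@dataclass(frozen=True)
class VisitSchedule:
    """Ordered months-on-ART sampling times; the first visit is baseline (0)."""

    times: tuple[float, ...] = DEFAULT_SCHEDULE

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.times)
        if len(t) == 0:
            raise ValueError("schedule must contain at least one visit")
        if t[0] != 0.0:
            raise ValueError("first scheduled visit must be baseline (t=0)")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("schedule times must be strictly increasing")
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class VisitSeries:
    """One patient's ordered (time, value) measurements for a single analyte."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("series times must be strictly increasing")

    def window(self, t_min: float, t_max: float) -> "VisitSeries":
        """Restrict to the closed interval [t_min, t_max]."""
        m = (self.times >= t_min) & (self.times <= t_max)
        return VisitSeries(self.times[m], self.values[m])

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class CohortTable:
    """Long-format visits plus wide-format baseline covariates."""

    visits: pd.DataFrame
    covariates: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame({"patient_id": pd.Series(dtype=object)})
    )

    def __post_init__(self) -> None:
        missing = [c for c in VISIT_COLUMNS if c not in self.visits.columns]
        if missing:
            raise CohortIOError(f"visits table lacks columns {missing}")
        dup = self.visits.duplicated(subset=["patient_id", "time_months", "analyte"])
        if dup.any():
            keys = self.visits.loc[dup, ["patient_id", "time_months", "analyte"]]
            raise CohortIOError(
                "duplicate (patient, time, analyte) rows: "
                + "; ".join(map(str, keys.itertuples(index=False, name=None)))
            )

    @property
    def patient_ids(self) -> list:
        ids = list(pd.unique(self.visits["patient_id"]))
        for p in self.covariates.get("patient_id", pd.Series(dtype=object)):
            if p not in ids:
                ids.append(p)
        return ids

    def series(self, patient_id, analyte: str) -> VisitSeries:
        sub = self.visits[
            (self.visits["patient_id"] == patient_id) & (self.visits["analyte"] == analyte)
        ].sort_values("time_months")
        sub = sub[np.isfinite(sub["value"].to_numpy(dtype=float))]
        return VisitSeries(sub["time_months"].to_numpy(dtype=float), sub["value"].to_numpy(dtype=float))

    def analyte_wide(self, analyte: str) -> pd.DataFrame:
        """Patients × times matrix for one analyte (NaN where unobserved)."""
        sub = self.visits[self.visits["analyte"] == analyte]
        return sub.pivot(index="patient_id", columns="time_months", values="value")

    def equals(self, other: "CohortTable") -> bool:
        a = self.visits.reset_index(drop=True)
        b = other.visits.reset_index(drop=True)
        try:
            pd.testing.assert_frame_equal(a, b, check_dtype=False)
            pd.testing.assert_frame_equal(
                self.covariates.reset_index(drop=True),
                other.covariates.reset_index(drop=True),
                check_dtype=False,
            )
        except AssertionError:
            return False
        return True


def write_cohort(table: CohortTable, visits_path, covariates_path=None) -> None:
    """Write the cohort as plain CSV (long visits; wide covariates)."""
    table.visits.to_csv(visits_path, index=False)
    if covariates_path is not None:
        table.covariates.to_csv(covariates_path, index=False)


def read_cohort(visits_path, covariates_path=None) -> CohortTable:
    """Read a cohort written by :func:`write_cohort`.

    Raises :class:`CohortIOError` on malformed headers, non-numeric cells or
    duplicated (patient, time, analyte) keys, naming the offending rows.
    """
    visits = pd.read_csv(visits_path, dtype={"patient_id": str})
    missing = [c for c in VISIT_COLUMNS if c not in visits.columns]
    if missing:
        raise CohortIOError(f"{visits_path}: malformed header, missing columns {missing}")
    for col in ("time_months", "value"):
        coerced = pd.to_numeric(visits[col], errors="coerce")
        bad = coerced.isna() & visits[col].notna()
        if bad.any():
            rows = ", ".join(str(i) for i in visits.index[bad][:5])
            raise CohortIOError(f"{visits_path}: non-numeric '{col}' at rows {rows}")
        visits[col] = coerced
    if covariates_path is not None:
        cov = pd.read_csv(covariates_path, dtype={"patient_id": str})
        if "patient_id" not in cov.columns:
            raise CohortIOError(f"{covariates_path}: malformed header, missing 'patient_id'")
    else:
        cov = pd.DataFrame({"patient_id": pd.Series(dtype=object)})
    return CohortTable(visits=visits, covariates=cov)


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    message: str


def validate_inputs(
    visits: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    schedule: Sequence[float] = DEFAULT_SCHEDULE,
) -> list[ValidationIssue]:
    """Screen input tables for structural problems.

    Returns a list of issues; never raises. Errors: negative counts,
    duplicate keys. Warnings: off-schedule visit times, unknown analytes.
    """
    issues: list[ValidationIssue] = []
    missing = [c for c in VISIT_COLUMNS if c not in visits.columns]
    if missing:
        issues.append(ValidationIssue("error", f"visits table lacks columns {missing}"))
        return issues
    dup = visits.duplicated(subset=["patient_id", "time_months", "analyte"])
    if dup.any():
        issues.append(
            ValidationIssue("error", f"{int(dup.sum())} duplicate (patient,time,analyte) rows")
        )
    counts = visits["analyte"].isin({"cd4_count", "cd8_count"})
    neg = counts & (visits["value"] < 0)
    for _, row in visits[neg].iterrows():
        issues.append(
            ValidationIssue(
                "error",
                f"negative {row['analyte']} ({row['value']}) for patient "
                f"{row['patient_id']} at t={row['time_months']}",
            )
        )
    sched = set(float(t) for t in schedule)
    off = ~visits["time_months"].astype(float).isin(sched)
    for t in sorted(set(visits.loc[off, "time_months"])):
        issues.append(ValidationIssue("warning", f"visit time {t} months is off-schedule"))
    unknown = set(visits["analyte"]) - KNOWN_ANALYTES
    for a in sorted(unknown):
        issues.append(ValidationIssue("warning", f"unknown analyte '{a}'"))
    return issues
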