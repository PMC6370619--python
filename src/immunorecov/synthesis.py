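"""Seeded synthetic cohorts with the structure the downstream analyses assume.

The study's patient-level data are not deposited, so analyses are exercised
on simulated cohorts. Each patient belongs to a latent responder group
(AIR-like or PIR-like, default sizes 14 and 19). CD4 counts and the CD4/CD8
ratio follow the exponential recovery model with group-level fixed effects
(defaults are the published estimates), additive Gaussian patient-level
random effects on A and B, and additive Gaussian measurement noise; counts
are floored at 1 cell/μL (the ratio at 0.001). CD8 counts are derived as
CD4 / ratio so the three analytes are mutually consistent.

Baseline covariates (age, log10 viral load, sex, clinical category, HCV) are
drawn per group with the cohort's published location/spread summaries.
Thymic variables use the published 0→12-month volume changes; RTE% follows a
logistic-in-time curve with a group offset; TREC frequencies are log-normal
with a group shift. The paper prints only summaries, not a generative model,
so these distributional forms are this package's own assumptions (see
docs/methods.md). Missingness is independent Bernoulli per non-baseline
visit (default 0.05); the baseline visit is never removed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import CohortTable, VisitSchedule, VisitSeries
from .kinetics import PUBLISHED_KINETICS

__all__ = [
    "GroupKinetics",
    "GroupCovariates",
    "CovariateModel",
    "SyntheticCohortConfig",
    "generate_trajectory",
    "generate_cohort",
    "default_config",
]

TREC_TIMES = (0.0, 6.0, 12.0, 24.0, 36.0)
THYMIC_TIMES = (0.0, 12.0)


@dataclass(frozen=True)
class GroupKinetics:
    """Recovery-curve parameters for one group and analyte.

    ``A``/``B`` in analyte units, ``tau`` in months; ``sigma_a``/``sigma_b``
    are SDs of the additive patient-level deviations on A and B; ``sigma_eps``
    the residual measurement SD; ``floor`` the physical lower bound.
    """

    A: float
    B: float
    tau: float
    sigma_a: float = 60.0
    sigma_b: float = 120.0
    sigma_eps: float = 50.0
    floor: float = 1.0
    ab_corr: float = 0.0

    def __post_init__(self) -> None:
        vals = dataclasses.asdict(self)
        for name, v in vals.items():
            if not np.isfinite(v):
                raise ValueError(f"kinetic parameter {name} must be finite, got {v!r}")
        if self.B < 0:
            raise ValueError("B must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if min(self.sigma_a, self.sigma_b, self.sigma_eps) < 0:
            raise ValueError("SDs must be >= 0")
        if not -1.0 <= self.ab_corr <= 1.0:
            raise ValueError("ab_corr must lie in [-1, 1]")


@dataclass(frozen=True)
class GroupCovariates:
    """Per-group baseline covariate distribution (location/spread summaries)."""

    age_mean: float
    age_sd: float
    log10_vl_mean: float
    log10_vl_sd: float
    male_prob: float
    hcv_prob: float
    clinical_category_probs: tuple[float, float, float]  # A, B, C
    rte_base_pct: float  # RTE% at ART start
    rte_plateau_pct: float  # long-run RTE%
    thymic_volume_mean: float  # cm3 at baseline
    thymic_volume_sd: float
    thymic_change_mean: float  # 0 -> 12 month volume change (printed)
    thymic_change_sd: float
    thymic_index_probs: tuple[float, ...]  # ordinal 1..3 (observed range)
    sj_trec_log_mean: float  # log sj-TREC per 1e5 PBMC
    sj_trec_log_sd: float
    sj_beta_ratio_mean: float
    sj_beta_ratio_sd: float

    def __post_init__(self) -> None:
        for p in (self.male_prob, self.hcv_prob, *self.clinical_category_probs,
                  *self.thymic_index_probs):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for s in (self.age_sd, self.log10_vl_sd, self.thymic_volume_sd,
                  self.thymic_change_sd, self.sj_trec_log_sd, self.sj_beta_ratio_sd):
            if s < 0:
                raise ValueError("spreads must be >= 0")


@dataclass(frozen=True)
class CovariateModel:
    """Covariate distributions per group plus shared nuisance settings."""

    groups: Mapping[str, GroupCovariates]
    missingness: float = 0.05
    rte_midpoint_months: float = 12.0
    rte_scale_months: float = 6.0
    rte_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missingness <= 1.0:
            raise ValueError("missingness probability must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Full generator configuration; a fixed seed reproduces the cohort bit-for-bit."""

    group_sizes: Mapping[str, int]
    schedule: VisitSchedule
    cd4: Mapping[str, GroupKinetics]
    ratio: Mapping[str, GroupKinetics]
    covariates: CovariateModel
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.group_sizes) != set(self.cd4) or set(self.cd4) != set(self.ratio):
            raise ValueError("group names must agree across sizes/cd4/ratio")
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 1")

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            raise TypeError(type(o))

        return json.dumps(dataclasses.asdict(self), default=enc, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticCohortConfig":
        d = json.loads(text)
        cov = d["covariates"]
        groups = {
            g: GroupCovariates(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in gc.items()
            })
            for g, gc in cov.pop("groups").items()
        }
        return cls(
            group_sizes=d["group_sizes"],
            schedule=VisitSchedule(tuple(d["schedule"]["times"])),
            cd4={g: GroupKinetics(**k) for g, k in d["cd4"].items()},
            ratio={g: GroupKinetics(**k) for g, k in d["ratio"].items()},
            covariates=CovariateModel(groups=groups, **cov),
            seed=int(d["seed"]),
        )


def default_config(seed: int = 0, missingness: float = 0.05) -> SyntheticCohortConfig:
    """Study-default cohort: groups of 14 (AIR-like) and 19 (PIR-like),
    the published kinetic fixed effects, and the published baseline summaries."""
    cd4 = PUBLISHED_KINETICS["cd4_count"]
    ratio = PUBLISHED_KINETICS["cd4_cd8_ratio"]
    groups = {
        "AIR": GroupCovariates(
            age_mean=38.1, age_sd=8.6,
            log10_vl_mean=5.96, log10_vl_sd=0.35,
            male_prob=9 / 14, hcv_prob=2 / 14,
            clinical_category_probs=(1 / 14, 4 / 14, 9 / 14),
            rte_base_pct=8.0, rte_plateau_pct=30.0,
            thymic_volume_mean=10.0, thymic_volume_sd=4.0,
            thymic_change_mean=6.47, thymic_change_sd=4.59,
            thymic_index_probs=(0.2, 0.4, 0.4),
            sj_trec_log_mean=np.log(3000.0), sj_trec_log_sd=0.8,
            sj_beta_ratio_mean=10.0, sj_beta_ratio_sd=3.0,
        ),
        "PIR": GroupCovariates(
            age_mean=45.3, age_sd=10.8,
            log10_vl_mean=5.41, log10_vl_sd=0.41,
            male_prob=14 / 19, hcv_prob=7 / 19,
            clinical_category_probs=(2 / 19, 10 / 19, 7 / 19),
            rte_base_pct=6.0, rte_plateau_pct=18.0,
            thymic_volume_mean=10.0, thymic_volume_sd=4.0,
            thymic_change_mean=1.43, thymic_change_sd=4.89,
            thymic_index_probs=(0.45, 0.40, 0.15),
            sj_trec_log_mean=np.log(1200.0), sj_trec_log_sd=0.8,
            sj_beta_ratio_mean=5.0, sj_beta_ratio_sd=2.5,
        ),
    }
    return SyntheticCohortConfig(
        group_sizes={"AIR": 14, "PIR": 19},
        schedule=VisitSchedule(),
        cd4={
            g: GroupKinetics(A=cd4["A"], B=cd4["B"][g], tau=cd4["tau"][g])
            for g in ("AIR", "PIR")
        },
        ratio={
            g: GroupKinetics(
                A=ratio["A"], B=ratio["B"][g], tau=ratio["tau"],
                sigma_a=0.05, sigma_b=0.10, sigma_eps=0.05, floor=0.001,
            )
            for g in ("AIR", "PIR")
        },
        covariates=CovariateModel(groups=groups, missingness=missingness),
        seed=seed,
    )


def generate_trajectory(
    kin: GroupKinetics, schedule: VisitSchedule, rng: np.random.Generator
) -> VisitSeries:
    """One patient's series: A_i + B_i(1-exp(-t/tau)) + eps, floored.

    A_i = A + N(0, sigma_a), B_i = B + N(0, sigma_b) (optionally correlated),
    eps ~ N(0, sigma_eps) i.i.d. per visit. With all SDs zero the series is
    exactly the deterministic mean curve.
    """
    t = np.asarray(schedule.times, dtype=float)
    cov = np.array(
        [
            [kin.sigma_a**2, kin.ab_corr * kin.sigma_a * kin.sigma_b],
            [kin.ab_corr * kin.sigma_a * kin.sigma_b, kin.sigma_b**2],
        ]
    )
    # draw via standard normals so sigma=0 degenerates exactly
    z = rng.standard_normal(2)
    L = np.linalg.cholesky(cov + 1e-300 * np.eye(2)) if cov.any() else np.zeros((2, 2))
    a_i, b_i = np.array([kin.A, kin.B]) + L @ z
    eps = kin.sigma_eps * rng.standard_normal(t.size)
    vals = a_i + b_i * (1.0 - np.exp(-t / kin.tau)) + eps
    return VisitSeries(t, np.maximum(vals, kin.floor))


def _draw_covariates(g: str, gc: GroupCovariates, rng: np.random.Generator) -> dict:
    age = float(np.clip(rng.normal(gc.age_mean, gc.age_sd), 18.0, 90.0))
    vl = float(rng.normal(gc.log10_vl_mean, gc.log10_vl_sd))
    sex = "male" if rng.random() < gc.male_prob else "female"
    cat = str(rng.choice(["A", "B", "C"], p=np.asarray(gc.clinical_category_probs)
                         / sum(gc.clinical_category_probs)))
    hcv = int(rng.random() < gc.hcv_prob)
    return {
        "age_years": age,
        "log10_vl_baseline": vl,
        "sex": sex,
        "clinical_category": cat,
        "hcv": hcv,
        "true_group": g,
    }


def _rte_curve(t: np.ndarray, gc: GroupCovariates, cm: CovariateModel) -> np.ndarray:
    """Logistic-in-time rise from the baseline RTE%% toward the group plateau."""
    frac = 1.0 / (1.0 + np.exp(-(t - cm.rte_midpoint_months) / cm.rte_scale_months))
    frac0 = 1.0 / (1.0 + np.exp(cm.rte_midpoint_months / cm.rte_scale_months))
    frac = (frac - frac0) / (1.0 - frac0)  # anchored at 0 at t=0
    return gc.rte_base_pct + (gc.rte_plateau_pct - gc.rte_base_pct) * frac


def generate_cohort(config: SyntheticCohortConfig, seed: int | None = None) -> CohortTable:
    """Generate the full synthetic cohort (pure function of config and seed)."""
    if sum(config.group_sizes.values()) == 0:
        raise ValueError("cohort must contain at least one patient")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sched = np.asarray(config.schedule.times, dtype=float)
    cm = config.covariates

    visit_rows: list[tuple] = []
    cov_rows: list[dict] = []
    pid_width = len(str(sum(config.group_sizes.values())))
    counter = 0
    for g in sorted(config.group_sizes):
        gc = cm.groups[g]
        for _ in range(config.group_sizes[g]):
            counter += 1
            pid = f"P{counter:0{pid_width}d}"
            cd4 = generate_trajectory(config.cd4[g], config.schedule, rng)
            ratio = generate_trajectory(config.ratio[g], config.schedule, rng)
            cd8 = np.maximum(cd4.values / ratio.values, 1.0)
            rte = np.clip(
                _rte_curve(sched, gc, cm) + cm.rte_noise_sd * rng.standard_normal(sched.size),
                0.0, 100.0,
            )
            # missingness: drop whole non-baseline visits independently
            keep = rng.random(sched.size) >= cm.missingness
            keep[0] = True
            for j, t in enumerate(sched):
                if not keep[j]:
                    continue
                visit_rows.append((pid, t, "cd4_count", cd4.values[j]))
                visit_rows.append((pid, t, "cd8_count", cd8[j]))
                visit_rows.append((pid, t, "cd4_cd8_ratio", ratio.values[j]))
                if t in TREC_TIMES:
                    visit_rows.append((pid, t, "rte_pct", rte[j]))

            cov = _draw_covariates(g, gc, rng)
            cov["patient_id"] = pid
            # thymic imaging at 0 and 12 months
            vol0 = max(rng.normal(gc.thymic_volume_mean, gc.thymic_volume_sd), 0.0)
            vol12 = max(vol0 + rng.normal(gc.thymic_change_mean, gc.thymic_change_sd), 0.0)
            idx_p = np.asarray(gc.thymic_index_probs) / sum(gc.thymic_index_probs)
            idx0, idx12 = rng.choice(np.arange(1, len(idx_p) + 1), size=2, p=idx_p)
            for t, vol, idx in ((0.0, vol0, idx0), (12.0, vol12, idx12)):
                visit_rows.append((pid, t, "thymic_volume", vol))
                visit_rows.append((pid, t, "thymic_index", float(idx)))
            # TREC panel on the TREC schedule
            for t in TREC_TIMES:
                sj = float(np.exp(rng.normal(gc.sj_trec_log_mean, gc.sj_trec_log_sd)))
                sb = max(rng.normal(gc.sj_beta_ratio_mean, gc.sj_beta_ratio_sd), 0.1)
                visit_rows.append((pid, t, "sj_trec_per1e5", sj))
                visit_rows.append((pid, t, "sj_beta_ratio", sb))
            cov_rows.append(cov)

    visits = pd.DataFrame(visit_rows, columns=["patient_id", "time_months", "analyte", "value"])
    visits = visits.drop_duplicates(subset=["patient_id", "time_months", "analyte"])
    cov_cols = ["patient_id", "age_years", "log10_vl_baseline", "sex",
                "clinical_category", "hcv", "true_group"]
    covariates = pd.DataFrame(cov_rows)[cov_cols]
    return CohortTable(visits=visits.reset_index(drop=True), covariates=covariates)
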