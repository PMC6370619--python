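"""End-to-end orchestration: simulate → cluster → kinetics → compare →
predict → report.

Every randomized stage consumes a sub-seed derived from the master seed and
the stage name, and the report echoes every sub-seed, threshold and
convention used, so a report is reproducible byte-for-byte from
(config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, kinetics, logistic, stats
from .cohort import CohortTable, read_cohort, validate_inputs, write_cohort
from .synthesis import SyntheticCohortConfig, default_config, generate_cohort

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

CONVENTIONS = {
    "odds_ratio": "cross-product (a*d)/(b*c)",
    "t_test": "pooled variance, df = n_a + n_b - 2",
    "quartiles": "linear interpolation",
    "outlier_rule": "P25 - 3*IQR, P75 + 3*IQR",
    "cd4_crossing": "strict > 500 cells/uL on [0, 36] months",
    "stepwise_removal_p": 0.05,
    "univariable_screen_p": 0.20,
    "classification_threshold": "P(PIR) >= 0.5",
}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic sub-seed below 2**31, recorded in the report."""
    return (int(master_seed) + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """Inputs, master seed and analysis settings for one pipeline run."""

    seed: int = 0
    visits_path: str | None = None
    covariates_path: str | None = None
    simulation: SyntheticCohortConfig | None = None
    window: tuple[float, float] = (0.0, 36.0)
    alpha: float = 0.05
    bonferroni_m: int = 14
    compare_features: tuple[str, ...] = ("cd4_count", "cd4_cd8_ratio", "rte_pct")
    compare_time: float = 12.0
    out_dir: str | None = None


def _load_or_simulate(cfg: PipelineConfig) -> tuple[CohortTable, dict]:
    if cfg.visits_path is not None:
        cohort = read_cohort(cfg.visits_path, cfg.covariates_path)
        return cohort, {"source": "files", "visits": str(cfg.visits_path)}
    sim = cfg.simulation or default_config()
    seed = stage_seed(cfg.seed, "simulate")
    cohort = generate_cohort(sim, seed=seed)
    return cohort, {"source": "simulated", "seed": seed,
                    "n_patients": int(sum(sim.group_sizes.values()))}


def _compare_stage(cohort: CohortTable, labels: dict, cfg: PipelineConfig) -> dict:
    out: dict = {"at_months": cfg.compare_time, "features": {}}
    pir = [p for p, l in labels.items() if l == "PIR"]
    air = [p for p, l in labels.items() if l == "AIR"]
    for analyte in cfg.compare_features:
        def at_time(pids):
            vals = []
            for pid in pids:
                s = cohort.series(pid, analyte)
                m = s.times == cfg.compare_time
                if m.any():
                    vals.append(float(s.values[m][0]))
            return np.asarray(vals)

        a, b = at_time(air), at_time(pir)
        if len(a) < 2 or len(b) < 2:
            out["features"][analyte] = {"skipped": "insufficient data"}
            continue
        try:
            with_o, without_o, agree = stats.extreme_outlier_sensitivity(
                stats.compare_feature, a, b
            )
        except ValueError:
            out["features"][analyte] = {"skipped": "outlier rule degenerate"}
            continue
        out["features"][analyte] = {
            "test": with_o.test,
            "statistic": with_o.statistic,
            "p": with_o.p,
            "effect_size": with_o.effect_size,
            "effect_kind": with_o.effect_kind,
            "magnitude": with_o.magnitude,
            "p_without_outliers": without_o.p,
            "outlier_agreement": bool(agree),
        }
    ps = [f["p"] for f in out["features"].values() if "p" in f]
    flags, threshold = stats.bonferroni_flags(ps, cfg.alpha, cfg.bonferroni_m)
    out["bonferroni"] = {
        "alpha": cfg.alpha, "m": cfg.bonferroni_m,
        "threshold": threshold, "significant": [bool(f) for f in flags],
    }
    return out


def _early_predictors(cohort: CohortTable, labels: dict) -> tuple[pd.DataFrame, pd.Series]:
    """Design table of baseline–6-month variables plus outcome (1 = AIR)."""
    cov = cohort.covariates.set_index("patient_id")
    rows = {}
    for pid in labels:
        s4 = cohort.series(pid, "cd4_count")
        rte = cohort.series(pid, "rte_pct")

        def at(series, t):
            m = series.times == t
            return float(series.values[m][0]) if m.any() else np.nan

        rte0, rte6 = at(rte, 0.0), at(rte, 6.0)
        rows[pid] = {
            "age_years": cov.at[pid, "age_years"] if pid in cov.index else np.nan,
            "log10_vl_baseline": cov.at[pid, "log10_vl_baseline"] if pid in cov.index else np.nan,
            "cd4_count_2mo": at(s4, 2.0),
            "cd4_count_6mo": at(s4, 6.0),
            "cd4_slope_0_6": stats.cd4_slope(s4, 0.0, 6.0),
            "rte_pct_6mo": rte6,
            "rte_ratio_0_6": rte0 / rte6 if rte6 not in (0.0,) and np.isfinite(rte6) else np.nan,
        }
    X = pd.DataFrame.from_dict(rows, orient="index")
    y = pd.Series({pid: 1.0 if labels[pid] == "AIR" else 0.0 for pid in labels})
    return X, y


def _predict_stage(cohort: CohortTable, labels: dict, cfg: PipelineConfig) -> dict:
    X, y = _early_predictors(cohort, labels)
    out: dict = {}
    # fitted pipeline: univariable screen -> backward stepwise -> evaluation
    retained, pvals = logistic.univariable_screen(X, y)
    out["screen"] = {"retained": retained,
                     "p_values": {k: (None if not np.isfinite(v) else v)
                                  for k, v in pvals.items()}}
    if retained:
        complete = X[retained].dropna()
        yc = y.loc[complete.index]
        if yc.nunique() == 2 and len(complete) >= 10:
            full = logistic.fit_logistic(complete, yc)
            model, trace = logistic.backward_stepwise(complete, yc)
            lrt_stat, lrt_df, lrt_p = logistic.likelihood_ratio_test(model, full)
            p_pir = 1.0 - model.fitted
            is_pir = yc.loc[list(model.row_index)] == 0.0
            ev = logistic.classify_and_tabulate(p_pir, is_pir)
            auc, auc_label, _ = logistic.roc_auc(model.fitted, yc.loc[list(model.row_index)])
            hl_stat, hl_p = (
                logistic.hosmer_lemeshow(model.fitted, yc.loc[list(model.row_index)])
                if model.n >= 10 else (None, None)
            )
            out["fitted_model"] = {
                "predictors": list(model.predictors),
                "coefficients": {k: float(v) for k, v in model.params.items()},
                "wald_p": {k: float(v) for k, v in model.wald_p.items()},
                "removal_trace": trace,
                "aic": model.aic,
                "n": model.n,
                "separation": model.separation,
                "lrt_vs_full": {"statistic": lrt_stat, "df": lrt_df, "p": lrt_p},
                "auc": auc, "auc_label": auc_label,
                "accuracy_pct": ev.accuracy,
                "sensitivity_pct": ev.sensitivity,
                "specificity_pct": ev.specificity,
                "hosmer_lemeshow": {"statistic": hl_stat, "p": hl_p},
            }
    # published coefficient sets
    published = {}
    for key, model in logistic.load_published_models().items():
        try:
            pred = logistic.evaluate_published_model(model, X)
        except KeyError:
            continue
        is_pir = pd.Series({pid: labels[pid] == "PIR" for pid in X.index})
        ok = pred["p_pir"].notna()
        if ok.sum() and is_pir[ok].nunique() == 2:
            ev = logistic.classify_and_tabulate(pred.loc[ok, "p_pir"], is_pir[ok])
            published[model.name] = {
                "n_predicted": int(ok.sum()),
                "accuracy_pct": ev.accuracy,
                "sensitivity_pct": ev.sensitivity,
                "specificity_pct": ev.specificity,
            }
    out["published_models"] = published
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages and return the report dict (also written to out_dir)."""
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "master_seed": cfg.seed,
        "conventions": dict(CONVENTIONS),
        "sub_seeds": {s: stage_seed(cfg.seed, s) for s in ("simulate", "cluster")},
    }
    try:
        cohort, src = _load_or_simulate(cfg)
        report["input"] = src
        issues = validate_inputs(cohort.visits, cohort.covariates)
        report["validation"] = [dataclasses.asdict(i) for i in issues]
        if any(i.severity == "error" for i in issues):
            raise ValueError("input validation failed: "
                             + "; ".join(i.message for i in issues if i.severity == "error"))
    except Exception as exc:
        raise RuntimeError(f"stage 'input' failed: {exc}") from exc

    try:
        mt, sel, asg = clustering.cluster_cohort(
            cohort, window=cfg.window, seed=stage_seed(cfg.seed, "cluster")
        )
        labels = asg.labels_map()
        report["clustering"] = {
            "n_factors": sel.n_factors,
            "eigenvalues_gt1": [float(e) for e in sel.eigenvalues if e > 1],
            "selected_measures": sel.selected_measures,
            "cluster_sizes": {lab: int((asg.assignments["label"] == lab).sum())
                              for lab in ("AIR", "PIR")},
            "crossed_500_counts": {str(k): v for k, v in asg.crossing_counts.items()},
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'cluster' failed: {exc}") from exc

    try:
        report["kinetics"] = {}
        for name, spec in (
            ("cd4_count", kinetics.KineticModelSpec.paper_cd4()),
            ("cd4_cd8_ratio", kinetics.KineticModelSpec.paper_ratio()),
        ):
            fit = kinetics.fit_nlme(cohort, spec, labels)
            report["kinetics"][name] = {
                "fixed_effects": _jsonable(fit.fixed_effects()),
                "asymptotes": _jsonable(fit.asymptotes()),
                "residual_sd": fit.sigma,
                "random_effect_sd": [float(x) for x in np.sqrt(np.diag(fit.psi))],
                "loglik": fit.loglik,
                "converged": fit.converged,
                "n_patients": fit.n_patients,
            }
    except Exception as exc:
        raise RuntimeError(f"stage 'kinetics' failed: {exc}") from exc

    have_covariates = len(cohort.covariates) > 0 and "age_years" in cohort.covariates.columns
    if have_covariates:
        try:
            report["comparisons"] = _compare_stage(cohort, labels, cfg)
        except Exception as exc:
            raise RuntimeError(f"stage 'compare' failed: {exc}") from exc
        try:
            report["prediction"] = _predict_stage(cohort, labels, cfg)
        except Exception as exc:
            raise RuntimeError(f"stage 'predict' failed: {exc}") from exc
    else:
        logger.info("no covariates available; compare/predict stages skipped")
        report["comparisons"] = {"skipped": "no covariates"}
        report["prediction"] = {"skipped": "no covariates"}

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_cohort(cohort, out / "visits.csv", out / "covariates.csv")
        asg.assignments.rename_axis("patient_id").to_csv(out / "assignments.csv")
        (out / "report.json").write_text(report_json(report))
        (out / "report.md").write_text(_report_markdown(report))
    return report


def report_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True, allow_nan=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return float(obj)
    return obj


def _report_markdown(report: dict) -> str:
    lines = ["# Immune-recovery pipeline report", ""]
    cl = report.get("clustering", {})
    if cl:
        lines += [
            f"- Clusters (AIR/PIR): {cl['cluster_sizes']}",
            f"- Selected trajectory measures: {', '.join(cl['selected_measures'])}",
        ]
    for name, k in report.get("kinetics", {}).items():
        lines.append(f"- {name} asymptotes: {k['asymptotes']}")
    pred = report.get("prediction", {})
    if "fitted_model" in pred:
        fm = pred["fitted_model"]
        lines.append(
            f"- Fitted model: {fm['predictors']} AUC={fm['auc']:.3f} "
            f"accuracy={fm['accuracy_pct']:.1f}%"
        )
    lines.append("")
    return "\n".join(lines)
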