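"""Logistic prediction of PIR/AIR outcome.

The outcome is coded Y = 1 for adequate responders (AIR), 0 for poor
responders (PIR). Candidate predictors measured between ART start and month
6 are screened univariably (retain p < 0.20), reduced by backward stepwise
elimination on Wald p-values, and the final model is checked with a
likelihood-ratio test against the full model, the Hosmer-Lemeshow
goodness-of-fit test, and ROC/AUC. Patients are classified "probably PIR"
when P(PIR) ≥ 0.5. The four published three-predictor coefficient sets are
shipped as a versioned JSON resource and evaluated with
P(PIR) = 1 / (1 + exp(a + b·x1 + c·x2 + d·x3)).
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass
from importlib import resources as importlib_resources
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "FittedLogisticModel",
    "PublishedLogisticModel",
    "ModelEvaluation",
    "fit_logistic",
    "univariable_screen",
    "backward_stepwise",
    "likelihood_ratio_test",
    "compare_aic",
    "hosmer_lemeshow",
    "roc_auc",
    "auc_quality_label",
    "classify_and_tabulate",
    "load_published_models",
    "evaluate_published_model",
]


@dataclass
class FittedLogisticModel:
    """Maximum-likelihood logistic fit (IRLS); outcome Y=1 for AIR."""

    params: pd.Series
    bse: pd.Series
    wald_p: pd.Series
    loglik: float
    aic: float
    n: int
    predictors: tuple[str, ...]
    fitted: pd.Series  # P(AIR) per row, indexed like the design
    row_index: tuple  # rows used (complete cases)
    separation: bool = False
    converged: bool = True
    n_dropped: int = 0

    def predict_p_air(self, X: pd.DataFrame) -> pd.Series:
        eta = self.params["const"] + sum(
            self.params[v] * X[v] for v in self.predictors
        )
        with np.errstate(over="ignore"):
            return 1.0 / (1.0 + np.exp(-eta))

    def predict_p_pir(self, X: pd.DataFrame) -> pd.Series:
        return 1.0 - self.predict_p_air(X)


def _complete_cases(X: pd.DataFrame, y: pd.Series) -> tuple[pd.DataFrame, pd.Series, int]:
    df = X.copy()
    df["__y__"] = y
    kept = df.dropna()
    n_dropped = len(df) - len(kept)
    if n_dropped:
        logger.info("dropped %d rows with missing predictor values", n_dropped)
    return kept.drop(columns="__y__"), kept["__y__"].astype(float), n_dropped


def fit_logistic(X: pd.DataFrame, y: pd.Series) -> FittedLogisticModel:
    """Fit by IRLS (statsmodels GLM-binomial). Complete cases only; perfect
    separation is flagged, never silent."""
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(X)
    y = pd.Series(y, index=X.index)
    Xc, yc, n_dropped = _complete_cases(X, y)
    if yc.nunique() < 2:
        raise ValueError("outcome is constant on the complete cases")
    design = sm.add_constant(Xc, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    separation = False
    converged = True
    with warnings.catch_warnings(), np.errstate(all="ignore"):
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(yc, design, family=sm.families.Binomial()).fit(maxiter=100)
            converged = bool(getattr(res, "converged", True))
        except Exception:  # pragma: no cover - IRLS failure path
            res = sm.GLM(yc, design, family=sm.families.Binomial()).fit(
                maxiter=25, tol=1e-4
            )
            converged = False
        fitted = pd.Series(np.asarray(res.fittedvalues), index=Xc.index)
    resid = np.abs(yc - fitted)
    if float(resid.max()) < 1e-4 or float(np.abs(res.params.iloc[1:]).max() if len(res.params) > 1 else 0) > 1e2:
        separation = True
        logger.warning("quasi-complete separation detected; coefficients unstable")
    k = design.shape[1]
    return FittedLogisticModel(
        params=res.params,
        bse=res.bse,
        wald_p=res.pvalues,
        loglik=float(res.llf),
        aic=float(2 * k - 2 * res.llf),
        n=int(len(yc)),
        predictors=tuple(Xc.columns),
        fitted=fitted,
        row_index=tuple(Xc.index),
        separation=separation,
        converged=converged,
        n_dropped=n_dropped,
    )


def univariable_screen(
    candidates: pd.DataFrame,
    y: pd.Series,
    threshold: float = 0.20,
    use_lrt: bool = False,
) -> tuple[list[str], dict[str, float]]:
    """Single-predictor logistic screen; retain variables with p < threshold.

    ``use_lrt`` switches the screening p from the Wald test to the
    likelihood-ratio test against the intercept-only model.
    """
    retained: list[str] = []
    pvals: dict[str, float] = {}
    for var in candidates.columns:
        try:
            m = fit_logistic(candidates[[var]], y)
        except ValueError:
            pvals[var] = np.nan
            continue
        if use_lrt:
            # intercept-only log-likelihood on the same rows, closed form
            yc = y.loc[list(m.row_index)].astype(float)
            p0 = yc.mean()
            ll0 = float(np.sum(yc * np.log(p0) + (1 - yc) * np.log1p(-p0)))
            stat = 2 * (m.loglik - ll0)
            p = float(sps.chi2.sf(max(stat, 0.0), 1))
        else:
            p = float(m.wald_p[var])
        if m.separation:
            logger.warning("candidate %s separates the outcome; retained with warning", var)
            retained.append(var)
            pvals[var] = p
            continue
        pvals[var] = p
        if p < threshold:
            retained.append(var)
    return retained, pvals


def backward_stepwise(
    X: pd.DataFrame, y: pd.Series, threshold: float = 0.05
) -> tuple[FittedLogisticModel, list[str]]:
    """Iteratively drop the least-significant coefficient (largest Wald
    p ≥ threshold) and refit, until all coefficients are significant or a
    single predictor remains. Returns the final model and the removal trace."""
    vars_ = list(X.columns)
    if not vars_:
        raise ValueError("need at least one retained variable")
    trace: list[str] = []
    while True:
        model = fit_logistic(X[vars_], y)
        coef_p = model.wald_p.drop("const")
        worst = coef_p.idxmax()
        if coef_p[worst] < threshold or len(vars_) == 1:
            return model, trace
        vars_.remove(worst)
        trace.append(worst)


def likelihood_ratio_test(
    reduced: FittedLogisticModel, full: FittedLogisticModel
) -> tuple[float, int, float]:
    """LRT of a reduced model nested in a full model on the same rows.

    Returns (statistic, df, p). A non-significant p endorses the reduced model.
    """
    if set(reduced.row_index) != set(full.row_index):
        raise ValueError("models were fitted on different rows")
    if not set(reduced.predictors) <= set(full.predictors):
        raise ValueError("reduced model is not nested in the full model")
    stat = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    df = len(full.predictors) - len(reduced.predictors)
    p = 1.0 if df == 0 else float(sps.chi2.sf(stat, df))
    if df == 0 and stat < 1e-10:
        p = 1.0
    return stat, df, p


def compare_aic(models: Sequence[FittedLogisticModel]) -> list[tuple[int, float]]:
    """Rank models by ascending AIC; all must share the same complete-case rows."""
    rows = {tuple(sorted(map(str, m.row_index))) for m in models}
    if len(rows) > 1:
        raise ValueError(
            "models were fitted on different row sets; subset to shared complete cases first"
        )
    order = sorted(range(len(models)), key=lambda i: models[i].aic)
    return [(i, models[i].aic) for i in order]


def hosmer_lemeshow(
    probabilities, outcomes, g: int = 10
) -> tuple[float, float]:
    """Hosmer-Lemeshow χ² over g deciles-of-risk bins; p from χ²(g-2).

    Bins are equal-count by predicted probability with ties kept together.
    """
    p = np.asarray(probabilities, float)
    y = np.asarray(outcomes, float)
    if g < 2:
        raise ValueError("g must be >= 2")
    if p.size < g:
        raise ValueError(f"need at least g={g} observations, got {p.size}")
    df = pd.DataFrame({"p": p, "y": y})
    df["bin"] = pd.qcut(df["p"].rank(method="first"), q=g, labels=False)
    stat = 0.0
    for _, grp in df.groupby("bin"):
        n_g = len(grp)
        exp1 = grp["p"].sum()
        obs1 = grp["y"].sum()
        exp0 = n_g - exp1
        obs0 = n_g - obs1
        if exp1 > 0:
            stat += (obs1 - exp1) ** 2 / exp1
        if exp0 > 0:
            stat += (obs0 - exp0) ** 2 / exp0
    pval = float(sps.chi2.sf(stat, g - 2))
    return float(stat), pval


def roc_auc(probabilities, outcomes) -> tuple[float, str, np.ndarray]:
    """Trapezoidal AUC over all thresholds (equals the Mann-Whitney pair-win
    probability) plus the printed quality label and the ROC points."""
    p = np.asarray(probabilities, float)
    y = np.asarray(outcomes, int)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(y, p)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, auc_quality_label(auc), np.column_stack([fpr, tpr])


def auc_quality_label(auc: float) -> str:
    """[0.5, 0.7) poor; [0.7, 0.8) fair; [0.8, 0.9) good; >0.9 excellent."""
    if auc < 0.7:
        return "poor"
    if auc < 0.8:
        return "fair"
    if auc <= 0.9:
        return "good"
    return "excellent"


@dataclass
class ModelEvaluation:
    """Classification summary at the 0.5 threshold (rates in percent)."""

    sensitivity: float
    specificity: float
    accuracy: float
    n_pir: int
    n_air: int
    auc: float | None = None
    auc_label: str = ""
    hl_statistic: float | None = None
    hl_p: float | None = None
    roc_points: np.ndarray | None = None


def classify_and_tabulate(p_pir, is_pir) -> ModelEvaluation:
    """Classify "probably PIR" when P(PIR) ≥ 0.5; sensitivity is the percent
    "probably PIR" among PIR, specificity the percent "probably AIR" among AIR."""
    p = np.asarray(p_pir, float)
    pir = np.asarray(is_pir, bool)
    prob_pir = p >= 0.5
    n_pir = int(pir.sum())
    n_air = int((~pir).sum())
    sens = 100.0 * float(prob_pir[pir].mean()) if n_pir else float("nan")
    spec = 100.0 * float((~prob_pir[~pir]).mean()) if n_air else float("nan")
    acc = 100.0 * float((prob_pir == pir).mean())
    return ModelEvaluation(sens, spec, acc, n_pir, n_air)


@dataclass(frozen=True)
class PublishedLogisticModel:
    """A published coefficient set mapping three predictors to P(PIR)."""

    name: str
    a: float
    b: float
    c: float
    d: float
    predictors: tuple[str, str, str]
    n: int

    def p_pir(self, x1: float, x2: float, x3: float) -> float:
        eta = self.a + self.b * x1 + self.c * x2 + self.d * x3
        return 1.0 / (1.0 + math.exp(eta))


def load_published_models() -> dict[str, PublishedLogisticModel]:
    path = importlib_resources.files("immunorecov.resources") / "published_models.json"
    raw = json.loads(path.read_text())
    out = {}
    for key, m in raw["models"].items():
        out[key] = PublishedLogisticModel(
            name=m["name"], a=m["a"], b=m["b"], c=m["c"], d=m["d"],
            predictors=tuple(m["predictors"]), n=m["n"],
        )
    return out


def evaluate_published_model(
    model: PublishedLogisticModel, covariates: pd.DataFrame
) -> pd.DataFrame:
    """P(PIR) and the 0.5-rule class for each patient row.

    ``covariates`` must carry the model's predictor columns in the study's
    units (years, log10 copies/mL, cells/μL, %). Rows with a missing
    predictor get no prediction (logged).
    """
    missing_cols = [c for c in model.predictors if c not in covariates.columns]
    if missing_cols:
        raise KeyError(f"covariate table lacks predictors {missing_cols}")
    p1, p2, p3 = model.predictors
    out = pd.DataFrame(index=covariates.index)
    eta = model.a + model.b * covariates[p1] + model.c * covariates[p2] + model.d * covariates[p3]
    with np.errstate(over="ignore"):
        out["p_pir"] = 1.0 / (1.0 + np.exp(eta))
    n_missing = int(out["p_pir"].isna().sum())
    if n_missing:
        logger.info("%s: no prediction for %d patients with missing predictors",
                    model.name, n_missing)
    out["class"] = np.where(
        out["p_pir"].isna(), "no-prediction",
        np.where(out["p_pir"] >= 0.5, "probably PIR", "probably AIR"),
    )
    return out
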