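"""Exponential recovery kinetics and nonlinear mixed-effects estimation.

The population model for CD4 count or CD4/CD8 ratio at time ``t`` (months on
ART) is

    X(t) = A + B * (1 - exp(-t / tau))

where ``A`` is the level at treatment start, ``B`` the maximum attainable
increase (so ``A + B`` is the long-run asymptote) and ``tau`` the recovery
timescale. Fixed effects may be shared across responder groups or
group-specific; patient-level random effects act additively on any subset of
{A, B, tau}.

Estimation maximizes the marginal likelihood of a model that is *linear* in
(A, B) given tau, so the fit profiles: for candidate variance/timescale
parameters the fixed effects are obtained by generalized least squares and
the Gaussian marginal log-likelihood is evaluated exactly per patient. A
random effect on tau (used for the CD4/CD8 ratio model) is handled by a
first-order linearization of the mean about tau_i = tau, updated over outer
iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .cohort import CohortTable, VisitSeries

__all__ = [
    "PUBLISHED_KINETICS",
    "KineticModelSpec",
    "KineticFit",
    "evaluate_kinetics",
    "asymptote",
    "fit_nlme",
    "fit_two_stage",
    "predict_mean_curve",
]

#: Group-wise fixed effects reported for the study cohort (months, cells/μL).
PUBLISHED_KINETICS: dict[str, dict] = {
    "cd4_count": {
        "A": 130.1,
        "B": {"AIR": 499.0, "PIR": 284.5},
        "tau": {"AIR": 17.6, "PIR": 31.9},
    },
    "cd4_cd8_ratio": {
        "A": 0.163,
        "B": {"AIR": 0.644, "PIR": 0.475},
        "tau": 27.620,
    },
}


def _check_params(A: float, B: float, tau: float) -> None:
    for name, v in (("A", A), ("B", B), ("tau", tau)):
        if not np.isfinite(v):
            raise ValueError(f"kinetic parameter {name} must be finite, got {v!r}")
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")


def evaluate_kinetics(A: float, B: float, tau: float, t) -> np.ndarray | float:
    """Mean recovery curve A + B(1 - exp(-t/tau)); exact A at t = 0."""
    _check_params(A, B, tau)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = A + B * (1.0 - np.exp(-t / tau))
    return float(out) if out.ndim == 0 else out


def asymptote(A: float, B) -> float | dict:
    """Long-run limit A + B; with a per-group B mapping, one value per group."""
    if isinstance(B, Mapping):
        return {g: A + b for g, b in B.items()}
    return A + B


@dataclass(frozen=True)
class KineticModelSpec:
    """Fixed-effect sharing structure and random-effect set for one analyte.

    The study's CD4 model: A shared, B and tau group-specific, random {A, B}.
    The study's ratio model: A and tau shared, B group-specific, random
    {A, B, tau}.
    """

    analyte: str = "cd4_count"
    a_by_group: bool = False
    b_by_group: bool = True
    tau_by_group: bool = True
    random_effects: tuple[str, ...] = ("A", "B")

    def __post_init__(self) -> None:
        bad = set(self.random_effects) - {"A", "B", "tau"}
        if bad:
            raise ValueError(f"unknown random effects {sorted(bad)}")

    @classmethod
    def paper_cd4(cls) -> "KineticModelSpec":
        return cls("cd4_count", False, True, True, ("A", "B"))

    @classmethod
    def paper_ratio(cls) -> "KineticModelSpec":
        return cls("cd4_cd8_ratio", False, True, False, ("A", "B", "tau"))


@dataclass
class KineticFit:
    """Result of an NLME fit."""

    spec: KineticModelSpec
    groups: tuple[str, ...]
    A: float | dict
    B: dict
    tau: dict | float
    psi: np.ndarray  # random-effect covariance (q x q)
    sigma: float  # residual SD
    loglik: float
    converged: bool
    n_patients: int
    n_obs: int
    patient_effects: "np.ndarray | None" = None  # empirical-Bayes modes (n x q)
    objective_trace: list = field(default_factory=list)  # best-so-far -loglik

    def fixed_effects(self) -> dict:
        return {"A": self.A, "B": dict(self.B), "tau": self.tau}

    def asymptotes(self) -> dict:
        a = self.A if not isinstance(self.A, Mapping) else None
        return {
            g: (self.A[g] if a is None else a) + self.B[g] for g in self.groups
        }

    def tau_of(self, group: str) -> float:
        return self.tau[group] if isinstance(self.tau, Mapping) else self.tau

    def a_of(self, group: str) -> float:
        return self.A[group] if isinstance(self.A, Mapping) else self.A


def predict_mean_curve(fit: KineticFit, group: str, times) -> VisitSeries:
    """Population mean curve for one group at the requested times."""
    if group not in fit.groups:
        raise KeyError(f"unknown group {group!r}; fit groups are {fit.groups}")
    times = np.asarray(times, dtype=float)
    vals = evaluate_kinetics(fit.a_of(group), fit.B[group], fit.tau_of(group), times)
    return VisitSeries(times, np.atleast_1d(vals))


# ---------------------------------------------------------------------------
# Estimation machinery


class _PatientData:
    __slots__ = ("t", "y", "group")

    def __init__(self, t: np.ndarray, y: np.ndarray, group: str):
        self.t, self.y, self.group = t, y, group


def _extract(cohort: CohortTable, analyte: str, groups_map: Mapping) -> list[_PatientData]:
    pats = []
    for pid in cohort.patient_ids:
        if pid not in groups_map:
            raise ValueError(
                f"patient {pid!r} has no group label; run trajectory clustering first"
            )
        s = cohort.series(pid, analyte)
        if len(s) >= 3:
            pats.append(_PatientData(s.times, s.values, str(groups_map[pid])))
    return pats


def _chol_from_log(theta: np.ndarray, q: int) -> np.ndarray:
    """Lower-triangular Cholesky factor with log-parameterized diagonal."""
    L = np.zeros((q, q))
    k = 0
    for i in range(q):
        for j in range(i + 1):
            if i == j:
                L[i, j] = np.exp(theta[k])
            else:
                L[i, j] = theta[k]
            k += 1
    return L


def _design(
    pat: _PatientData,
    spec: KineticModelSpec,
    groups: Sequence[str],
    taus: Mapping,
    b_ref: Mapping,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed design X and random design Z for one patient at given taus."""
    tau = taus[pat.group] if spec.tau_by_group else taus["__shared__"]
    f = 1.0 - np.exp(-pat.t / tau)
    cols = []
    if spec.a_by_group:
        for g in groups:
            cols.append(np.where(pat.group == g, 1.0, 0.0) * np.ones_like(pat.t))
    else:
        cols.append(np.ones_like(pat.t))
    if spec.b_by_group:
        for g in groups:
            cols.append(f if pat.group == g else np.zeros_like(f))
    else:
        cols.append(f)
    X = np.column_stack(cols)
    zcols = []
    for re in spec.random_effects:
        if re == "A":
            zcols.append(np.ones_like(pat.t))
        elif re == "B":
            zcols.append(f)
        else:  # tau: first-order derivative of the mean in tau_i about tau
            dB = b_ref[pat.group]
            zcols.append(-dB * (pat.t / tau**2) * np.exp(-pat.t / tau))
    Z = np.column_stack(zcols)
    return X, Z


class _Pattern:
    """Patients sharing a visit-time vector and group (one V per pattern)."""

    __slots__ = ("t", "group", "Y", "idx")

    def __init__(self, t: np.ndarray, group: str, Y: np.ndarray, idx: list[int]):
        self.t, self.group, self.Y, self.idx = t, group, Y, idx


def _make_patterns(pats: list[_PatientData]) -> list[_Pattern]:
    buckets: dict[tuple, list[int]] = {}
    for i, p in enumerate(pats):
        buckets.setdefault((p.group, tuple(p.t)), []).append(i)
    out = []
    for (group, t), idx in sorted(buckets.items()):
        Y = np.vstack([pats[i].y for i in idx])  # m x n_i
        out.append(_Pattern(np.asarray(t), group, Y, idx))
    return out


def _profile_neg_loglik(
    theta: np.ndarray,
    patterns: list[_Pattern],
    spec: KineticModelSpec,
    groups: Sequence[str],
    b_ref: Mapping,
    sigma_floor: float,
    return_fit: bool = False,
):
    """-loglik with fixed effects (GLS) and sigma (closed form) profiled out.

    theta = [log tau (1 or per group), chol params of Psi* = Psi / sigma^2].
    Marginal covariance per patient is sigma^2 * (Z Psi* Z' + I).
    """
    n_tau = len(groups) if spec.tau_by_group else 1
    q = len(spec.random_effects)
    taus_arr = np.exp(theta[:n_tau])
    if spec.tau_by_group:
        taus = {g: taus_arr[i] for i, g in enumerate(groups)}
    else:
        taus = {"__shared__": taus_arr[0]}
    L = _chol_from_log(theta[n_tau:], q)
    psi_star = L @ L.T

    cache = []
    xtvx = None
    xtvy = None
    logdet_sum = 0.0
    n_obs = 0
    for pat in patterns:
        X, Z = _design(pat, spec, groups, taus, b_ref)
        n_i = len(pat.t)
        m = pat.Y.shape[0]
        W = Z @ psi_star @ Z.T + np.eye(n_i)
        try:
            cf = np.linalg.cholesky(W)
        except np.linalg.LinAlgError:
            return (np.inf, None) if return_fit else np.inf
        Wi_X = np.linalg.solve(cf.T, np.linalg.solve(cf, X))
        Wi_ysum = np.linalg.solve(cf.T, np.linalg.solve(cf, pat.Y.sum(axis=0)))
        if xtvx is None:
            xtvx = m * (X.T @ Wi_X)
            xtvy = X.T @ Wi_ysum
        else:
            xtvx += m * (X.T @ Wi_X)
            xtvy += X.T @ Wi_ysum
        logdet_sum += m * 2.0 * np.sum(np.log(np.diag(cf)))
        n_obs += m * n_i
        cache.append((pat, X, Z, cf))
    try:
        beta = np.linalg.solve(xtvx, xtvy)
    except np.linalg.LinAlgError:
        return (np.inf, None) if return_fit else np.inf
    quad = 0.0
    blup_parts = []
    for pat, X, Z, cf in cache:
        R = pat.Y - X @ beta  # m x n_i residuals
        WiR = np.linalg.solve(cf.T, np.linalg.solve(cf, R.T))  # n_i x m
        quad += float(np.sum(R.T * WiR))
        if return_fit:
            blup_parts.append((pat, (psi_star @ Z.T @ WiR).T))  # m x q
    sigma2 = max(quad / n_obs, sigma_floor**2)
    nll = 0.5 * (logdet_sum + n_obs * np.log(sigma2) + quad / sigma2 + n_obs * np.log(2 * np.pi))
    if not np.isfinite(nll):
        return (np.inf, None) if return_fit else np.inf
    if return_fit:
        n_pats = sum(p.Y.shape[0] for p in patterns)
        blups = np.zeros((n_pats, q))
        for pat, bp in blup_parts:
            blups[pat.idx, :] = bp  # Psi Z' V^-1 r = Psi* Z' W^-1 r
        return nll, {
            "beta": beta,
            "taus": taus,
            "psi": psi_star * sigma2,
            "sigma": float(np.sqrt(sigma2)),
            "blups": blups,
            "n_obs": n_obs,
        }
    return nll


def fit_two_stage(
    pats: list[_PatientData], spec: KineticModelSpec, groups: Sequence[str]
) -> dict:
    """Starting-value heuristic: A0 = mean baseline, B0 = mean(last-first)
    per group, tau0 = 12 months refined on a coarse profile grid."""
    base = [p.y[np.argmin(p.t)] for p in pats]
    A0 = float(np.mean(base))
    B0 = {}
    for g in groups:
        deltas = [p.y[np.argmax(p.t)] - p.y[np.argmin(p.t)] for p in pats if p.group == g]
        B0[g] = max(float(np.mean(deltas)) if deltas else 1.0, 1e-6)
    return {"A": A0, "B": B0, "tau0": 12.0}


def _unpack_beta(beta: np.ndarray, spec: KineticModelSpec, groups: Sequence[str]):
    i = 0
    if spec.a_by_group:
        A = {g: float(beta[i + k]) for k, g in enumerate(groups)}
        i += len(groups)
    else:
        A = float(beta[i])
        i += 1
    if spec.b_by_group:
        B = {g: float(beta[i + k]) for k, g in enumerate(groups)}
        i += len(groups)
    else:
        b = float(beta[i])
        B = {g: b for g in groups}
        i += 1
    return A, B


def fit_nlme(
    cohort: CohortTable,
    spec: KineticModelSpec,
    groups_map: Mapping,
    *,
    censor_at: float | None = None,
    max_outer: int = 3,
    maxiter: int = 200,
    xtol: float = 1e-6,
) -> KineticFit:
    """Fit the exponential-recovery NLME model by profiled marginal ML.

    ``groups_map`` maps patient_id -> group label (e.g. from clustering).
    Requires >=2 patients per group with >=3 usable visits each.

    ``censor_at`` marks a detection floor: observations at or below it are
    treated as left-censored and replaced by their conditional means under
    the current fit (an EM-style correction, two passes), which removes the
    bias a hard floor otherwise induces in A, B and tau.
    """
    pats = _extract(cohort, spec.analyte, groups_map)
    if not pats:
        raise ValueError("no patients with >=3 usable visits")
    groups = tuple(sorted({p.group for p in pats}))
    for g in groups:
        if sum(p.group == g for p in pats) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 usable patients")
    times_all = np.concatenate([p.t for p in pats])
    if np.ptp(times_all) == 0:
        raise np.linalg.LinAlgError("degenerate design: all visits at a single time")

    scale = float(np.std(np.concatenate([p.y for p in pats]))) or 1.0
    sigma_floor = 1e-6 * scale
    start = fit_two_stage(pats, spec, groups)
    q = len(spec.random_effects)
    n_tau = len(groups) if spec.tau_by_group else 1
    trace: list[float] = []

    def optimize_once(patterns, b_ref_init, theta_warm):
        """b_ref outer loop + Nelder-Mead; returns (theta, b_ref, converged)."""
        b_ref = dict(b_ref_init)
        result_theta = theta_warm
        converged = False
        n_pass = max_outer if "tau" in spec.random_effects else 1
        for _ in range(n_pass):
            sigma0 = 0.2 * scale
            re_scales = {"A": 0.3 * scale, "B": 0.5 * scale, "tau": 4.0}
            chol0 = []
            for i in range(q):
                for j in range(i + 1):
                    chol0.append(
                        np.log(re_scales[spec.random_effects[i]] / sigma0) if i == j else 0.0
                    )
            theta0, best0 = None, np.inf
            cands = [np.concatenate([np.full(n_tau, np.log(tt)), chol0])
                     for tt in (6.0, start["tau0"], 18.0, 30.0)]
            if result_theta is not None:
                cands.append(result_theta)
            for cand in cands:
                v = _profile_neg_loglik(cand, patterns, spec, groups, b_ref, sigma_floor)
                if v < best0:
                    best0, theta0 = v, cand
            local_best = [best0]

            def obj(th):
                v = _profile_neg_loglik(th, patterns, spec, groups, b_ref, sigma_floor)
                if v < local_best[0]:
                    local_best[0] = v
                    trace.append(v)
                return v

            res = optimize.minimize(
                obj, theta0, method="Nelder-Mead",
                options={"maxiter": maxiter * len(theta0), "xatol": xtol,
                         "fatol": xtol, "adaptive": True},
            )
            nll, parts = _profile_neg_loglik(
                res.x, patterns, spec, groups, b_ref, sigma_floor, return_fit=True
            )
            if parts is None:
                continue
            converged = bool(res.success)
            result_theta = res.x
            _, B_hat = _unpack_beta(parts["beta"], spec, groups)
            if "tau" in spec.random_effects:
                changed = max(
                    abs(B_hat[g] - b_ref[g]) / max(abs(b_ref[g]), 1e-12) for g in groups
                )
                b_ref = B_hat
                if changed < 1e-4:
                    break
            else:
                break
        if result_theta is None:
            raise np.linalg.LinAlgError("singular fit: marginal likelihood not computable")
        return result_theta, b_ref, converged

    censored = None
    if censor_at is not None:
        censored = [np.flatnonzero(p.y <= censor_at + 1e-9) for p in pats]
        if not any(len(ix) for ix in censored):
            censored = None

    patterns = _make_patterns(pats)
    theta, b_ref, converged = optimize_once(patterns, start["B"], None)

    em_passes = 2 if censored is not None else 0
    for _ in range(em_passes):
        nll, parts = _profile_neg_loglik(
            theta, patterns, spec, groups, b_ref, sigma_floor, return_fit=True
        )
        A_hat, B_hat = _unpack_beta(parts["beta"], spec, groups)
        sig = max(parts["sigma"], sigma_floor)
        for i, (pat, ix) in enumerate(zip(pats, censored)):
            if len(ix) == 0:
                continue
            tau_i = parts["taus"][pat.group] if spec.tau_by_group else parts["taus"]["__shared__"]
            f = 1.0 - np.exp(-pat.t[ix] / tau_i)
            a_re = parts["blups"][i][spec.random_effects.index("A")] if "A" in spec.random_effects else 0.0
            b_re = parts["blups"][i][spec.random_effects.index("B")] if "B" in spec.random_effects else 0.0
            a_fix = A_hat[pat.group] if isinstance(A_hat, Mapping) else A_hat
            m = a_fix + a_re + (B_hat[pat.group] + b_re) * f
            z = (censor_at - m) / sig
            from scipy.stats import norm

            den = np.maximum(norm.cdf(z), 1e-12)
            cond = m - sig * norm.pdf(z) / den
            pat.y[ix] = np.minimum(cond, censor_at)
        patterns = _make_patterns(pats)
        theta, b_ref, converged = optimize_once(patterns, b_ref, theta)

    nll, parts = _profile_neg_loglik(
        theta, patterns, spec, groups, b_ref, sigma_floor, return_fit=True
    )
    A_hat, B_hat = _unpack_beta(parts["beta"], spec, groups)
    if spec.tau_by_group:
        tau_hat: dict | float = {g: float(parts["taus"][g]) for g in groups}
    else:
        tau_hat = float(parts["taus"]["__shared__"])
    if not converged:
        warnings.warn("NLME optimizer did not meet tolerance; fit flagged unconverged")
    return KineticFit(
        spec=spec,
        groups=groups,
        A=A_hat,
        B=B_hat,
        tau=tau_hat,
        psi=parts["psi"],
        sigma=float(parts["sigma"]),
        loglik=-float(nll),
        converged=converged,
        n_patients=len(pats),
        n_obs=int(parts["n_obs"]),
        patient_effects=parts["blups"],
        objective_trace=trace,
    )
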