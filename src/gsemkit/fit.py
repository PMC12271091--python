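"""Diagonally weighted least squares estimation of structural models on a
genetic covariance matrix S with sampling covariance V.

The fit function is F(theta) = sum_i (s_i - sigma_i(theta))^2 / V_ii over
the half-vectorized unique moments.  Parameter uncertainty uses the
sandwich

    cov(theta) = (D'WD)^-1 D'W V W D (D'WD)^-1,  W = diag(V)^-1, D = dsigma/dtheta

and the model chi-square is, by default, the weighted-residual statistic
rescaled by a V-based mean correction so that its reference distribution
is chi-square with the model's degrees of freedom; the Browne residual-
based statistic and the uncorrected statistic are available as options.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .ldsc import SVMatrices, vech, vech_indices
from .model import ModelSpec, Parameter, implied_cov, total_cov

__all__ = ["FitResult", "FitIndices", "fit_dwls", "fit_indices",
           "standardize_solution", "independence_spec", "saturated_spec"]

logger = logging.getLogger(__name__)

_CHISQ_KINDS = ("mean_corrected", "browne", "naive")


@dataclass
class FitResult:
    """Estimates, sandwich SEs and test statistic for one fitted model."""

    param_names: list[str]
    theta: np.ndarray
    cov_theta: np.ndarray
    chisq: float
    df: int
    chisq_p: float
    converged: bool
    n_iterations: int
    objective: float
    chisq_kind: str = "mean_corrected"
    standardized: bool = False

    @property
    def estimates(self) -> dict[str, float]:
        return dict(zip(self.param_names, map(float, self.theta)))

    @property
    def se(self) -> dict[str, float]:
        return dict(zip(self.param_names,
                        map(float, np.sqrt(np.maximum(np.diag(self.cov_theta), 0)))))

    @property
    def pvalues(self) -> dict[str, float]:
        out = {}
        for name, est in self.estimates.items():
            s = self.se[name]
            out[name] = 2 * stats.norm.sf(abs(est) / s) if s > 0 else np.nan
        return out

    def summary(self) -> str:
        lines = [f"{'parameter':<24}{'estimate':>10}{'se':>10}{'p':>12}"]
        pv = self.pvalues
        se = self.se
        for name, est in self.estimates.items():
            lines.append(f"{name:<24}{est:>10.4f}{se[name]:>10.4f}{pv[name]:>12.3g}")
        lines.append(f"chisq({self.df}) = {self.chisq:.3f}  p = {self.chisq_p:.3g}")
        return "\n".join(lines)


@dataclass
class FitIndices:
    cfi: float
    srmr: float
    aic: float


def _numeric_jacobian(fun, theta: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences; columns indexed by parameters."""
    f0 = fun(theta)
    jac = np.zeros((len(f0), len(theta)))
    for q in range(len(theta)):
        h = eps * max(1.0, abs(theta[q]))
        up, dn = theta.copy(), theta.copy()
        up[q] += h
        dn[q] -= h
        jac[:, q] = (fun(up) - fun(dn)) / (2 * h)
    return jac


def _align(sv: SVMatrices, spec: ModelSpec) -> SVMatrices:
    missing = [t for t in spec.observed if t not in sv.traits]
    if missing:
        raise ValueError(f"model variables absent from S: {missing}")
    if list(sv.traits) == list(spec.observed):
        return sv
    return sv.reorder(list(spec.observed))


def _smart_start(spec: ModelSpec, s_mat: np.ndarray) -> np.ndarray:
    """Scale-aware starting values from the observed covariance matrix."""
    idx = {v: i for i, v in enumerate(spec.observed)}
    indicators: dict[str, list[str]] = {}
    for p in spec.params:
        if p.matrix == "A" and p.rhs in spec.latents and p.lhs in spec.observed:
            indicators.setdefault(p.rhs, []).append(p.lhs)
    reg_outcomes = {p.lhs for p in spec.params
                    if p.matrix == "A" and p.rhs not in spec.latents or
                    (p.matrix == "A" and p.lhs in spec.observed and
                     p.rhs in spec.latents and False)}
    start = []
    for p in spec.free_params():
        if p.matrix == "A" and p.rhs in spec.latents and p.lhs in spec.observed:
            # loading: sqrt of mean |cov| with the factor's other indicators
            others = [o for o in indicators[p.rhs] if o != p.lhs and o in idx]
            if others and p.lhs in idx:
                cc = np.mean([abs(s_mat[idx[p.lhs], idx[o]]) for o in others])
                start.append(np.sqrt(max(cc, 1e-4)))
            else:
                start.append(p.value)
        elif p.matrix == "A":
            start.append(0.0)
        elif p.lhs == p.rhs and p.lhs in idx:
            scale = 1.0 if p.lhs not in {o for v in indicators.values() for o in v} \
                else 0.5
            start.append(max(scale * s_mat[idx[p.lhs], idx[p.lhs]], 1e-4))
        elif p.lhs == p.rhs:
            start.append(max(p.value, 0.1))
        elif p.lhs in idx and p.rhs in idx:
            start.append(s_mat[idx[p.lhs], idx[p.rhs]])
        else:
            start.append(0.0)
    return np.array(start)


def fit_dwls(
    sv: SVMatrices,
    spec: ModelSpec,
    chisq_kind: str = "mean_corrected",
    n_restarts: int = 10,
    seed: int = 0,
    theta0: np.ndarray | None = None,
) -> FitResult:
    """Fit ``spec`` to (S, V) by diagonally weighted least squares.

    On non-convergence the optimizer is restarted from up to ``n_restarts``
    jittered starting points; the best solution is returned flagged
    ``converged=False`` if none succeeds.  A negative estimated residual
    variance triggers a Heywood-case warning, not an error.
    """
    if chisq_kind not in _CHISQ_KINDS:
        raise ValueError(f"chisq_kind must be one of {_CHISQ_KINDS}")
    sv = _align(sv, spec)
    s = vech(sv.S)
    v_diag = np.diag(sv.V).copy()
    if np.any(v_diag <= 0):
        raise ValueError(
            "V has non-positive diagonal entries; smooth V (SVMatrices.smooth) "
            "before fitting"
        )
    w_sqrt = 1.0 / np.sqrt(v_diag)

    def sigma_of(theta: np.ndarray) -> np.ndarray:
        return vech(implied_cov(spec, theta))

    def resid(theta: np.ndarray) -> np.ndarray:
        return (s - sigma_of(theta)) * w_sqrt

    rng = np.random.default_rng(seed)
    x0 = _smart_start(spec, sv.S) if theta0 is None else np.asarray(theta0, float)
    best = None
    n_iter_total = 0
    converged = False
    for attempt in range(n_restarts + 1):
        start = x0 if attempt == 0 else x0 + rng.normal(0, 0.1 + 0.05 * attempt,
                                                        size=len(x0))
        try:
            res = optimize.least_squares(resid, start, method="trf",
                                         xtol=1e-12, ftol=1e-12, gtol=1e-10)
        except (ValueError, np.linalg.LinAlgError):
            continue
        n_iter_total += res.nfev
        cost = 2 * res.cost  # least_squares cost = 0.5 * sum r^2
        if best is None or cost < best[1] - 1e-12:
            best = (res.x, cost)
        if res.success and np.all(np.isfinite(res.x)):
            converged = True
            if attempt == 0 or cost <= best[1] + 1e-12:
                best = (res.x, cost)
            break
    if best is None:
        raise RuntimeError("DWLS optimization failed from every starting point")
    theta_hat, objective = best

    # Heywood check: negative residual variance of any indicator
    for p, val in zip(spec.free_params(), theta_hat):
        if p.matrix == "P" and p.lhs == p.rhs and val < -1e-8:
            warnings.warn(f"Heywood case: negative variance estimate for {p.lhs} "
                          f"({val:.4g})")

    delta = _numeric_jacobian(sigma_of, theta_hat)
    w_mat = np.diag(1.0 / v_diag)
    bread_inner = delta.T @ w_mat @ delta
    try:
        bread = np.linalg.inv(bread_inner)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError(
            "singular information matrix: model may be under-identified"
        ) from exc
    meat = delta.T @ w_mat @ sv.V @ w_mat @ delta
    cov_theta = bread @ meat @ bread
    cov_theta = (cov_theta + cov_theta.T) / 2

    df = spec.df
    e = s - sigma_of(theta_hat)
    if df <= 0:
        chisq, chisq_p = 0.0, np.nan
    else:
        u = w_mat - w_mat @ delta @ bread @ delta.T @ w_mat
        t_naive = float(e @ u @ e)
        if chisq_kind == "naive":
            chisq = t_naive
        elif chisq_kind == "mean_corrected":
            trace_uv = float(np.trace(u @ sv.V))
            chisq = t_naive * df / trace_uv
        else:  # browne residual-based statistic with full V
            vinv = np.linalg.pinv(sv.V)
            mid = vinv - vinv @ delta @ np.linalg.inv(delta.T @ vinv @ delta) \
                @ delta.T @ vinv
            chisq = float(e @ mid @ e)
        chisq = max(chisq, 0.0)
        chisq_p = float(stats.chi2.sf(chisq, df))

    return FitResult(
        param_names=spec.param_names(),
        theta=np.asarray(theta_hat),
        cov_theta=cov_theta,
        chisq=chisq,
        df=df,
        chisq_p=chisq_p,
        converged=converged,
        n_iterations=n_iter_total,
        objective=objective,
        chisq_kind=chisq_kind,
    )


def independence_spec(observed: list[str]) -> ModelSpec:
    """Baseline model freeing only the observed variances."""
    params = [Parameter(v, v, "P", True, 0.1, name=f"{v}~~{v}") for v in observed]
    return ModelSpec(observed=list(observed), latents=[], params=params)


def saturated_spec(observed: list[str]) -> ModelSpec:
    """All variances and covariances free."""
    params = []
    for j, b in enumerate(observed):
        for a in observed[j:]:
            params.append(Parameter(a, b, "P", True,
                                    0.1 if a == b else 0.0, name=f"{a}~~{b}"))
    return ModelSpec(observed=list(observed), latents=[], params=params)


def fit_indices(result: FitResult, sv: SVMatrices, spec: ModelSpec,
                ) -> FitIndices:
    """CFI (vs. variances-only independence model), SRMR on the
    correlation-standardized scale over unique moments (diagonal
    included), and AIC = chisq + 2q."""
    sv = _align(sv, spec)
    indep = independence_spec(spec.observed)
    base = fit_dwls(sv, indep, chisq_kind=result.chisq_kind, n_restarts=2)
    if not base.converged:
        raise RuntimeError("independence model failed to converge")

    num = max(result.chisq - result.df, 0.0)
    denom = max(base.chisq - base.df, num, 0.0)
    cfi = 1.0 - (num / denom if denom > 0 else 0.0)

    sigma = implied_cov(spec, result.theta)
    s_mat = sv.S
    d = np.sqrt(np.diag(s_mat))
    resid = []
    for i, j in vech_indices(len(spec.observed)):
        if i == j:
            resid.append((s_mat[i, i] - sigma[i, i]) / s_mat[i, i])
        else:
            resid.append((s_mat[i, j] - sigma[i, j]) / (d[i] * d[j]))
    srmr = float(np.sqrt(np.mean(np.square(resid))))
    aic = result.chisq + 2 * len(result.param_names)
    return FitIndices(cfi=float(cfi), srmr=srmr, aic=float(aic))


def standardize_solution(result: FitResult, spec: ModelSpec) -> FitResult:
    """Rescale estimates to the correlation metric (all variable variances
    1); SEs are carried over by the delta method."""
    free = spec.free_params()

    def g(theta: np.ndarray) -> np.ndarray:
        c = total_cov(spec, theta)
        var = np.diag(c)
        if np.any(var <= 0):
            bad = spec.variables[int(np.argmin(var))]
            raise ValueError(f"non-positive implied variance for {bad!r}")
        sd = np.sqrt(var)
        idx = {v: i for i, v in enumerate(spec.variables)}
        out = np.empty(len(free))
        for q, p in enumerate(free):
            i, j = idx[p.lhs], idx[p.rhs]
            if p.matrix == "A":
                out[q] = theta[q] * sd[j] / sd[i]
            else:
                out[q] = theta[q] / (sd[i] * sd[j])
        return out

    theta_std = g(result.theta)
    jac = _numeric_jacobian(g, result.theta)
    cov_std = jac @ result.cov_theta @ jac.T
    cov_std = (cov_std + cov_std.T) / 2
    return FitResult(
        param_names=list(result.param_names),
        theta=theta_std,
        cov_theta=cov_std,
        chisq=result.chisq,
        df=result.df,
        chisq_p=result.chisq_p,
        converged=result.converged,
        n_iterations=result.n_iterations,
        objective=result.objective,
        chisq_kind=result.chisq_kind,
        standardized=True,
    )
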