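"""Post-fit statistics: asymmetric profile-likelihood confidence intervals
with open-end detection, parameter dependency, ambiguity flags, the
individual/global/adjusted coefficient-of-determination family, and
delta-method confidence and prediction bands.

All of it operates on the :class:`~sabrefit.fitting.FitResult` / problem
surface, so the same machinery applies to the receptor model and to any
other curve model fitted through the engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .fitting import FitResult, profile_refit

__all__ = [
    "IntervalEstimate",
    "DiagnosticsReport",
    "profile_ci",
    "dependency",
    "flag_ambiguous",
    "r_squared",
    "bands",
    "diagnostics_report",
]

#: dependency above which a parameter is called redundant and the fit ambiguous
AMBIGUITY_THRESHOLD = 0.9999
#: interpretive annotation thresholds: "high" and "unacceptably high"
HIGH_DEPENDENCY = 0.9
UNACCEPTABLE_DEPENDENCY = 0.99


@dataclass(frozen=True)
class IntervalEstimate:
    """A confidence interval whose ends may be open (unbounded).

    An open end means the SSR profile never crossed the threshold before the
    parameter's domain bound — the data do not pin the parameter down in that
    direction.  Open ends render as ``"?"`` in text reports.
    """

    lower: float | None
    upper: float | None
    level: float = 0.95

    @property
    def open_lower(self) -> bool:
        return self.lower is None

    @property
    def open_upper(self) -> bool:
        return self.upper is None

    def contains(self, value: float) -> bool:
        lo = -np.inf if self.lower is None else self.lower
        hi = np.inf if self.upper is None else self.upper
        return lo <= value <= hi

    def __str__(self) -> str:
        lo = "?" if self.lower is None else f"{self.lower:.6g}"
        hi = "?" if self.upper is None else f"{self.upper:.6g}"
        return f"{lo} to {hi}"


@dataclass
class DiagnosticsReport:
    """Everything reported per fit: CIs, dependencies, flags, R² family."""

    ci: dict[str, IntervalEstimate]
    dependency: dict[str, float]
    ambiguous: dict[str, bool]
    high_dependency: dict[str, str]  # "", "high", "unacceptably high"
    ambiguous_fit: bool
    r2_individual: dict[str, float | None]
    r2_global: float | None
    r2_adjusted: float | None
    level: float = 0.95
    notes: list[str] = field(default_factory=list)


def _ssr_threshold(fit: FitResult, level: float) -> float:
    f_crit = stats.f.ppf(level, 1, fit.dof)
    return fit.ssr * (1.0 + f_crit / fit.dof)


def profile_ci(fit: FitResult, param: str, level: float = 0.95) -> IntervalEstimate:
    """Asymmetric (profile-likelihood) confidence interval for one parameter.

    The interval is the set of trial values v for which re-fitting all other
    free parameters with this one held at v keeps
    ``SSR(v) <= SSR_min * (1 + F(level; 1, dof)/dof)``.  Each end is located
    by walking outward from the optimum in growing steps (warm-starting each
    inner refit) and then root-finding on the bracketed crossing; if the
    threshold is not crossed before the domain bound the end is open.
    """
    if param not in fit.names:
        raise KeyError(f"{param!r} is not a free parameter of this fit")
    if not fit.converged:
        raise ValueError("profile_ci requires a converged fit")
    j = fit.names.index(param)
    vhat = fit.theta[j]
    lo_bound, hi_bound = fit.problem.lower[j], fit.problem.upper[j]
    thr = _ssr_threshold(fit, level)

    se = fit.se.get(param, 0.0)
    if not np.isfinite(se) or se <= 0:
        span = hi_bound - lo_bound
        se = span / 50.0 if np.isfinite(span) else max(abs(vhat), 1.0) / 10.0

    ends: list[float | None] = []
    for direction in (-1.0, +1.0):
        bound = lo_bound if direction < 0 else hi_bound
        ends.append(_profile_end(fit, j, vhat, direction, bound, se, thr))
    lower, upper = ends
    return IntervalEstimate(lower=lower, upper=upper, level=level)


def _profile_end(fit, j, vhat, direction, bound, scale, thr):
    problem = fit.problem
    warm = fit.theta.copy()
    v_in, ssr_in = vhat, fit.ssr
    step = 0.5 * scale
    v = vhat
    crossed = None
    for _ in range(200):
        v_next = v + direction * step
        if (direction < 0 and v_next <= bound) or (direction > 0 and v_next >= bound):
            v_next = bound
        ssr_next, warm = profile_refit(fit, j, v_next, warm=warm)
        if ssr_next > thr:
            crossed = (v_in, v_next, ssr_in, ssr_next)
            break
        v_in, ssr_in = v_next, ssr_next
        if v_next == bound:
            return None  # profile stayed under the threshold all the way out
        v = v_next
        step *= 1.7
    if crossed is None:
        return None
    v_ok, v_bad, _, _ = crossed

    # bisection on the bracketed SSR crossing; warm starts keep refits cheap
    warm_b = warm.copy()
    for _ in range(60):
        if abs(v_bad - v_ok) <= 1e-6 * max(abs(v_ok), abs(v_bad), scale):
            break
        mid = 0.5 * (v_ok + v_bad)
        ssr_mid, warm_b = profile_refit(fit, j, mid, warm=warm_b)
        if ssr_mid > thr:
            v_bad = mid
        else:
            v_ok = mid
    return 0.5 * (v_ok + v_bad)


def dependency(fit: FitResult) -> dict[str, float]:
    """How intertwined each parameter is with all others, from 0 (independent)
    to 1 (redundant): ``1 - 1/(R^-1)_ii`` on the estimate correlation matrix.

    For two parameters with estimate correlation r this reduces to r².  A
    singular correlation matrix reports 1 for every affected parameter.
    """
    cov = fit.covariance
    k = cov.shape[0]
    if k == 0:
        return {}
    sd = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    bad = sd <= 0
    if k == 1:
        return {fit.names[0]: 1.0 if bad[0] else 0.0}
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / np.outer(sd, sd)
    corr[bad, :] = 0.0
    corr[:, bad] = 0.0
    np.fill_diagonal(corr, 1.0)
    # a tiny ridge keeps the inverse defined for exactly collinear estimates;
    # the affected diagonal entries blow up and clip to dependency 1
    eigmin = float(np.linalg.eigvalsh(corr).min())
    if eigmin < 1e-12:
        corr = corr + np.eye(k) * (1e-12 - min(eigmin, 0.0))
    rinv_diag = np.diag(np.linalg.inv(corr))
    out: dict[str, float] = {}
    for i, name in enumerate(fit.names):
        if bad[i]:
            out[name] = 1.0
        else:
            d = 1.0 - 1.0 / rinv_diag[i] if rinv_diag[i] > 0 else 1.0
            out[name] = float(np.clip(d, 0.0, 1.0))
    return out


def flag_ambiguous(deps: dict[str, float]) -> tuple[dict[str, bool], dict[str, str], bool]:
    """Per-parameter ambiguity flags plus interpretive annotations.

    A parameter is ambiguous above 0.9999 dependency; the overall fit is
    ambiguous if any parameter is.  Dependencies above 0.9 and 0.99 are
    annotated "high" and "unacceptably high".
    """
    flags = {n: d > AMBIGUITY_THRESHOLD for n, d in deps.items()}
    notes = {}
    for n, d in deps.items():
        if d > UNACCEPTABLE_DEPENDENCY:
            notes[n] = "unacceptably high"
        elif d > HIGH_DEPENDENCY:
            notes[n] = "high"
        else:
            notes[n] = ""
    return flags, notes, any(flags.values())


def r_squared(
    fit: FitResult,
) -> tuple[dict[str, float | None], float | None, float | None]:
    """Individual (per dataset), global and adjusted-global R².

    Individual R² takes each dataset's total sum of squares about its own
    mean; the global R² pools all observations about their grand mean; the
    adjusted value penalizes the free-parameter count,
    ``1 - (1-R²)*(N-1)/(N-K-1)``.  Constant data (SST = 0) yields None.
    """
    y = fit.problem.y
    r2_ind: dict[str, float | None] = {}
    for label, sl in fit.problem.slices.items():
        yd = y[sl]
        resid = fit.per_dataset_residuals[label]
        sst = float(np.sum((yd - yd.mean()) ** 2))
        r2_ind[label] = None if sst == 0 else 1.0 - float(resid @ resid) / sst
    sst_pooled = float(np.sum((y - y.mean()) ** 2))
    if sst_pooled == 0:
        return r2_ind, None, None
    r2_g = 1.0 - fit.ssr / sst_pooled
    n, k = fit.n_points, fit.k_free
    if k == 0:
        r2_adj = r2_g
    elif n - k - 1 <= 0:
        r2_adj = None
    else:
        r2_adj = 1.0 - (1.0 - r2_g) * (n - 1) / (n - k - 1)
    return r2_ind, r2_g, r2_adj


def _prediction_gradients(fit: FitResult, label: str, xgrid) -> tuple[np.ndarray, np.ndarray]:
    """Best-fit curve and its gradient w.r.t. the free parameters (central
    differences, steps kept inside the bounds box)."""
    problem = fit.problem
    theta = fit.theta
    yhat = problem.predict_at(theta, label, xgrid)
    k = len(theta)
    grads = np.zeros((np.size(xgrid), k))
    for j in range(k):
        h = 1e-6 * max(abs(theta[j]), 1e-3)
        up = min(theta[j] + h, problem.upper[j])
        dn = max(theta[j] - h, problem.lower[j])
        if up == dn:
            continue
        tp, tm = theta.copy(), theta.copy()
        tp[j], tm[j] = up, dn
        grads[:, j] = (
            problem.predict_at(tp, label, xgrid) - problem.predict_at(tm, label, xgrid)
        ) / (up - dn)
    return yhat, grads


def bands(
    fit: FitResult, dataset: str, grid, level: float = 0.95
) -> dict[str, np.ndarray]:
    """Delta-method 95% confidence and prediction bands on a concentration grid.

    Confidence half-width: ``t(level, dof) * sqrt(g' Σ g)`` with g the
    response gradient w.r.t. the free parameters and Σ the fit covariance;
    the prediction band adds the residual variance ssr/dof inside the root,
    so it strictly contains the confidence band.  Degrees of freedom are
    those of the unified global fit.
    """
    if not fit.converged:
        raise ValueError("bands require a converged fit")
    grid = np.asarray(grid, dtype=float)
    yhat, g = _prediction_gradients(fit, dataset, grid)
    var_mean = np.clip(np.einsum("ij,jk,ik->i", g, fit.covariance, g), 0.0, np.inf)
    tcrit = stats.t.ppf(0.5 + level / 2.0, fit.dof)
    half_conf = tcrit * np.sqrt(var_mean)
    half_pred = tcrit * np.sqrt(var_mean + fit.sigma2)
    return {
        "x": grid,
        "yhat": yhat,
        "conf_lower": yhat - half_conf,
        "conf_upper": yhat + half_conf,
        "pred_lower": yhat - half_pred,
        "pred_upper": yhat + half_pred,
    }


def diagnostics_report(
    fit: FitResult, level: float = 0.95, compute_ci: bool = True
) -> DiagnosticsReport:
    """Assemble the full per-fit report (CIs, dependency, flags, R² family)."""
    deps = dependency(fit)
    flags, notes, overall = flag_ambiguous(deps)
    r2_ind, r2_g, r2_adj = r_squared(fit)
    ci = {}
    if compute_ci and fit.converged:
        for name in fit.names:
            ci[name] = profile_ci(fit, name, level=level)
    return DiagnosticsReport(
        ci=ci,
        dependency=deps,
        ambiguous=flags,
        high_dependency=notes,
        ambiguous_fit=overall,
        r2_individual=r2_ind,
        r2_global=r2_g,
        r2_adjusted=r2_adj,
        level=level,
    )
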