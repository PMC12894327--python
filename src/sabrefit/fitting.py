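"""Global bounded least-squares estimation of a multiline model.

All datasets are fitted simultaneously: the plan is compiled into a single
vectorized objective over the concatenated observations, with shared
parameters entering every equation that references them, so one regression
yields every estimate at once.  The solver is scipy's trust-region
reflective ``least_squares`` with seed-controlled multistart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .core import PARAM_BOUNDS
from .data import ECDataset
from .plan import ModelPlan, unpack_parameters

__all__ = [
    "FitOptions",
    "FitResult",
    "CurveProblem",
    "SabreProblem",
    "GenericCurveProblem",
    "fit_global",
    "fit_problem",
    "default_init",
    "profile_refit",
]

_SABRE_FIELDS = ("eps", "gamma", "n", "logKd", "q")


@dataclass(frozen=True)
class FitOptions:
    """Solver settings.

    ``tolerance`` is the relative convergence threshold on the cost (well
    below the 2-4 significant digits at which estimates are reported);
    ``multistart`` randomized restarts guard against the multimodality that
    the q/gamma trade-off can create, with log-uniform jitter on gains and
    affinities controlled by ``seed``.
    """

    max_iterations: int = 2000
    tolerance: float = 1e-10
    multistart: int = 5
    seed: int = 0
    bounds: dict[str, tuple[float, float]] | None = None
    use_means: bool = False  # fit per-concentration means instead of replicates

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.multistart < 1:
            raise ValueError("multistart must be >= 1")


class CurveProblem:
    """A compiled least-squares problem over one or more datasets.

    Concrete problems provide ``names``, ``lower``/``upper`` bound arrays,
    concatenated ``x``/``y`` arrays, per-dataset ``slices``, ``predict`` and
    ``predict_at``.  Diagnostics only use this surface, so profile CIs and
    bands work for any curve model, not just the receptor model.
    """

    names: list[str]
    lower: np.ndarray
    upper: np.ndarray
    x: np.ndarray
    y: np.ndarray
    slices: dict[str, slice]

    def predict(self, theta: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def predict_at(self, theta: np.ndarray, label: str, xgrid) -> np.ndarray:
        raise NotImplementedError

    def residuals(self, theta: np.ndarray) -> np.ndarray:
        return self.y - self.predict(theta)

    def ssr(self, theta: np.ndarray) -> float:
        r = self.residuals(theta)
        return float(r @ r)

    def jitter(self, rng: np.random.Generator, x0: np.ndarray) -> np.ndarray:
        """Randomized restart point near ``x0`` (default: +-10% of the box)."""
        span = self.upper - self.lower
        out = x0 + rng.uniform(-0.1, 0.1, size=x0.shape) * np.where(
            np.isfinite(span), span, np.maximum(1.0, np.abs(x0))
        )
        return np.clip(out, self.lower, self.upper)


class SabreProblem(CurveProblem):
    """A plan + datasets compiled to index arrays for vectorized evaluation.

    Each point carries its dataset's five model parameters; free parameters
    are gathered from the flat vector through precomputed (row, column,
    theta-index) triples, so one objective evaluation is a handful of numpy
    operations regardless of how parameters are shared.
    """

    def __init__(
        self,
        plan: ModelPlan,
        datasets: list[ECDataset],
        bounds: dict[str, tuple[float, float]] | None = None,
        use_means: bool = False,
    ):
        self.plan = plan
        self.labels = [ds.label for ds in datasets]
        if set(self.labels) != set(plan.bindings):
            raise ValueError(
                f"plan bindings {sorted(plan.bindings)} do not match "
                f"datasets {sorted(self.labels)}"
            )
        self.names = plan.free_names
        # stable dataset order: sorted by label, so fits are invariant to
        # the order datasets are supplied in
        order = np.argsort(self.labels)
        datasets = [datasets[i] for i in order]
        self.labels = [self.labels[i] for i in order]

        xs, ys, ds_idx = [], [], []
        self.slices = {}
        pos = 0
        for i, ds in enumerate(datasets):
            x, y = ds.x, ds.y
            if use_means:
                ux = np.unique(x)
                y = np.array([np.sort(y[x == v]).mean() for v in ux])
                x = ux
            # canonical (x, y) row order makes the objective — and hence the
            # solve — independent of input point ordering, replicates included
            srt = np.lexsort((y, x))
            x, y = x[srt], y[srt]
            xs.append(x)
            ys.append(y)
            ds_idx.append(np.full(x.size, i))
            self.slices[ds.label] = slice(pos, pos + x.size)
            pos += x.size
        self.x = np.concatenate(xs)
        self.y = np.concatenate(ys)
        self._ds_idx = np.concatenate(ds_idx)

        # base parameter matrix (one row per dataset) holds fixed values;
        # gather triples overwrite free entries from theta
        fixed_vals = {p.name: p.value for p in plan.params if not p.free}
        theta_pos = {n: j for j, n in enumerate(self.names)}
        self._base = np.empty((len(datasets), len(_SABRE_FIELDS)))
        rows, cols, tidx = [], [], []
        for i, ds in enumerate(datasets):
            pretreated = plan.bindings[ds.label][1]
            for f, fld in enumerate(_SABRE_FIELDS):
                spec = plan.spec_for(ds.label, fld)
                if spec is None:
                    if fld != "q" or pretreated:
                        raise ValueError(f"no {fld!r} parameter for {ds.label!r}")
                    self._base[i, f] = 1.0  # control form: q = 1
                elif spec.free:
                    self._base[i, f] = np.nan
                    rows.append(i)
                    cols.append(f)
                    tidx.append(theta_pos[spec.name])
                else:
                    self._base[i, f] = fixed_vals[spec.name]
        self._rows = np.array(rows, dtype=int)
        self._cols = np.array(cols, dtype=int)
        self._tidx = np.array(tidx, dtype=int)

        user_bounds = dict(bounds or {})
        lo, hi = [], []
        for p in plan.free_params:
            b = user_bounds.get(p.name, p.bounds())
            lo.append(b[0])
            hi.append(b[1])
        self.lower = np.array(lo)
        self.upper = np.array(hi)

    def param_matrix(self, theta: np.ndarray) -> np.ndarray:
        P = self._base.copy()
        P[self._rows, self._cols] = np.asarray(theta)[self._tidx]
        return P

    def _response(self, P: np.ndarray, ds_idx: np.ndarray, x: np.ndarray) -> np.ndarray:
        eps, gamma, n, logKd, q = (P[ds_idx, f] for f in range(5))
        d = np.clip(n * (x - logKd), -300.0, 300.0)
        denom = q * eps * gamma - q * eps + 1.0
        return 100.0 * q * eps * gamma / (denom + 10.0 ** (-d))

    def predict(self, theta: np.ndarray) -> np.ndarray:
        return self._response(self.param_matrix(theta), self._ds_idx, self.x)

    def predict_at(self, theta: np.ndarray, label: str, xgrid) -> np.ndarray:
        i = self.labels.index(label)
        xgrid = np.asarray(xgrid, dtype=float)
        return self._response(
            self.param_matrix(theta), np.full(xgrid.size, i), xgrid
        )

    def jitter(self, rng: np.random.Generator, x0: np.ndarray) -> np.ndarray:
        """Log-uniform (one decade) jitter on gains and affinities, uniform
        elsewhere, clipped to the box."""
        out = x0.copy()
        for j, name in enumerate(self.names):
            if name == "gamma" or name.startswith("eps"):
                out[j] = x0[j] * 10.0 ** rng.uniform(-1, 1)
            elif name.startswith("logKd"):
                out[j] = x0[j] + rng.uniform(-1, 1)
            elif name == "q":
                out[j] = rng.uniform(0.05, 0.95)
            else:
                out[j] = x0[j] * 10.0 ** rng.uniform(-0.3, 0.3)
        return np.clip(out, self.lower, self.upper)


class GenericCurveProblem(CurveProblem):
    """Arbitrary curve model ``model(theta, x)`` on a single dataset."""

    def __init__(self, model, x, y, names, lower=None, upper=None, label="data"):
        self._model = model
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.names = list(names)
        k = len(self.names)
        self.lower = np.full(k, -np.inf) if lower is None else np.asarray(lower, float)
        self.upper = np.full(k, np.inf) if upper is None else np.asarray(upper, float)
        self.slices = {label: slice(0, self.x.size)}
        self._label = label

    def predict(self, theta):
        return np.asarray(self._model(theta, self.x), dtype=float)

    def predict_at(self, theta, label, xgrid):
        if label != self._label:
            raise KeyError(label)
        return np.asarray(self._model(theta, np.asarray(xgrid, float)), dtype=float)


@dataclass
class FitResult:
    """Best-fit values with asymptotic uncertainty for one global fit."""

    problem: CurveProblem
    names: list[str]
    theta: np.ndarray
    values: dict[str, float]
    se: dict[str, float]
    covariance: np.ndarray
    ssr: float
    n_points: int
    k_free: int
    dof: int
    converged: bool
    rank_deficient: bool
    message: str
    per_dataset_residuals: dict[str, np.ndarray]
    plan: ModelPlan | None = None
    options: FitOptions = field(default_factory=FitOptions)
    init: dict[str, float] | None = None
    n_evaluations: int = 0
    min_cost_seen: float = np.inf

    @property
    def sigma2(self) -> float:
        """Residual variance estimate ssr/dof."""
        return self.ssr / self.dof

    def dataset_params(self) -> dict[str, "SabreParams"]:
        """Per-dataset resolved model parameters (plan-based fits only)."""
        if self.plan is None:
            raise ValueError("no plan attached to this fit")
        return unpack_parameters(self.plan, self.theta)


def fit_problem(
    problem: CurveProblem,
    x0: np.ndarray,
    options: FitOptions | None = None,
    plan: ModelPlan | None = None,
    init_values: dict[str, float] | None = None,
) -> FitResult:
    """Minimize the summed squared residuals of ``problem`` from ``x0`` with
    ``options.multistart`` jittered restarts; return the best optimum found."""
    options = options or FitOptions()
    n, k = problem.y.size, len(problem.names)
    if n <= k:
        raise ValueError(f"need more observations than free parameters (N={n}, K={k})")

    evals = {"count": 0, "min": np.inf}

    def residual_fn(theta):
        r = problem.residuals(theta)
        evals["count"] += 1
        evals["min"] = min(evals["min"], float(r @ r))
        return r

    x0 = np.clip(np.asarray(x0, dtype=float), problem.lower, problem.upper)
    rng = np.random.default_rng(options.seed)
    starts = [x0] + [problem.jitter(rng, x0) for _ in range(options.multistart - 1)]

    best = None
    # scipy's TRF internals emit benign divide-by-zero warnings on exactly
    # zero-residual (noise-free) problems
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        for start in starts:
            res = least_squares(
                residual_fn,
                start,
                bounds=(problem.lower, problem.upper),
                method="trf",
                ftol=options.tolerance,
                xtol=None,
                gtol=None,
                max_nfev=options.max_iterations * (k + 1),
            )
            if best is None or res.cost < best.cost:
                best = res

    theta = best.x
    ssr = float(2.0 * best.cost)
    dof = n - k
    jac = best.jac
    jtj = jac.T @ jac
    rank = int(np.linalg.matrix_rank(jtj)) if k else 0
    rank_deficient = rank < k
    cov = ssr / dof * np.linalg.pinv(jtj)
    cov = 0.5 * (cov + cov.T)
    se_arr = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))

    residuals = problem.y - problem.predict(theta)
    per_ds = {lb: residuals[sl].copy() for lb, sl in problem.slices.items()}

    return FitResult(
        problem=problem,
        names=list(problem.names),
        theta=theta,
        values=dict(zip(problem.names, theta)),
        se=dict(zip(problem.names, se_arr)),
        covariance=cov,
        ssr=ssr,
        n_points=n,
        k_free=k,
        dof=dof,
        converged=bool(best.status > 0),
        rank_deficient=rank_deficient,
        message=best.message,
        per_dataset_residuals=per_ds,
        plan=plan,
        options=options,
        init=init_values or dict(zip(problem.names, x0)),
        n_evaluations=evals["count"],
        min_cost_seen=evals["min"],
    )


def default_init(plan: ModelPlan, datasets: list[ECDataset]) -> dict[str, float]:
    """Heuristic start: the affinity guess puts each logKd on the correct
    decade from the control curve's interpolated midpoint crossing, shifted
    by the assumed gain; gamma starts at 10, q at 0.5, eps and n at 1."""
    gamma0 = 10.0
    init: dict[str, float] = {}
    by_label = {ds.label: ds for ds in datasets}
    for p in plan.free_params:
        if p.name == "gamma":
            init[p.name] = gamma0
        elif p.name == "n":
            init[p.name] = 1.0
        elif p.name == "q":
            init[p.name] = 0.5
        elif p.name.startswith("eps"):
            init[p.name] = 1.0
        elif p.name.startswith("logKd"):
            agonist = p.name.split("_", 1)[1]
            control = next(
                (
                    by_label[lb]
                    for lb in p.scope
                    if not plan.bindings[lb][1] and lb in by_label
                ),
                None,
            )
            logec50 = _midpoint_crossing(control) if control is not None else -6.0
            lo, hi = PARAM_BOUNDS["logKd"]
            init[p.name] = float(np.clip(logec50 + np.log10(gamma0), lo, hi))
    return init


def _midpoint_crossing(ds: ECDataset) -> float:
    """log10 EC50 of a curve by linear interpolation at half its top plateau."""
    x, y = ds.x, ds.y
    ux = np.unique(x)
    # sort replicates before averaging so the start point (and hence the whole
    # fit) is bit-identical under point reordering
    my = np.array([np.sort(y[x == v]).mean() for v in ux])
    half = 0.5 * my.max()
    above = np.nonzero(my >= half)[0]
    if above.size == 0 or above[0] == 0:
        return float(ux[0])
    j = above[0]
    x0, x1, y0, y1 = ux[j - 1], ux[j], my[j - 1], my[j]
    if y1 == y0:
        return float(x1)
    return float(x0 + (half - y0) * (x1 - x0) / (y1 - y0))


def fit_global(
    plan: ModelPlan,
    datasets: list[ECDataset],
    init: dict[str, float] | None = None,
    options: FitOptions | None = None,
) -> FitResult:
    """Fit every dataset simultaneously under the plan's sharing rules.

    Unweighted least squares over all replicate points (per-concentration
    means if ``options.use_means``); asymptotic covariance is
    ``ssr/dof * (J^T J)^+`` at the optimum, with a rank-deficiency flag when
    the Jacobian loses rank.
    """
    options = options or FitOptions()
    for ds in datasets:
        if len(ds.points) < 2:
            raise ValueError(f"dataset {ds.label!r} has fewer than 2 points")
    problem = SabreProblem(
        plan, datasets, bounds=options.bounds, use_means=options.use_means
    )
    init_values = dict(default_init(plan, datasets))
    if init:
        init_values.update(init)
    x0 = np.array([init_values[n] for n in plan.free_names])
    return fit_problem(problem, x0, options, plan=plan, init_values=init_values)


def profile_refit(
    fit: FitResult,
    index: int,
    value: float,
    warm: np.ndarray | None = None,
    tolerance: float = 1e-10,
) -> tuple[float, np.ndarray]:
    """Re-optimize all free parameters except ``index``, held at ``value``.

    Returns (SSR, full parameter vector).  Used by profile-likelihood
    confidence intervals; warm starts from the previous profile point keep
    the inner fits cheap.
    """
    problem = fit.problem
    k = len(problem.names)
    base = (warm if warm is not None else fit.theta).copy()
    base[index] = value
    free_idx = [j for j in range(k) if j != index]
    if not free_idx:
        return problem.ssr(base), base

    def residual_fn(sub):
        theta = base.copy()
        theta[free_idx] = sub
        return problem.residuals(theta)

    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        res = least_squares(
            residual_fn,
            np.clip(base[free_idx], problem.lower[free_idx], problem.upper[free_idx]),
            bounds=(problem.lower[free_idx], problem.upper[free_idx]),
            method="trf",
            ftol=tolerance,
            xtol=None,
            gtol=None,
            max_nfev=2000,
        )
    theta = base.copy()
    theta[free_idx] = res.x
    return float(2.0 * res.cost), theta
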