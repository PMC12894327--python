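"""A scikit-learn-style estimator over the global multiline fit.

``SabreGlobalRegression`` consumes long-format data — a DataFrame (or
record array) with columns ``agonist``, ``pretreatment`` ("N"/"X") and
``log_conc`` — and the effect (percent of E_max) as ``y``, builds the shared
-parameter plan for the paired multi-agonist design, and runs the unified
bounded least-squares fit.  It composes with sklearn model selection and
pipelines; the library modules remain the primitive interface.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .core import SabreParams, sabre_response
from .data import ECDataset, ECPoint
from .diagnostics import diagnostics_report
from .fitting import FitOptions, fit_global
from .plan import build_plan, unpack_parameters

__all__ = ["SabreGlobalRegression", "frame_to_datasets"]

_COLUMNS = ("agonist", "pretreatment", "log_conc")


def frame_to_datasets(X, y) -> list[ECDataset]:
    """Group long-format rows into one dataset per (agonist, pretreatment)."""
    X = pd.DataFrame(X).reset_index(drop=True)
    missing = [c for c in _COLUMNS if c not in X.columns]
    if missing:
        raise ValueError(f"X is missing column(s): {missing}")
    y = np.asarray(y, dtype=float)
    if y.shape != (len(X),):
        raise ValueError(f"y must have one effect value per row of X, got {y.shape}")
    groups: dict[tuple[str, bool], list[ECPoint]] = {}
    for (agonist, pre), idx in X.groupby(
        ["agonist", "pretreatment"], sort=False
    ).groups.items():
        if pre not in ("N", "X"):
            raise ValueError(f"pretreatment must be 'N' or 'X', got {pre!r}")
        xs = X.loc[idx, "log_conc"].to_numpy(dtype=float)
        groups[(str(agonist), pre == "X")] = [
            ECPoint(x=float(xv), y=float(yv)) for xv, yv in zip(xs, y[idx])
        ]
    return [
        ECDataset(agonist=ag, pretreated=pre, points=pts)
        for (ag, pre), pts in groups.items()
    ]


class SabreGlobalRegression(RegressorMixin, BaseEstimator):
    """Global receptor-model regression with shared gain, affinity and
    operable-fraction parameters.

    Parameters
    ----------
    phase : {"final", "preliminary"}
        "final" fixes the Hill coefficient and every efficacy at 1, leaving
        gain, operable fraction and one affinity per agonist free;
        "preliminary" also frees the (shared) efficacies and Hill coefficient.
    multistart : int
        Randomized restarts of the bounded least-squares solver.
    tolerance : float
        Relative convergence threshold on the cost.
    random_state : int
        Seed for the multistart jitter.
    compute_ci : bool
        Whether :meth:`fit` also computes profile-likelihood intervals
        (slower; they can always be computed later from ``result_``).

    Attributes
    ----------
    result_ : FitResult
        The full fit (values, covariance, residuals).
    report_ : DiagnosticsReport
        Dependency, ambiguity flags, R² family (and CIs if requested).
    gamma_, q_ : float
        Best-fit gain and operable-receptor fraction.
    log_kd_ : dict[str, float]
        Best-fit log10 Kd per agonist.
    """

    def __init__(
        self,
        phase: str = "final",
        multistart: int = 5,
        tolerance: float = 1e-10,
        max_iterations: int = 2000,
        random_state: int = 0,
        compute_ci: bool = False,
    ):
        self.phase = phase
        self.multistart = multistart
        self.tolerance = tolerance
        self.max_iterations = max_iterations
        self.random_state = random_state
        self.compute_ci = compute_ci

    def _options(self) -> FitOptions:
        return FitOptions(
            max_iterations=self.max_iterations,
            tolerance=self.tolerance,
            multistart=self.multistart,
            seed=self.random_state,
        )

    def fit(self, X, y):
        datasets = frame_to_datasets(X, y)
        plan = build_plan(datasets, phase=self.phase)
        self.result_ = fit_global(plan, datasets, options=self._options())
        if not self.result_.converged:
            raise RuntimeError(f"global fit failed to converge: {self.result_.message}")
        self.report_ = diagnostics_report(
            self.result_, compute_ci=self.compute_ci
        )
        self.params_ = dict(self.result_.values)
        self.dataset_params_ = unpack_parameters(plan, self.result_.theta)
        self.gamma_ = self.params_.get("gamma")
        self.q_ = self.params_.get("q")
        self.log_kd_ = {
            name.split("_", 1)[1]: val
            for name, val in self.params_.items()
            if name.startswith("logKd_")
        }
        self.n_features_in_ = 3
        return self

    def predict(self, X):
        if not hasattr(self, "result_"):
            raise RuntimeError("estimator is not fitted")
        X = pd.DataFrame(X)
        out = np.empty(len(X), dtype=float)
        for i, row in enumerate(X.itertuples(index=False)):
            label = f"{row.agonist}:{row.pretreatment}"
            try:
                p: SabreParams = self.dataset_params_[label]
            except KeyError:
                raise ValueError(f"unseen group {label!r}") from None
            out[i] = sabre_response(p, float(row.log_conc))
        return out
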