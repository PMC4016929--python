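"""Forward-backward splitting and the single-task group-sparse estimators.

The composite objective  F(w, b) = f1(w, b) + λ Ω(w)  couples the smooth
squared-hinge data term f1 with a possibly nonsmooth penalty Ω.  Forward-
backward splitting alternates a gradient step on f1 and a proximal step on
λΩ:

    w⁺ = prox_{τλΩ}( w − τ ∇_w f1(w, b) ),   b⁺ = b − τ ∇_b f1(w, b)

with a fixed stepsize τ = 1/L where L bounds the (w, b) gradient Lipschitz
constant of f1.  The bias is never thresholded.  With this stepsize the
objective decreases monotonically and the iterates converge to a minimizer.

Estimator naming used throughout the package (and standard in the ERP
decoding literature): SVM = ℓ2, SVM-1/GSVM-1 = ℓ1, GSVM-2 = ℓ1–ℓ2 group
penalty, GSVM-q = ℓ1–ℓq with q selected by cross-validation, GSVM-a =
two-stage adaptive ℓ1–ℓq with β_g = 1/||w*_g||_q.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from erpselect.core_model import (
    GroupStructure,
    LinearModel,
    TrialSet,
    lipschitz_constant,
    squared_hinge_gradient,
    squared_hinge_value,
)
from erpselect.regularizers import (
    RegularizerSpec,
    adaptive_weights,
    penalty_value,
    prox_for_spec,
)

__all__ = [
    "SolverOptions",
    "FitResult",
    "DivergenceError",
    "fbs_minimize",
    "fit_single_task",
    "selected_channels",
]

#: Relative threshold deciding when a sensor counts as selected.
SELECTION_THRESHOLD_REL = 1e-8


class DivergenceError(RuntimeError):
    """Non-finite objective encountered; the Lipschitz bound is likely wrong."""


@dataclass
class SolverOptions:
    """Forward-backward iteration controls.

    ``rel_tol`` is the relative objective-decrease stopping rule; the
    stepsize rule is fixed at 1/L (no line search, no acceleration).
    """

    max_iter: int = 5000
    rel_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be positive")


@dataclass
class FitResult:
    model: LinearModel
    objective_trace: np.ndarray
    n_iter: int
    converged: bool
    extras: dict = field(default_factory=dict)

    def to_dict(self, groups: GroupStructure | None = None) -> dict:
        d = {
            "model": self.model.to_dict(),
            "objective_trace": np.asarray(self.objective_trace).tolist(),
            "n_iter": self.n_iter,
            "converged": self.converged,
        }
        if groups is not None:
            d["group_norms"] = groups.group_norms(self.model.w).tolist()
        return d


def fbs_minimize(
    smooth: Callable[[np.ndarray, float], tuple[float, np.ndarray, float]],
    lipschitz: float,
    prox: Callable[[np.ndarray, float], np.ndarray],
    penalty: Callable[[np.ndarray], float],
    start: LinearModel,
    opts: SolverOptions,
) -> FitResult:
    """Minimize smooth(w, b) + penalty(w) by forward-backward splitting.

    Parameters
    ----------
    smooth : callable
        ``smooth(w, b) -> (value, grad_w, grad_b)`` for the differentiable
        part f1.
    lipschitz : float
        Valid Lipschitz bound for the joint (w, b) gradient of f1.
    prox : callable
        ``prox(v, τ)`` evaluating prox_{τ f2}(v) on the weight vector only.
    penalty : callable
        ``penalty(w)`` evaluating f2 (λ included) for the objective trace.
    start : LinearModel
        Initial iterate.
    """
    if lipschitz <= 0:
        raise ValueError("Lipschitz constant must be positive")
    tau = 1.0 / lipschitz
    w = start.w.copy()
    b = start.b
    val, gw, gb = smooth(w, b)
    obj = val + penalty(w)
    trace = [obj]
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        w = prox(w - tau * gw, tau)
        b = b - tau * gb
        val, gw, gb = smooth(w, b)
        obj_new = val + penalty(w)
        if not np.isfinite(obj_new):
            raise DivergenceError(
                "objective became non-finite; check the Lipschitz constant"
            )
        trace.append(obj_new)
        if obj - obj_new < opts.rel_tol * max(1.0, abs(obj)):
            converged = True
            obj = obj_new
            break
        obj = obj_new
    return FitResult(LinearModel(w, b), np.array(trace), it, converged)


def _single_task_smooth(trials: TrialSet):
    def smooth(w: np.ndarray, b: float):
        model = LinearModel(w, b)
        val = squared_hinge_value(model, trials)
        gw, gb = squared_hinge_gradient(model, trials)
        return val, gw, gb

    return smooth


def fit_single_task(
    trials: TrialSet,
    spec: RegularizerSpec,
    groups: GroupStructure | None = None,
    opts: SolverOptions | None = None,
    start: LinearModel | None = None,
) -> FitResult:
    """Fit one classifier minimizing Σᵢ squared-hinge + λ Ω(w).

    For an ``adaptive`` group spec the two-stage procedure runs: a plain
    ℓ1–ℓq fit, adaptive weights β_g = 1/||w*_g||_q (with sub-floor groups
    frozen at zero), then a warm-started weighted refit.  The returned
    result is the refit; the first stage is available in ``extras``.
    """
    if opts is None:
        opts = SolverOptions()
    if not trials.has_both_classes():
        raise ValueError("both classes must be present to fit a model")
    if spec.kind == "group_lq" and groups is None:
        groups = GroupStructure.for_trials(trials)

    if spec.adaptive:
        stage1_spec = RegularizerSpec(
            kind=spec.kind, lam=spec.lam, q=spec.q, beta=spec.beta,
            frozen=spec.frozen, adaptive=False,
        )
        stage1 = fit_single_task(trials, stage1_spec, groups, opts, start)
        beta, frozen = adaptive_weights(stage1.model.w, spec.q, groups)
        stage2_spec = RegularizerSpec(
            kind=spec.kind, lam=spec.lam, q=spec.q, beta=beta,
            frozen=frozen, adaptive=False,
        )
        result = fit_single_task(trials, stage2_spec, groups, opts, start=stage1.model)
        result.extras["stage1"] = stage1
        result.extras["beta"] = beta
        result.extras["frozen"] = frozen
        return result

    smooth = _single_task_smooth(trials)
    L = lipschitz_constant(trials)
    prox = prox_for_spec(spec, groups)
    pen = lambda w: spec.lam * penalty_value(spec, w, groups)
    if start is None:
        start = LinearModel(np.zeros(trials.d), 0.0)
    return fbs_minimize(smooth, L, prox, pen, start, opts)


def selected_channels(
    model: LinearModel,
    groups: GroupStructure,
    threshold_rel: float = SELECTION_THRESHOLD_REL,
) -> set[int]:
    """Sensors whose ℓ2 group norm exceeds ``threshold_rel`` times the max.

    An all-zero model selects nothing.
    """
    norms = groups.group_norms(model.w, q=2.0)
    top = norms.max()
    if top <= 0.0:
        return set()
    return {int(g) for g in np.flatnonzero(norms > threshold_rel * top)}
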