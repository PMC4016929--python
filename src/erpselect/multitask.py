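"""Joint sensor selection across subjects (multitask mixed-norm learning).

Given m subjects ("tasks") with per-subject trial sets sharing one sensor
layout, MGSVM fits the weight matrix W = [w_1 … w_m] and biases by
minimizing

    Σ_t Σ_i max(0, 1 − y_{i,t}(x_{i,t}·w_t + b_t))²
      + λ_s Σ_t ||w_t − ŵ||²  +  λ_r Σ_g ||W_g||_F

where ŵ = (1/m) Σ_t w_t is the across-subject mean classifier.  The
similarity term (weight λ_s) shrinks every subject's classifier toward the
mean — it minimizes the across-task parameter variance — while the group
term (weight λ_r) ties each sensor's r × m block of W together so sensors
are kept or discarded jointly for all subjects.  MGSVM-2 is the λ_s = 0
case; MGSVM-2s uses both terms.

The smooth part (losses + similarity) is handled by the gradient step of
forward-backward splitting, the group term by block soft thresholding of
each r × m sensor block at level τλ_r (Frobenius norm).  The stepsize is
1/L_mtl with the conservative bound L_mtl = max_t 2Σ_i||x̃_{i,t}||² + 4λ_s
(task losses are block-separable across columns; the similarity Hessian has
spectral norm at most 2λ_s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from erpselect.core_model import (
    GroupStructure,
    LinearModel,
    TrialSet,
    lipschitz_constant,
    squared_hinge_gradient,
    squared_hinge_value,
)
from erpselect.solver import DivergenceError, FitResult, SolverOptions

__all__ = [
    "MultiTaskData",
    "MultiTaskModel",
    "mtl_smooth_gradient",
    "mtl_prox",
    "mtl_objective",
    "fit_multitask",
]


@dataclass
class MultiTaskData:
    """Per-subject trial sets sharing one (p, r) sensor layout."""

    tasks: list[TrialSet]

    def __post_init__(self) -> None:
        if len(self.tasks) < 1:
            raise ValueError("need at least one task")
        first = self.tasks[0]
        for t in self.tasks:
            if (
                t.n_sensors != first.n_sensors
                or t.n_features_per_sensor != first.n_features_per_sensor
            ):
                raise ValueError("all tasks must share the same sensor layout")
            if not t.has_both_classes():
                raise ValueError("every task needs both classes")

    @property
    def m(self) -> int:
        return len(self.tasks)

    @property
    def d(self) -> int:
        return self.tasks[0].d

    def groups(self) -> GroupStructure:
        return GroupStructure.for_trials(self.tasks[0])


@dataclass
class MultiTaskModel:
    """Stacked per-task weights W (d × m), biases, and hyperparameters."""

    W: np.ndarray
    biases: np.ndarray
    lam_r: float
    lam_s: float

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.float64)
        self.biases = np.asarray(self.biases, dtype=np.float64).ravel()
        if self.W.ndim != 2 or self.W.shape[1] != self.biases.size:
            raise ValueError("W must be d × m with one bias per task")
        if self.lam_r < 0 or self.lam_s < 0:
            raise ValueError("λ_r and λ_s must be nonnegative")

    @property
    def m(self) -> int:
        return self.W.shape[1]

    def mean_classifier(self) -> np.ndarray:
        """ŵ = (1/m) Σ_t w_t; by construction Σ_t (w_t − ŵ) = 0."""
        return self.W.mean(axis=1)

    def task_model(self, t: int) -> LinearModel:
        return LinearModel(self.W[:, t], self.biases[t])

    def to_dict(self, groups: GroupStructure | None = None) -> dict:
        d = {
            "W": self.W.tolist(),
            "biases": self.biases.tolist(),
            "lam_r": self.lam_r,
            "lam_s": self.lam_s,
        }
        if groups is not None:
            norms = np.array(
                [np.linalg.norm(self.W[idx, :]) for idx in groups.groups]
            )
            d["block_norms"] = norms.tolist()
            top = norms.max()
            d["selected"] = (
                [] if top == 0 else np.flatnonzero(norms > 1e-8 * top).tolist()
            )
        return d


def similarity_value(W: np.ndarray, lam_s: float) -> float:
    """λ_s Σ_t ||w_t − ŵ||² — m times the (biased) per-coordinate variance sum."""
    centered = W - W.mean(axis=1, keepdims=True)
    return lam_s * float(np.sum(centered**2))


def mtl_smooth_gradient(
    model: MultiTaskModel, data: MultiTaskData
) -> tuple[np.ndarray, np.ndarray]:
    """Gradient of the smooth part: per-task squared hinges + similarity.

    The similarity gradient for task t reduces to 2λ_s (w_t − ŵ): the
    coupling through the mean cancels because Σ_t (w_t − ŵ) = 0.  Biases do
    not enter the similarity term.
    """
    grad_W = np.empty_like(model.W)
    grad_b = np.empty(model.m)
    for t, trials in enumerate(data.tasks):
        gw, gb = squared_hinge_gradient(model.task_model(t), trials)
        grad_W[:, t] = gw
        grad_b[t] = gb
    if model.lam_s > 0:
        centered = model.W - model.W.mean(axis=1, keepdims=True)
        grad_W += 2.0 * model.lam_s * centered
    return grad_W, grad_b


def mtl_prox(
    W: np.ndarray, tau: float, lam_r: float, groups: GroupStructure
) -> np.ndarray:
    """Block soft thresholding of each r × m sensor block at level τλ_r."""
    if tau < 0 or lam_r < 0:
        raise ValueError("τ and λ_r must be nonnegative")
    out = W.copy()
    t = tau * lam_r
    for idx in groups.groups:
        norm = np.linalg.norm(W[idx, :])  # Frobenius norm of the block
        out[idx, :] = 0.0 if norm <= t else W[idx, :] * (1.0 - t / norm)
    return out


def mtl_objective(model: MultiTaskModel, data: MultiTaskData, groups: GroupStructure) -> float:
    """Full objective: losses + similarity + λ_r Σ_g ||W_g||_F."""
    loss = sum(
        squared_hinge_value(model.task_model(t), trials)
        for t, trials in enumerate(data.tasks)
    )
    group_pen = model.lam_r * sum(
        float(np.linalg.norm(model.W[idx, :])) for idx in groups.groups
    )
    return loss + similarity_value(model.W, model.lam_s) + group_pen


def mtl_lipschitz(data: MultiTaskData, lam_s: float) -> float:
    """Conservative smooth-part bound: max_t 2Σ||x̃||² + 4λ_s."""
    return max(lipschitz_constant(t) for t in data.tasks) + 4.0 * lam_s


def fit_multitask(
    data: MultiTaskData,
    lam_r: float,
    lam_s: float,
    opts: SolverOptions | None = None,
    start: MultiTaskModel | None = None,
) -> tuple[MultiTaskModel, FitResult]:
    """Fit MGSVM by forward-backward splitting on the stacked problem.

    Returns the fitted model and a FitResult whose LinearModel holds the
    flattened W (column-stacked) for plumbing; use the MultiTaskModel.
    """
    if lam_r < 0 or lam_s < 0:
        raise ValueError("λ_r and λ_s must be nonnegative")
    if opts is None:
        opts = SolverOptions()
    groups = data.groups()
    m, d = data.m, data.d
    if start is None:
        W = np.zeros((d, m))
        biases = np.zeros(m)
    else:
        W = start.W.copy()
        biases = start.biases.copy()
    model = MultiTaskModel(W, biases, lam_r, lam_s)
    tau = 1.0 / mtl_lipschitz(data, lam_s)

    def objective(mdl: MultiTaskModel) -> float:
        return mtl_objective(mdl, data, groups)

    obj = objective(model)
    trace = [obj]
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        gW, gb = mtl_smooth_gradient(model, data)
        W_new = mtl_prox(model.W - tau * gW, tau, lam_r, groups)
        b_new = model.biases - tau * gb
        model = MultiTaskModel(W_new, b_new, lam_r, lam_s)
        obj_new = objective(model)
        if not np.isfinite(obj_new):
            raise DivergenceError("multitask objective became non-finite")
        trace.append(obj_new)
        if obj - obj_new < opts.rel_tol * max(1.0, abs(obj)):
            converged = True
            obj = obj_new
            break
        obj = obj_new
    flat = FitResult(
        LinearModel(model.W.T.ravel(), 0.0), np.array(trace), it, converged
    )
    return model, flat
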