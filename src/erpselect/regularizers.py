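"""Sparsity-inducing penalties and their proximal operators.

Three penalty families are supported, all evaluated without the global
regularization weight λ (the solver applies λ):

* ``l2``       : Ω(w) = ½||w||₂²                      (ridge; no selection)
* ``l1``       : Ω(w) = Σᵢ|wᵢ|                        (feature selection)
* ``group_lq`` : Ω(w) = Σ_g β_g ||w_g||_q, 1 ≤ q ≤ 2  (sensor selection)

The mixed norm acts as an ℓ1 norm on the vector of within-group ℓq norms, so
whole sensor groups of ``w`` vanish at once.  The adaptive variant reweights
groups by β_g = 1/||w*_g||_q computed from a first-stage unweighted fit,
sharpening the selection; groups whose first-stage norm is (relatively) below
a floor are frozen at zero, which realizes their infinite penalty.

Proximal operators: soft thresholding (ℓ1) and block soft thresholding
(ℓ1–ℓ2) are closed-form.  For 1 < q < 2 the group prox

    argmin_u  ½||v_g − u||² + t ||u||_q ,   t = τ β_g

has no closed form; ``prox_group_lq`` solves it by a two-level bracketing
iteration: an outer bisection on the scalar s = ||u||_q and, for each s, an
inner vectorized bisection solving the coordinatewise stationarity condition
u + t s^(1−q) u^(q−1) = |v| on [0, |v|].  The prox is exactly zero iff
||v_g||_{q*} ≤ t with 1/q* + 1/q = 1 (the dual-norm ball condition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from erpselect.core_model import GroupStructure

__all__ = [
    "RegularizerSpec",
    "penalty_value",
    "prox_l1",
    "prox_group_l2",
    "prox_group_lq",
    "adaptive_weights",
    "ProxConvergenceError",
]

KINDS = ("l2", "l1", "group_lq")

#: Inner tolerance and iteration cap of the generic lq prox.
LQ_PROX_TOL = 1e-10
LQ_PROX_MAX_ITER = 10_000

#: Relative floor below which a first-stage group norm freezes the group.
ADAPTIVE_FLOOR = 1e-10


class ProxConvergenceError(RuntimeError):
    """Raised when the iterative lq prox fails to converge for a group."""

    def __init__(self, group: int, n_iter: int):
        self.group = group
        super().__init__(
            f"lq prox did not converge for group {group} within {n_iter} iterations"
        )


@dataclass
class RegularizerSpec:
    """Which penalty Ω is in force and with what hyperparameters.

    Parameters
    ----------
    kind : {"l2", "l1", "group_lq"}
    lam : float
        Global regularization weight λ ≥ 0 (applied by the solver).
    q : float
        Inner exponent of the mixed norm, in [1, 2]; group_lq only.
    beta : ndarray or None
        Per-group positive weights β_g (group_lq only); ``None`` means
        all ones.
    frozen : frozenset of int
        Group ids permanently fixed at zero (adaptive refits).
    adaptive : bool
        If set, the single-task fitter runs the two-stage adaptive
        procedure: unweighted fit, then β_g = 1/||w*_g||_q refit.
    """

    kind: str
    lam: float
    q: float = 2.0
    beta: np.ndarray | None = None
    frozen: frozenset = field(default_factory=frozenset)
    adaptive: bool = False

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown regularizer kind {self.kind!r}")
        if self.lam < 0:
            raise ValueError("λ must be nonnegative")
        if not 1.0 <= self.q <= 2.0:
            raise ValueError(f"q={self.q} outside [1, 2]")
        if self.beta is not None:
            self.beta = np.asarray(self.beta, dtype=np.float64)
            active = np.setdiff1d(np.arange(self.beta.size), sorted(self.frozen))
            if np.any(self.beta[active] <= 0):
                raise ValueError("β_g must be positive for every active group")
        self.frozen = frozenset(self.frozen)

    def group_weights(self, n_groups: int) -> np.ndarray:
        if self.beta is None:
            return np.ones(n_groups)
        if self.beta.size != n_groups:
            raise ValueError("β length does not match the number of groups")
        return self.beta

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "lam": self.lam,
            "q": self.q,
            "beta": None if self.beta is None else self.beta.tolist(),
            "frozen": sorted(self.frozen),
            "adaptive": self.adaptive,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegularizerSpec":
        return cls(
            kind=d["kind"],
            lam=d["lam"],
            q=d.get("q", 2.0),
            beta=None if d.get("beta") is None else np.asarray(d["beta"]),
            frozen=frozenset(d.get("frozen", ())),
            adaptive=d.get("adaptive", False),
        )


def penalty_value(
    spec: RegularizerSpec, w: np.ndarray, groups: GroupStructure | None = None
) -> float:
    """Ω(w) for the penalty in force, excluding λ."""
    w = np.asarray(w, dtype=np.float64)
    if spec.kind == "l2":
        return 0.5 * float(w @ w)
    if spec.kind == "l1":
        return float(np.sum(np.abs(w)))
    if groups is None:
        raise ValueError("group_lq penalty requires a GroupStructure")
    beta = spec.group_weights(groups.n_groups)
    total = 0.0
    for g, idx in enumerate(groups.groups):
        if g in spec.frozen:
            continue  # frozen groups are constrained to zero, not penalized
        total += beta[g] * float(np.linalg.norm(w[idx], ord=spec.q))
    return total


def prox_l1(v: np.ndarray, tau: float) -> np.ndarray:
    """Soft thresholding: exact prox of τ||·||₁."""
    if tau < 0:
        raise ValueError("τ must be nonnegative")
    v = np.asarray(v, dtype=np.float64)
    return np.sign(v) * np.maximum(np.abs(v) - tau, 0.0)


def prox_group_l2(
    v: np.ndarray,
    tau: float,
    groups: GroupStructure,
    beta: np.ndarray | None = None,
) -> np.ndarray:
    """Block soft thresholding: exact prox of τ Σ_g β_g ||·_g||₂."""
    if tau < 0:
        raise ValueError("τ must be nonnegative")
    v = np.asarray(v, dtype=np.float64)
    out = v.copy()
    b = np.ones(groups.n_groups) if beta is None else beta
    for g, idx in enumerate(groups.groups):
        t = tau * b[g]
        if not np.isfinite(t):
            out[idx] = 0.0
            continue
        norm = np.linalg.norm(v[idx])
        out[idx] = 0.0 if norm <= t else v[idx] * (1.0 - t / norm)
    return out


def _prox_lq_scalar_group(
    a: np.ndarray, t: float, q: float, tol: float = LQ_PROX_TOL
) -> np.ndarray:
    """Prox of t||·||_q on a nonnegative vector a, 1 < q < 2."""
    qstar = q / (q - 1.0)
    if np.linalg.norm(a, ord=qstar) <= t:
        return np.zeros_like(a)
    a_max = float(a.max())

    def inner(s: float) -> np.ndarray:
        # solve u + c*u**(q-1) = a coordinatewise on (0, a]: safeguarded
        # Newton on the increasing residual, with a bisection fallback
        # whenever the Newton step leaves the current bracket
        c = t * s ** (1.0 - q)
        lo = np.zeros_like(a)
        hi = a.astype(np.float64).copy()
        u = hi.copy()
        pos = a > 0
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            for _ in range(200):
                f = u + c * u ** (q - 1.0) - a
                lo = np.where(f < 0, np.maximum(lo, u), lo)
                hi = np.where(f >= 0, np.minimum(hi, u), hi)
                fp = 1.0 + c * (q - 1.0) * u ** (q - 2.0)
                newton = u - f / fp
                bad = ~np.isfinite(newton) | (newton <= lo) | (newton >= hi)
                u = np.where(bad, 0.5 * (lo + hi), newton)
                if np.max((hi - lo)[pos], initial=0.0) < tol * max(1.0, a_max):
                    break
        return np.where(pos, u, 0.0)

    def phi(s: float) -> float:
        return float(np.linalg.norm(inner(s), ord=q)) - s

    s_hi = float(np.linalg.norm(a, ord=q))
    s_lo = 1e-9 * s_hi
    if phi(s_lo) <= 0:  # prox norm below resolution: numerically zero
        return np.zeros_like(a)
    try:
        s = brentq(
            phi, s_lo, s_hi, xtol=tol * max(1.0, s_hi), maxiter=LQ_PROX_MAX_ITER
        )
    except RuntimeError:
        return None  # caller raises with group id
    return inner(s)


def prox_group_lq(
    v: np.ndarray,
    tau: float,
    q: float,
    groups: GroupStructure,
    beta: np.ndarray | None = None,
    tol: float = LQ_PROX_TOL,
) -> np.ndarray:
    """Groupwise prox of τ Σ_g β_g ||·_g||_q for 1 ≤ q ≤ 2.

    Dispatches to the closed forms at q = 1 (soft thresholding, applied with
    the per-group weight) and q = 2 (block soft thresholding); otherwise runs
    the two-level bisection described in the module docstring.
    """
    if not 1.0 <= q <= 2.0:
        raise ValueError(f"q={q} outside [1, 2]")
    if tau < 0:
        raise ValueError("τ must be nonnegative")
    if q == 2.0:
        return prox_group_l2(v, tau, groups, beta)
    v = np.asarray(v, dtype=np.float64)
    b = np.ones(groups.n_groups) if beta is None else beta
    out = v.copy()
    for g, idx in enumerate(groups.groups):
        t = tau * b[g]
        if not np.isfinite(t):
            out[idx] = 0.0
            continue
        if t == 0.0:
            continue
        if q == 1.0:
            out[idx] = prox_l1(v[idx], t)
            continue
        a = np.abs(v[idx])
        if a.max() == 0.0:
            continue
        u = _prox_lq_scalar_group(a, t, q, tol)
        if u is None:
            raise ProxConvergenceError(g, LQ_PROX_MAX_ITER)
        out[idx] = np.sign(v[idx]) * u
    return out


def adaptive_weights(
    w_star: np.ndarray,
    q: float,
    groups: GroupStructure,
    floor: float = ADAPTIVE_FLOOR,
) -> tuple[np.ndarray, frozenset]:
    """Adaptive per-group weights β_g = 1/||w*_g||_q from a first-stage fit.

    Groups whose norm falls below ``floor`` times the largest group norm are
    returned in ``frozen`` and must be fixed at zero in the refit (their
    β would be infinite).

    Raises
    ------
    ValueError
        If every group is frozen (degenerate all-zero first stage).
    """
    w_star = np.asarray(w_star, dtype=np.float64)
    norms = np.array([np.linalg.norm(w_star[idx], ord=q) for idx in groups.groups])
    ref = norms.max()
    frozen = frozenset(np.flatnonzero(norms < floor * ref)) if ref > 0 else None
    if ref == 0.0 or len(frozen) == groups.n_groups:
        raise ValueError("all groups frozen: degenerate first-stage fit")
    beta = np.ones_like(norms)
    active = norms >= floor * ref
    beta[active] = 1.0 / norms[active]
    return beta, frozen


def prox_for_spec(spec: RegularizerSpec, groups: GroupStructure | None):
    """Return prox(v, τ) implementing the prox of τλΩ for ``spec``.

    The returned callable folds λ, β and frozen groups into the threshold.
    """
    lam = spec.lam

    if spec.kind == "l2":
        # prox of τλ·½||·||² is a pure shrink
        return lambda v, tau: v / (1.0 + tau * lam)
    if spec.kind == "l1":
        return lambda v, tau: prox_l1(v, tau * lam)

    if groups is None:
        raise ValueError("group_lq prox requires a GroupStructure")
    beta = spec.group_weights(groups.n_groups).copy()
    if spec.frozen:
        beta[sorted(spec.frozen)] = np.inf
    q = spec.q
    return lambda v, tau: prox_group_lq(v, tau * lam, q, groups, beta)
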