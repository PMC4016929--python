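"""Independent reference computations used only by the test suite.

Every oracle here deliberately avoids the code paths it checks: proximal
operators are verified against direct numerical minimization of the prox
objective, fitted objectives against generic smooth optimization combined
with enumeration of zero-group patterns, AUC against exhaustive pair
counting, and the signed-rank test against enumeration of all sign
assignments.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize
from scipy.stats import rankdata

from erpselect.core_model import (
    GroupStructure,
    LinearModel,
    TrialSet,
    squared_hinge_value,
)
from erpselect.regularizers import RegularizerSpec, penalty_value


# ---------------------------------------------------------------------------
# prox oracle: direct minimization of ½||v-u||² + pen(u)


def numeric_prox(v: np.ndarray, pen, x0: np.ndarray | None = None) -> np.ndarray:
    """Minimize the prox objective by Nelder-Mead from several starts."""
    v = np.asarray(v, dtype=np.float64)

    def obj(u):
        return 0.5 * np.sum((v - u) ** 2) + pen(u)

    starts = [v, np.zeros_like(v), 0.5 * v]
    if x0 is not None:
        starts.append(x0)
    best, best_val = None, np.inf
    for s in starts:
        for method, options in (
            ("Powell", {"xtol": 1e-12, "ftol": 1e-14, "maxiter": 20000}),
            ("Nelder-Mead", {"xatol": 1e-10, "fatol": 1e-14,
                             "maxiter": 20000, "maxfev": 20000}),
        ):
            res = minimize(obj, s, method=method, options=options)
            # one more pass from the found point sharpens kinky optima
            res = minimize(obj, res.x, method=method, options=options)
            if res.fun < best_val:
                best, best_val = res.x, res.fun
    return best


# ---------------------------------------------------------------------------
# generic convex-solver oracle for the fitted objectives


def _sqhinge_and_grad(w, b, X, y):
    margins = y * (X @ w + b)
    slack = np.maximum(0.0, 1.0 - margins)
    val = np.sum(slack**2)
    coef = -2.0 * y * slack
    return val, X.T @ coef, np.sum(coef)


def _min_l2(X, y, lam):
    d = X.shape[1]

    def fg(z):
        w, b = z[:d], z[d]
        val, gw, gb = _sqhinge_and_grad(w, b, X, y)
        return val + 0.5 * lam * w @ w, np.concatenate([gw + lam * w, [gb]])

    res = minimize(fg, np.zeros(d + 1), jac=True, method="L-BFGS-B",
                   options={"maxiter": 20000, "ftol": 1e-15, "gtol": 1e-12})
    return res.fun


def _min_l1(X, y, lam, feature_weights=None):
    """Exact smooth reformulation w = a - b with a, b >= 0."""
    d = X.shape[1]
    wts = np.ones(d) if feature_weights is None else feature_weights

    def fg(z):
        a, bm, bias = z[:d], z[d : 2 * d], z[2 * d]
        w = a - bm
        val, gw, gb = _sqhinge_and_grad(w, bias, X, y)
        val += lam * wts @ (a + bm)
        return val, np.concatenate([gw + lam * wts, -gw + lam * wts, [gb]])

    bounds = [(0, None)] * (2 * d) + [(None, None)]
    res = minimize(fg, np.zeros(2 * d + 1), jac=True, method="L-BFGS-B",
                   bounds=bounds,
                   options={"maxiter": 40000, "ftol": 1e-16, "gtol": 1e-12})
    return res.fun


def _min_group_pattern(X, y, lam, groups, beta, q, zero_groups):
    """Minimize with the groups in ``zero_groups`` pinned at zero.

    Away from group origins the lq penalty is smooth, so L-BFGS on the free
    coordinates (from a few starts) finds the restricted minimum.
    """
    free_idx = np.concatenate(
        [g for i, g in enumerate(groups.groups) if i not in zero_groups]
        or [np.array([], dtype=int)]
    )
    d = X.shape[1]

    def obj(z):
        w = np.zeros(d)
        w[free_idx] = z[:-1]
        val, _, _ = _sqhinge_and_grad(w, z[-1], X, y)
        for i, g in enumerate(groups.groups):
            if i not in zero_groups:
                val += lam * beta[i] * np.linalg.norm(w[g], ord=q)
        return val

    if free_idx.size == 0:
        # bias-only problem, 1-D smooth
        res = minimize(lambda z: obj(z), np.zeros(1), method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-15, "maxiter": 5000})
        return res.fun

    def obj_grad(z):
        w = np.zeros(d)
        w[free_idx] = z[:-1]
        val, gw, gb = _sqhinge_and_grad(w, z[-1], X, y)
        grad_w = gw.copy()
        for i, g in enumerate(groups.groups):
            if i in zero_groups:
                continue
            norm_q = np.linalg.norm(w[g], ord=q)
            val += lam * beta[i] * norm_q
            if norm_q > 0:
                grad_w[g] += (lam * beta[i] * np.sign(w[g])
                              * np.abs(w[g]) ** (q - 1.0) / norm_q ** (q - 1.0))
        return val, np.concatenate([grad_w[free_idx], [gb]])

    best = np.inf
    rng = np.random.default_rng(0)
    for start in (np.zeros(free_idx.size + 1),
                  0.01 * rng.standard_normal(free_idx.size + 1),
                  0.3 * rng.standard_normal(free_idx.size + 1)):
        res = minimize(obj_grad, start, jac=True, method="L-BFGS-B",
                       options={"maxiter": 20000, "ftol": 1e-16, "gtol": 1e-12})
        # short derivative-free polish guards against kink trouble
        res2 = minimize(obj, res.x, method="Nelder-Mead",
                        options={"xatol": 1e-10, "fatol": 1e-14,
                                 "maxiter": 4000, "maxfev": 4000})
        best = min(best, res.fun, res2.fun)
    return best


def min_objective(trials: TrialSet, spec: RegularizerSpec,
                  groups: GroupStructure | None = None) -> float:
    """Reference minimum of Σ squared-hinge + λΩ, independent of FBS."""
    X, y = trials.features, trials.labels.astype(float)
    lam = spec.lam
    if spec.kind == "l2":
        return _min_l2(X, y, lam)
    if spec.kind == "l1":
        return _min_l1(X, y, lam)
    beta = spec.group_weights(groups.n_groups)
    if spec.q == 1.0:
        wts = np.empty(X.shape[1])
        for g, idx in enumerate(groups.groups):
            wts[idx] = beta[g]
        return _min_l1(X, y, lam, feature_weights=wts)
    p = groups.n_groups
    always_zero = set(spec.frozen)
    free_groups = [g for g in range(p) if g not in always_zero]
    best = np.inf
    for k in range(len(free_groups) + 1):
        for combo in itertools.combinations(free_groups, k):
            zero = always_zero | set(combo)
            best = min(best, _min_group_pattern(X, y, lam, groups, beta,
                                                spec.q, zero))
    return best


def min_mtl_objective(tasks, lam_r, lam_s, groups: GroupStructure) -> float:
    """Reference minimum of the stacked multitask objective by pattern
    enumeration + smooth minimization over free blocks and biases."""
    m = len(tasks)
    d = tasks[0].d
    p = groups.n_groups

    def obj_full(W, biases):
        val = 0.0
        for t, tr in enumerate(tasks):
            val += squared_hinge_value(LinearModel(W[:, t], biases[t]), tr)
        centered = W - W.mean(axis=1, keepdims=True)
        val += lam_s * np.sum(centered**2)
        for idx in groups.groups:
            val += lam_r * np.linalg.norm(W[idx, :])
        return val

    best = np.inf
    for k in range(p + 1):
        for combo in itertools.combinations(range(p), k):
            zero = set(combo)
            free_idx = np.concatenate(
                [g for i, g in enumerate(groups.groups) if i not in zero]
                or [np.array([], dtype=int)]
            )
            nf = free_idx.size

            def obj(z):
                W = np.zeros((d, m))
                W[free_idx, :] = z[: nf * m].reshape(nf, m)
                return obj_full(W, z[nf * m :])

            res = minimize(obj, np.zeros(nf * m + m), method="Nelder-Mead",
                           options={"xatol": 1e-9, "fatol": 1e-13,
                                    "maxiter": 200000, "maxfev": 200000})
            res2 = minimize(obj, res.x, method="L-BFGS-B",
                            options={"maxiter": 20000, "ftol": 1e-16})
            best = min(best, res.fun, res2.fun)
    return best


# ---------------------------------------------------------------------------
# metric oracles


def pair_counting_auc(scores, labels) -> float:
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == -1]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (pos.size * neg.size)


def exhaustive_wilcoxon(diffs, alternative="two-sided") -> float:
    """Enumerate all 2^n sign assignments of the nonzero pairs (Pratt)."""
    d = np.asarray(diffs, float)
    if np.all(d == 0):
        return 1.0
    ranks = rankdata(np.abs(d))
    r = ranks[d != 0]
    w_obs = r[d[d != 0] > 0].sum()
    n = r.size
    stats = []
    for bits in itertools.product((0, 1), repeat=n):
        stats.append(float(np.dot(bits, r)))
    stats = np.array(stats)
    eps = 1e-9
    p_le = np.mean(stats <= w_obs + eps)
    p_ge = np.mean(stats >= w_obs - eps)
    if alternative == "greater":
        return min(1.0, p_ge)
    return min(1.0, 2.0 * min(p_le, p_ge))


# ---------------------------------------------------------------------------
# misc helpers


def finite_difference_gradient(f, x, h=1e-6):
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h
        g[i] = (f(x + e) - f(x - e)) / (2 * h)
    return g


def random_trials(rng, n=12, p=3, r=2, separation=1.0) -> TrialSet:
    d = p * r
    y = np.where(rng.random(n) < 0.5, 1, -1)
    if np.all(y == y[0]):
        y[0] = -y[0]
    X = rng.standard_normal((n, d)) + separation * np.outer(y, rng.standard_normal(d) / np.sqrt(d))
    return TrialSet(X, y, p, r)
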