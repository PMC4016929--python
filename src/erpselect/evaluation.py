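"""Evaluation protocol: AUC, selection metrics, nested CV, and the benchmark.

The protocol mirrors standard single-trial ERP decoding practice:

* performance is the area under the ROC curve (AUC), the probability that a
  positive trial outscores a negative one (Mann–Whitney pair counting with
  ties worth 1/2);
* selection quality against a known truth set C* uses the F-measure
  2|C ∩ C*| / (|C| + |C*|) and the selection rate 100|C|/p;
* λ (and, for GSVM-q, the inner exponent q) are chosen by a nested
  stratified 3-fold cross-validation maximizing mean validation AUC over a
  13-point log-spaced grid λ ∈ [1e-3, 1e1];
* the benchmark repeats {stratified split → nested CV → test AUC +
  selection metrics} over several runs and compares methods to the ℓ2
  baseline with a Wilcoxon signed-rank test (Pratt treatment of zeros,
  exact null for few pairs).

λ scale: the training objective sums the loss over trials, so a grid value
λ is interpreted per-trial and multiplied by the number of fitted trials
(``lambda_scale="n"``, the default).  This keeps one grid meaningful across
fold sizes; pass ``lambda_scale="none"`` to use grid values literally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold, train_test_split

from erpselect.core_model import (
    GroupStructure,
    TrialSet,
    decision_values,
)
from erpselect.regularizers import RegularizerSpec, adaptive_weights
from erpselect.solver import (
    FitResult,
    SolverOptions,
    fit_single_task,
    selected_channels,
)

__all__ = [
    "SelectionResult",
    "BenchmarkReport",
    "auc",
    "f_measure",
    "selection_rate",
    "nested_cv_select",
    "mtl_cv_select",
    "wilcoxon_signed_rank",
    "run_benchmark",
    "DEFAULT_LAMBDA_GRID",
    "DEFAULT_Q_GRID",
]

#: 13 log-spaced points on [1e-3, 1e1].
DEFAULT_LAMBDA_GRID = np.logspace(-3.0, 1.0, 13)

#: Candidate inner exponents for GSVM-q.
DEFAULT_Q_GRID = (1.0, 1.2, 1.4, 1.6, 1.8, 2.0)

#: Canonical method identifiers.
METHOD_IDS = ("svm", "svm-1", "gsvm-1", "gsvm-2", "gsvm-q", "gsvm-a")


# ---------------------------------------------------------------------------
# metrics


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann–Whitney AUC: P(score+ > score−) + ½ P(score+ = score−)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == -1
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class SelectionResult:
    """Selected sensor set C and (optionally) the true relevant set C*."""

    selected: set[int]
    truth: set[int] | None = None


def f_measure(sel: SelectionResult) -> float:
    """2|C ∩ C*| / (|C| + |C*|) — 1 iff the selection equals the truth."""
    if sel.truth is None or len(sel.truth) == 0:
        raise ValueError("F-measure needs a nonempty truth set")
    c, cstar = set(sel.selected), set(sel.truth)
    denom = len(c) + len(cstar)
    return 2.0 * len(c & cstar) / denom


def selection_rate(sel: SelectionResult, p: int) -> float:
    """Percentage of the p sensors that were selected."""
    if p < 1:
        raise ValueError("p must be >= 1")
    return 100.0 * len(sel.selected) / p


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank (Pratt zeros, exact null for small n)

EXACT_WILCOXON_MAX_N = 25


def wilcoxon_signed_rank(
    diffs: np.ndarray, alternative: str = "two-sided"
) -> float:
    """Signed-rank p-value with the tie-inclusive (Pratt) zero treatment.

    Zero differences are ranked together with the rest (average ranks of
    |d|) and then dropped from the statistic.  For at most 25 nonzero pairs
    the null distribution of W+ is computed exactly by enumerating the 2^n
    equally likely sign assignments (via a dynamic program over the ranks);
    beyond that a normal approximation with zero and tie corrections is
    used.  ``alternative`` is "two-sided" or "greater" (W+ larger than
    expected, i.e. positive shift).
    """
    d = np.asarray(diffs, dtype=np.float64)
    if d.size < 1:
        raise ValueError("need at least one pair")
    if np.all(d == 0):
        return 1.0
    ranks = rankdata(np.abs(d))
    nonzero = d != 0
    r = ranks[nonzero]
    w_plus = float(r[d[nonzero] > 0].sum())

    if r.size <= EXACT_WILCOXON_MAX_N:
        # doubled ranks are integers even with average-rank ties
        r2 = np.rint(2 * r).astype(int)
        total = int(r2.sum())
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for rank in r2:
            shifted = np.zeros_like(counts)
            shifted[rank:] = counts[: counts.size - rank]
            counts = counts + shifted
        counts /= counts.sum()
        w2 = int(np.rint(2 * w_plus))
        p_le = counts[: w2 + 1].sum()
        p_ge = counts[w2:].sum()
    else:
        n_all, n_zero = d.size, int(d.size - r.size)
        mean = (n_all * (n_all + 1) - n_zero * (n_zero + 1)) / 4.0
        var = (
            n_all * (n_all + 1) * (2 * n_all + 1)
            - n_zero * (n_zero + 1) * (2 * n_zero + 1)
        ) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts**3 - tie_counts).sum() / 48.0
        from scipy.stats import norm

        z_le = (w_plus - mean) / np.sqrt(var)
        p_le = float(norm.cdf(z_le))
        p_ge = float(norm.sf(z_le))

    if alternative == "greater":
        return float(min(1.0, p_ge))
    if alternative == "two-sided":
        return float(min(1.0, 2.0 * min(p_le, p_ge)))
    raise ValueError(f"unknown alternative {alternative!r}")


# ---------------------------------------------------------------------------
# nested cross-validation


def _spec_for(method: str, lam: float, q: float = 2.0) -> RegularizerSpec:
    method = method.lower()
    if method == "svm":
        return RegularizerSpec("l2", lam)
    if method in ("svm-1", "gsvm-1"):
        return RegularizerSpec("l1", lam)
    if method in ("gsvm-2", "gsvm-q"):
        return RegularizerSpec("group_lq", lam, q=q if method == "gsvm-q" else 2.0)
    raise ValueError(f"unknown method {method!r}")


def _effective_lam(lam: float, n: int, lambda_scale: str) -> float:
    if lambda_scale == "n":
        return lam * n
    if lambda_scale == "none":
        return lam
    raise ValueError(f"unknown lambda_scale {lambda_scale!r}")


def _cv_mean_auc_path(
    train: TrialSet,
    method: str,
    lam_grid: np.ndarray,
    q: float,
    folds: int,
    seed: int,
    opts: SolverOptions,
    lambda_scale: str,
    groups: GroupStructure,
    beta: np.ndarray | None = None,
    frozen: frozenset = frozenset(),
) -> np.ndarray:
    """Mean validation AUC per λ, warm-starting along the descending path."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    order = np.argsort(lam_grid)[::-1]  # strongest regularization first
    aucs = np.zeros(lam_grid.size)
    for tr_idx, va_idx in skf.split(train.features, train.labels):
        sub, val = train.subset(tr_idx), train.subset(va_idx)
        if not (sub.has_both_classes() and val.has_both_classes()):
            raise ValueError("degenerate fold: a class is missing")
        start = None
        for j in order:
            spec = _spec_for(method, _effective_lam(lam_grid[j], sub.n, lambda_scale), q)
            if beta is not None or frozen:
                spec = RegularizerSpec(
                    spec.kind, spec.lam, q=spec.q, beta=beta, frozen=frozen
                )
            res = fit_single_task(sub, spec, groups, opts, start=start)
            start = res.model
            aucs[j] += auc(decision_values(res.model, val), val.labels)
    return aucs / folds


def _pick_best(
    lam_grid: np.ndarray, q_grid: tuple, scores: np.ndarray
) -> tuple[float, float]:
    """Ties broken toward smaller λ, then smaller q. scores is (n_q, n_lam)."""
    best = (-np.inf, np.inf, np.inf)
    for iq, q in enumerate(q_grid):
        for il, lam in enumerate(lam_grid):
            cand = (scores[iq, il], -lam, -q)
            if cand > best:
                best = cand
                best_lq = (float(lam), float(q))
    return best_lq


def nested_cv_select(
    train: TrialSet,
    method: str,
    lam_grid: np.ndarray | None = None,
    q_grid: tuple | None = None,
    folds: int = 3,
    seed: int = 0,
    opts: SolverOptions | None = None,
    refit_opts: SolverOptions | None = None,
    lambda_scale: str = "n",
) -> tuple[dict, FitResult]:
    """Select hyperparameters by stratified k-fold CV and refit on all data.

    Returns ``(best, result)`` where ``best`` records the chosen λ (and q,
    and for ``gsvm-a`` the first-stage λ) and ``result`` is the refit on the
    full training set.  For ``gsvm-a`` the two stages each get their own CV:
    first the plain ℓ1–ℓ2 model is tuned and refit, its solution defines
    the adaptive weights β_g = 1/||w*_g||₂ (sub-floor groups frozen), and
    then λ of the weighted refit is tuned on the same folds.
    """
    if lam_grid is None:
        lam_grid = DEFAULT_LAMBDA_GRID
    lam_grid = np.asarray(lam_grid, dtype=np.float64)
    if opts is None:
        opts = SolverOptions(max_iter=2000, rel_tol=1e-7)
    if refit_opts is None:
        refit_opts = SolverOptions(max_iter=4000, rel_tol=1e-8)
    method = method.lower()
    if method not in METHOD_IDS:
        raise ValueError(f"unknown method {method!r}")
    groups = GroupStructure.for_trials(train)

    if method == "gsvm-a":
        best1, stage1 = nested_cv_select(
            train, "gsvm-2", lam_grid, None, folds, seed, opts, refit_opts,
            lambda_scale,
        )
        beta, frozen = adaptive_weights(stage1.model.w, 2.0, groups)
        aucs = _cv_mean_auc_path(
            train, "gsvm-2", lam_grid, 2.0, folds, seed, opts, lambda_scale,
            groups, beta=beta, frozen=frozen,
        )
        lam, q = _pick_best(lam_grid, (2.0,), aucs[None, :])
        spec = RegularizerSpec(
            "group_lq",
            _effective_lam(lam, train.n, lambda_scale),
            q=2.0,
            beta=beta,
            frozen=frozen,
        )
        result = fit_single_task(train, spec, groups, refit_opts, start=stage1.model)
        result.extras["stage1"] = stage1
        best = {"lam": lam, "q": 2.0, "stage1_lam": best1["lam"]}
        return best, result

    qs = q_grid if q_grid is not None else (
        DEFAULT_Q_GRID if method == "gsvm-q" else (2.0,)
    )
    scores = np.stack(
        [
            _cv_mean_auc_path(
                train, method, lam_grid, q, folds, seed, opts, lambda_scale, groups
            )
            for q in qs
        ]
    )
    lam, q = _pick_best(lam_grid, tuple(qs), scores)
    spec = _spec_for(method, _effective_lam(lam, train.n, lambda_scale), q)
    result = fit_single_task(train, spec, groups, refit_opts)
    return {"lam": lam, "q": q}, result


def mtl_cv_select(
    tasks: list[TrialSet],
    lam_r_grid: np.ndarray,
    lam_s_grid: np.ndarray,
    folds: int = 3,
    seed: int = 0,
    opts: SolverOptions | None = None,
    lambda_scale: str = "n",
):
    """Choose (λ_r, λ_s) for the multitask fit by stratified k-fold CV.

    The grid point maximizing the mean validation AUC across tasks and
    folds wins (ties toward smaller λ_r then smaller λ_s); the model is
    refit on the full per-task training sets.  λ values are per-trial and
    scaled by the summed task sizes under ``lambda_scale="n"``.
    """
    from erpselect.multitask import MultiTaskData, fit_multitask

    if opts is None:
        opts = SolverOptions(max_iter=1500, rel_tol=1e-6)
    lam_r_grid = np.asarray(lam_r_grid, dtype=np.float64)
    lam_s_grid = np.asarray(lam_s_grid, dtype=np.float64)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_splits = [
        list(skf.split(t.features, t.labels)) for t in tasks
    ]
    n_total = sum(t.n for t in tasks)
    scores = np.zeros((lam_r_grid.size, lam_s_grid.size))
    for f in range(folds):
        subs = [t.subset(fold_splits[i][f][0]) for i, t in enumerate(tasks)]
        vals = [t.subset(fold_splits[i][f][1]) for i, t in enumerate(tasks)]
        data = MultiTaskData(subs)
        n_sub = sum(s.n for s in subs)
        for ir, lam_r in enumerate(lam_r_grid):
            for is_, lam_s in enumerate(lam_s_grid):
                model, _ = fit_multitask(
                    data,
                    _effective_lam(lam_r, n_sub, lambda_scale),
                    _effective_lam(lam_s, n_sub, lambda_scale),
                    opts,
                )
                scores[ir, is_] += np.mean(
                    [
                        auc(decision_values(model.task_model(t), vals[t]),
                            vals[t].labels)
                        for t in range(len(tasks))
                    ]
                )
    best = (-np.inf, np.inf, np.inf)
    for ir, lam_r in enumerate(lam_r_grid):
        for is_, lam_s in enumerate(lam_s_grid):
            cand = (scores[ir, is_], -lam_r, -lam_s)
            if cand > best:
                best = cand
                best_rs = (float(lam_r), float(lam_s))
    lam_r, lam_s = best_rs
    model, result = fit_multitask(
        MultiTaskData(tasks),
        _effective_lam(lam_r, n_total, lambda_scale),
        _effective_lam(lam_s, n_total, lambda_scale),
        opts,
    )
    return {"lam_r": lam_r, "lam_s": lam_s}, model, result


# ---------------------------------------------------------------------------
# benchmark


@dataclass
class BenchmarkReport:
    """Per-run metrics, per-method means, and Wilcoxon p-values vs baseline."""

    per_run: pd.DataFrame
    summary: pd.DataFrame
    p_values: dict[str, float]
    baseline: str

    def to_csv(self, path: str | Path) -> None:
        self.per_run.to_csv(Path(path), index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "baseline": self.baseline,
            "summary": self.summary.reset_index().to_dict(orient="records"),
            "p_values": self.p_values,
            "per_run": self.per_run.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def run_benchmark(
    dataset: TrialSet,
    truth: set[int] | None,
    methods: list[str],
    n_runs: int = 10,
    n_train: int = 1000,
    seed: int = 0,
    lam_grid: np.ndarray | None = None,
    folds: int = 3,
    opts: SolverOptions | None = None,
    refit_opts: SolverOptions | None = None,
    lambda_scale: str = "n",
    baseline: str = "svm",
) -> BenchmarkReport:
    """Repeated {stratified split → nested CV → test metrics} benchmark.

    Each run draws a stratified random split of ``n_train`` training trials
    (the rest is the test set), tunes every method by nested CV on the
    training part, and scores test AUC plus — when ``truth`` is given —
    the selection rate and F-measure of the selected sensors.  Means over
    runs and paired Wilcoxon p-values against ``baseline`` (when it is
    among the methods) are reported.
    """
    if dataset.n <= n_train:
        raise ValueError("dataset must exceed n_train so a test set remains")
    groups = GroupStructure.for_trials(dataset)
    rows = []
    for run in range(n_runs):
        run_seed = seed + 1000 * run
        idx = np.arange(dataset.n)
        tr_idx, te_idx = train_test_split(
            idx,
            train_size=n_train,
            stratify=dataset.labels,
            random_state=run_seed % (2**31),
        )
        train, test = dataset.subset(tr_idx), dataset.subset(te_idx)
        for method in methods:
            best, result = nested_cv_select(
                train,
                method,
                lam_grid=lam_grid,
                folds=folds,
                seed=run_seed % (2**31),
                opts=opts,
                refit_opts=refit_opts,
                lambda_scale=lambda_scale,
            )
            test_auc = auc(decision_values(result.model, test), test.labels)
            chans = selected_channels(result.model, groups)
            sel = SelectionResult(chans, truth)
            row = {
                "run": run,
                "method": method,
                "auc": test_auc,
                "n_selected": len(chans),
                "selection_rate": selection_rate(sel, groups.n_groups),
                "lam": best["lam"],
                "q": best.get("q", np.nan),
            }
            if truth is not None:
                row["f_measure"] = f_measure(sel)
            rows.append(row)
    per_run = pd.DataFrame(rows)
    metric_cols = [
        c for c in ("auc", "selection_rate", "f_measure") if c in per_run
    ]
    summary = per_run.groupby("method")[metric_cols].mean()
    p_values = {}
    if baseline in methods:
        base_auc = per_run[per_run.method == baseline].sort_values("run")["auc"]
        for method in methods:
            if method == baseline:
                continue
            m_auc = per_run[per_run.method == method].sort_values("run")["auc"]
            p_values[method] = wilcoxon_signed_rank(
                m_auc.to_numpy() - base_auc.to_numpy()
            )
    return BenchmarkReport(per_run, summary, p_values, baseline)
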