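"""Simulated P300 dataset with known ground-truth discriminative sensors.

The generator emulates an oddball-style ERP decoding problem: ``p`` sensors
each contribute ``r`` time features; on positive (target) trials a fixed
P300-like waveform is added to the feature blocks of ``k`` designated
discriminative sensors; negative trials carry no evoked component; i.i.d.
Gaussian noise of standard deviation ``noise_sd`` is added to every feature
of every trial.  Defaults: 11000 trials, 16 sensors, 8 discriminative,
8 features per sensor, noise sd 0.2, 1000 trials for training.

The waveform is a parametric biphasic template (small early negative
deflection, dominant late positive peak — the P300), normalized so its
largest absolute value equals the amplitude ``a``.  The default amplitude
was fixed once by ``calibrate_amplitude``: the smallest value on a coarse
grid for which a baseline ℓ2 classifier reaches a test AUC in [0.75, 0.85]
under the default noise, i.e. a realistically hard single-trial regime.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from erpselect.core_model import TrialSet
from erpselect.multitask import MultiTaskData

__all__ = [
    "SimulationConfig",
    "p300_template",
    "generate_simulated_p300",
    "generate_multitask_p300",
    "calibrate_amplitude",
    "DEFAULT_AMPLITUDE",
]

#: Template amplitude frozen by the one-time AUC calibration (see module doc).
DEFAULT_AMPLITUDE = 0.06


@dataclass
class SimulationConfig:
    """Parameters of the simulated P300 dataset."""

    n_trials: int = 11000
    n_train: int = 1000
    p: int = 16
    r: int = 8
    k: int = 8
    noise_sd: float = 0.2
    amplitude: float = DEFAULT_AMPLITUDE
    pos_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k > self.p:
            raise ValueError("k discriminative sensors cannot exceed p")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not self.n_train < self.n_trials:
            raise ValueError("n_train must be smaller than n_trials")
        if not 0.0 < self.pos_fraction < 1.0:
            raise ValueError("pos_fraction must be in (0, 1)")


def p300_template(r: int, a: float) -> np.ndarray:
    """Deterministic biphasic ERP waveform of length r, max |value| = a.

    A small negative deflection (around 30% of the window) precedes a
    dominant positive peak (around 65%), mimicking the N200–P300 complex on
    a coarse post-stimulus time grid.
    """
    if r < 4:
        raise ValueError("template needs at least 4 samples")
    t = (np.arange(r) + 0.5) / r
    wave = np.exp(-((t - 0.65) ** 2) / (2 * 0.12**2)) - 0.4 * np.exp(
        -((t - 0.30) ** 2) / (2 * 0.08**2)
    )
    peak = np.max(np.abs(wave))
    return a * wave / peak


def _stratified_split(
    labels: np.ndarray, n_train: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Class-proportional random train/test index split."""
    train_parts = []
    frac = n_train / labels.size
    for cls in (-1, 1):
        cls_idx = np.flatnonzero(labels == cls)
        n_cls = int(round(frac * cls_idx.size))
        train_parts.append(rng.permutation(cls_idx)[:n_cls])
    train_idx = np.sort(np.concatenate(train_parts))
    mask = np.ones(labels.size, dtype=bool)
    mask[train_idx] = False
    return train_idx, np.flatnonzero(mask)


def generate_simulated_p300(
    cfg: SimulationConfig,
) -> tuple[TrialSet, set[int], tuple[np.ndarray, np.ndarray]]:
    """Draw the simulated dataset; deterministic given ``cfg.seed``.

    Returns the trial set, the set of truly discriminative sensor ids, and
    a stratified (train_idx, test_idx) split of size ``cfg.n_train``.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = np.sort(rng.choice(cfg.p, size=cfg.k, replace=False))
    labels = np.where(rng.random(cfg.n_trials) < cfg.pos_fraction, 1, -1)
    # guarantee both classes even at tiny n
    if np.all(labels == labels[0]):
        labels[0] = -labels[0]
    d = cfg.p * cfg.r
    X = np.zeros((cfg.n_trials, d))
    template = p300_template(cfg.r, cfg.amplitude)
    pos = labels == 1
    for g in truth:
        X[pos, g * cfg.r : (g + 1) * cfg.r] += template
    X += rng.normal(0.0, cfg.noise_sd, size=(cfg.n_trials, d))
    trials = TrialSet(X, labels, cfg.p, cfg.r)
    split = _stratified_split(labels, cfg.n_train, rng)
    return trials, {int(g) for g in truth}, split


def generate_multitask_p300(
    m: int,
    cfg: SimulationConfig,
    amp_jitter_sd: float = 0.0,
    n_swap: int = 0,
) -> tuple[MultiTaskData, list[set[int]], list[tuple[np.ndarray, np.ndarray]]]:
    """Per-subject variants of the simulated dataset for multitask fitting.

    Each of the ``m`` tasks is drawn as ``generate_simulated_p300`` with a
    per-task template amplitude ``a_t = a (1 + ε_t)``, ``ε_t ~ N(0,
    amp_jitter_sd)`` (clipped at −0.9), and with ``n_swap`` of the true
    sensors replaced by task-specific ones — so cross-subject similarity of
    both amplitude and topography is tunable.  ``n_swap = 0`` gives a truth
    set shared by all tasks.
    """
    if m < 2:
        raise ValueError("need at least two tasks")
    if n_swap > cfg.k:
        raise ValueError("cannot swap more sensors than are discriminative")
    rng = np.random.default_rng(cfg.seed)
    base_truth = np.sort(rng.choice(cfg.p, size=cfg.k, replace=False))
    tasks, truths, splits, amps = [], [], [], []
    for t in range(m):
        a_t = cfg.amplitude * max(0.1, 1.0 + rng.normal(0.0, amp_jitter_sd))
        truth_t = base_truth.copy()
        if n_swap > 0:
            outside = np.setdiff1d(np.arange(cfg.p), base_truth)
            swap_in = rng.choice(outside, size=n_swap, replace=False)
            swap_out = rng.choice(cfg.k, size=n_swap, replace=False)
            truth_t[swap_out] = swap_in
        cfg_t = replace(cfg, amplitude=a_t, seed=int(cfg.seed + 7919 * (t + 1)))
        # regenerate with the task's own seed but impose this task's truth
        rng_t = np.random.default_rng(cfg_t.seed)
        labels = np.where(rng_t.random(cfg.n_trials) < cfg.pos_fraction, 1, -1)
        if np.all(labels == labels[0]):
            labels[0] = -labels[0]
        d = cfg.p * cfg.r
        X = np.zeros((cfg.n_trials, d))
        template = p300_template(cfg.r, a_t)
        pos = labels == 1
        for g in truth_t:
            X[pos, g * cfg.r : (g + 1) * cfg.r] += template
        X += rng_t.normal(0.0, cfg.noise_sd, size=(cfg.n_trials, d))
        tasks.append(TrialSet(X, labels, cfg.p, cfg.r))
        truths.append({int(g) for g in truth_t})
        splits.append(_stratified_split(labels, cfg.n_train, rng_t))
        amps.append(a_t)
    data = MultiTaskData(tasks)
    data.amplitudes = np.array(amps)  # realized per-task amplitudes
    return data, truths, splits


def calibrate_amplitude(
    grid: np.ndarray | None = None,
    band: tuple[float, float] = (0.75, 0.85),
    cfg: SimulationConfig | None = None,
    seed: int = 0,
) -> float:
    """Smallest grid amplitude whose baseline ℓ2 test AUC falls in ``band``.

    One-time routine used to fix ``DEFAULT_AMPLITUDE``; the baseline is an
    ℓ2 (no selection) classifier tuned by the package's nested CV on the
    standard 1000-trial training split and scored on the held-out trials.

    Raises
    ------
    ValueError
        If no grid amplitude lands in the band.
    """
    from erpselect.evaluation import auc, nested_cv_select
    from erpselect.core_model import decision_values

    if grid is None:
        grid = np.round(np.arange(0.02, 0.17, 0.01), 3)
    if cfg is None:
        cfg = SimulationConfig(seed=seed)
    for a in np.sort(np.asarray(grid, dtype=float)):
        trials, _, (tr, te) = generate_simulated_p300(replace(cfg, amplitude=float(a)))
        train, test = trials.subset(tr), trials.subset(te)
        _, result = nested_cv_select(train, "svm", seed=seed)
        score = auc(decision_values(result.model, test), test.labels)
        if band[0] <= score <= band[1]:
            return float(a)
    raise ValueError("no amplitude on the grid reaches the target AUC band")
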