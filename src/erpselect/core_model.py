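"""Trial containers, sensor-group layout, and the squared-hinge data term.

A *trial* is one stimulus-locked EEG epoch flattened to a feature vector of
dimension ``d = p * r`` (``p`` sensors, ``r`` time features per sensor,
channel-major: the ``r`` features of sensor ``g`` are contiguous).  The data
term of every estimator in this package is the squared hinge loss

    f1(w, b) = sum_i max(0, 1 - y_i (x_i . w + b))**2

summed (not averaged) over trials.  ``f1`` is convex and gradient-Lipschitz;
``lipschitz_constant`` returns the bound ``2 * sum_i ||x_i||^2`` computed on
the bias-augmented representation (a constant-1 coordinate appended to each
trial) so a single constant covers joint descent on ``(w, b)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TrialSet",
    "GroupStructure",
    "LinearModel",
    "decision_values",
    "squared_hinge_value",
    "squared_hinge_gradient",
    "lipschitz_constant",
]


@dataclass
class TrialSet:
    """Labeled single-trial feature matrix with sensor layout metadata.

    Parameters
    ----------
    features : ndarray of shape (n, d)
        One row per trial.  Channel-major layout: columns
        ``[g*r, (g+1)*r)`` belong to sensor ``g``.
    labels : ndarray of shape (n,)
        Class labels in {-1, +1} (presence/absence of the target ERP).
    n_sensors : int
        Number of sensors ``p``.
    n_features_per_sensor : int
        Time features per sensor ``r``; ``d`` must equal ``p * r``.
    """

    features: np.ndarray
    labels: np.ndarray
    n_sensors: int
    n_features_per_sensor: int

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D (n_trials, d) array")
        if self.labels.shape != (self.features.shape[0],):
            raise ValueError(
                f"labels shape {self.labels.shape} does not match "
                f"{self.features.shape[0]} trials"
            )
        if not np.all(np.isin(self.labels, (-1, 1))):
            raise ValueError("labels must all be -1 or +1")
        self.labels = self.labels.astype(np.int8)
        d = self.features.shape[1]
        if d != self.n_sensors * self.n_features_per_sensor:
            raise ValueError(
                f"d={d} != p*r={self.n_sensors}*{self.n_features_per_sensor}"
            )
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain non-finite values")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]

    def subset(self, idx: np.ndarray) -> "TrialSet":
        """Return the trials indexed by ``idx`` as a new TrialSet."""
        return TrialSet(
            self.features[idx],
            self.labels[idx],
            self.n_sensors,
            self.n_features_per_sensor,
        )

    def has_both_classes(self) -> bool:
        return bool(np.any(self.labels == 1) and np.any(self.labels == -1))

    # ---- I/O -------------------------------------------------------------
    # CSV: one row per trial, feature columns then a final "label" column.
    # Parquet: same table in a columnar binary container.  Either format is
    # accompanied by a JSON sidecar (<path>.json) carrying p, r and layout.

    def _frame(self) -> pd.DataFrame:
        cols = [f"f{i}" for i in range(self.d)]
        df = pd.DataFrame(self.features, columns=cols)
        df["label"] = self.labels.astype(int)
        return df

    def _sidecar(self) -> dict:
        return {
            "n_sensors": self.n_sensors,
            "n_features_per_sensor": self.n_features_per_sensor,
            "layout": "channel-major",
        }

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self._frame().to_csv(path, index=False)
        _write_sidecar(path, self._sidecar())

    def to_parquet(self, path: str | Path) -> None:
        path = Path(path)
        self._frame().to_parquet(path, index=False)
        _write_sidecar(path, self._sidecar())

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrialSet":
        return cls._from_frame(pd.read_csv(Path(path)), _read_sidecar(path))

    @classmethod
    def from_parquet(cls, path: str | Path) -> "TrialSet":
        return cls._from_frame(pd.read_parquet(Path(path)), _read_sidecar(path))

    @classmethod
    def _from_frame(cls, df: pd.DataFrame, meta: dict) -> "TrialSet":
        labels = df["label"].to_numpy()
        feats = df.drop(columns="label").to_numpy(dtype=np.float64)
        return cls(feats, labels, meta["n_sensors"], meta["n_features_per_sensor"])


def _write_sidecar(path: Path, meta: dict) -> None:
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def _read_sidecar(path: str | Path) -> dict:
    return json.loads(Path(str(path) + ".json").read_text())


@dataclass
class GroupStructure:
    """Partition of feature indices {0, ..., d-1} into sensor groups."""

    groups: list[np.ndarray]

    def __post_init__(self) -> None:
        self.groups = [np.asarray(g, dtype=np.intp) for g in self.groups]
        all_idx = np.concatenate(self.groups) if self.groups else np.array([], int)
        d = all_idx.size
        if d == 0:
            raise ValueError("group structure must be non-empty")
        if np.unique(all_idx).size != d or all_idx.min() != 0 or all_idx.max() != d - 1:
            raise ValueError("groups must disjointly cover {0, ..., d-1}")

    @classmethod
    def contiguous(cls, p: int, r: int) -> "GroupStructure":
        """Channel-major layout: sensor g owns indices [g*r, (g+1)*r)."""
        return cls([np.arange(g * r, (g + 1) * r) for g in range(p)])

    @classmethod
    def for_trials(cls, trials: TrialSet) -> "GroupStructure":
        return cls.contiguous(trials.n_sensors, trials.n_features_per_sensor)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_features(self) -> int:
        return sum(g.size for g in self.groups)

    def group_norms(self, w: np.ndarray, q: float = 2.0) -> np.ndarray:
        """Per-group lq norms ||w_g||_q, g = 0..p-1."""
        w = np.asarray(w, dtype=np.float64)
        return np.array(
            [np.linalg.norm(w[g], ord=q if q != 2.0 else 2) for g in self.groups]
        )


@dataclass
class LinearModel:
    """Linear decision function f(x) = x.w + b."""

    w: np.ndarray
    b: float = 0.0

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.float64).ravel()
        self.b = float(self.b)
        if not (np.all(np.isfinite(self.w)) and np.isfinite(self.b)):
            raise ValueError("model parameters must be finite")

    @property
    def d(self) -> int:
        return self.w.size

    def group_norm(self, groups: GroupStructure, g: int, q: float = 2.0) -> float:
        return float(np.linalg.norm(self.w[groups.groups[g]], ord=q))

    def to_dict(self) -> dict:
        return {"w": self.w.tolist(), "b": self.b}


def decision_values(model: LinearModel, trials: TrialSet) -> np.ndarray:
    """Scores x_i.w + b; the predicted class is sign(score) with sign(0) = +1."""
    if trials.d != model.d:
        raise ValueError(f"feature dimension {trials.d} != model dimension {model.d}")
    return trials.features @ model.w + model.b


def predict_labels(model: LinearModel, trials: TrialSet) -> np.ndarray:
    s = decision_values(model, trials)
    return np.where(s >= 0, 1, -1).astype(np.int8)


def squared_hinge_value(model: LinearModel, trials: TrialSet) -> float:
    """Sum over trials of max(0, 1 - y_i * score_i)**2."""
    margins = trials.labels * decision_values(model, trials)
    return float(np.sum(np.maximum(0.0, 1.0 - margins) ** 2))


def squared_hinge_gradient(
    model: LinearModel, trials: TrialSet
) -> tuple[np.ndarray, float]:
    """Gradient of the summed squared hinge with respect to (w, b)."""
    y = trials.labels.astype(np.float64)
    margins = y * decision_values(model, trials)
    slack = np.maximum(0.0, 1.0 - margins)
    coef = -2.0 * y * slack  # d loss / d score per trial
    grad_w = trials.features.T @ coef
    grad_b = float(np.sum(coef))
    return grad_w, grad_b


def lipschitz_constant(trials: TrialSet, augment_bias: bool = True) -> float:
    """Gradient Lipschitz bound 2 * sum_i ||x_i||^2 for the squared hinge.

    With ``augment_bias`` (default) each trial is treated as carrying an
    extra constant-1 coordinate so the bound covers the joint (w, b)
    gradient used by the forward-backward solver.
    """
    if trials.n == 0:
        raise ValueError("empty trial set has no Lipschitz constant")
    sq = float(np.sum(trials.features**2))
    if augment_bias:
        sq += trials.n
    return 2.0 * sq
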