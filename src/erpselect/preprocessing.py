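"""Generic epoch-to-feature operators for user-supplied epoched EEG.

Real ERP pipelines band-pass the raw epochs (e.g. a [1, 8] Hz Butterworth of
order 3 or a [2, 20] Hz Chebyshev of order 5), downsample to a handful of
post-stimulus time samples per channel, and flatten channel-major into the
``d = p·r`` feature vector the classifiers consume.  This module provides
exactly those operators for arrays already epoched as
``(sensors, time samples, trials)``; reading vendor EEG formats (EDF/GDF) is
out of scope — bring your own array.

Filtering is zero-phase (forward-backward second-order sections), so evoked
component latencies are not shifted.  Downsampling picks ``r`` uniformly
spaced existing samples inside the requested post-stimulus window; no
interpolation is performed (the band-pass doubles as the anti-alias filter
for the bands of interest).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = ["EpochArray", "bandpass", "decimate_to_features"]


@dataclass
class EpochArray:
    """Epoched EEG: ``data`` of shape (sensors, time samples, trials)."""

    data: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be (sensors, time, trials)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contain non-finite values")

    @property
    def n_sensors(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]


def bandpass(
    epochs: EpochArray,
    low: float,
    high: float,
    order: int = 3,
    family: str = "butterworth",
) -> EpochArray:
    """Zero-phase band-pass along the time axis; shape is preserved.

    ``family`` is "butterworth" or "chebyshev" (type I, 0.5 dB passband
    ripple).  The band must lie strictly inside (0, Nyquist).
    """
    nyq = epochs.fs / 2.0
    if not 0.0 < low < high < nyq:
        raise ValueError(f"band [{low}, {high}] Hz outside (0, {nyq}) Hz")
    wn = (low / nyq, high / nyq)
    if family == "butterworth":
        sos = signal.butter(order, wn, btype="bandpass", output="sos")
    elif family == "chebyshev":
        sos = signal.cheby1(order, 0.5, wn, btype="bandpass", output="sos")
    else:
        raise ValueError(f"unknown filter family {family!r}")
    filtered = signal.sosfiltfilt(sos, epochs.data, axis=1)
    return EpochArray(filtered, epochs.fs)


def decimate_to_features(
    epochs: EpochArray,
    r: int,
    window_ms: tuple[float, float] | None = None,
) -> np.ndarray:
    """Retain r uniformly spaced samples per sensor and flatten channel-major.

    ``window_ms = (start, end)`` selects the post-stimulus window (epoch
    start = stimulus onset); default is the whole epoch.  Returns an
    ``(n_trials, p·r)`` matrix whose columns are ordered sensor by sensor,
    ready for :class:`~erpselect.core_model.TrialSet`.
    """
    if window_ms is None:
        lo_s, hi_s = 0, epochs.n_samples
    else:
        lo_s = int(round(window_ms[0] * epochs.fs / 1000.0))
        hi_s = int(round(window_ms[1] * epochs.fs / 1000.0))
        if lo_s < 0 or hi_s > epochs.n_samples or lo_s >= hi_s:
            raise ValueError("window exceeds the epoch or is empty")
    n_avail = hi_s - lo_s
    if r > n_avail:
        raise ValueError(f"cannot retain r={r} samples from a {n_avail}-sample window")
    picks = np.unique(np.round(np.linspace(lo_s, hi_s - 1, r)).astype(int))
    if picks.size < r:  # guard against rounding collisions
        picks = lo_s + np.arange(r)
    sub = epochs.data[:, picks, :]  # (p, r, n)
    return sub.transpose(2, 0, 1).reshape(epochs.n_trials, -1)
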