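"""Gold-standard heart rate from the pulse-oximeter PPG stream.

The 100 Hz PPG is brought onto the belt's 50 Hz timeline by linear
interpolation, segmented into the same 8 s windows, and systolic peaks are
located by the method of local maxima and minima: a peak counts if it rises
at least 30% of the window's (max - median) range above the median and is
separated from its neighbors by more than a 0.33 s refractory period
(<= 180 bpm).  HR follows as ``60 * Fs / Ns`` with ``Ns`` the mean
inter-peak interval in samples.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sp_signal
from sklearn.base import BaseEstimator

from .jpeak import hr_from_beats
from .preprocessing import WindowSet
from .series import BeatSequence, HRSeries

__all__ = [
    "detect_ppg_peaks",
    "hr_true",
    "estimate_ref_hr",
    "pair_windows",
    "PPGPeakDetector",
]

PROMINENCE_FRAC = 0.3
REFRACTORY_S = 0.33


def detect_ppg_peaks(
    window: np.ndarray,
    fs_hz: float = 50.0,
    prominence_frac: float = PROMINENCE_FRAC,
    refractory_s: float = REFRACTORY_S,
) -> np.ndarray:
    """Window-local systolic peak indices.

    The height threshold is median-relative, so a DC offset changes
    nothing; a flat window yields no peaks.  Minima only validate
    alternation: each accepted peak must be flanked by lower turning
    points, which strict local maxima with a refractory gap guarantee.
    """
    x = np.asarray(window, dtype=float)
    if len(x) < 3:
        return np.empty(0, dtype=np.int64)
    med = np.median(x)
    rng = np.max(x) - med
    if rng <= 0:
        return np.empty(0, dtype=np.int64)
    height = med + prominence_frac * rng
    distance = int(np.floor(refractory_s * fs_hz)) + 1
    peaks, _ = sp_signal.find_peaks(x, height=height, distance=distance)
    return peaks.astype(np.int64)


def hr_true(peak_indices: np.ndarray, fs_hz: float = 50.0) -> float:
    """HR = 60*Fs/Ns with Ns the mean inter-peak interval; NaN below 2 peaks."""
    return hr_from_beats(peak_indices, fs_hz)


def estimate_ref_hr(ws: WindowSet, fs_hz: float = 50.0, **kwargs) -> HRSeries:
    """Reference HR series over a resampled, segmented PPG WindowSet."""
    hr = np.full(len(ws), np.nan)
    n_peaks = np.zeros(len(ws), dtype=int)
    for i in range(len(ws)):
        if ws.excluded[i]:
            continue
        peaks = detect_ppg_peaks(ws.windows[i], fs_hz=fs_hz, **kwargs)
        n_peaks[i] = len(peaks)
        hr[i] = hr_true(peaks, fs_hz)
    return HRSeries(
        subject_id=ws.subject_id,
        window_index=np.arange(len(ws)),
        hr_bpm=hr,
        n_peaks=n_peaks,
        source="ppg",
        window_start_ms=ws.start_times_ms,
    )


def ppg_beat_sequence(ws: WindowSet, fs_hz: float = 50.0, **kwargs) -> BeatSequence:
    """All detected PPG peaks in recording coordinates."""
    idx = []
    for i in range(len(ws)):
        if ws.excluded[i]:
            continue
        peaks = detect_ppg_peaks(ws.windows[i], fs_hz=fs_hz, **kwargs)
        idx.append(peaks + ws.start_indices[i])
    merged = np.unique(np.concatenate(idx)) if idx else np.empty(0, dtype=np.int64)
    return BeatSequence(subject_id=ws.subject_id, peak_indices=merged, source="ppg", fs_hz=fs_hz)


def pair_windows(
    bcg_ws: WindowSet, ppg_ws: WindowSet, tolerance_ms: float = 20.0
) -> list[tuple[int, int]]:
    """Pairs (bcg_window, ppg_window) whose start times differ by < one 50 Hz sample.

    Unpaired windows take no part in evaluation.
    """
    pairs = []
    ppg_starts = np.asarray(ppg_ws.start_times_ms)
    for i, t in enumerate(bcg_ws.start_times_ms):
        j = int(np.argmin(np.abs(ppg_starts - t))) if len(ppg_starts) else -1
        if j >= 0 and abs(float(ppg_starts[j]) - float(t)) < tolerance_ms:
            pairs.append((i, j))
    return pairs


class PPGPeakDetector(BaseEstimator):
    """Per-window reference HR from resampled PPG windows (sklearn-style)."""

    def __init__(
        self,
        fs_hz: float = 50.0,
        prominence_frac: float = PROMINENCE_FRAC,
        refractory_s: float = REFRACTORY_S,
    ):
        self.fs_hz = fs_hz
        self.prominence_frac = prominence_frac
        self.refractory_s = refractory_s

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D window matrix")
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        out = np.empty(len(X))
        for i, row in enumerate(X):
            peaks = detect_ppg_peaks(
                row,
                fs_hz=self.fs_hz,
                prominence_frac=self.prominence_frac,
                refractory_s=self.refractory_s,
            )
            out[i] = hr_true(peaks, self.fs_hz)
        return out
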