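"""Algorithmic J-peak detection and per-window heart-rate estimation.

The detector enhances the ejection waves of the band-passed BCG by cubing
(sign preserved), low-pass filters the cubed signal into a coarse envelope
whose maxima mark candidate IJK complexes, scores valley-peak-valley
triplets of consecutive local extrema with weights (-1, +1, -1), suppresses
false peaks closer than the heartbeat interval, and converts the surviving
J-peaks into heart rate via the mean J-J spacing of each 8 s window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal
from sklearn.base import BaseEstimator

from .preprocessing import WindowSet, bandpass_group_delay_samples
from .series import HR_MAX_BPM, HR_MIN_BPM, BeatSequence, HRSeries

__all__ = [
    "TripletCandidate",
    "cube",
    "coarse_envelope",
    "find_extrema",
    "coarse_search_spans",
    "select_complexes",
    "suppress_false_peaks",
    "detect_window",
    "detect",
    "hr_from_beats",
    "estimate_hr",
    "JPeakHeartRateEstimator",
]

# weighted-sum weights for the valley-peak-valley triplet score
W_I = -1.0
W_J = +1.0
W_K = -1.0


@dataclass
class TripletCandidate:
    """A valley-peak-valley triplet with its weighted amplitude score."""

    i_idx: int
    j_idx: int
    k_idx: int
    score: float

    def __post_init__(self) -> None:
        if not self.i_idx < self.j_idx < self.k_idx:
            raise ValueError("triplet indices must satisfy i < j < k")


def cube(signal: np.ndarray) -> np.ndarray:
    """Elementwise cube; preserves sign while relatively enhancing large deflections."""
    x = np.asarray(signal, dtype=float)
    return x * x * x


def coarse_envelope(
    cubed: np.ndarray,
    fs_hz: float,
    cutoff_hz: float = 2.0,
    order: int = 2,
    rectify: bool = True,
) -> np.ndarray:
    """Coarse IJK-complex locator: zero-phase second-order Butterworth low-pass.

    The band-passed complex is oscillatory, so its cubed positive and
    negative lobes cancel under a 2 Hz low-pass; full-wave rectification
    (default) turns each complex into a single energy bump whose maximum
    tracks the complex.  Zero-phase filtering keeps those maxima aligned
    with the complexes they locate.
    """
    if cutoff_hz >= fs_hz / 2:
        raise ValueError("cutoff must lie below the Nyquist frequency")
    x = np.asarray(cubed, dtype=float)
    if rectify:
        x = np.abs(x)
    sos = sp_signal.butter(order, cutoff_hz, btype="lowpass", fs=fs_hz, output="sos")
    return sp_signal.sosfiltfilt(sos, x)


def find_extrema(signal: np.ndarray) -> list[tuple[int, str]]:
    """Alternating local valleys and peaks of a 1-D signal.

    Plateaus collapse to their first sample; adjacent same-kind extrema (a
    degenerate case) merge keeping the more extreme one.
    """
    x = np.asarray(signal, dtype=float)
    if len(x) < 3:
        return []
    # collapse plateaus: keep the first sample of each equal-value run
    keep = np.concatenate(([True], x[1:] != x[:-1]))
    comp_idx = np.flatnonzero(keep)
    xc = x[comp_idx]
    if len(xc) < 3:
        return []
    d = np.sign(np.diff(xc))
    turns = np.flatnonzero(d[1:] != d[:-1]) + 1
    out: list[tuple[int, str]] = []
    for t in turns:
        kind = "peak" if d[t - 1] > 0 else "valley"
        idx = int(comp_idx[t])
        if out and out[-1][1] == kind:
            prev_idx = out[-1][0]
            better = (x[idx] > x[prev_idx]) if kind == "peak" else (x[idx] < x[prev_idx])
            if better:
                out[-1] = (idx, kind)
        else:
            out.append((idx, kind))
    return out


def coarse_search_spans(
    coarse: np.ndarray,
    fs_hz: float,
    half_width_s: float = 0.25,
    min_rel_height: float = 0.05,
) -> list[tuple[int, int]]:
    """Neighborhoods (index ranges) around each coarse-envelope local maximum.

    Maxima below ``min_rel_height`` times the largest envelope maximum are
    noise wiggles between complexes, not complex locations, and spawn no
    span; the relative threshold keeps detection scale-equivariant.
    """
    peaks, _ = sp_signal.find_peaks(coarse)
    if len(peaks) and min_rel_height > 0:
        peaks = peaks[coarse[peaks] >= min_rel_height * coarse[peaks].max()]
    hw = int(round(half_width_s * fs_hz))
    n = len(coarse)
    return [(max(0, int(p) - hw), min(n, int(p) + hw + 1)) for p in peaks]


def select_complexes(
    extrema: list[tuple[int, str]],
    amplitudes: np.ndarray,
    search_spans: list[tuple[int, int]],
) -> list[TripletCandidate]:
    """Pick the best valley-peak-valley triplet inside each search span.

    All triplets of consecutive extrema whose peak falls inside the span are
    scored as ``-a(i) + a(j) - a(k)`` with the deflection amplitudes ``a``
    read from the cubed signal (the coarse envelope, being much smoother
    than the deflection spacing, only delimits the spans); the arg-max
    triplet wins (earlier peak on ties).  Spans holding fewer than three
    usable extrema yield no candidate.
    """
    winners: list[TripletCandidate] = []
    for lo, hi in search_spans:
        best: TripletCandidate | None = None
        for a, b, c in zip(extrema, extrema[1:], extrema[2:]):
            if a[1] != "valley" or b[1] != "peak" or c[1] != "valley":
                continue
            if not lo <= b[0] < hi:
                continue
            score = W_I * amplitudes[a[0]] + W_J * amplitudes[b[0]] + W_K * amplitudes[c[0]]
            if best is None or score > best.score:
                best = TripletCandidate(a[0], b[0], c[0], float(score))
        if best is not None:
            winners.append(best)
    return winners


def suppress_false_peaks(
    provisional_js: np.ndarray,
    signal: np.ndarray,
    fs_hz: float,
    span_s: float = 1.0,
) -> np.ndarray:
    """Non-maximum suppression of provisional J-peaks over the heartbeat interval.

    A provisional J survives iff its band-passed amplitude is the maximum
    among all provisional Js within ``span_s/2`` of it; on equal amplitudes
    the earlier index wins.  Survivors are strictly increasing with gaps
    larger than ``span_s/2``.
    """
    js = np.unique(np.asarray(provisional_js, dtype=np.int64))
    if len(js) <= 1:
        return js
    half = span_s / 2.0 * fs_hz
    amps = np.asarray(signal, dtype=float)[js]
    keep = []
    for i, j in enumerate(js):
        near = np.abs(js - j) <= half
        a_near = amps[near]
        # survivor: maximal amplitude in its neighborhood, earlier index on ties
        if amps[i] == a_near.max() and js[near][int(np.argmax(a_near))] == j:
            keep.append(j)
    out = []
    for j in keep:  # enforce the minimum-gap contract after ties
        if not out or j - out[-1] > half:
            out.append(j)
    return np.asarray(out, dtype=np.int64)


def detect_window(
    window: np.ndarray,
    fs_hz: float = 50.0,
    coarse_cutoff_hz: float = 2.0,
    search_half_width_s: float = 0.25,
    suppression_span_s: float = 1.0,
    min_coarse_rel_height: float = 0.05,
) -> np.ndarray:
    """J-peak indices (window-local) for one band-passed window."""
    x = np.asarray(window, dtype=float)
    cubed = cube(x)
    coarse = coarse_envelope(cubed, fs_hz, cutoff_hz=coarse_cutoff_hz)
    extrema = find_extrema(cubed)
    spans = coarse_search_spans(
        coarse, fs_hz, half_width_s=search_half_width_s, min_rel_height=min_coarse_rel_height
    )
    winners = select_complexes(extrema, cubed, spans)
    js = np.asarray(sorted({w.j_idx for w in winners}), dtype=np.int64)
    return suppress_false_peaks(js, x, fs_hz, span_s=suppression_span_s)


def hr_from_beats(beat_indices: np.ndarray, fs_hz: float) -> float:
    """HR in bpm from the mean successive J-J gap; NaN with fewer than 2 peaks."""
    idx = np.asarray(beat_indices)
    if len(idx) < 2:
        return float("nan")
    hr = 60.0 * fs_hz / float(np.mean(np.diff(idx)))
    if not HR_MIN_BPM <= hr <= HR_MAX_BPM:
        return float("nan")
    return hr


def detect(
    ws: WindowSet,
    fs_hz: float = 50.0,
    delay_compensation_samples: int | None = None,
    **kwargs,
) -> tuple[BeatSequence, list[np.ndarray]]:
    """Run the detector over every non-excluded window of a WindowSet.

    Window-local indices are mapped to recording coordinates; by default
    they are shifted back by the band-pass filter's centre-band group delay
    so detections align with the raw-signal J-peaks.  Excluded windows
    contribute no peaks.
    """
    if delay_compensation_samples is None:
        delay_compensation_samples = int(round(bandpass_group_delay_samples(fs_hz)))
    per_window: list[np.ndarray] = []
    all_peaks: list[np.ndarray] = []
    for w in range(len(ws)):
        if ws.excluded[w]:
            per_window.append(np.empty(0, dtype=np.int64))
            continue
        js = detect_window(ws.windows[w], fs_hz=fs_hz, **kwargs)
        per_window.append(js)
        if len(js):
            all_peaks.append(js + ws.start_indices[w] - delay_compensation_samples)
    if all_peaks:
        merged = np.concatenate(all_peaks)
        merged = np.unique(merged[merged >= 0])
    else:
        merged = np.empty(0, dtype=np.int64)
    return (
        BeatSequence(subject_id=ws.subject_id, peak_indices=merged, source="algorithm", fs_hz=fs_hz),
        per_window,
    )


def estimate_hr(ws: WindowSet, fs_hz: float = 50.0, **kwargs) -> HRSeries:
    """Per-window HR series from the algorithmic detector."""
    _, per_window = detect(ws, fs_hz=fs_hz, **kwargs)
    hr = np.array([hr_from_beats(js, fs_hz) for js in per_window])
    n_peaks = np.array([len(js) for js in per_window])
    return HRSeries(
        subject_id=ws.subject_id,
        window_index=np.arange(len(ws)),
        hr_bpm=hr,
        n_peaks=n_peaks,
        source="algorithm",
        window_start_ms=ws.start_times_ms,
    )


class JPeakHeartRateEstimator(BaseEstimator):
    """Per-window HR from band-passed BCG windows via J-peak detection.

    A stateless sklearn-style estimator: ``fit`` only validates input and
    ``predict`` maps an ``(n_windows, window_samples)`` matrix of band-passed
    windows to one HR value (bpm) per row, NaN where fewer than two J-peaks
    were found.
    """

    def __init__(
        self,
        fs_hz: float = 50.0,
        coarse_cutoff_hz: float = 2.0,
        search_half_width_s: float = 0.25,
        suppression_span_s: float = 1.0,
        min_coarse_rel_height: float = 0.05,
    ):
        self.fs_hz = fs_hz
        self.coarse_cutoff_hz = coarse_cutoff_hz
        self.search_half_width_s = search_half_width_s
        self.suppression_span_s = suppression_span_s
        self.min_coarse_rel_height = min_coarse_rel_height

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D window matrix")
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D window matrix")
        out = np.empty(X.shape[0])
        for i, row in enumerate(X):
            js = detect_window(
                row,
                fs_hz=self.fs_hz,
                coarse_cutoff_hz=self.coarse_cutoff_hz,
                search_half_width_s=self.search_half_width_s,
                suppression_span_s=self.suppression_span_s,
                min_coarse_rel_height=self.min_coarse_rel_height,
            )
            out[i] = hr_from_beats(js, self.fs_hz)
        return out

    def detect_beats(self, X):
        """Window-local J-peak indices per row."""
        X = np.asarray(X, dtype=float)
        return [
            detect_window(
                row,
                fs_hz=self.fs_hz,
                coarse_cutoff_hz=self.coarse_cutoff_hz,
                search_half_width_s=self.search_half_width_s,
                suppression_span_s=self.suppression_span_s,
                min_coarse_rel_height=self.min_coarse_rel_height,
            )
            for row in X
        ]
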