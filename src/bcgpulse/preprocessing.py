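"""Raw-recording conditioning: artifact repair, band-pass, windowing, resampling.

The belt's useful heartbeat energy sits in a 2-10 Hz band, below which
respiration dominates and above which broadband noise does.  The pipeline
is: repair saturation runs and isolated spikes, band-pass filter (2-10 Hz,
second-order digital Butterworth at the belt's 50 Hz rate), cut into
non-overlapping 400-sample (8 s) windows, and z-score each window.  The
100 Hz oximeter stream is brought onto the same 50 Hz timeline by linear
interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import signal as sp_signal
from sklearn.base import BaseEstimator, TransformerMixin

from .packets import QUALITY_MISSING, QUALITY_OK, QUALITY_REPAIRED, Recording

__all__ = [
    "WindowSet",
    "repair",
    "detect_saturation_runs",
    "artifact_spans_from_quality",
    "design_bandpass",
    "bandpass",
    "bandpass_attenuation_db",
    "bandpass_group_delay_samples",
    "segment",
    "normalize_windows",
    "resample_linear",
    "WindowNormalizer",
    "WINDOW_SAMPLES",
]

WINDOW_SAMPLES = 400  # 8 s at 50 Hz

DEFAULT_CONFIG = {
    "filter.low_hz": 2.0,
    "filter.high_hz": 10.0,
    "filter.order": 2,
    "window.samples": WINDOW_SAMPLES,
    "window.max_repaired_frac": 0.25,
    "repair.spike_z": 5.0,
    "repair.sat_run_min": 3,
}


@dataclass
class WindowSet:
    """Non-overlapping fixed-length analysis windows on a shared timeline.

    ``excluded[i]`` marks windows unusable for HR estimation, with
    ``reasons[i]`` one of ``saturation``, ``missing`` or ``flat``.
    """

    subject_id: str
    windows: np.ndarray  # (n_windows, window_samples)
    start_indices: np.ndarray
    start_times_ms: np.ndarray
    excluded: np.ndarray
    reasons: np.ndarray  # dtype=object, None where not excluded
    fs_hz: float

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if self.windows.ndim != 2:
            raise ValueError("windows must be a 2-D matrix")

    def __len__(self) -> int:
        return self.windows.shape[0]

    @property
    def n_included(self) -> int:
        return int((~self.excluded).sum())


def detect_saturation_runs(
    samples: np.ndarray, adc_limits: tuple[float, float], sat_run_min: int = 3
) -> np.ndarray:
    """Boolean mask of samples in runs of >= sat_run_min pinned at an ADC limit."""
    lo, hi = adc_limits
    at_limit = (samples <= lo) | (samples >= hi)
    mask = np.zeros(len(samples), dtype=bool)
    if not at_limit.any():
        return mask
    # run-length encode the at-limit indicator
    padded = np.concatenate(([False], at_limit, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start >= sat_run_min:
            mask[start:stop] = True
    return mask


def _interp_over_mask(samples: np.ndarray, bad: np.ndarray) -> np.ndarray:
    """Linear interpolation across bad samples from the nearest good ones."""
    out = samples.copy()
    good = ~bad
    if not good.any():
        raise ValueError("recording entirely flagged; nothing to interpolate from")
    idx = np.arange(len(samples))
    out[bad] = np.interp(idx[bad], idx[good], samples[good])
    return out


def repair(
    recording: Recording,
    sat_run_min: int = 3,
    spike_z: float = 5.0,
    adc_limits: tuple[float, float] | None = None,
) -> Recording:
    """Replace saturation runs and isolated spikes by linear interpolation.

    Saturation: runs of at least ``sat_run_min`` consecutive samples pinned
    at an ADC limit.  Spikes: samples whose robust z-score against a 2 s
    rolling median exceeds ``spike_z``.  Repaired samples keep the series
    trend seamless and are flagged ``QUALITY_REPAIRED``; samples already
    flagged missing are interpolated too but keep their missing flag.
    """
    if recording.fs_hz <= 0:
        raise ValueError("recording must have a positive sampling rate")
    x = recording.samples
    n = len(x)
    if n == 0:
        return recording.copy()
    if adc_limits is None:
        adc_limits = (float(np.min(x)), float(np.max(x)))
    sat = detect_saturation_runs(x, adc_limits, sat_run_min)

    # robust spike detection against a 2 s rolling median
    win = max(int(2 * recording.fs_hz) | 1, 3)  # odd
    rolling_med = sp_signal.medfilt(x, kernel_size=win)
    resid = x - rolling_med
    mad = np.median(np.abs(resid - np.median(resid)))
    scale = 1.4826 * mad if mad > 0 else np.std(resid) or 1.0
    spikes = np.abs(resid) > spike_z * scale

    missing = recording.quality == QUALITY_MISSING
    bad = sat | spikes | missing
    if not bad.any():
        return recording.copy()
    if bad.all():
        raise ValueError("recording entirely saturated or missing; cannot repair")
    out = recording.copy()
    out.samples = _interp_over_mask(x, bad)
    newly_repaired = (sat | spikes) & ~missing
    out.quality[newly_repaired] = QUALITY_REPAIRED
    return out


def artifact_spans_from_quality(
    recording: Recording, merge_gap_s: float = 1.0
) -> list[tuple[float, float]]:
    """Merge repaired/missing samples into artifact spans (seconds).

    Saturation transients oscillate between the ADC rails, so the pinned
    runs detected by :func:`repair` are fragments of one event; runs closer
    than ``merge_gap_s`` are merged into a single span.
    """
    flagged = recording.quality != QUALITY_OK
    if not flagged.any():
        return []
    padded = np.concatenate(([False], flagged, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    fs = recording.fs_hz
    spans: list[tuple[float, float]] = []
    for start, stop in zip(edges[::2], edges[1::2]):
        s, e = start / fs, stop / fs
        if spans and s - spans[-1][1] <= merge_gap_s:
            spans[-1] = (spans[-1][0], e)
        else:
            spans.append((s, e))
    return spans


def design_bandpass(
    fs_hz: float, low_hz: float = 2.0, high_hz: float = 10.0, order: int = 2
) -> np.ndarray:
    """Second-order digital Butterworth band-pass as second-order sections.

    The -3 dB points fall exactly at ``low_hz`` and ``high_hz``.
    """
    nyq = fs_hz / 2.0
    if high_hz >= nyq:
        raise ValueError("upper cutoff must lie below the Nyquist frequency")
    if not 0 < low_hz < high_hz:
        raise ValueError("cutoffs must satisfy 0 < low < high")
    return sp_signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs_hz, output="sos")


def bandpass(
    recording: Recording,
    low_hz: float = 2.0,
    high_hz: float = 10.0,
    order: int = 2,
    expected_fs_hz: float | None = 50.0,
) -> Recording:
    """Apply the 2-10 Hz Butterworth band-pass causally (forward only).

    By default only the belt's 50 Hz rate is accepted; pass
    ``expected_fs_hz=None`` to filter other rates with the same cutoffs.
    """
    if expected_fs_hz is not None and recording.fs_hz != expected_fs_hz:
        raise ValueError(
            f"bandpass configured for {expected_fs_hz} Hz, got {recording.fs_hz} Hz"
        )
    sos = design_bandpass(recording.fs_hz, low_hz, high_hz, order)
    out = recording.copy()
    out.samples = sp_signal.sosfilt(sos, recording.samples)
    return out


def bandpass_attenuation_db(
    freqs_hz, fs_hz: float = 50.0, low_hz: float = 2.0, high_hz: float = 10.0, order: int = 2
) -> np.ndarray:
    """Attenuation (positive dB) at given frequencies relative to peak passband gain."""
    sos = design_bandpass(fs_hz, low_hz, high_hz, order)
    grid = np.linspace(low_hz, high_hz, 4001)
    _, h_grid = sp_signal.sosfreqz(sos, worN=grid, fs=fs_hz)
    peak_db = 20 * np.log10(np.max(np.abs(h_grid)))
    _, h = sp_signal.sosfreqz(sos, worN=np.atleast_1d(freqs_hz), fs=fs_hz)
    return peak_db - 20 * np.log10(np.abs(h))


def bandpass_group_delay_samples(
    fs_hz: float = 50.0, low_hz: float = 2.0, high_hz: float = 10.0, order: int = 2,
    at_hz: float | None = None,
) -> float:
    """Causal filter group delay (samples) at ``at_hz`` (default: band centre)."""
    sos = design_bandpass(fs_hz, low_hz, high_hz, order)
    b, a = sp_signal.sos2tf(sos)
    if at_hz is None:
        at_hz = np.sqrt(low_hz * high_hz)  # geometric band centre
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, gd = sp_signal.group_delay((b, a), w=np.atleast_1d(at_hz), fs=fs_hz)
    return float(gd[0])


def segment(
    recording: Recording,
    window: int = WINDOW_SAMPLES,
    max_repaired_frac: float = 0.25,
) -> WindowSet:
    """Cut a recording into consecutive non-overlapping windows.

    The trailing remainder is dropped.  Windows whose repaired+missing
    fraction exceeds ``max_repaired_frac`` are marked excluded with reason
    ``missing`` or ``saturation`` (whichever share dominates).
    """
    n = len(recording.samples)
    n_windows = n // window
    if n_windows == 0:
        warnings.warn("recording shorter than one window; empty WindowSet")
    windows = recording.samples[: n_windows * window].reshape(n_windows, window)
    quality = recording.quality[: n_windows * window].reshape(n_windows, window)
    start_indices = np.arange(n_windows) * window
    start_times_ms = recording.t0_ms + np.round(start_indices * 1000.0 / recording.fs_hz).astype(
        np.int64
    )
    missing_frac = (quality == QUALITY_MISSING).mean(axis=1)
    repaired_frac = (quality == QUALITY_REPAIRED).mean(axis=1)
    excluded = (missing_frac + repaired_frac) > max_repaired_frac
    reasons = np.full(n_windows, None, dtype=object)
    reasons[excluded & (missing_frac > repaired_frac)] = "missing"
    reasons[excluded & (missing_frac <= repaired_frac)] = "saturation"
    return WindowSet(
        subject_id=recording.subject_id,
        windows=windows.copy(),
        start_indices=start_indices,
        start_times_ms=start_times_ms,
        excluded=excluded,
        reasons=reasons,
        fs_hz=recording.fs_hz,
    )


def normalize_windows(ws: WindowSet) -> WindowSet:
    """Z-score each non-excluded window (mean 0, variance 1).

    Constant windows cannot be normalized and are marked excluded with
    reason ``flat``; the operation is idempotent.
    """
    windows = ws.windows.copy()
    excluded = ws.excluded.copy()
    reasons = ws.reasons.copy()
    mu = windows.mean(axis=1, keepdims=True)
    sd = windows.std(axis=1, keepdims=True)
    flat = (sd[:, 0] == 0) & ~excluded
    excluded[flat] = True
    reasons[flat] = "flat"
    active = ~excluded
    windows[active] = (windows[active] - mu[active]) / sd[active]
    return WindowSet(
        subject_id=ws.subject_id,
        windows=windows,
        start_indices=ws.start_indices.copy(),
        start_times_ms=ws.start_times_ms.copy(),
        excluded=excluded,
        reasons=reasons,
        fs_hz=ws.fs_hz,
    )


def resample_linear(recording: Recording) -> Recording:
    """Downsample a 100 Hz oximeter recording to the 50 Hz belt timeline.

    Output sample ``k`` is the linear interpolant of the source at time
    ``k/50`` s; a target sample inherits a repaired/missing flag if either
    flanking source sample carries one.  Other rate pairs are rejected.
    """
    if recording.fs_hz != 100.0:
        raise ValueError("resample_linear expects a 100 Hz source recording")
    n_src = len(recording.samples)
    n_out = n_src // 2
    src_t = np.arange(n_src) / 100.0
    out_t = np.arange(n_out) / 50.0
    samples = np.interp(out_t, src_t, recording.samples)
    quality = np.zeros(n_out, dtype=np.uint8)
    # target k sits on source sample 2k; flag if source 2k or its successor is flagged
    left = recording.quality[0 : 2 * n_out : 2]
    right_idx = np.minimum(np.arange(n_out) * 2 + 1, n_src - 1)
    right = recording.quality[right_idx]
    quality = np.maximum(left, right)
    return Recording(
        subject_id=recording.subject_id,
        device_kind=recording.device_kind,
        fs_hz=50.0,
        t0_ms=recording.t0_ms,
        samples=samples,
        quality=quality,
    )


class WindowNormalizer(BaseEstimator, TransformerMixin):
    """Stateless per-row z-scoring of window matrices (sklearn transformer).

    Rows with zero variance are returned as zeros; use
    :func:`normalize_windows` on a :class:`WindowSet` to have such windows
    flagged instead.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D window matrix")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return (X - mu) / sd
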