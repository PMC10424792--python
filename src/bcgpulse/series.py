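"""Beat and heart-rate series containers shared by all detection paths."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BeatSequence", "HRSeries", "HR_MIN_BPM", "HR_MAX_BPM"]

# plausibility bounds for a defined per-window heart rate
HR_MIN_BPM = 20.0
HR_MAX_BPM = 250.0

_SOURCES = ("algorithm", "cnn", "ppg", "ground_truth")


@dataclass
class BeatSequence:
    """Strictly increasing sample indices of detected (or true) heartbeats."""

    subject_id: str
    peak_indices: np.ndarray
    source: str
    fs_hz: float = 50.0

    def __post_init__(self) -> None:
        self.peak_indices = np.asarray(self.peak_indices, dtype=np.int64)
        if self.source not in _SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if np.any(np.diff(self.peak_indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "peak_index": self.peak_indices,
                "peak_time_ms": np.round(self.peak_indices * 1000.0 / self.fs_hz).astype(np.int64),
                "source": self.source,
            }
        )


@dataclass
class HRSeries:
    """Per-window heart-rate values; NaN marks windows where HR is undefined."""

    subject_id: str
    window_index: np.ndarray
    hr_bpm: np.ndarray
    n_peaks: np.ndarray
    source: str = "algorithm"
    window_start_ms: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.window_index = np.asarray(self.window_index, dtype=np.int64)
        self.hr_bpm = np.asarray(self.hr_bpm, dtype=float)
        self.n_peaks = np.asarray(self.n_peaks, dtype=np.int64)
        if not (len(self.window_index) == len(self.hr_bpm) == len(self.n_peaks)):
            raise ValueError("window_index, hr_bpm and n_peaks must have equal length")

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.hr_bpm)

    def to_frame(self) -> pd.DataFrame:
        start_ms = (
            self.window_start_ms
            if self.window_start_ms is not None
            else np.full(len(self.window_index), -1, dtype=np.int64)
        )
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "window_index": self.window_index,
                "window_start_ms": start_ms,
                "hr_bpm": self.hr_bpm,
                "n_peaks": self.n_peaks,
                "source": self.source,
            }
        )
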