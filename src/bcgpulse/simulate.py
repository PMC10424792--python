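"""Seeded synthetic overnight BCG/PPG sessions with ground-truth annotation.

Real overnight belt recordings pair a quasi-periodic train of IJK heartbeat
complexes with a large respiration baseline, broadband noise, and
movement-induced sensor-saturation episodes.  This module renders all of
those ingredients from an explicit beat-time ground truth, so detector and
regressor accuracy can be scored exactly.

Signal model
------------
* Heart rate follows a mean-reverting (Ornstein-Uhlenbeck) random walk
  around the subject's resting rate; inter-beat intervals are ``60/HR(t)``
  plus white beat-to-beat jitter.
* Each beat contributes an IJK complex: Gaussian deflections I (valley,
  -60 ms, amplitude -0.4), J (peak, 0 ms, +1) and K (valley, +60 ms, -0.5),
  each ~20 ms wide, so the dominant energy lies in the 2-10 Hz band.
* Respiration is a sinusoidal baseline at 0.2-0.4 Hz, several times larger
  than the J deflection; white noise is added on top.
* Movement artifacts arrive as a Poisson process; within each event the
  signal is replaced by a large low-frequency transient clipped to the ADC
  limits, producing the flat-topped saturation runs seen on real belts.
* The oximeter PPG stream places one smooth unimodal pulse per beat,
  delayed by the pulse-arrival time (default 0.25 s after the J peak).

All outputs are pure functions of (profile, duration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .packets import PacketBatch, Recording, frame_packets, write_packets

__all__ = [
    "SubjectProfile",
    "GroundTruth",
    "make_beat_times",
    "render_bcg",
    "inject_artifacts",
    "render_ppg",
    "generate_cohort",
    "BELT_FS_HZ",
    "PPG_FS_HZ",
    "BELT_PACKET_SIZE",
    "PPG_PACKET_SIZE",
]

BELT_FS_HZ = 50.0
PPG_FS_HZ = 100.0
# belt packets align with 8-s analysis windows; oximeter packets hold 1 s
BELT_PACKET_SIZE = 400
PPG_PACKET_SIZE = 100

# IJK template geometry (seconds / J-relative amplitudes)
_IJK_OFFSETS_S = (-0.060, 0.0, 0.060)
_IJK_AMPLITUDES = (-0.4, 1.0, -0.5)
_IJK_WIDTH_S = 0.020

# PPG pulse: raised-cosine upstroke then exponential decay
_PPG_RISE_S = 0.15
_PPG_DECAY_TAU_S = 0.10
_PPG_SUPPORT_S = 0.55


@dataclass
class SubjectProfile:
    """Parameters of one simulated sleeper and their belt/oximeter."""

    subject_id: str = "S00"
    mean_hr_bpm: float = 55.0
    hr_wander_sd_bpm: float = 5.0
    ibi_jitter_sd_s: float = 0.03
    resp_rate_hz: float = 0.3
    resp_amp: float = 3.0
    noise_sd: float = 0.15
    artifact_events_per_hour: float = 6.0
    artifact_duration_s: float = 100.0
    pat_delay_s: float = 0.25
    adc_limits: tuple[float, float] = (-2048.0, 2047.0)
    gain: float = 300.0  # ADC codes per unit J amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        if not 30.0 <= self.mean_hr_bpm <= 120.0:
            raise ValueError("mean_hr_bpm must lie in [30, 120]")
        if not 0.1 <= self.resp_rate_hz <= 0.5:
            raise ValueError("resp_rate_hz must lie in [0.1, 0.5]")
        if self.artifact_events_per_hour < 0 or self.artifact_duration_s < 0:
            raise ValueError("artifact parameters must be >= 0")
        if self.adc_limits[0] >= self.adc_limits[1]:
            raise ValueError("adc_limits must be (min, max) with min < max")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one named noise source of this subject."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), int(stream)]))


# named noise streams, so each render is reproducible on its own
_STREAM_HR_WALK = 1
_STREAM_JITTER = 2
_STREAM_BCG_NOISE = 3
_STREAM_ARTIFACTS = 4
_STREAM_PPG_NOISE = 5


@dataclass
class GroundTruth:
    """True beat times and artifact spans for one session."""

    beat_times_s: np.ndarray
    artifact_spans: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        if np.any(np.diff(self.beat_times_s) <= 0):
            raise ValueError("beat times must be strictly increasing")

    def beats_in(self, start_s: float, end_s: float) -> np.ndarray:
        t = self.beat_times_s
        return t[(t >= start_s) & (t < end_s)]

    def hr_in_window(self, start_s: float, end_s: float) -> float:
        """Mean heart rate over [start, end) from successive beat gaps; NaN if <2 beats."""
        t = self.beats_in(start_s, end_s)
        if len(t) < 2:
            return float("nan")
        return 60.0 / float(np.mean(np.diff(t)))


def _hr_trace(profile: SubjectProfile, duration_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Smooth bounded HR(t): OU walk, 60 s relaxation, clipped to [30, 120] bpm."""
    dt = 1.0
    tau = 60.0
    n = int(np.ceil(duration_s / dt)) + 2
    rng = profile.rng(_STREAM_HR_WALK)
    hr = np.empty(n)
    hr[0] = profile.mean_hr_bpm
    sd = profile.hr_wander_sd_bpm
    # exact OU discretization: stationary sd equals hr_wander_sd_bpm
    a = np.exp(-dt / tau)
    innov_sd = sd * np.sqrt(1.0 - a * a)
    shocks = rng.standard_normal(n - 1)
    for i in range(1, n):
        hr[i] = profile.mean_hr_bpm + a * (hr[i - 1] - profile.mean_hr_bpm) + innov_sd * shocks[i - 1]
    np.clip(hr, 30.0, 120.0, out=hr)
    return np.arange(n) * dt, hr


def make_beat_times(profile: SubjectProfile, duration_s: float) -> GroundTruth:
    """Generate ground-truth beat times over ``[0, duration_s)``.

    Inter-beat intervals are ``60/HR(t)`` plus Gaussian jitter
    (sd ``profile.ibi_jitter_sd_s``), floored at 0.25 s.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    grid_t, grid_hr = _hr_trace(profile, duration_s)
    rng = profile.rng(_STREAM_JITTER)
    beats = []
    t = 0.3  # first beat shortly after session start
    while t < duration_s:
        beats.append(t)
        hr_now = float(np.interp(t, grid_t, grid_hr))
        ibi = 60.0 / hr_now
        if profile.ibi_jitter_sd_s > 0:
            ibi += profile.ibi_jitter_sd_s * rng.standard_normal()
        t += max(ibi, 0.25)
    return GroundTruth(beat_times_s=np.asarray(beats))


def _add_pulses(
    signal: np.ndarray,
    fs_hz: float,
    beat_times: np.ndarray,
    offsets_s: Sequence[float],
    amplitudes: Sequence[float],
    width_s: float,
) -> None:
    """Add Gaussian deflections at beat_time+offset, evaluated at exact sample times."""
    half = int(np.ceil((max(abs(o) for o in offsets_s) + 4 * width_s) * fs_hz))
    n = len(signal)
    for tb in beat_times:
        c = int(round(tb * fs_hz))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        if lo >= hi:
            continue
        t_rel = np.arange(lo, hi) / fs_hz - tb
        for off, amp in zip(offsets_s, amplitudes):
            signal[lo:hi] += amp * np.exp(-0.5 * ((t_rel - off) / width_s) ** 2)


def render_bcg(
    beats: GroundTruth | np.ndarray,
    duration_s: float,
    profile: SubjectProfile,
    fs_hz: float = BELT_FS_HZ,
) -> Recording:
    """Render the belt pressure signal (in ADC codes) for the given beat train.

    An empty beat list yields the pure respiration+noise baseline.
    """
    beat_times = beats.beat_times_s if isinstance(beats, GroundTruth) else np.asarray(beats, float)
    n = int(round(duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    signal = np.zeros(n)
    _add_pulses(signal, fs_hz, beat_times, _IJK_OFFSETS_S, _IJK_AMPLITUDES, _IJK_WIDTH_S)
    signal += profile.resp_amp * np.sin(2 * np.pi * profile.resp_rate_hz * t)
    if profile.noise_sd > 0:
        signal += profile.noise_sd * profile.rng(_STREAM_BCG_NOISE).standard_normal(n)
    signal *= profile.gain
    np.clip(signal, *profile.adc_limits, out=signal)
    return Recording(
        subject_id=profile.subject_id,
        device_kind="belt",
        fs_hz=fs_hz,
        t0_ms=0,
        samples=signal,
    )


def _draw_artifact_spans(
    profile: SubjectProfile, duration_s: float, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Poisson event process; overlapping events merged into single spans."""
    rate = profile.artifact_events_per_hour / 3600.0
    n_events = rng.poisson(rate * duration_s)
    if n_events == 0:
        return []
    starts = np.sort(rng.uniform(0.0, duration_s, size=n_events))
    durations = rng.exponential(profile.artifact_duration_s, size=n_events)
    spans: list[tuple[float, float]] = []
    for s, d in zip(starts, durations):
        e = min(s + d, duration_s)
        if spans and s <= spans[-1][1]:
            spans[-1] = (spans[-1][0], max(spans[-1][1], e))
        else:
            spans.append((s, e))
    return spans


def inject_artifacts(
    recording: Recording, profile: SubjectProfile
) -> tuple[Recording, list[tuple[float, float]]]:
    """Overwrite Poisson-drawn event spans with clipped motion transients.

    Each transient is a smoothed random walk scaled to three times the ADC
    range, so clipping produces realistic flat saturation runs touching the
    limits.  Returns the modified recording and the event spans in seconds.
    """
    rng = profile.rng(_STREAM_ARTIFACTS)
    duration_s = recording.duration_s
    spans = _draw_artifact_spans(profile, duration_s, rng)
    if not spans:
        return recording.copy(), []
    out = recording.copy()
    fs = recording.fs_hz
    lo, hi = profile.adc_limits
    amp = 3.0 * max(abs(lo), abs(hi))
    for start_s, end_s in spans:
        i0 = int(round(start_s * fs))
        i1 = min(int(round(end_s * fs)), len(out.samples))
        m = i1 - i0
        if m < 1:
            continue
        walk = np.cumsum(rng.standard_normal(m))
        # smooth over ~0.2 s so the transient is low-frequency like real motion
        k = max(int(0.2 * fs), 1)
        walk = np.convolve(walk, np.ones(k) / k, mode="same")
        peak = np.max(np.abs(walk))
        if peak == 0:
            walk = np.full(m, amp)
        else:
            walk = walk / peak * amp
        out.samples[i0:i1] = np.clip(walk, lo, hi)
    return out, spans


def render_ppg(
    beats: GroundTruth | np.ndarray,
    duration_s: float,
    profile: SubjectProfile,
    fs_hz: float = PPG_FS_HZ,
) -> Recording:
    """Render the oximeter PPG stream: one pulse per beat, apex at
    ``beat_time + pat_delay_s``, raised-cosine upstroke and exponential decay."""
    beat_times = beats.beat_times_s if isinstance(beats, GroundTruth) else np.asarray(beats, float)
    n = int(round(duration_s * fs_hz))
    signal = np.zeros(n)
    for tb in beat_times:
        apex = tb + profile.pat_delay_s
        lo = max(0, int(np.floor((apex - _PPG_RISE_S) * fs_hz)))
        hi = min(n, int(np.ceil((apex + _PPG_SUPPORT_S) * fs_hz)) + 1)
        if lo >= hi:
            continue
        t_rel = np.arange(lo, hi) / fs_hz - apex
        pulse = np.zeros(hi - lo)
        rising = (t_rel >= -_PPG_RISE_S) & (t_rel <= 0)
        pulse[rising] = 0.5 * (1 + np.cos(np.pi * t_rel[rising] / _PPG_RISE_S))
        falling = t_rel > 0
        pulse[falling] = np.exp(-t_rel[falling] / _PPG_DECAY_TAU_S)
        signal[lo:hi] += pulse
    if profile.noise_sd > 0:
        signal += 0.02 * profile.rng(_STREAM_PPG_NOISE).standard_normal(n)
    return Recording(
        subject_id=profile.subject_id,
        device_kind="oximeter",
        fs_hz=fs_hz,
        t0_ms=0,
        samples=signal,
    )


@dataclass
class SyntheticSession:
    """One subject's simulated night: packets plus ground truth."""

    profile: SubjectProfile
    truth: GroundTruth
    belt_packets: list[PacketBatch]
    ppg_packets: list[PacketBatch]


def simulate_session(
    profile: SubjectProfile, duration_s: float, with_artifacts: bool = True
) -> SyntheticSession:
    """Full single-subject simulation: beats -> BCG (+artifacts) and PPG -> packets."""
    truth = make_beat_times(profile, duration_s)
    bcg = render_bcg(truth, duration_s, profile)
    if with_artifacts and profile.artifact_events_per_hour > 0:
        bcg, spans = inject_artifacts(bcg, profile)
        truth.artifact_spans = spans
    ppg = render_ppg(truth, duration_s, profile)
    belt_packets = frame_packets(
        bcg.samples, BELT_FS_HZ, BELT_PACKET_SIZE,
        device_id=profile.subject_id, device_kind="belt",
    )
    ppg_packets = frame_packets(
        ppg.samples, PPG_FS_HZ, PPG_PACKET_SIZE,
        device_id=profile.subject_id, device_kind="oximeter",
    )
    return SyntheticSession(profile, truth, belt_packets, ppg_packets)


def _draw_profile(subject_id: str, seed: int, rng: np.random.Generator, **overrides) -> SubjectProfile:
    base = SubjectProfile(
        subject_id=subject_id,
        mean_hr_bpm=float(rng.uniform(45.0, 75.0)),
        resp_rate_hz=float(rng.uniform(0.2, 0.4)),
        seed=seed,
    )
    return replace(base, **overrides) if overrides else base


def generate_cohort(
    n_subjects: int,
    duration_s: float,
    seed: int,
    out_dir: str | Path | None = None,
    with_artifacts: bool = True,
    **profile_overrides,
) -> dict[str, SyntheticSession]:
    """Simulate a cohort; optionally write packet files and ground-truth CSVs.

    Subject resting rates are drawn uniformly from 45-75 bpm and respiration
    rates from 0.2-0.4 Hz; every other parameter takes the profile default
    unless overridden.  One cohort seed deterministically derives per-subject
    seeds, so identical calls produce byte-identical packet files.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    root = np.random.SeedSequence(int(seed))
    cohort_rng = np.random.default_rng(root.spawn(1)[0])
    subject_seeds = [int(s) for s in cohort_rng.integers(0, 2**31 - 1, size=n_subjects)]
    sessions: dict[str, SyntheticSession] = {}
    for k in range(n_subjects):
        sid = f"S{k:02d}"
        profile = _draw_profile(sid, subject_seeds[k], cohort_rng, **profile_overrides)
        sessions[sid] = simulate_session(profile, duration_s, with_artifacts=with_artifacts)
    if out_dir is not None:
        _write_cohort(sessions, Path(out_dir))
    return sessions


def _write_cohort(sessions: dict[str, SyntheticSession], out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    beat_rows, span_rows = [], []
    for sid, sess in sessions.items():
        subj_dir = out_dir / sid
        subj_dir.mkdir(exist_ok=True)
        write_packets(sess.belt_packets, subj_dir / "belt_000.json")
        write_packets(sess.ppg_packets, subj_dir / "ppg_000.json")
        (subj_dir / "manifest.json").write_text(
            f'{{"subject_id": "{sid}"}}\n'
        )
        beat_rows.extend((sid, t) for t in sess.truth.beat_times_s)
        span_rows.extend((sid, a, b) for a, b in sess.truth.artifact_spans)
    pd.DataFrame(beat_rows, columns=["subject_id", "beat_time_s"]).to_csv(
        out_dir / "ground_truth_beats.csv", index=False
    )
    pd.DataFrame(span_rows, columns=["subject_id", "artifact_start_s", "artifact_end_s"]).to_csv(
        out_dir / "ground_truth_artifacts.csv", index=False
    )
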