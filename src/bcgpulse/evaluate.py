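"""Patient-wise MAE/MAPE evaluation and end-to-end pipeline orchestration.

Errors are computed per window between a predicted HR series (algorithmic
or CNN path) and the PPG reference, summarized per subject as MAE and MAPE
over jointly-defined windows, then aggregated across subjects (mean and
sample standard deviation) — patient-wise, never pooled over windows.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cnn import CNNHeartRateRegressor, predict_hr, split_subjects
from .jpeak import estimate_hr
from .packets import Recording, assemble, read_packets
from .ppg import estimate_ref_hr, pair_windows
from .preprocessing import WindowSet, bandpass, normalize_windows, repair, resample_linear, segment
from .series import HRSeries
from .simulate import SyntheticSession, generate_cohort

__all__ = [
    "EvalReport",
    "mae",
    "mape",
    "aggregate",
    "evaluate_cohort",
    "run_pipeline",
    "DEFAULT_PIPELINE_CONFIG",
]


def _joint(pred: HRSeries, ref: HRSeries) -> tuple[np.ndarray, np.ndarray]:
    """Align two series on window_index and keep jointly-defined windows."""
    p = pd.Series(pred.hr_bpm, index=pred.window_index)
    r = pd.Series(ref.hr_bpm, index=ref.window_index)
    joined = pd.concat([p, r], axis=1, join="inner", keys=["pred", "ref"]).dropna()
    return joined["pred"].to_numpy(), joined["ref"].to_numpy()


def mae(pred: HRSeries, ref: HRSeries) -> float:
    """Mean absolute error (bpm) over jointly-defined windows; NaN if none."""
    p, r = _joint(pred, ref)
    if len(p) == 0:
        warnings.warn("no jointly-defined windows; MAE undefined")
        return float("nan")
    return float(np.mean(np.abs(p - r)))


def mape(pred: HRSeries, ref: HRSeries) -> float:
    """Mean absolute percentage error (%) over jointly-defined windows."""
    p, r = _joint(pred, ref)
    if len(p) == 0:
        warnings.warn("no jointly-defined windows; MAPE undefined")
        return float("nan")
    if np.any(r <= 0):
        raise ValueError("reference HR must be positive for MAPE")
    return float(100.0 * np.mean(np.abs(p - r) / r))


def aggregate(per_subject_values) -> tuple[float, float]:
    """Across-subject mean and sample (n-1) standard deviation.

    A single subject has no sample deviation; 0 is reported with a warning.
    """
    v = np.asarray(list(per_subject_values), dtype=float)
    if len(v) == 0:
        raise ValueError("need at least one subject")
    if len(v) == 1:
        warnings.warn("single subject: standard deviation undefined, reported as 0")
        return float(v[0]), 0.0
    return float(np.mean(v)), float(np.std(v, ddof=1))


@dataclass
class EvalReport:
    """Per-subject and aggregate HR-error statistics for one method."""

    method: str
    per_subject: pd.DataFrame  # subject_id, mae_bpm, mape_pct, n_windows_used, n_windows_excluded
    mae_mean: float
    mae_std: float
    mape_mean: float
    mape_std: float

    def summary(self) -> str:
        lines = [
            f"method: {self.method}",
            f"subjects: {len(self.per_subject)}",
            f"patient-wise MAE:  {self.mae_mean:.2f} bpm (std {self.mae_std:.2f})",
            f"patient-wise MAPE: {self.mape_mean:.2f} % (std {self.mape_std:.2f})",
        ]
        return "\n".join(lines)

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.per_subject.to_csv(out_dir / f"report_{self.method}.csv", index=False)
        (out_dir / f"summary_{self.method}.txt").write_text(self.summary() + "\n")


def evaluate_cohort(
    preds: dict[str, HRSeries],
    refs: dict[str, HRSeries],
    method: str,
    excluded_counts: dict[str, int] | None = None,
) -> EvalReport:
    """Patient-wise evaluation of per-subject predicted vs reference HR series."""
    rows = []
    for sid in sorted(preds):
        if sid not in refs:
            warnings.warn(f"subject {sid} has no reference series; skipped")
            continue
        p, r = _joint(preds[sid], refs[sid])
        rows.append(
            {
                "subject_id": sid,
                "mae_bpm": mae(preds[sid], refs[sid]),
                "mape_pct": mape(preds[sid], refs[sid]),
                "n_windows_used": len(p),
                "n_windows_excluded": (excluded_counts or {}).get(sid, 0),
            }
        )
    per_subject = pd.DataFrame(rows)
    mae_mean, mae_std = aggregate(per_subject["mae_bpm"])
    mape_mean, mape_std = aggregate(per_subject["mape_pct"])
    return EvalReport(method, per_subject, mae_mean, mae_std, mape_mean, mape_std)


# --- pipeline ------------------------------------------------------------

DEFAULT_PIPELINE_CONFIG = {
    "seed": 0,
    "method": "algorithm",  # or "cnn"
    "simulate.subjects": 8,
    "simulate.duration_s": 1200.0,
    "simulate.artifacts": True,
    "window.max_repaired_frac": 0.25,
    "repair.spike_z": 5.0,
    "repair.sat_run_min": 3,
    "cnn.epochs": 30,
    "cnn.batch_size": 64,
    "cnn.train_fraction": 2 / 3,
    "cnn.targets": "ppg",  # or "ground_truth"
    "out_dir": None,
}


@dataclass
class SubjectWindows:
    """Preprocessed per-subject inputs for both detection paths."""

    subject_id: str
    bcg_windows: WindowSet  # band-passed
    bcg_norm: WindowSet  # band-passed + per-window z-scored
    ppg_windows: WindowSet  # resampled to 50 Hz
    truth_hr: np.ndarray | None = None  # per-window ground-truth HR (synthetic only)


def prepare_subject(
    belt: Recording,
    ppg: Recording,
    adc_limits: tuple[float, float] | None = None,
    max_repaired_frac: float = 0.25,
    spike_z: float = 5.0,
    sat_run_min: int = 3,
) -> SubjectWindows:
    """Repair, filter and window one subject's belt + oximeter recordings."""
    repaired = repair(belt, sat_run_min=sat_run_min, spike_z=spike_z, adc_limits=adc_limits)
    filtered = bandpass(repaired)
    ws = segment(filtered, max_repaired_frac=max_repaired_frac)
    ppg50 = resample_linear(ppg)
    ppg_ws = segment(ppg50, max_repaired_frac=max_repaired_frac)
    return SubjectWindows(
        subject_id=belt.subject_id,
        bcg_windows=ws,
        bcg_norm=normalize_windows(ws),
        ppg_windows=ppg_ws,
    )


def prepare_session(sess: SyntheticSession, **kwargs) -> SubjectWindows:
    belt = assemble(sess.belt_packets, subject_id=sess.profile.subject_id)
    ppg = assemble(sess.ppg_packets, subject_id=sess.profile.subject_id)
    sw = prepare_subject(belt, ppg, adc_limits=sess.profile.adc_limits, **kwargs)
    n = len(sw.bcg_windows)
    sw.truth_hr = np.array([sess.truth.hr_in_window(i * 8.0, (i + 1) * 8.0) for i in range(n)])
    return sw


def load_session_dir(subject_dir: str | Path) -> tuple[Recording, Recording]:
    """Read one subject directory (belt_*.json, ppg_*.json, manifest.json)."""
    subject_dir = Path(subject_dir)
    manifest = json.loads((subject_dir / "manifest.json").read_text())
    sid = manifest["subject_id"]
    belt_packets = [p for f in sorted(subject_dir.glob("belt_*.json")) for p in read_packets(f)]
    ppg_packets = [p for f in sorted(subject_dir.glob("ppg_*.json")) for p in read_packets(f)]
    if not belt_packets or not ppg_packets:
        raise FileNotFoundError(f"missing belt or ppg packets under {subject_dir}")
    return assemble(belt_packets, subject_id=sid), assemble(ppg_packets, subject_id=sid)


def _reference_series(sw: SubjectWindows) -> HRSeries:
    ref = estimate_ref_hr(sw.ppg_windows)
    # drop reference values in windows not time-paired with a BCG window
    paired = {j for _, j in pair_windows(sw.bcg_windows, sw.ppg_windows)}
    hr = np.array(
        [v if i in paired else np.nan for i, v in zip(ref.window_index, ref.hr_bpm)]
    )
    return HRSeries(
        subject_id=ref.subject_id,
        window_index=ref.window_index,
        hr_bpm=hr,
        n_peaks=ref.n_peaks,
        source="ppg",
        window_start_ms=ref.window_start_ms,
    )


def run_pipeline(config: dict | str | Path | None = None) -> EvalReport:
    """Simulate (or load), preprocess, detect/train, and evaluate a cohort.

    ``config`` may be a flat key-value dict, a path to a JSON file of the
    same shape, or None for defaults; see ``DEFAULT_PIPELINE_CONFIG``.
    Fully seeded: identical configs reproduce identical reports.
    """
    if isinstance(config, (str, Path)):
        config = json.loads(Path(config).read_text())
    cfg = dict(DEFAULT_PIPELINE_CONFIG)
    cfg.update(config or {})
    seed = int(cfg["seed"])
    method = cfg["method"]
    if method not in ("algorithm", "cnn"):
        raise ValueError("method must be 'algorithm' or 'cnn'")

    sessions = generate_cohort(
        int(cfg["simulate.subjects"]),
        float(cfg["simulate.duration_s"]),
        seed=seed,
        with_artifacts=bool(cfg["simulate.artifacts"]),
    )
    prep_kwargs = dict(
        max_repaired_frac=float(cfg["window.max_repaired_frac"]),
        spike_z=float(cfg["repair.spike_z"]),
        sat_run_min=int(cfg["repair.sat_run_min"]),
    )
    subjects = {sid: prepare_session(s, **prep_kwargs) for sid, s in sessions.items()}
    refs = {sid: _reference_series(sw) for sid, sw in subjects.items()}
    excluded = {sid: int(sw.bcg_windows.excluded.sum()) for sid, sw in subjects.items()}

    if method == "algorithm":
        preds = {sid: estimate_hr(sw.bcg_windows) for sid, sw in subjects.items()}
        report = evaluate_cohort(preds, refs, "algorithm", excluded)
    else:
        train_ids, test_ids = split_subjects(list(subjects), float(cfg["cnn.train_fraction"]), seed)
        xs, ys = [], []
        for sid in train_ids:
            sw = subjects[sid]
            target = sw.truth_hr if cfg["cnn.targets"] == "ground_truth" else refs[sid].hr_bpm
            keep = ~np.isnan(target) & ~sw.bcg_norm.excluded
            xs.append(sw.bcg_norm.windows[keep])
            ys.append(np.asarray(target)[keep])
        est = CNNHeartRateRegressor(
            epochs=int(cfg["cnn.epochs"]), batch_size=int(cfg["cnn.batch_size"]), seed=seed
        ).fit(np.vstack(xs), np.concatenate(ys))
        preds = {sid: predict_hr(est, subjects[sid].bcg_norm) for sid in test_ids}
        report = evaluate_cohort(preds, {s: refs[s] for s in test_ids}, "cnn", excluded)
        if cfg.get("out_dir"):
            est.save(Path(cfg["out_dir"]) / "cnn_model")

    if cfg.get("out_dir"):
        report.write(cfg["out_dir"])
    return report
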