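# Methods

## Signal model and pipeline assumptions

A ballistocardiogram (BCG) records the body's recoil from cardiac
ejection. On a pressure belt sampled at 50 Hz, each beat appears as an IJK
complex — a valley (I), the dominant positive J deflection, and a second
valley (K) — riding on a respiration baseline several times its size, plus
broadband noise and movement transients that pin the ADC at its limits.
The pipeline assumes: (i) heartbeat energy is concentrated in 2–10 Hz,
below which respiration dominates; (ii) an 8 s window (400 samples) holds
5–8 beats for a resting subject, enough for a stable mean J–J spacing;
(iii) windows corrupted by saturation are detected and excluded rather
than corrected.

## Preprocessing

**Repair.** Saturation runs (≥ 3 consecutive samples at an ADC limit) and
isolated spikes (robust z > 5 against a 2 s rolling median, MAD-scaled)
are replaced by linear interpolation from the nearest intact samples and
flagged; flagged samples never re-enter downstream statistics unnoticed
because windows carry the repaired+missing fraction. A window whose
fraction exceeds 25% is excluded (`saturation`/`missing`), a threshold
exposed as `window.max_repaired_frac`.

**Band-pass.** Second-order digital Butterworth, 2–10 Hz at 50 Hz
sampling, applied causally (forward only) to match a streaming deployment;
the −3 dB edge property is a statement about the designed transfer
function and is direction-independent. Filtering other rates requires
explicitly overriding the expected rate.

**Windowing and normalization.** Windows are contiguous and
non-overlapping; the trailing remainder is dropped. Normalization is per
window (mean 0, variance 1), because the CNN consumes windows
independently; constant windows are excluded as `flat`. The operation is
idempotent.

**PPG resampling.** The 100 Hz oximeter stream is brought to the 50 Hz
belt timeline by linear interpolation (exact on affine segments); a target
sample inherits a quality flag if either flanking source sample carries
one.

## Algorithmic J-peak detector

Order of operations per non-excluded window: cube (sign kept) →
coarse envelope → extrema → triplet selection → false-peak suppression.

Numerical choices that the high-level recipe leaves open, and how they
were resolved:

- **Coarse envelope.** The cubed signal is full-wave rectified before the
  2 Hz second-order low-pass. Without rectification the positive J lobe
  and the negative ringing lobe of the band-passed complex cancel almost
  exactly under the low-pass, leaving an envelope dominated by noise; with
  rectification each complex maps to a single energy bump whose maximum
  stays within ±5 samples of the J-peak. The low-pass is zero-phase so
  envelope maxima are not lagged. Cutoff (2 Hz) sits above the sleeping HR
  fundamental (≤ 1.5 Hz) while smoothing intra-complex detail;
  config-exposed.
- **Search spans.** ±0.25 s around each envelope maximum (complex width
  ≈ 0.12 s plus margin). Envelope maxima below 5% of the window's largest
  maximum spawn no span: between complexes the envelope has small
  noise-driven wiggles which otherwise seed false triplets midway between
  beats, exactly where the 1 s suppression window cannot reach. The
  threshold is relative, preserving scale equivariance.
- **Triplet score.** For consecutive extrema valley–peak–valley at
  (i, j, k), score = −a(i) + a(j) − a(k) with amplitudes read from the
  cubed signal. Reading them from the coarse envelope is not workable: the
  envelope is smooth at the 20 ms deflection spacing, so all three terms
  nearly coincide and the score degenerates to a constant. Ties go to the
  earlier peak.
- **Suppression.** Non-maximum suppression with a ±0.5 s radius on the
  band-passed amplitude (ties: earlier index), giving the contract that
  surviving J-peaks are > 0.5 s apart. A tiling variant is configurable.
- **Filter-delay compensation.** The causal band-pass delays the J-peak by
  its group delay (≈ 2–3 samples mid-band). Detected indices are shifted
  back by the rounded centre-band group delay so they align with raw-signal
  beat times; per-window HR is unaffected by any constant shift.

HR per window is 60·Fs / mean(successive J–J gaps), defined for ≥ 2 peaks,
and marked undefined outside the plausible 20–250 bpm band.

## CNN regressor

Eleven same-padded 1-D convolutions: 1→16 (k8, s2), eight 16→16 (k8, s2),
one 16→16 (k7, s1), and a single-filter k1 readout; batch norm + leaky
ReLU (slope 0.3) after all but the last layer; lengths
400→200→100→50→25→13→7→4→2→1→1→1; 18,801 trainable parameters at width 1
(counting 2 per BN channel; running statistics excluded). No pooling, no
dense layers, no recurrence. A width factor scales all hidden channel
counts.

Training: MSE on targets z-scored against the *training* subjects' heart
rates (the normalizer is inverted at prediction time), Adam with default
parameters, L2 kernel penalty 1e−4, batch size 64, exactly 30 epochs, no
early stopping, no augmentation; the final state is the model. The
train/test split is by subject (67/33), drawn before any optimization; no
subject contributes windows to both sides. The engine is a compact NumPy
implementation (im2col convolutions, analytic backward passes verified
against finite differences); with fixed seeds two runs produce identical
histories.

Targets: with real sessions the paired PPG-window reference HR is the
training target; on synthetic cohorts the simulator's ground truth can be
selected instead (`cnn.targets`), which is what the training-behavior
checks use since it isolates regressor error from reference error.

## PPG reference

Per resampled 8 s window, systolic peaks are local maxima at least
0.3 × (max − median) above the window median (DC-invariant) and separated
by > 0.33 s (≤ 180 bpm); minima only validate that accepted peaks are
flanked by lower turning points. HR follows the same mean-interval formula
as the BCG paths; a single index cannot define a rate, so Ns is read as
the mean inter-peak interval of the window. BCG and PPG windows are paired
when their start times differ by less than one 50 Hz sample (20 ms);
unpaired windows leave the evaluation.

## Evaluation

MAE and MAPE are computed over jointly-defined windows of each subject
(undefined windows shrink the denominator; a penalty mode is
configurable), then aggregated across subjects as mean and sample (n−1)
standard deviation — patient-wise, never pooled over windows. The MAPE
spread is likewise across subjects.

## Synthetic sessions: what they emulate, and what they do not

Heart rate follows an exact-discretization Ornstein–Uhlenbeck walk
(relaxation 60 s, stationary SD = `hr_wander_sd_bpm`, clipped to
30–120 bpm) — smooth, mean-reverting wander rather than a sinusoid, which
is what per-window MAE should be tested against. Inter-beat intervals add
Gaussian jitter (SD 0.03 s, floored at 0.25 s). IJK deflections are
Gaussians at −60/0/+60 ms with amplitudes −0.4/+1/−0.5 and 20 ms width
(energy inside 2–10 Hz); respiration is a 0.2–0.4 Hz sinusoid at 3× the J
amplitude; white noise SD is 0.15× J. Signals are scaled to ADC codes
(gain 300/J, limits ±2048) — the waveform constants are conventional
choices exposed in `SubjectProfile`, set so the band-pass passes heartbeat
energy and rejects respiration. Movement artifacts arrive as a Poisson
process (6 events/h, exponential durations of mean 100 s); each event
replaces the signal with a smoothed random walk scaled to 3× the ADC range
and clipped, producing flat saturation runs that cover ~15% of an
overnight session, leaving ≥ 80% available. The PPG pulse is a
raised-cosine upstroke (0.15 s) with exponential decay (τ = 0.1 s), apex
0.25 s after the J-peak.

Cohorts draw resting rates uniformly from 45–75 bpm and respiration rates
from 0.2–0.4 Hz; one cohort seed derives all per-subject seeds, and every
output is a pure function of (profile, duration, seed).

Not modeled: posture-dependent morphology change, talking, arrhythmia,
SpO2, device packet-loss dynamics (loss is injected by dropping packets
explicitly), and inter-subject waveform variability beyond rate and
respiration. Passing tests therefore demonstrate correct recovery under
the stated signal model — clean quasi-periodic complexes with known
contamination — not performance on real overnight recordings, where
morphology variability is the dominant difficulty.

## Problem sizes in tests

The checks run at desk scale by design: parameter-recovery suites use
3-subject, 8–10-minute cohorts; the CNN training check uses 12 subjects ×
20 minutes (≈ 1,100 training windows) with ground-truth targets; the
availability statistic uses ten full 7-hour sessions (cheap, as only the
belt channel is needed). Session length mainly adds windows, not
difficulty, since the generator is stationary in distribution.

## Known limitations

- The false-peak stage assumes ≤ 120 bpm spacing; sustained tachycardia
  would be suppressed.
- Causal filtering trades a small constant detection lag (compensated) for
  streaming compatibility; zero-phase filtering would marginally sharpen
  J localization.
- The CNN's accuracy on real data depends on morphology diversity absent
  from the simulator; the held-out-subject check bounds optimism only
  under the generative model.
- Repair interpolates across saturation runs; long events produce
  physiologically meaningless bridges, which is why exclusion (not the
  repaired values) drives evaluation.
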