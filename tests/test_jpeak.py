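import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bcgpulse.jpeak import (
    JPeakHeartRateEstimator,
    coarse_envelope,
    cube,
    detect,
    detect_window,
    estimate_hr,
    find_extrema,
    hr_from_beats,
    select_complexes,
    suppress_false_peaks,
)
from bcgpulse.preprocessing import bandpass, segment
from bcgpulse.simulate import SubjectProfile, make_beat_times, render_bcg


class TestCube:
    def test_sign_preserved(self):
        np.testing.assert_array_equal(cube(np.array([2.0, -2.0, 0.0])), [8.0, -8.0, 0.0])

    def test_relative_enhancement(self):
        a, b = 3.0, 1.5
        assert abs(cube(np.array([a]))[0]) / abs(cube(np.array([b]))[0]) > a / b


class TestFindExtrema:
    def test_single_peak(self):
        assert find_extrema(np.array([0.0, 1.0, 0.0])) == [(1, "peak")]

    def test_monotone_has_no_interior_extrema(self):
        assert find_extrema(np.arange(10.0)) == []

    def test_sine_extrema_at_analytic_positions(self):
        t = np.arange(400) / 50.0
        ext = find_extrema(np.sin(2 * np.pi * 1.0 * t))
        peaks = [i for i, k in ext if k == "peak"]
        valleys = [i for i, k in ext if k == "valley"]
        assert len(peaks) == 8 and len(valleys) == 8
        # analytic peak positions: t = 0.25 + n, i.e. samples 12.5 + 50 n
        for n, p in enumerate(peaks):
            assert abs(p - (12.5 + 50 * n)) <= 1

    def test_alternation(self):
        x = np.random.default_rng(0).standard_normal(300)
        ext = find_extrema(x)
        kinds = [k for _, k in ext]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_plateau_collapses_to_first_sample(self):
        ext = find_extrema(np.array([0.0, 1.0, 1.0, 1.0, 0.0]))
        assert ext == [(1, "peak")]


class TestCoarseEnvelope:
    def test_zero_in_zero_out(self):
        np.testing.assert_allclose(coarse_envelope(np.zeros(400), 50.0), 0.0)

    def test_single_complex_maximum_near_j(self, clean_profile):
        rec = render_bcg(np.array([4.0]), 8.0, clean_profile)
        filtered = bandpass(rec).samples
        env = coarse_envelope(cube(filtered), 50.0)
        j_filtered = np.argmax(filtered)  # filtered J location
        assert abs(int(np.argmax(env)) - int(j_filtered)) <= 5

    def test_noise_variance_reduced(self):
        x = np.random.default_rng(0).standard_normal(2000)
        env = coarse_envelope(x, 50.0, rectify=False)
        assert np.var(x) / np.var(env) > 10


def brute_force_best_triplet(extrema, amplitudes, span):
    """Independent oracle: enumerate every consecutive valley-peak-valley
    triplet with the peak inside the span and return the best score."""
    lo, hi = span
    best = None
    for i in range(len(extrema) - 2):
        a, b, c = extrema[i], extrema[i + 1], extrema[i + 2]
        if (a[1], b[1], c[1]) != ("valley", "peak", "valley"):
            continue
        if not lo <= b[0] < hi:
            continue
        score = -amplitudes[a[0]] + amplitudes[b[0]] - amplitudes[c[0]]
        if best is None or score > best[1]:
            best = ((a[0], b[0], c[0]), score)
    return best


class TestSelectComplexes:
    def test_weight_arithmetic(self):
        amps = np.array([0.0, -2.0, 5.0, -3.0, 0.0])
        extrema = [(1, "valley"), (2, "peak"), (3, "valley")]
        winners = select_complexes(extrema, amps, [(0, 5)])
        assert len(winners) == 1
        assert winners[0].score == pytest.approx(10.0)  # -(-2) + 5 - (-3)

    def test_higher_score_wins(self):
        amps = np.array([0.0, -2.0, 5.0, -3.0, 4.0, -1.0, 0.0, 0.0])
        extrema = [(1, "valley"), (2, "peak"), (3, "valley"), (4, "peak"), (5, "valley")]
        winners = select_complexes(extrema, amps, [(0, 8)])
        assert len(winners) == 1
        assert (winners[0].i_idx, winners[0].j_idx, winners[0].k_idx) == (1, 2, 3)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(60)
        extrema = find_extrema(x)
        span = (10, 50)
        winners = select_complexes(extrema, x, [span])
        oracle = brute_force_best_triplet(extrema, x, span)
        if oracle is None:
            assert winners == []
        else:
            assert len(winners) == 1
            w = winners[0]
            assert w.score == pytest.approx(oracle[1])
            assert (w.i_idx, w.j_idx, w.k_idx) == oracle[0]


class TestSuppression:
    def test_single_peak_unchanged(self):
        x = np.zeros(100)
        x[50] = 1.0
        np.testing.assert_array_equal(suppress_false_peaks([50], x, 50.0), [50])

    def test_close_pair_keeps_larger(self):
        x = np.zeros(100)
        x[40], x[50] = 3.0, 5.0
        np.testing.assert_array_equal(suppress_false_peaks([40, 50], x, 50.0), [50])

    def test_equal_amplitudes_keep_earlier(self):
        x = np.zeros(100)
        x[40] = x[50] = 5.0
        np.testing.assert_array_equal(suppress_false_peaks([40, 50], x, 50.0), [40])

    def test_clean_metronome_untouched(self, clean_windows):
        ws, _ = clean_windows
        w = ws.windows[3]
        js = detect_window(w)
        gaps = np.diff(js)
        assert np.all(gaps > 25)  # all 1 s apart, beyond the 0.5 s suppression radius
        assert len(js) >= 7

    def test_minimum_gap_contract(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(400)
        js = suppress_false_peaks(np.sort(rng.choice(400, 30, replace=False)), x, 50.0)
        assert np.all(np.diff(js) > 25)


class TestDetect:
    def test_clean_window_recovers_all_beats(self, clean_windows):
        ws, truth = clean_windows
        beats, _ = detect(ws)
        true_idx = np.round(truth.beat_times_s * 50).astype(int)
        errs = [np.min(np.abs(beats.peak_indices - t)) for t in true_idx]
        assert np.mean(np.asarray(errs) <= 3) >= 0.95

    def test_zero_window_empty(self):
        assert len(detect_window(np.zeros(400))) == 0

    def test_hour_long_count_within_2_percent(self, clean_profile):
        duration = 3600.0
        truth = make_beat_times(clean_profile, duration)
        rec = render_bcg(truth, duration, clean_profile)
        beats, _ = detect(segment(bandpass(rec)))
        assert len(beats.peak_indices) == pytest.approx(len(truth.beat_times_s), rel=0.02)

    def test_determinism(self, clean_windows):
        ws, _ = clean_windows
        a, _ = detect(ws)
        b, _ = detect(ws)
        np.testing.assert_array_equal(a.peak_indices, b.peak_indices)

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(st.floats(0.01, 100.0))
    def test_scale_equivariance(self, scale):
        p = SubjectProfile(
            subject_id="s", mean_hr_bpm=60, hr_wander_sd_bpm=2, ibi_jitter_sd_s=0.02,
            noise_sd=0.1, artifact_events_per_hour=0, seed=12,
        )
        truth = make_beat_times(p, 16.0)
        rec = render_bcg(truth, 16.0, p)
        w = segment(bandpass(rec)).windows[1]
        np.testing.assert_array_equal(detect_window(w), detect_window(scale * w))

    def test_excluded_windows_yield_no_peaks(self, clean_windows):
        ws, _ = clean_windows
        ws.excluded[:] = True
        beats, per_window = detect(ws)
        assert len(beats.peak_indices) == 0
        assert all(len(j) == 0 for j in per_window)


class TestHRFromBeats:
    @pytest.mark.parametrize(
        "peaks,expected",
        [
            ([25, 75, 125, 175], 60.0),
            ([0, 40, 90, 150], 60.0),  # gaps 40,50,60 -> mean 50
            ([100], float("nan")),
            ([], float("nan")),
        ],
    )
    def test_mean_gap_formula(self, peaks, expected):
        got = hr_from_beats(np.asarray(peaks), 50.0)
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(expected)

    def test_implausible_rate_undefined(self):
        assert np.isnan(hr_from_beats(np.array([0, 2, 4, 6]), 50.0))  # 1500 bpm


class TestEstimator:
    def test_parameter_recovery_on_clean_cohort(self):
        # default noise, no artifacts: per-window HR MAE <= 3 bpm
        maes = []
        for seed in range(3):
            p = SubjectProfile(
                subject_id=f"s{seed}", mean_hr_bpm=55.0, noise_sd=0.15,
                artifact_events_per_hour=0.0, seed=seed,
            )
            duration = 480.0
            truth = make_beat_times(p, duration)
            ws = segment(bandpass(render_bcg(truth, duration, p)))
            hrs = estimate_hr(ws)
            true_hr = np.array([truth.hr_in_window(i * 8.0, (i + 1) * 8.0) for i in range(len(ws))])
            ok = ~np.isnan(hrs.hr_bpm) & ~np.isnan(true_hr)
            maes.append(np.mean(np.abs(hrs.hr_bpm[ok] - true_hr[ok])))
        assert np.mean(maes) <= 3.0

    def test_sklearn_interface(self, clean_windows):
        ws, truth = clean_windows
        est = JPeakHeartRateEstimator()
        hr = est.fit(ws.windows).predict(ws.windows)
        assert hr.shape == (len(ws),)
        assert np.nanmean(hr) == pytest.approx(60.0, abs=1.0)
        assert "coarse_cutoff_hz" in est.get_params()
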