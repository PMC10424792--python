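import numpy as np
import pytest

from bcgpulse.packets import QUALITY_OK, QUALITY_REPAIRED, Recording
from bcgpulse.preprocessing import (
    WindowNormalizer,
    bandpass,
    bandpass_attenuation_db,
    normalize_windows,
    repair,
    resample_linear,
    segment,
)


def make_rec(samples, fs=50.0, kind="belt", quality=None):
    return Recording(
        subject_id="t", device_kind=kind, fs_hz=fs, t0_ms=0, samples=samples, quality=quality
    )


class TestRepair:
    def test_clean_recording_untouched(self):
        x = np.sin(np.arange(500) / 10.0)
        out = repair(make_rec(x), adc_limits=(-10, 10))
        np.testing.assert_array_equal(out.samples, x)
        assert np.all(out.quality == QUALITY_OK)

    def test_spike_replaced_by_ramp_interpolant(self):
        x = np.arange(500, dtype=float)  # smooth ramp
        x[250] = 50000.0
        out = repair(make_rec(x), adc_limits=(-1e9, 1e9))
        assert out.quality[250] == QUALITY_REPAIRED
        assert out.samples[250] == pytest.approx(250.0, abs=1e-9)

    def test_flat_saturation_run_flagged(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(500)
        x[100:150] = 10.0  # 1 s at max code
        out = repair(make_rec(x), adc_limits=(-10, 10))
        assert np.all(out.quality[100:150] == QUALITY_REPAIRED)

    def test_ok_samples_bit_identical(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(1000)
        x[300:320] = 5.0
        out = repair(make_rec(x.copy()), adc_limits=(-5, 5))
        untouched = out.quality == QUALITY_OK
        np.testing.assert_array_equal(out.samples[untouched], x[untouched])

    def test_entirely_saturated_is_error(self):
        with pytest.raises(ValueError):
            repair(make_rec(np.full(200, 7.0)), adc_limits=(-7, 7))


class TestBandpass:
    def test_zero_in_zero_out(self):
        out = bandpass(make_rec(np.zeros(400)))
        np.testing.assert_allclose(out.samples, 0.0)

    def test_band_edges_at_minus_3_db(self):
        atten = bandpass_attenuation_db([2.0, 10.0])
        np.testing.assert_allclose(atten, 3.0, atol=0.1)

    def test_passband_and_stopband_response(self):
        # analytic transfer-function magnitudes, not simulation
        mid = bandpass_attenuation_db([6.0])[0]
        assert 10 ** (-mid / 20) > 0.95  # 6 Hz within 5% of unit gain
        resp = bandpass_attenuation_db([0.3])[0]
        assert resp > 15  # respiration band attenuated by > 15 dB

    def test_rejects_other_rates_unless_explicit(self):
        with pytest.raises(ValueError):
            bandpass(make_rec(np.zeros(100), fs=100.0))
        out = bandpass(make_rec(np.zeros(100), fs=100.0), expected_fs_hz=None)
        assert len(out.samples) == 100

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass(make_rec(np.zeros(100), fs=15.0), expected_fs_hz=None)

    def test_length_preserved(self):
        x = np.random.default_rng(0).standard_normal(1234)
        assert len(bandpass(make_rec(x)).samples) == 1234


class TestSegment:
    def test_exact_and_trailing_division(self):
        assert len(segment(make_rec(np.zeros(4000)))) == 10
        assert len(segment(make_rec(np.zeros(4399)))) == 10

    def test_sample_conservation(self):
        n = 4399
        ws = segment(make_rec(np.zeros(n)))
        assert len(ws) * 400 + (n - len(ws) * 400) == n
        assert ws.windows.shape == (10, 400)
        np.testing.assert_array_equal(np.diff(ws.start_indices), 400)

    def test_repaired_fraction_threshold(self):
        q = np.zeros(400, dtype=np.uint8)
        q[:50] = QUALITY_REPAIRED  # one saturated second = 12.5%
        ws_strict = segment(make_rec(np.zeros(400), quality=q), max_repaired_frac=0.1)
        assert ws_strict.excluded[0] and ws_strict.reasons[0] == "saturation"
        ws_default = segment(make_rec(np.zeros(400), quality=q))
        assert not ws_default.excluded[0]

    def test_short_recording_warns_empty(self):
        with pytest.warns(UserWarning):
            ws = segment(make_rec(np.zeros(399)))
        assert len(ws) == 0

    def test_window_start_times(self):
        rec = make_rec(np.zeros(1200))
        rec.t0_ms = 5000
        ws = segment(rec)
        np.testing.assert_array_equal(ws.start_times_ms, [5000, 13000, 21000])


class TestNormalize:
    def test_zero_mean_unit_variance(self):
        rng = np.random.default_rng(0)
        ws = segment(make_rec(rng.standard_normal(2000)))
        out = normalize_windows(ws)
        np.testing.assert_allclose(out.windows.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.windows.var(axis=1), 1.0, atol=1e-6)

    def test_flat_window_excluded(self):
        x = np.concatenate([np.full(400, 3.0), np.random.default_rng(0).standard_normal(400)])
        out = normalize_windows(segment(make_rec(x)))
        assert out.excluded[0] and out.reasons[0] == "flat"
        assert not out.excluded[1]
        np.testing.assert_array_equal(out.windows[0], 3.0)  # untouched

    def test_idempotent(self):
        ws = segment(make_rec(np.random.default_rng(2).standard_normal(1600)))
        once = normalize_windows(ws)
        twice = normalize_windows(once)
        np.testing.assert_allclose(twice.windows, once.windows, atol=1e-12)

    def test_window_count_and_order_preserved(self):
        ws = segment(make_rec(np.random.default_rng(3).standard_normal(4000)))
        out = normalize_windows(ws)
        assert len(out) == len(ws)
        np.testing.assert_array_equal(out.start_indices, ws.start_indices)


class TestResample:
    def test_halves_length(self):
        out = resample_linear(make_rec(np.zeros(1000), fs=100.0, kind="oximeter"))
        assert len(out.samples) == 500
        assert out.fs_hz == 50.0

    def test_constant_preserved(self):
        out = resample_linear(make_rec(np.full(200, 2.5), fs=100.0))
        np.testing.assert_allclose(out.samples, 2.5)

    def test_exact_on_affine_signal(self):
        t100 = np.arange(1000) / 100.0
        out = resample_linear(make_rec(3.0 * t100 + 1.0, fs=100.0))
        t50 = np.arange(500) / 50.0
        np.testing.assert_allclose(out.samples, 3.0 * t50 + 1.0, atol=1e-12)

    def test_other_rates_rejected(self):
        with pytest.raises(ValueError):
            resample_linear(make_rec(np.zeros(100), fs=50.0))

    def test_quality_propagates_from_flanking_samples(self):
        q = np.zeros(100, dtype=np.uint8)
        q[11] = QUALITY_REPAIRED
        out = resample_linear(make_rec(np.zeros(100), fs=100.0, quality=q))
        assert out.quality[5] == QUALITY_REPAIRED  # source samples 10 and 11
        assert out.quality[6] == QUALITY_OK


class TestWindowNormalizer:
    def test_transformer_matches_function(self):
        X = np.random.default_rng(4).standard_normal((5, 400))
        out = WindowNormalizer().fit_transform(X)
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.std(axis=1), 1.0, atol=1e-9)

    def test_sklearn_params_round_trip(self):
        wn = WindowNormalizer()
        assert wn.get_params() == {}
        wn.fit(np.zeros((2, 400)))
        assert wn.n_features_in_ == 400
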