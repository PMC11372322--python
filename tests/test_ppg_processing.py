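"""PPG chain: frame averaging, filtering, smoothing, resampling, peaks."""

import numpy as np
import pytest
from scipy import signal as sp_signal

import oracles
from conftest import make_signal
from pulsekit import (
    FrameSeries,
    InvalidInputError,
    PeakSet,
    PpgConfig,
    average_frame_luminosity,
    bandpass_filter,
    detect_local_maxima,
    extract_ppg_peaks,
    prominence_filter_global,
    prominence_filter_window,
    resample_cubic_spline,
    smooth,
)


def peakset_from_prominences(proms):
    proms = np.asarray(proms, dtype=float)
    idx = np.arange(len(proms)) * 10
    return PeakSet(idx / 30.0, idx, proms)


class TestFrameAveraging:
    def test_constant_and_small_frames(self):
        fs = average_frame_luminosity(
            [np.full((3, 3), 7.0), np.array([[0.0, 1.0], [2.0, 3.0]])], [0.0, 1 / 30])
        assert fs.values[0] == 7.0
        assert fs.values[1] == 1.5

    def test_matches_per_pixel_sum(self, rng):
        frames = [rng.normal(size=(8, 8)) for _ in range(3)]
        fs = average_frame_luminosity(frames, [0.0, 0.033, 0.066])
        for i, frame in enumerate(frames):
            total = sum(frame[r, c] for r in range(8) for c in range(8))
            assert fs.values[i] == pytest.approx(total / 64, abs=1e-12)

    def test_rejects_empty_frame_and_bad_timestamps(self):
        with pytest.raises(InvalidInputError):
            average_frame_luminosity([np.empty((0, 2)), np.ones((2, 2))], [0.0, 0.1])
        with pytest.raises(InvalidInputError):
            average_frame_luminosity([np.ones((2, 2))] * 2, [0.1, 0.1])


class TestBandpass:
    def test_dc_removed(self):
        out = bandpass_filter(make_signal(np.full(1800, 5.0)))
        assert np.max(np.abs(out.values)) < 1e-6

    def test_passband_tone_preserved(self):
        # expected gain from the squared (forward-backward) magnitude response
        cfg = PpgConfig()
        t = np.arange(1800) / 30.0
        out = bandpass_filter(make_signal(np.sin(2 * np.pi * 1.5 * t)), cfg)
        sos = sp_signal.butter(cfg.filter_order, [0.75, 3.0], btype="bandpass",
                               fs=30.0, output="sos")
        _, h = sp_signal.sosfreqz(sos, worN=[1.5], fs=30.0)
        expected = np.abs(h[0]) ** 2
        interior = out.values[300:-300]
        assert np.max(np.abs(interior)) == pytest.approx(expected, rel=0.05)
        assert abs(np.max(np.abs(interior)) - 1.0) < 0.05

    def test_stopband_tone_suppressed(self):
        t = np.arange(3600) / 30.0
        out = bandpass_filter(make_signal(np.sin(2 * np.pi * 0.1 * t)))
        assert np.max(np.abs(out.values[600:-600])) < 0.1

    def test_preserves_length_and_rate(self):
        sig = make_signal(np.random.default_rng(0).normal(size=901))
        out = bandpass_filter(sig)
        assert len(out) == len(sig) and out.rate == sig.rate

    def test_too_short_rejected(self):
        with pytest.raises(InvalidInputError):
            bandpass_filter(make_signal(np.zeros(10)))


class TestSmooth:
    def test_constant_unchanged(self):
        out = smooth(make_signal(np.full(50, 3.3)))
        np.testing.assert_allclose(out.values, 3.3, atol=1e-12)

    def test_impulse_reproduces_window(self):
        x = np.zeros(41)
        x[20] = 1.0
        out = smooth(make_signal(x))
        w = np.hanning(5)
        w /= w.sum()
        np.testing.assert_allclose(out.values[18:23], w, atol=1e-12)

    def test_ramp_interior_unchanged(self):
        x = np.arange(30.0)
        out = smooth(make_signal(x))
        np.testing.assert_allclose(out.values[2:-2], x[2:-2], atol=1e-9)

    def test_linearity(self, rng):
        x = rng.normal(size=100)
        y = rng.normal(size=100)
        lhs = smooth(make_signal(2.0 * x - 3.0 * y)).values
        rhs = 2.0 * smooth(make_signal(x)).values - 3.0 * smooth(make_signal(y)).values
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_flat_window_variant(self):
        cfg = PpgConfig(smooth_window_shape="flat")
        x = np.zeros(21)
        x[10] = 5.0
        out = smooth(make_signal(x), cfg)
        np.testing.assert_allclose(out.values[8:13], 1.0, atol=1e-12)


class TestResample:
    def test_reproduces_cubic_polynomial(self):
        t = np.arange(31) / 30.0
        p = t**3 - 2 * t + 1
        out = resample_cubic_spline(make_signal(p))
        tt = out.times
        np.testing.assert_allclose(out.values, tt**3 - 2 * tt + 1, atol=1e-9)

    def test_sample_count(self):
        out = resample_cubic_spline(make_signal(np.zeros(301)))  # 10 s at 30 Hz
        assert len(out) == 1801
        assert out.rate == 180.0

    def test_sine_interpolation_error(self):
        t = np.arange(300) / 30.0
        out = resample_cubic_spline(make_signal(np.sin(2 * np.pi * t)))
        assert np.max(np.abs(out.values - np.sin(2 * np.pi * out.times))) < 1e-3

    def test_interpolates_input_samples(self, rng):
        x = rng.normal(size=60)
        out = resample_cubic_spline(make_signal(x))
        # input sample k sits at output index 6k (30 Hz -> 180 Hz)
        np.testing.assert_allclose(out.values[::6], x, atol=1e-9)

    def test_too_few_samples(self):
        with pytest.raises(InvalidInputError):
            resample_cubic_spline(make_signal([1.0, 2.0, 3.0]))


class TestDetectLocalMaxima:
    def test_monotone_ramp_has_no_peaks(self):
        assert len(detect_local_maxima(make_signal(np.arange(10.0)))) == 0

    def test_single_triangle(self):
        peaks = detect_local_maxima(make_signal([0.0, 1.0, 0.0]))
        assert list(peaks.peak_indices) == [1]
        assert peaks.prominences[0] == pytest.approx(1.0)

    def test_plateau_yields_first_sample(self):
        peaks = detect_local_maxima(make_signal([0, 2, 2, 2, 0, 3, 0]))
        assert list(peaks.peak_indices) == [1, 5]

    @pytest.mark.parametrize("seed", range(5))
    def test_random_walk_matches_oracle(self, seed):
        v = np.cumsum(np.random.default_rng(seed).normal(size=200))
        peaks = detect_local_maxima(make_signal(v))
        expected = oracles.brute_local_maxima(v)
        assert list(peaks.peak_indices) == expected
        for idx, prom in zip(peaks.peak_indices, peaks.prominences):
            assert prom == pytest.approx(oracles.brute_prominence(v, idx), abs=1e-9)


class TestProminenceFilters:
    def test_global_keeps_strong(self):
        kept = prominence_filter_global(peakset_from_prominences([10, 10, 10, 1]))
        np.testing.assert_allclose(kept.prominences, [10, 10, 10])

    def test_global_all_equal_and_single(self):
        assert len(prominence_filter_global(peakset_from_prominences([4, 4, 4]))) == 3
        assert len(prominence_filter_global(peakset_from_prominences([2.5]))) == 1

    def test_window_discards_weak_tail(self):
        kept = prominence_filter_window(peakset_from_prominences([10, 10, 10, 10, 2]))
        np.testing.assert_allclose(kept.prominences, [10, 10, 10, 10])

    def test_window_all_equal_kept(self):
        assert len(prominence_filter_window(peakset_from_prominences([7] * 8))) == 8

    @pytest.mark.parametrize("proms", [
        [10, 2] * 10,
        [1, 5, 1, 9, 1, 5, 9, 2, 8, 8, 1, 1, 4],
    ])
    def test_window_matches_oracle(self, proms):
        cfg = PpgConfig()
        kept = prominence_filter_window(peakset_from_prominences(proms), cfg)
        expected = oracles.brute_window_filter(
            np.asarray(proms, float), cfg.window_prominence_fraction,
            cfg.prominence_window_peaks)
        np.testing.assert_allclose(kept.peak_indices, np.arange(len(proms))[expected] * 10)

    def test_filters_only_remove_and_preserve_times(self, rng):
        proms = rng.uniform(0.1, 10, size=40)
        peaks = peakset_from_prominences(proms)
        for filt in (prominence_filter_global, prominence_filter_window):
            out = filt(peaks)
            assert set(out.peak_times) <= set(peaks.peak_times)
            order = np.searchsorted(peaks.peak_times, out.peak_times)
            np.testing.assert_allclose(peaks.prominences[order], out.prominences)


class TestExtractPipeline:
    def test_clean_recording_recovers_every_beat(self, clean_subject):
        cfg, truth, ppg = clean_subject
        peaks = extract_ppg_peaks(ppg)
        assert len(peaks) == truth.n_beats
        err = np.abs(peaks.peak_times - truth.ppg_peak_times_s)
        assert err.max() <= 2 / 180.0

    def test_dicrotic_bumps_are_removed(self):
        from pulsekit import SimConfig, generate_rr_series, synthesize_ppg
        cfg = SimConfig(duration_s=120, seed=21, ppg_noise_sd=0.0,
                        drift_amplitude=0.0, dicrotic_rel_amplitude=0.4)
        truth = generate_rr_series(cfg)
        peaks = extract_ppg_peaks(synthesize_ppg(truth, cfg))
        assert len(peaks) == truth.n_beats

    def test_flat_input_yields_no_peaks(self):
        t = np.arange(900) / 30.0
        flat = FrameSeries(t, np.full(900, 42.0))
        assert len(extract_ppg_peaks(flat)) == 0

    def test_short_recording_rejected(self):
        t = np.arange(90) / 30.0
        with pytest.raises(InvalidInputError):
            extract_ppg_peaks(FrameSeries(t, np.sin(t)))

    def test_jittered_timestamps_rejected_beyond_tolerance(self):
        t = np.arange(900) / 30.0
        t[450] += 0.012  # > 20% of the 33 ms frame period
        with pytest.raises(InvalidInputError):
            extract_ppg_peaks(FrameSeries(t, np.sin(2 * np.pi * 1.2 * t)))
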