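"""SG filtering, peak detection, and peak statistics against oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glucopipe import synthetic
from glucopipe.errors import InsufficientPeaksError, ParameterError
from glucopipe.ppg import (PPG_FEATURE_NAMES, FilterConfig, PeakConfig,
                           baseline_correct, detect_peaks,
                           extract_ppg_features, peak_statistics, sg_smooth,
                           shannon_entropy)


def sg_oracle(x, window, order):
    """Per-window least-squares fit evaluated at the center; edge windows
    are fitted once and evaluated at the uncovered edge positions
    (matching 'interp' edge handling)."""
    x = np.asarray(x, float)
    n, half = len(x), window // 2
    out = np.empty(n)
    for i in range(half, n - half):
        seg = x[i - half:i + half + 1]
        coef = np.polynomial.polynomial.polyfit(np.arange(window), seg, order)
        out[i] = np.polynomial.polynomial.polyval(half, coef)
    head = np.polynomial.polynomial.polyfit(np.arange(window), x[:window], order)
    tail = np.polynomial.polynomial.polyfit(np.arange(window), x[-window:], order)
    for i in range(half):
        out[i] = np.polynomial.polynomial.polyval(i, head)
        out[n - 1 - i] = np.polynomial.polynomial.polyval(window - 1 - i, tail)
    return out


class TestSGSmooth:
    def test_constant_passes_through(self):
        x = np.full(50, 3.7)
        np.testing.assert_allclose(sg_smooth(x, 11, 3), x, rtol=1e-12)

    def test_cubic_reproduced_exactly(self):
        t = np.linspace(-1, 1, 101)
        x = t ** 3
        np.testing.assert_allclose(sg_smooth(x, 21, 3), x, rtol=1e-9, atol=1e-12)

    def test_matches_per_window_regression_oracle(self, rng):
        x = rng.normal(size=9)
        np.testing.assert_allclose(sg_smooth(x, 5, 2), sg_oracle(x, 5, 2),
                                   rtol=1e-9, atol=1e-10)

    def test_linearity(self, rng):
        for _ in range(10):
            x, y = rng.normal(size=(2, 60))
            a, b = rng.normal(size=2)
            lhs = sg_smooth(a * x + b * y, 15, 3)
            rhs = a * sg_smooth(x, 15, 3) + b * sg_smooth(y, 15, 3)
            np.testing.assert_allclose(lhs, rhs, rtol=1e-9, atol=1e-9)

    @pytest.mark.parametrize("window,order", [(10, 3), (5, 5), (3, 3)])
    def test_bad_window_rejected(self, window, order):
        with pytest.raises(ParameterError):
            sg_smooth(np.zeros(100), window, order)


class TestBaselineCorrect:
    def test_constant_maps_to_zero(self):
        out = baseline_correct(np.full(500, 2.5), 100.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_linear_ramp_maps_to_zero(self):
        out = baseline_correct(np.linspace(0, 5, 1000), 100.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_removes_drift_from_simulated_recording(self, participant):
        acq_drift = synthetic.AcquisitionConfig(duration_s=30.0, noise_sigma=0.0)
        acq_flat = synthetic.AcquisitionConfig(duration_s=30.0, noise_sigma=0.0,
                                               drift_amplitude=0.0)
        with_drift = synthetic.generate_dual_ppg(
            participant, acq_drift, np.random.default_rng(8))
        without = synthetic.generate_dual_ppg(
            participant, acq_flat, np.random.default_rng(8))
        c1 = baseline_correct(with_drift.red, 100.0)
        c2 = baseline_correct(without.red, 100.0)
        pulse_amp = without.red.max()
        assert np.max(np.abs(c1 - c2)) < 0.1 * pulse_amp

    def test_low_frequency_content_suppressed(self, participant):
        acq = synthetic.AcquisitionConfig(duration_s=30.0, noise_sigma=0.0)
        rec = synthetic.generate_dual_ppg(participant, acq,
                                          np.random.default_rng(8))
        corrected = baseline_correct(rec.red, 100.0)
        amp = corrected.max()
        # mean over any 2 s window stays a small fraction of pulse amplitude
        for start in range(0, len(corrected) - 200, 200):
            assert abs(corrected[start:start + 200].mean()) < 0.2 * amp


class TestDetectPeaks:
    def test_sine_peak_count_and_locations(self):
        t = np.arange(1000) / 100.0
        peaks = detect_peaks(np.sin(2 * np.pi * t), 100.0)
        assert len(peaks) == 10
        expected = 25 + 100 * np.arange(10)
        assert np.max(np.abs(peaks - expected)) <= 1

    def test_monotone_signal_has_no_peaks(self):
        assert len(detect_peaks(np.linspace(0, 1, 500), 100.0)) == 0

    def test_two_gaussians_detected_at_centers(self):
        t = np.arange(600) / 100.0
        x = (np.exp(-0.5 * ((t - 2.0) / 0.1) ** 2)
             + np.exp(-0.5 * ((t - 4.0) / 0.1) ** 2))
        peaks = detect_peaks(x, 100.0)
        assert list(peaks) == [200, 400]

    def test_min_distance_enforced(self):
        t = np.arange(2000) / 100.0
        peaks = detect_peaks(np.sin(2 * np.pi * 2.0 * t), 100.0,
                             PeakConfig(min_distance_s=0.6))
        assert len(peaks) >= 2
        assert np.min(np.diff(peaks)) >= 60


def naive_stats(a):
    a = np.asarray(a, float)
    m = a.mean()
    m2 = ((a - m) ** 2).mean()
    m3 = ((a - m) ** 3).mean()
    m4 = ((a - m) ** 4).mean()
    return (m, m2, 0.0 if m2 == 0 else m3 / m2 ** 1.5,
            0.0 if m2 == 0 else m4 / m2 ** 2 - 3.0, np.sqrt(m2))


class TestPeakStatistics:
    def test_frozen_four_point_example(self):
        s = peak_statistics(np.array([1.0, 2.0, 3.0, 4.0]))
        assert s.mean == pytest.approx(2.5)
        assert s.variance == pytest.approx(1.25)
        assert s.std == pytest.approx(1.118033988749895)
        assert s.skewness == pytest.approx(0.0, abs=1e-12)
        assert s.kurtosis == pytest.approx(-1.36)

    def test_degenerate_sample_uses_zero_conventions(self):
        s = peak_statistics(np.array([5.0, 5.0, 5.0]))
        assert (s.variance, s.skewness, s.kurtosis, s.entropy) == (0, 0, 0, 0)

    def test_symmetric_sample_has_zero_skewness(self, rng):
        half = rng.normal(size=20)
        s = peak_statistics(np.concatenate([half, -half]))
        assert abs(s.skewness) < 1e-12

    def test_matches_naive_moment_oracle(self, rng):
        for _ in range(1000):
            a = rng.normal(size=rng.integers(2, 30))
            s = peak_statistics(a)
            m, m2, sk, ku, sd = naive_stats(a)
            np.testing.assert_allclose(
                [s.mean, s.variance, s.skewness, s.kurtosis, s.std],
                [m, m2, sk, ku, sd], rtol=1e-10, atol=1e-12)

    def test_single_peak_rejected(self):
        with pytest.raises(InsufficientPeaksError):
            peak_statistics(np.array([1.0]))


class TestShannonEntropy:
    def test_all_equal_is_zero_bits(self):
        assert shannon_entropy(np.full(10, 2.0)) == 0.0

    def test_uniform_eight_categories_is_three_bits(self):
        assert shannon_entropy(np.arange(8.0), 8) == pytest.approx(3.0)

    def test_two_balanced_categories_is_one_bit(self):
        assert shannon_entropy(np.array([0.0, 0.0, 1.0, 1.0]), 2) == pytest.approx(1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=50),
           st.integers(1, 16))
    def test_entropy_bounds(self, values, n_bins):
        h = shannon_entropy(np.array(values), n_bins)
        assert 0.0 <= h <= np.log2(n_bins) + 1e-12

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            shannon_entropy(np.array([]))


class TestExtractFeatures:
    def test_returns_twelve_features(self, small_cohort):
        vec = extract_ppg_features(small_cohort.recordings[0])
        assert vec.valid
        assert vec.as_array().shape == (12,)
        assert len(PPG_FEATURE_NAMES) == 12

    def test_identical_channels_give_identical_statistics(self, small_cohort):
        rec = small_cohort.recordings[0]
        twin = synthetic.DualPPGRecording(rec.sampling_rate_hz,
                                          red=rec.red, infrared=rec.red)
        vec = extract_ppg_features(twin)
        np.testing.assert_allclose(vec.as_array()[0::2], vec.as_array()[1::2])

    def test_matches_hand_driven_composition(self, participant, clean_acq):
        rec = synthetic.generate_dual_ppg(participant, clean_acq,
                                          np.random.default_rng(2))
        vec = extract_ppg_features(rec)
        fc, pc = FilterConfig(), PeakConfig()
        expected = []
        for ch in (rec.infrared, rec.red):
            corr = baseline_correct(ch, rec.sampling_rate_hz, fc)
            s = peak_statistics(corr[detect_peaks(corr, rec.sampling_rate_hz, pc)])
            expected.append(s.as_array())
        manual = np.empty(12)
        manual[0::2], manual[1::2] = expected
        np.testing.assert_allclose(vec.as_array(), manual, rtol=1e-12)

    def test_flat_recording_flagged_invalid(self):
        rec = synthetic.DualPPGRecording(100.0, red=np.zeros(1000),
                                         infrared=np.zeros(1000))
        vec = extract_ppg_features(rec)
        assert not vec.valid
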