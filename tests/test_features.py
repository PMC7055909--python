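"""Feature formulas: spectra, f0, harmonic quotients, entropy, jitter, shimmer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nsavoice import (
    CycleSeries,
    InsufficientCyclesError,
    SpectrumView,
    UndefinedFeatureError,
    UnvoicedError,
    compute_spectrum,
    detect_cycles,
    estimate_f0,
    extract_features,
    harmonic_amplitudes,
    harmonic_quotients,
    jitter,
    shimmer,
    spectral_entropy,
    synthesize_waveform,
)
from nsavoice.synth import PROFILES

from conftest import clean_profile


def tone(freqs_amps, rate=44100.0, duration=2.0):
    t = np.arange(int(duration * rate)) / rate
    return sum(a * np.sin(2 * np.pi * f * t) for f, a in freqs_amps)


def delta_spectrum(harmonic_amps, f0=200.0, df=0.5, fmax=3500.0):
    """A spectrum that is zero except for delta peaks at the harmonics."""
    freqs = np.arange(0.0, fmax, df)
    mag = np.zeros_like(freqs)
    for i, a in enumerate(harmonic_amps, start=1):
        mag[int(round(i * f0 / df))] = a
    return SpectrumView(freqs_hz=freqs, magnitude=mag, resolution_hz=df)


class TestComputeSpectrum:
    def test_pure_tone_peak_location(self):
        spec = compute_spectrum(tone([(200.0, 1.0)]), 44100.0)
        assert spec.resolution_hz <= 1.0
        assert abs(spec.freqs_hz[np.argmax(spec.magnitude)] - 200.0) <= 1.0

    def test_two_tone_magnitude_ratio(self):
        spec = compute_spectrum(tone([(200.0, 1.0), (400.0, 0.5)]), 44100.0)
        a1 = spec.magnitude[np.abs(spec.freqs_hz - 200.0) <= 2.0].max()
        a2 = spec.magnitude[np.abs(spec.freqs_hz - 400.0) <= 2.0].max()
        assert a2 / a1 == pytest.approx(0.5, abs=0.02)

    def test_white_noise_spectrum_is_flat_after_smoothing(self, rng):
        from scipy.ndimage import uniform_filter1d

        spec = compute_spectrum(rng.standard_normal(2 * 44100), 44100.0)
        band = spec.magnitude[(spec.freqs_hz >= 50.0) & (spec.freqs_hz <= 3000.0)]
        smooth = uniform_filter1d(band, 501)
        assert smooth.max() <= 3.0 * np.median(smooth)

    def test_rejects_empty_and_silent_segments(self):
        with pytest.raises(ValueError):
            compute_spectrum(np.array([]), 44100.0)
        with pytest.raises(ValueError):
            compute_spectrum(np.zeros(1000), 44100.0)

    def test_amplitude_normalization_makes_gain_irrelevant(self):
        x = tone([(220.0, 1.0), (440.0, 0.3)])
        a = compute_spectrum(x, 44100.0)
        b = compute_spectrum(5.0 * x, 44100.0)
        assert np.allclose(a.magnitude, b.magnitude)


class TestEstimateF0:
    def test_synthetic_vowel_within_one_hz(self):
        rec = synthesize_waveform(clean_profile("modal", f0_hz=220.0), 2.0, seed=1)
        assert estimate_f0(rec.samples, rec.rate_hz) == pytest.approx(220.0, abs=1.0)

    def test_white_noise_unvoiced(self, rng):
        with pytest.raises(UnvoicedError):
            estimate_f0(rng.standard_normal(2 * 44100), 44100.0)

    def test_out_of_band_search_unvoiced(self):
        rec = synthesize_waveform(clean_profile("modal", f0_hz=220.0), 2.0, seed=1)
        with pytest.raises(UnvoicedError):
            estimate_f0(rec.samples, rec.rate_hz, fmin_hz=300.0, fmax_hz=400.0)


class TestHarmonicQuotients:
    def test_equal_amplitudes_symmetric(self):
        spec = delta_spectrum([1.0] * 5)
        assert harmonic_quotients(spec, 200.0) == pytest.approx((0.2,) * 4)

    def test_direct_arithmetic_oracle(self):
        spec = delta_spectrum([6.0, 2.0, 1.0, 0.6, 0.4])
        h = harmonic_quotients(spec, 200.0)
        assert h == pytest.approx((0.6, 0.2, 0.1, 0.06), abs=1e-12)

    def test_harmonics_above_band_count_zero(self):
        # f0 = 400: harmonics 4 and 5 sit above 1500 Hz
        spec = delta_spectrum([1.0, 1.0, 1.0, 1.0, 1.0], f0=400.0)
        h = harmonic_quotients(spec, 400.0)
        assert sum(h) == pytest.approx(1.0)  # A4 = A5 = 0, mass on H1..H3... H4
        assert h[3] == 0.0

    def test_all_zero_spectrum_undefined(self):
        spec = delta_spectrum([0.0] * 5)
        with pytest.raises(UndefinedFeatureError):
            harmonic_quotients(spec, 200.0)

    @given(st.lists(st.floats(0.01, 100.0), min_size=5, max_size=5))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_closure_sum_of_five_is_unity(self, amps):
        spec = delta_spectrum(amps)
        a = harmonic_amplitudes(spec, 200.0)
        h = a / a.sum()
        assert abs(h.sum() - 1.0) < 1e-12
        four = harmonic_quotients(spec, 200.0)
        assert 0.0 <= 1.0 - sum(four) <= 1.0 + 1e-12  # implied H5 in [0, 1]


class TestSpectralEntropy:
    def test_single_bin_zero_entropy(self):
        spec = delta_spectrum([1.0])
        assert spectral_entropy(spec) == 0.0

    def test_uniform_spectrum_ln_n(self):
        freqs = np.linspace(0.0, 3000.0, 1200)
        spec = SpectrumView(freqs, np.ones_like(freqs), freqs[1] - freqs[0])
        assert spectral_entropy(spec) == pytest.approx(np.log(1200), rel=1e-12)
        assert spectral_entropy(spec, base=2.0) == pytest.approx(np.log2(1200), rel=1e-12)

    def test_sinusoid_below_white_noise(self, rng):
        se_tone = spectral_entropy(compute_spectrum(tone([(220.0, 1.0)]), 44100.0))
        se_noise = spectral_entropy(compute_spectrum(rng.standard_normal(2 * 44100), 44100.0))
        assert se_tone < se_noise

    def test_entropy_bounded_by_ln_band_bins(self, rng):
        spec = compute_spectrum(rng.standard_normal(44100), 44100.0)
        n_bins = int(np.sum((spec.freqs_hz >= 0.0) & (spec.freqs_hz <= 3000.0)))
        assert 0.0 <= spectral_entropy(spec) <= np.log(n_bins)


class TestDetectCycles:
    def test_recovers_truth_periods_within_one_sample(self):
        rec = synthesize_waveform(clean_profile("modal", jitter_pct=1.0), 2.0, seed=2)
        cycles = detect_cycles(rec.samples, rec.truth.f0_hz, rec.rate_hz)
        truth = rec.truth.cycle_periods_s
        n = min(len(cycles.periods), len(truth))
        # align by best offset 0/1 (edge cycles may be dropped)
        err = np.abs(cycles.periods[:n] - truth[:n]).max()
        assert err <= 1.0 / rec.rate_hz

    def test_cycle_count_matches_duration_times_f0(self):
        rec = synthesize_waveform(clean_profile("modal", f0_hz=220.0), 2.0, seed=3)
        cycles = detect_cycles(rec.samples, 220.0, rec.rate_hz)
        assert abs(cycles.n_cycles - 440) <= 3

    def test_too_short_segment_insufficient(self):
        with pytest.raises(InsufficientCyclesError):
            detect_cycles(np.zeros(50), 220.0, 44100.0)


class TestPerturbationMeasures:
    def test_constant_series_zero(self):
        c = CycleSeries(np.full(10, 0.005), np.full(10, 1.0))
        assert jitter(c) == 0.0 and shimmer(c) == 0.0

    def test_alternating_period_oracle(self):
        periods = np.tile([0.010, 0.011], 50)
        c = CycleSeries(periods, np.ones_like(periods))
        assert jitter(c) == pytest.approx(0.001 / 0.0105, abs=1e-12)

    def test_alternating_amplitude_oracle(self):
        amps = np.tile([1.0, 1.2], 50)
        c = CycleSeries(np.full_like(amps, 0.005), amps)
        assert shimmer(c) == pytest.approx(0.2 / 1.1, abs=1e-12)

    @given(
        st.lists(st.floats(1e-4, 1e-1), min_size=2, max_size=40),
        st.floats(0.1, 10.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_scale_invariance(self, periods, gain):
        periods = np.asarray(periods)
        amps = periods * 3.0 + 0.01  # arbitrary positive amplitudes
        c = CycleSeries(periods, amps)
        scaled = CycleSeries(periods * gain, amps * gain)
        assert jitter(scaled) == pytest.approx(jitter(c), rel=1e-9)
        assert shimmer(scaled) == pytest.approx(shimmer(c), rel=1e-9)
        assert jitter(c) >= 0.0 and shimmer(c) >= 0.0

    def test_insufficient_cycles_rejected(self):
        with pytest.raises(InsufficientCyclesError):
            CycleSeries(np.array([0.005]), np.array([1.0]))


class TestExtractFeatures:
    def test_noiseless_profile_recovery(self, clean_modal_record):
        fv = extract_features(clean_modal_record)
        w = np.asarray(PROFILES["modal"].harmonic_weights)
        expected = w / w.sum()
        assert np.allclose([fv.H1, fv.H2, fv.H3, fv.H4], expected[:4], atol=0.02)
        assert fv.Jr < 0.001 and fv.Sr < 0.001
        assert fv.label == "modal"

    def test_deterministic(self, modal_record):
        a = extract_features(modal_record)
        b = extract_features(modal_record)
        assert a == b

    def test_pressed_entropy_exceeds_breathy(self):
        se = {}
        for name in ("pressed", "breathy"):
            vals = [
                extract_features(
                    synthesize_waveform(PROFILES[name], 2.0, silence_s=0.3, seed=50 + i)
                ).SE
                for i in range(5)
            ]
            se[name] = np.mean(vals)
        assert se["pressed"] > se["breathy"]

    def test_gain_invariance_of_all_features(self, clean_modal_record):
        from nsavoice import WaveformRecord

        louder = WaveformRecord(
            clean_modal_record.samples * 5.0,
            clean_modal_record.rate_hz,
            clean_modal_record.truth,
        )
        a = extract_features(clean_modal_record)
        b = extract_features(louder)
        assert np.allclose(a.as_array(), b.as_array(), rtol=1e-9)
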