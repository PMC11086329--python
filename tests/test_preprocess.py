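"""Filtering, baseline removal, SNR and windowing tests."""

import numpy as np
import pytest
from scipy.signal import sosfreqz, sos2zpk

from ppgrehab.preprocess import (
    FilterSpec,
    apply_filter,
    compute_snr,
    design_chebyshev2,
    remove_baseline_spline,
    segment_windows,
)
from ppgrehab.synth import generate_dataset

FS = 100.0


def response_db(sos, f, fs=FS):
    w, h = sosfreqz(sos, worN=2 ** 15, fs=fs)
    return 20.0 * np.log10(np.abs(h[np.argmin(np.abs(w - f))]) + 1e-300)


def sine_amplitude(x, f, fs=FS):
    # Fourier-magnitude amplitude oracle at frequency f
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(len(x), 1 / fs)
    return 2.0 * np.abs(spec[np.argmin(np.abs(freqs - f))]) / len(x)


class TestChebyshevDesign:
    def test_stopband_attenuation_met(self):
        spec = FilterSpec.default_chebyshev2()
        sos = design_chebyshev2(spec, FS)
        for edge in spec.stopband_hz:
            assert response_db(sos, edge) <= -spec.stopband_atten_db

    def test_passband_center_near_unity(self):
        spec = FilterSpec.default_chebyshev2()
        sos = design_chebyshev2(spec, FS)
        center = np.sqrt(spec.passband_hz[0] * spec.passband_hz[1])
        assert abs(response_db(sos, center)) <= 1.0

    def test_poles_strictly_stable(self):
        sos = design_chebyshev2(FilterSpec.default_chebyshev2(), FS)
        _, p, _ = sos2zpk(sos)
        assert np.all(np.abs(p) < 1.0)

    def test_band_edges_beyond_nyquist_raise(self):
        spec = FilterSpec(stopband_hz=(0.2, 60.0))
        with pytest.raises(ValueError):
            design_chebyshev2(spec, FS)


class TestApplyFilter:
    def test_zero_input_zero_output(self):
        out = apply_filter(np.zeros(1000), FilterSpec.default_chebyshev2(), FS)
        np.testing.assert_allclose(out, 0.0)

    def test_in_band_sinusoid_preserved(self):
        t = np.arange(0, 60, 1 / FS)
        x = np.sin(2 * np.pi * 1.2 * t)
        y = apply_filter(x, FilterSpec.default_chebyshev2(), FS)
        assert abs(sine_amplitude(y, 1.2) - 1.0) <= 0.05

    def test_drift_band_sinusoid_removed(self):
        t = np.arange(0, 120, 1 / FS)
        x = np.sin(2 * np.pi * 0.05 * t)
        y = apply_filter(x, FilterSpec.default_chebyshev2(), FS)
        assert sine_amplitude(y, 0.05) <= 0.01

    def test_short_signal_raises_length_error(self):
        with pytest.raises(ValueError, match="length"):
            apply_filter(np.ones(10), FilterSpec.default_chebyshev2(), FS)

    def test_zero_phase_no_lag(self, quiet_record):
        rec = quiet_record(hr_bpm=75.0)
        x = rec.green - rec.green.mean()
        y = apply_filter(rec.green, FilterSpec.default_chebyshev2(), FS)
        corr = np.correlate(y, x, mode="full")
        lag = int(np.argmax(corr)) - (len(x) - 1)
        assert lag == 0

    @pytest.mark.parametrize("spec", [
        FilterSpec.default_chebyshev2(),
        FilterSpec.default_gaussian(),
        FilterSpec.default_moving_average(),
    ])
    def test_filtering_never_increases_power(self, spec):
        rng = np.random.default_rng(0)
        t = np.arange(0, 30, 1 / FS)
        x = np.sin(2 * np.pi * 1.3 * t) + 0.5 * rng.standard_normal(t.size)
        y = apply_filter(x, spec, FS)
        assert np.sum(y ** 2) <= np.sum(x ** 2) * (1 + 1e-9)


class TestBaselineSpline:
    def test_constant_signal_maps_to_zero(self):
        out = remove_baseline_spline(np.full(500, 3.7), FS)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_linear_trend_removed_from_beat_train(self, quiet_record):
        rec = quiet_record(hr_bpm=70.0)
        slope = 0.05  # per sample
        trend = slope * np.arange(rec.n_samples)
        x = (rec.green - rec.green.mean()) + trend
        y = remove_baseline_spline(x, FS)
        # least-squares slope oracle
        n = np.arange(y.size)
        fit = np.polyfit(n, y, 1)[0]
        assert abs(fit) <= 0.05 * slope

    def test_idempotent_on_valley_anchored_input(self):
        # pulse bumps separated by exact-zero valleys
        bump = np.sin(np.linspace(0, np.pi, 60)) ** 2
        x = np.concatenate([np.r_[np.zeros(20), bump, np.zeros(20)]] * 8)
        y = remove_baseline_spline(x, FS)
        np.testing.assert_allclose(y, x, atol=1e-6 * np.max(x))


class TestSnr:
    def test_pure_in_band_tone_has_high_snr(self):
        t = np.arange(0, 30, 1 / FS)
        assert compute_snr(np.sin(2 * np.pi * 2.0 * t), FS) >= 60.0

    def test_matches_analytic_band_power_ratio(self):
        # analytic expectation oracle: white noise spreads its variance
        # uniformly across [0, fs/2]
        rng = np.random.default_rng(7)
        t = np.arange(0, 120, 1 / FS)
        a, sigma = 1.0, 0.5
        lo, hi = 0.5, 10.0
        x = a * np.sin(2 * np.pi * 2.0 * t) + sigma * rng.standard_normal(t.size)
        frac_in = (hi - lo) / (FS / 2)
        expected = 10 * np.log10(
            (a ** 2 / 2 + sigma ** 2 * frac_in) / (sigma ** 2 * (1 - frac_in))
        )
        assert abs(compute_snr(x, FS) - expected) <= 1.0

    def test_halving_noise_raises_snr_six_db(self):
        rng = np.random.default_rng(8)
        t = np.arange(0, 120, 1 / FS)
        tone = np.sin(2 * np.pi * 2.0 * t)
        noise = rng.standard_normal(t.size)
        delta = compute_snr(tone + 0.25 * noise, FS) - compute_snr(
            tone + 0.5 * noise, FS)
        assert abs(delta - 6.0) <= 1.0

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError):
            compute_snr(np.ones(100), FS)


class TestSegmentWindows:
    def test_window_counts(self, quiet_record):
        rec = quiet_record(duration_s=60.0)
        assert len(segment_windows([rec], 5.0)) == 12
        assert len(segment_windows([rec], 5.0, overlap_frac=0.5)) == 23

    def test_empty_record_list(self):
        ws = segment_windows([], 5.0)
        assert len(ws) == 0

    def test_windows_are_z_scored_and_labelled(self, quiet_record):
        rec = quiet_record(duration_s=20.0)
        ws = segment_windows([rec], 5.0)
        np.testing.assert_allclose(ws.windows.mean(axis=2), 0.0, atol=1e-9)
        np.testing.assert_allclose(ws.windows.std(axis=2), 1.0, atol=1e-6)
        assert set(ws.labels) == {rec.stage}
        assert set(ws.subject_ids) == {rec.subject_id}

    def test_invalid_overlap_raises(self, quiet_record):
        with pytest.raises(ValueError):
            segment_windows([quiet_record(duration_s=10.0)], 5.0, overlap_frac=1.0)


def test_filter_snr_ordering_on_corrupted_records():
    """With all three noise classes at default levels the Chebyshev II
    band-pass beats the smoothing filters on in-band/out-of-band SNR."""
    from ppgrehab.synth import SynthConfig

    wins = 0
    for seed in range(3):
        cfg = SynthConfig(subjects_per_class={"V": 0, "VI": 0, "VII": 1},
                          duration_s=60.0, seed=seed)
        rec = generate_dataset(cfg)[0]
        snr = {
            fam: compute_snr(apply_filter(rec.green, spec, rec.fs), rec.fs)
            for fam, spec in [
                ("cheb", FilterSpec.default_chebyshev2()),
                ("gauss", FilterSpec.default_gaussian()),
                ("ma", FilterSpec.default_moving_average()),
            ]
        }
        if snr["cheb"] >= snr["gauss"] and snr["cheb"] >= snr["ma"]:
            wins += 1
    assert wins == 3
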