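"""Unit tests of the dual-channel processing chain."""

import numpy as np
import pytest
from numpy.lib.stride_tricks import sliding_window_view

from photolock.errors import (
    DegenerateFitError,
    NumericDomainError,
    ParameterError,
    ShapeError,
)
from photolock.photometry import (
    PhotometryRecording,
    ProcessParams,
    compute_dff,
    detrend,
    fit_control_channel,
    loess_smooth,
    lowpass_filter,
    moving_minima_baseline,
    process_recording,
    running_minimum,
    zscore_trace,
)
from photolock.synthdata import SimConfig, simulate_photometry

from conftest import make_recording


class TestLowpass:
    def test_dc_preserved(self):
        rec = make_recording(np.full(500, 7.0), np.full(500, 3.0), rate_hz=100.0)
        out = lowpass_filter(rec, 12.0)
        assert np.allclose(out.ch465, 7.0, atol=1e-9)
        assert np.allclose(out.ch405, 3.0, atol=1e-9)

    def test_stopband_attenuation_and_passband_flatness(self):
        # 1 Hz kept within 1%, 50 Hz attenuated by >= 20 dB (FFT oracle)
        rate = 200.0
        t = np.arange(4000) / rate
        sig = np.sin(2 * np.pi * 1.0 * t) + np.sin(2 * np.pi * 50.0 * t)
        rec = make_recording(sig, sig, rate_hz=rate)
        out = lowpass_filter(rec, 12.0)
        spec_in = np.abs(np.fft.rfft(sig))
        spec_out = np.abs(np.fft.rfft(out.ch465))
        freqs = np.fft.rfftfreq(len(t), 1 / rate)
        i1 = np.argmin(np.abs(freqs - 1.0))
        i50 = np.argmin(np.abs(freqs - 50.0))
        assert spec_out[i1] / spec_in[i1] > 0.99
        assert spec_out[i50] / spec_in[i50] < 10 ** (-20 / 20)

    def test_zero_phase_impulse(self):
        x = np.zeros(801)
        x[400] = 1.0
        rec = make_recording(x, x, rate_hz=100.0)
        out = lowpass_filter(rec, 12.0)
        assert int(np.argmax(out.ch465)) == 400

    def test_cutoff_above_nyquist_rejected(self):
        rec = make_recording(np.zeros(100), np.zeros(100), rate_hz=20.0)
        with pytest.raises(ParameterError):
            lowpass_filter(rec, 12.0)


class TestLoess:
    def test_constant_reproduced(self):
        out = loess_smooth(np.full(200, 4.2), 0.1)
        assert np.allclose(out, 4.2, atol=1e-12)

    def test_linear_ramp_reproduced(self):
        y = np.linspace(0.0, 9.0, 300)
        out = loess_smooth(y, 0.1)
        assert np.allclose(out[15:-15], y[15:-15], atol=1e-8)

    def test_noise_reduction_on_sine(self, rng):
        t = np.linspace(0, 4 * np.pi, 2000)
        clean = np.sin(t)
        noisy = clean + rng.normal(0, 0.5, len(t))
        sm = loess_smooth(noisy, 0.05)
        assert np.sqrt(np.mean((sm - clean) ** 2)) < np.sqrt(np.mean((noisy - clean) ** 2))

    def test_span_too_small_rejected(self):
        with pytest.raises(ParameterError):
            loess_smooth(np.arange(1000.0), 0.0005)  # covers < 2 samples


class TestMovingMinima:
    def test_running_minimum_matches_bruteforce(self, rng):
        # exact agreement with a naive O(n*w) centered, clamped window
        for w in (5, 20, 101):
            y = np.cumsum(rng.normal(size=2000))
            half = w // 2
            padded = np.concatenate([np.full(half, np.inf), y, np.full(w - half - 1, np.inf)])
            naive = sliding_window_view(padded, w).min(axis=1)
            assert np.array_equal(running_minimum(y, w), naive)

    def test_monotone_series_clamped(self):
        y = np.arange(100.0)
        w = 11
        out = running_minimum(y, w)
        expect = np.maximum(np.arange(100) - w // 2, 0).astype(float)
        assert np.array_equal(out, expect)

    def test_constant_baseline(self):
        base = moving_minima_baseline(np.full(400, 3.0), 1.0, 20.0)
        assert np.allclose(base, 3.0, atol=1e-9)

    def test_envelope_ignores_short_transients(self):
        # flat floor with positive bumps shorter than the window: the
        # pre-smoothing envelope equals the floor everywhere
        y = np.zeros(2000)
        for k in (300, 900, 1500):
            y[k : k + 20] = 5.0
        _, raw = moving_minima_baseline(y, window_s=10.0, rate_hz=20.0, return_raw=True)
        assert np.allclose(raw, 0.0, atol=1e-12)

    def test_envelope_below_signal(self, rng):
        y = np.cumsum(rng.normal(size=3000)) + rng.normal(size=3000)
        _, raw = moving_minima_baseline(y, window_s=5.0, rate_hz=20.0, return_raw=True)
        assert np.all(raw <= y + 1e-12)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ParameterError):
            moving_minima_baseline(np.zeros(100), window_s=10.0, rate_hz=20.0)


class TestDetrend:
    def test_exact_baseline_gives_zero(self):
        y = np.linspace(1, 5, 50)
        assert np.allclose(detrend(y, y), 0.0)

    def test_shift_invariance(self, rng):
        y = rng.normal(size=100)
        b = rng.normal(size=100)
        assert np.allclose(detrend(y + 3.7, b + 3.7), detrend(y, b))

    def test_removes_monotone_trend(self, rng):
        from scipy.stats import spearmanr

        t = np.arange(6000) / 20.0
        bleach = 100 * (0.8 + 0.2 * np.exp(-t / 200.0))
        sig = bleach + rng.normal(0, 0.5, len(t))
        for k in range(500, 5500, 500):
            sig[k : k + 30] += 5.0
        base = moving_minima_baseline(sig, window_s=30.0, rate_hz=20.0)
        out = detrend(sig, base)
        rho, _ = spearmanr(out, t)
        assert abs(rho) < 0.05

    def test_length_mismatch(self):
        with pytest.raises(ShapeError):
            detrend(np.zeros(10), np.zeros(9))


class TestControlFit:
    def test_exact_linear_relation(self):
        x = np.linspace(1, 10, 50)
        fitted, slope, intercept = fit_control_channel(2 * x + 3, x)
        assert slope == pytest.approx(2.0, abs=1e-12)
        assert intercept == pytest.approx(3.0, abs=1e-10)
        assert np.allclose(fitted, 2 * x + 3)

    def test_independent_noise_slope_near_zero(self, rng):
        x = rng.normal(size=100_000)
        y = rng.normal(size=100_000)
        _, slope, _ = fit_control_channel(y, x)
        assert abs(slope) < 0.02

    def test_slope_recovery_within_3se(self, rng):
        n = 2000
        x = rng.normal(0, 1.0, n)
        noise = rng.normal(0, 0.5, n)
        y = 1.5 * x + noise
        fitted, slope, intercept = fit_control_channel(y, x)
        resid = y - fitted
        se = np.sqrt(np.sum(resid**2) / (n - 2) / np.sum((x - x.mean()) ** 2))
        assert abs(slope - 1.5) < 3 * se
        assert abs(np.mean(resid)) < 1e-9

    def test_constant_control_rejected(self):
        with pytest.raises(DegenerateFitError):
            fit_control_channel(np.arange(10.0), np.full(10, 2.0))


class TestDff:
    def test_equal_signals_zero(self):
        f = np.linspace(1, 2, 20)
        assert np.allclose(compute_dff(f, f), 0.0)

    def test_constant_ratio(self):
        f = np.linspace(1, 2, 20)
        assert np.allclose(compute_dff(1.1 * f, f), 0.1)

    def test_matches_elementwise_formula(self, rng):
        f = rng.uniform(1, 5, 300)
        s = rng.uniform(1, 5, 300)
        assert np.allclose(compute_dff(s, f), (s - f) / f)

    def test_nonpositive_denominator_names_index(self):
        f = np.ones(10)
        f[4] = -1.0
        with pytest.raises(NumericDomainError, match="index 4"):
            compute_dff(np.ones(10), f)


class TestZscore:
    def test_whole_trace_normalization(self, rng):
        z = zscore_trace(rng.normal(5, 2, 10_000))
        assert abs(z.mean()) < 1e-9
        assert abs(z.std() - 1) < 1e-9

    def test_constant_rejected(self):
        with pytest.raises(NumericDomainError):
            zscore_trace(np.full(100, 2.0))

    def test_window_normalization_closed_form(self):
        # two-level series normalized on the first half: the second half's
        # mean is (level2 - level1) / sd1
        level1 = np.array([0.0, 2.0] * 50)  # mean 1, sd 1
        level2 = np.full(100, 4.0)
        y = np.concatenate([level1, level2])
        z = zscore_trace(y, (0, 100))
        assert z[100:].mean() == pytest.approx((4.0 - 1.0) / 1.0)

    def test_idempotent(self, rng):
        y = rng.normal(3, 4, 5000)
        z = zscore_trace(y)
        assert np.allclose(zscore_trace(z), z)


class TestProcessRecording:
    def test_deterministic(self):
        cfg = SimConfig(duration_s=120.0, rate_hz=20.0, n_transients=5, seed=9, quiet_start_s=20.0)
        rec, _ = simulate_photometry(cfg)
        params = ProcessParams(cutoff_hz=None, loess_span=0.002)
        a = process_recording(rec, params)
        b = process_recording(rec, params)
        assert np.array_equal(a.dff, b.dff)
        assert np.array_equal(a.zscore, b.zscore)

    def test_artifacts_rejected(self):
        # shared artifacts, no transients: no structure beyond noise
        cfg = SimConfig(
            duration_s=200.0, rate_hz=50.0, artifact_rate_hz=0.1, artifact_amp_frac=0.2,
            noise_sd=1.0, seed=4,
        )
        rec, _ = simulate_photometry(cfg)
        trace = process_recording(rec, ProcessParams(cutoff_hz=12.0, loess_span=5 / len(rec)))
        assert np.mean(np.abs(trace.zscore) <= 3.0) > 0.99
        assert np.sqrt(np.mean(trace.zscore**2)) <= 1.2

    def test_noiseless_peak_location(self):
        cfg = SimConfig(duration_s=150.0, rate_hz=20.0, n_transients=1, noise_sd=0.0,
                        quiet_start_s=40.0, seed=2)
        rec, truth = simulate_photometry(cfg)
        trace = process_recording(
            rec, ProcessParams(cutoff_hz=None, loess_span=5 / len(rec), zscore_window_s=(5.0, 40.0))
        )
        peak_t = trace.time_s[np.argmax(trace.dff)]
        assert abs(peak_t - truth.injected_transients[0][1]) <= 2 / 20.0

    def test_common_scaling_leaves_dff_unchanged(self):
        cfg = SimConfig(duration_s=120.0, rate_hz=20.0, n_transients=3, seed=5, quiet_start_s=20.0)
        rec, _ = simulate_photometry(cfg)
        params = ProcessParams(cutoff_hz=None, loess_span=0.002)
        a = process_recording(rec, params)
        rec2 = PhotometryRecording(rec.time_s, 3.0 * rec.ch465, 3.0 * rec.ch405, rec.rate_hz)
        b = process_recording(rec2, params)
        assert np.allclose(a.dff, b.dff, atol=1e-10)

    def test_fitted_control_identity(self):
        cfg = SimConfig(duration_s=120.0, rate_hz=20.0, n_transients=3, seed=6, quiet_start_s=20.0)
        rec, _ = simulate_photometry(cfg)
        trace = process_recording(rec, ProcessParams(cutoff_hz=None, loess_span=0.002))
        # invariants recorded in the dataclass contract
        assert len(trace.dff) == len(rec)
        assert abs(trace.zscore.mean()) < 1e-9
        assert abs(trace.zscore.std() - 1) < 1e-9
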