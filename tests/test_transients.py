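"""Transient detection, AUC/width quantification and peri-event alignment."""

import dataclasses

import numpy as np
import pytest

from photolock.errors import ParameterError, ScheduleError
from photolock.photometry import ProcessParams, process_recording
from photolock.synthdata import SimConfig, simulate_photometry
from photolock.transients import (
    Event,
    EventStream,
    TrialBlock,
    detect_transients,
    peri_event_average,
    pre_post_change,
    transient_auc,
    trial_block_summary,
)

from conftest import trace_from_z


def triangle(n_up, peak, rate=20.0, pad=50):
    z = np.zeros(2 * pad + 2 * n_up + 1)
    z[pad : pad + n_up + 1] = np.linspace(0, peak, n_up + 1)
    z[pad + n_up : pad + 2 * n_up + 1] = np.linspace(peak, 0, n_up + 1)
    return trace_from_z(z, rate)


class TestDetect:
    def test_empty_trace(self):
        assert detect_transients(trace_from_z(np.zeros(500))) == []

    def test_triangle_width_and_auc(self):
        # 0 -> 6 -> 0 SD over 2 s: one transient, base 2 s, AUC 6 SD*s
        tr = triangle(n_up=20, peak=6.0, rate=20.0)
        out = detect_transients(tr, threshold_sd=3.0, min_gap_s=0.1, min_width_s=0.2)
        assert len(out) == 1
        t = out[0]
        assert t.width_base_s == pytest.approx(2.0, abs=1e-9)
        assert t.peak_z == pytest.approx(6.0)
        assert t.auc_positive == pytest.approx(6.0, rel=0.01)  # triangle area

    def test_merge_rule(self):
        rate = 20.0
        z = np.zeros(1000)
        z[100:121] = np.concatenate([np.linspace(0, 5, 11), np.linspace(5, 0, 11)[1:]])
        far = 400  # 14 s later: separate
        z[far : far + 21] = z[100:121]
        tr = trace_from_z(z, rate)
        assert len(detect_transients(tr, 3.0, min_gap_s=0.5, min_width_s=0.2)) == 2
        z2 = np.zeros(1000)
        z2[100:121] = z[100:121]
        z2[127:148] = z[100:121]  # gap 6 samples = 0.3 s < min_gap
        tr2 = trace_from_z(z2, rate)
        assert len(detect_transients(tr2, 3.0, min_gap_s=0.5, min_width_s=0.2)) == 1

    def test_min_width_filters(self):
        z = np.zeros(500)
        z[100] = 5.0  # single-sample spike
        tr = trace_from_z(z)
        assert detect_transients(tr, 3.0, 0.1, min_width_s=0.5) == []

    def test_threshold_positive_required(self):
        with pytest.raises(ParameterError):
            detect_transients(trace_from_z(np.zeros(100)), threshold_sd=0.0)

    def test_threshold_monotonicity(self, rng):
        # raising the threshold never increases count or total AUC
        from scipy.ndimage import uniform_filter1d

        z = uniform_filter1d(rng.normal(size=20_000), 5)
        z /= z.std()
        tr = trace_from_z(z)
        prev_count, prev_auc = np.inf, np.inf
        for thr in (2.0, 3.0, 4.0):
            out = detect_transients(tr, thr, 0.1, min_width_s=0.05)
            total = sum(t.auc_positive for t in out)
            assert len(out) <= prev_count
            assert total <= prev_auc + 1e-12
            prev_count, prev_auc = len(out), total

    def test_white_noise_has_no_sustained_structure(self, rng):
        # median base width of threshold crossings on white noise stays a
        # few samples: positive runs are geometric(1/2), and conditioning
        # on containing a >3 SD sample size-biases the run length, so the
        # base (run + its two bounding samples) has median 3-4 samples
        z = zscore(rng.normal(size=200_000))
        tr = trace_from_z(z)
        out = detect_transients(tr, 3.0, min_gap_s=0.0, min_width_s=0.0)
        widths = np.array([t.width_base_s for t in out]) * tr.rate_hz
        assert np.median(widths) <= 4.0


def zscore(x):
    return (x - x.mean()) / x.std()


class TestAuc:
    def test_rectangle(self):
        z = np.zeros(300)
        z[100:140] = 5.0  # 2 s x 5 SD
        tr = trace_from_z(z)
        t = detect_transients(tr, 3.0, 0.1, 0.1)[0]
        assert t.auc_positive == pytest.approx(10.0, rel=0.03)

    def test_half_sine(self):
        rate = 100.0
        w = 2.0
        amp = 6.0
        n = int(w * rate)
        z = np.zeros(1000)
        z[300 : 300 + n] = amp * np.sin(np.pi * np.arange(n) / n)
        tr = trace_from_z(z, rate)
        t = detect_transients(tr, 3.0, 0.1, 0.1)[0]
        assert t.auc_positive == pytest.approx(2 * amp * w / np.pi, rel=0.01)

    def test_undershoot_contributes_zero(self):
        z = np.zeros(400)
        z[100:120] = 5.0
        z[120:140] = -4.0
        z[160] = 0.0
        tr = trace_from_z(z)
        t = detect_transients(tr, 3.0, 0.1, 0.1)[0]
        ref = transient_auc(tr, t)
        assert ref == t.auc_positive
        assert ref == pytest.approx(5.0 * 1.0, rel=0.06)  # 20 samples at 20 Hz

    def test_out_of_range_rejected(self):
        tr = trace_from_z(np.zeros(100))
        t = detect_transients(triangle(20, 6.0), 3.0, 0.1, 0.1)[0]
        bad = dataclasses.replace(t, onset_s=t.onset_s, offset_s=1e6)
        with pytest.raises(IndexError):
            transient_auc(tr, bad)


class TestPeriEvent:
    def test_single_event_ramp(self):
        rate = 20.0
        z = np.arange(400) / 100.0
        tr = trace_from_z(z, rate)
        ev = EventStream([Event(10.0, None, "turn_away", 0)])
        tens = peri_event_average(tr, ev, "turn_away", 2.0, 2.0)
        assert tens.matrix.shape == (1, 81)
        assert np.allclose(tens.matrix[0], z[160:241])
        assert np.allclose(tens.mean, z[160:241])

    def test_identical_responses_zero_sem(self):
        rate = 20.0
        z = np.zeros(2000)
        wave = np.sin(np.linspace(0, np.pi, 20))
        times = [20.0, 40.0, 60.0]
        for t0 in times:
            i = int(t0 * rate)
            z[i : i + 20] += wave
        tr = trace_from_z(z, rate)
        ev = EventStream([Event(t0, None, "turn_away", 0) for t0 in times])
        tens = peri_event_average(tr, ev, "turn_away", 5.0, 5.0)
        assert np.allclose(tens.sem, 0.0)
        i0 = int(5.0 * rate)
        assert np.allclose(tens.mean[i0 : i0 + 20], wave)

    def test_edge_events_dropped(self):
        tr = trace_from_z(np.zeros(200), 20.0)
        ev = EventStream([Event(0.5, None, "turn_away", 0), Event(5.0, None, "turn_away", 0)])
        tens = peri_event_average(tr, ev, "turn_away", 2.0, 2.0)
        assert tens.n_events == 1
        assert tens.n_dropped == 1

    def test_no_usable_events_is_empty_not_error(self):
        tr = trace_from_z(np.zeros(100), 20.0)
        tens = peri_event_average(tr, EventStream([]), "turn_away", 1.0, 1.0)
        assert tens.n_events == 0
        assert np.all(np.isnan(tens.mean))


class TestPrePost:
    def test_flat_rows_zero_delta(self):
        tr = trace_from_z(np.zeros(2000), 20.0)
        ev = EventStream([Event(t, None, "turn_away", 0) for t in (20.0, 40.0, 60.0)])
        tens = peri_event_average(tr, ev, "turn_away", 5.0, 5.0)
        ch = pre_post_change(tens)
        assert np.allclose(ch["deltas"], 0.0)

    def test_step_gives_step_height(self):
        rate = 20.0
        z = np.zeros(2000)
        for t0 in (20.0, 40.0, 60.0):
            z[int(t0 * rate) :] += 0.0  # keep baseline flat
        z2 = np.zeros(2000)
        for t0 in (20.0, 40.0, 60.0):
            i = int(t0 * rate)
            z2[i : i + int(5 * rate) + 1] += 2.0
        tr = trace_from_z(z2, rate)
        ev = EventStream([Event(t, None, "turn_away", 0) for t in (20.0, 40.0, 60.0)])
        tens = peri_event_average(tr, ev, "turn_away", 5.0, 5.0)
        ch = pre_post_change(tens, (-5.0, -0.05), (0.0, 5.0))
        assert np.allclose(ch["deltas"], 2.0, atol=0.05)

    def test_window_validation(self):
        tr = trace_from_z(np.zeros(1000), 20.0)
        ev = EventStream([Event(20.0, None, "turn_away", 0)])
        tens = peri_event_average(tr, ev, "turn_away", 5.0, 5.0)
        with pytest.raises(ParameterError):
            pre_post_change(tens, (-5.0, 1.0), (0.0, 5.0))


class TestTrialSummary:
    def _transients(self):
        tr = triangle(20, 6.0)
        return detect_transients(tr, 3.0, 0.1, 0.1)

    def test_no_transients_all_zero(self):
        bounds = [TrialBlock(0, 0.0, 10.0, "empty"), TrialBlock(1, 20.0, 30.0, "mouse1")]
        out = trial_block_summary([], bounds)
        assert all(s.transient_count == 0 and s.auc_total == 0 for s in out)

    def test_assignment_by_peak(self):
        z = np.zeros(2000)
        for t0 in (32.0, 35.0, 38.0):  # peaks inside trial 2 (30-40 s)
            i = int(t0 * 20)
            z[i : i + 21] = np.concatenate([np.linspace(0, 5, 11), np.linspace(5, 0, 11)[1:]])
        trs = detect_transients(trace_from_z(z, 20.0), 3.0, 0.01, 0.1)
        bounds = [
            TrialBlock(1, 10.0, 20.0, "empty"),
            TrialBlock(2, 30.0, 40.0, "mouse1"),
            TrialBlock(3, 50.0, 60.0, "mouse1"),
        ]
        out = trial_block_summary(trs, bounds)
        counts = {s.trial_id: s.transient_count for s in out}
        assert counts == {1: 0, 2: 3, 3: 0, None: 0}

    def test_partition_of_total_auc(self):
        z = np.zeros(4000)
        rng = np.random.default_rng(3)
        for t0 in rng.uniform(5, 195, 12):
            i = int(t0 * 20)
            z[i : i + 21] += np.concatenate([np.linspace(0, 5, 11), np.linspace(5, 0, 11)[1:]])
        trs = detect_transients(trace_from_z(z, 20.0), 3.0, 0.01, 0.1)
        bounds = [TrialBlock(k, 20.0 * k, 20.0 * k + 15.0, "mouse1") for k in range(5)]
        out = trial_block_summary(trs, bounds)
        total = sum(s.auc_total for s in out)
        assert total == pytest.approx(sum(t.auc_positive for t in trs), abs=1e-9)

    def test_overlapping_trials_rejected(self):
        bounds = [TrialBlock(0, 0.0, 10.0, "a"), TrialBlock(1, 5.0, 15.0, "b")]
        with pytest.raises(ScheduleError):
            trial_block_summary([], bounds)


class TestRecoveryFromGenerator:
    def test_noiseless_bounds_and_auc(self):
        """Detected support matches the injected ground truth on
        noiseless data (median within 2 samples; AUC within a few %)."""
        cfg = SimConfig(
            duration_s=600.0, rate_hz=20.0, n_transients=50, noise_sd=0.0,
            bleach_frac=0.2, quiet_start_s=90.0, seed=11,
        )
        rec, truth = simulate_photometry(cfg)
        trace = process_recording(
            rec,
            ProcessParams(cutoff_hz=None, loess_span=5 / len(rec), zscore_window_s=(10.0, 90.0)),
        )
        trs = detect_transients(trace, 3.0, 0.5, 1.0)
        sd = trace.params["zscore_sd"]
        werr, berr, aerr = [], [], []
        for t in truth.injected_transients:
            cands = [d for d in trs if d.onset_s - 1.0 <= t[1] <= d.offset_s + 1.0]
            assert cands, f"missed transient at {t[0]:.1f}s"
            d = max(cands, key=lambda d: d.peak_z)
            werr.append(abs(d.width_base_s - t[4]) * cfg.rate_hz)
            berr.append(max(abs(d.onset_s - t[0]), abs(d.offset_s - (t[0] + t[4]))) * cfg.rate_hz)
            aerr.append(abs(d.auc_positive * sd / t[3] - 1.0))
        assert np.median(werr) <= 2.0 + 1e-6
        assert np.median(berr) <= 2.0 + 1e-6
        assert np.median(aerr) <= 0.05
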