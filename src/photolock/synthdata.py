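"""Synthetic photometry, behavior and spike-train generators with ground truth.

The generators emulate the statistical structure the analysis assumes:
exponential photobleaching shared (with independent time constants)
between channels, brief biphasic motion artifacts common to both
channels, calcium transients present only in the signal channel,
trial-structured social exposures with turn-away events that anchor
event-locked responses, drug-inhibition epochs in spike-rate series, and
habituation/novelty-discrimination patterns in contact durations.

Every generator records its injected components (``SimulationTruth``) so
downstream stages can be scored against a known answer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ScheduleError
from .photometry import PhotometryRecording
from .transients import Event, EventStream, TrialBlock

__all__ = [
    "SimConfig",
    "SimulationTruth",
    "TrialSchedule",
    "TrialSpec",
    "transient_kernel",
    "simulate_photometry",
    "simulate_events",
    "simulate_spike_recording",
    "simulate_behavior_table",
    "SpikeRateSeries",
]

# Condition B emulates a group with larger, longer event-locked responses
# (a KO-like contrast); condition A is the reference group.
_CONDITION_SCALE = {"A": (1.0, 1.0), "B": (1.5, 1.6)}  # (amplitude, decay) multipliers


@dataclass
class SimConfig:
    """Parameters of a synthetic dual-channel photometry recording.

    Transient amplitudes are expressed in units of the additive noise SD
    (``noise_sd``); when ``noise_sd`` is zero the unit falls back to
    1 a.u. so degenerate noiseless configurations still carry signal.
    """

    duration_s: float = 600.0
    rate_hz: float = 20.0
    f0: float = 100.0  # initial baseline fluorescence, a.u.
    bleach_tau_s: float = 600.0
    bleach_frac: float = 0.2
    artifact_rate_hz: float = 0.05
    artifact_amp_frac: float = 0.0
    artifact_dur_s: float = 0.2
    artifact_gain_405: float = 1.0
    n_transients: int | None = None
    transient_rate_hz: float = 0.0
    transient_amp_sd: float = 6.0
    transient_amp_jitter_sd: float = 0.0  # uniform half-range around transient_amp_sd
    transient_rise_s: float = 0.1
    transient_decay_s: float = 1.0
    noise_sd: float = 1.0
    event_locked_amp_sd: float = 0.0
    quiet_start_s: float = 10.0  # guaranteed transient-free lead-in
    condition: str = "A"
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.duration_s) or self.duration_s <= 0:
            raise ConfigurationError("duration_s must be positive and finite")
        if not np.isfinite(self.rate_hz) or self.rate_hz <= 0:
            raise ConfigurationError("rate_hz must be positive and finite")
        if not 0 <= self.bleach_frac < 1:
            raise ConfigurationError("bleach_frac must lie in [0, 1)")
        for name in (
            "f0",
            "bleach_tau_s",
            "artifact_rate_hz",
            "artifact_amp_frac",
            "artifact_dur_s",
            "transient_rate_hz",
            "transient_amp_sd",
            "transient_amp_jitter_sd",
            "transient_rise_s",
            "transient_decay_s",
            "noise_sd",
            "event_locked_amp_sd",
            "quiet_start_s",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ConfigurationError(f"{name} must be non-negative and finite")
        if self.condition not in _CONDITION_SCALE:
            raise ConfigurationError(f"condition must be one of {sorted(_CONDITION_SCALE)}")

    @property
    def amp_unit_au(self) -> float:
        """Arbitrary-unit value of one amplitude unit (one noise SD)."""
        return self.noise_sd if self.noise_sd > 0 else 1.0


@dataclass
class SimulationTruth:
    """Ground truth of every injected component.

    ``injected_transients`` rows are (onset_s, peak_s, amplitude_frac,
    true_auc, true_width_s) with AUC in fractional-fluorescence x seconds
    (the dF/F scale) from refinement-converged numerical integration of
    the noiseless waveform; ``transient_trace`` is the full noiseless
    fractional transient waveform on the recording's grid.
    """

    injected_transients: list[tuple[float, float, float, float, float]]
    artifact_trace: np.ndarray
    bleach_trace: np.ndarray
    transient_trace: np.ndarray
    event_response_amp: dict[float, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "injected_transients": [list(t) for t in self.injected_transients],
                    "event_response_amp": {str(k): v for k, v in self.event_response_amp.items()},
                },
                indent=2,
            )
        )


def transient_kernel(
    rise_s: float,
    decay_s: float,
    rate_hz: float,
    floor_frac: float = 0.05,
    refine: int = 1,
) -> tuple[np.ndarray, float]:
    """Compact-support calcium-transient waveform with unit peak.

    A double exponential (fast rise, slow decay) truncated where it falls
    below ``floor_frac`` of its peak (default 5%), floor-subtracted and renormalized,
    so the waveform reaches exactly zero at both ends of its support —
    giving the generator an exact ground-truth width at base.

    Returns ``(kernel, integral)`` where the integral is computed on a
    grid refined ``refine``-fold (trapezoid), in units of seconds.
    """
    if rise_s <= 0 or decay_s <= 0:
        raise ConfigurationError("rise and decay constants must be positive")
    if decay_s <= rise_s:
        raise ConfigurationError("decay_s must exceed rise_s")
    dt = 1.0 / (rate_hz * refine)
    t_end = decay_s * np.log(1.0 / floor_frac) * 1.5 + 5 * rise_s
    t = np.arange(0.0, t_end, dt)
    raw = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    peak = raw.max()
    k = (raw - floor_frac * peak) / (peak * (1.0 - floor_frac))
    k = np.clip(k, 0.0, None)
    nz = np.nonzero(k > 0)[0]
    k = k[: nz[-1] + 2] if nz[-1] + 2 <= len(k) else k
    integral = float(np.trapezoid(k, dx=dt))
    return k, integral


def _poisson_times(rng: np.random.Generator, rate_hz: float, t0: float, t1: float) -> np.ndarray:
    n = rng.poisson(rate_hz * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, size=n))


def _spaced_times(
    rng: np.random.Generator, n: int, t0: float, t1: float, spacing_s: float
) -> np.ndarray:
    """n times in [t0, t1) with pairwise spacing >= spacing_s (slot jitter)."""
    span = t1 - t0
    if n * spacing_s > span:
        raise ConfigurationError(
            f"cannot place {n} transients with {spacing_s}s spacing in {span}s"
        )
    slot = span / n
    jitter = rng.uniform(0.0, max(slot - spacing_s, 0.0), size=n)
    return t0 + np.arange(n) * slot + jitter


def simulate_photometry(
    config: SimConfig, events: EventStream | None = None
) -> tuple[PhotometryRecording, SimulationTruth]:
    """Generate a dual-channel recording plus its ground truth.

    465 = bleach_465 x (1 + artifacts + transients) + noise
    405 = bleach_405 x (1 + artifacts x gain_405)   + noise'

    Transients appear only in the signal channel; artifacts appear in
    both (scaled by a per-channel gain); bleaching is a per-channel
    single exponential with independent time constants.  If ``events``
    is given, an extra transient of amplitude ``event_locked_amp_sd`` is
    injected at each ``turn_away`` event.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_trans, rng_art, rng_noise465, rng_noise405, rng_amp = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    n = int(round(config.duration_s * config.rate_hz))
    t = np.arange(n) / config.rate_hz
    dt = 1.0 / config.rate_hz

    amp_scale, decay_scale = _CONDITION_SCALE[config.condition]
    rise = config.transient_rise_s
    decay = config.transient_decay_s * decay_scale
    kernel, kernel_int = transient_kernel(rise, decay, config.rate_hz, refine=16)
    kernel_coarse = kernel[::16]
    k_peak = int(np.argmax(kernel_coarse))
    k_support = np.nonzero(kernel_coarse > 0)[0]
    width_s = (k_support[-1] - k_support[0]) * dt if k_support.size else 0.0

    # ---- transient onsets ----------------------------------------------------
    t0 = config.quiet_start_s
    t1 = config.duration_s - (len(kernel_coarse) * dt) - 1.0
    onsets: np.ndarray
    if config.n_transients is not None and config.n_transients > 0:
        spacing = width_s + 1.0
        onsets = _spaced_times(rng_trans, config.n_transients, t0, t1, spacing)
    elif config.transient_rate_hz > 0:
        onsets = _poisson_times(rng_trans, config.transient_rate_hz, t0, max(t1, t0))
    else:
        onsets = np.empty(0)

    unit = config.amp_unit_au
    trans_frac = np.zeros(n)
    injected: list[tuple[float, float, float, float, float]] = []

    def _inject(onset_s: float, amp_sd: float) -> tuple[float, float, float, float, float]:
        amp_frac = amp_sd * unit / config.f0
        i0 = int(round(onset_s * config.rate_hz))
        seg = kernel_coarse[: n - i0]
        trans_frac[i0 : i0 + len(seg)] += amp_frac * seg
        # truth onset/width refer to the support of the sampled waveform
        return (
            float(t[min(i0 + k_support[0], n - 1)]),
            float(t[min(i0 + k_peak, n - 1)]),
            amp_frac,
            amp_frac * kernel_int,
            width_s,
        )

    for on in onsets:
        amp = config.transient_amp_sd * amp_scale
        if config.transient_amp_jitter_sd > 0:
            amp += rng_amp.uniform(-1.0, 1.0) * config.transient_amp_jitter_sd
        injected.append(_inject(float(on), amp))

    event_amp: dict[float, float] = {}
    if events is not None and config.event_locked_amp_sd > 0:
        for ev in events.with_label("turn_away"):
            if ev.start_s + len(kernel_coarse) * dt >= config.duration_s:
                continue
            injected.append(_inject(ev.start_s, config.event_locked_amp_sd * amp_scale))
            event_amp[ev.start_s] = config.event_locked_amp_sd * amp_scale

    # ---- artifacts (shared across channels) ----------------------------------
    art_frac = np.zeros(n)
    if config.artifact_rate_hz > 0 and config.artifact_amp_frac > 0:
        dur = max(int(round(config.artifact_dur_s * config.rate_hz)), 2)
        phase = np.sin(2 * np.pi * np.arange(dur) / dur)  # one biphasic cycle
        for at in _poisson_times(rng_art, config.artifact_rate_hz, 0.0, config.duration_s - config.artifact_dur_s):
            i0 = int(round(at * config.rate_hz))
            seg = phase[: n - i0]
            amp = config.artifact_amp_frac * rng_art.uniform(0.5, 1.0)
            art_frac[i0 : i0 + len(seg)] += amp * seg

    # ---- bleaching and assembly ----------------------------------------------
    bleach465 = config.f0 * ((1 - config.bleach_frac) + config.bleach_frac * np.exp(-t / config.bleach_tau_s))
    bleach405 = 0.8 * config.f0 * (
        (1 - config.bleach_frac) + config.bleach_frac * np.exp(-t / (1.15 * config.bleach_tau_s))
    )
    noise465 = rng_noise465.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else np.zeros(n)
    noise405 = rng_noise405.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else np.zeros(n)

    ch465 = bleach465 * (1.0 + art_frac + trans_frac) + noise465
    ch405 = bleach405 * (1.0 + art_frac * config.artifact_gain_405) + noise405

    rec = PhotometryRecording(t, ch465, ch405, config.rate_hz)
    truth = SimulationTruth(
        injected_transients=sorted(injected),
        artifact_trace=art_frac,
        bleach_trace=bleach465,
        transient_trace=trans_frac,
        event_response_amp=event_amp,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# behavioral event streams
# ---------------------------------------------------------------------------


@dataclass
class TrialSpec:
    block_label: str  # empty / mouse1 / mouse2 / object ...
    duration_s: float = 60.0
    n_turn_away: int = 2


@dataclass
class TrialSchedule:
    """Ordered trial blocks with inter-trial gaps.

    The default scaled-down schedule (60 s trials, 30 s gaps) mirrors the
    structure of a repeated social-exposure task — empty box, the same
    stimulus mouse four times, then a novel mouse — at a duration test
    suites can afford; pass 300 s / 1200 s for the full-scale task.
    """

    trials: list[TrialSpec] = field(default_factory=list)
    gap_s: float = 30.0
    start_s: float = 30.0
    min_event_spacing_s: float = 12.0

    @classmethod
    def social_task(cls, trial_s: float = 60.0, gap_s: float = 30.0, n_turn_away: int = 2) -> "TrialSchedule":
        labels = ["empty", "mouse1", "mouse1", "mouse1", "mouse1", "mouse2"]
        return cls(
            trials=[TrialSpec(lbl, trial_s, n_turn_away) for lbl in labels],
            gap_s=gap_s,
        )


def simulate_events(config: SimConfig, schedule: TrialSchedule) -> EventStream:
    """Generate contact bouts and turn-away/turn-toward events per trial.

    Each trial holds ``n_turn_away`` contact bouts; a ``turn_toward``
    point event marks each bout start and a ``turn_away`` event marks the
    bout end (turning away terminates contact).  Events in ``empty`` /
    ``object`` blocks get ``_object``-suffixed labels and anchor no
    photometric response.  Trials beyond the recording duration raise a
    schedule error.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(6)[5])
    events: list[Event] = []
    bounds: list[TrialBlock] = []
    t_cursor = schedule.start_s
    for idx, spec in enumerate(schedule.trials):
        start, stop = t_cursor, t_cursor + spec.duration_s
        if stop > config.duration_s:
            raise ScheduleError(
                f"trial {idx} ends at {stop}s, beyond the {config.duration_s}s recording"
            )
        bounds.append(TrialBlock(idx, start, stop, spec.block_label))
        is_object = spec.block_label in ("empty", "object")
        suffix = "_object" if is_object else ""
        if spec.n_turn_away > 0:
            stops = _spaced_times(
                rng,
                spec.n_turn_away,
                start + schedule.min_event_spacing_s / 2,
                stop - 1.0,
                schedule.min_event_spacing_s,
            )
            for ts in stops:
                bout_len = rng.uniform(2.0, min(8.0, schedule.min_event_spacing_s / 2))
                b0 = max(start, ts - bout_len)
                events.append(Event(float(b0), float(ts), "contact" + suffix, idx))
                events.append(Event(float(b0), None, "turn_toward" + suffix, idx))
                events.append(Event(float(ts), None, "turn_away" + suffix, idx))
        t_cursor = stop + schedule.gap_s
    events.sort(key=lambda e: (e.start_s, e.label))
    return EventStream(events, bounds)


# ---------------------------------------------------------------------------
# spike-rate series
# ---------------------------------------------------------------------------


@dataclass
class SpikeRateSeries:
    """Binned spike-frequency series with stimulation-epoch annotations."""

    bin_start_s: np.ndarray
    rate_hz: np.ndarray
    epochs: list[tuple[str, float, float]]
    percent_baseline: np.ndarray | None = None

    def to_csv(self, path: str | Path) -> None:
        labels = []
        for b in self.bin_start_s:
            lbl = ""
            for name, s0, s1 in self.epochs:
                if s0 <= b < s1:
                    lbl = name
                    break
            labels.append(lbl)
        pd.DataFrame(
            {"bin_start_s": self.bin_start_s, "rate_hz": self.rate_hz, "epoch_label": labels}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpikeRateSeries":
        df = pd.read_csv(path)
        required = {"bin_start_s", "rate_hz", "epoch_label"}
        missing = required - set(df.columns)
        if missing:
            raise ConfigurationError(f"spike CSV missing columns: {sorted(missing)}")
        epochs = []
        for lbl, grp in df.groupby("epoch_label", sort=False):
            if not isinstance(lbl, str) or not lbl:
                continue
            dt = float(np.median(np.diff(df["bin_start_s"]))) if len(df) > 1 else 1.0
            epochs.append((lbl, float(grp["bin_start_s"].min()), float(grp["bin_start_s"].max()) + dt))
        return cls(df["bin_start_s"].to_numpy(float), df["rate_hz"].to_numpy(float), epochs)


def simulate_spike_recording(
    n_cells: int,
    inhibition_frac: float,
    inhibition_magnitude: float,
    seed: int,
    n_baseline_bins: int = 10,
    n_drug_bins: int = 4,
    n_wash_bins: int = 10,
    bin_s: float = 60.0,
    base_rate_hz: float = 4.0,
    noise_cv: float = 0.05,
    drug_label: str = "drug_AVP",
) -> list[tuple[SpikeRateSeries, str]]:
    """Simulate per-cell spike-rate series with a drug-inhibition epoch.

    A fraction ``inhibition_frac`` of cells are responders whose rate
    drops by ``inhibition_magnitude`` during the drug epoch; the rest
    fluctuate around baseline.  Returns (series, truth_label) pairs with
    truth_label in {"responding", "insensitive"}.
    """
    if n_cells <= 0:
        raise ConfigurationError("n_cells must be positive")
    if not 0 <= inhibition_frac <= 1:
        raise ConfigurationError("inhibition_frac must lie in [0, 1]")
    if not 0 <= inhibition_magnitude <= 1:
        raise ConfigurationError("inhibition_magnitude must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_bins = n_baseline_bins + n_drug_bins + n_wash_bins
    bins = np.arange(n_bins) * bin_s
    epochs = [
        ("baseline", 0.0, n_baseline_bins * bin_s),
        (drug_label, n_baseline_bins * bin_s, (n_baseline_bins + n_drug_bins) * bin_s),
        ("wash", (n_baseline_bins + n_drug_bins) * bin_s, n_bins * bin_s),
    ]
    out = []
    for _ in range(n_cells):
        responder = bool(rng.random() < inhibition_frac)
        profile = np.ones(n_bins)
        if responder:
            profile[n_baseline_bins : n_baseline_bins + n_drug_bins] = 1.0 - inhibition_magnitude
        rates = base_rate_hz * profile
        if noise_cv > 0:
            rates = rates * (1.0 + rng.normal(0.0, noise_cv, n_bins))
        rates = np.clip(rates, 0.0, None)
        out.append(
            (
                SpikeRateSeries(bins.copy(), rates, list(epochs)),
                "responding" if responder else "insensitive",
            )
        )
    return out


# ---------------------------------------------------------------------------
# behavior tables
# ---------------------------------------------------------------------------

_PATTERN_MEANS = {
    # trials 1..4: habituation to the same stimulus mouse; trial 5: novel mouse.
    "habituating": (110.0, 80.0, 55.0, 40.0, 95.0),  # novelty rebound at trial 5
    "non_discriminating": (110.0, 80.0, 55.0, 40.0, 40.0),  # no rebound
}


def simulate_behavior_table(
    n_per_group: int,
    pattern: str,
    seed: int,
    noise_sd: float = 10.0,
    trial_len_s: float = 300.0,
    group_label: str | None = None,
) -> pd.DataFrame:
    """Contact-duration table for one group following a trial pattern.

    Rows are (subject_id, group, trial, duration_s) with durations
    clipped to [0, trial_len_s].  ``habituating`` decays across trials
    1-4 and rebounds at trial 5 (novel conspecific); ``non_discriminating``
    decays with no rebound.
    """
    if pattern not in _PATTERN_MEANS:
        raise ConfigurationError(
            f"unknown pattern {pattern!r}; choose from {sorted(_PATTERN_MEANS)}"
        )
    if n_per_group < 2:
        raise ConfigurationError("n_per_group must be >= 2")
    rng = np.random.default_rng(seed)
    means = _PATTERN_MEANS[pattern]
    group = group_label or pattern
    rows = []
    for s in range(n_per_group):
        sid = f"{group}_{s:03d}"
        for trial, mu in enumerate(means, start=1):
            dur = mu + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append((sid, group, trial, float(np.clip(dur, 0.0, trial_len_s))))
    return pd.DataFrame(rows, columns=["subject_id", "group", "trial", "duration_s"])
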