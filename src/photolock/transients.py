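"""Calcium-transient detection, quantification and peri-event alignment.

A transient ("spike" in the photometry sense) is an excursion of the
z-scored trace above a detection threshold (default +3 SD), extended
outward to the nearest zero-crossings — the "base" of the spike.  The
positive area under the curve (AUC, SD·s) and the width at base are the
quantities compared between trial blocks and condition groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError, ScheduleError
from .photometry import ProcessedTrace

__all__ = [
    "Transient",
    "Event",
    "TrialBlock",
    "EventStream",
    "PeriEventTensor",
    "TrialSummary",
    "detect_transients",
    "transient_auc",
    "peri_event_average",
    "pre_post_change",
    "trial_block_summary",
]


@dataclass
class Transient:
    onset_s: float
    peak_s: float
    offset_s: float
    peak_z: float
    auc_positive: float
    width_base_s: float

    def __post_init__(self) -> None:
        if not self.onset_s <= self.peak_s <= self.offset_s:
            raise DataError("transient times must satisfy onset <= peak <= offset")


@dataclass
class Event:
    """A behavioral event: a bout (start/stop) or a point event (stop None)."""

    start_s: float
    stop_s: float | None
    label: str
    trial_id: int | None = None

    @property
    def is_point(self) -> bool:
        return self.stop_s is None


@dataclass
class TrialBlock:
    trial_id: int
    start_s: float
    stop_s: float
    block_label: str  # e.g. empty, mouse1, mouse1_x4, mouse2

    def __post_init__(self) -> None:
        if not self.start_s < self.stop_s:
            raise ScheduleError("trial start must precede stop")


@dataclass
class EventStream:
    events: list[Event] = field(default_factory=list)
    trial_bounds: list[TrialBlock] = field(default_factory=list)

    def with_label(self, label: str) -> list[Event]:
        return [e for e in self.events if e.label == label]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "time_s": [e.start_s for e in self.events],
                "stop_s": [e.stop_s if e.stop_s is not None else np.nan for e in self.events],
                "label": [e.label for e in self.events],
                "trial_id": [e.trial_id for e in self.events],
            }
        ).to_csv(path, index=False)

    def trials_to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "trial_id": [t.trial_id for t in self.trial_bounds],
                "start_s": [t.start_s for t in self.trial_bounds],
                "stop_s": [t.stop_s for t in self.trial_bounds],
                "block_label": [t.block_label for t in self.trial_bounds],
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, events_path: str | Path, trials_path: str | Path | None = None) -> "EventStream":
        df = pd.read_csv(events_path)
        required = {"time_s", "label"}
        missing = required - set(df.columns)
        if missing:
            raise DataError(f"event CSV missing columns: {sorted(missing)}")
        events = []
        for _, row in df.iterrows():
            stop = row.get("stop_s", np.nan)
            stop = None if pd.isna(stop) else float(stop)
            tid = row.get("trial_id", np.nan)
            tid = None if pd.isna(tid) else int(tid)
            events.append(Event(float(row["time_s"]), stop, str(row["label"]), tid))
        trials = []
        if trials_path is not None:
            tf = pd.read_csv(trials_path)
            trials = [
                TrialBlock(int(r.trial_id), float(r.start_s), float(r.stop_s), str(r.block_label))
                for r in tf.itertuples()
            ]
        return cls(events, trials)


@dataclass
class PeriEventTensor:
    """Event-aligned z-score segments on a common relative time grid."""

    rel_time_s: np.ndarray
    matrix: np.ndarray  # events x samples
    mean: np.ndarray
    sem: np.ndarray
    n_dropped: int = 0

    @property
    def n_events(self) -> int:
        return self.matrix.shape[0]

    def to_csv(self, path: str | Path) -> None:
        cols = {"rel_time_s": self.rel_time_s}
        for i in range(self.n_events):
            cols[f"event_{i}"] = self.matrix[i]
        pd.DataFrame(cols).to_csv(path, index=False)


@dataclass
class TrialSummary:
    trial_id: int | None  # None = outside all trials
    block_label: str
    auc_total: float
    transient_count: int
    widths: list[float]
    duration_s: float


def _base_bounds(z: np.ndarray, run_start: int, run_end: int) -> tuple[int, int]:
    """Extend a supra-threshold run [run_start, run_end] to the nearest
    samples at or below zero on each side (clamped to the trace)."""
    i = run_start
    while i > 0 and z[i - 1] > 0:
        i -= 1
    if i > 0:
        i -= 1  # include the bounding zero/negative sample
    j = run_end
    n = len(z)
    while j < n - 1 and z[j + 1] > 0:
        j += 1
    if j < n - 1:
        j += 1
    return i, j


def detect_transients(
    trace: ProcessedTrace,
    threshold_sd: float = 3.0,
    min_gap_s: float = 0.5,
    min_width_s: float | None = None,
    auc_mode: str = "base",
) -> list[Transient]:
    """Detect supra-threshold transients on the z-scored trace.

    Each maximal run of samples above ``threshold_sd`` is extended
    outward to the nearest zero-crossings of the z-score; bases that
    overlap or sit closer than ``min_gap_s`` are merged; transients
    narrower than ``min_width_s`` (default: 2 samples) are discarded.

    ``auc_mode='base'`` integrates the positive part of z from base to
    base (trapezoid); ``'supra'`` integrates only the part above the
    threshold.
    """
    if threshold_sd <= 0:
        raise ParameterError("threshold_sd must be positive")
    if auc_mode not in ("base", "supra"):
        raise ParameterError("auc_mode must be 'base' or 'supra'")
    z = np.asarray(trace.zscore, dtype=float)
    t = np.asarray(trace.time_s, dtype=float)
    if min_width_s is None:
        min_width_s = 2.0 / trace.rate_hz

    above = z > threshold_sd
    if not above.any():
        return []
    # contiguous runs of supra-threshold samples
    edges = np.diff(above.astype(np.int8))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0])
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(z) - 1)

    intervals = [_base_bounds(z, s, e) for s, e in zip(starts, ends)]
    # merge overlapping bases or bases separated by less than min_gap_s
    merged: list[list[int]] = []
    for i0, i1 in intervals:
        if merged and (t[i0] - t[merged[-1][1]]) < min_gap_s:
            merged[-1][1] = max(merged[-1][1], i1)
        else:
            merged.append([i0, i1])

    out: list[Transient] = []
    for i0, i1 in merged:
        width = t[i1] - t[i0]
        if width < min_width_s:
            continue
        seg = z[i0 : i1 + 1]
        k = int(np.argmax(seg))
        if auc_mode == "base":
            integrand = np.clip(seg, 0.0, None)
        else:
            integrand = np.clip(seg - threshold_sd, 0.0, None)
        auc = float(np.trapezoid(integrand, t[i0 : i1 + 1]))
        out.append(
            Transient(
                onset_s=float(t[i0]),
                peak_s=float(t[i0 + k]),
                offset_s=float(t[i1]),
                peak_z=float(seg[k]),
                auc_positive=auc,
                width_base_s=float(width),
            )
        )
    return out


def transient_auc(trace: ProcessedTrace, transient: Transient) -> float:
    """Trapezoidal integral of the positive z-score over the transient."""
    t = np.asarray(trace.time_s, dtype=float)
    if transient.onset_s < t[0] - 1e-9 or transient.offset_s > t[-1] + 1e-9:
        raise IndexError("transient bounds outside the trace")
    i0 = int(np.searchsorted(t, transient.onset_s - 1e-9))
    i1 = int(np.searchsorted(t, transient.offset_s + 1e-9)) - 1
    seg = np.clip(trace.zscore[i0 : i1 + 1], 0.0, None)
    return float(np.trapezoid(seg, t[i0 : i1 + 1]))


def peri_event_average(
    trace: ProcessedTrace,
    events: EventStream,
    label: str,
    pre_s: float = 5.0,
    post_s: float = 5.0,
) -> PeriEventTensor:
    """Align z-score segments to events of a label and average them.

    Events whose full [-pre_s, +post_s] window falls outside the
    recording are dropped (and counted) rather than zero-padded, which
    would bias the SEM.  Zero usable events yields an empty tensor, not
    an exception.
    """
    if pre_s < 0 or post_s < 0:
        raise ParameterError("pre_s and post_s must be non-negative")
    t = trace.time_s
    z = trace.zscore
    rate = trace.rate_hz
    k_pre = int(round(pre_s * rate))
    k_post = int(round(post_s * rate))
    rel = np.arange(-k_pre, k_post + 1) / rate

    rows = []
    dropped = 0
    for ev in events.with_label(label):
        c = int(round((ev.start_s - t[0]) * rate))
        if c - k_pre < 0 or c + k_post >= len(z):
            dropped += 1
            continue
        rows.append(z[c - k_pre : c + k_post + 1])
    if not rows:
        empty = np.empty((0, len(rel)))
        nan = np.full(len(rel), np.nan)
        return PeriEventTensor(rel, empty, nan.copy(), nan.copy(), n_dropped=dropped)
    mat = np.vstack(rows)
    mean = mat.mean(axis=0)
    if mat.shape[0] > 1:
        sem = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
    else:
        sem = np.zeros(len(rel))
    return PeriEventTensor(rel, mat, mean, sem, n_dropped=dropped)


def pre_post_change(
    tensor: PeriEventTensor,
    pre_win: tuple[float, float] = (-5.0, 0.0),
    post_win: tuple[float, float] = (0.0, 5.0),
) -> dict:
    """Per-event change mean(post window) - mean(pre window), with summary.

    The summary reports the group mean, SD and Cohen's d of the deltas
    against zero (mean / SD), the standardized size of the event-locked
    change in the signal.
    """
    if pre_win[1] > 0 or post_win[0] < 0:
        raise ParameterError("pre_win must end at <= 0 and post_win start at >= 0")
    rel = tensor.rel_time_s
    pre_mask = (rel >= pre_win[0]) & (rel <= pre_win[1])
    post_mask = (rel >= post_win[0]) & (rel <= post_win[1])
    if not pre_mask.any() or not post_mask.any():
        raise ParameterError("pre/post windows contain no samples")
    if tensor.n_events == 0:
        return {"deltas": np.empty(0), "mean": np.nan, "sd": np.nan, "cohens_d_vs_zero": np.nan,
                "n": 0}
    deltas = tensor.matrix[:, post_mask].mean(axis=1) - tensor.matrix[:, pre_mask].mean(axis=1)
    sd = float(np.std(deltas, ddof=1)) if len(deltas) > 1 else np.nan
    mean = float(np.mean(deltas))
    d = mean / sd if sd and sd > 0 else np.nan
    return {"deltas": deltas, "mean": mean, "sd": sd, "cohens_d_vs_zero": d, "n": len(deltas)}


def trial_block_summary(
    transients: list[Transient], trial_bounds: list[TrialBlock]
) -> list[TrialSummary]:
    """Assign transients to trials by peak time and summarize per block.

    Trials are half-open [start, stop): a peak exactly on a boundary
    belongs to the earlier trial.  Transients outside every trial are
    collected in a summary with ``trial_id=None``.
    """
    bounds = sorted(trial_bounds, key=lambda b: b.start_s)
    for a, b in zip(bounds, bounds[1:]):
        if b.start_s < a.stop_s:
            raise ScheduleError(
                f"trials {a.trial_id} and {b.trial_id} overlap ({a.stop_s} > {b.start_s})"
            )
    summaries = []
    assigned = set()
    for blk in bounds:
        members = [
            (i, tr)
            for i, tr in enumerate(transients)
            if blk.start_s <= tr.peak_s < blk.stop_s
        ]
        assigned.update(i for i, _ in members)
        summaries.append(
            TrialSummary(
                trial_id=blk.trial_id,
                block_label=blk.block_label,
                auc_total=float(sum(tr.auc_positive for _, tr in members)),
                transient_count=len(members),
                widths=[tr.width_base_s for _, tr in members],
                duration_s=blk.stop_s - blk.start_s,
            )
        )
    outside = [tr for i, tr in enumerate(transients) if i not in assigned]
    summaries.append(
        TrialSummary(
            trial_id=None,
            block_label="outside_trials",
            auc_total=float(sum(tr.auc_positive for tr in outside)),
            transient_count=len(outside),
            widths=[tr.width_base_s for tr in outside],
            duration_s=float("nan"),
        )
    )
    return summaries


def transients_to_csv(transients: list[Transient], path: str | Path) -> None:
    pd.DataFrame(
        {
            "onset_s": [tr.onset_s for tr in transients],
            "peak_s": [tr.peak_s for tr in transients],
            "offset_s": [tr.offset_s for tr in transients],
            "peak_z": [tr.peak_z for tr in transients],
            "auc": [tr.auc_positive for tr in transients],
            "width_s": [tr.width_base_s for tr in transients],
        }
    ).to_csv(path, index=False)
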