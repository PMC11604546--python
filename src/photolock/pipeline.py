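"""End-to-end orchestration: simulate -> process -> transients -> summaries.

A run is driven by a single ``RunConfig`` (YAML on disk); every stage
parameter has a default, the resolved configuration is serialized next
to the outputs, and a manifest records SHA-256 hashes of every file so
identical (config, seed) pairs are verifiably byte-identical.  No output
file contains wall-clock information.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .photometry import PhotometryRecording, ProcessParams, process_recording
from .synthdata import SimConfig, TrialSchedule, TrialSpec, simulate_events, simulate_photometry
from .transients import (
    EventStream,
    detect_transients,
    peri_event_average,
    pre_post_change,
    transients_to_csv,
    trial_block_summary,
)

log = logging.getLogger("photolock")

__all__ = ["RunConfig", "run_pipeline", "validate_inputs"]


@dataclass
class RunConfig:
    """Resolved configuration of an end-to-end run."""

    out_dir: str = "photolock_run"
    seed: int = 0
    # either a simulation block ...
    simulate: bool = True
    sim: SimConfig = field(
        default_factory=lambda: SimConfig(
            duration_s=600.0,
            rate_hz=20.0,
            transient_rate_hz=0.05,
            event_locked_amp_sd=4.0,
            quiet_start_s=30.0,
        )
    )
    schedule: TrialSchedule = field(default_factory=TrialSchedule.social_task)
    # ... or input paths
    recording_csv: str | None = None
    events_csv: str | None = None
    trials_csv: str | None = None
    # stage parameters
    process: ProcessParams = field(
        default_factory=lambda: ProcessParams(cutoff_hz=None, loess_span=0.0005)
    )
    threshold_sd: float = 3.0
    min_gap_s: float = 0.5
    min_width_s: float = 0.75
    pre_s: float = 5.0
    post_s: float = 5.0
    event_label: str = "turn_away"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "sim" in kwargs:
            kwargs["sim"] = SimConfig(**kwargs["sim"])
        if "schedule" in kwargs:
            sched = kwargs["schedule"]
            trials = [TrialSpec(**t) for t in sched.pop("trials", [])]
            kwargs["schedule"] = TrialSchedule(trials=trials, **sched)
        if "process" in kwargs:
            p = dict(kwargs["process"])
            if p.get("zscore_window_s") is not None:
                p["zscore_window_s"] = tuple(p["zscore_window_s"])
            kwargs["process"] = ProcessParams(**p)
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**kwargs)

    def resolved_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["process"] = self.process.to_dict()
        # the output location is environmental, not part of the analysis
        d.pop("out_dir", None)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def validate_inputs(paths: dict[str, str | Path]) -> dict:
    """Structural checks on input CSVs; failures are reported, not raised.

    Checks: required headers, finite values, strictly increasing uniform
    time base, bout start < stop, events inside some trial.  Returns
    ``{"failures": [...], "warnings": [...]}``.
    """
    failures: list[str] = []
    warnings: list[str] = []

    rec_path = paths.get("recording_csv")
    if rec_path is not None:
        try:
            df = pd.read_csv(rec_path)
            missing = {"time_s", "ch465", "ch405"} - set(df.columns)
            if missing:
                failures.append(f"recording: missing columns {sorted(missing)}")
            else:
                t = df["time_s"].to_numpy(float)
                dt = np.diff(t)
                if np.any(dt <= 0):
                    failures.append(
                        f"recording: time_s not strictly increasing at row {int(np.argmax(dt <= 0)) + 1}"
                    )
                elif np.ptp(dt) > 1e-6:
                    failures.append("recording: non-uniform time step")
                for col in ("ch465", "ch405"):
                    vals = df[col].to_numpy(float)
                    if not np.all(np.isfinite(vals)):
                        failures.append(
                            f"recording: non-finite {col} at row {int(np.argmax(~np.isfinite(vals)))}"
                        )
        except Exception as exc:  # unreadable file is itself a failure
            failures.append(f"recording: {exc}")

    ev_path = paths.get("events_csv")
    trials = None
    if paths.get("trials_csv") is not None:
        try:
            trials = pd.read_csv(paths["trials_csv"])
        except Exception as exc:
            failures.append(f"trials: {exc}")
    if ev_path is not None:
        try:
            ev = pd.read_csv(ev_path)
            missing = {"time_s", "label"} - set(ev.columns)
            if missing:
                failures.append(f"events: missing columns {sorted(missing)}")
            else:
                if "stop_s" in ev.columns:
                    bad = ev.dropna(subset=["stop_s"])
                    bad = bad[bad["stop_s"] < bad["time_s"]]
                    for i in bad.index:
                        failures.append(f"events: stop before start at row {int(i)}")
                if trials is not None and {"start_s", "stop_s"} <= set(trials.columns):
                    for i, row in ev.iterrows():
                        inside = (
                            (trials["start_s"] <= row["time_s"]) & (row["time_s"] < trials["stop_s"])
                        ).any()
                        if not inside:
                            warnings.append(
                                f"events: event at {row['time_s']}s (row {int(i)}) outside all trials"
                            )
        except Exception as exc:
            failures.append(f"events: {exc}")

    return {"failures": failures, "warnings": warnings}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full chain and return the run manifest.

    Writes: recording/events/trials CSVs (when simulating), processed
    trace CSV + params JSON, transient table CSV, peri-event matrix CSV,
    trial-block summary JSON, resolved config YAML and the manifest
    JSON.  The manifest maps each output to its SHA-256 hash; identical
    (config, seed) yield identical hashes.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if config.simulate:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        events = simulate_events(sim, config.schedule)
        rec, truth = simulate_photometry(sim, events=events)
        rec.to_csv(out / "recording.csv")
        events.to_csv(out / "events.csv")
        events.trials_to_csv(out / "trials.csv")
        truth.to_json(out / "truth.json")
        written += [out / "recording.csv", out / "events.csv", out / "trials.csv", out / "truth.json"]
    else:
        if not config.recording_csv:
            raise ConfigurationError("recording_csv is required when simulate is false")
        rec = PhotometryRecording.from_csv(config.recording_csv)
        if config.events_csv:
            events = EventStream.from_csv(config.events_csv, config.trials_csv)
        else:
            events = EventStream()
    log.info("recording: %d samples at %.3g Hz", len(rec), rec.rate_hz)

    trace = process_recording(rec, config.process)
    trace.to_csv(out / "processed.csv")
    trace.params_json(out / "processed_params.json")
    written += [out / "processed.csv", out / "processed_params.json"]
    log.info("fit: slope=%.4f intercept=%.4f", trace.fit_slope, trace.fit_intercept)

    trs = detect_transients(
        trace,
        threshold_sd=config.threshold_sd,
        min_gap_s=config.min_gap_s,
        min_width_s=config.min_width_s,
    )
    transients_to_csv(trs, out / "transients.csv")
    written.append(out / "transients.csv")
    log.info("detected %d transients", len(trs))

    summary: dict = {"n_transients": len(trs)}
    if events.trial_bounds:
        blocks = trial_block_summary(trs, events.trial_bounds)
        summary["trial_blocks"] = [
            {
                "trial_id": b.trial_id,
                "block_label": b.block_label,
                "auc_total": b.auc_total,
                "transient_count": b.transient_count,
                "mean_width_s": float(np.mean(b.widths)) if b.widths else None,
            }
            for b in blocks
        ]
    if events.with_label(config.event_label):
        tensor = peri_event_average(trace, events, config.event_label, config.pre_s, config.post_s)
        tensor.to_csv(out / "peri_event.csv")
        written.append(out / "peri_event.csv")
        change = pre_post_change(tensor, (-config.pre_s, 0.0), (0.0, config.post_s))
        summary["pre_post_change"] = {
            "mean": change["mean"],
            "sd": change["sd"],
            "cohens_d_vs_zero": change["cohens_d_vs_zero"],
            "n_events": change["n"],
            "n_dropped": tensor.n_dropped,
        }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    written.append(out / "summary.json")

    (out / "config_resolved.yaml").write_text(yaml.safe_dump(config.resolved_dict(), sort_keys=True))
    written.append(out / "config_resolved.yaml")

    manifest = {
        "seed": config.seed,
        "outputs": {p.name: _sha256(p) for p in sorted(written)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
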