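"""Dual-channel fiber-photometry processing.

Turns a raw (465 nm GCaMP, 405 nm isosbestic) recording into a
motion-corrected, drift-free, z-scored trace.  The chain is

    low-pass filter -> loess smoothing -> moving-minima detrending
    -> positive re-offset -> isosbestic regression fit -> dF/F -> z-score

The isosbestic channel captures motion artifacts and bleaching that are
calcium-independent; regressing the signal channel onto it and taking
(signal - fit) / fit cancels structure shared between the channels while
preserving calcium transients, which exist only in the 465 nm channel.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import maximum_filter1d, minimum_filter1d
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import (
    DataError,
    DegenerateFitError,
    NumericDomainError,
    ParameterError,
    ShapeError,
    StageError,
)

__all__ = [
    "PhotometryRecording",
    "ProcessedTrace",
    "ProcessParams",
    "lowpass_filter",
    "loess_smooth",
    "running_minimum",
    "moving_minima_baseline",
    "detrend",
    "fit_control_channel",
    "compute_dff",
    "zscore_trace",
    "process_recording",
]

_TIME_TOL_S = 1e-6


@dataclass
class PhotometryRecording:
    """Raw dual-channel recording on a uniform time base.

    Attributes
    ----------
    time_s : np.ndarray
        Sample times in seconds, strictly increasing, uniform step.
    ch465 : np.ndarray
        Calcium-dependent GCaMP fluorescence (arbitrary units).
    ch405 : np.ndarray
        Isosbestic control fluorescence (arbitrary units).
    rate_hz : float
        Sampling rate; ``time_s[i] = time_s[0] + i / rate_hz``.
    """

    time_s: np.ndarray
    ch465: np.ndarray
    ch405: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.ch465 = np.asarray(self.ch465, dtype=float)
        self.ch405 = np.asarray(self.ch405, dtype=float)
        n = len(self.time_s)
        if len(self.ch465) != n or len(self.ch405) != n:
            raise ShapeError("time and channel arrays must have equal length")
        if n < 2:
            raise ShapeError("recording must contain at least 2 samples")
        for name, arr in (("time_s", self.time_s), ("ch465", self.ch465), ("ch405", self.ch405)):
            if not np.all(np.isfinite(arr)):
                raise NumericDomainError(f"non-finite values in {name}")
        dt = np.diff(self.time_s)
        if np.any(dt <= 0):
            raise ShapeError("time_s must be strictly increasing")
        if np.any(np.abs(dt - 1.0 / self.rate_hz) > _TIME_TOL_S):
            raise ShapeError("time_s step inconsistent with rate_hz")

    def __len__(self) -> int:
        return len(self.time_s)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"time_s": self.time_s, "ch465": self.ch465, "ch405": self.ch405}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PhotometryRecording":
        df = pd.read_csv(path)
        required = {"time_s", "ch465", "ch405"}
        missing = required - set(df.columns)
        if missing:
            raise ShapeError(f"recording CSV missing columns: {sorted(missing)}")
        t = df["time_s"].to_numpy(float)
        rate = 1.0 / float(np.median(np.diff(t)))
        return cls(t, df["ch465"].to_numpy(float), df["ch405"].to_numpy(float), rate)


@dataclass
class ProcessedTrace:
    """Fully processed trace with intermediates for auditing."""

    time_s: np.ndarray
    dff: np.ndarray
    zscore: np.ndarray
    fitted_control: np.ndarray
    baseline_465: np.ndarray
    baseline_405: np.ndarray
    fit_slope: float
    fit_intercept: float
    rate_hz: float
    params: dict = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"time_s": self.time_s, "dff": self.dff, "zscore": self.zscore}
        ).to_csv(path, index=False)

    def params_json(self, path: str | Path) -> None:
        payload = dict(self.params)
        payload["fit_slope"] = self.fit_slope
        payload["fit_intercept"] = self.fit_intercept
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


@dataclass
class ProcessParams:
    """Parameters of the full processing chain.

    cutoff_hz
        Low-pass cutoff (default 12 Hz).  ``None`` skips the filter,
        required when the sampling rate puts 12 Hz above Nyquist.
    loess_span
        Loess span as a fraction of the number of samples.
    minima_window_s
        Running-minimum window; must exceed the longest transient.
    minima_presmooth_s
        Extra loess smoothing (seconds of span) applied to the copy of
        the signal used for envelope estimation only; keeps the envelope
        from tracking noise minima.  0 disables.
    zscore_window_s
        ``None`` normalizes over the whole trace; otherwise a
        ``(start_s, stop_s)`` baseline interval (half-open).
    """

    cutoff_hz: float | None = 12.0
    loess_span: float = 0.01
    minima_window_s: float = 60.0
    minima_presmooth_s: float = 5.0
    zscore_window_s: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["zscore_window_s"] is not None:
            d["zscore_window_s"] = list(d["zscore_window_s"])
        return d


def lowpass_filter(recording: PhotometryRecording, cutoff_hz: float) -> PhotometryRecording:
    """Zero-phase 4th-order Butterworth low-pass of both channels.

    Zero phase (forward-backward) so transient peak latencies are not
    shifted; DC gain is 1 so baselines are preserved.
    """
    nyq = recording.rate_hz / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ParameterError(f"cutoff_hz must lie in (0, {nyq}); got {cutoff_hz}")
    sos = sps.butter(4, cutoff_hz, btype="low", fs=recording.rate_hz, output="sos")
    return PhotometryRecording(
        recording.time_s,
        sps.sosfiltfilt(sos, recording.ch465),
        sps.sosfiltfilt(sos, recording.ch405),
        recording.rate_hz,
    )


def loess_smooth(values: np.ndarray, span_frac: float) -> np.ndarray:
    """Locally weighted linear (loess) smoothing with tricube weights.

    ``span_frac`` is the fraction of samples in each local fit; the span
    must cover at least two points for the local line to be defined.
    """
    y = np.asarray(values, dtype=float)
    n = len(y)
    if n < 10:
        raise ParameterError("series too short for loess (need >= 10 samples)")
    if not 0 < span_frac <= 1:
        raise ParameterError("span_frac must lie in (0, 1]")
    w = int(np.ceil(span_frac * n))
    if w < 2:
        raise ParameterError(
            f"span_frac {span_frac} covers {w} sample(s); local linear fit needs >= 2"
        )
    x = np.arange(n, dtype=float)
    # delta > 0 makes lowess interpolate linearly between anchor points,
    # which is exact for locally linear signals and much faster.
    delta = float(w // 10)
    return lowess(y, x, frac=span_frac, it=0, delta=delta, return_sorted=False)


def running_minimum(values: np.ndarray, window_samples: int) -> np.ndarray:
    """Centered running minimum with edges clamped to the series bounds."""
    y = np.asarray(values, dtype=float)
    if window_samples < 1:
        raise ParameterError("window must cover at least one sample")
    if window_samples > len(y):
        raise ParameterError("window longer than the series")
    return minimum_filter1d(y, size=window_samples, mode="nearest")


def moving_minima_baseline(
    values: np.ndarray,
    window_s: float,
    rate_hz: float,
    smooth_span_frac: float | None = None,
    return_raw: bool = False,
):
    """Slow-drift baseline: moving-minima envelope, then loess-smoothed.

    The envelope is a morphological opening — a centered running minimum
    followed by a running maximum with the same window.  The minimum
    alone underestimates a monotonically bleaching baseline by the
    within-window drift (the minimum of a decaying curve sits at the
    window's trailing edge); the following maximum restores the envelope
    to the local floor while still ignoring any transient narrower than
    the window.  The envelope lies at or below the signal pointwise;
    loess smoothing removes the residual staircase steps.
    """
    y = np.asarray(values, dtype=float)
    n = len(y)
    w = int(round(window_s * rate_hz))
    if w < 1:
        raise ParameterError("window_s x rate_hz must be >= 1")
    if w > n:
        raise ParameterError("baseline window longer than the recording")
    # point-reflection padding continues the local trend through the
    # edges; clamped padding would bias the envelope low by the
    # within-window drift over the first/last half window
    pad = min(w, n - 1)
    left = 2 * y[0] - y[pad:0:-1]
    right = 2 * y[-1] - y[-2 : -pad - 2 : -1]
    ypad = np.concatenate([left, y, right])
    opened = maximum_filter1d(minimum_filter1d(ypad, size=w, mode="nearest"), size=w, mode="nearest")
    raw = np.minimum(opened[pad : pad + n], y)
    if smooth_span_frac is None:
        smooth_span_frac = min(1.0, max(w / n, 10.0 / n))
    smoothed = loess_smooth(raw, smooth_span_frac) if n >= 10 else raw.copy()
    if return_raw:
        return smoothed, raw
    return smoothed


def detrend(values: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Subtract a baseline envelope (additive drift removal)."""
    y = np.asarray(values, dtype=float)
    b = np.asarray(baseline, dtype=float)
    if y.shape != b.shape:
        raise ShapeError("values and baseline must have the same length")
    return y - b


def fit_control_channel(sig465: np.ndarray, sig405: np.ndarray):
    """OLS fit predicting the 465 nm signal from the 405 nm control.

    Returns ``(fitted_control, slope, intercept)`` where
    ``fitted_control = slope * sig405 + intercept``.  The fitted control
    is the motion/bleach reference used as the dF/F denominator.
    """
    x = np.asarray(sig405, dtype=float)
    y = np.asarray(sig465, dtype=float)
    if x.shape != y.shape:
        raise ShapeError("channels must have equal length")
    if len(x) < 3:
        raise DataError("need at least 3 samples for the regression")
    vx = np.var(x)
    if vx == 0 or np.ptp(x) < 1e-12 * max(1.0, abs(float(x[0]))):
        raise DegenerateFitError("isosbestic channel is constant; fit undefined")
    slope = float(np.cov(x, y, bias=True)[0, 1] / vx)
    intercept = float(np.mean(y) - slope * np.mean(x))
    return slope * x + intercept, slope, intercept


def compute_dff(sig465: np.ndarray, fitted_control: np.ndarray) -> np.ndarray:
    """dF/F = (signal - fitted control) / fitted control, per sample."""
    s = np.asarray(sig465, dtype=float)
    f = np.asarray(fitted_control, dtype=float)
    if s.shape != f.shape:
        raise ShapeError("signal and control must have equal length")
    bad = np.nonzero(f <= 0)[0]
    if bad.size:
        raise NumericDomainError(
            f"fitted control is non-positive at index {bad[0]} (value {f[bad[0]]:g})"
        )
    return (s - f) / f


def zscore_trace(dff: np.ndarray, norm_window: tuple[int, int] | None = None) -> np.ndarray:
    """Z-score against a normalization window (whole trace if ``None``).

    With a whole-trace window the output has mean 0 and SD 1; with a
    baseline window the rest of the trace is expressed in baseline SD
    units, the convention behind "+3 SD from baseline" thresholds.
    """
    y = np.asarray(dff, dtype=float)
    if norm_window is None:
        ref = y
    else:
        i0, i1 = int(norm_window[0]), int(norm_window[1])
        if not 0 <= i0 < i1 <= len(y):
            raise ParameterError(f"norm_window [{i0}, {i1}) outside trace of length {len(y)}")
        ref = y[i0:i1]
    mu = float(np.mean(ref))
    sd = float(np.std(ref))
    if sd == 0:
        raise NumericDomainError("zero variance in the normalization window")
    return (y - mu) / sd


def process_recording(
    recording: PhotometryRecording, params: ProcessParams | None = None
) -> ProcessedTrace:
    """Run the full chain on a recording.

    Stage order: low-pass filter, loess smoothing of each channel,
    moving-minima detrending of each channel, re-offset to a positive
    scale (each channel gets its own baseline-envelope mean added back so
    the dF/F denominator stays positive), isosbestic regression, dF/F,
    z-score.  All parameters and the normalization constants are recorded
    in ``ProcessedTrace.params``.
    """
    if params is None:
        params = ProcessParams()
    rec = recording

    def _stage(name, fn, *a, **kw):
        try:
            return fn(*a, **kw)
        except StageError:
            raise
        except Exception as exc:  # annotate with the stage name
            raise StageError(name, exc) from exc

    if params.cutoff_hz is not None:
        rec = _stage("lowpass_filter", lowpass_filter, rec, params.cutoff_hz)

    s465 = _stage("loess_smooth", loess_smooth, rec.ch465, params.loess_span)
    s405 = _stage("loess_smooth", loess_smooth, rec.ch405, params.loess_span)

    if params.minima_presmooth_s > 0:
        pre_frac = min(1.0, params.minima_presmooth_s * rec.rate_hz / len(rec))
        e465 = _stage("loess_smooth", loess_smooth, s465, pre_frac)
        e405 = _stage("loess_smooth", loess_smooth, s405, pre_frac)
    else:
        e465, e405 = s465, s405
    base465 = _stage(
        "moving_minima_baseline", moving_minima_baseline, e465, params.minima_window_s, rec.rate_hz
    )
    base405 = _stage(
        "moving_minima_baseline", moving_minima_baseline, e405, params.minima_window_s, rec.rate_hz
    )
    d465 = detrend(s465, base465) + float(np.mean(base465))
    d405 = detrend(s405, base405) + float(np.mean(base405))

    fitted, slope, intercept = _stage("fit_control_channel", fit_control_channel, d465, d405)
    if np.any(fitted <= 0):
        # regression can undershoot on extreme artifacts; surface as a domain error
        bad = int(np.nonzero(fitted <= 0)[0][0])
        raise StageError(
            "fit_control_channel",
            NumericDomainError(f"fitted control non-positive at index {bad}"),
        )
    dff = _stage("compute_dff", compute_dff, d465, fitted)

    if params.zscore_window_s is None:
        win = None
        ref = dff
    else:
        t0 = float(rec.time_s[0])
        i0 = int(round((params.zscore_window_s[0] - t0) * rec.rate_hz))
        i1 = int(round((params.zscore_window_s[1] - t0) * rec.rate_hz))
        win = (max(i0, 0), min(i1, len(dff)))
        ref = dff[win[0] : win[1]]
    z = _stage("zscore_trace", zscore_trace, dff, win)

    pdict = params.to_dict()
    pdict["zscore_mean"] = float(np.mean(ref))
    pdict["zscore_sd"] = float(np.std(ref))
    pdict["rate_hz"] = rec.rate_hz
    return ProcessedTrace(
        time_s=rec.time_s,
        dff=dff,
        zscore=z,
        fitted_control=fitted,
        baseline_465=base465,
        baseline_405=base405,
        fit_slope=slope,
        fit_intercept=intercept,
        rate_hz=rec.rate_hz,
        params=pdict,
    )
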