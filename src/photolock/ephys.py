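"""Responder classification of spike-rate series.

Spike frequency is expressed as % of the pre-drug baseline mean; a cell
is *responding* when its activity persistently deviates from baseline —
a run of at least ``consecutive_bins`` non-baseline bins whose deviation
is at least ``change_threshold_pct`` — and *insensitive* otherwise
(deviations under 10% on consecutive timepoints).  A paired signed-rank
test against the 100% baseline expectation assesses significance of the
post-stimulation change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DataError, NumericDomainError, ParameterError
from .synthdata import SpikeRateSeries

__all__ = [
    "CellResponse",
    "percent_baseline",
    "classify_cell",
    "signed_rank_change",
    "responder_fraction",
]


@dataclass
class CellResponse:
    label: str  # "responding" | "insensitive"
    max_abs_change_pct: float
    significant_change: bool | None
    per_epoch_summary: dict


def _epoch_mask(series: SpikeRateSeries, epoch_label: str) -> np.ndarray:
    for name, s0, s1 in series.epochs:
        if name == epoch_label:
            return (series.bin_start_s >= s0) & (series.bin_start_s < s1)
    raise DataError(f"epoch {epoch_label!r} not found in series")


def percent_baseline(series: SpikeRateSeries, baseline_epoch: str = "baseline") -> SpikeRateSeries:
    """Populate ``percent_baseline`` = 100 x rate / mean(baseline rate)."""
    mask = _epoch_mask(series, baseline_epoch)
    if not mask.any():
        raise DataError("baseline epoch contains no bins")
    mu = float(np.mean(series.rate_hz[mask]))
    if mu <= 0:
        raise NumericDomainError("baseline mean rate is zero; % baseline undefined")
    return SpikeRateSeries(
        bin_start_s=series.bin_start_s,
        rate_hz=series.rate_hz,
        epochs=list(series.epochs),
        percent_baseline=100.0 * series.rate_hz / mu,
    )


def classify_cell(
    series: SpikeRateSeries,
    change_threshold_pct: float = 10.0,
    consecutive_bins: int = 2,
    baseline_epoch: str = "baseline",
) -> CellResponse:
    """Apply the responder rule to a % baseline series.

    Responding iff some run of >= ``consecutive_bins`` consecutive
    non-baseline bins all deviate from 100% by at least
    ``change_threshold_pct`` (boundary counts as responding; "less than
    10% change" is insensitive).  Direction-agnostic: sustained
    excitation classifies the same as inhibition.
    """
    if change_threshold_pct < 0:
        raise ParameterError("change_threshold_pct must be non-negative")
    if consecutive_bins < 1:
        raise ParameterError("consecutive_bins must be >= 1")
    if series.percent_baseline is None:
        series = percent_baseline(series, baseline_epoch)
    pct = np.asarray(series.percent_baseline, dtype=float)
    base = _epoch_mask(series, baseline_epoch)
    outside = ~base
    if outside.sum() < consecutive_bins:
        raise DataError(
            f"need >= {consecutive_bins} non-baseline bins, have {int(outside.sum())}"
        )
    dev = np.abs(pct - 100.0)
    hit = (dev >= change_threshold_pct) & outside
    # longest run of consecutive hits within the non-baseline bins
    run = best = 0
    for h, o in zip(hit, outside):
        if h:
            run += 1
            best = max(best, run)
        elif o:
            run = 0
        # baseline bins neither extend nor break runs of non-baseline bins;
        # epochs are contiguous so this only matters at the boundary
        else:
            run = 0
    responding = best >= consecutive_bins
    per_epoch = {}
    for name, _, _ in series.epochs:
        m = _epoch_mask(series, name)
        if m.any():
            per_epoch[name] = {
                "mean_pct": float(np.mean(pct[m])),
                "min_pct": float(np.min(pct[m])),
                "max_pct": float(np.max(pct[m])),
            }
    return CellResponse(
        label="responding" if responding else "insensitive",
        max_abs_change_pct=float(dev[outside].max()),
        significant_change=None,
        per_epoch_summary=per_epoch,
    )


def signed_rank_change(
    series: SpikeRateSeries, epoch_label: str, baseline_epoch: str = "baseline"
) -> dict:
    """Two-sided Wilcoxon signed-rank test of an epoch against baseline.

    Pairs each epoch bin with a baseline bin (the last baseline bins,
    closest in time to the stimulation) and tests the paired differences
    of % baseline.  Pairing against observed baseline bins rather than
    the fitted 100% expectation keeps the test calibrated: the
    baseline-mean estimation error would otherwise shift every epoch bin
    coherently and inflate the false-positive rate.  All-zero
    differences are a degenerate case reported as such rather than
    raised.
    """
    if series.percent_baseline is None:
        series = percent_baseline(series, baseline_epoch)
    mask = _epoch_mask(series, epoch_label)
    base_mask = _epoch_mask(series, baseline_epoch)
    epoch_pct = series.percent_baseline[mask]
    base_pct = series.percent_baseline[base_mask]
    m = min(len(epoch_pct), len(base_pct))
    diffs = epoch_pct[:m] - base_pct[-m:]
    if len(diffs) < 5:
        raise DataError("need >= 5 paired bins for the signed-rank test")
    if np.all(diffs == 0):
        return {"statistic": np.nan, "p_value": np.nan, "n": len(diffs), "degenerate": True}
    res = stats.wilcoxon(diffs, alternative="two-sided", method="exact" if len(diffs) <= 25 else "auto")
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "n": int(len(diffs)),
        "degenerate": False,
    }


def responder_fraction(
    responses: list[CellResponse],
    group_labels: list[str],
    basis: str = "cell",
    animal_ids: list[str] | None = None,
) -> dict:
    """Per-group insensitive proportions plus a two-group comparison.

    ``basis='cell'`` compares the two groups' responding/insensitive
    counts with Fisher's exact test (exact at any sample size);
    ``basis='animal'`` compares per-animal insensitive fractions with an
    exact Mann-Whitney test and requires ``animal_ids``.
    """
    if len(responses) != len(group_labels):
        raise DataError("responses and group_labels must have equal length")
    if not responses:
        raise DataError("no cells given")
    groups = sorted(set(group_labels))
    insensitive = np.array([r.label == "insensitive" for r in responses])
    out: dict = {"proportion_insensitive": {}, "n_cells": {}}
    for g in groups:
        m = np.array([gl == g for gl in group_labels])
        if not m.any():
            raise DataError(f"group {g!r} is empty")
        out["proportion_insensitive"][g] = float(insensitive[m].mean())
        out["n_cells"][g] = int(m.sum())
    if len(groups) == 2:
        g0, g1 = groups
        m0 = np.array([gl == g0 for gl in group_labels])
        m1 = ~m0
        if basis == "cell":
            table = [
                [int(insensitive[m0].sum()), int((~insensitive)[m0].sum())],
                [int(insensitive[m1].sum()), int((~insensitive)[m1].sum())],
            ]
            _, p = stats.fisher_exact(table)
            out["test"] = {"name": "fisher_exact", "p_value": float(p)}
        elif basis == "animal":
            if animal_ids is None:
                raise DataError("basis='animal' requires animal_ids")
            fr: dict[str, dict[str, list[bool]]] = {g0: {}, g1: {}}
            for ins, g, a in zip(insensitive, group_labels, animal_ids):
                fr[g].setdefault(a, []).append(bool(ins))
            f0 = [float(np.mean(v)) for v in fr[g0].values()]
            f1 = [float(np.mean(v)) for v in fr[g1].values()]
            res = stats.mannwhitneyu(f0, f1, alternative="two-sided", method="exact")
            out["test"] = {"name": "mannwhitneyu_exact", "p_value": float(res.pvalue)}
        else:
            raise ParameterError("basis must be 'cell' or 'animal'")
    return out
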