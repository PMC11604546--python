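"""Social contact-duration summaries across repeated-exposure trials.

The task is five 5-minute exposures: an empty box control is not part of
the table; trials 1-4 present the same stimulus mouse (habituation) and
trial 5 a novel mouse (discrimination).  Inclusion rules act on trial 1
only: subjects exploring less than 15 s, or lying outside mean +/- k SD
of their group's trial-1 distribution, are excluded; later-trial
performance never excludes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, NumericDomainError

__all__ = [
    "qc_filter",
    "subject_metrics",
    "cohens_d",
    "group_contrast",
]

_COLUMNS = ["subject_id", "group", "trial", "duration_s"]


def _check_table(table: pd.DataFrame) -> None:
    missing = set(_COLUMNS) - set(table.columns)
    if missing:
        raise DataError(f"behavior table missing columns: {sorted(missing)}")


def qc_filter(
    table: pd.DataFrame,
    sd_k: float = 2.0,
    min_trial1_s: float = 15.0,
    min_group_n_for_sd: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply trial-1 inclusion rules; returns (filtered table, exclusion log).

    Rule 1: trial-1 contact duration < ``min_trial1_s`` excludes (strict:
    exactly 15 s is retained).  Rule 2: trial-1 duration outside
    mean +/- ``sd_k`` SD of the subject's own group's trial-1 values
    excludes; the band is computed once from the trial-1 distribution of
    subjects surviving rule 1, matching an a-priori inclusion criterion.
    Groups below ``min_group_n_for_sd`` subjects skip the SD rule with a
    log entry.  Later-trial values never exclude.
    """
    _check_table(table)
    t1 = table[table["trial"] == 1]
    subjects = table["subject_id"].unique()
    missing_t1 = set(subjects) - set(t1["subject_id"])
    if missing_t1:
        raise DataError(f"subjects without a trial-1 row: {sorted(missing_t1)}")

    excluded: dict[str, str] = {}
    for row in t1.itertuples():
        if row.duration_s < min_trial1_s:
            excluded[row.subject_id] = f"trial1 duration {row.duration_s:g}s < {min_trial1_s:g}s"

    log_rows = []
    for group, grp in t1.groupby("group"):
        # band computed after the minimum-duration rule, so near-zero
        # explorers do not drag it toward zero
        kept = grp[~grp["subject_id"].isin(excluded)]
        vals = kept["duration_s"].to_numpy(float)
        if len(vals) < min_group_n_for_sd:
            log_rows.append(
                {
                    "subject_id": "",
                    "group": group,
                    "reason": f"SD rule skipped: only {len(vals)} subjects",
                    "excluded": False,
                }
            )
            continue
        mu, sd = float(np.mean(vals)), float(np.std(vals, ddof=1))
        lo, hi = mu - sd_k * sd, mu + sd_k * sd
        for row in kept.itertuples():
            if not lo <= row.duration_s <= hi:
                excluded[row.subject_id] = (
                    f"trial1 duration {row.duration_s:g}s outside "
                    f"[{lo:.3g}, {hi:.3g}] (mean±{sd_k:g}SD of group {group})"
                )

    for row in t1.itertuples():
        if row.subject_id in excluded:
            log_rows.append(
                {
                    "subject_id": row.subject_id,
                    "group": row.group,
                    "reason": excluded[row.subject_id],
                    "excluded": True,
                }
            )
    filtered = table[~table["subject_id"].isin(excluded)].reset_index(drop=True)
    log = pd.DataFrame(log_rows, columns=["subject_id", "group", "reason", "excluded"])
    return filtered, log


def subject_metrics(table: pd.DataFrame, n_trials: int = 5) -> pd.DataFrame:
    """Habituation and discrimination indices per subject.

    habituation_index = trial4 / trial1 (decline toward familiarity);
    discrimination_index = trial5 - trial4 in seconds (novelty rebound).
    Subjects missing any of the ``n_trials`` trials are skipped with a
    log column rather than an exception.
    """
    _check_table(table)
    rows = []
    for (sid, group), grp in table.groupby(["subject_id", "group"]):
        durs = dict(zip(grp["trial"], grp["duration_s"]))
        if any(tr not in durs for tr in range(1, n_trials + 1)):
            rows.append(
                {"subject_id": sid, "group": group, "habituation_index": np.nan,
                 "discrimination_index_s": np.nan, "included": False,
                 "note": "missing trial(s)"}
            )
            continue
        hab = durs[4] / durs[1] if durs[1] > 0 else np.nan
        rows.append(
            {"subject_id": sid, "group": group, "habituation_index": hab,
             "discrimination_index_s": durs[5] - durs[4], "included": True, "note": ""}
        )
    return pd.DataFrame(rows)


def cohens_d(sample_a, sample_b) -> float:
    """Cohen's d with the pooled standard deviation.

    d = (mean_a - mean_b) / s_p,
    s_p = sqrt(((n_a-1)s_a^2 + (n_b-1)s_b^2) / (n_a+n_b-2)),
    positive when sample_a exceeds sample_b.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DataError("each sample needs n >= 2")
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    if sp2 <= 0:
        raise NumericDomainError("pooled SD is zero; d undefined")
    return float((np.mean(a) - np.mean(b)) / np.sqrt(sp2))


def group_contrast(table: pd.DataFrame, trial: int, groups: tuple[str, str] | None = None) -> dict:
    """Two-group contrast of contact duration at one trial.

    Reports per-group mean +/- SEM, a two-sided Mann-Whitney rank test
    (exact at small n) and Cohen's d (first group minus second).
    """
    _check_table(table)
    sub = table[table["trial"] == trial]
    if groups is None:
        uniq = sorted(sub["group"].unique())
        if len(uniq) != 2:
            raise DataError(f"need exactly 2 groups, found {uniq}; pass groups=")
        groups = (uniq[0], uniq[1])
    a = sub[sub["group"] == groups[0]]["duration_s"].to_numpy(float)
    b = sub[sub["group"] == groups[1]]["duration_s"].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise DataError("each group needs >= 2 subjects at the requested trial")
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if max(len(a), len(b)) <= 25 else "auto"
    )
    identical = np.var(np.concatenate([a, b])) == 0
    pooled_zero = np.var(a, ddof=1) + np.var(b, ddof=1) == 0
    if identical:
        d = 0.0
    elif pooled_zero:
        d = float("nan")  # degenerate: means differ but there is no spread
    else:
        d = cohens_d(a, b)
    return {
        "trial": trial,
        "groups": groups,
        "mean": {groups[0]: float(np.mean(a)), groups[1]: float(np.mean(b))},
        "sem": {
            groups[0]: float(np.std(a, ddof=1) / np.sqrt(len(a))),
            groups[1]: float(np.std(b, ddof=1) / np.sqrt(len(b))),
        },
        "mannwhitney_p": 1.0 if identical else float(res.pvalue),
        "cohens_d": d,
        "n": {groups[0]: len(a), groups[1]: len(b)},
    }
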