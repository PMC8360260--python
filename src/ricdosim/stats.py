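"""Comparison statistics for biodistribution studies.

Tumour-to-blood ratios, fold differences between group means, and an
exact small-sample two-sided Mann–Whitney (Wilcoxon rank-sum) test by
full enumeration — the appropriate regime for groups of 3–5 animals,
where the normal approximation is meaningless.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .biodist import BiodistMeasurement, BiodistSummary, summarize, to_frame
from .errors import MissingDataError, ValidationError


@dataclass(frozen=True)
class RatioEstimate:
    """A tumour/blood-style ratio.

    ``ratio_of_means`` divides the two group means (what a published wide
    table of means supports); ``mean_of_ratios`` pairs animals by
    subject_id and averages the per-animal ratios, which is what a
    destructive-sampling design actually measures, and carries an SEM.
    """

    label: str
    value: float
    mode: str  # "ratio_of_means" | "mean_of_ratios"
    dispersion: float | None = None

    def __post_init__(self):
        if self.value < 0:
            raise ValidationError("ratio must be ≥ 0")


def fold_difference(mean_a: float, mean_b: float) -> float:
    """mean_a / mean_b, e.g. specific vs irrelevant-conjugate tumour uptake."""
    if not (mean_b > 0 and math.isfinite(mean_b)):
        raise ZeroDivisionError(f"denominator mean must be > 0, got {mean_b}")
    return mean_a / mean_b


def _cell(measurements: Sequence[BiodistMeasurement], group: str, time_h: float, organ: str):
    rows = [
        m for m in measurements
        if m.group_id == group and m.organ == organ and m.time_h == time_h
    ]
    if not rows:
        raise MissingDataError(f"no {organ} measurements for group {group!r} at {time_h} h")
    return rows


def tumour_to_blood(
    data: Sequence[BiodistMeasurement] | Sequence[BiodistSummary],
    group: str,
    time_h: float,
    mode: str | None = None,
) -> RatioEstimate:
    """Tumour/blood ratio for one group at one time point.

    With per-animal measurements the default mode is ``mean_of_ratios``
    (animals paired by subject_id); with summaries only, or when requested
    explicitly, ``ratio_of_means`` divides the printed means.
    """
    label = f"T/B {group} {time_h} h"
    is_summary = bool(data) and isinstance(data[0], BiodistSummary)
    if mode is None:
        mode = "ratio_of_means" if is_summary else "mean_of_ratios"
    if mode not in ("ratio_of_means", "mean_of_ratios"):
        raise ValidationError(f"unknown mode {mode!r}")

    if is_summary:
        if mode == "mean_of_ratios":
            raise ValidationError("mean_of_ratios requires per-animal measurements")
        by = {
            s.organ: s
            for s in data
            if s.group_id == group and s.time_h == time_h
        }
        for organ in ("tumour", "blood"):
            if organ not in by:
                raise MissingDataError(f"no {organ} summary for group {group!r} at {time_h} h")
        if by["blood"].mean_pct_id_per_g == 0:
            raise ZeroDivisionError("blood mean is zero")
        return RatioEstimate(
            label, by["tumour"].mean_pct_id_per_g / by["blood"].mean_pct_id_per_g,
            "ratio_of_means",
        )

    tumour = _cell(data, group, time_h, "tumour")
    blood = _cell(data, group, time_h, "blood")
    if mode == "ratio_of_means":
        mb = float(np.mean([m.pct_id_per_g for m in blood]))
        if mb == 0:
            raise ZeroDivisionError("blood mean is zero")
        mt = float(np.mean([m.pct_id_per_g for m in tumour]))
        return RatioEstimate(label, mt / mb, mode)

    blood_by_subject = {m.subject_id: m.pct_id_per_g for m in blood}
    ratios = []
    for m in tumour:
        if m.subject_id not in blood_by_subject:
            raise MissingDataError(f"no blood value for subject {m.subject_id!r}")
        b = blood_by_subject[m.subject_id]
        if b == 0:
            raise ZeroDivisionError(f"blood value is zero for subject {m.subject_id!r}")
        ratios.append(m.pct_id_per_g / b)
    n = len(ratios)
    sem = 0.0 if n == 1 else float(np.std(ratios, ddof=1) / math.sqrt(n))
    return RatioEstimate(label, float(np.mean(ratios)), mode, dispersion=sem)


def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    # U for group a from its midranks within the pooled sample
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def rank_sum_exact(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Exact two-sided Mann–Whitney p-value by full enumeration.

    All C(n_a+n_b, n_a) assignments of the pooled midranks are enumerated;
    the two-sided p is the probability, under that uniform null, of a U
    statistic at least as far from its null mean n_a·n_b/2 as observed.
    Ties take midranks, which keeps the test well-defined for the heavily
    rounded values typical of published tables.  Intended for n ≤ 10 per
    group; identical samples give p = 1, complete separation of 4 vs 4
    gives p = 2/70.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    if a.size > 10 or b.size > 10:
        raise ValidationError("exact enumeration supports at most 10 per group")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # midranks for ties
    n_a, n = a.size, pooled.size
    centre = n_a * (n - n_a) / 2.0
    obs_dev = abs(_u_statistic(ranks[:n_a], n_a) - centre)

    count = 0
    total = 0
    eps = 1e-9
    for idx in itertools.combinations(range(n), n_a):
        u = _u_statistic(ranks[list(idx)], n_a)
        if abs(u - centre) >= obs_dev - eps:
            count += 1
        total += 1
    return count / total


def group_values(
    measurements: Sequence[BiodistMeasurement], group: str, organ: str, time_h: float
) -> list[float]:
    """Per-animal %ID/g values for one cell, for feeding rank_sum_exact."""
    return [m.pct_id_per_g for m in _cell(measurements, group, time_h, organ)]


def wide_report(
    measurements: Sequence[BiodistMeasurement],
    compare: Sequence[tuple[str, str]] = (),
    decimals: int = 1,
) -> pd.DataFrame:
    """Assemble a publication-style wide table: organ rows, group × time
    columns with "mean ± sem" cells, plus exact rank-sum p-value columns
    for each requested pair of groups (compared at every shared time).
    """
    summaries = summarize(measurements)
    df = to_frame(measurements)
    wide: dict[str, dict[str, str]] = {}
    organs = list(dict.fromkeys(df["organ"]))
    for s in summaries:
        col = f"{s.group_id} {s.time_h:g} h"
        wide.setdefault(col, {})[s.organ] = (
            f"{s.mean_pct_id_per_g:.{decimals}f} ± {s.sem:.{decimals}f}"
        )
    out = pd.DataFrame(index=organs)
    for col, cells in wide.items():
        out[col] = pd.Series(cells)
    for ga, gb in compare:
        times = sorted(
            set(df.loc[df.group_id == ga, "time_h"]) & set(df.loc[df.group_id == gb, "time_h"])
        )
        for t in times:
            col = f"P {ga} vs {gb} {t:g} h"
            pvals = {}
            for organ in organs:
                try:
                    pvals[organ] = f"{rank_sum_exact(group_values(measurements, ga, organ, t), group_values(measurements, gb, organ, t)):.3f}"
                except MissingDataError:
                    pvals[organ] = ""
            out[col] = pd.Series(pvals)
    out.index.name = "organ"
    return out
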