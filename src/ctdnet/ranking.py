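"""Ranking, tie diagnostics and the median-threshold classifier.

The web-style presentation ranks each chemical's disease inferences with
curated relationships first, then by descending network score.  Tie
diagnostics quantify how often a statistic fails to separate inferences
for the same chemical; aggregate statistics (S_XYA, W_XYA) are expected to
tie far less often than C_xy or p1, which ignore connector identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

STATISTICS = ("c_xy", "p1", "p2", "s_xya", "w_xya", "w_bonferroni")

EXACT_DISPLAY = "exact_display"
NUMERIC = "numeric"
NUMERIC_TOLERANCE = 1e-9


@dataclass(frozen=True)
class TieSummary:
    statistic: str
    n_tied_inferences: int
    n_chemicals_with_ties: int


def _check_statistic(statistic: str) -> None:
    if statistic not in STATISTICS:
        raise ValueError(
            f"unknown statistic {statistic!r}; expected one of {STATISTICS}"
        )


def rank_inferences(
    scores: pd.DataFrame,
    group_by: str = "chemical",
    sort_score: str = "w_xya",
) -> pd.DataFrame:
    """Rank inferences within each chemical (or disease) group.

    Within a group, curated rows precede novel rows; then descending
    ``sort_score``.  Residual ties break by larger m, then ascending
    partner id, making the order total and permutation-invariant.
    Adds a 1-based ``rank`` column per group.
    """
    if scores.empty:
        raise ValueError("cannot rank an empty score table")
    _check_statistic(sort_score)
    if group_by == "chemical":
        group_col, partner_col = "chemical_id", "disease_id"
    elif group_by == "disease":
        group_col, partner_col = "disease_id", "chemical_id"
    else:
        raise ValueError(f"group_by must be 'chemical' or 'disease', got {group_by!r}")
    ordered = scores.sort_values(
        by=[group_col, "curated", sort_score, "m", partner_col],
        ascending=[True, False, False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    ordered["rank"] = ordered.groupby(group_col).cumcount() + 1
    return ordered


def count_ties(
    scores: pd.DataFrame,
    statistic: str = "w_xya",
    tolerance_mode: str = EXACT_DISPLAY,
    group_col: str = "chemical_id",
) -> TieSummary:
    """Count tied inferences per chemical under one statistic.

    A row is tied when another row for the same chemical carries an equal
    statistic value — equal after 2-decimal display rounding
    (``exact_display``) or within 1e-9 (``numeric``).
    """
    _check_statistic(statistic)
    n_tied = 0
    n_chems = 0
    for _, group in scores.groupby(group_col, sort=False):
        values = group[statistic].to_numpy(dtype=float)
        if values.size < 2:
            continue
        if tolerance_mode == EXACT_DISPLAY:
            rounded = np.round(values, 2)
            _, inverse, counts = np.unique(
                rounded, return_inverse=True, return_counts=True
            )
            tied_mask = counts[inverse] >= 2
        elif tolerance_mode == NUMERIC:
            order = np.argsort(values)
            sorted_vals = values[order]
            gaps = np.diff(sorted_vals) <= NUMERIC_TOLERANCE
            tied_sorted = np.zeros(values.size, dtype=bool)
            tied_sorted[:-1] |= gaps
            tied_sorted[1:] |= gaps
            tied_mask = np.zeros(values.size, dtype=bool)
            tied_mask[order] = tied_sorted
        else:
            raise ValueError(f"unknown tolerance mode {tolerance_mode!r}")
        k = int(tied_mask.sum())
        if k:
            n_tied += k
            n_chems += 1
    return TieSummary(statistic, n_tied, n_chems)


def median_threshold_classifier(
    curated_w: Sequence[float], novel_w: Sequence[float]
) -> dict:
    """Flag novel inferences scoring strictly above the curated median.

    Returns the threshold, the fraction of novel inferences above it, and
    the curated sensitivity (fraction of curated inferences above their own
    median — 1/2 by construction for odd-sized samples of distinct values,
    0 when all curated scores are equal, because the inequality is strict).
    """
    curated = np.asarray(curated_w, dtype=float)
    novel = np.asarray(novel_w, dtype=float)
    if curated.size == 0:
        raise ValueError("curated score list must be non-empty")
    threshold = float(np.median(curated))
    novel_above = float(np.mean(novel > threshold)) if novel.size else 0.0
    sensitivity = float(np.mean(curated > threshold))
    return {
        "threshold": threshold,
        "novel_above_fraction": novel_above,
        "curated_sensitivity": sensitivity,
    }


def top_k_curated_overlap(
    scores: pd.DataFrame, k: int, statistic: str = "w_xya"
) -> int:
    """Curated inferences among the global top k by pure score order.

    Unlike :func:`rank_inferences` this ignores the curated-first display
    rule: the question is whether high scores coincide with curation.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    _check_statistic(statistic)
    if k > len(scores):
        warnings.warn(
            f"k={k} exceeds table size {len(scores)}; counting over all rows",
            stacklevel=2,
        )
        k = len(scores)
    top = scores.sort_values(
        by=[statistic, "m", "chemical_id", "disease_id"],
        ascending=[False, False, True, True],
        kind="mergesort",
    ).head(k)
    return int(top["curated"].sum())
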