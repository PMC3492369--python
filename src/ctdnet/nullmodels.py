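"""Degree-preserving randomization and real-vs-shuffled score comparison.

The null model repeatedly picks two chemical-gene edges and switches the
genes between the two chemicals.  Every node keeps its exact chemical-gene
degree, so the power-law topology survives while specific co-association
structure is destroyed.  Inferences scored on a shuffled network calibrate
how much of a real inference's W_XYA score is explained by connectivity
alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .network import CHEM_GENE, GENE_DISEASE, TripartiteNetwork

CURATED = "curated"
NOVEL = "novel"
TOTAL = "total"


@dataclass(frozen=True)
class ShuffleConfig:
    """Swap count, replicate count and seed for the shuffle null model.

    ``n_swaps`` counts *applied* swaps: a proposal that would duplicate an
    existing edge (or pair an edge with itself) is rejected and redrawn
    without consuming the budget, so mixing depth is comparable across
    network densities.
    """

    n_swaps: int = 1_000_000
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_swaps < 1:
            raise ValueError("n_swaps must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class ShuffleComparison:
    """Real-vs-shuffled W_XYA summary for one stratum (Table-4 style)."""

    stratum: str
    n_real: int
    n_shuffled: int
    n_matching: int
    mean_difference: float
    t_statistic: float
    p_value: float
    undefined: bool = False


def shuffle_network(
    net: TripartiteNetwork,
    cfg: ShuffleConfig,
    layer: str = CHEM_GENE,
    max_attempts_factor: int = 200,
) -> TripartiteNetwork:
    """Return a copy with ``cfg.n_swaps`` degree-preserving edge swaps applied.

    Only the chemical-gene layer is shuffled by default (``layer`` may be
    set to ``gene_disease`` for sensitivity analysis; that variant is not
    part of the published procedure).  Deterministic under ``cfg.seed``.
    """
    edges = sorted(net.edges[layer])
    if len(edges) < 2:
        raise ValueError(
            f"need at least 2 edges in layer {layer!r} to shuffle, "
            f"got {len(edges)}"
        )
    rng = np.random.default_rng(cfg.seed)
    edge_set = set(edges)
    applied = 0
    attempts = 0
    max_attempts = max_attempts_factor * cfg.n_swaps
    n = len(edges)
    while applied < cfg.n_swaps:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"shuffle stalled: {applied} applied swaps after "
                f"{attempts - 1} proposals; the layer may be too dense or "
                "too small to randomize further"
            )
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        (c1, g1), (c2, g2) = edges[i], edges[j]
        if g1 == g2 or c1 == c2:
            continue  # swap would be a no-op or create a parallel pair
        e1, e2 = (c1, g2), (c2, g1)
        if e1 in edge_set or e2 in edge_set:
            continue  # duplicate edge; reject and redraw
        edge_set.remove((c1, g1))
        edge_set.remove((c2, g2))
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i], edges[j] = e1, e2
        applied += 1
    shuffled = net.copy()
    shuffled.edges[layer] = edge_set
    shuffled._adjacency = None
    shuffled.metadata = dict(net.metadata)
    shuffled.metadata["shuffle"] = {
        "layer": layer,
        "n_swaps": cfg.n_swaps,
        "seed": cfg.seed,
        "proposals": attempts,
    }
    return shuffled


def welch_t_test(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Welch's t-test (unequal variances).

    Uses the Welch-Satterthwaite degrees of freedom; requires both samples
    to have at least two observations and nonzero variance in at least one.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(
            f"Welch's t-test needs >= 2 observations per sample "
            f"(got {a.size}, {b.size})"
        )
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise ValueError("both samples have zero variance with unequal means")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def compare_real_vs_shuffled(
    real_scores: pd.DataFrame,
    shuffled_scores: pd.DataFrame,
    score_column: str = "w_xya",
    paired: bool = False,
) -> list[ShuffleComparison]:
    """Match inferences by (chemical, disease) and compare score levels.

    ``mean_difference`` is real minus shuffled over the matched pairs; the
    significance test is Welch's two-sample t on the matched real and
    shuffled score lists per stratum (curated / novel / total), or a paired
    t-test when ``paired`` is set.
    """
    key = ["chemical_id", "disease_id"]
    merged = real_scores.merge(
        shuffled_scores[key + [score_column, "curated"]],
        on=key,
        suffixes=("_real", "_shuffled"),
    )
    out: list[ShuffleComparison] = []
    for stratum in (CURATED, NOVEL, TOTAL):
        if stratum == TOTAL:
            real_rows = real_scores
            shuf_rows = shuffled_scores
            pairs = merged
        else:
            want = stratum == CURATED
            real_rows = real_scores[real_scores["curated"] == want]
            shuf_rows = shuffled_scores[shuffled_scores["curated"] == want]
            pairs = merged[merged["curated_real"] == want]
        a = pairs[f"{score_column}_real"].to_numpy(dtype=float)
        b = pairs[f"{score_column}_shuffled"].to_numpy(dtype=float)
        if a.size == 0:
            out.append(
                ShuffleComparison(
                    stratum, len(real_rows), len(shuf_rows), 0,
                    math.nan, math.nan, math.nan, undefined=True,
                )
            )
            continue
        mean_diff = float(np.mean(a - b))
        try:
            if paired:
                res = sps.ttest_rel(a, b)
                t, p = float(res.statistic), float(res.pvalue)
            else:
                t, p = welch_t_test(a, b)
            undefined = False
        except ValueError:
            t, p, undefined = math.nan, math.nan, True
        out.append(
            ShuffleComparison(
                stratum, len(real_rows), len(shuf_rows), int(a.size),
                mean_diff, t, p, undefined=undefined,
            )
        )
    return out


def comparison_report(comparisons: Sequence[ShuffleComparison]) -> pd.DataFrame:
    """Tabular report mirroring the real-vs-shuffled summary columns."""
    return pd.DataFrame(
        [
            {
                "stratum": c.stratum,
                "n_real": c.n_real,
                "n_shuffled": c.n_shuffled,
                "n_matching": c.n_matching,
                "mean_difference": c.mean_difference,
                "t_statistic": c.t_statistic,
                "p_value": c.p_value,
                "undefined": c.undefined,
            }
            for c in comparisons
        ]
    )
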