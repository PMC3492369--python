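"""Local-network-topology statistics for ranking transitive inferences.

Five statistics score an inferred relationship between a chemical ``x`` and
a disease ``y`` connected through a set ``A`` of ``m`` genes, inside a
network of ``N`` connected nodes:

``C_xy``
    Hypergeometric mutual clustering coefficient: the upper-tail
    probability of observing ``m`` or more common neighbors between nodes
    of degree ``n_x`` and ``n_y``, on the -log10 scale.  Penalizes hub
    endpoints, ignores connector identity.

``p1``
    The point probability of the observed common-neighbor count — the
    hypergeometric mass at exactly ``m`` — on the natural-log scale (the
    scale on which the CTD network scores are published; see the methods
    note on the mixed logarithm bases of the published score system).

``p2``
    Connector-degree statistic: the chance that each connecting gene,
    carrying ``n_i`` edges, touches two designated nodes is proportional to
    ``n_i(n_i-1)/(N(N-1))``; ``p2`` is the -log10 of the product over the
    gene set.  Low-degree connectors are more surprising, so hubs in ``A``
    drag ``p2`` down.

``S_XYA``
    Equal-weight logarithmic opinion pool of ``p1`` and ``p2``
    (``w1 = w2 = 1/2``, ``k = 1``): the arithmetic mean on the log scale.

``W_XYA``
    Weighted pool whose weights are a function of ``m``; as the gene set
    grows the weight shifts onto ``p1``, so diseases inferred through very
    many genes are not dominated by the additive ``p2`` term.

Probability work is done in log space end to end (log-gamma binomials,
log-sum-exp tails) so degrees in the thousands against N ~ 10^4..10^5 do
not underflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .inference import Inference
from .network import CHEMICAL, GENE, NodeRef, TripartiteNetwork

LN10 = math.log(10.0)

# W_XYA weight schedule: residual weight drains off p2 geometrically with m.
# The constants are calibrated so the weights at m = 5 equal the pair
# (0.97697, 0.010594) implied by the published CTD score tables.
W_POOL_DECAY = 2.0
W_POOL_ALPHA = 0.737
W_POOL_BETA = 0.339

SCORE_COLUMNS = (
    "chemical_id", "disease_id", "m", "curated",
    "c_xy", "p1", "p2", "s_xya", "w_xya", "w_bonferroni",
)


@dataclass(frozen=True)
class ScoreInputs:
    """Degree/count tuple feeding all five statistics.

    ``gene_degrees`` lists the total degree ``n_i`` of each connecting gene;
    a connecting gene touches both endpoints, so each ``n_i >= 2``.
    """

    n_x: int
    n_y: int
    m: int
    N: int
    gene_degrees: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if self.m > min(self.n_x, self.n_y):
            raise ValueError(
                f"m={self.m} exceeds min(n_x, n_y)={min(self.n_x, self.n_y)}: "
                "an endpoint cannot have more common neighbors than edges"
            )
        if self.gene_degrees:
            if len(self.gene_degrees) != self.m:
                raise ValueError(
                    f"got {len(self.gene_degrees)} gene degrees for m={self.m}"
                )
            bad = [d for d in self.gene_degrees if d < 2]
            if bad:
                raise ValueError(
                    f"connecting genes touch both endpoints, so each degree "
                    f"must be >= 2; got {bad}"
                )
        upper = max(self.n_x, self.n_y, max(self.gene_degrees, default=0))
        if self.N <= upper:
            raise ValueError(f"N={self.N} must exceed every node degree ({upper})")


@dataclass(frozen=True)
class PoolWeights:
    """Weights of the logarithmic opinion pool (normalization k fixed at 1)."""

    w1: float
    w2: float

    def __post_init__(self) -> None:
        if self.w1 < 0 or self.w2 < 0:
            raise ValueError("pool weights must be non-negative")

    @classmethod
    def equal(cls) -> "PoolWeights":
        return cls(0.5, 0.5)

    @classmethod
    def m_weighted(cls, m: int) -> "PoolWeights":
        """Weights as a function of the connector count m.

        ``w1`` rises toward 1 and ``w2`` decays geometrically as the gene
        set grows, so the count-based statistic dominates for large m.
        """
        if m < 1:
            raise ValueError(f"m must be >= 1, got {m}")
        decay = W_POOL_DECAY ** (-m)
        return cls(1.0 - W_POOL_ALPHA * decay, W_POOL_BETA * decay)


@dataclass(frozen=True)
class ScoreVector:
    """The five statistics of one inference, plus the Bonferroni-corrected W."""

    c_xy: float
    p1: float
    p2: float
    s_xya: float
    w_xya: float
    w_bonferroni: float


def log_choose(n: int, r: int) -> float:
    """Natural-log binomial coefficient via log-gamma; exact for small n."""
    if r < 0 or n < 0 or r > n:
        raise ValueError(f"invalid binomial coefficient C({n}, {r})")
    return float(gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1))


def _ln_hypergeom_pmf(n_x: int, n_y: int, m: int, N: int) -> float:
    """ln P[exactly m common neighbors | degrees n_x, n_y among N nodes]."""
    return (
        log_choose(n_x, m)
        + log_choose(N - n_x, n_y - m)
        - log_choose(N, n_y)
    )


def c_xy(inputs: ScoreInputs) -> float:
    """Hypergeometric mutual clustering coefficient, -log10 scale.

    Upper tail from the observed overlap m to min(n_x, n_y), the largest
    combinatorially possible overlap.
    """
    n_x, n_y, m, N = inputs.n_x, inputs.n_y, inputs.m, inputs.N
    return c_xy_tail(n_x, n_y, m, N)


def c_xy_tail(n_x: int, n_y: int, m: int, N: int) -> float:
    """Raw tail form of C_xy; unlike :func:`c_xy` it admits m = 0."""
    upper = min(n_x, n_y)
    if m == 0:
        return 0.0  # the tail from zero is the certain event
    # overlaps below n_x + n_y - N are impossible when the endpoints cover
    # most of the network; their hypergeometric mass is zero
    ks = np.arange(max(m, n_x + n_y - N), upper + 1)
    terms = (
        gammaln(n_x + 1) - gammaln(ks + 1) - gammaln(n_x - ks + 1)
        + gammaln(N - n_x + 1) - gammaln(n_y - ks + 1)
        - gammaln(N - n_x - n_y + ks + 1)
        - (gammaln(N + 1) - gammaln(n_y + 1) - gammaln(N - n_y + 1))
    )
    log_tail = float(logsumexp(terms))
    return max(0.0, -log_tail / LN10)


def p1_score(inputs: ScoreInputs) -> float:
    """Common-neighbor count statistic: -ln of the hypergeometric mass at m."""
    return max(
        0.0, -_ln_hypergeom_pmf(inputs.n_x, inputs.n_y, inputs.m, inputs.N)
    )


def p2_score(inputs: ScoreInputs) -> float:
    """Connector-degree statistic over the gene set A, -log10 scale.

    -log10 of the product over connecting genes of
    ``n_i (n_i - 1) / (N (N - 1))``; additive over disjoint gene subsets.
    """
    if not inputs.gene_degrees:
        raise ValueError("p2 requires the connecting genes' degrees")
    N = float(inputs.N)
    total = 0.0
    for n_i in inputs.gene_degrees:
        total += math.log10(N * (N - 1.0)) - math.log10(n_i * (n_i - 1.0))
    return total


def opinion_pool(p1: float, p2: float, weights: PoolWeights) -> float:
    """Logarithmic opinion pool with k = 1: a weighted sum on the log scale."""
    if p1 < 0 or p2 < 0:
        raise ValueError("pooled statistics must be non-negative")
    return weights.w1 * p1 + weights.w2 * p2


def s_score(p1: float, p2: float) -> float:
    """Equal-weight pool S_XYA = (p1 + p2) / 2."""
    return opinion_pool(p1, p2, PoolWeights.equal())


def w_score(p1: float, p2: float, m: int) -> float:
    """m-weighted pool W_XYA = w1(m) p1 + w2(m) p2."""
    return opinion_pool(p1, p2, PoolWeights.m_weighted(m))


def bonferroni_correct(score: float, n_tests: int) -> float:
    """Bonferroni correction on the -log10 scale.

    Multiplying the probability by the number of tests (capped at 1)
    subtracts log10(n_tests) from the score, floored at zero.
    """
    if score < 0:
        raise ValueError("score must be non-negative")
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    return max(0.0, score - math.log10(n_tests))


def geometric_mean_degree(degrees: Sequence[float]) -> float:
    """exp(mean(log(degrees))); degrees must be positive."""
    if len(degrees) == 0:
        raise ValueError("empty degree list")
    if any(d < 1 for d in degrees):
        raise ValueError("degrees must be >= 1 for a geometric mean")
    return float(np.exp(np.mean(np.log(np.asarray(degrees, dtype=float)))))


def score_inputs_for(
    net: TripartiteNetwork, inf: Inference, n_override: Optional[int] = None
) -> ScoreInputs:
    """Assemble ScoreInputs from network degrees and N for one inference."""
    connector_kind = GENE if inf.source.kind == CHEMICAL else CHEMICAL
    return ScoreInputs(
        n_x=net.degree(inf.source),
        n_y=net.degree(inf.disease),
        m=inf.m,
        N=int(n_override) if n_override else net.N,
        gene_degrees=tuple(
            net.degree(NodeRef(connector_kind, g)) for g in inf.connectors
        ),
    )


def score_inference(
    net: TripartiteNetwork,
    inf: Inference,
    n_override: Optional[int] = None,
    n_tests: int = 1,
) -> ScoreVector:
    """Evaluate all five statistics for one inference.

    ``n_tests`` is the size of the inference family being scored in this
    run; the Bonferroni-corrected W uses it directly.
    """
    try:
        inputs = score_inputs_for(net, inf, n_override)
        p1 = p1_score(inputs)
        p2 = p2_score(inputs)
        w = w_score(p1, p2, inputs.m)
        return ScoreVector(
            c_xy=c_xy(inputs),
            p1=p1,
            p2=p2,
            s_xya=s_score(p1, p2),
            w_xya=w,
            w_bonferroni=bonferroni_correct(w, n_tests),
        )
    except (ValueError, KeyError) as exc:
        raise type(exc)(
            f"scoring {inf.source.id} - {inf.disease.id}: {exc}"
        ) from exc


def score_table(
    net: TripartiteNetwork,
    inferences: Sequence[Inference],
    n_override: Optional[int] = None,
    n_tests_override: Optional[int] = None,
) -> pd.DataFrame:
    """Score a family of inferences into the standard score table.

    Vectorized across the family (one flattened hypergeometric-tail pass
    for C_xy); each row equals a direct :func:`score_inference` call.
    Bonferroni correction defaults to the family size — the number of
    inferences scored in this run.
    """
    if not inferences:
        return pd.DataFrame(columns=list(SCORE_COLUMNS))
    n_tests = n_tests_override if n_tests_override else max(1, len(inferences))
    N = int(n_override) if n_override else net.N

    adj = net._build_adjacency()  # noqa: SLF001 - same-package fast path
    deg: dict[tuple[str, str], int] = {}

    def degree_of(kind: str, node_id: str) -> int:
        key = (kind, node_id)
        if key not in deg:
            deg[key] = net.degree(NodeRef(kind, node_id))
        return deg[key]

    n_rows = len(inferences)
    n_x = np.empty(n_rows, dtype=np.int64)
    n_y = np.empty(n_rows, dtype=np.int64)
    m = np.empty(n_rows, dtype=np.int64)
    flat_genes: list[int] = []
    for i, inf in enumerate(inferences):
        connector_kind = GENE if inf.source.kind == CHEMICAL else CHEMICAL
        n_x[i] = degree_of(inf.source.kind, inf.source.id)
        n_y[i] = degree_of(inf.disease.kind, inf.disease.id)
        m[i] = inf.m
        flat_genes.extend(
            degree_of(connector_kind, g) for g in inf.connectors
        )
    gene_deg = np.asarray(flat_genes, dtype=np.float64)

    bad = (m > np.minimum(n_x, n_y)) | (n_x >= N) | (n_y >= N)
    if bad.any() or (gene_deg < 2).any() or (gene_deg >= N).any():
        i = int(np.argmax(bad)) if bad.any() else 0
        inf = inferences[i]
        raise ValueError(
            f"scoring {inf.source.id} - {inf.disease.id}: inputs violate "
            f"the degree invariants (n_x={n_x[i]}, n_y={n_y[i]}, m={m[i]}, N={N})"
        )

    def lC(n, r):
        return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)

    p1 = -(lC(n_x, m) + lC(N - n_x, n_y - m) - lC(N, n_y))
    np.clip(p1, 0.0, None, out=p1)

    # p2: segment sums over the flattened connector-degree list
    offsets = np.zeros(n_rows, dtype=np.int64)
    np.cumsum(m[:-1], out=offsets[1:])
    p2_terms = np.log10(N * (N - 1.0)) - np.log10(gene_deg * (gene_deg - 1.0))
    p2 = np.add.reduceat(p2_terms, offsets)

    # C_xy: flattened ragged tails with segmented log-sum-exp
    lo = np.maximum(m, n_x + n_y - N)
    hi = np.minimum(n_x, n_y)
    lengths = hi - lo + 1
    starts = np.zeros(n_rows, dtype=np.int64)
    np.cumsum(lengths[:-1], out=starts[1:])
    total = int(lengths.sum())
    ks = np.arange(total) - np.repeat(starts, lengths) + np.repeat(lo, lengths)
    nx_r = np.repeat(n_x, lengths)
    ny_r = np.repeat(n_y, lengths)
    terms = (
        lC(nx_r, ks) + lC(N - nx_r, ny_r - ks) - lC(N, ny_r)
    )
    seg_max = np.maximum.reduceat(terms, starts)
    shifted = np.exp(terms - np.repeat(seg_max, lengths))
    log_tail = seg_max + np.log(np.add.reduceat(shifted, starts))
    cxy = np.maximum(0.0, -log_tail / LN10)

    s = 0.5 * p1 + 0.5 * p2
    decay = W_POOL_DECAY ** (-m.astype(np.float64))
    w = (1.0 - W_POOL_ALPHA * decay) * p1 + W_POOL_BETA * decay * p2
    w_bonf = np.maximum(0.0, w - math.log10(n_tests))

    return pd.DataFrame(
        {
            "chemical_id": [inf.source.id for inf in inferences],
            "disease_id": [inf.disease.id for inf in inferences],
            "m": m,
            "curated": [inf.curated for inf in inferences],
            "c_xy": cxy,
            "p1": p1,
            "p2": p2,
            "s_xya": s,
            "w_xya": w,
            "w_bonferroni": w_bonf,
        },
        columns=list(SCORE_COLUMNS),
    )


def write_score_table(df: pd.DataFrame, path, display_precision: bool = False) -> None:
    """Write the score table as TSV; optionally at 2-decimal display precision."""
    out = df.copy()
    if display_precision:
        for col in ("c_xy", "p1", "p2", "s_xya", "w_xya", "w_bonferroni"):
            out[col] = out[col].map(lambda v: f"{v:.2f}")
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")
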