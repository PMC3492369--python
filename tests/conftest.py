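"""Shared fixtures and exact-arithmetic oracles for the test suite."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest

from ctdnet import (
    CHEM_DISEASE,
    CHEM_GENE,
    GENE_DISEASE,
    TripartiteNetwork,
)

LN10 = math.log(10.0)


# -- exact rational oracles (independent of the scipy log-gamma path) -------

def frac_hypergeom_pmf(n_x: int, n_y: int, m: int, N: int) -> Fraction:
    """P[exactly m common neighbors] by exact big-integer arithmetic."""
    if n_y - m > N - n_x or m > min(n_x, n_y):
        return Fraction(0)
    return Fraction(
        math.comb(n_x, m) * math.comb(N - n_x, n_y - m), math.comb(N, n_y)
    )


def frac_hypergeom_tail(n_x: int, n_y: int, m: int, N: int) -> Fraction:
    total = Fraction(0)
    for i in range(m, min(n_x, n_y) + 1):
        total += frac_hypergeom_pmf(n_x, n_y, i, N)
    return total


def log10_fraction(frac: Fraction) -> float:
    return (math.log(frac.numerator) - math.log(frac.denominator)) / LN10


def ln_fraction(frac: Fraction) -> float:
    return math.log(frac.numerator) - math.log(frac.denominator)


def oracle_c_xy(n_x: int, n_y: int, m: int, N: int) -> float:
    return -log10_fraction(frac_hypergeom_tail(n_x, n_y, m, N))


def oracle_p1(n_x: int, n_y: int, m: int, N: int) -> float:
    return -ln_fraction(frac_hypergeom_pmf(n_x, n_y, m, N))


def oracle_p2(gene_degrees, N: int) -> float:
    total = 0.0
    for n_i in gene_degrees:
        total += log10_fraction(Fraction(N * (N - 1), n_i * (n_i - 1)))
    return total


def random_sparse_inputs(rng: np.random.Generator) -> tuple[int, int, int, int]:
    """(n_x, n_y, m, N) in the sparse regime typical of curated networks.

    Endpoint degrees are small relative to N, so the expected overlap
    n_x n_y / N stays below one and larger observed overlaps are rarer.
    """
    N = int(rng.integers(300, 40_000))
    cap = max(3, int(0.7 * math.sqrt(N)))
    n_x = int(rng.integers(2, cap + 1))
    n_y = int(rng.integers(2, cap + 1))
    m = int(rng.integers(1, min(n_x, n_y, 8) + 1))
    return n_x, n_y, m, N


# -- shared network fixtures -------------------------------------------------

@pytest.fixture
def toy_net() -> TripartiteNetwork:
    """The 4-node worked network: X-g1, X-g2, g1-Y, g2-Y."""
    net = TripartiteNetwork()
    net.add_edge(CHEM_GENE, "X", "g1")
    net.add_edge(CHEM_GENE, "X", "g2")
    net.add_edge(GENE_DISEASE, "g1", "Y")
    net.add_edge(GENE_DISEASE, "g2", "Y")
    return net


def random_network(
    n_chem: int = 20,
    n_gene: int = 40,
    n_dis: int = 10,
    p: float = 0.1,
    seed: int = 0,
) -> TripartiteNetwork:
    """Erdos-Renyi-style layered network for brute-force comparisons."""
    rng = np.random.default_rng(seed)
    net = TripartiteNetwork()
    chems = [f"c{i}" for i in range(n_chem)]
    genes = [f"g{i}" for i in range(n_gene)]
    diss = [f"d{i}" for i in range(n_dis)]
    for layer, left, right in (
        (CHEM_GENE, chems, genes),
        (GENE_DISEASE, genes, diss),
        (CHEM_DISEASE, chems, diss),
    ):
        for a in left:
            for b in right:
                if rng.random() < p:
                    net.add_edge(layer, a, b)
    return net
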