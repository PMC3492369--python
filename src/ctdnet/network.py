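"""Tripartite chemical-gene-disease association network.

Chemicals, genes and diseases are nodes; curated associations are binary,
undirected edges confined to three layers: chemical-gene, gene-disease and
chemical-disease.  ``N`` — the count of nodes with at least one edge across
any layer — is the population size for all hypergeometric statistics, and a
node's total degree (edges summed over layers) is its connectivity.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

CHEMICAL = "chemical"
GENE = "gene"
DISEASE = "disease"
KINDS = (CHEMICAL, GENE, DISEASE)

CHEM_GENE = "chem_gene"
GENE_DISEASE = "gene_disease"
CHEM_DISEASE = "chem_disease"
LAYERS = (CHEM_GENE, GENE_DISEASE, CHEM_DISEASE)

#: node kinds at the two ends of each layer, in canonical storage order
LAYER_KINDS: Mapping[str, tuple[str, str]] = {
    CHEM_GENE: (CHEMICAL, GENE),
    GENE_DISEASE: (GENE, DISEASE),
    CHEM_DISEASE: (CHEMICAL, DISEASE),
}


@dataclass(frozen=True, order=True)
class NodeRef:
    """A typed node identifier: ``(kind, id)`` is unique within a network."""

    kind: str
    id: str

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown node kind {self.kind!r}")
        if not self.id:
            raise ValueError("node id must be non-empty")


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares line on log10(degree) vs log10(frequency)."""

    slope: float
    intercept: float
    r_squared: float


class TripartiteNetwork:
    """Binary three-layer association graph.

    Edges are stored per layer as canonical ``(id_a, id_b)`` pairs following
    :data:`LAYER_KINDS` order; duplicates within a layer are impossible by
    construction.  Nodes may be declared without edges (isolated); they do
    not count toward ``N``.
    """

    def __init__(self) -> None:
        self.nodes: dict[str, set[str]] = {k: set() for k in KINDS}
        self.edges: dict[str, set[tuple[str, str]]] = {l: set() for l in LAYERS}
        self.metadata: dict = {}
        self._adjacency: Optional[dict[str, dict[str, set[str]]]] = None

    # -- construction -------------------------------------------------------

    def add_node(self, kind: str, node_id: str) -> None:
        if kind not in KINDS:
            raise ValueError(f"unknown node kind {kind!r}")
        for other in KINDS:
            if other != kind and node_id in self.nodes[other]:
                raise ValueError(
                    f"identifier collision: {node_id!r} already declared as {other}"
                )
        self.nodes[kind].add(node_id)
        self._adjacency = None

    def add_edge(self, layer: str, id_a: str, id_b: str) -> bool:
        """Add one binary edge; returns False if it already existed."""
        if layer not in LAYERS:
            raise ValueError(f"unknown layer {layer!r}")
        kind_a, kind_b = LAYER_KINDS[layer]
        self.add_node(kind_a, id_a)
        self.add_node(kind_b, id_b)
        pair = (id_a, id_b)
        if pair in self.edges[layer]:
            return False
        self.edges[layer].add(pair)
        self._adjacency = None
        return True

    def remove_edge(self, layer: str, id_a: str, id_b: str) -> None:
        self.edges[layer].remove((id_a, id_b))
        self._adjacency = None

    def copy(self) -> "TripartiteNetwork":
        dup = TripartiteNetwork()
        dup.nodes = {k: set(v) for k, v in self.nodes.items()}
        dup.edges = {l: set(e) for l, e in self.edges.items()}
        dup.metadata = dict(self.metadata)
        return dup

    # -- queries ------------------------------------------------------------

    def _build_adjacency(self) -> dict[str, dict[str, set[str]]]:
        if self._adjacency is None:
            adj: dict[str, dict[str, set[str]]] = {l: {} for l in LAYERS}
            for layer, pairs in self.edges.items():
                index = adj[layer]
                for a, b in pairs:
                    index.setdefault(a, set()).add(b)
                    index.setdefault(b, set()).add(a)
            self._adjacency = adj
        return self._adjacency

    def neighbors(self, layer: str, node_id: str) -> set[str]:
        return self._build_adjacency()[layer].get(node_id, set())

    def has_node(self, kind: str, node_id: str) -> bool:
        return node_id in self.nodes[kind]

    def degree(self, node: NodeRef, layer_filter: Optional[str] = None) -> int:
        """Total degree of ``node`` across all layers (or within one layer).

        A chemical accrues degree from both the chemical-gene and the
        chemical-disease layers; this pooled count is what the scoring
        statistics use.
        """
        if not self.has_node(node.kind, node.id):
            raise KeyError(f"unknown node {node.kind}:{node.id}")
        layers = LAYERS if layer_filter is None else (layer_filter,)
        total = 0
        adj = self._build_adjacency()
        for layer in layers:
            if layer not in LAYERS:
                raise ValueError(f"unknown layer {layer!r}")
            if node.kind in LAYER_KINDS[layer]:
                total += len(adj[layer].get(node.id, ()))
        return total

    @property
    def degree_index(self) -> dict[NodeRef, int]:
        adj = self._build_adjacency()
        index: dict[NodeRef, int] = {}
        for kind in KINDS:
            for node_id in self.nodes[kind]:
                d = 0
                for layer in LAYERS:
                    if kind in LAYER_KINDS[layer]:
                        d += len(adj[layer].get(node_id, ())) if node_id in adj[layer] else 0
                index[NodeRef(kind, node_id)] = d
        return index

    @property
    def n_edges(self) -> int:
        return sum(len(e) for e in self.edges.values())

    @property
    def N(self) -> int:
        """Number of nodes with at least one edge in any layer."""
        adj = self._build_adjacency()
        connected: set[tuple[str, str]] = set()
        for layer in LAYERS:
            kind_a, kind_b = LAYER_KINDS[layer]
            for a, b in self.edges[layer]:
                connected.add((kind_a, a))
                connected.add((kind_b, b))
        return len(connected)

    def iter_nodes(self) -> Iterator[NodeRef]:
        for kind in KINDS:
            for node_id in sorted(self.nodes[kind]):
                yield NodeRef(kind, node_id)


# -- delimited-file I/O -----------------------------------------------------

PAIRS = "pairs"
CTD_EXPORT = "ctd_export"

#: default column names for the ctd_export dialect, overridable per call
DEFAULT_EXPORT_COLUMNS: Mapping[str, tuple[str, str]] = {
    CHEM_GENE: ("ChemicalID", "GeneSymbol"),
    GENE_DISEASE: ("GeneSymbol", "DiseaseID"),
    CHEM_DISEASE: ("ChemicalID", "DiseaseID"),
}


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def _iter_pairs(
    path: Path, dialect: str, columns: Optional[tuple[str, str]]
) -> Iterator[tuple[int, str, str]]:
    """Yield (line number, id_a, id_b) after dialect-specific mapping."""
    with _open_text(path) as handle:
        header: Optional[list[str]] = None
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == PAIRS:
                if len(fields) < 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected two tab-separated columns, "
                        f"got {len(fields)}"
                    )
                a, b = fields[0].strip(), fields[1].strip()
            elif dialect == CTD_EXPORT:
                if header is None:
                    header = [f.strip() for f in fields]
                    missing = [c for c in columns if c not in header]
                    if missing:
                        raise ValueError(
                            f"{path}:{lineno}: header lacks column(s) {missing}"
                        )
                    continue
                if len(fields) < len(header):
                    raise ValueError(
                        f"{path}:{lineno}: row has {len(fields)} fields, "
                        f"header has {len(header)}"
                    )
                row = dict(zip(header, fields))
                a = row[columns[0]].strip()
                b = row[columns[1]].strip()
            else:
                raise ValueError(f"unknown dialect {dialect!r}")
            if not a or not b:
                raise ValueError(f"{path}:{lineno}: empty identifier")
            yield lineno, a, b


def load_network(
    chem_gene_path,
    gene_disease_path,
    chem_disease_path,
    dialect: str = PAIRS,
    export_columns: Optional[Mapping[str, tuple[str, str]]] = None,
) -> TripartiteNetwork:
    """Load a network from three delimited association tables.

    ``pairs`` dialect: two tab-separated id columns, ``#`` comments ignored.
    ``ctd_export`` dialect: tab-separated with a header row; the id columns
    per layer come from ``export_columns`` (defaults cover a typical export).
    Duplicate pairs collapse to one binary edge; identifiers are
    whitespace-trimmed and case-sensitive.
    """
    columns = dict(DEFAULT_EXPORT_COLUMNS)
    if export_columns:
        columns.update(export_columns)
    net = TripartiteNetwork()
    paths = {
        CHEM_GENE: Path(chem_gene_path),
        GENE_DISEASE: Path(gene_disease_path),
        CHEM_DISEASE: Path(chem_disease_path),
    }
    for layer, path in paths.items():
        if not path.exists():
            raise FileNotFoundError(f"association table not found: {path}")
        n_rows = 0
        n_unique = 0
        for _lineno, a, b in _iter_pairs(path, dialect, columns.get(layer)):
            n_rows += 1
            if net.add_edge(layer, a, b):
                n_unique += 1
        logger.info(
            "%s: %d rows, %d unique pairs after dedup (%s)",
            layer, n_rows, n_unique, path,
        )
    return net


def save_network(net: TripartiteNetwork, out_dir) -> dict:
    """Write three TSV layer files plus a small JSON header; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    for layer in LAYERS:
        path = out / f"{layer}.tsv"
        with open(path, "w", encoding="utf-8", newline="\n") as handle:
            handle.write(f"# {LAYER_KINDS[layer][0]}\t{LAYER_KINDS[layer][1]}\n")
            for a, b in sorted(net.edges[layer]):
                handle.write(f"{a}\t{b}\n")
        written[layer] = str(path)
    header = {
        "dialect": PAIRS,
        "N": net.N,
        "edge_counts": {l: len(net.edges[l]) for l in LAYERS},
        "node_counts": {k: len(net.nodes[k]) for k in KINDS},
    }
    header_path = out / "network.json"
    with open(header_path, "w", encoding="utf-8", newline="\n") as handle:
        json.dump(header, handle, indent=1, sort_keys=True)
        handle.write("\n")
    written["header"] = str(header_path)
    return written


def degree_distribution(net: TripartiteNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Unit-width degree histogram over connected nodes: (degrees, counts)."""
    degs = np.array([d for d in net.degree_index.values() if d > 0], dtype=int)
    if degs.size == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    values, counts = np.unique(degs, return_counts=True)
    return values, counts


def fit_powerlaw_slope(net: TripartiteNetwork) -> PowerLawFit:
    """Fit a line to log10(frequency) vs log10(degree).

    Degrees with zero frequency are dropped before the log transform, as in
    a straight-line fit to a log-log degree histogram.  Requires at least
    three distinct observed degree values.
    """
    values, counts = degree_distribution(net)
    return fit_powerlaw_points(values, counts)


def fit_powerlaw_points(degrees, frequencies) -> PowerLawFit:
    """Least-squares log-log line through (degree, frequency) points."""
    values = np.asarray(degrees, dtype=float)
    counts = np.asarray(frequencies, dtype=float)
    keep = counts > 0
    values, counts = values[keep], counts[keep]
    if values.size < 3:
        raise ValueError(
            f"degenerate degree distribution: {values.size} distinct degree value(s), "
            "need at least 3"
        )
    x = np.log10(values)
    y = np.log10(counts)
    slope, intercept = np.polyfit(x, y, 1)
    y_hat = slope * x + intercept
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return PowerLawFit(float(slope), float(intercept), float(r_squared))
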