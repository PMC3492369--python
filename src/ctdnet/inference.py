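"""Enumeration of transitive inferences in the tripartite network.

A chemical-disease inference exists when one or more genes carry a curated
edge to both the chemical and the disease; the shared genes form the
connector set ``A`` of size ``m``.  The symmetric gene-disease mode uses
chemicals as connectors.  An inference whose endpoint pair also has a
direct curated edge is flagged ``curated`` — it is still enumerated and
scored; curation is a flag, never a filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

from .network import (
    CHEM_DISEASE,
    CHEM_GENE,
    CHEMICAL,
    DISEASE,
    GENE,
    GENE_DISEASE,
    NodeRef,
    TripartiteNetwork,
)

CHEM_DISEASE_MODE = "chem_disease"
GENE_DISEASE_MODE = "gene_disease"


@dataclass(frozen=True)
class Inference:
    """A transitive (source, disease) pair with its connector set.

    ``source`` is a chemical in chem_disease mode and a gene in gene_disease
    mode; ``connectors`` are the shared neighbors (genes, respectively
    chemicals), sorted for determinism.
    """

    source: NodeRef
    disease: NodeRef
    connectors: tuple[str, ...]
    curated: bool

    def __post_init__(self) -> None:
        if not self.connectors:
            raise ValueError("inference requires a non-empty connector set")

    @property
    def m(self) -> int:
        return len(self.connectors)


def enumerate_cd_inferences(
    net: TripartiteNetwork, mode: str = CHEM_DISEASE_MODE
) -> list[Inference]:
    """Enumerate all transitive inferences, sorted by (source id, disease id).

    Works one source node at a time, so the peak cost per step is bounded by
    a single node's two-hop neighborhood rather than the full cross product
    of sources and diseases.
    """
    return list(iter_cd_inferences(net, mode))


def iter_cd_inferences(
    net: TripartiteNetwork, mode: str = CHEM_DISEASE_MODE
) -> Iterator[Inference]:
    if mode == CHEM_DISEASE_MODE:
        source_kind, first_layer, second_layer, direct_layer = (
            CHEMICAL, CHEM_GENE, GENE_DISEASE, CHEM_DISEASE,
        )
    elif mode == GENE_DISEASE_MODE:
        source_kind, first_layer, second_layer, direct_layer = (
            GENE, CHEM_GENE, CHEM_DISEASE, GENE_DISEASE,
        )
    else:
        raise ValueError(f"unknown inference mode {mode!r}")

    for source_id in sorted(net.nodes[source_kind]):
        connectors = net.neighbors(first_layer, source_id)
        if not connectors:
            continue
        by_disease: dict[str, list[str]] = {}
        for conn in connectors:
            for disease_id in net.neighbors(second_layer, conn):
                by_disease.setdefault(disease_id, []).append(conn)
        for disease_id in sorted(by_disease):
            direct = net.neighbors(direct_layer, source_id)
            yield Inference(
                source=NodeRef(source_kind, source_id),
                disease=NodeRef(DISEASE, disease_id),
                connectors=tuple(sorted(by_disease[disease_id])),
                curated=disease_id in direct,
            )


def classify_counts(inferences: Iterable[Inference]) -> dict:
    """Tally total/curated/novel inference counts, plus counts per source."""
    n_total = 0
    n_curated = 0
    per_source: dict[str, int] = {}
    for inf in inferences:
        n_total += 1
        if inf.curated:
            n_curated += 1
        per_source[inf.source.id] = per_source.get(inf.source.id, 0) + 1
    return {
        "n_total": n_total,
        "n_curated": n_curated,
        "n_novel": n_total - n_curated,
        "per_chemical": per_source,
    }


def write_inferences(inferences: Iterable[Inference], path) -> None:
    """Serialize to TSV: source, disease, m, curated, semicolon-joined connectors."""
    with open(Path(path), "w", encoding="utf-8", newline="\n") as handle:
        handle.write("chemical_id\tdisease_id\tm\tcurated\tgenes\n")
        for inf in inferences:
            handle.write(
                f"{inf.source.id}\t{inf.disease.id}\t{inf.m}\t"
                f"{str(inf.curated).lower()}\t{';'.join(inf.connectors)}\n"
            )
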