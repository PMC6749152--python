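"""Disease-specific subnetwork extraction and risk-circRNA prioritization.

A crosstalk triple belongs to the disease subnetwork when its mRNA is a
consistently differentially expressed gene (CDEG) or its miRNA is
differentially expressed (DEmiR). Within that subnetwork a triple is a
*risk* crosstalk when it contains a curated known disease gene or miRNA.
circRNAs are ranked by how many risk crosstalks they occur in.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field

import pandas as pd

from circenet.network import CeRNATriple, TripartiteNetwork, network_from_triples


@dataclass(frozen=True)
class DiseaseAnnotation:
    """Differential-expression calls plus curated disease id lists."""

    cdeg_set: frozenset[str] = field(default_factory=frozenset)
    demir_set: frozenset[str] = field(default_factory=frozenset)
    known_genes: frozenset[str] = field(default_factory=frozenset)
    known_mirs: frozenset[str] = field(default_factory=frozenset)

    @classmethod
    def build(cls, cdegs=(), demirs=(), known_genes=(), known_mirs=()):
        return cls(
            frozenset(cdegs), frozenset(demirs),
            frozenset(known_genes), frozenset(known_mirs),
        )


def extract_disease_network(
    triples: list[CeRNATriple], annotation: DiseaseAnnotation
) -> tuple[TripartiteNetwork, list[CeRNATriple]]:
    """Keep triples whose mRNA is a CDEG or whose miRNA is a DEmiR.

    The subnetwork is rebuilt from the retained triples' edges, so the
    edge-triple closure of the full network is preserved.
    """
    retained = [
        t
        for t in triples
        if t.mrna_id in annotation.cdeg_set or t.mirna_id in annotation.demir_set
    ]
    return network_from_triples(retained), retained


def flag_risk_triples(
    disease_triples: list[CeRNATriple], annotation: DiseaseAnnotation
) -> list[CeRNATriple]:
    """Risk crosstalks: triples containing a known disease gene or miRNA."""
    return [
        t
        for t in disease_triples
        if t.mrna_id in annotation.known_genes or t.mirna_id in annotation.known_mirs
    ]


def rank_circrnas(
    risk_triples: list[CeRNATriple],
    disease_triples: list[CeRNATriple] | None = None,
) -> pd.DataFrame:
    """Rank circRNAs by descending risk-crosstalk count.

    Ties are broken by ascending circRNA id so runs are reproducible. When
    the full disease triple list is supplied, a normalized ``coverage``
    column (risk / total crosstalks per circRNA) is added as an auxiliary
    view; the rank itself always uses the raw count.
    """
    counts: dict[str, int] = {}
    for t in risk_triples:
        counts[t.circ_id] = counts.get(t.circ_id, 0) + 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    df = pd.DataFrame(rows, columns=["circ_id", "risk_triple_count"])
    df["rank"] = range(1, len(df) + 1)
    if disease_triples is not None:
        totals: dict[str, int] = {}
        for t in disease_triples:
            totals[t.circ_id] = totals.get(t.circ_id, 0) + 1
        df["total_triple_count"] = df["circ_id"].map(totals)
        df["coverage"] = df["risk_triple_count"] / df["total_triple_count"]
    return df.set_index("circ_id")


def circ_neighborhood(
    circ_id: str,
    disease_triples: list[CeRNATriple],
    annotation: DiseaseAnnotation | None = None,
) -> tuple[TripartiteNetwork, pd.DataFrame]:
    """Subnetwork induced by one circRNA's crosstalks, plus a partner table.

    The summary lists each mediating miRNA and mRNA partner with flags for
    differential expression and curated disease membership.
    """
    mine = [t for t in disease_triples if t.circ_id == circ_id]
    if not mine:
        known_ids = sorted({t.circ_id for t in disease_triples})
        near = difflib.get_close_matches(circ_id, known_ids, n=3)
        raise KeyError(f"circRNA {circ_id!r} not found; close matches: {near}")
    net = network_from_triples(mine)
    ann = annotation or DiseaseAnnotation()
    rows = []
    for m in sorted(net.mirna_nodes):
        rows.append(
            {
                "partner_id": m,
                "role": "miRNA",
                "n_triples": sum(1 for t in mine if t.mirna_id == m),
                "is_de": m in ann.demir_set,
                "is_known_disease": m in ann.known_mirs,
            }
        )
    for g in sorted(net.mrna_nodes):
        rows.append(
            {
                "partner_id": g,
                "role": "mRNA",
                "n_triples": sum(1 for t in mine if t.mrna_id == g),
                "is_de": g in ann.cdeg_set,
                "is_known_disease": g in ann.known_genes,
            }
        )
    return net, pd.DataFrame(rows)
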