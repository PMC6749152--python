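"""Readers and writers for every on-disk format the pipeline touches.

All formats are plain text: expression and annotation TSV, interaction
TSV, id-list text files, GMT gene sets, triples TSV, GraphML networks and
a ground-truth JSON. Every writer has a matching reader that reconstructs
an equal in-memory object (round-trip property, covered by tests).
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from circenet.diffexpr import ExpressionDataset
from circenet.enrichment import GeneSetCollection
from circenet.network import (
    CIRC,
    MRNA,
    CeRNATriple,
    InteractionSet,
    TripartiteNetwork,
)
from circenet.simulate import GroundTruth


# expression ---------------------------------------------------------------

def write_expression(dataset: ExpressionDataset, values_path, annot_path) -> None:
    df = dataset.values.copy()
    df.index.name = "feature_id"
    df.to_csv(values_path, sep="\t")
    annot = pd.DataFrame(
        {
            "sample_id": dataset.values.columns,
            "condition": dataset.conditions.loc[dataset.values.columns].to_numpy(),
            "dataset": dataset.tag,
        }
    )
    annot.to_csv(annot_path, sep="\t", index=False)


def read_expression(values_path, annot_path) -> ExpressionDataset:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    values.index.name = None
    annot = pd.read_csv(annot_path, sep="\t", dtype=str)
    tags = annot["dataset"].unique()
    if len(tags) != 1:
        raise ValueError(f"annotation file mixes datasets: {list(tags)}")
    conditions = pd.Series(
        annot["condition"].to_numpy(), index=annot["sample_id"], name="condition"
    )
    return ExpressionDataset(values=values, conditions=conditions, tag=str(tags[0]))


# interactions -------------------------------------------------------------

_INTERACTION_COLS = ["miRNA", "target", "target_class"]


def write_interactions(interactions: InteractionSet, path) -> None:
    rows = sorted(interactions.edges)
    pd.DataFrame(rows, columns=_INTERACTION_COLS).to_csv(path, sep="\t", index=False)


def load_interactions(path) -> InteractionSet:
    """Read a miRNA-target TSV, deduplicating rows (duplicates logged)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _INTERACTION_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"interaction file {path} lacks columns {missing}")
    records = list(df.itertuples(index=False, name=None))
    return InteractionSet.from_records(records)


# id lists -----------------------------------------------------------------

def write_id_list(ids, path) -> None:
    Path(path).write_text("".join(f"{i}\n" for i in sorted(ids)))


def read_id_list(path) -> set[str]:
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}


# gene sets (GMT) ----------------------------------------------------------

def write_gmt(collection: GeneSetCollection, path) -> None:
    lines = []
    for term in sorted(collection.sets):
        desc = collection.descriptions.get(term, "")
        genes = "\t".join(sorted(collection.sets[term]))
        lines.append(f"{term}\t{desc}\t{genes}\n")
    Path(path).write_text("".join(lines))


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line {lineno} has fewer than 3 fields")
        term, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
        if term in sets:
            raise ValueError(f"duplicate GMT term {term!r} at line {lineno}")
        sets[term] = frozenset(genes)
        descriptions[term] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


# triples ------------------------------------------------------------------

_TRIPLE_COLS = ["circ_id", "mirna_id", "mrna_id", "shared_count"]


def write_triples(triples: list[CeRNATriple], path) -> None:
    df = pd.DataFrame(sorted(triples, key=lambda t: t.key), columns=_TRIPLE_COLS)
    df.to_csv(path, sep="\t", index=False)


def read_triples(path) -> list[CeRNATriple]:
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in _TRIPLE_COLS[:3]})
    missing = [c for c in _TRIPLE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"triples file {path} lacks columns {missing}")
    return [
        CeRNATriple(r.circ_id, r.mirna_id, r.mrna_id, int(r.shared_count))
        for r in df.itertuples(index=False)
    ]


# networks -----------------------------------------------------------------

def network_to_graphml(network: TripartiteNetwork, path) -> None:
    g = nx.Graph()
    for node in sorted(network.circ_nodes):
        g.add_node(node, node_type=CIRC)
    for node in sorted(network.mirna_nodes):
        g.add_node(node, node_type="miRNA")
    for node in sorted(network.mrna_nodes):
        g.add_node(node, node_type=MRNA)
    for mir, target, cls in sorted(network.edges):
        g.add_edge(mir, target, edge_type=f"miRNA-{cls}")
    nx.write_graphml(g, path)


def network_from_graphml(path) -> TripartiteNetwork:
    g = nx.read_graphml(path)
    pools = {CIRC: set(), "miRNA": set(), MRNA: set()}
    for node, data in g.nodes(data=True):
        ntype = data.get("node_type")
        if ntype not in pools:
            raise ValueError(f"node {node!r} has unknown node_type {ntype!r}")
        pools[ntype].add(node)
    edges = set()
    for u, v in g.edges():
        mir, target = (u, v) if u in pools["miRNA"] else (v, u)
        cls = CIRC if target in pools[CIRC] else MRNA
        edges.add((mir, target, cls))
    return TripartiteNetwork(
        frozenset(pools[CIRC]),
        frozenset(pools["miRNA"]),
        frozenset(pools[MRNA]),
        frozenset(edges),
    )


def write_edge_list(network: TripartiteNetwork, path) -> None:
    rows = sorted(network.edges)
    pd.DataFrame(rows, columns=["miRNA", "target", "target_class"]).to_csv(
        path, sep="\t", index=False
    )


# ground truth -------------------------------------------------------------

def write_truth(truth: GroundTruth, path) -> None:
    payload = {
        "de_features": sorted(truth.de_features),
        "de_mirs": sorted(truth.de_mirs),
        "planted_pairs": [list(p) for p in truth.planted_pairs],
        "planted_triples": sorted(list(t) for t in truth.planted_triples),
        "planted_risk_circ": truth.planted_risk_circ,
        "known_genes": sorted(truth.known_genes),
        "known_mirs": sorted(truth.known_mirs),
        "enriched_term": truth.enriched_term,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        de_features=set(payload["de_features"]),
        de_mirs=set(payload["de_mirs"]),
        planted_pairs=[tuple(p) for p in payload["planted_pairs"]],
        planted_triples={tuple(t) for t in payload["planted_triples"]},
        planted_risk_circ=payload["planted_risk_circ"],
        known_genes=set(payload["known_genes"]),
        known_mirs=set(payload["known_mirs"]),
        enriched_term=payload["enriched_term"],
    )
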