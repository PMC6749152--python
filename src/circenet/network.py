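"""Tripartite ceRNA network construction via the shared-miRNA rule.

A circRNA and an mRNA are candidate competing endogenous RNAs when they are
targeted by at least ``min_shared`` common miRNAs (default 5). Every
(circRNA, miRNA, mRNA) combination where the pair qualifies and the miRNA
lies in the shared set is one unit of miRNA-mediated ceRNA crosstalk; the
network keeps exactly the interaction edges that participate in at least
one such triple.
"""

from __future__ import annotations

import difflib
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

logger = logging.getLogger(__name__)

CIRC = "circRNA"
MRNA = "mRNA"
VALID_CLASSES = frozenset({CIRC, MRNA})


class CeRNATriple(NamedTuple):
    """One miRNA-mediated circRNA-mRNA crosstalk."""

    circ_id: str
    mirna_id: str
    mrna_id: str
    shared_count: int

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.circ_id, self.mirna_id, self.mrna_id)


def triple_keys(triples: Iterable[CeRNATriple]) -> set[tuple[str, str, str]]:
    """Identity of a triple set, ignoring the shared_count annotation."""
    return {t.key for t in triples}


@dataclass(frozen=True)
class InteractionSet:
    """Deduplicated miRNA->target edges typed by target class."""

    edges: frozenset[tuple[str, str, str]]

    def __post_init__(self) -> None:
        classes: dict[str, str] = {}
        pairs: set[tuple[str, str]] = set()
        for mir, target, cls in self.edges:
            if cls not in VALID_CLASSES:
                raise ValueError(f"unknown target class {cls!r} for edge ({mir}, {target})")
            if classes.setdefault(target, cls) != cls:
                raise ValueError(f"target {target!r} appears with two classes")
            if (mir, target) in pairs:
                raise ValueError(f"duplicate (miRNA, target) pair ({mir}, {target})")
            pairs.add((mir, target))

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, str]]
    ) -> "InteractionSet":
        """Build from possibly duplicated rows; duplicates are logged."""
        seen: dict[tuple[str, str], str] = {}
        dup = 0
        for mir, target, klass in records:
            if klass not in VALID_CLASSES:
                raise ValueError(
                    f"unknown target class {klass!r} in row ({mir}, {target}, {klass})"
                )
            key = (mir, target)
            if key in seen:
                if seen[key] != klass:
                    raise ValueError(f"target {target!r} appears with two classes")
                dup += 1
            else:
                seen[key] = klass
        if dup:
            logger.info("dropped %d duplicate interaction rows", dup)
        if not seen:
            logger.warning("interaction set is empty")
        return cls(frozenset((m, t, k) for (m, t), k in seen.items()))

    def mirna_index(self) -> dict[str, tuple[list[str], list[str]]]:
        """miRNA -> (sorted circRNA targets, sorted mRNA targets)."""
        circ: dict[str, list[str]] = defaultdict(list)
        mrna: dict[str, list[str]] = defaultdict(list)
        for mir, target, cls in self.edges:
            (circ if cls == CIRC else mrna)[mir].append(target)
        out: dict[str, tuple[list[str], list[str]]] = {}
        for mir in set(circ) | set(mrna):
            out[mir] = (sorted(circ.get(mir, [])), sorted(mrna.get(mir, [])))
        return out

    def __len__(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class TripartiteNetwork:
    """Node sets of the three RNA classes plus typed miRNA-target edges."""

    circ_nodes: frozenset[str]
    mirna_nodes: frozenset[str]
    mrna_nodes: frozenset[str]
    edges: frozenset[tuple[str, str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for mir, target, cls in self.edges:
            if mir not in self.mirna_nodes:
                raise ValueError(f"edge miRNA {mir!r} missing from miRNA nodes")
            pool = self.circ_nodes if cls == CIRC else self.mrna_nodes
            if target not in pool:
                raise ValueError(f"edge target {target!r} missing from {cls} nodes")

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, str]]) -> "TripartiteNetwork":
        edges = frozenset(edges)
        mirs = frozenset(m for m, _, _ in edges)
        circs = frozenset(t for _, t, c in edges if c == CIRC)
        mrnas = frozenset(t for _, t, c in edges if c == MRNA)
        return cls(circs, mirs, mrnas, edges)

    @property
    def n_nodes(self) -> int:
        return len(self.circ_nodes) + len(self.mirna_nodes) + len(self.mrna_nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_class(self, node: str) -> str:
        if node in self.circ_nodes:
            return CIRC
        if node in self.mirna_nodes:
            return "miRNA"
        if node in self.mrna_nodes:
            return MRNA
        near = difflib.get_close_matches(node, self.all_nodes(), n=3)
        raise KeyError(f"node {node!r} not in network; close matches: {near}")

    def all_nodes(self) -> list[str]:
        return sorted(self.circ_nodes | self.mirna_nodes | self.mrna_nodes)

    def summary(self) -> dict:
        return {
            "n_circ": len(self.circ_nodes),
            "n_mirna": len(self.mirna_nodes),
            "n_mrna": len(self.mrna_nodes),
            "n_nodes": self.n_nodes,
            "n_edges_mirna_circ": sum(1 for e in self.edges if e[2] == CIRC),
            "n_edges_mirna_mrna": sum(1 for e in self.edges if e[2] == MRNA),
            "n_edges": self.n_edges,
        }


def _shared_mirna_sets(
    interactions: InteractionSet,
) -> dict[tuple[str, str], list[str]]:
    """(circ, mrna) -> sorted miRNAs targeting both, via an inverted index.

    Accumulates per-miRNA target-list cross products rather than scanning
    all circRNA x mRNA pairs, so pairs with empty intersections never cost
    anything.
    """
    shared: dict[tuple[str, str], list[str]] = defaultdict(list)
    index = interactions.mirna_index()
    for mir in sorted(index):
        circs, mrnas = index[mir]
        for c in circs:
            for g in mrnas:
                shared[(c, g)].append(mir)
    return dict(shared)


def shared_mirna_counts(interactions: InteractionSet) -> dict[tuple[str, str], int]:
    """Number of shared miRNA regulators for every co-targeted pair.

    Pairs with zero shared miRNAs are absent from the result.
    """
    return {pair: len(mirs) for pair, mirs in _shared_mirna_sets(interactions).items()}


def build_circenet(
    interactions: InteractionSet, min_shared: int = 5
) -> tuple[TripartiteNetwork, list[CeRNATriple]]:
    """Assemble the competitive network from raw interactions.

    Retains circRNA-mRNA pairs sharing at least ``min_shared`` miRNAs,
    enumerates one triple per mediating miRNA of each qualifying pair, and
    keeps exactly the edges participating in at least one triple. Triples
    are returned sorted by (circ, miRNA, mRNA).
    """
    if min_shared < 1:
        raise ValueError(f"min_shared must be >= 1, got {min_shared}")
    shared = _shared_mirna_sets(interactions)
    triples: list[CeRNATriple] = []
    edges: set[tuple[str, str, str]] = set()
    for (c, g) in sorted(shared):
        mirs = shared[(c, g)]
        if len(mirs) < min_shared:
            continue
        for m in mirs:
            triples.append(CeRNATriple(c, m, g, len(mirs)))
            edges.add((m, c, CIRC))
            edges.add((m, g, MRNA))
    triples.sort(key=lambda t: t.key)
    return TripartiteNetwork.from_edges(edges), triples


def network_from_triples(triples: Iterable[CeRNATriple]) -> TripartiteNetwork:
    """Rebuild the edge-filtered network implied by a set of triples."""
    edges: set[tuple[str, str, str]] = set()
    for t in triples:
        edges.add((t.mirna_id, t.circ_id, CIRC))
        edges.add((t.mirna_id, t.mrna_id, MRNA))
    return TripartiteNetwork.from_edges(edges)
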