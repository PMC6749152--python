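"""Independent brute-force reference implementations used only by tests.

Deliberately naive (all-pairs scans, exact rational arithmetic) so they
share no code path with the package.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

from circenet.network import CIRC, MRNA, InteractionSet


def targets_by_class(interactions: InteractionSet):
    circ_regs: dict[str, set[str]] = {}
    mrna_regs: dict[str, set[str]] = {}
    for mir, target, cls in interactions.edges:
        pool = circ_regs if cls == CIRC else mrna_regs
        pool.setdefault(target, set()).add(mir)
    return circ_regs, mrna_regs


def brute_shared_counts(interactions: InteractionSet) -> dict[tuple[str, str], int]:
    """All-pairs miRNA-regulator set intersections."""
    circ_regs, mrna_regs = targets_by_class(interactions)
    out = {}
    for c, cm in circ_regs.items():
        for g, gm in mrna_regs.items():
            k = len(cm & gm)
            if k:
                out[(c, g)] = k
    return out


def brute_triples(interactions: InteractionSet, min_shared: int):
    """Exhaustive (circ, miRNA, mRNA) enumeration."""
    circ_regs, mrna_regs = targets_by_class(interactions)
    triples = set()
    for c, cm in circ_regs.items():
        for g, gm in mrna_regs.items():
            shared = cm & gm
            if len(shared) >= min_shared:
                for m in shared:
                    triples.add((c, m, g))
    return triples


def brute_disease_filter(triple_keys, cdegs, demirs):
    return {t for t in triple_keys if t[2] in cdegs or t[1] in demirs}


def brute_risk_filter(triple_keys, known_genes, known_mirs):
    return {t for t in triple_keys if t[2] in known_genes or t[1] in known_mirs}


def brute_hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Exact rational upper tail of the hypergeometric distribution."""
    total = comb(N, n)
    p = Fraction(0)
    for j in range(k, min(K, n) + 1):
        p += Fraction(comb(K, j) * comb(N - K, n - j), total)
    return float(p)


def brute_bh(p_values):
    """Textbook step-up BH from the definition (independent of numpy)."""
    m = len(p_values)
    indexed = sorted(enumerate(p_values), key=lambda kv: kv[1])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        idx, p = indexed[rank - 1]
        running = min(running, p * m / rank)
        adjusted[idx] = running
    return adjusted
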