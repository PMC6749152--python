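"""Hypergeometric over-representation analysis (ORA) with BH correction.

For a query gene list of size n drawn from a universe of size N, a term
annotating K universe genes, and k genes in common, the enrichment p-value
is the upper tail P(X >= k) for X ~ Hypergeometric(N, K, n). BH adjustment
reuses the same step-up implementation as the differential-expression
stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from circenet.diffexpr import bh_adjust

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (GMT semantics): term id -> gene id set."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {term!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    description: str
    k: int
    K: int
    n: int
    N: int
    p: float
    fdr: float


def _check_quadruple(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"invalid hypergeometric quadruple (k={k}, K={K}, n={n}, N={N})")


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k), X ~ Hypergeometric(N, K, n)."""
    _check_quadruple(k, K, n, N)
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_randomized_pvalue(
    k: int, K: int, n: int, N: int, u: float
) -> float:
    """Randomized p-value P(X > k) + u * P(X = k), u ~ Uniform(0,1).

    Exactly Uniform(0,1) under the null, unlike the discrete upper-tail p
    which is super-uniform; used to assess calibration of the discrete
    test.
    """
    _check_quadruple(k, K, n, N)
    return float(stats.hypergeom.sf(k, N, K, n) + u * stats.hypergeom.pmf(k, N, K, n))


def run_ora(
    query,
    collection: GeneSetCollection,
    universe,
) -> pd.DataFrame:
    """Test every term of the collection against the query gene list.

    Query genes and term genes outside the universe are dropped (with a
    logged count); terms empty after intersection are skipped. Returns a
    DataFrame indexed by term, sorted by (p, term id), with columns
    description, k, K, n, N, p, fdr.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    query = frozenset(query)
    dropped = len(query - universe)
    if dropped:
        logger.info("dropped %d query genes outside the universe", dropped)
    query = query & universe
    if not query:
        raise ValueError("query is empty after intersecting with the universe")

    N, n = len(universe), len(query)
    rows = []
    for term in sorted(collection.sets):
        genes = collection.sets[term] & universe
        K = len(genes)
        if K == 0:
            continue
        k = len(genes & query)
        rows.append(
            {
                "term": term,
                "description": collection.descriptions.get(term, ""),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": hypergeom_upper(k, K, n, N),
            }
        )
    if not rows:
        raise ValueError("no gene set overlaps the universe")
    df = pd.DataFrame(rows)
    df["fdr"] = bh_adjust(df["p"].to_numpy())
    df = df.sort_values(["p", "term"], kind="stable").set_index("term")
    return df


def significant_terms(results: pd.DataFrame, fdr_threshold: float = 0.05) -> list[str]:
    """Terms called enriched at ``fdr < fdr_threshold`` (strict)."""
    if not (0.0 < fdr_threshold <= 1.0):
        raise ValueError(f"fdr threshold must be in (0, 1], got {fdr_threshold}")
    return list(results.index[results["fdr"] < fdr_threshold])
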