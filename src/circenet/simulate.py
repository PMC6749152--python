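"""Seeded synthetic study generator for the full ceRNA pipeline.

Everything the pipeline consumes is generated here with the statistical
structure the analysis assumes, plus ground-truth labels:

* multi-dataset two-group log2 expression with per-feature variances drawn
  from the scaled inverse chi-square prior of the moderated-t model, a
  shared differentially expressed (DE) feature set across datasets, and
  per-dataset effect magnitudes (fixed per-feature sign);
* a single small miRNA expression dataset (two groups of four samples,
  mirroring a typical microarray miRNA profile);
* miRNA-target interaction tables in which planted circRNA-mRNA pairs
  share a pool of miRNAs exceeding the crosstalk threshold, over a sparse
  random background;
* curated known disease gene/miRNA lists arranged so one planted circRNA
  accumulates the most risk crosstalks;
* a gene-set collection with one term over-representing the planted
  triples' mRNAs.

All randomness flows from a single seed through independent per-component
substreams, so regenerating one component never shifts another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from circenet.diffexpr import ExpressionDataset
from circenet.enrichment import GeneSetCollection
from circenet.network import CIRC, MRNA, CeRNATriple, InteractionSet

# Spawn keys for the per-component RNG substreams; adding a component at
# the end never disturbs existing ones.
_STREAMS = {
    "layout": 0,
    "expression": 1,
    "mir_expression": 2,
    "background": 3,
    "known": 4,
    "genesets": 5,
}


def _rng(seed: int, component: str) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[component],))
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic generator.

    Expression: ``n_datasets`` gene datasets ("brain regions") of
    ``n_case`` + ``n_control`` samples over ``n_features`` features, of
    which a fraction ``frac_de`` is differentially expressed with log2
    shift magnitude ~ Normal(effect_mean, effect_sd^2) redrawn per dataset
    (sign fixed per feature). Per-feature true variances follow the scaled
    inverse chi-square prior (d0, s0_sq). The miRNA dataset has
    ``n_mir_case`` + ``n_mir_control`` samples.

    Interactions: ``n_planted_circ`` circRNAs each paired with
    ``n_pairs_per_circ`` distinct mRNAs; every planted pair shares a pool
    of ``shared_pool`` miRNAs; background edges are added independently
    with probability ``background_edge_prob``. circRNAs have no expression
    values: only genes and miRNAs are measured.

    Known lists: ``n_known_genes`` / ``n_known_mirs`` curated ids, seeded
    so the designated risk circRNA's partner mRNAs are all known.
    """

    seed: int = 0
    # expression
    n_features: int = 1500
    n_case: int = 8
    n_control: int = 8
    n_datasets: int = 6
    frac_de: float = 0.10
    effect_mean: float = 1.0
    effect_sd: float = 0.3
    d0: float = 4.0
    s0_sq: float = 0.05
    n_mir_case: int = 4
    n_mir_control: int = 4
    # interaction universe
    n_circ: int = 60
    n_mir: int = 200
    n_mrna: int = 500
    n_planted_circ: int = 12
    n_pairs_per_circ: int = 4
    shared_pool: int = 6
    background_edge_prob: float = 0.01
    # curated lists
    n_known_genes: int = 27
    n_known_mirs: int = 45
    # gene sets
    n_genesets: int = 50
    geneset_size: int = 40
    geneset_planted_extra: int = 10

    def __post_init__(self) -> None:
        for name in (
            "frac_de", "effect_mean", "effect_sd", "d0", "s0_sq",
            "background_edge_prob",
        ):
            v = getattr(self, name)
            if name != "d0" and not math.isfinite(float(v)):
                raise ValueError(f"{name} must be finite, got {v}")
        if math.isnan(float(self.d0)) or self.d0 <= 0:
            raise ValueError(f"d0 must be positive (possibly inf), got {self.d0}")
        if self.s0_sq <= 0:
            raise ValueError(f"s0_sq must be positive, got {self.s0_sq}")
        for name in ("frac_de", "background_edge_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.effect_sd < 0:
            raise ValueError("effect_sd must be >= 0")
        for name in (
            "n_features", "n_case", "n_control", "n_datasets", "n_circ",
            "n_mir", "n_mrna", "shared_pool", "n_mir_case", "n_mir_control",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in (
            "n_planted_circ", "n_pairs_per_circ", "n_known_genes",
            "n_known_mirs", "n_genesets", "geneset_size",
            "geneset_planted_extra",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_mrna > self.n_features:
            raise ValueError("n_mrna cannot exceed n_features (mRNAs are measured features)")
        if self.n_planted_circ > self.n_circ:
            raise ValueError("more planted circRNAs than circRNAs")
        if self.n_planted_circ * self.n_pairs_per_circ > self.n_mrna:
            raise ValueError("planted pairs need more distinct mRNAs than available")
        if self.shared_pool > self.n_mir:
            raise ValueError("shared_pool exceeds the number of miRNAs")

    # id vocabularies -----------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return [f"gene_{i + 1:05d}" for i in range(self.n_features)]

    @property
    def mrna_ids(self) -> list[str]:
        return self.feature_ids[: self.n_mrna]

    @property
    def circ_ids(self) -> list[str]:
        return [f"circ_{i + 1:04d}" for i in range(self.n_circ)]

    @property
    def mir_ids(self) -> list[str]:
        return [f"mir_{i + 1:04d}" for i in range(self.n_mir)]


@dataclass
class GroundTruth:
    """Planted labels against which pipeline output is scored."""

    de_features: set[str] = field(default_factory=set)
    de_mirs: set[str] = field(default_factory=set)
    planted_pairs: list[tuple[str, str]] = field(default_factory=list)
    planted_triples: set[tuple[str, str, str]] = field(default_factory=set)
    planted_risk_circ: str | None = None
    known_genes: set[str] = field(default_factory=set)
    known_mirs: set[str] = field(default_factory=set)
    enriched_term: str | None = None

    @property
    def planted_mrnas(self) -> set[str]:
        return {g for _, g in self.planted_pairs}

    def planted_triple_objects(self) -> list[CeRNATriple]:
        counts: dict[tuple[str, str], int] = {}
        for c, _m, g in self.planted_triples:
            counts[(c, g)] = counts.get((c, g), 0) + 1
        return sorted(
            (CeRNATriple(c, m, g, counts[(c, g)]) for c, m, g in self.planted_triples),
            key=lambda t: t.key,
        )

    def risk_counts(self) -> dict[str, int]:
        """Risk-crosstalk count per circRNA on the planted triples."""
        counts: dict[str, int] = {}
        for c, m, g in self.planted_triples:
            if g in self.known_genes or m in self.known_mirs:
                counts[c] = counts.get(c, 0) + 1
        return counts


@dataclass
class _PlantedLayout:
    pairs: list[tuple[str, str]]          # (circ, mrna), mRNAs all distinct
    pools: dict[tuple[str, str], tuple[str, ...]]
    risk_circ: str | None


def _planted_layout(config: SimulationConfig) -> _PlantedLayout:
    """Deterministic planted structure shared by every generator component."""
    rng = _rng(config.seed, "layout")
    n_pairs = config.n_planted_circ * config.n_pairs_per_circ
    if n_pairs == 0:
        return _PlantedLayout([], {}, None)
    circs = [config.circ_ids[i] for i in rng.choice(config.n_circ, size=config.n_planted_circ, replace=False)]
    mrnas = [config.mrna_ids[i] for i in rng.choice(config.n_mrna, size=n_pairs, replace=False)]
    pairs: list[tuple[str, str]] = []
    pools: dict[tuple[str, str], tuple[str, ...]] = {}
    for i, c in enumerate(circs):
        for j in range(config.n_pairs_per_circ):
            g = mrnas[i * config.n_pairs_per_circ + j]
            pool = tuple(
                config.mir_ids[k]
                for k in sorted(rng.choice(config.n_mir, size=config.shared_pool, replace=False))
            )
            pairs.append((c, g))
            pools[(c, g)] = pool
    risk_circ = circs[int(rng.integers(len(circs)))]
    return _PlantedLayout(pairs, pools, risk_circ)


def _draw_variances(rng: np.random.Generator, config: SimulationConfig, n: int) -> np.ndarray:
    if math.isinf(config.d0):
        return np.full(n, config.s0_sq)
    return config.s0_sq * config.d0 / rng.chisquare(config.d0, size=n)


def _simulate_two_group(
    rng: np.random.Generator,
    feature_ids: list[str],
    de_ids: set[str],
    signs: dict[str, int],
    n_case: int,
    n_control: int,
    config: SimulationConfig,
    tag: str,
) -> ExpressionDataset:
    n = len(feature_ids)
    sigma2 = _draw_variances(rng, config, n)
    base = rng.uniform(5.0, 10.0, size=n)
    shift = np.zeros(n)
    is_de = np.array([f in de_ids for f in feature_ids])
    if is_de.any():
        mags = rng.normal(config.effect_mean, config.effect_sd, size=int(is_de.sum()))
        sgn = np.array([signs[f] for f in np.array(feature_ids)[is_de]])
        shift[is_de] = sgn * mags
    cols = [f"{tag}_case_{i + 1}" for i in range(n_case)] + [
        f"{tag}_ctrl_{i + 1}" for i in range(n_control)
    ]
    noise = rng.normal(size=(n, n_case + n_control)) * np.sqrt(sigma2)[:, None]
    means = base[:, None] + shift[:, None] * np.array([1] * n_case + [0] * n_control)[None, :]
    values = pd.DataFrame(means + noise, index=feature_ids, columns=cols)
    conditions = pd.Series(
        ["case"] * n_case + ["control"] * n_control, index=cols, name="condition"
    )
    return ExpressionDataset(values=values, conditions=conditions, tag=tag)


def simulate_expression(
    config: SimulationConfig, truth: GroundTruth | None = None
) -> tuple[list[ExpressionDataset], GroundTruth]:
    """Generate the multi-dataset gene expression matrices.

    DE membership is shared across datasets; the DE set contains the
    planted pairs' mRNAs first (so planted crosstalks are recoverable
    downstream), filled up with randomly chosen features to
    round(frac_de * n_features).
    """
    truth = truth if truth is not None else GroundTruth()
    layout = _planted_layout(config)
    truth.planted_pairs = list(layout.pairs)
    truth.planted_triples = {
        (c, m, g) for (c, g), pool in layout.pools.items() for m in pool
    }
    truth.planted_risk_circ = layout.risk_circ

    rng = _rng(config.seed, "expression")
    features = config.feature_ids
    n_de = int(round(config.frac_de * config.n_features))
    planted = sorted({g for _, g in layout.pairs})
    if n_de >= len(planted):
        remaining = [f for f in features if f not in set(planted)]
        extra_idx = rng.choice(len(remaining), size=n_de - len(planted), replace=False)
        de_ids = set(planted) | {remaining[i] for i in sorted(extra_idx)}
    else:
        de_ids = set(planted[:n_de])
    signs = {f: int(s) for f, s in zip(sorted(de_ids), rng.choice([-1, 1], size=len(de_ids)))}
    truth.de_features = set(de_ids)

    datasets = [
        _simulate_two_group(
            rng, features, de_ids, signs, config.n_case, config.n_control,
            config, tag=f"region{d + 1}",
        )
        for d in range(config.n_datasets)
    ]
    return datasets, truth


def simulate_mirna_expression(
    config: SimulationConfig, truth: GroundTruth | None = None
) -> tuple[ExpressionDataset, GroundTruth]:
    """Generate the single small miRNA expression dataset."""
    truth = truth if truth is not None else GroundTruth()
    rng = _rng(config.seed, "mir_expression")
    mirs = config.mir_ids
    n_de = int(round(config.frac_de * config.n_mir))
    de_idx = sorted(rng.choice(config.n_mir, size=n_de, replace=False))
    de_ids = {mirs[i] for i in de_idx}
    signs = {m: int(s) for m, s in zip(sorted(de_ids), rng.choice([-1, 1], size=len(de_ids)))}
    truth.de_mirs = set(de_ids)
    dataset = _simulate_two_group(
        rng, mirs, de_ids, signs, config.n_mir_case, config.n_mir_control,
        config, tag="mirna",
    )
    return dataset, truth


def simulate_interactions(
    config: SimulationConfig, truth: GroundTruth | None = None
) -> tuple[InteractionSet, GroundTruth]:
    """Generate the miRNA-target interaction table.

    Planted circRNA-mRNA pairs each share a pool of ``shared_pool``
    miRNAs; background edges are added independently with probability
    ``background_edge_prob`` over the full miRNA x target grid.
    """
    truth = truth if truth is not None else GroundTruth()
    if config.shared_pool > config.n_mir:
        raise ValueError("shared_pool exceeds the number of miRNAs")
    layout = _planted_layout(config)
    truth.planted_pairs = list(layout.pairs)
    truth.planted_triples = {
        (c, m, g) for (c, g), pool in layout.pools.items() for m in pool
    }
    truth.planted_risk_circ = layout.risk_circ

    edges: dict[tuple[str, str], str] = {}
    for (c, g), pool in layout.pools.items():
        for m in pool:
            edges[(m, c)] = CIRC
            edges[(m, g)] = MRNA

    if config.background_edge_prob > 0:
        rng = _rng(config.seed, "background")
        targets = config.circ_ids + config.mrna_ids
        classes = [CIRC] * config.n_circ + [MRNA] * config.n_mrna
        mask = rng.random((config.n_mir, len(targets))) < config.background_edge_prob
        for i, j in zip(*np.nonzero(mask)):
            key = (config.mir_ids[i], targets[j])
            edges.setdefault(key, classes[j])

    iset = InteractionSet(frozenset((m, t, k) for (m, t), k in edges.items()))
    return iset, truth


def simulate_known_lists(config: SimulationConfig, truth: GroundTruth) -> GroundTruth:
    """Sample the curated known disease gene / miRNA lists.

    The designated risk circRNA's partner mRNAs are placed in the known
    gene list first, so its crosstalks achieve full known coverage; the
    remainder of both lists is random. The sampled lists are checked (and
    the miRNA list deterministically resampled if needed) so that the risk
    circRNA participates in strictly more risk crosstalks than any other
    circRNA.
    """
    if config.n_known_genes > config.n_mrna:
        raise ValueError("n_known_genes exceeds the mRNA universe")
    if config.n_known_mirs > config.n_mir:
        raise ValueError("n_known_mirs exceeds the miRNA universe")
    rng = _rng(config.seed, "known")

    risk_partners = sorted(
        g for c, g in truth.planted_pairs if c == truth.planted_risk_circ
    )[: config.n_known_genes]
    others = [g for g in config.mrna_ids if g not in set(risk_partners)]
    n_extra = config.n_known_genes - len(risk_partners)
    extra_idx = sorted(rng.choice(len(others), size=n_extra, replace=False)) if n_extra else []
    known_genes = set(risk_partners) | {others[i] for i in extra_idx}

    known_mirs: set[str] = set()
    for attempt in range(100):
        idx = sorted(rng.choice(config.n_mir, size=config.n_known_mirs, replace=False))
        known_mirs = {config.mir_ids[i] for i in idx}
        if not (config.n_known_genes or config.n_known_mirs):
            break
        if truth.planted_risk_circ is None or not truth.planted_triples:
            break
        counts = GroundTruth(
            planted_triples=truth.planted_triples,
            known_genes=known_genes,
            known_mirs=known_mirs,
        ).risk_counts()
        top = counts.get(truth.planted_risk_circ, 0)
        rest = max((v for c, v in counts.items() if c != truth.planted_risk_circ), default=-1)
        if top > rest:
            break
    else:
        raise RuntimeError(
            "could not arrange known lists so the planted risk circRNA "
            "dominates; increase n_known_genes or reduce n_known_mirs"
        )
    truth.known_genes = known_genes
    truth.known_mirs = known_mirs
    return truth


def simulate_genesets(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[GeneSetCollection, GroundTruth]:
    """Random gene sets over the mRNA universe plus one planted term.

    The planted term contains every planted triple's mRNA plus
    ``geneset_planted_extra`` random other genes, so a query made of the
    planted mRNAs is strongly over-represented in exactly one term.
    """
    if config.geneset_size > config.n_mrna:
        raise ValueError("geneset_size exceeds the mRNA universe")
    if config.geneset_size < 1 and config.n_genesets > 0:
        raise ValueError("geneset_size must be >= 1")
    rng = _rng(config.seed, "genesets")
    universe = config.mrna_ids
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for i in range(config.n_genesets):
        term = f"T{i + 1:03d}"
        idx = sorted(rng.choice(config.n_mrna, size=config.geneset_size, replace=False))
        sets[term] = frozenset(universe[j] for j in idx)
        descriptions[term] = f"random gene set {i + 1}"

    planted_mrnas = sorted(truth.planted_mrnas)
    if planted_mrnas:
        term = f"T{config.n_genesets + 1:03d}"
        others = [g for g in universe if g not in set(planted_mrnas)]
        n_extra = min(config.geneset_planted_extra, len(others))
        extra_idx = sorted(rng.choice(len(others), size=n_extra, replace=False)) if n_extra else []
        sets[term] = frozenset(planted_mrnas) | {others[i] for i in extra_idx}
        descriptions[term] = "planted enriched set"
        truth.enriched_term = term
    return GeneSetCollection(sets=sets, descriptions=descriptions), truth


@dataclass
class SimulatedStudy:
    """Every pipeline input for one seeded synthetic study."""

    config: SimulationConfig
    datasets: list[ExpressionDataset]
    mir_dataset: ExpressionDataset
    interactions: InteractionSet
    genesets: GeneSetCollection
    truth: GroundTruth


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate all inputs plus merged ground truth for one seed."""
    datasets, truth = simulate_expression(config)
    mir_dataset, truth = simulate_mirna_expression(config, truth)
    interactions, truth = simulate_interactions(config, truth)
    truth = simulate_known_lists(config, truth)
    genesets, truth = simulate_genesets(config, truth)
    return SimulatedStudy(
        config=config,
        datasets=datasets,
        mir_dataset=mir_dataset,
        interactions=interactions,
        genesets=genesets,
        truth=truth,
    )
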