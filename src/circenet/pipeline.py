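"""End-to-end orchestration: simulate/load -> DE -> network -> disease ->
prioritize -> topology -> enrichment.

Two entry points:

* :func:`analyze_study` runs the whole analysis in memory on already
  loaded inputs and returns a :class:`StudyResult`;
* :func:`run_pipeline` drives the file-based staged pipeline into a run
  directory, writing every intermediate artifact plus a manifest with
  checksums so identical configurations produce identical runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from circenet import io as cio
from circenet.diffexpr import (
    ExpressionDataset,
    MetaDEResult,
    combine_datasets,
    moderated_t,
    select_de,
)
from circenet.disease import (
    DiseaseAnnotation,
    extract_disease_network,
    flag_risk_triples,
    rank_circrnas,
)
from circenet.enrichment import GeneSetCollection, run_ora, significant_terms
from circenet.netstats import degree_distribution, fit_power_law, network_degrees
from circenet.network import (
    CeRNATriple,
    InteractionSet,
    TripartiteNetwork,
    build_circenet,
)
from circenet.simulate import SimulationConfig, simulate_study

logger = logging.getLogger(__name__)

UNIVERSE_POLICIES = ("interactions", "network", "file")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException | str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds, seed and paths for one pipeline run."""

    seed: int = 0
    out_dir: str = "run"
    gene_fdr: float = 0.01
    mir_fdr: float = 0.05
    min_shared: int = 5
    ora_fdr: float = 0.05
    universe: str = "interactions"
    universe_file: str | None = None
    simulate: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    # external inputs, used when simulate is False
    expression_paths: tuple[tuple[str, str], ...] = ()
    mir_expression_paths: tuple[str, str] | None = None
    interactions_path: str | None = None
    known_genes_path: str | None = None
    known_mirs_path: str | None = None
    gmt_path: str | None = None

    def __post_init__(self) -> None:
        for name in ("gene_fdr", "mir_fdr", "ora_fdr"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.min_shared < 1:
            raise ValueError(f"min_shared must be >= 1, got {self.min_shared}")
        if self.universe not in UNIVERSE_POLICIES:
            raise ValueError(f"universe must be one of {UNIVERSE_POLICIES}")
        if self.universe == "file" and not self.universe_file:
            raise ValueError("universe policy 'file' requires universe_file")
        if object.__getattribute__(self, "sim").seed != self.seed:
            object.__setattr__(
                self, "sim", dataclasses.replace(self.sim, seed=self.seed)
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["expression_paths"] = [list(p) for p in self.expression_paths]
        if self.mir_expression_paths:
            d["mir_expression_paths"] = list(self.mir_expression_paths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = SimulationConfig(**d["sim"])
        d["expression_paths"] = tuple(
            tuple(p) for p in d.get("expression_paths", ())
        )
        if d.get("mir_expression_paths"):
            d["mir_expression_paths"] = tuple(d["mir_expression_paths"])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class StudyResult:
    """Everything the analysis computes for one study."""

    gene_meta: MetaDEResult
    mir_de: MetaDEResult
    cdegs: set[str]
    demirs: set[str]
    circenet: TripartiteNetwork
    triples: list[CeRNATriple]
    disease_network: TripartiteNetwork
    disease_triples: list[CeRNATriple]
    risk_triples: list[CeRNATriple]
    ranking: pd.DataFrame
    degree_dist: dict[int, int] | None
    power_fit: object | None
    ora: pd.DataFrame | None
    enriched: list[str]

    @property
    def top_circ(self) -> str | None:
        return self.ranking.index[0] if len(self.ranking) else None


def gene_meta_analysis(datasets: list[ExpressionDataset]) -> MetaDEResult:
    """Per-dataset moderated t followed by Stouffer combination."""
    return combine_datasets([moderated_t(ds) for ds in datasets])


def analyze_study(
    datasets: list[ExpressionDataset],
    mir_dataset: ExpressionDataset,
    interactions: InteractionSet,
    genesets: GeneSetCollection | None,
    known_genes: set[str],
    known_mirs: set[str],
    gene_fdr: float = 0.01,
    mir_fdr: float = 0.05,
    min_shared: int = 5,
    ora_fdr: float = 0.05,
    universe: set[str] | None = None,
) -> StudyResult:
    """Run the complete analysis in memory.

    ``universe`` defaults to all mRNA ids of the interaction set; the ORA
    query is the mRNA set of the risk crosstalks (falling back to the
    disease network's mRNAs when no crosstalk is flagged as risk).
    """
    gene_meta = gene_meta_analysis(datasets)
    cdegs = select_de(gene_meta, gene_fdr)
    mir_de = combine_datasets([moderated_t(mir_dataset)])
    demirs = select_de(mir_de, mir_fdr)

    circenet, triples = build_circenet(interactions, min_shared=min_shared)
    annotation = DiseaseAnnotation.build(cdegs, demirs, known_genes, known_mirs)
    disease_network, disease_triples = extract_disease_network(triples, annotation)
    risk_triples = flag_risk_triples(disease_triples, annotation)
    ranking = rank_circrnas(risk_triples, disease_triples)

    degree_dist = power_fit = None
    stats_net = disease_network if disease_network.n_nodes else circenet
    if stats_net.n_nodes:
        degree_dist = degree_distribution(stats_net)
        try:
            power_fit = fit_power_law(network_degrees(stats_net))
        except ValueError as exc:  # e.g. all degrees equal
            logger.warning("power-law fit unavailable: %s", exc)

    ora = None
    enriched: list[str] = []
    if genesets is not None and len(genesets):
        if universe is None:
            universe = {t for _, t, c in interactions.edges if c == "mRNA"}
        query = {t.mrna_id for t in risk_triples} or {
            t.mrna_id for t in disease_triples
        }
        if query:
            ora = run_ora(query, genesets, universe)
            enriched = significant_terms(ora, ora_fdr)

    return StudyResult(
        gene_meta=gene_meta,
        mir_de=mir_de,
        cdegs=cdegs,
        demirs=demirs,
        circenet=circenet,
        triples=triples,
        disease_network=disease_network,
        disease_triples=disease_triples,
        risk_triples=risk_triples,
        ranking=ranking,
        degree_dist=degree_dist,
        power_fit=power_fit,
        ora=ora,
        enriched=enriched,
    )


# ---------------------------------------------------------------------------
# file-based staged pipeline
# ---------------------------------------------------------------------------

def _run_dirs(run_dir: Path) -> dict[str, Path]:
    return {
        name: run_dir / name
        for name in ("inputs", "de", "network", "disease", "stats", "enrichment")
    }


def _expression_files(run_dir: Path) -> list[tuple[Path, Path]]:
    inputs = run_dir / "inputs"
    pairs = []
    for values in sorted(inputs.glob("expr_region*.tsv")):
        tag = values.stem.removeprefix("expr_")
        pairs.append((values, inputs / f"annot_{tag}.tsv"))
    return pairs


def stage_inputs(config: PipelineConfig, run_dir: Path) -> None:
    """Simulate all inputs, or normalize user-supplied files into the run."""
    inputs = run_dir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    if config.simulate:
        study = simulate_study(config.sim)
        for ds in study.datasets:
            cio.write_expression(
                ds, inputs / f"expr_{ds.tag}.tsv", inputs / f"annot_{ds.tag}.tsv"
            )
        cio.write_expression(
            study.mir_dataset, inputs / "expr_mirna.tsv", inputs / "annot_mirna.tsv"
        )
        cio.write_interactions(study.interactions, inputs / "interactions.tsv")
        cio.write_id_list(study.truth.known_genes, inputs / "known_genes.txt")
        cio.write_id_list(study.truth.known_mirs, inputs / "known_mirs.txt")
        cio.write_gmt(study.genesets, inputs / "genesets.gmt")
        cio.write_truth(study.truth, inputs / "truth.json")
        return
    if not config.expression_paths or config.mir_expression_paths is None:
        raise FileNotFoundError("expression inputs not configured and simulate=False")
    for i, (values_path, annot_path) in enumerate(config.expression_paths, start=1):
        ds = cio.read_expression(values_path, annot_path)
        ds.tag = f"region{i}"
        cio.write_expression(ds, inputs / f"expr_{ds.tag}.tsv", inputs / f"annot_{ds.tag}.tsv")
    mv, ma = config.mir_expression_paths
    mir_ds = cio.read_expression(mv, ma)
    mir_ds.tag = "mirna"
    cio.write_expression(mir_ds, inputs / "expr_mirna.tsv", inputs / "annot_mirna.tsv")
    for src, dest in (
        (config.interactions_path, "interactions.tsv"),
        (config.known_genes_path, "known_genes.txt"),
        (config.known_mirs_path, "known_mirs.txt"),
        (config.gmt_path, "genesets.gmt"),
    ):
        if src is None:
            raise FileNotFoundError(f"input for {dest} not configured")
        if not Path(src).exists():
            raise FileNotFoundError(f"input file missing: {src}")
        (inputs / dest).write_text(Path(src).read_text())


def stage_de(config: PipelineConfig, run_dir: Path) -> None:
    """Gene meta differential expression plus single-dataset miRNA DE."""
    de_dir = run_dir / "de"
    de_dir.mkdir(parents=True, exist_ok=True)
    stats_list = []
    for values, annot in _expression_files(run_dir):
        ds = cio.read_expression(values, annot)
        stats_list.append(moderated_t(ds))
    if not stats_list:
        raise FileNotFoundError("no expression datasets found under inputs/")
    meta = combine_datasets(stats_list)
    table = meta.table.copy()
    for s in stats_list:
        table[f"effect_{s.tag}"] = s.table["effect"]
    table.index.name = "feature_id"
    table.to_csv(de_dir / "gene_meta.tsv", sep="\t")
    cio.write_id_list(select_de(meta, config.gene_fdr), de_dir / "cdegs.txt")

    mir_ds = cio.read_expression(
        run_dir / "inputs" / "expr_mirna.tsv", run_dir / "inputs" / "annot_mirna.tsv"
    )
    mir_de = combine_datasets([moderated_t(mir_ds)])
    out = mir_de.table.copy()
    out.index.name = "feature_id"
    out.to_csv(de_dir / "mir_de.tsv", sep="\t")
    cio.write_id_list(select_de(mir_de, config.mir_fdr), de_dir / "demirs.txt")


def stage_network(config: PipelineConfig, run_dir: Path) -> None:
    """Build the competitive network from the interaction table."""
    net_dir = run_dir / "network"
    net_dir.mkdir(parents=True, exist_ok=True)
    path = run_dir / "inputs" / "interactions.tsv"
    if not path.exists():
        raise FileNotFoundError(f"interaction file missing: {path}")
    interactions = cio.load_interactions(path)
    network, triples = build_circenet(interactions, min_shared=config.min_shared)
    cio.network_to_graphml(network, net_dir / "circenet.graphml")
    cio.write_edge_list(network, net_dir / "circenet_edges.tsv")
    cio.write_triples(triples, net_dir / "triples.tsv")
    (net_dir / "summary.json").write_text(
        json.dumps(network.summary() | {"n_triples": len(triples)}, sort_keys=True)
    )


def _load_annotation(run_dir: Path) -> DiseaseAnnotation:
    return DiseaseAnnotation.build(
        cio.read_id_list(run_dir / "de" / "cdegs.txt"),
        cio.read_id_list(run_dir / "de" / "demirs.txt"),
        cio.read_id_list(run_dir / "inputs" / "known_genes.txt"),
        cio.read_id_list(run_dir / "inputs" / "known_mirs.txt"),
    )


def stage_extract(config: PipelineConfig, run_dir: Path) -> None:
    """Map DE calls into the network to get the disease subnetwork."""
    dis_dir = run_dir / "disease"
    dis_dir.mkdir(parents=True, exist_ok=True)
    triples = cio.read_triples(run_dir / "network" / "triples.tsv")
    annotation = _load_annotation(run_dir)
    network, disease_triples = extract_disease_network(triples, annotation)
    if not disease_triples:
        logger.warning("disease subnetwork is empty")
    cio.network_to_graphml(network, dis_dir / "adcircenet.graphml")
    cio.write_edge_list(network, dis_dir / "adcircenet_edges.tsv")
    cio.write_triples(disease_triples, dis_dir / "disease_triples.tsv")
    (dis_dir / "summary.json").write_text(
        json.dumps(network.summary() | {"n_triples": len(disease_triples)}, sort_keys=True)
    )


def stage_prioritize(config: PipelineConfig, run_dir: Path) -> None:
    """Flag risk crosstalks and rank circRNAs by risk frequency."""
    dis_dir = run_dir / "disease"
    disease_triples = cio.read_triples(dis_dir / "disease_triples.tsv")
    annotation = _load_annotation(run_dir)
    risk = flag_risk_triples(disease_triples, annotation)
    cio.write_triples(risk, dis_dir / "risk_triples.tsv")
    ranking = rank_circrnas(risk, disease_triples)
    ranking.to_csv(dis_dir / "ranking.tsv", sep="\t")


def stage_stats(config: PipelineConfig, run_dir: Path) -> None:
    """Degree distribution and power-law fit of the disease network."""
    stats_dir = run_dir / "stats"
    stats_dir.mkdir(parents=True, exist_ok=True)
    network = cio.network_from_graphml(run_dir / "disease" / "adcircenet.graphml")
    if network.n_nodes == 0:
        network = cio.network_from_graphml(run_dir / "network" / "circenet.graphml")
    dist = degree_distribution(network)
    pd.DataFrame(
        {"degree": list(dist.keys()), "n_nodes": list(dist.values())}
    ).to_csv(stats_dir / "degree_histogram.tsv", sep="\t", index=False)
    try:
        fit = fit_power_law(network_degrees(network))
        payload = dataclasses.asdict(fit)
    except ValueError as exc:
        payload = {"error": str(exc)}
    (stats_dir / "powerlaw.json").write_text(json.dumps(payload, sort_keys=True))


def stage_enrich(config: PipelineConfig, run_dir: Path) -> None:
    """ORA of the risk-crosstalk mRNAs against the gene-set collection."""
    enr_dir = run_dir / "enrichment"
    enr_dir.mkdir(parents=True, exist_ok=True)
    collection = cio.read_gmt(run_dir / "inputs" / "genesets.gmt")
    risk = cio.read_triples(run_dir / "disease" / "risk_triples.tsv")
    disease = cio.read_triples(run_dir / "disease" / "disease_triples.tsv")
    query = {t.mrna_id for t in risk} or {t.mrna_id for t in disease}
    if not query:
        logger.warning("no query genes for enrichment; skipping")
        (enr_dir / "ora.tsv").write_text("")
        cio.write_id_list([], enr_dir / "significant_terms.txt")
        return
    if config.universe == "interactions":
        interactions = cio.load_interactions(run_dir / "inputs" / "interactions.tsv")
        universe = {t for _, t, c in interactions.edges if c == "mRNA"}
    elif config.universe == "network":
        net = cio.network_from_graphml(run_dir / "network" / "circenet.graphml")
        universe = set(net.mrna_nodes)
    else:
        universe = cio.read_id_list(config.universe_file)
    logger.info("ORA universe policy %s: %d genes", config.universe, len(universe))
    results = run_ora(query, collection, universe)
    results.to_csv(enr_dir / "ora.tsv", sep="\t")
    cio.write_id_list(significant_terms(results, config.ora_fdr), enr_dir / "significant_terms.txt")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(config: PipelineConfig, run_dir: Path) -> dict:
    """Checksums plus headline numbers for the finished run."""
    import circenet

    checksums = {
        str(p.relative_to(run_dir)): _sha256(p)
        for p in sorted(run_dir.rglob("*"))
        if p.is_file() and p.name not in ("manifest.json", "config.yaml")
    }
    summary: dict = {}
    net_summary = run_dir / "network" / "summary.json"
    if net_summary.exists():
        summary["circenet"] = json.loads(net_summary.read_text())
    dis_summary = run_dir / "disease" / "summary.json"
    if dis_summary.exists():
        summary["adcircenet"] = json.loads(dis_summary.read_text())
    cdegs = run_dir / "de" / "cdegs.txt"
    if cdegs.exists():
        summary["n_cdegs"] = len(cio.read_id_list(cdegs))
        summary["n_demirs"] = len(cio.read_id_list(run_dir / "de" / "demirs.txt"))
    ranking_path = run_dir / "disease" / "ranking.tsv"
    if ranking_path.exists():
        ranking = pd.read_csv(ranking_path, sep="\t", index_col=0)
        summary["n_risk_crosstalks"] = int(ranking["risk_triple_count"].sum())
        summary["top_circ"] = str(ranking.index[0]) if len(ranking) else None
    truth_path = run_dir / "inputs" / "truth.json"
    if truth_path.exists():
        truth = cio.read_truth(truth_path)
        summary["planted_risk_circ"] = truth.planted_risk_circ
        summary["top_circ_is_planted"] = bool(
            summary.get("top_circ") == truth.planted_risk_circ
        )
    manifest = {
        "package_version": circenet.__version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "checksums": checksums,
        "summary": summary,
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


_STAGES = (
    ("inputs", stage_inputs),
    ("de", stage_de),
    ("build-net", stage_network),
    ("extract", stage_extract),
    ("prioritize", stage_prioritize),
    ("stats", stage_stats),
    ("enrich", stage_enrich),
)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage into ``config.out_dir`` and write the manifest.

    Any stage failure raises :class:`PipelineError` naming the stage;
    outputs of completed stages are retained for debugging.
    """
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.save(run_dir / "config.yaml")
    for name, fn in _STAGES:
        logger.info("stage %s", name)
        try:
            fn(config, run_dir)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, exc) from exc
    write_manifest(config, run_dir)
    return run_dir
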