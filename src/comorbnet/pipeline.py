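"""End-to-end pipeline orchestration.

A run takes the four input tables (read from disk or simulated), builds
the two layers and the multiplex network, quantifies layer concordance,
detects modules, characterizes them by gene-group and phenotype
enrichment, and prioritizes candidate genes.  Every stage draws its
randomness from seeds derived from one configured seed, and a run with an
identical resolved configuration is byte-identical on disk.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io
from .community import (
    ModularityParams,
    filter_modules,
    louvain_multiplex,
    louvain_single,
    resolution_sweep,
)
from .compare import degree_correlation, edge_overlap_test, partition_nmi_test
from .containers import GeneUniverse, MultiplexNetwork, Partition
from .enrich import (
    DEFAULT_GENOME_BACKGROUND,
    gene_group_enrichment,
    hpo_subtree,
    phenotype_score_panel,
)
from .network import (
    assemble_multiplex,
    build_phenotype_layer,
    build_phenotype_vectors,
    build_ppi_layer,
    top_k_filter,
)
from .prioritize import (
    candidate_genes,
    centrality_table,
    common_gene_centrality_test,
    match_modules,
)
from .synthetic import (
    AUTISTIC_ROOT,
    ONTOLOGY_ROOT,
    SEIZURE_ROOT,
    SimulationConfig,
    simulate_bundle,
)


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved settings of a full pipeline run.

    Defaults are the reference settings of the analysis: PPI confidence
    threshold 700, top-1000 score filter (500 for the WES profile),
    permutation threshold 10th largest of 1000 shuffles, 1000 Louvain
    restarts, module filters min_size 2 / keep_top 14 (WES profile uses
    min_size 5), 10,000-trial empirical enrichment, genome background
    19,556 genes.
    """

    input_dir: Optional[str] = None
    simulate: Optional[SimulationConfig] = None
    output_dir: Optional[str] = None

    phenotype_root: str = ONTOLOGY_ROOT
    phenotype_panel_roots: tuple[str, ...] = (
        SEIZURE_ROOT,
        AUTISTIC_ROOT,
        "HP:0001250",
        "HP:0000729",
    )
    min_confidence: int = 700
    top_k: int = 1000
    n_shuffles: int = 1000
    rank: int = 10
    joint_shuffle: bool = False
    modularity: ModularityParams = field(default_factory=lambda: ModularityParams(n_restarts=1000))
    min_size: int = 2
    keep_top: Optional[int] = 14
    overlap_trials: int = 10_000
    nmi_trials: int = 1000
    nmi_null_restarts: int = 1
    enrichment_trials: int = 10_000
    genome_size: int = DEFAULT_GENOME_BACKGROUND
    run_sweep: bool = False
    seed: int = 0

    def resolved(self) -> dict:
        # where the outputs land is not part of the run's identity
        d = asdict(self)
        d.pop("output_dir", None)
        return d


@dataclass
class PipelineResult:
    config: PipelineConfig
    universe: GeneUniverse
    net: MultiplexNetwork
    comparison: dict
    partition: Partition
    ppi_partition: Partition
    phenotype_partition: Partition
    kept_modules: list[int]
    gene_enrichment_network: pd.DataFrame
    gene_enrichment_genome: pd.DataFrame
    phenotype_enrichment: pd.DataFrame
    centralities: dict[int, pd.DataFrame]
    module_matches: pd.DataFrame
    candidates: pd.DataFrame
    focused_modules: dict[str, Optional[int]]
    centrality_test: tuple[float, str]
    sweep: Optional[list] = None


def wes_profile(cfg: PipelineConfig) -> PipelineConfig:
    """The settings used for the smaller WES-only network: top-500 score
    filter and a minimum module size of 5 genes, no module-count cap."""
    return replace(cfg, top_k=500, min_size=5, keep_top=None)


def _focused_module(panel: pd.DataFrame, terms: frozenset[str]) -> Optional[int]:
    sub = panel[panel["target"].isin(terms)]
    if not len(sub):
        return None
    best = sub.sort_values(["fdr", "module"], kind="mergesort").iloc[0]
    return int(best["module"])


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute every stage and (optionally) persist the output bundle."""
    if (cfg.input_dir is None) == (cfg.simulate is None):
        raise ValueError("exactly one of input_dir / simulate must be given")

    cfg_hash = io.config_hash(cfg.resolved())
    seed = cfg.seed

    # --- inputs -----------------------------------------------------------
    if cfg.simulate is not None:
        bundle = simulate_bundle(cfg.simulate)
        universe, ppi_edges = bundle.universe, bundle.ppi_edges
        ontology, scores = bundle.ontology, bundle.scores
    else:
        universe, ppi_edges, ontology, scores = io.read_tables(cfg.input_dir)

    # --- layers -----------------------------------------------------------
    ppi = build_ppi_layer(ppi_edges, universe, cfg.min_confidence)
    kept_scores = top_k_filter(scores, cfg.top_k)
    vectors = build_phenotype_vectors(kept_scores, ontology, cfg.phenotype_root, universe)
    phen = build_phenotype_layer(
        vectors,
        universe,
        n_shuffles=cfg.n_shuffles,
        rank=cfg.rank,
        seed=seed,
        joint=cfg.joint_shuffle,
    )
    net = assemble_multiplex(ppi, phen, universe, cfg.modularity.layer_weights)

    # --- layer concordance ------------------------------------------------
    params = replace(cfg.modularity, seed=seed)
    overlap = edge_overlap_test(ppi, phen, n_trials=cfg.overlap_trials, seed=seed + 1)
    nmi = partition_nmi_test(
        ppi,
        phen,
        n_trials=cfg.nmi_trials,
        params=params,
        seed=seed + 2,
        null_restarts=cfg.nmi_null_restarts,
    )
    comparison = {
        "edge_overlap": overlap.to_dict(),
        "partition_nmi": nmi.to_dict(),
        "degree_correlation_spearman": degree_correlation(ppi, phen, "spearman"),
        "n_active_nodes": net.n_active_nodes(),
        "n_ppi_edges": ppi.n_edges,
        "n_phenotype_edges": phen.n_edges,
    }

    # --- community detection ----------------------------------------------
    partition = louvain_multiplex(net, params)
    ppi_part = louvain_single(ppi, params)
    phen_part = louvain_single(phen, params)
    kept = filter_modules(partition, cfg.min_size, cfg.keep_top)
    sweep = resolution_sweep(net, params) if cfg.run_sweep else None

    # --- enrichment ---------------------------------------------------------
    gene_net = gene_group_enrichment(
        partition, universe, background="network", module_ids=kept
    )
    gene_genome = gene_group_enrichment(
        partition,
        universe,
        background="genome",
        module_ids=kept,
        genome_size=cfg.genome_size,
    )

    known_terms = set(ontology["term_id"])
    panel_terms: set[str] = set()
    for root in cfg.phenotype_panel_roots:
        if root in known_terms:
            panel_terms |= hpo_subtree(ontology, root)
    scored_terms = set(kept_scores["term_id"])
    panel_term_list = sorted(panel_terms & scored_terms)
    phen_panel = phenotype_score_panel(
        partition,
        kept,
        panel_term_list,
        kept_scores,
        universe.genes,
        n_trials=cfg.enrichment_trials,
        seed=seed + 3,
    )

    # --- prioritization -----------------------------------------------------
    seiz_terms = frozenset(
        t
        for root in (SEIZURE_ROOT, "HP:0001250")
        if root in known_terms
        for t in hpo_subtree(ontology, root)
    )
    aut_terms = frozenset(
        t
        for root in (AUTISTIC_ROOT, "HP:0000729")
        if root in known_terms
        for t in hpo_subtree(ontology, root)
    )
    focused = {
        "epilepsy": _focused_module(phen_panel, seiz_terms),
        "autism": _focused_module(phen_panel, aut_terms),
    }

    cand_rows = []
    for focus, mod in focused.items():
        if mod is None:
            continue
        for g in candidate_genes(partition.members(mod), universe, focus=focus):
            cand_rows.append(
                {"gene": g, "focus": focus, "module": mod, "rule": "focused_module_specific"}
            )
    candidates = pd.DataFrame(cand_rows, columns=["gene", "focus", "module", "rule"])

    centralities = {
        mod: centrality_table(net, partition.members(mod))
        for mod in [m for m in focused.values() if m is not None]
    }
    matches = match_modules(partition, ppi_part)
    centrality_test = common_gene_centrality_test(net)

    result = PipelineResult(
        config=cfg,
        universe=universe,
        net=net,
        comparison=comparison,
        partition=partition,
        ppi_partition=ppi_part,
        phenotype_partition=phen_part,
        kept_modules=kept,
        gene_enrichment_network=gene_net,
        gene_enrichment_genome=gene_genome,
        phenotype_enrichment=phen_panel,
        centralities=centralities,
        module_matches=matches,
        candidates=candidates,
        focused_modules=focused,
        centrality_test=centrality_test,
        sweep=sweep,
    )
    if cfg.output_dir is not None:
        write_outputs(result, Path(cfg.output_dir), seed, cfg_hash)
    return result


def write_outputs(result: PipelineResult, outdir: Path, seed: int, cfg_hash: str) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_json(result.config.resolved(), outdir / "resolved_config.json", seed, cfg_hash)
    io.write_layer(result.net.ppi, outdir / "layer_ppi.tsv", seed, cfg_hash)
    io.write_layer(result.net.phenotype, outdir / "layer_phenotype.tsv", seed, cfg_hash)
    io.write_partition(result.partition, outdir / "partition_multiplex.tsv", seed, cfg_hash)
    io.write_partition(result.ppi_partition, outdir / "partition_ppi.tsv", seed, cfg_hash)
    io.write_partition(
        result.phenotype_partition, outdir / "partition_phenotype.tsv", seed, cfg_hash
    )
    io.write_json(result.comparison, outdir / "layer_comparison.json", seed, cfg_hash)
    io.write_table(
        result.gene_enrichment_network, outdir / "enrichment_genes_network.csv", seed, cfg_hash, sep=","
    )
    io.write_table(
        result.gene_enrichment_genome, outdir / "enrichment_genes_genome.csv", seed, cfg_hash, sep=","
    )
    io.write_table(
        result.phenotype_enrichment, outdir / "enrichment_phenotypes.csv", seed, cfg_hash, sep=","
    )
    for mod, table in result.centralities.items():
        io.write_table(table, outdir / f"centrality_module_{mod}.csv", seed, cfg_hash, sep=",")
    io.write_table(result.module_matches, outdir / "module_matches.csv", seed, cfg_hash, sep=",")
    io.write_table(result.candidates, outdir / "candidates.tsv", seed, cfg_hash)
    p, direction = result.centrality_test
    io.write_json(
        {
            "focused_modules": result.focused_modules,
            "kept_modules": result.kept_modules,
            "common_vs_specific_centrality_p": p,
            "common_vs_specific_direction": direction,
            "multiplex_quality": result.partition.quality,
            "sweep": [
                {
                    "gamma": e.gamma,
                    "quality": e.quality,
                    "n_modules": e.n_modules,
                    "per_layer_quality": list(e.per_layer_quality),
                }
                for e in (result.sweep or [])
            ],
        },
        outdir / "summary.json",
        seed,
        cfg_hash,
    )
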