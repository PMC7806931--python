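"""Synthetic generators for the four pipeline inputs.

Real runs of this analysis consume (a) two curated disease gene lists with
subgroup labels, (b) a STRING-style PPI edge table with combined confidence
scores, (c) an HPO-like rooted ontology and (d) a gene-phenotype
association score table with per-term skewness weights.  None of these can
be redistributed here, so this module emulates all four with *planted*
module structure: blocks of genes that share both dense PPI connectivity
and characteristic phenotype terms.  Every downstream stage of the
pipeline is therefore testable end to end, with ground truth available via
``GeneUniverse.planted_module``.

One global seed drives independent per-stage substreams (universe, edges,
ontology, scores) so each stage is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    AUX_GROUP_NAMES,
    AUTISM_SUBGROUPS,
    EPILEPSY_SUBGROUPS,
    NO_LABEL,
    ROOT_MARKER,
    GeneUniverse,
)

#: root term of the synthetic ontology (phenotypic-abnormality analogue)
ONTOLOGY_ROOT = "HP:0000118"
#: roots of the two marked subtrees (seizure-like / autistic-behavior-like)
SEIZURE_ROOT = "SEIZ:0001"
AUTISTIC_ROOT = "AUT:0001"

# stage tags for independent RNG substreams
_STAGE_UNIVERSE, _STAGE_EDGES, _STAGE_ONTOLOGY, _STAGE_SCORES = 1, 2, 3, 4

# subgroup draw weights mirroring the relative sizes of the curated lists
_EPI_WEIGHTS = np.array([84, 273, 529, 314], dtype=float)
_AUT_WEIGHTS = np.array([144, 219, 472, 119], dtype=float)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted-structure simulation.

    Defaults are the study conditions of the reference analysis scaled to
    desk size: label fractions follow the real lists (999 and 913 genes of
    1707, 205 shared), and the planted blocks are recoverable but noisy
    (p_in=0.4 vs p_out=0.01, phenotype signal-to-noise 10).
    """

    n_genes: int = 200
    n_modules: int = 4
    frac_disease_a: float = 0.585  # epilepsy-labelled fraction
    frac_disease_b: float = 0.535  # autism-labelled fraction
    frac_common: float = 0.12  # genes carrying both labels
    common_module_bias: float = 0.8  # fraction of common genes planted in module 1
    p_in: float = 0.4
    p_out: float = 0.01
    n_terms: int = 120
    terms_per_module: int = 8
    noise_terms_per_gene: int = 3
    score_signal: float = 10.0
    score_noise: float = 1.0
    aux_group_frac: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_modules <= 0:
            raise ValueError("n_genes and n_modules must be positive")
        for name in (
            "frac_disease_a",
            "frac_disease_b",
            "frac_common",
            "common_module_bias",
            "p_in",
            "p_out",
            "aux_group_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.frac_common > min(self.frac_disease_a, self.frac_disease_b):
            raise ValueError("frac_common exceeds a disease fraction")
        if self.score_signal < 0 or self.score_noise < 0:
            raise ValueError("score magnitudes must be nonnegative")

    def stage_rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stage])


def generate_universe(cfg: SimulationConfig) -> GeneUniverse:
    """Draw the gene universe with disease labels and planted modules.

    Label counts are rounded to the nearest gene; common genes get both
    labels.  Common genes are planted into module 1 with probability
    ``common_module_bias`` (uniform otherwise) so one module is enriched in
    dual-label genes, as in the real networks; all other genes are assigned
    uniformly over modules.
    """
    rng = cfg.stage_rng(_STAGE_UNIVERSE)
    n = cfg.n_genes
    genes = tuple(f"G{i:04d}" for i in range(n))

    n_common = round(cfg.frac_common * n)
    n_a = round(cfg.frac_disease_a * n)
    n_b = round(cfg.frac_disease_b * n)
    n_a_only = min(n_a - n_common, n - n_common)
    n_b_only = min(n_b - n_common, n - n_common - n_a_only)

    order = rng.permutation(n)
    common = [genes[i] for i in order[:n_common]]
    a_only = [genes[i] for i in order[n_common : n_common + n_a_only]]
    b_only = [
        genes[i] for i in order[n_common + n_a_only : n_common + n_a_only + n_b_only]
    ]

    epi = {g: NO_LABEL for g in genes}
    aut = {g: NO_LABEL for g in genes}
    for g in common + a_only:
        epi[g] = str(rng.choice(EPILEPSY_SUBGROUPS, p=_EPI_WEIGHTS / _EPI_WEIGHTS.sum()))
    for g in common + b_only:
        aut[g] = str(rng.choice(AUTISM_SUBGROUPS, p=_AUT_WEIGHTS / _AUT_WEIGHTS.sum()))

    planted = {}
    common_set = set(common)
    for g in genes:
        if g in common_set and rng.random() < cfg.common_module_bias:
            planted[g] = 1
        else:
            planted[g] = int(rng.integers(1, cfg.n_modules + 1))

    aux = {}
    for name in AUX_GROUP_NAMES:
        mask = rng.random(n) < cfg.aux_group_frac
        aux[name] = frozenset(g for g, keep in zip(genes, mask) if keep)

    return GeneUniverse(genes, epi, aut, aux, planted)


def generate_ppi_edges(universe: GeneUniverse, cfg: SimulationConfig) -> pd.DataFrame:
    """Draw a STRING-style edge table over the planted blocks.

    Within-module pairs are linked with probability ``p_in`` and receive
    integer confidence scores >= 700 so planted structure survives the
    high-confidence threshold; between-module pairs are linked with
    probability ``p_out`` and scored uniformly over 150-999 so some fall
    below it.  Undirected, no self-loops, no duplicate pairs.
    """
    if universe.planted_module is None:
        raise ValueError("universe lacks planted modules")
    rng = cfg.stage_rng(_STAGE_EDGES)
    genes = universe.genes
    planted = universe.planted_module
    rows = []
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            same = planted[a] == planted[b]
            p = cfg.p_in if same else cfg.p_out
            if p > 0 and rng.random() < p:
                lo, hi = (700, 1000) if same else (150, 1000)
                rows.append((a, b, int(rng.integers(lo, hi))))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "combined_score"])


def generate_ontology(cfg: SimulationConfig) -> pd.DataFrame:
    """Build a rooted ontology tree with marked SEIZ and AUT subtrees.

    Returns a two-column (term_id, parent_id) table: the root, the two
    marked subtree roots, then remaining terms split evenly between the
    seizure-like subtree, the autistic-behavior-like subtree, and generic
    terms, each attached to a uniformly chosen earlier term of its branch
    (so subtrees can be several levels deep).
    """
    if cfg.n_terms < 3:
        raise ValueError("need at least 3 terms (root + two subtree roots)")
    rng = cfg.stage_rng(_STAGE_ONTOLOGY)
    rows = [
        (ONTOLOGY_ROOT, ROOT_MARKER),
        (SEIZURE_ROOT, ONTOLOGY_ROOT),
        (AUTISTIC_ROOT, ONTOLOGY_ROOT),
    ]
    branches = {
        "SEIZ": [SEIZURE_ROOT],
        "AUT": [AUTISTIC_ROOT],
        "HP": [ONTOLOGY_ROOT],
    }
    prefixes = ["SEIZ", "AUT", "HP"]
    for k in range(cfg.n_terms - 3):
        prefix = prefixes[k % 3]
        pool = branches[prefix]
        parent = pool[int(rng.integers(len(pool)))]
        term = f"{prefix}:{1000 + k:04d}"
        rows.append((term, parent))
        pool.append(term)
    return pd.DataFrame(rows, columns=["term_id", "parent_id"])


def module_characteristic_terms(
    ontology: pd.DataFrame, cfg: SimulationConfig
) -> dict[int, list[str]]:
    """Deterministic characteristic-term assignment for each planted module.

    Module 1 draws from the seizure-like subtree and module 2 from the
    autistic-behavior-like subtree (so phenotype-subtree enrichment has a
    planted signal); remaining modules draw generic terms.  Term lists are
    disjoint across modules.
    """
    terms = list(ontology["term_id"])
    pools = {
        "SEIZ": [t for t in terms if t.startswith("SEIZ:") and t != SEIZURE_ROOT],
        "AUT": [t for t in terms if t.startswith("AUT:") and t != AUTISTIC_ROOT],
        "HP": [t for t in terms if t.startswith("HP:") and t != ONTOLOGY_ROOT],
    }
    out: dict[int, list[str]] = {}
    cursors = {k: 0 for k in pools}
    for mod in range(1, cfg.n_modules + 1):
        branch = "SEIZ" if mod == 1 else "AUT" if mod == 2 else "HP"
        pool, c = pools[branch], cursors[branch]
        take = pool[c : c + cfg.terms_per_module]
        if len(take) < cfg.terms_per_module:
            raise ValueError("ontology too small for terms_per_module per module")
        cursors[branch] = c + cfg.terms_per_module
        out[mod] = take
    return out


def generate_scores(
    universe: GeneUniverse, ontology: pd.DataFrame, cfg: SimulationConfig
) -> pd.DataFrame:
    """Draw the gene-phenotype association score table.

    Genes score ~``score_signal`` on their module's characteristic terms
    and ~``score_noise`` on a few random background terms; with zero noise
    the supports of genes from different modules are disjoint.  Each term
    carries a positive skewness weight shared by all of its rows.
    """
    if universe.planted_module is None:
        raise ValueError("universe lacks planted modules")
    rng = cfg.stage_rng(_STAGE_SCORES)
    char_terms = module_characteristic_terms(ontology, cfg)
    all_terms = [t for t in ontology["term_id"] if t != ONTOLOGY_ROOT]
    skew = {t: float(np.round(rng.uniform(0.5, 2.0), 6)) for t in ontology["term_id"]}

    scores: dict[tuple[str, str], float] = {}
    for g in universe.genes:
        mod = universe.planted_module[g]
        if cfg.score_signal > 0:
            for t in char_terms[mod]:
                scores[(t, g)] = cfg.score_signal * float(rng.uniform(0.5, 1.5))
        if cfg.score_noise > 0 and cfg.noise_terms_per_gene > 0:
            picks = rng.choice(
                len(all_terms),
                size=min(cfg.noise_terms_per_gene, len(all_terms)),
                replace=False,
            )
            for idx in picks:
                t = all_terms[int(idx)]
                key = (t, g)
                if key not in scores:
                    scores[key] = cfg.score_noise * float(rng.uniform(0.5, 1.5))
    rows = [
        (t, g, round(s, 6), skew[t]) for (t, g), s in sorted(scores.items())
    ]
    return pd.DataFrame(rows, columns=["term_id", "gene", "score", "skew"])


@dataclass(frozen=True)
class SimulatedBundle:
    """All four simulated inputs plus the configuration that produced them."""

    config: SimulationConfig
    universe: GeneUniverse
    ppi_edges: pd.DataFrame
    ontology: pd.DataFrame
    scores: pd.DataFrame


def simulate_bundle(cfg: SimulationConfig | None = None, **overrides) -> SimulatedBundle:
    """Generate a complete, internally consistent input bundle."""
    if cfg is None:
        cfg = SimulationConfig(**overrides)
    elif overrides:
        cfg = replace(cfg, **overrides)
    universe = generate_universe(cfg)
    return SimulatedBundle(
        config=cfg,
        universe=universe,
        ppi_edges=generate_ppi_edges(universe, cfg),
        ontology=generate_ontology(cfg),
        scores=generate_scores(universe, generate_ontology(cfg), cfg),
    )
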