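"""Module characterization: gene-group and phenotype enrichment with FDR.

Gene-group enrichment asks whether a module holds more members of a named
gene set (a disease subgroup, the common genes, a WES list, ...) than a
random draw of the same size from the background would, with an
upper-tail hypergeometric p-value.  Two backgrounds are supported: the
network's own gene universe, or a configurable genome-scale count
(default 19,556 genes).

Phenotype enrichment comes in two flavours: an empirical test comparing
the module's mean gene-phenotype association score for a term against
means of random same-size draws (add-one estimator, draws without
replacement), and a hypergeometric variant over annotated term-gene sets.
Benjamini-Hochberg correction is applied within each test family (all
rows of one panel).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GeneUniverse, Partition
from .ontology import subtree_terms

#: genome-scale background size (count of genes in the PPI source database)
DEFAULT_GENOME_BACKGROUND = 19_556

RESULT_COLUMNS = [
    "module",
    "target",
    "k",
    "K",
    "n",
    "N",
    "statistic",
    "p",
    "fdr",
    "background",
    "mode",
    "stars",
]


@dataclass
class EnrichmentResult:
    """One enrichment row: a module tested against one gene group or term."""

    module: int
    target: str
    k: float
    K: float
    n: int
    N: int
    statistic: float
    p: float
    fdr: float = float("nan")
    background: str = "network"
    mode: str = "hypergeom"
    stars: str = ""


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(pvals: Iterable[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = list(pvals)
    if not p:
        return []
    if any(not (0 < x <= 1) for x in p):
        raise ValueError("p-values must lie in (0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def significance_stars(fdr: float) -> str:
    """The star bands used on enrichment panels."""
    if fdr < 1e-4:
        return "****"
    if fdr < 0.01:
        return "***"
    if fdr < 0.05:
        return "**"
    if fdr < 0.1:
        return "*"
    return ""


def _finalize(rows: list[EnrichmentResult]) -> pd.DataFrame:
    qs = bh_fdr([r.p for r in rows])
    for r, q in zip(rows, qs):
        r.fdr = float(q)
        r.stars = significance_stars(r.fdr)
    df = pd.DataFrame([asdict(r) for r in rows], columns=RESULT_COLUMNS)
    return df


def gene_group_enrichment(
    partition: Partition,
    universe: GeneUniverse,
    groups: Mapping[str, frozenset[str]] | None = None,
    background: str = "network",
    module_ids: Iterable[int] | None = None,
    genome_size: int = DEFAULT_GENOME_BACKGROUND,
) -> pd.DataFrame:
    """Hypergeometric enrichment of every gene group in every module.

    ``background="network"`` uses the universe itself (N = universe size);
    ``background="genome"`` uses ``genome_size`` as N with module and
    group counts unchanged.  FDR is corrected across all rows of the
    panel.
    """
    if groups is None:
        groups = universe.gene_groups()
    if module_ids is None:
        module_ids = partition.module_ids()
    net_genes = set(universe.genes)
    if background == "network":
        N = len(net_genes)
    elif background == "genome":
        N = int(genome_size)
    else:
        raise ValueError(f"unknown background {background!r}")

    rows: list[EnrichmentResult] = []
    for mod in module_ids:
        members = partition.members(mod) & net_genes
        n = len(members)
        for name, group in sorted(groups.items()):
            group_in = set(group) & net_genes
            K = len(group_in)
            if K > N:
                raise ValueError(f"group {name!r} larger than background")
            k = len(members & group_in)
            rows.append(
                EnrichmentResult(
                    module=mod,
                    target=name,
                    k=k,
                    K=K,
                    n=n,
                    N=N,
                    statistic=float(k),
                    p=hypergeom_p(k, K, n, N),
                    background=background,
                )
            )
    return _finalize(rows)


def hpo_subtree(ontology: pd.DataFrame, root: str) -> frozenset[str]:
    """The term set of the subtree rooted at ``root`` (root + descendants)."""
    return subtree_terms(ontology, root)


def term_score_map(scores: pd.DataFrame, term_id: str) -> dict[str, float]:
    sub = scores[scores["term_id"] == term_id]
    return dict(zip(sub["gene"], sub["score"].astype(float)))


def phenotype_score_enrichment(
    module_genes: Iterable[str],
    term_id: str,
    scores: pd.DataFrame,
    background_genes: Iterable[str],
    n_trials: int = 10_000,
    seed: int | np.random.Generator = 0,
    background_label: str = "network",
) -> EnrichmentResult:
    """Empirical mean-score enrichment of one term in one module.

    The statistic is the mean association score of the module's genes for
    the term (genes without a score row count 0).  The null draws
    |module| genes uniformly without replacement from the background,
    n_trials times; p = (1 + #{trial mean >= observed}) / (1 + n_trials).
    """
    module = sorted(set(module_genes))
    bg = sorted(set(background_genes))
    if not module:
        raise ValueError("module is empty")
    if not set(module) <= set(bg):
        raise ValueError("module genes must lie in the background")
    if n_trials < 100:
        raise ValueError("empirical mode needs n_trials >= 100")

    smap = term_score_map(scores, term_id)
    if not smap:
        raise ValueError(f"term {term_id!r} has no score rows")
    values = np.array([smap.get(g, 0.0) for g in bg])
    idx = {g: i for i, g in enumerate(bg)}
    observed = float(np.mean([values[idx[g]] for g in module]))

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    size = len(module)
    trial_means = np.empty(n_trials)
    for t in range(n_trials):
        draw = rng.choice(len(bg), size=size, replace=False)
        trial_means[t] = values[draw].mean()
    p = float((1 + int(np.sum(trial_means >= observed))) / (1 + n_trials))

    return EnrichmentResult(
        module=-1,
        target=term_id,
        k=float("nan"),
        K=float("nan"),
        n=size,
        N=len(bg),
        statistic=observed,
        p=p,
        background=background_label,
        mode="empirical_score",
    )


def phenotype_score_panel(
    partition: Partition,
    module_ids: Iterable[int],
    term_ids: Iterable[str],
    scores: pd.DataFrame,
    background_genes: Iterable[str],
    n_trials: int = 10_000,
    seed: int = 0,
    background_label: str = "network",
) -> pd.DataFrame:
    """Empirical phenotype enrichment over a module x term panel, with BH
    correction across all rows of the panel."""
    rows: list[EnrichmentResult] = []
    rng = np.random.default_rng(seed)
    for mod in module_ids:
        members = partition.members(mod)
        for term in term_ids:
            r = phenotype_score_enrichment(
                members,
                term,
                scores,
                background_genes,
                n_trials=n_trials,
                seed=rng,
                background_label=background_label,
            )
            r.module = mod
            rows.append(r)
    return _finalize(rows)


def annotated_term_enrichment(
    module_genes: Iterable[str],
    term_annotations: Mapping[str, Iterable[str]],
    background_genes: Iterable[str],
    module_id: int = -1,
    background_label: str = "network",
) -> pd.DataFrame:
    """Hypergeometric enrichment of annotated term-gene sets in a module.

    FDR is corrected across the tested terms.
    """
    module = set(module_genes)
    bg = set(background_genes)
    if not module <= bg:
        raise ValueError("module genes must lie in the background")
    rows: list[EnrichmentResult] = []
    for term in sorted(term_annotations):
        annotated = set(term_annotations[term]) & bg
        k = len(module & annotated)
        rows.append(
            EnrichmentResult(
                module=module_id,
                target=term,
                k=k,
                K=len(annotated),
                n=len(module),
                N=len(bg),
                statistic=float(k),
                p=hypergeom_p(k, len(annotated), len(module), len(bg)),
                background=background_label,
                mode="annotated_hypergeom",
            )
        )
    if not rows:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    return _finalize(rows)


def annotation_set_enrichment(
    module_genes: Iterable[str],
    named_sets: Mapping[str, Iterable[str]],
    background_genes: Iterable[str],
    module_id: int = -1,
) -> pd.DataFrame:
    """Enrichment of arbitrary user-supplied annotation sets in a module.

    Generic replacement for external GO/pathway services: mechanics are
    identical to annotated-term enrichment over named gene sets.
    """
    df = annotated_term_enrichment(
        module_genes, named_sets, background_genes, module_id=module_id
    )
    if len(df):
        df["mode"] = "annotation_set"
    return df
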