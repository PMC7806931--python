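"""Candidate-gene prioritization: centrality ranking, cross-network module
matching, and the candidate rules.

Genes inside a disease-A-focused module that carry only the disease-B
label are candidate disease-A genes: they sit in a module enriched in
disease-A genes and phenotypes yet were never curated for disease A.  The
primary rule applies this filter to the overlap of the focused modules of
two networks; the secondary rule catches focused-module genes of the
smaller network whose module in the larger network is the *other*
prioritized module.

Centralities are per-layer degree and shortest-path betweenness
B(v) = sum_{s,t} sigma(s,t|v) / sigma(s,t), with sigma(s,t) = 1 when
s = t and sigma(s,t|v) = 0 when v is an endpoint.  The normalized mode
(default) divides by the number of eligible unordered pairs excluding v,
matching the scale of standard network tooling; the raw ordered-pair sum
of the formula is available via ``ordered_pairs=True`` and equals twice
the unnormalized unordered-pair value on undirected graphs.
"""

from __future__ import annotations

from typing import Iterable

import networkx as nx
import pandas as pd
from scipy import stats

from .containers import NO_LABEL, GeneUniverse, Layer, MultiplexNetwork, Partition


def betweenness(
    layer: Layer, normalized: bool = True, ordered_pairs: bool = False
) -> dict[str, float]:
    """Shortest-path betweenness per node.

    ``ordered_pairs=True`` returns the raw ordered-(s,t) sum of the
    betweenness formula (twice the undirected unordered-pair count) and
    ignores normalization.
    """
    g = layer.to_networkx()
    if ordered_pairs:
        raw = nx.betweenness_centrality(g, normalized=False)
        return {v: 2.0 * b for v, b in raw.items()}
    return dict(nx.betweenness_centrality(g, normalized=normalized))


def _annotation(universe: GeneUniverse, gene: str) -> str:
    parts = []
    e = universe.epilepsy_subgroup[gene]
    a = universe.autism_subgroup[gene]
    if e != NO_LABEL:
        parts.append(f"Epilepsy {e}")
    if a != NO_LABEL:
        parts.append(f"Autism {a}")
    return ", ".join(parts)


def centrality_table(
    net: MultiplexNetwork,
    module_genes: Iterable[str],
    normalized: bool = True,
) -> pd.DataFrame:
    """Per-layer degree and betweenness for the module's genes.

    Betweenness is computed on each full layer and then restricted to the
    module members; averages are plain arithmetic means of the two
    layers.  Ranks break ties deterministically by gene symbol.
    """
    module = sorted(set(module_genes))
    unknown = set(module) - set(net.universe.genes)
    if unknown:
        raise ValueError(f"genes outside the universe: {sorted(unknown)}")
    deg_ppi = net.ppi.degree()
    deg_phen = net.phenotype.degree()
    bc_ppi = betweenness(net.ppi, normalized=normalized)
    bc_phen = betweenness(net.phenotype, normalized=normalized)

    df = pd.DataFrame(
        {
            "gene": module,
            "ppi_degree": [deg_ppi[g] for g in module],
            "phen_degree": [deg_phen[g] for g in module],
            "ppi_bc": [bc_ppi[g] for g in module],
            "phen_bc": [bc_phen[g] for g in module],
            "annotation": [_annotation(net.universe, g) for g in module],
        }
    )
    df["avg_degree"] = (df["ppi_degree"] + df["phen_degree"]) / 2.0
    df["avg_bc"] = (df["ppi_bc"] + df["phen_bc"]) / 2.0
    df = df.sort_values(["avg_degree", "gene"], ascending=[False, True], kind="mergesort")
    df["rank_by_degree"] = range(1, len(df) + 1)
    order_bc = df.sort_values(
        ["avg_bc", "gene"], ascending=[False, True], kind="mergesort"
    )["gene"]
    bc_rank = {g: i for i, g in enumerate(order_bc, start=1)}
    df["rank_by_bc"] = df["gene"].map(bc_rank)
    return df.reset_index(drop=True)


def match_modules(pa: Partition, pb: Partition) -> pd.DataFrame:
    """Cross-partition module correspondence.

    For each module pair, counts the shared genes and the fraction of
    module-b genes (among those present in partition a's universe) that
    fall in module-a; flags the best match per module-b by maximal
    fraction (ties: more shared genes, then smaller module-a id).
    """
    a_genes = set(pa.assignment)
    rows = []
    for mb in pb.module_ids():
        members_b = pb.members(mb)
        in_a = members_b & a_genes
        denom = len(in_a)
        for ma in pa.module_ids():
            shared = in_a & pa.members(ma)
            if not shared:
                continue
            rows.append(
                {
                    "module_a": ma,
                    "module_b": mb,
                    "shared": len(shared),
                    "shared_genes": ",".join(sorted(shared)),
                    "frac_of_b_in_a": len(shared) / denom,
                    "best": False,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["module_a", "module_b", "shared", "shared_genes", "frac_of_b_in_a", "best"],
    )
    for mb, sub in df.groupby("module_b"):
        best_idx = sub.sort_values(
            ["frac_of_b_in_a", "shared", "module_a"],
            ascending=[False, False, True],
            kind="mergesort",
        ).index[0]
        df.loc[best_idx, "best"] = True
    return df.reset_index(drop=True)


def candidate_genes(
    overlap_genes: Iterable[str],
    universe: GeneUniverse,
    focus: str = "epilepsy",
) -> list[str]:
    """Disease-B-specific genes inside a disease-A-focused module overlap.

    With ``focus="epilepsy"`` this returns overlap genes that carry an
    autism label but no epilepsy label: plausible new epilepsy genes.
    ``focus="autism"`` flips the label test symmetrically.
    """
    if focus not in ("epilepsy", "autism"):
        raise ValueError("focus must be 'epilepsy' or 'autism'")
    out = []
    for g in sorted(set(overlap_genes)):
        e = universe.epilepsy_subgroup[g]
        a = universe.autism_subgroup[g]
        if focus == "epilepsy" and e == NO_LABEL and a != NO_LABEL:
            out.append(g)
        elif focus == "autism" and a == NO_LABEL and e != NO_LABEL:
            out.append(g)
    return out


def cross_module_candidates(
    focused_module_genes: Iterable[str],
    large_partition: Partition,
    other_module_id: int,
    universe: GeneUniverse,
    focus: str = "epilepsy",
) -> list[str]:
    """Secondary rule: disease-B-specific genes of the small network's
    focused module whose module in the large network is the *other*
    prioritized module (rather than the directly matched one)."""
    specific = set(candidate_genes(focused_module_genes, universe, focus=focus))
    return sorted(
        g
        for g in specific
        if g in large_partition.assignment
        and large_partition.assignment[g] == other_module_id
    )


def common_gene_centrality_test(
    net: MultiplexNetwork,
    metric: str = "avg_degree",
    normalized: bool = True,
) -> tuple[float, str]:
    """Two-sided rank-sum comparison of centrality: common vs specific genes.

    Returns (p-value, direction), direction being "common_higher" or
    "specific_higher" by mean rank.  Centrality defaults to the average
    of the two layer degrees; ``metric="avg_bc"`` uses betweenness.
    """
    universe = net.universe
    table = centrality_table(net, universe.genes, normalized=normalized)
    common = universe.common_genes
    values = dict(zip(table["gene"], table[metric]))
    x = [values[g] for g in universe.genes if g in common]
    y = [
        values[g]
        for g in universe.genes
        if g not in common
        and (
            universe.epilepsy_subgroup[g] != NO_LABEL
            or universe.autism_subgroup[g] != NO_LABEL
        )
    ]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 genes per class")
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    direction = (
        "common_higher"
        if res.statistic > len(x) * len(y) / 2.0
        else "specific_higher"
    )
    return float(res.pvalue), direction
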