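"""Core data containers shared across the pipeline.

The analysis operates on a fixed *gene universe* (the union of two disease
gene lists with subgroup labels), two node-aligned binary network layers
over that universe (protein-protein interaction and phenotype similarity),
and partitions of the universe into modules.  All containers are plain
dataclasses over hashable primitives so that pipeline outputs are
deterministic and serializable as flat tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import networkx as nx
import pandas as pd

#: marker used in ontology tables for the parent of the root term
ROOT_MARKER = "-"

#: subgroup label meaning "gene not on this disease list"
NO_LABEL = "none"

EPILEPSY_SUBGROUPS = ("1", "2", "3", "4")
AUTISM_SUBGROUPS = ("1", "2", "3", "S")

#: auxiliary gene-group names carried by the universe
AUX_GROUP_NAMES = ("WES_EPILEPSY", "WES_AUTISM", "BD", "SCZ", "ID", "BEG")


def canonical_edge(a: str, b: str) -> tuple[str, str]:
    """Return the unordered gene pair (a, b) in canonical sorted order."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class GeneUniverse:
    """The node set: genes with disease-subgroup and auxiliary labels.

    Parameters
    ----------
    genes
        Ordered unique gene symbols.
    epilepsy_subgroup, autism_subgroup
        Per-gene label; one of the subgroup codes or ``"none"``.
    aux_groups
        Named auxiliary gene sets (WES lists, other brain disorders,
        brain-enriched genes); each a subset of ``genes``.
    planted_module
        Ground-truth module per gene; present only for simulated data.
    """

    genes: tuple[str, ...]
    epilepsy_subgroup: Mapping[str, str]
    autism_subgroup: Mapping[str, str]
    aux_groups: Mapping[str, frozenset[str]] = field(default_factory=dict)
    planted_module: Optional[Mapping[str, int]] = None

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene symbols must be unique")
        gene_set = set(self.genes)
        for g in self.genes:
            if g not in self.epilepsy_subgroup or g not in self.autism_subgroup:
                raise ValueError(f"gene {g!r} missing a subgroup label")
        for name, members in self.aux_groups.items():
            if not set(members) <= gene_set:
                raise ValueError(f"aux group {name!r} is not a subset of the universe")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def epilepsy_genes(self) -> frozenset[str]:
        return frozenset(
            g for g in self.genes if self.epilepsy_subgroup[g] != NO_LABEL
        )

    @property
    def autism_genes(self) -> frozenset[str]:
        return frozenset(g for g in self.genes if self.autism_subgroup[g] != NO_LABEL)

    @property
    def common_genes(self) -> frozenset[str]:
        """Genes carrying both disease labels."""
        return self.epilepsy_genes & self.autism_genes

    def subgroup(self, disease: str, code: str) -> frozenset[str]:
        labels = (
            self.epilepsy_subgroup if disease == "epilepsy" else self.autism_subgroup
        )
        return frozenset(g for g in self.genes if labels[g] == code)

    def gene_groups(self) -> dict[str, frozenset[str]]:
        """All named gene groups used in module enrichment panels."""
        groups: dict[str, frozenset[str]] = {}
        for code in EPILEPSY_SUBGROUPS:
            groups[f"EPILEPSY_{code}"] = self.subgroup("epilepsy", code)
        for code in AUTISM_SUBGROUPS:
            groups[f"AUTISM_{code}"] = self.subgroup("autism", code)
        groups["COMMON_ALL"] = self.common_genes
        groups["COMMON_HC"] = self.subgroup("epilepsy", "1") & self.subgroup(
            "autism", "1"
        )
        for name, members in self.aux_groups.items():
            groups[name] = frozenset(members)
        if "WES_EPILEPSY" in self.aux_groups and "WES_AUTISM" in self.aux_groups:
            groups["COMMON_WES"] = frozenset(
                self.aux_groups["WES_EPILEPSY"] & self.aux_groups["WES_AUTISM"]
            )
        return groups

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.genes:
            row = {
                "gene": g,
                "epilepsy_subgroup": self.epilepsy_subgroup[g],
                "autism_subgroup": self.autism_subgroup[g],
            }
            for name in self.aux_groups:
                row[name] = int(g in self.aux_groups[name])
            if self.planted_module is not None:
                row["planted_module"] = self.planted_module[g]
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneUniverse":
        genes = tuple(df["gene"])
        epi = dict(zip(df["gene"], df["epilepsy_subgroup"].astype(str)))
        aut = dict(zip(df["gene"], df["autism_subgroup"].astype(str)))
        aux = {}
        for col in df.columns:
            if col in ("gene", "epilepsy_subgroup", "autism_subgroup", "planted_module"):
                continue
            aux[col] = frozenset(df.loc[df[col].astype(int) == 1, "gene"])
        planted = None
        if "planted_module" in df.columns:
            planted = dict(zip(df["gene"], df["planted_module"].astype(int)))
        return cls(genes, epi, aut, aux, planted)


@dataclass(frozen=True)
class Layer:
    """An undirected simple graph with unit edge weights over the full universe.

    Every universe gene is a node even when isolated: genes absent from the
    PPI source are kept as degree-zero nodes because they may be connected
    in the phenotype layer.
    """

    name: str
    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if (a, b) != canonical_edge(a, b):
                raise ValueError(f"edge {(a, b)!r} not in canonical order")
            if a not in node_set or b not in node_set:
                raise ValueError(f"edge {(a, b)!r} references unknown gene")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self) -> dict[str, int]:
        deg = {g: 0 for g in self.nodes}
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_edges(
        cls, name: str, nodes: Iterable[str], edges: Iterable[tuple[str, str]]
    ) -> "Layer":
        return cls(
            name,
            tuple(nodes),
            frozenset(canonical_edge(a, b) for a, b in edges if a != b),
        )


@dataclass(frozen=True)
class MultiplexNetwork:
    """Two node-aligned layers with per-layer modularity weights.

    The inter-layer coupling (each gene linked to its own copy in the other
    layer) is represented implicitly: community detection optimizes one
    shared partition across layers, which is exactly the coupled objective.
    """

    universe: GeneUniverse
    ppi: Layer
    phenotype: Layer
    layer_weights: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        if set(self.ppi.nodes) != set(self.phenotype.nodes):
            raise ValueError("layer node sets differ")
        if set(self.ppi.nodes) != set(self.universe.genes):
            raise ValueError("layer nodes do not match the universe")
        if any(w < 0 for w in self.layer_weights) or sum(self.layer_weights) == 0:
            raise ValueError("layer weights must be nonnegative, not both zero")

    @property
    def layers(self) -> tuple[Layer, Layer]:
        return (self.ppi, self.phenotype)

    def n_active_nodes(self) -> int:
        """Count genes with degree >= 1 in at least one layer."""
        d1 = self.ppi.degree()
        d2 = self.phenotype.degree()
        return sum(1 for g in self.universe.genes if d1[g] > 0 or d2[g] > 0)


@dataclass(frozen=True)
class Partition:
    """Node-to-module assignment with size-ordered contiguous module ids.

    Modules are renumbered 1..k by decreasing size, ties broken by the
    lexicographically smallest member symbol, so module numbering is stable
    across runs and platforms.
    """

    assignment: Mapping[str, int]
    quality: float = float("nan")
    params: Optional["object"] = None
    per_layer_quality: Optional[tuple[float, ...]] = None

    @classmethod
    def from_membership(
        cls,
        membership: Mapping[str, int],
        quality: float = float("nan"),
        params: Optional[object] = None,
        per_layer_quality: Optional[tuple[float, ...]] = None,
    ) -> "Partition":
        groups: dict[int, list[str]] = {}
        for gene, mod in membership.items():
            groups.setdefault(mod, []).append(gene)
        ordered = sorted(
            groups.values(), key=lambda members: (-len(members), min(members))
        )
        assignment = {}
        for new_id, members in enumerate(ordered, start=1):
            for gene in members:
                assignment[gene] = new_id
        return cls(assignment, quality, params, per_layer_quality)

    def module_ids(self) -> list[int]:
        return sorted(set(self.assignment.values()))

    def members(self, module_id: int) -> frozenset[str]:
        return frozenset(g for g, m in self.assignment.items() if m == module_id)

    def sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for m in self.assignment.values():
            sizes[m] = sizes.get(m, 0) + 1
        return sizes

    def labels(self, order: Iterable[str]) -> list[int]:
        return [self.assignment[g] for g in order]
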