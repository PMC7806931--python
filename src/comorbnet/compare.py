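"""Concordance statistics between the PPI and phenotype layers.

If the two layers carry consistent information, their edge sets overlap
and their community structures agree more than expected for random
networks with the same degree sequences.  Nulls are built by
degree-preserving double-edge-swap rewiring (10 x |E| swaps per trial,
which preserves every node's degree exactly); empirical p-values use the
add-one estimator p = (1 + #{null >= observed}) / (1 + n_trials), so they
are never exactly zero and the floor at n trials is 1/(n+1).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
from scipy import stats
from sklearn.metrics import normalized_mutual_info_score

from .community import ModularityParams, louvain_single
from .containers import Layer, Partition

#: swaps per rewiring trial, as a multiple of the edge count
SWAP_FACTOR = 10


@dataclass(frozen=True)
class NullEnsembleResult:
    """An observed statistic against a randomized-network null ensemble."""

    observed: float
    null_values: tuple[float, ...]
    empirical_p: float
    metadata: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.null_values)

    def to_dict(self) -> dict:
        nulls = np.asarray(self.null_values, dtype=float)
        return {
            "observed": self.observed,
            "n_trials": self.n_trials,
            "empirical_p": self.empirical_p,
            "null_quantiles": {
                q: float(np.quantile(nulls, float(q)))
                for q in ("0.05", "0.5", "0.95")
            }
            if len(nulls)
            else {},
            **self.metadata,
        }


def empirical_p(observed: float, null_values) -> float:
    nulls = np.asarray(list(null_values), dtype=float)
    return float((1 + int(np.sum(nulls >= observed))) / (1 + len(nulls)))


def degree_distribution(layer: Layer) -> dict[int, int]:
    """Histogram of node degrees; counts sum to the node count."""
    hist: dict[int, int] = {}
    for d in layer.degree().values():
        hist[d] = hist.get(d, 0) + 1
    return hist


def _to_igraph(layer: Layer, node_index: dict[str, int]) -> ig.Graph:
    edges = [(node_index[a], node_index[b]) for a, b in layer.edges]
    return ig.Graph(n=len(node_index), edges=edges, directed=False)


def _edge_set(g: ig.Graph) -> frozenset[tuple[int, int]]:
    return frozenset(
        (e.source, e.target) if e.source < e.target else (e.target, e.source)
        for e in g.es
    )


def rewired_layer(layer: Layer, seed: int, swap_factor: int = SWAP_FACTOR) -> Layer:
    """One degree-preserving randomization of a layer (double-edge swaps)."""
    nodes = layer.nodes
    node_index = {g: i for i, g in enumerate(nodes)}
    g = _to_igraph(layer, node_index)
    random.seed(seed)
    if g.ecount() >= 2:
        g.rewire(n=swap_factor * g.ecount(), mode="simple")
    return Layer.from_edges(
        layer.name, nodes, ((nodes[i], nodes[j]) for i, j in _edge_set(g))
    )


def edge_overlap_test(
    l1: Layer,
    l2: Layer,
    n_trials: int = 10000,
    seed: int = 0,
    swap_factor: int = SWAP_FACTOR,
) -> NullEnsembleResult:
    """Shared-edge count of the two layers vs degree-preserving nulls.

    Each trial independently rewires both layers and recounts the overlap.
    """
    if set(l1.nodes) != set(l2.nodes):
        raise ValueError("layers must share a node set")
    node_index = {g: i for i, g in enumerate(l1.nodes)}
    g1 = _to_igraph(l1, node_index)
    g2 = _to_igraph(Layer(l2.name, l1.nodes, l2.edges), node_index)
    e1, e2 = _edge_set(g1), _edge_set(g2)
    observed = float(len(e1 & e2))

    nulls = []
    for t in range(n_trials):
        random.seed(((seed + 1) * 1_000_003 + t) & 0x7FFFFFFF)
        r1, r2 = g1.copy(), g2.copy()
        if r1.ecount() >= 2:
            r1.rewire(n=swap_factor * r1.ecount(), mode="simple")
        if r2.ecount() >= 2:
            r2.rewire(n=swap_factor * r2.ecount(), mode="simple")
        nulls.append(float(len(_edge_set(r1) & _edge_set(r2))))

    return NullEnsembleResult(
        observed,
        tuple(nulls),
        empirical_p(observed, nulls),
        metadata={"statistic": "edge_overlap", "swap_factor": swap_factor},
    )


def partition_nmi(p1: Partition, p2: Partition, order) -> float:
    """Arithmetic-mean-normalized mutual information of two partitions."""
    return float(
        normalized_mutual_info_score(
            p1.labels(order), p2.labels(order), average_method="arithmetic"
        )
    )


def partition_nmi_test(
    l1: Layer,
    l2: Layer,
    n_trials: int = 1000,
    params: ModularityParams | None = None,
    seed: int = 0,
    null_restarts: int = 1,
    swap_factor: int = SWAP_FACTOR,
) -> NullEnsembleResult:
    """NMI between the layers' Louvain partitions vs rewired-layer nulls.

    The observed statistic clusters both layers with identical optimizer
    settings; each null trial rewires both layers (degrees preserved) and
    clusters the rewired graphs with ``null_restarts`` restarts.
    """
    if set(l1.nodes) != set(l2.nodes):
        raise ValueError("layers must share a node set")
    if params is None:
        params = ModularityParams()
    order = l1.nodes
    l2a = Layer(l2.name, order, l2.edges)

    p1 = louvain_single(l1, params)
    p2 = louvain_single(l2a, params)
    observed = partition_nmi(p1, p2, order)

    from dataclasses import replace

    null_params = replace(params, n_restarts=null_restarts)
    nulls = []
    for t in range(n_trials):
        r1 = rewired_layer(
            l1, seed=((seed + 1) * 2_000_003 + 2 * t) & 0x7FFFFFFF, swap_factor=swap_factor
        )
        r2 = rewired_layer(
            l2a, seed=((seed + 1) * 2_000_003 + 2 * t + 1) & 0x7FFFFFFF, swap_factor=swap_factor
        )
        q1 = louvain_single(r1, null_params)
        q2 = louvain_single(r2, null_params)
        nulls.append(partition_nmi(q1, q2, order))

    return NullEnsembleResult(
        observed,
        tuple(nulls),
        empirical_p(observed, nulls),
        metadata={
            "statistic": "partition_nmi",
            "nmi_normalization": "arithmetic",
            "gamma": params.gamma,
            "swap_factor": swap_factor,
        },
    )


def degree_correlation(l1: Layer, l2: Layer, method: str = "spearman") -> float:
    """Correlation of per-node degrees across the two layers.

    Spearman by default (degree distributions are heavy-tailed); Pearson
    available by flag.  Requires at least 3 nodes.
    """
    if set(l1.nodes) != set(l2.nodes):
        raise ValueError("layers must share a node set")
    if len(l1.nodes) < 3:
        raise ValueError("degree correlation undefined for fewer than 3 nodes")
    d1 = l1.degree()
    d2 = l2.degree()
    x = [d1[g] for g in l1.nodes]
    y = [d2[g] for g in l1.nodes]
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")
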