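"""Modularity and Louvain community detection, single-layer and multiplex.

The quality function is the resolution-parameterised Newman-Girvan
modularity

    H = (1/2m) * sum_c ( e_c - gamma * K_c^2 / (2m) )

where e_c is the within-community sum of adjacency entries (twice the
internal edge count), m the total edge count, K_c the summed degree of the
community and gamma the resolution parameter.  Under this convention the
whole-graph single-community partition scores exactly 0 at gamma = 1.

For the multiplex network one partition is shared by both layers and the
objective is the weighted sum of per-layer modularities,

    H = w_ppi * H_ppi + w_phenotype * H_phenotype,

with equal weights by default so both layers contribute equally.  The
optimizer is a multilevel Louvain: greedy local moves on the combined
per-layer gain followed by simultaneous aggregation of both layers, with
seeded restarts (seeds seed, seed+1, ..., seed+n_restarts-1; quality ties
keep the lowest seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import Layer, MultiplexNetwork, Partition

_EPS = 1e-12


@dataclass(frozen=True)
class ModularityParams:
    """Settings for modularity optimization.

    gamma is the primary resolution used for the reported partition;
    ``resolutions`` lists the gammas covered by a sweep (quality values at
    different gammas are not comparable, so the sweep is reported in full
    rather than collapsed to one winner).
    """

    gamma: float = 1.0
    layer_weights: tuple[float, float] = (0.5, 0.5)
    n_restarts: int = 20
    resolutions: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if any(w < 0 for w in self.layer_weights) or sum(self.layer_weights) == 0:
            raise ValueError("layer weights must be nonnegative, not both zero")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be positive")


def modularity(layer: Layer, partition: Partition, gamma: float = 1.0) -> float:
    """Evaluate H for one layer; defined as 0 on an empty layer."""
    m = layer.n_edges
    if m == 0:
        return 0.0
    two_m = 2.0 * m
    deg = layer.degree()
    internal: dict[int, float] = {}
    ktot: dict[int, float] = {}
    for g in layer.nodes:
        c = partition.assignment[g]
        ktot[c] = ktot.get(c, 0.0) + deg[g]
        internal.setdefault(c, 0.0)
    for a, b in layer.edges:
        if partition.assignment[a] == partition.assignment[b]:
            internal[partition.assignment[a]] += 2.0
    return sum(
        (internal[c] - gamma * ktot[c] ** 2 / two_m) for c in internal
    ) / two_m


def multiplex_modularity(
    net: MultiplexNetwork, partition: Partition, params: ModularityParams
) -> float:
    """Weighted sum of per-layer modularities under one shared partition."""
    w_ppi, w_phen = params.layer_weights
    return w_ppi * modularity(net.ppi, partition, params.gamma) + w_phen * modularity(
        net.phenotype, partition, params.gamma
    )


# ---------------------------------------------------------------------------
# Louvain engine over an arbitrary list of weighted layers
# ---------------------------------------------------------------------------


def _layer_arrays(layer: Layer, node_index: dict[str, int]):
    n = len(node_index)
    neigh: list[dict[int, float]] = [dict() for _ in range(n)]
    for a, b in layer.edges:
        i, j = node_index[a], node_index[b]
        neigh[i][j] = neigh[i].get(j, 0.0) + 1.0
        neigh[j][i] = neigh[j].get(i, 0.0) + 1.0
    return neigh


def _louvain_run(
    layer_neighs: list[list[dict[int, float]]],
    weights: list[float],
    gamma: float,
    rng: np.random.Generator,
) -> list[int]:
    """One full multilevel Louvain pass; returns a membership per node."""
    n0 = len(layer_neighs[0])
    n_layers = len(layer_neighs)

    neighs = [[dict(d) for d in ln] for ln in layer_neighs]
    selfw = [[0.0] * n0 for _ in range(n_layers)]
    mapping = list(range(n0))  # original node -> current aggregated node

    # per-layer total degree (2m), fixed across levels
    m2 = []
    for ln in neighs:
        m2.append(sum(sum(d.values()) for d in ln))
    active = [l for l in range(n_layers) if m2[l] > 0 and weights[l] > 0]

    while True:
        n = len(neighs[0])
        deg = [
            [sum(neighs[l][i].values()) + 2.0 * selfw[l][i] for i in range(n)]
            for l in range(n_layers)
        ]
        comm = list(range(n))
        sigma = [list(deg[l]) for l in range(n_layers)]

        moved_any = False
        improving = True
        passes = 0
        while improving and passes < 200:
            improving = False
            passes += 1
            for i in rng.permutation(n):
                i = int(i)
                a = comm[i]
                # weights to neighbouring communities per layer
                cand: set[int] = {a}
                w2c = [dict() for _ in range(n_layers)]
                for l in active:
                    for j, w in neighs[l][i].items():
                        c = comm[j]
                        w2c[l][c] = w2c[l].get(c, 0.0) + w
                        cand.add(c)
                # remove i from its community
                for l in active:
                    sigma[l][a] -= deg[l][i]
                best_c, best_gain = a, -np.inf
                for c in sorted(cand):
                    gain = 0.0
                    for l in active:
                        gain += (
                            weights[l]
                            * 2.0
                            / m2[l]
                            * (
                                w2c[l].get(c, 0.0)
                                - gamma * deg[l][i] * sigma[l][c] / m2[l]
                            )
                        )
                    if gain > best_gain + _EPS:
                        best_c, best_gain = c, gain
                for l in active:
                    sigma[l][best_c] += deg[l][i]
                if best_c != a:
                    comm[i] = best_c
                    improving = True
                    moved_any = True

        if not moved_any:
            break

        # compact community labels and aggregate all layers simultaneously
        labels = sorted(set(comm))
        relabel = {c: k for k, c in enumerate(labels)}
        comm = [relabel[c] for c in comm]
        nc = len(labels)
        new_neighs = [[dict() for _ in range(nc)] for _ in range(n_layers)]
        new_selfw = [[0.0] * nc for _ in range(n_layers)]
        for l in range(n_layers):
            for i in range(n):
                ci = comm[i]
                new_selfw[l][ci] += selfw[l][i]
                for j, w in neighs[l][i].items():
                    if j < i:
                        continue
                    cj = comm[j]
                    if ci == cj:
                        new_selfw[l][ci] += w
                    else:
                        d = new_neighs[l][ci]
                        d[cj] = d.get(cj, 0.0) + w
                        new_neighs[l][cj][ci] = d[cj]
        neighs, selfw = new_neighs, new_selfw
        mapping = [comm[x] for x in mapping]
        if nc == n:
            break

    return mapping


def _optimize(
    layers: list[Layer],
    weights: list[float],
    params: ModularityParams,
    gamma: float,
) -> tuple[dict[str, int], float, tuple[float, ...]]:
    nodes = layers[0].nodes
    node_index = {g: i for i, g in enumerate(nodes)}
    layer_neighs = [_layer_arrays(l, node_index) for l in layers]

    best_membership = None
    best_quality = -np.inf
    for r in range(params.n_restarts):
        rng = np.random.default_rng(params.seed + r)
        membership = _louvain_run(layer_neighs, weights, gamma, rng)
        assignment = {g: membership[i] for i, g in enumerate(nodes)}
        part = Partition(assignment)
        quality = sum(
            w * modularity(l, part, gamma) for l, w in zip(layers, weights)
        )
        if quality > best_quality + 1e-12:
            best_quality = quality
            best_membership = assignment

    part = Partition(best_membership)
    per_layer = tuple(modularity(l, part, gamma) for l in layers)
    return best_membership, best_quality, per_layer


def louvain_single(layer: Layer, params: ModularityParams) -> Partition:
    """Best-of-restarts Louvain partition of one layer at params.gamma."""
    membership, quality, per_layer = _optimize([layer], [1.0], params, params.gamma)
    return Partition.from_membership(
        membership, quality, params, per_layer_quality=per_layer
    )


def louvain_multiplex(net: MultiplexNetwork, params: ModularityParams) -> Partition:
    """Shared partition maximizing the weighted multiplex modularity."""
    weights = list(params.layer_weights)
    membership, quality, per_layer = _optimize(
        [net.ppi, net.phenotype], weights, params, params.gamma
    )
    return Partition.from_membership(
        membership, quality, params, per_layer_quality=per_layer
    )


@dataclass(frozen=True)
class SweepEntry:
    gamma: float
    quality: float
    n_modules: int
    per_layer_quality: tuple[float, ...]
    partition: Partition = field(repr=False)


def resolution_sweep(
    obj: Layer | MultiplexNetwork, params: ModularityParams
) -> list[SweepEntry]:
    """Run the optimizer at every gamma in ``params.resolutions``.

    Quality values at different gammas are not mutually comparable; the
    caller reports the sweep and designates the partition at the primary
    gamma (params.gamma) as the headline result.
    """
    entries = []
    for gamma in params.resolutions:
        if isinstance(obj, MultiplexNetwork):
            layers, weights = [obj.ppi, obj.phenotype], list(params.layer_weights)
        else:
            layers, weights = [obj], [1.0]
        membership, quality, per_layer = _optimize(layers, weights, params, gamma)
        part = Partition.from_membership(membership, quality, params, per_layer)
        entries.append(
            SweepEntry(gamma, quality, len(part.module_ids()), per_layer, part)
        )
    return entries


def filter_modules(
    partition: Partition, min_size: int = 2, keep_top: int | None = None
) -> list[int]:
    """Module ids with at least ``min_size`` genes, largest first.

    Module ids are already ordered by decreasing size, so the returned
    list is ascending in id; ``keep_top`` truncates to the largest few.
    """
    sizes = partition.sizes()
    kept = [m for m in sorted(sizes) if sizes[m] >= min_size]
    if keep_top is not None:
        kept = kept[:keep_top]
    return kept
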