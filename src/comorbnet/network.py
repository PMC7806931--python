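"""Construction of the PPI layer, the phenotype-similarity layer, and the
node-aligned multiplex network.

The PPI layer keeps STRING-style edges at or above a combined-confidence
threshold (default 700, the customary "high confidence" cut) and binarizes
them.  The phenotype layer links two genes when the cosine similarity of
their skew-weighted phenotype vectors exceeds a per-pair permutation
threshold: the rank-th largest of ``n_shuffles`` similarities computed
after independently permuting the entries of both vectors (defaults 10 of
1000, a nominal tail probability of 0.01).  Both layers span the full gene
universe; genes missing from one source stay as degree-zero nodes so they
can still be placed by the other layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import GeneUniverse, Layer, MultiplexNetwork, canonical_edge
from .ontology import subtree_terms


def build_ppi_layer(
    edges: pd.DataFrame,
    universe: GeneUniverse,
    min_confidence: int = 700,
) -> Layer:
    """Binary PPI layer from a (gene_a, gene_b, combined_score) table.

    An edge is kept iff both genes belong to the universe and the score is
    at least ``min_confidence``.  Raises a parse error naming the row when
    a score is not numeric.
    """
    required = {"gene_a", "gene_b", "combined_score"}
    if not required <= set(edges.columns):
        raise ValueError(f"edge table missing columns {sorted(required - set(edges.columns))}")
    scores = pd.to_numeric(edges["combined_score"], errors="coerce")
    bad = scores.isna()
    if bad.any():
        line = int(bad.idxmax())
        raise ValueError(f"malformed combined_score at row {line}")
    in_universe = set(universe.genes)
    kept = []
    for a, b, s in zip(edges["gene_a"], edges["gene_b"], scores):
        if a in in_universe and b in in_universe and a != b and s >= min_confidence:
            kept.append(canonical_edge(a, b))
    return Layer("ppi", universe.genes, frozenset(kept))


def top_k_filter(scores: pd.DataFrame, k: int) -> pd.DataFrame:
    """Keep, per term, only the k highest-scoring gene rows.

    All rows tied with the k-th score are kept, so the output is invariant
    to the input order of tied rows.
    """
    if k < 1:
        raise ValueError("k must be >= 1")

    def _keep(group: pd.DataFrame) -> pd.DataFrame:
        if len(group) <= k:
            return group
        cutoff = group["score"].nlargest(k).iloc[-1]
        return group[group["score"] >= cutoff]

    out = (
        scores.groupby("term_id", group_keys=False, sort=False)[scores.columns]
        .apply(_keep)
        .reset_index(drop=True)
    )
    return out


@dataclass(frozen=True)
class PhenotypeVectors:
    """Skew-weighted phenotype vectors for every gene over a shared term index."""

    terms: tuple[str, ...]
    vectors: Mapping[str, np.ndarray]

    def __getitem__(self, gene: str) -> np.ndarray:
        return self.vectors[gene]


def build_phenotype_vectors(
    scores: pd.DataFrame,
    ontology: pd.DataFrame,
    root: str,
    universe: GeneUniverse | None = None,
) -> PhenotypeVectors:
    """Per-gene vectors of score x skew over terms in the subtree of ``root``.

    Terms outside the root's subtree are excluded entirely; genes with no
    scored term (or not present in the score table) get all-zero vectors.
    """
    retained = subtree_terms(ontology, root)
    terms = tuple(sorted(retained))
    index = {t: i for i, t in enumerate(terms)}
    genes = universe.genes if universe is not None else tuple(sorted(set(scores["gene"])))
    vectors = {g: np.zeros(len(terms)) for g in genes}
    for t, g, s, w in zip(
        scores["term_id"], scores["gene"], scores["score"], scores["skew"]
    ):
        if t in index and g in vectors:
            vectors[g][index[t]] = float(s) * float(w)
    return PhenotypeVectors(terms, vectors)


def phenotype_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity for nonnegative vectors; 0 when either is all-zero."""
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def permutation_threshold(
    u: np.ndarray,
    v: np.ndarray,
    n_shuffles: int = 1000,
    rank: int = 10,
    seed: int | np.random.Generator = 0,
    joint: bool = False,
    exhaustive: bool = False,
) -> float:
    """Rank-th largest similarity over shuffles of the two vectors.

    Each trial independently permutes the entries of both vectors and
    recomputes the cosine similarity; the returned threshold has empirical
    tail probability rank/n_shuffles.  ``joint=True`` applies one shared
    permutation to both vectors per trial (a degenerate null: similarity
    is then permutation-invariant).  ``exhaustive=True`` enumerates all
    ordered permutation pairs instead of sampling (only for short
    vectors); ``rank`` then indexes into the exact null.

    Returns +inf when either vector is all-zero, so no edge can ever be
    added for such a pair.
    """
    if not exhaustive and not (n_shuffles >= rank >= 1):
        raise ValueError("need n_shuffles >= rank >= 1")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return float("inf")

    if exhaustive:
        if joint:
            # one shared permutation leaves the dot product unchanged
            n_perms = math.factorial(u.size)
            sims = [float(np.dot(u, v))] * n_perms
        else:
            sims = [
                float(np.dot(np.asarray(pu), np.asarray(pv)))
                for pu in permutations(u)
                for pv in permutations(v)
            ]
        sims = np.sort(np.asarray(sims) / (nu * nv))
        if rank > len(sims):
            raise ValueError("rank exceeds the exhaustive null size")
        return float(sims[-rank])

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if joint:
        # one shared permutation per trial leaves the similarity unchanged
        sims = np.full(n_shuffles, np.dot(u, v) / (nu * nv))
        return float(np.sort(sims)[-rank])

    # Independent permutations of two nonnegative vectors only interact on
    # the positions where both permuted supports coincide: the overlap size
    # is hypergeometric in the support sizes, and given the overlap the
    # contributing values are uniform random subsets of each support, paired
    # at random.  Sampling that directly is distribution-identical to
    # permuting the full vectors and far cheaper for sparse vectors.
    d = u.size
    u_nz = u[u != 0.0]
    v_nz = v[v != 0.0]
    su, sv = u_nz.size, v_nz.size
    mmax = min(su, sv)
    overlap = rng.hypergeometric(su, d - su, sv, size=n_shuffles)
    pu = rng.permuted(np.tile(u_nz, (n_shuffles, 1)), axis=1)[:, :mmax]
    pv = rng.permuted(np.tile(v_nz, (n_shuffles, 1)), axis=1)[:, :mmax]
    csum = np.cumsum(pu * pv, axis=1)
    sims = np.where(overlap > 0, csum[np.arange(n_shuffles), np.maximum(overlap, 1) - 1], 0.0)
    sims = sims / (nu * nv)
    return float(np.sort(sims)[-rank])


def build_phenotype_layer(
    vectors: PhenotypeVectors,
    universe: GeneUniverse,
    n_shuffles: int = 1000,
    rank: int = 10,
    seed: int = 0,
    joint: bool = False,
) -> Layer:
    """Phenotype-similarity layer: edge iff similarity strictly exceeds the
    per-pair permutation threshold.

    The comparison is strict, so a pair whose null is degenerate at the
    observed value (e.g. constant vectors) is never linked.  The per-pair
    RNG is derived from (seed, sorted gene indices) so the layer is
    reproducible and independent of pair evaluation order.
    """
    genes = universe.genes
    order = {g: i for i, g in enumerate(sorted(genes))}
    edges = []
    for i, a in enumerate(genes):
        ua = vectors[a]
        for b in genes[i + 1 :]:
            sim = phenotype_similarity(ua, vectors[b])
            if sim <= 0.0:
                continue
            x, y = canonical_edge(a, b)
            rng = np.random.default_rng([int(seed), order[x], order[y]])
            thr = permutation_threshold(
                vectors[x], vectors[y], n_shuffles, rank, rng, joint=joint
            )
            if sim > thr:
                edges.append((x, y))
    return Layer("phenotype", genes, frozenset(edges))


def assemble_multiplex(
    ppi: Layer,
    phenotype: Layer,
    universe: GeneUniverse,
    weights: tuple[float, float] = (0.5, 0.5),
) -> MultiplexNetwork:
    """Stack the two layers into a node-aligned multiplex network.

    Layers may arrive with different node orders; they are realigned to
    the universe order.  A node-set mismatch raises an alignment error.
    """
    if set(ppi.nodes) != set(phenotype.nodes) or set(ppi.nodes) != set(universe.genes):
        raise ValueError("node sets differ between layers and universe")
    ppi_aligned = Layer(ppi.name, universe.genes, ppi.edges)
    phen_aligned = Layer(phenotype.name, universe.genes, phenotype.edges)
    return MultiplexNetwork(universe, ppi_aligned, phen_aligned, weights)
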