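"""Layer construction: thresholding, phenotype vectors, the permutation
null and the multiplex assembly."""

import math
from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comorbnet.containers import GeneUniverse, Layer, NO_LABEL
from comorbnet.network import (
    PhenotypeVectors,
    assemble_multiplex,
    build_phenotype_layer,
    build_phenotype_vectors,
    build_ppi_layer,
    permutation_threshold,
    phenotype_similarity,
    top_k_filter,
)
from comorbnet.containers import ROOT_MARKER
from comorbnet.synthetic import ONTOLOGY_ROOT


def tiny_universe(symbols):
    return GeneUniverse(
        tuple(symbols),
        {g: NO_LABEL for g in symbols},
        {g: NO_LABEL for g in symbols},
    )


@pytest.fixture
def five_genes():
    return tiny_universe(["G1", "G2", "G3", "G4", "G5"])


class TestPPILayer:
    def test_confidence_boundary(self, five_genes):
        edges = pd.DataFrame(
            [("G1", "G2", 700), ("G1", "G3", 699)],
            columns=["gene_a", "gene_b", "combined_score"],
        )
        layer = build_ppi_layer(edges, five_genes)
        assert layer.edges == frozenset({("G1", "G2")})

    def test_empty_table_gives_isolated_nodes(self, five_genes):
        edges = pd.DataFrame(columns=["gene_a", "gene_b", "combined_score"])
        layer = build_ppi_layer(edges, five_genes)
        assert layer.n_edges == 0
        assert set(layer.nodes) == set(five_genes.genes)

    def test_unknown_genes_dropped(self, five_genes):
        edges = pd.DataFrame(
            [("G1", "ZZZ", 900)], columns=["gene_a", "gene_b", "combined_score"]
        )
        assert build_ppi_layer(edges, five_genes).n_edges == 0

    def test_malformed_score_names_row(self, five_genes):
        edges = pd.DataFrame(
            [("G1", "G2", 900), ("G1", "G3", "high")],
            columns=["gene_a", "gene_b", "combined_score"],
        )
        with pytest.raises(ValueError, match="row 1"):
            build_ppi_layer(edges, five_genes)

    def test_thresholding_is_monotone(self, five_genes):
        rng = np.random.default_rng(0)
        rows = [
            ("G%d" % (i + 1), "G%d" % (j + 1), int(rng.integers(150, 1000)))
            for i in range(5)
            for j in range(i + 1, 5)
        ]
        edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "combined_score"])
        previous = None
        for thr in (0, 400, 700, 900, 1000):
            layer = build_ppi_layer(edges, five_genes, min_confidence=thr)
            if previous is not None:
                assert layer.edges <= previous
            previous = layer.edges


class TestTopKFilter:
    def test_large_k_is_identity(self):
        df = pd.DataFrame(
            {"term_id": ["t"] * 3, "gene": list("abc"), "score": [5, 4, 3], "skew": 1.0}
        )
        pd.testing.assert_frame_equal(top_k_filter(df, 10), df)

    def test_keeps_k_highest(self):
        df = pd.DataFrame(
            {"term_id": ["t"] * 3, "gene": list("abc"), "score": [5, 4, 3], "skew": 1.0}
        )
        out = top_k_filter(df, 2)
        assert sorted(out["score"]) == [4, 5]

    def test_ties_at_rank_k_all_kept_and_order_invariant(self):
        df = pd.DataFrame(
            {"term_id": ["t"] * 3, "gene": list("abc"), "score": [5, 4, 4], "skew": 1.0}
        )
        out = top_k_filter(df, 2)
        assert len(out) == 3
        shuffled = df.iloc[[2, 0, 1]].reset_index(drop=True)
        out2 = top_k_filter(shuffled, 2)
        assert set(zip(out["gene"], out["score"])) == set(
            zip(out2["gene"], out2["score"])
        )

    def test_other_terms_untouched(self):
        df = pd.DataFrame(
            {
                "term_id": ["t1"] * 3 + ["t2"],
                "gene": list("abcd"),
                "score": [5, 4, 3, 1],
                "skew": 1.0,
            }
        )
        out = top_k_filter(df, 2)
        assert ("d" in set(out["gene"]))


def small_ontology():
    return pd.DataFrame(
        [
            ("R", ROOT_MARKER),
            ("A", "R"),
            ("B", "A"),
            ("C", "R"),
            ("X", "R"),
        ],
        columns=["term_id", "parent_id"],
    )


class TestPhenotypeVectors:
    def test_entry_is_score_times_skew(self):
        scores = pd.DataFrame(
            [("B", "g1", 2.0, 3.0)], columns=["term_id", "gene", "score", "skew"]
        )
        vecs = build_phenotype_vectors(scores, small_ontology(), "A")
        assert vecs.terms == ("A", "B")
        assert vecs["g1"].tolist() == [0.0, 6.0]

    def test_terms_outside_root_subtree_excluded(self):
        scores = pd.DataFrame(
            [("B", "g1", 2.0, 3.0), ("C", "g1", 9.0, 1.0)],
            columns=["term_id", "gene", "score", "skew"],
        )
        vecs = build_phenotype_vectors(scores, small_ontology(), "A")
        assert "C" not in vecs.terms
        assert vecs["g1"].sum() == 6.0

    def test_gene_without_scores_gets_zero_vector(self):
        scores = pd.DataFrame(
            [("B", "g1", 2.0, 3.0)], columns=["term_id", "gene", "score", "skew"]
        )
        u = tiny_universe(["G1"])  # no score rows for G1
        vecs = build_phenotype_vectors(scores, small_ontology(), "A", u)
        assert not vecs["G1"].any()

    def test_unknown_root_raises(self):
        scores = pd.DataFrame(columns=["term_id", "gene", "score", "skew"])
        with pytest.raises(KeyError):
            build_phenotype_vectors(scores, small_ontology(), "NOPE")


class TestCosine:
    def test_identity_and_orthogonality(self):
        u = np.array([1.0, 2.0, 0.0])
        assert phenotype_similarity(u, u) == pytest.approx(1.0)
        assert phenotype_similarity(
            np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 1.0])
        ) == 0.0

    def test_hand_computed_value(self):
        assert phenotype_similarity(
            np.array([1.0, 1.0, 0.0]), np.array([1.0, 0.0, 1.0])
        ) == pytest.approx(0.5)

    def test_zero_vector_defined_as_zero(self):
        assert phenotype_similarity(np.zeros(3), np.ones(3)) == 0.0

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(0, 100), min_size=2, max_size=6),
        st.lists(st.floats(0, 100), min_size=2, max_size=6),
    )
    def test_symmetric_and_bounded(self, xs, ys):
        n = min(len(xs), len(ys))
        u, v = np.array(xs[:n]), np.array(ys[:n])
        s = phenotype_similarity(u, v)
        assert s == phenotype_similarity(v, u)
        assert 0.0 <= s <= 1.0 + 1e-12


class TestPermutationThreshold:
    def test_constant_vectors_threshold_equals_observed(self):
        u = np.full(5, 2.0)
        v = np.full(5, 3.0)
        obs = phenotype_similarity(u, v)
        thr = permutation_threshold(u, v, n_shuffles=500, rank=5, seed=0)
        assert thr == pytest.approx(obs)

    def test_zero_vector_gives_infinite_threshold(self):
        assert math.isinf(permutation_threshold(np.zeros(4), np.ones(4)))

    def test_exhaustive_rank1_equals_enumerated_max(self):
        u = np.array([3.0, 1.0, 0.0])
        v = np.array([2.0, 0.0, 1.0])
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        enumerated = sorted(
            float(np.dot(pu, pv)) / (nu * nv)
            for pu in permutations(u)
            for pv in permutations(v)
        )
        assert len(enumerated) == 36
        thr = permutation_threshold(u, v, rank=1, exhaustive=True)
        assert thr == pytest.approx(enumerated[-1])

    def test_monte_carlo_converges_to_exhaustive_order_statistic(self):
        u = np.array([1.0, 2.0, 0.0, 0.5])
        v = np.array([0.0, 1.0, 3.0, 0.0])
        exact_max = permutation_threshold(u, v, rank=1, exhaustive=True)
        exact_med = permutation_threshold(u, v, rank=288, exhaustive=True)
        mc_max = permutation_threshold(u, v, n_shuffles=4000, rank=1, seed=0)
        mc_med = permutation_threshold(u, v, n_shuffles=4000, rank=2000, seed=0)
        assert mc_max == pytest.approx(exact_max)
        assert mc_med == pytest.approx(exact_med, abs=0.05)

    def test_nominal_tail_probability(self):
        # threshold is the rank-th largest of the null, so with distinct
        # null values its empirical tail probability is rank/n
        u = np.array([1.0, 2.0, 3.0, 4.0])
        v = np.array([4.0, 1.0, 2.0, 3.0])
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        null = np.sort(
            [
                float(np.dot(pu, pv)) / (nu * nv)
                for pu in permutations(u)
                for pv in permutations(v)
            ]
        )
        rank = 10
        thr = permutation_threshold(u, v, rank=rank, exhaustive=True)
        tail = np.mean(null >= thr)
        assert tail * len(null) >= rank  # at least `rank` values in the tail

    def test_invalid_rank_rejected(self):
        with pytest.raises(ValueError):
            permutation_threshold(np.ones(3), np.ones(3), n_shuffles=5, rank=6)


class TestPhenotypeLayer:
    def test_all_zero_vectors_give_empty_layer(self):
        u = tiny_universe(["G1", "G2", "G3"])
        vecs = PhenotypeVectors(("t1", "t2"), {g: np.zeros(2) for g in u.genes})
        layer = build_phenotype_layer(vecs, u, n_shuffles=100, rank=1, seed=0)
        assert layer.n_edges == 0

    def test_identical_strong_vectors_are_linked(self):
        # two genes share one dominant term among many: observed similarity 1
        # beats any non-degenerate permuted alignment
        u = tiny_universe(["G1", "G2"])
        vec = np.array([10.0, 1.0, 0.5, 0.0, 0.0, 0.0, 0.0, 0.0])
        vecs = PhenotypeVectors(
            tuple(f"t{i}" for i in range(8)), {"G1": vec, "G2": vec.copy()}
        )
        layer = build_phenotype_layer(vecs, u, n_shuffles=500, rank=5, seed=0)
        assert layer.edges == frozenset({("G1", "G2")})

    def test_scale_invariance(self):
        u = tiny_universe(["G1", "G2", "G3"])
        rng = np.random.default_rng(1)
        base = {g: rng.uniform(0, 5, size=10) * (rng.random(10) < 0.4) for g in u.genes}
        vecs1 = PhenotypeVectors(tuple(f"t{i}" for i in range(10)), base)
        vecs2 = PhenotypeVectors(
            vecs1.terms, {g: 7.3 * v for g, v in base.items()}
        )
        l1 = build_phenotype_layer(vecs1, u, n_shuffles=300, rank=3, seed=5)
        l2 = build_phenotype_layer(vecs2, u, n_shuffles=300, rank=3, seed=5)
        assert l1.edges == l2.edges

    def test_node_order_invariance(self):
        symbols = ["G1", "G2", "G3", "G4"]
        rng = np.random.default_rng(2)
        base = {g: rng.uniform(0, 5, size=12) * (rng.random(12) < 0.4) for g in symbols}
        vecs = PhenotypeVectors(tuple(f"t{i}" for i in range(12)), base)
        l1 = build_phenotype_layer(vecs, tiny_universe(symbols), seed=9, n_shuffles=300, rank=3)
        l2 = build_phenotype_layer(
            vecs, tiny_universe(symbols[::-1]), seed=9, n_shuffles=300, rank=3
        )
        assert l1.edges == l2.edges

    def test_planted_fixture_within_density_exceeds_between(self, bundle):
        from comorbnet.network import build_phenotype_vectors

        u = bundle.universe
        vecs = build_phenotype_vectors(bundle.scores, bundle.ontology, ONTOLOGY_ROOT, u)
        layer = build_phenotype_layer(vecs, u, n_shuffles=200, rank=2, seed=0)
        planted = u.planted_module
        win = wpairs = btw = bpairs = 0
        for i, a in enumerate(u.genes):
            for b in u.genes[i + 1 :]:
                same = planted[a] == planted[b]
                edge = (a, b) in layer.edges or (b, a) in layer.edges
                if same:
                    wpairs += 1
                    win += edge
                else:
                    bpairs += 1
                    btw += edge
        assert win / wpairs > btw / bpairs


class TestAssemble:
    def test_empty_layers_zero_active(self, five_genes):
        empty = Layer("ppi", five_genes.genes, frozenset())
        empty2 = Layer("phenotype", five_genes.genes, frozenset())
        net = assemble_multiplex(empty, empty2, five_genes)
        assert net.n_active_nodes() == 0

    def test_isolated_in_one_layer_still_active(self, five_genes):
        # a gene absent from the PPI source can still be placed through the
        # phenotype layer, so it counts as active
        ppi = Layer("ppi", five_genes.genes, frozenset())
        phen = Layer.from_edges("phenotype", five_genes.genes, [("G1", "G2")])
        net = assemble_multiplex(ppi, phen, five_genes)
        assert net.n_active_nodes() == 2

    def test_node_sets_realigned(self, five_genes):
        order1 = five_genes.genes
        ppi = Layer.from_edges("ppi", order1, [("G1", "G2")])
        phen = Layer.from_edges("phenotype", order1[::-1], [("G2", "G3")])
        net = assemble_multiplex(ppi, phen, five_genes)
        assert net.ppi.nodes == net.phenotype.nodes == order1

    def test_node_set_mismatch_raises(self, five_genes):
        ppi = Layer("ppi", five_genes.genes, frozenset())
        phen = Layer("phenotype", ("G1", "G2"), frozenset())
        with pytest.raises(ValueError):
            assemble_multiplex(ppi, phen, five_genes)
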