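"""Graph container, generators, and graph-level descriptors."""

import numpy as np
import pytest

import lollinet as ln
from lollinet.descriptors import (
    count_chain_motif_nodes,
    count_chain_motifs,
    count_chain_motifs_bruteforce,
)
from lollinet.errors import (
    ConnectivityError,
    InvalidSizeError,
    ValidationError,
)


class TestWeightedGraph:
    def test_rejects_asymmetry_nan_and_negative(self):
        with pytest.raises(ValidationError):
            ln.WeightedGraph(np.array([[0, 1], [2, 0]], float))
        with pytest.raises(ValidationError):
            ln.WeightedGraph(np.array([[0, np.nan], [np.nan, 0]]))
        with pytest.raises(ValidationError):
            ln.WeightedGraph(np.array([[0, -1], [-1, 0]], float))

    def test_zeroes_diagonal_and_counts_edges(self):
        g = ln.WeightedGraph(np.array([[5, 1], [1, 5]], float))
        assert g.weights[0, 0] == 0
        assert g.n_edges == 1

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValidationError):
            ln.WeightedGraph(np.zeros((2, 2)), labels=["a", "a"])

    def test_edgelist_roundtrip(self, tmp_path, fig1_toy):
        path = tmp_path / "toy.tsv"
        fig1_toy.to_edgelist(path)
        back = ln.WeightedGraph.from_edgelist(path)
        assert back.labels == fig1_toy.labels
        np.testing.assert_allclose(back.weights, fig1_toy.weights, atol=1e-10)


class TestGeneratorInvariants:
    """Every family emits symmetric, nonnegative, zero-diagonal matrices."""

    @pytest.mark.parametrize("family", ["complete", "lollipop", "random", "smallworld", "sbm"])
    def test_structural_invariants_over_seeds(self, family):
        for seed in range(100):
            if family == "complete":
                g = ln.make_complete(2 + seed % 14)
            elif family == "lollipop":
                g = ln.make_lollipop(12, 1 + seed % 10)
            elif family == "random":
                g = ln.make_random(15, edges=20, seed=seed)
            elif family == "smallworld":
                g = ln.make_small_world(15, ring_k=4, beta=0.2, seed=seed)
            else:
                g, _ = ln.make_sbm(20, p_in=0.8, q_out=0.2, seed=seed, size_range=(5, 12))
            w = g.weights
            np.testing.assert_array_equal(w, w.T)
            assert (np.diag(w) == 0).all()
            assert (w >= 0).all()


class TestComplete:
    def test_k5_edges_and_degrees(self):
        g = ln.make_complete(5)
        assert g.n_edges == 10
        np.testing.assert_array_equal(g.degrees(), np.full(5, 4.0))

    def test_two_nodes_single_edge(self):
        g = ln.make_complete(2)
        assert g.n_edges == 1 and g.weights[0, 1] == 1.0

    def test_too_small(self):
        with pytest.raises(InvalidSizeError):
            ln.make_complete(1)


class TestLollipop:
    def test_edge_count_formula(self):
        # clique on 67 nodes + 33 path edges (32 internal + 1 attachment)
        g = ln.make_lollipop(100, 33)
        assert g.n_edges == 67 * 66 // 2 + 33

    def test_k3_plus_pendant(self):
        g = ln.make_lollipop(4, 1)
        assert g.n_edges == 4
        assert sorted(g.degrees()) == [1, 2, 2, 3]

    def test_connected(self):
        assert ln.is_connected(ln.make_lollipop(10, 3).weights)

    def test_invalid_split(self):
        with pytest.raises(InvalidSizeError):
            ln.make_lollipop(5, 4)


class TestRandom:
    def test_gnm_exact_edge_count(self):
        for seed in range(10):
            assert ln.make_random(100, edges=200, seed=seed).n_edges == 200

    def test_deterministic_given_seed(self):
        a = ln.make_random(50, prob=0.6, seed=7)
        b = ln.make_random(50, prob=0.6, seed=7)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_gnp_edge_count_in_support(self):
        g = ln.make_random(50, prob=0.6, seed=3)
        assert 0 < g.n_edges <= 1225

    def test_too_many_edges(self):
        with pytest.raises(InvalidSizeError):
            ln.make_random(10, edges=46)

    def test_exactly_one_mode(self):
        with pytest.raises(ValueError):
            ln.make_random(10, edges=5, prob=0.5)


class TestSmallWorld:
    def test_beta_zero_is_ring_lattice(self):
        g = ln.make_small_world(20, ring_k=4, beta=0.0)
        np.testing.assert_array_equal(g.degrees(), np.full(20, 4.0))

    def test_rewiring_preserves_edge_count(self):
        g = ln.make_small_world(100, ring_k=4, beta=1.0, seed=0)
        assert g.n_edges == 100 * 4 // 2

    def test_ring_k_bound(self):
        with pytest.raises(InvalidSizeError):
            ln.make_small_world(4, ring_k=4)


class TestSBM:
    def test_within_blocks_complete_at_p_one(self):
        g, labels = ln.make_sbm(10, p_in=1.0, q_out=0.5, seed=0, size_range=(5, 5))
        for c in np.unique(labels):
            idx = np.nonzero(labels == c)[0]
            block = g.weights[np.ix_(idx, idx)]
            assert (block[~np.eye(len(idx), dtype=bool)] == 1).all()

    def test_deterministic(self):
        g1, l1 = ln.make_sbm(60, seed=11)
        g2, l2 = ln.make_sbm(60, seed=11)
        np.testing.assert_array_equal(g1.weights, g2.weights)
        np.testing.assert_array_equal(l1, l2)

    def test_sizes_sum_to_total(self):
        for seed in range(20):
            g, labels = ln.make_sbm(180, seed=seed)
            assert len(labels) == 180 and g.n_nodes == 180

    def test_precondition(self):
        with pytest.raises(InvalidSizeError):
            ln.make_sbm(20, p_in=0.1, q_out=0.7)


class TestIsolationSequence:
    def test_final_decayed_weight(self):
        seq = ln.make_isolation_sequence(seed=0)
        chain = seq.chain_nodes
        rest = [i for i in range(50) if i not in chain]
        last = seq.graphs[-1].weights
        base = seq.graphs[0].weights
        cross = last[np.ix_(chain, rest)][base[np.ix_(chain, rest)] > 0]
        np.testing.assert_allclose(cross, 0.05, atol=1e-12)

    def test_zero_iterations_identity(self):
        seq = ln.make_isolation_sequence(iters=0, seed=1)
        assert len(seq.graphs) == 1

    def test_weights_elementwise_nonincreasing_both_modes(self):
        for mode in ("isolate_chain", "global_reduction"):
            seq = ln.make_isolation_sequence(iters=5, mode=mode, seed=2)
            for a, b in zip(seq.graphs, seq.graphs[1:]):
                assert (b.weights <= a.weights + 1e-12).all()

    def test_path_edges_held_constant(self):
        seq = ln.make_isolation_sequence(seed=3)
        chain = seq.chain_nodes
        assert len(chain) == 10
        for g in seq.graphs:
            for a, b in zip(chain[:-1], chain[1:]):
                assert g.weights[a, b] == 1.0

    def test_same_baseline_across_modes(self):
        a = ln.make_isolation_sequence(mode="isolate_chain", seed=4)
        b = ln.make_isolation_sequence(mode="global_reduction", seed=4)
        np.testing.assert_array_equal(a.graphs[0].weights, b.graphs[0].weights)

    def test_all_graphs_connected(self):
        seq = ln.make_isolation_sequence(seed=5)
        assert all(ln.is_connected(g.weights) for g in seq.graphs)


class TestChainMotifs:
    def test_triangle_has_none(self):
        assert count_chain_motifs(ln.make_complete(3)) == 0

    def test_path_has_one(self, p3):
        assert count_chain_motifs(p3) == 1

    def test_star_has_three(self):
        w = np.zeros((4, 4))
        w[0, 1:] = w[1:, 0] = 1.0
        assert count_chain_motifs(ln.WeightedGraph(w)) == 3

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        g = ln.make_random(n, prob=0.4, seed=seed)
        assert count_chain_motifs(g) == count_chain_motifs_bruteforce(g)

    def test_threshold_removes_weak_edges(self):
        w = np.array([[0, 1, 0], [1, 0, 0.2], [0, 0.2, 0]])
        g = ln.WeightedGraph(w)
        assert count_chain_motifs(g, binarize_threshold=0.0) == 1
        assert count_chain_motifs(g, binarize_threshold=0.5) == 0

    def test_member_count_is_degree_two_linear_pieces(self, p3):
        assert count_chain_motif_nodes(p3) == 1  # only the center
        assert count_chain_motif_nodes(ln.make_complete(4)) == 0


class TestLouvainModularity:
    def test_complete_graph_single_community(self):
        assert abs(ln.louvain_modularity(ln.make_complete(10), seed=0)) < 1e-12

    def test_two_cliques_bridge(self):
        # oracle: two-clique partition of K5-K5 plus one bridge, m=21 edges,
        # Q = 2*(10/21 - (21/42)^2) = 20/21 - 1/2 = 0.452381
        w = np.zeros((10, 10))
        w[:5, :5] = 1.0
        w[5:, 5:] = 1.0
        np.fill_diagonal(w, 0.0)
        w[4, 5] = w[5, 4] = 1.0
        q = ln.louvain_modularity(ln.WeightedGraph(w), seed=0)
        assert 0.45 <= q <= 0.5
        np.testing.assert_allclose(q, 20 / 21 - 0.5, atol=1e-9)

    def test_disconnected_rejected(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        with pytest.raises(ConnectivityError):
            ln.louvain_modularity(ln.WeightedGraph(w))
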