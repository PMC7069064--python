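"""Normalized walk model, Laplacian, and the three hitting-time solvers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lollinet as ln
from lollinet.errors import ConnectivityError, DegenerateInputError, ValidationError
from lollinet.timeseries import PartialCorrelationMatrix

from conftest import random_connected_weighted


class TestBuildGraph:
    def test_absolute_values_become_weights(self):
        rho = np.array([[1, -0.4], [-0.4, 1]])
        g = ln.build_graph(PartialCorrelationMatrix(rho, ["a", "b"]))
        assert g.weights[0, 1] == pytest.approx(0.4)

    def test_identity_gives_empty_graph(self):
        g = ln.build_graph(PartialCorrelationMatrix(np.eye(3), list("abc")))
        assert g.n_edges == 0

    def test_toy_degrees(self, fig1_toy):
        d = fig1_toy.degrees()
        assert d[0] == pytest.approx(2.7)
        assert d[1] == pytest.approx(0.3)


class TestNormalize:
    def test_toy_transitions_and_self_loops(self, fig1_toy):
        m = ln.normalize(fig1_toy)
        assert m.d_max == pytest.approx(2.7)
        np.testing.assert_allclose(m.p_prime[0, 2:], 0.9 / 2.7)
        assert m.p_prime[0, 0] == pytest.approx(0.0)
        np.testing.assert_allclose(m.p_prime[1, 2:], 0.1 / 2.7)
        assert m.p_prime[1, 1] == pytest.approx(2.4 / 2.7)

    def test_complete_graph_uniform(self, k5):
        m = ln.normalize(k5)
        assert (np.diag(m.a_prime) == 0).all()
        off = m.p_prime[~np.eye(5, dtype=bool)]
        np.testing.assert_allclose(off, 0.25)

    def test_p3_hand_computation(self, p3):
        m = ln.normalize(p3)
        assert m.d_max == 2
        np.testing.assert_allclose(np.diag(m.a_prime), [1, 0, 1])
        np.testing.assert_allclose(m.p_prime[0], [0.5, 0.5, 0.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_model_invariants(self, seed):
        g = random_connected_weighted(12, seed)
        m = ln.normalize(g)
        np.testing.assert_allclose(m.a_prime.sum(axis=1), m.d_max, rtol=1e-10)
        np.testing.assert_allclose(m.p_prime.sum(axis=1), 1.0, rtol=1e-10)
        assert ((m.p_prime >= 0) & (m.p_prime <= 1 + 1e-12)).all()
        assert m.a_prime[np.argmax(m.degrees), np.argmax(m.degrees)] == pytest.approx(0.0)
        off = ~np.eye(g.n_nodes, dtype=bool)
        np.testing.assert_array_equal(m.a_prime[off], m.a_prime.T[off])

    def test_disconnected_rejected(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = w[2, 3] = w[3, 2] = 1.0
        with pytest.raises(ConnectivityError):
            ln.normalize(ln.WeightedGraph(w))

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateInputError):
            ln.normalize(ln.WeightedGraph(np.zeros((3, 3))))

    def test_external_reference_degree_adds_self_loops(self, k5):
        m = ln.normalize(k5, d_ref=8.0)
        np.testing.assert_allclose(np.diag(m.a_prime), 4.0)
        with pytest.raises(ValidationError):
            ln.normalize(k5, d_ref=1.0)  # below max degree


class TestLaplacian:
    def test_identity_minus_transition(self, p3):
        m = ln.normalize(p3)
        np.testing.assert_allclose(ln.laplacian(m), np.eye(3) - m.p_prime, atol=1e-12)

    def test_complete_graph_spectrum(self):
        n = 6
        lam = np.linalg.eigvalsh(ln.laplacian(ln.normalize(ln.make_complete(n))))
        np.testing.assert_allclose(lam, [0] + [n / (n - 1)] * (n - 1), atol=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_symmetric_bounded_spectrum_zero_rowsums(self, seed):
        g = random_connected_weighted(10, seed)
        L = ln.laplacian(ln.normalize(g))
        np.testing.assert_allclose(L, L.T, atol=1e-10)
        lam = np.linalg.eigvalsh(L)
        assert lam.min() > -1e-10 and lam.max() < 2 + 1e-10
        np.testing.assert_allclose(L @ np.ones(10), 0.0, atol=1e-10)


class TestHittingSolvers:
    def test_complete_graph_closed_form(self, k5):
        H = ln.hitting_spectral(ln.normalize(k5))
        off = H.offdiag()
        np.testing.assert_allclose(off, 4.0, atol=1e-8)
        assert len(off) == 20

    def test_p3_hand_solved_values(self, p3):
        H = ln.hitting_spectral(ln.normalize(p3))
        assert H.h[0, 1] == pytest.approx(2.0, abs=1e-9)
        assert H.h[1, 2] == pytest.approx(4.0, abs=1e-9)
        assert H.h[0, 2] == pytest.approx(6.0, abs=1e-9)

    def test_degenerate_eigenvalues_handled(self):
        # K_n has an (n-1)-fold eigenvalue; any orthonormal basis must work
        H = ln.hitting_spectral(ln.normalize(ln.make_complete(10)))
        np.testing.assert_allclose(H.offdiag(), 9.0, atol=1e-8)

    def test_two_node_graph(self):
        g = ln.WeightedGraph(np.array([[0, 1], [1, 0]], float))
        assert ln.hitting_linear(ln.normalize(g)).h[0, 1] == pytest.approx(1.0)
        assert ln.hitting_spectral(ln.normalize(g)).h[1, 0] == pytest.approx(1.0)

    def test_diagonal_zero_and_offdiag_at_least_one(self):
        g = random_connected_weighted(15, 3)
        H = ln.hitting_spectral(ln.normalize(g))
        assert (np.diag(H.h) == 0).all()
        assert (H.offdiag() >= 1 - 1e-9).all()

    def test_asymmetry_on_lollipop(self, small_lollipop):
        H = ln.hitting_spectral(ln.normalize(small_lollipop))
        # reaching the stick tip from the clique takes far longer than back
        tip, clique_node = 11, 0
        assert H.h[clique_node, tip] > 2 * H.h[tip, clique_node]

    @pytest.mark.parametrize("seed", range(8))
    def test_spectral_matches_linear_oracle(self, seed):
        g = random_connected_weighted(int(5 + 4 * seed), seed + 50)
        m = ln.normalize(g)
        hs = ln.hitting_spectral(m).h
        hl = ln.hitting_linear(m).h
        np.testing.assert_allclose(hs, hl, rtol=1e-6, atol=1e-8)

    def test_montecarlo_two_node(self):
        g = ln.WeightedGraph(np.array([[0, 1], [1, 0]], float))
        est, se = ln.hitting_montecarlo(ln.normalize(g), 0, 1, n_walks=500, seed=0)
        assert est == pytest.approx(1.0)
        assert se == pytest.approx(0.0)

    def test_montecarlo_matches_linear_on_p3(self, p3):
        m = ln.normalize(p3)
        est, se = ln.hitting_montecarlo(m, 0, 2, n_walks=10_000, seed=1)
        assert abs(est - 6.0) <= 3 * se

    def test_montecarlo_censoring_refused(self, small_lollipop):
        m = ln.normalize(small_lollipop)
        with pytest.raises(Exception):
            with pytest.warns(UserWarning):
                ln.hitting_montecarlo(m, 0, 11, n_walks=200, max_steps=3, seed=0)


class TestWalkProperties:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 50), seed=st.integers(0, 10))
    def test_global_rescaling_leaves_hitting_unchanged(self, scale, seed):
        """P', L and H are invariant to multiplying all weights by c > 0."""
        g = random_connected_weighted(8, seed)
        g2 = ln.WeightedGraph(g.weights * scale)
        h1 = ln.hitting_spectral(ln.normalize(g)).h
        h2 = ln.hitting_spectral(ln.normalize(g2)).h
        np.testing.assert_allclose(h1, h2, rtol=1e-8, atol=1e-8)

    def test_self_loops_keep_chain_irreducible(self):
        """Hitting times stay finite on connected graphs after adding the
        normalization self loops, including highly unbalanced weights."""
        w = np.zeros((6, 6))
        w[0, 1:] = w[1:, 0] = [1e-3, 1e-3, 5, 5, 5]
        g = ln.WeightedGraph(w)
        H = ln.hitting_spectral(ln.normalize(g))
        assert np.isfinite(H.h).all()
        assert (H.offdiag() > 0).all()
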