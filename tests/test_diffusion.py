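import numpy as np
import pytest

from conftest import random_weighted_graph
from dtiwalk.diffusion import (
    DiffusionConfig,
    NetworkGraph,
    build_imrwr_transition,
    build_islrwr_transition,
    build_mhrw_transition,
    build_rwr_transition,
    build_transition,
    diffuse_all,
    stationary_closed_form,
    stationary_power_iteration,
)


def path_graph(n):
    W = np.zeros((n, n))
    for i in range(n - 1):
        W[i, i + 1] = W[i + 1, i] = 1.0
    return W


def star_graph(n_leaves):
    n = n_leaves + 1
    W = np.zeros((n, n))
    W[0, 1:] = W[1:, 0] = 1.0
    return W


def ring_graph(n):
    W = np.zeros((n, n))
    for i in range(n):
        W[i, (i + 1) % n] = W[(i + 1) % n, i] = 1.0
    return W


class TestGraph:
    def test_degrees_and_isolated_count(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.5
        g = NetworkGraph(W)
        assert list(g.degrees) == [1, 1, 0, 0]
        assert g.n_iso == 2

    def test_diagonal_is_ignored(self):
        g = NetworkGraph.from_similarity(np.eye(3))
        assert g.n_iso == 3


class TestRWR:
    def test_path_middle_node_splits_evenly(self):
        P = build_rwr_transition(NetworkGraph(path_graph(3))).P
        assert np.allclose(P[1], [0.5, 0, 0.5])

    def test_star_center_row_uniform_over_leaves(self):
        P = build_rwr_transition(NetworkGraph(star_graph(4))).P
        assert np.allclose(P[0], [0, 0.25, 0.25, 0.25, 0.25])

    def test_isolated_node_gets_unit_self_loop(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        P = build_rwr_transition(NetworkGraph(W)).P
        assert P[2, 2] == 1.0
        assert np.allclose(P.sum(axis=1), 1.0)


class TestMHRW:
    def test_unequal_degree_edge_uses_min_inverse_degree(self):
        # node 0 (degree 1) -- node 1 (degree 3): both entries min(1, 1/3)
        W = star_graph(3)  # center node 0 has degree 3, leaves degree 1
        P = build_mhrw_transition(NetworkGraph(W)).P
        assert P[0, 1] == pytest.approx(1 / 3)
        assert P[1, 0] == pytest.approx(1 / 3)

    def test_three_leaf_star_rows(self):
        P = build_mhrw_transition(NetworkGraph(star_graph(3))).P
        assert np.allclose(P[0], [0, 1 / 3, 1 / 3, 1 / 3])
        for leaf in (1, 2, 3):
            assert P[leaf, 0] == pytest.approx(1 / 3)
            assert P[leaf, leaf] == pytest.approx(2 / 3)

    def test_regular_graph_equals_rwr_with_zero_self_loops(self):
        W = ring_graph(6)
        g = NetworkGraph(W)
        P_mhrw = build_mhrw_transition(g).P
        P_rwr = build_rwr_transition(g).P
        assert np.allclose(P_mhrw, P_rwr)
        assert np.allclose(np.diag(P_mhrw), 0.0)

    def test_off_diagonal_symmetry(self, rng):
        for _ in range(10):
            W = random_weighted_graph(rng, n=12, p=0.4)
            P = build_mhrw_transition(NetworkGraph(W)).P
            off = P - np.diag(np.diag(P))
            assert np.allclose(off, off.T)

    def test_no_restart_stationary_is_uniform(self, rng):
        """Off-diagonal symmetry makes P doubly stochastic, so the
        unrestarted walk's stationary distribution on a connected
        non-bipartite graph is uniform."""
        for seed in range(3):
            local = np.random.default_rng(seed)
            while True:
                W = random_weighted_graph(local, n=10, p=0.5)
                g = NetworkGraph(W)
                if g.n_iso == 0 and _connected(g.adjacency):
                    break
            P = build_mhrw_transition(g).P
            x = np.full(10, 0.1)
            for _ in range(5000):
                x_new = x @ P
                if np.abs(x_new - x).max() < 1e-14:
                    break
                x = x_new
            assert np.abs(x - 0.1).max() < 1e-6


def _connected(adj):
    n = adj.shape[0]
    seen = {0}
    frontier = [0]
    while frontier:
        i = frontier.pop()
        for j in np.nonzero(adj[i])[0]:
            if j not in seen:
                seen.add(int(j))
                frontier.append(int(j))
    return len(seen) == n


class TestIMRWR:
    def test_three_leaf_star_leaf_moves_to_center_with_certainty(self):
        P = build_imrwr_transition(NetworkGraph(star_graph(3))).P
        for leaf in (1, 2, 3):
            assert P[leaf, 0] == pytest.approx(1.0)
            assert P[leaf, leaf] == 0.0

    def test_regular_graph_reduces_to_rwr(self):
        W = ring_graph(8)
        g = NetworkGraph(W)
        assert np.allclose(build_imrwr_transition(g).P, build_rwr_transition(g).P)

    def test_diagonal_zero_and_rows_conserved(self, rng):
        for _ in range(10):
            W = random_weighted_graph(rng, n=15, p=0.4)
            g = NetworkGraph(W)
            P = build_imrwr_transition(g).P
            active = ~g.isolated
            assert np.allclose(np.diag(P)[active], 0.0)
            assert np.abs(P.sum(axis=1) - 1.0).max() < 1e-12


class TestISLRWR:
    def test_worked_five_node_example_teleport(self):
        """Nodes 1-2-3 connected with J(1,2)=0.5, J(1,3)=0.3; nodes 4,5
        isolated.  Row 1 = (0, 0.5, 0.3, 1, 1) / 2.8."""
        J = np.zeros((5, 5))
        J[0, 1] = J[1, 0] = 0.5
        J[0, 2] = J[2, 0] = 0.3
        J[1, 2] = J[2, 1] = 0.2
        g = NetworkGraph(J)
        assert g.n_iso == 2
        P = build_islrwr_transition(g, J, isolated_policy="teleport").P
        assert np.allclose(P[0], [0, 0.5 / 2.8, 0.3 / 2.8, 1 / 2.8, 1 / 2.8])
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_selfloop_policy_puts_residual_on_diagonal(self):
        J = np.zeros((4, 4))
        J[0, 1] = J[1, 0] = 0.5
        g = NetworkGraph(J)  # nodes 2, 3 isolated
        P = build_islrwr_transition(g, J, isolated_policy="selfloop").P
        assert P[0, 0] == pytest.approx(2 / 2.5)
        assert P[0, 1] == pytest.approx(0.5 / 2.5)
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_no_isolated_nodes_is_similarity_normalized(self, rng):
        W = random_weighted_graph(rng, n=8, p=0.9)
        g = NetworkGraph(W)
        assert g.n_iso == 0
        P = build_islrwr_transition(g, W).P
        expected = W / W.sum(axis=1, keepdims=True)
        assert np.allclose(P, expected)

    def test_edgeless_graph_is_identity(self):
        P = build_islrwr_transition(NetworkGraph(np.zeros((4, 4)))).P
        assert np.array_equal(P, np.eye(4))

    def test_binary_weights_no_isolated_reduces_to_rwr(self):
        W = (path_graph(5) > 0).astype(float)
        g = NetworkGraph(W)
        P_isl = build_islrwr_transition(g, W).P
        P_rwr = build_rwr_transition(g).P
        assert np.allclose(P_isl, P_rwr)

    def test_zero_similarity_row_falls_back_to_self_loop(self):
        W = path_graph(3)
        J = np.zeros((3, 3))  # support from W, but zero weights
        with pytest.warns(UserWarning, match="self-loop"):
            P = build_islrwr_transition(NetworkGraph(W), J).P
        assert np.allclose(P.sum(axis=1), 1.0)


class TestStationarySolvers:
    def test_zero_continuation_gives_identity(self, rng):
        W = random_weighted_graph(rng, n=6, p=0.6)
        P = build_rwr_transition(NetworkGraph(W))
        cfg = DiffusionConfig(c=0.0)
        assert np.allclose(stationary_closed_form(P, cfg).Pi, np.eye(6))
        assert np.allclose(stationary_power_iteration(P, cfg).Pi, np.eye(6))

    def test_two_node_complete_graph_hand_solution(self):
        """Seeding node 1 of an edge with c=0.5 gives pi = (2/3, 1/3),
        the solution of the 2x2 restart linear system."""
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        P = build_rwr_transition(NetworkGraph(W))
        state = stationary_closed_form(P, DiffusionConfig(c=0.5))
        assert np.allclose(state.Pi[:, 0], [2 / 3, 1 / 3])

    @pytest.mark.parametrize("variant", ["RWR", "MHRW", "IMRWR", "ISLRWR"])
    @pytest.mark.parametrize("c", [0.1, 0.5, 0.85])
    def test_closed_form_matches_power_iteration(self, variant, c, rng):
        W = random_weighted_graph(rng, n=20, p=0.3)
        g = NetworkGraph(W)
        P = build_transition(g, variant, J=W)
        cfg = DiffusionConfig(c=c)
        Pi_closed = stationary_closed_form(P, cfg).Pi
        Pi_power = stationary_power_iteration(P, cfg).Pi
        assert np.abs(Pi_closed - Pi_power).max() <= 1e-8

    def test_columns_sum_to_one(self, rng):
        W = random_weighted_graph(rng, n=15, p=0.4)
        P = build_mhrw_transition(NetworkGraph(W))
        Pi = stationary_closed_form(P, DiffusionConfig(c=0.85)).Pi
        assert np.allclose(Pi.sum(axis=0), 1.0)

    def test_seed_mass_decreases_with_continuation(self):
        """On a path graph the walk spreads further as c grows, so the
        seed's own stationary mass strictly decreases."""
        P = build_rwr_transition(NetworkGraph(path_graph(7)))
        masses = []
        for c in (0.1, 0.5, 0.9):
            Pi = stationary_closed_form(P, DiffusionConfig(c=c)).Pi
            masses.append(Pi[3, 3])
        assert masses[0] > masses[1] > masses[2]

    def test_nonconvergence_raises(self):
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        P = build_rwr_transition(NetworkGraph(W))
        cfg = DiffusionConfig(c=0.99, tolerance=1e-14, max_iterations=3)
        with pytest.raises(RuntimeError, match="converge"):
            stationary_power_iteration(P, cfg)


class TestDiffuseAll:
    def test_one_state_per_view_with_shapes(self, rng):
        views = {f"v{i}": random_weighted_graph(rng, n=10, p=0.5) for i in range(4)}
        states = diffuse_all(views, "RWR", DiffusionConfig())
        assert len(states) == 4
        assert all(s.Pi.shape == (10, 10) for s in states)

    def test_duplicated_views_give_identical_states(self, rng):
        W = random_weighted_graph(rng, n=8, p=0.5)
        states = diffuse_all([W, W.copy()], "RWR", DiffusionConfig())
        assert np.array_equal(states[0].Pi, states[1].Pi)

    def test_islrwr_teleport_columns_stochastic(self, rng):
        views = [random_weighted_graph(rng, n=12, p=0.2) for _ in range(3)]
        states = diffuse_all(views, "ISLRWR", DiffusionConfig())
        for s in states:
            assert np.abs(s.Pi.sum(axis=0) - 1.0).max() < 1e-8
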