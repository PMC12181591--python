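import numpy as np
import pytest

import oracles
from cogconnectome import (
    WeightedConnectome,
    build_connectome,
    build_stack,
    clustering_and_pathlength,
    compute_measures,
    global_efficiency,
    local_efficiency,
    modularity,
    modularity_q,
    network_strength,
    small_worldness,
)
from cogconnectome.measures import (
    UndefinedMeasureError,
    measure_over_stack,
)


def complete_graph(n):
    return ~np.eye(n, dtype=bool)


def path_graph(n):
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = True
    return adj


def ring_lattice(n, k):
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for d in range(1, k // 2 + 1):
            j = (i + d) % n
            adj[i, j] = adj[j, i] = True
    return adj


def two_cliques(size=4):
    adj = np.zeros((2 * size, 2 * size), dtype=bool)
    adj[:size, :size] = complete_graph(size)
    adj[size:, size:] = complete_graph(size)
    return adj


class TestClosedForms:
    def test_global_efficiency_complete(self):
        assert global_efficiency(complete_graph(7)) == pytest.approx(1.0)

    def test_global_efficiency_path3(self):
        assert global_efficiency(path_graph(3)) == pytest.approx(5 / 6)

    def test_global_efficiency_empty(self):
        assert global_efficiency(np.zeros((5, 5), dtype=bool)) == 0.0

    def test_local_efficiency_triangle_and_star(self):
        assert local_efficiency(complete_graph(3)) == pytest.approx(1.0)
        star = np.zeros((4, 4), dtype=bool)
        star[0, 1:] = star[1:, 0] = True
        assert local_efficiency(star) == 0.0
        assert local_efficiency(np.zeros((4, 4), dtype=bool)) == 0.0

    def test_clustering_pathlength_examples(self):
        assert clustering_and_pathlength(complete_graph(3)) == (
            pytest.approx(1.0), pytest.approx(1.0))
        c, l = clustering_and_pathlength(path_graph(3))
        assert c == 0.0
        assert l == pytest.approx(4 / 3)
        assert clustering_and_pathlength(complete_graph(6)) == (
            pytest.approx(1.0), pytest.approx(1.0))

    def test_modularity_two_cliques_component_partition(self):
        adj = two_cliques(4)
        q = modularity_q(adj, np.array([0] * 4 + [1] * 4))
        assert q == pytest.approx(0.5)

    def test_modularity_single_community_is_zero(self):
        assert modularity_q(complete_graph(5), np.zeros(5)) == pytest.approx(0.0)

    def test_sigma_complete_graph_is_exactly_one(self):
        assert small_worldness(complete_graph(8), ensemble_size=5, seed=0) == 1.0

    def test_strength_closed_forms(self):
        tri = np.full((3, 3), 0.5)
        np.fill_diagonal(tri, 0.0)
        conn = WeightedConnectome(tri, ("a", "b", "c"))
        assert network_strength(conn) == pytest.approx(1.0)
        n = 6
        w = np.ones((n, n)) - np.eye(n)
        assert network_strength(WeightedConnectome(w, tuple("abcdef"))) == n - 1
        assert network_strength(np.zeros((4, 4))) == 0.0


class TestOracleEquivalence:
    """Fast spot check against the naive oracles (the exhaustive sweep over
    >= 500 graphs lives in the acceptance suite)."""

    @pytest.mark.parametrize("seed", range(5))
    def test_random_small_graphs(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            n = int(rng.integers(3, 9))
            adj = oracles.random_graph(n, rng.uniform(0.2, 0.9), rng)
            assert global_efficiency(adj) == pytest.approx(
                oracles.global_efficiency(adj), abs=1e-12)
            assert local_efficiency(adj) == pytest.approx(
                oracles.local_efficiency(adj), abs=1e-12)
            if adj.any():
                c, l = clustering_and_pathlength(adj)
                assert c == pytest.approx(oracles.clustering(adj), abs=1e-12)
                assert l == pytest.approx(oracles.path_length(adj), abs=1e-12)
                q, membership = modularity(adj)
                assert q == pytest.approx(
                    oracles.modularity_q(adj, membership), abs=1e-12)

    def test_networkx_cross_check(self, rng):
        import networkx as nx

        for _ in range(10):
            adj = oracles.random_graph(10, 0.4, rng)
            g = nx.from_numpy_array(adj.astype(int))
            assert global_efficiency(adj) == pytest.approx(
                nx.global_efficiency(g), abs=1e-12)
            assert clustering_and_pathlength(adj)[0] == pytest.approx(
                nx.average_clustering(g), abs=1e-12)


class TestModularityOptimizer:
    def test_recovers_planted_two_clique_partition(self):
        adj = two_cliques(4)
        q, membership = modularity(adj)
        assert q == pytest.approx(0.5)
        assert len(set(membership[:4])) == 1
        assert len(set(membership[4:])) == 1
        assert membership[0] != membership[4]

    @pytest.mark.parametrize("seed", range(8))
    def test_near_exhaustive_optimum_on_small_graphs(self, seed):
        rng = np.random.default_rng(100 + seed)
        adj = oracles.random_graph(int(rng.integers(4, 9)), 0.5, rng)
        if not adj.any():
            return
        q, _ = modularity(adj)
        best = oracles.best_partition_q(adj)
        # spectral bisection + refinement is a heuristic, but on graphs this
        # small it should sit essentially at the exhaustive optimum
        assert q >= best - 0.05
        assert q <= best + 1e-9

    def test_never_worse_than_trivial_partition(self, rng):
        for _ in range(10):
            adj = oracles.random_graph(12, 0.3, rng)
            if adj.any():
                q, _ = modularity(adj)
                assert q >= -1e-12

    def test_igraph_leading_eigenvector_cross_check(self, rng):
        # two spectral heuristics with different refinements: each run must
        # land close to the reference, and ours should not be worse overall
        igraph = pytest.importorskip("igraph")
        gaps = []
        for _ in range(20):
            adj = oracles.random_graph(15, 0.3, rng)
            if not adj.any():
                continue
            g = igraph.Graph.Adjacency(adj.tolist(), mode="undirected")
            q_ig = g.modularity(g.community_leading_eigenvector())
            q_ours, _ = modularity(adj)
            assert q_ours >= q_ig - 0.05
            gaps.append(q_ours - q_ig)
        assert np.mean(gaps) >= 0.0

    def test_edgeless_graph_rejected(self):
        with pytest.raises(UndefinedMeasureError):
            modularity(np.zeros((5, 5), dtype=bool))


class TestSmallWorldness:
    def test_ring_lattice_is_small_world(self):
        adj = ring_lattice(47, 10)
        hits = sum(
            small_worldness(adj, ensemble_size=10, seed=s) > 1 for s in range(20)
        )
        assert hits >= 19

    def test_deterministic_under_seed(self, rng):
        adj = oracles.random_graph(30, 0.3, rng)
        a = small_worldness(adj, ensemble_size=10, seed=5)
        b = small_worldness(adj, ensemble_size=10, seed=5)
        assert a == b

    def test_rewiring_preserves_degree_sequence(self, rng):
        from cogconnectome._kernels import rewire_edges

        adj = oracles.random_graph(20, 0.3, rng)
        iu, ju = np.nonzero(np.triu(adj, 1))
        ei, ej = iu.astype(np.int32).copy(), ju.astype(np.int32).copy()
        m = ei.size
        rewire_edges(
            ei, ej, 20,
            rng.integers(0, m, 10 * m), rng.integers(0, m, 10 * m),
            rng.integers(0, 2, 10 * m).astype(np.bool_),
        )
        new = np.zeros((20, 20), dtype=bool)
        new[ei, ej] = True
        new[ej, ei] = True
        assert not np.any(np.diag(new))
        assert new.sum() == adj.sum()
        np.testing.assert_array_equal(new.sum(0), adj.sum(0))


@pytest.fixture(scope="module")
def stack():
    rng = np.random.default_rng(7)
    conn = build_connectome(rng.standard_normal((50, 47)) +
                            0.5 * rng.standard_normal((50, 1)))
    return build_stack(conn)


class TestMeasureCurves:
    def test_fast_efficiency_curve_matches_per_graph(self, stack):
        fast = measure_over_stack(stack, "global_efficiency")
        slow = np.array([global_efficiency(a) for a in stack.adjacency])
        np.testing.assert_allclose(fast, slow, atol=1e-12)

    def test_global_efficiency_monotone_along_nested_stack(self, stack):
        curve = measure_over_stack(stack, "global_efficiency")
        assert np.all(np.diff(curve) >= -1e-12)

    def test_node_relabelling_invariance(self, rng):
        adj = oracles.random_graph(15, 0.4, rng)
        perm = rng.permutation(15)
        padj = adj[np.ix_(perm, perm)]
        assert global_efficiency(adj) == pytest.approx(
            global_efficiency(padj), abs=1e-12)
        assert local_efficiency(adj) == pytest.approx(
            local_efficiency(padj), abs=1e-12)
        assert modularity(adj)[0] == pytest.approx(
            modularity(padj)[0], abs=1e-9)

    def test_compute_measures_shapes_and_bounds(self):
        rng = np.random.default_rng(21)
        conn = build_connectome(
            rng.standard_normal((40, 47)) + 0.6 * rng.standard_normal((40, 1)),
            group=("EMA", "high"),
        )
        curves = compute_measures(conn, measures=("strength", "global_efficiency",
                                                  "modularity"), sw_ensemble=5)
        assert curves["strength"].is_scalar
        eff = curves["global_efficiency"]
        assert len(eff.values) == 41
        assert all(0 <= v <= 1 for v in eff.values.values())
        q = curves["modularity"]
        assert all(-0.5 <= v <= 1 for v in q.values.values())
        frame = eff.to_frame()
        assert set(frame.columns) == {"group", "measure", "density", "value"}
        assert (frame["group"] == "EMA-high").all()
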