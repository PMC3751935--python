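import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from corticonet.metrics import (
    MetricError,
    betweenness,
    compute_node_metrics,
    degree_and_clustering,
    fit_hierarchy_exponent,
    global_efficiency,
    local_efficiency,
    modularity_partition,
    module_roles,
    shortest_path_matrix,
)
from corticonet.network import BinaryNetwork
from corticonet.simulate import toy_graph


def _net(adj):
    return BinaryNetwork(np.asarray(adj, dtype=np.int8), sparsity=1.0)


def _random_nets(n_graphs=30, seed=314):
    rng = np.random.default_rng(seed)
    for _ in range(n_graphs):
        n = int(rng.integers(4, 9))
        p = float(rng.uniform(0.25, 0.75))
        yield oracles.random_adjacency(rng, n, p)


class TestDistancesAndEfficiency:
    def test_path3_distance_and_efficiency(self):
        net = toy_graph("path3")
        d = shortest_path_matrix(net)
        assert d[0, 2] == 2
        assert global_efficiency(net) == pytest.approx(5 / 6)

    def test_disconnected_components_are_infinite(self):
        adj = np.zeros((4, 4), dtype=np.int8)
        adj[0, 1] = adj[1, 0] = adj[2, 3] = adj[3, 2] = 1
        d = shortest_path_matrix(_net(adj))
        assert np.isinf(d[0, 2]) and np.isinf(d[1, 3])

    def test_complete_graph_efficiencies_are_one(self):
        k5 = toy_graph("complete_n", n=5)
        assert global_efficiency(k5) == pytest.approx(1.0)
        assert local_efficiency(toy_graph("complete_n", n=4)) == pytest.approx(1.0)

    def test_edgeless_and_star_limits(self):
        assert global_efficiency(_net(np.zeros((5, 5)))) == 0.0
        assert local_efficiency(toy_graph("star_k", k=3)) == 0.0

    def test_random_graphs_match_brute_force(self):
        for adj in _random_nets():
            net = _net(adj)
            assert np.array_equal(
                shortest_path_matrix(net), oracles.floyd_warshall(adj)
            )
            assert global_efficiency(net) == pytest.approx(
                oracles.global_efficiency(adj), abs=1e-12
            )
            assert local_efficiency(net) == pytest.approx(
                oracles.local_efficiency(adj), abs=1e-12
            )

    def test_adding_an_edge_never_decreases_global_efficiency(self, rng):
        adj = oracles.random_adjacency(rng, 8, 0.3)
        base = global_efficiency(_net(adj))
        free = [(i, j) for i in range(8) for j in range(i + 1, 8) if not adj[i, j]]
        for i, j in free:
            plus = adj.copy()
            plus[i, j] = plus[j, i] = 1
            assert global_efficiency(_net(plus)) >= base - 1e-15


class TestDegreeClusteringBetweenness:
    def test_triangle_and_star(self):
        k, c = degree_and_clustering(toy_graph("triangle"))
        assert np.array_equal(k, [2, 2, 2]) and np.allclose(c, 1.0)
        k, c = degree_and_clustering(toy_graph("star_k", k=3))
        assert k[0] == 3 and c[0] == 0.0

    def test_path3_betweenness_and_normalization(self):
        b, bn = betweenness(toy_graph("path3"))
        assert np.allclose(b, [0, 1, 0])
        assert bn[1] == pytest.approx(3.0)  # mean b = 1/3

    def test_complete_graph_betweenness_zero_with_zero_mean_fallback(self):
        b, bn = betweenness(toy_graph("complete_n", n=6))
        assert np.all(b == 0) and np.all(bn == 0)

    def test_random_graphs_match_enumeration_oracles(self):
        for adj in _random_nets():
            net = _net(adj)
            k, c = degree_and_clustering(net)
            assert np.array_equal(k, adj.sum(axis=1))
            assert np.allclose(c, oracles.clustering(adj), atol=1e-12)
            b, bn = betweenness(net)
            assert np.allclose(b, oracles.betweenness(adj), atol=1e-9)
            if b.mean() > 0:
                assert bn.mean() == pytest.approx(1.0)

    def test_total_betweenness_accounts_for_transit_hops(self):
        # sum_i b_i = sum over connected pairs of (d_st - 1)
        for adj in _random_nets(10, seed=99):
            b = oracles.betweenness(adj)
            d = oracles.floyd_warshall(adj)
            iu, ju = np.triu_indices(adj.shape[0], k=1)
            finite = np.isfinite(d[iu, ju])
            expected = np.sum(d[iu, ju][finite] - 1)
            bb, _ = betweenness(_net(adj))
            assert bb.sum() == pytest.approx(expected, abs=1e-9)

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_metrics_are_equivariant_under_relabeling(self, seed):
        rng = np.random.default_rng(seed)
        adj = oracles.random_adjacency(rng, 7, 0.5)
        perm = rng.permutation(7)
        relabeled = adj[np.ix_(perm, perm)]
        k, c = degree_and_clustering(_net(adj))
        kp, cp = degree_and_clustering(_net(relabeled))
        assert np.array_equal(k[perm], kp) and np.allclose(c[perm], cp)
        b, _ = betweenness(_net(adj))
        bp, _ = betweenness(_net(relabeled))
        assert np.allclose(b[perm], bp, atol=1e-9)
        assert global_efficiency(_net(adj)) == pytest.approx(
            global_efficiency(_net(relabeled)), abs=1e-12
        )


class TestHierarchyFit:
    def test_exact_power_law_recovered(self):
        pts = np.array([[2, 0.8], [4, 0.4], [8, 0.2]])  # C = 1.6 / k
        fit = fit_hierarchy_exponent(pts)
        assert fit.beta == pytest.approx(1.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.n_points == 3

    def test_flat_clustering_gives_zero_exponent(self):
        pts = np.array([[2, 0.5], [5, 0.5], [9, 0.5]])
        assert fit_hierarchy_exponent(pts).beta == pytest.approx(0.0, abs=1e-12)

    def test_no_degree_spread_is_degenerate(self):
        with pytest.raises(MetricError, match="distinct degrees"):
            fit_hierarchy_exponent(np.array([[3, 1.0], [3, 1.0], [3, 1.0]]))

    def test_low_degree_and_zero_clustering_points_are_excluded(self):
        pts = np.array([[1, 0.9], [2, 0.8], [4, 0.4], [6, 0.0]])
        assert fit_hierarchy_exponent(pts).n_points == 2


class TestModularity:
    def test_two_triangles_bridge_recovers_planted_split(self):
        net = toy_graph("two_triangles_bridge")
        part = modularity_partition(net, seed=0)
        assert part.n_modules == 2
        assert len(set(part.labels[:3])) == 1 and len(set(part.labels[3:])) == 1
        assert part.labels[0] != part.labels[3]
        assert part.q == pytest.approx(5 / 14, abs=1e-12)

    def test_exhaustive_search_confirms_bridge_optimum(self):
        adj = toy_graph("two_triangles_bridge").adjacency
        best_q, best = oracles.best_partition_exhaustive(adj)
        assert best_q == pytest.approx(5 / 14, abs=1e-12)
        assert sorted(sorted(b) for b in best) == [[0, 1, 2], [3, 4, 5]]

    def test_complete_graph_is_one_module_with_zero_q(self):
        part = modularity_partition(toy_graph("complete_n", n=6), seed=0)
        assert part.n_modules == 1 and part.q == pytest.approx(0.0, abs=1e-12)

    def test_edgeless_graph_is_undefined(self):
        with pytest.raises(MetricError, match="edgeless"):
            modularity_partition(_net(np.zeros((4, 4))), seed=0)

    def test_found_q_beats_trivial_partitions_and_small_exhaustive(self):
        for adj in _random_nets(8, seed=5):
            if adj.sum() == 0:
                continue
            part = modularity_partition(_net(adj), seed=1)
            n = adj.shape[0]
            singletons = oracles.newman_q(adj, [[i] for i in range(n)])
            whole = oracles.newman_q(adj, [list(range(n))])
            assert part.q >= singletons - 1e-12
            assert part.q >= whole - 1e-12
            best_q, _ = oracles.best_partition_exhaustive(adj)
            assert part.q <= best_q + 1e-12

    def test_planted_two_block_graph_recovered(self):
        net = toy_graph("planted_2block", n=40, seed=3)
        part = modularity_partition(net, seed=3)
        labels = part.labels
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[20]

    def test_deterministic_given_seed(self):
        net = toy_graph("planted_2block", n=30, seed=8)
        a = modularity_partition(net, seed=4)
        b = modularity_partition(net, seed=4)
        assert np.array_equal(a.labels, b.labels) and a.q == b.q


class TestModuleRoles:
    def test_internal_node_has_zero_participation(self):
        net = toy_graph("two_triangles_bridge")
        part = modularity_partition(net, seed=0)
        p, z = module_roles(net, part)
        # nodes 0 and 1 connect only within their triangle
        assert p[0] == 0.0 and p[1] == 0.0
        assert p[2] > 0 and p[3] > 0  # bridge endpoints reach both modules

    def test_split_degree_between_two_modules(self):
        # path a-b-c with a,b in module 0 and c in module 1: K_b = 2, one
        # edge per module
        net = toy_graph("path3")
        from corticonet.metrics import Partition

        part = Partition(labels=np.array([0, 0, 1]), q=0.0, n_modules=2)
        p, _ = module_roles(net, part)
        assert p[1] == pytest.approx(0.5)

    def test_equal_within_degrees_give_zero_z(self):
        net = toy_graph("two_triangles_bridge")
        part = modularity_partition(net, seed=0)
        _, z = module_roles(net, part)
        # within each triangle every node has within-degree 2
        assert np.allclose(z, 0.0)

    def test_node_metrics_table_shape_and_degree_sum(self):
        net = toy_graph("planted_2block", n=20, seed=2)
        table = compute_node_metrics(net, seed=0)
        assert list(table.columns) == ["region", "K", "C", "b", "B", "P", "Z", "module"]
        assert table["K"].sum() == 2 * net.edge_count
        assert ((table["P"] >= 0) & (table["P"] <= 1)).all()
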