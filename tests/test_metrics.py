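"""Graph measures: closed-form cases, oracle checks, invariances."""

import numpy as np
import pytest

from scnet import (
    MetricError,
    assortativity,
    betweenness_centrality,
    characteristic_path_length,
    clustering_coefficient,
    compute_metric_panel,
    degree_strength,
    distance_matrix,
    eccentricity_radius_diameter,
    global_efficiency,
    local_efficiency,
    modularity,
    partial_correlation_network,
    small_worldness,
    transitivity,
)
from scnet.metrics import DisconnectedGraphWarning, global_measure_values, \
    GLOBAL_MEASURES
from _oracles import (
    oracle_clustering,
    oracle_modularity_max,
    oracle_modularity_q,
    set_partitions,
)


def complete_graph(n):
    return np.ones((n, n)) - np.eye(n)


def path_graph(n):
    w = np.zeros((n, n))
    for i in range(n - 1):
        w[i, i + 1] = w[i + 1, i] = 1.0
    return w


def star_graph(n_leaves):
    w = np.zeros((n_leaves + 1, n_leaves + 1))
    w[0, 1:] = w[1:, 0] = 1.0
    return w


def two_triangles():
    w = np.zeros((6, 6))
    for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        w[i, j] = w[j, i] = 1.0
    return w


class TestDegreeStrength:
    def test_complete_binary(self):
        deg, stren, avg_deg, avg_stren = degree_strength(complete_graph(4))
        assert (deg == 3).all() and avg_deg == 3.0
        assert (stren == 3).all()

    def test_weighted_triangle(self):
        w = 0.5 * complete_graph(3)
        _, stren, _, avg_stren = degree_strength(w)
        assert (stren == 1.0).all() and avg_stren == 1.0

    def test_random_graph_matches_row_scan(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(0, 1, (6, 6))
        w = np.triu(w, 1)
        w = w + w.T
        deg, stren, *_ = degree_strength(w)
        for i in range(6):
            assert deg[i] == sum(1 for j in range(6) if w[i, j] != 0)
            assert stren[i] == pytest.approx(
                sum(w[i, j] for j in range(6)))


class TestDistances:
    def test_inverse_weight_length(self):
        w = np.array([[0.0, 0.5], [0.5, 0.0]])
        assert distance_matrix(w)[0, 1] == pytest.approx(2.0)

    def test_binary_path_hops(self):
        d = distance_matrix(path_graph(3))
        assert d[0, 2] == pytest.approx(2.0)

    def test_negative_weight_directs_to_policy(self):
        w = np.array([[0.0, -0.5], [-0.5, 0.0]])
        with pytest.raises(MetricError, match="zero_negative"):
            distance_matrix(w)

    def test_unreachable_is_infinite(self):
        d = distance_matrix(np.zeros((2, 2)))
        assert np.isinf(d[0, 1]) and d[0, 0] == 0


class TestPathMeasures:
    def test_complete_graph_cpl_is_one(self):
        assert characteristic_path_length(
            distance_matrix(complete_graph(5))) == pytest.approx(1.0)

    def test_three_node_path_enumeration(self):
        d = distance_matrix(path_graph(3))
        assert characteristic_path_length(d) == pytest.approx(4.0 / 3.0)
        assert global_efficiency(d) == pytest.approx(5.0 / 6.0)
        ecc = eccentricity_radius_diameter(d)
        np.testing.assert_allclose(ecc.per_node, [2, 1, 2])
        assert (ecc.radius, ecc.diameter) == (1.0, 2.0)
        assert ecc.mean == pytest.approx(5.0 / 3.0)

    def test_disconnected_pair_excluded_with_warning(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        d = distance_matrix(w)
        with pytest.warns(DisconnectedGraphWarning):
            cpl = characteristic_path_length(d)
        assert cpl == pytest.approx(1.0)

    def test_all_isolated_nodes_error(self):
        d = distance_matrix(np.zeros((3, 3)))
        with pytest.raises(MetricError, match="finite"):
            characteristic_path_length(d)
        assert global_efficiency(d) == 0.0

    def test_weighted_two_node_radius_diameter(self):
        d = distance_matrix(np.array([[0.0, 0.25], [0.25, 0.0]]))
        ecc = eccentricity_radius_diameter(d)
        assert ecc.radius == ecc.diameter == pytest.approx(4.0)

    def test_eccentricity_uses_largest_component(self):
        w = np.zeros((5, 5))
        for i, j in [(0, 1), (1, 2)]:
            w[i, j] = w[j, i] = 1.0
        w[3, 4] = w[4, 3] = 1.0
        with pytest.warns(DisconnectedGraphWarning):
            ecc = eccentricity_radius_diameter(distance_matrix(w))
        assert list(ecc.component) == [0, 1, 2]
        assert np.isnan(ecc.per_node[3]) and np.isnan(ecc.per_node[4])

    def test_singleton_component_error(self):
        with pytest.raises(MetricError, match="singleton"):
            eccentricity_radius_diameter(distance_matrix(np.zeros((1, 1))))


class TestTriangleMeasures:
    def test_uniform_weighted_triangle_is_fully_clustered(self):
        w = 0.5 * complete_graph(3)
        per_node, mean = clustering_coefficient(w)
        np.testing.assert_allclose(per_node, 1.0)
        assert mean == pytest.approx(1.0)

    def test_trees_have_zero_clustering(self):
        assert clustering_coefficient(path_graph(5))[1] == 0.0
        assert clustering_coefficient(star_graph(4))[1] == 0.0

    def test_four_node_example_matches_oracle(self):
        w = np.zeros((4, 4))
        for (i, j), v in {(0, 1): 1.0, (0, 2): 1.0, (1, 2): 0.5,
                          (2, 3): 0.8}.items():
            w[i, j] = w[j, i] = v
        per_node, mean = clustering_coefficient(w)
        oracle_nodes, oracle_mean = oracle_clustering(w)
        np.testing.assert_allclose(per_node, oracle_nodes, atol=1e-12)
        assert mean == pytest.approx(oracle_mean, abs=1e-12)

    def test_binary_triangle_transitivity(self):
        assert transitivity(complete_graph(3)) == pytest.approx(1.0)

    def test_star_transitivity_zero(self):
        assert transitivity(star_graph(4)) == 0.0

    def test_no_connected_triples_error(self):
        with pytest.raises(MetricError, match="triples"):
            transitivity(path_graph(2))

    def test_local_efficiency_complete_and_star(self):
        assert local_efficiency(complete_graph(4)) == pytest.approx(1.0)
        assert local_efficiency(star_graph(4)) == 0.0


class TestBetweenness:
    def test_path_middle_node(self):
        b = betweenness_centrality(path_graph(3))
        np.testing.assert_allclose(b, [0.0, 1.0, 0.0])

    def test_complete_graph_all_zero(self):
        assert (betweenness_centrality(complete_graph(6)) == 0).all()

    def test_requires_three_nodes(self):
        with pytest.raises(MetricError, match="3 nodes"):
            betweenness_centrality(np.zeros((2, 2)))

    def test_weighted_detour_through_strong_edges(self):
        # direct edge weight 0.2 (length 5) loses to the 0.9-0.9 detour
        w = np.zeros((3, 3))
        w[0, 2] = w[2, 0] = 0.2
        w[0, 1] = w[1, 0] = 0.9
        w[1, 2] = w[2, 1] = 0.9
        b = betweenness_centrality(w)
        assert b[1] == pytest.approx(1.0)


class TestModularityAssortativity:
    def test_two_triangles_partition(self):
        w = two_triangles()
        partition, q = modularity(w, seed=0)
        assert q == pytest.approx(0.5, abs=1e-12)
        assert sorted(sorted(c) for c in partition) == [[0, 1, 2], [3, 4, 5]]
        assert q == pytest.approx(oracle_modularity_max(w), abs=1e-12)

    def test_complete_graph_single_community(self):
        _, q = modularity(complete_graph(6), seed=0)
        assert q == pytest.approx(
            oracle_modularity_q(complete_graph(6), [list(range(6))]),
            abs=1e-12)
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_heuristic_close_to_exhaustive_best(self):
        rng = np.random.default_rng(3)
        w = rng.uniform(0, 1, (8, 8)) * (rng.random((8, 8)) < 0.45)
        w = np.triu(w, 1)
        w = w + w.T
        if not (w > 0).any():
            pytest.skip("empty draw")
        best = oracle_modularity_max(w)
        _, q = modularity(w, seed=0)
        assert q <= best + 1e-12
        assert q >= best - 0.05

    def test_empty_graph_error(self):
        with pytest.raises(MetricError, match="empty"):
            modularity(np.zeros((4, 4)), seed=0)

    def test_star_assortativity_minus_one(self):
        assert assortativity(star_graph(5)) == pytest.approx(-1.0)

    def test_regular_graph_undefined(self):
        assert assortativity(complete_graph(5)) is None

    def test_partition_count_sanity(self):
        # the exhaustive-modularity oracle enumerates Bell(4)=15 partitions
        assert sum(1 for _ in set_partitions(range(4))) == 15


class TestSmallWorldness:
    def test_binary_complete_graph_is_exactly_one(self):
        assert small_worldness(complete_graph(6), n_null=20, seed=0) == 1.0

    def test_ring_lattice_exceeds_one(self):
        n, k = 30, 4
        w = np.zeros((n, n))
        for i in range(n):
            for step in range(1, k // 2 + 1):
                j = (i + step) % n
                w[i, j] = w[j, i] = 1.0
        assert small_worldness(w, n_null=20, seed=1) > 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        w = rng.uniform(0.2, 1, (12, 12)) * (rng.random((12, 12)) < 0.6)
        w = np.triu(w, 1)
        w = w + w.T
        a = small_worldness(w, n_null=20, seed=9)
        b = small_worldness(w, n_null=20, seed=9)
        assert a == b

    def test_rejects_small_null_and_disconnection(self):
        with pytest.raises(MetricError, match="n_null"):
            small_worldness(complete_graph(5), n_null=5, seed=0)
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        with pytest.raises(MetricError, match="connected"):
            small_worldness(w, n_null=20, seed=0)


class TestInvariances:
    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        w = rng.uniform(0.2, 1, (10, 10)) * (rng.random((10, 10)) < 0.7)
        w = np.triu(w, 1)
        w = w + w.T
        c = 3.7
        assert clustering_coefficient(w)[1] == pytest.approx(
            clustering_coefficient(c * w)[1], abs=1e-12)
        np.testing.assert_allclose(betweenness_centrality(w),
                                   betweenness_centrality(c * w),
                                   atol=1e-12)
        assert degree_strength(c * w)[2] == degree_strength(w)[2]
        assert degree_strength(c * w)[3] == pytest.approx(
            c * degree_strength(w)[3])
        assert characteristic_path_length(
            distance_matrix(c * w)) == pytest.approx(
            characteristic_path_length(distance_matrix(w)) / c)
        a1, a2 = assortativity(w), assortativity(c * w)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_node_relabeling_equivariance(self):
        rng = np.random.default_rng(6)
        w = rng.uniform(0.2, 1, (9, 9)) * (rng.random((9, 9)) < 0.7)
        w = np.triu(w, 1)
        w = w + w.T
        perm = rng.permutation(9)
        wp = w[np.ix_(perm, perm)]
        np.testing.assert_allclose(betweenness_centrality(wp),
                                   betweenness_centrality(w)[perm],
                                   atol=1e-12)
        np.testing.assert_allclose(clustering_coefficient(wp)[0],
                                   clustering_coefficient(w)[0][perm],
                                   atol=1e-12)
        assert transitivity(wp) == pytest.approx(transitivity(w), abs=1e-12)
        assert global_efficiency(
            distance_matrix(wp)) == pytest.approx(
            global_efficiency(distance_matrix(w)), abs=1e-12)


class TestMetricPanel:
    def test_complete_graph_panel(self):
        panel = compute_metric_panel(complete_graph(4),
                                     {"n_null_graphs": 20}, seed=0)
        assert panel.average_degree == 3.0
        assert panel.characteristic_path_length == pytest.approx(1.0)
        assert panel.global_efficiency == pytest.approx(1.0)
        assert panel.mean_clustering_coefficient == pytest.approx(1.0)
        assert panel.transitivity == pytest.approx(1.0)
        assert panel.small_worldness == 1.0
        assert (panel.betweenness == 0).all()
        assert not panel.assortativity_defined

    def test_study_network_panel_is_complete_and_deterministic(
            self, study_cohort):
        net = partial_correlation_network(study_cohort, "patients")
        p1 = compute_metric_panel(net, {"n_null_graphs": 20}, seed=5)
        p2 = compute_metric_panel(net, {"n_null_graphs": 20}, seed=5)
        values = p1.global_values()
        assert len(values) == 13
        for name, value in values.items():
            if name == "assortativity" and value is None:
                continue
            assert np.isfinite(value), name
        assert p1.betweenness.shape == (56,)
        assert p1.global_values() == p2.global_values()
        np.testing.assert_array_equal(p1.betweenness, p2.betweenness)

    def test_panel_agrees_with_fast_measure_vector(self, study_cohort):
        net = partial_correlation_network(study_cohort, "controls")
        panel = compute_metric_panel(net, {"n_null_graphs": 20}, seed=3)
        fast = global_measure_values(net.weights, GLOBAL_MEASURES,
                                     seed=3, n_null=20)
        for idx, name in enumerate(GLOBAL_MEASURES):
            expected = panel.global_values()[name]
            if expected is None:
                assert np.isnan(fast[idx])
            else:
                assert fast[idx] == pytest.approx(expected, abs=1e-12), name
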