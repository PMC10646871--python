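import numpy as np
import pytest

from ecprofiles import (
    build_local_graph,
    codensity,
    ecc_vr,
    local_contributions,
    order_vertices,
    vr_contributions,
    vr_multiparameter,
)
from ecprofiles.oracles import (
    brute_vr,
    brute_vr_multiparameter,
    complex_contributions,
)


class TestOrdering:
    def test_star_hub_goes_last_under_ascending_degree(self):
        hub = np.zeros((1, 2))
        leaves = np.array([[1, 0], [-1, 0], [0, 1], [0, -1]], dtype=float)
        points = np.vstack([hub, leaves])
        order = order_vertices(points, threshold=1.0, strategy="ascending_degree")
        assert order[-1] == 0  # the hub touches every leaf

    def test_all_isolated_points_keep_identity_order(self):
        points = np.arange(5, dtype=float)[:, None] * 100
        order = order_vertices(points, threshold=1.0, strategy="ascending_degree")
        assert list(order) == [0, 1, 2, 3, 4]

    def test_hub_last_ordering_evens_out_tree_sizes(self):
        # a hub touching four pairwise-distant leaves: processing the hub last
        # splits the simplex tree instead of concentrating it on the hub
        hub = np.zeros((1, 2))
        leaves = np.array([[1.0, 0], [-1.0, 0], [0, 1.0], [0, -1.0]])
        points = np.vstack([hub, leaves])
        thr = 1.1

        def tree_sizes(strategy):
            order = order_vertices(points, thr, strategy)
            return [
                len(local_contributions(build_local_graph(points, order, i, thr), thr))
                for i in range(len(points))
            ]

        assert max(tree_sizes("ascending_degree")) < max(tree_sizes("given"))


class TestLocalGraph:
    def test_last_vertex_has_no_neighbors(self, rng):
        points = rng.normal(size=(6, 2))
        order = order_vertices(points, 10.0, "given")
        g = build_local_graph(points, order, 5, threshold=10.0)
        assert g.neighbors.size == 0

    def test_triangle_first_vertex_sees_both_others(self, unit_triangle):
        order = np.arange(3)
        g = build_local_graph(unit_triangle, order, 0, threshold=1.0)
        assert sorted(g.neighbors) == [1, 2]
        assert g.distances.shape == (3, 3)
        assert np.allclose(g.distances, g.distances.T)
        assert np.allclose(np.diag(g.distances), 0)

    def test_union_of_local_graphs_is_the_neighborhood_graph(self, rng):
        points = rng.normal(size=(12, 3))
        thr = 1.2
        order = order_vertices(points, thr, "ascending_degree")
        edges = set()
        for i in range(len(points)):
            g = build_local_graph(points, order, i, thr)
            for j in g.neighbors:
                edges.add(frozenset((g.center, int(j))))
        expected = {
            frozenset((i, j))
            for i in range(12)
            for j in range(i + 1, 12)
            if np.linalg.norm(points[i] - points[j]) <= thr
        }
        assert edges == expected


class TestLocalContributions:
    def test_isolated_vertex(self, rng):
        points = rng.normal(size=(4, 2)) * 100
        g = build_local_graph(points, np.arange(4), 0, threshold=0.5)
        assert local_contributions(g, 0.5) == [((0.0,), 1)]

    def test_triangle_enumeration(self):
        # collinear points at 0, 1, 2 with threshold 2: exact distances, so
        # the emitted filtrations are exact too
        points = np.array([[0.0], [1.0], [2.0]])
        g = build_local_graph(points, np.arange(3), 0, threshold=2.0)
        contribs = sorted(local_contributions(g, 2.0))
        # vertex, two edges, one triangle at the diameter
        assert contribs == sorted(
            [((0.0,), 1), ((1.0,), -1), ((2.0,), -1), ((2.0,), 1)]
        )


class TestEccVr:
    def test_triangle_curve(self, unit_triangle):
        curve = ecc_vr(unit_triangle, threshold=1.5)
        assert list(curve.values) == [3, 1]
        assert np.allclose(curve.jumps, [0.0, 1.0])

    def test_isolated_points_constant_curve(self, rng):
        points = rng.normal(size=(7, 2)) * 1000
        curve = ecc_vr(points, threshold=0.1)
        assert list(curve.jumps) == [0.0]
        assert list(curve.values) == [7]

    def test_empty_pointcloud(self):
        curve = ecc_vr(np.empty((0, 3)), threshold=1.0)
        assert len(curve) == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        points = rng.normal(size=(n, int(rng.integers(2, 5))))
        thr = float(rng.uniform(0.3, 3.0))
        engine = vr_contributions(points, thr, strategy="ascending_degree")
        oracle = complex_contributions(brute_vr(points, thr))
        assert engine == oracle

    @pytest.mark.parametrize("workers", [1, 2, 4])
    @pytest.mark.parametrize("strategy", ["given", "ascending_degree"])
    def test_worker_and_ordering_invariance(self, workers, strategy):
        rng = np.random.default_rng(7)
        points = rng.normal(size=(14, 2))
        reference = ecc_vr(points, 1.0, workers=1, strategy="given")
        assert ecc_vr(points, 1.0, workers=workers, strategy=strategy) == reference

    def test_full_complex_terminal_value_is_one(self, rng):
        points = rng.normal(size=(9, 3))
        diam = max(
            np.linalg.norm(points[i] - points[j])
            for i in range(9)
            for j in range(i + 1, 9)
        )
        curve = ecc_vr(points, threshold=diam * 1.01)
        assert curve.values[-1] == 1

    def test_mutually_close_points_give_full_powerset(self):
        rng = np.random.default_rng(3)
        for n in (2, 5, 9):
            points = rng.uniform(0, 0.01, size=(n, 2))
            raw = vr_contributions(points, threshold=1.0, aggregated=False)
            assert len(raw) == 2**n - 1


class TestMultiparameter:
    def test_single_vertex(self):
        profile = vr_multiparameter(np.zeros((1, 2)), 1.0, np.array([3.0]))
        assert profile.contributions() == [((0.0, 3.0), 1)]

    def test_edge_with_max_rule(self):
        points = np.array([[0.0], [2.0]])
        profile = vr_multiparameter(points, 2.5, np.array([1.0, 5.0]))
        assert profile.contributions() == [
            ((0.0, 1.0), 1),
            ((0.0, 5.0), 1),
            ((2.0, 5.0), -1),
        ]

    def test_codensity_bifiltration_matches_brute_force(self):
        rng = np.random.default_rng(11)
        angles = rng.uniform(0, 2 * np.pi, 12)
        points = np.column_stack([np.cos(angles), np.sin(angles)])
        points += rng.normal(0, 0.05, points.shape)
        values = codensity(points, k=3)
        thr = 0.8
        engine = vr_multiparameter(points, thr, values)
        oracle = brute_vr_multiparameter(points, thr, values)
        from ecprofiles.oracles import complex_to_curve

        assert engine.contributions() == complex_to_curve(oracle).contributions()

    def test_non_monotone_rule_rejected(self):
        points = np.array([[0.0], [0.5]])
        with pytest.raises(ValueError, match="monotone"):
            vr_multiparameter(
                points, 1.0, np.array([1.0, 2.0]),
                extension_rule=lambda vals: vals.min(axis=0),
            )


class TestCodensity:
    def test_regular_polygon_is_symmetric(self):
        angles = 2 * np.pi * np.arange(11) / 11
        points = np.column_stack([np.cos(angles), np.sin(angles)])
        values = codensity(points, k=10)
        assert np.allclose(values, values[0])

    def test_coincident_neighbors_give_zero(self):
        points = np.zeros((11, 2))
        assert np.allclose(codensity(points, k=10), 0.0)

    def test_matches_distance_matrix_sort_oracle(self, rng):
        points = rng.normal(size=(20, 3))
        k = 5
        values = codensity(points, k=k)
        dist = np.linalg.norm(points[:, None] - points[None, :], axis=2)
        for i in range(20):
            expected = np.sort(dist[i])[1 : k + 1].mean()
            assert values[i] == pytest.approx(expected)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="points"):
            codensity(np.zeros((5, 2)), k=10)
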