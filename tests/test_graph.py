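import numpy as np
import pytest

import phasegraph as pg
from phasegraph.wavelets import ParameterError

from _oracles import (betweenness_paths, binary_clustering_loop,
                      clustering_loop, global_efficiency_loop,
                      local_efficiency_loop, strength_loop)


def random_weighted_graph(rng, n, density=0.5):
    w = rng.uniform(0.05, 1.0, size=(n, n))
    mask = rng.random((n, n)) < density
    w = np.triu(w * mask, k=1)
    return w + w.T


class TestNodeStrength:
    def test_row_arithmetic(self):
        w = np.array([[0, 0.5, 0.25],
                      [0.5, 0, 0],
                      [0.25, 0, 0]])
        np.testing.assert_allclose(pg.node_strength(w), [0.75, 0.5, 0.25])

    def test_zero_matrix(self):
        assert np.all(pg.node_strength(np.zeros((4, 4))) == 0)

    def test_monotone_in_single_edge(self, rng):
        w = random_weighted_graph(rng, 6)
        s0 = pg.node_strength(w)
        w2 = w.copy()
        w2[0, 1] = w2[1, 0] = w[0, 1] + 0.5
        s1 = pg.node_strength(w2)
        assert s1[0] > s0[0] and s1[1] > s0[1]
        np.testing.assert_allclose(s1[2:], s0[2:])


class TestClusteringCoefficient:
    def test_binary_triangle(self):
        w = np.ones((3, 3)) - np.eye(3)
        np.testing.assert_allclose(pg.clustering_coefficient(w), 1.0)

    def test_star_center_has_no_triangles(self):
        w = np.zeros((4, 4))
        w[0, 1:] = w[1:, 0] = 1.0
        assert pg.clustering_coefficient(w)[0] == 0.0

    def test_geometric_mean_hand_case(self):
        # triangle with weights (1, 1, 0.125); node 0 opposite the weak edge
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[0, 2] = w[2, 0] = 1.0
        w[1, 2] = w[2, 1] = 0.125
        c = pg.clustering_coefficient(w)
        assert c[0] == pytest.approx((1 * 1 * 0.125) ** (1 / 3))
        assert c[0] == pytest.approx(0.5)

    def test_binary_graphs_reduce_to_textbook_definition(self, rng):
        for _ in range(20):
            n = rng.integers(3, 7)
            adj = random_weighted_graph(rng, n, 0.6) > 0
            np.testing.assert_allclose(
                pg.clustering_coefficient(adj.astype(float)),
                binary_clustering_loop(adj), atol=1e-12)


class TestLocalEfficiency:
    def test_complete_triangle(self):
        w = np.ones((3, 3)) - np.eye(3)
        np.testing.assert_allclose(pg.local_efficiency(w), 1.0)

    def test_path_middle_node_zero(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 1.0
        assert pg.local_efficiency(w)[1] == 0.0

    def test_matches_floyd_warshall_oracle(self, rng):
        for _ in range(5):
            w = random_weighted_graph(rng, 7)
            np.testing.assert_allclose(pg.local_efficiency(w),
                                       local_efficiency_loop(w), atol=1e-10)


class TestBetweenness:
    def test_path_graph(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 1.0
        np.testing.assert_allclose(pg.betweenness_centrality(w), [0, 1, 0])

    def test_star_center(self):
        w = np.zeros((4, 4))
        w[0, 1:] = w[1:, 0] = 1.0
        np.testing.assert_allclose(pg.betweenness_centrality(w), [3, 0, 0, 0])

    def test_edgeless_graph(self):
        assert np.all(pg.betweenness_centrality(np.zeros((5, 5))) == 0)

    def test_matches_path_enumeration(self, rng):
        for _ in range(5):
            w = random_weighted_graph(rng, 6, 0.5)
            np.testing.assert_allclose(pg.betweenness_centrality(w),
                                       betweenness_paths(w), atol=1e-10)


class TestPermutationEquivariance:
    def test_all_metrics(self, rng):
        w = random_weighted_graph(rng, 7)
        perm = rng.permutation(7)
        wp = w[perm][:, perm]
        for func in (pg.node_strength, pg.clustering_coefficient,
                     pg.local_efficiency, pg.betweenness_centrality):
            np.testing.assert_allclose(func(wp), func(w)[perm], atol=1e-10)


class TestThresholding:
    def test_zero_threshold_only_clears_diagonal(self, rng):
        w = random_weighted_graph(rng, 5) + np.eye(5)
        spec = pg.ThresholdSpec(1, 0.0, 1.0)
        out = pg.apply_threshold(w, spec)
        assert np.all(np.diag(out) == 0)
        np.testing.assert_allclose(out - np.diag(np.diag(out)),
                                   w - np.diag(np.diag(w)))

    def test_threshold_above_max_empties_graph(self, rng):
        w = random_weighted_graph(rng, 5)
        assert np.all(pg.apply_threshold(w, pg.ThresholdSpec(1, 2.0, 0.0)) == 0)

    def test_survivor_count(self, rng):
        w = random_weighted_graph(rng, 8)
        thr = np.median(w[np.triu_indices(8, 1)])
        out = pg.apply_threshold(w, pg.ThresholdSpec(1, thr, 0.5))
        iu = np.triu_indices(8, 1)
        assert (out[iu] > 0).sum() == (w[iu] >= thr).sum()


class TestCostEfficiencyThreshold:
    @staticmethod
    def exhaustive_best(w, grid):
        iu = np.triu_indices(w.shape[0], 1)
        best_score, best_cost, best_thr = -np.inf, None, None
        for cost in grid:
            thr = np.quantile(w[iu], 1 - cost)
            adj = (w >= thr).astype(float)
            np.fill_diagonal(adj, 0)
            score = global_efficiency_loop(adj) - cost  # binary: weights are 1
            if score > best_score + 1e-12:
                best_score, best_cost, best_thr = score, cost, thr
        return best_cost, best_thr

    def test_two_clique_bridge_matches_exhaustive_search(self):
        w = np.zeros((8, 8))
        for block in (range(4), range(4, 8)):
            for i in block:
                for j in block:
                    if i != j:
                        w[i, j] = 0.9
        w[3, 4] = w[4, 3] = 0.1
        grid = np.round(np.arange(0.1, 0.91, 0.1), 10)
        spec = pg.cost_efficiency_threshold(w, grid)
        _, best_thr = self.exhaustive_best(w, grid)
        assert spec.threshold_value == pytest.approx(best_thr)

    def test_returned_cost_is_achievable(self, rng):
        w = random_weighted_graph(rng, 10, 0.9)
        spec = pg.cost_efficiency_threshold(w)
        assert 0 < spec.cost_at_threshold <= 1
        assert w[np.triu_indices(10, 1)].min() <= spec.threshold_value \
            <= w[np.triu_indices(10, 1)].max()

    def test_uniform_star_optimum_at_minimal_spanning_cost(self):
        """For K1,4 with equal spoke weights every cost that keeps all
        spokes has the same efficiency, so the sparsest such cost wins."""
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 0.8
        grid = np.round(np.arange(0.1, 0.91, 0.1), 10)
        spec = pg.cost_efficiency_threshold(w, grid)
        best_cost, _ = self.exhaustive_best(w, grid)
        assert spec.cost_at_threshold == pytest.approx(0.4)  # 4 of 10 edges
        assert best_cost <= 0.4 + 1e-9

    def test_empty_grid_raises(self, rng):
        with pytest.raises(ParameterError):
            pg.cost_efficiency_threshold(random_weighted_graph(rng, 5), [])


class TestMetricTables:
    def test_static_table_equals_individual_calls(self, rng):
        w = random_weighted_graph(rng, 6)
        fc = pg.StaticFC(matrix=w + np.eye(6), scale_index=1)
        spec = pg.cost_efficiency_threshold(fc)
        table = pg.compute_metric_table({1: fc}, {1: spec})
        thr = pg.apply_threshold(fc, spec)
        for mi, metric in enumerate(pg.METRICS):
            func = getattr(pg, metric)
            np.testing.assert_allclose(table.values[:, mi, 0], func(thr),
                                       atol=1e-12)

    def test_dynamic_constant_series_equals_static(self, rng):
        w = random_weighted_graph(rng, 5)
        r = np.repeat((w + np.eye(5))[:, :, None], 4, axis=2)
        sync = pg.SyncSeries(r_xy=r, scale_index=1)
        spec = pg.ThresholdSpec(1, np.median(w[w > 0]), 0.5)
        dyn = pg.compute_dynamic_metrics(sync, spec)
        static = pg.compute_node_metrics(pg.apply_threshold(w, spec))
        for t in range(4):
            np.testing.assert_allclose(dyn[t], static, atol=1e-12)

    def test_dynamic_matches_per_timepoint_loop(self, rng):
        n, t = 5, 10
        theta = rng.uniform(-np.pi, np.pi, (n, t))
        diff = theta[:, None, :] - theta[None, :, :]
        r = np.abs(np.cos(diff / 2))
        r[np.arange(n), np.arange(n)] = 1.0
        sync = pg.SyncSeries(r_xy=r, scale_index=2)
        spec = pg.ThresholdSpec(2, 0.4, 0.6)
        dyn = pg.compute_dynamic_metrics(sync, spec)
        for ti in range(t):
            w = r[:, :, ti].copy()
            w[w < 0.4] = 0
            np.fill_diagonal(w, 0)
            np.testing.assert_allclose(dyn[ti], pg.compute_node_metrics(w),
                                       atol=1e-12)
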