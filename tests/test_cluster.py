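"""DBSCAN vs a brute-force reachability oracle, sparrow search behavior,
and the adaptive SSA-DBSCAN hybrid."""
import numpy as np
import pytest

from eegclust import (
    SSAParams,
    SearchBounds,
    clustering_fitness,
    dbscan,
    region_query,
    ssa_dbscan,
    ssa_optimize,
)
from .conftest import canonical_labels, dbscan_oracle


class TestRegionQuery:
    def test_small_example(self):
        pts = np.array([[0.0, 0], [0, 1], [3, 3]])
        assert region_query(pts, 0, 1.0).tolist() == [0, 1]

    def test_tiny_radius_returns_self(self):
        pts = np.array([[0.0], [5.0], [9.0]])
        assert region_query(pts, 1, 0.1).tolist() == [1]

    def test_radius_beyond_diameter_returns_all(self):
        pts = np.random.default_rng(0).normal(size=(8, 2))
        assert region_query(pts, 3, 100.0).size == 8

    def test_bad_index_rejected(self):
        with pytest.raises(IndexError):
            region_query(np.zeros((3, 2)), 5, 1.0)


class TestDBSCAN:
    def test_line_with_outlier(self):
        pts = np.array([[0.0], [0.5], [1.0], [10.0]])
        r = dbscan(pts, eps=0.6, min_pts=3)
        assert r.labels.tolist() == [0, 0, 0, -1]
        assert r.n_clusters == 1

    def test_huge_eps_single_component(self):
        pts = np.random.default_rng(1).normal(size=(12, 2))
        r = dbscan(pts, eps=100.0, min_pts=1)
        assert r.n_clusters == 1
        assert np.all(r.labels == 0)

    def test_coincident_points_form_one_cluster(self):
        pts = np.zeros((6, 2))
        r = dbscan(pts, eps=0.5, min_pts=4)
        assert r.n_clusters == 1
        assert not np.any(r.labels == -1)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dbscan(np.empty((0, 2)), 1.0, 2)

    def test_agrees_with_bruteforce_closure(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(5, 61))
            pts = rng.uniform(-5, 5, size=(n, 2))
            if rng.random() < 0.5:
                pts[: n // 2] *= 0.2
            eps = float(rng.uniform(0.3, 3.0))
            mp = int(rng.integers(2, 8))
            got = dbscan(pts, eps, mp).labels
            want = dbscan_oracle(pts, eps, mp)
            assert canonical_labels(got) == canonical_labels(want)

    def test_partition_invariant_to_input_order(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-3, 3, size=(40, 2))
        perm = rng.permutation(40)
        a = dbscan(pts, 0.8, 3).labels
        b = dbscan(pts[perm], 0.8, 3).labels
        inv = np.empty_like(perm)
        inv[perm] = np.arange(40)
        assert canonical_labels(a) == canonical_labels(b[inv])


class TestFitness:
    def test_all_noise_is_penalized(self):
        assert clustering_fitness(np.zeros((5, 2)), np.full(5, -1)) == -1.0

    def test_single_cluster_is_penalized(self):
        assert clustering_fitness(np.zeros((5, 2)), np.zeros(5, int)) == -1.0

    def test_two_pair_hand_value(self):
        pts = np.array([[0.0], [1.0], [10.0], [11.0]])
        assert clustering_fitness(pts, np.array([0, 0, 1, 1])) == pytest.approx(
            0.89975, abs=1e-4
        )

    def test_noise_fraction_discounts_fitness(self):
        pts = np.array([[0.0], [1.0], [10.0], [11.0], [100.0]])
        labels = np.array([0, 0, 1, 1, -1])
        clean = clustering_fitness(pts[:4], labels[:4])
        assert clustering_fitness(pts, labels) == pytest.approx(0.8 * clean,
                                                                rel=1e-6)


class TestSSA:
    @staticmethod
    def sphere(p):
        return float(np.sum(p**2))

    def test_sphere_convergence_multiple_seeds(self):
        wins = 0
        for seed in range(1, 6):
            _, best, _ = ssa_optimize(
                self.sphere, [(-5, 5), (-5, 5)],
                SSAParams(pop=20, iter_max=100, seed=seed),
            )
            wins += best <= 1e-3
        assert wins >= 4

    def test_trace_monotone_and_positions_bounded(self):
        pos, best, trace = ssa_optimize(
            self.sphere, [(-2, 2), (-2, 2)],
            SSAParams(pop=10, iter_max=30, seed=0),
        )
        assert np.all(np.diff(trace) <= 0)
        assert np.all((pos >= -2) & (pos <= 2))
        assert trace[-1] == best

    def test_single_sparrow_population(self):
        pos, best, _ = ssa_optimize(
            self.sphere, [(-1, 1)], SSAParams(pop=1, iter_max=10, seed=0)
        )
        assert pos.shape == (1,)
        assert np.isfinite(best)

    def test_nonfinite_objective_treated_as_worst(self):
        def spiky(p):
            return np.nan if p[0] > 0 else float(p[0] ** 2)

        pos, best, _ = ssa_optimize(
            spiky, [(-1, 1)], SSAParams(pop=8, iter_max=20, seed=0)
        )
        assert np.isfinite(best)

    def test_deterministic_under_seed(self):
        runs = [
            ssa_optimize(self.sphere, [(-3, 3)] * 2,
                         SSAParams(pop=12, iter_max=25, seed=9))
            for _ in range(2)
        ]
        assert np.array_equal(runs[0][0], runs[1][0])
        assert runs[0][1] == runs[1][1]


class TestSSADBSCAN:
    def test_three_blobs_recovered(self, blobs3):
        pts, labels = blobs3
        r = ssa_dbscan(pts, params=SSAParams(pop=20, iter_max=50, seed=1))
        assert r.n_clusters == 3
        assert r.fitness >= 0.8

    def test_two_blobs_recovered(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(c, 0.3, size=(50, 2))
                         for c in [(0, 0), (6, 6)]])
        r = ssa_dbscan(pts, params=SSAParams(pop=20, iter_max=40, seed=1))
        assert r.n_clusters == 2

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ssa_dbscan(np.zeros((4, 2)))

    def test_beats_random_parameter_draws(self, blobs3):
        pts, _ = blobs3
        from eegclust.cluster import default_bounds

        bounds = default_bounds(pts)
        best = ssa_dbscan(pts, bounds,
                          SSAParams(pop=20, iter_max=40, seed=2)).fitness
        rng = np.random.default_rng(123)
        draws = []
        for _ in range(20):
            eps = rng.uniform(*bounds.eps_range)
            mp = int(rng.integers(bounds.minpts_range[0],
                                  bounds.minpts_range[1] + 1))
            draws.append(dbscan(pts, eps, mp).fitness)
        assert best >= max(draws)

    def test_explicit_bounds_respected(self, blobs3):
        pts, _ = blobs3
        bounds = SearchBounds(eps_range=(0.2, 2.0), minpts_range=(2, 10))
        r = ssa_dbscan(pts, bounds, SSAParams(pop=15, iter_max=30, seed=0))
        assert bounds.eps_range[0] <= r.eps <= bounds.eps_range[1]
        assert 2 <= r.min_pts <= 10
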