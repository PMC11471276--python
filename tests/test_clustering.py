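import itertools

import numpy as np
import pytest

from conftest import euclidean_distance_matrix
from msfeast.clustering import ClusterSolution, k_grid, kmedoids, silhouette
from msfeast.similarity import DistanceMatrix, pairwise_similarity, to_distance


def two_blobs(n_per=4, within=0.05, between=0.9):
    n = 2 * n_per
    D = np.full((n, n), between)
    D[:n_per, :n_per] = within
    D[n_per:, n_per:] = within
    np.fill_diagonal(D, 0.0)
    ids = [f"B{i:02d}" for i in range(n)]
    return DistanceMatrix(ids, D), [0] * n_per + [1] * n_per


def exhaustive_optimum(D: np.ndarray, k: int) -> float:
    n = D.shape[0]
    return min(
        sum(D[i, list(med)].min() for i in range(n))
        for med in itertools.combinations(range(n), k)
    )


class TestKmedoids:
    def test_recovers_well_separated_blobs(self):
        dm, truth = two_blobs()
        sol = kmedoids(dm, 2, seed=0)
        labels = sol.labels_for(dm.feature_ids)
        # partition equality up to relabeling
        assert len({(t, l) for t, l in zip(truth, labels)}) == 2

    def test_seven_points_matches_exhaustive_optimum(self):
        # enough restarts that local search reaches the global optimum on a
        # 7-point instance (with few restarts it may stop at a local minimum,
        # which the acceptance-rate property bounds separately)
        rng = np.random.default_rng(4)
        dm = euclidean_distance_matrix(rng.uniform(size=(7, 2)))
        sol = kmedoids(dm, 2, seed=3, n_restarts=21)
        assert sol.total_cost == pytest.approx(exhaustive_optimum(dm.distances, 2), abs=1e-12)

    def test_k_n_minus_one_forces_singletons(self):
        rng = np.random.default_rng(8)
        dm = euclidean_distance_matrix(rng.uniform(size=(6, 2)))
        sol = kmedoids(dm, 5, seed=1)
        sizes = np.bincount(sol.labels_for(dm.feature_ids), minlength=5)
        assert sorted(sizes) == [1, 1, 1, 1, 2]
        # cost is the distance of the one merged pair
        off = dm.distances[np.triu_indices(6, 1)]
        assert any(abs(sol.total_cost - d) < 1e-12 for d in off)
        assert sol.total_cost >= off.min() - 1e-12

    def test_cost_matches_assignment_and_medoids_self_assigned(self):
        dm, _ = two_blobs()
        sol = kmedoids(dm, 2, seed=5)
        med_idx = {m: c for c, m in enumerate(sol.medoids)}
        for m, c in med_idx.items():
            assert sol.assignment[m] == c
        recomputed = sum(
            dm.distances[dm.feature_ids.index(f), dm.feature_ids.index(sol.medoids[c])]
            for f, c in sol.assignment.items()
        )
        assert sol.total_cost == pytest.approx(recomputed, abs=1e-9)

    def test_iteration_costs_non_increasing(self):
        rng = np.random.default_rng(12)
        dm = euclidean_distance_matrix(rng.uniform(size=(20, 2)))
        sol = kmedoids(dm, 4, seed=2)
        assert all(b <= a + 1e-12 for a, b in zip(sol.iteration_costs, sol.iteration_costs[1:]))

    def test_k_out_of_range(self):
        dm, _ = two_blobs()
        with pytest.raises(ValueError):
            kmedoids(dm, 1, seed=0)
        with pytest.raises(ValueError):
            kmedoids(dm, 8, seed=0)


class TestSilhouette:
    def test_perfectly_separated_blobs_score_one(self):
        dm, truth = two_blobs(within=0.0, between=1.0)
        sol = kmedoids(dm, 2, seed=0)
        assert silhouette(dm, sol) == pytest.approx(1.0, abs=1e-12)

    def test_matches_per_point_formula(self):
        # 6-point instance recomputed literally from the definition
        rng = np.random.default_rng(9)
        dm = euclidean_distance_matrix(rng.uniform(size=(6, 2)))
        sol = kmedoids(dm, 2, seed=0)
        labels = sol.labels_for(dm.feature_ids)
        D = dm.distances
        expected = []
        for i in range(6):
            own = [j for j in range(6) if labels[j] == labels[i] and j != i]
            other = [j for j in range(6) if labels[j] != labels[i]]
            a = np.mean([D[i, j] for j in own])
            b = np.mean([D[i, j] for j in other])
            expected.append((b - a) / max(a, b))
        assert silhouette(dm, sol) == pytest.approx(np.mean(expected), abs=1e-12)

    def test_bounded_on_random_distances(self):
        rng = np.random.default_rng(2)
        n = 10
        D = rng.uniform(0.1, 1.0, size=(n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        dm = DistanceMatrix([f"P{i}" for i in range(n)], D)
        for k in (2, 3, 5):
            assert -1 <= silhouette(dm, kmedoids(dm, k, seed=k)) <= 1

    def test_relabeling_invariance(self):
        dm, _ = two_blobs()
        sol = kmedoids(dm, 2, seed=0)
        swapped = ClusterSolution(
            k=2,
            assignment={f: 1 - c for f, c in sol.assignment.items()},
            medoids=list(reversed(sol.medoids)),
            total_cost=sol.total_cost,
            seed=sol.seed,
        )
        assert silhouette(dm, swapped) == pytest.approx(silhouette(dm, sol), abs=1e-12)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(21)
        dm = euclidean_distance_matrix(rng.uniform(size=(12, 2)))
        sol = kmedoids(dm, 3, seed=0)
        labels = sol.labels_for(dm.feature_ids)
        assert silhouette(dm, sol) == pytest.approx(
            silhouette_score(dm.distances, labels, metric="precomputed"), abs=1e-9
        )


class TestKGrid:
    def test_planted_three_clusters_argmax(self, planted):
        dataset, labels, _ = planted
        dist = to_distance(pairwise_similarity(dataset.spectra))
        grid = k_grid(dist, [2, 3, 4, 5, 6], seed=7)
        assert grid.k_values[int(np.argmax(grid.silhouettes))] == 3

    def test_single_value_grid(self, planted):
        dataset, _, _ = planted
        dist = to_distance(pairwise_similarity(dataset.spectra))
        grid = k_grid(dist, [3], seed=1)
        assert len(grid.k_values) == len(grid.silhouettes) == len(grid.costs) == 1

    def test_deterministic_for_fixed_seed(self, planted):
        dataset, _, _ = planted
        dist = to_distance(pairwise_similarity(dataset.spectra))
        g1 = k_grid(dist, [2, 3, 4], seed=9)
        g2 = k_grid(dist, [2, 3, 4], seed=9)
        assert g1.silhouettes == g2.silhouettes and g1.costs == g2.costs

    def test_empty_grid_rejected(self, planted):
        dataset, _, _ = planted
        dist = to_distance(pairwise_similarity(dataset.spectra))
        with pytest.raises(ValueError):
            k_grid(dist, [], seed=0)
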