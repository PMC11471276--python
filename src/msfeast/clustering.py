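"""k-medoids partitioning of the spectral distance matrix, plus Silhouette.

Clusters of structurally similar spectra are the feature sets tested
downstream.  The partitioner is a PAM-style alternating optimisation on a
precomputed distance matrix: seeded random medoid initialisation, then
alternate (1) assign each point to its nearest medoid and (2) move each
cluster's medoid to the member minimising the intra-cluster distance sum,
until the assignment reaches a fixed point.  Multiple random restarts are
run and the lowest-cost solution kept.  All tie-breaks are deterministic
(nearest-medoid ties go to the lower cluster index, medoid ties to the
lexicographically smallest feature id) so runs are reproducible across
platforms.

The Silhouette grid over candidate k values is advisory output only; the
choice of k is left to the user.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .similarity import DistanceMatrix

__all__ = ["ClusterSolution", "KGridResult", "kmedoids", "silhouette", "k_grid"]

MAX_ITER = 300
N_RESTARTS = 5


@dataclass
class ClusterSolution:
    """A feature -> cluster partition with its medoids and cost."""

    k: int
    assignment: dict[str, int]
    medoids: list[str]
    total_cost: float
    seed: int
    iteration_costs: list[float] = field(default_factory=list)

    def members(self, cluster_index: int) -> list[str]:
        return [f for f, c in self.assignment.items() if c == cluster_index]

    def labels_for(self, feature_ids: list[str]) -> np.ndarray:
        return np.array([self.assignment[f] for f in feature_ids], dtype=int)


@dataclass
class KGridResult:
    k_values: list[int]
    silhouettes: list[float]
    costs: list[float]

    def __post_init__(self) -> None:
        if not (len(self.k_values) == len(self.silhouettes) == len(self.costs)):
            raise ValueError("grid lists must have equal length")
        if any(s < -1 - 1e-9 or s > 1 + 1e-9 for s in self.silhouettes):
            raise ValueError("silhouette values must lie in [-1, 1]")


def _assign(D: np.ndarray, medoids: list[int]) -> np.ndarray:
    # argmin returns the first (lowest cluster index) on ties
    return np.argmin(D[:, medoids], axis=1)


def _update_medoids(
    D: np.ndarray, labels: np.ndarray, k: int, feature_ids: list[str], medoids: list[int]
) -> list[int]:
    new: list[int] = []
    for c in range(k):
        members = np.flatnonzero(labels == c)
        if members.size == 0:
            # keep the old medoid for an emptied cluster; reassignment next
            # round will either repopulate or the restart loop discards it
            new.append(medoids[c])
            continue
        intra = D[np.ix_(members, members)].sum(axis=1)
        best = intra.min()
        ties = members[np.flatnonzero(intra <= best + 0.0)]
        new.append(int(min(ties, key=lambda i: feature_ids[i])))
    return new


def _cost(D: np.ndarray, labels: np.ndarray, medoids: list[int]) -> float:
    return float(D[np.arange(D.shape[0]), np.asarray(medoids)[labels]].sum())


def _single_run(
    D: np.ndarray, k: int, rng: np.random.Generator, feature_ids: list[str]
) -> tuple[np.ndarray, list[int], float, list[float]]:
    n = D.shape[0]
    medoids = sorted(rng.choice(n, size=k, replace=False).tolist())
    labels = _assign(D, medoids)
    costs = [_cost(D, labels, medoids)]
    for _ in range(MAX_ITER):
        medoids = _update_medoids(D, labels, k, feature_ids, medoids)
        new_labels = _assign(D, medoids)
        costs.append(_cost(D, new_labels, medoids))
        if np.array_equal(new_labels, labels):
            labels = new_labels
            break
        labels = new_labels
    return labels, medoids, costs[-1], costs


def kmedoids(
    dist: DistanceMatrix, k: int, seed: int, n_restarts: int = N_RESTARTS
) -> ClusterSolution:
    """Partition the distance matrix into k clusters around medoids.

    Runs ``n_restarts`` seeded random initialisations and keeps the solution
    with the lowest total cost (sum of distances of each point to its medoid).
    Per-iteration costs of the winning run are recorded; they are
    non-increasing by construction of the alternating updates.
    """
    D = dist.distances
    n = D.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n (k={k}, n={n})")
    if not np.all(np.isfinite(D)):
        raise ValueError("distance matrix contains non-finite values")
    best: tuple[float, np.ndarray, list[int], list[float]] | None = None
    for r in range(n_restarts):
        rng = np.random.default_rng(seed + r)
        labels, medoids, cost, costs = _single_run(D, k, rng, dist.feature_ids)
        if len(set(labels.tolist())) < k:
            continue  # collapsed solution; skip
        if best is None or cost < best[0] - 1e-15:
            best = (cost, labels, medoids, costs)
    if best is None:
        raise RuntimeError(f"k-medoids failed to find a non-degenerate {k}-cluster solution")
    cost, labels, medoids, costs = best
    # canonical cluster indexing: clusters ordered by medoid feature id
    order = sorted(range(k), key=lambda c: dist.feature_ids[medoids[c]])
    remap = {old: new for new, old in enumerate(order)}
    assignment = {dist.feature_ids[i]: remap[int(labels[i])] for i in range(n)}
    medoid_ids = [dist.feature_ids[medoids[c]] for c in order]
    return ClusterSolution(
        k=k,
        assignment=assignment,
        medoids=medoid_ids,
        total_cost=cost,
        seed=seed,
        iteration_costs=costs,
    )


def silhouette(dist: DistanceMatrix, solution: ClusterSolution) -> float:
    """Mean Silhouette score of a partition on the precomputed distances.

    Per point, s(i) = (b - a) / max(a, b) with a the mean distance to the
    point's own cluster (excluding itself) and b the minimum over other
    clusters of the mean distance to that cluster.  Members of singleton
    clusters score 0 by convention.
    """
    if solution.k < 2:
        raise ValueError("silhouette undefined for k < 2")
    return float(np.mean(silhouette_samples(dist, solution)))


def silhouette_samples(dist: DistanceMatrix, solution: ClusterSolution) -> np.ndarray:
    """Per-point Silhouette values, ordered like ``dist.feature_ids``."""
    D = dist.distances
    labels = solution.labels_for(dist.feature_ids)
    k = solution.k
    n = D.shape[0]
    sizes = np.bincount(labels, minlength=k)
    s = np.zeros(n)
    for i in range(n):
        c = labels[i]
        if sizes[c] == 1:
            continue  # singleton convention: 0
        a = D[i, labels == c].sum() / (sizes[c] - 1)
        b = np.inf
        for other in range(k):
            if other == c or sizes[other] == 0:
                continue
            b = min(b, D[i, labels == other].mean())
        s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return s


def k_grid(dist: DistanceMatrix, k_values: list[int], seed: int) -> KGridResult:
    """Run k-medoids + Silhouette over a grid of k values.

    Each k uses the derived seed ``seed + k`` so grid entries are independent
    of grid composition.  Results are reported, never auto-selected.
    """
    if not k_values:
        raise ValueError("empty k grid")
    n = dist.n
    bad = [k for k in k_values if not 2 <= k <= n - 1]
    if bad:
        raise ValueError(f"k values out of range [2, {n - 1}]: {bad}")
    sils: list[float] = []
    costs: list[float] = []
    for k in k_values:
        sol = kmedoids(dist, k, seed=seed + k)
        sils.append(silhouette(dist, sol))
        costs.append(sol.total_cost)
    return KGridResult(k_values=list(k_values), silhouettes=sils, costs=costs)
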