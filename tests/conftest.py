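import itertools

import numpy as np
import pytest

from msfeast.similarity import DistanceMatrix, _candidate_weights, _norms
from msfeast.simulate import SyntheticScenario, make_dataset
from msfeast.spectra import Spectrum


@pytest.fixture(scope="session")
def planted():
    """Reconciled 3-cluster / 5-features-each synthetic dataset with truth."""
    dataset, labels, truth = make_dataset(SyntheticScenario(seed=1))
    return dataset, labels, truth


def random_spectrum(rng: np.random.Generator, n_peaks: int, mz_lo=100.0, mz_hi=300.0) -> Spectrum:
    mz = np.sort(rng.uniform(mz_lo, mz_hi, n_peaks))
    return Spectrum(
        feature_id=f"R{rng.integers(1 << 30)}",
        precursor_mz=float(rng.uniform(mz_hi, mz_hi + 200)),
        mz=mz,
        intensities=rng.uniform(0.1, 10.0, n_peaks),
    )


def brute_force_modified_cosine(a: Spectrum, b: Spectrum, tol: float) -> float:
    """Exhaustive maximum over all one-to-one peak matchings (oracle)."""
    W = _candidate_weights(a, b, tol, True)
    na, nb = W.shape
    best = 0.0
    for r in range(min(na, nb) + 1):
        for rows in itertools.combinations(range(na), r):
            for cols in itertools.permutations(range(nb), r):
                best = max(best, sum(W[i, j] for i, j in zip(rows, cols)))
    return best / _norms(a, b, True)


def euclidean_distance_matrix(points: np.ndarray, prefix: str = "P") -> DistanceMatrix:
    D = np.sqrt(((points[:, None] - points[None, :]) ** 2).sum(-1))
    np.fill_diagonal(D, 0.0)
    ids = [f"{prefix}{i:03d}" for i in range(len(points))]
    return DistanceMatrix(feature_ids=ids, distances=D)
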