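"""Pairwise spectral similarity (modified cosine) and the derived distances.

The modified cosine score aligns two fragmentation spectra allowing each
fragment pair to match either directly (|mz_a - mz_b| <= tol) or shifted by
the precursor mass difference Delta = precursor_a - precursor_b
(|mz_a - mz_b - Delta| <= tol).  Candidate pairs are weighted by the product
of square-root intensities and an exact maximum-weight one-to-one matching is
solved over the candidate graph, so the score is deterministic and equals the
brute-force optimum over all matchings.  The score is normalised by the L2
norms of the square-root intensity vectors, hence lies in [0, 1] with unit
self-similarity.

The similarity function is pluggable: any symmetric callable
``(Spectrum, Spectrum) -> (score, n_matched)`` with unit self-score can be
passed to :func:`pairwise_similarity` (e.g. a learned score).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .spectra import Spectrum

__all__ = [
    "SimilarityMatrix",
    "DistanceMatrix",
    "modified_cosine",
    "greedy_modified_cosine",
    "pairwise_similarity",
    "to_distance",
]

DEFAULT_FRAGMENT_TOL = 0.1  # Da


@dataclass
class SimilarityMatrix:
    feature_ids: list[str]
    scores: np.ndarray
    matched_peaks: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.feature_ids)
        self.scores = np.asarray(self.scores, dtype=float)
        self.matched_peaks = np.asarray(self.matched_peaks, dtype=int)
        if self.scores.shape != (n, n) or self.matched_peaks.shape != (n, n):
            raise ValueError("matrix shapes must be n x n")
        if not np.allclose(self.scores, self.scores.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if np.any(self.scores < -1e-12) or np.any(self.scores > 1 + 1e-12):
            raise ValueError("similarity scores must lie in [0, 1]")

    def index_of(self, feature_id: str) -> int:
        return self.feature_ids.index(feature_id)


@dataclass
class DistanceMatrix:
    feature_ids: list[str]
    distances: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.feature_ids)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.distances.shape != (n, n):
            raise ValueError("distance matrix must be n x n")
        if not np.allclose(self.distances, self.distances.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(self.distances)) > 1e-12):
            raise ValueError("distance diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.feature_ids)


def _candidate_weights(
    a: Spectrum, b: Spectrum, fragment_tol: float, sqrt_intensity: bool
) -> np.ndarray:
    """Weight matrix over candidate fragment pairs; zero where not a candidate.

    A pair satisfying both the direct and the Delta-shifted window counts once.
    """
    delta = a.precursor_mz - b.precursor_mz
    diff = a.mz[:, None] - b.mz[None, :]
    candidate = (np.abs(diff) <= fragment_tol) | (np.abs(diff - delta) <= fragment_tol)
    ia = np.sqrt(a.intensities) if sqrt_intensity else a.intensities
    ib = np.sqrt(b.intensities) if sqrt_intensity else b.intensities
    return np.where(candidate, ia[:, None] * ib[None, :], 0.0)


def _norms(a: Spectrum, b: Spectrum, sqrt_intensity: bool) -> float:
    ia = np.sqrt(a.intensities) if sqrt_intensity else a.intensities
    ib = np.sqrt(b.intensities) if sqrt_intensity else b.intensities
    return float(np.linalg.norm(ia) * np.linalg.norm(ib))


def modified_cosine(
    a: Spectrum,
    b: Spectrum,
    fragment_tol: float = DEFAULT_FRAGMENT_TOL,
    sqrt_intensity: bool = True,
) -> tuple[float, int]:
    """Exact-assignment modified cosine score between two spectra.

    Returns
    -------
    (score, n_matched)
        ``score`` in [0, 1]; ``n_matched`` is the number of fragment pairs
        used by the optimal one-to-one matching.
    """
    if fragment_tol <= 0:
        raise ValueError("fragment_tol must be positive")
    if a.n_peaks == 0 or b.n_peaks == 0:
        raise ValueError("cannot score a spectrum without peaks")
    weights = _candidate_weights(a, b, fragment_tol, sqrt_intensity)
    if not weights.any():
        return 0.0, 0
    rows, cols = linear_sum_assignment(weights, maximize=True)
    used = weights[rows, cols] > 0
    total = float(weights[rows, cols].sum())
    score = total / _norms(a, b, sqrt_intensity)
    return float(min(score, 1.0)), int(used.sum())


def greedy_modified_cosine(
    a: Spectrum,
    b: Spectrum,
    fragment_tol: float = DEFAULT_FRAGMENT_TOL,
    sqrt_intensity: bool = True,
) -> tuple[float, int]:
    """Greedy-matching variant: repeatedly take the heaviest unused pair.

    A lower bound on the exact score; kept for parity checks with common
    implementations.  Ties broken by lowest (i, j) index pair.
    """
    if fragment_tol <= 0:
        raise ValueError("fragment_tol must be positive")
    if a.n_peaks == 0 or b.n_peaks == 0:
        raise ValueError("cannot score a spectrum without peaks")
    weights = _candidate_weights(a, b, fragment_tol, sqrt_intensity)
    pairs = np.argwhere(weights > 0)
    if pairs.size == 0:
        return 0.0, 0
    order = sorted(range(len(pairs)), key=lambda k: (-weights[pairs[k][0], pairs[k][1]], pairs[k][0], pairs[k][1]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    total = 0.0
    n_matched = 0
    for k in order:
        i, j = int(pairs[k][0]), int(pairs[k][1])
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        total += float(weights[i, j])
        n_matched += 1
    return float(min(total / _norms(a, b, sqrt_intensity), 1.0)), n_matched


SimilarityFn = Callable[[Spectrum, Spectrum], tuple[float, int]]


def pairwise_similarity(
    spectra: Sequence[Spectrum],
    fragment_tol: float = DEFAULT_FRAGMENT_TOL,
    similarity_fn: SimilarityFn | None = None,
) -> SimilarityMatrix:
    """Fill a symmetric similarity matrix from a pairwise score.

    The diagonal is forced to exactly 1.0 and the diagonal of the matched-peak
    count matrix to each spectrum's peak count.
    """
    if len(spectra) < 2:
        raise ValueError("need at least 2 spectra")
    fn: SimilarityFn = similarity_fn or (lambda x, y: modified_cosine(x, y, fragment_tol))
    n = len(spectra)
    scores = np.eye(n)
    matched = np.zeros((n, n), dtype=int)
    for i in range(n):
        matched[i, i] = spectra[i].n_peaks
        for j in range(i + 1, n):
            try:
                s, m = fn(spectra[i], spectra[j])
            except Exception as exc:  # noqa: BLE001 - annotate pair identity
                raise RuntimeError(
                    f"similarity failed for pair ({spectra[i].feature_id!r}, {spectra[j].feature_id!r})"
                ) from exc
            scores[i, j] = scores[j, i] = s
            matched[i, j] = matched[j, i] = m
    return SimilarityMatrix(
        feature_ids=[s.feature_id for s in spectra], scores=scores, matched_peaks=matched
    )


def to_distance(sim: SimilarityMatrix) -> DistanceMatrix:
    """Distance transform d = 1 - s, clamped into [0, 1] with a zero diagonal."""
    d = 1.0 - sim.scores
    d = np.clip(d, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(feature_ids=list(sim.feature_ids), distances=d)
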