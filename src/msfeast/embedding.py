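"""2-D overview embedding of the spectral distance matrix.

A t-SNE embedding (precomputed-distance mode) gives a single overview layout
of all features; a perplexity tuning grid reports, for each candidate
perplexity, how faithfully embedded Euclidean distances preserve the original
spectral distances.  Preservation is measured as the Pearson correlation over
all feature pairs (Spearman available via ``method=``); grids are advisory
and nothing is auto-selected.

The embedding backend is injectable: any callable satisfying the
``(DistanceMatrix, perplexity, seed) -> (n, 2) array`` contract may replace
the default scikit-learn t-SNE.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr, spearmanr
from sklearn.manifold import TSNE

from .similarity import DistanceMatrix

__all__ = [
    "Embedding2D",
    "PerplexityGrid",
    "embed",
    "distance_preservation",
    "perplexity_grid",
]


@dataclass
class Embedding2D:
    feature_ids: list[str]
    coords: np.ndarray  # (n, 2)
    perplexity: float
    seed: int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.feature_ids), 2):
            raise ValueError("coords must be (n, 2)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")


@dataclass
class PerplexityGrid:
    perplexities: list[float]
    preservation: list[float]

    def __post_init__(self) -> None:
        if len(self.perplexities) != len(self.preservation):
            raise ValueError("grid lists must have equal length")


def check_perplexity(n: int, perplexity: float) -> None:
    hi = (n - 1) / 3
    if not 2 <= perplexity < hi:
        raise ValueError(
            f"perplexity {perplexity} infeasible for n={n}: requires 2 <= perplexity < (n-1)/3 = {hi:.2f}"
        )


def _tsne_backend(dist: DistanceMatrix, perplexity: float, seed: int) -> np.ndarray:
    tsne = TSNE(
        n_components=2,
        metric="precomputed",
        init="random",
        perplexity=perplexity,
        random_state=seed,
        method="exact",
    )
    # scikit-learn may modify a precomputed distance matrix in place; never
    # let it touch the caller's array
    return tsne.fit_transform(dist.distances.copy())


EmbedBackend = Callable[[DistanceMatrix, float, int], np.ndarray]


def embed(
    dist: DistanceMatrix,
    perplexity: float,
    seed: int,
    backend: EmbedBackend = _tsne_backend,
) -> Embedding2D:
    """Embed the distance matrix in 2-D, deterministically for a fixed seed.

    Coordinates are mean-centred before return so serialised layouts are
    stable for golden-file comparisons.
    """
    check_perplexity(dist.n, perplexity)
    coords = np.asarray(backend(dist, perplexity, seed), dtype=float)
    coords = coords - coords.mean(axis=0, keepdims=True)
    return Embedding2D(
        feature_ids=list(dist.feature_ids), coords=coords, perplexity=float(perplexity), seed=seed
    )


def distance_preservation(
    dist: DistanceMatrix, emb: Embedding2D, method: str = "pearson"
) -> float:
    """Correlation between original and embedded pairwise distances, in [-1, 1]."""
    if emb.feature_ids != dist.feature_ids:
        raise ValueError("embedding and distance matrix ids do not match")
    orig = squareform(dist.distances, checks=False)
    embedded = pdist(emb.coords)
    if np.std(orig) == 0 or np.std(embedded) == 0:
        raise ValueError("zero variance in pairwise distances; preservation undefined")
    if method == "pearson":
        r = pearsonr(orig, embedded).statistic
    elif method == "spearman":
        r = spearmanr(orig, embedded).statistic
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r)


def perplexity_grid(
    dist: DistanceMatrix,
    perplexities: list[float],
    seed: int,
    backend: EmbedBackend = _tsne_backend,
    method: str = "pearson",
) -> PerplexityGrid:
    """Preservation score for each candidate perplexity (advisory output)."""
    if not perplexities:
        raise ValueError("empty perplexity grid")
    scores = [
        distance_preservation(dist, embed(dist, p, seed, backend=backend), method=method)
        for p in perplexities
    ]
    return PerplexityGrid(perplexities=[float(p) for p in perplexities], preservation=scores)
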