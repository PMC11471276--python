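"""Self-contained feature-set testing per cluster and contrast.

Each spectral cluster is treated as one feature set and tested, per
two-group contrast (reference vs one treatment group), with a self-contained
score statistic: with per-feature standardised intensities X (samples x m
features) and centred group indicator c = y - mean(y),

    Q = c' (X X' / m) c = ||X'c||^2 / m,

the quadratic-form statistic of the global test for a set of covariates.  Q
is zero when no feature co-varies with the group labels and grows with any
(not necessarily concordant) association, giving high power for small
concordant shifts across a set.

Significance is assessed by a permutation null on the group labels.  When
the number of distinct labelings is small (at most ``n_perm``) all of them
are enumerated, giving an exact test whose p-values are multiples of
1/#labelings; otherwise uniformly random permutations are drawn and the
add-one estimate p = (1 + #{Q_perm >= Q_obs}) / (1 + n_perm) is used, so
p is never zero.  Set p-values are Bonferroni-adjusted at family size
(#clusters x #contrasts); per-feature univariate p-values (the m = 1
specialisation) are descriptive and left unadjusted.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb, log2

import numpy as np
import pandas as pd

from .clustering import ClusterSolution
from .spectra import Dataset, SampleMetadata

logger = logging.getLogger(__name__)

__all__ = [
    "Contrast",
    "SetTestResult",
    "FeatureStatistics",
    "build_contrasts",
    "global_test_statistic",
    "permutation_pvalue",
    "univariate_pvalues",
    "log2_fold_change",
    "bonferroni",
    "run_settest",
    "child_seed",
]

DEFAULT_N_PERM = 9999


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison: reference/control vs one treatment group."""

    name: str
    reference_samples: tuple[str, ...]
    treatment_samples: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.reference_samples) & set(self.treatment_samples):
            raise ValueError(f"contrast {self.name!r}: overlapping sample sets")
        if len(self.reference_samples) < 2 or len(self.treatment_samples) < 2:
            raise ValueError(f"contrast {self.name!r}: each side needs >= 2 samples")

    @property
    def samples(self) -> list[str]:
        return list(self.reference_samples) + list(self.treatment_samples)

    @property
    def y(self) -> np.ndarray:
        return np.array([0] * len(self.reference_samples) + [1] * len(self.treatment_samples))


@dataclass
class SetTestResult:
    cluster_id: int
    contrast_name: str
    q_statistic: float
    p_raw: float
    p_adjusted: float
    n_permutations_used: int
    exhaustive: bool
    untestable: bool = False


@dataclass
class FeatureStatistics:
    feature_id: str
    contrast_name: str
    p_univariate: float
    log2_fold_change: float
    zero_variance: bool = False

    @property
    def abs_log2_fold_change(self) -> float:
        return abs(self.log2_fold_change)


def build_contrasts(metadata: SampleMetadata) -> list[Contrast]:
    """One contrast per non-reference group, in sorted group-label order."""
    ref = metadata.reference_group
    ref_samples = tuple(metadata.samples_of(ref))
    contrasts = []
    for group in metadata.groups:
        if group == ref:
            continue
        contrasts.append(
            Contrast(
                name=f"{ref}_vs_{group}",
                reference_samples=ref_samples,
                treatment_samples=tuple(metadata.samples_of(group)),
            )
        )
    return contrasts


def standardize_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and unit-scale columns; returns (Z over kept columns, kept mask).

    Zero-variance columns carry no group information and are dropped (logged).
    """
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not np.all(keep):
        logger.info("dropping %d zero-variance feature column(s) before testing", int((~keep).sum()))
    Z = (X[:, keep] - mu[keep]) / sd[keep]
    return Z, keep


def _q_from_standardized(Z: np.ndarray, y: np.ndarray) -> float:
    c = y - y.mean()
    v = Z.T @ c
    return float(v @ v / Z.shape[1])


def global_test_statistic(X: np.ndarray, y: np.ndarray) -> float | None:
    """Q statistic for one feature set; ``None`` marks an untestable set.

    ``X`` is the raw samples x m intensity submatrix for the set; columns are
    standardised internally (zero-variance columns dropped).  Returns None
    when every column is constant.
    """
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both group labels")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        raise ValueError("X rows must match y length")
    Z, keep = standardize_columns(X)
    if Z.shape[1] == 0:
        return None
    return _q_from_standardized(Z, y)


def _exhaustive_labelings(y: np.ndarray):
    n = y.size
    n1 = int(y.sum())
    for ones in combinations(range(n), n1):
        perm = np.zeros(n)
        perm[list(ones)] = 1.0
        yield perm


def permutation_pvalue(
    X: np.ndarray, y: np.ndarray, n_perm: int = DEFAULT_N_PERM, seed: int = 0
) -> tuple[float, int, bool]:
    """Permutation p-value for the set statistic Q.

    Returns ``(p_raw, n_used, exhaustive)``.  If the number of distinct
    binary labelings C(n, n1) is at most ``n_perm``, all of them are
    enumerated (exact test; the observed labeling is among them so p > 0);
    otherwise ``n_perm`` uniformly random label permutations are drawn and
    the add-one estimate is returned.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both group labels")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z, keep = standardize_columns(X)
    if Z.shape[1] == 0:
        return 1.0, 0, False
    q_obs = _q_from_standardized(Z, y)
    tol = 1e-9 * max(1.0, abs(q_obs))
    total = comb(y.size, int(y.sum()))
    if total <= n_perm:
        count = sum(
            1 for perm in _exhaustive_labelings(y) if _q_from_standardized(Z, perm) >= q_obs - tol
        )
        return count / total, total, True
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(y)
        if _q_from_standardized(Z, perm) >= q_obs - tol:
            count += 1
    return (1 + count) / (1 + n_perm), n_perm, False


def univariate_pvalues(
    X: np.ndarray, y: np.ndarray, n_perm: int = DEFAULT_N_PERM, seed: int = 0
) -> list[tuple[float, bool]]:
    """Per-feature permutation p-values (m = 1 specialisation of Q).

    Returns one ``(p, zero_variance)`` pair per column.  Constant columns get
    p = 1.0 with the flag set.  Each column is tested with the same seed, so
    a single-column matrix reproduces :func:`permutation_pvalue` bitwise.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out: list[tuple[float, bool]] = []
    for j in range(X.shape[1]):
        col = X[:, j : j + 1]
        if np.std(col, ddof=1) == 0:
            out.append((1.0, True))
            continue
        p, _, _ = permutation_pvalue(col, y, n_perm=n_perm, seed=seed)
        out.append((p, False))
    return out


def log2_fold_change(
    feature_row: pd.Series, contrast: Contrast, pseudocount: float
) -> float:
    """Signed log2 ratio of treatment to reference group mean intensity.

    ``pseudocount`` stabilises zero-heavy intensity data; the pipeline default
    is half the smallest nonzero intensity in the whole table.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    mean_ref = float(feature_row[list(contrast.reference_samples)].mean())
    mean_trt = float(feature_row[list(contrast.treatment_samples)].mean())
    if mean_ref + pseudocount == 0 or mean_trt + pseudocount == 0:
        raise ValueError("zero group mean with zero pseudocount; provide a pseudocount > 0")
    return log2((mean_trt + pseudocount) / (mean_ref + pseudocount))


def default_pseudocount(intensities: np.ndarray) -> float:
    """Half the smallest nonzero intensity; 0 if the table is all-zero."""
    nz = intensities[intensities > 0]
    return float(nz.min() / 2) if nz.size else 0.0


def bonferroni(p_raw_values: list[float], family_size: int) -> list[float]:
    """min(1, p * family_size) per value; family covers every tested pair."""
    if family_size < len(p_raw_values):
        raise ValueError(
            f"family_size {family_size} smaller than number of p-values {len(p_raw_values)}"
        )
    return [min(1.0, p * family_size) for p in p_raw_values]


def child_seed(master_seed: int, cluster_id: int | str, contrast_name: str) -> int:
    """Stable per-(cluster, contrast) seed derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}|{cluster_id}|{contrast_name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_settest(
    dataset: Dataset,
    clusters: ClusterSolution,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    pseudocount: float | None = None,
    log_transform: bool = False,
) -> tuple[list[SetTestResult], list[FeatureStatistics]]:
    """Test every cluster x contrast pair and every feature x contrast pair.

    Set p-values are Bonferroni-adjusted at family size #clusters x
    #contrasts (untestable pairs count toward the family, carrying p = 1).
    Univariate p-values share the child seed of the feature's cluster, so a
    singleton cluster's set p equals its feature's univariate p bitwise.
    ``log_transform`` applies log2(x + pseudocount) before testing only; fold
    changes always use the intensities as loaded.
    """
    contrasts = build_contrasts(dataset.metadata)
    frame = dataset.quant.to_frame()  # features x samples
    pc = default_pseudocount(dataset.quant.intensities) if pseudocount is None else pseudocount
    if log_transform:
        test_frame = np.log2(frame + (pc if pc > 0 else 1.0))
    else:
        test_frame = frame
    cluster_ids = sorted(set(clusters.assignment.values()))
    family_size = len(cluster_ids) * len(contrasts)

    set_results: list[SetTestResult] = []
    feature_stats: list[FeatureStatistics] = []
    for contrast in contrasts:
        samples = contrast.samples
        y = contrast.y
        for cid in cluster_ids:
            members = [f for f in dataset.feature_ids if clusters.assignment[f] == cid]
            X = test_frame.loc[members, samples].to_numpy().T  # samples x m
            cseed = child_seed(seed, cid, contrast.name)
            q = global_test_statistic(X, y)
            if q is None:
                logger.warning(
                    "cluster %s is untestable for contrast %s (all features constant)",
                    cid,
                    contrast.name,
                )
                set_results.append(
                    SetTestResult(
                        cluster_id=cid,
                        contrast_name=contrast.name,
                        q_statistic=0.0,
                        p_raw=1.0,
                        p_adjusted=1.0,
                        n_permutations_used=0,
                        exhaustive=False,
                        untestable=True,
                    )
                )
            else:
                p, n_used, exhaustive = permutation_pvalue(X, y, n_perm=n_perm, seed=cseed)
                set_results.append(
                    SetTestResult(
                        cluster_id=cid,
                        contrast_name=contrast.name,
                        q_statistic=q,
                        p_raw=p,
                        p_adjusted=p,  # adjusted below
                        n_permutations_used=n_used,
                        exhaustive=exhaustive,
                    )
                )
            uni = univariate_pvalues(X, y, n_perm=n_perm, seed=cseed)
            for fid, (p_uni, flat) in zip(members, uni):
                lfc = log2_fold_change(frame.loc[fid], contrast, pc)
                feature_stats.append(
                    FeatureStatistics(
                        feature_id=fid,
                        contrast_name=contrast.name,
                        p_univariate=p_uni,
                        log2_fold_change=lfc,
                        zero_variance=flat,
                    )
                )
    adjusted = bonferroni([r.p_raw for r in set_results], family_size)
    for r, p_adj in zip(set_results, adjusted):
        r.p_adjusted = p_adj
    return set_results, feature_stats


def set_results_frame(results: list[SetTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cluster": [r.cluster_id for r in results],
            "contrast": [r.contrast_name for r in results],
            "Q": [r.q_statistic for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "n_perm_used": [r.n_permutations_used for r in results],
            "exhaustive": [r.exhaustive for r in results],
            "untestable": [r.untestable for r in results],
        }
    )


def feature_stats_frame(stats: list[FeatureStatistics]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature": [s.feature_id for s in stats],
            "contrast": [s.contrast_name for s in stats],
            "p_univariate": [s.p_univariate for s in stats],
            "log2fc": [s.log2_fold_change for s in stats],
            "abs_log2fc": [s.abs_log2_fold_change for s in stats],
            "zero_variance": [s.zero_variance for s in stats],
        }
    )
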