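"""Deterministic synthetic benchmark data with planted structure.

Generates the three workflow inputs without any external downloads:

* spectra with planted cluster structure — each cluster owns a disjoint m/z
  region and a shared random "backbone" of fragment peaks; members perturb
  backbone intensities log-normally, jitter peak positions, and drop/add up
  to 20% of peaks.  Disjoint regions make the true partition unambiguous, so
  clustering accuracy is assertable rather than fuzzy.
* a quantification table with planted differential feature sets — baseline
  intensities are log-normal; features in the designated differential
  clusters have their log-mean shifted by ``effect_size x noise_sd`` in
  every treatment (non-reference) group.  ``effect_size`` is therefore in
  units of the within-group standard deviation on the log scale.
* a truth table recording which (cluster, contrast) pairs carry signal.

Everything is driven by a single integer seed through numpy's PCG64
generator, so scenarios are reproducible across platforms.  The generator
emulates cluster structure and concordant abundance shifts only; it makes
no attempt at real fragmentation chemistry (adducts, isotopes, neutral
losses) or chromatographic effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import QuantTable, SampleMetadata, Spectrum

__all__ = ["SyntheticScenario", "make_spectra", "make_quant", "make_dataset"]


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic benchmark dataset.

    Defaults emulate a small two-group untargeted metabolomics comparison
    (three samples per group, one differential cluster with a clearly
    detectable concordant shift of two within-group SDs on the log scale).
    """

    n_clusters: int = 3
    features_per_cluster: int = 5
    backbone_peaks_per_cluster: int = 8
    peak_jitter: float = 0.01  # Da
    n_samples_per_group: int = 3
    group_labels: tuple[str, ...] = ("control", "treatment")
    reference_group: str = "control"
    differential_cluster_ids: tuple[int, ...] = (0,)
    effect_size: float = 2.0  # in within-group SDs on the log scale
    noise_sd: float = 0.5  # log-scale within-group SD
    seed: int = 0
    mz_region_width: float = 100.0
    mz_region_gap: float = 50.0
    mz_region_start: float = 200.0
    intensity_perturbation_sd: float = 0.3
    peak_turnover: float = 0.2  # max fraction of peaks dropped and added per member

    def __post_init__(self) -> None:
        for name in (
            "n_clusters",
            "features_per_cluster",
            "backbone_peaks_per_cluster",
            "n_samples_per_group",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.mz_region_gap <= 0:
            raise ValueError(
                "mz_region_gap must be positive: overlapping m/z regions would "
                "break the planted cluster separation"
            )
        if self.reference_group not in self.group_labels:
            raise ValueError("reference_group must be among group_labels")
        bad = [c for c in self.differential_cluster_ids if not 0 <= c < self.n_clusters]
        if bad:
            raise ValueError(f"unknown differential cluster ids {bad}")

    def region(self, cluster: int) -> tuple[float, float]:
        lo = self.mz_region_start + cluster * (self.mz_region_width + self.mz_region_gap)
        return lo, lo + self.mz_region_width


def make_spectra(scenario: SyntheticScenario) -> tuple[list[Spectrum], dict[str, int]]:
    """Generate spectra with planted clusters; returns (spectra, true labels)."""
    rng = np.random.default_rng(scenario.seed)
    spectra: list[Spectrum] = []
    labels: dict[str, int] = {}
    for c in range(scenario.n_clusters):
        lo, hi = scenario.region(c)
        nb = scenario.backbone_peaks_per_cluster
        backbone_mz = np.sort(rng.uniform(lo, hi, size=nb))
        backbone_int = rng.lognormal(mean=0.0, sigma=1.0, size=nb)
        precursor_base = hi + scenario.mz_region_gap / 2
        for m in range(scenario.features_per_cluster):
            mz = backbone_mz + rng.uniform(-scenario.peak_jitter, scenario.peak_jitter, size=nb)
            inten = backbone_int * rng.lognormal(0.0, scenario.intensity_perturbation_sd, size=nb)
            n_drop = rng.integers(0, max(1, int(scenario.peak_turnover * nb)) + 1)
            keep = np.ones(nb, dtype=bool)
            if n_drop:
                keep[rng.choice(nb, size=int(n_drop), replace=False)] = False
            mz, inten = mz[keep], inten[keep]
            n_add = rng.integers(0, max(1, int(scenario.peak_turnover * nb)) + 1)
            if n_add:
                mz = np.concatenate([mz, rng.uniform(lo, hi, size=int(n_add))])
                inten = np.concatenate(
                    [inten, rng.lognormal(-1.0, 0.5, size=int(n_add))]
                )
            fid = f"F{c}_{m}"
            spectra.append(
                Spectrum(
                    feature_id=fid,
                    precursor_mz=float(precursor_base + rng.uniform(-1.0, 1.0)),
                    mz=mz,
                    intensities=inten,
                )
            )
            labels[fid] = c
    return spectra, labels


def make_quant(
    scenario: SyntheticScenario, labels: dict[str, int]
) -> tuple[QuantTable, SampleMetadata, pd.DataFrame]:
    """Generate the quantification table, metadata, and the ground-truth table.

    The truth table has one row per (cluster, contrast) with a boolean
    ``differential`` column marking planted signal.
    """
    bad = [c for c in scenario.differential_cluster_ids if c not in set(labels.values())]
    if bad:
        raise ValueError(f"differential cluster ids not present in labels: {bad}")
    rng = np.random.default_rng(scenario.seed + 1)
    feature_ids = list(labels)
    groups = list(scenario.group_labels)
    sample_ids = [f"{g}_{i}" for g in groups for i in range(scenario.n_samples_per_group)]
    sample_group = {s: s.rsplit("_", 1)[0] for s in sample_ids}
    is_treatment = np.array([sample_group[s] != scenario.reference_group for s in sample_ids])

    n_f, n_s = len(feature_ids), len(sample_ids)
    base_log = rng.normal(loc=5.0, scale=1.0, size=n_f)
    log_mat = base_log[:, None] + rng.normal(0.0, scenario.noise_sd, size=(n_f, n_s))
    shift = scenario.effect_size * scenario.noise_sd
    for i, fid in enumerate(feature_ids):
        if labels[fid] in scenario.differential_cluster_ids:
            log_mat[i, is_treatment] += shift
    quant = QuantTable(
        feature_ids=feature_ids, sample_ids=sample_ids, intensities=np.exp(log_mat)
    )
    metadata = SampleMetadata(
        sample_to_group=sample_group, reference_group=scenario.reference_group
    )
    rows = []
    for c in sorted(set(labels.values())):
        for g in sorted(groups):
            if g == scenario.reference_group:
                continue
            rows.append(
                {
                    "cluster": c,
                    "contrast": f"{scenario.reference_group}_vs_{g}",
                    "differential": c in scenario.differential_cluster_ids,
                }
            )
    return quant, metadata, pd.DataFrame(rows)


def make_dataset(scenario: SyntheticScenario):
    """Convenience: full reconciled Dataset plus true labels and truth table."""
    from .spectra import reconcile

    spectra, labels = make_spectra(scenario)
    quant, metadata, truth = make_quant(scenario, labels)
    return reconcile(spectra, quant, metadata), labels, truth
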