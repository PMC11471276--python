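"""Input parsing and reconciliation for the three workflow artifacts.

The workflow consumes three files: an MGF file with one MS/MS spectrum per
feature, a CSV quantification table (features x samples, non-negative
intensities), and a CSV sample-to-group metadata table with a designated
reference (control) group.  This module loads each, validates it, and
intersects them into a single consistently-ordered :class:`Dataset`.

Intensities are used exactly as loaded: no normalization, imputation or log
transformation is applied here.  Any scaling (TIC normalization, log) is the
user's upstream responsibility; downstream statistics standardize per feature
but otherwise see the table as-is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "QuantTable",
    "SampleMetadata",
    "Dataset",
    "read_mgf",
    "write_mgf",
    "read_quant_table",
    "read_metadata",
    "reconcile",
]

#: identifier fields recognised in MGF blocks, in decreasing precedence.
ID_FIELDS = ("feature_id", "scans", "title")


@dataclass(frozen=True)
class Spectrum:
    """One feature's fragmentation pattern.

    Parameters
    ----------
    feature_id
        Opaque unique identifier of the LC-MS/MS feature.
    precursor_mz
        Precursor mass-to-charge ratio in Da; must be positive.
    mz
        Fragment m/z values in Da, strictly positive, ascending.
    intensities
        Fragment intensities (arbitrary units), strictly positive (zero
        intensity peaks are dropped at parse time since they cannot
        contribute to cosine-family scores).
    """

    feature_id: str
    precursor_mz: float
    mz: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if mz.ndim != 1 or inten.shape != mz.shape:
            raise ValueError("mz and intensities must be 1-D arrays of equal length")
        keep = inten > 0
        mz, inten = mz[keep], inten[keep]
        order = np.argsort(mz, kind="stable")
        object.__setattr__(self, "mz", mz[order])
        object.__setattr__(self, "intensities", inten[order])
        if self.mz.size < 1:
            raise ValueError(f"spectrum {self.feature_id!r} has no peaks with positive intensity")
        if np.any(self.mz <= 0):
            raise ValueError(f"spectrum {self.feature_id!r} has non-positive fragment m/z")
        if not np.isfinite(self.precursor_mz) or self.precursor_mz <= 0:
            raise ValueError(f"spectrum {self.feature_id!r} has invalid precursor m/z {self.precursor_mz}")

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    def peaks(self) -> list[tuple[float, float]]:
        """Peak list as (mz, intensity) tuples, ascending in mz."""
        return list(zip(self.mz.tolist(), self.intensities.tolist()))


@dataclass
class QuantTable:
    """Feature quantification matrix (features x samples, non-negative)."""

    feature_ids: list[str]
    sample_ids: list[str]
    intensities: np.ndarray  # shape (n_features, n_samples)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("intensity matrix shape does not match id lists")
        if np.any(~np.isfinite(self.intensities)) or np.any(self.intensities < 0):
            raise ValueError("intensities must be finite and non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intensities, index=self.feature_ids, columns=self.sample_ids)

    def row(self, feature_id: str) -> np.ndarray:
        return self.intensities[self.feature_ids.index(feature_id)]


@dataclass
class SampleMetadata:
    """Sample-to-group assignment with a designated reference group."""

    sample_to_group: dict[str, str]
    reference_group: str

    def __post_init__(self) -> None:
        groups = self.group_sizes()
        if len(groups) < 2:
            raise ValueError(f"need >= 2 groups, found {sorted(groups)}")
        small = sorted(g for g, n in groups.items() if n < 2)
        if small:
            raise ValueError(f"every group needs >= 2 samples; too small: {small}")
        if self.reference_group not in groups:
            raise ValueError(
                f"reference group {self.reference_group!r} not among groups {sorted(groups)}"
            )

    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for g in self.sample_to_group.values():
            sizes[g] = sizes.get(g, 0) + 1
        return sizes

    @property
    def groups(self) -> list[str]:
        return sorted(self.group_sizes())

    def samples_of(self, group: str) -> list[str]:
        return [s for s, g in self.sample_to_group.items() if g == group]


@dataclass
class Dataset:
    """The three artifacts intersected and ordered consistently.

    Feature order follows the quantification table; every feature has both a
    spectrum and a quantification row.
    """

    spectra: list[Spectrum]
    quant: QuantTable
    metadata: SampleMetadata
    dropped_spectra: int = 0
    dropped_quant: int = 0
    spectrum_by_id: dict[str, Spectrum] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids_s = [s.feature_id for s in self.spectra]
        if ids_s != self.quant.feature_ids:
            raise ValueError("spectra and quant table are not aligned; use reconcile()")
        if set(self.metadata.sample_to_group) != set(self.quant.sample_ids):
            raise ValueError("metadata samples do not match quant table samples")
        self.spectrum_by_id = {s.feature_id: s for s in self.spectra}

    @property
    def feature_ids(self) -> list[str]:
        return self.quant.feature_ids

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)


def _block_identifier(params: dict) -> str | None:
    for key in ID_FIELDS:
        if key in params:
            val = params[key]
            # pyteomics may parse SCANS into an int or ChargeList-ish object
            return str(val).strip()
    return None


def read_mgf(path: str) -> list[Spectrum]:
    """Read an MGF file into a list of :class:`Spectrum`.

    The feature identifier is taken from the first present of ``FEATURE_ID``,
    ``SCANS``, ``TITLE`` (the common FBMN-export dialects).  Peaks are
    re-sorted ascending by m/z and zero-intensity peaks dropped.

    Raises
    ------
    ValueError
        On duplicate feature ids, or a block missing an identifier or PEPMASS.
    """
    spectra: list[Spectrum] = []
    seen: set[str] = set()
    with _mgf.MGF(str(path), convert_arrays=1) as reader:
        for idx, entry in enumerate(reader):
            params = entry.get("params", {})
            fid = _block_identifier(params)
            if fid is None or fid == "":
                raise ValueError(f"MGF block {idx} has no identifier field ({'/'.join(ID_FIELDS)})")
            pepmass = params.get("pepmass")
            if pepmass is None:
                raise ValueError(f"MGF block {idx} (id {fid!r}) has no PEPMASS")
            precursor = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            if fid in seen:
                raise ValueError(f"duplicate feature id {fid!r} in MGF file")
            seen.add(fid)
            spectra.append(
                Spectrum(
                    feature_id=fid,
                    precursor_mz=precursor,
                    mz=np.asarray(entry["m/z array"], dtype=float),
                    intensities=np.asarray(entry["intensity array"], dtype=float),
                )
            )
    return spectra


def write_mgf(spectra: list[Spectrum], path: str) -> None:
    """Write spectra to an MGF file (FEATURE_ID + PEPMASS per block)."""
    entries = [
        {
            "m/z array": s.mz,
            "intensity array": s.intensities,
            "params": {"feature_id": s.feature_id, "pepmass": s.precursor_mz},
        }
        for s in spectra
    ]
    _mgf.write(entries, str(path), file_mode="w")


def read_quant_table(path: str) -> QuantTable:
    """Read a features x samples CSV; blank cells become 0.

    First column holds feature ids; remaining columns are samples.  Negative
    values and duplicate feature rows are hard errors.
    """
    df = pd.read_csv(path, header=0, dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError("quantification table needs a feature id column plus >= 1 sample column")
    id_col = df.columns[0]
    feature_ids = df[id_col].astype(str).tolist()
    dup = pd.Series(feature_ids)[pd.Series(feature_ids).duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate feature rows in quantification table: {sorted(set(dup))}")
    values = df.drop(columns=[id_col]).apply(pd.to_numeric, errors="raise")
    sample_ids = [str(c) for c in values.columns]
    mat = values.to_numpy(dtype=float)
    nan_mask = np.isnan(mat)
    mat[nan_mask] = 0.0
    neg = np.argwhere(mat < 0)
    if neg.size:
        i, j = neg[0]
        raise ValueError(
            f"negative intensity {mat[i, j]} at feature {feature_ids[i]!r}, sample {sample_ids[j]!r}"
        )
    return QuantTable(feature_ids=feature_ids, sample_ids=sample_ids, intensities=mat)


def read_metadata(path: str, reference_group: str) -> SampleMetadata:
    """Read a sample_id,group CSV and validate against a reference group."""
    df = pd.read_csv(path, header=0, dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "sample_id" not in cols or "group" not in cols:
        raise ValueError("metadata CSV needs columns 'sample_id' and 'group'")
    samples = df[cols["sample_id"]].astype(str)
    if samples.duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    mapping = dict(zip(samples, df[cols["group"]].astype(str)))
    return SampleMetadata(sample_to_group=mapping, reference_group=reference_group)


def reconcile(spectra: list[Spectrum], quant: QuantTable, metadata: SampleMetadata) -> Dataset:
    """Intersect spectra and quantification features; order follows the table.

    Features present on only one side are dropped with a log line giving the
    counts; an empty intersection is a hard error.
    """
    by_id = {s.feature_id: s for s in spectra}
    if len(by_id) != len(spectra):
        raise ValueError("duplicate feature ids among spectra")
    keep = [fid for fid in quant.feature_ids if fid in by_id]
    if not keep:
        raise ValueError("no features shared between spectra and quantification table")
    dropped_quant = len(quant.feature_ids) - len(keep)
    dropped_spectra = len(spectra) - len(keep)
    if dropped_quant or dropped_spectra:
        logger.info(
            "reconcile: dropped %d spectra without quantification and %d quant rows without spectra; %d features kept",
            dropped_spectra,
            dropped_quant,
            len(keep),
        )
    rows = [quant.feature_ids.index(fid) for fid in keep]
    sub = QuantTable(
        feature_ids=keep,
        sample_ids=list(quant.sample_ids),
        intensities=quant.intensities[rows, :],
    )
    return Dataset(
        spectra=[by_id[fid] for fid in keep],
        quant=sub,
        metadata=metadata,
        dropped_spectra=dropped_spectra,
        dropped_quant=dropped_quant,
    )
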