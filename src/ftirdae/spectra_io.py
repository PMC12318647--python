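"""Spectra containers, wide-CSV input/output and manual preprocessing.

Serum FTIR absorbance spectra are handled as a :class:`SpectraSet`: a
wavenumber grid (cm^-1), an ``n_samples x n_points`` absorbance matrix and a
per-sample metadata table (case/control label, age, sex, BMI, tumour stage and
optional clinical biomarkers).  The manual preprocessing chain consists of
truncation to the 1000-3000 cm^-1 fingerprint window followed by L2 (vector)
normalization of every spectrum.  The 1800-2300 cm^-1 "silent region" — where
serum absorbs very little and instrument drift dominates — is described by a
:class:`RegionMask`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "WavenumberGrid",
    "SpectraSet",
    "RegionMask",
    "default_grid",
    "load_spectra",
    "save_spectra",
    "truncate",
    "l2_normalize",
    "silent_mask",
]

#: Columns the metadata table always carries (missing ones are added as NA).
METADATA_COLUMNS = ("label", "age", "sex", "bmi", "stage")

STAGE_LEVELS = ("I", "II", "III", "IV", "unknown")


class SpectraFormatError(ValueError):
    """Malformed spectra/metadata file (shape, header or cell contents)."""


class SpectraValidationError(ValueError):
    """Internally inconsistent spectra (duplicate ids, non-finite values...)."""


@dataclass(frozen=True)
class WavenumberGrid:
    """Strictly increasing, (near-)evenly spaced wavenumber axis in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise SpectraValidationError("grid needs at least 2 wavenumbers")
        if not np.all(np.isfinite(values)):
            raise SpectraValidationError("grid contains non-finite wavenumbers")
        steps = np.diff(values)
        if np.any(steps <= 0):
            raise SpectraValidationError("grid must be strictly increasing")
        if np.ptp(steps) > 1e-6 * steps.mean():
            warnings.warn("wavenumber spacing is uneven", stacklevel=2)

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def spacing(self) -> float:
        return float(np.mean(np.diff(self.values)))


def default_grid(n_points: int = 1037, lo: float = 1000.0, hi: float = 3000.0) -> WavenumberGrid:
    """The default working grid: 1037 points spanning 1000-3000 cm^-1.

    The length matches the input layer of the bundled autoencoder
    architecture (spacing ~1.9305 cm^-1).
    """
    return WavenumberGrid(np.linspace(lo, hi, n_points))


@dataclass
class SpectraSet:
    """Absorbance matrix plus per-sample metadata, the pipeline's currency."""

    grid: WavenumberGrid
    absorbance: np.ndarray  # (n_samples, n_points)
    sample_ids: list[str]
    metadata: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.absorbance.shape[1] != len(self.grid):
            raise SpectraValidationError(
                f"absorbance has {self.absorbance.shape[1]} columns, grid has {len(self.grid)} points"
            )
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != self.absorbance.shape[0]:
            raise SpectraValidationError("sample_ids length != number of rows")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise SpectraValidationError(f"duplicate sample_id(s): {dupes}")
        if not np.all(np.isfinite(self.absorbance)):
            bad = np.argwhere(~np.isfinite(self.absorbance))[0]
            raise SpectraValidationError(
                f"non-finite absorbance at sample {self.sample_ids[bad[0]]!r}, "
                f"wavenumber {self.grid.values[bad[1]]:g}"
            )
        if self.metadata is None:
            self.metadata = pd.DataFrame(index=pd.Index(self.sample_ids, name="sample_id"))
        meta = self.metadata.reindex(self.sample_ids)
        for col in METADATA_COLUMNS:
            if col not in meta.columns:
                meta[col] = pd.NA
        self.metadata = meta

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def labels(self) -> np.ndarray:
        """Case/control labels as a float array (NaN where unknown)."""
        return self.metadata["label"].to_numpy(dtype=float, na_value=np.nan)

    def subset(self, indices) -> "SpectraSet":
        indices = np.asarray(indices)
        if indices.dtype == bool:
            indices = np.flatnonzero(indices)
        ids = [self.sample_ids[i] for i in indices]
        return SpectraSet(
            grid=self.grid,
            absorbance=self.absorbance[indices],
            sample_ids=ids,
            metadata=self.metadata.iloc[indices],
        )

    def copy_with(self, absorbance: np.ndarray) -> "SpectraSet":
        return SpectraSet(
            grid=self.grid,
            absorbance=absorbance,
            sample_ids=list(self.sample_ids),
            metadata=self.metadata.copy(),
        )


@dataclass(frozen=True)
class RegionMask:
    """Boolean membership flags over a grid for a wavenumber interval."""

    member_flags: np.ndarray
    lo: float
    hi: float

    def __post_init__(self) -> None:
        flags = np.asarray(self.member_flags, dtype=bool)
        object.__setattr__(self, "member_flags", flags)

    @property
    def n_flagged(self) -> int:
        return int(self.member_flags.sum())

    @property
    def complement(self) -> np.ndarray:
        return ~self.member_flags


# ---------------------------------------------------------------------------
# Input / output: wide CSV (row = sample, header = wavenumbers in cm^-1)
# ---------------------------------------------------------------------------

def _read_table(path, **kw) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep, **kw)


def load_spectra(spectra_path, metadata_path=None) -> SpectraSet:
    """Load a wide spectra CSV/TSV and (optionally) join a metadata table.

    The spectra file has ``sample_id`` as its first column and one column per
    wavenumber (decimal cm^-1 header).  Samples missing from the metadata are
    retained with null covariates.
    """
    raw = _read_table(spectra_path, dtype=str)
    if raw.shape[1] < 3:
        raise SpectraFormatError("spectra file needs sample_id plus >=2 wavenumber columns")
    ids = raw.iloc[:, 0].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise SpectraValidationError(f"duplicate sample_id(s) in {spectra_path}: {dupes}")
    try:
        wavenumbers = np.array([float(c) for c in raw.columns[1:]])
    except ValueError as exc:
        raise SpectraFormatError(f"non-numeric wavenumber header in {spectra_path}: {exc}") from exc
    values = np.empty((len(ids), wavenumbers.size))
    for j, col in enumerate(raw.columns[1:]):
        try:
            values[:, j] = raw[col].astype(float).to_numpy()
        except ValueError:
            for i, cell in enumerate(raw[col]):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise SpectraFormatError(
                        f"non-numeric absorbance at row {ids[i]!r}, column {col!r}: {cell!r}"
                    ) from None
            raise
    metadata = None
    if metadata_path is not None:
        metadata = _read_table(metadata_path)
        if "sample_id" not in metadata.columns:
            raise SpectraFormatError("metadata file must have a sample_id column")
        metadata["sample_id"] = metadata["sample_id"].astype(str)
        if metadata["sample_id"].duplicated().any():
            dupes = metadata.loc[metadata["sample_id"].duplicated(), "sample_id"].tolist()
            raise SpectraValidationError(f"duplicate sample_id(s) in metadata: {dupes}")
        metadata = metadata.set_index("sample_id")
    return SpectraSet(WavenumberGrid(wavenumbers), values, ids, metadata)


def save_spectra(spectra: SpectraSet, spectra_path, metadata_path=None) -> None:
    """Write the wide-CSV dialect that :func:`load_spectra` reads back."""
    frame = pd.DataFrame(
        spectra.absorbance,
        columns=[repr(float(w)) for w in spectra.grid.values],
    )
    frame.insert(0, "sample_id", spectra.sample_ids)
    sep = "\t" if str(spectra_path).endswith((".tsv", ".tab")) else ","
    frame.to_csv(spectra_path, sep=sep, index=False)
    if metadata_path is not None:
        spectra.metadata.rename_axis("sample_id").to_csv(metadata_path)


# ---------------------------------------------------------------------------
# Manual preprocessing
# ---------------------------------------------------------------------------

def truncate(spectra: SpectraSet, lo: float = 1000.0, hi: float = 3000.0) -> SpectraSet:
    """Restrict to grid points with ``lo <= w <= hi`` (inclusive both ends)."""
    if lo >= hi:
        raise ValueError(f"need lo < hi, got [{lo}, {hi}]")
    keep = (spectra.grid.values >= lo) & (spectra.grid.values <= hi)
    if not keep.any():
        raise ValueError(f"truncation range [{lo}, {hi}] contains no grid points")
    return SpectraSet(
        grid=WavenumberGrid(spectra.grid.values[keep]),
        absorbance=spectra.absorbance[:, keep],
        sample_ids=list(spectra.sample_ids),
        metadata=spectra.metadata.copy(),
    )


def l2_normalize(spectra: SpectraSet) -> SpectraSet:
    """Scale every spectrum to unit Euclidean norm."""
    norms = np.linalg.norm(spectra.absorbance, axis=1)
    zero = norms == 0
    if zero.any():
        bad = [spectra.sample_ids[i] for i in np.flatnonzero(zero)]
        raise SpectraValidationError(f"cannot L2-normalize zero spectra: {bad}")
    return spectra.copy_with(spectra.absorbance / norms[:, None])


def silent_mask(grid: WavenumberGrid, lo: float = 1800.0, hi: float = 2300.0) -> RegionMask:
    """Flag grid points inside the silent region [lo, hi] (inclusive)."""
    if lo >= hi:
        raise ValueError(f"need lo < hi, got [{lo}, {hi}]")
    flags = (grid.values >= lo) & (grid.values <= hi)
    if not flags.any():
        warnings.warn(
            f"silent region [{lo}, {hi}] cm^-1 does not intersect the grid", stacklevel=2
        )
    return RegionMask(flags, lo, hi)
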