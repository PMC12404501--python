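"""Core containers for Raman spectra and labeled spectral datasets.

A spectrum is a pair of equal-length vectors: a wavenumber axis in cm^-1
(strictly increasing, finite, positive) and relative intensities. Datasets
bundle many spectra sharing one axis with per-spectrum metadata (tissue
class, subject, raster-map coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AxisError",
    "Spectrum",
    "LabeledSpectrum",
    "RamanMap",
    "LabeledDataset",
    "validate_wavenumbers",
    "default_axis",
    "wide_axis",
]


class AxisError(ValueError):
    """Raised when a wavenumber axis violates its invariants."""


def validate_wavenumbers(values: np.ndarray) -> np.ndarray:
    """Validate a wavenumber axis: finite, positive, strictly increasing.

    Returns the validated array as float64.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise AxisError("wavenumber axis must be a non-empty 1-D vector")
    if not np.all(np.isfinite(values)):
        raise AxisError("wavenumber axis contains non-finite values")
    if np.any(values <= 0):
        raise AxisError("wavenumbers must be positive (cm^-1)")
    if np.any(np.diff(values) <= 0):
        raise AxisError("wavenumber axis must be strictly increasing")
    return values


def default_axis() -> np.ndarray:
    """Default axis: 400-1800 cm^-1 at 1.0 cm^-1 spacing (fingerprint region)."""
    return np.arange(400.0, 1801.0, 1.0)


def wide_axis() -> np.ndarray:
    """Wider 300-2000 cm^-1 axis preset, used to exercise fingerprint truncation."""
    return np.arange(300.0, 2001.0, 1.0)


@dataclass
class Spectrum:
    """One Raman spectrum: wavenumber axis (cm^-1) plus intensity vector.

    ``provenance`` records the processing stages already applied, as a list
    of dicts appended by the preprocessing pipeline; it does not take part
    in equality.
    """

    wavenumbers: np.ndarray
    intensity: np.ndarray
    provenance: list = field(default_factory=list, compare=False, repr=False)

    def __post_init__(self) -> None:
        self.wavenumbers = validate_wavenumbers(self.wavenumbers)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != self.wavenumbers.shape:
            raise ValueError(
                f"intensity length {self.intensity.size} != axis length "
                f"{self.wavenumbers.size}"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity contains non-finite values")

    def __len__(self) -> int:
        return self.wavenumbers.size

    def copy(self) -> "Spectrum":
        return Spectrum(
            self.wavenumbers.copy(), self.intensity.copy(), list(self.provenance)
        )


@dataclass
class LabeledSpectrum:
    """A spectrum with its tissue-class label and acquisition metadata."""

    spectrum: Spectrum
    label: str
    subject_id: str = ""
    map_row: Optional[int] = None
    map_col: Optional[int] = None


@dataclass
class RamanMap:
    """A raster map: ``rows x cols`` spectra in row-major order."""

    rows: int
    cols: int
    spectra: list  # list[LabeledSpectrum], row-major

    def __post_init__(self) -> None:
        if len(self.spectra) != self.rows * self.cols:
            raise ValueError(
                f"expected {self.rows * self.cols} spectra, got {len(self.spectra)}"
            )

    def __len__(self) -> int:
        return len(self.spectra)


META_COLUMNS = ("label", "subject_id", "map_row", "map_col")


@dataclass
class LabeledDataset:
    """Many spectra on a shared axis, with per-spectrum metadata.

    ``intensities`` is an (n_spectra, n_channels) matrix; ``meta`` is a
    DataFrame with columns label / subject_id / map_row / map_col, one row
    per spectrum and a RangeIndex.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.wavenumbers = validate_wavenumbers(self.wavenumbers)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.intensities.shape[1] != self.wavenumbers.size and self.intensities.size:
            raise ValueError("intensity matrix width does not match axis length")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if len(self.meta) != self.intensities.shape[0]:
            raise ValueError("metadata row count does not match spectrum count")
        self.meta = self.meta.reset_index(drop=True)

    def __len__(self) -> int:
        return self.intensities.shape[0]

    @property
    def labels(self) -> np.ndarray:
        return self.meta["label"].to_numpy()

    def class_counts(self) -> dict:
        """Per-class spectrum tallies, keyed by class code."""
        vc = self.meta["label"].value_counts()
        return {str(k): int(v) for k, v in vc.items()}

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        indices = np.asarray(indices, dtype=int)
        return LabeledDataset(
            self.wavenumbers.copy(),
            self.intensities[indices].copy(),
            self.meta.iloc[indices].reset_index(drop=True),
        )

    def iter_spectra(self) -> Iterator[LabeledSpectrum]:
        for i in range(len(self)):
            row = self.meta.iloc[i]
            mr = row["map_row"]
            mc = row["map_col"]
            yield LabeledSpectrum(
                Spectrum(self.wavenumbers, self.intensities[i]),
                label=str(row["label"]),
                subject_id=str(row["subject_id"]),
                map_row=None if pd.isna(mr) else int(mr),
                map_col=None if pd.isna(mc) else int(mc),
            )

    @classmethod
    def from_spectra(cls, spectra: Sequence[LabeledSpectrum]) -> "LabeledDataset":
        """Stack labeled spectra (all on an identical axis) into a dataset."""
        if not spectra:
            raise ValueError("cannot build a dataset from zero spectra")
        axis = spectra[0].spectrum.wavenumbers
        for ls in spectra[1:]:
            if not np.array_equal(ls.spectrum.wavenumbers, axis):
                raise AxisError("spectra do not share a common wavenumber axis")
        mat = np.stack([ls.spectrum.intensity for ls in spectra])
        meta = pd.DataFrame(
            {
                "label": [ls.label for ls in spectra],
                "subject_id": [ls.subject_id for ls in spectra],
                "map_row": [ls.map_row for ls in spectra],
                "map_col": [ls.map_col for ls in spectra],
            }
        )
        return cls(axis.copy(), mat, meta)

    @classmethod
    def empty(cls, wavenumbers: np.ndarray) -> "LabeledDataset":
        return cls(
            np.asarray(wavenumbers, dtype=float),
            np.empty((0, np.asarray(wavenumbers).size)),
            pd.DataFrame({c: [] for c in META_COLUMNS}),
        )

    @classmethod
    def concat(cls, parts: Sequence["LabeledDataset"]) -> "LabeledDataset":
        parts = [p for p in parts]
        if not parts:
            raise ValueError("nothing to concatenate")
        axis = parts[0].wavenumbers
        for p in parts[1:]:
            if not np.array_equal(p.wavenumbers, axis):
                raise AxisError("datasets do not share a common wavenumber axis")
        return cls(
            axis.copy(),
            np.concatenate([p.intensities for p in parts], axis=0),
            pd.concat([p.meta for p in parts], ignore_index=True),
        )
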