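"""Readers and writers for the package's spectrum file dialects.

Two on-disk dialects are supported, both UTF-8 CSV with '.' decimals:

* **wide CSV** — first column ``wavenumber``, one column per spectrum
  (``spec_000001`` ...), plus a sidecar ``<stem>_labels.csv`` holding
  ``spectrum_id, label, subject_id, map_row, map_col``;
* **two-column text** — one file per spectrum (``wavenumber, intensity``,
  optional header auto-skipped), mirroring common instrument ASCII
  exports, with an optional ``labels.csv`` sidecar in the directory
  keyed by filename stem.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .spectra import AxisError, LabeledDataset, META_COLUMNS

__all__ = [
    "write_wide_csv",
    "read_wide_csv",
    "write_two_column_dir",
    "read_two_column_dir",
    "read_spectra",
    "write_spectra",
]

PathLike = Union[str, Path]


def _labels_sidecar(path: Path) -> Path:
    return path.with_name(path.stem + "_labels.csv")


def write_wide_csv(ds: LabeledDataset, path: PathLike) -> Path:
    """Write a dataset as wide CSV + label sidecar; returns the CSV path."""
    path = Path(path)
    ids = [f"spec_{i:06d}" for i in range(len(ds))]
    frame = pd.DataFrame(ds.intensities.T, columns=ids)
    frame.insert(0, "wavenumber", ds.wavenumbers)
    frame.to_csv(path, index=False)
    sidecar = ds.meta.copy()
    sidecar.insert(0, "spectrum_id", ids)
    sidecar.to_csv(_labels_sidecar(path), index=False)
    return path


def read_wide_csv(path: PathLike) -> LabeledDataset:
    """Read a wide CSV (with its label sidecar when present)."""
    path = Path(path)
    frame = pd.read_csv(path)
    if "wavenumber" not in frame.columns:
        raise ValueError(f"{path.name}: first column must be 'wavenumber'")
    axis = frame["wavenumber"].to_numpy(dtype=float)
    ids = [c for c in frame.columns if c != "wavenumber"]
    mat = frame[ids].to_numpy(dtype=float).T
    sidecar_path = _labels_sidecar(path)
    if sidecar_path.exists():
        sidecar = pd.read_csv(sidecar_path).set_index("spectrum_id")
        meta = sidecar.reindex(ids).reset_index(drop=True)
        for col in META_COLUMNS:
            if col not in meta.columns:
                meta[col] = None
        meta = meta[list(META_COLUMNS)]
        meta["label"] = meta["label"].fillna("UNKNOWN")
        meta["subject_id"] = meta["subject_id"].fillna("")
    else:
        meta = pd.DataFrame(
            {"label": ["UNKNOWN"] * len(ids), "subject_id": [""] * len(ids),
             "map_row": [None] * len(ids), "map_col": [None] * len(ids)}
        )
    return LabeledDataset(axis, mat, meta)


def write_two_column_dir(ds: LabeledDataset, directory: PathLike,
                         header: bool = True) -> Path:
    """Write one two-column text file per spectrum plus a labels.csv sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ids = []
    for i in range(len(ds)):
        label = str(ds.meta.iloc[i]["label"])
        stem = f"{label}_{i:06d}"
        ids.append(stem)
        lines = []
        if header:
            lines.append("wavenumber,intensity")
        lines.extend(
            f"{w:.6f},{y:.10g}"
            for w, y in zip(ds.wavenumbers, ds.intensities[i])
        )
        (directory / f"{stem}.txt").write_text("\n".join(lines) + "\n")
    sidecar = ds.meta.copy()
    sidecar.insert(0, "spectrum_id", ids)
    sidecar.to_csv(directory / "labels.csv", index=False)
    return directory


def _read_two_column_file(path: Path) -> tuple:
    """Parse one two-column file; returns (axis, intensity)."""
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.replace("\t", ",").split(",")
            if len(parts) < 2:
                raise ValueError(f"{path.name}:{lineno}: expected two columns")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError:
                if lineno == 1:  # header line: auto-skip
                    continue
                raise ValueError(
                    f"{path.name}:{lineno}: non-numeric cell {parts[:2]!r}"
                ) from None
    if not rows:
        raise ValueError(f"{path.name}: no data rows")
    arr = np.asarray(rows, dtype=float)
    return arr[:, 0], arr[:, 1]


def read_two_column_dir(directory: PathLike) -> LabeledDataset:
    """Read every two-column text file in a directory into one dataset.

    All files must share an identical wavenumber axis; a mismatch raises
    an error naming the offending file. Labels come from ``labels.csv``
    when present, else from the filename prefix before the last ``_``.
    """
    directory = Path(directory)
    files = sorted(
        p for p in directory.iterdir()
        if p.suffix.lower() in (".txt", ".csv") and p.name != "labels.csv"
    )
    if not files:
        raise FileNotFoundError(f"no spectrum files in {directory}")
    sidecar = None
    sidecar_path = directory / "labels.csv"
    if sidecar_path.exists():
        sidecar = pd.read_csv(sidecar_path).set_index("spectrum_id")
        # The sidecar fixes the row order; files it does not know about
        # follow in name order.
        by_stem = {p.stem: p for p in files}
        ordered = [by_stem[s] for s in sidecar.index if s in by_stem]
        ordered += [p for p in files if p.stem not in set(sidecar.index)]
        files = ordered

    axis = None
    mats, meta_rows = [], []
    for path in files:
        w, y = _read_two_column_file(path)
        if axis is None:
            axis = w
        elif w.shape != axis.shape or not np.allclose(w, axis):
            raise AxisError(
                f"axis mismatch in {path.name}: does not match {files[0].name}"
            )
        mats.append(y)
        stem = path.stem
        if sidecar is not None and stem in sidecar.index:
            row = sidecar.loc[stem]
            meta_rows.append({
                "label": row.get("label", "UNKNOWN"),
                "subject_id": row.get("subject_id", ""),
                "map_row": row.get("map_row"),
                "map_col": row.get("map_col"),
            })
        else:
            label = stem.rsplit("_", 1)[0] if "_" in stem else "UNKNOWN"
            meta_rows.append({"label": label, "subject_id": "",
                              "map_row": None, "map_col": None})
    return LabeledDataset(axis, np.stack(mats), pd.DataFrame(meta_rows))


def read_spectra(path: PathLike) -> LabeledDataset:
    """Read spectra from a wide CSV file or a directory of two-column files."""
    path = Path(path)
    if path.is_dir():
        return read_two_column_dir(path)
    if path.suffix.lower() == ".csv":
        return read_wide_csv(path)
    raise ValueError(f"cannot infer spectrum format for {path}")


def write_spectra(ds: LabeledDataset, path: PathLike,
                  fmt: str = "wide") -> Path:
    """Write a dataset; ``fmt`` is ``"wide"`` (CSV) or ``"two-column"`` (dir)."""
    if fmt == "wide":
        return write_wide_csv(ds, path)
    if fmt == "two-column":
        return write_two_column_dir(ds, path)
    raise ValueError(f"unknown format {fmt!r}")
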