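"""Spectral conditioning chain for Raman spectra.

The chain runs in a fixed order: polynomial baseline correction, median
despiking (cosmic-ray removal), Savitzky-Golay smoothing, per-spectrum
min-max normalization to [0, 1], and truncation to the 400-1800 cm^-1
fingerprint region. The order is part of the contract: configuration can
skip a stage explicitly but never reorder the chain.

The baseline fitter defaults to an iterative asymmetric polynomial scheme
(ModPoly-style): fit a polynomial by least squares, clip the working
spectrum to the fit wherever it lies above it, and refit until the
coefficients stabilize. Clipping makes the polynomial track the slowly
varying fluorescence floor through the valleys instead of being pulled up
by Raman peaks. A plain single-pass least-squares fit is available for
comparison via ``method="ls"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import savgol_filter

from .spectra import LabeledDataset, Spectrum

__all__ = [
    "PreprocessConfig",
    "DegenerateSpectrumWarning",
    "EmptySpectrumError",
    "fit_baseline",
    "subtract_baseline",
    "despike_median",
    "smooth_savgol",
    "normalize_minmax",
    "truncate_fingerprint",
    "preprocess_pipeline",
    "preprocess_dataset",
]

#: The canonical stage order. Immutable; configs may only skip stages.
STAGE_ORDER: Tuple[str, ...] = (
    "baseline", "despike", "smooth", "normalize", "truncate",
)


class DegenerateSpectrumWarning(UserWarning):
    """Emitted when a degenerate (constant) spectrum is normalized to zeros."""


class EmptySpectrumError(ValueError):
    """Raised when truncation would leave no samples."""


@dataclass
class PreprocessConfig:
    """Parameters of the conditioning chain.

    ``baseline_poly_order=5`` and ``savgol_polyorder=3`` follow the
    acquisition protocol; the median kernel (5) and SG window (11) are
    conventions chosen so that a single-channel spike is removed while
    ~5 cm^-1 wide bands survive smoothing. ``truncate_first=False`` keeps
    normalization before truncation (the protocol's stated order); setting
    it swaps the two final stages for the more common alternative.
    """

    baseline_poly_order: int = 5
    baseline_method: str = "modpoly"  # or "ls"
    median_kernel: int = 5
    savgol_window: int = 11
    savgol_polyorder: int = 3
    norm_min: float = 0.0
    norm_max: float = 1.0
    fingerprint_lo: float = 400.0
    fingerprint_hi: float = 1800.0
    skip_stages: Tuple[str, ...] = ()
    truncate_first: bool = False

    def __post_init__(self) -> None:
        if self.median_kernel < 3 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be odd and >= 3")
        if self.savgol_window < 3 or self.savgol_window % 2 == 0:
            raise ValueError("savgol_window must be odd and >= 3")
        if self.savgol_window <= self.savgol_polyorder:
            raise ValueError("savgol_window must exceed savgol_polyorder")
        if self.fingerprint_lo >= self.fingerprint_hi:
            raise ValueError("fingerprint_lo must be < fingerprint_hi")
        unknown = set(self.skip_stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stage(s) to skip: {sorted(unknown)}")


def _design_matrix(wavenumbers: np.ndarray, order: int) -> np.ndarray:
    # Rescale to [-1, 1] for conditioning before building the Vandermonde.
    lo, hi = wavenumbers[0], wavenumbers[-1]
    t = 2.0 * (wavenumbers - lo) / (hi - lo) - 1.0 if hi > lo else wavenumbers * 0.0
    return np.polynomial.polynomial.polyvander(t, order)


def _modpoly(y: np.ndarray, vander: np.ndarray, pinv: np.ndarray,
             tol: float = 1e-6, max_iter: int = 100) -> np.ndarray:
    """Iterative asymmetric polynomial baseline on (n_spectra, n_channels) rows.

    Each round clips the *original* spectrum to the current fit before
    refitting. Re-clipping from the original (rather than from the
    previous working copy) means an isolated large outlier — a cosmic-ray
    spike — contributes only its fit value at the fixed point, so it
    cannot drag the converged baseline.
    """
    coeffs = y @ pinv.T
    for _ in range(max_iter):
        fit = coeffs @ vander.T
        work = np.minimum(y, fit)
        new_coeffs = work @ pinv.T
        delta = np.max(np.abs(new_coeffs - coeffs))
        coeffs = new_coeffs
        if delta < tol:
            break
    return coeffs @ vander.T


def fit_baseline(s: Spectrum, order: int, method: str = "modpoly") -> np.ndarray:
    """Fit the fluorescence baseline of a spectrum with a degree-``order`` polynomial.

    Returns the evaluated baseline, same length as the input. ``method``
    is ``"modpoly"`` (iterative asymmetric refit, default) or ``"ls"``
    (plain least squares).
    """
    if order < 0:
        raise ValueError("polynomial order must be >= 0")
    n = len(s)
    if n <= order:
        raise ValueError(
            f"spectrum of length {n} cannot constrain a degree-{order} polynomial"
        )
    vander = _design_matrix(s.wavenumbers, order)
    pinv = np.linalg.pinv(vander)
    y = s.intensity[np.newaxis, :]
    if method == "ls":
        return ((y @ pinv.T) @ vander.T)[0]
    if method == "modpoly":
        return _modpoly(y, vander, pinv)[0]
    raise ValueError(f"unknown baseline method {method!r}")


def subtract_baseline(s: Spectrum, baseline: np.ndarray) -> Spectrum:
    """Subtract an evaluated baseline from a spectrum, preserving the axis."""
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape != s.intensity.shape:
        raise ValueError("baseline length does not match spectrum length")
    return Spectrum(s.wavenumbers, s.intensity - baseline, list(s.provenance))


def despike_median(s: Spectrum, kernel: int = 5) -> Spectrum:
    """Remove cosmic-ray spikes with a running median.

    Edges are handled by mirror reflection (the edge sample is not
    duplicated), so a spike on the first or last channel still sees real
    neighbors and is rejected.
    """
    if kernel % 2 == 0:
        raise ValueError("median kernel must be odd")
    if kernel < 3 or kernel > len(s):
        raise ValueError("median kernel must be >= 3 and <= spectrum length")
    out = median_filter(s.intensity, size=kernel, mode="mirror")
    return Spectrum(s.wavenumbers, out, list(s.provenance))


def smooth_savgol(s: Spectrum, window: int = 11, polyorder: int = 3) -> Spectrum:
    """Savitzky-Golay smoothing; exact on polynomials up to ``polyorder``."""
    if window % 2 == 0:
        raise ValueError("savgol window must be odd")
    if window <= polyorder:
        raise ValueError("savgol window must exceed the polynomial order")
    out = savgol_filter(s.intensity, window_length=window, polyorder=polyorder)
    return Spectrum(s.wavenumbers, out, list(s.provenance))


def normalize_minmax(s: Spectrum) -> Spectrum:
    """Rescale intensities to [0, 1] per spectrum.

    A constant spectrum has no range to scale; it maps to all zeros and a
    :class:`DegenerateSpectrumWarning` is emitted.
    """
    lo = float(np.min(s.intensity))
    hi = float(np.max(s.intensity))
    if hi == lo:
        warnings.warn(
            "constant spectrum normalized to zeros", DegenerateSpectrumWarning
        )
        return Spectrum(s.wavenumbers, np.zeros_like(s.intensity), list(s.provenance))
    return Spectrum(s.wavenumbers, (s.intensity - lo) / (hi - lo), list(s.provenance))


def truncate_fingerprint(s: Spectrum, lo: float = 400.0, hi: float = 1800.0) -> Spectrum:
    """Keep the samples with ``lo <= wavenumber <= hi`` (closed interval)."""
    if lo >= hi:
        raise ValueError("truncation interval must satisfy lo < hi")
    mask = (s.wavenumbers >= lo) & (s.wavenumbers <= hi)
    if not np.any(mask):
        raise EmptySpectrumError(
            f"no samples in [{lo}, {hi}] cm^-1 on axis "
            f"[{s.wavenumbers[0]}, {s.wavenumbers[-1]}]"
        )
    return Spectrum(s.wavenumbers[mask], s.intensity[mask], list(s.provenance))


def preprocess_pipeline(s: Spectrum, cfg: Optional[PreprocessConfig] = None) -> Spectrum:
    """Run the full conditioning chain on one spectrum.

    Stages execute in the fixed order baseline -> despike -> smooth ->
    normalize -> truncate (normalize/truncate swap if ``truncate_first``).
    Each executed stage appends a provenance record to the output spectrum.
    """
    cfg = cfg or PreprocessConfig()
    order = list(STAGE_ORDER)
    if cfg.truncate_first:
        i, j = order.index("normalize"), order.index("truncate")
        order[i], order[j] = order[j], order[i]
    out = s.copy()
    for stage in order:
        if stage in cfg.skip_stages:
            out.provenance.append({"stage": stage, "skipped": True})
            continue
        if stage == "baseline":
            baseline = fit_baseline(out, cfg.baseline_poly_order, cfg.baseline_method)
            out = subtract_baseline(out, baseline)
            record = {"stage": stage, "order": cfg.baseline_poly_order,
                      "method": cfg.baseline_method}
        elif stage == "despike":
            out = despike_median(out, cfg.median_kernel)
            record = {"stage": stage, "kernel": cfg.median_kernel}
        elif stage == "smooth":
            out = smooth_savgol(out, cfg.savgol_window, cfg.savgol_polyorder)
            record = {"stage": stage, "window": cfg.savgol_window,
                      "polyorder": cfg.savgol_polyorder}
        elif stage == "normalize":
            out = normalize_minmax(out)
            record = {"stage": stage, "range": [cfg.norm_min, cfg.norm_max]}
        else:  # truncate
            out = truncate_fingerprint(out, cfg.fingerprint_lo, cfg.fingerprint_hi)
            record = {"stage": stage,
                      "interval": [cfg.fingerprint_lo, cfg.fingerprint_hi]}
        out.provenance.append(record)
    return out


def preprocess_dataset(ds: LabeledDataset,
                       cfg: Optional[PreprocessConfig] = None) -> LabeledDataset:
    """Vectorized conditioning chain over every spectrum of a dataset.

    Equivalent to mapping :func:`preprocess_pipeline` over the rows, but the
    baseline/filter/normalization stages operate on the whole intensity
    matrix at once.
    """
    cfg = cfg or PreprocessConfig()
    order = list(STAGE_ORDER)
    if cfg.truncate_first:
        i, j = order.index("normalize"), order.index("truncate")
        order[i], order[j] = order[j], order[i]
    axis = ds.wavenumbers.copy()
    mat = ds.intensities.copy()
    for stage in order:
        if stage in cfg.skip_stages:
            continue
        if stage == "baseline":
            if axis.size <= cfg.baseline_poly_order:
                raise ValueError("spectra too short for the baseline polynomial")
            vander = _design_matrix(axis, cfg.baseline_poly_order)
            pinv = np.linalg.pinv(vander)
            if cfg.baseline_method == "ls":
                mat = mat - (mat @ pinv.T) @ vander.T
            else:
                mat = mat - _modpoly(mat, vander, pinv)
        elif stage == "despike":
            mat = median_filter(mat, size=(1, cfg.median_kernel), mode="mirror")
        elif stage == "smooth":
            mat = savgol_filter(mat, window_length=cfg.savgol_window,
                                polyorder=cfg.savgol_polyorder, axis=1)
        elif stage == "normalize":
            lo = mat.min(axis=1, keepdims=True)
            hi = mat.max(axis=1, keepdims=True)
            span = hi - lo
            flat = (span == 0.0).ravel()
            if np.any(flat):
                warnings.warn(
                    f"{int(flat.sum())} constant spectrum(s) normalized to zeros",
                    DegenerateSpectrumWarning,
                )
            span[span == 0.0] = 1.0
            mat = (mat - lo) / span
            mat[flat] = 0.0
        else:  # truncate
            mask = (axis >= cfg.fingerprint_lo) & (axis <= cfg.fingerprint_hi)
            if not np.any(mask):
                raise EmptySpectrumError(
                    f"no samples in [{cfg.fingerprint_lo}, {cfg.fingerprint_hi}]"
                )
            axis = axis[mask]
            mat = mat[:, mask]
    return LabeledDataset(axis, mat, ds.meta.copy())
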