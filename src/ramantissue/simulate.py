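"""Synthetic Raman spectrum generator for the eight-class tissue ontology.

Real patient spectra from surgical resections are not publicly deposited,
so this module generates labeled spectra carrying the statistical structure
the downstream analysis assumes: per-class vibrational band templates
(Lorentzian/Gaussian lineshapes at the characteristic band positions of
each tissue type), a smooth fluorescence-like polynomial baseline drawn
fresh per spectrum, i.i.d. Gaussian detector noise, occasional
single-channel cosmic-ray spikes, per-spectrum peak-center jitter and
multiplicative amplitude variation, raster maps of 51 x 51 spectra per
measurement area, and the class imbalance of the clinical dataset.

Band-position conventions
-------------------------
Normal fat (FAT) carries lipid bands at 1266, 1300, 1438 and 1654 cm^-1.
The malignant adipocytic tumors (MLS, PLS) share the fat band set, add
carotenoid bands near 1000 and 1554 cm^-1, and show an elevated intensity
ratio of the ~1654 cm^-1 C=C stretch relative to the ~1438 cm^-1 C-H bend
(higher lipid polyunsaturation in tumor). Muscle (MSC) and the sarcomas
HMS, LEI and MLS carry a strong composite band between 650 and 850 cm^-1
(amino-acid / nucleotide region). The LEM and SKN templates are synthetic
conventions, not measured biology: LEM is a muscle-like template without
the 650-850 cm^-1 amplification, and SKN is broad amide/CH bands plus a
unique marker band at 1745 cm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .spectra import (
    LabeledDataset,
    LabeledSpectrum,
    RamanMap,
    Spectrum,
    default_axis,
    validate_wavenumbers,
    wide_axis,
)

__all__ = [
    "PeakSpec",
    "TissueProfile",
    "TISSUE_CLASSES",
    "TABLE1_COUNTS",
    "default_profiles",
    "template_intensity",
    "generate_spectrum",
    "generate_map",
    "generate_dataset",
    "table1_counts",
    "table1_scaled",
]

#: Canonical class order (also the ontology order used in evaluation).
TISSUE_CLASSES: Tuple[str, ...] = (
    "MSC", "SKN", "FAT", "LEM", "MLS", "PLS", "LEI", "HMS",
)

#: Per-class spectrum counts of the clinical dataset (sums to 286,672).
TABLE1_COUNTS: Dict[str, int] = {
    "MSC": 33_712,
    "SKN": 62_424,
    "FAT": 31_212,
    "LEM": 10_404,
    "MLS": 83_742,
    "PLS": 28_764,
    "LEI": 18_207,
    "HMS": 18_207,
}


@dataclass(frozen=True)
class PeakSpec:
    """One vibrational band: center (cm^-1), HWHM width (cm^-1), amplitude, shape."""

    center: float
    width: float
    amplitude: float
    shape: str = "lorentzian"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("peak width must be > 0")
        if self.amplitude < 0:
            raise ValueError("peak amplitude must be >= 0")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown lineshape {self.shape!r}")

    def evaluate(self, wavenumbers: np.ndarray, center: Optional[float] = None,
                 amplitude: Optional[float] = None) -> np.ndarray:
        """Evaluate the lineshape on an axis, optionally overriding center/amplitude."""
        c = self.center if center is None else center
        a = self.amplitude if amplitude is None else amplitude
        x = np.asarray(wavenumbers, dtype=float)
        if self.shape == "lorentzian":
            return a * self.width**2 / ((x - c) ** 2 + self.width**2)
        # Gaussian parameterized by HWHM for consistency with the Lorentzian.
        sigma = self.width / np.sqrt(2.0 * np.log(2.0))
        return a * np.exp(-0.5 * ((x - c) / sigma) ** 2)


# Per-coefficient uniform ranges for the fluorescence-like baseline polynomial,
# in the rescaled coordinate t in [0, 1] across the axis. Degree <= 5. The
# constant term dominates so baselines are comparable to or larger than the
# (unit-scale) Raman peaks, as fluorescence backgrounds typically are.
DEFAULT_BASELINE_RANGES: Tuple[Tuple[float, float], ...] = (
    (1.0, 3.0),
    (-1.0, 1.0),
    (-1.0, 1.0),
    (-0.5, 0.5),
    (-0.5, 0.5),
    (-0.5, 0.5),
)


@dataclass(frozen=True)
class TissueProfile:
    """Generative template for one tissue class.

    Parameters
    ----------
    tissue_class
        One of the eight class codes.
    peaks
        Band templates summed to form the noiseless spectrum.
    baseline_coeff_ranges
        Uniform ranges for the polynomial baseline coefficients (degree <= 5),
        drawn fresh per spectrum so the baseline carries no class information.
    noise_sigma
        Standard deviation of i.i.d. Gaussian noise, in relative intensity
        units (peak amplitudes are O(1)).
    peak_jitter
        Scale (cm^-1) of the per-spectrum Gaussian perturbation of each
        band center.
    amplitude_cv
        Coefficient of variation of the per-spectrum multiplicative
        amplitude factor applied to each band.
    spike_prob
        Probability that a spectrum carries one cosmic-ray spike: a single
        random channel incremented by a uniform draw from [10, 50] times
        the maximum template amplitude.
    """

    tissue_class: str
    peaks: Tuple[PeakSpec, ...]
    baseline_coeff_ranges: Tuple[Tuple[float, float], ...] = DEFAULT_BASELINE_RANGES
    noise_sigma: float = 0.02
    peak_jitter: float = 1.5
    amplitude_cv: float = 0.08
    spike_prob: float = 0.05

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0.0 <= self.spike_prob <= 1.0:
            raise ValueError("spike_prob must be in [0, 1]")
        if self.peak_jitter < 0:
            raise ValueError("peak_jitter must be >= 0")
        if self.amplitude_cv < 0:
            raise ValueError("amplitude_cv must be >= 0")
        if len(self.baseline_coeff_ranges) > 6:
            raise ValueError("baseline polynomial degree is limited to 5")

    @property
    def max_amplitude(self) -> float:
        return max((p.amplitude for p in self.peaks), default=1.0)


def _p(center, amplitude, width, shape="lorentzian"):
    return PeakSpec(center=center, width=width, amplitude=amplitude, shape=shape)


def default_profiles(**overrides) -> Dict[str, TissueProfile]:
    """Default generative templates for the eight tissue classes.

    Keyword overrides (e.g. ``noise_sigma=0.0``, ``spike_prob=1.0``) are
    applied uniformly to every class, which is convenient for tests that
    need noise-free or always-spiked spectra.
    """
    peak_sets: Dict[str, Tuple[PeakSpec, ...]] = {
        # Muscle: strong 650-850 composite + protein bands.
        "MSC": (
            _p(680, 0.45, 20), _p(756, 0.55, 15), _p(820, 0.40, 15),
            _p(1003, 0.50, 6), _p(1315, 0.45, 12), _p(1448, 0.85, 10),
            _p(1657, 0.90, 12),
        ),
        # Skin: broad amide/CH bands + synthetic 1745 marker (convention).
        "SKN": (
            _p(1002, 0.45, 6), _p(1270, 0.50, 20, "gaussian"),
            _p(1450, 0.80, 12), _p(1655, 0.85, 16, "gaussian"),
            _p(1745, 0.40, 8),
        ),
        # Fat: lipid bands; 1654:1438 ratio 0.70 (reference for the tumors).
        "FAT": (
            _p(1080, 0.30, 10), _p(1266, 0.50, 8), _p(1300, 0.80, 8),
            _p(1438, 1.00, 9), _p(1654, 0.70, 10),
        ),
        # Leiomyoma: muscle-like template without the 650-850 amplification
        # (synthetic convention).
        "LEM": (
            _p(935, 0.30, 10), _p(1003, 0.40, 6), _p(1260, 0.40, 10),
            _p(1448, 0.75, 10), _p(1657, 0.80, 12),
        ),
        # Myxoid liposarcoma: fat band set + carotenoid 1000/1554 + 650-850
        # band; 1654:1438 ratio 0.94 > fat's 0.70.
        "MLS": (
            _p(740, 0.40, 25), _p(1000, 0.50, 6), _p(1266, 0.45, 8),
            _p(1300, 0.70, 8), _p(1438, 0.90, 9), _p(1554, 0.45, 8),
            _p(1654, 0.85, 10),
        ),
        # Pleomorphic liposarcoma: as MLS minus the 650-850 band, with the
        # highest unsaturation ratio (1654:1438 = 1.15).
        "PLS": (
            _p(1000, 0.55, 6), _p(1266, 0.40, 8), _p(1300, 0.65, 8),
            _p(1438, 0.80, 9), _p(1554, 0.50, 8), _p(1654, 0.92, 10),
        ),
        # Leiomyosarcoma: muscle-like with shifted amide III (1335) and its
        # own 650-850 weighting.
        "LEI": (
            _p(690, 0.50, 18), _p(745, 0.70, 14), _p(830, 0.35, 12),
            _p(1003, 0.45, 6), _p(1335, 0.60, 12), _p(1448, 0.80, 10),
            _p(1657, 0.85, 12),
        ),
        # High-grade myxofibrosarcoma: 650-850 band + broad amide III 1245.
        "HMS": (
            _p(700, 0.50, 22), _p(770, 0.55, 18), _p(1003, 0.35, 6),
            _p(1245, 0.50, 18, "gaussian"), _p(1438, 0.75, 10),
            _p(1654, 0.80, 12),
        ),
    }
    return {
        cls: TissueProfile(tissue_class=cls, peaks=peak_sets[cls], **overrides)
        for cls in TISSUE_CLASSES
    }


def template_intensity(profile: TissueProfile, wavenumbers: np.ndarray) -> np.ndarray:
    """Noise-free, baseline-free template spectrum for a profile."""
    wavenumbers = validate_wavenumbers(wavenumbers)
    out = np.zeros_like(wavenumbers)
    for pk in profile.peaks:
        out += pk.evaluate(wavenumbers)
    return out


def _random_baseline(profile: TissueProfile, wavenumbers: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    ranges = profile.baseline_coeff_ranges
    if not ranges:
        return np.zeros_like(wavenumbers)
    lo = np.array([r[0] for r in ranges])
    hi = np.array([r[1] for r in ranges])
    coeffs = rng.uniform(lo, hi)
    span = wavenumbers[-1] - wavenumbers[0]
    t = (wavenumbers - wavenumbers[0]) / (span if span > 0 else 1.0)
    return np.polynomial.polynomial.polyval(t, coeffs)


def generate_spectrum(profile: TissueProfile, wavenumbers: np.ndarray,
                      rng: np.random.Generator,
                      subject_id: str = "",
                      map_row: Optional[int] = None,
                      map_col: Optional[int] = None) -> LabeledSpectrum:
    """Draw one labeled spectrum from a tissue profile.

    intensity = sum of jittered/amplitude-varied lineshapes
              + random polynomial baseline + Gaussian noise
              (+ one cosmic-ray spike with probability ``spike_prob``).
    """
    wavenumbers = validate_wavenumbers(wavenumbers)
    intensity = np.zeros_like(wavenumbers)
    for pk in profile.peaks:
        center = pk.center + rng.normal(0.0, profile.peak_jitter) \
            if profile.peak_jitter > 0 else pk.center
        amp = pk.amplitude
        if profile.amplitude_cv > 0:
            amp = amp * max(0.0, 1.0 + rng.normal(0.0, profile.amplitude_cv))
        intensity += pk.evaluate(wavenumbers, center=center, amplitude=amp)
    intensity += _random_baseline(profile, wavenumbers, rng)
    if profile.noise_sigma > 0:
        intensity += rng.normal(0.0, profile.noise_sigma, size=wavenumbers.size)
    if profile.spike_prob > 0 and rng.random() < profile.spike_prob:
        channel = int(rng.integers(0, wavenumbers.size))
        intensity[channel] += rng.uniform(10.0, 50.0) * profile.max_amplitude
    return LabeledSpectrum(
        Spectrum(wavenumbers, intensity),
        label=profile.tissue_class,
        subject_id=subject_id,
        map_row=map_row,
        map_col=map_col,
    )


def generate_map(profile: TissueProfile, rows: int, cols: int,
                 rng: np.random.Generator,
                 wavenumbers: Optional[np.ndarray] = None,
                 subject_id: str = "") -> RamanMap:
    """Generate a raster map of ``rows x cols`` spectra with grid coordinates.

    The clinical acquisition raster is 51 x 51 per measurement area,
    i.e. 2,601 spectra.
    """
    if rows < 1 or cols < 1:
        raise ValueError("map dimensions must be >= 1")
    if wavenumbers is None:
        wavenumbers = default_axis()
    spectra = [
        generate_spectrum(profile, wavenumbers, rng, subject_id=subject_id,
                          map_row=r, map_col=c)
        for r in range(rows) for c in range(cols)
    ]
    return RamanMap(rows=rows, cols=cols, spectra=spectra)


def table1_counts() -> Dict[str, int]:
    """The clinical per-class spectrum counts preset."""
    return dict(TABLE1_COUNTS)


def table1_scaled(factor: float) -> Dict[str, int]:
    """The clinical counts scaled by ``factor``, rounded to nearest integer."""
    if factor < 0:
        raise ValueError("scale factor must be >= 0")
    return {cls: int(round(n * factor)) for cls, n in TABLE1_COUNTS.items()}


def generate_dataset(profiles: Mapping[str, TissueProfile],
                     class_counts: Mapping[str, int],
                     rng: np.random.Generator,
                     wavenumbers: Optional[np.ndarray] = None) -> LabeledDataset:
    """Generate a labeled dataset with exactly the requested per-class counts.

    Classes are generated in canonical ontology order so that identical
    seed + configuration yields a bit-identical dataset.
    """
    unknown = set(class_counts) - set(profiles)
    if unknown:
        raise KeyError(f"unknown tissue class(es): {sorted(unknown)}")
    for cls, n in class_counts.items():
        if n < 0:
            raise ValueError(f"negative count for class {cls}")
    if wavenumbers is None:
        wavenumbers = default_axis()
    wavenumbers = validate_wavenumbers(wavenumbers)

    order = [c for c in TISSUE_CLASSES if c in class_counts]
    order += [c for c in class_counts if c not in TISSUE_CLASSES]
    mats, labels, subjects = [], [], []
    for cls in order:
        n = int(class_counts[cls])
        if n == 0:
            continue
        profile = profiles[cls]
        block = np.empty((n, wavenumbers.size))
        for i in range(n):
            block[i] = generate_spectrum(profile, wavenumbers, rng).spectrum.intensity
        mats.append(block)
        labels.extend([cls] * n)
        subjects.extend([f"sim-{cls}"] * n)

    if not mats:
        return LabeledDataset.empty(wavenumbers)
    meta = pd.DataFrame(
        {
            "label": labels,
            "subject_id": subjects,
            "map_row": [None] * len(labels),
            "map_col": [None] * len(labels),
        }
    )
    return LabeledDataset(wavenumbers.copy(), np.concatenate(mats, axis=0), meta)
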