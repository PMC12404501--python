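# Methods

## Problem and scope

The package classifies single Raman spectra of soft tissue into eight
classes — three normal (MSC muscle, SKN skin, FAT fat), one benign (LEM
leiomyoma) and four malignant (MLS myxoid liposarcoma, PLS pleomorphic
liposarcoma, LEI leiomyosarcoma, HMS high-grade myxofibrosarcoma) — and
evaluates the result with an emphasis on the clinically costly error:
calling a malignant spectrum normal or benign. Patient spectra are not
publicly deposited, so every stage is developed and validated against a
synthetic generator that reproduces the statistical structure the
analysis relies on.

## Synthetic spectrum model

A spectrum on the wavenumber axis ν (default 400–1800 cm⁻¹ at
1.0 cm⁻¹ spacing; a 300–2000 cm⁻¹ preset exercises truncation) is

    y(ν) = Σ_k a_k·(1+ε_k)·L(ν; c_k+δ_k, w_k) + b(ν) + η(ν) [+ spike]

where `L` is a Lorentzian (or Gaussian) lineshape with HWHM `w_k`,
`δ_k ~ N(0, jitter²)` with jitter 1.5 cm⁻¹ models instrument drift,
`ε_k ~ N(0, cv²)` with cv 0.08 models biological amplitude variation,
`b` is a degree-≤5 polynomial with coefficients drawn uniformly per
spectrum (constant term 1–3, i.e. the fluorescence background is
comparable to or larger than the unit-scale Raman peaks), and
`η ~ N(0, σ²)` with σ = 0.02 relative intensity. With probability 0.05 a
single random channel receives a cosmic-ray spike of 10–50 × the largest
template amplitude. Baseline coefficients are re-drawn for every spectrum
so the background carries no class information.

Class templates encode the established band structure: FAT carries the
lipid bands 1266/1300/1438/1654 cm⁻¹ with a 1654:1438 amplitude ratio of
0.70; MLS and PLS share the fat set, add carotenoid bands near 1000 and
1554 cm⁻¹, and carry elevated 1654:1438 ratios (0.94 and 1.15) modelling
higher lipid polyunsaturation in malignant adipocytic tissue; MSC, LEI,
HMS and MLS carry composite bands in 650–850 cm⁻¹. The LEM and SKN
templates are **synthetic conventions, not measured biology**: LEM is a
muscle-like template without the 650–850 cm⁻¹ amplification, SKN is
broad amide/CH bands plus a marker band at 1745 cm⁻¹ chosen to make the
class identifiable. A learning-free nearest-template-correlation
classifier exceeds 90% accuracy at the default noise level (tested), so
the learning task is well-posed by construction.

The generator deliberately omits spatial autocorrelation across raster
pixels, detector response, laser-power drift and subject-level
heterogeneity (each synthetic class has a single template; real patients
vary). Consequently, passing results here demonstrate the correctness of
the pipeline's machinery — not clinical performance on patient spectra,
which the source data would be required to assess.

## Conditioning chain

Fixed stage order: baseline → despike → smooth → normalize → truncate.
Configuration can skip a stage explicitly (logged in the per-spectrum
provenance) but never reorder. Choices:

- **Baseline**: degree-5 polynomial. A plain least-squares fit absorbs
  peaks, so the default is an iterative asymmetric scheme: fit, clip the
  *original* spectrum to the fit, refit; stop at coefficient change
  < 1e-6 or 100 iterations. Clipping from the original each round (rather
  than from the previous working copy) means an isolated cosmic-ray spike
  contributes only its fitted value at the fixed point and cannot drag
  the converged baseline. Plain least squares is available via
  `baseline_method="ls"`. The Vandermonde basis is built on the axis
  rescaled to [−1, 1] for conditioning.
- **Despiking**: running median, default kernel 5, mirror-reflected edges
  so a spike on the first or last channel still sees real neighbors.
- **Smoothing**: Savitzky–Golay, polynomial order 3, default window 11 —
  wide enough to suppress noise, narrow enough that ~5 cm⁻¹ bands
  survive. Kernel and window sizes are conventions (configurable).
- **Normalization**: per-spectrum min–max to [0, 1]. A constant spectrum
  maps to zeros with a `DegenerateSpectrumWarning` instead of NaN.
- **Truncation**: closed interval [400, 1800] cm⁻¹. Normalization runs
  *before* truncation by default, matching the acquisition protocol's
  stated order; `truncate_first=True` exposes the more common alternative.

The vectorized dataset path is tested to agree with the per-spectrum path
to 1e-10.

## Network

1-D residual network: stem (conv k=7 s=2 → batch norm → ReLU → max-pool
3/2), four layers × two residual blocks, adaptive average pooling,
fully connected softmax head. Identity blocks (stride 1, equal channels)
add the unmodified input to the two-convolution main path;
convolutional blocks reshape the shortcut with a 1-tap convolution +
batch norm, and carry all channel growth (64→128→256→512 in the default
plan) and stride-2 downsampling. Per-layer stride schedules only make
sense if downsampling lives in the shape-changing blocks; identity
blocks are constrained to stride 1 at the type level. Kernel sizes (stem
7, blocks 3) are conventions translated from canonical 2-D residual
practice. Softmax lives in the inference path (`predict_proba`);
training consumes pre-softmax scores through a log-softmax loss, so
evaluation code never double-applies softmax.

The network is implemented self-contained in numpy (im2col convolutions,
explicit backward passes, verified against finite differences to ~1e-7
relative error). He-normal initialization for convolutions; all
randomness flows through seeded generators, so builds and training runs
are bit-reproducible on CPU.

## Training recipe

- Stratified 80/20 split: per class, `floor(0.8·n_c)` spectra to the
  training side after a seeded shuffle; the floor rule is the documented
  rounding convention.
- A stratified 10% of the training split is held out as a validation set
  for model selection; the test split is never touched during training.
- Class weights `w_c = N/(K·n_c)`; loss reduction
  `Σ w_i·nll_i / Σ w_i` — batch-size independent, and exactly the
  unweighted mean when all weights are 1.
- SGD with momentum 0.9 under a triangular cyclical learning rate, base
  0.001, max 0.01, half-period 8 epochs of batches; default batch size
  128.
- 50 epochs at full scale; the epoch with minimum validation loss is
  returned (earliest epoch on ties). Non-finite loss aborts with the
  offending epoch/batch/learning-rate in the message.

## Evaluation

Confusion matrix in fixed ontology order (rows true, columns predicted);
sensitivity, specificity, precision, F1 per class with support-weighted
averages; 0/0 cells report 0 with a degenerate-class flag rather than
NaN so aggregates stay total. Precision–recall curves are one-vs-rest
with step-interpolated average precision. The clinical-alert metric is
computed per malignant class (`FNC = FN − FNM`, `CA = FNC/(TP+FN)`) and
aggregated two ways: pooled numerator/denominator over malignant classes
(micro, reported as `overall_ca`) and the mean of per-class values
(macro) — either aggregation is defensible, so both are emitted. The
implementation is tested for exact integer agreement against a
brute-force enumeration of off-diagonal cells on 1,000 random matrices.

## Problem sizes and reproducibility

The packaged CPU-scale study (`scaled_down_config`) uses 250 spectra per
class (200 train / 50 test after the 80/20 split), the reduced-width
network (stem 16; blocks 16/16/32/32/64), batch size 32 and 10 epochs —
sizes chosen so a full run completes in about a minute on a single core
while remaining comfortably above the 90%-accuracy bar the simulator's
separability guarantees. The full-scale defaults (widths up to 512,
batch 128, 50 epochs, the 286,672-spectrum count preset) are available
through the same configs.

One global seed fans out to per-stage seeds through fixed seed-sequence
spawn keys; `metrics.json` contains no timestamps, and two runs of the
same config and seed are byte-identical (tested).

## Known limitations

- Synthetic templates are stylized; no claim about patient-level
  generalization, subject effects, or real instrument artifacts.
- Batch-norm statistics make training-mode forward passes
  batch-composition dependent (as usual); evaluation mode is
  batch-independent (tested to 1e-5).
- The numpy implementation targets correctness and reproducibility over
  speed; full-scale (286k-spectrum) training is impractical on one CPU
  and is out of scope of the packaged experiments.
- No bootstrap confidence intervals, calibration analysis, or
  per-subject aggregation; evaluation is per spectrum.
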