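# Methods

`libsbridge` implements a calibration-transfer pipeline for laser-induced
breakdown spectroscopy (LIBS): a classifier is trained on emission spectra
from a low-resolution spectrometer (L) and applied to spectra from a
high-resolution spectrometer (H). Three stages bridge the instruments —
standard-lamp spectral correction (SC), ANOVA-driven feature selection (FS),
and DBSCAN post-processing (PP) — and a synthetic two-instrument simulator
makes the full chain testable without measured data.

## The measurement model

A spectrometer records `I(λ) = S(λ) · η(λ) + ε`, where `S` is the source
spectral flux, `η` the wavelength-dependent response of the
optics/grating/detector chain, and `ε` detector noise. The two instruments
modeled are:

* **L** — a CCD fiber spectrometer, 190–1100 nm, ~0.25 nm FWHM resolution,
  sensitivity rising toward the infrared;
* **H** — an echelle ICCD spectrometer, 200–850 nm, ~0.015–0.02 nm FWHM,
  sensitivity falling from the ultraviolet, with a periodic ~8 nm "ripple"
  from diffraction-order overlap.

Because `η_L ≠ η_H`, the same plasma produces spectra with different
relative line intensities on the two instruments, and a model trained on one
fails on the other.

## Spectral correction (SC)

Measuring a radiometrically certified lamp with irradiance `E(λ)` gives the
response correction `R(λ) = E(λ)/I_lamp(λ) ∝ 1/η(λ)` on each instrument
(`estimate_response`). The transfer function

    R_[L/H](λ) = R_H(λ) / R_L(λ) = η_L(λ) / η_H(λ)

maps an H-measured spectrum onto the L response scale:
`I_H · R_[L/H] = S · η_L`, i.e. what L would have measured up to resolution
(`build_transfer`, `apply_correction`). The direction of the ratio is fixed
by this derivation and verified by a simulator round trip: a flat broadband
source measured by H and corrected matches the L measurement of the same
source within 2% RMS; the opposite convention fails the test. All grid
alignment is piecewise-linear interpolation; the correction is restricted to
the overlap of both instruments with the lamp's certified range (350–850 nm).

Response denoising: `ResponseFunction.smoothed()` applies a median filter
followed by a Savitzky–Golay pass with a ~1 nm window — wide enough to
suppress shot noise in the lamp ratio, far narrower than the ~8 nm echelle
ripple, which must *survive* in `R_H` so the correction cancels it in
spectra. `estimate_response` leaves smoothing off by default so the
estimator is exact on noiseless input; the pipeline enables it (the lamp
measurements it consumes carry noise).

Scale invariance: the per-spectrum max–min normalization applied downstream
removes any global factor, so only the *shape* of `R` matters; the arbitrary
absolute scale of the lamp curve is irrelevant.

## Preprocessing

Low-resolution shots are averaged in blocks of four per sample
(`average_blocks`), Savitzky–Golay smoothed (`savgol_smooth`, default window
11, polynomial order 3; the filter fits a polynomial in a moving window and
evaluates the terminal windows' fits at the edges, no padding), and max–min
normalized (`minmax_normalize`, `y = (x − min x)/(max x − min x)` with
per-spectrum scalar min/max). High-resolution spectra are normalized but not
smoothed, matching the asymmetric acquisition (each H spectrum already
accumulates ten shots).

Two numerical choices matter here:

* **Zero flooring.** An 11-point cubic SG filter has negative side lobes;
  on peaks only ~1 pixel wide it rings below zero by up to ~8% of the
  tallest peak. Left alone, that undershoot becomes the per-spectrum
  minimum of the normalization and shifts every normalized L feature by a
  constant the H spectra do not share — a systematic train/test offset that
  destroys transfer. Emission intensities are physically non-negative, so
  the pipeline floors every trace at zero before normalizing (smoothed L,
  raw H, corrected H alike).
* **Peak localization on unsmoothed data.** The same wide-window smoothing
  flat-tops narrow peaks, letting blended band shoulders displace the
  apparent maximum by more than a grid step. Peak detection and the
  intensity-threshold candidate gate therefore run on the block-averaged,
  *unsmoothed* counts; the smoothed, normalized traces feed the classifier.

## Feature selection (FS)

The base features are strict local maxima (5-point window) of the class-mean
L spectra above 1500 detector counts, annotated against the bundled line
table; O and H lines are excluded because ambient air contributes to them.
The threshold applies to pre-normalization counts (a normalized spectrum
never exceeds 1).

Candidate wavelengths for augmentation are all grid points whose class-mean
raw intensity exceeds the same threshold, inside the correction range. Each
candidate is scored by the one-way ANOVA F statistic

    F = [SSB/(k−1)] / [SSW/(N−k)],
    SSB = Σᵢ nᵢ (x̄ᵢ − x̄)², SSW = Σᵢ Σⱼ (xᵢⱼ − x̄ᵢ)²,

computed on the normalized training-instrument data (F is invariant to any
affine transform common to all spectra at a wavelength, so this choice
affects values, not substance; it is used purely as a ranking, never as a
hypothesis test). Candidates are appended in descending-F order — skipping
any within one L grid step of an existing feature (overlap deduplication) —
the forest is retrained at each count, and the count with the highest test
accuracy is kept (ties favor fewer features; `select_incremental`). The
default cap is eight added features.

### Cross-instrument feature matching

Features are read off the other instrument by point-to-point matching
(`match_peaks`). The rigid wavelength registration offset between
instruments (|shift| 0.05–0.3 nm) is first calibrated as the median
apex-offset of the few strongest features; windows of ±0.3 nm around each
shift-corrected nominal wavelength are then searched for the nearest strict
local maximum. A candidate maximum must rise `noise_k` (default 10) noise
sigmas above the local baseline; baseline and sigma come from the median and
the (q84 − median) spread of a wider side window, a quantile pair that stays
correct when the trace is floored at zero or rides on a baseline. Exact
distance ties resolve to the lower wavelength. Unmatched features fall back
to the intensity interpolated at the shift-corrected nominal wavelength and
lower the reported per-feature match rate.

Design history worth recording: matching the *nearest* local maximum without
a noise gate selects noise wiggles on the flank of strong lines whenever the
true apex sits off-center (grid quantization plus shift), silently zeroing a
strong feature for a few percent of spectra — enough to blur the clean
cluster DBSCAN must see. The local-baseline prominence gate removes this
failure mode.

## Classification

A standard random forest (500 trees, minimum leaf size 20, √p features per
split, Gini impurity `G = Σ p_k(1−p_k)`, majority vote; `scikit-learn`
backend) with a fixed seed for bit-reproducible predictions. Vote ties
break to the alphabetically first class. The single-instrument protocol
splits each class 7:3 in acquisition order (first 70% train), mirroring a
deployment where later shots are evaluated against earlier ones; the
cross-instrument protocol trains on all L spectra and tests on all H
spectra.

## Post-processing (PP)

Abnormal test spectra are removed unsupervised before evaluation: DBSCAN
(Euclidean, `min_points` 15) on the same corrected, normalized feature
matrix the classifier consumes; only noise points are removed, border points
are retained. Features are already in [0, 1], so no standardization is
applied by default (a z-score flag exists). Epsilon defaults to the
K-Distance-Graph elbow: the k-th nearest-neighbor distances sorted
ascending, lightly smoothed, with the knee located as the point of maximum
distance below the chord joining the curve's endpoints. (A raw
second-difference rule was tried first and locks onto the extreme tail of
the convex outlier ramp rather than the visual elbow; the chord rule is
scale-invariant and lands at the ramp onset.) A manual `eps` override is
available; `DbscanConfig` documents a reference operating point of eps 2.5
with min_points 15, typical for minmax-scaled feature matrices of this
dimensionality.

## The simulator

`simulate` renders each spectrum as a sum of Gaussian lines — center from
the bundled line table plus the instrument's rigid shift, width from the
instrument FWHM — scaled by class/sample/shot intensity factors and the
instrument response, plus additive and signal-proportional Gaussian noise.
The line table carries the twenty principal peaks (CN violet band heads,
Ca, Fe, V, C₂, Na, K lines between 383.8 and 769.9 nm), weak fine-structure
satellites in the CN band and near the Fe and Ca lines (resolved by H,
merged into shoulders by L — these are what incremental selection can
genuinely add), and class-neutral O and H lines so the exclusion rule is
exercised.

Class structure: three classes separated by a Latin square of ±0.3
log-offsets over three emphasized bands (CN 381–388 nm, weak metals
402–403 nm, K 766–770 nm); lines outside those bands carry no class signal.
Sample-level line factors are log-normal with σ = 0.15 (ten samples per
class), shot-level jitter σ = 0.05, all per line. Source amplitude scale is
5000 detector-count units so every principal line's class-mean clears the
1500-count threshold on the L instrument with margin.

Instrument defaults: L = 190–1100 nm, 4096 points, 0.25 nm FWHM, response
rising linearly 0.5→1.5; H = 200–850 nm, 87 000 points, 0.018 nm FWHM
(~2.4 px per resolution element), response falling 1.5→0.4 with 15% ripple
of 8 nm period, registration shift drawn from ±[0.05, 0.3] nm, additive
noise σ = 6000 against ~10⁵-count peaks. The H grid is deliberately sampled
above ~2 px/FWHM: at ~1 px/FWHM the detector aliases sampled peak heights
by up to 2× per line — a systematic distortion no response correction can
undo, which does not reflect real echelle sampling.

Planted outliers (default 10% of the H set) take one of two forms, flagged
in metadata for ground truth: a *collapse* (global intensity ×U(0.05, 0.2)
**and** per-line log-normal scatter σ = 0.6 — a pure global rescaling would
be exactly invisible to per-spectrum max–min normalized features, and real
weak-ablation shots do shift the plasma excitation balance and hence line
ratios) and a *baseline surge* (a broad Gaussian pedestal, amplitude 1–3×
the spectrum maximum, centered inside the analysis range).

### What the simulator does and does not emulate

It reproduces the structure the pipeline's assumptions rest on: different
resolutions and response shapes, echelle ripple, inter-instrument wavelength
shift, band fine structure, class-dependent line intensities, shot noise,
corrupted minority spectra. It does **not** model plasma physics
(Saha–Boltzmann equilibria, self-absorption, Stark broadening, matrix
effects), continuum background, wavelength-calibration drift within an
instrument, or inter-batch sample chemistry differences. Passing tests
therefore demonstrate that the *transfer machinery* behaves correctly under
its stated model, not that any particular accuracy will be attained on real
measurements; simulated accuracies are asserted only as orderings and
margins, never as point values.

## Problem sizes and defaults

End-to-end runs use 3 classes × 500 spectra per instrument (the L set is
simulated as 2000 shots per class and block-averaged 4→1), ten samples per
class, 10% planted outliers in the H set. The acceptance suite averages ten
seeded runs. Reduced-size bundles used in unit tests scale the instrument
grids and FWHM together so the pixels-per-resolution-element ratio — which
the matching and correction quality depend on — matches the defaults.

## Known limitations

* Feature values are sampled peak intensities, not band integrals; residual
  per-line sampling attenuation (≤ ~11% at 2.4 px/FWHM) survives correction
  and contributes to the gap between single-instrument and corrected
  cross-instrument accuracy — as resolution mismatch does in practice.
* Incremental selection maximizes accuracy on the test set itself (the
  protocol it mirrors does the same); the reported best count is therefore
  optimistically biased and should be read as a curve, not a point estimate.
* The elbow automation assumes a single dominant clean cluster; data whose
  k-distance curve has several knees need the manual `eps` override.
* `estimate_response` requires a smooth, strictly positive lamp spectrum;
  emission-line sources are not supported as references.
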