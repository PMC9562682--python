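# Methods

## Problem and model

The package classifies beef *longissimus thoracis* steaks into two tenderness
groups — tender (Warner–Bratzler shear force, WBSF < 53 N) and tough
(WBSF ≥ 53 N) — from near-infrared hyperspectral images (900–1700 nm,
256 bands), at the pixel level. The classifier is PLS-DA: a PLS2 regression
of a two-column dummy class coding **Y** (group 1 → [1, 0], group 2 → [0, 1])
on the pre-processed pixel spectra **X**. Latent variables (LVs) t_a = X w_a
are extracted by NIPALS as directions of maximal covariance between X and Y,
with X- and Y-deflation after each component; prediction is
ŷ = (x − x̄)ᵀ B + ȳ with B = W (PᵀW)⁻¹ Qᵀ, and the hard label is the argmax
over the two class scores (equivalent to a 0.5 threshold under the symmetric
coding). For a two-class problem the centred Y block has rank one, so the
NIPALS inner loop converges in a single pass and the fit is deterministic —
no random initialisation anywhere in the model.

Evaluation follows the conventions of the chemometrics literature for this
problem: confusion matrices are laid out predicted × real and column-
normalised to 100 per real group; sensitivity and specificity (positive =
group 1) are SEN = TP/(TP+FN), SPE = TN/(TN+FP), which for the binary
problem equal the diagonal column percentages / 100 and satisfy
SEN(group 1) = SPE(group 2); the headline %CC is the **macro average of the
two diagonal column percentages**, not pooled pixel accuracy (pooled
accuracy is reported alongside). This macro definition is what makes a
(74.58, 67.09) diagonal average to 70.83.

## Image-processing stages

1. **Reflectance calibration.** I_c = (I_raw − I_black)/(I_white − I_black),
   bandwise, with row-averaged white/black reference scans. Values are not
   clipped to [0, 1]; segmentation operates on unclipped reflectance.
2. **Dead pixels.** Flagged on raw data: a pixel is dead when its across-band
   mean does not exceed the black level at its column by more than
   k·(black-frame SD), k = 3 by default (the field describes dead pixels as
   isolated positions stuck at black; the exact decision rule is this
   package's choice, exposed in config). Repair is per-band 2-D linear
   scattered interpolation over live pixels (joint Delaunay triangulation,
   evaluated at all bands at once), nearest-neighbour at the frame edge.
3. **Spikes.** Per pixel spectrum, single pass: mean m and SD s (n−1
   denominator) over bands; any value outside m ± 6s is replaced by the mean
   of its two nearest non-spike spectral neighbours (two nearest same-side
   neighbours at the spectrum ends). Statistics are not re-estimated after
   replacement. Note an arithmetic consequence: a single outlier among n
   bands deviates by at most (n−1)/√n single-pass SDs, so the 6-SD rule is
   only meaningful for spectra with ≳ 38 bands — trivially satisfied at 256.
4. **Segmentation.** At the band nearest 1210 nm (no interpolation):
   reflectance < 0.068 → background, > 0.19 → fat, between → lean. Both
   thresholds are the published operating values for this instrument class.
5. **ROI.** Calibration-set samples are reduced to the ⌈0.25 × n_lean⌉ lean
   pixels nearest the lean centroid (arithmetic mean of lean coordinates,
   ties broken by raster order). "Inner ring counting from the central
   point" is ambiguous between a central disk and an annulus; the central
   disk was chosen because it is deterministic and matches "counting from
   the central point"; the fraction is configurable. Prediction-set samples
   keep their full lean mask.
6. **Unfolding and trimming.** Cubes unfold to pixels × wavelengths matrices
   in raster order with (sample, row, col) bookkeeping; the first 33 bands
   (noisy detector edge below ~1000 nm) are removed, 256 → 223 bands.

## Pre-processing

Savitzky–Golay smoothing and derivatives (window 15, polynomial order 2 by
default; derivatives reuse those unless overridden), SNV (per-spectrum
centring and scaling with the n−1 denominator), and mean-centring. Chains are
ordered step lists; row-wise steps (SG, SNV) act per spectrum and cannot leak
between blocks, while mean-centring is learned on calibration data only and
applied unchanged to CV held-out folds and the prediction set. Derivatives
are per-band-step (no division by Δλ): classification is invariant to that
monotone column rescale. SG edge handling fits the edge polynomial over the
terminal half-windows so output length equals input length.

## Cross-validation and model selection

Venetian blinds with 10 splits and up to 20 LVs: blocking units are sorted
canonically and unit i goes to fold i mod 10. The default blocking unit is
the **sample** (all pixels of a steak stay in one fold), preventing
pixel-level leakage between folds; pixel-level blinds are available behind a
config flag. Per fold, the centring statistic and the model are refit on the
retained folds; held-out predictions are pooled into one confusion summary
per LV count. The LV count is chosen by parsimony: the smallest count whose
mean CV %CC is within 1 point of the maximum (the window is a convention,
exposed in config).

VIP scores use the standard definition
VIP_j = √( p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a ) with SSY_a the
Y-variance explained by LV a; mean(VIP²) = 1 identically, and wavelengths
with VIP > 1.0 are reported as influential.

The 70/30 calibration/test split is stratified and **balanced**: each group
contributes ⌈0.70 × n_max⌉ calibration samples (n_max the larger group),
capped to leave one test sample per group. For the 30 + 28 cohort this gives
21 + 21 = 42 calibration and 16 test samples — the split sizes the reference
workflow reports, which no per-group rounding rule reproduces (0.70 × 28 =
19.6 rounds to 20, giving 41). Balancing the calibration set is also the
statistically preferable choice for a discriminant model.

## Synthetic scenes

Because no steak hypercubes are publicly deposited, the pipeline is exercised
on synthetic scenes with known ground truth. The generator emulates:

* lean reflectance as a gentle upward slope (0.10 → 0.18 over 900–1700 nm)
  minus Gaussian absorption features at 1113, 1187 and 1289 nm — lean sits
  near 0.11 at 1210 nm, inside the published segmentation window;
* a class offset: group 1 (tender) is brighter than group 2 by a smooth bump
  peaking at `class_effect` inside `class_bands` (default 0.02 inside
  1000–1100 nm, the window where real tenderness groups separate most);
* fat streaks at lean + 0.12 reflectance (≈ 0.23 at 1210 nm, caught by the
  0.19 high mask) and dark background at 0.03 (below the 0.068 low mask);
* per-pixel multiplicative scatter (SD 0.05), additive baseline drift
  (SD 0.01) and white noise (SD 0.005), all in reflectance units — scatter
  and drift model sample surface geometry and therefore apply to foreground
  pixels only;
* ~1% isolated dead pixels stuck at the black level, and rare spikes
  (probability 0.002 per pixel) placed at mean ± 8 pre-injection SDs, safely
  beyond the 6-SD detection rule;
* white/black reference scans with smooth column/band illumination structure,
  inverted through raw = R·(white − black) + black so calibration recovers
  the clean scene exactly outside injected artifacts.

WBSF values are drawn from per-group truncated normals (47.27 ± 4.92 N on
[34.68, 53) and 64.97 ± 11.90 N on [53, 106.10]), and group sizes follow a
30/58 fraction, giving the 30/28 near-parity cohort at n = 58.

Default frames are 64 × 64 pixels — a scaled-down geometry relative to the
320-column instrument, chosen so a 58-sample cohort (≈ 17 000 calibration
ROI pixels, ≈ 25 000 prediction pixels after trimming to 223 bands) runs the
whole pipeline in well under a minute; all counts scale with `image_shape`.
A `headline_scene()` preset (weaker contrast 0.006, noise 0.012, scatter
0.08, drift 0.015) produces the harder regime where pixel %CC lands in the
70–80% range, qualitatively similar to published real-data performance.

**What the generator does not emulate** — and therefore what passing tests do
not show about real steaks: pixels are conditionally independent given their
class (no per-animal spectral random effect, no spatial texture in the lean
signal, no wavelength-correlated noise), the two classes differ by a single
deterministic offset rather than overlapping biochemical gradients, and the
radiometry ignores camera PSFs and pushbroom motion. Synthetic
classification is consequently much easier than the real problem: the
default cohort cross-validates near 99% while real steaks sit near 70%.
Recovery tests establish that the machinery finds known signal and finds
nothing in its absence — not that real tenderness is this separable.

## Numerical choices and degenerate inputs

* NIPALS convergence: relative score change ≤ 1e−12, ≤ 500 iterations
  (one pass suffices for rank-one Y); LV counts are capped at the rank of
  centred X, checked exactly for small matrices.
* SNV raises a descriptive error listing the offending pixel rows for
  zero-variance spectra; constant spectra have no spikes by definition
  (zero SD).
* Segmentation with no lean pixels, all-dead frames, empty ROIs, degenerate
  scenes (no foreground) and white ≤ black references all raise typed
  errors; pipeline stages rewrap errors with the stage name and sample id.
* Distance ties in ROI selection and equal class scores are broken
  deterministically (raster order; ties favour group 1).
* ENVI I/O stores float32 by default; round trips are exact at stored
  precision.

## Known limitations

* The Bayes-threshold variant of PLS-DA class assignment (as offered by some
  commercial toolboxes) is not implemented; the argmax rule is equivalent to
  a fixed 0.5 threshold.
* Dead-pixel detection assumes the black reference is representative of the
  sensor's dark level; drifting dark current between acquisition and
  reference capture would need a recalibrated k.
* The per-window SG edge fit can amplify noise in the outermost ~7 bands of
  derivative spectra; with the first 33 bands trimmed this does not affect
  the modelled range's informative window.
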