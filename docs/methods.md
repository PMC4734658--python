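# Methods

This note records the scientific and numerical choices behind `hazepm`:
what is modeled, which constants matter, what the synthetic scenes do and
do not emulate, and where the design was genuinely open.

## Image formation and transmission estimation

All images are float RGB in [0, 1] (8-bit inputs divided by 255), row-major
with the origin at the top-left; boxes are half-open. The pipeline treats a
photograph as `I = t·J + (1−t)·A` with per-pixel transmission
`t = exp(−β d)`. Transmission is recovered with the dark-channel prior:
`t̃ = 1 − darkchannel(I/A)`, where the dark channel takes the minimum over
RGB and over a square window.

* **Window size Ω = 15×15** (configurable). The prior needs the window
  large enough to catch a dark pixel on essentially every structure, and
  small enough not to blur depth discontinuities; 15 is the standard
  operating point at these image scales and is used everywhere, including
  the synthetic experiments.
* **Airlight** is the per-channel mean of the brightest 0.1 % of pixels
  ranked by dark-channel value, restricted to the sky mask when the mask
  covers ≥ 2 % of the image (otherwise the whole image), floored at 0.05
  per channel so the division in the transmission formula stays stable.
  The quantile/fallback/floor are configurable; only the qualitative rule
  ("estimate A from the sky or the brightest region") is fixed by the
  physics.
* The scalar **transmission feature** is the mean of `t̃` over non-sky
  pixels: over the sky the estimator returns ≈ 0 by construction (sky *is*
  airlight), so including it would only dilute the signal. If the non-sky
  region covers < 1 % of the frame the mean falls back to the whole image.

## Sky segmentation

Grayscale is BT.601 luma (0.299 R + 0.587 G + 0.114 B). The sky mask is the
bright Otsu class (buildings are darker than sky in these scenes), cleaned
by a morphological opening and hole filling, keeping only connected
components that touch the top image row.

* **Otsu threshold**: 256-bin histogram on [0, 1]; the returned value is
  the bin edge maximizing between-class variance, smallest edge on ties.
  The implementation is an exact vectorized maximizer and is tested for
  equality against an exhaustive candidate search (and, loosely, against
  scikit-image, which bins over the data range instead of [0, 1]).
* **Structuring element**: a "4×4 disk" has no symmetric center; the
  package uses a radius-2 disk (5×5 support), configurable. Downstream
  features depend on segmentation quality, not on the exact element.
* **Connectivity**: 8-connectivity for components, 4-connectivity for hole
  filling — the common image-processing pairing that avoids classifying
  diagonal leaks as holes.
* Watermark rows (timestamp banners) are stripped first: explicit row
  counts, or auto-detection of leading/trailing rows whose fraction of
  near-white pixels (all channels > 0.92) exceeds 0.5; both constants are
  configurable since watermark styles vary. An image with no sky yields an
  empty mask with a warning flag (sky features go missing, not crashing).
* For fixed cameras the caller may pass a scene-level mask into
  `extract_features`, mirroring the field protocol of drawing ROIs once
  and reusing them. This matters for controlled β-sweeps: under deep haze
  the most distant buildings become photometrically inseparable from sky,
  so a per-image mask flips discretely along the sweep and the non-sky
  mean jumps when a building band drops out — a segmentation artifact, not
  a property of the features. The monotonicity experiments therefore use
  the scene's known mask; the end-to-end regression experiments use
  per-image segmentation, artifacts included.

## Haze features

RMS contrast is the population standard deviation of intensities (the
image definition, divisor MN); entropy uses the 256-bin histogram matching
the 8-bit provenance of the data; whole-image contrast and entropy are
computed on the full (watermark-stripped) frame, not the non-sky part, per
the protocol of treating them as global visibility proxies. ROI contrast
uses the most distant ROI, where the airlight term dominates soonest and
the PM signal is strongest. Sky smoothness is the mean gradient amplitude
(central differences, one-sided at borders) over sky pixels whose entire
difference stencil is sky, so building edges never leak in. Sky color is
the mean blue channel over the mask.

The Beer–Lambert fit regresses `ln t̃` of the per-ROI means on ROI distance
by ordinary least squares; β = −slope. Non-positive transmissions are
excluded (no logarithm); at least two usable points at distinct distances
are required.

## Solar position

Declination and the equation of time come from Spencer's truncated Fourier
series in the day angle (fractional day included); the hour angle follows
from apparent solar time with the longitude correction; the zenith is the
spherical-trigonometry identity. Verified against an independent
Michalsky-type ephemeris over 5 000 random time/place pairs spanning
1950–2050: maximum zenith deviation 0.41°, typical well under 0.25° — far
below anything a regression covariate can resolve. Altitude is accepted in
the data model but unused: the zenith identity has no altitude term and no
refraction correction is applied (sub-degree effects near the horizon
only).

## Regression

ε-SVR with RBF kernel, solved by scikit-learn's libsvm backend. Features
are z-scored with training-fold statistics; targets are z-scored too, so
the default tube ε = 0.1 is scale-free (a deliberate assumption — the
original protocol does not state its scaling). Grid search covers
C ∈ {2⁻⁵ … 2¹⁵}, γ ∈ {2⁻¹⁵ … 2⁵} in factor-of-4 steps, scored by 2-fold
CV RMSE with one recorded fold seed shared across the grid; ties prefer
smaller C, then smaller γ. 2-fold CV is a random half/half split: each
half is predicted by a model trained on the other, every sample predicted
once.

PCA-SVR fits the standardization and the PCA basis on each training fold
only (no leakage) and runs the SVR in component space *without* re-scaling
the components: full-rank PCA is then a pure rotation, and since the RBF
kernel is isotropic the k = p sweep point reproduces the no-PCA pipeline
exactly — a built-in consistency check. Fitting PCA per fold is a
deliberate anti-leakage choice even though it is not the only reading of
the original protocol.

SBFS removes, at each level, the feature whose removal minimizes the CV
RMSE, using one fixed fold seed throughout so errors across levels are
comparable (otherwise fold noise dominates the selection); the optimum is
the recorded subset with the smallest error, ties to the smaller subset.

The F-test construction is OLS of observed on predicted with intercept,
F = regression MS / residual MS on (1, n−2) df — the only regression
available when the predictor is a kernel machine; this is an
interpretation, stated as such. Distance correlation uses the standard
double-centered pairwise-distance form and returns 0 for constant input.

## Synthetic scenes

The renderer draws the exact forward model: a sky band (depth → ∞, so sky
renders as airlight, with optional vertical blue gradient and band-limited
cloud texture) above four textured building blocks at 500–4000 m. Defaults:
240×160 px, sky fraction 0.45, airlight (0.78, 0.84, 0.92), noiseless; the
dataset generator adds Gaussian pixel noise of sd 0.01 (about 2.5 8-bit
levels — mild sensor noise).

* **Dark anchors.** With `dark_anchor=True` (default) building pixels have
  zero blue reflectance, so *every* dark-channel window contains a zero
  and transmission recovery is exact by construction; disabling it floors
  reflectance away from zero for robustness experiments. This separates
  estimator error from prior violation.
* **Block reflectance ranges** (0.03–0.14, 0.17–0.28, 0.31–0.42,
  0.45–0.56, brighter with distance) are disjoint, and because a farther
  block contracts toward the airlight faster than a nearer one, a range
  that starts above a nearer block's range stays above it for every β:
  the gray histogram's support shrinks monotonically with haze, making
  contrast and entropy cleanly monotone rather than an artifact-prone
  mixture of crossing distributions.
* **β↔PM link**: β = 2.5×10⁻⁶ m⁻¹ per index unit, giving transmission at
  the farthest block from ≈ 0.99 (PM ≈ 5) down to ≈ 0.05 (PM ≈ 300) — the
  full visual range from crisp to whiteout. PM is drawn uniformly on
  [0, 300] (spanning the range reported for heavily polluted cities). The
  optional humidity coupling multiplies β by (1 + humidity), emulating
  hygroscopic particle growth; humidity is uniform on [0.3, 0.9].
  Timestamps/coordinates come from city-like presets (daily morning
  captures) so the solar covariate is exercised end to end.

What the synthetic scenes do **not** emulate: changing illumination and
cast shadows, moving objects, camera auto-exposure and white balance,
JPEG artifacts, rain/fog as distinct from particle haze, and spectrally
correct sky radiance (Rayleigh/Mie simulation is out of scope). Passing
the synthetic experiments therefore demonstrates that the pipeline is a
correct implementation of the stated model and recovers its parameters
under that model — not that field accuracy on real archives will match;
on real photographs reported fits are far looser (R² around 0.6–0.7 for
wide PM ranges, worse for narrow ones).

## Problem sizes and numerics

The standard experiments use 200 images (150 for the humidity study) at
240×160 — ample for the SVR to saturate on this clean signal while keeping
a full run in seconds. All randomness flows through explicit integer
seeds; fold splits, scene textures and noise streams are all reproducible.
Degenerate inputs are contracted, not patched over: constant images fail
Otsu with a specific error, empty skies yield missing sky features,
constant targets make R² undefined, and transmission values are clipped to
[0, 1] only after the physics, never before.

## Known limitations

* The Otsu-based sky mask assumes sky brighter than structures; sunset or
  backlit scenes violate this.
* The airlight estimate assumes the sky (or brightest region) is
  representative; strongly colored illumination biases `t̃`.
* The SBFS criterion inherits fold noise from a single seed; rankings of
  closely matched features are not stable across seeds (by design it
  matches the printed procedure rather than averaging over resamples).
* The ephemeris ignores refraction and the equation-of-time drift beyond
  the Spencer series; do not use it for horizon-grazing photometry.
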