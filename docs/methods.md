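# Methods

## The measurement problem

Cerenkov luminescence imaging (CLI) detects the visible light emitted by
beta particles from an injected radionuclide. When a tracer such as
[68Ga]GaCl3 stays in circulation, the combined emission of all deeper
tissues acts as a diffuse *backlight* at the skin surface. Superficial
blood vessels — strong absorbers of red/near-infrared light — then appear
as dark lines: **negative contrast**. The quantities this package computes
are all ratio statistics on that radiance field, plus the radioactive-decay
and calibration bookkeeping needed to interpret them.

## Model and estimators

**Decay.** Activity follows A(t) = A0 · 2^(−t/T½). Half-lives are package
constants from standard nuclide tables (Ga-68: 67.71 min; F-18: 109.77 min).
`decay_correct_activity` decays forward from the reference (injection) time
by default; `to_reference=True` applies the exact inverse, which is the
convention used inside %ID/g.

**Calibration.** Radiance vs activity over a phantom vial ladder is fitted
by ordinary least squares *with* an intercept. The intercept absorbs any
ambient/dark floor so the slope remains an unbiased light yield
(photons/s/cm²/sr per MBq); on noiseless data it is recovered as ~0, so
nothing is lost in the clean case. The ratio of two slopes compares the
light output of two nuclides per unit activity.

**Vessel attenuation.** The estimator divides the mean radiance in a
rectangular vessel ROI by the mean of two congruent ROIs translated
perpendicular to the vessel axis by one ROI width plus an optional gap
(default gap 0: the flanks abut the vessel ROI). The two flank means are
averaged as means-of-means, not pooled pixels, so unequal edge clipping
cannot weight one side (`pooled_flanks=True` switches). Attenuation is
1 − vessel/flank; negative values are kept and flagged — clipping them
would bias cohort means. Pixel membership is pixel-center-in-region with
half-open rectangles [x, x+w).

**Necrotic core.** The same local-ratio idea with a free reference:
1 − mean(core ROI)/mean(rim reference). The reference may be a list of
ROIs placed symmetrically around the core; averaging their means cancels
smooth backlight gradients to first order, which is why the default
recovery geometry uses four rim rectangles at ±2.5 mm.

**Biodistribution.** %ID/g = 100 · (counts/counts-per-MBq, decay-corrected
back to injection) / injected dose / organ weight. Both the gamma-count and
the optical-flux channel are normalized to the thigh-muscle sample, and the
per-organ ratio of normalized flux to normalized activity isolates optical
transmission. Blood is the extreme: 6.2× muscle activity, 0.32× muscle
light, a light-to-activity ratio of ≈0.05.

**Cohort test.** Pooled-variance two-tailed Student's t
(df = nₐ + n_b − 2), chosen because that is the named design; Welch's
correction is available behind a flag since the two groups plainly have
unequal variances. Zero pooled variance with equal means returns p = 1 by
convention; with unequal means it is an error rather than an infinite
statistic.

## The synthetic scene generator

The simulator is deliberately a 2-D projected model: only surface radiance
is quantified, so no depth axis or photon-transport solution is modelled.

* **Backlight**: mean level × (1 + σ_rel · G), where G is unit-variance
  Gaussian-filtered white noise with correlation length
  `backlight_smoothness_mm`. Defaults: mean 10⁶ p/s/cm²/sr (the scale
  implied by ~8 MBq of Ga-68 at ~1.5×10⁶ per MBq, attenuated and spread
  over the body), smoothness 3 mm, relative sd 3%. The camera vendor's
  noise figures are not public; these are assumptions chosen once to be
  realistic for a 5-min exposure, and are documented as such.
* **Vessels**: a vessel of diameter D multiplies the field by
  T(u) = 1 − a·√(1 − (2u/D)²), the chord-length (semicircular) profile
  under a thin-absorber linearization. At ≤20% attenuation this differs
  from the exponential Beer–Lambert form by <2% and has the closed-form
  strip integral mean = a·π/4 used as the test oracle. Each pixel value is
  the 4×4-subpixel midpoint average of the profile, so discrete ROI means
  agree with the analytic integral to <0.5%.
* **Tumor/core**: antialiased disks; the rim multiplies the field by
  `rim_brightness` (default 1), the core by 1 − reduction.
* **Camera noise**: Gaussian PSF (σ in mm), Poisson shot noise on photon
  counts via `photons_per_radiance_unit` (default 2×10⁻³ → ≈2000 counts
  per pixel at the default backlight, ~2% pixel noise), an additive dark
  floor, and Poisson-rate single-pixel cosmic spikes at 100× the mean
  radiance (removed by `despike`, a median/MAD filter with k = 10 on the
  1.4826-scaled MAD).
* **Determinism**: one master seed; per-scene seeds are master + index;
  every random draw flows from `numpy.random.default_rng(seed)` in a fixed
  order, so identical specs give bit-identical images.

**Cohort convention.** The study-level numbers (tumor-side 10% ± 4%,
contralateral 3% ± 1%) describe *measured* attenuations, i.e. ROI averages
across the vessel. The generator therefore draws the strip-averaged
attenuation from those normals (clipped to 0.5%–50% to stay physical) and
sets the rendered center-line peak to drawn × 4/π. Cohort scenes use an
image-plane vessel diameter of 6 pixels (0.5 mm at the 0.083 mm pitch,
matching the apparent width of focused in-vivo vessels) with a light
0.02 mm PSF; the separate "realistic" default PSF of 0.17 mm reproduces the
~10× apparent widening of a truly 40 µm vessel, but convolving attenuation
depth and blur would make the ground truth of the cohort statistic
ill-defined, so the cohort works at the rendered scale. Measurement ROIs
are built from the ground-truth geometry: automatic vessel segmentation is
out of scope.

**What the generator does not emulate.** Depth-dependent scattering,
spectral (per-wavelength) absorption, respiratory motion blur, fur and skin
texture, and anatomy beyond disks and line vessels. Passing round-trip
tests therefore shows the *estimators* are correct and unbiased under the
stated noise model — not that the noise model captures every property of
real IVIS images.

**Biodistribution tables.** Blood is constrained (6.2× activity, 0.32×
light, i.e. transmission 0.32/6.2 ≈ 0.0516); intestines, tumor, brain,
muscle and femur transmit like muscle; heart, lungs, spleen, liver and
kidneys sit in between (0.45–0.60); the remaining relative activities
reconstruct the reported ordering (blood > liver, spleen > kidneys, lungs,
heart; low gut/tumor; negligible brain) and are qualitative. The absolute
scale is anchored so blood comes out at 15 %ID/g measured 65 min after a
10 MBq injection. Measurement noise is unit-mean lognormal (default
sd 5%) applied independently to counts and flux.

## Numerical and design choices

* Regression: `numpy.linalg.lstsq` on a two-column design; R² from residual
  and total sums of squares, with the 0/0 (constant-response) case defined
  as 1. Degenerate abscissae (<2 distinct activities) raise.
* ROI means over edge-straddling rectangles use in-bounds pixels only and
  log a warning; fully out-of-bounds flanks raise.
* `subtract_background` may produce small negative radiances; they are
  preserved, since clipping would bias downstream ratio statistics.
* Reported precision follows the conventions of the measurements (one
  decimal for MBq, two/three decimals for mm, p-values at two significant
  figures); all internal computation is double precision.
* Power of the 13-vs-13 design is estimated by Monte Carlo on the drawn
  per-animal attenuations directly (1000 replicate cohorts). Rendering adds
  ~0.2 pp of estimator noise per vessel — negligible against the 4 pp
  between-animal spread — so the shortcut does not change the answer and
  keeps the computation to seconds.

## Problem sizes

Cohort recovery uses 120 scenes of 192×192 px at the view-A pixel pitch
(two vessels each); core recovery averages 20 seeds; phantom calibration
averages 20 renders of an 8-vial ladder spanning 0–0.61 MBq on a
240×240 px grid. These sizes put Monte-Carlo standard errors comfortably
below the quantities' tolerances (3×SE for group means, 1 pp for the core,
2% for the slope).

## Known limitations

* The 2-D model cannot address depth-dependent vessel visibility or
  quantify absolute blood volume from attenuation.
* The flanking-ROI geometry assumes a locally straight, axis-aligned
  vessel and a user-supplied ROI; tortuous or branching vessels need
  manual ROI placement.
* An additive offset (uncorrected dark floor) biases all attenuation
  ratios toward zero; `subtract_background` must be applied first, and the
  test suite demonstrates both the bias and its removal.
* The pooled t test inherits its usual normality/equal-variance
  assumptions; with the strongly unequal group variances here the Welch
  flag is the safer choice, and both are exposed.
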