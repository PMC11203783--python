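# Methods

## Colour-hexagon model

The hexagon model treats the bee as a trichromat adapted to its visual
background. For receptor class *i* with spectral sensitivity S_i(λ), stimulus
reflectance R(λ), background reflectance R_B(λ), and illuminant I(λ), the
adapted quantum catch is

    P_i = R_i ∫ I(λ) R(λ) S_i(λ) dλ,      R_i = 1 / ∫ I(λ) R_B(λ) S_i(λ) dλ.

The von Kries factor R_i makes the model invariant to global illuminant
scale (tested), so the D65 normalisation (mean 1 over the grid) is purely a
convention. Excitation saturates hyperbolically, E_i = P_i/(P_i+1), mapping
the background to 0.5 in every channel, and the locus coordinates are
x = (√3/2)(E_G − E_U), y = E_B − (E_U + E_G)/2. All six corners of the unit
hexagon lie at distance 1 from the centre, and no excitation triplet can
exceed that circumradius.

Assumptions worth keeping in mind: receptor adaptation is fully determined
by the background (no partial adaptation), spatial and temporal vision are
ignored, and no receptor-noise model is applied — distances are geometric,
not discriminability units (JNDs).

### Numerical choices

* All model math runs on one shared uniform wavelength grid, by default
  300–700 nm at 1 nm — the range bee photoreceptors cover. Inputs are
  linearly interpolated onto the background's grid; extrapolation is refused.
* Integration is trapezoidal on that grid. Against direct quadrature of the
  continuous integrands at 0.1 nm the adapted catches agree to relative
  error < 1e-4 for smooth spectra (tested), which is far below measurement
  noise in field spectrometry.
* The hue angle is measured from vertical-up, increasing clockwise, which
  places the green vertex at 120° and a yellow long-pass reflector in the
  120–180° sector; the orientation is configurable
  (`orientation="counterclockwise"`) because only the zero direction, not
  the sense of rotation, is fixed by convention. Angles are undefined within
  1e-6 units of the centre and reported as such rather than as a number.
* "Achromatic contrast" in the two-choice experiment's sense is the distance
  of a locus from the hexagon centre and is reported as `center_distance`.
  Much of the colour-vision literature reserves "achromatic contrast" for
  the green-receptor signal; that quantity, |E_G − 0.5|, is exposed
  separately as `green_contrast` so the two are never conflated.

### Receptor sensitivities

Defaults are generated from the Govardovskii A1 visual-pigment nomogram
(alpha band) at the honeybee peak wavelengths 344, 436, and 544 nm, each
peak-normalised to 1. The beta band is omitted: it contributes a secondary
short-wavelength bump, and the template contract here is a unimodal curve;
for bee-relevant peak wavelengths the alpha band dominates the 300–700 nm
window. Measured sensitivity curves can be supplied as a CSV
(`uv`, `blue`, `green` columns) and are renormalised to unit peak.

### Spectral data handling

Reflectance is computed from raw counts as (raw − black)/(white − black)
with the white/black calibration standards, clipped at 0; values slightly
above 1 are legitimate (samples can out-reflect the white standard), so the
validity ceiling is 1.2. No smoothing is applied by default, since smoothing
settings are instrument-specific. The embedded CIE D65 tabulation covers
300–780 nm at 5 nm.

## Two-choice preference inference

Each assay contributes one Bernoulli observation (which of the two variants
a bee approached first). Per trait we fit a binomial logistic GLM; the
per-species model is intercept-only, so the intercept is the log-odds of
choosing the "success" variant and its two-sided Wald z tests the null of
indifference. The success level is the alphabetically second variant label —
a single rule that makes yellow, large-vs-small, intense-vs-light, and
simple-vs-complex codings consistent — and can be overridden.

Design choices made where the design was genuinely open:

* **Blocking factors.** Base colour (for the contrast experiment) and
  mixture identity (for the scent experiment) enter as additional *fixed*
  factors rather than random intercepts: with one or two blocks per trait
  there is no information to estimate a variance component, and the pooled
  per-species fits are identical under either reading. A mixed model is a
  defensible alternative at larger block counts.
* **Separation.** If one variant is never chosen, the MLE is infinite. The
  fit reports a signed infinite estimate with a `separation` flag instead of
  applying a bias correction, keeping the contract transparent; the summary
  table reports the unanimous variant with NaN test statistics.
* **Significance.** Two-sided Wald test at α = 0.05, strict inequality
  (p exactly equal to α is "no preference"), no multiple-testing correction.

For intercept-only fits the closed forms estimate = ln(a/b),
SE = √(1/a + 1/b) hold exactly; the GLM is run with IRLS tolerance 1e-12 so
the two routes agree to 1e-6, and the closed form serves as an independent
oracle in the tests.

### Count recovery from printed coefficients

`recover_counts` searches all integer pairs with a + b ≤ 500 (configurable)
for those whose closed-form estimate and SE both round to a printed pair at
3 decimals, returning the squared-discrepancy minimiser and a uniqueness
flag. Printed tables can be ambiguous: occasionally two count pairs match
(estimate, SE) at 3 decimals but differ in the third decimal of z. Passing
the printed z as an optional third constraint resolves such cases.
Recovered counts are reconstructions of unpublished data and are labelled
as such wherever the package uses them.

## Antennal activity and mixtures

Response calling from raw electroantennogram traces is upstream of this
package (no amplitude threshold generalises across rigs); tables arrive as
binary antenna × compound matrices, one antenna per female. A compound is
active for a species when its response fraction is ≥ 1/2 — inclusive, so
5 of 10 antennae is active. Percentages are carried both as exact fractions
and as display values; the display convention (round vs truncate) is
configurable because published tables are inconsistent about 4/6 → 66.7 vs
66%. Downstream logic always uses the exact fraction.

Mixture math: a total concentration C split over n substances in equal
volumes gives C/n per substance (10 µg/mL → 2.5 for a 4-VOC mixture,
0.8333… ≈ 0.83 for the 12-VOC complex mixture); an applied volume V µL of
concentration C µg/mL delivers V·C ng of substance. Note that some published
dosing parentheticals are a factor of 10 below what their stated volumes and
concentrations imply (30 µL of 10 µg/mL is 300 ng, not 30 ng); this package
always computes from the concentrations and volumes it is given.

## Consumption analysis

Weighings at t0, 40 min, and 2 h define two windows; the rate is the mass
loss over the window divided by its duration in hours. Negative losses
(condensation, balance drift) are clipped to zero with a warning. Flat vs
deep flowers are compared with a Mann–Whitney U test: exact enumeration of
all C(n, n_x) group assignments for combined n ≤ 12 (valid under ties, with
midranks), otherwise the tie-corrected normal approximation. The two-sided
exact p is P(|U − n_x n_y/2| ≥ |U_obs − n_x n_y/2|) under the permutation
null.

## Synthetic data

The generator provides every input the pipeline needs, with the structure
the analyses assume; all draws come from one integer-seeded RNG and are
bit-reproducible.

* **Spectra.** Smooth parametric reflectances: a logistic long-pass edge at
  500 nm (yellow), a Gaussian bump at 450 nm (blue), and a mid-band bump at
  550 nm (green background). "Light" variants are convex mixtures of a
  parent colour with the background. Defaults (baseline 0.12, green bump
  amplitude 0.30/σ65, yellow high 0.80/edge width 10, blue amplitude
  0.25/σ30, mix weight 0.5) were chosen so the palette shows the structure
  real coloured cardboards show against green: intense yellow and blue near
  opposition with centre distances around 0.2, light variants at the same
  hue (Δ < 5°) but roughly half the contrast. The hue-preservation property
  is approximate — the excitation transform is nonlinear, so reflectance
  mixing bends the locus path slightly; the drift grows with the parent's
  centre distance, which bounds how saturated the default palette can be.
* **Choices.** Independent Bernoulli draws at a per-arm preference
  probability. The default scenario's sample sizes and probabilities are the
  count reconstructions recovered from the published per-species coefficient
  rows (e.g. 206 hue choices at p = 0.718 for the bumblebee); they are
  labelled reconstructions, not data.
* **EAG tables.** Bernoulli responses per antenna × compound (default
  10/10/6 antennae per species), or exact forced responder counts for
  reconstructing a printed response grid deterministically.
* **Consumption.** Lognormal per-flower rates with depth-specific means
  (defaults 90 mg/h flat vs 30 mg/h deep, log-sd 0.4, 9 flowers per arm),
  converted to nonincreasing weighings. At these defaults the Mann–Whitney
  comparison rejects at α = 0.05 in well over 80% of replicates.

What passing on synthetic data does and does not show: the generators share
no code with the analysis paths they exercise, so round-trip recovery tests
genuinely validate the estimators; but real reflectance spectra are less
smooth, real choices are not independent (bees learn within a session), and
real weighings drift with evaporation. Conclusions about any particular
measured dataset still require that dataset.

## Known limitations

* No receptor-noise (JND) discrimination model; hexagon distances are not
  perceptual thresholds.
* No GLMM variance components; blocks are fixed factors.
* The exact Mann–Whitney branch enumerates C(n, n_x) assignments and is
  limited to small samples by design (combined n ≤ 12 in auto mode).
* Problem sizes in the test suite (e.g. 10⁵ excitation triplets for the
  geometry sweep, 200 replicates for the power check, 10⁴ choices for
  parameter recovery) are the package's reference scales for these
  properties; they keep every check well inside interactive runtimes.
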