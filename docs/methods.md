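# Methods

This note documents the models, algorithms and numerical choices behind
`vinemetrics`, in the order the pipeline runs.

## Canopy architecture from gap fractions

An upward photograph of a canopy against the sky is reduced to two gap
fractions: the total sky fraction `gT` and the fraction `gL` belonging to
*large* gaps — connected sky components covering at least a threshold
fraction of the frame (default 1%), which in a vineyard correspond to the
openings *between* crowns rather than porosity *within* a crown. From these,

- canopy cover `fc = 1 − gT`,
- crown cover `ff = 1 − gL`,
- crown porosity `phi = 1 − fc/ff`,
- `LAI = −ff · ln(phi) / k` (Beer–Lambert inversion of the within-crown
  gap fraction, scaled by the crown footprint),
- clumping index `omega = (1 − phi) · ln(1 − fc) / (ln(phi) · fc)`,
  the ratio of the apparent (random-foliage) attenuation implied by total
  cover to that implied by within-crown porosity,
- effective `LAI_e = omega · LAI`.

Choices and their reasons:

- **Binarization on the blue channel** (Otsu by default, isodata and fixed
  thresholds available). Sky dominates blue in upward photographs; leaves
  absorb it. This is the conventional channel for cover photography.
- **Extinction coefficient `k = 0.7`**, configurable. This value makes the
  LAI equation consistent with published per-group means for VSP-trained
  vineyard canopies (checked in the acceptance tests); physically it
  reflects a mixed leaf-angle distribution.
- **8-connectivity** for gap components, the conservative choice: diagonal
  speckle chains merge into one component rather than fragmenting into
  many, so large-gap detection is not diluted.
- **`phi` clamped to [1e−6, 1 − 1e−6] before logs.** Degenerate frames
  (all sky, all canopy, `fc = ff`) would otherwise produce infinities; the
  clamp leaves realistic values (phi of order 0.1–0.4) untouched, and a
  warning is recorded whenever it engages.
- **`omega = 1` by convention when `fc ∈ {0, 1}`**, where the defining
  ratio is indeterminate; flagged in the result.
- **Per-plant metrics are the mean of the two side images**, matching the
  two-images-per-vine field protocol.

Degenerate inputs warn rather than raise: an all-one-intensity image
binarizes to all-sky or all-canopy by brightness (midpoint 127), and an
image that is entirely large gap yields `fc = ff = lai = 0` with a warning.

## Berry vitality from fluorescence images

FDA staining makes living mesocarp fluoresce green. The pipeline:

1. **Berry detection.** Otsu threshold on mean-channel brightness,
   morphological closing (disk radius 3 px), hole filling, largest
   8-connected component. A component smaller than 1% of the frame is
   rejected ("no berry detected"). Both sizes are configurable; they are
   scale parameters with no single correct value.
2. **Living-tissue segmentation.** Each pixel inside the berry gets a
   green-dominance score `g − max(r, b)`; living tissue is strongly
   positive, dead mesocarp (dull brown) near or below zero. The score is
   thresholded by Otsu *within the berry*. Otsu always splits a histogram
   in two, so a homogeneous interior (all living, or all dead) would be
   cut in half; when both Otsu classes fall on the same side of zero the
   sign of the score decides instead. A fixed threshold can be supplied.
3. **Vitality arithmetic.** With an optional manually supplied seed
   polygon S (seeds sit inside living tissue and would otherwise inflate
   BCD): effective area = berry \ S, `LT% = 100·|LT \ S|/|berry \ S|`,
   `BCD% = 100 − LT%`. The BCD mask is the complement of the LT mask
   within the effective area, so the two percentages always sum to 100.
   A seed polygon covering the whole berry is an error.

Masks export losslessly as PNG (JPG is offered for compatibility with
legacy microscope workflows but is lossy on binary masks; round-trip error
stays within half a percentage point on the shipped fixtures).

## NIR preprocessing

Spectra live on the uniform instrument grid 1596–2396 nm. The feature
matrix is built in a fixed order:

1. Savitzky–Golay **first derivative** on the full range (window 9 points,
   polynomial order 2 by default — conventional for handheld-NIR
   resolution; both configurable). Edge points use polynomial
   extrapolation within the terminal window.
2. **Band selection** to 1596–1919 nm, the modelling band containing the
   H₂O₂ overtone signal related to cell death. Slicing after the
   derivative keeps filter edge artifacts outside the modelling band
   (only the 1919 nm edge is interior to the instrument range).
3. **Replicate averaging** to one spectrum per berry. Derivative and mean
   are both linear so the order is immaterial; it is fixed for
   reproducibility.

## Network training

One hidden tanh layer, linear output, inputs and targets min-max scaled to
[−1, 1] (the standard companion of tan-sigmoid units; constant features
map to 0 and unscale back to their constant). Weights start from a seeded
Nguyen–Widrow-style initialization. The error Jacobian is analytic
(per-sample backpropagation) and verified against central finite
differences in the tests.

**Levenberg–Marquardt.** Damped Gauss–Newton on `F = E_D` with
`E_D = ½Σe²` over scaled errors: solve `(JᵀJ + μI)δ = −Jᵀe`, accept a step
only if F decreases (μ ÷ 10), otherwise μ × 10 and retry. Stops at
`max_epochs` (1000), μ > 1e10, gradient ∞-norm < 1e−7, or — when a
validation stage exists — after 6 consecutive validation-MSE increases,
restoring the best-validation weights. Accepted steps never increase the
training objective by construction.

**Bayesian regularization.** The same engine on
`F = β·E_D + α·E_W`, `E_W = ½Σw²`, starting from α = 0, β = 1. After every
accepted step the evidence-framework updates run:
`γ = N_w − α·tr(H⁻¹)` with `H = β·JᵀJ + α·I` (equivalently
`γ = Σ βλ/(βλ + α)` over Hessian eigenvalues — the effective number of
well-determined weights, clipped to `[0, min(N_w, N)]`), then
`α = γ/(2E_W)`, `β = (N − γ)/(2E_D)`. This is the self-consistent form for
the half-sum conventions used here; β is floored at 1e−12 and α capped at
1e10 if the weight norm vanishes while γ > 0. With α pinned at 0 the
trajectory is identical to plain LM (tested to 1e−9). BR uses no
validation stage: γ ≪ N_w on pure-noise targets is its overfitting control.

**Splits.** Seeded random partitions. Stage counts follow the convention
that validation and test receive `round(fraction·n)` samples and training
the remainder — the convention that reproduces the published stage tables
(432 → 324/108 and 260/86/86; 216 → 130/43/43). Same seed, same
assignment, bitwise.

**Neuron trimming.** One network per candidate hidden size (default
{3, 5, 7, 10}) on a shared split and seed. A candidate is admissible when
`MSE_train ≤ MSE_test` and, when a validation stage exists,
`|MSE_val − MSE_test| ≤ 0.25·MSE_test`. Among admissible candidates the
highest overall R wins, with R compared at two decimals — the precision at
which such models are reported — so that sub-0.01 differences count as
ties, broken toward fewer neurons ("most efficient"). If nothing is
admissible the best-R candidate is returned flagged.

## Evaluation

Multi-target models are scored on observations flattened across targets
(432 samples × 2 targets = 864 observations), matching the bookkeeping of
published stage tables. R is the Pearson correlation of flattened
predictions vs targets; the slope is the least-squares coefficient of
predictions on targets; MSE is in target units². Outliers are observations
outside the two-sided t-based OLS prediction interval (residual variance
inflated by leverage, n − 2 degrees of freedom) of the pooled overall fit
at the 95% level; on data simulated from the fitted model the rate is ~5%
by construction. Group comparisons: one-way ANOVA, Tukey HSD
(statsmodels), and a compact letter display computed from maximal cliques
of the not-significantly-different graph (exact for the small group counts
used here; letters ordered by descending group mean). All-identical values
give p = 1 by convention.

## Synthetic data: what it emulates and what it does not

Every generator is a pure function of its seed and serializes its latent
truth; recovery tests read only the serialized truth.

- **Berry images**: elliptical berry on dark background, interior split by
  a smoothed Gaussian random field into green/brown regions whose pixel
  counts hit the requested LT fraction exactly (order-statistic
  threshold); optional seed ellipse; Gaussian pixel noise (σ = 4 of 255).
  Not emulated: staining artifacts, uneven illumination, out-of-focus
  edges, berry-to-berry morphology. Passing recovery (±2 points) shows the
  segmentation logic is correct, not that it is robust to field imaging
  conditions.
- **Canopy scenes**: crown mask from a thresholded smooth field covering
  exactly `ff` of the frame, with the complement concentrated into a
  configurable number of large gaps; within-crown porosity as exact-count
  sky speckles, so `fc = ff(1 − phi)` holds in pixels. Not emulated: sun
  glare, mixed pixels at leaf edges, wood/trellis. Recovery tolerances
  (±0.02 on ff, ±0.03 on phi) absorb boundary-speckle merging.
- **NIR spectra**: smooth baseline + fixed water/sugar overtone bands +
  a 1620 nm marker band affine in BCD, berry-level offsets, iid noise
  (σ = 0.002 AU), three replicates per berry. Not emulated: scatter
  effects (the pipeline deliberately omits SNV/MSC), instrument drift.
- **Vineyard tables**: (ff, phi) uniform within published field ranges
  (group means ± 3 SE: ff ∈ [0.61, 0.90], phi ∈ [0.13, 0.34]); the other
  four canopy parameters follow the gap-fraction identities exactly.
  Targets come from a frozen random shallow tanh teacher map (4 hidden
  units, bounded and smooth, hence realizable by the 3–10-neuron student
  networks) plus iid noise, default σ = 0.05 on the teacher's unit scale,
  which places well-fit models in the R ≈ 0.98 class reported for field
  campaigns. The cultivar enters the seed stream, so the two
  questionnaires get distinct data.

## Problem sizes and tolerances in the test suite

Training tests use 80–300 samples and networks up to 6-10-2 — sizes at
which LM/BR behaviour (monotone objective, early stopping, shrinkage,
teacher recovery at R ≥ 0.95) is already unambiguous. End-to-end workflow
tests run the four model replicas at 60–432 samples. Image recovery runs
at 256×256. Numerical tolerances: Jacobian vs finite differences 1e−5
relative; LM step vs normal equations 1e−8; scaling round trip 1e−10;
porosity/LAI identities 1e−9; segmentation recovery ±2 percentage points
(the segmentation-noise budget); canopy recovery ±0.02/±0.03; JPG
round-trip ±0.5 points.

## Known limitations

- The seed region is manual by design (a polygon); automatic seed
  detection is out of scope.
- No scatter correction or calibration transfer for NIR; features are raw
  derivative absorbances.
- The ANOVA/Tukey utilities assume one-way designs; repeated measures
  across sampling dates are not modelled.
- BR computes `tr(H⁻¹)` by direct inversion each accepted step — fine for
  the few-hundred-weight networks in scope, quadratic memory beyond that.
- The prediction-bound outlier count uses the pooled overall fit; per-stage
  bounds would differ slightly.
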