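# Methods

This note documents the models, numerical choices and limitations behind
`lc_relaxo`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from external data.

## Signal models

**SPGR (spoiled gradient echo).** Single-component steady state

    S(α) = M0 (1 − E1) sin(κα) / (1 − E1 cos(κα)),   E1 = exp(−TR/T1),

with κ the dimensionless B1 (flip-angle) scale. The TE decay
`exp(−TE/T2*)` is a constant factor across flip angles and is absorbed
into M0; it cancels in every ratio-based estimator in this package.
Validated against a brute-force iteration of the longitudinal recursion
(ideal spoiling) to better than 1e−8 relative.

**bSSFP (balanced steady-state free precession).** The steady state is the
fixed point of one TR of propagation: RF rotation by κα about x, free
precession about z by β, and relaxation (E1, E2). We use the sign
convention **β = 2π·Δf·TR − Δφ** (off-resonance Δf in Hz, RF phase
increment Δφ); only the Δφ ∈ {0, π} pair matters downstream, and the
convention is irrelevant to magnitudes after the joint fit. `bssfp_signal`
evaluates the closed-form solution of the 3×3 fixed point (vectorized);
`bssfp_signal_matrix` solves the same system explicitly and the two agree
to machine precision. The echo is read at TE = TR/2 with `exp(−TE/T2)`
applied; echo-time precession rotates the transverse magnetization without
changing its magnitude. With effective precession π the expression reduces
to the classic `M0 sinα (1−E1)/(1−(E1−E2)cosα−E1E2)` form.

**Two-pool model.** Non-exchanging short pool (myelin water: short T1/T2)
and long pool (intra/extra-cellular water), sharing M0, Δf and κ:
`S = f·S_short + (1−f)·S_long` with f the myelin water fraction (MWF).
No exchange, no third (CSF) pool, no magnetization-transfer or
finite-pulse effects.

**Double-angle pair.** Two fast-spin-echo images at α and 2α with a long
TR (complete T1 recovery assumed): S ∝ (sin κα, sin 2κα), so
κ = arccos(S2/(2S1))/α exactly, independent of the common scale.

## Estimators

**DESPOT1.** Linearized unweighted regression of S/sin(κα) on S/tan(κα);
slope = E1, so T1 = −TR/ln(slope); the intercept gives M0. Slopes outside
(0, 1) are flagged failed. Unweighted least squares is the classic
estimator; a noiseless round trip through the phantom recovers T1 to
≈1e−11 relative, and at SNR 200 the estimator is unbiased within
Monte-Carlo error (10 000 repeats).

**DESPOT2.** Default is a joint bounded nonlinear least-squares fit of
(M0, T2, Δf) over both phase cycles with the full steady-state model,
T2 ∈ (1, 500] ms and Δf ∈ ±1/(2TR), initialized from the linearized
single-cycle (π) estimator and multi-started over Δf (3 seeds, early exit
when the residual is at noise floor) to avoid the periodic off-resonance
ambiguity. The linearized π-cycle path (slope m = (E1−E2)/(1−E1·E2)) is
retained: it is exact on resonance, biased off resonance, and serves as
oracle and fast path. Which path a volume uses is a configuration flag,
as is the number of Δf starts (on-resonance simulations need only one).

**B1.** Double-angle κ per voxel with the ratio clamped to the arccos
domain (clamped and zero-signal voxels carry status flags, never a silent
κ = 1). Low-resolution maps are resampled by trilinear interpolation with
grid corners aligned; affine fields are reproduced exactly at interior
voxels.

**MWF (Bayesian Monte-Carlo).** Per voxel, the two-pool model is fitted to
the SPGR stack and both bSSFP cycles. Signals are normalized per sequence
by their mean over flip angles, removing M0 and constant TE-decay scale
differences so only signal shapes inform the fit. Samples of
(f, T1s, T1l, T2s, T2l, Δf) are weighted by exp(−RSS/(2σ²)) and the
estimate is the posterior-weighted mean of f (not the MAP), with the
effective sample size (ESS) as a diagnostic. σ is either fixed or
estimated from the best sample, σ = (RSS_min/dof)^½, floored at 1e−6 in
normalized units.

Default priors (configuration, not constants — plausible 3T brain ranges):
f ∈ [0, 0.4], T1s ∈ [150, 600] ms, T1l ∈ [600, 2500] ms,
T2s ∈ [5, 40] ms, T2l ∈ [40, 150] ms, Δf ∈ ±1/(2TR).

Two samplers:

* `adaptive` (default): annealed adaptive importance sampling (population
  Monte Carlo). An initial uniform draw over the prior box is followed by
  stages (default 5) that fit a full-covariance Gaussian to the tempered
  posterior (temperature chosen by bisection for a target ESS of 2000,
  covariance inflated ×1.5) and re-sample from it; the final stage uses
  proper importance weights (target/proposal), so the estimate is a
  consistent posterior mean under the uniform prior. The Gaussian proposal
  is essential: the two-pool likelihood has a long, oblique
  MWF–nuisance ridge, and measurement showed a plain uniform-prior
  sampler leaves MWF errors of up to ±0.07 on noiseless voxels at 10⁶
  samples, versus ≲0.01 for the adaptive sampler. Degenerate proposals
  (drifting outside the prior) fall back to a fresh uniform draw.
* `prior`: single-stage importance sampling with the prior as proposal —
  the transparent textbook estimator. Its Monte-Carlo error follows the
  classical ~n^(−1/2) law (demonstrated in fixed-σ mode, where the
  weights do not depend on the sample realization); the staged sampler's
  error law is not a single power law, so scaling diagnostics use the
  prior sampler.

Posterior shrinkage behaves as expected: increasing data noise pulls the
estimate toward the prior mean.

## Synthetic phantom

Two parallel circular cylinders (left/right LC) along the rostro-caudal
grid axis in a uniform background, generated directly on the analysis
grid: length 14.5 mm, diameter 2.5 mm (the average in-vivo LC dimensions),
0.5 mm isotropic voxels by default, lateral centers at ±3 mm. Voxels are
assigned by center-of-voxel inclusion — the simplest geometry that makes
slice counts exact (29 slices at the defaults). Tissue parameters inside
the tubes are interpolated linearly along the axis between a rostral and a
caudal set, giving known topographic gradients. Since in-vivo LC
R1/R2/MWF ranges are published graphically rather than numerically, the
defaults (background T1/T2 1100/75 ms; LC rostral 900/60, caudal 1000/70;
MWF 0.10 → 0.05) are plausible brainstem magnitudes, not authoritative
values; every recovery test is a round trip against the phantom's own
ground truth, so conclusions do not depend on these choices.

Noise is additive Gaussian on magnitude signals (high-SNR Rician limit,
clipped at zero), keeping the estimators unbiased in tests; exact Rician
noise is available. B1 fields are constant or a low-order linear ramp to
exercise the correction path. The phantom does not simulate registration
error, motion, slice profiles, partial-volume averaging at tube edges, or
scanner reconstruction — so passing round trips demonstrate estimator
correctness, not robustness to those real-data effects.

## Topography

Left and right LC are pooled into one ROI. Slice k of n mask-intersecting
slices (k = 0 most rostral) gets the midpoint percentile 100·(k+0.5)/n;
slices below the 66th percentile form the rostral-middle subregion, the
rest the caudal subregion, with finer bands (rostral 0–44, restricted
caudal 86–100) as optional outputs. The midpoint rule avoids
double-counting a boundary slice and is symmetric under flipping the
rostro-caudal direction (profile reverses, percentiles map p → 100−p).
Subregion means are voxel-count weighted, so they reconstruct the
whole-LC mean exactly (tested to 1e−12). Only ok-status voxels enter any
mean; a slice with no usable voxels is NaN and recorded.

Sensitivity masks: a shell (6-connected dilation by 3 voxels, iteratively,
minus the ROI — always disjoint from it) and lateral translations by a
whole number of voxels (default ±1.5 mm = 3 voxels at 0.5 mm), with any
overlap against the original removed and counted. Because the default LC
tube is 5 voxels across, a 3-voxel lateral shift overlaps its own
original; the overlap-removal diagnostics make this explicit.

## Cognition preprocessing

Trail-Making completion times are transformed with −log(seconds) (natural
log; the base cancels after z-scoring) so all instruments are
higher-is-better. Each instrument is z-scored against the pooled mean/SD
of participants' first assessments ("baseline"). Domains are constituent
means: memory (CVLT immediate + delayed), attention (TMT-A + Digit Span
forward), executive (TMT-B + Digit Span backward), fluency (category +
letter), processing speed (TMT-A + DSST). A missing constituent degrades
the domain to the mean of available tests with a completeness flag rather
than dropping the visit, since the mixed model can use partial data.

## Statistical models

All models adjust for sex, race (dummy-coded with the largest category as
reference) and years of education.

1. Linear age trend of a qMRI metric (OLS; matches the closed-form normal
   equations to 1e−10).
2. Quadratic age trend with mean-centered age; centering changes the
   coefficient parameterization, not the fitted values.
3. Cross-sectional domain z-score on age + covariates + metric (OLS);
   type-I error of the metric coefficient calibrates to ≈5% under the
   null, and age confounding is absorbed by the adjustment.
4. Longitudinal linear mixed model: domain z on
   age × metric × time (all lower-order terms included) + covariates,
   random intercept per participant, REML (ML available for
   likelihood-ratio work). The metric is always mean-centered; age is
   mean-centered by default (disable with a flag) — an equivalent
   reparameterization that stabilizes the three-way interaction. The key
   outputs are the metric×time coefficient (difference in annual
   cognitive change per unit metric) and metric×time×age (its age
   moderation). REML fixed effects match a generalized-least-squares
   oracle evaluated at the true variance components on simulated data.

Per-slice linear-age fits support predicted metric profiles at reference
ages (default 40 and 75, the cohort's quartiles), with covariates fixed at
reference levels (sex/race reference category, education at the cohort
mean — the choice is configuration).

BH-FDR: step-up adjusted p_(i) = min_{j≥i} m·p_(j)/j, capped at 1;
verified against brute-force enumeration and the standard library
implementation on random vectors. The declared family per metric and
effect is subregion variants × five domains.

## Synthetic cohort

Defaults emulate a cognitively normal aging cohort: n = 120, age uniform
on [22, 94] (mean 58, SD 20.8), 53.3% male, race 68.3/19.2/12.5%
White/Black/other, education N(16.3, 2.7²) years, visit counts from a
≥1-truncated Poisson with mean 3, visits spaced 1.5 years ending at the
MRI date (time 0), matching designs where testing mostly precedes
imaging. qMRI summaries follow configurable age-trend models; cognition
follows exactly the fixed-effect structure of the longitudinal model with
a Gaussian random intercept and i.i.d. residuals, with age and the metric
entering mean-centered — so a fitted model estimates the generating
coefficients directly (the three-way coefficient is covered by its 95% CI
in ≥90% of replicates at n = 300). Subregion metrics are drawn
independently given age; real rostral/caudal summaries are correlated,
which the generator does not emulate.

Default planted effects mirror the qualitative in-vivo pattern: a
positive rostral-R2 × time and rostral-R2 × time × age effect on memory
(lower rostral R2 → steeper memory decline, more so at older ages) and an
R1-linked fluency slope.

One caveat found during validation: when cognition is generated with a
metric×time effect, any model fitted with a *different* (control) metric
leaves per-participant random slopes in the residual that a
random-intercept model cannot absorb, deflating its standard errors. The
mask-specificity checks therefore assert attenuation of the control
effect size (and exclusion of the planted value from the control CI)
rather than a raw p-value threshold.

## Problem sizes

Defaults used by the test suite and acceptance script: phantom grid
32×32×40 at 0.5 mm (~930 LC voxels; fitting restricted to the ROI plus a
margin); MWF recovery at 10⁶ samples per voxel and volume MWF at 2×10⁴;
mixed-model coverage over 50 replicates of n = 300 with ~4 visits;
calibration nulls over 10³ replicates. These sizes give stable Monte-Carlo
estimates of every reported quantity on a single CPU.

## Known limitations

* No water exchange, MT, finite-pulse or slice-profile physics; the LC
  contrast debate around MT effects is out of scope.
* No registration or segmentation: masks and maps are assumed
  co-registered; mask ingestion is format-only.
* The BMC-MWF posterior is an approximation under a uniform prior with
  per-sequence normalization; it is validated by parameter recovery, not
  by equivalence to any particular published implementation.
* Rician bias is not modeled in the estimators (the Gaussian noise
  default keeps tests unbiased); at very low SNR the magnitude floor
  would bias R2 and MWF.
* The cohort generator's independence assumptions (metrics given age,
  residuals across domains) are simplifications of real cohort structure.
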