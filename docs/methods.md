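# Methods

This note documents the statistical model implemented in `tractlat`, the
numerical choices behind the fitting engine, what the synthetic-data
generator does and does not emulate, and known limitations.

## Lateralization index

For a strictly positive bilateral feature (FA, MD, AD, RD in their native
units; tract volume in mm³; mean streamline length in mm), the
lateralization index LI = (R − L)/(R + L) is dimensionless, lies strictly
inside (−1, 1), equals 0 at perfect symmetry, is antisymmetric under
hemisphere exchange, and is invariant to any common positive rescaling of
both hemispheres — which is what makes it robust to global scanner scaling.
Non-positive hemisphere values (possible in pathological extractions) make
the index degenerate; such rows are excluded and counted, never clamped.

Tract-level features are aggregates of upstream extractions: DTI indices
are streamline-count-weighted means over the voxels of a tract mask, volume
is voxel count × voxel volume, length is the mean streamline length.
Voxel/streamline geometry itself (gridding, resampling, segmentation) is
upstream of this package.

## Normative location-scale model

LI is modeled as Gaussian with both parameters depending on covariates:

    mu        = b0 + B_mu(age) b  + b_sex [male] + u_mu[cohort]
    log sigma = g0 + B_sig(age) g + g_sex [male] + u_sig[cohort]

- **Age smooths.** B(age) is a fractional-polynomial basis of shifted age
  a = age + age_offset (default offset 1.0 year, recorded in the model, so
  age 0 is admissible; the likelihood itself is invariant to the particular
  offset up to reparameterization of the basis). Powers come from
  {−2, −1, −0.5, 0, 0.5, 1, 2, 3}; power 0 is ln(a); a power repeated k
  times contributes ln(a)^(j−1)-multiplied copies (j = 1..k). Orders 1–3
  give 8 + 36 + 120 = 164 candidate smooths per predictor. The empty
  (intercept-only) spec is supported by the fitter as a degenerate case but
  excluded from enumeration.
- **Sex.** One additive indicator per predictor, "female" as reference,
  included when both levels are present. Population charts are produced per
  sex; "average" context averages the two sex-specific quantile curves (and
  prevalences) with equal weight.
- **Cohorts.** Study cohort enters as an offset on each predictor. Default
  "ridge" mode keeps one penalized indicator per cohort (Gaussian shrinkage
  with variance tau²); "fixed" mode is the unpenalized reference-coded
  fallback; single-cohort data drop the term. Population predictions set
  offsets to zero.
- **Distribution family.** Fixed to the normal; no shape parameters. The
  normal support exceeds (−1, 1), but fitted sigma values for realistic LI
  data are small enough that the violation is immaterial (see generator
  bounds below).

### Fitting

The penalized log-likelihood is maximized by alternating two exact/fast
steps until the penalized log-likelihood changes by less than 1e-10
(absolute, required twice in a row; cap 300 alternations):

1. given sigma, the mu coefficients solve a weighted least-squares system
   (weights 1/sigma²) in closed form;
2. given mu, the log-sigma coefficients take one Fisher-scoring step
   (expected information 2 ZᵀZ + penalty, Cholesky-factored once) with step
   halving, which makes every sweep a monotone ascent.

FP columns are standardized internally (mean/SD) for conditioning and the
coefficients are reported on the raw scale. Non-convergence triggers up to
three jittered restarts and is flagged on the returned model, never hidden.
The model also records the final gradient sup-norm, the iteration count,
and the delta-method covariance of the population mu coefficients
(intercept, FP terms, sex), from which the standard error of the fitted
median curve is available. That model-based SE is what recovery checks use
as their "within k standard errors" yardstick; a replicate-based Monte
Carlo SE would require many refits to measure the same quantity.

### Penalty variance for cohort offsets

tau²_mu and tau²_sigma are selected by maximizing a Laplace approximation
to the marginal likelihood (offsets integrated out) over a geometric grid
of 11 values spanning 1e-6 to 1e-1 (LI² units), in two passes: tau²_mu
first with tau²_sigma anchored at 0.05², then tau²_sigma at the selected
tau²_mu. An earlier EM-style moment update was abandoned: for the scale
offsets it exhibits a near-flat spurious fixed-point region in which the
update drifts for hundreds of iterations. Within a BIC search the grid
search runs once on the anchor specification (sigma spec (1)) and the
selected tau² values are held fixed for all candidates — tau² is a
cohort-level nuisance that depends only weakly on the age smooth.

### Model selection

BIC = −2 loglik + k log n, where k counts every fitted regression
coefficient: intercepts, FP terms, sex terms, and one parameter per cohort
offset on each predictor (a deliberate simplification; an effective-degrees-
of-freedom count for the shrunken offsets would be smaller and is noted as
an alternative). The default "staged" strategy selects the mu spec over all
164 candidates with the sigma spec held at (1), then the sigma spec with
the chosen mu frozen (328 fits); "full_grid" fits all 164² pairs and is
practical for reduced power sets. Ties break toward fewer parameters, then
lexicographic spec order. A selection report records BIC for every
candidate tried; only converged candidates can win.

### Charts, prevalence, dynamics

Centile charts evaluate q_p(age) = mu + sigma z_p on a dense grid (default
500 equally spaced points spanning the fitted age range; grids beyond the
support are flagged as extrapolation). Rightward prevalence is
100 Φ(mu/sigma). The median derivative uses central differences (one-sided
at the ends). Reversals are sign changes of the median between adjacent
grid points, with linearly interpolated crossing ages; a `min_excursion`
threshold (default 0: report all crossings) can suppress micro-crossings
whose flanking excursions both stay below it. Epoch slopes are the mean of
first-difference derivatives of |median| over grid pairs inside each epoch
— on a uniform grid, the endpoint difference divided by the span. |median|
is non-differentiable at a crossing, so an epoch containing one mixes
signs; the finite-difference definition is applied verbatim rather than
splitting epochs at crossings. Ages below 2 belong to no epoch. The final
epoch (60–100) closes its upper bound so a grid ending at 100 contributes.

Handedness analyses fit right- and left-handed subjects independently
(ambidextrous/unknown excluded; undersized strata are skipped with an
explicit record) and summarize the separation as Cohen's d with the
balanced pooled SD, sqrt((sigma_a² + sigma_b²)/2), at integer ages 1–80.
Both the signed mean and the mean absolute d across ages are reported,
since signed averaging can cancel a systematic separation.

## Synthetic-cohort generator

The generator emulates the structure of pooled multi-site lifespan
consortia: configurable numbers of cohorts with heterogeneous age windows
(the first cohort spans the full requested range so the union always covers
it; later cohorts get 10–50-year windows with uniform onsets), 53.7% female
and 9.3% left-handed defaults, Gaussian LI with FP-shaped age-varying mean
and log-SD, additive sex effects, and cohort offsets drawn from N(0, tau²).
Bilateral pairs are constructed as right = B(age)(1 + LI), left =
B(age)(1 − LI) around a positive baseline profile, so recomputing the index
returns the drawn LI exactly. Draws outside (−1, 1) are redrawn and
counted; truths must satisfy |mu| + 3 sigma < 1 across the design range
(checked, with a warn-or-abort switch), keeping truncation events rare
enough that fitting an untruncated normal is consistent. All randomness
derives from one integer seed through hashed SeedSequence spawn keys, so
each stage (design, offsets, each tract–feature draw) has an independent,
individually reproducible stream.

Truth presets: `constant`; `log_growth` (log-shaped median crossing zero in
late childhood with SD growing from 0.05 to 0.125 — the heteroscedastic
coverage-check truth); `recovery` (log-shaped median, constant SD 0.04,
tight cohort spread — sized so the median-curve sampling error at n = 5,000
sits well below recovery tolerances); `crossing35` (linear median, slope
2.5e-3 LI/yr, crossing exactly at 35 y — steep enough that the crossing is
localizable to about half a year at n = 5,000); `quadratic` (inverted-U);
and `varied` (per-tract–feature randomized bounded truths for pipeline
simulations).

What the generator does **not** emulate: longitudinal repeat scans,
non-Gaussian LI shapes (skew, heavy tails), age-dependent sampling density
within a cohort, missingness correlated with covariates, or feature-level
artifacts (segmentation failures appear only as the non-positive-value
exclusion path). Passing recovery tests therefore demonstrates the
correctness of the estimation machinery under the model's own assumptions,
not robustness to real-data violations of them.

## Problem sizes used in validation

Recovery, coverage and reversal checks use 20 cohorts × 250 subjects
(n = 5,000) — large enough that estimation noise sits comfortably below the
stated tolerances, small enough to run in seconds. The handedness null
calibration uses two strata of n = 2,000 drawn from one truth in a single
cohort with ages uniform over the 1–80 contrast range, 100 replicates; the
null SD of mean d is then close to its theoretical floor sqrt(2/n) ≈ 0.032,
dominated by pooled-median estimation noise. Oracle comparisons against a
generic derivative-free optimizer use n ≤ 200 with ≤ 2 cohorts and
unpenalized fixed effects, where the likelihood surface is small enough for
Nelder–Mead plus BFGS polishing to locate the global optimum reliably.

## Limitations

- The normal family cannot represent skewed or heavy-tailed LI
  distributions; no shape parameters are fitted.
- Cohort offsets are compound-symmetric per predictor (one scalar offset
  per cohort); cohort-by-age interactions are not modeled.
- BIC's parameter count treats each shrunken cohort offset as one full
  parameter, which is conservative toward flexible specs when cohorts are
  many.
- The staged BIC search is not guaranteed to find the joint (mu, sigma)
  optimum of the full 164² grid, though the full grid is available.
- Epoch slopes and reversal ages are point summaries without uncertainty
  bands.
- Chart contexts average the two sexes with equal weight; other population
  weightings are not implemented.
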