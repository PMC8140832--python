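# Methods

## The problem

Lung function in cystic fibrosis (CF), tracked as FEV₁ % predicted at clinic
encounters, declines heterogeneously: patients differ in when and how fast
they lose function, and care centers differ in the mix of decline phenotypes
they see. This package implements a center-level analysis of rapid decline:
sparse functional principal components analysis (FPCA) of irregularly
sampled FEV₁ trajectories, quartile classification of patients into
early/middle/late decline phenotypes from the first component score,
aggregation of fitted curves and rate-of-change curves to the primary care
center, size-category benchmarking, and a static animated dashboard.

Registry data of this kind cannot be shared, so every stage is developed and
validated against a synthetic cohort generator whose latent structure is the
model the analysis assumes.

## Model

For patient *i* with encounter ages *t_ij* (years, 6–21),

    Y_ij = μ(t_ij) + Σ_k ξ_ik φ_k(t_ij) + ε_ij,
    ξ_ik ~ N(0, λ_k),   ε_ij ~ N(0, σ²),

with μ the population mean curve, φ_k orthonormal eigenfunctions of the
between-patient covariance function, λ_k their (descending) variances, and
ε white spirometry measurement error. Components are oriented so that a
*higher* first-component score ξ₁ means *more rapid* decline; the decline
phenotypes are then

* early (rapid): ξ₁ above the cohort-wide third quartile,
* middle: between the quartiles (inclusive),
* late: below the first quartile.

Quartiles use the linear-interpolation convention of `numpy.quantile`; the
thresholds are recorded in every output because the label boundaries depend
on the convention. By construction the middle group is 50% of any cohort
with distinct scores (±1 patient).

## Estimation pipeline

1. **Mean.** A natural cubic smoothing spline is fit to count-weighted
   0.1-year bin means of the pooled (age, FEV₁) scatter, with bins anchored
   at their mean observed age (so linear data are reproduced exactly) and
   near-empty edge bins trimmed. The penalty is a fixed default
   (`lam = 0.5` on a mean-normalized weight scale) rather than GCV: the
   pooled residuals are dominated by *between-patient* variation, which is
   correlated within patients, so held-out/GCV criteria are nearly flat in
   the penalty and select erratically. The fixed value was calibrated on
   simulated cohorts across noise levels and cohort sizes and is
   overridable in `FpcaConfig`.
2. **Covariance surface.** Within-patient residual cross-products for
   *distinct* encounters are binned onto the 61-point age grid and smoothed
   with a count-weighted tensor-product P-spline (second-difference
   penalty, GCV). Excluding same-encounter products keeps the measurement
   error out of the surface; σ² is first estimated as the average gap
   between the smoothed raw diagonal and the surface diagonal over the
   central half of the age range, truncated at zero.
3. **Eigendecomposition.** Trapezoid-quadrature-weighted eigenpairs of the
   smoothed surface; negative eigenvalues truncated; eigenfunctions have
   unit L² norm under the grid quadrature (the Gram matrix is the identity
   to machine precision). The number of components K is the smallest K
   whose cumulative fraction of variance explained reaches 0.90 (the
   default cohort selects K = 2).
4. **Likelihood refinement.** The smoothed eigenstructure initializes a
   reduced-rank maximum-likelihood fit: r_i = B_i W ξ_i + ε_i with B_i a
   12-function cubic B-spline basis, fit by penalized EM over the loading
   matrix W (light second-difference penalty on its columns, penalty 10).
   This is the estimation flavor classically used for this model; the
   surface-smoothing stage alone recovers eigenfunctions only to within
   ~5–10°, while the refined fit reaches ~1–4° and tracks the identifiable
   variance components closely. The refined (φ, λ, σ²) replace the
   initial estimates; `FpcaConfig(refine=False)` disables the stage.
5. **Scores.** Per-patient best linear unbiased prediction (the Gaussian
   conditional mean): ξ̂_i = Λ Φ_iᵀ (Φ_i Λ Φ_iᵀ + σ̂² I)⁻¹ (Y_i − μ̂_i),
   with σ̂² floored at 1e-8 and a ridge fallback if the solve is singular.
   Sparse or noisy patients shrink toward the population mean.
6. **Orientation.** Each component is sign-flipped if its scores correlate
   positively with the fitted total change f̂_i(21) − f̂_i(6), so higher
   scores always mean more decline. Reconstructions are unchanged.

Fitted curves are the exact reconstruction μ̂ + Σ ξ̂_k φ̂_k on the grid;
rate-of-change curves differentiate a cubic-spline interpolant of the
reconstruction (they agree with central finite differences to well under
0.1 % predicted/year). Peak decline is the minimum of the rate curve and
the first grid age attaining it.

## Center benchmarking

Each patient's primary center is the center with the most distinct years of
follow-up (ties: earliest attended, then lexicographic id). Centers are
categorized by primary-patient count: small < 30, medium 30–150, large
> 150. Within each center × phenotype cell the fitted curves (and rate
curves) are averaged pointwise; empty cells are reported absent, not zero.
The size-category summary reports, per category, the number of centers and
patients and the mean (SD) *across centers* of center-level means of:
baseline age and FEV₁ (each patient's first in-window encounter), FPC₁
score, phenotype prevalences, and peak-decline extent and age — centers
weighted equally within category. Pairwise category differences use
two-sample Welch t-tests with Bonferroni factor 3 (the three pairs),
adjusted p capped at 1.

## Synthetic registry generator

Defaults define the reference study conditions:

| parameter | default | meaning |
|---|---|---|
| n_patients | 500 | cohort size |
| μ(t) | logistic decline 95 → 70 %pred | steepest mean decline ≈ −3 %pred/yr at age 14.5 |
| φ₁ | negated logistic ramp centered at age 12 (scale 1.5 y), unit L² norm | timing/severity of adolescent decline; higher ξ₁ ⇒ earlier, steeper loss |
| φ₂ | constant level shift, orthonormalized against φ₁ | stable between-patient level (random intercept) |
| score SDs | (25, 12) %pred·(L² scale) | component SDs; chosen so both components and the quartile classification stand well above the measurement-error floor, giving the recovery checks ≈2σ margins at n = 500 |
| noise_sd | 5 %pred | spirometry measurement error |
| entry age | uniform 6–10 y | registry entry |
| follow-up | uniform 8–12 y (encounters truncated at age 21) | so the cohort collectively covers ages 6–21 |
| visits/year | max(1, Poisson(0.9)) per designated year, jittered uniformly within the year | ≈8–14 encounters per patient; at least one annual registry contact |
| centers | sizes drawn in (8–26)/(40–140)/(160–230) patient bands, mix (0.6, 0.3, 0.1), one of each category forced | straddles the 30/150 category boundaries |
| transfers | 2%/year, destination proportional to center size | preserves the size distribution |

The generator records full ground truth (scores, quartile labels on the true
ξ₁, per-year centers, curves on the reference grid) for recovery testing.
Optional knobs shift small-center patients' entry ages up and ξ₁ down to
emulate the older, milder case mix of small programs; this is what the
size-category ordering tests exercise.

What the generator does *not* emulate: pulmonary exacerbations, treatment
effects, death/attrition, informative (non-MAR) missingness, secular birth-
cohort trends, or serial correlation beyond the smooth latent curve. Passing
tests therefore demonstrate correctness of the estimation machinery under
the assumed model, not robustness to those real-data features.

## Numerical choices and degenerate inputs

* Grid: 61 equally spaced ages on [6, 21] (0.25-y step); all curves live on
  it. The mean smoother tolerates up to one year of boundary extrapolation
  (linear, by the natural spline); a grid extending further beyond the
  observed ages is an error.
* Negative smoothed-covariance eigenvalues are truncated at zero; σ̂² is
  floored at 1e-8 in the scoring solve.
* Identical scores make the quartiles degenerate: everyone is labeled
  middle, with a warning. Fewer than 4 scored patients is an error.
* Peak-decline ties take the first (youngest) grid age. The *age* of peak
  decline is only sharply identified when the rate curve has a pronounced
  dip; for near-flat rate curves the arg-min can jump between shallow
  competing minima, which the recovery tests acknowledge by checking the
  cohort median and the pronounced-decline subgroup.
* EM refinement stops when the penalized log-likelihood stagnates
  (relative 1e-10) or at 500 iterations; fitting is fully deterministic.

## Validation summary (what the tests compute)

On the default seed-0 cohort the suite verifies eigenvalue recovery within
15%, first-eigenfunction angle within 10°, error-variance recovery within
20%, and ≥85% agreement between estimated and oracle phenotype labels; BLUP
scores match a brute-force joint-Gaussian conditional mean to 1e-8;
aggregation is conservative to 1e-9; Welch statistics match a hand-coded
textbook formula to 1e-9. Estimation error at these conditions is dominated
by the finite-sample draw (the realized score variance of 500 patients has
≈6% sampling SD), so recovery tests fix the cohort seed. Problem sizes
(n = 500–1200 patients, ~13 encounters each) were chosen as the smallest
cohorts at which all recovery targets are statistically comfortable.

## Known limitations

* No covariate adjustment or supervised clustering; no bootstrap confidence
  bands around the estimated curves.
* The quartile rule is relative to the analyzed cohort: scores and labels
  are not transferable across cohorts without refitting.
* The smoothing-based covariance stage assumes exchangeable measurement
  error; serially correlated within-patient noise would bias σ̂² low.
* Dashboard output is plain static HTML/PNG/GIF; no interactivity beyond
  links.
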