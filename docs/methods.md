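# Methods

This note records the models implemented in `pubgrowth`, their
assumptions, the defaults and why they were chosen, and what the synthetic
data do and do not establish.

## Stage 1: the SITAR growth model

### Model and conventions

Height of child *i* (cohort *C(i)*) at age *t*:

    y_it = (β₀ + a_C + a_i) + h( t₀ + (t − t₀ − b_C − b_i) e^{c_C + c_i} ) + ε_it,
    ε_it ~ N(0, σ²),   (a_i, b_i, c_i) ~ N(0, Ω).

* `h` is a natural cubic spline (linear beyond its boundary knots,
  continuous second derivative), dimension `df` = interior knots + 1,
  knots at quantiles of age. Default `df` = 5 for ages 7–19, selectable
  4–6 by BIC (`select_df`).
* **Sign convention:** `exp(c)` multiplies growth velocity, so a positive
  intensity effect means a faster, more intense spurt; for small `c` it
  reads as a percentage change. (The opposite sign convention, where
  `exp(−c)` divides the age scale, is equivalent up to the sign of `c`.)
* **Centering:** the intensity effect rescales age about a centering age
  `t₀` (the mean observed age by default, ~13 years). Without centering,
  rotation about age 0 makes a child's intensity leak heavily into its
  apparent timing (a ±10% velocity change would shift the apparent aPHV by
  more than a year), producing strongly correlated, poorly interpretable
  `b` and `c` estimates. With centering the two dimensions are close to
  orthogonal. One consequence worth knowing: increasing `c` pulls the
  individual aPHV *toward* `t₀` (for a rotation centre above the peak age,
  a more intense spurt is also slightly later on the fitted scale); PHV is
  strictly increasing in `c` regardless.
* The reference cohort (first alphabetically unless knots/cohorts are
  supplied explicitly) has offsets pinned to zero.

### Estimation

Penalized joint optimization alternating with Laplace-style variance
updates, no external NLME fitter:

1. **Random effects:** damped Gauss–Newton on each child's penalized
   residual (vectorized 3×3 solves across children).
2. **Recentering:** cohort-mean random effects are moved into the cohort
   fixed offsets, and the *global* mean timing/intensity effects are
   absorbed into the spline itself — a common timing shift is exactly a
   knot translation, and a common intensity shift exactly a knot rescaling
   about `t₀` with a deterministic rescaling of the truncated-power
   coefficients. This removes the flat directions (curve location/scale
   versus random-effect means) that otherwise let the mean curve drift away
   from the population average. Knot moves are restricted to a 30-iteration
   burn-in; afterwards a residual boundary-knot creep (which improves the
   approximate likelihood microscopically for hundreds of iterations
   without changing any parameter materially) is frozen out.
3. **Cohort shape offsets** `(b_C, c_C)`: Gauss–Newton per cohort.
4. **Linear parameters** `(β₀, γ, a_C)`: exact least squares given the
   transformed ages.
5. **Variance components:** Laplace/EM updates
   `Ω ← mean(û ûᵀ + V̂_i)`, `σ² ← (RSS + trace term)/N`, with `Ω` projected
   to the PSD cone.

The outer loop iterates to a relative change of 1e-5 in the Laplace
marginal log-likelihood (max 200 iterations); non-convergence is flagged
on the returned fit, never silent. Starting values: `b_i` from the age of
the largest observed height increment (centered, clipped to ±3 y), `a_i`
from mean residuals of an initial curve-only fit, `c_i = 0`.

The **fixed-effect covariance** is the linearized GLS information
`(Σ X̃ᵀ V_y⁻¹ X̃)⁻¹` with `V_y = J Ω Jᵀ + σ² I` per child. The design X̃
includes, besides `β₀`, the spline coefficients and the cohort offsets,
two *global* curve-location columns (`b₀`, `c₀` — the timing and intensity
analogues of `β₀`). These are pinned to zero during estimation (the
recentering absorbs them into the knots) but must be present in the
information matrix so that cohort-offset standard errors include the
reference cohort's own sampling noise; omitting them halves the timing
offsets' SEs and visibly inflates the Wald tests' size. With them, null
simulations show empirical-SD/SE ratios of ~1.0 for all three offset
dimensions and overall-Wald type-I error at the nominal 5%.

### Growth markers

Velocity is the analytic spline derivative, `v(t) = e^c h'(θ(t))` — never
a finite difference of data. aPHV/PHV come from an argmax on a 0.01-year
grid refined by bounded golden-section search to ~1e-4 years, or
equivalently from the closed-form shift identities
`aPHV = t₀ + b + (u* − t₀)e^{−c}`, `PHV = e^c h'(u*)` with `u*` the
mean-curve peak; the two routes agree to 1e-3 and the identities are the
default for whole-cohort tables. Takeoff is the velocity minimum on
[first observed age, aPHV); both searches flag boundary solutions, and
flagged children are excluded from stage 2 with logged counts rather than
imputed. Cohort contrasts propagate the fixed-effect covariance through
these maps (delta method): timing through `(b_C, c_C)`, intensity through
`c_C`, size directly; the per-marker overall P is a joint Wald chi-square
over all cohort-versus-reference differences.

## Overweight at takeoff

BMI against age is a polynomial mixed model (default global cubic, every
coefficient with a random effect) fitted by ML via statsmodels MixedLM on
centred/scaled age; exactly-polynomial (zero-residual) data are detected
and fall back to per-child least squares, since the variance components
are then unidentifiable. BMI at the child's takeoff age is converted to an
adult-equivalent ISO-BMI by a pluggable reference table (CSV: sex,
age_years, bmi_child, bmi_adult_equiv; monotone in BMI at each age,
linear across ages). Overweight means ISO-BMI **strictly** above 25;
exactly 25 is "other". No national reference values are bundled; the
package ships a deliberately synthetic reference (adult-equivalent =
BMI × 25/cutoff(age, sex), cutoff rising linearly to 25 at age 18) for
simulation and testing only.

## Stage 2: interval-censored Gaussian onset model

Onset intervals follow the staging rules exactly: girls, (last B1, first
stage ≥ 2]; boys, two successive testis lengths ≥ 25 mm, interval from the
last sub-threshold visit to the first of the confirmed pair (an
unconfirmed final-visit crossing stays right-censored; the legacy 20 mm
threshold is available only as an override). All-prepubertal children are
right-censored at the last visit; children pubertal at first visit are
left-censored with the likelihood's lower bound at 0 (onset age is
positive). Intervals are left-open/right-closed by convention; a
continuous model is insensitive to the choice. Eligibility for stage 2
requires ≥ 4 height measurements within ages 7–19 and a defined interval.

The onset age is Gaussian on the untransformed year scale — chosen because
predictions are reported as normal quantiles centred on `x'β̂` with
variance `σ̂²` and onset summaries as means/SDs in years; a log-normal
variant is a config switch. The likelihood sums `log[Φ((R−μ)/σ) −
Φ((L−μ)/σ)]` terms evaluated via `log_ndtr` with tail-symmetric
`log1p(−exp(·))` differences, so narrow intervals and far tails are
accurate to ~1e-8 (verified against adaptive quadrature); zero-width
intervals are treated as exact observations (Gaussian log-density), in
which limit the MLE equals ordinary least squares. Optimization is BFGS
over `(β, log σ)` with analytic gradients from a least-squares start on
interval midpoints; the covariance is the inverse observed information
(central-difference Hessian of the analytic gradient).

### Lasso selection

Candidates: aPHV, PHV, size `a_i`, overweight, and all second-order
interactions; continuous columns standardized, binary left 0/1. The L1
penalty is applied to the censored likelihood itself (FISTA with
backtracking and adaptive restart, warm-started down a 50-value λ path
spanning 4 decades from the smallest all-zero λ), not to imputed
midpoints — the midpoint-imputation variant exists behind
`method="midpoint"` for comparison. λ is chosen by child-wise 10-fold CV
deviance with the **1-SE rule** (sparsest λ within one standard error of
the CV minimum); the raw CV minimum systematically over-selects — it
retains the inert size parameter and noise interactions in most
replicates — while the 1-SE rule recovers the active set {aPHV,
overweight} and excludes size in ≥ 90% of replicates at n = 300.
`rule="min"` is available. Selected solutions are polished by a smooth
refit on the active orthant; at λ = 0 this reproduces the unpenalized MLE
to 1e-4. Selected interactions pull their main effects in (hierarchy
repair). Intercept and σ are never penalized.

### Prediction and evaluation

Prediction intervals use `σ̂` only (no parameter-uncertainty inflation),
matching the quantile construction above; empirical 95% coverage on
held-out synthetic children is 0.95 ± 0.01. Cross-validation draws seeded
child-wise folds; when lasso is part of the model it re-runs inside every
training fold (no selection leakage; the leaky select-once variant is a
flag). The agreement statistic compares the observed interval with
[pred − 0.5, pred + 0.5]; a single shared endpoint counts as overlap, and
only interval-censored children with observed width < 1.5 years enter the
denominator.

## The synthetic cohort generator

The generator defines the conditions under which the pipeline is tested.

* **Template curves.** Each sex has a mean height curve built from a
  declining childhood velocity plus a Gaussian spurt bump, calibrated so
  aPHV/PHV and the heights at 8 and 18 years hit typical Finnish cohort
  values (girls 11.7 y / 7.8 cm·y⁻¹, 127.7/165.6 cm; boys 13.7 y /
  9.9 cm·y⁻¹, 129.8/179.6 cm). The default template is the exact
  projection of that curve onto a df-6 natural spline with an affine
  correction restoring all four calibration targets exactly — i.e. a curve
  inside the model family the analysis assumes, which is the right basis
  for parameter-recovery experiments; the closed-form (non-spline)
  original is available as `kind="smooth"` for robustness checks.
* **Children** deviate by `(a, b, c) ~ N(0, Ω)` (default SDs 5 cm, 0.8 y,
  0.11) plus cohort offsets; the default three cohorts mirror a
  reference cohort without pubertal follow-up, a large cohort with annual
  staging, and a small boys-only cohort with 6-monthly staging, with
  cohort shifts at published-scale magnitudes (~1.5–2.3 cm size, ~0.1 y
  timing, ~1–3% intensity).
* **Onset link:** `onset = μ₀ + 0.9·aPHV − 0.15·PHV + β_ow·OW +
  β_int·(aPHV − aPHV_template)·OW + N(0, 0.8²)`, with β_ow = −1.0 y for
  girls (interaction −0.3/y) and 0 for boys. The residual SD 0.8 y makes
  the implied marginal onset SDs ~1.1–1.2 y and the cross-validated
  agreement fall at the reported scale of such analyses (~70–80%); the
  per-sex intercepts put mean onsets near 10.7 y (girls) and 11.5 y
  (boys).
* **Overweight truth** thresholds the child's simulated BMI trajectory at
  its true takeoff age against the synthetic ISO-BMI reference; the BMI
  level distribution is placed so that a configurable fraction of children
  (defaults 15% girls, 17.8% boys) is overweight.
* **Staging emission** is noise-free for Tanner stages (stage = 1 before
  the true onset, then advancing yearly) and noisy-but-monotone for testis
  length (a logistic growth curve crossing 25 mm exactly at the true
  onset, clipped Gaussian measurement noise), so constructed intervals
  bracket the true onset exactly under noise-free settings.
* **Dropout** is an independent geometric stopping visit applied to both
  visit series (non-informative censoring, matching the onset model's
  assumption). Visit-time jitter and the dropout law are not pinned down
  by any published description; both are plain choices exposed in the
  config.
* Seeding uses `SeedSequence(entropy=seed, spawn_key=(purpose, child))`
  streams; naive list-based seeds left measurable cross-child correlation
  that inflated cohort-mean sampling variance by ~20% and broke Wald-test
  calibration checks.

**What passing tests do and do not show.** The generator's staging is
idealized (no stage mis-assessment, no informative dropout, Gaussian
onset residuals, linear marker–onset link) and its growth curves come
from a single template family. Passing recovery and calibration tests
demonstrates that the estimation machinery is correct and calibrated under
the model's own assumptions at realistic effect sizes — not that those
assumptions hold in any real cohort, nor that real-data agreement would
match the synthetic values.

## Problem sizes and numerical choices

Test and acceptance experiments use deliberately scaled designs: SITAR
recovery at 400 girls × ~16 visits; AFT coverage at 100 replicates of
n = 300; lasso selection at 50 replicates of n = 300; Wald-test size at
200 two-cohort nulls of 20 girls/cohort; the end-to-end demo at ~500
children per run. Tolerances: spline/velocity identities 1e-3 (grid
refinement is to 1e-4 years), likelihood vs quadrature 1e-8, censoring-free
OLS limit 1e-6, λ→0 equivalence 1e-4. Degenerate inputs (all-right-censored
groups, zero-residual BMI data, boundary velocity extrema, non-monotone
stage sequences, duplicate visit rows) are either handled with a
documented fallback and a log entry or rejected with a named error — never
silently.

## Known limitations

* The Laplace/FOCE machinery shares the usual NLME small-sample caveats;
  variance components are ML-flavoured (no REML correction).
* Takeoff is undefined for children first observed after their spurt has
  begun (left-boundary flag); such children are excluded from stage 2
  rather than imputed.
* The delta-method timing contrast treats the mean-curve peak argument
  `u*` as fixed; its sampling noise cancels in cohort differences only to
  first order.
* Only a synthetic ISO-BMI reference ships with the package; real analyses
  must supply a national reference CSV.

## Simulation config schema (YAML)

`pubgrowth simulate --config sim.yaml` accepts the fields of `SimConfig`;
everything is optional and defaults to the study conditions above.

```yaml
n_children_per_cohort: 160
seed: 42
cohorts:                      # list of cohort specs
  - name: DIPP                # reference cohort (alphabetical first)
  - name: STRIP
    a_offset: 1.5             # size shift, cm
    b_offset: -0.09           # timing shift, years
    c_offset: 0.025           # intensity shift, log scale
    growth_spacing_months: [6, 12]   # within [6, 12]
    pubertal_spacing_months: 12      # omit for no pubertal follow-up
    pubertal_start_age: 8.0
    n: 200                    # overrides n_children_per_cohort
    sexes: [F, M]
omega: [[25, 0, 0], [0, 0.64, 0], [0, 0, 0.0121]]   # symmetric PSD
sigma_height: 0.5             # cm
sigma_bmi: 0.3
onset_link:
  F: {intercept: 1.5, aphv: 0.9, phv: -0.15, overweight: -1.0,
      interaction: -0.3, sigma: 0.8}
  M: {intercept: 0.65, aphv: 0.9, phv: -0.15, overweight: 0.0,
      interaction: 0.0, sigma: 0.8}
ow_prevalence: {F: 0.15, M: 0.178}
dropout_hazard: 0.02          # per growth visit
age_range: [7.0, 19.0]
```
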