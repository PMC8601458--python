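# pubgrowth

Determining the timing of pubertal onset from longitudinal growth data.

Pubertal onset is conventionally staged clinically — Tanner breast stage 2
(B2) in girls, testicular enlargement to ≥ 25 mm length in boys — but many
cohort studies collect repeated height measurements without pubertal
staging. `pubgrowth` implements a two-stage statistical pipeline that
determines the age at pubertal onset from growth alone:

**Stage 1 — SITAR growth modelling.** Heights of child *i* at ages *t* are
fitted with the shape-invariant Super-Imposition by Translation And
Rotation model

```
y_it = (β₀ + a_C + a_i) + h( t₀ + (t − t₀ − b_C − b_i)·exp(c_C + c_i) ) + ε_it
```

where `h` is a shared natural cubic spline, `(a_i, b_i, c_i) ~ N(0, Ω)` are
per-child random effects for **size** (cm), **timing** (years) and
**intensity** (log velocity scale), and `a_C, b_C, c_C` are cohort fixed
offsets against a reference cohort. Differentiating the fitted curve gives
each child's age at peak height velocity (aPHV, years) and the peak height
velocity itself (PHV, cm/year); cohort differences in size, timing and
intensity are reported with delta-method 95% CIs and Wald tests. The
growth-spurt takeoff (velocity minimum before aPHV) anchors an overweight
classification: the child's BMI at takeoff, read off a polynomial
random-coefficients trajectory, is converted to its adult-equivalent scale
(ISO-BMI) with a pluggable reference; ISO-BMI > 25 is overweight.

**Stage 2 — interval-censored time-to-onset regression.** Staging visits
only bracket onset, so the onset age `T` is modelled as

```
T = x'β + ε,   ε ~ N(0, σ²)
```

by maximum likelihood over interval-, right- and left-censored
observations, with aPHV, PHV, size and overweight status (and their
second-order interactions) as candidate covariates, selected by an L1
penalty on the censored likelihood (cross-validated λ). Point predictions
are `x'β̂`; prediction intervals are normal quantiles with SD `σ̂`.
Predictive ability is the *agreement* statistic: under child-wise 10-fold
cross-validation, a one-year window centred on the predicted onset is
compared with the observed onset interval (intervals of ≥ 1.5 years
excluded), and any overlap counts as agreement.

Because the motivating cohort data are not public, the package includes a
first-class multi-cohort synthetic generator (`pubgrowth.synthetic`) that
emulates the study structure — cohort-specific visit schedules, cohort
shifts in size/intensity, dropout, staging schedules, and an onset age
linearly linked to the true growth markers — together with a ground-truth
table, so every stage is testable end to end.

## Worked example

Run the full pipeline for girls on the default synthetic study (three
cohorts, one without pubertal follow-up, ~500 children):

```python
from pubgrowth import RunConfig, run_full_pipeline

config = RunConfig(sex="F", out_dir="runs/girls", model="extended", seed=0)
artifacts = run_full_pipeline(config)
for name, block in artifacts["agreement"].items():
    print(f"{name}: {block.agreement_pct:.1f}% agreement "
          f"({block.n_agreements}/{block.n_evaluated} evaluated)")
fit = artifacts["onset_fits"]["extended"]
print(fit.summary_frame().round(3).to_string(index=False))
print(f"residual SD sigma = {fit.sigma:.3f} years")
```

prints

```
simple: 71.1% agreement (54/76 evaluated)
extended: 75.0% agreement (57/76 evaluated)
           term  estimate    se  ci_lo  ci_hi     p
    (Intercept)     2.261 1.820 -1.306  5.827 0.214
           aphv     0.931 0.157  0.622  1.239 0.000
            phv    -0.289 0.144 -0.571 -0.006 0.045
     overweight     1.011 4.894 -8.581 10.602 0.836
aphv:overweight    -0.168 0.418 -0.986  0.650 0.688
residual SD sigma = 0.949 years
```

Reading this: the simple model (aPHV + PHV only) already agrees with the
observed onset interval for 71% of evaluable girls; adding overweight
status and its aPHV interaction raises that to 75%. aPHV dominates the
prediction (0.93 years of onset shift per year of aPHV). The overweight
main effect and interaction are jointly interpretable: the overweight
shift *at a given aPHV* is `1.01 − 0.17·aPHV`, about −0.9 years at the
mean aPHV of 11.6 — overweight girls start puberty earlier. The run
directory contains every artifact (SITAR fit, marker table, censoring
intervals, cohort contrast tables, per-child predictions, a Fig-style
prediction-interval plot and `report.md`).

The same stages are scriptable from the shell:

```sh
pubgrowth simulate --seed 42 --out data/
pubgrowth run-all --sex M --growth data/growth.csv --pubertal data/pubertal.csv \
    --model extended --seed 42 --out runs/boys
```

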