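# Methods

## Model and estimation scheme

The package fits a heteroskedastic linear mixed model in which both the
mean and the log residual variance carry linear predictors with fixed
and random effects (a double hierarchical GLM). Conditional on the
random vectors the trait is normal; `u ~ N(0, I σ²_u)` and
`u_d ~ N(0, I σ²_d)` are assumed independent of each other. A genetic
correlation between mean and dispersion effects is deliberately **not**
estimated: when the generator draws correlated `(u, u_d)` the model is
still fitted under independence, and the simulation study shows the
variance components are not materially impaired by that misspecification.
Identity link for the mean and log link for the dispersion are the only
links offered; non-normal responses are out of scope.

Estimation iterates between two augmented weighted least-squares
problems:

* the mean-part mixed-model equations, solved as one WLS problem on the
  stacked design `T = [[X, Z], [0, I]]` with augmented response
  `(y, 0)` and covariance `diag(φ, σ²_u I)` — algebraically identical
  to Henderson's equations;
* a gamma GLM/GLMM with log link on the REML-corrected squared
  residuals `ê²/(1−h)` with prior weights `(1−h)/2`, where `h` are the
  augmented-model leverages. The correction removes the downward bias
  of predicted residuals; the gamma scale parameter 2 (squared normal
  residuals are `φ·χ²₁`) is absorbed into those weights and never
  estimated separately.

Variance components are updated by the closed-form intercept-only
gamma-GLM estimators `σ²_u = Σû_j²/Σ(1−h_j)` and
`σ²_d = Σd_j/Σ(1−h_dj)`, and the residual weights by
`W = diag(exp(−X_d b_d − Z_d u_d))`. The outer loop stops when no
variance component (including the mean of `φ`) changes by more than
`tol` between iterations.

## The two variants

`variant="pql"` (default) takes `d_j = û_d,j²`, the squared scaled
residual of dispersion pseudo-record `j` in the linearized (adjusted
dependent variable) system. `variant="hlik"` takes the gamma deviance
of the pseudo-record, `d_j = 2(û_d,j + e^{−û_d,j} − 1)`, following the
augmented-gamma structure in which the pseudo-records pass through the
same log link as the data.

These agree to first order (`d_j ≈ û²` for small `û`), but the gamma
deviance has expectation `≈ E[û²](1 + Var(û)/4)`, so at substantial
dispersion heterogeneity the hlik variant estimates σ²_d systematically
higher — about 15–35% at σ²_d = 1 with well-replicated groups. The PQL
update is unbiased at the fixed point (`E[û_j²] = σ²_d(1−h_j)` exactly,
since `1−h_j` is the reliability) and is the default; the replicated
recovery study and all reported summaries use it. Mean-part estimates
agree across variants to well under 1%.

The two variants also initialize differently, as a matter of
definition: hlik starts from `φ = var(y)` uniformly, PQL from `W = I`.
Both start `σ²_u = σ²_d = 0.1·var(y)`. The fixed points do not depend
on initialization in any case we have observed.

## Numerical choices

* **Mean solve.** The augmented normal equations are solved through a
  p×p Schur complement whenever the random-by-random block is diagonal
  (a single one-hot grouping factor — the common large-q case), making
  each solve O(n·p²); otherwise a dense pseudo-inverse path is used,
  which also absorbs rank-deficient designs. Collinear fixed-effect
  columns are dropped left-to-right with a warning. Leverages are
  clipped at `1 − 1e−8` before any division by `1 − h`; a record at the
  cap keeps a vanishing weight rather than being deleted (it carries no
  information but its removal would change bookkeeping).
* **Dispersion solve.** The penalized gamma fit iterates Newton steps
  (observed information, step-halved on the penalized quasi-likelihood)
  rather than plain Fisher scoring: squared residuals are so dispersed
  (`χ²₁`-type) that Fisher scoring contracts at rates as poor as ~0.93
  per step on realistic data, while Newton converges in a handful of
  steps. Because the score vanishes at the optimum, one final solve
  with the standard expected-information (prior) weights reproduces the
  same coefficients and yields the conventional hat-matrix leverages.
  Warm starts from the previous outer iteration are used throughout.
  Inner tolerance 1e−8 on coefficients, cap 50 iterations.
* **Floors and guards.** Variance estimates are floored at 1e−8 (with a
  boundary flag) to keep the augmented covariance positive definite;
  zero dispersion responses (exact fits) are floored at 1e−12 × mean
  response so the log link is defined, keeping their weight; linear
  predictors are clipped at ±700 before exponentiation. A variance
  exceeding 1e8·var(y) flags divergence and stops the loop.
* **Convergence.** `tol = 1e−5` on the largest absolute change across
  all variance components, cap 100 outer iterations; non-convergence is
  flagged on the result, never raised. Typical runs converge in 5–15
  outer iterations. No damping is applied by default; a `relaxation`
  factor is available for pathological cases.
* **Pedigrees.** The relationship factor `L` (with `A = LL'`) is built
  by the recursive construction directly from the pedigree — exact,
  order-stable, and immune to the numerical rank problems of
  factorizing a semi-definite `A`. Folding `Z → ZL` trades sparsity for
  i.i.d. effects; no sparsity-preserving reformulation is attempted.
  Phenotyped individuals absent from the pedigree are appended as
  unrelated founders with a warning. BLUPs are reported on the original
  (correlated) scale for all pedigree members, including non-phenotyped
  ancestors; the variance update uses the i.i.d. transformed effects.

## Synthetic data

`simulate()` generates the validation design: equal-size groups,
`y = 1.0 + 0.5x + u_l + e`, `Var(e) = exp(0.5 + 1.5x_d + u_dl)`, with
`(u_l, u_dl)` bivariate normal (variances 0.5 and 1.0 by default,
correlation ρ) and binary sex-like covariates coded `±0.5` with equal
frequency. The `±0.5` coding is what makes the average conditional
residual variance come out near 3.5
(`0.5(e^{1.75} + e^{0.25})·e^{0.5} ≈ 3.5`); `{0,1}` coding would about
double it. `x` and `x_d` are drawn independently by default
(`shared_covariate=True` ties them). The `E[e^{u_d}] = e^{σ²_d/2}`
inflation of the mean residual variance is an intentional part of the
design and lands in the fitted dispersion intercept, not in σ²_d.

What the generator does *not* emulate: unbalanced group sizes, selection
or non-random mating, pedigree structure at scale, repeated records per
individual, or non-normal residuals. Passing recovery tests on these
data therefore demonstrates correctness of the estimator under the
stated design, not robustness to real-data pathologies — although the
leverage machinery specifically targets imbalance and is exercised by
dedicated imbalance tests.

The replicated study (`run_study`) fits 20 replicates per scenario at
n = 10,000 with 1000/100/10 groups and ρ ∈ {0, −0.5}, reporting
across-replicate means and standard errors; per-replicate seeds are
spawned from one base seed. These sizes run in roughly 15 seconds total
on one CPU. The homoskedastic oracle comparisons use n = 200 with 20
groups, where a dense restricted-likelihood surface can be maximized
directly to high precision.

## Known limitations

* σ²_d estimates at very few dispersion levels (q_d ≈ 10) carry large
  sampling error (across-replicate s.e. ≈ 0.1 even with 20 replicates).
* The hlik variant's σ²_d is upward-shifted at large σ²_d (see above);
  prefer PQL unless deviance-based estimates are wanted for comparison.
* Standard errors of variance components within a single fit are not
  produced; the study reports across-replicate spread instead.
* Relationship folding densifies the random-effect block, so very large
  pedigrees are slow through the dense path.
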