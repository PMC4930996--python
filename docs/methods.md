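# Methods

This note documents the statistical models, the numerical choices, and the
assumptions behind `isoniche`, at the level of detail a user needs to judge
what the results mean and where they stop applying.

## Niche variance decomposition

For one tissue × isotope, let x_ij be the value of individual j in year i.
The package computes

* WIC — the unweighted mean over individuals of Var_i(x_ij), each
  individual's variance taken over its own sampled years only;
* AIC — the variance over individuals of the per-individual means x̄_j;
* TNW = WIC + AIC, and the specialization ratio WIC/TNW.

Every individual contributes equally to WIC regardless of how often it was
sampled; this is the moment-framework convention for unbalanced designs and
matches the verbal definition of averaging per-individual variances. A
sample-size-weighted variant would approach the pooled within-group
variance instead; it is not offered because the equal-weight definition is
the one the decomposition's interpretation rests on.

**Variance denominator.** Whether variances use n or n−1 is a declared
parameter, `convention ∈ {population, sample}`, defaulting to `population`.
Rationale: with the n-denominator the law of total variance is exact — on
any balanced design WIC + AIC equals the pooled population variance of all
samples (tested to 1e-10) — so TNW is literally the population niche
variance. The sample convention is available for comparability with
software that defaults to n−1. With few samples per individual the
population convention biases each per-individual variance down by the
factor (1 − 1/n_j); at the default design (≈4.3 samples per individual) a
population with no among-individual differences therefore shows an expected
WIC/TNW near 0.77, not 1. This finite-sampling ceiling is a property of the
estimator, not a bug, and the test suite asserts against it explicitly.

**Eligibility.** Individuals need ≥ 2 samples of a tissue to contribute a
within-individual variance; individuals below the threshold are dropped
from that tissue's decomposition only (warning, or error if configured).
AIC and the sample counts are computed over the same retained individuals
so TNW is internally coherent.

**Rounding.** Report tables round half-up to 2 decimals, the convention of
printed tables; all computation is done unrounded.

## Mixed-model engine

Models are Gaussian LMMs y = Xβ + Σ_k Z_k u_k + ε with u_k ~ N(0, σ²_k I)
and ε ~ N(0, σ²_ε I). Random terms are crossed intercepts (individual,
year) and optionally an individual random slope on a covariate. The slope
is **uncorrelated** with the intercept (the `||` form): the slope covariate
is individual-centered, which leaves the intercept–slope correlation weakly
identified at 100–200 observations, and the uncorrelated form keeps every
variance parameter a single non-negative scalar.

**Estimation.** With variance ratios γ_k = σ²_k/σ²_ε, the marginal
correlation matrix is V₀ = I + Σ_k γ_k Z_k Z_kᵀ. For fixed γ the GLS β̂ and
the closed-form σ̂²_ε maximize the (restricted) likelihood, leaving a
profiled criterion over γ alone:

* ML: −2ℓ = n log(2πσ̂²) + log|V₀| + n, σ̂² = rᵀV₀⁻¹r / n
* REML: −2ℓ_R = (n−p) log(2πσ̂²) + log|V₀| + log|XᵀV₀⁻¹X| + (n−p),
  σ̂² = rᵀV₀⁻¹r / (n−p)

Quadratic forms in V₀⁻¹ and log|V₀| are evaluated through the Woodbury
identity on the q × q inner matrix (q = total random-effect levels, ≈ 40
at the default design), so one evaluation costs O(q³) rather than O(n³).
These conventions match lme4/statsmodels log-likelihoods exactly (the test
suite pins this against statsmodels MixedLM to ≤ 1e-4).

**Optimization.** The criterion is minimized over θ_k = √γ_k ∈ [0, 10³]:
θ = 0 puts a component exactly on the boundary (singular fit, flagged but
returned). One variance component uses bounded scalar minimization with an
explicit boundary candidate; several components use L-BFGS-B from two
starts (θ = 1 and θ = 0.05) followed by a Nelder–Mead polish iterated until
the deviance is stationary — the line search can stall near the zero
boundary, and the polish guarantees monotone model hierarchies (adding a
fixed effect never decreases the ML likelihood, asserted to 1e-8).
A fit is `converged` when a start succeeds at the final minimum or the
polish cannot improve it by more than 1e-6 relative; non-convergence is
flagged on the fit object, never silent. An exactly constant response
returns the degenerate fit (all variances 0, β = constant) directly.

**Inference.**

* LRTs use ML fits: p from χ²_df, or from the boundary mixture
  ½χ²₀ + ½χ²₁ when one variance component is tested against zero.
* AIC = −2ℓ_ML + 2k with k = fixed effects + all variance parameters
  including σ²_ε. Model-comparison tables are built from ML fits even
  though coefficient/variance reporting uses REML: REML likelihoods are not
  comparable across fixed-effect structures, so REML-based AIC would be
  meaningless for exactly the comparisons the tables make. This is the one
  place the package deliberately deviates from "everything REML".
* Marginal/conditional R²: Rm² = σ²_f/(σ²_f + σ²_rand + σ²_ε) and
  Rc² = (σ²_f + σ²_rand)/(·), with σ²_f the population (ddof = 0) variance
  of Xβ̂ over the observations and σ²_rand the summed intercept variances
  plus σ²_slope·mean(w²) for a random slope on covariate w.
* Wald F statistics with residual-containment denominator df (n − p) are
  available, clearly labelled approximate; LRT is the primary path.

**Repeatability.** R = σ̂²_ind/(σ̂²_ind + σ̂²_ε) from the intercept-only REML
fit with the individual as the sole random factor — agreement
repeatability, unadjusted; pass fixed covariates (e.g. year dummies) for
the adjusted variant. The SE is a parametric bootstrap (default 1000
simulate-and-refit replicates, seeded); the p-value is the boundary LRT.
The bootstrap SE is the package's choice — the distribution of R̂ near the
boundary is skewed, and a delta-method SE would misrepresent it.

## Centering and the two model families

`center_within_individual` splits a covariate into the individual's mean
over its own observed years (between effect) and the per-observation
deviation (within effect); within + between reconstructs the covariate
exactly and the within column sums to zero per individual. Because
individuals are observed in different year subsets, a purely year-level
covariate (an environmental index) still yields among-individual variation
in the between column.

Environment → isotope models use two-month window means (defaults: months
8–9 of the sampling year for red blood cells, 2–3 for feathers; both
windows are configuration, not hard-coded, and no cross-year wrap is
applied). Quadratic models square the centered columns (within² and
between²), not the raw covariate. One environmental variable per model is
enforced — the indices are mutually correlated and joint models would be
collinear; pairwise window-mean correlations are reported instead.

Isotope → trait models z-standardize the response and covariate within
year (sample SD; a constant year stratum is an error naming the year)
before centering, which removes year-level baseline shifts and makes
inference invariant to per-year positive rescaling of the trait.

**Random-slope gate.** Individual random slopes are tested only when the
within-individual fixed effect is significant (ML LRT, α = 0.05 by
default): with no mean within-individual response there is no plasticity
whose among-individual heterogeneity could be interpreted, and the slope
variance test would burn power for nothing. When the gate does not fire the
result is marked "not evaluated", never silently zero.

## Synthetic generator

The generator emulates the motivating study design: 30 females over
calendar years 2006–2013, no fieldwork at all in 2011, no feathers in 2009;
per-female blood-year counts drawn from {3,4,5,6} with probabilities
(.25,.35,.25,.15) (mean 4.3) and feather-year counts from {2,3,4,5} with
(.13,.27,.40,.20) (mean 3.67), giving ≈130 blood and ≈110 feather records.
Isotope values are μ + individual + year + β_w(env − env̄_j) + β_b env̄_j +
slope_j(env − env̄_j) + residual with all effects Gaussian; defaults
σ²_ind = 0.5, σ²_year = 0.3, σ²_res = 0.3 permil² were chosen to match the
magnitude of a decomposition whose among-individual component is ≈0.5 and
whose within-individual variance splits between year and residual, with
tissue means at realistic values (blood δ¹⁵N 13.0, δ¹³C −21.5; feather
13.5 / −20.5 — feathers higher in δ¹³C, as tissue fractionation gives).
Environmental indices are monthly AR(1) series (φ = 0.5, marginal SD 1.04;
SSTA 0.6) so two-month window means vary among years with SD ≈ 1 index
unit. Traits are linked to the realized blood isotope on the z-scale
(so link coefficients are directly comparable to the analysis stage's
standardized estimates) and mapped to grams / day-of-season units; A- and
B-egg masses split the total clutch mass at a fraction ≈ 0.42.

What the generator does **not** emulate: correlation between δ¹⁵N and δ¹³C
within a tissue (the four series draw independent effects), isotopic
baseline (isoscape) shifts between years or regions, heavy-tailed or
skewed effect distributions, and enrollment history (per-year sample counts
match the marginal summaries, not any specific yearly ledger). Passing
recovery tests on this generator therefore demonstrates correctness of the
estimators under the model's own assumptions — not robustness to baseline
drift or non-Gaussian behaviour in field data.

## Problem sizes and determinism

Monte-Carlo suites run at the study design scale (30 individuals, 3–6
observations each, crossed year effects): 200 replicates for recovery
checks, 500 for the type-I error of the boundary test, 100 for gate rates,
50 seeds × 5 points for the specialization sweep. All simulations take a
single integer seed through `numpy.random.default_rng`; identical config +
seed reproduces CSV output byte-for-byte, and the pipeline report is
identical across reruns up to timestamps in its provenance block.

## Known limitations

* Dense-covariance likelihood: fine to a few thousand observations,
  not beyond (by design).
* No generalized (non-Gaussian) mixed models, no Satterthwaite/
  Kenward–Roger df, no Bayesian estimation, no model averaging.
* Correlated intercept–slope random effects are not offered (see above).
* The trait join reports row losses but does not impute; records missing
  any required trait simply drop out of the affected model.
* Capture-date corrections for traits measured off the clutch-initiation
  date are assumed already applied to the input tables.
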