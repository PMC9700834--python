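# Methods

This note documents the statistical model, its priors and defaults, the
sampler design, the synthetic-data generator's scope, and the numerical
choices the package makes. Every empirical number quoted here is computed
by the test suite or by `scripts/acceptance.py`.

## Data model

Observed anemic counts `O_ik` for zone `i = 1..m` and survey period
`k = 1..K` with denominators `n_ik` are modelled as

```
O_ik ~ Poisson(μ_ik)
log μ_ik = log E_ik + α + u_i + v_i + β₁ t_k + x_ik' β
```

- `E_ik` are **internally standardized expected counts**:
  `E_ik = n_ik · r` with the pooled reference rate `r = Σ O / Σ n`
  (per-period and externally stratified variants are available). By
  construction `Σ E = Σ O`, so relative risks are centred at 1 and the
  crude relative risk `O_ik / E_ik` is the SMR. Cells with `n_ik = 0` are
  excluded from the likelihood and reported as missing.
- `t_k` are the period codes (1, 2, 3 for the three survey rounds), giving
  a linear time trend in log risk.
- `x_ik` stacks quartile indicator columns (quartiles 2–4; quartile 1 is
  the reference) for the three zone-level covariates.

## Zone-level quartile covariates

For each covariate the zone proportion is computed from child records
(education: mother has any education; SES: household in the richer or
richest quintile; maternal anemia: mother anemic at any severity), and
zones are cut at the 25/50/75 percentiles of these proportions. A
direction flag puts the *advantaged* zones in quartile 1: high education,
high SES, and **low** maternal anemia. Ties at a cut point go to the lower
quartile (the rule is `quartile = 1 + #{cuts strictly below the score}`).
Quartiles are recomputed within each survey period by default. Fewer than
four zones is an error; all-equal proportions collapse to quartile 1 with
a warning.

## Priors

- `α, β₁, β_j ~ N(0, 10⁶)` — effectively flat fixed effects.
- `u ~ ICAR(τ_u)` with queen-contiguity binary weights `w_ij`: kernel
  `(r/2)·log τ_u − (τ_u/2) Σ_{i<j} w_ij (u_i − u_j)²`, where the rank `r`
  is summed over connected components as `max(size − 1, 1)`. Zones with no
  neighbors (islands) get an independent `N(0, 1/τ_u)` term, which is why
  a size-1 component contributes 1 to the rank; on island-free graphs `r`
  reduces to the usual `m − (number of components)`.
- `v_i ~ N(0, 1/τ_v)` i.i.d. (the unstructured BYM half).
- `τ_u, τ_v ~ Gamma(0.5, 0.0005)` — a conventional diffuse precision
  prior for disease mapping.

Identifiability: `u` is constrained to sum to zero (per sweep, its mean is
folded into `α`; per connected component in the exact generator).

## MCMC

Adaptive Metropolis-within-Gibbs, multiple chains from independent
`SeedSequence` spawns:

- `u` updated by single-site random walks, vectorized over the classes of
  a greedy graph coloring — zones in one color class share no edge, so
  their full conditionals are mutually independent and can be updated
  simultaneously. Each update uses an O(1) local change of the ICAR
  quadratic form.
- `v` updated all at once (conditionally independent given the rest).
- `α, β₁, β_j` updated by scalar random walks with O(1) delta
  log-likelihoods (`Δll = d·ΣO − Σμ·(e^d − 1)` over the affected cells).
- `τ_u, τ_v` drawn exactly from their conjugate Gamma full conditionals.
- Proposal scales adapt Robbins-Monro-style toward 0.35 acceptance during
  burn-in **only** and are frozen afterwards, preserving detailed balance
  of the retained chain.
- The log posterior is tracked incrementally; every `check_every` sweeps
  it is recomputed from scratch and the maximum discrepancy is recorded in
  the run metadata (`logpost_check_max_abs_diff`, asserted < 1e-8 in the
  tests).

Chain 1 starts at zeros; later chains are over-dispersed by ±`init_spread`
(default 0.5) on the log-risk-scale coefficients and ×10 / ÷10 on the
precisions. A literal "±2 prior standard deviations" dispersion is
numerically absurd under `Var = 10⁶` (it would overflow the Poisson mean),
so the spread is a package choice, documented here, and over-dispersed
relative to any realistic posterior.

Correctness evidence (all in the test suite / acceptance script): bitwise
determinism per seed; the intercept-only posterior matches 1-D quadrature
within Monte-Carlo error; with random effects and covariates disabled the
posterior centres on the maximum-likelihood Poisson regression; conjugate
updates match closed-form moments; 95% credible intervals cover the
generator's true covariate effects at 173/180 over 20 replicates
(seed 1).

## Diagnostics

- Gelman–Rubin R̂ in the classic form
  `sqrt(((n−1)/n · W + B/n) / W)` over ≥ 2 chains.
- Batch-means Monte Carlo error (20 batches); the conventional adequacy
  rule MC error < 5% of the posterior SD is reported as a ratio.
- DIC: `Dbar + pD` with `pD = Dbar − D(θ̄)`, the plug-in deviance
  evaluated at posterior means with `u` recentred. Lower is better; over
  50 synthetic replicates with nonzero covariate effects the covariate
  model beats the covariate-free model (same random effects and trend) in
  50/50 runs (seed 1), mean DIC improvement ≈ 87.
- A quick quasi-Poisson overdispersion ratio on raw counts.

## Risk surfaces

Smoothed relative risk per cell is summarized by the **posterior median**
of `exp(α + u_i + v_i + β₁ t_k + x_ik'β)` (the mean is also emitted; the
median is the headline because the draws are log-scale symmetric, hence
right-skewed after exponentiation), with equal-tailed 95% credible
intervals. Exceedance probability is the posterior mass of RR > 1.
Choropleth classes: RR < 0.85 low, 0.85–1.1 middle, > 1.1 high;
probability bands [0, 0.25], (0.25, 0.5], (0.5, 0.8], (0.8, 1]. Fixed
effects are reported as `RR = exp(coef)` rounded to two decimals, starred
when the 95% CrI excludes 1.

## Synthetic-data generator

`simulate_dataset` builds a rectangular grid of unit-square zones (default
8 × 9 = 72 zones — deliberately close to the 74 Ethiopian zones while
keeping a closed-form queen edge count for testing), draws the spatial
field exactly by spectral decomposition of the component-wise graph
Laplacian (no warm-up chain), the unstructured field i.i.d. normal, forms
Poisson counts under the model above, and dresses them into child-level
records with fixed categorical splits (severity 736:5400:4257 among the
anemic, and analogous pooled splits for education, wealth, maternal age,
residence, sex, birth weight and birth order).

Default effect sizes are typical published zone-level quartile effects
(e.g. education quartile 3 at +0.149, trend +0.02 per period); field
scales default to σ_u = 0.2, σ_v = 0.1; baseline anemia rate 0.55.

Two design points matter for interpretation:

- **Centred linear predictor.** Time and covariate contributions are
  centred inside the generator (`t − t̄`, `x − x̄`), so `baseline_rate` is
  the pooled anemia rate rather than the rate of the rare all-reference
  cell. Centring shifts only the intercept — `β₁` and `β` are unchanged
  as estimands — and the implied uncentred intercept
  `α − β₁ t̄ − x̄'β` is recorded in the truth manifest as
  `alpha_uncentred`. Without centring, an all-positive effect set at a
  0.55 baseline implies Poisson rates above 1 in adverse cells for every
  seed.
- **Feasibility and tail capping.** A deterministic check rejects
  parameter sets whose most adverse covariate cell implies an expected
  rate above 1; random Poisson excursions above the denominator are
  capped at `n` with a warning (counts are of anemic children among `n`
  examined).

Limitations: the generator emulates *structure*, not the sampling design
of a real survey — no survey weights, no within-zone clustering beyond the
zone effects, covariate splits independent across variables, and the
record dressing is marginal (it reproduces proportions, not joint
distributions). Recovery tests therefore pass the generator's own
covariate design to the fitter; re-deriving quartiles from the dressed
records can flip assignments near cut points, which is covariate
misclassification, not a sampler property.

## Descriptive fixture

`table1_fixture()` builds 18,939 child records across 74 zones and three
periods whose categorical margins reproduce a fixed set of published
survey counts exactly (checked cell-by-cell in the tests): 10,393 anemic
children, 16,048 rural (84.74%), 6,137 in the poorest quintile. One
source margin is internally inconsistent by a count of 1 (resolved by
decrementing the largest category) and one column is 104 records short
(treated as missing values, with percentages over non-missing totals).
Zones are assigned round-robin and each variable is shuffled
independently, so the fixture is for tabulation and pipeline testing, not
for estimating real covariate-outcome associations.

## Numerical choices

- Poisson log-likelihood via `gammaln`; empty cells skipped.
- Quartile cuts by `numpy.percentile` on zone proportions; strict
  inequality at cuts implements the tie-to-lower rule.
- ICAR draws: eigendecomposition of each component's Laplacian, zero
  eigenvalues dropped, per-component sum-to-zero.
- All randomness flows from a single integer seed through
  `numpy.random.SeedSequence`; derived seeds are reduced below 2³¹.
- Desk-scale defaults (2 chains, 5,000 burn-in, 20,000 iterations, thin
  10) are the package's own: they give clean diagnostics on 72-zone
  synthetic data in well under a minute, whereas production-scale runs of
  areal models in the literature use orders of magnitude more iterations.
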