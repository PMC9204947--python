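# Methods

## Model

`hssurv` fits a Bayesian accelerated failure time (AFT) model to grouped
survival data in which the covariate sets may differ between groups.  Let
*i* index groups (e.g. disease cohorts), *j* subjects within group *i*, and
let S_i be the set of covariates measured on group *i*.  Log survival time
is normal:

    log y_ij ~ Normal( β_0i + Σ_{ℓ∈S_i} β_iℓ x_ijℓ , σ² )

Each coefficient carries a hierarchical spike-and-slab prior:

    β_iℓ | γ_iℓ  ~  (1 − γ_iℓ) · Normal(0, z²)  +  γ_iℓ · Normal(β̃_ℓ, λ²_ℓ)
    γ_iℓ | π_ℓ   ~  Bernoulli(π_ℓ),      π_ℓ ~ Beta(1, 1)
    β̃_ℓ ~ Normal(0, τ²),                λ²_ℓ ~ Inverse-Gamma(α₁, α₂)

The spike variance z² is a near-point mass (default 1/10000), so γ_iℓ has an
include/exclude reading and its posterior mean γ̂_iℓ is the posterior
inclusion probability of covariate ℓ for group *i*.  The slab location and
scale are *inferred from the groups whose indicator is on*, which is how the
model borrows strength: concordant effects across groups sharpen β̃_ℓ and
raise the evidence for inclusion elsewhere.  The per-covariate π_ℓ plays the
same role one level up — it pools inclusion evidence across groups.

Intercepts are exchangeable, β_0i ~ Normal(β̃₀, λ²₀) with β̃₀ ~ Normal(0, 10²)
and λ²₀ ~ IG(1, 1); the error variance is shared across groups with
σ² ~ IG(0.01, 0.01).  Defaults for the slab hierarchy are τ² = 1 and
(α₁, α₂) = (5, 1); all hyperparameters are exposed on `Hyperparameters` and
as flat estimator parameters.

## Posterior computation

All full conditionals are standard conjugate forms, derived by conjugacy and
each exposed as its own function so it can be verified against an
independent numerical oracle (the test suite checks the coefficient, error
variance and slab updates against brute-force grid posteriors by KS test,
and the sweep as a whole by a Geweke-style successive-conditional
simulation).  One Gibbs sweep updates, in a fixed order:

1. **Censored outcomes.**  For right-censored subjects the latent log event
   time is drawn from Normal(μ_ij, σ²) truncated below at the log censoring
   time.  Truncated-normal draws use the inverse survival function in the
   well-conditioned regime and switch to Robert's exponential-proposal
   rejection sampler when the bound sits more than 5 sd above the mean,
   where the inverse CDF underflows.
2. **Coefficients and indicators**, per group, per covariate: β_iℓ from its
   conjugate normal conditional (spike or slab prior according to the
   current γ_iℓ, partial residuals maintained incrementally), then γ_iℓ from
   a Bernoulli whose odds combine π_ℓ with the slab/spike density ratio at
   the freshly drawn β_iℓ.  The ratio is computed in log space — spike
   densities reach e^(−1000) for coefficients far from zero.
3. **Inclusion probabilities**: π_ℓ ~ Beta(1 + s_ℓ, 1 + n_ℓ − s_ℓ) with s_ℓ
   the number of carrying groups whose indicator is on.
4. **Slab parameters**: β̃_ℓ by a conjugate normal update over the
   coefficients currently in the slab, then λ²_ℓ by the conjugate
   inverse-gamma update; with no group in the slab both are refreshed from
   their priors.
5. **Intercepts** and their hyperparameters (normal / normal /
   inverse-gamma updates).
6. **σ²** from IG(a + N/2, b + RSS/2) with the residual sum of squares
   pooled over groups.

Initialization is deterministic given the seed: coefficients start at 0,
indicators all-on (γ = 1 wherever the covariate is available), π = 0.5, σ²
at the sample variance of observed log times, imputed outcomes just above
their bounds.  The all-inclusive start is deliberate: dropping a covariate
into the spike is an easy move for the sampler, while escaping the spike is
the slow direction (see below), so starting all-in shortens the burn-in
transient.  The chain is bit-identical under a fixed seed.

Conditioning γ on the current β (rather than marginalizing β out) matches
the mixture-on-β prior statement exactly but mixes slowly when a
truly-active covariate is trapped in the spike: the spike posterior keeps β
near zero, which in turn keeps the indicator off.  Short chains on
small-group data therefore occasionally misclassify slots whose true
coefficients are small; run lengths in the 10³–10⁵ range (see the
simulation scale notes below) are the practical remedy, and the package
reports inclusion probabilities rather than hard selections so such
uncertainty stays visible.

## Model variants

Seven configurations of the same engine form the comparison suite:
`hierarchical` (the full model), `null` (group intercepts only), `full`
(every indicator pinned at 1 — hierarchical shrinkage without selection),
`fixed_0.5` (π_ℓ ≡ 0.5), `shared` (a single Beta-updated π pooled over all
slots), `joint` (all groups appended row-wise and fit as one group), and
`separate` (each group fit independently).  In the joint model a covariate
unavailable for some source groups is zero-filled for their subjects: the
rectangular design requires *some* value and zero is the covariate mean on
the standardized scale; this choice is a modelling convention, and the
joint model's inclusion estimate for a covariate is broadcast back to every
original group that carries it.  An external horseshoe AFT baseline is not
shipped; the variant registry rejects unknown names so adapters can be
added deliberately.

## Predictive validation

Out-of-sample fit is the log posterior predictive likelihood: per retained
draw, the product over uncensored test subjects of the log-normal density at
the observed time (density of *y*, including the 1/y Jacobian) times, over
censored subjects, the probability of surviving past the censoring time;
the T per-draw values are averaged on the likelihood scale via
log-mean-exp.  K-fold cross validation (default k = 5) stratifies folds by
group with a seeded shuffle and proportional allocation, because every
training fold must contain every group for its intercept to be estimable;
censored subjects are not balanced separately.  Fold scores are averaged
arithmetically.  Standardization is computed once on the full dataset by
default rather than per training fold (`standardize` on the estimator);
fold-wise restandardization was considered and left as a caller decision
since the transform object is returned.

## Component predictors

When predictors come from a low-rank factorization of multi-source,
multi-cohort data, each module (a features × samples matrix spanning a
declared subset of sources and cohorts) is decomposed by SVD and the
component scores d_r·v_r become candidate predictors, available exactly for
the groups the module spans.  Selection keeps each module's first component
unconditionally plus any later component whose eigenvalue d_r² exceeds 1%
(configurable) of the total sum of squares of the concatenated data.  The
threshold is interpreted against the *original* data's total variability,
supplied as a scalar so modules can be processed without the raw data.
Since singular vectors are defined only up to sign, each (u_r, v_r) pair is
flipped so the largest-magnitude entry of v_r is positive; effect signs in
downstream summaries are interpretable only up to this convention.  Age (or
any clinical covariate) is appended to every group's covariate set and all
predictors are standardized to mean 0, sd 1 (sample sd, divisor n − 1,
pooled over the subjects possessing each covariate).

## Subject filtering

Three cleaning rules, applied in order and reported by count: subjects
missing both a survival and a censoring time are dropped; subjects with
nonpositive observed times are dropped (the log transform must exist);
subjects missing a value for a covariate their group measures are dropped —
the model has structural (whole-group) missingness but no within-group
missingness mechanism.  A covariate column that is entirely missing within
a group is treated as structurally absent from that group's S_i, not as an
error.

## Synthetic data and the simulation study

The generator emulates a multi-cohort application: equal-sized groups; a
packaged availability pattern of 29 groups × 66 covariates of which 8 span
all groups, 30 span subsets of 2–15 groups and 28 are group-specific (the
pattern is deterministic package data; scaled shapes keep the same mix);
standard-normal covariates; log-normal survival; independent log-normal
censoring with the location calibrated by bisection on the *analytic*
marginal censoring probability so that ≈50% of subjects are censored (both
log times are normal once covariates are integrated out, so no pilot sample
is needed and the calibration is deterministic).  True coefficients are
drawn from the model's own slab hierarchy — β̃_ℓ ~ N(0,1),
λ²_ℓ ~ IG(5,1), β_iℓ ~ N(β̃_ℓ, λ²_ℓ) — so that block-shared inclusion
regimes genuinely reward borrowing; intercepts are N(0,1) and σ² = 1.  A
consequence worth noting: IG(5,1) slab scales put many true coefficients
below 0.5, so a fraction of truly-included slots is intrinsically hard to
classify at moderate n, and selection-accuracy comparisons between model
variants need either many groups or many replications to stabilize.

Six inclusion regimes define the study conditions: block-shared
Bernoulli(0.5) and Bernoulli(0.1) (a covariate is in or out for *all* its
groups at once), independent Bernoulli(0.5) and Bernoulli(0.1) per
(group, covariate) slot, all-in, and none-in.  Selection accuracy is the
mean squared deviation (SSD) between truth indicators and posterior
inclusion probabilities over all M coefficient slots; predictive accuracy
is the log posterior predictive likelihood on a test set generated with the
same true parameters.  Both are averaged over replications, and pairwise
paired t-tests at the 0.01 level mark the models statistically tied with
the best (identical metric vectors are tied; a constant nonzero difference
counts as significant).  Two identities serve as oracles: the full model's
SSD equals the fraction of truth slots that are zero, the null model's the
fraction that are one; under the degenerate all-in/none-in regimes these
are exactly 0 and 1.

All study randomness derives from a master seed through per-(replication,
condition, variant) seed sequences, so studies are reproducible
bit-for-bit and any replication can be regenerated in isolation.

### Problem sizes used by the shipped checks

The packaged test suite exercises the qualitative variant comparisons at a
reduced scale chosen so the whole suite runs in minutes on one CPU: 10
groups × 16 covariates (availability mix as above), n = 50 per group, 2000
iterations with 1000 burn-in and thinning 10, and 5 replications.  At this
scale the suite asserts orderings only (e.g. the hierarchical model's SSD
beats the separate model's under block-shared truth; the joint model's
predictive likelihood is markedly worst when inclusion is truly
group-specific), never the magnitudes, which depend on group count and
sample sizes.  The analytic SSD figures (full/null models under the
degenerate and independent regimes) are computed at the full 29 × 66
pattern with 100 replications, where no MCMC is involved.

## What the synthetic data does not emulate

Real multi-omics component scores are only approximately orthogonal, have
heavy-tailed score distributions, and their availability pattern is tied to
platform coverage rather than drawn from a sharing profile; real censoring
is not independent log-normal; cohort sample sizes are unequal; and real
effects are not drawn from the model's own slab.  Passing tests therefore
demonstrate correctness of the algorithms and calibration *under the
model*, not robustness to model misspecification.

## Numerical choices

- Mixture weights, survival probabilities and predictive likelihoods are
  computed in log space throughout (log-sum-exp, `log_ndtr`).
- The truncated-normal sampler switches regimes at bound − mean = 5 sd.
- Credible intervals are central empirical quantiles of the retained draws.
- Chains raise `FloatingPointError` with the iteration index if σ²
  degenerates (non-finite or nonpositive).
- Datasets round-trip exactly through CSV (`%.17g` on write, round-trip
  float parsing on read).
- A zero-variance predictor is an error, not a silent constant column.

## Known limitations

- Shared σ² across groups is a modelling assumption, not relaxed here.
- The γ|β update's slow mixing under strong signal-to-noise (above).
- The joint model's zero-fill makes its coefficients for partially
  available covariates attenuated by construction.
- No collapsed/marginalized samplers, adaptive MCMC or convergence
  diagnostics beyond multi-seed comparison and draw export.
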