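# hssurv

Hierarchical spike-and-slab Bayesian survival modelling for grouped data
with partially overlapping covariate sets.

## The problem

Cohort studies that span many patient groups — for example, many cancer
types profiled on several omics platforms — face two coupled difficulties
when modelling a censored outcome such as overall survival: not every
covariate is measured on every group, and an effect that is weak in any one
group may be strong evidence when it recurs across groups.  `hssurv` fits a
log-normal accelerated failure time (AFT) model per group while *borrowing
strength* across groups through a hierarchical spike-and-slab prior, giving
every (group, covariate) pair a posterior probability of inclusion.

For subject *j* in group *i* with covariates x over the group's availability
set S_i:

    log y_ij ~ Normal( β_0i + Σ_{ℓ∈S_i} β_iℓ x_ijℓ , σ² )
    β_iℓ | γ_iℓ ~ (1 − γ_iℓ) N(0, z²) + γ_iℓ N(β̃_ℓ, λ²_ℓ)      (spike / slab)
    γ_iℓ ~ Bernoulli(π_ℓ),  π_ℓ ~ Beta(1, 1)
    β̃_ℓ ~ N(0, τ²),  λ²_ℓ ~ IG(α₁, α₂)

The slab location/scale (β̃_ℓ, λ²_ℓ) are learned from the groups whose
indicator is on, and π_ℓ pools inclusion evidence across groups.
Right-censored outcomes are imputed inside the Gibbs sampler from their
truncated-normal full conditionals.  See `docs/methods.md` for the full
model, the sampler, and all design choices.

The package ships:

- a scikit-learn style estimator (`SpikeSlabAFT`) plus the functional layer
  beneath it (`run_chain`, `fit_variant`, ...);
- seven comparison variants of the model (hierarchical, null, full,
  fixed-0.5, shared-π, joint, separate) and cross-validated log posterior
  predictive likelihood for comparing them;
- SVD-based component-score extraction from low-rank modules of a
  multi-source factorization, with the 1%-of-total-variability selection
  rule;
- a six-condition simulation study measuring selection accuracy (mean SSD
  between truth indicators and posterior inclusion probabilities) and
  predictive accuracy, with paired-t significance marks;
- a CLI (`hssurv fit | cv | suite | simulate | extract-components`).

## Worked example

```python
import numpy as np, pandas as pd
from hssurv import SpikeSlabAFT

rng = np.random.default_rng(0)
n = 240
groups = np.repeat(["a", "b", "c"], n // 3)
X = pd.DataFrame({"x1": rng.standard_normal(n), "x2": rng.standard_normal(n)})
logt = 0.5 + 2.0 * X["x1"].to_numpy() + rng.standard_normal(n)   # x1 drives survival
y = (np.exp(logt), np.ones(n, dtype=bool))                       # (time, event)

est = SpikeSlabAFT(iterations=600, burn_in=300, random_state=7)
est.fit(X, y, groups=groups)
print(est.inclusion_probs_)
print("sigma2:", round(est.sigma2_, 3))
print("log predictive likelihood:", round(est.score(X, y, groups=groups), 1))
```

prints

```
    x1        x2
a  1.0  0.023333
b  1.0  0.033333
c  1.0  0.093333
sigma2: 0.926
log predictive likelihood: -436.3
```

The posterior inclusion probability of the active covariate `x1` is 1.0 in
every group — each group's data and the shared slab agree it belongs in the
model — while the noise covariate `x2` stays near 0.  `sigma2` recovers the
unit error variance, and `score` is the log of the draw-averaged test
likelihood (higher is better; here scored in-sample for brevity).  Columns
a subject's group does not measure are passed as `NaN` and simply drop out
of that group's model.

The same model is available from the shell:

```sh
hssurv fit --data cohort.csv --variant hierarchical --iterations 100000 \
           --burn-in 50000 --thin 10 --seed 1 --out results/
hssurv simulate --replications 100 --seed 1 --out study/
```

Each output directory contains the draws, summary tables and a
`manifest.json` (inputs, settings, seed, versions) sufficient to re-run the
command exactly.

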