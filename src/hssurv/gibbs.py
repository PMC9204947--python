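"""Gibbs sampler for the hierarchical spike-and-slab log-normal AFT model.

The model: for subject j in group i with covariates ``X_ij`` over the group's
availability set S_i,

.. math::

    \\log y_{ij} \\sim N\\Big(\\beta_{0i} + \\sum_{\\ell \\in S_i}
        \\beta_{i\\ell} X_{ij\\ell}, \\; \\sigma^2\\Big)

with a hierarchical spike-and-slab prior on each coefficient:
:math:`\\beta_{i\\ell}` comes from a near-point-mass spike
:math:`N(0, z^2)` when its binary indicator :math:`\\gamma_{i\\ell}` is 0 and
from a slab :math:`N(\\tilde\\beta_\\ell, \\lambda^2_\\ell)` when it is 1.
The slab mean and variance are inferred from the groups whose indicator is on
(borrowing strength across groups), the per-covariate inclusion probability
:math:`\\pi_\\ell` gets a Beta(1,1) prior, intercepts are exchangeable around
a hypermean with an inverse-gamma hypervariance, and a single error variance
:math:`\\sigma^2` is shared across groups.  Right-censored log outcomes are
imputed each sweep from their truncated-normal full conditional (truncated
below at the log censoring time).

All full conditionals are standard conjugate forms; each is exposed as a
small function so it can be checked against an independent numerical oracle.
A sweep updates, in this fixed order: imputed outcomes → per-group
coefficients and indicators → inclusion probabilities → slab parameters →
intercepts and their hyperparameters → error variance.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import special

from .data import ChainConfig, GroupedSurvivalData, Hyperparameters

__all__ = [
    "ParameterState",
    "PosteriorSamples",
    "sample_truncated_normal",
    "impute_censored",
    "conjugate_normal_posterior",
    "update_coefficient",
    "indicator_probability",
    "update_indicator",
    "update_inclusion_prob",
    "update_slab",
    "update_intercepts",
    "update_sigma2",
    "gibbs_sweep",
    "run_chain",
]

SELECTION_MODES = ("spike_slab", "all_in", "none")
PI_MODES = ("per_covariate", "fixed", "shared")

# switch to the tail-robust rejection sampler this many sd above the mean
_TAIL_CUTOFF = 5.0


# ---------------------------------------------------------------------------
# truncated-normal sampling


def sample_truncated_normal(rng, mean, sd, lower):
    """Draw from N(mean, sd²) truncated below at ``lower`` (vectorized).

    Uses the inverse survival function in the well-conditioned regime and
    Robert's exponential-proposal rejection sampler when the bound sits more
    than 5 sd above the mean, where the naive inverse CDF underflows.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.broadcast_to(np.asarray(sd, dtype=float), mean.shape)
    lower = np.broadcast_to(np.asarray(lower, dtype=float), mean.shape)
    if not np.all(np.isfinite(lower)):
        raise ValueError("non-finite truncation bound")
    a = (lower - mean) / sd
    x = np.empty_like(a)

    easy = a < _TAIL_CUTOFF
    if easy.any():
        # P(X > x) = ndtr(-x); draw the survival value uniformly on (0, ndtr(-a)].
        q = special.ndtr(-a[easy])
        u = rng.uniform(size=q.shape)
        x[easy] = -special.ndtri(np.clip(u * q, 1e-300, 1.0))
    hard = ~easy
    if hard.any():
        ah = a[hard]
        lam = 0.5 * (ah + np.sqrt(ah**2 + 4.0))
        out = np.empty_like(ah)
        todo = np.ones(ah.shape, dtype=bool)
        while todo.any():
            n = int(todo.sum())
            prop = ah[todo] + rng.exponential(size=n) / lam[todo]
            accept = rng.uniform(size=n) <= np.exp(-0.5 * (prop - lam[todo]) ** 2)
            idx = np.flatnonzero(todo)[accept]
            out[idx] = prop[accept]
            todo[idx] = False
        x[hard] = out
    res = mean + sd * x
    # guard against u*q rounding exactly to the bound from below
    return np.maximum(res, lower)


# ---------------------------------------------------------------------------
# parameter state


@dataclasses.dataclass
class ParameterState:
    """One complete draw of all model unknowns.

    Coefficient-shaped arrays are (I, L) on the full covariate grid; entries
    outside a group's availability set are identically zero and never read.
    ``w`` holds per-group log outcomes: observed log event times where the
    event occurred, current imputations (each ≥ its log censoring time)
    where censored.
    """

    beta0: np.ndarray          # (I,)
    beta: np.ndarray           # (I, L)
    gamma: np.ndarray          # (I, L) in {0, 1}
    pi: np.ndarray             # (L,)
    slab_mean: np.ndarray      # (L,)
    slab_var: np.ndarray       # (L,)
    beta0_mean: float
    beta0_var: float
    sigma2: float
    w: list                    # per group (n_i,) log outcomes

    def validate(self, data: GroupedSurvivalData | None = None) -> None:
        if not (self.sigma2 > 0 and self.beta0_var > 0 and np.all(self.slab_var > 0)):
            raise ValueError("variances must be strictly positive")
        if not np.isin(self.gamma, (0, 1)).all():
            raise ValueError("indicators must be binary")
        if np.any(self.pi < 0) or np.any(self.pi > 1):
            raise ValueError("inclusion probabilities must lie in [0, 1]")
        if data is not None:
            for i in range(data.n_groups):
                cens = ~data.events[i]
                if np.any(self.w[i][cens] < np.log(data.times[i][cens]) - 1e-12):
                    raise ValueError("imputed outcome below its censoring bound")


# ---------------------------------------------------------------------------
# full-conditional updates


def impute_censored(state: ParameterState, data: GroupedSurvivalData, rng) -> None:
    """Redraw censored log outcomes from N(mu_ij, sigma²) truncated below at
    the log censoring time; observed event times are left untouched."""
    sd = math.sqrt(state.sigma2)
    for i in range(data.n_groups):
        cens = ~data.events[i]
        if not cens.any():
            continue
        mu = state.beta0[i] + data.X[i][cens] @ state.beta[i]
        state.w[i][cens] = sample_truncated_normal(rng, mu, sd, np.log(data.times[i][cens]))


def conjugate_normal_posterior(prior_mean, prior_var, xtx, xtr, sigma2):
    """Posterior (mean, var) of a scalar normal coefficient.

    Prior N(prior_mean, prior_var); likelihood contribution from residuals r
    on covariate x with noise variance sigma²: sufficient statistics
    ``xtx = x'x`` and ``xtr = x'r``.  With no information (x ≡ 0) the
    posterior is the prior.
    """
    precision = xtx / sigma2 + 1.0 / prior_var
    var = 1.0 / precision
    mean = var * (xtr / sigma2 + prior_mean / prior_var)
    return mean, var


def update_coefficient(i, l, state, data, rng, hyper):
    """Draw beta_il from its conjugate normal full conditional.

    The prior is the spike N(0, z²) when gamma_il = 0 and the slab
    N(slab_mean_l, slab_var_l) when gamma_il = 1; the likelihood uses the
    group-i partial residuals excluding covariate l.
    """
    x = data.X[i][:, l]
    partial = state.w[i] - state.beta0[i] - data.X[i] @ state.beta[i] + x * state.beta[i, l]
    if state.gamma[i, l] == 1:
        m0, v0 = state.slab_mean[l], state.slab_var[l]
    else:
        m0, v0 = 0.0, hyper.spike_var
    mean, var = conjugate_normal_posterior(m0, v0, x @ x, x @ partial, state.sigma2)
    return mean + math.sqrt(var) * rng.standard_normal()


def indicator_probability(beta, slab_mean, slab_var, spike_var, pi):
    """P(gamma = 1 | beta, ...) for the two-component normal mixture,
    evaluated stably in log space (the spike density reaches e^{-1000})."""
    if pi >= 1.0:
        return 1.0
    if pi <= 0.0:
        return 0.0
    log_slab = -0.5 * (math.log(2 * math.pi * slab_var) + (beta - slab_mean) ** 2 / slab_var)
    log_spike = -0.5 * (math.log(2 * math.pi * spike_var) + beta**2 / spike_var)
    logit = math.log(pi) - math.log1p(-pi) + log_slab - log_spike
    return float(special.expit(logit))


def update_indicator(i, l, state, rng, hyper) -> int:
    """Bernoulli draw of gamma_il given the current beta_il."""
    p = indicator_probability(
        state.beta[i, l], state.slab_mean[l], state.slab_var[l], hyper.spike_var, state.pi[l]
    )
    return int(rng.uniform() < p)


def update_inclusion_prob(s, n, rng, a: float = 1.0, b: float = 1.0) -> float:
    """Beta(a + s, b + n − s) draw for an inclusion probability, where s of
    the n groups carrying the covariate currently have gamma = 1."""
    return float(rng.beta(a + s, b + n - s))


def update_slab(betas_in_slab, slab_var, rng, hyper):
    """Draw (slab mean, slab variance) for one covariate.

    ``betas_in_slab`` are the current coefficients of the groups whose
    indicator is 1.  The mean gets a conjugate normal update against its
    N(0, tau²) prior (given the current slab variance), then the variance an
    inverse-gamma update IG(a1 + |A|/2, a2 + sum (beta − mean)²/2) given the
    new mean.  With no group in the slab both are drawn from their priors.
    """
    betas = np.asarray(betas_in_slab, dtype=float)
    nA = betas.size
    precision = 1.0 / hyper.slab_mean_var + nA / slab_var
    var = 1.0 / precision
    mean = var * (betas.sum() / slab_var)
    new_mean = mean + math.sqrt(var) * rng.standard_normal()
    shape = hyper.slab_var_shape + 0.5 * nA
    rate = hyper.slab_var_rate + 0.5 * float(((betas - new_mean) ** 2).sum())
    new_var = rate / rng.gamma(shape)
    return new_mean, new_var


def update_intercepts(state, data, rng, hyper) -> None:
    """Gibbs block for the group intercepts and their hyperparameters.

    Each beta_0i has a conjugate normal update against prior
    N(beta0_mean, beta0_var) with the group's covariate-adjusted residuals;
    the hypermean is then updated against its normal prior over the I
    intercepts, and the hypervariance from its inverse-gamma conditional.
    """
    I = data.n_groups
    for i in range(I):
        resid = state.w[i] - data.X[i] @ state.beta[i]
        n_i = resid.shape[0]
        mean, var = conjugate_normal_posterior(
            state.beta0_mean, state.beta0_var, n_i, resid.sum(), state.sigma2
        )
        state.beta0[i] = mean + math.sqrt(var) * rng.standard_normal()
    precision = 1.0 / hyper.intercept_mean_var + I / state.beta0_var
    var = 1.0 / precision
    mean = var * (
        state.beta0.sum() / state.beta0_var
        + hyper.intercept_mean_loc / hyper.intercept_mean_var
    )
    state.beta0_mean = mean + math.sqrt(var) * rng.standard_normal()
    shape = hyper.intercept_var_shape + 0.5 * I
    rate = hyper.intercept_var_rate + 0.5 * float(((state.beta0 - state.beta0_mean) ** 2).sum())
    state.beta0_var = rate / rng.gamma(shape)


def update_sigma2(state, data, rng, hyper) -> float:
    """IG(a + N/2, b + RSS/2) draw for the shared error variance, with the
    residual sum of squares pooled over all groups."""
    rss = 0.0
    n_total = 0
    for i in range(data.n_groups):
        resid = state.w[i] - state.beta0[i] - data.X[i] @ state.beta[i]
        rss += float(resid @ resid)
        n_total += resid.shape[0]
    shape = hyper.error_var_shape + 0.5 * n_total
    rate = hyper.error_var_rate + 0.5 * rss
    return rate / rng.gamma(shape)


# ---------------------------------------------------------------------------
# posterior container


@dataclasses.dataclass
class PosteriorSamples:
    """Thinned post burn-in draws plus summaries.

    Array draws are stacked along the first axis (length T).  Coefficient
    and indicator draws live on the full (I, L) grid; slots outside the
    availability mask are structurally zero and are masked out of the
    summaries.
    """

    group_ids: list
    covariate_names: list
    availability: np.ndarray
    selection: str
    pi_mode: str
    beta0: np.ndarray        # (T, I)
    beta: np.ndarray         # (T, I, L)
    gamma: np.ndarray        # (T, I, L)
    pi: np.ndarray           # (T, L)
    slab_mean: np.ndarray    # (T, L)
    slab_var: np.ndarray     # (T, L)
    beta0_mean: np.ndarray   # (T,)
    beta0_var: np.ndarray    # (T,)
    sigma2: np.ndarray       # (T,)

    @property
    def n_draws(self) -> int:
        return self.sigma2.shape[0]

    def inclusion_probs(self) -> np.ndarray:
        """Posterior inclusion probabilities γ̂_il: the average of the
        retained inclusion-indicator draws.  NaN outside availability.
        Exactly 1 everywhere for the always-in model and exactly 0 for the
        intercept-only model, with no sampling noise."""
        probs = self.gamma.mean(axis=0)
        return np.where(self.availability, probs, np.nan)

    def coefficient_means(self) -> np.ndarray:
        return np.where(self.availability, self.beta.mean(axis=0), np.nan)

    def credible_intervals(self, level: float = 0.95):
        """Central credible intervals for each coefficient slot; returns
        (lower, upper) arrays of shape (I, L), NaN outside availability."""
        alpha = 0.5 * (1.0 - level)
        lower = np.quantile(self.beta, alpha, axis=0)
        upper = np.quantile(self.beta, 1.0 - alpha, axis=0)
        return (
            np.where(self.availability, lower, np.nan),
            np.where(self.availability, upper, np.nan),
        )

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        """Tidy summary table: one row per (covariate, group) slot with the
        posterior mean effect, central credible interval and inclusion
        probability, followed by intercept and error-variance rows.  The
        intercept-only model reports intercepts and sigma² only."""
        rows = []
        if self.selection != "none":
            pip = self.inclusion_probs()
            mean = self.coefficient_means()
            lo, hi = self.credible_intervals(level)
            for l, name in enumerate(self.covariate_names):
                for i, gid in enumerate(self.group_ids):
                    if self.availability[i, l]:
                        rows.append(
                            {
                                "parameter": "coefficient",
                                "component": name,
                                "group": gid,
                                "mean_effect": mean[i, l],
                                "ci_lower": lo[i, l],
                                "ci_upper": hi[i, l],
                                "inclusion_probability": pip[i, l],
                            }
                        )
        alpha = 0.5 * (1.0 - level)
        for i, gid in enumerate(self.group_ids):
            draws = self.beta0[:, i]
            rows.append(
                {
                    "parameter": "intercept",
                    "component": "(intercept)",
                    "group": gid,
                    "mean_effect": draws.mean(),
                    "ci_lower": np.quantile(draws, alpha),
                    "ci_upper": np.quantile(draws, 1 - alpha),
                    "inclusion_probability": np.nan,
                }
            )
        rows.append(
            {
                "parameter": "error_variance",
                "component": "sigma2",
                "group": "(shared)",
                "mean_effect": self.sigma2.mean(),
                "ci_lower": np.quantile(self.sigma2, alpha),
                "ci_upper": np.quantile(self.sigma2, 1 - alpha),
                "inclusion_probability": np.nan,
            }
        )
        return pd.DataFrame(rows)

    def draws_frame(self) -> pd.DataFrame:
        """All scalar draws as one wide table (one row per retained draw)."""
        cols = {"sigma2": self.sigma2, "beta0_mean": self.beta0_mean, "beta0_var": self.beta0_var}
        for i, gid in enumerate(self.group_ids):
            cols[f"beta0[{gid}]"] = self.beta0[:, i]
        for l, name in enumerate(self.covariate_names):
            if self.selection == "none":
                break
            for i, gid in enumerate(self.group_ids):
                if self.availability[i, l]:
                    cols[f"beta[{gid},{name}]"] = self.beta[:, i, l]
                    cols[f"gamma[{gid},{name}]"] = self.gamma[:, i, l]
            cols[f"pi[{name}]"] = self.pi[:, l]
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# the chain


def _initial_state(data: GroupedSurvivalData, hyper, selection, pi_mode, fixed_pi, rng):
    I, L = data.n_groups, data.n_covariates
    logs = np.concatenate(
        [np.log(data.times[i][data.events[i]]) for i in range(I)]
        or [np.array([0.0])]
    )
    sigma2 = float(np.var(logs, ddof=1)) if logs.size > 1 else 1.0
    sigma2 = sigma2 if sigma2 > 0 else 1.0
    center = float(logs.mean()) if logs.size else 0.0
    if selection == "all_in":
        gamma = data.availability.astype(np.int8)
        pi = np.ones(L)
    elif selection == "none":
        gamma = np.zeros((I, L), dtype=np.int8)
        pi = np.zeros(L)
    else:
        # all-inclusive start: leaving the slab is easy for the sampler,
        # entering it from the spike is the slow direction
        gamma = data.availability.astype(np.int8)
        pi = np.full(L, fixed_pi if pi_mode == "fixed" else 0.5)
    w = []
    for i in range(I):
        wi = np.log(data.times[i]).copy()
        wi[~data.events[i]] += 0.01  # start imputations just above the bound
        w.append(wi)
    prior_slab_var = hyper.slab_var_rate / max(hyper.slab_var_shape - 1.0, 0.5)
    return ParameterState(
        beta0=np.full(I, center),
        beta=np.zeros((I, L)),
        gamma=gamma,
        pi=pi,
        slab_mean=np.zeros(L),
        slab_var=np.full(L, prior_slab_var),
        beta0_mean=center,
        beta0_var=1.0,
        sigma2=sigma2,
        w=w,
    )


def gibbs_sweep(
    state: ParameterState,
    data: GroupedSurvivalData,
    rng,
    hyper: Hyperparameters,
    selection: str = "spike_slab",
    pi_mode: str = "per_covariate",
    fixed_pi: float = 0.5,
    _cache: dict | None = None,
) -> None:
    """One full pass over all blocks, updating ``state`` in place.

    Fixed order: censored-outcome imputation → per-group coefficients and
    indicators → inclusion probabilities → slab parameters → intercepts and
    hyperparameters → error variance.  ``_cache`` lets a long chain reuse
    the per-dataset precomputations (availability indices, x'x columns).
    """
    I, L = data.n_groups, data.n_covariates
    if _cache is None:
        _cache = _sweep_cache(data)
    avail_idx, xtx, carriers = _cache["avail_idx"], _cache["xtx"], _cache["carriers"]
    update_covariates = selection != "none" and L > 0

    impute_censored(state, data, rng)

    if update_covariates:
        for i in range(I):
            # residual excluding no covariate; maintained incrementally
            resid = state.w[i] - state.beta0[i] - data.X[i] @ state.beta[i]
            for l in avail_idx[i]:
                x = data.X[i][:, l]
                resid += x * state.beta[i, l]
                if state.gamma[i, l] == 1:
                    m0, v0 = state.slab_mean[l], state.slab_var[l]
                else:
                    m0, v0 = 0.0, hyper.spike_var
                mean, var = conjugate_normal_posterior(m0, v0, xtx[i][l], x @ resid, state.sigma2)
                new = mean + math.sqrt(var) * rng.standard_normal()
                state.beta[i, l] = new
                resid -= x * new
                if selection == "spike_slab":
                    state.gamma[i, l] = update_indicator(i, l, state, rng, hyper)

        if selection == "spike_slab":
            if pi_mode == "per_covariate":
                for l in range(L):
                    s = int(state.gamma[carriers[l], l].sum())
                    state.pi[l] = update_inclusion_prob(
                        s, carriers[l].size, rng, hyper.inclusion_a, hyper.inclusion_b
                    )
            elif pi_mode == "shared":
                s = int(state.gamma[data.availability].sum())
                n = int(data.availability.sum())
                state.pi[:] = update_inclusion_prob(
                    s, n, rng, hyper.inclusion_a, hyper.inclusion_b
                )
            # "fixed": pi stays at fixed_pi

        for l in range(L):
            in_slab = carriers[l][state.gamma[carriers[l], l] == 1]
            state.slab_mean[l], state.slab_var[l] = update_slab(
                state.beta[in_slab, l], state.slab_var[l], rng, hyper
            )

    update_intercepts(state, data, rng, hyper)
    state.sigma2 = update_sigma2(state, data, rng, hyper)


def _sweep_cache(data: GroupedSurvivalData) -> dict:
    return {
        "avail_idx": [np.flatnonzero(data.availability[i]) for i in range(data.n_groups)],
        "xtx": [np.einsum("ij,ij->j", data.X[i], data.X[i]) for i in range(data.n_groups)],
        "carriers": [np.flatnonzero(data.availability[:, l]) for l in range(data.n_covariates)],
    }


def run_chain(
    data: GroupedSurvivalData,
    hyper: Hyperparameters | None = None,
    config: ChainConfig | None = None,
    *,
    selection: str = "spike_slab",
    pi_mode: str = "per_covariate",
    fixed_pi: float = 0.5,
    rng: np.random.Generator | None = None,
) -> PosteriorSamples:
    """Run the Gibbs sampler and return thinned post burn-in draws.

    Parameters
    ----------
    selection : {"spike_slab", "all_in", "none"}
        "spike_slab" is the full machinery; "all_in" pins every indicator at
        1 (no spike, pure hierarchical shrinkage); "none" drops all
        covariates (intercept-only).
    pi_mode : {"per_covariate", "fixed", "shared"}
        How inclusion probabilities are treated under "spike_slab": one
        Beta-updated probability per covariate, a constant ``fixed_pi`` for
        all, or a single Beta-updated probability pooled over every
        (group, covariate) slot.
    rng : numpy Generator, optional
        Overrides ``config.seed``; the chain is bit-identical given the same
        generator state.
    """
    if selection not in SELECTION_MODES:
        raise ValueError(f"unknown selection mode {selection!r}; expected one of {SELECTION_MODES}")
    if pi_mode not in PI_MODES:
        raise ValueError(f"unknown pi mode {pi_mode!r}; expected one of {PI_MODES}")
    hyper = hyper or Hyperparameters()
    config = config or ChainConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    data.validate()

    I, L = data.n_groups, data.n_covariates
    cache = _sweep_cache(data)
    state = _initial_state(data, hyper, selection, pi_mode, fixed_pi, rng)
    T = config.n_retained
    keep = dict(
        beta0=np.empty((T, I)),
        beta=np.zeros((T, I, L)),
        gamma=np.zeros((T, I, L), dtype=np.int8),
        pi=np.empty((T, L)),
        slab_mean=np.empty((T, L)),
        slab_var=np.empty((T, L)),
        beta0_mean=np.empty(T),
        beta0_var=np.empty(T),
        sigma2=np.empty(T),
    )

    t_out = 0
    for t in range(1, config.iterations + 1):
        gibbs_sweep(state, data, rng, hyper, selection, pi_mode, fixed_pi, _cache=cache)
        if not np.isfinite(state.sigma2) or state.sigma2 <= 0:
            raise FloatingPointError(f"error variance degenerated at iteration {t}: {state}")

        if t > config.burn_in and (t - config.burn_in) % config.thin == 0:
            keep["beta0"][t_out] = state.beta0
            keep["beta"][t_out] = state.beta
            keep["gamma"][t_out] = state.gamma
            keep["pi"][t_out] = state.pi
            keep["slab_mean"][t_out] = state.slab_mean
            keep["slab_var"][t_out] = state.slab_var
            keep["beta0_mean"][t_out] = state.beta0_mean
            keep["beta0_var"][t_out] = state.beta0_var
            keep["sigma2"][t_out] = state.sigma2
            t_out += 1

    return PosteriorSamples(
        group_ids=list(data.group_ids),
        covariate_names=list(data.covariate_names),
        availability=data.availability.copy(),
        selection=selection,
        pi_mode=pi_mode,
        **keep,
    )
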