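import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from hssurv import ChainConfig, GroupedSurvivalData, Hyperparameters, run_chain
from hssurv.gibbs import (
    ParameterState,
    conjugate_normal_posterior,
    gibbs_sweep,
    impute_censored,
    indicator_probability,
    sample_truncated_normal,
    update_coefficient,
    update_inclusion_prob,
    update_intercepts,
    update_sigma2,
    update_slab,
)

KS_ALPHA = 0.001


class StubRng:
    """Deterministic stand-in capturing the conjugate bookkeeping: normal
    draws land on the posterior mean, gamma draws record their shape."""

    def __init__(self, gamma_value=1.0):
        self.gamma_shapes = []
        self.gamma_value = gamma_value

    def standard_normal(self, size=None):
        return 0.0 if size is None else np.zeros(size)

    def gamma(self, shape, size=None):
        self.gamma_shapes.append(shape)
        return self.gamma_value if size is None else np.full(size, self.gamma_value)


def one_group_data(times, events, X=None, names=None):
    times = np.asarray(times, float)
    X = np.zeros((times.size, 0)) if X is None else np.asarray(X, float)
    names = names or [f"x{j+1}" for j in range(X.shape[1])]
    return GroupedSurvivalData(
        ["g1"], names, [times], [np.asarray(events, bool)], [X],
        np.ones((1, len(names)), dtype=bool),
    )


def blank_state(I, L, sigma2=1.0, w=None):
    return ParameterState(
        beta0=np.zeros(I),
        beta=np.zeros((I, L)),
        gamma=np.ones((I, L), dtype=np.int8),
        pi=np.full(L, 0.5),
        slab_mean=np.zeros(L),
        slab_var=np.ones(L),
        beta0_mean=0.0,
        beta0_var=1.0,
        sigma2=sigma2,
        w=w or [],
    )


def grid_cdf(grid, log_density):
    """Numerically normalized CDF on a grid, for KS tests against samplers."""
    dens = np.exp(log_density - log_density.max())
    cdf = integrate.cumulative_trapezoid(dens, grid, initial=0.0)
    cdf /= cdf[-1]
    return lambda x: np.interp(x, grid, cdf)


class TestTruncatedNormal:
    def test_every_draw_respects_the_bound(self, rng):
        mean = rng.normal(size=500)
        lower = mean + rng.uniform(-8, 8, size=500)
        draws = sample_truncated_normal(rng, mean, 1.0, lower)
        assert np.all(draws >= lower)

    def test_negligible_truncation_recovers_the_mean(self, rng):
        mu, sd = 2.0, 0.5
        draws = sample_truncated_normal(rng, np.full(10_000, mu), sd, mu - 10 * sd)
        assert abs(draws.mean() - mu) < 4 * sd / math.sqrt(10_000)

    def test_mean_at_the_bound_matches_closed_form(self, rng):
        # bound at the mean, sd 1: E[X] = mu + phi(0)/(1-Phi(0)) = mu + 0.7979
        mu = 1.3
        draws = sample_truncated_normal(rng, np.full(20_000, mu), 1.0, mu)
        expected = mu + math.sqrt(2.0 / math.pi)
        se = draws.std() / math.sqrt(draws.size)
        assert abs(draws.mean() - expected) < 4 * se

    def test_far_tail_regime_matches_scipy(self, rng):
        a = 8.0  # beyond the inverse-CDF cutoff
        draws = sample_truncated_normal(rng, np.zeros(20_000), 1.0, np.full(20_000, a))
        ref = stats.truncnorm(a, np.inf)
        assert np.all(np.isfinite(draws)) and np.all(draws >= a)
        assert abs(draws.mean() - ref.mean()) < 5 * ref.std() / math.sqrt(draws.size)
        assert stats.kstest(draws - 0.0, ref.cdf).pvalue > KS_ALPHA

    def test_non_finite_bound_rejected(self, rng):
        with pytest.raises(ValueError, match="bound"):
            sample_truncated_normal(rng, np.zeros(2), 1.0, np.array([0.0, np.inf]))


class TestConjugatePosterior:
    def test_single_observation_slab_update(self):
        # x = 1, partial residual 1, sigma2 = 1, prior N(0, 1) -> N(0.5, 0.5)
        mean, var = conjugate_normal_posterior(0.0, 1.0, xtx=1.0, xtr=1.0, sigma2=1.0)
        assert (mean, var) == pytest.approx((0.5, 0.5))

    def test_single_observation_spike_update(self):
        # spike precision 10^4 dominates: mean 1/10001, variance ~ 1e-4
        mean, var = conjugate_normal_posterior(0.0, 1e-4, xtx=1.0, xtr=1.0, sigma2=1.0)
        assert mean == pytest.approx(1.0 / 10001.0)
        assert var == pytest.approx(1.0 / 10001.0)

    def test_no_information_returns_prior(self):
        mean, var = conjugate_normal_posterior(0.7, 2.0, xtx=0.0, xtr=0.0, sigma2=1.0)
        assert (mean, var) == pytest.approx((0.7, 2.0))

    def test_coefficient_draw_matches_grid_oracle(self):
        rng = np.random.default_rng(3)
        n = 10
        x = rng.standard_normal(n)
        w = 0.3 + 0.8 * x + rng.standard_normal(n)
        data = one_group_data(np.exp(w), np.ones(n), X=x[:, None])
        state = blank_state(1, 1, sigma2=1.3, w=[w.copy()])
        state.beta0[:] = 0.3
        state.slab_mean[:] = 0.4
        state.slab_var[:] = 0.7
        draws = np.array([update_coefficient(0, 0, state, data, rng, Hyperparameters())
                          for _ in range(10_000)])
        grid = np.linspace(-3, 4, 4001)
        resid = w - 0.3
        loglik = np.array([-0.5 * np.sum((resid - b * x) ** 2) / 1.3 for b in grid])
        logprior = -0.5 * (grid - 0.4) ** 2 / 0.7
        assert stats.ks_1samp(draws, grid_cdf(grid, loglik + logprior)).pvalue > KS_ALPHA


class TestIndicatorUpdate:
    def test_probability_at_zero_coefficient(self):
        # slab density 0.39894 vs spike density 39.894 -> p ~ 0.00990
        p = indicator_probability(0.0, 0.0, 1.0, 1e-4, 0.5)
        assert p == pytest.approx(0.39894 / (0.39894 + 39.894), rel=1e-3)

    def test_spike_vanishes_away_from_zero(self):
        assert indicator_probability(0.5, 0.0, 1.0, 1e-4, 0.5) == pytest.approx(1.0)

    def test_certain_inclusion(self):
        assert indicator_probability(0.0, 0.0, 1.0, 1e-4, 1.0) == 1.0
        assert indicator_probability(0.0, 0.0, 1.0, 1e-4, 0.0) == 0.0


class TestInclusionProbability:
    def test_beta_counts_distribution(self, rng):
        draws = np.array([update_inclusion_prob(2, 4, rng) for _ in range(10_000)])
        assert stats.kstest(draws, stats.beta(3, 3).cdf).pvalue > KS_ALPHA

    def test_all_in_mean(self, rng):
        draws = np.array([update_inclusion_prob(5, 5, rng) for _ in range(10_000)])
        assert abs(draws.mean() - 6.0 / 7.0) < 4 * draws.std() / 100

    def test_single_group_excluded_mean(self, rng):
        draws = np.array([update_inclusion_prob(0, 1, rng) for _ in range(10_000)])
        assert abs(draws.mean() - 1.0 / 3.0) < 4 * draws.std() / 100


class TestSlabUpdate:
    def test_empty_slab_draws_from_priors(self, rng):
        hyper = Hyperparameters()
        pairs = np.array([update_slab(np.array([]), 1.0, rng, hyper) for _ in range(10_000)])
        means, variances = pairs[:, 0], pairs[:, 1]
        # prior IG(5, 1) has mean 1/4; prior slab mean N(0, 1)
        assert abs(variances.mean() - 0.25) < 4 * variances.std() / 100
        assert abs(means.mean()) < 4 * means.std() / 100
        assert abs(means.var() - 1.0) < 0.06

    def test_single_group_posterior_mean(self, rng):
        # one included group with beta = 2, slab var 1, tau2 = 1 -> N(1, 0.5)
        hyper = Hyperparameters()
        draws = np.array([update_slab(np.array([2.0]), 1.0, rng, hyper)[0] for _ in range(10_000)])
        assert abs(draws.mean() - 1.0) < 4 * math.sqrt(0.5) / 100
        assert abs(draws.var() - 0.5) < 0.03

    def test_variance_bookkeeping_two_concordant_groups(self):
        # betas equal to the posterior-mean slab mean -> IG(5 + 1, 1 + 0)
        stub = StubRng()
        mean, var = update_slab(np.array([0.0, 0.0]), 1.0, stub, Hyperparameters())
        assert mean == 0.0
        assert stub.gamma_shapes == [6.0]
        assert var == 1.0  # rate / stub gamma value

    def test_joint_draw_matches_grid_oracle(self):
        rng = np.random.default_rng(11)
        hyper = Hyperparameters()
        betas = np.array([0.5, 1.5, -0.2])
        draws = np.array([update_slab(betas, 0.8, rng, hyper)[1] for _ in range(10_000)])
        # marginal of the new slab variance: integrate the conditional IG over
        # the normal draw of the slab mean
        m_post_var = 1.0 / (1.0 / hyper.slab_mean_var + betas.size / 0.8)
        m_post_mean = m_post_var * betas.sum() / 0.8
        m_grid = np.linspace(m_post_mean - 6 * math.sqrt(m_post_var),
                             m_post_mean + 6 * math.sqrt(m_post_var), 401)
        m_dens = stats.norm(m_post_mean, math.sqrt(m_post_var)).pdf(m_grid)
        shape = hyper.slab_var_shape + 0.5 * betas.size

        def cdf(v):
            v = np.atleast_1d(v)
            rates = hyper.slab_var_rate + 0.5 * ((betas[None, :] - m_grid[:, None]) ** 2).sum(axis=1)
            vals = stats.invgamma(shape, scale=rates[None, :]).cdf(v[:, None])
            return np.trapezoid(vals * m_dens[None, :], m_grid, axis=1) / np.trapezoid(m_dens, m_grid)

        assert stats.ks_1samp(draws, cdf).pvalue > KS_ALPHA


class TestInterceptAndVarianceUpdates:
    def test_intercept_hypervariance_bookkeeping(self):
        # one group whose intercept lands on the hypermean -> IG(1 + 1/2, 1 + 0)
        data = one_group_data(np.ones(4), np.ones(4))
        state = blank_state(1, 0, w=[np.zeros(4)])
        stub = StubRng()
        update_intercepts(state, data, stub, Hyperparameters())
        assert state.beta0[0] == 0.0 and state.beta0_mean == 0.0
        assert stub.gamma_shapes == [1.5]
        assert state.beta0_var == 1.0

    def test_sigma2_bookkeeping(self):
        # two subjects with residuals (1, -1): IG(0.01 + 1, 0.01 + 1)
        data = one_group_data(np.exp([1.0, -1.0]), np.ones(2))
        state = blank_state(1, 0, w=[np.array([1.0, -1.0])])
        stub = StubRng()
        value = update_sigma2(state, data, stub, Hyperparameters())
        assert stub.gamma_shapes == [1.01]
        assert value == pytest.approx(1.01)  # rate, since the stub gamma draw is 1

    def test_sigma2_permutation_invariant(self):
        resid = np.array([0.3, -1.2, 0.8, 2.0])
        for perm in (slice(None), [3, 1, 0, 2]):
            data = one_group_data(np.ones(4), np.ones(4))
            state = blank_state(1, 0, w=[resid[perm].copy()])
            stub = StubRng()
            update_sigma2(state, data, stub, Hyperparameters())
        # same shape recorded; the rate enters through the returned value
        assert stub.gamma_shapes == [2.01]

    def test_sigma2_draw_matches_grid_oracle(self):
        rng = np.random.default_rng(21)
        resid = np.array([0.4, -0.9, 1.3, 0.2, -0.6])
        data = one_group_data(np.ones(5), np.ones(5))
        state = blank_state(1, 0, w=[resid.copy()])
        draws = np.array([update_sigma2(state, data, rng, Hyperparameters()) for _ in range(10_000)])
        grid = np.linspace(1e-3, 40.0, 30_000)
        logp = (-(0.01 + 1) * np.log(grid) - 0.01 / grid
                - 2.5 * np.log(grid) - 0.5 * np.sum(resid**2) / grid)
        assert stats.ks_1samp(draws, grid_cdf(grid, logp)).pvalue > KS_ALPHA

    def test_large_sample_intercept_recovers_log_time_mean(self):
        rng = np.random.default_rng(5)
        logt = rng.normal(1.7, 0.6, size=400)
        data = one_group_data(np.exp(logt), np.ones(400))
        samples = run_chain(data, config=ChainConfig(iterations=600, burn_in=300, thin=1, seed=0),
                            selection="none")
        assert abs(samples.beta0.mean() - logt.mean()) < 0.05

    def test_two_group_hypermean_shrinks_between_group_means(self):
        rng = np.random.default_rng(6)
        t1, t2 = np.exp(rng.normal(0.0, 0.3, 60)), np.exp(rng.normal(2.0, 0.3, 60))
        frame = pd.DataFrame({
            "group": ["a"] * 60 + ["b"] * 60,
            "time": np.concatenate([t1, t2]),
            "event": 1,
        })
        data = GroupedSurvivalData.from_frame(frame)
        samples = run_chain(data, config=ChainConfig(iterations=600, burn_in=300, thin=1, seed=0),
                            selection="none")
        m = samples.beta0_mean.mean()
        assert np.log(t1).mean() < m < np.log(t2).mean()


class TestImputation:
    def test_draws_respect_bounds_and_mean(self, rng):
        n = 10_000
        times = np.full(n, math.e)  # log censor time = 1
        data = one_group_data(times, np.zeros(n))
        state = blank_state(1, 0, w=[np.log(times).copy()])
        state.beta0[:] = 1.0  # mean exactly at the bound, sigma = 1
        impute_censored(state, data, rng)
        assert np.all(state.w[0] >= 1.0)
        se = state.w[0].std() / math.sqrt(n)
        assert abs(state.w[0].mean() - (1.0 + math.sqrt(2 / math.pi))) < 4 * se
        state.validate(data)


class TestChain:
    def test_same_seed_bit_identical(self, small_simulated):
        data, _, _ = small_simulated
        cfg = ChainConfig(iterations=120, burn_in=60, thin=2, seed=42)
        a = run_chain(data, config=cfg)
        b = run_chain(data, config=cfg)
        for field in ("beta0", "beta", "gamma", "pi", "slab_mean", "slab_var", "sigma2"):
            np.testing.assert_array_equal(getattr(a, field), getattr(b, field))

    def test_strong_signal_recovery(self):
        rng = np.random.default_rng(9)
        frames = []
        for g in ("a", "b", "c"):
            x = rng.standard_normal((200, 2))
            logt = 0.5 + 2.0 * x[:, 0] + rng.standard_normal(200)
            frames.append(pd.DataFrame({
                "group": g, "time": np.exp(logt), "event": 1,
                "x1": x[:, 0], "x2": x[:, 1],
            }))
        data = GroupedSurvivalData.from_frame(pd.concat(frames, ignore_index=True))
        samples = run_chain(data, config=ChainConfig(iterations=1000, burn_in=500, thin=2, seed=1))
        pip = samples.inclusion_probs()
        assert np.all(pip[:, 0] > 0.9)
        assert np.all(pip[:, 1] < 0.5)

    def test_null_selection_reports_zero_inclusion(self, small_simulated):
        data, _, avail = small_simulated
        samples = run_chain(data, config=ChainConfig(iterations=100, burn_in=50, thin=1, seed=0),
                            selection="none")
        pip = samples.inclusion_probs()
        assert np.all(pip[avail] == 0.0)
        summary = samples.summary()
        assert set(summary["parameter"]) == {"intercept", "error_variance"}

    def test_all_in_selection_is_exactly_one(self, small_simulated):
        data, _, avail = small_simulated
        samples = run_chain(data, config=ChainConfig(iterations=100, burn_in=50, thin=1, seed=0),
                            selection="all_in")
        assert np.all(samples.inclusion_probs()[avail] == 1.0)

    def test_intercept_only_posterior_matches_numerical_marginal(self):
        """Intercept-only, uncensored: the chain's posterior for (beta_01,
        sigma²) must match a brute-force 2-D grid posterior in which the
        intercept hypermean and hypervariance are integrated out
        numerically."""
        rng = np.random.default_rng(14)
        w = rng.normal(0.8, 1.1, size=30)
        data = one_group_data(np.exp(w), np.ones(30))
        samples = run_chain(
            data,
            config=ChainConfig(iterations=6000, burn_in=1000, thin=1, seed=2),
            selection="none",
        )
        # marginal prior of beta_01: N(0, 100 + v) mixed over v ~ IG(1, 1)
        v_grid = np.linspace(1e-3, 60, 2000)
        ig_v = stats.invgamma(1.0, scale=1.0).pdf(v_grid)
        b_grid = np.linspace(-2, 3, 401)
        prior_b = np.trapezoid(
            stats.norm(0.0, np.sqrt(100.0 + v_grid)[None, :]).pdf(b_grid[:, None]) * ig_v[None, :],
            v_grid, axis=1,
        )
        s_grid = np.linspace(0.3, 5.0, 400)
        loglik = (
            -0.5 * 30 * np.log(s_grid)[None, :]
            - 0.5 * ((w[None, None, :] - b_grid[:, None, None]) ** 2).sum(-1) / s_grid[None, :]
        )
        post = np.exp(loglik - loglik.max()) * prior_b[:, None] * stats.invgamma(0.01, scale=0.01).pdf(s_grid)[None, :]
        post /= np.trapezoid(np.trapezoid(post, s_grid, axis=1), b_grid)
        marg_b = np.trapezoid(post, s_grid, axis=1)
        marg_s = np.trapezoid(post, b_grid, axis=0)
        eb = np.trapezoid(b_grid * marg_b, b_grid)
        es = np.trapezoid(s_grid * marg_s, s_grid)
        sdb = math.sqrt(np.trapezoid((b_grid - eb) ** 2 * marg_b, b_grid))
        assert abs(samples.beta0.mean() - eb) < 0.05
        assert abs(samples.sigma2.mean() - es) < 0.12
        assert abs(samples.beta0.std() - sdb) < 0.04


class TestJointCorrectness:
    def test_successive_conditional_marginals_match_priors(self):
        """Geweke-style check: alternating one production Gibbs sweep with
        regeneration of the outcomes from the likelihood must leave each
        parameter's marginal distribution equal to its prior."""
        rng = np.random.default_rng(77)
        hyper = Hyperparameters(
            error_var_shape=3.0, error_var_rate=3.0,
            intercept_var_shape=3.0, intercept_var_rate=3.0,
            intercept_mean_var=1.0,
        )
        I, L, n = 2, 2, 4
        X = [rng.standard_normal((n, L)) for _ in range(I)]
        data = GroupedSurvivalData(
            ["a", "b"], ["x1", "x2"],
            [np.ones(n), np.ones(n)], [np.ones(n, bool), np.ones(n, bool)],
            X, np.ones((I, L), bool),
        )
        # start from a prior draw
        state = ParameterState(
            beta0=rng.normal(0, 1, I), beta=np.zeros((I, L)),
            gamma=np.ones((I, L), np.int8), pi=np.full(L, 0.5),
            slab_mean=rng.normal(0, 1, L),
            slab_var=hyper.slab_var_rate / rng.gamma(hyper.slab_var_shape, size=L),
            beta0_mean=0.0, beta0_var=1.0, sigma2=1.0,
            w=[np.zeros(n), np.zeros(n)],
        )
        sweeps = 20_000
        kept = {"pi": [], "gamma": [], "slab_mean": [], "slab_var": [], "sigma2": []}
        for _ in range(sweeps):
            # regenerate outcomes from the likelihood given the current state
            for i in range(I):
                mu = state.beta0[i] + X[i] @ state.beta[i]
                w = mu + math.sqrt(state.sigma2) * rng.standard_normal(n)
                state.w[i] = w
                data.times[i] = np.exp(w)
            gibbs_sweep(state, data, rng, hyper)
            kept["pi"].append(state.pi.copy())
            kept["gamma"].append(state.gamma.mean())
            kept["slab_mean"].append(state.slab_mean.copy())
            kept["slab_var"].append(state.slab_var.copy())
            kept["sigma2"].append(state.sigma2)
        pi = np.concatenate(kept["pi"])
        slab_mean = np.concatenate(kept["slab_mean"])
        slab_var = np.concatenate(kept["slab_var"])
        sigma2 = np.array(kept["sigma2"])
        # priors: pi ~ U(0,1); gamma marginally Bernoulli(1/2);
        # slab mean ~ N(0,1); slab var ~ IG(5,1) (mean 1/4);
        # sigma2 ~ IG(3,3) (mean 3/2)
        assert abs(pi.mean() - 0.5) < 0.02
        assert abs(pi.var() - 1.0 / 12.0) < 0.01
        assert abs(np.mean(kept["gamma"]) - 0.5) < 0.02
        assert abs(slab_mean.mean()) < 0.03
        assert abs(slab_mean.var() - 1.0) < 0.06
        assert abs(slab_var.mean() - 0.25) < 0.02
        assert abs(sigma2.mean() - 1.5) < 0.1
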