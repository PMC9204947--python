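"""Scikit-learn style estimator interface.

:class:`SpikeSlabAFT` wraps the Gibbs engine behind the familiar
``fit`` / ``predict`` / ``score`` surface so the model composes with sklearn
pipelines and model selection.  ``X`` is a feature matrix (DataFrame or
ndarray) in which NaN marks a covariate structurally absent for a subject's
group; ``y`` is survival outcome in any of the common encodings (a
scikit-survival style structured array with ``event``/``time`` fields, a
two-column DataFrame, or an ``(time, event)`` pair of arrays); ``groups``
assigns each subject to a cohort.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data import ChainConfig, GroupedSurvivalData, Hyperparameters, standardize_predictors
from .validation import _draw_log_likelihoods, posterior_predictive_estimate
from .variants import VARIANT_NAMES, fit_variant, make_variant, merge_groups, _single_group

__all__ = ["SpikeSlabAFT", "make_estimator"]


def _parse_survival_y(y, n: int):
    """Return (time, event) float/bool arrays from any supported encoding."""
    if isinstance(y, pd.DataFrame):
        if not {"time", "event"}.issubset(y.columns):
            raise ValueError("y DataFrame must have 'time' and 'event' columns")
        return y["time"].to_numpy(float), y["event"].to_numpy(float).astype(bool)
    arr = np.asarray(y)
    if arr.dtype.names:  # structured (scikit-survival convention, either field order)
        names = set(arr.dtype.names)
        if not {"time", "event"} <= {n.lower() for n in names}:
            # fall back to positional: first bool-like field is the event
            fields = list(arr.dtype.names)
            event_field = next(f for f in fields if arr[f].dtype == bool)
            time_field = next(f for f in fields if f != event_field)
        else:
            lookup = {n.lower(): n for n in arr.dtype.names}
            time_field, event_field = lookup["time"], lookup["event"]
        return arr[time_field].astype(float), arr[event_field].astype(bool)
    if isinstance(y, (tuple, list)) and len(y) == 2:
        return np.asarray(y[0], float), np.asarray(y[1]).astype(bool)
    arr = np.asarray(y, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 2:
        return arr[:, 0], arr[:, 1].astype(bool)
    raise ValueError("unsupported survival outcome encoding")


class SpikeSlabAFT(BaseEstimator):
    """Hierarchical spike-and-slab log-normal accelerated failure time model.

    Parameters
    ----------
    variant : str
        One of ``hierarchical, null, full, fixed_0.5, shared, joint,
        separate`` (see the variants module).
    iterations, burn_in, thin : int
        Gibbs chain settings; ``burn_in=None`` means half the iterations.
    standardize : bool
        Standardize predictors (mean 0, sd 1 over the subjects possessing
        each one) before fitting; the transform is stored as ``transform_``.
    spike_var, slab_mean_var, slab_var_shape, slab_var_rate, ... : float
        Prior hyperparameters, see :class:`~hssurv.data.Hyperparameters`.
    random_state : int or None
        Seed; the same seed gives a bit-identical fit.

    Attributes
    ----------
    result_ : FitResult
        The fitted chain(s) with variant bookkeeping.
    inclusion_probs_ : DataFrame (groups × covariates)
        Posterior inclusion probabilities, NaN where a covariate is
        unavailable for a group.
    coef_ : DataFrame (groups × covariates)
        Posterior mean effects on the (standardized) log-time scale.
    ci_lower_, ci_upper_ : DataFrame
        Central 95% credible interval endpoints.
    intercepts_ : Series, sigma2_ : float
        Posterior mean group intercepts and error variance.
    """

    def __init__(
        self,
        variant: str = "hierarchical",
        iterations: int = 2000,
        burn_in: int | None = None,
        thin: int = 1,
        standardize: bool = False,
        spike_var: float = 1e-4,
        slab_mean_var: float = 1.0,
        slab_var_shape: float = 5.0,
        slab_var_rate: float = 1.0,
        intercept_mean_var: float = 100.0,
        intercept_var_shape: float = 1.0,
        intercept_var_rate: float = 1.0,
        error_var_shape: float = 0.01,
        error_var_rate: float = 0.01,
        fixed_pi: float = 0.5,
        credible_level: float = 0.95,
        random_state: int | None = None,
    ):
        self.variant = variant
        self.iterations = iterations
        self.burn_in = burn_in
        self.thin = thin
        self.standardize = standardize
        self.spike_var = spike_var
        self.slab_mean_var = slab_mean_var
        self.slab_var_shape = slab_var_shape
        self.slab_var_rate = slab_var_rate
        self.intercept_mean_var = intercept_mean_var
        self.intercept_var_shape = intercept_var_shape
        self.intercept_var_rate = intercept_var_rate
        self.error_var_shape = error_var_shape
        self.error_var_rate = error_var_rate
        self.fixed_pi = fixed_pi
        self.credible_level = credible_level
        self.random_state = random_state

    # -- assembly ---------------------------------------------------------
    def _hyper(self) -> Hyperparameters:
        return Hyperparameters(
            spike_var=self.spike_var,
            slab_mean_var=self.slab_mean_var,
            slab_var_shape=self.slab_var_shape,
            slab_var_rate=self.slab_var_rate,
            intercept_mean_var=self.intercept_mean_var,
            intercept_var_shape=self.intercept_var_shape,
            intercept_var_rate=self.intercept_var_rate,
            error_var_shape=self.error_var_shape,
            error_var_rate=self.error_var_rate,
        )

    def _config(self) -> ChainConfig:
        burn = self.iterations // 2 if self.burn_in is None else self.burn_in
        return ChainConfig(
            iterations=self.iterations, burn_in=burn, thin=self.thin, seed=self.random_state
        )

    def _to_grouped(self, X, y, groups) -> GroupedSurvivalData:
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            if values.ndim != 2:
                raise ValueError("X must be two-dimensional")
            names = [f"x{j + 1}" for j in range(values.shape[1])]
        n = values.shape[0]
        time, event = _parse_survival_y(y, n)
        if time.shape[0] != n:
            raise ValueError("X and y have inconsistent lengths")
        groups = np.asarray(["g1"] * n) if groups is None else np.asarray(groups)
        frame = pd.DataFrame(values, columns=names)
        frame.insert(0, "event", event.astype(int))
        frame.insert(0, "time", time)
        frame.insert(0, "group", groups)
        return GroupedSurvivalData.from_frame(frame)

    # -- sklearn surface --------------------------------------------------
    def fit(self, X, y, groups=None):
        """Run the Gibbs sampler for the configured variant."""
        make_variant(self.variant)  # validate the name before any work
        data = self._to_grouped(X, y, groups)
        self.transform_ = None
        if self.standardize:
            data, self.transform_ = standardize_predictors(data)
        self.n_features_in_ = data.n_covariates
        self.feature_names_in_ = np.asarray(data.covariate_names, dtype=object)
        result = fit_variant(
            data, self.variant, hyper=self._hyper(), config=self._config()
        )
        self.result_ = result
        self.group_ids_ = list(data.group_ids)
        self.availability_ = pd.DataFrame(
            data.availability, index=self.group_ids_, columns=data.covariate_names
        )
        grid = lambda a: pd.DataFrame(a, index=self.group_ids_, columns=data.covariate_names)
        self.inclusion_probs_ = grid(result.inclusion_probs())
        primary = result.samples if not isinstance(result.samples, list) else None
        if primary is not None and result.variant.structure == "grouped":
            self.coef_ = grid(primary.coefficient_means())
            lo, hi = primary.credible_intervals(self.credible_level)
            self.ci_lower_, self.ci_upper_ = grid(lo), grid(hi)
            self.intercepts_ = pd.Series(primary.beta0.mean(axis=0), index=self.group_ids_)
            self.sigma2_ = float(primary.sigma2.mean())
        elif result.variant.structure == "joint":
            self.coef_ = grid(np.broadcast_to(primary.coefficient_means(), data.availability.shape))
            self.intercepts_ = pd.Series(
                [float(primary.beta0.mean())] * len(self.group_ids_), index=self.group_ids_
            )
            self.sigma2_ = float(primary.sigma2.mean())
        else:  # separate: one chain per group
            coef = np.full(data.availability.shape, np.nan)
            inter = []
            for i, s in enumerate(result.samples):
                cols = [data.covariate_names.index(c) for c in s.covariate_names]
                coef[i, cols] = s.coefficient_means()[0]
                inter.append(float(s.beta0.mean()))
            self.coef_ = grid(coef)
            self.intercepts_ = pd.Series(inter, index=self.group_ids_)
            self.sigma2_ = float(np.mean([s.sigma2.mean() for s in result.samples]))
        self.coef_ = self.coef_.where(self.availability_)
        return self

    def _check_fitted(self):
        if not hasattr(self, "result_"):
            raise RuntimeError("estimator is not fitted; call fit first")

    def predict(self, X, groups=None):
        """Posterior-median survival time prediction, exp(E[mu | data]).

        The linear predictor mu is the model's mean log survival time; its
        posterior mean is averaged over retained draws and exponentiated,
        giving the predicted median survival time of the log-normal model.
        """
        self._check_fitted()
        n = len(X)
        dummy_y = (np.ones(n), np.ones(n, dtype=bool))
        data = self._to_grouped(X, dummy_y, groups)
        if self.transform_ is not None:
            mean, scale = self.transform_.mean_, self.transform_.scale_
            data = GroupedSurvivalData(
                data.group_ids,
                data.covariate_names,
                data.times,
                data.events,
                [np.where(data.availability[i], (x - mean) / scale, 0.0) for i, x in enumerate(data.X)],
                data.availability,
            )
        result = self.result_
        out = np.empty(0)
        order = []
        if result.variant.structure == "joint":
            merged = merge_groups(data)
            s = result.samples
            mu = s.beta0[:, 0][:, None] + s.beta[:, 0, :] @ merged.X[0].T
            return np.exp(mu.mean(axis=0))
        group_index = {g: i for i, g in enumerate(result.group_ids)}
        preds = []
        for gpos, gid in enumerate(data.group_ids):
            if gid not in group_index:
                raise ValueError(f"group {gid!r} was not present at fit time")
            gi = group_index[gid]
            if result.variant.structure == "separate":
                s = result.samples[gi]
                cols = [data.covariate_names.index(c) for c in s.covariate_names]
                mu = s.beta0[:, 0][:, None] + s.beta[:, 0, :] @ data.X[gpos][:, cols].T
            else:
                s = result.samples
                mu = s.beta0[:, gi][:, None] + s.beta[:, gi, :] @ data.X[gpos].T
            preds.append(mu.mean(axis=0))
        # restore input row order (groups were regrouped by appearance)
        groups_arr = np.asarray(["g1"] * n) if groups is None else np.asarray(groups)
        out = np.empty(n)
        for gpos, gid in enumerate(data.group_ids):
            out[np.asarray(groups_arr) == gid] = preds[gpos]
        return np.exp(out)

    def score(self, X, y, groups=None):
        """Out-of-sample log posterior predictive likelihood (higher is
        better): the log of the draw-averaged test likelihood."""
        self._check_fitted()
        data = self._to_grouped(X, y, groups)
        if self.transform_ is not None:
            mean, scale = self.transform_.mean_, self.transform_.scale_
            data = GroupedSurvivalData(
                data.group_ids,
                data.covariate_names,
                data.times,
                data.events,
                [np.where(data.availability[i], (x - mean) / scale, 0.0) for i, x in enumerate(data.X)],
                data.availability,
            )
        return self.result_.log_predictive_likelihood(data)

    def summary(self) -> pd.DataFrame:
        """Tidy posterior summary (mean effects, credible intervals,
        inclusion probabilities); grouped-structure variants only."""
        self._check_fitted()
        if isinstance(self.result_.samples, list):
            return pd.concat([s.summary(self.credible_level) for s in self.result_.samples])
        return self.result_.samples.summary(self.credible_level)


def make_estimator(name: str, **kwargs) -> SpikeSlabAFT:
    """Configured estimator for a named model variant."""
    if name not in VARIANT_NAMES:
        raise ValueError(f"unknown model variant {name!r}; expected one of {VARIANT_NAMES}")
    return SpikeSlabAFT(variant=name, **kwargs)
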