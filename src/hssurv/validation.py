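"""Cross-validated log posterior predictive likelihood.

For a posterior draw :math:`\\Theta^t` and a held-out test set, the test
likelihood multiplies, over uncensored subjects, the log-normal density at
the observed event time, and, over censored subjects, the probability of
surviving past the censoring time.  The out-of-sample posterior predictive
likelihood is estimated by averaging that quantity over the T retained
draws, and its log is computed with a stable log-mean-exp.  Model comparison
uses the mean of the per-fold log estimates under k-fold cross validation,
with folds stratified by group so every training fold contains every group
(group intercepts must be estimable on every fold).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import special

from .data import ChainConfig, GroupedSurvivalData, Hyperparameters
from .gibbs import PosteriorSamples

__all__ = [
    "FoldSplit",
    "PredictiveScore",
    "log_test_likelihood",
    "posterior_predictive_estimate",
    "make_folds",
    "kfold_cv",
]


@dataclasses.dataclass
class FoldSplit:
    """Per-group train/test subject index arrays for one fold."""

    fold: int
    train: list  # per group ndarray of indices
    test: list


@dataclasses.dataclass
class PredictiveScore:
    """Per-fold log posterior predictive likelihoods and their mean."""

    per_fold: list
    mean: float


def _draw_log_likelihoods(samples: PosteriorSamples, test: GroupedSurvivalData) -> np.ndarray:
    """Log test likelihood of every retained draw; shape (T,).

    The test set must be laid out on the training grid: same covariate
    names, and every test group present among the fitted groups.
    """
    if list(test.covariate_names) != list(samples.covariate_names):
        raise ValueError("test covariates do not match the fitted model")
    group_index = {g: i for i, g in enumerate(samples.group_ids)}
    T = samples.n_draws
    sigma = np.sqrt(samples.sigma2)[:, None]  # (T, 1)
    total = np.zeros(T)
    for gpos, gid in enumerate(test.group_ids):
        if gid not in group_index:
            raise ValueError(f"test subjects from group {gid!r} absent from the training fit")
        gi = group_index[gid]
        if test.times[gpos].size == 0:
            continue
        logt = np.log(test.times[gpos])  # (n,)
        mu = samples.beta0[:, gi][:, None] + samples.beta[:, gi, :] @ test.X[gpos].T  # (T, n)
        z = (logt[None, :] - mu) / sigma
        events = test.events[gpos]
        if events.any():
            dens = -0.5 * np.log(2 * np.pi) - np.log(sigma) - 0.5 * z[:, events] ** 2
            total += dens.sum(axis=1) - logt[events].sum()
        if (~events).any():
            total += special.log_ndtr(-z[:, ~events]).sum(axis=1)
    return total


def log_test_likelihood(
    samples: PosteriorSamples, t: int, test: GroupedSurvivalData
) -> float:
    """Log test likelihood of the single retained draw ``t``: the sum of
    log-normal log densities over uncensored test subjects plus log survival
    probabilities past the censoring times of censored subjects.  An empty
    test set gives log 1 = 0."""
    one = PosteriorSamples(
        group_ids=samples.group_ids,
        covariate_names=samples.covariate_names,
        availability=samples.availability,
        selection=samples.selection,
        pi_mode=samples.pi_mode,
        beta0=samples.beta0[t : t + 1],
        beta=samples.beta[t : t + 1],
        gamma=samples.gamma[t : t + 1],
        pi=samples.pi[t : t + 1],
        slab_mean=samples.slab_mean[t : t + 1],
        slab_var=samples.slab_var[t : t + 1],
        beta0_mean=samples.beta0_mean[t : t + 1],
        beta0_var=samples.beta0_var[t : t + 1],
        sigma2=samples.sigma2[t : t + 1],
    )
    return float(_draw_log_likelihoods(one, test)[0])


def posterior_predictive_estimate(log_likelihoods: np.ndarray) -> float:
    """Log of the draw-averaged test likelihood.

    Given per-draw log likelihoods :math:`\\log L_t`, returns
    :math:`\\log \\frac{1}{T} \\sum_t L_t` via log-sum-exp; the result is
    bounded by the min and max per-draw values (Jensen).
    """
    ll = np.asarray(log_likelihoods, dtype=float)
    if ll.size == 0:
        raise ValueError("need at least one draw")
    return float(special.logsumexp(ll) - np.log(ll.size))


def make_folds(data: GroupedSurvivalData, k: int = 5, seed: int | None = None) -> list:
    """Seeded group-stratified k-fold split.

    Within each group the subjects are shuffled and dealt proportionally
    into the k folds, so folds partition each group and every group appears
    in every training fold.  Censored subjects are not balanced separately.
    Requires every group to have at least k subjects; k must be ≥ 2.
    """
    if k < 2:
        raise ValueError("k-fold cross validation requires k ≥ 2 (k=1 leaves no test set)")
    small = [g for g, n in zip(data.group_ids, data.n_per_group) if n < k]
    if small:
        raise ValueError(f"groups too small to split into {k} folds: {small}")
    rng = np.random.default_rng(seed)
    assignment = []  # per group: fold label per subject
    for n in data.n_per_group:
        perm = rng.permutation(n)
        folds = np.empty(n, dtype=int)
        for f, chunk in enumerate(np.array_split(perm, k)):
            folds[chunk] = f
        assignment.append(folds)
    return [
        FoldSplit(
            fold=f,
            train=[np.flatnonzero(a != f) for a in assignment],
            test=[np.flatnonzero(a == f) for a in assignment],
        )
        for f in range(k)
    ]


def kfold_cv(
    data: GroupedSurvivalData,
    variant: str = "hierarchical",
    hyper: Hyperparameters | None = None,
    config: ChainConfig | None = None,
    k: int = 5,
    seed: int | None = None,
    folds: list | None = None,
) -> PredictiveScore:
    """Fit a variant on each training fold, score the matching test fold,
    and average the per-fold log posterior predictive likelihoods."""
    from .variants import fit_variant

    config = config or ChainConfig()
    if folds is None:
        folds = make_folds(data, k=k, seed=seed)
    chain_seed = seed if seed is not None else config.seed
    per_fold = []
    for split in folds:
        train = data.subset(split.train)
        test = data.subset(split.test)
        rng = np.random.default_rng(
            None if chain_seed is None else (chain_seed, split.fold)
        )
        fit = fit_variant(train, variant, hyper=hyper, config=config, rng=rng)
        per_fold.append(fit.log_predictive_likelihood(test))
    return PredictiveScore(per_fold=per_fold, mean=float(np.mean(per_fold)))
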