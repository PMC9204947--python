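"""The comparison suite: seven configurations of the Gibbs engine.

========== ======================================================================
name       meaning
========== ======================================================================
hierarchical  the full hierarchical spike-and-slab model
null          random intercept per group only, no covariates
full          all covariates permanently included (no spike-and-slab)
fixed_0.5     spike-and-slab with every prior inclusion probability fixed at 0.5
shared        one inclusion probability shared by all covariates and groups,
              Beta(1,1)-updated with pooled indicator counts
joint         all groups appended row-wise and fit as a single group; a
              covariate unavailable for some source groups is zero-filled for
              their subjects (the design must be rectangular; documented choice)
separate      the hierarchical machinery fit to each group independently (I=1)
========== ======================================================================

``fit_variant`` returns a :class:`FitResult` that exposes a uniform surface —
posterior inclusion probabilities on the *original* (group, covariate) grid
and out-of-sample log posterior predictive likelihood — regardless of the
group-structure transformation a variant applies.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .data import ChainConfig, GroupedSurvivalData, Hyperparameters
from .gibbs import PosteriorSamples, run_chain

__all__ = [
    "VARIANT_NAMES",
    "VariantSpec",
    "make_variant",
    "merge_groups",
    "fit_variant",
    "analytic_inclusion",
    "run_suite",
    "FitResult",
]

VARIANT_NAMES = ("hierarchical", "null", "full", "fixed_0.5", "shared", "joint", "separate")


@dataclasses.dataclass(frozen=True)
class VariantSpec:
    """Engine-level flags realizing one named model variant."""

    name: str
    selection: str = "spike_slab"      # "spike_slab" | "all_in" | "none"
    pi_mode: str = "per_covariate"     # "per_covariate" | "fixed" | "shared"
    fixed_pi: float = 0.5
    structure: str = "grouped"         # "grouped" | "joint" | "separate"


_REGISTRY = {
    "hierarchical": VariantSpec("hierarchical"),
    "null": VariantSpec("null", selection="none"),
    "full": VariantSpec("full", selection="all_in"),
    "fixed_0.5": VariantSpec("fixed_0.5", pi_mode="fixed", fixed_pi=0.5),
    "shared": VariantSpec("shared", pi_mode="shared"),
    "joint": VariantSpec("joint", structure="joint"),
    "separate": VariantSpec("separate", structure="separate"),
}


def make_variant(name: str) -> VariantSpec:
    """Look up a variant by name; unknown names raise ``ValueError``."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ValueError(f"unknown model variant {name!r}; expected one of {VARIANT_NAMES}") from None


def merge_groups(data: GroupedSurvivalData, group_id="(all)") -> GroupedSurvivalData:
    """Append all groups row-wise into a single group.

    A covariate is available for the merged group if it is available in any
    source group; subjects from groups lacking it get zero-filled values
    (zero is the covariate mean on the standardized scale).
    """
    avail = data.availability.any(axis=0, keepdims=True)
    X = np.vstack([x for x in data.X]) if data.n_groups else np.empty((0, data.n_covariates))
    return GroupedSurvivalData(
        group_ids=[group_id],
        covariate_names=list(data.covariate_names),
        times=[np.concatenate(data.times)],
        events=[np.concatenate(data.events)],
        X=[X],
        availability=avail,
    )


def _single_group(data: GroupedSurvivalData, i: int) -> GroupedSurvivalData:
    keep = np.flatnonzero(data.availability[i])
    return GroupedSurvivalData(
        group_ids=[data.group_ids[i]],
        covariate_names=[data.covariate_names[j] for j in keep],
        times=[data.times[i].copy()],
        events=[data.events[i].copy()],
        X=[data.X[i][:, keep]],
        availability=data.availability[i:i + 1, keep],
    )


@dataclasses.dataclass
class FitResult:
    """A fitted variant, mapped back onto the original data layout.

    ``samples`` is a single :class:`PosteriorSamples` for grouped/joint
    structures and a list (one per group) for the separate variant.
    """

    variant: VariantSpec
    group_ids: list
    covariate_names: list
    availability: np.ndarray
    samples: object

    def inclusion_probs(self) -> np.ndarray:
        """Posterior inclusion probabilities on the original (I, L) grid,
        NaN outside availability.

        The joint variant estimates one probability per covariate; it is
        broadcast to every original group carrying that covariate.  The
        null and full variants are exactly 0 / 1 with no sampling noise.
        """
        I, L = self.availability.shape
        if self.variant.name == "null":
            probs = np.zeros((I, L))
        elif self.variant.name == "full":
            probs = np.ones((I, L))
        elif self.variant.structure == "joint":
            probs = np.broadcast_to(self.samples.inclusion_probs(), (I, L)).copy()
        elif self.variant.structure == "separate":
            probs = np.full((I, L), np.nan)
            for i, s in enumerate(self.samples):
                cols = [self.covariate_names.index(c) for c in s.covariate_names]
                probs[i, cols] = s.inclusion_probs()[0]
        else:
            probs = self.samples.inclusion_probs()
        return np.where(self.availability, probs, np.nan)

    def log_predictive_likelihood(self, test: GroupedSurvivalData) -> float:
        """Out-of-sample log posterior predictive likelihood on a test set
        laid out like the training data (see the validation module)."""
        from .validation import posterior_predictive_estimate, _draw_log_likelihoods

        if self.variant.structure == "joint":
            test = merge_groups(test)
            return posterior_predictive_estimate(_draw_log_likelihoods(self.samples, test))
        if self.variant.structure == "separate":
            total = None
            for i, s in enumerate(self.samples):
                ll = _draw_log_likelihoods(s, _single_group(test, i))
                total = ll if total is None else total + ll
            return posterior_predictive_estimate(total)
        return posterior_predictive_estimate(_draw_log_likelihoods(self.samples, test))


def fit_variant(
    data: GroupedSurvivalData,
    name: str,
    hyper: Hyperparameters | None = None,
    config: ChainConfig | None = None,
    rng: np.random.Generator | None = None,
) -> FitResult:
    """Fit one named variant, handling its group-structure transformation."""
    spec = make_variant(name)
    config = config or ChainConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    kwargs = dict(selection=spec.selection, pi_mode=spec.pi_mode, fixed_pi=spec.fixed_pi)
    if spec.structure == "joint":
        samples = run_chain(merge_groups(data), hyper, config, rng=rng, **kwargs)
    elif spec.structure == "separate":
        # one independent stream per group: group i's fit must not depend on
        # the other groups' presence or content
        streams = rng.spawn(data.n_groups)
        samples = [
            run_chain(_single_group(data, i), hyper, config, rng=streams[i], **kwargs)
            for i in range(data.n_groups)
        ]
    else:
        samples = run_chain(data, hyper, config, rng=rng, **kwargs)
    return FitResult(
        variant=spec,
        group_ids=list(data.group_ids),
        covariate_names=list(data.covariate_names),
        availability=data.availability.copy(),
        samples=samples,
    )


def analytic_inclusion(name: str, availability: np.ndarray) -> np.ndarray:
    """Closed-form posterior inclusion probabilities for the two variants
    whose selection output is deterministic: 1 everywhere for "full",
    0 everywhere for "null" (NaN outside availability)."""
    availability = np.asarray(availability, dtype=bool)
    if name == "full":
        probs = np.ones(availability.shape)
    elif name == "null":
        probs = np.zeros(availability.shape)
    else:
        raise ValueError(f"variant {name!r} has no closed-form inclusion probabilities")
    return np.where(availability, probs, np.nan)


def run_suite(
    data: GroupedSurvivalData,
    variants=VARIANT_NAMES,
    hyper: Hyperparameters | None = None,
    config: ChainConfig | None = None,
    k: int = 5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Cross-validated model comparison over a set of variants.

    Runs k-fold cross validation of the log posterior predictive likelihood
    with folds shared across variants, and returns one row per variant with
    the per-fold scores and their mean (the comparison table, best fit =
    highest mean).
    """
    from .validation import kfold_cv, make_folds

    folds = make_folds(data, k=k, seed=seed)
    rows = []
    for name in variants:
        make_variant(name)  # validate early
        score = kfold_cv(data, name, hyper=hyper, config=config, folds=folds, seed=seed)
        row = {"variant": name}
        row.update({f"fold_{j + 1}": v for j, v in enumerate(score.per_fold)})
        row["mean_log_predictive_likelihood"] = score.mean
        rows.append(row)
    return pd.DataFrame(rows)
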