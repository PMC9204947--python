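"""Grouped censored-survival data structures.

The central container is :class:`GroupedSurvivalData`: subjects are
partitioned into groups (e.g. disease cohorts), each subject carries a
strictly positive observed time, an event flag (``True`` = the event was
observed, ``False`` = right-censored, so the time is a censoring time) and a
covariate vector.  Covariate sets may differ between groups: the boolean
``availability`` matrix records, per group, which covariates are structurally
measured (the set :math:`S_i`), and the total number of coefficient slots is
:math:`M = \\sum_i |S_i|`.

On disk a dataset is one delimited table with a header row
``group, time, event, <covariate...>``; an empty covariate cell marks a
covariate that is structurally absent for that subject's group.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

RESERVED_COLUMNS = ("group", "time", "event", "survival_time", "censoring_time")

__all__ = [
    "GroupedSurvivalData",
    "Hyperparameters",
    "ChainConfig",
    "FilterReport",
    "StandardizationTransform",
    "filter_subjects",
    "standardize_predictors",
    "read_csv",
    "write_csv",
]


@dataclasses.dataclass
class Hyperparameters:
    """Prior settings of the hierarchical spike-and-slab survival model.

    Parameters
    ----------
    spike_var : float
        Variance :math:`z^2` of the near-point-mass spike at zero
        (default 1/10000).
    slab_mean_var : float
        Prior variance :math:`\\tau^2` of the slab mean
        :math:`\\tilde\\beta_\\ell \\sim N(0, \\tau^2)` (default 1).
    slab_var_shape, slab_var_rate : float
        Shape/rate :math:`(\\alpha_1, \\alpha_2)` of the inverse-gamma prior on
        the slab variance :math:`\\lambda^2_\\ell` (default 5, 1).
    intercept_mean_loc, intercept_mean_var : float
        Normal prior on the intercept hypermean :math:`\\tilde\\beta_0`
        (default N(0, 10^2)).
    intercept_var_shape, intercept_var_rate : float
        Inverse-gamma prior on the intercept hypervariance
        :math:`\\lambda^2_0` (default IG(1, 1)).
    error_var_shape, error_var_rate : float
        Inverse-gamma prior on the shared error variance :math:`\\sigma^2`
        (default IG(0.01, 0.01)).
    inclusion_a, inclusion_b : float
        Beta prior on the per-covariate inclusion probability
        :math:`\\pi_\\ell` (default Beta(1, 1)).
    """

    spike_var: float = 1.0 / 10000.0
    slab_mean_var: float = 1.0
    slab_var_shape: float = 5.0
    slab_var_rate: float = 1.0
    intercept_mean_loc: float = 0.0
    intercept_mean_var: float = 100.0
    intercept_var_shape: float = 1.0
    intercept_var_rate: float = 1.0
    error_var_shape: float = 0.01
    error_var_rate: float = 0.01
    inclusion_a: float = 1.0
    inclusion_b: float = 1.0

    def __post_init__(self) -> None:
        positive = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name != "intercept_mean_loc"
        }
        for name, value in positive.items():
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"hyperparameter {name!r} must be strictly positive, got {value}")
        if self.spike_var >= self.slab_mean_var:
            raise ValueError(
                "spike variance must be much smaller than the slab-mean prior variance "
                f"(got z²={self.spike_var} ≥ τ²={self.slab_mean_var})"
            )


@dataclasses.dataclass
class ChainConfig:
    """MCMC run length settings: iterations, burn-in, thinning, seed.

    ``n_retained`` is the number of post burn-in draws kept after thinning,
    T = (iterations − burn_in) // thin.  The same seed yields a bit-identical
    chain.
    """

    iterations: int = 10000
    burn_in: int = 5000
    thin: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.iterations <= 0:
            raise ValueError("iterations must be positive and burn_in non-negative")
        if self.burn_in >= self.iterations:
            raise ValueError(f"burn_in ({self.burn_in}) must be < iterations ({self.iterations})")
        if self.thin < 1:
            raise ValueError("thin must be ≥ 1")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclasses.dataclass
class GroupedSurvivalData:
    """Survival outcomes and covariates for I groups with per-group
    covariate availability.

    Attributes
    ----------
    group_ids : list
        Group labels, length I, in a fixed order.
    covariate_names : list of str
        Global covariate labels, length L.
    times : list of ndarray
        Per group, observed times ``y*`` (> 0): event time if the event was
        observed, censoring time otherwise.
    events : list of ndarray (bool)
        Per group, ``True`` where the event was observed.
    X : list of ndarray, shape (n_i, L)
        Per-group covariate matrices on the full covariate grid; entries in
        columns outside the group's availability set are zero and carry no
        information.
    availability : ndarray of bool, shape (I, L)
        ``availability[i, l]`` is True iff covariate ``l`` is measured on
        group ``i`` (``l`` in :math:`S_i`).
    """

    group_ids: list
    covariate_names: list
    times: list
    events: list
    X: list
    availability: np.ndarray

    def __post_init__(self) -> None:
        self.availability = np.asarray(self.availability, dtype=bool)
        self.times = [np.asarray(t, dtype=float) for t in self.times]
        self.events = [np.asarray(e, dtype=bool) for e in self.events]
        self.X = [np.asarray(x, dtype=float) for x in self.X]
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        I, L = len(self.group_ids), len(self.covariate_names)
        if self.availability.shape != (I, L):
            raise ValueError(f"availability must have shape ({I}, {L})")
        if not (len(self.times) == len(self.events) == len(self.X) == I):
            raise ValueError("per-group lists must all have length I")
        for i in range(I):
            n_i = self.times[i].shape[0]
            if self.events[i].shape[0] != n_i or self.X[i].shape != (n_i, L):
                raise ValueError(f"group {self.group_ids[i]!r}: inconsistent array shapes")
            if not np.all(self.times[i] > 0):
                raise ValueError(f"group {self.group_ids[i]!r}: all observed times must be > 0")
            if not np.all(np.isfinite(self.X[i][:, self.availability[i]])):
                raise ValueError(f"group {self.group_ids[i]!r}: non-finite covariate values")
        if L and not np.all(self.availability.any(axis=0)):
            missing = [self.covariate_names[j] for j in np.flatnonzero(~self.availability.any(axis=0))]
            raise ValueError(f"covariates available in no group: {missing}")

    # -- sizes ------------------------------------------------------------
    @property
    def n_groups(self) -> int:
        return len(self.group_ids)

    @property
    def n_covariates(self) -> int:
        return len(self.covariate_names)

    @property
    def n_per_group(self) -> np.ndarray:
        return np.array([t.shape[0] for t in self.times])

    @property
    def n_total(self) -> int:
        return int(self.n_per_group.sum())

    @property
    def n_coefficients(self) -> int:
        """Total number of coefficient slots, M = sum_i |S_i|."""
        return int(self.availability.sum())

    # -- manipulation -----------------------------------------------------
    def subset(self, indices_per_group: Sequence[np.ndarray]) -> "GroupedSurvivalData":
        """Return a copy restricted to the given per-group subject indices."""
        return GroupedSurvivalData(
            group_ids=list(self.group_ids),
            covariate_names=list(self.covariate_names),
            times=[self.times[i][idx] for i, idx in enumerate(indices_per_group)],
            events=[self.events[i][idx] for i, idx in enumerate(indices_per_group)],
            X=[self.X[i][idx] for i, idx in enumerate(indices_per_group)],
            availability=self.availability.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """One row per subject: group, time, event, covariates.

        Covariates outside a group's availability set are NaN (written as
        empty cells on disk).
        """
        frames = []
        for i, gid in enumerate(self.group_ids):
            x = self.X[i].copy()
            x[:, ~self.availability[i]] = np.nan
            frame = pd.DataFrame(x, columns=self.covariate_names)
            frame.insert(0, "event", self.events[i].astype(int))
            frame.insert(0, "time", self.times[i])
            frame.insert(0, "group", gid)
            frames.append(frame)
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GroupedSurvivalData":
        """Build from a tidy table with columns group, time, event, covariates.

        The availability set of each group is inferred: a covariate column
        that is entirely missing within a group is structurally absent for
        that group.  Partial missingness within a group is rejected — the
        model has no within-group missingness mechanism; use
        :func:`filter_subjects` to drop such records first.
        """
        required = {"group", "time", "event"}
        if not required.issubset(frame.columns):
            raise ValueError(f"table must contain columns {sorted(required)}")
        covariate_names = [c for c in frame.columns if c not in RESERVED_COLUMNS]
        group_ids = list(pd.unique(frame["group"]))
        times, events, X, avail = [], [], [], []
        for gid in group_ids:
            sub = frame.loc[frame["group"] == gid]
            cov = sub[covariate_names].to_numpy(dtype=float) if covariate_names else np.empty((len(sub), 0))
            present = ~np.isnan(cov) if covariate_names else np.empty((len(sub), 0), dtype=bool)
            col_avail = present.any(axis=0)
            partial = col_avail & ~present.all(axis=0)
            if partial.any():
                bad = [covariate_names[j] for j in np.flatnonzero(partial)]
                raise ValueError(
                    f"group {gid!r}: covariates {bad} are missing for some subjects but "
                    "not the whole group; filter those records first"
                )
            cov = np.where(np.isnan(cov), 0.0, cov) if covariate_names else cov
            times.append(sub["time"].to_numpy(dtype=float))
            events.append(sub["event"].to_numpy(dtype=float).astype(bool))
            X.append(cov)
            avail.append(col_avail)
        return cls(group_ids, covariate_names, times, events, X, np.array(avail))


# ---------------------------------------------------------------------------
# subject filtering


@dataclasses.dataclass
class FilterReport:
    """Counts of subjects removed by each filtering rule, in rule order."""

    n_input: int
    n_retained: int
    removed: dict

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def filter_subjects(raw: pd.DataFrame, required_covariates: Sequence[str] | None = None):
    """Apply the subject-level cleaning rules and build a validated dataset.

    Rules, in order:

    1. remove subjects missing both a survival time and a censoring time;
    2. remove subjects whose observed time is negative or zero;
    3. remove subjects missing a value for a covariate their group measures
       (e.g. age).

    ``raw`` may either carry separate ``survival_time`` / ``censoring_time``
    columns (a subject with only a censoring time is retained as censored),
    or already-derived ``time`` / ``event`` columns, in which case rule 1
    removes rows with a missing time.

    Returns ``(GroupedSurvivalData, FilterReport)``.  Idempotent: filtering
    an already-clean table removes nothing.
    """
    frame = raw.copy()
    n_input = len(frame)
    removed = {"missing_both_times": 0, "nonpositive_time": 0, "missing_covariate": 0}

    if "time" not in frame.columns:
        if not {"survival_time", "censoring_time"}.issubset(frame.columns):
            raise ValueError(
                "raw table needs either a 'time'/'event' pair or "
                "'survival_time'/'censoring_time' columns"
            )
        surv = pd.to_numeric(frame["survival_time"], errors="coerce")
        cens = pd.to_numeric(frame["censoring_time"], errors="coerce")
        both_missing = surv.isna() & cens.isna()
        removed["missing_both_times"] = int(both_missing.sum())
        frame = frame.loc[~both_missing].copy()
        surv, cens = surv[~both_missing], cens[~both_missing]
        frame["event"] = (~surv.isna()).astype(int)
        frame["time"] = surv.where(~surv.isna(), cens)
        frame = frame.drop(columns=["survival_time", "censoring_time"])
    else:
        if "event" not in frame.columns:
            raise ValueError("a 'time' column requires an 'event' column")
        frame["time"] = pd.to_numeric(frame["time"], errors="coerce")
        missing = frame["time"].isna()
        removed["missing_both_times"] = int(missing.sum())
        frame = frame.loc[~missing].copy()

    nonpositive = frame["time"] <= 0
    removed["nonpositive_time"] = int(nonpositive.sum())
    frame = frame.loc[~nonpositive].copy()

    covariate_names = [c for c in frame.columns if c not in RESERVED_COLUMNS]
    if required_covariates:
        missing_cols = set(required_covariates) - set(covariate_names)
        if missing_cols:
            raise ValueError(f"required covariate columns absent from table: {sorted(missing_cols)}")
    # Per group, a covariate with at least one observed value is treated as
    # measured on that group; subjects lacking it are then invalid records.
    drop = pd.Series(False, index=frame.index)
    for _, sub in frame.groupby("group", sort=False):
        cov = sub[covariate_names]
        available = [c for c in covariate_names if cov[c].notna().any()]
        if required_covariates:
            available = sorted(set(available) | set(required_covariates), key=covariate_names.index)
        if available:
            drop.loc[sub.index] = cov[available].isna().any(axis=1)
    removed["missing_covariate"] = int(drop.sum())
    frame = frame.loc[~drop]

    if frame.empty:
        raise ValueError("no subjects remain after filtering; input is unusable")
    data = GroupedSurvivalData.from_frame(frame.reset_index(drop=True))
    return data, FilterReport(n_input=n_input, n_retained=data.n_total, removed=removed)


# ---------------------------------------------------------------------------
# standardization


@dataclasses.dataclass
class StandardizationTransform:
    """Per-covariate centring/scaling actually applied, for inverse mapping.

    ``mean_`` and ``scale_`` are computed over the union of subjects whose
    group measures the covariate; ``scale_`` uses the sample standard
    deviation (divisor n−1).
    """

    covariate_names: list
    mean_: np.ndarray
    scale_: np.ndarray
    ddof: int = 1

    def inverse_coefficient(self, name: str, beta_standardized: float) -> float:
        """Map a coefficient on the standardized scale back to the raw scale."""
        j = self.covariate_names.index(name)
        return beta_standardized / self.scale_[j]


def standardize_predictors(data: GroupedSurvivalData, ddof: int = 1):
    """Centre and scale every covariate to mean 0, sd 1.

    Moments are pooled over all subjects possessing the covariate, across
    groups.  A zero-variance column raises ``ValueError`` (degenerate
    predictor).  Returns ``(standardized data, StandardizationTransform)``.
    """
    L = data.n_covariates
    mean = np.zeros(L)
    scale = np.ones(L)
    for j in range(L):
        groups = np.flatnonzero(data.availability[:, j])
        values = np.concatenate([data.X[i][:, j] for i in groups]) if groups.size else np.array([])
        if values.size == 0:
            continue
        mean[j] = values.mean()
        scale[j] = values.std(ddof=ddof) if values.size > ddof else 0.0
        if not scale[j] > 0:
            raise ValueError(
                f"covariate {data.covariate_names[j]!r} has zero variance; degenerate predictor"
            )
    new_X = []
    for i in range(data.n_groups):
        x = (data.X[i] - mean) / scale
        x[:, ~data.availability[i]] = 0.0
        new_X.append(x)
    out = GroupedSurvivalData(
        group_ids=list(data.group_ids),
        covariate_names=list(data.covariate_names),
        times=[t.copy() for t in data.times],
        events=[e.copy() for e in data.events],
        X=new_X,
        availability=data.availability.copy(),
    )
    return out, StandardizationTransform(list(data.covariate_names), mean, scale, ddof)


# ---------------------------------------------------------------------------
# on-disk round trip


def write_csv(data: GroupedSurvivalData, path, sep: str = ",") -> None:
    """Write a dataset as delimited text; floats keep full precision."""
    data.to_frame().to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_csv(path, sep: str = ",") -> GroupedSurvivalData:
    """Read a dataset written by :func:`write_csv` (or any conforming table)."""
    return GroupedSurvivalData.from_frame(
        pd.read_csv(path, sep=sep, float_precision="round_trip")
    )
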