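"""Predictors from low-rank modules of a bidimensionally-linked factorization.

A multi-source, multi-cohort data grid (sources × cohorts of matrices sharing
features within a source and samples within a cohort) can be decomposed into a
sum of low-rank *modules*, each explaining structured variation on a declared
subset of sources and cohorts, plus noise.  This module consumes such modules
(the factorization itself is produced upstream) and turns them into survival
predictors: the SVD of each module yields components, the product of a
singular value with its right singular vector gives per-sample *component
scores*, and components are kept when they explain enough of the total
variability of the original concatenated data.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import GroupedSurvivalData, RESERVED_COLUMNS, standardize_predictors

__all__ = [
    "LowRankModule",
    "ComponentPredictor",
    "module_svd",
    "component_scores",
    "select_components",
    "assemble_design",
]


@dataclasses.dataclass
class LowRankModule:
    """One low-rank module: a features × samples matrix with its block map.

    Parameters
    ----------
    index : int
        Module label k.
    values : ndarray, shape (p, n)
        The module matrix (rows: features of the spanned sources stacked;
        columns: samples of the spanned groups concatenated).
    groups : tuple
        Group (cohort) identifiers the module spans; blocks outside this
        span are exactly zero in the full grid and are not stored.
    sources : tuple
        Source (platform) identifiers the module spans.
    sample_ids : ndarray or None
        Per-column sample identifiers, used to align scores with subjects.
    sample_groups : ndarray or None
        Per-column group identifier (each must be in ``groups``).
    """

    index: int
    values: np.ndarray
    groups: tuple = ()
    sources: tuple = ()
    sample_ids: np.ndarray | None = None
    sample_groups: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("module matrix must be two-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"module {self.index}: non-finite entries")
        if self.sample_ids is not None:
            self.sample_ids = np.asarray(self.sample_ids)
            if self.sample_ids.shape[0] != self.values.shape[1]:
                raise ValueError("sample_ids must have one entry per matrix column")
        if self.sample_groups is not None:
            self.sample_groups = np.asarray(self.sample_groups)
            if set(map(str, np.unique(self.sample_groups))) - set(map(str, self.groups)):
                raise ValueError("sample_groups contains groups outside the module's span")

    @property
    def rank(self) -> int:
        d = module_svd(self)[0]
        if d.size == 0:
            return 0
        tol = d[0] * max(self.values.shape) * np.finfo(float).eps
        return int(np.sum(d > tol))


@dataclasses.dataclass
class ComponentPredictor:
    """One component of a module's SVD, as a per-sample predictor.

    ``scores = d_r * v_r`` (singular value times right singular vector, one
    entry per sample of the module's group span), with a deterministic sign:
    the largest-magnitude entry of ``v_r`` is made positive.  The label is
    "k.r", e.g. "16.1" for the first component of module 16.
    """

    module_index: int
    rank: int
    scores: np.ndarray
    eigenvalue_ratio: float | None = None
    groups: tuple = ()
    sample_ids: np.ndarray | None = None

    @property
    def label(self) -> str:
        return f"{self.module_index}.{self.rank}"


def module_svd(module: LowRankModule):
    """SVD of the module matrix.

    Returns ``(d, U, V)`` with singular values ``d`` sorted descending,
    ``U`` of shape (p, m) (loadings) and ``V`` of shape (n, m) so that
    ``U @ diag(d) @ V.T`` reconstructs the matrix.
    """
    U, d, Vt = np.linalg.svd(module.values, full_matrices=False)
    return d, U, Vt.T


def _canonical_sign(u: np.ndarray, v: np.ndarray):
    # Singular vectors are defined only up to a joint sign flip of (u, v);
    # pin the largest-|.| entry of v positive for reproducibility.
    j = int(np.argmax(np.abs(v)))
    if v[j] < 0:
        return -u, -v
    return u, v


def component_scores(
    module: LowRankModule, r: int, total_ss: float | None = None
) -> ComponentPredictor:
    """Scores of the ``r``-th component (1-based) of a module.

    ``total_ss``, if given, is the squared Frobenius norm of the full
    concatenated multi-source data and yields the component's eigenvalue
    ratio :math:`d_r^2 / \\text{total SS}`.
    """
    d, U, V = module_svd(module)
    if r < 1 or r > module.rank:
        raise ValueError(f"component rank {r} exceeds module rank {module.rank}")
    _, v = _canonical_sign(U[:, r - 1], V[:, r - 1])
    ratio = None if total_ss is None else float(d[r - 1] ** 2 / total_ss)
    return ComponentPredictor(
        module_index=module.index,
        rank=r,
        scores=d[r - 1] * v,
        eigenvalue_ratio=ratio,
        groups=tuple(module.groups),
        sample_ids=None if module.sample_ids is None else module.sample_ids.copy(),
    )


def select_components(
    modules: Iterable[LowRankModule], total_ss: float, threshold: float = 0.01
) -> list:
    """Apply the two component-inclusion rules across modules.

    Per module: keep component 1 unconditionally (it explains the most
    variation within the module); additionally keep any component r ≥ 2 whose
    eigenvalue (squared singular value) exceeds ``threshold`` as a fraction
    of ``total_ss``, the total sum of squares of the original multi-source,
    multi-cohort data.  All-zero modules contribute nothing.  Lowering the
    threshold never removes a selected component.
    """
    if not total_ss > 0:
        raise ValueError("total_ss must be positive")
    selected = []
    for module in modules:
        rank = module.rank
        if rank == 0:
            continue
        d = module_svd(module)[0]
        ratios = d**2 / total_ss
        for r in range(1, rank + 1):
            if r == 1 or ratios[r - 1] > threshold:
                selected.append(component_scores(module, r, total_ss))
    return selected


def assemble_design(
    components: Sequence[ComponentPredictor],
    base: pd.DataFrame,
    clinical_covariates: Sequence[str] = ("age",),
    standardize: bool = True,
):
    """Combine component scores and clinical covariates into a survival design.

    Parameters
    ----------
    components : sequence of ComponentPredictor
        Each must carry ``sample_ids``; its scores become a covariate
        available exactly for the groups its module spans.
    base : DataFrame
        One row per subject, indexed by sample id, with columns ``group``,
        ``time``, ``event`` and the clinical covariate columns.
    clinical_covariates : sequence of str
        Columns of ``base`` appended to every group's covariate set.
    standardize : bool
        Standardize all predictor columns to mean 0, sd 1 (pooled over the
        subjects possessing each column).

    Returns ``(GroupedSurvivalData, StandardizationTransform or None)``.
    """
    for col in ("group", "time", "event"):
        if col not in base.columns:
            raise ValueError(f"base table must contain a {col!r} column")
    frame = base[["group", "time", "event"]].copy()
    for name in clinical_covariates:
        if name not in base.columns:
            raise ValueError(f"clinical covariate {name!r} not in base table")
        frame[name] = base[name]
    group_of = base["group"]
    for comp in components:
        if comp.sample_ids is None:
            raise ValueError(f"component {comp.label}: sample_ids required to align with subjects")
        ids = pd.Index(comp.sample_ids)
        if ids.has_duplicates or not ids.isin(base.index).all():
            raise ValueError(f"component {comp.label}: sample ids do not align with the base table")
        expected = set(base.index[group_of.astype(str).isin({str(g) for g in comp.groups})])
        if set(ids) != expected:
            raise ValueError(
                f"component {comp.label}: samples do not cover exactly the subjects "
                f"of its group span {comp.groups}"
            )
        if comp.label in frame.columns or comp.label in RESERVED_COLUMNS:
            raise ValueError(f"duplicate predictor label {comp.label!r}")
        frame[comp.label] = pd.Series(comp.scores, index=ids)
    data = GroupedSurvivalData.from_frame(frame.reset_index(drop=True))
    if not standardize:
        return data, None
    return standardize_predictors(data)
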