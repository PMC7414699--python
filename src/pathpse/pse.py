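"""Standardized per-group path effects and the two-group PSE statistic.

For two disjoint samples (case g = 1, control g = 0) the standardized
path-specific effect in group g is

    PSE_g = ACE_g(path) / S_{ACE_g(path)},

the product-form path effect divided by its standard error, and the test
statistic for H0: PSE_1 = PSE_0 is the studentized difference

    PSE = (PSE_1 - PSE_0) / sqrt(Var(PSE_1 - PSE_0)).

The standard error S_ACE is estimated either by a nonparametric bootstrap
within the group (default for reporting) or by the delta-method product
formula (used inside heavy resampling loops).  Because the groups are
disjoint samples, Var(PSE_1 - PSE_0) is estimated as Var(PSE_1) + Var(PSE_0)
from the two independent per-group bootstraps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from ._engine import PathEngine
from .ace import EstimationError, PathACE, infer_kinds, path_ace_from_data
from .graph import AdjustmentPlan, SpecificPath

__all__ = [
    "GroupedDataset",
    "PathEffectPair",
    "ace_standard_error",
    "pse_per_group",
    "pse_statistic",
]


@dataclass(frozen=True)
class GroupedDataset:
    """A data table with a binary condition column (case vs control)."""

    data: pd.DataFrame
    group_col: str
    case: object = 1
    control: object = 0

    def __post_init__(self) -> None:
        if self.group_col not in self.data.columns:
            raise EstimationError(f"group column {self.group_col!r} not in data")
        vals = set(pd.unique(self.data[self.group_col]))
        if not vals <= {self.case, self.control}:
            raise EstimationError(
                f"group column has values {sorted(map(repr, vals))}, expected "
                f"{{{self.case!r}, {self.control!r}}}"
            )
        n1, n0 = len(self.case_indices()), len(self.control_indices())
        if n1 == 0 or n0 == 0:
            empty = repr(self.case) if n1 == 0 else repr(self.control)
            raise EstimationError(f"group {empty} is empty")

    def case_indices(self) -> np.ndarray:
        return np.flatnonzero(self.data[self.group_col].to_numpy() == self.case)

    def control_indices(self) -> np.ndarray:
        return np.flatnonzero(self.data[self.group_col].to_numpy() == self.control)

    def swapped(self) -> "GroupedDataset":
        return GroupedDataset(self.data, self.group_col, self.control, self.case)


@dataclass(frozen=True)
class PathEffectPair:
    """Per-group standardized path effects and (optionally) their contrast."""

    ace1: PathACE
    ace0: PathACE
    se1: float
    se0: float
    pse1: float
    pse0: float
    var_pse1: float | None = None
    var_pse0: float | None = None
    statistic: float | None = None


def build_engine(
    data: pd.DataFrame,
    path: SpecificPath,
    plan: AdjustmentPlan,
    kinds: Mapping[str, str] | None = None,
    effect_scale: str = "rd",
) -> PathEngine:
    """Construct the resampling engine for one path and adjustment plan."""
    cols = set(path.nodes) | set(plan.confounders)
    if kinds is None:
        kinds = infer_kinds(data, cols)
    return PathEngine(
        data,
        edges=path.edges,
        covariates={e: plan.covariates(e) for e in path.edges},
        child_kinds=kinds,
        effect_scale=effect_scale,
    )


def ace_standard_error(
    data: pd.DataFrame,
    path: SpecificPath,
    plan: AdjustmentPlan,
    B: int = 500,
    seed: int | np.random.Generator | None = None,
    kinds: Mapping[str, str] | None = None,
) -> float:
    """Bootstrap standard error of the path-specific effect on one sample.

    Resamples the rows with replacement B times (B >= 100), re-estimates the
    path product on each resample, and returns the standard deviation of the
    draws.  Degenerate resamples (a constant edge regressor) are skipped and
    counted; more than 10% skips is an error.  Deterministic at a fixed seed.
    """
    if B < 100:
        raise ValueError(f"B={B} is too small; need B >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    engine = build_engine(data, path, plan, kinds)
    idx = np.arange(len(data))
    return engine.bootstrap_se(idx, B, rng)


def pse_per_group(
    grouped: GroupedDataset,
    path: SpecificPath,
    plan: AdjustmentPlan,
    B: int = 500,
    seed: int | None = None,
    se_method: str = "bootstrap",
    kinds: Mapping[str, str] | None = None,
) -> PathEffectPair:
    """Standardized path effect in each group, computed on that group only.

    Also records a bootstrap estimate of Var(PSE_g) (the variance of the
    standardized quantity itself) for the studentized two-group statistic;
    the within-draw standardization uses the delta-method SE to keep the
    bootstrap single-level.
    """
    data = grouped.data
    idx1 = grouped.case_indices()
    idx0 = grouped.control_indices()
    n_cov = len(plan.confounders)
    for label, idx in ((grouped.case, idx1), (grouped.control, idx0)):
        if len(idx) <= n_cov + 2:
            raise EstimationError(
                f"group {label!r} has only {len(idx)} rows for {n_cov} covariates"
            )
    if kinds is None:
        kinds = infer_kinds(data, set(path.nodes) | set(plan.confounders))
    engine = build_engine(data, path, plan, kinds)
    rng = np.random.default_rng(seed)

    out = {}
    for tag, idx in (("1", idx1), ("0", idx0)):
        est, se = engine.path_ace_se(idx, se_method=se_method, B_se=B, rng=rng)
        if se <= 0 or not np.isfinite(se):
            raise EstimationError(f"zero path-effect SE in group {tag}")
        # detailed per-edge estimates for reporting
        ace = path_ace_from_data(
            data.iloc[idx], path, plan, kinds=kinds
        )
        ace = PathACE(
            path=ace.path, edge_aces=ace.edge_aces, estimate=ace.estimate,
            scale_divisor=ace.scale_divisor, se=se,
        )
        std_draws = engine.bootstrap_draws(idx, B, rng, standardized=True)
        out[tag] = (ace, se, est / se, float(np.var(std_draws, ddof=1)))

    ace1, se1, pse1, var1 = out["1"]
    ace0, se0, pse0, var0 = out["0"]
    return PathEffectPair(
        ace1=ace1, ace0=ace0, se1=se1, se0=se0,
        pse1=pse1, pse0=pse0, var_pse1=var1, var_pse0=var0,
    )


def pse_statistic(pair: PathEffectPair, var_estimate: float | None = None) -> float:
    """Studentized two-group statistic (PSE_1 - PSE_0) / sqrt(Var).

    ``var_estimate`` defaults to the sum of the per-group bootstrap variances
    of the standardized effects (the groups are independent samples).
    Antisymmetric under swapping the group labels.
    """
    if var_estimate is None:
        if pair.var_pse1 is None or pair.var_pse0 is None:
            raise EstimationError("no variance estimate available")
        var_estimate = pair.var_pse1 + pair.var_pse0
    if var_estimate <= 0 or not np.isfinite(var_estimate):
        raise EstimationError(f"variance estimate must be positive, got {var_estimate}")
    return float((pair.pse1 - pair.pse0) / np.sqrt(var_estimate))
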