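"""Per-edge average causal effects and their product-form path combination.

For a directed path X1 -> X2 -> ... -> XK -> Y in a causal DAG, each edge
(A, B) carries an average causal effect identified by back-door adjustment
for parents(B) \\ {A}:

* continuous child: the partial derivative dE(B | A, C)/dA, estimated as the
  coefficient of A in a least-squares fit of B on (A, C);
* binary child: the standardized risk difference
  sum_c [P(B=1 | A=x', c) - P(B=1 | A=x'', c)] P(c);
* ordered discrete child: the mean difference written as a sum of CDF
  differences over adjacent levels.

The path-specific effect is the product of the per-edge effects divided by
prod_i (x_i' - x_i'') over interior mediators estimated on a level-contrast
scale; with the derivative convention each slope is already a unit-change
effect and the divisor is 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._glm import (
    CollinearityError,
    FitError,
    logistic_fit,
    ols_fit,
    standardized_risk_difference,
)
from .graph import AdjustmentPlan, CausalDAG, SpecificPath

__all__ = [
    "EdgeACE",
    "PathACE",
    "EstimationError",
    "CollinearityError",
    "edge_ace_continuous",
    "edge_ace_binary",
    "edge_ace_discrete",
    "path_ace",
    "path_ace_from_data",
    "total_ace",
    "infer_kinds",
]


class EstimationError(RuntimeError):
    """An effect could not be estimated from the data at hand."""


@dataclass(frozen=True)
class EdgeACE:
    """Back-door-adjusted average causal effect of one directed edge."""

    edge: tuple[str, str]
    estimate: float
    contrast: tuple[float, float] | None = None
    n_used: int = 0
    se: float | None = None
    scale: str = "slope"  # slope | risk_difference | mean_difference | coef

    def __post_init__(self) -> None:
        if not np.isfinite(self.estimate):
            raise EstimationError(f"non-finite estimate for edge {self.edge}")
        if self.contrast is not None and self.contrast[0] == self.contrast[1]:
            # a declared contrast with x' == x'' is only legal for the zero effect
            if self.estimate != 0.0:
                raise EstimationError("contrast x' == x'' with nonzero estimate")


@dataclass(frozen=True)
class PathACE:
    """Product-form path-specific effect with its per-edge factors."""

    path: tuple[str, ...]
    edge_aces: tuple[EdgeACE, ...]
    estimate: float
    scale_divisor: float = 1.0
    se: float | None = None


def infer_kinds(data: pd.DataFrame, columns: Iterable[str]) -> dict[str, str]:
    """Crude variable-kind inference: {0,1}-valued -> binary, else continuous."""
    kinds = {}
    for c in columns:
        vals = pd.unique(data[c].dropna())
        kinds[c] = "binary" if set(np.asarray(vals).tolist()) <= {0, 1} else "continuous"
    return kinds


def _design(
    data: pd.DataFrame,
    child: str,
    parent: str,
    covariates: Sequence[str],
    dropna: bool,
) -> tuple[np.ndarray, np.ndarray, int]:
    cols = [child, parent, *covariates]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise EstimationError(f"columns not in data: {missing}")
    sub = data[cols]
    if sub.isna().any().any():
        if not dropna:
            raise EstimationError(
                f"missing values in columns {sorted(sub.columns[sub.isna().any()])}; "
                "pass dropna=True for complete-case analysis"
            )
        sub = sub.dropna()
    n = len(sub)
    X = np.column_stack([np.ones(n)] + [sub[c].to_numpy(dtype=float) for c in cols[1:]])
    y = sub[child].to_numpy(dtype=float)
    return X, y, n


def _name_collinear(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Columns linearly dependent on the preceding ones (for error messages)."""
    bad = []
    for j in range(1, X.shape[1]):
        sub = X[:, : j + 1]
        if np.linalg.matrix_rank(sub) < j + 1:
            bad.append(names[j - 1] if j - 1 < len(names) else f"col{j}")
    return bad


def edge_ace_continuous(
    data: pd.DataFrame,
    edge: tuple[str, str],
    covariates: Sequence[str] = (),
    dropna: bool = False,
) -> EdgeACE:
    """Slope of the child on the parent, adjusting for the covariates.

    The estimate is dE(B | A, C)/dA from the least-squares fit of B on
    (A, C); on this derivative scale the edge contributes divisor 1 to the
    path product.
    """
    parent, child = edge
    X, y, n = _design(data, child, parent, covariates, dropna)
    if n <= len(covariates) + 2:
        raise EstimationError(
            f"n={n} too small for edge {parent}->{child} with "
            f"{len(covariates)} covariates"
        )
    if np.ptp(y) == 0.0:
        return EdgeACE(edge=edge, estimate=0.0, n_used=n, se=0.0, scale="slope")
    try:
        beta, cov, _ = ols_fit(X, y)
    except CollinearityError:
        names = [parent, *covariates]
        bad = _name_collinear(X, names)
        raise CollinearityError(
            f"collinear design for edge {parent}->{child}: columns {bad}"
        ) from None
    return EdgeACE(
        edge=edge,
        estimate=float(beta[1]),
        n_used=n,
        se=float(np.sqrt(max(cov[1, 1], 0.0))),
        scale="slope",
    )


def _stratified_rd(
    X: np.ndarray, y: np.ndarray, x_hi: float, x_lo: float
) -> float:
    """Nonparametric standardized risk difference over covariate strata.

    X columns: [1, A, C...].  Strata are the observed covariate cells; an
    empty (A = x, C = c) cell with nonzero cell weight is an error.
    """
    a = X[:, 1]
    if X.shape[1] > 2:
        cells, inverse = np.unique(X[:, 2:], axis=0, return_inverse=True)
    else:
        cells, inverse = np.zeros((1, 0)), np.zeros(len(a), dtype=int)
    n = len(a)
    total = 0.0
    for k in range(len(cells)):
        mask = inverse == k
        w = mask.sum() / n
        hi = mask & (a == x_hi)
        lo = mask & (a == x_lo)
        if hi.sum() == 0 or lo.sum() == 0:
            raise EstimationError(
                f"empty stratum for parent level {x_hi if hi.sum() == 0 else x_lo} "
                f"in covariate cell {cells[k].tolist()} (weight {w:.3f}); "
                "use the model-based estimator to extrapolate"
            )
        total += w * (y[hi].mean() - y[lo].mean())
    return float(total)


def edge_ace_binary(
    data: pd.DataFrame,
    edge: tuple[str, str],
    covariates: Sequence[str] = (),
    x_hi: float = 1.0,
    x_lo: float = 0.0,
    estimator: str = "model",
    dropna: bool = False,
) -> EdgeACE:
    """Standardized risk difference for a binary child.

    estimator="model" (default) fits a main-effects logistic model of the
    child on (A, C) and averages predicted risks over the empirical covariate
    distribution; estimator="stratified" evaluates the nonparametric sum over
    observed covariate strata directly (and is the oracle the model-based
    route is tested against).
    """
    parent, child = edge
    X, y, n = _design(data, child, parent, covariates, dropna)
    vals = set(np.unique(y).tolist())
    if not vals <= {0.0, 1.0}:
        raise EstimationError(f"child {child} is not binary: values {sorted(vals)}")
    if x_hi == x_lo:
        return EdgeACE(edge=edge, estimate=0.0, contrast=(x_hi, x_lo), n_used=n,
                       se=0.0, scale="risk_difference")
    if estimator == "stratified":
        est = _stratified_rd(X, y, x_hi, x_lo)
        se = None
    elif estimator == "model":
        if len(vals) == 1:
            est, se = 0.0, 0.0
        else:
            try:
                beta, cov = logistic_fit(X, y)
            except CollinearityError:
                bad = _name_collinear(X, [parent, *covariates])
                raise CollinearityError(
                    f"collinear design for edge {parent}->{child}: columns {bad}"
                ) from None
            est, var = standardized_risk_difference(X, beta, cov, 1, x_hi, x_lo)
            se = float(np.sqrt(var))
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    if not -1.0 - 1e-9 <= est <= 1.0 + 1e-9:
        raise EstimationError(f"risk difference {est} outside [-1, 1]")
    return EdgeACE(
        edge=edge,
        estimate=float(np.clip(est, -1.0, 1.0)),
        contrast=(x_hi, x_lo),
        n_used=n,
        se=se,
        scale="risk_difference",
    )


def edge_ace_discrete(
    data: pd.DataFrame,
    edge: tuple[str, str],
    covariates: Sequence[str] = (),
    x_hi: float = 1.0,
    x_lo: float = 0.0,
    levels: Sequence[float] | None = None,
    estimator: str = "stratified",
    dropna: bool = False,
) -> EdgeACE:
    """Mean-difference ACE for an ordered discrete child via CDF differences.

    With ordered levels m = 0..M the mean difference decomposes as
    sum_{m<M} [F(m | c, x'') - F(m | c, x')] averaged over strata; for M = 1
    this reduces exactly to the binary standardized risk difference.
    ``levels`` must be an ordered sequence (sets are rejected: the CDF form
    requires an ordering).
    """
    parent, child = edge
    if levels is not None and isinstance(levels, (set, frozenset)):
        raise EstimationError(
            "levels must be an ordered sequence; got an unordered set"
        )
    X, y, n = _design(data, child, parent, covariates, dropna)
    obs = np.unique(y)
    if levels is None:
        levels = obs.tolist()
    levels = [float(v) for v in levels]
    if sorted(levels) != levels:
        raise EstimationError("declared levels are not in increasing order")
    if not set(obs.tolist()) <= set(levels):
        raise EstimationError(f"observed values {obs.tolist()} outside levels {levels}")
    if len(obs) <= 1 or x_hi == x_lo:
        return EdgeACE(edge=edge, estimate=0.0, contrast=(x_hi, x_lo), n_used=n,
                       scale="mean_difference")

    thresholds = levels[:-1]
    steps = np.diff(levels)
    a = X[:, 1]
    if estimator == "stratified":
        if X.shape[1] > 2:
            cells, inverse = np.unique(X[:, 2:], axis=0, return_inverse=True)
        else:
            cells, inverse = np.zeros((1, 0)), np.zeros(n, dtype=int)
        est = 0.0
        for k in range(len(cells)):
            mask = inverse == k
            w = mask.sum() / n
            hi = mask & (a == x_hi)
            lo = mask & (a == x_lo)
            if hi.sum() == 0 or lo.sum() == 0:
                raise EstimationError(
                    f"empty stratum in covariate cell {cells[k].tolist()}"
                )
            for m, step in zip(thresholds, steps):
                f_hi = np.mean(y[hi] <= m)
                f_lo = np.mean(y[lo] <= m)
                est += w * step * (f_lo - f_hi)
    elif estimator == "model":
        # one logistic standardization per CDF threshold
        est = 0.0
        for m, step in zip(thresholds, steps):
            ym = (y <= m).astype(float)
            if np.ptp(ym) == 0.0:
                continue
            beta, cov = logistic_fit(X, ym)
            d, _ = standardized_risk_difference(X, beta, cov, 1, x_hi, x_lo)
            est += step * (-d)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return EdgeACE(
        edge=edge,
        estimate=float(est),
        contrast=(x_hi, x_lo),
        n_used=n,
        scale="mean_difference",
    )


def path_ace(
    edge_aces: Sequence[EdgeACE],
    mediator_contrasts: Sequence[tuple[float, float]] = (),
    path: Sequence[str] | None = None,
) -> PathACE:
    """Combine per-edge effects into the product-form path effect.

    ``mediator_contrasts`` lists (x_i', x_i'') for each interior mediator
    whose downstream edge was estimated on a level-contrast scale; the
    product of edge estimates is divided by prod_i (x_i' - x_i'').  Under the
    derivative (slope) convention no contrasts are supplied and the divisor
    is 1.
    """
    if not edge_aces:
        raise EstimationError("a path needs at least one edge effect")
    divisor = 1.0
    for hi, lo in mediator_contrasts:
        divisor *= hi - lo
    if divisor == 0.0:
        raise EstimationError("zero scale divisor: some contrast has x' == x''")
    prod = 1.0
    for ea in edge_aces:
        prod *= ea.estimate
    nodes = tuple(path) if path is not None else tuple(
        [edge_aces[0].edge[0]] + [ea.edge[1] for ea in edge_aces]
    )
    return PathACE(
        path=nodes,
        edge_aces=tuple(edge_aces),
        estimate=prod / divisor,
        scale_divisor=divisor,
    )


def path_ace_from_data(
    data: pd.DataFrame,
    path: SpecificPath,
    plan: AdjustmentPlan,
    kinds: Mapping[str, str] | None = None,
    dropna: bool = False,
    estimator: str = "model",
) -> PathACE:
    """Estimate every edge of a specific path and form the product.

    Each edge uses the slope estimator for a continuous child and the
    standardized risk difference (contrast 1 vs 0) for a binary child; both
    are unit-change effects, so the scale divisor is 1.
    """
    if kinds is None:
        kinds = infer_kinds(data, path.nodes)
    aces = []
    for edge in path.edges:
        cov = plan.covariates(edge)
        child_kind = kinds.get(edge[1], "continuous")
        if child_kind == "binary":
            aces.append(edge_ace_binary(data, edge, cov, estimator=estimator,
                                        dropna=dropna))
        else:
            aces.append(edge_ace_continuous(data, edge, cov, dropna=dropna))
    return path_ace(aces, path=path.nodes)


def total_ace(
    data: pd.DataFrame,
    exposure: str,
    outcome: str,
    covariates: Sequence[str] | None = None,
    dag: CausalDAG | None = None,
    kinds: Mapping[str, str] | None = None,
    dropna: bool = False,
) -> EdgeACE:
    """Total causal effect of the exposure on the outcome.

    Back-door adjustment uses the exposure's parents (taken from ``dag`` when
    ``covariates`` is not given); for a root exposure this is the unadjusted
    contrast.  The total effect sums transmission over every directed route,
    which is what makes it blind to redistributions of effect among parallel
    paths that the path-specific statistic is designed to detect.
    """
    if exposure == outcome:
        raise EstimationError("exposure and outcome must differ")
    if covariates is None:
        covariates = dag.parents(exposure) if dag is not None else ()
    if kinds is None:
        kinds = infer_kinds(data, [outcome])
    if kinds.get(outcome, "continuous") == "binary":
        return edge_ace_binary(data, (exposure, outcome), covariates, dropna=dropna)
    return edge_ace_continuous(data, (exposure, outcome), covariates, dropna=dropna)
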