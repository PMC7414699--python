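"""Permutation and bootstrap tests of H0: PSE_1 = PSE_0.

The permutation test reassigns the case/control labels across rows without
replacement (group sizes fixed), recomputes the difference of standardized
per-group path effects for each reassignment, and locates the observed
difference in that null distribution; the two-sided p-value uses the add-one
convention (1 + #{|T_b| >= |T_obs|}) / (B + 1).

The bootstrap tests resample rows with replacement within each group,
compute theta* = PSE_1 - PSE_0 per resample, and reject when the chosen 95%
interval excludes zero.  Four intervals are provided with names mapped to
the formulas as this method family prints them:

* ``normal``      theta_hat -/+ z_{1-alpha/2} * se_B(theta*)
* ``basic``       (theta*_[(B+1)alpha/2], theta*_[(B+1)(1-alpha/2)])
* ``percentile``  (2 theta_hat - theta*_[(B+1)(1-alpha/2)],
                   2 theta_hat - theta*_[(B+1)alpha/2])
* ``bca``         order statistics at Phi-corrected quantiles using the
                  median-bias constant z0 and jackknife acceleration a.

Note the ``basic``/``percentile`` labels are swapped relative to the most
common textbook convention; ``METHOD_ALIASES`` maps the conventional names
onto these formulas.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import comb
from typing import Mapping, Sequence

import numpy as np
from scipy.special import ndtr, ndtri

from ._engine import PathEngine
from .ace import CollinearityError, EstimationError
from .graph import AdjustmentPlan, SpecificPath
from .pse import GroupedDataset, build_engine

__all__ = [
    "PSETestResult",
    "permutation_test",
    "bootstrap_test",
    "bca_constants",
    "BOOTSTRAP_METHODS",
    "METHOD_ALIASES",
]

BOOTSTRAP_METHODS = ("normal", "basic", "percentile", "bca")
# conventional textbook name -> name used here (formula as printed)
METHOD_ALIASES = {"percentile_classic": "basic", "basic_classic": "percentile"}


@dataclass(frozen=True)
class PSETestResult:
    """Outcome of one two-group path-specific effect test."""

    method: str
    statistic: float
    p_value: float | None
    ci: tuple[float, float] | None
    reject: bool
    B: int
    alpha: float
    seed: int | None = None
    info: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ci is not None and self.ci[0] > self.ci[1]:
            raise ValueError(f"CI lower bound exceeds upper: {self.ci}")


def _indices(grouped: GroupedDataset) -> tuple[np.ndarray, np.ndarray]:
    return grouped.case_indices(), grouped.control_indices()


def _statistic(engine: PathEngine, idx1, idx0, se_method, B_se, rng) -> float:
    return engine.pse_difference(idx1, idx0, se_method=se_method, B_se=B_se, rng=rng)


def _statistic_batch(engine, mat1, mat0, se_method, B_se, rng):
    """Statistic over stacked subset pairs; returns (finite draws, n skipped).

    Delta standardization evaluates all subsets in one batched pass; the
    bootstrap-SE variant falls back to a per-subset loop.
    """
    if se_method == "delta":
        t = engine.pse_batch(mat1) - engine.pse_batch(mat0)
        finite = np.isfinite(t)
        return t[finite], int((~finite).sum())
    draws = []
    skipped = 0
    for i1, i0 in zip(mat1, mat0):
        try:
            draws.append(_statistic(engine, i1, i0, se_method, B_se, rng))
        except (EstimationError, CollinearityError):
            skipped += 1
    return np.asarray(draws), skipped


def permutation_test(
    grouped: GroupedDataset,
    path: SpecificPath,
    plan: AdjustmentPlan,
    B: int = 999,
    alpha: float = 0.05,
    seed: int | None = None,
    se_method: str = "delta",
    B_se: int = 200,
    exact: bool = False,
    kinds: Mapping[str, str] | None = None,
    engine: PathEngine | None = None,
    max_exact: int = 200_000,
) -> PSETestResult:
    """Permutation test of H0: PSE_1 = PSE_0 on one specific path.

    ``exact=True`` enumerates every assignment of the case labels (guarded by
    ``max_exact``); otherwise B random label permutations are drawn.  The
    statistic is the unstandardized difference PSE_1 - PSE_0 of the per-group
    standardized path effects.
    """
    if not exact and B < 99:
        raise ValueError(f"B={B} is too small; need B >= 99")
    rng = np.random.default_rng(seed)
    if engine is None:
        engine = build_engine(grouped.data, path, plan, kinds)
    idx1, idx0 = _indices(grouped)
    n1 = len(idx1)
    pool = np.concatenate([idx1, idx0])

    t_obs = _statistic(engine, idx1, idx0, se_method, B_se, rng)

    if exact:
        total = comb(len(pool), n1)
        if total > max_exact:
            raise EstimationError(
                f"{total} label assignments exceed max_exact={max_exact}"
            )
        pool_sorted = np.sort(pool)
        assigns = np.zeros((total, len(pool)), dtype=bool)
        for r, picked in enumerate(itertools.combinations(range(len(pool)), n1)):
            assigns[r, list(picked)] = True
        mat1 = np.stack([pool_sorted[m] for m in assigns])
        mat0 = np.stack([pool_sorted[~m] for m in assigns])
    else:
        perms = np.stack([rng.permutation(pool) for _ in range(B)])
        mat1, mat0 = perms[:, :n1], perms[:, n1:]

    draws, skipped = _statistic_batch(engine, mat1, mat0, se_method, B_se, rng)
    n_perm = len(draws)
    count = int(np.sum(np.abs(draws) >= abs(t_obs) - 1e-12))
    if exact:
        p = count / n_perm
    else:
        if skipped > 0.1 * B:
            raise EstimationError(
                f"path inestimable in {skipped}/{B} permutations"
            )
        p = (1 + count) / (n_perm + 1)

    return PSETestResult(
        method="permutation",
        statistic=t_obs,
        p_value=float(p),
        ci=None,
        reject=bool(p < alpha),
        B=n_perm,
        alpha=alpha,
        seed=seed,
        info={"n_skipped": skipped, "exact": exact},
    )


def _order_statistic(sorted_draws: np.ndarray, q: float) -> float:
    """theta*_[(B+1)q] with the index clipped into [1, B]."""
    B = len(sorted_draws)
    k = int(np.ceil((B + 1) * q))
    k = min(max(k, 1), B)
    return float(sorted_draws[k - 1])


def bca_constants(
    theta_hat: float,
    boot_draws: Sequence[float],
    jackknife_draws: Sequence[float],
) -> tuple[float, float]:
    """Median-bias constant z0 and jackknife acceleration a for BCa.

    z0 = Phi^-1(#{theta* < theta_hat} / B); a is the jackknife skewness
    a = sum (theta_bar - theta_-i)^3 / (6 [sum (theta_bar - theta_-i)^2]^1.5).
    Raises if every bootstrap draw falls on one side of theta_hat (z0 would
    be infinite: increase B) or if the jackknife variance is zero.
    """
    boot = np.asarray(boot_draws, dtype=float)
    jack = np.asarray(jackknife_draws, dtype=float)
    if len(jack) < 3:
        raise ValueError("need at least 3 jackknife draws")
    B = len(boot)
    below = int(np.sum(boot < theta_hat))
    if below == 0 or below == B:
        raise EstimationError(
            "all bootstrap draws on one side of the estimate; "
            "z0 is infinite - increase B"
        )
    z0 = float(ndtri(below / B))
    d = jack.mean() - jack
    denom = np.sum(d**2) ** 1.5
    if denom == 0.0:
        raise EstimationError("zero jackknife variance; acceleration undefined")
    a = float(np.sum(d**3) / (6.0 * denom))
    return z0, a


def _bca_interval(theta_hat, sorted_draws, z0, a, alpha):
    z_lo = ndtri(alpha / 2.0)
    z_hi = ndtri(1.0 - alpha / 2.0)
    q_lo = float(ndtr(z0 + (z0 + z_lo) / (1.0 - a * (z0 + z_lo))))
    q_hi = float(ndtr(z0 + (z0 + z_hi) / (1.0 - a * (z0 + z_hi))))
    return (
        _order_statistic(sorted_draws, q_lo),
        _order_statistic(sorted_draws, q_hi),
    )


def _ci_from_draws(method, theta_hat, draws, alpha, z0=None, a=None):
    """One confidence interval from a fixed set of bootstrap draws."""
    draws = np.asarray(draws, dtype=float)
    s = np.sort(draws)
    z = ndtri(1.0 - alpha / 2.0)
    if method == "normal":
        se = float(np.std(draws, ddof=1))
        return theta_hat - z * se, theta_hat + z * se
    if method == "basic":  # order-statistic formula as printed
        return (
            _order_statistic(s, alpha / 2.0),
            _order_statistic(s, 1.0 - alpha / 2.0),
        )
    if method == "percentile":  # reflected formula as printed
        return (
            2.0 * theta_hat - _order_statistic(s, 1.0 - alpha / 2.0),
            2.0 * theta_hat - _order_statistic(s, alpha / 2.0),
        )
    if method == "bca":
        return _bca_interval(theta_hat, s, z0, a, alpha)
    raise ValueError(f"unknown bootstrap method {method!r}")


def _leave_out_matrix(g: np.ndarray, n_blocks: int) -> np.ndarray:
    """Stacked leave-out index rows for one group (all rows equal length).

    Leave-one-out when the group is small; otherwise ``n_blocks`` equal-size
    contiguous blocks are left out in turn (remainder rows always kept).
    """
    n = len(g)
    if n <= 250:
        return np.stack([np.delete(g, i) for i in range(n)])
    size = n // n_blocks
    return np.stack([
        np.concatenate([g[: i * size], g[(i + 1) * size:]])
        for i in range(n_blocks)
    ])


def _bootstrap_draws(engine, idx1, idx0, B, rng, se_method, B_se):
    """Stratified bootstrap draws of PSE_1 - PSE_0 (group sizes fixed)."""
    n1, n0 = len(idx1), len(idx0)
    mat1 = idx1[rng.integers(0, n1, (B, n1))]
    mat0 = idx0[rng.integers(0, n0, (B, n0))]
    draws, skipped = _statistic_batch(engine, mat1, mat0, se_method, B_se, rng)
    if skipped > 0.1 * B:
        raise EstimationError(f"path inestimable in {skipped}/{B} resamples")
    return draws, skipped


def _jackknife_draws(engine, idx1, idx0, se_method, B_se, rng, n_blocks=25):
    """Jackknife draws of the statistic, leaving out rows of either group."""
    draws = []
    for own, other, case_side in ((idx1, idx0, True), (idx0, idx1, False)):
        mat = _leave_out_matrix(own, n_blocks)
        if se_method == "delta":
            s_own = engine.pse_batch(mat)
            s_other = engine.pse(other)
            part = (s_own - s_other) if case_side else (s_other - s_own)
            part = part[np.isfinite(part)]
        else:
            vals = []
            for row in mat:
                pair = (row, other) if case_side else (other, row)
                try:
                    vals.append(_statistic(engine, *pair, se_method, B_se, rng))
                except (EstimationError, CollinearityError):
                    continue
            part = np.asarray(vals)
        draws.append(part)
    return np.concatenate(draws)


def bootstrap_test(
    grouped: GroupedDataset,
    path: SpecificPath,
    plan: AdjustmentPlan,
    B: int = 1000,
    alpha: float = 0.05,
    method: str = "normal",
    seed: int | None = None,
    se_method: str = "delta",
    B_se: int = 200,
    kinds: Mapping[str, str] | None = None,
    engine: PathEngine | None = None,
) -> PSETestResult:
    """Bootstrap CI test of H0: PSE_1 = PSE_0 (reject iff 0 is outside).

    Resampling is stratified: rows are drawn with replacement within each
    group independently, keeping both group sizes fixed.  For ``bca`` with an
    undefined acceleration constant the interval falls back to the
    order-statistic (``basic``) formula with a warning.
    """
    method = METHOD_ALIASES.get(method, method)
    if method not in BOOTSTRAP_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {BOOTSTRAP_METHODS}")
    if B < 200:
        raise ValueError(f"B={B} is too small; need B >= 200")
    rng = np.random.default_rng(seed)
    if engine is None:
        engine = build_engine(grouped.data, path, plan, kinds)
    idx1, idx0 = _indices(grouped)
    theta_hat = _statistic(engine, idx1, idx0, se_method, B_se, rng)
    draws, skipped = _bootstrap_draws(engine, idx1, idx0, B, rng, se_method, B_se)

    info: dict[str, object] = {"n_skipped": skipped}
    used = method
    if method == "bca":
        jack = _jackknife_draws(engine, idx1, idx0, se_method, B_se, rng)
        try:
            z0, a = bca_constants(theta_hat, draws, jack)
            ci = _ci_from_draws("bca", theta_hat, draws, alpha, z0, a)
            info.update(z0=z0, a=a)
        except EstimationError as exc:
            warnings.warn(f"BCa unavailable ({exc}); falling back to the "
                          "order-statistic interval")
            ci = _ci_from_draws("basic", theta_hat, draws, alpha)
            info["fallback"] = "basic"
    else:
        ci = _ci_from_draws(method, theta_hat, draws, alpha)

    lo, hi = float(ci[0]), float(ci[1])
    return PSETestResult(
        method=used,
        statistic=theta_hat,
        p_value=None,
        ci=(lo, hi),
        reject=bool(lo > 0.0 or hi < 0.0),
        B=len(draws),
        alpha=alpha,
        seed=seed,
        info=info,
    )
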