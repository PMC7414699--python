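"""Synthetic network generators and the Monte-Carlo evaluation harness.

Two generating schemes are provided:

* a binary systems-epidemiology network on myocardial infarction, generated
  node by node in topological order with logistic child models
  logit P(child = 1 | parents) = alpha0 + sum_j beta_j (pa_j - 1/2), and the
  target specific path Calorific excess -> Visceral adiposity ->
  Inflammatory milieu -> Atherosclerosis -> Myocardial infarction;
* a continuous five-edge graph (X1 -> X2, X2 -> X3, X1 -> X3, X2 -> Y,
  X3 -> Y) generated by linear-Gaussian child models, in which a single
  differential edge X2 -> Y makes X1 -> X2 -> Y the unique differential
  path among the three routes from X1 to Y.

Edge coefficients are specified per group (control = group 0, case =
group 1); "a vs b" scenarios generate with coefficient a in the control
group and b in the case group, so delta = b - a is the per-edge effect
difference.  Unstated constants are fixed symmetric and non-degenerate:
intercepts 0 with parent values centered at the root prevalence (so every
node keeps prevalence near 1/2 and risk differences do not saturate), root
prevalence 0.5, non-differential edges 0.5 in both groups, Gaussian noise
sd 1; published grid sample sizes are totals split equally across the two
conditions.

``run_mc`` estimates a rejection rate over independent replicates and
``table_experiment`` instantiates the standard experiment grids T1-T8
(type-I error vs sample size for the total and path-specific statistics,
power vs per-edge effect size, power vs effect difference delta, and the
two sensitivity grids over off-path parent and child edges).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from ._engine import PathEngine
from .ace import CollinearityError, EstimationError
from .graph import CausalDAG, SpecificPath, adjustment_sets, parse_graph
from .inference import (
    BOOTSTRAP_METHODS,
    _bootstrap_draws,
    _ci_from_draws,
    _jackknife_draws,
    _statistic_batch,
    bca_constants,
)

__all__ = [
    "Scenario",
    "MCResult",
    "myocardial_infarction_dag",
    "three_path_dag",
    "mi_scenario",
    "continuous_scenario",
    "generate_binary_network",
    "generate_continuous_network",
    "generate_grouped",
    "run_mc",
    "table_experiment",
    "TABLE_IDS",
]

GROUP_COL = "group"

MI_EDGES: tuple[tuple[str, str], ...] = (
    ("ph", "vi"), ("ca", "vi"), ("vi", "inf"), ("inf", "at"),
    ("hdl", "at"), ("tr", "at"), ("hy", "at"), ("glu", "at"),
    ("at", "my"), ("vi", "pl"), ("vi", "ins"), ("inf", "ins"),
)
MI_TARGET = ("ca", "vi", "inf", "at", "my")
MI_PATH_EDGES = tuple(zip(MI_TARGET[:-1], MI_TARGET[1:]))
MI_PARENT_EDGES = (("ph", "vi"), ("hdl", "at"), ("tr", "at"),
                   ("hy", "at"), ("glu", "at"))
MI_CHILD_EDGES = (("vi", "pl"), ("vi", "ins"), ("inf", "ins"))

FIG6_EDGES: tuple[tuple[str, str], ...] = (
    ("X1", "X2"), ("X2", "X3"), ("X1", "X3"), ("X2", "Y"), ("X3", "Y"),
)
FIG6_TARGET = ("X1", "X2", "Y")


def myocardial_infarction_dag() -> CausalDAG:
    """The binary myocardial-infarction network (all nodes binary)."""
    return parse_graph(MI_EDGES, var_kinds={n: "binary" for e in MI_EDGES for n in e})


def three_path_dag() -> CausalDAG:
    """The continuous three-path graph linking X1 and Y."""
    return parse_graph(FIG6_EDGES)


@dataclass(frozen=True)
class Scenario:
    """A two-group generative specification for one network."""

    dag: CausalDAG
    coeffs: Mapping[tuple[str, str], tuple[float, float]]  # edge -> (b_ctrl, b_case)
    kind: str  # "binary" | "continuous"
    n_per_group: int
    target_path: tuple[str, ...]
    intercepts: Mapping[str, float] = field(default_factory=dict)
    root_p: float = 0.5
    noise_sd: float = 1.0
    center_parents: bool = True
    name: str = ""

    def __post_init__(self) -> None:
        missing = [e for e in self.dag.edges if e not in self.coeffs]
        if missing:
            raise ValueError(f"coefficients missing for edges {missing}")
        if self.kind not in ("binary", "continuous"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.kind == "continuous" and self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def differential_edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(e for e, (b0, b1) in self.coeffs.items() if b0 != b1)

    @property
    def delta(self) -> float:
        diffs = {b1 - b0 for e, (b0, b1) in self.coeffs.items() if b0 != b1}
        return diffs.pop() if len(diffs) == 1 else float("nan")


@dataclass(frozen=True)
class MCResult:
    """Monte-Carlo rejection rate for one scenario cell and one method."""

    scenario: str
    method: str
    n: int
    reps: int
    rejection_rate: float
    mc_se: float
    seed: int | None


def mi_scenario(
    n_per_group: int = 1000,
    differential: Mapping[tuple[str, str], tuple[float, float]] | None = None,
    base: float = 0.5,
    name: str = "",
) -> Scenario:
    """Myocardial-infarction scenario: every edge at ``base`` in both groups,
    overridden per edge by ``differential`` (control, case) pairs."""
    dag = myocardial_infarction_dag()
    coeffs = {e: (base, base) for e in dag.edges}
    coeffs.update(differential or {})
    return Scenario(dag=dag, coeffs=coeffs, kind="binary",
                    n_per_group=n_per_group, target_path=MI_TARGET, name=name)


def continuous_scenario(
    n_per_group: int = 1000,
    differential: Mapping[tuple[str, str], tuple[float, float]] | None = None,
    base: float = 0.5,
    name: str = "",
) -> Scenario:
    """Three-path continuous scenario; default differential edge X2 -> Y."""
    if differential is None:
        differential = {("X2", "Y"): (0.5, 1.5)}
    dag = three_path_dag()
    coeffs = {e: (base, base) for e in dag.edges}
    coeffs.update(differential)
    return Scenario(dag=dag, coeffs=coeffs, kind="continuous",
                    n_per_group=n_per_group, target_path=FIG6_TARGET, name=name)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_binary_network(scenario: Scenario, group: int, seed=None) -> pd.DataFrame:
    """One group's sample: roots Bernoulli(root_p), children logistic.

    With ``center_parents`` (default) the linear predictor uses parent values
    centered at the root prevalence, logit P = alpha0 + sum_j beta_j (pa_j -
    root_p).  This keeps every node's prevalence near 1/2 regardless of edge
    strength, so risk differences do not saturate as coefficients grow; the
    identification of per-edge effects is unaffected (it only shifts the
    intercept of each child model).
    """
    rng = _rng(seed)
    n = scenario.n_per_group
    shift = scenario.root_p if scenario.center_parents else 0.0
    cols: dict[str, np.ndarray] = {}
    for node in scenario.dag.topological_order():
        parents = scenario.dag.parents(node)
        if not parents:
            cols[node] = rng.binomial(1, scenario.root_p, n).astype(float)
            continue
        eta = np.full(n, scenario.intercepts.get(node, 0.0))
        for pa in parents:
            eta += scenario.coeffs[(pa, node)][group] * (cols[pa] - shift)
        if np.all(np.abs(eta) > 20.0):
            warnings.warn(f"node {node!r} is numerically degenerate "
                          "(|linear predictor| > 20 everywhere)")
        cols[node] = rng.binomial(1, expit(eta)).astype(float)
    return pd.DataFrame(cols)


def generate_continuous_network(scenario: Scenario, group: int, seed=None) -> pd.DataFrame:
    """One group's sample from the linear-Gaussian child models."""
    rng = _rng(seed)
    n = scenario.n_per_group
    sd = scenario.noise_sd
    cols: dict[str, np.ndarray] = {}
    for node in scenario.dag.topological_order():
        val = np.full(n, scenario.intercepts.get(node, 0.0))
        for pa in scenario.dag.parents(node):
            val = val + scenario.coeffs[(pa, node)][group] * cols[pa]
        cols[node] = val + rng.normal(0.0, sd, n)
    return pd.DataFrame(cols)


def generate_grouped(scenario: Scenario, seed=None) -> pd.DataFrame:
    """Both groups stacked, with a 0/1 ``group`` column (case = 1)."""
    rng = _rng(seed)
    gen = (generate_binary_network if scenario.kind == "binary"
           else generate_continuous_network)
    d0 = gen(scenario, 0, rng)
    d1 = gen(scenario, 1, rng)
    d0[GROUP_COL] = 0
    d1[GROUP_COL] = 1
    return pd.concat([d1, d0], ignore_index=True)


# ---------------------------------------------------------------------------
# Monte-Carlo harness


def _target_engine(
    scenario: Scenario,
    data: pd.DataFrame,
    statistic: str,
    effect_scale: str = "rd",
) -> PathEngine:
    kinds = {n: scenario.dag.kind(n) for n in scenario.dag.nodes}
    if statistic == "pse":
        path = SpecificPath(scenario.target_path)
        plan = adjustment_sets(scenario.dag, path)
        edges = path.edges
        cov = {e: plan.covariates(e) for e in edges}
    elif statistic == "tce":
        src, sink = scenario.target_path[0], scenario.target_path[-1]
        edges = ((src, sink),)
        cov = {(src, sink): scenario.dag.parents(src)}
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return PathEngine(data, edges=edges, covariates=cov, child_kinds=kinds,
                      effect_scale=effect_scale)


def _rep_rejections(
    scenario, methods, rng, B_perm, B_boot, alpha, statistic, se_method, B_se,
    effect_scale,
) -> dict[str, bool]:
    data = generate_grouped(scenario, rng)
    engine = _target_engine(scenario, data, statistic, effect_scale)
    idx1 = np.flatnonzero(data[GROUP_COL].to_numpy() == 1)
    idx0 = np.flatnonzero(data[GROUP_COL].to_numpy() == 0)
    out: dict[str, bool] = {}
    t_obs = engine.pse_difference(idx1, idx0, se_method=se_method,
                                  B_se=B_se, rng=rng)

    if "permutation" in methods:
        pool = np.concatenate([idx1, idx0])
        n1 = len(idx1)
        perms = np.stack([rng.permutation(pool) for _ in range(B_perm)])
        draws, _ = _statistic_batch(engine, perms[:, :n1], perms[:, n1:],
                                    se_method, B_se, rng)
        count = int(np.sum(np.abs(draws) >= abs(t_obs) - 1e-12))
        p = (1 + count) / (len(draws) + 1)
        out["permutation"] = p < alpha

    ci_methods = [m for m in methods if m in BOOTSTRAP_METHODS]
    if ci_methods:
        draws, _ = _bootstrap_draws(engine, idx1, idx0, B_boot, rng,
                                    se_method, B_se)
        z0 = a = None
        if "bca" in ci_methods:
            jack = _jackknife_draws(engine, idx1, idx0, se_method, B_se, rng)
            try:
                z0, a = bca_constants(t_obs, draws, jack)
            except EstimationError:
                z0 = a = None
        for m in ci_methods:
            if m == "bca" and z0 is None:
                lo, hi = _ci_from_draws("basic", t_obs, draws, alpha)
            else:
                lo, hi = _ci_from_draws(m, t_obs, draws, alpha, z0, a)
            out[m] = lo > 0.0 or hi < 0.0
    return out


def run_mc(
    scenario: Scenario,
    methods: str | Sequence[str] = "permutation",
    reps: int = 1000,
    seed: int = 0,
    B_perm: int = 199,
    B_boot: int = 200,
    alpha: float = 0.05,
    statistic: str = "pse",
    se_method: str = "delta",
    B_se: int = 200,
    effect_scale: str = "rd",
) -> list[MCResult]:
    """Monte-Carlo rejection rate of the chosen tests on one scenario.

    Each replicate generates both groups afresh (per-replicate RNG streams
    spawned from ``seed``, so results do not depend on evaluation order),
    runs every requested method on the target path (or on the exposure ->
    outcome total effect for ``statistic="tce"``), and records rejection at
    level ``alpha``.  More than 5% failed replicates is an error.
    """
    if reps < 50:
        raise ValueError(f"reps={reps} is too small; need reps >= 50")
    if isinstance(methods, str):
        methods = [methods]
    unknown = [m for m in methods
               if m != "permutation" and m not in BOOTSTRAP_METHODS]
    if unknown:
        raise ValueError(f"unknown methods {unknown}")
    streams = np.random.SeedSequence(seed).spawn(reps)
    counts = Counter()
    failures = Counter()
    done = 0
    for r in range(reps):
        rng = np.random.default_rng(streams[r])
        try:
            rej = _rep_rejections(scenario, methods, rng, B_perm, B_boot,
                                  alpha, statistic, se_method, B_se,
                                  effect_scale)
        except (EstimationError, CollinearityError) as exc:
            failures[type(exc).__name__] += 1
            continue
        done += 1
        for m, r_ in rej.items():
            counts[m] += int(r_)
    if sum(failures.values()) > 0.05 * reps:
        raise EstimationError(
            f"{sum(failures.values())}/{reps} replicates failed: {dict(failures)}"
        )
    out = []
    for m in methods:
        rate = counts[m] / done
        out.append(MCResult(
            scenario=scenario.name or f"{statistic}:{scenario.kind}",
            method=m, n=scenario.n_per_group, reps=done,
            rejection_rate=rate,
            mc_se=float(np.sqrt(rate * (1 - rate) / done)),
            seed=seed,
        ))
    return out


# ---------------------------------------------------------------------------
# published experiment grids

ALL_METHODS = ("permutation",) + BOOTSTRAP_METHODS
SIZES = (200, 400, 600, 800, 1000)
EFFECT_GRID = ((0.2, 1.2), (0.4, 1.4), (0.6, 1.6), (0.8, 1.8), (1.0, 2.0))
DELTA_GRID = ((0.5, 1.0), (0.5, 1.5), (0.5, 2.0),
              (0.5, 2.5), (0.5, 3.0), (0.5, 3.5))
# the delta grids print only three of the four target-path edges; by default
# the fourth (vi -> inf) is treated as differential too, which is what makes
# the power response monotone in delta (toggle: vi_inf_differential=False)
DELTA_EDGES = (("ca", "vi"), ("inf", "at"), ("at", "my"))
TABLE_IDS = ("T1", "T2", "T3", "T4", "T5", "T6", "T7", "T8")


def _table_cells(table_id: str, n_total: int, vi_inf_differential: bool):
    """(cell name, scenario, statistic, methods) for each grid row.

    Stated sample sizes are totals across both conditions, split equally.
    """
    delta_edges = MI_PATH_EDGES if vi_inf_differential else DELTA_EDGES
    n = max(n_total // 2, 1)
    cells = []
    if table_id in ("T1", "T2"):
        stat = "tce" if table_id == "T1" else "pse"
        for size in SIZES:
            sc = mi_scenario(max(size // 2, 1), name=f"{table_id}:n={size}")
            cells.append((sc.name, sc, stat, ALL_METHODS))
    elif table_id in ("T3", "T4"):
        stat = "tce" if table_id == "T3" else "pse"
        methods = ALL_METHODS if table_id == "T3" else ("permutation",)
        for pair in EFFECT_GRID:
            sc = mi_scenario(n, {e: pair for e in MI_PATH_EDGES},
                             name=f"{table_id}:{pair[0]}v{pair[1]}")
            cells.append((sc.name, sc, stat, methods))
    elif table_id in ("T5", "T6"):
        stat = "tce" if table_id == "T5" else "pse"
        methods = ALL_METHODS if table_id == "T5" else ("permutation",)
        for pair in DELTA_GRID:
            sc = mi_scenario(n, {e: pair for e in delta_edges},
                             name=f"{table_id}:delta={pair[1] - pair[0]:g}")
            cells.append((sc.name, sc, stat, methods))
    elif table_id in ("T7", "T8"):
        off_edges = MI_PARENT_EDGES if table_id == "T7" else MI_CHILD_EDGES
        for pair in EFFECT_GRID:
            diff = {e: (0.5, 1.5) for e in delta_edges}
            diff.update({e: pair for e in off_edges})
            sc = mi_scenario(n, diff,
                             name=f"{table_id}:{pair[0]}v{pair[1]}")
            cells.append((sc.name, sc, "pse", ("permutation",)))
    else:
        raise ValueError(f"unknown table id {table_id!r}; valid: {TABLE_IDS}")
    return cells


def table_experiment(
    table_id: str,
    reps: int = 1000,
    seed: int = 0,
    n_total: int = 1000,
    B_perm: int = 199,
    B_boot: int = 200,
    alpha: float = 0.05,
    vi_inf_differential: bool = True,
    progress=None,
) -> list[MCResult]:
    """Run one published experiment grid and return one result per cell
    per method.  ``progress`` (optional callable) receives each cell name."""
    cells = _table_cells(table_id, n_total, vi_inf_differential)
    streams = np.random.SeedSequence(seed).spawn(len(cells))
    results: list[MCResult] = []
    for (name, sc, stat, methods), stream in zip(cells, streams):
        if progress is not None:
            progress(name)
        cell_seed = int(stream.generate_state(1)[0] % (2**31))
        results.extend(run_mc(sc, methods, reps=reps, seed=cell_seed,
                              B_perm=B_perm, B_boot=B_boot, alpha=alpha,
                              statistic=stat))
    return results
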