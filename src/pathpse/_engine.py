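"""Resampling workhorse: repeated path-effect evaluation on row subsets.

Permutation and bootstrap tests evaluate the two-group path statistic
hundreds of times per dataset, and the Monte-Carlo harness repeats that over
hundreds of generated datasets.  The engine precomputes one design matrix per
path edge over the full table and then re-estimates every edge effect on an
arbitrary row-index subset: OLS slope for continuous children, warm-started
IRLS logistic standardization for binary children.  The path product's
standard error comes either from the delta method (Sobel product formula over
the per-edge model variances) or from a stratified bootstrap.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from ._glm import (
    CollinearityError,
    logistic_fit,
    logistic_fit_weighted,
    ols_fit,
    standardized_risk_difference,
    standardized_risk_difference_weighted,
)
from .ace import EstimationError

_MIN_SE = 1e-12
_MAX_PATTERNS = 256


class PathEngine:
    """Evaluate a path product and its SE on arbitrary row subsets.

    Parameters
    ----------
    data : DataFrame containing every node and covariate column.
    edges : ordered path edges [(A, B), ...] (a single pseudo-edge for a
        total-effect analysis).
    covariates : mapping edge -> covariate name sequence.
    child_kinds : mapping child name -> {"binary", "continuous"}.
    effect_scale : "rd" standardizes binary children to a risk difference;
        "coef" uses the raw logistic coefficient of the parent instead.
    """

    def __init__(
        self,
        data,
        edges: Sequence[tuple[str, str]],
        covariates: Mapping[tuple[str, str], Sequence[str]],
        child_kinds: Mapping[str, str],
        contrast: tuple[float, float] = (1.0, 0.0),
        effect_scale: str = "rd",
    ) -> None:
        if effect_scale not in ("rd", "coef"):
            raise ValueError(f"unknown effect_scale {effect_scale!r}")
        self.edges = list(edges)
        self.contrast = contrast
        self.effect_scale = effect_scale
        self.n_rows = len(data)
        self._edge_data = []
        for edge in self.edges:
            a, b = edge
            cov = list(covariates[edge])
            cols = [a, *cov]
            arrs = []
            for c in cols + [b]:
                if c not in data.columns:
                    raise EstimationError(f"column {c!r} not in data")
                arr = data[c].to_numpy(dtype=float)
                if np.isnan(arr).any():
                    raise EstimationError(f"missing values in column {c!r}")
                arrs.append(arr)
            X = np.column_stack([np.ones(self.n_rows)] + arrs[:-1])
            y = arrs[-1]
            kind = child_kinds.get(b, "continuous")
            if kind == "binary" and not set(np.unique(y)) <= {0.0, 1.0}:
                raise EstimationError(f"child {b!r} declared binary but is not 0/1")
            warm = None
            if kind == "binary" and np.ptp(y) > 0:
                try:
                    warm, _ = logistic_fit(X, y)
                except CollinearityError:
                    warm = None
            ed = {"edge": edge, "X": X, "y": y, "kind": kind, "warm": warm,
                  "patterns": None}
            if kind == "binary":
                ed["patterns"] = self._compress(X, y)
            self._edge_data.append(ed)

    @staticmethod
    def _compress(X: np.ndarray, y: np.ndarray):
        """Unique-design-pattern compression for all-discrete binary edges.

        When the design has few distinct rows, a logistic fit on any row
        subset is a binomial fit over pattern counts, so per-subset work
        reduces to one bincount plus IRLS on the pattern matrix.
        """
        uniq, inverse = np.unique(X[:, 1:], axis=0, return_inverse=True)
        if len(uniq) > _MAX_PATTERNS:
            return None
        Xp = np.column_stack([np.ones(len(uniq)), uniq])
        codes = inverse * 2 + (y > 0.5)
        return {"Xp": Xp, "codes": codes, "K": len(uniq)}

    # -- single-edge evaluation ------------------------------------------

    def _edge_stat(self, ed, idx: np.ndarray) -> tuple[float, float]:
        if ed["patterns"] is not None:
            return self._edge_stat_compressed(ed, idx)
        X = ed["X"][idx]
        y = ed["y"][idx]
        a = X[:, 1]
        if np.ptp(a) == 0.0:
            raise EstimationError(
                f"degenerate resample: parent of edge {ed['edge']} is constant"
            )
        if ed["kind"] == "binary":
            if np.ptp(y) == 0.0:
                return 0.0, 0.0
            beta, cov = logistic_fit(X, y, beta0=ed["warm"], max_iter=30)
            if self.effect_scale == "coef":
                return float(beta[1]), float(max(cov[1, 1], 0.0))
            hi, lo = self.contrast
            return standardized_risk_difference(X, beta, cov, 1, hi, lo)
        if np.ptp(y) == 0.0:
            return 0.0, 0.0
        beta, cov, _ = ols_fit(X, y, check_rank=False)
        return float(beta[1]), float(max(cov[1, 1], 0.0))

    def _edge_stat_compressed(self, ed, idx: np.ndarray) -> tuple[float, float]:
        pat = ed["patterns"]
        Xp, K = pat["Xp"], pat["K"]
        counts = np.bincount(pat["codes"][idx], minlength=2 * K)
        n1 = counts[1::2].astype(float)
        nt = n1 + counts[0::2]
        active = nt > 0
        a_active = Xp[active, 1]
        if a_active.max() == a_active.min():
            raise EstimationError(
                f"degenerate resample: parent of edge {ed['edge']} is constant"
            )
        s1 = n1.sum()
        if s1 == 0 or s1 == nt.sum():
            return 0.0, 0.0
        beta, cov = logistic_fit_weighted(Xp, n1, nt, beta0=ed["warm"],
                                          max_iter=30)
        if self.effect_scale == "coef":
            return float(beta[1]), float(max(cov[1, 1], 0.0))
        hi, lo = self.contrast
        return standardized_risk_difference_weighted(Xp, nt, beta, cov, 1, hi, lo)

    def edge_stats(self, idx: np.ndarray) -> list[tuple[float, float]]:
        """(estimate, model variance) per path edge on the rows in ``idx``."""
        return [self._edge_stat(ed, idx) for ed in self._edge_data]

    # -- batched evaluation over many row subsets -------------------------

    def _edge_stat_batch(self, ed, idx_mat: np.ndarray):
        """(estimates, variances) arrays over m row subsets (rows of idx_mat).

        Compressed binary edges run one batched binomial IRLS across all
        subsets; other edges fall back to a per-subset loop.  Degenerate
        subsets (constant parent) yield NaN.
        """
        pat = ed["patterns"]
        m = idx_mat.shape[0]
        if pat is None:
            est = np.empty(m)
            var = np.empty(m)
            for i in range(m):
                try:
                    est[i], var[i] = self._edge_stat(ed, idx_mat[i])
                except (EstimationError, CollinearityError):
                    est[i] = var[i] = np.nan
            return est, var

        Xp, codes, K = pat["Xp"], pat["codes"], pat["K"]
        p = Xp.shape[1]
        offsets = (np.arange(m) * 2 * K)[:, None]
        counts = np.bincount(
            (codes[idx_mat] + offsets).ravel(), minlength=m * 2 * K
        ).reshape(m, 2 * K)
        N1 = counts[:, 1::2].astype(float)
        NT = N1 + counts[:, 0::2]

        active = NT > 0
        a_vals = Xp[:, 1][None, :]
        a_max = np.where(active, a_vals, -np.inf).max(axis=1)
        a_min = np.where(active, a_vals, np.inf).min(axis=1)
        degenerate = a_max == a_min
        s1 = N1.sum(axis=1)
        total = NT.sum(axis=1)
        constant = (s1 == 0) | (s1 == total)

        warm = ed["warm"] if ed["warm"] is not None else np.zeros(p)
        beta = np.tile(warm, (m, 1))
        H = None
        for _ in range(30):
            eta = np.clip(beta @ Xp.T, -30.0, 30.0)
            mu = expit(eta)
            W = NT * mu * (1.0 - mu) + 1e-12
            g = np.einsum("mk,kp->mp", N1 - NT * mu, Xp)
            H = np.einsum("mk,kp,kq->mpq", W, Xp, Xp)
            H[:, np.arange(p), np.arange(p)] += 1e-9
            step = np.linalg.solve(H, g[:, :, None])[:, :, 0]
            norm = np.abs(step).max(axis=1)
            scale = np.minimum(1.0, 10.0 / np.maximum(norm, 1e-300))
            beta += step * scale[:, None]
            if norm.max() < 1e-9:
                break
        cov = np.linalg.inv(H)

        if self.effect_scale == "coef":
            est = beta[:, 1].copy()
            var = np.maximum(cov[:, 1, 1], 0.0)
        else:
            hi, lo = self.contrast
            Xh = Xp.copy()
            Xh[:, 1] = hi
            Xl = Xp.copy()
            Xl[:, 1] = lo
            mh = expit(np.clip(beta @ Xh.T, -30.0, 30.0))
            ml = expit(np.clip(beta @ Xl.T, -30.0, 30.0))
            tot = total[:, None]
            est = (NT * (mh - ml)).sum(axis=1) / total
            gh = np.einsum("mk,kp->mp", NT * mh * (1.0 - mh), Xh) / tot
            gl = np.einsum("mk,kp->mp", NT * ml * (1.0 - ml), Xl) / tot
            gv = gh - gl
            var = np.maximum(np.einsum("mp,mpq,mq->m", gv, cov, gv), 0.0)
        est[constant] = 0.0
        var[constant] = 0.0
        est[degenerate] = np.nan
        var[degenerate] = np.nan
        return est, var

    def path_products_batch(self, idx_mat: np.ndarray):
        """Path products and delta variances over m subsets; NaN = failed."""
        per_edge = [self._edge_stat_batch(ed, idx_mat) for ed in self._edge_data]
        ests = np.column_stack([e for e, _ in per_edge])
        variances = np.column_stack([v for _, v in per_edge])
        prod = np.prod(ests, axis=1)
        n_edges = ests.shape[1]
        var = np.zeros_like(prod)
        for i in range(n_edges):
            others = [j for j in range(n_edges) if j != i]
            coef = np.prod(ests[:, others], axis=1) if others else np.ones_like(prod)
            var += coef**2 * variances[:, i]
        return prod, var

    def pse_batch(self, idx_mat: np.ndarray) -> np.ndarray:
        """Delta-standardized path effect per subset; NaN where inestimable."""
        est, var = self.path_products_batch(idx_mat)
        se = np.sqrt(var)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(se > _MIN_SE, est / se, np.nan)
        return out

    # -- path product -----------------------------------------------------

    def path_product(self, idx: np.ndarray) -> tuple[float, float]:
        """Path product and its delta-method variance on ``idx``.

        Var(prod_i e_i) ~= sum_i (prod_{j != i} e_j)^2 Var(e_i), the product
        (Sobel) formula with the per-edge fits treated as uncorrelated.
        """
        stats = self.edge_stats(idx)
        ests = np.array([s[0] for s in stats])
        variances = np.array([s[1] for s in stats])
        prod = float(np.prod(ests))
        coefs = np.array(
            [np.prod(np.delete(ests, i)) for i in range(len(ests))]
        )
        var = float(np.sum(coefs**2 * variances))
        return prod, var

    def bootstrap_draws(
        self,
        idx: np.ndarray,
        B: int,
        rng: np.random.Generator,
        standardized: bool = False,
        max_skip_frac: float = 0.1,
    ) -> np.ndarray:
        """Path products (optionally delta-standardized) over B resamples."""
        n = len(idx)
        out = []
        skipped = 0
        for _ in range(B):
            sub = idx[rng.integers(0, n, n)]
            try:
                est, var = self.path_product(sub)
            except (EstimationError, CollinearityError):
                skipped += 1
                continue
            if standardized:
                se = np.sqrt(var)
                if se <= _MIN_SE:
                    skipped += 1
                    continue
                out.append(est / se)
            else:
                out.append(est)
        if skipped > max_skip_frac * B:
            raise EstimationError(
                f"{skipped}/{B} bootstrap resamples were degenerate"
            )
        return np.asarray(out)

    def bootstrap_se(self, idx: np.ndarray, B: int, rng: np.random.Generator) -> float:
        draws = self.bootstrap_draws(idx, B, rng)
        return float(np.std(draws, ddof=1))

    # -- standardized per-group effect and the two-group statistic --------

    def path_ace_se(
        self,
        idx: np.ndarray,
        se_method: str = "delta",
        B_se: int = 200,
        rng: np.random.Generator | None = None,
    ) -> tuple[float, float]:
        est, var = self.path_product(idx)
        if se_method == "delta":
            se = float(np.sqrt(var))
        elif se_method == "bootstrap":
            if rng is None:
                raise ValueError("bootstrap SE needs an rng")
            se = self.bootstrap_se(idx, B_se, rng)
        else:
            raise ValueError(f"unknown se_method {se_method!r}")
        return est, se

    def pse(self, idx, se_method="delta", B_se=200, rng=None) -> float:
        est, se = self.path_ace_se(idx, se_method, B_se, rng)
        if not np.isfinite(se) or se <= _MIN_SE:
            raise EstimationError("standard error of the path effect is zero")
        return est / se

    def pse_difference(
        self, idx1, idx0, se_method="delta", B_se=200, rng=None
    ) -> float:
        """PSE_1 - PSE_0: the two-group permutation/bootstrap statistic."""
        return (
            self.pse(idx1, se_method, B_se, rng)
            - self.pse(idx0, se_method, B_se, rng)
        )
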