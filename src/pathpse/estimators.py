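"""Scikit-learn-style estimator interfaces.

Three fit-shaped wrappers around the library: :class:`PathEffect` estimates
one path's product-form effect on a single sample, and
:class:`PSEPermutationTest` / :class:`PSEBootstrapTest` run the two-group
tests with ``fit(X, y)`` where ``X`` is the node table and ``y`` the binary
condition labels.  All follow the usual conventions: parameters are stored
verbatim in ``__init__``, fitted results live in trailing-underscore
attributes, and ``get_params``/``set_params`` work with sklearn model
selection utilities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import graph as _graph
from .ace import path_ace_from_data
from .inference import bootstrap_test, permutation_test
from .pse import GroupedDataset, ace_standard_error

__all__ = ["PathEffect", "PSEPermutationTest", "PSEBootstrapTest"]

_GROUP = "__group__"


def _as_frame(X) -> pd.DataFrame:
    if not isinstance(X, pd.DataFrame):
        raise TypeError("X must be a pandas DataFrame with named node columns")
    return X


def _resolve(graph, path):
    if not isinstance(graph, _graph.CausalDAG):
        graph = _graph.parse_graph(list(graph))
    sp = _graph.SpecificPath(tuple(path))
    sp.validate(graph)
    plan = _graph.adjustment_sets(graph, sp)
    return graph, sp, plan


class PathEffect(BaseEstimator):
    """Product-form path-specific effect on one sample.

    Parameters
    ----------
    graph : CausalDAG or edge list defining parent sets.
    path : ordered node names of the specific path.
    B : bootstrap resamples for the standard error.
    seed : RNG seed for the bootstrap.

    Attributes (after ``fit``)
    --------------------------
    estimate_ : the path product.
    se_ : bootstrap standard error of the product.
    standardized_ : estimate_ / se_.
    edge_aces_ : per-edge :class:`~pathpse.ace.EdgeACE` factors.
    """

    def __init__(self, graph=None, path=None, B=500, seed=None):
        self.graph = graph
        self.path = path
        self.B = B
        self.seed = seed

    def fit(self, X, y=None):
        X = _as_frame(X)
        _, sp, plan = _resolve(self.graph, self.path)
        ace = path_ace_from_data(X, sp, plan)
        se = ace_standard_error(X, sp, plan, B=self.B, seed=self.seed)
        self.path_ = sp
        self.adjustment_ = plan
        self.edge_aces_ = ace.edge_aces
        self.estimate_ = ace.estimate
        self.se_ = se
        self.standardized_ = ace.estimate / se if se > 0 else np.nan
        self.n_ = len(X)
        return self


class _BaseTwoGroupTest(BaseEstimator):
    def _grouped(self, X, y):
        X = _as_frame(X)
        y = np.asarray(y)
        if len(y) != len(X):
            raise ValueError("y must have one label per row of X")
        data = X.copy()
        data[_GROUP] = y
        labels = sorted(set(y.tolist()))
        if len(labels) != 2:
            raise ValueError(f"y must be binary, got labels {labels}")
        return GroupedDataset(data, _GROUP, case=labels[1], control=labels[0])


class PSEPermutationTest(_BaseTwoGroupTest):
    """Permutation test of equal standardized path effects in two groups.

    ``fit(X, y)`` computes the observed statistic PSE_1 - PSE_0 and its
    permutation p-value; see :func:`pathpse.inference.permutation_test`.

    Attributes: ``statistic_``, ``p_value_``, ``reject_``, ``result_``.
    """

    def __init__(self, graph=None, path=None, B=999, alpha=0.05, seed=None,
                 se_method="delta", B_se=200, exact=False):
        self.graph = graph
        self.path = path
        self.B = B
        self.alpha = alpha
        self.seed = seed
        self.se_method = se_method
        self.B_se = B_se
        self.exact = exact

    def fit(self, X, y):
        grouped = self._grouped(X, y)
        _, sp, plan = _resolve(self.graph, self.path)
        res = permutation_test(
            grouped, sp, plan, B=self.B, alpha=self.alpha, seed=self.seed,
            se_method=self.se_method, B_se=self.B_se, exact=self.exact,
        )
        self.result_ = res
        self.statistic_ = res.statistic
        self.p_value_ = res.p_value
        self.reject_ = res.reject
        return self


class PSEBootstrapTest(_BaseTwoGroupTest):
    """Bootstrap confidence-interval test of equal path effects.

    ``method`` is one of normal / basic / percentile / bca (names follow the
    formulas as printed; see :mod:`pathpse.inference`).

    Attributes: ``statistic_``, ``ci_``, ``reject_``, ``result_``.
    """

    def __init__(self, graph=None, path=None, B=1000, alpha=0.05,
                 method="normal", seed=None, se_method="delta", B_se=200):
        self.graph = graph
        self.path = path
        self.B = B
        self.alpha = alpha
        self.method = method
        self.seed = seed
        self.se_method = se_method
        self.B_se = B_se

    def fit(self, X, y):
        grouped = self._grouped(X, y)
        _, sp, plan = _resolve(self.graph, self.path)
        res = bootstrap_test(
            grouped, sp, plan, B=self.B, alpha=self.alpha, method=self.method,
            seed=self.seed, se_method=self.se_method, B_se=self.B_se,
        )
        self.result_ = res
        self.statistic_ = res.statistic
        self.ci_ = res.ci
        self.reject_ = res.reject
        return self
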