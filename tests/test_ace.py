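import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathpse.ace import (
    CollinearityError,
    EstimationError,
    edge_ace_binary,
    edge_ace_continuous,
    edge_ace_discrete,
    path_ace,
    path_ace_from_data,
    total_ace,
)
from pathpse.graph import SpecificPath, adjustment_sets, parse_graph

from conftest import linear_sem_chain


class TestContinuousEdge:
    def test_recovers_generating_slope(self, rng):
        a = rng.normal(size=500)
        b = 2.0 * a + rng.normal(size=500)
        df = pd.DataFrame({"A": a, "B": b})
        est = edge_ace_continuous(df, ("A", "B"))
        # closed-form least-squares oracle on the same sample
        oracle = float(np.cov(a, b)[0, 1] / np.var(a, ddof=1))
        assert est.estimate == pytest.approx(oracle, abs=1e-10)
        assert est.estimate == pytest.approx(2.0, abs=0.2)

    def test_constant_child_gives_zero(self, rng):
        df = pd.DataFrame({"A": rng.normal(size=50), "B": np.ones(50)})
        assert edge_ace_continuous(df, ("A", "B")).estimate == 0.0

    def test_duplicated_regressor_raises_naming_column(self, rng):
        a = rng.normal(size=50)
        df = pd.DataFrame({"A": a, "A2": a, "B": rng.normal(size=50)})
        with pytest.raises(CollinearityError, match="A2"):
            edge_ace_continuous(df, ("A", "B"), covariates=["A2"])

    def test_missing_values_error_unless_dropped(self, rng):
        df = pd.DataFrame({"A": [1.0, np.nan, 3.0] * 10, "B": rng.normal(size=30)})
        with pytest.raises(EstimationError, match="missing"):
            edge_ace_continuous(df, ("A", "B"))
        est = edge_ace_continuous(df, ("A", "B"), dropna=True)
        assert est.n_used == 20


def _binary_table(n11, n10, n01, n00):
    """Rows with child=1/0 by parent=1/0 counts."""
    a = np.r_[np.ones(n11 + n10), np.zeros(n01 + n00)]
    b = np.r_[np.ones(n11), np.zeros(n10), np.ones(n01), np.zeros(n00)]
    return pd.DataFrame({"A": a, "B": b})


class TestBinaryEdge:
    def test_collapses_to_risk_difference_without_covariates(self):
        df = _binary_table(80, 20, 30, 70)  # P(B|A=1)=.8, P(B|A=0)=.3
        for estimator in ("model", "stratified"):
            est = edge_ace_binary(df, ("A", "B"), estimator=estimator)
            assert est.estimate == pytest.approx(0.5, abs=1e-9)

    def test_stratified_matches_bruteforce_sum(self, rng):
        # exhaustive standardization oracle over all (A, C) cells
        n = 600
        c = rng.binomial(1, 0.4, n).astype(float)
        a = rng.binomial(1, 0.3 + 0.3 * c).astype(float)
        b = rng.binomial(1, 0.2 + 0.3 * a + 0.25 * c).astype(float)
        df = pd.DataFrame({"A": a, "B": b, "C": c})
        est = edge_ace_binary(df, ("A", "B"), ["C"], estimator="stratified")
        oracle = 0.0
        for cv in (0.0, 1.0):
            w = np.mean(c == cv)
            p1 = b[(a == 1) & (c == cv)].mean()
            p0 = b[(a == 0) & (c == cv)].mean()
            oracle += w * (p1 - p0)
        assert est.estimate == pytest.approx(oracle, abs=1e-12)

    def test_model_agrees_with_stratified_without_interaction(self, rng):
        from scipy.special import expit

        n = 4000
        c = rng.binomial(1, 0.5, n).astype(float)
        a = rng.binomial(1, expit(0.8 * c - 0.4)).astype(float)
        b = rng.binomial(1, expit(0.9 * a + 0.7 * c - 0.8)).astype(float)
        df = pd.DataFrame({"A": a, "B": b, "C": c})
        m = edge_ace_binary(df, ("A", "B"), ["C"], estimator="model").estimate
        s = edge_ace_binary(df, ("A", "B"), ["C"], estimator="stratified").estimate
        assert m == pytest.approx(s, abs=0.03)

    def test_equal_contrast_levels_give_zero(self):
        df = _binary_table(10, 10, 10, 10)
        est = edge_ace_binary(df, ("A", "B"), x_hi=1, x_lo=1)
        assert est.estimate == 0.0

    def test_empty_stratum_raises_for_stratified(self):
        df = pd.DataFrame(
            {"A": [1, 1, 0, 0, 1], "B": [1, 0, 1, 0, 1], "C": [0, 0, 0, 0, 1]},
            dtype=float,
        )
        with pytest.raises(EstimationError, match="stratum"):
            edge_ace_binary(df, ("A", "B"), ["C"], estimator="stratified")

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.lists(st.tuples(st.booleans(), st.booleans(), st.booleans()),
                 min_size=12, max_size=60),
        st.sampled_from(["model", "stratified"]),
    )
    def test_estimate_always_within_unit_interval(self, rows, estimator):
        a, b, c = (np.array(col, dtype=float) for col in zip(*rows))
        df = pd.DataFrame({"A": a, "B": b, "C": c})
        if a.min() == a.max():
            return
        try:
            est = edge_ace_binary(df, ("A", "B"), ["C"], estimator=estimator)
        except EstimationError:
            return  # empty stratum under pure stratification
        assert -1.0 <= est.estimate <= 1.0


class TestDiscreteEdge:
    def test_binary_reduction_is_exact(self, rng):
        df = _binary_table(40, 25, 15, 50)
        d = edge_ace_discrete(df, ("A", "B"), levels=[0, 1])
        b = edge_ace_binary(df, ("A", "B"), estimator="stratified")
        assert d.estimate == pytest.approx(b.estimate, abs=1e-12)

    def test_three_level_matches_direct_summation(self, rng):
        # brute force over levels and strata
        n = 900
        c = rng.binomial(1, 0.5, n).astype(float)
        a = rng.binomial(1, 0.5, n).astype(float)
        b = np.clip(rng.poisson(0.6 + 0.8 * a + 0.4 * c), 0, 2).astype(float)
        df = pd.DataFrame({"A": a, "B": b, "C": c})
        est = edge_ace_discrete(df, ("A", "B"), ["C"], levels=[0, 1, 2])
        oracle = 0.0
        for cv in (0.0, 1.0):
            w = np.mean(c == cv)
            hi = b[(a == 1) & (c == cv)]
            lo = b[(a == 0) & (c == cv)]
            oracle += w * (hi.mean() - lo.mean())
        assert est.estimate == pytest.approx(oracle, abs=1e-12)

    def test_degenerate_child_gives_zero(self):
        df = pd.DataFrame({"A": [0.0, 1.0] * 10, "B": np.ones(20)})
        assert edge_ace_discrete(df, ("A", "B")).estimate == 0.0

    def test_unordered_levels_rejected(self):
        df = pd.DataFrame({"A": [0.0, 1.0] * 10, "B": [0.0, 1.0] * 10})
        with pytest.raises(EstimationError, match="unordered|increasing"):
            edge_ace_discrete(df, ("A", "B"), levels={0, 1})
        with pytest.raises(EstimationError, match="increasing"):
            edge_ace_discrete(df, ("A", "B"), levels=[1, 0])


class TestPathProduct:
    def test_product_of_slopes(self):
        aces = [
            edge_ace_continuous(
                pd.DataFrame({"A": [0.0, 1, 2, 3], "B": [0.0, 2, 4, 6]}), ("A", "B")
            ),
            edge_ace_continuous(
                pd.DataFrame({"B": [0.0, 1, 2, 3], "C": [0.0, 3, 6, 9]}), ("B", "C")
            ),
        ]
        result = path_ace(aces)
        assert result.estimate == pytest.approx(6.0)

    def test_any_zero_edge_zeroes_the_path(self, rng):
        df1 = pd.DataFrame({"A": rng.normal(size=30), "B": np.ones(30)})
        zero = edge_ace_continuous(df1, ("A", "B"))
        df2 = pd.DataFrame({"B": rng.normal(size=30)})
        df2["C"] = 3 * df2["B"]
        other = edge_ace_continuous(df2, ("B", "C"))
        assert path_ace([zero, other]).estimate == 0.0

    def test_level_contrast_divisor(self):
        df = pd.DataFrame({"A": [0.0, 1, 2, 3], "B": [0.0, 2, 4, 6]})
        ace = edge_ace_continuous(df, ("A", "B"))
        result = path_ace([ace, ace], mediator_contrasts=[(3.0, 1.0)])
        assert result.scale_divisor == 2.0
        assert result.estimate == pytest.approx(2.0)

    def test_zero_divisor_rejected(self):
        df = pd.DataFrame({"A": [0.0, 1, 2, 3], "B": [0.0, 2, 4, 6]})
        ace = edge_ace_continuous(df, ("A", "B"))
        with pytest.raises(EstimationError, match="divisor"):
            path_ace([ace, ace], mediator_contrasts=[(1.0, 1.0)])

    def test_product_commutes_over_edge_order(self, rng):
        df = linear_sem_chain(2000, rng)
        dag = parse_graph(
            [("C1", "C2"), ("C1", "X1"), ("C1", "X2"), ("C2", "X2"),
             ("C2", "Y"), ("X1", "X2"), ("X2", "Y")]
        )
        path = SpecificPath(("X1", "X2", "Y"))
        plan = adjustment_sets(dag, path)
        result = path_ace_from_data(df, path, plan)
        reversed_product = path_ace(list(result.edge_aces)[::-1])
        assert result.estimate == pytest.approx(reversed_product.estimate)


class TestProductDecomposition:
    def test_two_edge_product_matches_interventional_effect(self, rng):
        """The product of back-door-adjusted slopes equals the interventional
        mean contrast of Y under do(x1') vs do(x1''), checked against a
        Monte-Carlo oracle on the confounded linear-Gaussian chain."""
        a, b = 0.7, 0.6
        df = linear_sem_chain(10_000, rng, a=a, b=b)
        dag = parse_graph(
            [("C1", "C2"), ("C1", "X1"), ("C1", "X2"), ("C2", "X2"),
             ("C2", "Y"), ("X1", "X2"), ("X2", "Y")]
        )
        path = SpecificPath(("X1", "X2", "Y"))
        plan = adjustment_sets(dag, path)
        assert plan.covariates(("X1", "X2")) == ("C1", "C2")
        assert plan.covariates(("X2", "Y")) == ("C2",)
        est = path_ace_from_data(df, path, plan).estimate

        # interventional oracle: simulate do(X1=1) and do(X1=0)
        m = 100_000
        orng = np.random.default_rng(7)
        c1 = orng.normal(size=m)
        c2 = 0.6 * c1 + orng.normal(size=m)
        e2 = orng.normal(size=m)
        ey = orng.normal(size=m)
        y_do = {}
        for x1 in (1.0, 0.0):
            x2 = a * x1 + 0.5 * c1 + 0.4 * c2 + e2
            y_do[x1] = (b * x2 + 0.7 * c2 + ey).mean()
        oracle = y_do[1.0] - y_do[0.0]
        assert est == pytest.approx(oracle, rel=0.02)


class TestTotalEffect:
    def test_root_exposure_binary_chain_is_raw_risk_difference(self):
        df = _binary_table(70, 30, 40, 60)
        dag = parse_graph([("A", "B")], var_kinds={"B": "binary"})
        est = total_ace(df, "A", "B", dag=dag)
        assert est.estimate == pytest.approx(0.3, abs=1e-9)

    def test_matches_path_tracing_on_linear_sem(self, rng):
        # C -> X, C -> Y, X -> M, M -> Y, X -> Y; total = direct + a*b
        n = 20_000
        c = rng.normal(size=n)
        x = 0.8 * c + rng.normal(size=n)
        m = 0.5 * x + rng.normal(size=n)
        y = 0.3 * x + 0.6 * m + 0.9 * c + rng.normal(size=n)
        df = pd.DataFrame({"C": c, "X": x, "M": m, "Y": y})
        dag = parse_graph([("C", "X"), ("C", "Y"), ("X", "M"), ("M", "Y"),
                           ("X", "Y")])
        est = total_ace(df, "X", "Y", dag=dag)
        assert est.estimate == pytest.approx(0.3 + 0.5 * 0.6, abs=0.05)

    def test_exposure_equal_outcome_rejected(self, rng):
        df = pd.DataFrame({"A": rng.normal(size=10)})
        with pytest.raises(EstimationError):
            total_ace(df, "A", "A")
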