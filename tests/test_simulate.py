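import numpy as np
import pytest
from scipy.special import expit

from pathpse.graph import enumerate_paths, parse_graph
from pathpse.ace import path_ace_from_data
from pathpse.simulate import (
    DELTA_GRID,
    EFFECT_GRID,
    MI_PATH_EDGES,
    MI_TARGET,
    Scenario,
    _table_cells,
    continuous_scenario,
    generate_binary_network,
    generate_continuous_network,
    generate_grouped,
    mi_scenario,
    myocardial_infarction_dag,
    run_mc,
    table_experiment,
    three_path_dag,
)


class TestBinaryGenerator:
    def test_independent_fair_coins_when_effects_vanish(self, rng):
        sc = mi_scenario(4000, base=0.0)
        df = generate_binary_network(sc, 0, rng)
        assert df.shape == (4000, 12)
        se = 3 * 0.5 / np.sqrt(4000)
        assert np.all(np.abs(df.mean() - 0.5) < se + 0.02)
        corr = df.corr().to_numpy() - np.eye(12)
        assert np.abs(corr).max() < 0.08

    def test_single_edge_conditional_probability_oracle(self, rng):
        dag = parse_graph([("A", "B")], var_kinds={"A": "binary", "B": "binary"})
        sc = Scenario(dag=dag, coeffs={("A", "B"): (1.2, 1.2)}, kind="binary",
                      n_per_group=20_000, target_path=("A", "B"),
                      center_parents=False)
        df = generate_binary_network(sc, 0, rng)
        p1 = df.loc[df.A == 1, "B"].mean()
        p0 = df.loc[df.A == 0, "B"].mean()
        n1 = (df.A == 1).sum()
        assert p1 == pytest.approx(expit(1.2), abs=3 * np.sqrt(0.25 / n1))
        assert p0 == pytest.approx(0.5, abs=3 * np.sqrt(0.25 / n1))

    def test_centered_generation_keeps_prevalence_balanced(self, rng):
        sc = mi_scenario(20_000, {e: (2.5, 2.5) for e in MI_PATH_EDGES})
        df = generate_binary_network(sc, 1, rng)
        assert np.all(np.abs(df.mean() - 0.5) < 0.05)

    def test_child_model_matches_logistic_closed_form(self, rng):
        # P(vi=1 | ca, ph) = expit(0.5(ca - .5) + 0.5(ph - .5)), within 3 SE
        sc = mi_scenario(40_000)
        df = generate_binary_network(sc, 0, rng)
        for ca in (0, 1):
            for ph in (0, 1):
                cell = df[(df.ca == ca) & (df.ph == ph)]
                want = expit(0.5 * (ca - 0.5) + 0.5 * (ph - 0.5))
                se = np.sqrt(want * (1 - want) / len(cell))
                assert cell["vi"].mean() == pytest.approx(want, abs=3 * se + 1e-3)

    def test_target_path_nodes_present(self, rng):
        df = generate_binary_network(mi_scenario(50), 0, rng)
        assert set(MI_TARGET) <= set(df.columns)

    def test_degenerate_linear_predictor_warns(self, rng):
        dag = parse_graph([("A", "B")], var_kinds={"A": "binary", "B": "binary"})
        sc = Scenario(dag=dag, coeffs={("A", "B"): (0.1, 0.1)}, kind="binary",
                      n_per_group=100, target_path=("A", "B"),
                      intercepts={"B": -30.0})
        with pytest.warns(UserWarning, match="degenerate"):
            generate_binary_network(sc, 0, rng)


class TestContinuousGenerator:
    def test_independent_gaussians_when_effects_vanish(self, rng):
        sc = continuous_scenario(5000, differential={}, base=0.0)
        df = generate_continuous_network(sc, 0, rng)
        corr = df.corr().to_numpy() - np.eye(4)
        assert np.abs(corr).max() < 0.06

    def test_chain_transmits_product_of_slopes(self, rng):
        # marginal slope of Y on X1 equals a*b for a Gaussian chain
        dag = parse_graph([("X1", "X2"), ("X2", "Y")])
        sc = Scenario(dag=dag, coeffs={("X1", "X2"): (0.8, 0.8),
                                       ("X2", "Y"): (0.7, 0.7)},
                      kind="continuous", n_per_group=30_000,
                      target_path=("X1", "X2", "Y"))
        df = generate_continuous_network(sc, 0, rng)
        slope = np.cov(df.X1, df.Y)[0, 1] / np.var(df.X1, ddof=1)
        assert slope == pytest.approx(0.8 * 0.7, abs=0.03)

    def test_nonpositive_noise_sd_rejected(self):
        dag = three_path_dag()
        with pytest.raises(ValueError, match="noise_sd"):
            Scenario(dag=dag, coeffs={e: (0.5, 0.5) for e in dag.edges},
                     kind="continuous", n_per_group=10,
                     target_path=("X1", "X2", "Y"), noise_sd=0.0)

    def test_unique_differential_path(self, rng):
        """Only X1 -> X2 -> Y transmits a group difference when X2 -> Y is
        the sole differential edge."""
        sc = continuous_scenario(30_000)
        assert sc.differential_edges == (("X2", "Y"),)
        data = generate_grouped(sc, rng)
        dag = sc.dag
        diffs = {}
        for path, plan in enumerate_paths(dag, "X1", "Y"):
            est = {}
            for g in (0, 1):
                sub = data[data.group == g]
                est[g] = path_ace_from_data(sub, path, plan).estimate
            diffs[path.nodes] = est[1] - est[0]
        assert diffs[("X1", "X2", "Y")] == pytest.approx(0.5 * 1.0, abs=0.08)
        del diffs[("X1", "X2", "Y")]
        assert all(abs(d) < 0.05 for d in diffs.values())


class TestScenario:
    def test_missing_coefficients_rejected(self):
        dag = myocardial_infarction_dag()
        with pytest.raises(ValueError, match="missing"):
            Scenario(dag=dag, coeffs={}, kind="binary", n_per_group=10,
                     target_path=MI_TARGET)

    def test_delta_property(self):
        sc = mi_scenario(100, {e: (0.5, 1.5) for e in MI_PATH_EDGES})
        assert sc.delta == pytest.approx(1.0)


class TestMonteCarlo:
    def test_fixed_seed_reproducible(self):
        sc = mi_scenario(120, name="h0-small")
        r1 = run_mc(sc, "permutation", reps=50, seed=5, B_perm=99)
        r2 = run_mc(sc, "permutation", reps=50, seed=5, B_perm=99)
        assert r1 == r2
        assert r1[0].mc_se == pytest.approx(
            np.sqrt(r1[0].rejection_rate * (1 - r1[0].rejection_rate) / 50))

    def test_small_reps_rejected(self):
        with pytest.raises(ValueError):
            run_mc(mi_scenario(100), reps=10)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            run_mc(mi_scenario(100), methods="anova", reps=50)


class TestTableGrids:
    def test_type_one_error_grid_shape(self):
        cells = _table_cells("T2", 1000, True)
        assert len(cells) == 5
        assert all(len(methods) == 5 for _, _, _, methods in cells)
        assert {sc.n_per_group for _, sc, _, _ in cells} == {100, 200, 300, 400, 500}

    def test_power_grid_shape_and_methods(self):
        cells = _table_cells("T4", 1000, True)
        assert len(cells) == len(EFFECT_GRID)
        assert all(methods == ("permutation",) for _, _, _, methods in cells)
        assert all(stat == "pse" for _, _, stat, _ in cells)

    def test_tce_tables_use_total_effect(self):
        for tid in ("T1", "T3", "T5"):
            assert all(stat == "tce" for _, _, stat, _ in _table_cells(tid, 1000, True))

    def test_delta_grid_covers_all_path_edges_by_default(self):
        cells = _table_cells("T6", 1000, True)
        assert len(cells) == len(DELTA_GRID)
        for _, sc, _, _ in cells:
            assert set(sc.differential_edges) == set(MI_PATH_EDGES)
        cells3 = _table_cells("T6", 1000, False)
        assert all(len(sc.differential_edges) == 3 for _, sc, _, _ in cells3)

    def test_sensitivity_grids_vary_off_path_edges(self):
        for tid, extra in (("T7", ("ph", "vi")), ("T8", ("vi", "pl"))):
            cells = _table_cells(tid, 1000, True)
            assert len(cells) == 5
            for (_, sc, _, _), pair in zip(cells, EFFECT_GRID):
                assert sc.coeffs[extra] == pair
                assert sc.coeffs[("ca", "vi")] == (0.5, 1.5)

    def test_unknown_table_id_lists_valid_ids(self):
        with pytest.raises(ValueError, match="T1"):
            table_experiment("T9", reps=50)

    def test_experiment_runs_end_to_end(self):
        res = table_experiment("T4", reps=50, seed=3, n_total=160, B_perm=99)
        assert len(res) == 5
        assert all(0.0 <= r.rejection_rate <= 1.0 for r in res)
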