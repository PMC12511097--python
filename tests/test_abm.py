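import numpy as np
import pytest

from tradmod.abm import (AgentPopulation, EdgeList, MarketSimulation,
                         SimulationParams, build_network, calibrate,
                         init_agents, intervention_experiment,
                         relative_uplift, sensitivity_sweep, step)
from tradmod.population import build_population_spec


class TestNetwork:
    def test_determinism(self):
        a = build_network(300, 3, seed=5)
        b = build_network(300, 3, seed=5)
        np.testing.assert_array_equal(a.src, b.src)
        np.testing.assert_array_equal(a.dst, b.dst)

    def test_two_nodes_single_edge(self):
        net = build_network(2, 1, seed=0)
        assert net.n_edges == 1

    def test_heavy_tailed_degrees(self):
        net = build_network(1000, 3, seed=1)
        deg = net.degree
        assert deg.max() >= 8 * np.median(deg)
        # preferential attachment: far more low-degree than mid-degree nodes
        assert (deg <= 4).sum() > (deg > 20).sum()

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            build_network(3, 3)

    def test_edge_list_roundtrip(self, tmp_path):
        net = build_network(50, 2, seed=3)
        p = tmp_path / "edges.csv"
        net.to_csv(p)
        back = EdgeList.read_csv(p)
        np.testing.assert_array_equal(back.src, net.src)
        assert back.n_nodes == net.n_nodes

    def test_no_self_loops(self):
        with pytest.raises(ValueError, match="self-loops"):
            EdgeList(np.array([0, 1]), np.array([0, 2]), 3)


class TestInitAgents:
    def test_core_age_share_matches_spec(self, spec):
        pop = init_agents(spec, n=5000, seed=2)
        core = np.isin(pop.age_group.astype(str), ["26-40", "41-55"])
        assert core.mean() == pytest.approx(0.451 + 0.249, abs=0.03)

    def test_degenerate_spec_identical_agents(self):
        s = build_population_spec(
            {"constructs": {c: {"sd": 0.0} for c in
                            ("CI", "MFSC", "ATT", "PP")}})
        pop = init_agents(s, n=100, seed=0)
        assert np.ptp(pop.states, axis=0).max() == 0.0

    def test_survey_derived_moments(self, survey_model):
        pop = init_agents(survey_model, n=4000, seed=3)
        target = survey_model.composites(["CI", "MFSC", "ATT", "PP"]).mean()
        np.testing.assert_allclose(pop.states.mean(axis=0),
                                   target.to_numpy(), atol=0.05)

    def test_state_bounds_enforced(self, spec):
        pop = init_agents(spec, n=2000, seed=4)
        assert pop.states.min() >= 1.0 and pop.states.max() <= 5.0


def tiny_population(ci):
    """Hand-built population on a path network, switched-off covariates."""
    n = len(ci)
    states = np.full((n, 4), 3.0)
    states[:, 0] = ci
    net = EdgeList(np.arange(n - 1), np.arange(1, n), n)
    return AgentPopulation(states=states,
                           age_group=np.array(["26-40"] * n, dtype=object),
                           location=np.array(["urban"] * n, dtype=object),
                           network=net,
                           state_means=np.array([3.8, 3.0, 3.7, 3.2]),
                           state_sds=np.ones(4))


class TestStep:
    def test_switched_off_dynamics(self):
        pop = tiny_population([3.0, 4.0])
        params = SimulationParams(tau=0.0, noise_sd=0.0, threshold_sd=0.0)
        rng = np.random.default_rng(0)
        before = pop.states.copy()
        step(pop, params, rng)
        np.testing.assert_array_equal(pop.states, before)   # CI frozen
        z = (before - pop.state_means) / pop.state_sds
        expected = np.clip(3.73 + 1.07 * (z @ params.beta_vector()), 1, 5)
        np.testing.assert_allclose(pop.pi, expected, atol=1e-12)

    def test_single_neighbour_update(self):
        pop = tiny_population([3.0, 4.0])
        params = SimulationParams(tau=0.05, noise_sd=0.0)
        step(pop, params, np.random.default_rng(0))
        assert pop.states[0, 0] == pytest.approx(3.05)
        # the higher-CI neighbour is not pulled down
        assert pop.states[1, 0] == pytest.approx(4.0)

    def test_sum_mode_aggregates_over_neighbours(self):
        pop = tiny_population([3.0, 4.0, 3.0])  # path: 0-1-2; node 1 highest
        params = SimulationParams(tau=0.05, noise_sd=0.0, diffusion_mode="sum")
        step(pop, params, np.random.default_rng(0))
        assert pop.states[1, 0] == pytest.approx(4.0)
        assert pop.states[0, 0] == pytest.approx(3.05)


class TestRun:
    def test_bit_identical_under_fixed_seed(self):
        a = MarketSimulation(SimulationParams(steps=30, n_agents=200), seed=9).run()
        b = MarketSimulation(SimulationParams(steps=30, n_agents=200), seed=9).run()
        np.testing.assert_array_equal(a.mean_pi, b.mean_pi)
        np.testing.assert_array_equal(a.final.states, b.final.states)
        np.testing.assert_array_equal(a.purchase_rate, b.purchase_rate)

    def test_tau_zero_is_fixed_point(self):
        res = MarketSimulation(SimulationParams(tau=0.0, steps=60,
                                                n_agents=500), seed=1).run()
        assert np.ptp(res.mean_ci) == 0.0
        # mean PI stationary up to Monte-Carlo noise
        assert abs(res.mean_pi[:10].mean() - res.mean_pi[-10:].mean()) < 0.1

    def test_ci_ratchet_and_bounds(self):
        params = SimulationParams(tau=0.2, steps=50, n_agents=300,
                                  diffusion_mode="sum")
        pop = init_agents(n=300, seed=5)
        rng = np.random.default_rng(5)
        prev = pop.states[:, 0].copy()
        for _ in range(params.steps):
            step(pop, params, rng)
            ci = pop.states[:, 0]
            assert (ci >= prev - 1e-12).all()       # per-agent ratchet
            assert ci.min() >= 1.0 and ci.max() <= 5.0
            prev = ci.copy()

    def test_series_lengths_and_rate_bounds(self):
        res = MarketSimulation(SimulationParams(steps=40, n_agents=200), seed=2).run()
        assert len(res.mean_pi) == 40
        assert (res.purchase_rate >= 0).all() and (res.purchase_rate <= 1).all()

    def test_plot_smoke(self):
        import matplotlib
        matplotlib.use("Agg")
        res = MarketSimulation(SimulationParams(steps=10, n_agents=100), seed=0).run()
        ax = res.plot()
        assert ax is not None


class TestExperiments:
    def test_null_intervention_is_null(self):
        res = intervention_experiment(SimulationParams(steps=40, n_agents=300),
                                      delta_ci=0.0, replicates=2, seed=3)
        assert res.uplift_vs_control == pytest.approx(0.0, abs=1e-12)

    def test_dose_monotonicity_paired(self):
        ups = []
        for d in (0.0, 0.1, 0.2):
            r = intervention_experiment(SimulationParams(), delta_ci=d,
                                        replicates=2, seed=11)
            ups.append(r.uplift_vs_control)
        assert ups[0] < ups[1] < ups[2]

    def test_empty_target_set_rejected(self):
        with pytest.raises(ValueError, match="target age"):
            intervention_experiment(delta_ci=0.1, target_ages=(), replicates=1)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError, match="delta_ci"):
            intervention_experiment(delta_ci=-0.1, replicates=1)

    def test_calibration_table_and_argmin(self):
        best, table = calibrate([0.01, 0.05], replicates=1, seed=1)
        assert best in (0.01, 0.05)
        assert set(table.columns) == {"tau", "mean_pi", "sd_pi", "distance"}
        assert len(table) == 2

    def test_calibration_null_pattern_prefers_smallest_tau(self):
        base = MarketSimulation(SimulationParams(tau=0.0), seed=2).run()
        w = base.window_stats()
        best, _ = calibrate([0.01, 0.05, 0.10],
                            targets=(w["mean_pi"], w["sd_pi"]),
                            replicates=2, seed=2)
        assert best == 0.01

    def test_calibration_empty_grid(self):
        with pytest.raises(ValueError, match="empty"):
            calibrate([], replicates=1)

    def test_sweep_single_tau_single_row(self):
        tab = sensitivity_sweep([0.05], replicates=1, seed=0,
                                params=SimulationParams(steps=40, n_agents=300))
        assert len(tab) == 1 and tab.loc[0, "tau"] == 0.05

    def test_relative_uplift_formula(self):
        assert relative_uplift(3.20, 3.83) == pytest.approx(19.6875)
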