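"""Agent-based simulator: kinematics, switching statistics, boundaries,
trajectory bookkeeping and the drift estimator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import runtumble as rt
from runtumble.simulator import (
    AgentState,
    GradientChannel,
    SimConfig,
    initialize_population,
    measure_drift,
    run_simulation,
    step_agent,
    weighted_drift,
)


class TestChannel:
    def test_linear_profile_endpoints(self):
        ch = GradientChannel(length=2000.0, c_low=5.0, c_high=105.0)
        assert ch.concentration(0.0) == 5.0
        assert ch.concentration(2000.0) == 105.0
        assert ch.concentration(1000.0) == pytest.approx(55.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            GradientChannel(c_low=-1.0)


class TestConfig:
    def test_dt_must_resolve_tumbles(self):
        with pytest.raises(ValueError):
            SimConfig(dt=0.1, tumble_time=0.2)

    def test_positive_population(self):
        with pytest.raises(ValueError):
            SimConfig(n_agents=0)


class TestInitialization:
    def test_containment_and_state(self, flat_response):
        ch = GradientChannel()
        agents = initialize_population(SimConfig(n_agents=50, seed=7),
                                       flat_response, ch)
        assert len(agents) == 50
        for a in agents:
            assert 0.0 <= a.x <= ch.width and 0.0 <= a.y <= ch.length
            assert 0.0 <= a.theta < 2 * math.pi
            assert a.running and a.m == 0.0

    def test_deterministic_given_seed(self, flat_response):
        ch = GradientChannel()
        cfg = SimConfig(n_agents=20, seed=42)
        a = initialize_population(cfg, flat_response, ch)
        b = initialize_population(cfg, flat_response, ch)
        assert all(x.x == y.x and x.y == y.y and x.theta == y.theta
                   for x, y in zip(a, b))

    def test_local_adaptation_initialization(self, flat_response):
        ch = GradientChannel(c_low=0.0, c_high=100.0)
        cfg = SimConfig(n_agents=30, seed=3, tau_adapt=3600.0, adapt_init="local")
        for a in initialize_population(cfg, flat_response, ch):
            assert a.m == pytest.approx(float(ch.concentration(a.y)))


class TestStepAgent:
    def test_deterministic_ballistic_step(self):
        """A runner with TB = 0 and no rotational diffusion advances exactly
        v dt along its heading."""
        phen = rt.Phenotype(tb0=0.0, k=1.0, rho=0.0, speed=25.0)
        model = rt.HomogeneousResponse(tb0=0.0, tb_inf=0.0, k_r=1.0, h_r=1.0)
        a = AgentState(x=100.0, y=100.0, theta=math.pi / 2, running=True,
                       phenotype=phen)
        out = step_agent(a, GradientChannel(), model, 0.02,
                         np.random.default_rng(0), rot_diffusion=0.0)
        assert out.y == pytest.approx(100.5, abs=1e-12)
        assert out.x == pytest.approx(100.0, abs=1e-9)
        assert out.running

    def test_tumbling_agent_does_not_move(self, flat_response):
        phen = rt.Phenotype(tb0=0.2, k=1.0, rho=1.0, speed=25.0)
        a = AgentState(x=50.0, y=60.0, theta=1.0, running=False, phenotype=phen)
        out = step_agent(a, GradientChannel(), flat_response, 0.02,
                         np.random.default_rng(0))
        assert (out.x, out.y) == (50.0, 60.0)

    def test_side_wall_reflection(self):
        phen = rt.Phenotype(tb0=0.0, k=1.0, rho=0.0, speed=25.0)
        model = rt.HomogeneousResponse(tb0=0.0, tb_inf=0.0, k_r=1.0, h_r=1.0)
        a = AgentState(x=0.2, y=500.0, theta=math.pi, running=True, phenotype=phen)
        out = step_agent(a, GradientChannel(), model, 0.02,
                         np.random.default_rng(0), rot_diffusion=0.0)
        assert out.x == pytest.approx(0.3)  # reflected off x = 0
        assert math.cos(out.theta) > 0      # now heading inward

    def test_open_end_respawn(self, flat_response):
        ch = GradientChannel()
        phen = rt.Phenotype(tb0=0.2, k=1.0, rho=1.0, speed=25.0)
        a = AgentState(x=500.0, y=0.2, theta=-math.pi / 2, running=True,
                       phenotype=phen)
        out = step_agent(a, ch, flat_response, 0.02, np.random.default_rng(5),
                         rot_diffusion=0.0)
        assert out.y in (0.0, ch.length)
        assert math.sin(out.theta) > 0 if out.y == 0.0 else math.sin(out.theta) < 0
        assert out.running

    def test_switching_rate_matches_prescription(self, flat_response):
        """Observed run->tumble frequency matches lambda_RT dt = 0.025 for
        TB = 0.2, tau_T = 0.2 s within 3 binomial standard errors."""
        rng = np.random.default_rng(11)
        phen = rt.Phenotype(tb0=0.2, k=1.0, rho=1.0, speed=25.0)
        n, switched = 40_000, 0
        base = AgentState(x=500.0, y=1000.0, theta=0.0, running=True,
                          phenotype=phen)
        for _ in range(n):
            out = step_agent(base, GradientChannel(), flat_response, 0.02, rng,
                             rot_diffusion=0.0)
            switched += not out.running
        p = 0.2 / (0.2 * 0.8) * 0.02
        se = math.sqrt(p * (1 - p) / n)
        assert abs(switched / n - p) < 3 * se


class TestDriftEstimator:
    def test_duration_weighted_mean(self):
        drift, _ = weighted_drift(np.array([1.0, 3.0]), np.array([1.0, 3.0]))
        assert drift == pytest.approx(2.5)

    def test_equal_velocities_identity(self, rng):
        t = rng.uniform(0.5, 10.0, 50)
        drift, sem = weighted_drift(np.full(50, 7.3), t)
        assert drift == pytest.approx(7.3)
        assert sem == pytest.approx(0.0, abs=1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_algebraic_identity_total_displacement(self, seed):
        """V_chem from V_i = dy_i/T_i equals sum(dy)/sum(T) exactly."""
        r = np.random.default_rng(seed)
        n = r.integers(2, 40)
        dy = r.normal(0, 50, n)
        t = r.uniform(0.1, 60, n)
        drift, _ = measure_drift(dy, t)
        assert drift == pytest.approx(np.sum(dy) / np.sum(t), rel=1e-10)

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            weighted_drift(np.array([1.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            weighted_drift(np.array([1.0, 2.0]), np.array([1.0, 0.0]))


class TestRunSimulation:
    def test_determinism(self, flat_response):
        cfg = SimConfig(n_agents=200, seed=9, t_max=10.0, total_time=10.0)
        a = run_simulation(cfg, flat_response, GradientChannel())
        b = run_simulation(cfg, flat_response, GradientChannel())
        np.testing.assert_array_equal(a.dy, b.dy)
        np.testing.assert_array_equal(a.duration, b.duration)

    def test_containment_and_conservation(self, r1_hom):
        """Recorded positions stay inside the channel and the active-agent
        count is conserved (every sample column is always populated)."""
        ch = GradientChannel(c_low=0.0, c_high=1000.0)
        cfg = SimConfig(n_agents=100, seed=2, t_max=20.0, total_time=20.0,
                        record=True)
        res = run_simulation(cfg, r1_hom, ch)
        assert res.positions.shape[1] == 100
        assert np.all(np.isfinite(res.positions))
        assert np.all((res.positions[..., 0] >= 0) & (res.positions[..., 0] <= ch.width))
        assert np.all((res.positions[..., 1] >= 0) & (res.positions[..., 1] <= ch.length))

    def test_at_least_n_trajectories_and_duration_cap(self, flat_response):
        cfg = SimConfig(n_agents=150, seed=4, t_max=5.0, total_time=15.0)
        res = run_simulation(cfg, flat_response, GradientChannel())
        assert res.n_trajectories >= 150
        assert np.all(res.duration <= 5.0 + 1e-9)
        assert np.all(res.duration > 0)

    def test_stationary_tumble_fraction(self, flat_response):
        """In a uniform environment the pooled tumble-time fraction matches
        the model bias (two-state Markov stationary distribution)."""
        cfg = SimConfig(n_agents=400, seed=6)
        res = run_simulation(cfg, flat_response, GradientChannel())
        assert res.tumble_fraction == pytest.approx(0.2, abs=0.01)

    def test_zero_gradient_symmetry(self, flat_response):
        cfg = SimConfig(n_agents=2000, seed=8)
        res = run_simulation(cfg, flat_response, GradientChannel())
        assert abs(res.drift) < 3 * res.drift_sem
        mean, sem = res.drift_per_trajectory
        assert abs(mean) < 3 * sem

    def test_recorded_dataframe_schema(self, flat_response):
        cfg = SimConfig(n_agents=20, seed=1, t_max=4.0, total_time=4.0,
                        record=True)
        res = run_simulation(cfg, flat_response, GradientChannel())
        df = res.to_dataframe()
        assert set(df.columns) == {"traj_id", "frame", "t_s", "x_um", "y_um",
                                   "state", "phenotype_id"}
        assert set(df["state"].unique()) <= {"run", "tumble"}
        first = df[df["traj_id"] == df["traj_id"].iloc[0]]
        assert list(first["frame"]) == list(range(len(first)))
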