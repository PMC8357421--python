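import numpy as np
import pytest
from scipy.optimize import brentq

from gridcan.network import (
    NetworkSpec, HeterogeneitySpec, build_preference_map,
    build_weight_matrix, apply_heterogeneities, WeightMatrix,
)
from gridcan.dynamics import (
    NeuronModel, SimulationConfig, feedforward_drive, step_integrator,
    step_phenomenological, step_mechanistic, simulate,
    StructuredRecurrence, DenseRecurrence, _m_inf,
)
from gridcan.trajectory import Trajectory, generate_virtual_trajectory


def _stationary_traj(arena, duration, dt=1e-3):
    n = int(round(duration / dt))
    pos = np.tile(arena.center, (n + 1, 1))
    return Trajectory(positions=pos, dt_sample=dt, arena=arena)


class TestFeedforwardDrive:
    def test_zero_velocity_gives_unit_drive(self):
        prefs = build_preference_map(4)
        B = feedforward_drive(prefs, 45.0, (0.0, 0.0))
        np.testing.assert_allclose(B, 1.0)

    def test_east_neuron_east_velocity(self):
        prefs = build_preference_map(2)
        B = feedforward_drive(prefs, 45.0, (0.002, 0.0))
        east = np.isclose(prefs.theta, 0.0)
        np.testing.assert_allclose(B[east], 1.09)

    def test_orthogonal_direction_unmodulated(self):
        prefs = build_preference_map(2)
        B = feedforward_drive(prefs, 45.0, (0.002, 0.0))
        north = np.isclose(prefs.theta, np.pi / 2)
        np.testing.assert_allclose(B[north], 1.0)


class TestSteps:
    def test_euler_decay(self):
        # zero net drive: S decays by the factor (1 - dt/tau)
        S = np.array([1.0])
        W = np.array([[0.0]])
        S1 = step_integrator(S, W, np.array([0.0]), 0.010, 1e-3)
        assert S1[0] == pytest.approx(0.9)

    def test_negative_drive_rectified(self):
        S = np.array([0.5])
        W = np.array([[0.0]])
        S1 = step_integrator(S, W, np.array([-3.0]), 0.010, 1e-3)
        assert S1[0] == pytest.approx(0.5 * 0.9)

    def test_fixed_point_is_stationary(self):
        # S = f(W S + B) stays put
        W = np.array([[0.0, -0.5], [-0.5, 0.0]])
        B = np.array([1.5, 1.5])
        S = np.array([1.0, 1.0])  # f(-0.5 + 1.5) = 1
        S1 = step_integrator(S, W, B, 0.010, 1e-3)
        np.testing.assert_allclose(S1, S)

    def test_sigmoid_midpoint(self):
        assert _m_inf(0.3, 0.3, 0.1) == pytest.approx(0.5)

    def test_phenomenological_eps0_equals_integrator(self):
        rng = np.random.default_rng(0)
        W = -rng.random((5, 5)) * 0.1
        B = rng.random(5)
        S = rng.random(5)
        state = (S.copy(), S.copy())
        for _ in range(20):
            S = step_integrator(S, W, B, 0.010, 1e-3)
            state, out = step_phenomenological(state, W, B, 0.010, 0.0, 1.0, 1e-3)
        np.testing.assert_array_equal(out, S)

    def test_mechanistic_g0_equals_integrator(self):
        rng = np.random.default_rng(1)
        W = -rng.random((5, 5)) * 0.1
        B = rng.random(5)
        S = rng.random(5)
        Sm, m = S.copy(), _m_inf(S, 0.3, 0.1)
        for _ in range(20):
            S = step_integrator(S, W, B, 0.010, 1e-3)
            Sm, m = step_mechanistic(Sm, m, W, B, 0.010, 0.0, 0.1, 0.3, 0.075, 1e-3)
        np.testing.assert_array_equal(Sm, S)

    def test_mechanistic_steady_state_matches_root(self):
        """Long-run single-neuron activity under constant drive solves
        S = f(I) - g * m_inf(S) (scalar root-finding oracle)."""
        I, g, k, S_half, tau_m = 0.8, 0.015, 0.1, 0.3, 0.075
        S_star = brentq(lambda s: s - (I - g * _m_inf(s, S_half, k)), -1, 2)
        S, m = np.array([0.0]), np.array([_m_inf(0.0, S_half, k)])
        W = np.array([[0.0]])
        for _ in range(20000):
            S, m = step_mechanistic(S, m, W, np.array([I]), 0.010, g, k,
                                    S_half, tau_m, 1e-3)
        assert S[0] == pytest.approx(S_star, abs=1e-6)


class TestRecurrence:
    def test_structured_matches_dense(self, small_spec, small_weights):
        prefs = build_preference_map(small_spec.n)
        dense = DenseRecurrence(small_weights.W)
        struct = StructuredRecurrence(small_spec, prefs)
        rng = np.random.default_rng(3)
        for _ in range(5):
            S = rng.random(small_spec.n_neurons)
            np.testing.assert_allclose(dense(S), struct(S), atol=2e-6)


class TestSimulate:
    def test_deterministic(self, small_spec, small_weights, circle_arena):
        traj = generate_virtual_trajectory(circle_arena, 0.5, seed=2)
        assign = apply_heterogeneities(small_spec, small_weights,
                                       HeterogeneitySpec(degree=0))
        cfg = SimulationConfig(init_seed=4)
        a = simulate(small_spec, assign, traj, NeuronModel(), cfg)
        b = simulate(small_spec, assign, traj, NeuronModel(), cfg)
        np.testing.assert_array_equal(a.S, b.S)

    def test_reduction_chain_bitwise(self, small_spec, small_weights,
                                     circle_arena):
        """eps=0/R=1 resonator and g=0 feedback model reproduce the
        integrator trace bit for bit."""
        traj = generate_virtual_trajectory(circle_arena, 0.5, seed=2)
        assign = apply_heterogeneities(small_spec, small_weights,
                                       HeterogeneitySpec(degree=0))
        cfg = SimulationConfig(init_seed=4)
        base = simulate(small_spec, assign, traj, NeuronModel(), cfg)
        phen = simulate(small_spec, assign, traj,
                        NeuronModel(kind="phenomenological", epsilon=0.0,
                                    R=1.0), cfg)
        mech = simulate(small_spec, assign, traj,
                        NeuronModel(kind="mechanistic", g=0.0), cfg)
        np.testing.assert_array_equal(phen.S, base.S)
        np.testing.assert_array_equal(mech.S, base.S)

    def test_integrator_nonnegative_and_bounded(self, small_spec,
                                                small_weights, circle_arena):
        """All-inhibitory recurrence: activity stays in [0, max(S0, max B)]."""
        traj = generate_virtual_trajectory(circle_arena, 1.0, seed=6)
        assign = apply_heterogeneities(small_spec, small_weights,
                                       HeterogeneitySpec(degree=0))
        trace = simulate(small_spec, assign, traj, NeuronModel(),
                         SimulationConfig(init_seed=0))
        assert trace.S.min() >= 0.0
        B_max = 1.0 + 45.0 * 0.004
        assert trace.S.max() <= max(1.0, B_max) + 1e-6

    def test_settling_forms_multibump_pattern(self, circle_arena):
        """Zero-velocity settling on the 60-lattice produces a stationary
        pattern with a bump count set by the weight-kernel period."""
        from scipy import ndimage

        spec = NetworkSpec(n=60)
        traj = _stationary_traj(circle_arena, 0.3)
        assign = apply_heterogeneities(
            spec, WeightMatrix(W=None, spec=spec), HeterogeneitySpec(degree=0))
        trace = simulate(spec, assign, traj, NeuronModel(),
                         SimulationConfig(init_seed=7, settle=1.0))
        sheet = trace.S[-1].reshape(60, 60)
        # convergence: residual motion shrinks and is small at the end
        early = np.abs(trace.S[50] - trace.S[0]).max()
        late = np.abs(trace.S[-1] - trace.S[-50]).max()
        assert late < 5e-3
        assert late < early
        smooth = ndimage.gaussian_filter(sheet, 1.0, mode="wrap")
        mx = ndimage.maximum_filter(smooth, size=9, mode="wrap")
        n_bumps = int(((smooth == mx) & (smooth > 0.5 * smooth.max())).sum())
        # lambda = 13 gives a sheet period near 15 -> (60/15)*(60/13) ~ 16-18
        assert 10 <= n_bumps <= 26

    def test_dt_mismatch_rejected(self, small_spec, small_weights,
                                  circle_arena):
        traj = generate_virtual_trajectory(circle_arena, 0.1, seed=1,
                                           dt_sample=5e-4)
        assign = apply_heterogeneities(small_spec, small_weights,
                                       HeterogeneitySpec(degree=0))
        with pytest.raises(ValueError, match="dt"):
            simulate(small_spec, assign, traj, NeuronModel(),
                     SimulationConfig(dt=1e-3))

    def test_euler_stability_guard(self, small_spec, small_weights,
                                   circle_arena):
        traj = generate_virtual_trajectory(circle_arena, 0.1, seed=1)
        assign = apply_heterogeneities(small_spec, small_weights,
                                       HeterogeneitySpec(degree=0))
        bad = type(assign)(tau_i=np.full(small_spec.n_neurons, 5e-4),
                           alpha_i=assign.alpha_i, weights=assign.weights)
        with pytest.raises(ValueError, match="stability"):
            simulate(small_spec, bad, traj, NeuronModel(),
                     SimulationConfig(dt=1e-3))

    def test_divergence_aborts(self, small_spec, circle_arena):
        # strongly excitatory recurrence blows up and must be caught
        N = small_spec.n_neurons
        W = WeightMatrix(W=np.full((N, N), 0.5, dtype=np.float32),
                         spec=small_spec, jitter_seed=0)
        assign = apply_heterogeneities(small_spec, W,
                                       HeterogeneitySpec(degree=0))
        assign.weights = W
        traj = generate_virtual_trajectory(circle_arena, 20.0, seed=1)
        with pytest.raises(FloatingPointError):
            simulate(small_spec, assign, traj, NeuronModel(),
                     SimulationConfig(init_seed=0))
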