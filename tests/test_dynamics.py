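"""RNN stepping, Jacobians, overflow-safe linear dynamics, order parameter."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from levynet.dynamics import (
    FeedforwardConfig,
    GaussianInput,
    LogLinearState,
    order_parameter,
    order_parameter_gain_sweep,
    rnn_jacobian,
    simulate_feedforward,
    simulate_linear,
    simulate_rnn,
    step_rnn,
)
from levynet.stable import NetworkConfig
from levynet.theory import critical_gain, xi_monte_carlo


class TestStepRnn:
    def test_quiescent_state_is_fixed_point(self):
        w = np.random.default_rng(0).standard_normal((5, 5))
        assert np.all(step_rnn(np.zeros(5), w) == 0.0)

    def test_hand_evaluated_two_unit_step(self):
        out = step_rnn([0.5, -0.25], [[0.0, 1.0], [1.0, 0.0]])
        assert out == pytest.approx([math.tanh(-0.25), math.tanh(0.5)], abs=1e-12)

    def test_outputs_strictly_inside_unit_interval(self, rng):
        # moderate preactivations: strictly inside (-1, 1) even in floats
        w = rng.standard_normal((20, 20))
        out = step_rnn(rng.uniform(-1, 1, 20), w, rng.standard_normal(20))
        assert np.all(np.abs(out) < 1.0)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            step_rnn(np.zeros(3), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            step_rnn(np.zeros(2), np.zeros((2, 2)), np.zeros(3))


class TestJacobian:
    def test_equals_weights_at_quiescent_point(self, rng):
        w = rng.standard_normal((6, 6))
        assert np.array_equal(rnn_jacobian(np.zeros(6), w), w)

    def test_row_scalings_in_unit_interval(self, rng):
        x = np.tanh(rng.standard_normal(8))
        w = rng.standard_normal((8, 8))
        scaling = rnn_jacobian(x, w) / w
        assert np.all(scaling > 0.0) and np.all(scaling <= 1.0)

    def test_matches_finite_differences(self, rng):
        n = 7
        w = rng.standard_normal((n, n))
        x = rng.uniform(-0.9, 0.9, n)
        inp = rng.standard_normal(n)
        x_next = step_rnn(x, w, inp)
        jac = rnn_jacobian(x_next, w)
        h = 1e-6
        fd = np.empty((n, n))
        for j in range(n):
            e = np.zeros(n)
            e[j] = h
            fd[:, j] = (step_rnn(x + e, w, inp) - step_rnn(x - e, w, inp)) / (2 * h)
        assert np.allclose(jac, fd, atol=1e-6)


class TestSimulateRnn:
    def test_zero_gain_collapses_to_zero(self):
        cfg = NetworkConfig(n_units=10, alpha=1.5, gain=0.0, seed=1)
        traj = simulate_rnn(cfg, horizon=5)
        assert np.all(traj.states[1:] == 0.0)
        assert traj.states.shape == (6, 10)

    def test_zero_gain_with_input_is_tanh_of_input(self):
        cfg = NetworkConfig(n_units=4, alpha=2.0, gain=0.0, seed=2)
        inputs = np.random.default_rng(3).standard_normal((6, 4))
        traj = simulate_rnn(cfg, horizon=6, input_spec=inputs)
        assert np.allclose(traj.states[1:], np.tanh(inputs))

    def test_subcritical_network_decays_to_quiescence(self, rng):
        # gain far below the Gaussian critical gain 1/sqrt(2)
        cfg = NetworkConfig(n_units=200, alpha=2.0, gain=0.07, seed=5)
        traj = simulate_rnn(cfg, horizon=500)
        assert np.max(np.abs(traj.final_state())) < 1e-6

    def test_trajectory_roundtrip(self, tmp_path):
        from levynet.dynamics import load_trajectory, save_trajectory

        cfg = NetworkConfig(n_units=8, alpha=1.5, gain=0.4, seed=6)
        traj = simulate_rnn(cfg, 12, input_spec=GaussianInput(0.01))
        save_trajectory(tmp_path / "run", traj, cfg, GaussianInput(0.01))
        traj2, cfg2 = load_trajectory(tmp_path / "run")
        assert np.array_equal(traj.states, traj2.states)
        assert cfg2 == cfg and traj2.input_kind == "gaussian_noise"

    def test_seed_reproducibility_with_noise(self):
        cfg = NetworkConfig(n_units=20, alpha=1.0, gain=0.5, seed=9)
        t1 = simulate_rnn(cfg, 50, input_spec=GaussianInput(0.01))
        t2 = simulate_rnn(cfg, 50, input_spec=GaussianInput(0.01))
        assert np.array_equal(t1.states, t2.states)
        assert t1.input_kind == "gaussian_noise"


class TestSimulateLinear:
    def test_rotation_preserves_log_magnitude(self):
        th = 0.31
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        cfg = NetworkConfig(n_units=2, alpha=2.0, gain=1.0, seed=0)
        run = simulate_linear(cfg, "quenched", 57, initial=np.array([1.0, 0.0]), weights=rot)
        assert abs(run.final.log_magnitude) < 1e-10

    def test_scaled_identity_grows_exactly(self):
        c, depth, n = 0.5, 30, 4
        cfg = NetworkConfig(n_units=n, alpha=2.0, gain=1.0, seed=0)
        init = np.full(n, 2.0)
        run = simulate_linear(cfg, "quenched", depth, initial=init, weights=c * np.eye(n))
        expected = depth * math.log(abs(c)) + math.log(np.linalg.norm(init))
        assert run.final.log_magnitude == pytest.approx(expected, abs=1e-10)

    def test_direction_stays_unit_norm(self):
        cfg = NetworkConfig(n_units=50, alpha=1.0, gain=2.0, seed=7)
        run = simulate_linear(cfg, "annealed", 40)
        assert np.linalg.norm(run.final.direction) == pytest.approx(1.0, abs=1e-12)

    def test_no_overflow_far_above_transition(self):
        # 100 steps at gain 50: |eps| ~ exp(400); must stay finite in log space
        cfg = NetworkConfig(n_units=100, alpha=1.0, gain=50.0, seed=3)
        run = simulate_linear(cfg, "annealed", 100)
        assert np.isfinite(run.final.log_magnitude)
        assert run.final.log_magnitude > 100.0

    def test_zero_initial_rejected(self):
        cfg = NetworkConfig(n_units=5, alpha=1.0, gain=1.0, seed=0)
        with pytest.raises(ValueError):
            simulate_linear(cfg, "quenched", 5, initial=np.zeros(5))

    def test_annealed_alpha_norm_growth_matches_scalar_recursion_mean(self, rng):
        """Stability property: mean per-step log alpha-norm growth = ln g + Xi."""
        n, depth, alpha = 500, 200, 1.0
        gain = 0.7
        cfg = NetworkConfig(n_units=n, alpha=alpha, gain=gain, seed=21)
        growths = []
        for seed in range(6):
            run = simulate_linear(cfg.replace(seed=100 + seed), "annealed", depth)
            growths.append(run.log_growth_alpha)
        growths = np.concatenate(growths)
        pred = xi_monte_carlo(n, alpha, 4000, rng)
        expected = math.log(gain) + pred.xi
        se = growths.std(ddof=1) / math.sqrt(len(growths))
        assert abs(growths.mean() - expected) < 3 * math.hypot(se, pred.xi_stderr)


class TestQuenchedLinear:
    def test_growth_rate_converges_to_spectral_radius(self):
        """Long products of one fixed matrix grow at ln(spectral radius)."""
        rng = np.random.default_rng(8)
        n = 100
        w = 0.8 * rng.standard_normal((n, n)) / math.sqrt(n)
        cfg = NetworkConfig(n_units=n, alpha=2.0, gain=1.0, seed=8)
        run = simulate_linear(cfg, "quenched", 600, rng=rng, weights=w)
        rate = run.log_growth[-200:].mean()
        exact = math.log(np.max(np.abs(np.linalg.eigvals(w))))
        assert rate == pytest.approx(exact, abs=1e-3)

    def test_transition_gain_disperses_more_in_small_networks(self):
        """Across quenched realizations (alpha=1), the per-realization
        escape gain varies more at N=100 than at N=3000."""

        def escape_gains(n, n_real, seed):
            gains = np.geomspace(0.02, 2.0, 60)
            out = []
            for s in range(n_real):
                cfg = NetworkConfig(n_units=n, alpha=1.0, gain=1.0, seed=seed + s)
                run = simulate_linear(cfg, "quenched", 100, track_alpha_norm=False)
                f = order_parameter_gain_sweep(run, gains, 0.1)
                idx = np.argmax(f < 0.5)  # first gain with most components escaped
                out.append(math.log(gains[idx]))
            return np.array(out)

        small = escape_gains(100, 20, 500)
        large = escape_gains(3000, 20, 900)
        assert small.std(ddof=1) > large.std(ddof=1)

    def test_annealed_window_contains_theory_gain(self):
        """The annealed escape happens between 0.5x and 2x the predicted
        critical gain for both Gaussian and Cauchy networks."""
        for alpha in (1.0, 2.0):
            g_star = critical_gain(100, alpha, n_samples=4000, rng=17)
            cfg = NetworkConfig(n_units=100, alpha=alpha, gain=1.0, seed=23)
            fr = np.array([
                order_parameter_gain_sweep(
                    simulate_linear(cfg.replace(seed=23 + s), "annealed", 100,
                                    track_alpha_norm=False),
                    [0.5 * g_star, 2.0 * g_star], 0.1,
                )
                for s in range(5)
            ])
            assert np.all(fr[:, 0] == 1.0)
            assert np.all(fr[:, 1] == 0.0)


class TestOrderParameter:
    def test_limiting_values_and_fraction(self):
        assert order_parameter(np.zeros(8), 0.1) == 1.0
        assert order_parameter(np.array([0.5, -0.3, 0.9]), 0.1) == 0.0
        assert order_parameter(np.array([0.05, 0.5, -0.9, 0.3]), 0.1) == 0.25

    def test_log_space_evaluation_handles_huge_magnitudes(self):
        # |eps| ~ exp(500): far beyond double range, still classified correctly
        state = LogLinearState(direction=np.array([1.0, 1e-300]), log_magnitude=500.0)
        assert order_parameter(state, 0.1) == 0.5

    @given(
        st.lists(st.floats(-10, 10), min_size=1, max_size=30),
        st.floats(1e-3, 5.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_fraction_bounds_property(self, comps, eps):
        f = order_parameter(np.array(comps), eps)
        assert 0.0 <= f <= 1.0
        assert f * len(comps) == pytest.approx(round(f * len(comps)))

    def test_gain_sweep_matches_direct_runs(self):
        """Rescaling a unit-gain run must agree with simulating each gain."""
        n, depth = 80, 40
        base_cfg = NetworkConfig(n_units=n, alpha=1.0, gain=1.0, seed=13)
        init = np.random.default_rng(13).uniform(-1, 1, n)
        base = simulate_linear(base_cfg, "quenched", depth, initial=init)
        gains = [0.0, 0.3, 1.0, 2.7]
        swept = order_parameter_gain_sweep(base, gains, threshold=0.1)
        for g, f_swept in zip(gains, swept):
            if g == 0.0:
                assert f_swept == 1.0
                continue
            direct = simulate_linear(
                NetworkConfig(n_units=n, alpha=1.0, gain=g, seed=13),
                "quenched",
                depth,
                initial=init,
            )
            assert order_parameter(direct.final, 0.1) == f_swept


class TestFeedforward:
    def test_constant_width_matches_annealed_dimension(self):
        ff = FeedforwardConfig(layer_widths=(8, 8, 8), alpha=1.5, gain=0.5, seed=2)
        out = simulate_feedforward(ff, np.linspace(-1, 1, 8))
        assert out.shape == (8,)
        assert np.all(np.abs(out) < 1.0)

    def test_varying_widths(self):
        ff = FeedforwardConfig(layer_widths=(5, 9, 3), alpha=2.0, gain=1.0, seed=4)
        out = simulate_feedforward(ff, np.ones(5))
        assert out.shape == (3,)

    def test_invalid_widths_rejected(self):
        with pytest.raises(ValueError):
            FeedforwardConfig(layer_widths=(5,), alpha=1.0, gain=1.0)
        with pytest.raises(ValueError):
            FeedforwardConfig(layer_widths=(5, 0), alpha=1.0, gain=1.0)
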