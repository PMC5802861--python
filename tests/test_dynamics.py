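"""Unit tests for the rate-network dynamics layer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fullforce import (
    NetworkParams,
    NumericalError,
    WeightSet,
    init_random_weights,
    readout,
    simulate,
    step_driven_network,
    step_force_network,
    step_task_network,
)


class TestParams:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            NetworkParams(n_units=0)
        with pytest.raises(ValueError):
            NetworkParams(n_units=10, dt=5.0, tau=10.0)  # dt > tau/5
        with pytest.raises(ValueError):
            NetworkParams(n_units=10, g=-0.1)
        with pytest.raises(ValueError):
            NetworkParams(n_units=10, nonlinearity="relu")


class TestInitRandomWeights:
    def test_recurrent_variance_matches_g(self):
        params = NetworkParams(n_units=300, g=1.5)
        ws = init_random_weights(params, seed=0)
        expected = 1.5**2 / 300
        assert np.var(ws.J) == pytest.approx(expected, rel=0.2)

    def test_zero_gain_gives_zero_matrix(self):
        ws = init_random_weights(NetworkParams(n_units=50, g=0.0), seed=0)
        assert np.all(ws.J == 0.0)

    def test_input_vectors_uniform_and_readout_zero(self):
        ws = init_random_weights(NetworkParams(n_units=500), seed=3)
        for v in (ws.u_in, ws.u, ws.u_hint):
            assert np.all(np.abs(v) <= 1.0)
            assert np.std(v) == pytest.approx(1.0 / np.sqrt(3.0), rel=0.15)
        assert np.all(ws.w == 0.0)

    def test_same_seed_reproduces_weights(self):
        params = NetworkParams(n_units=40)
        a = init_random_weights(params, seed=9)
        b = init_random_weights(params, seed=9)
        assert np.array_equal(a.J, b.J) and np.array_equal(a.u_in, b.u_in)

    def test_spectral_radius_near_g(self):
        # Circular law: eigenvalues of J fill a disk of radius ~g.
        ws = init_random_weights(NetworkParams(n_units=1000, g=1.5), seed=1)
        radius = np.abs(np.linalg.eigvals(ws.J)).max()
        assert 1.3 <= radius <= 1.7


class TestStepping:
    def test_origin_is_fixed_point_without_input(self, small_params):
        n = small_params.n_units
        ws = WeightSet(J=np.zeros((n, n)), u_in=np.zeros(n), u=np.zeros(n),
                       u_hint=np.zeros(n), w=np.zeros(n))
        x = step_task_network(np.zeros(n), ws, 0.0, None, small_params)
        assert np.all(x == 0.0)

    def test_constant_input_fixed_point(self, small_params, rng):
        # With J=0 and x = u_in * c, dx/dt = 0 exactly.
        n = small_params.n_units
        u_in = rng.uniform(-1, 1, n)
        ws = WeightSet(J=np.zeros((n, n)), u_in=u_in, u=np.zeros(n),
                       u_hint=np.zeros(n), w=np.zeros(n))
        c = 0.7
        x = u_in * c
        x_next = step_task_network(x, ws, c, None, small_params)
        assert x_next == pytest.approx(x, abs=1e-14)

    def test_leak_decay_matches_closed_form(self, small_params, rng):
        n = small_params.n_units
        ws = WeightSet(J=np.zeros((n, n)), u_in=np.zeros(n), u=np.zeros(n),
                       u_hint=np.zeros(n), w=np.zeros(n))
        x0 = rng.normal(size=n)
        x = x0.copy()
        k = 25
        for _ in range(k):
            x = step_task_network(x, ws, 0.0, None, small_params)
        decay = (1.0 - small_params.dt / small_params.tau) ** k
        assert x == pytest.approx(x0 * decay, rel=1e-12)

    def test_zero_feedback_equals_task_step(self, small_params, small_weights, rng):
        x = rng.normal(size=small_params.n_units)
        a = step_task_network(x, small_weights, 0.3, None, small_params)
        b = step_force_network(x, small_weights, 0.3, 0.0, None, small_params)
        assert np.array_equal(a, b)

    def test_teacher_forced_feedback_equals_driven_dynamics(self, small_params, rng):
        # Feedback of f_out through u reproduces the driven network when
        # the recurrences match and the hint is zero.
        ws = init_random_weights(small_params, seed=5)
        T = 120
        f_in = np.sin(np.arange(T) / 10.0)
        f_out = np.cos(np.arange(T) / 7.0)
        x0 = rng.uniform(-0.1, 0.1, small_params.n_units)
        forced = simulate(small_params, ws, f_in, mode="force", f_out=f_out,
                          teacher_force=True, x0=x0)
        driven = simulate(small_params, ws, f_in, mode="driven", f_out=f_out,
                          x0=x0)
        assert forced.x == pytest.approx(driven.x, abs=1e-12)

    def test_zero_hint_driven_step_matches_plain_driven(self, small_params,
                                                        small_weights, rng):
        x = rng.normal(size=small_params.n_units)
        a = step_driven_network(x, small_weights, 0.2, 0.5, 0.0, small_params)
        ws2 = small_weights.copy()
        ws2.u_hint[:] = 0.0
        b = step_driven_network(x, ws2, 0.2, 0.5, 0.9, small_params)
        assert np.array_equal(a, b)

    def test_nonfinite_state_raises_with_step_index(self, small_params,
                                                    small_weights):
        x = np.full(small_params.n_units, 1e308)
        x[0] = np.inf
        with pytest.raises(NumericalError, match="step 3"):
            step_task_network(x, small_weights, 0.0, None, small_params, step=3)

    def test_rates_bounded_and_trajectory_bounded(self, small_params, rng):
        ws = init_random_weights(small_params, seed=2)
        T = 2000
        f_in = np.ones(T)
        trace = simulate(small_params, ws, f_in, mode="task",
                         x0=rng.uniform(-1, 1, small_params.n_units))
        assert np.all(np.abs(trace.rates) <= 1.0)
        bound = np.abs(ws.J).sum(axis=1).max() + np.abs(ws.u_in).max() + 1.0
        assert np.all(np.abs(trace.x) <= bound)

    def test_euler_first_order_convergence(self):
        # Halving dt changes a fixed-horizon trajectory by O(dt): the
        # deviation from a quarter-step reference halves too.
        n = 12
        ws = init_random_weights(NetworkParams(n_units=n), seed=8)
        horizon = 500.0
        x0 = np.random.default_rng(0).uniform(-0.5, 0.5, n)

        def final_state(dt):
            params = NetworkParams(n_units=n, dt=dt)
            T = int(round(horizon / dt))
            f_in = np.sin(np.arange(T) * dt / 50.0)
            return simulate(params, ws, f_in, mode="task", x0=x0).x[-1]

        ref = final_state(0.25)
        err1 = np.linalg.norm(final_state(1.0) - ref)
        err2 = np.linalg.norm(final_state(0.5) - ref)
        assert err2 < 0.75 * err1


class TestReadout:
    def test_zero_cases(self, rng):
        assert readout(rng.normal(size=5), np.zeros(5)) == 0.0
        assert readout(np.zeros(5), rng.normal(size=5)) == 0.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            readout(np.zeros(4), np.zeros(5))

    @settings(deadline=None, max_examples=25)
    @given(st.integers(min_value=1, max_value=30), st.integers(0, 2**31 - 1))
    def test_matches_elementwise_loop(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        w = rng.normal(size=n)
        expected = sum(w[i] * np.tanh(x[i]) for i in range(n))
        assert readout(x, w) == pytest.approx(expected, abs=1e-12)


class TestChaosAndSuppression:
    def test_undriven_chaotic_network_diverges(self):
        # g = 1.5 > 1: a 1e-6 per-unit perturbation of an undriven
        # trajectory is amplified to order-one separation within a few
        # seconds (positive Lyapunov exponent).
        from fullforce import _kernels

        params = NetworkParams(n_units=500)
        ws = init_random_weights(params, seed=4)
        # Finite random networks at g = 1.5 can be multistable (a stable
        # limit cycle coexists with the chaotic sea); this initial state
        # lies in the chaotic basin.
        rng = np.random.default_rng(1)
        x0 = rng.uniform(-1, 1, 500)
        T = 5000
        f_in = np.zeros(T)
        dtau = params.dt / params.tau
        _, Xa = _kernels.sim_task_kernel(ws.J, ws.u_in, ws.w, x0.copy(),
                                         f_in, 0.0, dtau, 1, 1)
        _, Xb = _kernels.sim_task_kernel(ws.J, ws.u_in, ws.w, x0 + 1e-6,
                                         f_in, 0.0, dtau, 1, 1)
        sep = np.linalg.norm(Xa - Xb, axis=1)
        assert sep[-1] > 0.5
        assert sep[-1] > 1e4 * sep[0]

    def test_driven_network_forgets_initial_conditions(self):
        # The oscillation drive suppresses chaos: trajectories from
        # distinct random initial states converge (echo-state property),
        # in contrast to the undriven divergence above.
        from fullforce import _kernels, make_oscillation_stream

        params = NetworkParams(n_units=300)
        ws = init_random_weights(params, seed=4)
        trial = make_oscillation_stream(4, params.dt)
        rng = np.random.default_rng(1)
        x0a = rng.uniform(-1, 1, 300)
        x0b = rng.uniform(-1, 1, 300)
        dtau = params.dt / params.tau
        _, Ra = _kernels.sim_driven_kernel(ws.J, ws.u, ws.u_in, ws.u_hint,
                                           x0a, trial.f_in, trial.f_out,
                                           trial.f_hint, dtau, 1)
        _, Rb = _kernels.sim_driven_kernel(ws.J, ws.u, ws.u_in, ws.u_hint,
                                           x0b, trial.f_in, trial.f_out,
                                           trial.f_hint, dtau, 1)
        d = np.linalg.norm(Ra - Rb, axis=1)
        assert d[-1] < 0.02 * d[0]
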