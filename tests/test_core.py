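import numpy as np
import pytest

import bcmring as b


class TestResponseAndThreshold:
    def test_response_basics(self):
        assert b.response(np.zeros(4), np.ones(4)) == 0.0
        e2 = np.eye(4)[2]
        assert b.response(e2, np.array([5.0, 6.0, 7.0, 8.0])) == 7.0
        assert b.response(np.array([1.0, 2.0]), np.array([3.0, 4.0])) == 11.0
        with pytest.raises(ValueError, match="mismatch"):
            b.response(np.zeros(3), np.zeros(4))

    def test_batch_threshold_identity_ensemble(self):
        ens = b.ensemble_from_profile(b.delta_profile(6))
        w = 6.0 * np.eye(6)[1]
        assert b.batch_threshold(np.zeros(6), ens) == 0.0
        assert b.batch_threshold(w, ens) == pytest.approx(6.0)

    def test_batch_threshold_matches_loop(self, vm8, rng):
        w = rng.normal(size=8)
        loop = sum(b.response(w, vm8.matrix[:, k]) ** 2 for k in range(8)) / 8
        assert b.batch_threshold(w, vm8) == pytest.approx(loop, rel=1e-12)


class TestStep:
    def test_step_is_null_at_selective_fixed_point(self, vm8):
        fp = b.selective_fixed_point(vm8, 2)
        params = b.BCMParams()
        state = b.BCMState(weights=fp.weights)
        # the selective stimulus: y = theta so y(y - theta) = 0
        new = b.bcm_step(state, vm8.matrix[:, 2], params, vm8)
        np.testing.assert_allclose(new.weights, fp.weights, rtol=1e-12)
        # any non-selective stimulus: y = 0
        new = b.bcm_step(state, vm8.matrix[:, 5], params, vm8)
        np.testing.assert_allclose(new.weights, fp.weights, rtol=1e-12)

    @pytest.mark.parametrize("mode", ["averaged", "online"])
    def test_step_matches_scalar_computation(self, vm4, mode):
        params = b.BCMParams(threshold_mode=mode, tau_theta=50.0 if mode == "online" else None)
        w = np.array([0.3, -1.2, 2.0, 0.7])
        theta0 = 1.5
        x = vm4.matrix[:, 1]
        y = sum(w[i] * x[i] for i in range(4))
        if mode == "averaged":
            theta = sum(sum(w[i] * vm4.matrix[i, k] for i in range(4)) ** 2 for k in range(4)) / 4
        else:
            theta = theta0 + (-theta0 + y * y) / 50.0
        expected = [w[i] + x[i] * y * (y - theta) / params.tau_w for i in range(4)]
        new = b.bcm_step(b.BCMState(weights=w, theta=theta0), x, params, vm4)
        np.testing.assert_allclose(new.weights, expected, rtol=1e-12)
        assert new.theta == pytest.approx(theta)
        assert new.step == 1


class TestDrift:
    def test_drift_zero_weights(self, vm8):
        np.testing.assert_array_equal(b.averaged_drift(np.zeros(8), vm8), np.zeros(8))

    def test_drift_vanishes_at_fixed_point(self, vm8):
        fp = b.selective_fixed_point(vm8, 3)
        assert np.linalg.norm(b.averaged_drift(fp.weights, vm8)) < 1e-8 * np.linalg.norm(vm8.matrix)

    def test_drift_matches_term_by_term_loop(self, vm4, rng):
        w = rng.normal(size=4)
        y = [b.response(w, vm4.matrix[:, k]) for k in range(4)]
        theta = sum(v * v for v in y) / 4
        expected = [
            sum(vm4.matrix[i, k] * y[k] * (y[k] - theta) for k in range(4)) for i in range(4)
        ]
        np.testing.assert_allclose(b.averaged_drift(w, vm4), expected, rtol=1e-12)

    def test_drift_scale_covariance(self, vm8, rng):
        w = rng.normal(size=8)
        c = 2.0
        y = vm8.matrix.T @ w
        theta = np.mean(y * y)
        explicit = vm8.matrix @ ((c * y) * (c * y - c * c * theta))
        np.testing.assert_allclose(b.averaged_drift(c * w, vm8), explicit, rtol=1e-12)


class TestSimulate:
    def test_fixed_point_is_invariant(self, vm8):
        fp = b.selective_fixed_point(vm8, 0)
        params = b.BCMParams(seed=0, max_steps=5000)
        traj = b.simulate(vm8, params, fp.weights, record_every=500)
        drift = np.linalg.norm(traj.final_weights - fp.weights) / np.linalg.norm(fp.weights)
        assert drift < 1e-10

    def test_same_seed_bit_identical(self, vm8):
        fp1 = b.selective_fixed_point(vm8, 0)
        fp2 = b.selective_fixed_point(vm8, 1)
        w0 = b.mixed_initial_condition(fp1, fp2, 0.1)
        params = b.BCMParams(seed=7, max_steps=20_000)
        t1 = b.simulate(vm8, params, w0, record_every=100)
        t2 = b.simulate(vm8, params, w0, record_every=100)
        np.testing.assert_array_equal(t1.weight_history, t2.weight_history)
        np.testing.assert_array_equal(t1.theta_history, t2.theta_history)

    @pytest.mark.parametrize("mode", ["averaged", "online"])
    def test_simulate_agrees_with_stepwise_updates(self, vm8, rng, mode):
        w0 = rng.uniform(0, 1, 8)
        schedule = rng.integers(0, 8, size=24)
        params = b.BCMParams(threshold_mode=mode, max_steps=24)
        traj = b.simulate(vm8, params, w0, record_every=1, schedule=schedule)
        state = b.BCMState(weights=w0.copy())
        if mode == "online":
            state.theta = b.batch_threshold(w0, vm8)
        for k in schedule:
            state = b.bcm_step(state, vm8.matrix[:, k], params, vm8)
        np.testing.assert_allclose(traj.final_weights, state.weights, rtol=1e-10)

    def test_mixed_init_converges_toward_first_fixed_point(self, vm8):
        fp1 = b.selective_fixed_point(vm8, 0)
        fp2 = b.selective_fixed_point(vm8, 1)
        w0 = b.mixed_initial_condition(fp1, fp2, 0.1)
        params = b.BCMParams(seed=0, max_steps=250_000)
        traj = b.simulate(vm8, params, w0, record_every=1000)
        a0 = b.angle_to_target(w0, fp1.weights)
        a_end = b.angle_to_target(traj.final_weights, fp1.weights)
        assert a_end < 0.1 * a0

    def test_divergence_raises_with_step(self, vm8):
        fp1 = b.selective_fixed_point(vm8, 0)
        w0 = 1.5 * fp1.weights  # off the manifold; huge learning rate blows up
        params = b.BCMParams(tau_w=1.0, seed=0, max_steps=50_000)
        with pytest.raises(b.SimulationDivergedError, match="step"):
            b.simulate(vm8, params, w0, record_every=1000)

    @pytest.mark.parametrize("n", [8, 10])
    def test_online_and_averaged_agree_on_winner(self, n):
        """With tau_theta << tau_w the (N+1)-dim online system selects the
        same stimulus as the reduced averaged system."""
        ens = b.build_ensemble("von_mises", n, n, 0.5)
        fp1 = b.selective_fixed_point(ens, 0)
        fp2 = b.selective_fixed_point(ens, 1)
        w0 = b.mixed_initial_condition(fp1, fp2, 0.1)
        winners = {}
        for mode in ("averaged", "online"):
            params = b.BCMParams(
                threshold_mode=mode,
                tau_theta=10.0 if mode == "online" else None,
                seed=0,
                max_steps=60_000,
            )
            traj = b.simulate(ens, params, w0, record_every=5000)
            winners[mode] = int(np.argmax(ens.matrix.T @ traj.final_weights))
        assert winners["averaged"] == winners["online"] == 0

    def test_record_times_strictly_increasing(self, vm8):
        fp = b.selective_fixed_point(vm8, 0)
        traj = b.simulate(vm8, b.BCMParams(max_steps=1037), fp.weights, record_every=100)
        assert traj.times[0] == 0 and traj.times[-1] == 1037
        assert np.all(np.diff(traj.times) > 0)


class TestDriftIntegrator:
    def test_matches_linearized_decay(self, vm4):
        """Euler flow of the summed drift relaxes a critical-mode
        perturbation at rate |lambda_crit|/tau_w."""
        fp = b.selective_fixed_point(vm4, 0)
        spec = b.eigen_spectrum(vm4.profile, tau_w=1000.0)
        v = np.array([1.0, -1.0, 1.0, -1.0])  # m = N/2 mode
        w0 = fp.weights + 1e-3 * np.linalg.norm(fp.weights) * v / np.linalg.norm(v)
        traj = b.integrate_drift(vm4, w0, tau_w=1000.0, n_steps=2000, record_every=5)
        trace = b.trace_convergence(traj, fp, normalize=True)
        fit = b.fit_time_constant(trace)
        assert fit.tau_sim == pytest.approx(spec.tau_crit, rel=0.05)


def test_params_validation():
    with pytest.raises(ValueError, match="tau_w"):
        b.BCMParams(tau_w=0.0)
    with pytest.raises(ValueError, match="tau_theta"):
        b.BCMParams(threshold_mode="online", tau_theta=2000.0)
    with pytest.raises(ValueError, match="threshold_mode"):
        b.BCMParams(threshold_mode="batch")
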