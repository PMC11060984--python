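import numpy as np
import pytest
from dataclasses import replace

from mskpinn.dynamics import (
    ActivationParams,
    ElbowModel,
    MuscleParams,
    Trial,
    _torque_scalar,
    activation,
    active_force_length,
    eom_residual,
    excitation_from_emg,
    fiber_state,
    force_velocity,
    joint_torque,
    mt_force,
    mt_length_and_moment_arm,
    passive_force_length,
    simulate_motion,
)


class TestActivation:
    def test_endpoints_for_any_shape_factor(self):
        for A in (0.2, -0.5, 1.0, 3.0):
            assert activation(0.0, A) == pytest.approx(0.0, abs=1e-15)
            assert activation(1.0, A) == pytest.approx(1.0, rel=1e-12)

    def test_reference_value(self):
        # direct evaluation of the exponential shape map at u = 1/2
        expected = (np.exp(0.1) - 1.0) / (np.exp(0.2) - 1.0)
        assert activation(0.5, 0.2) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.47502, abs=1e-5)

    def test_convex_below_identity_for_positive_shape(self):
        u = np.linspace(0.01, 0.99, 50)
        a = activation(u, 0.2)
        assert np.all(a < u)
        assert np.all(np.diff(a) > 0)  # monotone
        assert np.all(np.diff(a, 2) > 0)  # convex

    def test_zero_shape_factor_rejected(self):
        with pytest.raises(ValueError):
            activation(0.5, 0.0)
        with pytest.raises(ValueError):
            ActivationParams(d=0.08, A=0.0)

    def test_excitation_clipped_before_mapping(self):
        assert activation(1.7, 0.2) == pytest.approx(1.0)
        assert activation(-0.3, 0.2) == pytest.approx(0.0)


class TestExcitation:
    def test_zero_delay_is_identity(self):
        t = np.linspace(0, 1, 50)
        e = np.sin(t)
        assert np.allclose(excitation_from_emg(e, t, 0.0), e)

    def test_constant_signal_invariant_under_delay(self):
        t = np.linspace(0, 2, 100)
        e = np.full_like(t, 0.7)
        assert np.allclose(excitation_from_emg(e, t, 0.33), 0.7)

    def test_reference_delay_shifts_signal(self):
        t = np.arange(0, 10, 0.02)
        e = np.sin(2 * np.pi * t)
        u = excitation_from_emg(e, t, 0.08)
        assert np.allclose(u[4:], e[:-4], atol=1e-12)
        assert np.allclose(u[:4], e[0])  # padded with the first sample

    def test_delay_exceeding_span_rejected(self):
        t = np.linspace(0, 1, 10)
        with pytest.raises(ValueError, match="delay exceeds"):
            excitation_from_emg(np.zeros(10), t, 2.0)


class TestGeometry:
    def test_right_angle_reference_values(self):
        lmt, r = mt_length_and_moment_arm(np.pi / 2, 0.3, 0.8, sign=1)
        assert lmt == pytest.approx(np.sqrt(0.73), rel=1e-12)
        assert abs(r) == pytest.approx(0.3 * 0.8 / np.sqrt(0.73), rel=1e-12)
        assert abs(r) == pytest.approx(0.28090, abs=1e-5)

    def test_moment_arm_vanishes_toward_full_extension(self):
        _, r = mt_length_and_moment_arm(1e-6, 0.3, 0.8, sign=1)
        assert abs(r) < 1e-5

    @pytest.mark.parametrize("sign", [1, -1])
    def test_moment_arm_is_minus_path_length_derivative(self, sign):
        # central finite differences reproduce R to O(h^2)
        h = 1e-5
        for q in (0.4, 1.0, np.pi / 2, 2.2):
            lp, _ = mt_length_and_moment_arm(q + h, 0.3, 0.8, sign)
            lm, _ = mt_length_and_moment_arm(q - h, 0.3, 0.8, sign)
            _, r = mt_length_and_moment_arm(q, 0.3, 0.8, sign)
            assert -(lp - lm) / (2 * h) == pytest.approx(r, abs=1e-8)

    def test_flexor_positive_extensor_negative(self):
        _, r_fl = mt_length_and_moment_arm(1.0, 0.3, 0.8, sign=1)
        _, r_ex = mt_length_and_moment_arm(1.0, 0.2, 0.7, sign=-1)
        assert r_fl > 0 > r_ex

    def test_anatomical_range_enforced(self):
        for q in (-0.1, 0.0, np.pi, 3.5):
            with pytest.raises(ValueError, match="anatomical range"):
                mt_length_and_moment_arm(q, 0.3, 0.8)


class TestFiberState:
    def test_zero_pennation_reduces_to_path_minus_slack(self, elbow):
        kappa = elbow.biceps  # theta0 = 0 per the reference setup
        lmt, r = mt_length_and_moment_arm(1.0, 0.3, 0.8, 1)
        ltilde, vtilde, cos_theta = fiber_state(lmt, 0.0, r, kappa)
        assert np.allclose(cos_theta, 1.0)
        assert ltilde == pytest.approx((lmt - kappa.lsT) / kappa.l0M)

    def test_static_joint_gives_zero_fiber_velocity(self, elbow):
        lmt, r = mt_length_and_moment_arm(1.2, 0.3, 0.8, 1)
        _, vtilde, _ = fiber_state(lmt, 0.0, r, elbow.biceps)
        assert vtilde == 0.0

    def test_normalized_length_unity_at_matching_path(self):
        kappa = MuscleParams(l0M=0.6, vmaxM=6.0, f0M=300.0, lsT=0.55)
        ltilde, _, _ = fiber_state(1.15, 0.0, 0.1, kappa)
        assert ltilde == pytest.approx(1.0)

    def test_path_shorter_than_slack_rejected(self, elbow):
        with pytest.raises(ValueError, match="slack"):
            fiber_state(0.5, 0.0, 0.1, elbow.biceps)


class TestHillForce:
    def test_maximum_isometric_force_at_optimum(self, elbow):
        f = mt_force(1.0, 1.0, 0.0, 1.0, elbow.biceps, passive=False)
        assert f == pytest.approx(elbow.biceps.f0M)

    def test_no_activation_no_passive_no_force(self, elbow):
        assert mt_force(0.0, 0.9, 0.0, 1.0, elbow.biceps, passive=False) == 0.0

    def test_pennation_cosine_scales_force(self, elbow):
        f1 = mt_force(0.6, 0.9, -0.1, 1.0, elbow.biceps, passive=False)
        f2 = mt_force(0.6, 0.9, -0.1, 0.8, elbow.biceps, passive=False)
        assert f2 == pytest.approx(0.8 * f1)

    def test_force_velocity_shape(self):
        assert force_velocity(-1.5) == 0.0
        assert force_velocity(-1.0) == 0.0
        assert force_velocity(0.0) == pytest.approx(1.0)
        v = np.linspace(-0.99, 3.0, 200)
        fv = force_velocity(v)
        assert np.all(np.diff(fv) > 0)
        assert np.all(fv < 1.4)

    def test_passive_curve_zero_at_optimum_and_below(self):
        assert passive_force_length(1.0) == pytest.approx(0.0, abs=1e-12)
        assert passive_force_length(0.7) == 0.0
        assert passive_force_length(1.3) > 0.0

    def test_active_curve_peaks_at_optimum(self):
        assert active_force_length(1.0) == pytest.approx(1.0)
        assert active_force_length(0.7) < 1.0


class TestJointTorque:
    def test_silent_muscles_give_zero_torque(self, elbow):
        model = replace(elbow, passive=False)
        t = joint_torque(0.0, 0.0, np.array([1.0]), np.array([0.0]), model)
        assert np.allclose(t, 0.0)

    def test_flexor_activation_increases_torque(self, elbow):
        q, qd = np.array([1.0]), np.array([0.0])
        t_lo = joint_torque(0.2, 0.3, q, qd, elbow)
        t_hi = joint_torque(0.6, 0.3, q, qd, elbow)
        assert t_hi > t_lo

    def test_torque_linear_in_maximum_isometric_force(self, elbow):
        q, qd = np.array([1.3]), np.array([0.5])
        base = joint_torque(0.5, 0.4, q, qd, elbow, params={"f0_Bi": 300.0})
        off = joint_torque(0.5, 0.4, q, qd, elbow, params={"f0_Bi": 0.0})
        double = joint_torque(0.5, 0.4, q, qd, elbow, params={"f0_Bi": 600.0})
        assert double - off == pytest.approx(2 * (base - off), rel=1e-9)

    def test_scalar_fast_path_matches_generic(self, elbow):
        rng = np.random.default_rng(3)
        for _ in range(50):
            q = rng.uniform(0.5, 2.3)
            qd = rng.uniform(-4, 4)
            a_bi, a_tri = rng.uniform(0, 1, 2)
            generic = joint_torque(a_bi, a_tri, np.array([q]), np.array([qd]), elbow)[0]
            fast = _torque_scalar(a_bi, a_tri, q, qd, elbow)
            assert fast == pytest.approx(generic, rel=1e-12)


class TestForwardDynamics:
    def test_passive_pendulum_period(self, elbow):
        # muscles (and passive joint structures) off: point-mass pendulum
        t = np.linspace(0, 12, 4001)
        tr = simulate_motion(
            t, np.zeros((t.size, 2)), elbow,
            q0=np.deg2rad(4), qdot0=0.0, muscles_enabled=False,
        )
        crossings = t[1:][np.diff(np.sign(tr.q)) != 0]
        period = 2 * np.mean(np.diff(crossings))
        expected = 2 * np.pi * np.sqrt(elbow.lfa / elbow.g)
        assert period == pytest.approx(expected, rel=5e-3)

    def test_equilibrium_stays_put(self, elbow):
        model = replace(elbow, passive=False, joint_limits=False)
        t = np.linspace(0, 2, 101)
        # equilibrium of gravity alone is the hanging position; hold a tiny
        # angle with zero emg and the passive terms disabled: torque-free
        tr = simulate_motion(t, np.zeros((t.size, 2)), model,
                             q0=0.0, qdot0=0.0, muscles_enabled=False)
        assert np.max(np.abs(tr.q)) < 1e-12

    def test_integrator_convergence(self, elbow):
        from mskpinn.synthetic import SynthSpec, synth_emg

        spec = SynthSpec(n=201, duration=4.0, frequencies=(0.8, 1.0, 1.2, 1.4, 1.6),
                         baseline_bi=0.65, depth_bi=0.15,
                         baseline_tri=0.35, depth_tri=0.15)
        emg = np.column_stack(synth_emg(1, spec))
        tr1 = simulate_motion(spec.t, emg, elbow, q0=1.1, rtol=1e-9, atol=1e-11)
        tr2 = simulate_motion(spec.t, emg, elbow, q0=1.1, rtol=5e-10, atol=5e-12)
        assert np.max(np.abs(tr1.q - tr2.q)) < 1e-6

    def test_reference_inertia(self, elbow):
        assert elbow.inertia == pytest.approx(1.0)


class TestEomResidual:
    def _residual_sup(self, trial, elbow, t_min=0.0):
        t, q = trial.t, trial.q
        dt = t[1] - t[0]
        qd = (q[2:] - q[:-2]) / (2 * dt)
        qdd = (q[2:] - 2 * q[1:-1] + q[:-2]) / dt**2
        acts = np.column_stack(
            [
                activation(excitation_from_emg(trial.emg[:, c], t, elbow.act.d), elbow.act.A)
                for c in (0, 1)
            ]
        )
        r = eom_residual(q[1:-1], qd, qdd, acts[1:-1, 0], acts[1:-1, 1], {}, elbow)
        keep = t[1:-1] >= t_min
        return np.max(np.abs(r[keep]))

    def test_truncation_error_second_order(self, elbow):
        # residual on a simulated smooth trajectory with the true parameters
        # shrinks ~4x when the grid is refined 2x (central differences);
        # the first 0.2 s are excluded: the excitation padding before the
        # electromechanical delay creates an O(1) drive-slope kink there
        from mskpinn.synthetic import SynthSpec, synth_emg

        sups = {}
        for n in (200, 400):
            spec = SynthSpec(n=n + 1, duration=4.0,
                             frequencies=(0.8, 1.0, 1.2, 1.4, 1.6),
                             baseline_bi=0.65, depth_bi=0.15,
                             baseline_tri=0.35, depth_tri=0.15)
            emg = np.column_stack(synth_emg(2, spec))
            trial = simulate_motion(spec.t, emg, elbow, q0=1.1, rtol=1e-10, atol=1e-12)
            sups[n] = self._residual_sup(trial, elbow, t_min=0.2)
        assert sups[400] < sups[200] / 2.5

    def test_zero_dynamics(self, elbow):
        model = replace(elbow, passive=False, joint_limits=False, g=1e-300)
        n = 20
        q = np.full(n, 1.0)
        z = np.zeros(n)
        r = eom_residual(q, z, z, z, z, {}, model)
        assert np.allclose(r, 0.0, atol=1e-12)

    def test_monotone_in_flexor_force_perturbation(self, case1_trials, elbow):
        trial = case1_trials[0]
        t, q = trial.t, trial.q
        dt = t[1] - t[0]
        qd = (q[2:] - q[:-2]) / (2 * dt)
        qdd = (q[2:] - 2 * q[1:-1] + q[:-2]) / dt**2
        acts = np.column_stack(
            [
                activation(excitation_from_emg(trial.emg[:, c], t, elbow.act.d), elbow.act.A)
                for c in (0, 1)
            ]
        )
        means = []
        for scale in (1.0, 1.05, 1.1):
            r = eom_residual(
                q[1:-1], qd, qdd, acts[1:-1, 0], acts[1:-1, 1],
                {"f0_Bi": 300.0 * scale}, elbow,
            )
            means.append(np.mean(r))
        # torque is linear in f0: the mean residual shifts monotonically
        assert means[0] > means[1] > means[2]


class TestTrial:
    def test_shape_and_grid_validation(self):
        t = np.linspace(0, 1, 10)
        with pytest.raises(ValueError, match="length"):
            Trial(t=t, emg=np.zeros((9, 2)), q=np.zeros(10))
        with pytest.raises(ValueError, match="uniform"):
            Trial(t=np.array([0, 0.1, 0.3]), emg=np.zeros((3, 2)), q=np.zeros(3))
        with pytest.raises(ValueError, match="increasing"):
            Trial(t=t[::-1].copy(), emg=np.zeros((10, 2)), q=np.zeros(10))

    def test_properties(self, smooth_trial):
        assert smooth_trial.n == 60
        assert smooth_trial.dt == pytest.approx(1.2 / 59)
        assert smooth_trial.duration == pytest.approx(1.2)
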