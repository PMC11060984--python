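import numpy as np
import pytest

from mskpinn import autodiff as ad
from mskpinn.autodiff import Tensor
from mskpinn.cells import GRUWeights, WindowBatch, make_windows
from mskpinn.dynamics import ElbowModel
from mskpinn.loss import (
    IdentifiedParams,
    LossConfig,
    Standardizer,
    composite_loss,
    constrained_params,
    data_loss,
    predicted_derivatives,
    residual_loss,
    residual_window_mask,
    valid_q_range,
)
from mskpinn.training import attach_activations


@pytest.fixture()
def std_setup(smooth_trial):
    stats = Standardizer.from_trials([smooth_trial])
    trial_std = stats.transform_trial(smooth_trial)
    return stats, trial_std


class TestDataLoss:
    def test_perfect_prediction(self):
        q = np.arange(5.0)
        assert float(ad.value_of(data_loss(q, q))) == 0.0

    def test_constant_offset(self):
        q = np.zeros(7)
        assert float(ad.value_of(data_loss(q + 2.0, q))) == pytest.approx(4.0)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            data_loss(np.array([]), np.array([]))


class TestStandardizer:
    def test_roundtrip(self, smooth_trial):
        stats = Standardizer.from_trials([smooth_trial])
        ts = stats.transform_trial(smooth_trial)
        assert np.allclose(stats.destandardize_q(ts.q), smooth_trial.q)
        assert abs(ts.q.mean()) < 1e-12 and ts.q.std() == pytest.approx(1.0)

    def test_identity(self):
        stats = Standardizer.identity(3)
        assert stats.t_std == 1.0 and stats.q_std == 1.0

    def test_degenerate_std_rejected(self):
        with pytest.raises(ValueError):
            Standardizer(np.zeros(3), np.zeros(3), 0.0, 1.0)


class TestConstrainedParams:
    def test_midpoint_at_zero(self):
        anchors = np.array([100.0, 300.0])
        got = float(ad.value_of(constrained_params(np.zeros(2), anchors)))
        assert got == pytest.approx(anchors.mean() / 2)

    def test_saturates_to_anchor_mean(self):
        anchors = np.array([100.0, 300.0])
        got = float(ad.value_of(constrained_params(np.full(2, 40.0), anchors)))
        assert got == pytest.approx(anchors.mean(), rel=1e-9)

    def test_single_anchor(self):
        assert float(ad.value_of(constrained_params(np.zeros(1), np.array([600.0])))) == pytest.approx(300.0)

    def test_empty_anchors_rejected(self):
        with pytest.raises(ValueError):
            constrained_params(np.zeros(0), np.array([]))


class TestIdentifiedParams:
    def test_normalized_mode_starts_at_init(self):
        g0 = {"f0_Bi": 240.0, "l0_Bi": 0.5, "f0_Tri": 360.0, "l0_Tri": 0.48}
        ident = IdentifiedParams(g0)
        assert ident.values() == pytest.approx(g0)

    def test_state_roundtrip(self):
        g0 = {"f0_Bi": 240.0, "l0_Bi": 0.5, "f0_Tri": 360.0, "l0_Tri": 0.48}
        ident = IdentifiedParams(g0)
        ident.trainables()[0].value = np.array(1.25)
        state = ident.state()
        other = IdentifiedParams(g0)
        other.load_state(state)
        assert other.values()["f0_Bi"] == pytest.approx(300.0)

    def test_constrained_mode_bounds(self):
        g0 = {"f0_Bi": 240.0, "l0_Bi": 0.5, "f0_Tri": 360.0, "l0_Tri": 0.48}
        anchors = {n: np.array([2 * v]) for n, v in g0.items()}
        ident = IdentifiedParams(g0, mode="constrained", anchors=anchors)
        vals = ident.values()
        for n in vals:
            assert 0 < vals[n] < 2 * g0[n]

    def test_validation(self):
        with pytest.raises(ValueError):
            IdentifiedParams({"f0_Bi": 240.0})
        with pytest.raises(ValueError):
            IdentifiedParams({"f0_Bi": -1, "l0_Bi": 0.5, "f0_Tri": 1, "l0_Tri": 1})


class TestDerivatives:
    def test_cross_mode_consistency(self, elbow, std_setup):
        # autodiff jet and grid differences agree for a model whose output
        # depends on the current-step time only (there the partial
        # time-derivative and the along-trajectory difference coincide)
        stats, trial_std = std_setup
        rng = np.random.default_rng(0)
        w = GRUWeights.init(3, 6, rng)
        w.params = {k: 0.5 * v for k, v in w.params.items()}
        for k in ("W_qr", "W_qu", "W_qc", "W_hr", "W_hu", "W_hc"):
            w.params[k] = np.zeros_like(w.params[k])
        for k in ("W_xr", "W_xu", "W_xc"):
            w.params[k][1:] = 0.0  # keep only the time channel
        batch = make_windows(trial_std, 2)
        cfg_fd = LossConfig(stats=stats, derivative_mode="finite_difference")
        cfg_ad = LossConfig(stats=stats, derivative_mode="autodiff")
        q_fd, qd_fd, qdd_fd, keep_fd = predicted_derivatives(w.params, batch, cfg_fd)
        q_ad, qd_ad, qdd_ad, keep_ad = predicted_derivatives(w.params, batch, cfg_ad)
        qd_ad = ad.value_of(qd_ad)[keep_fd]
        qd_fd = ad.value_of(qd_fd)
        # first derivatives agree to O(dt^2) of the (coarse) trial grid
        scale = np.max(np.abs(qd_ad)) + 1.0
        assert np.max(np.abs(qd_ad - qd_fd)) < 0.05 * scale
        qdd_ad = ad.value_of(qdd_ad)[keep_fd]
        qdd_fd = ad.value_of(qdd_fd)
        scale2 = np.max(np.abs(qdd_ad)) + 1.0
        assert np.max(np.abs(qdd_ad - qdd_fd)) < 0.1 * scale2

    def test_identity_standardization_passthrough(self, smooth_trial):
        stats = Standardizer.identity(3)
        rng = np.random.default_rng(1)
        w = GRUWeights.init(3, 4, rng)
        batch = make_windows(smooth_trial, 2)
        cfg = LossConfig(stats=stats, derivative_mode="autodiff")
        q, qd, qdd, _ = predicted_derivatives(w.params, batch, cfg)
        # with unit scales the physical outputs equal the raw network jets
        from mskpinn.cells import gru_step, step_time_jet

        h = np.zeros((batch.n_windows, 4))
        for i in range(2):
            h = gru_step(w.params, h, batch.X[:, i, :], batch.Qh_clean[:, i].reshape(-1, 1))
        q2, qd2, qdd2 = step_time_jet(w.params, h, batch.X[:, 2, :])
        assert np.allclose(ad.value_of(q), ad.value_of(q2))
        assert np.allclose(ad.value_of(qd), ad.value_of(qd2))

    def test_unknown_mode_rejected(self, std_setup):
        stats, _ = std_setup
        with pytest.raises(ValueError, match="derivative_mode"):
            LossConfig(stats=stats, derivative_mode="spectral")


class TestResidualMachinery:
    def test_valid_q_range_reference_model(self, elbow):
        lo, hi = valid_q_range(elbow)
        # biceps path meets its tendon slack length near 2.67 rad
        assert hi == pytest.approx(2.669, abs=5e-3)
        assert lo < 0.01

    def test_mask_excludes_end_stop_zones(self, elbow):
        q = np.array([0.2, 0.5, 1.0, 2.0, 2.3])
        mask = residual_window_mask(elbow, q)
        assert mask.tolist() == [False, True, True, True, False]

    def test_mask_everything_without_limits(self, elbow):
        from dataclasses import replace

        m = residual_window_mask(replace(elbow, joint_limits=False), np.array([0.01, 3.0]))
        assert m.all()


class TestCompositeLoss:
    def _setup(self, elbow, trial, stats, sigma=0.0):
        trial_std = stats.transform_trial(trial)
        rng = np.random.default_rng(2)
        batch = make_windows(trial_std, 2, sigma, rng)
        attach_activations(batch, trial, elbow)
        batch.res_mask = residual_window_mask(elbow, trial.q[batch.idx])
        w = GRUWeights.init(3, 5, rng)
        params = {k: Tensor(v, requires_grad=True) for k, v in w.params.items()}
        ident = IdentifiedParams(
            {"f0_Bi": 240.0, "l0_Bi": 0.5, "f0_Tri": 360.0, "l0_Tri": 0.48}
        )
        return batch, params, ident

    def test_beta_zero_reduces_to_data_loss(self, elbow, smooth_trial, std_setup):
        stats, _ = std_setup
        batch, params, ident = self._setup(elbow, smooth_trial, stats)
        cfg0 = LossConfig(stats=stats, beta=0.0)
        j, jd, jr = composite_loss(params, ident, batch, batch, cfg0, elbow)
        assert jr == 0.0
        assert float(ad.value_of(j)) == pytest.approx(jd)
        # parameter trainables receive no gradient without the physics term
        j.backward()
        assert all(t.grad is None for t in ident.trainables())

    def test_penalty_only_adds(self, elbow, smooth_trial, std_setup):
        stats, _ = std_setup
        batch, params, ident = self._setup(elbow, smooth_trial, stats)
        cfg = LossConfig(stats=stats, beta=1e-3)
        j, jd, jr = composite_loss(params, ident, batch, batch, cfg, elbow)
        assert jr >= 0.0
        assert float(ad.value_of(j)) >= jd

    def test_gradients_match_finite_differences(self, elbow, smooth_trial, std_setup):
        stats, _ = std_setup
        batch, params, ident = self._setup(elbow, smooth_trial, stats, sigma=0.01)
        cfg = LossConfig(stats=stats, beta=1e-3)

        def loss():
            j, _, _ = composite_loss(params, ident, batch, batch, cfg, elbow)
            return j

        j = loss()
        j.backward()
        rng = np.random.default_rng(3)
        checks = []
        for name in ("W_hr", "W_xc", "W_hq", "b_h"):
            tsr = params[name]
            idx = tuple(rng.integers(0, s) for s in tsr.value.shape)
            checks.append((tsr, idx, tsr.grad[idx]))
        for tsr in ident.trainables():
            checks.append((tsr, (), float(tsr.grad)))
        for tsr, idx, analytic in checks:
            h = 1e-6
            old = tsr.value.copy()
            v = old.copy(); v[idx] += h; tsr.value = v
            jp = float(ad.value_of(loss()))
            v = old.copy(); v[idx] -= h; tsr.value = v
            jm = float(ad.value_of(loss()))
            tsr.value = old
            numeric = (jp - jm) / (2 * h)
            assert analytic == pytest.approx(numeric, rel=1e-5, abs=1e-10)

    def test_residual_requires_activations(self, elbow, smooth_trial, std_setup):
        stats, _ = std_setup
        trial_std = stats.transform_trial(smooth_trial)
        batch = make_windows(trial_std, 2)
        rng = np.random.default_rng(4)
        w = GRUWeights.init(3, 4, rng)
        with pytest.raises(ValueError, match="activations"):
            residual_loss(w.params, {}, batch, LossConfig(stats=stats), elbow)


class TestIdentifiability:
    def test_residual_minimum_recovers_reference_parameters(self, noiseless_trials, elbow):
        """With the surrogate replaced by the true trajectory, minimizing the
        physics residual alone recovers the reference parameters to <0.1%."""
        from scipy.optimize import minimize
        from mskpinn.dynamics import activation, excitation_from_emg, joint_torque

        truth = np.array([300.0, 0.6, 300.0, 0.4])
        names = ["f0_Bi", "l0_Bi", "f0_Tri", "l0_Tri"]
        trials = noiseless_trials

        def jres(gvec):
            gamma = {n: g for n, g in zip(names, gvec)}
            tot, cnt = 0.0, 0
            for tr in trials:
                t, q = tr.t, tr.q
                h = t[1] - t[0]
                qd = (q[2:] - q[:-2]) / (2 * h)
                qdd = (q[2:] - 2 * q[1:-1] + q[:-2]) / h**2
                acts = np.column_stack(
                    [activation(excitation_from_emg(tr.emg[:, c], t, 0.08), 0.2) for c in (0, 1)]
                )
                qh = (-q[:-3] + 9 * q[1:-2] + 9 * q[2:-1] - q[3:]) / 16.0
                qdh = (q[:-3] - 27 * q[1:-2] + 27 * q[2:-1] - q[3:]) / (24 * h)
                ah = 0.5 * (acts[:-1] + acts[1:])

                def G(qv, qdv, a0, a1):
                    return elbow.external_torque(qv) + joint_torque(a0, a1, qv, qdv, elbow, params=gamma)

                gn = G(q[1:-1], qd, acts[1:-1, 0], acts[1:-1, 1])
                gh = G(qh, qdh, ah[1:-1][:, 0], ah[1:-1][:, 1])
                ks = np.arange(2, len(q) - 2)
                r = elbow.inertia * qdd[ks - 1] - (gh[ks - 2] + gh[ks - 1] + gn[ks - 1]) / 3.0
                mask = residual_window_mask(elbow, q[ks])
                tot += np.sum(r[mask] ** 2)
                cnt += mask.sum()
            return tot / cnt

        res = minimize(
            jres, truth * np.array([1.05, 0.95, 0.95, 1.05]), method="Nelder-Mead",
            options=dict(xatol=1e-6, fatol=1e-16, maxiter=4000),
        )
        err = np.abs(res.x - truth) / truth * 100
        assert np.all(err < 0.1)
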