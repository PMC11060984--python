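"""Composite physics-informed loss and parameter handling.

The training objective is

    J(theta, Gamma) = J_data(theta) + beta * J_res(theta, Gamma)

where J_data is the mean squared one-step-ahead prediction error on the
(standardized) motion and J_res is the mean squared residual of the elbow
equation of motion, in N m, evaluated at the network's predicted motion
and its time derivatives. Minimizing J simultaneously fits the
forward-dynamics surrogate (theta) and identifies the Hill-type
parameters Gamma = {f0_Bi, l0_Bi, f0_Tri, l0_Tri}.

Gamma enters in one of two parameterizations:

* normalized (default, used for synthetic verification): trainables are
  Gammabar_l = Gamma_l / Gamma_l^(0) relative to the initial guess, which
  conditions the mixed-unit parameter set;
* sigmoid-constrained (for subject-like data): Gamma_l(psi) is an average
  of literature anchor values gated by sigmoids, confining the search to a
  physiological box.

Time derivatives of the prediction come either from central finite
differences of the batched predictions over the trial grid (default; the
residual batch uses noise-free teacher history so differencing does not
amplify augmentation noise) or from a second-order derivative jet with
respect to the current-step time input ("autodiff" mode). Both modes
rescale from standardized to physical units before the residual is formed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.special import comb

from . import autodiff as ad
from .autodiff import Tensor
from .cells import WindowBatch, forward_windows, gru_step, rnn_step, step_time_jet
from .dynamics import (ElbowModel, Trial, eom_residual, joint_torque,
                       mt_length_and_moment_arm)

__all__ = [
    "Standardizer",
    "LossConfig",
    "IdentifiedParams",
    "data_loss",
    "predicted_derivatives",
    "residual_loss",
    "composite_loss",
    "constrained_params",
    "valid_q_range",
]

PARAM_NAMES = ("f0_Bi", "l0_Bi", "f0_Tri", "l0_Tri")


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Standardizer:
    """Per-channel mean/std of the inputs [t, e^1, ..., e^{Na}] and output q."""

    x_mean: np.ndarray
    x_std: np.ndarray
    q_mean: float
    q_std: float

    def __post_init__(self):
        if np.any(self.x_std <= 0) or self.q_std <= 0:
            raise ValueError("standard deviations must be positive")

    @classmethod
    def from_trials(cls, trials: Sequence[Trial]) -> "Standardizer":
        feats = np.concatenate(
            [np.column_stack([tr.t, tr.emg]) for tr in trials], axis=0
        )
        q = np.concatenate([tr.q for tr in trials])
        return cls(
            x_mean=feats.mean(axis=0),
            x_std=feats.std(axis=0),
            q_mean=float(q.mean()),
            q_std=float(q.std()),
        )

    @classmethod
    def identity(cls, n_in: int) -> "Standardizer":
        return cls(np.zeros(n_in), np.ones(n_in), 0.0, 1.0)

    def transform_trial(self, trial: Trial) -> Trial:
        feats = (np.column_stack([trial.t, trial.emg]) - self.x_mean) / self.x_std
        return Trial(
            t=feats[:, 0],
            emg=feats[:, 1:],
            q=(trial.q - self.q_mean) / self.q_std,
            muscle_names=trial.muscle_names,
        )

    def destandardize_q(self, q_std):
        return self.q_mean + self.q_std * q_std

    @property
    def t_std(self) -> float:
        return float(self.x_std[0])


@dataclass
class LossConfig:
    """Settings of the composite loss.

    beta            : weight of the equation-of-motion residual penalty
                      (dimensionless; the verification setup uses
                      beta ~ dt^2 / I = 1e-3)
    stats           : standardization statistics of all channels
    derivative_mode : "finite_difference" (default) or "autodiff"
    """

    stats: Standardizer
    beta: float = 1e-3
    derivative_mode: str = "finite_difference"
    residual_scales: tuple = (0,)  # scales at which the physics penalty acts
    detach_residual: bool = False  # physics term updates Gamma only, not theta
    residual_smoothing: int = 8  # binomial smoothing order of the weak-form stencil

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.derivative_mode not in ("finite_difference", "autodiff"):
            raise ValueError(f"unsupported derivative_mode {self.derivative_mode!r}")


# ---------------------------------------------------------------------------
# identified parameters
# ---------------------------------------------------------------------------


def constrained_params(psi, anchors):
    """Sigmoid-constrained parameter Gamma = (1/N) sum_r anchors_r sig(psi_r).

    Smooth in psi and confined to (0, max anchor); with all psi = 0 the
    value is half the anchor mean.
    """
    anchors = np.asarray(ad.value_of(anchors), dtype=np.float64)
    if anchors.size == 0:
        raise ValueError("anchors must be non-empty")
    return ad.mean(anchors * ad.sigmoid(psi))


class IdentifiedParams:
    """ODE parameters under identification with their trainable encoding.

    ``gamma0`` maps each name in ``PARAM_NAMES`` to its initialization value
    (N for forces, m for lengths). In ``normalized`` mode the trainables are
    the dimensionless ratios Gammabar = Gamma/Gamma0 (initialized at 1); in
    ``constrained`` mode each parameter carries a psi vector gating literature
    anchor values through sigmoids.
    """

    def __init__(
        self,
        gamma0: Mapping[str, float],
        mode: str = "normalized",
        anchors: Optional[Mapping[str, np.ndarray]] = None,
    ):
        self.names = tuple(PARAM_NAMES)
        missing = [n for n in self.names if n not in gamma0]
        if missing:
            raise ValueError(f"missing initialization values: {missing}")
        if any(gamma0[n] <= 0 for n in self.names):
            raise ValueError("initialization values must be positive")
        self.gamma0 = {n: float(gamma0[n]) for n in self.names}
        self.mode = mode
        if mode == "normalized":
            self._trainables = {n: Tensor(1.0, requires_grad=True) for n in self.names}
            self.anchors = None
        elif mode == "constrained":
            if anchors is None:
                raise ValueError("constrained mode requires anchor values")
            self.anchors = {n: np.asarray(anchors[n], dtype=np.float64) for n in self.names}
            self._trainables = {
                n: Tensor(np.zeros(self.anchors[n].size), requires_grad=True)
                for n in self.names
            }
        else:
            raise ValueError(f"unknown parameter mode {mode!r}")

    def trainables(self):
        return [self._trainables[n] for n in self.names]

    def physical(self) -> Dict[str, Tensor]:
        """Current parameters in physical units, as tape tensors."""
        if self.mode == "normalized":
            return {n: self._trainables[n] * self.gamma0[n] for n in self.names}
        return {n: constrained_params(self._trainables[n], self.anchors[n]) for n in self.names}

    def values(self) -> Dict[str, float]:
        return {n: float(ad.value_of(t)) for n, t in self.physical().items()}

    def state(self) -> Dict[str, np.ndarray]:
        return {n: self._trainables[n].value.copy() for n in self.names}

    def load_state(self, state: Mapping[str, np.ndarray]) -> None:
        for n in self.names:
            self._trainables[n].value = np.array(state[n], dtype=np.float64)

    def to_dict(self) -> Dict:
        out = {
            "mode": self.mode,
            "gamma0": self.gamma0,
            "values": self.values(),
            "trainables": {n: np.asarray(v).tolist() for n, v in self.state().items()},
        }
        if self.anchors is not None:
            out["anchors"] = {n: a.tolist() for n, a in self.anchors.items()}
        return out


# ---------------------------------------------------------------------------
# loss terms
# ---------------------------------------------------------------------------


def data_loss(q_hat, q):
    """Mean squared misfit (1/N) sum ||q_hat - q||^2 over the batch."""
    q = ad.value_of(q)
    if q.size == 0:
        raise ValueError("empty batch")
    diff = q_hat - q
    return ad.mean(diff * diff)


def predicted_derivatives(
    params: Mapping,
    batch: WindowBatch,
    config: LossConfig,
    kind: str = "gru",
    standard: bool = False,
):
    """Predicted motion and its first two time derivatives, physical units.

    Predictions use the noise-free teacher history. Returns
    ``(q_hat, q_dot, q_ddot, sl)`` where ``sl`` is the slice of windows at
    which the derivatives are defined (the interior in finite-difference
    mode, everything in autodiff mode) and ``q_hat`` is full length.
    """
    stats = config.stats
    if config.derivative_mode == "finite_difference":
        for s, e in batch.segments:
            if not np.all(np.diff(batch.idx[s:e]) == 1):
                raise ValueError("finite-difference mode needs consecutive windows")
        q_std = forward_windows(params, batch, kind=kind, clean=True, standard=standard)
        q_phys = stats.destandardize_q(q_std)
        dt = batch.dt * stats.t_std  # window grid step in seconds
        qd_parts, qdd_parts, keep = [], [], []
        for s, e in batch.segments:
            seg = q_phys[s:e]
            qd_parts.append((seg[2:] - seg[:-2]) / (2.0 * dt))
            qdd_parts.append((seg[2:] - 2.0 * seg[1:-1] + seg[:-2]) / dt**2)
            keep.extend(range(s + 1, e - 1))
        q_dot = ad.concatenate(qd_parts)
        q_ddot = ad.concatenate(qdd_parts)
        return q_phys, q_dot, q_ddot, np.asarray(keep)
    # autodiff: second-order jet w.r.t. the current-step (standardized) time
    m = batch.m
    n_batch = batch.n_windows
    hidden = ad.value_of(params["W_hr" if kind == "gru" else "W_hh"]).shape[0]
    h = np.zeros((n_batch, hidden))
    step = gru_step if kind == "gru" else rnn_step
    kwargs = {"standard": standard} if kind == "gru" else {}
    for i in range(m):
        h = step(params, h, batch.X[:, i, :], batch.Qh_clean[:, i].reshape(-1, 1), **kwargs)
    q_s, qd_s, qdd_s = step_time_jet(params, h, batch.X[:, m, :], kind=kind, **kwargs)
    scale1 = stats.q_std / stats.t_std
    scale2 = stats.q_std / stats.t_std**2
    return (
        stats.destandardize_q(q_s),
        qd_s * scale1,
        qdd_s * scale2,
        np.arange(n_batch),
    )


@lru_cache(maxsize=16)
def _weak_form_kernel(p: int):
    """Smoothed second-difference filter and its matching force kernel.

    ``f2`` is the second difference convolved with the order-``p`` binomial
    smoother (units 1/h^2 applied by the caller); applying it to a
    trajectory equals integrating the acceleration against a
    piecewise-linear Peano kernel whose node values are the binomial
    weights. Returns (f2, node kernel values, half-node kernel values,
    node offsets) with offsets relative to the residual's center.
    """
    if p < 0:
        raise ValueError("smoothing order must be >= 0")
    if p > 0:
        b = np.array([comb(2 * p, i) for i in range(2 * p + 1)]) / 4.0**p
    else:
        b = np.array([1.0])
    f2 = np.convolve([1.0, -2.0, 1.0], b)
    k_node = np.zeros(2 * p + 3)
    k_node[1:-1] = b
    k_half = 0.5 * (k_node[:-1] + k_node[1:])  # value at (m, m+1) midpoint
    offs = np.arange(-(p + 1), p + 2)
    return f2, k_node, k_half, offs


def residual_window_mask(model: ElbowModel, q_measured: np.ndarray,
                         torque_eps: float = 0.05) -> np.ndarray:
    """Windows eligible for the physics residual: measured motion outside the
    joint-limit engagement zones (limit torque below ``torque_eps`` N m).

    Near the end stops the trajectory's acceleration contains stiff,
    under-resolved transients; the equation-of-motion penalty is evaluated
    only where the smooth muscle-gravity dynamics governs.
    """
    if not model.joint_limits:
        return np.ones_like(q_measured, dtype=bool)
    margin = model.s_lim * np.log(model.k_lim / torque_eps)
    lo = model.q_lo + margin
    hi = model.q_hi - margin
    return (q_measured > lo) & (q_measured < hi)


@lru_cache(maxsize=8)
def valid_q_range(model: ElbowModel, margin: float = 1e-3, n_scan: int = 4096):
    """Anatomical angle interval on which every muscle path exceeds its
    tendon slack length (the rigid-tendon model is undefined beyond it)."""
    qs = np.linspace(margin, np.pi - margin, n_scan)
    ok = np.ones_like(qs, dtype=bool)
    for _, kappa, path in model.muscles():
        lmt, _ = mt_length_and_moment_arm(qs, path.l1, path.l2, path.sign)
        ok &= lmt > kappa.lsT * (1.0 + 1e-6)
    if not np.any(ok):
        raise ValueError("no admissible joint angle for this geometry")
    return float(qs[ok][0]), float(qs[ok][-1])


def residual_loss(
    params: Mapping,
    gamma: Mapping,
    batch: WindowBatch,
    config: LossConfig,
    msk_model: ElbowModel,
    kind: str = "gru",
    standard: bool = False,
):
    """Mean squared equation-of-motion residual (N m)^2 over the batch.

    Activations must have been attached to the batch (``batch.act``) from
    the trial's sEMG in physical units. The predicted angle is clipped to
    the admissible anatomical interval before the torque evaluation so an
    untrained network cannot drive the muscle geometry out of its domain.

    In finite-difference mode the residual is evaluated in locally
    integrated (weak) form: the central second difference of the predicted
    motion equals the hat-weighted average of the acceleration over its
    stencil *exactly*, so the generalized force side is averaged with the
    same hat weights, integrated with node and half-node samples (the
    activation drive is piecewise linear between samples, making the
    quadrature exact in the drive). Without this consistency, the
    sample-to-sample torque fluctuations of noisy sEMG bias the identified
    parameters downward.
    """
    if batch.act is None:
        raise ValueError("batch carries no activations; attach them before training")
    lo, hi = valid_q_range(msk_model)
    inertia = msk_model.inertia
    if config.derivative_mode == "autodiff":
        q_hat, q_dot, q_ddot, keep = predicted_derivatives(
            params, batch, config, kind=kind, standard=standard
        )
        if batch.res_mask is not None:
            sel = np.flatnonzero(batch.res_mask[keep])
            if sel.size == 0:
                return ad.mean(q_hat * 0.0)
            keep, q_dot, q_ddot = keep[sel], q_dot[sel], q_ddot[sel]
        q_r = ad.clip(q_hat[keep], lo, hi)
        r = eom_residual(
            q_r, q_dot, q_ddot,
            batch.act[keep, 0], batch.act[keep, 1],
            gamma, msk_model,
        )
        return ad.mean(r * r)
    # finite differences, locally integrated (weak) form: the smoothed
    # second-difference filter applied to the predicted motion equals the
    # integral of the acceleration against a piecewise-linear Peano kernel
    # exactly; the generalized force G = E + T^MT is integrated against the
    # same kernel with node and half-node samples (exact for the
    # piecewise-linear activation drive)
    for s, e in batch.segments:
        if not np.all(np.diff(batch.idx[s:e]) == 1):
            raise ValueError("finite-difference mode needs consecutive windows")
    stats = config.stats
    q_std = forward_windows(params, batch, kind=kind, clean=True, standard=standard)
    q_hat = stats.destandardize_q(q_std)
    dt = batch.dt * stats.t_std
    f2, k_node, k_half, offs = _weak_form_kernel(config.residual_smoothing)
    half = len(f2) // 2

    def g_force(qv, qdv, a0, a1):
        qv = ad.clip(qv, lo, hi)
        tmt = joint_torque(a0, a1, qv, qdv, msk_model, params=gamma)
        return msk_model.external_torque(qv) + tmt

    r_parts = []
    mask_parts = []
    for s, e in batch.segments:
        L = e - s
        if L < 2 * half + 6:
            continue
        q = q_hat[s:e]
        a = batch.act[s:e]
        qd = (q[2:] - q[:-2]) / (2.0 * dt)  # nodes 1 .. L-2
        # half-node motion by cubic interpolation, velocity by the 4-point
        # midpoint formula; half-node activation is the exact node average
        qh = (-1.0 * q[:-3] + 9.0 * q[1:-2] + 9.0 * q[2:-1] - 1.0 * q[3:]) / 16.0
        qdh = (q[:-3] - 27.0 * q[1:-2] + 27.0 * q[2:-1] - q[3:]) / (24.0 * dt)
        ah = 0.5 * (a[1:-2] + a[2:-1])  # midpoints (j+1, j+2), j = 0 .. L-4
        gn = g_force(q[1:-1], qd, a[1:-1, 0], a[1:-1, 1])  # nodes 1 .. L-2
        gh = g_force(qh, qdh, ah[:, 0], ah[:, 1])  # midpoints 1.5 .. L-2.5
        ks = np.arange(half + 2, L - half - 2)
        if ks.size == 0:
            continue
        q_side = 0.0
        for j, c in enumerate(f2):
            q_side = q_side + c * q[ks + j - half]
        q_side = q_side * (inertia / dt**2)
        g_side = 0.0
        for m, kv in zip(offs, k_node):
            if kv:
                g_side = g_side + (kv / 3.0) * gn[ks + m - 1]
        for m, kv in zip(offs, k_half):
            if kv:
                g_side = g_side + (2.0 * kv / 3.0) * gh[ks + m - 1]
        r_parts.append(q_side - g_side)
        if batch.res_mask is not None:
            m0 = binary_erosion(batch.res_mask[s:e], np.ones(2 * (half + 1) + 1))
            mask_parts.append(m0[ks])
    if not r_parts:
        raise ValueError("no segment long enough for the residual stencil")
    r = ad.concatenate(r_parts)
    if mask_parts:
        sel = np.flatnonzero(np.concatenate(mask_parts))
        if sel.size == 0:
            return ad.mean(q_hat * 0.0)
        r = r[sel]
    return ad.mean(r * r)


def composite_loss(
    params: Mapping,
    ident: IdentifiedParams,
    data_batch: WindowBatch,
    res_batch: WindowBatch,
    config: LossConfig,
    msk_model: ElbowModel,
    kind: str = "gru",
    standard: bool = False,
    with_residual: bool = True,
):
    """J = J_data + beta * J_res; returns (J, J_data value, J_res value).

    ``data_batch`` uses the noise-augmented teacher history; ``res_batch``
    the noise-free one. Gradients flow to the network weights through both
    terms and to the parameter trainables through the residual only.
    ``with_residual=False`` (used at coarse training scales) drops the
    physics term for this call.
    """
    q_hat = forward_windows(params, data_batch, kind=kind, clean=False, standard=standard)
    j_data = data_loss(q_hat, data_batch.target)
    if config.beta == 0.0 or not with_residual:
        zero = 0.0
        return j_data, float(ad.value_of(j_data)), zero
    res_params = params
    if config.detach_residual:
        res_params = {k: ad.value_of(v) for k, v in params.items()}
    j_res = residual_loss(
        res_params, ident.physical(), res_batch, config, msk_model,
        kind=kind, standard=standard,
    )
    j = j_data + config.beta * j_res
    return j, float(ad.value_of(j_data)), float(ad.value_of(j_res))
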