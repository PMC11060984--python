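"""Hill-type muscle mechanics and rigid-body elbow forward dynamics.

The model is a single-degree-of-freedom elbow: two rigid links (upper arm
fixed vertically, forearm hinged at the elbow) actuated by an antagonist
pair of lumped muscle-tendon complexes, biceps (flexor) and triceps
(extensor). The chain is

    sEMG e(t) --delay d--> excitation u(t) --shape A--> activation a(t)
    a(t) --Hill model--> muscle force F^MT --moment arm R(q)--> torque
    I q'' = T^MT(a, q, q') + E(q)

with a rigid tendon (tendon length fixed at its slack length), so fiber
kinematics follow algebraically from the muscle-tendon path length.

Conventions
-----------
* ``q`` is the elbow flexion angle measured from the fully extended,
  hanging forearm: q = 0 is the forearm hanging straight down, q = pi/2
  horizontal. Anatomical range is (0, pi).
* Gravity torque ``E(q) = -m_fa * g * l_fa * sin(q)`` (point mass at the
  wrist); the passive system is a pendulum with stable equilibrium at q = 0.
* Moment arms use the shortening-positive convention ``R = -d(lMT)/dq``:
  the flexor's arm is positive, the extensor's negative, so flexor
  activation produces positive (flexion) torque.

All force/torque expressions are written against :mod:`mskpinn.autodiff`
primitives, so they accept either numpy arrays or tape ``Tensor`` objects;
the physics-informed residual differentiates through them.

The Hill curve shapes (active force-length, force-velocity, passive) are
standard rigid-tendon forms and are exposed as module-level functions so a
user with different curve calibrations can swap them.
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from . import autodiff as ad

__all__ = [
    "ActivationParams",
    "MuscleParams",
    "MusclePath",
    "ElbowModel",
    "JointState",
    "Trial",
    "excitation_from_emg",
    "activation",
    "mt_length_and_moment_arm",
    "fiber_state",
    "active_force_length",
    "force_velocity",
    "passive_force_length",
    "mt_force",
    "joint_torque",
    "forward_rhs",
    "simulate_motion",
    "eom_residual",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ActivationParams:
    """Excitation-to-activation dynamics constants.

    d : electromechanical delay between sEMG and neural excitation [s]
    A : activation nonlinearity shape factor (dimensionless, != 0)
    """

    d: float = 0.08
    A: float = 0.2

    def __post_init__(self):
        if self.d < 0:
            raise ValueError("delay d must be >= 0")
        if self.A == 0:
            raise ValueError("shape factor A must be nonzero")


@dataclass(frozen=True)
class MuscleParams:
    """Hill-type muscle-tendon constants kappa = [l0M, vmaxM, f0M, lsT, theta0]."""

    l0M: float  # optimal fiber length [m]
    vmaxM: float  # maximum contraction velocity [m/s]
    f0M: float  # maximum isometric force [N]
    lsT: float  # tendon slack length [m]
    theta0: float = 0.0  # pennation angle at optimal fiber length [rad]

    def __post_init__(self):
        for name in ("l0M", "vmaxM", "f0M", "lsT"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.theta0 < np.pi / 2:
            raise ValueError("theta0 must lie in [0, pi/2)")


@dataclass(frozen=True)
class MusclePath:
    """Straight-line muscle routing over the elbow hinge.

    l1, l2 : attachment distances from the joint on either link [m]
    sign   : +1 for the flexor (biceps), -1 for the extensor (triceps)
    """

    l1: float
    l2: float
    sign: int = 1

    def __post_init__(self):
        if self.l1 <= 0 or self.l2 <= 0:
            raise ValueError("attachment distances must be > 0")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 (flexor) or -1 (extensor)")


@dataclass(frozen=True)
class ElbowModel:
    """Single-DOF elbow flexion-extension model with an antagonist muscle pair."""

    lua: float = 1.0  # upper-arm link length [m]
    lfa: float = 1.0  # forearm link length / wrist-mass moment arm [m]
    m_fa: float = 1.0  # lumped wrist mass [kg]
    biceps: MuscleParams = field(
        default_factory=lambda: MuscleParams(l0M=0.6, vmaxM=6.0, f0M=300.0, lsT=0.55)
    )
    triceps: MuscleParams = field(
        default_factory=lambda: MuscleParams(l0M=0.4, vmaxM=4.0, f0M=300.0, lsT=0.33)
    )
    bi_path: MusclePath = field(default_factory=lambda: MusclePath(l1=0.3, l2=0.8, sign=1))
    tri_path: MusclePath = field(default_factory=lambda: MusclePath(l1=0.2, l2=0.7, sign=-1))
    act: ActivationParams = field(default_factory=ActivationParams)
    g: float = 9.81  # gravitational acceleration [m/s^2]
    passive: bool = True  # include the passive force-length element
    joint_limits: bool = True  # include the passive joint-limit torque
    q_lo: float = 0.30  # lower joint-limit engagement angle [rad]
    q_hi: float = 2.30  # upper joint-limit engagement angle [rad]
    k_lim: float = 3.0  # joint-limit torque scale [N m]
    s_lim: float = 0.04  # joint-limit exponential width [rad]

    def __post_init__(self):
        for name in ("lua", "lfa", "m_fa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.q_lo < self.q_hi < np.pi:
            raise ValueError("joint limits must satisfy 0 < q_lo < q_hi < pi")

    @property
    def inertia(self) -> float:
        """Point-mass-at-wrist moment of inertia I = m_fa * lfa**2 [kg m^2]."""
        return self.m_fa * self.lfa**2

    def gravity_torque(self, q):
        """Gravity part of E(q): -m_fa * g * lfa * sin(q) [N m]; restores toward q = 0."""
        return -self.m_fa * self.g * self.lfa * ad.sin(q)

    def limit_torque(self, q):
        """Passive joint-limit torque: stiff exponential barriers at the ends
        of the anatomical range (ligamentous end-stops). Negligible
        (< 1e-10 N m) away from the limits; keeps the joint off the angles
        where the rigid-tendon muscle geometry degenerates."""
        if not self.joint_limits:
            return 0.0 * ad.sin(q)  # zero of matching shape/type
        up = self.k_lim * ad.exp(-(q - self.q_lo) / self.s_lim)
        down = self.k_lim * ad.exp((q - self.q_hi) / self.s_lim)
        return up - down

    def external_torque(self, q):
        """E(q): gravity plus passive joint-limit torque [N m]."""
        return self.gravity_torque(q) + self.limit_torque(q)

    def muscles(self):
        return (("bi", self.biceps, self.bi_path), ("tri", self.triceps, self.tri_path))

    def with_params(self, updates: Mapping[str, float]) -> "ElbowModel":
        """Return a copy with identified parameters substituted.

        Keys follow the identification vector convention: ``f0_Bi``,
        ``l0_Bi``, ``f0_Tri``, ``l0_Tri``.
        """
        bi_kw, tri_kw = {}, {}
        for key, val in updates.items():
            attr = {"f0": "f0M", "l0": "l0M"}[key.split("_")[0]]
            (bi_kw if key.endswith("Bi") else tri_kw)[attr] = float(val)
        return replace(
            self,
            biceps=replace(self.biceps, **bi_kw) if bi_kw else self.biceps,
            triceps=replace(self.triceps, **tri_kw) if tri_kw else self.triceps,
        )


@dataclass
class JointState:
    """Generalized coordinate of the elbow: flexion angle and its rate."""

    q: float
    qdot: float

    def __post_init__(self):
        if not (np.isfinite(self.q) and np.isfinite(self.qdot)):
            raise ValueError("joint state must be finite")


@dataclass
class Trial:
    """One movement recording: uniform time grid, sEMG channels, joint angle.

    t   : (n,) strictly increasing, uniform step
    emg : (n, Na) per-muscle sEMG, dimensionless
    q   : (n,) elbow flexion angle [rad]
    """

    t: np.ndarray
    emg: np.ndarray
    q: np.ndarray
    muscle_names: Sequence[str] = ("bi", "tri")

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=np.float64)
        self.emg = np.atleast_2d(np.asarray(self.emg, dtype=np.float64))
        if self.emg.shape[0] != self.t.size and self.emg.shape[1] == self.t.size:
            self.emg = self.emg.T
        self.q = np.asarray(self.q, dtype=np.float64)
        n = self.t.size
        if self.emg.shape[0] != n or self.q.size != n:
            raise ValueError("t, emg and q must share the same length")
        steps = np.diff(self.t)
        if n < 2 or np.any(steps <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.max(np.abs(steps - steps[0])) > 1e-9 * max(abs(steps[0]), 1e-300):
            raise ValueError("time grid must be uniform")

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


# ---------------------------------------------------------------------------
# activation dynamics
# ---------------------------------------------------------------------------


def excitation_from_emg(e: np.ndarray, t: np.ndarray, d: float) -> np.ndarray:
    """Neural excitation u(t) = e(t - d) on the sample grid.

    Linear interpolation between samples; times before the recording start
    are padded with the first sample (no extrapolation).
    """
    e = np.asarray(e, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    if d < 0:
        raise ValueError("delay d must be >= 0")
    if d > t[-1] - t[0]:
        raise ValueError("delay exceeds trial span")
    return np.interp(t - d, t, e, left=e[0])


def activation(u, A: float):
    """Muscle activation a = (exp(A u) - 1) / (exp(A) - 1), u clipped to [0, 1].

    Maps u = 0 -> a = 0 and u = 1 -> a = 1 for every A != 0; the clipping
    guards against additive sEMG noise pushing u outside the physiological
    range.
    """
    if A == 0:
        raise ValueError("shape factor A must be nonzero")
    u = ad.clip(u, 0.0, 1.0)
    return (ad.exp(A * u) - 1.0) / (np.exp(A) - 1.0)


# ---------------------------------------------------------------------------
# musculotendon geometry and Hill curves
# ---------------------------------------------------------------------------


def mt_length_and_moment_arm(q, l1: float, l2: float, sign: int = 1):
    """Muscle-tendon path length lMT(q) and moment arm R(q) = -d(lMT)/dq.

    Law-of-cosines routing over the hinge. The flexor (sign = +1) spans the
    exterior angle pi - q, so it is longest at full extension and shortens
    with flexion (positive moment arm); the extensor (sign = -1) uses the
    mirrored path and lengthens with flexion (negative moment arm).
    """
    q_val = ad.value_of(q)
    if np.any(q_val <= 0.0) or np.any(q_val >= np.pi):
        raise ValueError("joint angle out of anatomical range")
    # cos(pi - q) = -cos(q): flexor +2 l1 l2 cos q, extensor -2 l1 l2 cos q
    lmt = ad.sqrt(l1**2 + l2**2 + sign * 2.0 * l1 * l2 * ad.cos(q))
    r = sign * l1 * l2 * ad.sin(q) / lmt  # = -d(lmt)/dq
    return lmt, r


def fiber_state(lmt, qdot, r, kappa: MuscleParams):
    """Rigid-tendon fiber kinematics from the muscle-tendon path.

    Returns (ltilde, vtilde, cos_theta): normalized fiber length lM/l0M,
    normalized fiber velocity (dlM/dt)/vmaxM, and the pennation cosine.
    Constant-thickness pennation: lM sin(theta) = l0M sin(theta0).
    """
    lmt_val = ad.value_of(lmt)
    if np.any(lmt_val <= kappa.lsT * (1.0 - 1e-9)):
        raise ValueError("muscle-tendon shorter than tendon slack length")
    along = lmt - kappa.lsT  # fiber projection on the tendon line
    w = kappa.l0M * np.sin(kappa.theta0)  # constant fiber thickness
    if w == 0.0:
        lm = along
        cos_theta = np.ones_like(lmt_val)  # pennation stays zero
    else:
        lm = ad.sqrt(along * along + w * w)
        cos_theta = along / lm
    # dlM/dt = cos(theta) * d(lMT)/dt, with d(lMT)/dt = -R * qdot
    vm = cos_theta * (-r) * qdot
    return lm / kappa.l0M, vm / kappa.vmaxM, cos_theta


_FL_WIDTH = 0.45  # active force-length Gaussian width (dimensionless)
_FV_ECC_C = 0.08  # eccentric hyperbola constant; C1 match to concentric slope 5


def active_force_length(ltilde):
    """Active force-length curve fl(l~) = exp(-(l~ - 1)^2 / 0.45); fl(1) = 1."""
    dev = ltilde - 1.0
    return ad.exp(-(dev * dev) / _FL_WIDTH)


def force_velocity(vtilde):
    """Force-velocity curve, shortening negative.

    fv = 0 for v~ <= -1; (1 + v~)/(1 - 4 v~) on (-1, 0]; eccentric hyperbola
    (1.4 v~ + c)/(v~ + c), c = 0.08, approaching the 1.4 cap — C1-continuous
    at v~ = 0 where fv = 1.
    """
    v = vtilde
    v_val = ad.value_of(v)
    conc = ad.where(v_val > -1.0, (1.0 + v) / (1.0 - 4.0 * v), 0.0)
    ecc = (1.4 * v + _FV_ECC_C) / (v + _FV_ECC_C)
    return ad.where(v_val > 0.0, ecc, conc)


def passive_force_length(ltilde):
    """Passive force-length fp(l~) = (exp(10 (l~ - 1)) - 1)/(exp(5) - 1), >= 0."""
    fp = (ad.exp(10.0 * (ltilde - 1.0)) - 1.0) / (np.exp(5.0) - 1.0)
    return ad.maximum(fp, 0.0)


def mt_force(a, ltilde, vtilde, cos_theta, kappa: MuscleParams, passive: bool = True):
    """Muscle-tendon force F^MT = f0M (a fl(l~) fv(v~) + fp(l~)) cos(theta) [N]."""
    fm = a * active_force_length(ltilde) * force_velocity(vtilde)
    if passive:
        fm = fm + passive_force_length(ltilde)
    return kappa.f0M * fm * cos_theta


# ---------------------------------------------------------------------------
# joint torque, forward dynamics, equation-of-motion residual
# ---------------------------------------------------------------------------


def joint_torque(a_bi, a_tri, q, qdot, model: ElbowModel, params: Mapping | None = None):
    """Net muscle torque T^MT = R_bi F_bi + R_tri F_tri [N m].

    ``params`` optionally overrides identified quantities {f0_Bi, l0_Bi,
    f0_Tri, l0_Tri}; values may be tape tensors, in which case the returned
    torque is differentiable in them (the torque is linear in each f0M).
    """
    params = dict(params or {})
    total = 0.0
    acts = {"bi": a_bi, "tri": a_tri}
    for name, kappa, path in model.muscles():
        suffix = "Bi" if name == "bi" else "Tri"
        f0 = params.get(f"f0_{suffix}", kappa.f0M)
        l0 = params.get(f"l0_{suffix}", kappa.l0M)
        lmt, r = mt_length_and_moment_arm(q, path.l1, path.l2, path.sign)
        # rebuild fiber state with the (possibly trainable) l0
        lmt_val = ad.value_of(lmt)
        if np.any(lmt_val <= kappa.lsT * (1.0 - 1e-9)):
            raise ValueError("muscle-tendon shorter than tendon slack length")
        along = lmt - kappa.lsT
        w = ad.value_of(l0) * np.sin(kappa.theta0)
        if np.all(w == 0.0):
            lm = along
            cos_theta = 1.0
        else:
            lm = ad.sqrt(along * along + w * w)
            cos_theta = along / lm
        vm = cos_theta * (-r) * qdot
        ltilde = lm / l0
        vtilde = vm / kappa.vmaxM
        fm = acts[name] * active_force_length(ltilde) * force_velocity(vtilde)
        if model.passive:
            fm = fm + passive_force_length(ltilde)
        total = total + r * (f0 * fm * cos_theta)
    return total


def _torque_scalar(a_bi: float, a_tri: float, q: float, qdot: float,
                   model: ElbowModel) -> float:
    """Scalar-float twin of :func:`joint_torque` for the ODE right-hand side.

    The generic implementation dispatches through the autodiff layer and is
    array-oriented; inside an adaptive integrator that overhead dominates.
    This path uses plain ``math`` calls and is asserted equal to the generic
    one in the test suite.
    """
    if not 0.0 < q < math.pi:
        raise ValueError("joint angle out of anatomical range")
    total = 0.0
    acts = (a_bi, a_tri)
    for (name, kappa, path), a in zip(model.muscles(), acts):
        l1, l2 = path.l1, path.l2
        lmt = math.sqrt(l1 * l1 + l2 * l2 + path.sign * 2.0 * l1 * l2 * math.cos(q))
        if lmt <= kappa.lsT * (1.0 - 1e-9):
            raise ValueError("muscle-tendon shorter than tendon slack length")
        r = path.sign * l1 * l2 * math.sin(q) / lmt
        along = lmt - kappa.lsT
        w = kappa.l0M * math.sin(kappa.theta0)
        if w == 0.0:
            lm = along
            cos_theta = 1.0
        else:
            lm = math.sqrt(along * along + w * w)
            cos_theta = along / lm
        lt = lm / kappa.l0M
        vt = cos_theta * (-r) * qdot / kappa.vmaxM
        fl = math.exp(-(lt - 1.0) ** 2 / _FL_WIDTH)
        if vt <= -1.0:
            fv = 0.0
        elif vt <= 0.0:
            fv = (1.0 + vt) / (1.0 - 4.0 * vt)
        else:
            fv = (1.4 * vt + _FV_ECC_C) / (vt + _FV_ECC_C)
        fm = a * fl * fv
        if model.passive:
            fp = (math.exp(10.0 * (lt - 1.0)) - 1.0) / (math.exp(5.0) - 1.0)
            fm += max(fp, 0.0)
        total += r * kappa.f0M * fm * cos_theta
    return total


def _activation_interpolant(trial_t, emg, model: ElbowModel) -> Callable:
    """Activation a(t) from sampled sEMG.

    Activations are evaluated at the sample nodes (delayed excitation,
    clipped, shape-factor map) and linearly interpolated between nodes:
    activation dynamics are low-pass, and a piecewise-linear activation
    drive makes the sampled trajectory exactly consistent with
    grid-stencil evaluations of the equation of motion.
    """
    trial_t = np.asarray(trial_t, dtype=np.float64)
    emg = np.asarray(emg, dtype=np.float64)
    a_nodes = np.column_stack(
        [
            activation(excitation_from_emg(emg[:, c], trial_t, model.act.d), model.act.A)
            for c in range(emg.shape[1])
        ]
    )

    def act(t, channel):
        return np.interp(t, trial_t, a_nodes[:, channel])

    return act


def forward_rhs(t, state, emg_interp, model: ElbowModel):
    """Right-hand side (qdot, qddot) of the first-order elbow system."""
    q, qdot = float(state[0]), float(state[1])
    a_bi = float(emg_interp(t, 0))
    a_tri = float(emg_interp(t, 1))
    tmt = _torque_scalar(a_bi, a_tri, q, qdot, model)
    ext = -model.m_fa * model.g * model.lfa * math.sin(q)
    if model.joint_limits:
        ext += model.k_lim * (
            math.exp(-(q - model.q_lo) / model.s_lim)
            - math.exp((q - model.q_hi) / model.s_lim)
        )
    return np.array([qdot, (tmt + ext) / model.inertia])


def simulate_motion(
    t_grid: np.ndarray,
    emg: np.ndarray,
    model: ElbowModel,
    q0: float = np.pi / 6,
    qdot0: float = 0.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    muscles_enabled: bool = True,
) -> Trial:
    """Solve the forward dynamics on ``t_grid`` driven by sampled sEMG.

    Adaptive explicit Runge-Kutta (RK45) with dense output sampled at the
    grid; sEMG between samples by linear interpolation. Returns a
    :class:`Trial` carrying the inputs and the solved motion.
    """
    t_grid = np.asarray(t_grid, dtype=np.float64)
    emg = np.atleast_2d(np.asarray(emg, dtype=np.float64))
    if emg.shape[0] != t_grid.size:
        emg = emg.T
    if muscles_enabled:
        interp = _activation_interpolant(t_grid, emg, model)

        def rhs(t, y):
            return forward_rhs(t, y, interp, model)

    else:

        def rhs(t, y):
            q, qdot = y
            gravity = -model.m_fa * model.g * model.lfa * math.sin(q)
            return np.array([qdot, gravity / model.inertia])

    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        [q0, qdot0],
        method="RK45",
        t_eval=t_grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"integrator failed at t = {sol.t[-1]:.4f} s: {sol.message}")
    return Trial(t=t_grid, emg=emg, q=sol.y[0])


def eom_residual(q, qdot, qddot, a_bi, a_tri, gamma: Mapping, model: ElbowModel):
    """Equation-of-motion residual r = I q'' - E(q) - T^MT(a, q, q'; Gamma) [N m].

    ``gamma`` supplies the identified parameters {f0_Bi, l0_Bi, f0_Tri,
    l0_Tri}; the remaining Hill constants come from ``model``. All kinematic
    inputs may be tape tensors.
    """
    tmt = joint_torque(a_bi, a_tri, q, qdot, model, params=gamma)
    return model.inertia * qddot - model.external_torque(q) - tmt
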