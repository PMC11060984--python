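"""Recurrent cells with motion feedback, teacher forcing and rollout.

The forward-dynamics surrogate maps windows of ``m`` history steps of
inputs x_i = [t_i, e_i^1, ..., e_i^{Na}] plus the measured motion q_i at
those history steps (teacher forcing) to the motion at the current step;
at test time the model's own predictions are fed back (autoregressive
rollout).

Two cells are provided. The GRU uses a variant hidden-state update

    h_i = u_i (.) h_{i-1} + h~_i - u_i (.) h~_i + b_h

which carries an extra additive bias ``b_h`` relative to the textbook GRU
interpolation; it is implemented verbatim, with ``standard=True`` dropping
that bias. History steps receive the motion q_i through dedicated weights
(W_qr, W_qu, W_qc); the current step receives inputs only.

Weights are plain ``{name: array}`` mappings so the same forward code runs
on numpy arrays (fast inference) or autodiff tensors (training). The
batched window forward used in the training loop is a single fused tape
operation with a hand-derived backpropagation-through-time VJP; the
op-by-op path (`*_forward`) is retained and the two are cross-checked in
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .dynamics import Trial

__all__ = [
    "GRUWeights",
    "RNNWeights",
    "WindowBatch",
    "make_windows",
    "gru_step",
    "rnn_step",
    "gru_forward",
    "rnn_forward",
    "forward_windows",
    "fused_gru_windows",
    "step_time_jet",
    "rollout",
]


# ---------------------------------------------------------------------------
# weight containers
# ---------------------------------------------------------------------------

_GRU_NAMES = (
    "W_hr", "W_xr", "W_qr", "W_hu", "W_xu", "W_qu",
    "W_hc", "W_xc", "W_qc", "W_hq",
    "b_r", "b_u", "b_c", "b_h", "b_q",
)
_RNN_NAMES = ("W_hh", "W_xh", "W_qh", "W_hq", "b_h", "b_q")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


@dataclass
class GRUWeights:
    """All trainable tensors of the gated cell, keyed by role.

    Shapes (hidden width H, input width n_in): W_h* (H, H); W_x* (n_in, H);
    W_q* (1, H); W_hq (H, 1); biases (H,) except b_q (1,).
    """

    params: Dict[str, np.ndarray]
    hidden: int
    n_in: int
    kind: str = field(default="gru", init=False)

    @classmethod
    def init(cls, n_in: int, hidden: int, rng: np.random.Generator) -> "GRUWeights":
        p: Dict[str, np.ndarray] = {}
        for name in _GRU_NAMES:
            if name.startswith("W_h") and name != "W_hq":
                p[name] = _glorot(rng, hidden, hidden)
            elif name.startswith("W_x"):
                p[name] = _glorot(rng, n_in, hidden)
            elif name.startswith("W_q"):
                p[name] = _glorot(rng, 1, hidden)
            elif name == "W_hq":
                p[name] = _glorot(rng, hidden, 1)
            elif name == "b_q":
                p[name] = np.zeros(1)
            else:
                p[name] = np.zeros(hidden)
        cls._validate(p, hidden, n_in)
        return cls(params=p, hidden=hidden, n_in=n_in)

    @staticmethod
    def _validate(p: Mapping[str, np.ndarray], hidden: int, n_in: int) -> None:
        for name, arr in p.items():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite entries in {name}")

    def copy(self) -> "GRUWeights":
        return GRUWeights({k: v.copy() for k, v in self.params.items()}, self.hidden, self.n_in)


@dataclass
class RNNWeights:
    """Trainable tensors of the vanilla recurrent cell."""

    params: Dict[str, np.ndarray]
    hidden: int
    n_in: int
    kind: str = field(default="rnn", init=False)

    @classmethod
    def init(cls, n_in: int, hidden: int, rng: np.random.Generator) -> "RNNWeights":
        p = {
            "W_hh": _glorot(rng, hidden, hidden),
            "W_xh": _glorot(rng, n_in, hidden),
            "W_qh": _glorot(rng, 1, hidden),
            "W_hq": _glorot(rng, hidden, 1),
            "b_h": np.zeros(hidden),
            "b_q": np.zeros(1),
        }
        return cls(params=p, hidden=hidden, n_in=n_in)

    def copy(self) -> "RNNWeights":
        return RNNWeights({k: v.copy() for k, v in self.params.items()}, self.hidden, self.n_in)


def _shape_check(p: Mapping, names: Sequence[str]) -> None:
    missing = [n for n in names if n not in p]
    if missing:
        raise ValueError(f"missing weight tensors: {missing}")


# ---------------------------------------------------------------------------
# cell steps (generic: numpy arrays or tape tensors)
# ---------------------------------------------------------------------------


def gru_step(p: Mapping, h_prev, x, q=None, standard: bool = False):
    """One gated-cell update; ``q`` present on history steps only.

    x : (N, n_in) batch of inputs, q : (N, 1) motion or None, h : (N, H).
    """
    _shape_check(p, _GRU_NAMES)
    pre_r = h_prev @ p["W_hr"] + x @ p["W_xr"] + p["b_r"]
    pre_u = h_prev @ p["W_hu"] + x @ p["W_xu"] + p["b_u"]
    pre_c = x @ p["W_xc"] + p["b_c"]
    if q is not None:
        pre_r = pre_r + q @ p["W_qr"]
        pre_u = pre_u + q @ p["W_qu"]
        pre_c = pre_c + q @ p["W_qc"]
    r = ad.sigmoid(pre_r)
    u = ad.sigmoid(pre_u)
    z = r * (h_prev @ p["W_hc"])
    c_tilde = ad.tanh(z + pre_c)
    h = u * h_prev + c_tilde - u * c_tilde
    if not standard:
        h = h + p["b_h"]
    return h


def rnn_step(p: Mapping, h_prev, x, q=None):
    """One vanilla recurrent update h = tanh(W_hh h + W_xh x [+ W_qh q] + b_h)."""
    _shape_check(p, _RNN_NAMES)
    pre = h_prev @ p["W_hh"] + x @ p["W_xh"] + p["b_h"]
    if q is not None:
        pre = pre + q @ p["W_qh"]
    return ad.tanh(pre)


def _readout(p: Mapping, h):
    out = h @ p["W_hq"] + p["b_q"]
    return out[:, 0] if out.ndim == 2 else out


def _as2d(q_col):
    return q_col.reshape(-1, 1) if q_col.ndim == 1 else q_col


def gru_forward(p: Mapping, x_steps, q_steps, h_init=None, standard: bool = False):
    """Window forward pass of the gated cell.

    x_steps : sequence of m+1 input batches (N, n_in), history first;
    q_steps : sequence of m motion batches (N,) or (N, 1) for the history
    steps. Returns (q_hat (N,), h_n (N, H)).
    """
    m = len(q_steps)
    if len(x_steps) != m + 1:
        raise ValueError("need one more input step than motion steps")
    n_batch = ad.value_of(x_steps[0]).shape[0]
    hidden = ad.value_of(p["W_hr"]).shape[0]
    h = np.zeros((n_batch, hidden)) if h_init is None else h_init
    for i in range(m):
        h = gru_step(p, h, x_steps[i], _as2d(q_steps[i]), standard=standard)
    h = gru_step(p, h, x_steps[m], None, standard=standard)
    return _readout(p, h), h


def rnn_forward(p: Mapping, x_steps, q_steps, h_init=None):
    """Window forward pass of the vanilla cell (motion on history steps only)."""
    m = len(q_steps)
    if len(x_steps) != m + 1:
        raise ValueError("need one more input step than motion steps")
    n_batch = ad.value_of(x_steps[0]).shape[0]
    hidden = ad.value_of(p["W_hh"]).shape[0]
    h = np.zeros((n_batch, hidden)) if h_init is None else h_init
    for i in range(m):
        h = rnn_step(p, h, x_steps[i], _as2d(q_steps[i]))
    h = rnn_step(p, h, x_steps[m], None)
    return _readout(p, h), h


# ---------------------------------------------------------------------------
# fused batched window forward (training hot path)
# ---------------------------------------------------------------------------


def _sigmoid(v):
    e = np.exp(-np.abs(v))
    return np.where(v >= 0, 1.0 / (1.0 + e), e / (1.0 + e))


def fused_gru_windows(params: Mapping[str, Tensor], X: np.ndarray, Qh: np.ndarray,
                      standard: bool = False) -> Tensor:
    """Batched GRU window forward as one tape node with a hand-coded BPTT VJP.

    X : (N, m+1, n_in) constant inputs, Qh : (N, m) constant teacher motion.
    Returns the predicted motion q_hat as a (N,) tensor differentiable in
    every weight. Functionally identical to :func:`gru_forward`; fused for
    speed (the backward pass computes all weight gradients in one sweep and
    memoizes them across the tape's per-parent VJP calls).
    """
    vals = {k: (t.value if isinstance(t, Tensor) else np.asarray(t, float)) for k, t in params.items()}
    _shape_check(vals, _GRU_NAMES)
    dtype = vals["W_hr"].dtype
    X = np.ascontiguousarray(X, dtype=dtype)
    Qh = np.ascontiguousarray(Qh, dtype=dtype)
    N, m_plus_1, _ = X.shape
    m = m_plus_1 - 1
    H = vals["W_hr"].shape[0]

    hs = [np.zeros((N, H), dtype=dtype)]
    saved = []  # per step: (x, q, r, u, hc, ct)
    h = hs[0]
    for i in range(m + 1):
        x = X[:, i, :]
        q = Qh[:, i : i + 1] if i < m else None
        pre_r = h @ vals["W_hr"] + x @ vals["W_xr"] + vals["b_r"]
        pre_u = h @ vals["W_hu"] + x @ vals["W_xu"] + vals["b_u"]
        pre_c = x @ vals["W_xc"] + vals["b_c"]
        if q is not None:
            pre_r += q @ vals["W_qr"]
            pre_u += q @ vals["W_qu"]
            pre_c += q @ vals["W_qc"]
        r = _sigmoid(pre_r)
        u = _sigmoid(pre_u)
        hc = h @ vals["W_hc"]
        ct = np.tanh(r * hc + pre_c)
        h_new = u * (h - ct) + ct
        if not standard:
            h_new = h_new + vals["b_h"]
        saved.append((x, q, r, u, hc, ct))
        hs.append(h_new)
        h = h_new
    q_hat = (h @ vals["W_hq"])[:, 0] + vals["b_q"][0]

    cache: dict = {}

    def full_bptt(g: np.ndarray) -> Dict[str, np.ndarray]:
        grads = {k: np.zeros_like(v) for k, v in vals.items()}
        grads["W_hq"] += hs[-1].T @ g[:, None]
        grads["b_q"] += np.array([g.sum()])
        dh = g[:, None] * vals["W_hq"][:, 0]
        for i in range(m, -1, -1):
            x, q, r, u, hc, ct = saved[i]
            h_prev = hs[i]
            if not standard:
                grads["b_h"] += dh.sum(axis=0)
            du = dh * (h_prev - ct)
            dct = dh * (1.0 - u)
            dh_prev = dh * u
            dpre_c = dct * (1.0 - ct * ct)
            grads["b_c"] += dpre_c.sum(axis=0)
            grads["W_xc"] += x.T @ dpre_c
            dr = dpre_c * hc
            dhc = dpre_c * r
            grads["W_hc"] += h_prev.T @ dhc
            dh_prev = dh_prev + dhc @ vals["W_hc"].T
            dpre_u = du * u * (1.0 - u)
            grads["b_u"] += dpre_u.sum(axis=0)
            grads["W_xu"] += x.T @ dpre_u
            grads["W_hu"] += h_prev.T @ dpre_u
            dh_prev = dh_prev + dpre_u @ vals["W_hu"].T
            dpre_r = dr * r * (1.0 - r)
            grads["b_r"] += dpre_r.sum(axis=0)
            grads["W_xr"] += x.T @ dpre_r
            grads["W_hr"] += h_prev.T @ dpre_r
            dh_prev = dh_prev + dpre_r @ vals["W_hr"].T
            if q is not None:
                grads["W_qr"] += q.T @ dpre_r
                grads["W_qu"] += q.T @ dpre_u
                grads["W_qc"] += q.T @ dpre_c
            dh = dh_prev
        return grads

    def make_vjp(name: str):
        def vjp(g: np.ndarray) -> np.ndarray:
            if "g" not in cache or cache["g"] is not g:
                cache["g"] = g
                cache["grads"] = full_bptt(np.asarray(g, dtype=dtype))
            return cache["grads"][name]

        return vjp

    parents = [
        (t, make_vjp(name))
        for name, t in params.items()
        if isinstance(t, Tensor) and t.requires_grad
    ]
    return Tensor(q_hat, parents=parents)


# ---------------------------------------------------------------------------
# time-derivative jet through the final step (autodiff derivative mode)
# ---------------------------------------------------------------------------


def step_time_jet(p: Mapping, h_prev, x, kind: str = "gru", time_channel: int = 0,
                  standard: bool = False):
    """Final (current) cell step with first/second derivatives w.r.t. its time input.

    ``h_prev`` carries no dependence on the current-step time, so the jet is
    seeded only through the time channel of ``x``. Returns
    (q_hat, dq_hat/dt, d2q_hat/dt2), each (N,), built from tape primitives
    so weight gradients flow through all three outputs. Derivatives are in
    the (standardized) units of the network inputs/outputs.
    """
    if kind == "rnn":
        k = p["W_xh"][time_channel] if isinstance(p["W_xh"], Tensor) else p["W_xh"][time_channel]
        pre = h_prev @ p["W_hh"] + x @ p["W_xh"] + p["b_h"]
        h = ad.tanh(pre)
        sech2 = 1.0 - h * h
        h1 = sech2 * k
        h2 = (-2.0 * h * h1) * k
        q_hat = _readout(p, h)
        return q_hat, _readout_derivative(p, h1), _readout_derivative(p, h2)
    kr = p["W_xr"][time_channel]
    ku = p["W_xu"][time_channel]
    kc = p["W_xc"][time_channel]
    r = ad.sigmoid(h_prev @ p["W_hr"] + x @ p["W_xr"] + p["b_r"])
    u = ad.sigmoid(h_prev @ p["W_hu"] + x @ p["W_xu"] + p["b_u"])
    hc = h_prev @ p["W_hc"]
    pre_c = r * hc + x @ p["W_xc"] + p["b_c"]
    ct = ad.tanh(pre_c)
    # first and second time-derivatives of the gates (h_prev is constant)
    r1 = r * (1.0 - r) * kr
    r2 = (1.0 - 2.0 * r) * r1 * kr
    u1 = u * (1.0 - u) * ku
    u2 = (1.0 - 2.0 * u) * u1 * ku
    pre_c1 = r1 * hc + kc
    pre_c2 = r2 * hc
    sech2 = 1.0 - ct * ct
    ct1 = sech2 * pre_c1
    ct2 = sech2 * pre_c2 - 2.0 * ct * ct1 * pre_c1
    h = u * (h_prev - ct) + ct
    if not standard:
        h = h + p["b_h"]
    h1 = u1 * (h_prev - ct) + (1.0 - u) * ct1
    h2 = u2 * (h_prev - ct) - 2.0 * u1 * ct1 + (1.0 - u) * ct2
    return _readout(p, h), _readout_derivative(p, h1), _readout_derivative(p, h2)


def _readout_derivative(p: Mapping, h_derivative):
    out = h_derivative @ p["W_hq"]
    return out[:, 0] if out.ndim == 2 else out


# ---------------------------------------------------------------------------
# teacher-forcing windows and autoregressive rollout
# ---------------------------------------------------------------------------


@dataclass
class WindowBatch:
    """All predictable windows of one trial, batched.

    X        : (N, m+1, n_in) inputs, history steps first, current step last
    Qh       : (N, m) teacher motion at history steps (noise-augmented)
    Qh_clean : (N, m) teacher motion without augmentation noise
    target   : (N,) motion at the current step (always clean)
    idx      : (N,) index of the current step in the trial grid
    act      : optional (N, Na) muscle activations at the current step,
               attached by the trainer for the physics residual
    """

    X: np.ndarray
    Qh: np.ndarray
    Qh_clean: np.ndarray
    target: np.ndarray
    idx: np.ndarray
    dt: float
    act: Optional[np.ndarray] = None
    res_mask: Optional[np.ndarray] = None  # windows eligible for the physics residual
    segments: Optional[Sequence] = None  # (start, end) runs of consecutive windows

    def __post_init__(self):
        if self.segments is None:
            self.segments = [(0, self.X.shape[0])]

    @property
    def n_windows(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.Qh.shape[1]

    def chunks(self, size: int) -> list:
        """Split into contiguous sub-batches of at most ``size`` windows,
        never crossing a segment (trial) boundary — grid-based derivative
        stencils stay valid inside every chunk."""
        if size < 4:
            raise ValueError("chunk size must allow an interior stencil")
        out = []
        for s, e in self.segments:
            n_pieces = max(1, round((e - s) / size))
            bounds = np.linspace(s, e, n_pieces + 1).astype(int)
            for a, b in zip(bounds[:-1], bounds[1:]):
                out.append(
                    WindowBatch(
                        X=self.X[a:b], Qh=self.Qh[a:b], Qh_clean=self.Qh_clean[a:b],
                        target=self.target[a:b], idx=self.idx[a:b], dt=self.dt,
                        act=None if self.act is None else self.act[a:b],
                        res_mask=None if self.res_mask is None else self.res_mask[a:b],
                        segments=[(0, b - a)],
                    )
                )
        return out

    @staticmethod
    def concat(batches: Sequence["WindowBatch"]) -> "WindowBatch":
        """Stack several trials' window batches into one, keeping per-trial
        segment boundaries so grid-based derivatives never cross trials."""
        if not batches:
            raise ValueError("no batches to concatenate")
        if len({b.m for b in batches}) != 1:
            raise ValueError("history lengths differ")
        segments = []
        offset = 0
        for b in batches:
            for s, e in b.segments:
                segments.append((offset + s, offset + e))
            offset += b.n_windows
        acts = [b.act for b in batches]
        masks = [
            np.ones(b.n_windows, dtype=bool) if b.res_mask is None else b.res_mask
            for b in batches
        ]
        return WindowBatch(
            X=np.concatenate([b.X for b in batches]),
            Qh=np.concatenate([b.Qh for b in batches]),
            Qh_clean=np.concatenate([b.Qh_clean for b in batches]),
            target=np.concatenate([b.target for b in batches]),
            idx=np.concatenate([b.idx for b in batches]),
            dt=batches[0].dt,
            act=None if any(a is None for a in acts) else np.concatenate(acts),
            res_mask=np.concatenate(masks),
            segments=segments,
        )


def make_windows(trial: Trial, m: int, noise_sigma: float = 0.0,
                 rng: Optional[np.random.Generator] = None) -> WindowBatch:
    """Teacher-forcing windows: one per predictable step (n - m windows).

    Teacher-noise augmentation emulates the error the model faces in
    autoregressive rollout, where mistakes accumulate as a slowly drifting
    offset: a shared N(0, noise_sigma^2) offset is added to all history
    steps of a window, plus independent per-step jitter at a tenth of that
    scale. Targets are left clean. Deterministic for a given ``rng`` state.
    """
    if m >= trial.n:
        raise ValueError("history length m must be smaller than the trial length")
    if m < 1:
        raise ValueError("need at least one history step")
    n = trial.n
    feats = np.column_stack([trial.t, trial.emg])  # (n, 1 + Na)
    n_win = n - m
    starts = np.arange(n_win)
    X = np.stack([feats[starts + i] for i in range(m + 1)], axis=1)
    Qh_clean = np.stack([trial.q[starts + i] for i in range(m)], axis=1)
    if noise_sigma > 0.0:
        if rng is None:
            raise ValueError("rng required when noise_sigma > 0")
        offset = rng.normal(0.0, noise_sigma, size=(n_win, 1))
        jitter = rng.normal(0.0, 0.1 * noise_sigma, size=Qh_clean.shape)
        Qh = Qh_clean + offset + jitter
    else:
        Qh = Qh_clean.copy()
    target = trial.q[starts + m]
    return WindowBatch(
        X=X, Qh=Qh, Qh_clean=Qh_clean, target=target,
        idx=starts + m, dt=trial.dt,
    )


def forward_windows(params: Mapping, batch: WindowBatch, kind: str = "gru",
                    clean: bool = False, standard: bool = False, fused: bool = True):
    """Predicted motion for every window in the batch; tape-aware.

    ``clean`` selects the noise-free teacher history (used by the physics
    residual). The fused path is used for the GRU when no per-equation
    trace is required.
    """
    Qh = batch.Qh_clean if clean else batch.Qh
    if kind == "gru" and fused:
        return fused_gru_windows(params, batch.X, Qh, standard=standard)
    x_steps = [batch.X[:, i, :] for i in range(batch.m + 1)]
    q_steps = [Qh[:, i] for i in range(batch.m)]
    fwd = gru_forward if kind == "gru" else rnn_forward
    if kind == "gru":
        q_hat, _ = fwd(params, x_steps, q_steps, standard=standard)
    else:
        q_hat, _ = fwd(params, x_steps, q_steps)
    return q_hat


def rollout(params: Mapping, inputs: np.ndarray, q_seed: np.ndarray, m: int,
            kind: str = "gru", standard: bool = False) -> np.ndarray:
    """Autoregressive prediction over a full trial.

    inputs : (n, n_in) input features [t, e^1, ..., e^{Na}];
    q_seed : first m motion values. Steps m ... n-1 are predicted from the
    model's own previous outputs; measured motion is never consulted beyond
    the seed.
    """
    q_seed = np.asarray(q_seed, dtype=np.float64)
    if q_seed.size != m:
        raise ValueError("q_seed must supply exactly m history values")
    vals = {k: (t.value if isinstance(t, Tensor) else np.asarray(t, float)) for k, t in params.items()}
    n = inputs.shape[0]
    preds = np.empty(n)
    preds[:m] = q_seed
    step = gru_step if kind == "gru" else rnn_step
    kwargs = {"standard": standard} if kind == "gru" else {}
    for k in range(m, n):
        h = np.zeros((1, vals["W_hr" if kind == "gru" else "W_hh"].shape[0]))
        for i in range(k - m, k):
            h = step(vals, h, inputs[i : i + 1], preds[i].reshape(1, 1), **kwargs)
        h = step(vals, h, inputs[k : k + 1], None, **kwargs)
        pred = _readout(vals, h)[0]
        if not np.isfinite(pred):
            raise FloatingPointError(f"rollout diverged at step {k}")
        preds[k] = pred
    return preds
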