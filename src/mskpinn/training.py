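"""Coarse-to-fine training of the physics-informed recurrent surrogate.

Training proceeds through the multi-resolution ladder from the coarsest
scale [-J] to the raw scale [0]. At each scale the composite loss (data
misfit + beta * equation-of-motion residual) is minimized by Adam over the
cell weights and the parameter trainables; the early-stopped best weights
and the parameter state are then transferred unchanged to the next finer
scale, where fresh teacher-forcing noise is drawn. The final parameter
read-out happens after the scale-[0] stage.

Test-time metrics are computed in autoregressive rollout mode (the model
sees measured motion only in the m-step seed): MSE, the coefficient of
determination R^2, and the normalized MSE, which satisfies
NMSE = (1 - R^2) / n identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .cells import GRUWeights, RNNWeights, WindowBatch, make_windows, rollout
from .dynamics import ElbowModel, Trial, activation, excitation_from_emg
from .loss import (IdentifiedParams, LossConfig, Standardizer, composite_loss,
                   residual_loss, residual_window_mask)

__all__ = [
    "Adam",
    "TrainingSchedule",
    "TrainingRecord",
    "train_at_scale",
    "mr_train",
    "evaluate",
    "attach_activations",
]


class Adam:
    """Adam with bias-corrected moments; updates tensor values in place."""

    def __init__(self, tensors: Sequence[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.tensors = list(tensors)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(t.value) for t in self.tensors]
        self.v = [np.zeros_like(t.value) for t in self.tensors]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, tensor in enumerate(self.tensors):
            g = tensor.grad
            if g is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            step = self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
            tensor.value = (tensor.value - step).astype(tensor.value.dtype, copy=False)

    def zero_grad(self) -> None:
        for t in self.tensors:
            t.grad = None


@dataclass
class TrainingSchedule:
    """Protocol of one multi-resolution run.

    scales           : ordered training scales, coarsest first, ending at 0
    epochs_per_scale : epoch budget per scale (int, applied to every scale,
                       or one entry per scale)
    lr               : Adam initial learning rate
    patience / min_delta : early stopping on the training loss, with
                       best-weight restoration
    m                : teacher-forcing history steps
    hidden           : cell width
    kind             : "gru" or "rnn"
    standard_gru     : drop the extra additive bias from the gated update
    noise_sigma      : teacher-noise scale in standardized motion units;
                       None selects 0.1 * std(q) (= 0.1 after
                       standardization)
    """

    scales: Tuple[int, ...] = (-2, -1, 0)
    epochs_per_scale: object = 300
    lr: float = 1e-3
    patience: int = 100
    min_delta: float = 1e-6
    m: int = 2
    hidden: int = 50
    kind: str = "gru"
    standard_gru: bool = False
    noise_sigma: Optional[object] = None  # scalar, per-scale list, or None
    batch_size: int = 50  # contiguous windows per data-misfit step
    gamma_lr: float = 5e-3  # Adam rate for the identified-parameter trainables
    lr_decay: str = "cosine"  # "cosine" (to ~1% of lr within a scale) or "none"
    dtype: str = "float32"  # training arithmetic; float32 doubles BLAS throughput

    def __post_init__(self):
        scales = tuple(self.scales)
        if not scales or scales[-1] != 0:
            raise ValueError("scales must end at the full scale [0]")
        if any(b <= a for a, b in zip(scales, scales[1:])):
            raise ValueError("scales must be strictly increasing")
        self.scales = scales
        if np.any(np.asarray(self.epochs, dtype=int) <= 0):
            raise ValueError("epoch budgets must be positive")
        if self.kind not in ("gru", "rnn"):
            raise ValueError("kind must be 'gru' or 'rnn'")

    def sigma_for(self, scale: int):
        s = self.noise_sigma
        if s is None or np.isscalar(s):
            return s
        return s[list(self.scales).index(scale)]

    @property
    def epochs(self) -> List[int]:
        if np.isscalar(self.epochs_per_scale):
            return [int(self.epochs_per_scale)] * len(self.scales)
        eps = [int(e) for e in self.epochs_per_scale]
        if len(eps) != len(self.scales):
            raise ValueError("one epoch budget per scale required")
        return eps


@dataclass
class TrainingRecord:
    """Per-epoch training history plus the identified-parameter trajectory."""

    epochs: List[Dict] = field(default_factory=list)

    def append(self, **row) -> None:
        self.epochs.append(row)

    def losses(self, scale: Optional[int] = None) -> np.ndarray:
        rows = self.epochs if scale is None else [r for r in self.epochs if r["scale"] == scale]
        return np.array([r["loss"] for r in rows])

    def to_rows(self) -> List[Dict]:
        return list(self.epochs)


def attach_activations(batch: WindowBatch, trial: Trial, model: ElbowModel) -> None:
    """Attach muscle activations at each window's current step.

    Computed from the trial's sEMG in physical (unstandardized) units via
    the delayed-excitation and shape-factor transforms.
    """
    acts = np.column_stack(
        [
            activation(
                excitation_from_emg(trial.emg[:, c], trial.t, model.act.d),
                model.act.A,
            )
            for c in range(trial.emg.shape[1])
        ]
    )
    batch.act = acts[batch.idx]


def _init_weights(kind: str, n_in: int, hidden: int, rng: np.random.Generator):
    cls = GRUWeights if kind == "gru" else RNNWeights
    return cls.init(n_in, hidden, rng)


def _as_tensors(weights) -> Dict[str, Tensor]:
    return {k: Tensor(v, requires_grad=True) for k, v in weights.params.items()}


def _values(params: Mapping[str, Tensor]) -> Dict[str, np.ndarray]:
    return {k: t.value.copy() for k, t in params.items()}


def _load_values(params: Mapping[str, Tensor], values: Mapping[str, np.ndarray]) -> None:
    for k in params:
        params[k].value = values[k].copy()


def train_at_scale(
    scale_trials_std: Sequence[Trial],
    scale_trials_raw: Sequence[Trial],
    params: Mapping[str, Tensor],
    ident: IdentifiedParams,
    msk_model: ElbowModel,
    config: LossConfig,
    schedule: TrainingSchedule,
    epochs: int,
    rng: np.random.Generator,
    scale: int,
    record: Optional[TrainingRecord] = None,
) -> TrainingRecord:
    """Minimize the composite loss on one scale's data; early-stopped.

    Fresh teacher-forcing noise is drawn from ``rng`` for this scale. The
    best (lowest training loss) weight and parameter states are restored
    before returning, implementing the transfer contract between scales.
    """
    record = record if record is not None else TrainingRecord()
    sigma = schedule.sigma_for(scale)
    if sigma is None:
        q_all = np.concatenate([tr.q for tr in scale_trials_std])
        # strong noise while the curriculum runs at coarse scales (rollout
        # robustness), light noise at the full scale where the physics
        # residual identifies the parameters
        sigma = (0.1 if scale < 0 else 0.03) * float(q_all.std())
    per_trial = []
    for tr_std, tr_raw in zip(scale_trials_std, scale_trials_raw):
        batch = make_windows(tr_std, schedule.m, noise_sigma=sigma, rng=rng)
        attach_activations(batch, tr_raw, msk_model)
        batch.res_mask = residual_window_mask(msk_model, tr_raw.q[batch.idx])
        per_trial.append(batch)
    # the data misfit is minimized over small contiguous chunks (one
    # shuffled pass per epoch); the physics residual takes one full-batch
    # step per epoch so the parameter gradients are low-noise
    full = WindowBatch.concat(per_trial)
    chunks = full.chunks(schedule.batch_size)
    n_total = sum(c.n_windows for c in chunks)
    opt = Adam(list(params.values()), lr=schedule.lr)
    opt_gamma = Adam(ident.trainables(), lr=schedule.gamma_lr)
    best = {"loss": np.inf, "weights": _values(params), "ident": ident.state(), "epoch": -1}
    stale = 0
    order = np.arange(len(chunks))
    use_residual = config.beta > 0.0 and scale in config.residual_scales
    for epoch in range(epochs):
        if schedule.lr_decay == "cosine":
            decay = 0.01 + 0.99 * 0.5 * (1 + np.cos(np.pi * epoch / epochs))
            opt.lr = schedule.lr * decay
            opt_gamma.lr = schedule.gamma_lr * decay
        rng.shuffle(order)
        jd_total = 0.0
        for ci in order:
            chunk = chunks[ci]
            opt.zero_grad()
            j, jd, _ = composite_loss(
                params, ident, chunk, chunk, config, msk_model,
                kind=schedule.kind, standard=schedule.standard_gru,
                with_residual=False,
            )
            j.backward()
            opt.step()
            jd_total += (chunk.n_windows / n_total) * jd
        jr_total = 0.0
        if use_residual:
            opt.zero_grad()
            opt_gamma.zero_grad()
            j_res = residual_loss(
                params, ident.physical(), full, config, msk_model,
                kind=schedule.kind, standard=schedule.standard_gru,
            )
            jr_total = float(ad.value_of(j_res))
            (config.beta * j_res).backward()
            if not config.detach_residual:
                opt.step()
            opt_gamma.step()
        loss_val = jd_total + config.beta * jr_total
        if not np.isfinite(loss_val):
            record.append(scale=scale, epoch=epoch, loss=loss_val,
                          j_data=jd_total, j_res=jr_total, diverged=True,
                          gamma=ident.values())
            raise FloatingPointError(
                f"non-finite training loss at scale [{scale}], epoch {epoch}"
            )
        record.append(scale=scale, epoch=epoch, loss=loss_val,
                      j_data=jd_total, j_res=jr_total, gamma=ident.values())
        if loss_val < best["loss"] - schedule.min_delta:
            best = {"loss": loss_val, "weights": _values(params),
                    "ident": ident.state(), "epoch": epoch}
            stale = 0
        else:
            stale += 1
            if stale > schedule.patience:
                break
    _load_values(params, best["weights"])
    ident.load_state(best["ident"])
    return record


def mr_train(
    mr_train_trials: Mapping[int, Sequence[Trial]],
    schedule: TrainingSchedule,
    msk_model: ElbowModel,
    gamma0: Mapping[str, float],
    seed: int = 0,
    config: Optional[LossConfig] = None,
    stats: Optional[Standardizer] = None,
    param_mode: str = "normalized",
    anchors: Optional[Mapping[str, np.ndarray]] = None,
):
    """Sequential multi-resolution training with weight transfer.

    ``mr_train_trials`` maps each scale in the schedule to that scale's
    projected training trials (physical units). Returns
    ``(params, ident, record, stats)`` where ``params`` are the final
    (scale-[0]) weight tensors.
    """
    for s in schedule.scales:
        if s not in mr_train_trials:
            raise ValueError(f"scale [{s}] missing from the training dataset")
    if stats is None:
        stats = Standardizer.from_trials(mr_train_trials[0])
    if config is None:
        config = LossConfig(stats=stats)
    elif config.stats is not stats:
        config = LossConfig(stats=stats, beta=config.beta,
                            derivative_mode=config.derivative_mode)
    rng = np.random.default_rng(seed)
    n_in = 1 + mr_train_trials[0][0].emg.shape[1]
    weights = _init_weights(schedule.kind, n_in, schedule.hidden, rng)
    dtype = np.dtype(schedule.dtype)
    weights.params = {k: v.astype(dtype) for k, v in weights.params.items()}
    params = _as_tensors(weights)
    ident = IdentifiedParams(gamma0, mode=param_mode, anchors=anchors)
    record = TrainingRecord()
    for scale, epochs in zip(schedule.scales, schedule.epochs):
        raw = list(mr_train_trials[scale])
        std = [stats.transform_trial(tr) for tr in raw]
        train_at_scale(
            std, raw, params, ident, msk_model, config, schedule,
            epochs, rng, scale, record,
        )
    return params, ident, record, stats


def evaluate(
    params: Mapping,
    test_trial: Trial,
    stats: Standardizer,
    m: int,
    kind: str = "gru",
    standard: bool = False,
) -> Dict[str, float]:
    """Rollout metrics {MSE, R2, NMSE} on a full-scale test trial.

    The model is seeded with the first m measured motion values and then
    predicts autoregressively; metrics are computed in physical units.
    """
    q = test_trial.q
    denom = float(np.sum((q - q.mean()) ** 2))
    if denom == 0.0:
        raise ValueError("test trial has zero motion variance; R2/NMSE undefined")
    tr_std = stats.transform_trial(test_trial)
    inputs = np.column_stack([tr_std.t, tr_std.emg])
    q_hat_std = rollout(params, inputs, tr_std.q[:m], m, kind=kind, standard=standard)
    q_hat = stats.destandardize_q(q_hat_std)
    n = q.size
    sq = np.sum((q - q_hat) ** 2)
    mse = sq / n
    r2 = 1.0 - sq / denom
    nmse = sq / (n * denom)
    return {"MSE": float(mse), "R2": float(r2), "NMSE": float(nmse)}
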