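"""Synthetic verification data: sinusoidal sEMG trials and solved motions.

The verification study uses five trials of noiseless periodic sinusoidal
sEMG envelopes with unit maximum amplitude and trial-to-trial frequency
variation, an antagonist pair in antiphase (see :class:`SynthSpec` for the
exact waveform family), sampled at n = 500 points over 10 s. Zero-mean
Gaussian noise is added to the sEMG (three cases, sigma in
{0.1, 0.15, 0.2} — 10-20 % of the unit signal maximum), and the
ground-truth elbow motion of every trial is then solved from the forward
dynamics driven by the *noisy* sEMG, from q(0) = pi/6, qdot(0) = 0. The
waveform family is isolated in :func:`synth_emg` so an alternative
envelope set can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .dynamics import ElbowModel, Trial, simulate_motion

__all__ = [
    "NoiseCase",
    "SynthSpec",
    "NOISE_CASES",
    "synth_emg",
    "apply_noise",
    "generate_verification_set",
]


@dataclass(frozen=True)
class NoiseCase:
    """Additive Gaussian sEMG noise level of one verification case."""

    case_id: int
    sigma: float
    mu: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.sigma <= 0.2:
            raise ValueError("sigma must stay within 10-20% of the unit signal maximum")


NOISE_CASES = {
    1: NoiseCase(1, 0.1),
    2: NoiseCase(2, 0.15),
    3: NoiseCase(3, 0.2),
}


@dataclass(frozen=True)
class SynthSpec:
    """Sampling grid and waveform settings of the five-trial verification set.

    The antagonist envelopes are antiphase sinusoids with a flexor bias,

        e_bi  = 0.65 + 0.35 sin(2 pi f_k t),
        e_tri = 0.35 + 0.35 sin(2 pi f_k t + pi),

    so e_bi + e_tri = 1 at every instant, the noiseless maximum is exactly
    1, and the mean flexor excess holds the elbow near mid-range: with the
    reference model the solved motions stay strictly inside the admissible
    angle interval (end stops essentially unengaged) for every trial
    frequency and noise case, which keeps the verification study
    well-posed. Trial frequencies span 1.5-2.5 Hz.
    """

    n: int = 500
    duration: float = 10.0  # s
    frequencies: Sequence[float] = (1.5, 1.75, 2.0, 2.25, 2.5)  # Hz, trials 1-5
    baseline_bi: float = 0.65
    depth_bi: float = 0.35
    baseline_tri: float = 0.35
    depth_tri: float = 0.35
    phase_bi: float = 0.0
    phase_tri: float = np.pi  # antagonists in antiphase
    q0: float = np.pi / 6
    qdot0: float = 0.0

    def __post_init__(self):
        if self.n < 2 or self.duration <= 0:
            raise ValueError("invalid sampling settings")
        if any(f <= 0 for f in self.frequencies):
            raise ValueError("frequencies must be positive")

    @property
    def t(self) -> np.ndarray:
        return np.linspace(0.0, self.duration, self.n)

    @property
    def n_trials(self) -> int:
        return len(self.frequencies)


def synth_emg(trial_k: int, spec: SynthSpec = SynthSpec()):
    """Noiseless sEMG envelopes (e_bi, e_tri) of trial ``trial_k`` (1-based).

    Flexor-biased antiphase sinusoids bounded in [0, 1] with overall
    maximum exactly 1 and e_bi + e_tri = 1 at every sample.
    """
    if not 1 <= trial_k <= spec.n_trials:
        raise ValueError(f"trial_k must be in 1..{spec.n_trials}")
    f = spec.frequencies[trial_k - 1]
    t = spec.t
    e_bi = spec.baseline_bi + spec.depth_bi * np.sin(2.0 * np.pi * f * t + spec.phase_bi)
    e_tri = spec.baseline_tri + spec.depth_tri * np.sin(2.0 * np.pi * f * t + spec.phase_tri)
    return e_bi, e_tri


def apply_noise(signals: np.ndarray, case: NoiseCase,
                rng: np.random.Generator) -> np.ndarray:
    """Add i.i.d. zero-mean Gaussian noise per sample per channel.

    No clipping here — out-of-range excitation values are clipped later in
    the activation dynamics.
    """
    signals = np.asarray(signals, dtype=np.float64)
    if case.sigma == 0.0:
        return signals.copy()
    return signals + rng.normal(case.mu, case.sigma, size=signals.shape)


def generate_verification_set(
    noise_case: int | NoiseCase,
    spec: SynthSpec = SynthSpec(),
    model: Optional[ElbowModel] = None,
    seed: int = 0,
) -> List[Trial]:
    """The five verification trials of one noise case.

    For each trial the noisy sEMG pair drives the forward dynamics from
    q(0) = pi/6, qdot(0) = 0; the returned :class:`Trial` objects carry the
    noisy sEMG and the solved motion on the common grid. Deterministic in
    ``seed``.
    """
    if isinstance(noise_case, int):
        if noise_case not in NOISE_CASES:
            raise ValueError(f"unknown noise case {noise_case}; choose from {sorted(NOISE_CASES)}")
        noise_case = NOISE_CASES[noise_case]
    model = model if model is not None else ElbowModel()
    rng = np.random.default_rng(seed)
    trials = []
    for k in range(1, spec.n_trials + 1):
        e_bi, e_tri = synth_emg(k, spec)
        emg = apply_noise(np.column_stack([e_bi, e_tri]), noise_case, rng)
        trial = simulate_motion(spec.t, emg, model, q0=spec.q0, qdot0=spec.qdot0)
        trials.append(trial)
    return trials
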