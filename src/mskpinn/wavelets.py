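"""Wavelet multi-resolution projection of trial signals.

Mixed-frequency sEMG drives low-frequency joint motion; training the
sequence model coarse-to-fine requires each trial signal at a ladder of
dyadic scales. A signal at scale [0] (raw) is decomposed with the discrete
wavelet transform; zeroing all detail coefficients and reconstructing
yields the coarse approximation P_j f at scale [-j] *at the original
length* — every scale keeps the same n time steps, only the frequency
content changes. The telescoping identity

    f = P_J f + sum_{b=0}^{J-1} H_b f,      H_b f = P_b f - P_{b+1} f

holds to machine precision, and with the default ``periodization``
boundary mode the projection is orthogonal, so projections nest
(P_2 P_1 = P_2) and approximation energy is non-increasing with depth.

The wavelet family defaults to Daubechies-2; the time column of a dataset
is never filtered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np
import pywt

from .dynamics import Trial

__all__ = ["MRSignal", "MRDataset", "project", "detail", "decompose", "build_mr_dataset"]

DEFAULT_WAVELET = "db2"
DEFAULT_MODE = "periodization"


def _check_depth(n: int, j: int, wavelet: str) -> None:
    if j < 0:
        raise ValueError("number of levels j must be >= 0")
    max_level = pywt.dwt_max_level(n, pywt.Wavelet(wavelet).dec_len)
    if j > max_level:
        raise ValueError(
            f"insufficient samples for requested scale: {n} samples support "
            f"at most {max_level} levels, got {j}"
        )


def project(
    signal: np.ndarray,
    j: int,
    wavelet: str = DEFAULT_WAVELET,
    mode: str = DEFAULT_MODE,
) -> np.ndarray:
    """Coarse approximation of ``signal`` at scale [-j], full length.

    Decomposes ``j`` levels, zeroes every detail band and reconstructs —
    a low-pass projection, not a decimation. ``j = 0`` is the identity.
    """
    signal = np.asarray(signal, dtype=np.float64)
    _check_depth(signal.size, j, wavelet)
    if j == 0:
        return signal.copy()
    coeffs = pywt.wavedec(signal, wavelet, mode=mode, level=j)
    coeffs = [coeffs[0]] + [np.zeros_like(c) for c in coeffs[1:]]
    return pywt.waverec(coeffs, wavelet, mode=mode)[: signal.size]


def detail(
    signal: np.ndarray,
    b: int,
    wavelet: str = DEFAULT_WAVELET,
    mode: str = DEFAULT_MODE,
) -> np.ndarray:
    """Detail component H_b f = P_b f - P_{b+1} f (full length)."""
    return project(signal, b, wavelet, mode) - project(signal, b + 1, wavelet, mode)


@dataclass
class MRSignal:
    """A signal with its ladder of coarse approximations and details.

    ``approximations[-j]`` is P_j f; ``details[-j-1]`` is H_j f, so
    ``base = approximations[-J] + sum(details.values())`` exactly.
    """

    base: np.ndarray
    approximations: Dict[int, np.ndarray] = field(default_factory=dict)
    details: Dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return -min(self.approximations) if self.approximations else 0

    def reconstruct(self) -> np.ndarray:
        out = self.approximations[-self.depth].copy()
        for d in self.details.values():
            out += d
        return out


def decompose(
    signal: np.ndarray,
    J: int,
    wavelet: str = DEFAULT_WAVELET,
    mode: str = DEFAULT_MODE,
) -> MRSignal:
    """Full multi-resolution ladder of ``signal`` down to scale [-J]."""
    signal = np.asarray(signal, dtype=np.float64)
    approx = {0: signal.copy()}
    for j in range(1, J + 1):
        approx[-j] = project(signal, j, wavelet, mode)
    details = {-(b + 1): approx[-b] - approx[-(b + 1)] for b in range(J)}
    return MRSignal(base=signal, approximations=approx, details=details)


@dataclass
class MRDataset:
    """Nested multi-resolution training data: projected trials per scale.

    ``levels[-j]`` holds one projected :class:`Trial` per input trial, with
    every sEMG channel and the joint angle independently projected to scale
    [-j] and the time column untouched. ``levels[0]`` is the raw data.
    """

    levels: Dict[int, Sequence[Trial]]

    @property
    def depth(self) -> int:
        return -min(self.levels)

    @property
    def scales(self):
        """Scales in training order, coarsest first: [-J, ..., -1, 0]."""
        return sorted(self.levels)

    def __getitem__(self, scale: int) -> Sequence[Trial]:
        if scale not in self.levels:
            raise KeyError(f"scale [{scale}] not present in dataset")
        return self.levels[scale]


def build_mr_dataset(
    trials: Sequence[Trial],
    J: int,
    wavelet: str = DEFAULT_WAVELET,
    mode: str = DEFAULT_MODE,
) -> MRDataset:
    """Project each trial's sEMG channels and angle onto scales 0 ... -J."""
    trials = list(trials)
    if not trials:
        raise ValueError("no trials given")
    n0 = trials[0].n
    dt0 = trials[0].dt
    for tr in trials:
        if tr.n != n0:
            raise ValueError("inconsistent trial lengths")
        if abs(tr.dt - dt0) > 1e-9 * dt0:
            raise ValueError("trials must share the sampling step")
    levels: Dict[int, list] = {}
    for j in range(J + 1):
        scale_trials = []
        for tr in trials:
            emg_proj = np.column_stack(
                [project(tr.emg[:, c], j, wavelet, mode) for c in range(tr.emg.shape[1])]
            )
            q_proj = project(tr.q, j, wavelet, mode)
            scale_trials.append(
                Trial(t=tr.t.copy(), emg=emg_proj, q=q_proj, muscle_names=tr.muscle_names)
            )
        levels[-j] = scale_trials
    return MRDataset(levels=levels)
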