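"""Model/Results facade for multi-resolution physics-informed training.

:class:`MultiResolutionPIGRU` bundles the full workflow — wavelet ladder,
coarse-to-fine GRU training with the physics penalty, multi-seed
aggregation and rollout evaluation — behind a statsmodels-style interface:
construct the model from trials, call :meth:`fit`, inspect the returned
:class:`MRPIGRUResults` (identified parameter estimates with their
across-seed spread, rollout metrics, ``summary()`` table, prediction and
simulation helpers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dynamics import ElbowModel, Trial, simulate_motion
from .loss import PARAM_NAMES, LossConfig, Standardizer
from .training import TrainingRecord, TrainingSchedule, evaluate, mr_train
from .wavelets import build_mr_dataset

__all__ = ["MultiResolutionPIGRU", "MRPIGRUResults"]


class MultiResolutionPIGRU:
    """sEMG-to-motion surrogate with simultaneous Hill-parameter identification.

    Parameters
    ----------
    train_trials : training movement recordings (raw, physical units)
    test_trial : held-out trial for rollout metrics
    msk_model : forward-dynamics model supplying the fixed constants
        (geometry, tendon slack lengths, activation dynamics, ...)
    gamma0 : initialization values of the identified parameters
        {f0_Bi [N], l0_Bi [m], f0_Tri [N], l0_Tri [m]}; per-seed
        initializations are drawn within +-10 % of these
    schedule : training protocol (scales, epochs, optimizer settings)
    loss : composite-loss settings (beta, derivative mode, ...); the
        standardization statistics are computed from the training split
    param_mode : "normalized" (ratios to gamma0) or "constrained"
        (sigmoid-gated literature anchors, for subject-like data)
    """

    def __init__(
        self,
        train_trials: Sequence[Trial],
        test_trial: Trial,
        msk_model: Optional[ElbowModel] = None,
        gamma0: Optional[Mapping[str, float]] = None,
        schedule: Optional[TrainingSchedule] = None,
        loss: Optional[LossConfig] = None,
        param_mode: str = "normalized",
        anchors: Optional[Mapping[str, np.ndarray]] = None,
    ):
        self.train_trials = list(train_trials)
        if not self.train_trials:
            raise ValueError("need at least one training trial")
        self.test_trial = test_trial
        self.msk_model = msk_model if msk_model is not None else ElbowModel()
        self.gamma0 = dict(
            gamma0
            if gamma0 is not None
            else {"f0_Bi": 240.0, "l0_Bi": 0.5, "f0_Tri": 360.0, "l0_Tri": 0.48}
        )
        self.schedule = schedule if schedule is not None else TrainingSchedule()
        self.stats = Standardizer.from_trials(self.train_trials)
        if loss is None:
            loss = LossConfig(stats=self.stats)
        else:
            loss = LossConfig(
                stats=self.stats, beta=loss.beta,
                derivative_mode=loss.derivative_mode,
                residual_scales=loss.residual_scales,
                detach_residual=loss.detach_residual,
                residual_smoothing=loss.residual_smoothing,
            )
        self.loss = loss
        self.param_mode = param_mode
        self.anchors = anchors
        depth = -min(self.schedule.scales)
        self._mr = build_mr_dataset(self.train_trials, depth)

    @classmethod
    def from_dataframes(
        cls,
        train: Sequence[pd.DataFrame],
        test: pd.DataFrame,
        **kwargs,
    ) -> "MultiResolutionPIGRU":
        """Build from data frames with columns ``time, emg_bi, emg_tri, q``."""

        def to_trial(df: pd.DataFrame) -> Trial:
            return Trial(
                t=df["time"].to_numpy(),
                emg=df[["emg_bi", "emg_tri"]].to_numpy(),
                q=df["q"].to_numpy(),
            )

        return cls([to_trial(df) for df in train], to_trial(test), **kwargs)

    def fit(self, seeds: Sequence[int] = (0, 1, 2, 3, 4)) -> "MRPIGRUResults":
        """Run the multi-resolution training once per initialization seed.

        Each seed draws its own network initialization and its own
        parameter starting point (within +-10 % of ``gamma0``); estimates
        and rollout metrics are aggregated across seeds.
        """
        fits = []
        for seed in seeds:
            rng = np.random.default_rng(1000 + int(seed))
            g0 = {k: v * rng.uniform(0.9, 1.1) for k, v in self.gamma0.items()}
            params, ident, record, _ = mr_train(
                {s: self._mr[s] for s in self.schedule.scales},
                self.schedule,
                self.msk_model,
                g0,
                seed=int(seed),
                config=self.loss,
                stats=self.stats,
                param_mode=self.param_mode,
                anchors=self.anchors,
            )
            metrics = evaluate(
                params, self.test_trial, self.stats, self.schedule.m,
                kind=self.schedule.kind, standard=self.schedule.standard_gru,
            )
            fits.append(
                {
                    "seed": int(seed),
                    "weights": {k: v.value.copy() for k, v in params.items()},
                    "gamma": ident.values(),
                    "gamma0": g0,
                    "metrics": metrics,
                    "record": record,
                }
            )
        return MRPIGRUResults(model=self, fits=fits)


@dataclass
class MRPIGRUResults:
    """Aggregated estimates and diagnostics of a multi-seed fit."""

    model: MultiResolutionPIGRU
    fits: List[Dict]

    @property
    def seeds(self) -> List[int]:
        return [f["seed"] for f in self.fits]

    @property
    def params(self) -> Dict[str, float]:
        """Across-seed mean of the identified parameters (N, m)."""
        return {
            n: float(np.mean([f["gamma"][n] for f in self.fits])) for n in PARAM_NAMES
        }

    @property
    def bse(self) -> Dict[str, float]:
        """Across-seed standard deviation of the identified parameters."""
        return {
            n: float(np.std([f["gamma"][n] for f in self.fits])) for n in PARAM_NAMES
        }

    def percentage_errors(self, truth: Mapping[str, float]) -> pd.DataFrame:
        """Signed percentage error of every seed's estimate against a known
        ground truth, plus across-seed mean and std rows."""
        rows = {
            f["seed"]: {
                n: 100.0 * (f["gamma"][n] - truth[n]) / truth[n] for n in PARAM_NAMES
            }
            for f in self.fits
        }
        df = pd.DataFrame(rows).T
        df.loc["mean"] = df.mean()
        df.loc["std"] = df.iloc[:-1].std(ddof=0)
        return df

    def metrics(self) -> pd.DataFrame:
        """Per-seed rollout metrics (MSE, R2, NMSE) on the test trial."""
        df = pd.DataFrame({f["seed"]: f["metrics"] for f in self.fits}).T
        df.loc["mean"] = df.mean()
        df.loc["std"] = df.iloc[:-1].std(ddof=0)
        return df

    def predict(self, trial: Trial, seed: Optional[int] = None) -> np.ndarray:
        """Autoregressive rollout prediction of a trial's motion [rad].

        Uses the fit of ``seed`` (default: the first fitted seed); the
        model sees the measured motion only through the m-step seed.
        """
        from .cells import rollout

        fit = self.fits[0] if seed is None else next(
            f for f in self.fits if f["seed"] == seed
        )
        stats = self.model.stats
        tr_std = stats.transform_trial(trial)
        inputs = np.column_stack([tr_std.t, tr_std.emg])
        m = self.model.schedule.m
        q_std = rollout(
            fit["weights"], inputs, tr_std.q[:m], m,
            kind=self.model.schedule.kind,
            standard=self.model.schedule.standard_gru,
        )
        return stats.destandardize_q(q_std)

    def simulate(self, emg: np.ndarray, t: np.ndarray, seed: Optional[int] = None,
                 **kwargs) -> Trial:
        """Forward-dynamics simulation with the identified parameters."""
        fit = self.fits[0] if seed is None else next(
            f for f in self.fits if f["seed"] == seed
        )
        model = self.model.msk_model.with_params(fit["gamma"])
        return simulate_motion(np.asarray(t), np.asarray(emg), model, **kwargs)

    def summary(self, truth: Optional[Mapping[str, float]] = None) -> str:
        """Human-readable fit report."""
        lines = []
        lines.append("Multi-resolution physics-informed GRU fit")
        lines.append("=" * 58)
        sch = self.model.schedule
        lines.append(
            f"scales {list(sch.scales)}  epochs/scale {sch.epochs}  "
            f"hidden {sch.hidden}  history m={sch.m}  seeds {self.seeds}"
        )
        lines.append(
            f"beta {self.model.loss.beta:g}  derivative {self.model.loss.derivative_mode}"
        )
        lines.append("-" * 58)
        lines.append(f"{'parameter':<10}{'estimate':>14}{'seed std':>14}")
        units = {"f0_Bi": "N", "l0_Bi": "m", "f0_Tri": "N", "l0_Tri": "m"}
        for n in PARAM_NAMES:
            lines.append(
                f"{n:<10}{self.params[n]:>12.4f} {units[n]}{self.bse[n]:>13.4f}"
            )
        if truth is not None:
            pe = self.percentage_errors(truth)
            lines.append("-" * 58)
            lines.append("mean %error vs truth: " + "  ".join(
                f"{n}:{pe.loc['mean', n]:+.2f}%" for n in PARAM_NAMES
            ))
        met = self.metrics()
        lines.append("-" * 58)
        lines.append(
            "rollout on test trial: "
            f"MSE {met.loc['mean', 'MSE']:.3e}  R2 {met.loc['mean', 'R2']:.3f}  "
            f"NMSE {met.loc['mean', 'NMSE']:.3e}"
        )
        return "\n".join(lines)
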