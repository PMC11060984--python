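"""Reading and writing trials, configurations, checkpoints and results.

Trial files are delimited text (CSV) with a header row and SI units:
``time,emg_bi,emg_tri,q``. An HDF5 container with one group per trial is
supported as an alternative for many-trial collections. Model and muscle
parameters mirror the forward-dynamics parameter table keys in a YAML
config. Weight checkpoints are single-file ``.npz`` archives of named
arrays with a JSON sidecar recording widths, history length and scale tag.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .cells import GRUWeights, RNNWeights
from .dynamics import ActivationParams, ElbowModel, MuscleParams, MusclePath, Trial

__all__ = [
    "read_trial_csv",
    "write_trial_csv",
    "read_trials_hdf5",
    "write_trials_hdf5",
    "load_model_config",
    "model_to_config",
    "save_checkpoint",
    "load_checkpoint",
    "write_json",
]

TRIAL_COLUMNS = ["time", "emg_bi", "emg_tri", "q"]


def write_trial_csv(trial: Trial, path) -> None:
    df = pd.DataFrame(
        {
            "time": trial.t,
            "emg_bi": trial.emg[:, 0],
            "emg_tri": trial.emg[:, 1],
            "q": trial.q,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_trial_csv(path) -> Trial:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial file {path} lacks columns {missing}")
    return Trial(
        t=df["time"].to_numpy(),
        emg=df[["emg_bi", "emg_tri"]].to_numpy(),
        q=df["q"].to_numpy(),
    )


def write_trials_hdf5(trials: Sequence[Trial], path, names: Optional[Sequence[str]] = None) -> None:
    import h5py

    names = names or [f"trial_{i + 1}" for i in range(len(trials))]
    with h5py.File(path, "w") as f:
        for name, tr in zip(names, trials):
            grp = f.create_group(name)
            grp.create_dataset("time", data=tr.t)
            grp.create_dataset("emg", data=tr.emg)
            grp.create_dataset("q", data=tr.q)


def read_trials_hdf5(path) -> Dict[str, Trial]:
    import h5py

    out = {}
    with h5py.File(path, "r") as f:
        for name in f:
            grp = f[name]
            out[name] = Trial(t=grp["time"][...], emg=grp["emg"][...], q=grp["q"][...])
    return out


# ---------------------------------------------------------------------------
# model configuration
# ---------------------------------------------------------------------------

_MUSCLE_KEYS = ("l0M", "vmaxM", "f0M", "lsT", "theta0")


def model_to_config(model: ElbowModel) -> Dict:
    """Serialize an elbow model to a plain mapping mirroring the parameter table."""

    def kappa(m: MuscleParams):
        return {k: float(getattr(m, k)) for k in _MUSCLE_KEYS}

    return {
        "geometry": {
            "lua": model.lua,
            "lfa": model.lfa,
            "m_fa": model.m_fa,
            "l1_Bi": model.bi_path.l1,
            "l2_Bi": model.bi_path.l2,
            "l1_Tri": model.tri_path.l1,
            "l2_Tri": model.tri_path.l2,
        },
        "biceps": kappa(model.biceps),
        "triceps": kappa(model.triceps),
        "activation": {"d": model.act.d, "A": model.act.A},
        "g": model.g,
        "passive": model.passive,
    }


def load_model_config(source) -> ElbowModel:
    """Build an :class:`ElbowModel` from a YAML path or a mapping."""
    if isinstance(source, (str, Path)):
        with open(source) as f:
            cfg = yaml.safe_load(f)
    else:
        cfg = dict(source)
    geo = cfg.get("geometry", {})
    def muscle(key):
        spec = cfg.get(key, {})
        return MuscleParams(**{k: spec[k] for k in _MUSCLE_KEYS if k in spec}) if spec else None

    kwargs = {}
    for name in ("lua", "lfa", "m_fa"):
        if name in geo:
            kwargs[name] = float(geo[name])
    bi = muscle("biceps")
    tri = muscle("triceps")
    if bi is not None:
        kwargs["biceps"] = bi
    if tri is not None:
        kwargs["triceps"] = tri
    if {"l1_Bi", "l2_Bi"} <= set(geo):
        kwargs["bi_path"] = MusclePath(geo["l1_Bi"], geo["l2_Bi"], sign=1)
    if {"l1_Tri", "l2_Tri"} <= set(geo):
        kwargs["tri_path"] = MusclePath(geo["l1_Tri"], geo["l2_Tri"], sign=-1)
    if "activation" in cfg:
        kwargs["act"] = ActivationParams(**cfg["activation"])
    for name in ("g", "passive"):
        if name in cfg:
            kwargs[name] = cfg[name]
    return ElbowModel(**kwargs)


# ---------------------------------------------------------------------------
# checkpoints and JSON artifacts
# ---------------------------------------------------------------------------


def save_checkpoint(weights, path, m: int, scale: int, extra: Optional[Mapping] = None) -> None:
    """Write named weight arrays (.npz) plus a JSON sidecar with metadata."""
    path = Path(path)
    arrays = {k: np.asarray(v) for k, v in weights.params.items()}
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = {
        "kind": weights.kind,
        "hidden": weights.hidden,
        "n_in": weights.n_in,
        "m": m,
        "scale": scale,
    }
    if extra:
        meta.update(extra)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path):
    """Load a checkpoint; returns (weights, metadata)."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as data:
        params = {k: data[k].copy() for k in data.files}
    cls = GRUWeights if meta["kind"] == "gru" else RNNWeights
    return cls(params=params, hidden=meta["hidden"], n_in=meta["n_in"]), meta


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
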