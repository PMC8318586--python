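"""Readers and writers for the pipeline's on-disk formats.

Behaviour lives in CSV/TSV (subject, condition, food, tastiness,
healthiness, choice, rt; empty rt = no response); epoched EEG in an HDF5
container with one group per subject x condition (datasets ``data``,
``trial_index``; attrs ``fs``, ``t0``, ``channels``).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .eeg import EpochArray

__all__ = [
    "read_behaviour",
    "write_behaviour",
    "write_epochs_h5",
    "read_epochs_h5",
    "write_params",
    "read_params",
]

BEHAVIOUR_COLUMNS = ["subject", "condition", "food", "tastiness", "healthiness", "choice", "rt"]


def write_behaviour(trials: pd.DataFrame, path) -> None:
    sep = "\t" if str(path).endswith(".tsv") else ","
    trials[BEHAVIOUR_COLUMNS].to_csv(path, index=False, sep=sep)


def read_behaviour(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith(".tsv") else ","
    df = pd.read_csv(path, sep=sep)
    missing = set(BEHAVIOUR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"behaviour table missing columns {sorted(missing)}")
    df["choice"] = df["choice"].fillna("none")
    bad = ~df.choice.isin(["accept", "reject", "none"])
    if bad.any():
        raise ValueError("choice must be accept/reject/none")
    if ((df.tastiness < 1) | (df.tastiness > 6) | (df.healthiness < 1) | (df.healthiness > 6)).any():
        raise ValueError("ratings must lie in 1..6")
    has_rt = df.rt.notna()
    if ((df.choice == "none") == has_rt).any():
        raise ValueError("rt must be present exactly when a choice was made")
    return df


def write_epochs_h5(epochs: dict, path) -> None:
    """``epochs`` maps (subject, condition) -> EpochArray."""
    with h5py.File(path, "w") as f:
        for (subj, cond), ep in epochs.items():
            g = f.create_group(f"{subj}/{cond}")
            g.create_dataset("data", data=ep.data.astype(np.float32), compression="gzip", compression_opts=1)
            g.create_dataset("trial_index", data=np.asarray(ep.trial_index))
            g.attrs["fs"] = ep.fs
            g.attrs["t0"] = ep.t0
            g.attrs["channels"] = json.dumps(list(ep.channels))


def read_epochs_h5(path) -> dict:
    out = {}
    with h5py.File(path, "r") as f:
        for subj in f:
            for cond in f[subj]:
                g = f[subj][cond]
                out[(subj, cond)] = EpochArray(
                    data=g["data"][()],
                    fs=float(g.attrs["fs"]),
                    t0=float(g.attrs["t0"]),
                    channels=json.loads(g.attrs["channels"]),
                    trial_index=g["trial_index"][()],
                )
    return out


def write_params(fits: pd.DataFrame, path) -> None:
    path = Path(path)
    fits.to_csv(path, index=False)
    path.with_suffix(".json").write_text(json.dumps(fits.to_dict(orient="records"), indent=1, default=str))


def read_params(path) -> pd.DataFrame:
    return pd.read_csv(path)
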