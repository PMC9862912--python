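"""HDF5 / NPZ containers for trials, crops, and predictive stacks.

HDF5 layout mirrors the in-memory containers: datasets ``data``, ``labels``
plus scalar attributes (``fs``, ``cue_onset``, ...).  NPZ files use the
same names.  Writes are atomic (temp file + rename).
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path

import h5py
import numpy as np

from .containers import CropSet, TrialSet

__all__ = ["save_trialset", "load_trialset", "save_cropset", "load_cropset",
           "save_stacks", "load_stacks", "atomic_path"]


class atomic_path:
    """Context manager: write to a temp file, rename into place on success."""

    def __init__(self, path: str | Path):
        self.path = Path(path)

    def __enter__(self) -> Path:
        fd, tmp = tempfile.mkstemp(dir=self.path.parent or Path("."),
                                   suffix=self.path.suffix + ".tmp")
        os.close(fd)
        self.tmp = Path(tmp)
        return self.tmp

    def __exit__(self, exc_type, exc, tb) -> None:
        if exc_type is None:
            self.tmp.replace(self.path)
        else:
            self.tmp.unlink(missing_ok=True)


def _is_npz(path: Path) -> bool:
    return path.suffix.lower() == ".npz"


def save_trialset(trials: TrialSet, path: str | Path) -> None:
    path = Path(path)
    fields = dict(data=trials.data, labels=trials.labels,
                  fs=np.float64(trials.fs),
                  cue_onset=np.int64(trials.cue_onset_index),
                  rest_window=np.asarray(trials.rest_window),
                  preprocessed=np.bool_(trials.preprocessed))
    with atomic_path(path) as tmp:
        if _is_npz(path):
            with open(tmp, 'wb') as fh:
                np.savez(fh, **fields)
        else:
            with h5py.File(tmp, "w") as f:
                for k, v in fields.items():
                    f.create_dataset(k, data=v)


def load_trialset(path: str | Path) -> TrialSet:
    path = Path(path)
    if _is_npz(path):
        with np.load(path) as f:
            d = {k: f[k] for k in f.files}
    else:
        with h5py.File(path, "r") as f:
            d = {k: f[k][()] for k in f}
    return TrialSet(data=d["data"], labels=d["labels"], fs=float(d["fs"]),
                    cue_onset_index=int(d["cue_onset"]),
                    rest_window=tuple(int(v) for v in d["rest_window"]),
                    preprocessed=bool(d["preprocessed"]))


def save_cropset(crops: CropSet, path: str | Path) -> None:
    path = Path(path)
    fields = dict(crops=crops.crops, trial_index=crops.trial_index,
                  crop_position=crops.crop_position,
                  start_time_s=crops.start_time_s, labels=crops.labels,
                  fs=np.float64(crops.fs))
    with atomic_path(path) as tmp:
        if _is_npz(path):
            with open(tmp, 'wb') as fh:
                np.savez(fh, **fields)
        else:
            with h5py.File(tmp, "w") as f:
                for k, v in fields.items():
                    f.create_dataset(k, data=v)


def load_cropset(path: str | Path) -> CropSet:
    path = Path(path)
    if _is_npz(path):
        with np.load(path) as f:
            d = {k: f[k] for k in f.files}
    else:
        with h5py.File(path, "r") as f:
            d = {k: f[k][()] for k in f}
    return CropSet(crops=d["crops"], trial_index=d["trial_index"],
                   crop_position=d["crop_position"],
                   start_time_s=d["start_time_s"], labels=d["labels"],
                   fs=float(d["fs"]))


def save_stacks(stacks: np.ndarray, labels: np.ndarray,
                path: str | Path) -> None:
    """Persist (n, T, C) predictive stacks with per-input true labels."""
    path = Path(path)
    with atomic_path(path) as tmp:
        if _is_npz(path):
            with open(tmp, 'wb') as fh:
                np.savez(fh, stacks=stacks, labels=labels)
        else:
            with h5py.File(tmp, "w") as f:
                f.create_dataset("stacks", data=stacks)
                f.create_dataset("labels", data=labels)


def load_stacks(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    if _is_npz(path):
        with np.load(path) as f:
            return f["stacks"], f["labels"]
    with h5py.File(path, "r") as f:
        return f["stacks"][()], f["labels"][()]
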