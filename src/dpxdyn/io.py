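"""Epochs archives (HDF5) and trial-table CSV I/O.

Archive layout::

    /data               float32, (trial, channel, time), microvolts
    /times              float64, seconds
    /channel_labels     UTF-8 strings
    /channel_positions  float64, (channel, 2)
    /trials/<column>    one dataset per trial-table column
    attrs: subject_id, sfreq, lock_event

Amplitudes are stored as float32 and computed in float64; round trips are
bit-exact at the stored precision. Writes are atomic (write to a temporary
file in the same directory, then rename over the target).
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .data import (
    TRIAL_COLUMNS,
    ChannelSet,
    ConsistencyError,
    SubjectEpochs,
    TimeAxis,
    validate_trials,
)

_REQUIRED = ("data", "times", "channel_labels", "channel_positions")

_STR = h5py.string_dtype(encoding="utf-8")


class FormatError(ValueError):
    """Raised when an archive misses or mangles a required dataset."""


def _trials_to_group(grp: h5py.Group, trials: pd.DataFrame) -> None:
    for col in TRIAL_COLUMNS:
        vals = trials[col]
        if col in ("trial_id", "block"):
            grp.create_dataset(col, data=np.asarray(vals, dtype=np.int64))
        elif col == "rt":
            grp.create_dataset(col, data=np.asarray(vals, dtype=np.float64))
        elif col == "correct":
            # missing -> -1, False -> 0, True -> 1
            coded = np.full(len(vals), -1, dtype=np.int8)
            notna = vals.notna()
            coded[notna.to_numpy()] = vals[notna].astype(bool).to_numpy()
            grp.create_dataset(col, data=coded)
        else:
            s = vals.fillna("").astype(str).to_numpy()
            grp.create_dataset(col, data=s.astype(object), dtype=_STR)


def _trials_from_group(grp: h5py.Group) -> pd.DataFrame:
    out = {}
    for col in TRIAL_COLUMNS:
        if col not in grp:
            raise FormatError(f"trial table misses dataset /trials/{col}")
        raw = grp[col][()]
        if col in ("trial_id", "block"):
            out[col] = raw.astype(int)
        elif col == "rt":
            out[col] = raw.astype(float)
        elif col == "correct":
            vals = raw.astype(int)
            out[col] = pd.array(
                [None if v < 0 else bool(v) for v in vals], dtype="boolean"
            )
        else:
            decoded = [v.decode() if isinstance(v, bytes) else str(v) for v in raw]
            out[col] = [None if v == "" else v for v in decoded]
    return pd.DataFrame(out, columns=TRIAL_COLUMNS)


def save_epochs(epochs: SubjectEpochs, path) -> None:
    """Write an epochs archive; overwrites the target atomically."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(suffix=".h5", dir=path.parent or Path("."))
    os.close(fd)
    try:
        with h5py.File(tmp, "w") as f:
            f.create_dataset("data", data=epochs.data.astype(np.float32))
            f.create_dataset("times", data=epochs.timeaxis.times)
            f.create_dataset(
                "channel_labels",
                data=np.asarray(epochs.channels.labels, dtype=object),
                dtype=_STR,
            )
            f.create_dataset("channel_positions", data=epochs.channels.positions)
            _trials_to_group(f.create_group("trials"), epochs.trials)
            f.attrs["subject_id"] = str(epochs.subject_id)
            f.attrs["sfreq"] = float(epochs.timeaxis.sfreq)
            f.attrs["lock_event"] = epochs.lock_event
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def load_epochs(path) -> SubjectEpochs:
    """Read an epochs archive written by :func:`save_epochs`."""
    with h5py.File(path, "r") as f:
        for name in _REQUIRED:
            if name not in f:
                raise FormatError(f"archive misses dataset /{name}")
        if "trials" not in f:
            raise FormatError("archive misses group /trials")
        data = f["data"][()].astype(np.float64)
        times = f["times"][()]
        labels = [
            v.decode() if isinstance(v, bytes) else str(v)
            for v in f["channel_labels"][()]
        ]
        positions = f["channel_positions"][()]
        trials = _trials_from_group(f["trials"])
        subject_id = str(f.attrs["subject_id"])
        sfreq = float(f.attrs["sfreq"])
        lock_event = str(f.attrs["lock_event"])
    channels = ChannelSet(tuple(labels), positions)
    timeaxis = TimeAxis(times, sfreq)
    try:
        return SubjectEpochs(
            subject_id=subject_id,
            data=data,
            channels=channels,
            timeaxis=timeaxis,
            trials=trials,
            lock_event=lock_event,
        )
    except ConsistencyError:
        raise


def save_trials_csv(trials: pd.DataFrame, path) -> None:
    """Trial table as UTF-8 CSV, missing values as empty fields."""
    validate_trials(trials)
    trials.to_csv(path, index=False, columns=TRIAL_COLUMNS)


def load_trials_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"cue": str, "probe": str, "pair": str})
    if "correct" in df.columns:
        df["correct"] = pd.array(
            [None if pd.isna(v) else bool(v) for v in df["correct"]], dtype="boolean"
        )
    if "response" in df.columns:
        df["response"] = df["response"].where(df["response"].notna(), None)
    return validate_trials(df[TRIAL_COLUMNS])
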