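"""Core containers for epoched EEG data.

Amplitudes are in microvolts, time in seconds with the locking event at 0.
Trial metadata travels with the data: row ``i`` of the trial table describes
slice ``i`` of the epochs array.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Columns every trial table must carry, in canonical order.
TRIAL_COLUMNS = ["trial_id", "block", "cue", "probe", "pair", "response", "correct", "rt"]

PAIRS = ("AX", "AY", "BX", "BY")


class ConsistencyError(ValueError):
    """Raised when container axes or metadata disagree."""


class WindowError(ValueError):
    """Raised when a requested time window misses the time axis."""


@dataclass(frozen=True)
class ChannelSet:
    """An ordered set of scalp channels with 2-D topographic positions.

    Positions follow the usual unit-disc convention (vertex at the origin,
    nose along +y); units are arbitrary but distances between channels are
    meaningful for spatial noise correlation.
    """

    labels: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 2)

    def __post_init__(self):
        labels = tuple(str(l) for l in self.labels)
        object.__setattr__(self, "labels", labels)
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ConsistencyError("positions must be an (n_channels, 2) array")
        if len(labels) != pos.shape[0]:
            raise ConsistencyError(
                f"{len(labels)} labels but {pos.shape[0]} positions"
            )
        if len(set(labels)) != len(labels):
            raise ConsistencyError("channel labels must be unique")
        if not np.all(np.isfinite(pos)):
            raise ConsistencyError("channel positions must be finite")
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def distances(self) -> np.ndarray:
        """Pairwise Euclidean inter-channel distances, (n, n)."""
        d = self.positions[:, None, :] - self.positions[None, :, :]
        return np.sqrt((d ** 2).sum(-1))


@dataclass(frozen=True)
class TimeAxis:
    """Uniformly sampled time axis in seconds, locking event at t = 0."""

    times: np.ndarray
    sfreq: float

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size == 0:
            raise ConsistencyError("times must be a non-empty 1-D array")
        if t.size > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ConsistencyError("times must be strictly increasing")
            if np.max(np.abs(dt - 1.0 / self.sfreq)) > 1e-9:
                raise ConsistencyError("times must be uniform at 1/sfreq spacing")
        if not np.all(np.isfinite(t)):
            raise ConsistencyError("times must be finite")
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return self.times.size

    @classmethod
    def from_span(cls, tmin: float, tmax: float, sfreq: float) -> "TimeAxis":
        """Axis of samples ``tmin, tmin + 1/sfreq, ...`` up to and including tmax."""
        n = int(round((tmax - tmin) * sfreq)) + 1
        return cls(tmin + np.arange(n) / sfreq, sfreq)


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Check the trial-table invariants and return the frame.

    ``pair`` must equal ``cue + probe``; ``rt`` is missing iff ``response``
    is 'none'; present RTs are strictly positive.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ConsistencyError(f"trial table misses columns: {missing}")
    if len(trials):
        if not (trials["cue"].isin(["A", "B"])).all():
            raise ConsistencyError("cue must be 'A' or 'B'")
        if not (trials["probe"].isin(["X", "Y"])).all():
            raise ConsistencyError("probe must be 'X' or 'Y'")
        if not (trials["pair"] == trials["cue"] + trials["probe"]).all():
            raise ConsistencyError("pair must equal cue + probe")
        responded = trials["response"].notna() & (trials["response"] != "none")
        has_rt = trials["rt"].notna()
        if not (responded == has_rt).all():
            raise ConsistencyError("rt must be present iff a response was given")
        if has_rt.any() and not (trials.loc[has_rt, "rt"] > 0).all():
            raise ConsistencyError("present RTs must be > 0")
    return trials


@dataclass
class SubjectEpochs:
    """One subject's epoched data: trials x channels x time, in microvolts."""

    subject_id: str
    data: np.ndarray  # (n_trials, n_channels, n_times), float64
    channels: ChannelSet
    timeaxis: TimeAxis
    trials: pd.DataFrame
    lock_event: str = "cue"  # 'cue' or 'probe'

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ConsistencyError("data must be trials x channels x time")
        n_tr, n_ch, n_t = self.data.shape
        if n_ch != len(self.channels):
            raise ConsistencyError(
                f"data has {n_ch} channels, channel set has {len(self.channels)}"
            )
        if n_t != len(self.timeaxis):
            raise ConsistencyError(
                f"data has {n_t} samples, time axis has {len(self.timeaxis)}"
            )
        if len(self.trials) != n_tr:
            raise ConsistencyError(
                f"data has {n_tr} trials, trial table has {len(self.trials)} rows"
            )
        if self.data.size and not np.all(np.isfinite(self.data)):
            raise ConsistencyError("amplitudes must be finite")
        if self.lock_event not in ("cue", "probe"):
            raise ConsistencyError("lock_event must be 'cue' or 'probe'")
        validate_trials(self.trials)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.timeaxis.times


def select_window(epochs: SubjectEpochs, tmin: float, tmax: float) -> SubjectEpochs:
    """Restrict epochs to the closed time interval [tmin, tmax].

    Samples exactly at the bounds are retained; the trial table is unchanged.
    """
    if not tmin < tmax:
        if tmin != tmax:
            raise WindowError("tmin must not exceed tmax")
    t = epochs.timeaxis.times
    keep = (t >= tmin) & (t <= tmax)
    if not keep.any():
        raise WindowError(
            f"window [{tmin}, {tmax}] s does not intersect the axis "
            f"[{t[0]}, {t[-1]}] s"
        )
    new_axis = TimeAxis(t[keep], epochs.timeaxis.sfreq)
    return SubjectEpochs(
        subject_id=epochs.subject_id,
        data=epochs.data[:, :, keep],
        channels=epochs.channels,
        timeaxis=new_axis,
        trials=epochs.trials,
        lock_event=epochs.lock_event,
    )


@dataclass(frozen=True)
class VectorisedData:
    """Trials x (channel * time) matrix plus the feature -> (channel, time) map.

    Feature ordering is channel-major: all time samples of channel 0, then
    channel 1, and so on. ``channel_index[f]`` and ``time_index[f]`` give the
    source coordinates of column ``f``.
    """

    Y: np.ndarray          # (m, n)
    n_channels: int
    n_times: int
    channel_index: np.ndarray  # (n,)
    time_index: np.ndarray     # (n,)

    @property
    def m(self) -> int:
        return self.Y.shape[0]

    @property
    def n(self) -> int:
        return self.Y.shape[1]


def vectorise_epochs(epochs: SubjectEpochs) -> VectorisedData:
    """Flatten each trial's channel x time block into one feature row.

    The inverse is :func:`unvectorise`; the round trip is exact.
    """
    n_tr, n_ch, n_t = epochs.data.shape
    Y = epochs.data.reshape(n_tr, n_ch * n_t)
    ch_idx = np.repeat(np.arange(n_ch), n_t)
    t_idx = np.tile(np.arange(n_t), n_ch)
    return VectorisedData(Y=Y, n_channels=n_ch, n_times=n_t,
                          channel_index=ch_idx, time_index=t_idx)


def unvectorise(Y: np.ndarray, n_channels: int, n_times: int) -> np.ndarray:
    """Reshape rows of a vectorised matrix back to (…, channel, time)."""
    Y = np.asarray(Y)
    if Y.shape[-1] != n_channels * n_times:
        raise ConsistencyError("feature count does not factor as channels * times")
    return Y.reshape(Y.shape[:-1] + (n_channels, n_times))
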