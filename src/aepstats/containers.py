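"""In-memory containers for epoched EEG and averaged evoked potentials,
plus their HDF5 round-trip I/O.

All voltages are µV, all times are ms, sampling is 1000 Hz.  An epoch runs
from -100 ms to +500 ms inclusive (601 samples); t = 0 is the stimulus
trigger, which precedes the acoustic onset by the per-stimulus silence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import h5py
import numpy as np
import pandas as pd

from .errors import DimensionError, IOFormatError
from .montage import Montage

__all__ = ["default_times", "EpochSet", "Evoked", "SimTruth", "StudyDataset",
           "write_study", "read_study", "write_evokeds", "read_evokeds"]

CONTAINER_VERSION = 1
SFREQ = 1000.0

STIMULI = ("mba", "ba")


def default_times(tmin: float = -100.0, tmax: float = 500.0) -> np.ndarray:
    """Inclusive epoch time axis in ms at 1 kHz."""
    n = int(round(tmax - tmin)) + 1
    return tmin + np.arange(n, dtype=float)


def _check_times(times: np.ndarray) -> None:
    d = np.diff(times)
    if len(times) < 2 or not np.allclose(d, d[0]):
        raise IOFormatError("time axis must be uniform")


@dataclass
class EpochSet:
    """Single-trial epochs for one subject / session / stimulus.

    data has shape (n_trials, n_channels, n_samples) in µV; channel order
    matches ``channels`` which must match the montage labels.
    """

    data: np.ndarray
    times: np.ndarray
    channels: list[str]
    subject: str
    group: int
    session: int
    stimulus: str
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise DimensionError("epoch data must be trials x channels x samples")
        if self.data.shape[1] != len(self.channels):
            raise DimensionError(
                f"{self.data.shape[1]} data channels vs {len(self.channels)} labels")
        if self.data.shape[2] != len(self.times):
            raise DimensionError("time axis length does not match data")
        _check_times(self.times)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data contains non-finite values")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def sfreq(self) -> float:
        return 1000.0 / float(self.times[1] - self.times[0])

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"unknown electrode label: {label!r}") from None

    def copy_with(self, **kw) -> "EpochSet":
        return replace(self, **kw)

    @property
    def key(self) -> tuple:
        return (self.subject, self.group, self.session, self.stimulus)


@dataclass
class Evoked:
    """Trial-averaged AEP: channels x samples in µV, with provenance."""

    data: np.ndarray
    times: np.ndarray
    channels: list[str]
    subject: str
    group: int
    session: int
    stimulus: str
    n_trials_included: int
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 2:
            raise DimensionError("evoked data must be channels x samples")
        if self.data.shape[0] != len(self.channels):
            raise DimensionError("channel count mismatch")
        if self.data.shape[1] != len(self.times):
            raise DimensionError("time axis length does not match data")
        _check_times(self.times)

    @property
    def sfreq(self) -> float:
        return 1000.0 / float(self.times[1] - self.times[0])

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"unknown electrode label: {label!r}") from None

    def get(self, label: str) -> np.ndarray:
        return self.data[self.channel_index(label)]

    def time_mask(self, window: tuple[float, float]) -> np.ndarray:
        lo, hi = window
        return (self.times >= lo) & (self.times <= hi)

    def copy_with(self, **kw) -> "Evoked":
        return replace(self, **kw)

    @property
    def key(self) -> tuple:
        return (self.subject, self.group, self.session, self.stimulus)


@dataclass
class SimTruth:
    """Ground truth for one simulated study.

    components: long table of realized per-subject component parameters
        (subject, group, session, stimulus, component, electrode-region
        independent amplitude, latency ms, gain µV).
    dprime: planted sensitivity per (group, session).
    artifacts: rows (subject, group, session, stimulus, trial) for every
        trial whose absolute voltage exceeds the rejection threshold.
    """

    components: pd.DataFrame
    dprime: pd.DataFrame
    artifacts: pd.DataFrame
    seed: int
    config: dict[str, Any] = field(default_factory=dict)

    def artifact_indices(self, subject: str, session: int,
                         stimulus: str) -> list[int]:
        a = self.artifacts
        sel = a[(a["subject"] == subject) & (a["session"] == session)
                & (a["stimulus"] == stimulus)]
        return sorted(sel["trial"].tolist())


@dataclass
class StudyDataset:
    """Everything one simulated (or imported) study contains."""

    epochs: dict[tuple, EpochSet]          # keyed (subject, group, session, stimulus)
    behavior: pd.DataFrame                 # subject, group, session, trial, stimulus, response
    montage: Montage
    truth: SimTruth | None = None
    seed: int | None = None

    def epoch_keys(self) -> list[tuple]:
        return sorted(self.epochs.keys())


# ---------------------------------------------------------------------------
# HDF5 I/O
# ---------------------------------------------------------------------------

def _key_name(key: tuple) -> str:
    subject, group, session, stimulus = key
    return f"{subject}|g{group}|s{session}|{stimulus}"


def write_study(path, study: StudyDataset) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["container_version"] = CONTAINER_VERSION
        f.attrs["kind"] = "epochs"
        if study.seed is not None:
            f.attrs["seed"] = study.seed
        g = f.create_group("epochs")
        for key, ep in study.epochs.items():
            grp = g.create_group(_key_name(key))
            grp.create_dataset("data", data=ep.data, compression="gzip",
                               compression_opts=1)
            grp.create_dataset("times", data=ep.times)
            grp.attrs["channels"] = np.array(ep.channels, dtype="S16")
            grp.attrs["subject"] = ep.subject
            grp.attrs["group"] = ep.group
            grp.attrs["session"] = ep.session
            grp.attrs["stimulus"] = ep.stimulus
            grp.attrs["units"] = "uV"


def read_study(path, montage: Montage,
               behavior: pd.DataFrame | None = None) -> StudyDataset:
    epochs: dict[tuple, EpochSet] = {}
    with h5py.File(path, "r") as f:
        if int(f.attrs.get("container_version", -1)) != CONTAINER_VERSION:
            raise IOFormatError(
                f"unsupported container version {f.attrs.get('container_version')}")
        seed = int(f.attrs["seed"]) if "seed" in f.attrs else None
        for name, grp in f["epochs"].items():
            channels = [c.decode() for c in grp.attrs["channels"]]
            missing = [c for c in channels if c not in montage.labels]
            if missing:
                raise IOFormatError(f"channels absent from montage: {missing}")
            ep = EpochSet(
                data=grp["data"][()], times=grp["times"][()], channels=channels,
                subject=str(grp.attrs["subject"]), group=int(grp.attrs["group"]),
                session=int(grp.attrs["session"]),
                stimulus=str(grp.attrs["stimulus"]))
            epochs[ep.key] = ep
    beh = behavior if behavior is not None else pd.DataFrame(
        columns=["subject", "group", "session", "trial", "stimulus", "response"])
    return StudyDataset(epochs=epochs, behavior=beh, montage=montage, seed=seed)


def write_evokeds(path, evokeds: dict[tuple, Evoked]) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["container_version"] = CONTAINER_VERSION
        f.attrs["kind"] = "evokeds"
        for key, ev in evokeds.items():
            grp = f.create_group(_key_name(key))
            grp.create_dataset("data", data=ev.data)
            grp.create_dataset("times", data=ev.times)
            grp.attrs["channels"] = np.array(ev.channels, dtype="S16")
            grp.attrs["subject"] = ev.subject
            grp.attrs["group"] = ev.group
            grp.attrs["session"] = ev.session
            grp.attrs["stimulus"] = ev.stimulus
            grp.attrs["n_trials_included"] = ev.n_trials_included
            grp.attrs["provenance"] = repr(sorted(ev.provenance.items()))


def read_evokeds(path) -> dict[tuple, Evoked]:
    out: dict[tuple, Evoked] = {}
    with h5py.File(path, "r") as f:
        if int(f.attrs.get("container_version", -1)) != CONTAINER_VERSION:
            raise IOFormatError("unsupported container version")
        for name, grp in f.items():
            ev = Evoked(
                data=grp["data"][()], times=grp["times"][()],
                channels=[c.decode() for c in grp.attrs["channels"]],
                subject=str(grp.attrs["subject"]), group=int(grp.attrs["group"]),
                session=int(grp.attrs["session"]),
                stimulus=str(grp.attrs["stimulus"]),
                n_trials_included=int(grp.attrs["n_trials_included"]))
            out[ev.key] = ev
    return out
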