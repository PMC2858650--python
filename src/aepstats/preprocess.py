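"""Preprocessing of epoched EEG into averaged, filtered, average-referenced
auditory evoked potentials.

The pipeline order is fixed: baseline correction -> artifact rejection ->
averaging -> band-pass filtering -> common-average re-referencing.  Every
stage stamps the provenance record exactly once; repeating a stage raises
:class:`~aepstats.errors.ProvenanceError`.

The band-pass emulates the recording software's "analog simulation"
filter: a causal Butterworth cascade, 1.0 Hz high-pass at 24 dB/octave
(order 4) and 20 Hz low-pass at 12 dB/octave (order 2), applied
forward-only by default (a zero-phase option exists behind a flag).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

from .containers import EpochSet, Evoked
from .errors import ConfigError, EmptyAverageError, ProvenanceError
from .montage import Montage

__all__ = ["baseline_correct", "reject_artifacts", "average_epochs",
           "filter_band", "rereference_common_average", "preprocess_block",
           "bandpass_sos", "bandpass_response_db"]

DEFAULT_BASELINE = (-100.0, 0.0)
DEFAULT_THRESHOLD = 70.0
DEFAULT_HP = 1.0
DEFAULT_LP = 20.0


def _stamp(prov: dict, step: str, value) -> dict:
    if step in prov:
        raise ProvenanceError(f"step {step!r} already applied")
    out = dict(prov)
    out[step] = value
    return out


def baseline_correct(epochs: EpochSet,
                     window: tuple[float, float] = DEFAULT_BASELINE) -> EpochSet:
    """Subtract, per trial and channel, the mean over the baseline window."""
    lo, hi = window
    if lo >= hi:
        raise ConfigError("empty baseline window")
    if lo < epochs.times[0] - 1e-9 or hi > epochs.times[-1] + 1e-9:
        raise ConfigError("baseline window outside epoch span")
    mask = (epochs.times >= lo) & (epochs.times <= hi)
    if not mask.any():
        raise ConfigError("baseline window contains no samples")
    means = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return epochs.copy_with(data=epochs.data - means,
                            provenance=_stamp(epochs.provenance, "baseline",
                                              list(window)))


def reject_artifacts(epochs: EpochSet,
                     threshold: float = DEFAULT_THRESHOLD,
                     ) -> tuple[EpochSet, pd.DataFrame]:
    """Drop trials whose absolute voltage exceeds ``threshold`` µV on any
    channel (scalp and eye channels alike).  A trial peaking exactly at
    the threshold is retained (the rule is "exceeding").

    Returns the retained EpochSet and a rejection log with one row per
    removed trial (subject, session, stimulus, trial, max_abs_uv).
    """
    if threshold <= 0:
        raise ConfigError("threshold must be > 0")
    peak = np.abs(epochs.data).max(axis=(1, 2))
    bad = peak > threshold
    log = pd.DataFrame({
        "subject": epochs.subject, "group": epochs.group,
        "session": epochs.session, "stimulus": epochs.stimulus,
        "trial": np.where(bad)[0], "max_abs_uv": peak[bad],
    })
    kept = epochs.copy_with(data=epochs.data[~bad],
                            provenance=_stamp(epochs.provenance, "rejected",
                                              int(bad.sum())))
    return kept, log


def average_epochs(epochs: EpochSet) -> Evoked:
    """Arithmetic per-sample mean over retained trials."""
    if epochs.n_trials == 0:
        raise EmptyAverageError(
            f"no trials left to average for {epochs.key}")
    prov = _stamp(epochs.provenance, "averaged", epochs.n_trials)
    return Evoked(data=epochs.data.mean(axis=0), times=epochs.times,
                  channels=list(epochs.channels), subject=epochs.subject,
                  group=epochs.group, session=epochs.session,
                  stimulus=epochs.stimulus,
                  n_trials_included=epochs.n_trials, provenance=prov)


def bandpass_sos(hp: float = DEFAULT_HP, lp: float = DEFAULT_LP,
                 sfreq: float = 1000.0, hp_order: int = 4,
                 lp_order: int = 2) -> np.ndarray:
    """Second-order sections of the Butterworth cascade (high-pass order 4
    = 24 dB/octave, low-pass order 2 = 12 dB/octave)."""
    if hp >= lp:
        raise ConfigError("high-pass corner must lie below low-pass corner")
    sos_hp = signal.butter(hp_order, hp, btype="highpass", fs=sfreq,
                           output="sos")
    sos_lp = signal.butter(lp_order, lp, btype="lowpass", fs=sfreq,
                           output="sos")
    return np.vstack([sos_hp, sos_lp])


def bandpass_response_db(freqs: np.ndarray, hp: float = DEFAULT_HP,
                         lp: float = DEFAULT_LP, sfreq: float = 1000.0,
                         ) -> np.ndarray:
    """Magnitude response of the cascade in dB at the given frequencies."""
    sos = bandpass_sos(hp, lp, sfreq)
    _, h = signal.sosfreqz(sos, worN=np.asarray(freqs, float), fs=sfreq)
    return 20.0 * np.log10(np.maximum(np.abs(h), 1e-300))


def filter_band(evoked: Evoked, hp: float = DEFAULT_HP, lp: float = DEFAULT_LP,
                zero_phase: bool = False) -> Evoked:
    """Apply the band-pass cascade along time (causal by default)."""
    sos = bandpass_sos(hp, lp, evoked.sfreq)
    if zero_phase:
        data = signal.sosfiltfilt(sos, evoked.data, axis=1)
    else:
        data = signal.sosfilt(sos, evoked.data, axis=1)
    return evoked.copy_with(data=np.asarray(data),
                            provenance=_stamp(evoked.provenance, "filtered",
                                              {"hp": hp, "lp": lp,
                                               "zero_phase": zero_phase}))


def rereference_common_average(evoked: Evoked, montage: Montage) -> Evoked:
    """Re-express every channel relative to the instantaneous mean of the
    scalp (non-eye) electrodes.  Eye channels never affect scalp output;
    applying the operation twice is the identity."""
    scalp = [c for c in evoked.channels if c not in montage.eye_labels]
    if not scalp:
        raise ConfigError("no scalp electrodes to reference against")
    idx = [evoked.channel_index(c) for c in scalp]
    ref = evoked.data[idx].mean(axis=0)
    # mathematically idempotent; the provenance record is kept single
    prov = (dict(evoked.provenance) if "reference" in evoked.provenance
            else _stamp(evoked.provenance, "reference", "common_average"))
    return evoked.copy_with(data=evoked.data - ref, provenance=prov)


def preprocess_block(epochs: EpochSet, montage: Montage,
                     baseline: tuple[float, float] = DEFAULT_BASELINE,
                     threshold: float = DEFAULT_THRESHOLD,
                     hp: float = DEFAULT_HP, lp: float = DEFAULT_LP,
                     zero_phase: bool = False,
                     ) -> tuple[Evoked, pd.DataFrame]:
    """Full fixed-order pipeline for one subject/session/stimulus block."""
    ep = baseline_correct(epochs, baseline)
    ep, log = reject_artifacts(ep, threshold)
    ev = average_epochs(ep)
    ev = filter_band(ev, hp, lp, zero_phase=zero_phase)
    ev = rereference_common_average(ev, montage)
    return ev, log
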