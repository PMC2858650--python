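"""P1/N1/P2 peak and windowed-amplitude quantification.

Peak amplitude is the extremum of the stated polarity relative to the
(already zero-mean) pre-stimulus baseline; peak latency is measured from
the stimulus trigger.  Search windows default to P1 [80, 160], N1
[120, 220] and P2 [190, 320] ms — wide enough to absorb the ~50-60 ms
stimulus-internal silence — and are configurable per run.  A peak found
on a window edge is flagged rather than dropped (a deterministic stand-in
for manual confirmation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import Evoked
from .errors import ConfigError, MissingDesignError

__all__ = ["PeakMeasure", "RoiSpec", "ROIS", "DEFAULT_WINDOWS",
           "COMPONENT_POLARITY", "detect_peak", "mean_window_amplitude",
           "build_peak_table"]

#: default component search windows, ms post trigger
DEFAULT_WINDOWS: dict[str, tuple[float, float]] = {
    "P1": (80.0, 160.0),
    "N1": (120.0, 220.0),
    "P2": (190.0, 320.0),
}

COMPONENT_POLARITY = {"P1": +1, "N1": -1, "P2": +1}

#: window used for mean P2 amplitude in brain-behavior correlations, ms
P2_MEAN_WINDOW = (190.0, 290.0)


@dataclass(frozen=True)
class RoiSpec:
    """Named electrode set used for region-of-interest averaging."""

    name: str
    electrodes: tuple[str, ...]


ROIS: dict[str, RoiSpec] = {
    "vertex": RoiSpec("vertex", ("CZ",)),
    "anterior-central": RoiSpec("anterior-central", ("FC1", "FZ", "FC2")),
    "temporal-occipital": RoiSpec("temporal-occipital", ("TP9", "IZ", "TP10")),
}


@dataclass(frozen=True)
class PeakMeasure:
    component: str
    electrode: str
    amplitude: float     # µV relative to pre-stimulus baseline
    latency: float       # ms from stimulus trigger
    boundary: bool = False  # extremum sits on a window edge


def detect_peak(evoked: Evoked, electrode: str, component: str,
                window: tuple[float, float] | None = None,
                polarity: int | None = None) -> PeakMeasure:
    """Extremum of the stated polarity inside the window; ties broken by
    the earliest latency."""
    if window is None:
        window = DEFAULT_WINDOWS[component]
    if polarity is None:
        polarity = COMPONENT_POLARITY[component]
    lo, hi = window
    if lo < evoked.times[0] - 1e-9 or hi > evoked.times[-1] + 1e-9:
        raise ConfigError(f"window {window} outside epoch span")
    mask = evoked.time_mask(window)
    if not mask.any():
        raise ConfigError("window contains no samples")
    trace = evoked.get(electrode)[mask]
    times = evoked.times[mask]
    signed = polarity * trace
    i = int(np.argmax(signed))           # argmax returns the first maximum
    boundary = i == 0 or i == len(trace) - 1
    return PeakMeasure(component=component, electrode=electrode,
                       amplitude=float(trace[i]), latency=float(times[i]),
                       boundary=boundary)


def mean_window_amplitude(evoked: Evoked,
                          where: str | RoiSpec,
                          window: tuple[float, float] = P2_MEAN_WINDOW,
                          ) -> float:
    """Arithmetic mean over samples in the window — and over the ROI's
    electrodes when given a ROI (unweighted)."""
    lo, hi = window
    if lo < evoked.times[0] - 1e-9 or hi > evoked.times[-1] + 1e-9:
        raise ConfigError(f"window {window} outside epoch span")
    mask = evoked.time_mask(window)
    electrodes = (where.electrodes if isinstance(where, RoiSpec)
                  else (where,))
    vals = [evoked.get(e)[mask].mean() for e in electrodes]
    return float(np.mean(vals))


def build_peak_table(evokeds: dict[tuple, Evoked],
                     electrodes: list[str] | None = None,
                     components: tuple[str, ...] = ("P1", "N1", "P2"),
                     windows: dict[str, tuple[float, float]] | None = None,
                     ) -> pd.DataFrame:
    """Long-format peak table: one row per (subject, session, stimulus,
    electrode, component), the sole input to the repeated-measures ANOVA.

    Raises :class:`MissingDesignError` when the subject x session x
    stimulus design is not complete (the analysis is balanced-only).
    """
    windows = windows if windows is not None else DEFAULT_WINDOWS
    if electrodes is None:
        electrodes = sorted({e for roi in ROIS.values() for e in roi.electrodes})
    keys = sorted(evokeds.keys())
    subjects = sorted({k[0] for k in keys})
    sessions = sorted({k[2] for k in keys})
    stimuli = sorted({k[3] for k in keys})
    group_of = {k[0]: k[1] for k in keys}
    expected = {(sub, group_of[sub], ses, stim)
                for sub in subjects for ses in sessions for stim in stimuli}
    missing = expected - set(keys)
    if missing:
        raise MissingDesignError(
            f"missing design cells (subject, group, session, stimulus): "
            f"{sorted(missing)[:5]}{'...' if len(missing) > 5 else ''}")
    rows = []
    for key in keys:
        ev = evokeds[key]
        for electrode in electrodes:
            for comp in components:
                pk = detect_peak(ev, electrode, comp, windows[comp])
                rows.append(dict(subject=ev.subject, group=ev.group,
                                 session=ev.session, stimulus=ev.stimulus,
                                 electrode=electrode, component=comp,
                                 amplitude=pk.amplitude, latency=pk.latency,
                                 boundary=pk.boundary))
    table = pd.DataFrame(rows)
    table.attrs["windows"] = dict(windows)
    return table
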