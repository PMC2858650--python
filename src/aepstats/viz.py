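"""Optional figures: evoked butterfly/waveform plots and the
electrode x time salience image with bootstrap-stable time points."""

from __future__ import annotations

import numpy as np

from .containers import Evoked
from .montage import Montage
from .pls import TaskPLSResults


def plot_evoked(evoked: Evoked, electrodes=("CZ",), ax=None):
    """Waveforms for a few electrodes; returns the matplotlib Axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for e in electrodes:
        ax.plot(evoked.times, evoked.get(e), label=e)
    ax.axvline(0.0, color="k", lw=0.5)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("amplitude (µV)")
    ax.set_title(f"{evoked.subject} g{evoked.group} s{evoked.session} "
                 f"{evoked.stimulus}")
    ax.legend(loc="best", fontsize="small")
    return ax


def plot_salience_image(res: TaskPLSResults, montage: Montage, lv: int = 0,
                        ax=None):
    """Electrode (rows, ordered by sagittal layer) x latency salience map;
    stable columns (|BSR| above threshold) are overlaid as black dots."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 10))
    order = [e for e in montage.layer_order()
             if e in set(res.column_index["electrode"])]
    lat = np.sort(res.column_index["latency"].unique())
    n_lat = len(lat)
    img = np.zeros((len(order), n_lat))
    stable = (res.stable_mask[:, lv].reshape(-1, n_lat)
              if res.stable_mask is not None else None)
    sal = res.electrode_saliencies[:, lv].reshape(-1, n_lat)
    electrodes = list(dict.fromkeys(res.column_index["electrode"]))
    for i, e in enumerate(order):
        img[i] = sal[electrodes.index(e)] * res.singular_values[lv]
    vmax = np.abs(img).max() or 1.0
    ax.imshow(img, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax,
              extent=[lat[0], lat[-1], len(order), 0])
    if stable is not None:
        for i, e in enumerate(order):
            cols = np.flatnonzero(stable[electrodes.index(e)])
            ax.plot(lat[cols], np.full(len(cols), i + 0.5), "k.", ms=2)
    ax.set_yticks(np.arange(len(order)) + 0.5, order, fontsize=4)
    ax.set_xlabel("latency (ms)")
    ax.set_title(f"LV{lv + 1} salience "
                 f"({100 * res.covariance_fractions[lv]:.1f}% covariance)")
    return ax
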