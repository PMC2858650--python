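"""Electrode montage: labels, schematic scalp positions, sagittal layers.

The cap is a 59-channel extended 10-20/10-10 subset plus four periocular
channels (inferior and outer canthus of each eye).  Scalp positions are
schematic 2-D coordinates (unit head radius, nose up) — sufficient for
distance-based noise correlation and salience-image ordering; no forward
head model is implied.

Electrodes are classified into 11 sagittal layers used to order channels
in salience images: three lateral (lat1-3) and two medial (med1-2) layers
per hemisphere plus one midline layer (mid).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Montage", "default_montage", "REQUIRED_LABELS"]

#: labels that any montage used with the ROI/PLS reporting must provide
REQUIRED_LABELS = (
    "CZ", "FZ", "FCZ", "FC1", "FC2", "F1", "F2", "F9",
    "FT9", "FT10", "TP9", "TP10", "CB1", "CB2", "IZ",
)

# anterior-posterior coordinate per 10-10 row (nose = +1)
_ROW_Y = {
    "FP": 0.95, "AF": 0.80, "F": 0.62, "FT": 0.45, "FC": 0.40,
    "C": 0.15, "T": 0.15, "CP": -0.10, "TP": -0.15, "P": -0.38,
    "PO": -0.60, "O": -0.78, "CB": -0.88, "I": -0.95,
}
# lateral coordinate per terminal digit (left negative, right positive)
_DIGIT_X = {1: 0.18, 2: 0.18, 3: 0.38, 4: 0.38, 5: 0.58, 6: 0.58,
            7: 0.78, 8: 0.78, 9: 0.95, 10: 0.95}
# sagittal layer per terminal digit
_DIGIT_LAYER = {1: "med1", 2: "med1", 3: "med2", 4: "med2",
                5: "lat1", 6: "lat1", 7: "lat2", 8: "lat2",
                9: "lat3", 10: "lat3"}

_LEFT = ["FP1", "F1", "F3", "F5", "F7", "F9",
         "FC1", "FC3", "FC5", "FT7", "FT9",
         "C1", "C3", "C5", "T7",
         "CP3", "CP5", "TP7", "TP9",
         "P3", "P5", "P7",
         "PO3", "O1", "CB1"]
_MIDLINE = ["FPZ", "FZ", "FCZ", "CZ", "CPZ", "PZ", "POZ", "OZ", "IZ"]

_EYE = [  # label, x, y
    ("EOG_LI", -0.30, 1.05), ("EOG_LO", -0.60, 1.00),
    ("EOG_RI", 0.30, 1.05), ("EOG_RO", 0.60, 1.00),
]


def _split_label(label: str) -> tuple[str, int]:
    row = label.rstrip("0123456789")
    digit = int(label[len(row):])
    return row, digit


def _mirror(label: str) -> str:
    row, digit = _split_label(label)
    return f"{row}{digit + 1}"


@dataclass
class Montage:
    """Channel table with scalp/eye flags, positions and sagittal layers."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"label", "x", "y", "layer", "is_eye"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"montage table missing columns: {sorted(missing)}")
        if self.table["label"].duplicated().any():
            dupes = self.table.loc[self.table["label"].duplicated(), "label"]
            raise ValueError(f"duplicate montage labels: {list(dupes)}")
        scalp = self.table.loc[~self.table["is_eye"]]
        hemi_layers = {layer if layer == "mid"
                       else f"{layer}_{'L' if x < 0 else 'R'}"
                       for layer, x in zip(scalp["layer"], scalp["x"])}
        if len(hemi_layers) != 11:
            raise ValueError(
                f"expected 11 sagittal layers, got {len(hemi_layers)}")
        absent = [lab for lab in REQUIRED_LABELS
                  if lab not in set(self.table["label"])]
        if absent:
            raise ValueError(f"montage is missing required electrodes: {absent}")
        self.table = self.table.reset_index(drop=True)

    # -- basic accessors ---------------------------------------------------
    @property
    def labels(self) -> list[str]:
        return list(self.table["label"])

    @property
    def scalp_labels(self) -> list[str]:
        return list(self.table.loc[~self.table["is_eye"], "label"])

    @property
    def eye_labels(self) -> list[str]:
        return list(self.table.loc[self.table["is_eye"], "label"])

    @property
    def n_scalp(self) -> int:
        return len(self.scalp_labels)

    def index_of(self, label: str) -> int:
        idx = self.table.index[self.table["label"] == label]
        if len(idx) == 0:
            raise KeyError(f"unknown electrode label: {label!r}")
        return int(idx[0])

    def positions(self, labels: list[str] | None = None) -> np.ndarray:
        tab = self.table.set_index("label")
        labels = labels if labels is not None else self.labels
        return tab.loc[labels, ["x", "y"]].to_numpy(float)

    def distance_matrix(self, labels: list[str] | None = None) -> np.ndarray:
        pos = self.positions(labels)
        diff = pos[:, None, :] - pos[None, :, :]
        return np.sqrt((diff ** 2).sum(-1))

    def layer_order(self) -> list[str]:
        """Scalp labels ordered by sagittal layer (left lateral to right
        lateral), anterior to posterior within each layer."""
        order = ["lat3_L", "lat2_L", "lat1_L", "med2_L", "med1_L", "mid",
                 "med1_R", "med2_R", "lat1_R", "lat2_R", "lat3_R"]
        scalp = self.table.loc[~self.table["is_eye"]].copy()
        scalp["hemi_layer"] = [
            row.layer if row.layer == "mid"
            else f"{row.layer}_{'L' if row.x < 0 else 'R'}"
            for row in scalp.itertuples()
        ]
        out: list[str] = []
        for key in order:
            block = scalp[scalp["hemi_layer"] == key].sort_values(
                "y", ascending=False)
            out.extend(block["label"])
        return out

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Montage":
        table = pd.read_csv(path, sep="\t")
        table["is_eye"] = table["is_eye"].astype(bool)
        return cls(table)

    def to_tsv_string(self) -> str:
        buf = io.StringIO()
        self.to_tsv(buf)
        return buf.getvalue()


def default_montage() -> Montage:
    """The default 59-scalp + 4-eye channel montage.

    Hemispheric labels are mirrored from the left-hemisphere list; layer
    membership follows the terminal digit (1/2 med1, 3/4 med2, 5/6 lat1,
    7/8 lat2, 9/10 lat3) with FP1/FP2, O1/O2 and CB1/CB2 assigned to
    med1, med1 and lat3 respectively.
    """
    rows = []

    def add_scalp(label: str, x: float, y: float, layer: str) -> None:
        rows.append({"label": label, "x": x, "y": y,
                     "layer": layer, "is_eye": False})

    for label in _MIDLINE:
        row = label[:-1] if label != "IZ" else "I"
        add_scalp(label, 0.0, _ROW_Y[row], "mid")
    for left in _LEFT:
        row, digit = _split_label(left)
        if left == "FP1":
            x, layer = 0.25, "med1"
        elif left == "O1":
            x, layer = 0.25, "med1"
        elif left == "CB1":
            x, layer = 0.45, "lat3"
        else:
            x, layer = _DIGIT_X[digit], _DIGIT_LAYER[digit]
        y = _ROW_Y[row]
        add_scalp(left, -x, y, layer)
        add_scalp(_mirror(left), x, y, layer)
    for label, x, y in _EYE:
        rows.append({"label": label, "x": x, "y": y,
                     "layer": "eye", "is_eye": True})
    return Montage(pd.DataFrame(rows))
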