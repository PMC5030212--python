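"""Electrode layouts for two-slice MEA cultures.

The standard preparation places two organotypic spinal-cord slices on one
multi-electrode array, one group of 34 electrodes under each slice, separated
by a central groove of ~300 µm where the lesion is made and cells are grafted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SLICE_LABELS = ("left", "right")


@dataclass(frozen=True)
class ElectrodeLayout:
    """Positions and slice assignment of the MEA electrodes.

    Parameters
    ----------
    electrode_ids
        Unique integer ids, one per electrode.
    x_um, y_um
        Planar positions in micrometres.
    slice_labels
        ``"left"`` or ``"right"`` per electrode; both labels must occur.
    selected
        Whether the electrode is included in network-activity analysis.
    """

    electrode_ids: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    slice_labels: np.ndarray
    selected: np.ndarray

    def __post_init__(self) -> None:
        ids = np.asarray(self.electrode_ids, dtype=np.int64)
        object.__setattr__(self, "electrode_ids", ids)
        object.__setattr__(self, "x_um", np.asarray(self.x_um, dtype=float))
        object.__setattr__(self, "y_um", np.asarray(self.y_um, dtype=float))
        object.__setattr__(self, "slice_labels", np.asarray(self.slice_labels, dtype="U8"))
        object.__setattr__(self, "selected", np.asarray(self.selected, dtype=bool))
        n = ids.size
        for name in ("x_um", "y_um", "slice_labels", "selected"):
            if getattr(self, name).size != n:
                raise ValueError(f"layout field {name!r} has length != number of electrodes")
        if n == 0:
            raise ValueError("layout has no electrodes")
        if np.unique(ids).size != n:
            raise ValueError("electrode_ids are not unique")
        bad = set(self.slice_labels) - set(SLICE_LABELS)
        if bad:
            raise ValueError(f"unknown slice labels: {sorted(bad)}")
        if set(self.slice_labels) != set(SLICE_LABELS):
            raise ValueError("layout must contain electrodes of both slices")

    @property
    def n_electrodes(self) -> int:
        return int(self.electrode_ids.size)

    def ids_for_slice(self, label: str, selected_only: bool = True) -> np.ndarray:
        if label not in SLICE_LABELS:
            raise ValueError(f"unknown slice label {label!r}")
        mask = self.slice_labels == label
        if selected_only:
            mask &= self.selected
        return self.electrode_ids[mask]

    def slice_of(self) -> dict[int, str]:
        """Mapping electrode_id -> slice label."""
        return {int(e): str(s) for e, s in zip(self.electrode_ids, self.slice_labels)}


def two_slice_grid(
    n_per_slice: int = 34,
    pitch_um: float = 200.0,
    groove_um: float = 300.0,
) -> ElectrodeLayout:
    """Build the default two-slice layout: two rectangular electrode groups
    flanking a central groove.

    Each group is laid out column-major on a square grid of ``pitch_um``
    spacing, 6 rows per column, mirrored about the groove.
    """
    if n_per_slice < 1:
        raise ValueError("n_per_slice must be >= 1")
    rows = 6
    ids, xs, ys, labels = [], [], [], []
    for side, label in enumerate(SLICE_LABELS):
        sign = -1.0 if label == "left" else 1.0
        for k in range(n_per_slice):
            col, row = divmod(k, rows)
            ids.append(side * n_per_slice + k)
            xs.append(sign * (groove_um / 2.0 + pitch_um / 2.0 + col * pitch_um))
            ys.append(row * pitch_um)
            labels.append(label)
    return ElectrodeLayout(
        electrode_ids=np.array(ids),
        x_um=np.array(xs),
        y_um=np.array(ys),
        slice_labels=np.array(labels),
        selected=np.ones(len(ids), dtype=bool),
    )
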