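"""Raster and network-activity figures for two-slice recordings."""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .bursts import Burst, NetworkActivityTrace  # noqa: E402
from .layout import SLICE_LABELS  # noqa: E402
from .recording import EventRaster, LightPulse  # noqa: E402

_SLICE_COLORS = {"left": "tab:blue", "right": "tab:red"}


def raster_figure(
    raster: EventRaster,
    t_range: tuple[float, float] | None = None,
    light_pulses: Sequence[LightPulse] = (),
) -> plt.Figure:
    """Event time markers per electrode, grouped by slice."""
    fig, ax = plt.subplots(figsize=(10, 5))
    order = np.argsort(raster.layout.slice_labels, kind="stable")
    row_of = {int(e): i for i, e in enumerate(raster.layout.electrode_ids[order])}
    rows = np.array([row_of[int(e)] for e in raster.electrode_ids])
    colors = [
        _SLICE_COLORS[s]
        for s in raster.layout.slice_labels[order][rows]
    ]
    ax.scatter(raster.times, rows, s=1, c=colors, marker="|")
    for p in light_pulses:
        ax.axvspan(p.onset, p.offset, color="gold", alpha=0.3)
    if t_range:
        ax.set_xlim(*t_range)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("electrode")
    ax.set_title("event raster")
    return fig


def network_activity_figure(
    traces: Mapping[str, NetworkActivityTrace],
    bursts: Mapping[str, Sequence[Burst]] | None = None,
    t_range: tuple[float, float] | None = None,
) -> plt.Figure:
    """Per-slice network activity (events per bin) with burst markers."""
    fig, axes = plt.subplots(len(SLICE_LABELS), 1, sharex=True, figsize=(10, 5))
    for ax, label in zip(np.atleast_1d(axes), SLICE_LABELS):
        tr = traces[label]
        t = np.arange(tr.counts.size) * tr.bin_width_s
        ax.plot(t, tr.counts, color=_SLICE_COLORS[label], lw=0.7)
        if bursts:
            for b in bursts.get(label, []):
                ax.axvspan(b.onset, b.offset, color="gray", alpha=0.3)
        ax.set_ylabel(f"{label}\n(events/bin)")
        if t_range:
            ax.set_xlim(*t_range)
    np.atleast_1d(axes)[-1].set_xlabel("time (s)")
    fig.suptitle("network activity")
    return fig
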