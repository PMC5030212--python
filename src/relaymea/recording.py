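"""Core containers: raw multichannel recordings, event rasters, pulses.

Conventions: times are seconds internally (delays and windows are reported in
milliseconds by the analysis layer); intervals are half-open ``[start, end)``
unless noted otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .layout import ElectrodeLayout


@dataclass(frozen=True)
class LightPulse:
    """One LED illumination interval; intensity in % of the LED maximum."""

    onset: float
    offset: float
    intensity: float = 94.0

    def __post_init__(self) -> None:
        if not (self.onset < self.offset):
            raise ValueError("light pulse requires onset < offset")
        if not (0.0 <= self.intensity <= 100.0):
            raise ValueError("light intensity must be in [0, 100] %")


@dataclass(frozen=True)
class StimulationProtocol:
    """Monopolar biphasic stimulation through one MEA electrode.

    Printed operating ranges: pulse width 0.1-0.5 ms, amplitude 1-3 V,
    repetition rate 0.05-0.1 Hz.
    """

    electrode_id: int
    pulse_width_ms: float = 0.3
    amplitude_v: float = 2.0
    rate_hz: float = 0.1

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ValueError("stimulation rate must be positive")
        if not (0.1 <= self.pulse_width_ms <= 0.5):
            raise ValueError("pulse width outside the 0.1-0.5 ms operating range")
        if not (1.0 <= self.amplitude_v <= 3.0):
            raise ValueError("amplitude outside the 1-3 V operating range")


@dataclass
class RawRecording:
    """Multichannel extracellular voltage traces in µV.

    ``signals`` has shape ``(n_electrodes, n_samples)``, row order matching
    ``layout.electrode_ids``.
    """

    signals: np.ndarray
    sampling_rate: float
    layout: ElectrodeLayout
    stim_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    light_pulses: tuple[LightPulse, ...] = ()

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals)
        if self.signals.ndim != 2:
            raise ValueError("signals must be 2-D (n_electrodes, n_samples)")
        if self.signals.shape[0] != self.layout.n_electrodes:
            raise ValueError("signals row count does not match layout")
        if self.signals.shape[1] == 0:
            raise ValueError("zero-length channels")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.stim_times = np.asarray(self.stim_times, dtype=float)
        self.light_pulses = tuple(self.light_pulses)
        dur = self.duration
        if self.stim_times.size and (
            self.stim_times.min() < 0 or self.stim_times.max() > dur
        ):
            raise ValueError("stimulation times outside [0, duration]")
        for p in self.light_pulses:
            if p.onset < 0 or p.offset > dur:
                raise ValueError("light pulse outside [0, duration]")

    @property
    def duration(self) -> float:
        return self.signals.shape[1] / self.sampling_rate


@dataclass
class EventRaster:
    """Timestamped multiunit events per electrode — the pipeline's currency.

    Events are kept sorted by time (stable with respect to input order for
    ties). No spike sorting is implied: an event is one threshold crossing on
    one electrode.
    """

    electrode_ids: np.ndarray
    times: np.ndarray
    duration: float
    layout: ElectrodeLayout

    def __post_init__(self) -> None:
        self.electrode_ids = np.asarray(self.electrode_ids, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=float)
        if self.electrode_ids.shape != self.times.shape or self.times.ndim != 1:
            raise ValueError("electrode_ids and times must be matching 1-D arrays")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.times.size:
            if self.times.min() < 0 or self.times.max() > self.duration:
                raise ValueError("event times outside [0, duration]")
            order = np.argsort(self.times, kind="stable")
            self.times = self.times[order]
            self.electrode_ids = self.electrode_ids[order]
        known = set(int(e) for e in self.layout.electrode_ids)
        if self.electrode_ids.size and not set(np.unique(self.electrode_ids)).issubset(known):
            raise ValueError("raster references electrodes absent from layout")

    @property
    def n_events(self) -> int:
        return int(self.times.size)

    def for_electrode(self, electrode_id: int) -> np.ndarray:
        return self.times[self.electrode_ids == electrode_id]

    def subset(self, mask: np.ndarray) -> "EventRaster":
        return EventRaster(
            electrode_ids=self.electrode_ids[mask],
            times=self.times[mask],
            duration=self.duration,
            layout=self.layout,
        )


def merge_rasters(rasters: Sequence[EventRaster]) -> EventRaster:
    """Concatenate rasters sharing a layout and duration."""
    if not rasters:
        raise ValueError("nothing to merge")
    first = rasters[0]
    ids = np.concatenate([r.electrode_ids for r in rasters])
    times = np.concatenate([r.times for r in rasters])
    return EventRaster(ids, times, first.duration, first.layout)
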