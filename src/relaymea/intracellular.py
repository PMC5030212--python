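"""Current-clamp trace analysis: action potentials, light-evoked
hyperpolarization, neuron-maturity classification and graft-host coupling.

Cells are accepted only with resting potentials at or below -45 mV (more
depolarized cells are considered damaged and discarded). Maturity follows the
standard qualitative picture: mature neurons fire fast, repetitive action
potentials throughout a depolarizing current step; immature neurons manage one
or two small, slow spikes; glia respond passively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .bursts import Burst
from .recording import LightPulse


@dataclass(frozen=True)
class CurrentStep:
    """Square current injection: onset (s), duration (s), amplitude (pA)."""

    onset: float
    duration: float
    amplitude_pa: float


@dataclass
class IntracellularTrace:
    """Membrane potential in mV with protocol annotations."""

    v_mv: np.ndarray
    sampling_rate: float
    resting_potential_mv: float
    current_steps: tuple[CurrentStep, ...] = ()
    light_pulses: tuple[LightPulse, ...] = ()

    def __post_init__(self) -> None:
        self.v_mv = np.asarray(self.v_mv, dtype=float)
        if self.v_mv.ndim != 1 or self.v_mv.size == 0:
            raise ValueError("trace must be a non-empty 1-D array")
        if not np.isfinite(self.v_mv).all():
            raise ValueError("non-finite samples in trace")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.resting_potential_mv > -45.0:
            raise ValueError(
                "cell rejected: resting potential above -45 mV (depolarized/damaged)"
            )
        self.current_steps = tuple(self.current_steps)
        self.light_pulses = tuple(self.light_pulses)

    @property
    def duration(self) -> float:
        return self.v_mv.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.v_mv.size) / self.sampling_rate


@dataclass(frozen=True)
class Spike:
    time: float
    amplitude_mv: float
    width_ms: float


@dataclass(frozen=True)
class CellClass:
    label: str  # mature_neuron | immature_neuron | glia
    n_spikes: int
    mean_amplitude_mv: float | None
    mean_width_ms: float | None
    passive_linearity: float | None = None


@dataclass(frozen=True)
class GraftCouplingResult:
    delays_ms: np.ndarray
    mean_ms: float | None
    sem_ms: float | None
    input_slice: str | None
    n_coupled: int
    n_bursts: int
    coupled_counts: dict = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return self.n_coupled == 0


def detect_action_potentials(
    trace: IntracellularTrace,
    threshold_mv: float = -20.0,
    min_amplitude_mv: float = 30.0,
) -> list[Spike]:
    """Detect spikes as upward crossings of a fixed voltage threshold.

    For each upward crossing of ``threshold_mv`` the local peak (until the
    trace falls back below threshold) is taken; the spike baseline is the
    median potential 2-7 ms before the crossing, the amplitude is peak minus
    baseline (kept only if >= ``min_amplitude_mv``), and the width is
    measured at half amplitude above baseline.
    """
    v = trace.v_mv
    fs = trace.sampling_rate
    above = v > threshold_mv
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    spikes: list[Spike] = []
    pre_a = max(1, int(round(7e-3 * fs)))
    pre_b = max(1, int(round(2e-3 * fs)))
    for c in crossings:
        end = c + np.argmax(~above[c:]) if (~above[c:]).any() else v.size
        peak_idx = c + int(np.argmax(v[c:end])) if end > c else c
        base_lo = max(0, c - pre_a)
        base_hi = max(base_lo + 1, c - pre_b)
        baseline = float(np.median(v[base_lo:base_hi]))
        amp = float(v[peak_idx] - baseline)
        if amp < min_amplitude_mv:
            continue
        half = baseline + amp / 2.0
        lo = peak_idx
        while lo > 0 and v[lo - 1] > half:
            lo -= 1
        hi = peak_idx
        while hi < v.size - 1 and v[hi + 1] > half:
            hi += 1
        spikes.append(
            Spike(
                time=peak_idx / fs,
                amplitude_mv=amp,
                width_ms=(hi - lo + 1) / fs * 1e3,
            )
        )
    return spikes


def measure_hyperpolarization(
    trace: IntracellularTrace,
    pulse: LightPulse,
    baseline_ms: float = 200.0,
) -> float:
    """Light-evoked hyperpolarization amplitude in mV (positive = more negative).

    ``dV = median(V over the 200 ms before pulse onset) - median(V over the
    steady-state window)``, where steady state is the last 50% of the pulse
    (skipping the capacitive/onset transient). Medians make the measure
    robust to spikes and additive noise.
    """
    fs = trace.sampling_rate
    b = baseline_ms * 1e-3
    if pulse.onset - b < 0 or pulse.offset > trace.duration:
        raise ValueError("pulse too close to trace edge for a baseline window")
    i0 = int(round((pulse.onset - b) * fs))
    i1 = int(round(pulse.onset * fs))
    ss0 = int(round((pulse.onset + 0.5 * (pulse.offset - pulse.onset)) * fs))
    ss1 = int(round(pulse.offset * fs))
    if i1 <= i0 or ss1 <= ss0:
        raise ValueError("degenerate baseline or steady-state window")
    return float(np.median(trace.v_mv[i0:i1]) - np.median(trace.v_mv[ss0:ss1]))


def classify_cell(
    trace: IntracellularTrace,
    mature_min_spikes: int = 5,
    immature_max_amplitude_mv: float = 40.0,
    immature_min_width_ms: float = 4.0,
) -> CellClass:
    """Classify a cell from its response to depolarizing current steps.

    mature_neuron: >= ``mature_min_spikes`` action potentials during the
    largest depolarizing step, with firing sustained through the step.
    immature_neuron: a few (1-4) small (< 40 mV) and slow (> 4 ms wide)
    spikes; any spiking below the mature count is treated as immature.
    glia: no spikes and a passive, quasi-linear voltage response to the
    injected currents.
    """
    depol = [s for s in trace.current_steps if s.amplitude_pa > 0]
    if not depol:
        raise ValueError("no depolarizing current step annotation on trace")
    step = max(depol, key=lambda s: s.amplitude_pa)
    spikes = detect_action_potentials(trace)
    in_step = [s for s in spikes if step.onset <= s.time < step.onset + step.duration]
    n = len(in_step)
    if n == 0:
        linearity = _passive_linearity(trace, depol)
        return CellClass("glia", 0, None, None, passive_linearity=linearity)
    amps = float(np.mean([s.amplitude_mv for s in in_step]))
    widths = float(np.mean([s.width_ms for s in in_step]))
    if n >= mature_min_spikes:
        span = in_step[-1].time - in_step[0].time
        sustained = span >= 0.5 * step.duration
        if sustained:
            return CellClass("mature_neuron", n, amps, widths)
    if amps < immature_max_amplitude_mv and widths > immature_min_width_ms:
        return CellClass("immature_neuron", n, amps, widths)
    # few large fast spikes: not yet repetitive firing -> immature stage
    return CellClass("immature_neuron", n, amps, widths)


def _passive_linearity(
    trace: IntracellularTrace, steps: Sequence[CurrentStep]
) -> float | None:
    """R^2 of plateau deflection vs injected current through the origin."""
    if len(steps) < 2:
        return None
    fs = trace.sampling_rate
    amps, dvs = [], []
    for s in steps:
        base = np.median(
            trace.v_mv[max(0, int((s.onset - 0.05) * fs)) : int(s.onset * fs)]
        )
        p0 = int((s.onset + 0.5 * s.duration) * fs)
        p1 = int((s.onset + s.duration) * fs)
        plateau = np.median(trace.v_mv[p0:p1])
        amps.append(s.amplitude_pa)
        dvs.append(plateau - base)
    a = np.asarray(amps)
    d = np.asarray(dvs)
    slope = float((a * d).sum() / (a * a).sum())
    resid = d - slope * a
    ss_tot = float((d**2).sum())
    if ss_tot == 0:
        return 1.0
    return float(1.0 - (resid**2).sum() / ss_tot)


def measure_graft_coupling(
    event_times: np.ndarray,
    bursts_by_slice: Mapping[str, Sequence[Burst]],
    window_ms: float = 300.0,
) -> GraftCouplingResult:
    """Temporal coupling of graft-neuron firing (or EPSPs) to host bursts.

    For every burst of each slice, the first graft event in
    ``(onset, onset + window]`` yields a delay; the input slice is the one
    whose bursts capture the most coupled events, and the reported delay
    statistics are computed over that slice's bursts. An empty result (no
    coupled events anywhere) is flagged rather than an error.
    """
    if window_ms <= 0:
        raise ValueError("coupling window must be positive")
    n_bursts = sum(len(v) for v in bursts_by_slice.values())
    if n_bursts == 0:
        raise ValueError("need at least one burst")
    ev = np.sort(np.asarray(event_times, dtype=float))
    w = window_ms * 1e-3
    per_slice: dict[str, list[float]] = {}
    for label, bursts in bursts_by_slice.items():
        delays = []
        for b in bursts:
            j = np.searchsorted(ev, b.onset, side="right")
            if j < ev.size and ev[j] <= b.onset + w:
                delays.append((ev[j] - b.onset) * 1e3)
        per_slice[label] = delays
    counts = {k: len(v) for k, v in per_slice.items()}
    n_coupled = sum(counts.values())
    if n_coupled == 0:
        return GraftCouplingResult(
            delays_ms=np.empty(0),
            mean_ms=None,
            sem_ms=None,
            input_slice=None,
            n_coupled=0,
            n_bursts=n_bursts,
            coupled_counts=counts,
        )
    input_slice = max(sorted(counts), key=lambda k: counts[k])
    d = np.asarray(per_slice[input_slice])
    sem = float(d.std(ddof=1) / math.sqrt(d.size)) if d.size > 1 else None
    return GraftCouplingResult(
        delays_ms=d,
        mean_ms=float(d.mean()),
        sem_ms=sem,
        input_slice=input_slice,
        n_coupled=n_coupled,
        n_bursts=n_bursts,
        coupled_counts=counts,
    )
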