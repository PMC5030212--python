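"""Ground-truthed synthetic two-slice cultures with relay-mediated propagation.

The generator emulates the statistical structure the analysis assumes:

* two electrode groups (34 each) flanking a lesion groove, with sparse
  background multiunit activity;
* spontaneous population bursts under disinhibition, drawn as a Poisson
  process with a minimum inter-burst gap (disinhibited cultures burst
  quasi-rhythmically every ~10 s);
* graft relay neurons that start firing ``relay_delay`` after each leading
  burst onset and keep firing through the burst; the follower slice is
  induced at ``follower_delay`` if and only if the relay is still firing
  (unsilenced) at that moment and an independent Bernoulli(p) draw succeeds
  — relay necessity is the generative assumption that makes the silencing
  experiments meaningful;
* opsin-expressing relays hyperpolarized by yellow light through a
  saturating intensity map; silencing removes relay spikes that fall inside
  light pulses;
* a raw mode that renders events as biphasic extracellular templates in
  Gaussian noise, with stimulation/light-edge artifacts.

Everything is reproducible from one seed; per-burst event rendering uses
spawned child streams so that adding or removing light never shifts the
random draws of unrelated bursts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .closedloop import (
    ClosedLoopConfig,
    bin_electrode_stream,
    online_burst_detector,
    schedule_pulses,
)
from .intracellular import CurrentStep, IntracellularTrace
from .layout import SLICE_LABELS, ElectrodeLayout, two_slice_grid
from .recording import EventRaster, LightPulse, RawRecording, StimulationProtocol
from .spikes import _thin_refractory, robust_noise_sd

#: Half-saturation intensity (% LED max) calibrated so that the default map
#: passes through 11.8 mV at 94% intensity.
DEFAULT_DV_MAX_MV = 12.6
DEFAULT_I_HALF_PCT = 94.0 * math.sqrt(DEFAULT_DV_MAX_MV / 11.8 - 1.0)


def hyperpolarization_mv(
    intensity_pct: float | np.ndarray,
    dv_max_mv: float = DEFAULT_DV_MAX_MV,
    i_half_pct: float = DEFAULT_I_HALF_PCT,
) -> float | np.ndarray:
    """Saturating light-intensity -> hyperpolarization map (mV).

    ``dV(I) = dV_max * I^2 / (I^2 + I_half^2)`` — monotone non-decreasing in
    intensity and saturating at ``dv_max_mv``.
    """
    i = np.asarray(intensity_pct, dtype=float)
    out = dv_max_mv * i**2 / (i**2 + i_half_pct**2)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class BurstEnvelope:
    """Double-exponential burst rate envelope, per unit-gain electrode."""

    peak_rate_hz: float = 100.0
    rise_ms: float = 2.0
    decay_ms: float = 60.0

    def __post_init__(self) -> None:
        if self.rise_ms >= self.decay_ms:
            raise ValueError("rise must be faster than decay")
        if self.peak_rate_hz <= 0:
            raise ValueError("peak rate must be positive")

    @property
    def support_s(self) -> float:
        return (self.rise_ms + 5.0 * self.decay_ms) * 1e-3

    def shape(self, t_s: np.ndarray) -> np.ndarray:
        """Normalized envelope (peak 1) on t >= 0 seconds."""
        tr, td = self.rise_ms * 1e-3, self.decay_ms * 1e-3
        f = np.exp(-t_s / td) - np.exp(-t_s / tr)
        t_peak = tr * td / (td - tr) * math.log(td / tr)
        f_max = math.exp(-t_peak / td) - math.exp(-t_peak / tr)
        return np.clip(f / f_max, 0.0, None)

    def events_per_unit_gain(self) -> float:
        """Expected events per electrode of gain 1 per burst."""
        tr, td = self.rise_ms * 1e-3, self.decay_ms * 1e-3
        t_peak = tr * td / (td - tr) * math.log(td / tr)
        f_max = math.exp(-t_peak / td) - math.exp(-t_peak / tr)
        return self.peak_rate_hz * (td - tr) / f_max


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic two-slice culture.

    Delay distributions use the reported relay/follower statistics as
    generative truth: relay firing delay ~ Normal(111, 20) ms, follower burst
    delay ~ Normal(170, 55) ms truncated at 0 (both truncated at +-3 sigma and
    drawn comonotonically so the relay always fires before follower
    induction).
    """

    n_electrodes_per_slice: int = 34
    duration_s: float = 600.0
    background_rate_hz: float = 0.3
    burst_rate_per_min: float = 5.0
    min_interburst_s: float = 8.0
    envelope: BurstEnvelope = field(default_factory=BurstEnvelope)
    leading_bias: float = 0.5
    propagation_p: float = 0.8
    delay_mean_ms: float = 170.0
    delay_sd_ms: float = 55.0
    relay_delay_mean_ms: float = 111.0
    relay_delay_sd_ms: float = 20.0
    relay_count: int = 5
    relay_isi_ms: float = 10.0
    induction_window_ms: float = 25.0
    opsin: bool = True
    dv_max_mv: float = DEFAULT_DV_MAX_MV
    i_half_pct: float = DEFAULT_I_HALF_PCT
    silencing_threshold_mv: float = 8.0
    rebound: bool = False
    spontaneous_follower_rate_per_min: float = 0.0
    trigger_gain: float = 6.0
    stimulation: StimulationProtocol | None = None
    noise_sd_uv: float = 10.0
    spike_amp_uv: float = 80.0
    sampling_rate: float = 10_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.propagation_p <= 1.0):
            raise ValueError("propagation probability must be in [0, 1]")
        if not (0.0 <= self.leading_bias <= 1.0):
            raise ValueError("leading bias must be in [0, 1]")
        if self.relay_delay_mean_ms >= self.delay_mean_ms:
            raise ValueError("relay delay mean must be below follower delay mean")
        if min(self.background_rate_hz, self.burst_rate_per_min) < 0:
            raise ValueError("rates must be non-negative")
        if self.duration_s <= 0 or self.sampling_rate <= 0:
            raise ValueError("duration and sampling rate must be positive")
        if self.delay_sd_ms <= 0 or self.relay_delay_sd_ms <= 0:
            raise ValueError("delay SDs must be positive")
        if self.silencing_threshold_mv <= 0:
            raise ValueError("silencing threshold must be positive")

    def silences(self, intensity_pct: float) -> bool:
        """Whether light at this intensity hyperpolarizes relays past threshold."""
        dv = hyperpolarization_mv(intensity_pct, self.dv_max_mv, self.i_half_pct)
        return bool(dv >= self.silencing_threshold_mv)


@dataclass
class GroundTruth:
    """The generator's hidden state, used as oracle by the test suite."""

    bursts: pd.DataFrame
    relay_spikes: np.ndarray
    pulses: list[LightPulse]
    config: SimulationConfig

    @property
    def n_propagated(self) -> int:
        return int(self.bursts["propagated"].sum())


# ----------------------------------------------------------------- internals


def _rngs(cfg: SimulationConfig, n_bursts_hint: int = 4096) -> dict:
    ss = np.random.SeedSequence(cfg.seed)
    keys = ("structure", "background", "noise", "intracellular")
    children = ss.spawn(len(keys) + 1)
    rngs = {k: np.random.default_rng(c) for k, c in zip(keys, children[:-1])}
    rngs["bursts"] = [np.random.default_rng(c) for c in children[-1].spawn(n_bursts_hint)]
    return rngs


def _truncated_normal(rng: np.random.Generator, n: int, clip: float = 3.0) -> np.ndarray:
    z = rng.standard_normal(n)
    bad = np.abs(z) > clip
    while bad.any():
        z[bad] = rng.standard_normal(int(bad.sum()))
        bad = np.abs(z) > clip
    return z


def _draw_burst_times(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    if cfg.burst_rate_per_min <= 0:
        return np.empty(0)
    mean_ibi = 60.0 / cfg.burst_rate_per_min
    exp_mean = max(mean_ibi - cfg.min_interburst_s, 0.1)
    margin = 1.0
    times = []
    t = margin + rng.exponential(exp_mean)
    while t < cfg.duration_s - margin:
        times.append(t)
        t += cfg.min_interburst_s + rng.exponential(exp_mean)
    return np.asarray(times)


def _draw_structure(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Burst onsets, slices, delay draws and propagation coin flips."""
    t_on = _draw_burst_times(rng, cfg)
    n = t_on.size
    lead = np.where(rng.random(n) < cfg.leading_bias, "left", "right")
    z = _truncated_normal(rng, n)
    d_r = (cfg.relay_delay_mean_ms + cfg.relay_delay_sd_ms * z) * 1e-3
    d_d = (cfg.delay_mean_ms + cfg.delay_sd_ms * z) * 1e-3
    d_r = np.minimum(d_r, d_d - 1e-3)
    bern = rng.random(n) < cfg.propagation_p
    df = pd.DataFrame(
        {
            "t_on": t_on,
            "lead_slice": lead,
            "relay_delay_s": d_r,
            "follower_delay_s": d_d,
            "bernoulli": bern,
        }
    )
    if cfg.spontaneous_follower_rate_per_min > 0:
        sub = replace(cfg, burst_rate_per_min=cfg.spontaneous_follower_rate_per_min)
        extra = _draw_burst_times(rng, sub)
        m = extra.size
        if m:
            zx = _truncated_normal(rng, m)
            dfx = pd.DataFrame(
                {
                    "t_on": extra,
                    "lead_slice": np.where(rng.random(m) < 0.5, "left", "right"),
                    "relay_delay_s": (cfg.relay_delay_mean_ms + cfg.relay_delay_sd_ms * zx)
                    * 1e-3,
                    "follower_delay_s": (cfg.delay_mean_ms + cfg.delay_sd_ms * zx) * 1e-3,
                    "bernoulli": np.zeros(m, dtype=bool),
                }
            )
            df = (
                pd.concat([df, dfx], ignore_index=True)
                .sort_values("t_on")
                .reset_index(drop=True)
            )
    return df


def _relay_trains(
    bursts: pd.DataFrame, cfg: SimulationConfig, rng: np.random.Generator
) -> list[np.ndarray]:
    """Per-burst relay spike trains (absolute times, no silencing applied).

    The relay starts firing at the relay delay and keeps firing (ISI
    ``relay_isi_ms`` with 1 ms jitter) until the end of the leading burst or
    just past follower induction, whichever is later.
    """
    isi = cfg.relay_isi_ms * 1e-3
    trains: list[np.ndarray] = []
    for row in bursts.itertuples():
        end = max(cfg.envelope.support_s, row.follower_delay_s + 0.005)
        base = np.arange(row.relay_delay_s, end, isi)
        jitter = rng.normal(0.0, 1e-3, base.size)
        jitter[0] = 0.0  # first spike exactly at the relay delay
        spikes = np.clip(base + jitter, row.relay_delay_s, None)
        trains.append(row.t_on + np.sort(spikes))
    return trains


def _electrode_gains(cfg: SimulationConfig, rng: np.random.Generator, layout) -> np.ndarray:
    gains = rng.uniform(0.5, 1.5, layout.n_electrodes)
    # one hand-picked hot electrode per slice serves as online trigger
    for label in SLICE_LABELS:
        ids = layout.ids_for_slice(label, selected_only=False)
        row = int(np.flatnonzero(layout.electrode_ids == ids[0])[0])
        gains[row] = cfg.trigger_gain
    return gains


def trigger_electrode_ids(layout: ElectrodeLayout) -> dict[str, int]:
    """The designated hot trigger electrode of each slice (first id)."""
    return {label: int(layout.ids_for_slice(label, selected_only=False)[0]) for label in SLICE_LABELS}


class _BurstRenderer:
    """Inverse-CDF sampler for event times under the burst envelope."""

    def __init__(self, cfg: SimulationConfig, layout: ElectrodeLayout, gains: np.ndarray):
        self.cfg = cfg
        self.layout = layout
        self.gains = gains
        grid = np.linspace(0.0, cfg.envelope.support_s, 2048)
        pdf = cfg.envelope.shape(grid)
        cdf = np.cumsum(pdf)
        cdf /= cdf[-1]
        self._grid = grid
        self._cdf = cdf
        self._per_gain = cfg.envelope.events_per_unit_gain()
        self._slice_rows = {
            label: np.flatnonzero((layout.slice_labels == label) & layout.selected)
            for label in SLICE_LABELS
        }

    def render(
        self, rng: np.random.Generator, slice_label: str, t0: float
    ) -> tuple[np.ndarray, np.ndarray]:
        rows = self._slice_rows[slice_label]
        lam = self.gains[rows] * self._per_gain
        counts = rng.poisson(lam)
        total = int(counts.sum())
        if total == 0:
            return np.empty(0, dtype=np.int64), np.empty(0)
        ids = np.repeat(self.layout.electrode_ids[rows], counts)
        offs = np.interp(rng.random(total), self._cdf, self._grid)
        return ids, t0 + offs


def _background_events(
    cfg: SimulationConfig, layout: ElectrodeLayout, gains: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    sel = np.flatnonzero(layout.selected)
    lam = cfg.background_rate_hz * gains[sel] * cfg.duration_s
    counts = rng.poisson(lam)
    total = int(counts.sum())
    ids = np.repeat(layout.electrode_ids[sel], counts)
    times = rng.uniform(0.0, cfg.duration_s, total)
    return ids, times


def _opposite(label: str) -> str:
    return "right" if label == "left" else "left"


def _assemble_raster(
    cfg: SimulationConfig,
    layout: ElectrodeLayout,
    parts: list[tuple[np.ndarray, np.ndarray]],
) -> EventRaster:
    ids = np.concatenate([p[0] for p in parts]) if parts else np.empty(0, dtype=np.int64)
    times = np.concatenate([p[1] for p in parts]) if parts else np.empty(0)
    keep = (times >= 0.0) & (times <= cfg.duration_s)
    return EventRaster(ids[keep], times[keep], cfg.duration_s, layout)


# ----------------------------------------------------------------- public API


def generate_culture(
    cfg: SimulationConfig,
    mode: str = "events",
) -> tuple[EventRaster | RawRecording, GroundTruth]:
    """Simulate one spontaneous two-slice recording (no light).

    ``mode="events"`` returns the event raster directly; ``mode="raw"``
    renders biphasic spike templates into Gaussian noise and returns a
    :class:`RawRecording` for the threshold detector to chew on.
    """
    if mode not in ("events", "raw"):
        raise ValueError("mode must be 'events' or 'raw'")
    layout = two_slice_grid(cfg.n_electrodes_per_slice)
    rngs = _rngs(cfg)
    bursts = _draw_structure(cfg, rngs["structure"])
    gains = _electrode_gains(cfg, rngs["structure"], layout)
    trains = _relay_trains(bursts, cfg, rngs["structure"])

    # no light: relay always fires through induction -> propagation = Bernoulli
    bursts["relay_fired"] = [t.size > 0 for t in trains]
    bursts["silenced"] = False
    bursts["blocked"] = False
    bursts["propagated"] = bursts["bernoulli"] & bursts["relay_fired"]
    bursts["follower_onset"] = np.where(
        bursts["propagated"], bursts["t_on"] + bursts["follower_delay_s"], np.nan
    )

    renderer = _BurstRenderer(cfg, layout, gains)
    parts = [_background_events(cfg, layout, gains, rngs["background"])]
    for i, row in enumerate(bursts.itertuples()):
        brng = rngs["bursts"][i % len(rngs["bursts"])]
        parts.append(renderer.render(brng, row.lead_slice, row.t_on))
        if row.propagated:
            parts.append(renderer.render(brng, _opposite(row.lead_slice), row.follower_onset))
    raster = _assemble_raster(cfg, layout, parts)

    relay_spikes = (
        np.sort(np.concatenate(trains)) if trains else np.empty(0)
    )
    truth = GroundTruth(bursts=bursts, relay_spikes=relay_spikes, pulses=[], config=cfg)
    if mode == "events":
        return raster, truth
    return render_raw(raster, cfg, rngs["noise"]), truth


def spike_template(sampling_rate: float) -> np.ndarray:
    """Biphasic extracellular spike template, peak-normalized to -1."""
    neg_n = max(2, int(round(0.4e-3 * sampling_rate)))
    pos_n = max(2, int(round(0.8e-3 * sampling_rate)))
    neg = -np.hanning(neg_n + 2)[1:-1]
    pos = 0.45 * np.hanning(pos_n + 2)[1:-1]
    return np.concatenate([neg, pos])


def _artifact_template(sampling_rate: float) -> np.ndarray:
    n = max(4, int(round(2e-3 * sampling_rate)))
    t = np.arange(n) / sampling_rate
    return 500.0 * np.exp(-t / 0.5e-3) * np.cos(2 * np.pi * 2000.0 * t)


def _render_channel(
    times: np.ndarray,
    n_samples: int,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    artifact_times: np.ndarray,
) -> np.ndarray:
    x = rng.standard_normal(n_samples, dtype=np.float32)
    x *= cfg.noise_sd_uv
    tpl = spike_template(cfg.sampling_rate).astype(np.float32)
    idx = np.round(times * cfg.sampling_rate).astype(np.int64)
    idx = idx[idx < n_samples - tpl.size]
    if idx.size:
        amps = (cfg.spike_amp_uv * rng.uniform(0.8, 1.2, idx.size)).astype(np.float32)
        for k in range(tpl.size):
            np.add.at(x, idx + k, amps * tpl[k])
    if artifact_times.size:
        atpl = _artifact_template(cfg.sampling_rate).astype(np.float32)
        aidx = np.round(artifact_times * cfg.sampling_rate).astype(np.int64)
        aidx = aidx[aidx < n_samples - atpl.size]
        for k in range(atpl.size):
            np.add.at(x, aidx + k, atpl[k])
    return x


def render_raw(
    raster: EventRaster,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    stim_times: np.ndarray | None = None,
    light_pulses: tuple[LightPulse, ...] = (),
) -> RawRecording:
    """Render an event raster into multichannel voltage traces (µV)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    stim_times = np.asarray(stim_times if stim_times is not None else [], dtype=float)
    edges = [stim_times] + [np.array([p.onset, p.offset]) for p in light_pulses]
    artifact_times = np.sort(np.concatenate(edges)) if edges else np.empty(0)
    n_samples = int(round(raster.duration * cfg.sampling_rate))
    layout = raster.layout
    signals = np.empty((layout.n_electrodes, n_samples), dtype=np.float32)
    for row, eid in enumerate(layout.electrode_ids):
        signals[row] = _render_channel(
            raster.for_electrode(int(eid)), n_samples, cfg, rng, artifact_times
        )
    return RawRecording(
        signals=signals,
        sampling_rate=cfg.sampling_rate,
        layout=layout,
        stim_times=stim_times,
        light_pulses=light_pulses,
    )


def generate_detected_raster(
    cfg: SimulationConfig,
    threshold_k: float = 5.0,
    refractory_ms: float = 1.0,
) -> tuple[EventRaster, GroundTruth]:
    """Raw-mode culture pushed through per-channel threshold detection,
    rendering one channel at a time (a 40-minute 68-channel recording never
    exists in memory at once).

    Equivalent to ``detect_events(generate_culture(cfg, mode="raw")[0])``.
    """
    raster_true, truth = generate_culture(cfg, mode="events")
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(5)[2])  # noise stream
    n_samples = int(round(cfg.duration_s * cfg.sampling_rate))
    dead = max(1, int(round(refractory_ms * 1e-3 * cfg.sampling_rate)))
    layout = raster_true.layout
    all_ids, all_times = [], []
    for eid in layout.electrode_ids:
        x = _render_channel(
            raster_true.for_electrode(int(eid)), n_samples, cfg, rng, np.empty(0)
        )
        thr = threshold_k * robust_noise_sd(x)
        idx = np.flatnonzero(np.abs(x) > thr)
        kept = _thin_refractory(idx, dead)
        if kept:
            all_times.append(np.asarray(kept, dtype=np.int64) / cfg.sampling_rate)
            all_ids.append(np.full(len(kept), eid, dtype=np.int64))
    ids = np.concatenate(all_ids) if all_ids else np.empty(0, dtype=np.int64)
    times = np.concatenate(all_times) if all_times else np.empty(0)
    detected = EventRaster(ids, times, cfg.duration_s, layout)
    return detected, truth


def _silence_windows(
    pulses: list[LightPulse], cfg: SimulationConfig, opsin: bool
) -> list[tuple[float, float]]:
    if not opsin:
        return []
    return [(p.onset, p.offset) for p in pulses if cfg.silences(p.intensity)]


def _censor(train: np.ndarray, windows: list[tuple[float, float]]) -> np.ndarray:
    keep = np.ones(train.size, dtype=bool)
    for a, b in windows:
        keep &= (train < a) | (train > b)
    return train[keep]


def generate_closed_loop_session(
    cfg: SimulationConfig,
    loop_cfg: ClosedLoopConfig,
    light_on: bool = True,
    opsin: bool | None = None,
) -> tuple[EventRaster, list[LightPulse], GroundTruth]:
    """Simulate a spontaneous session with burst-triggered light pulses.

    The online detector runs per slice on the designated trigger electrode's
    10 ms count stream; accepted triggers schedule pulses; pulses silence
    opsin-positive relays whose hyperpolarization exceeds threshold, and a
    burst's follower is induced only if an unsilenced relay spike falls in
    the induction window ending at onset + follower_delay. With
    ``light_on=False`` (or opsin off) the session reduces to
    :func:`generate_culture`'s propagation outcomes with identical draws.
    """
    opsin = cfg.opsin if opsin is None else opsin
    layout = two_slice_grid(cfg.n_electrodes_per_slice)
    rngs = _rngs(cfg)
    bursts = _draw_structure(cfg, rngs["structure"])
    gains = _electrode_gains(cfg, rngs["structure"], layout)
    trains = _relay_trains(bursts, cfg, rngs["structure"])
    renderer = _BurstRenderer(cfg, layout, gains)

    # provisional rendering: leading + background + Bernoulli-successful followers
    lead_parts = [_background_events(cfg, layout, gains, rngs["background"])]
    follower_parts: list[tuple[np.ndarray, np.ndarray] | None] = []
    for i, row in enumerate(bursts.itertuples()):
        brng = rngs["bursts"][i % len(rngs["bursts"])]
        lead_parts.append(renderer.render(brng, row.lead_slice, row.t_on))
        if row.bernoulli:
            follower_parts.append(
                renderer.render(
                    brng, _opposite(row.lead_slice), row.t_on + row.follower_delay_s
                )
            )
        else:
            follower_parts.append(None)

    pulses: list[LightPulse] = []
    triggers = np.empty(0)
    if light_on:
        provisional = _assemble_raster(
            cfg, layout, lead_parts + [p for p in follower_parts if p is not None]
        )
        trig_ids = dict(loop_cfg.trigger_electrodes) or trigger_electrode_ids(layout)
        trig_list = []
        for label in SLICE_LABELS:
            stream = bin_electrode_stream(
                provisional.for_electrode(trig_ids[label]),
                cfg.duration_s,
                loop_cfg.detection_window_ms,
            )
            trig_list.append(online_burst_detector(stream, loop_cfg))
        triggers = np.sort(np.concatenate(trig_list))
        pulses = schedule_pulses(triggers, loop_cfg)

    windows = _silence_windows(pulses, cfg, opsin)
    w_ind = cfg.induction_window_ms * 1e-3
    silenced, propagated, blocked = [], [], []
    censored_trains = []
    for row, train in zip(bursts.itertuples(), trains):
        surv = _censor(train, windows) if windows else train
        censored_trains.append(surv)
        t_ind = row.t_on + row.follower_delay_s
        ok = bool(np.any((surv > t_ind - w_ind) & (surv <= t_ind)))
        was_silenced = surv.size < train.size
        prop = bool(row.bernoulli and ok)
        silenced.append(was_silenced)
        propagated.append(prop)
        blocked.append(bool(row.bernoulli and not ok))
    bursts["relay_fired"] = [t.size > 0 for t in censored_trains]
    bursts["silenced"] = silenced
    bursts["propagated"] = propagated
    bursts["blocked"] = blocked
    bursts["follower_onset"] = np.where(
        bursts["propagated"], bursts["t_on"] + bursts["follower_delay_s"], np.nan
    )

    parts = list(lead_parts)
    removed_follower_onsets = []
    for row, fpart in zip(bursts.itertuples(), follower_parts):
        if fpart is None:
            continue
        if row.propagated:
            parts.append(fpart)
        else:
            removed_follower_onsets.append(row.t_on + row.follower_delay_s)
    if cfg.rebound:
        reb_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(6)[-1])
        for row in bursts.itertuples():
            if row.blocked:
                covering = [p for p in pulses if p.onset <= row.t_on + row.follower_delay_s <= p.offset]
                if covering:
                    t_reb = covering[0].offset + 0.15
                    if t_reb + cfg.envelope.support_s < cfg.duration_s:
                        parts.append(renderer.render(reb_rng, row.lead_slice, t_reb))

    # pulses whose trigger was caused by a follower burst that the light itself
    # removed would not exist physically; drop them from the report
    if removed_follower_onsets and pulses:
        bad = []
        win = 5 * loop_cfg.detection_window_ms * 1e-3
        delay = loop_cfg.pulse_delay_ms * 1e-3
        for p in pulses:
            trig = p.onset - delay
            if any(fo < trig <= fo + win for fo in removed_follower_onsets):
                bad.append(p)
        pulses = [p for p in pulses if p not in bad]

    raster = _assemble_raster(cfg, layout, parts)
    relay_spikes = (
        np.sort(np.concatenate(censored_trains)) if censored_trains else np.empty(0)
    )
    truth = GroundTruth(bursts=bursts, relay_spikes=relay_spikes, pulses=pulses, config=cfg)
    return raster, pulses, truth


def generate_stimulation_sweep(
    cfg: SimulationConfig,
    loop_cfg: ClosedLoopConfig,
    pulse_delays_ms: np.ndarray | list[float],
    n_per_delay: int,
    n_control: int | None = None,
) -> pd.DataFrame:
    """Stimulated-burst trials with light pulses at fixed delays after the
    stimulus (the stimulated-trial convention), plus no-light control trials.

    Each trial elicits a leading burst at the stimulation time; the light
    pulse starts ``pulse_delay_ms`` later and blocks propagation iff it is
    still silencing the relay at the induction time. Returns a trial table
    with columns trial_id, condition, pulse_delay_ms, follower_delay_ms,
    propagated, blocked.
    """
    delays = np.asarray(pulse_delays_ms, dtype=float)
    if delays.size < 1 or n_per_delay < 1:
        raise ValueError("need at least one delay and one trial per delay")
    n_control = n_per_delay if n_control is None else n_control
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0xC0FFEE)))
    silences = cfg.silences(loop_cfg.light_intensity)
    rows = []
    trial = 0
    conditions = [("control", np.nan)] + [("light", d) for d in delays]
    for cond, d in conditions:
        n = n_control if cond == "control" else n_per_delay
        z = _truncated_normal(rng, n)
        d_r = (cfg.relay_delay_mean_ms + cfg.relay_delay_sd_ms * z) * 1e-3
        d_d = (cfg.delay_mean_ms + cfg.delay_sd_ms * z) * 1e-3
        d_r = np.minimum(d_r, d_d - 1e-3)
        bern = rng.random(n) < cfg.propagation_p
        for k in range(n):
            if cond == "light" and silences and cfg.opsin:
                pulse_on = d * 1e-3
                pulse_off = pulse_on + loop_cfg.pulse_duration_s
                covered = pulse_on < d_d[k] <= pulse_off
            else:
                covered = False
            prop = bool(bern[k] and not covered)
            rows.append(
                {
                    "trial_id": trial,
                    "condition": cond,
                    "pulse_delay_ms": d if cond == "light" else np.nan,
                    "relay_delay_ms": d_r[k] * 1e3,
                    "follower_delay_ms": d_d[k] * 1e3,
                    "propagated": prop,
                    "blocked": bool(bern[k] and covered),
                }
            )
            trial += 1
    return pd.DataFrame(rows)


# ------------------------------------------------------ intracellular traces

#: Per-role membrane parameters: input resistance (MOhm), membrane tau (ms),
#: spike amplitude above local baseline (mV), spike FWHM (ms).
_ROLE_PARAMS = {
    "mature": dict(r_mohm=150.0, tau_ms=20.0, spike_amp=68.0, spike_width_ms=1.5),
    "relay": dict(r_mohm=150.0, tau_ms=20.0, spike_amp=68.0, spike_width_ms=1.5),
    "immature": dict(r_mohm=200.0, tau_ms=30.0, spike_amp=34.0, spike_width_ms=6.0),
    "glia": dict(r_mohm=30.0, tau_ms=5.0, spike_amp=0.0, spike_width_ms=0.0),
}

_IC_FS = 10_000.0


def _gauss_bump(v: np.ndarray, fs: float, t0: float, amp: float, fwhm_ms: float) -> None:
    sigma = fwhm_ms * 1e-3 / 2.355
    half = 4.0 * sigma
    i0 = max(0, int((t0 - half) * fs))
    i1 = min(v.size, int((t0 + half) * fs))
    if i1 <= i0:
        return
    t = np.arange(i0, i1) / fs
    v[i0:i1] += amp * np.exp(-0.5 * ((t - t0) / sigma) ** 2)


def _alpha_bump(v: np.ndarray, fs: float, t0: float, amp: float, tau_ms: float) -> None:
    tau = tau_ms * 1e-3
    i0 = max(0, int(t0 * fs))
    i1 = min(v.size, int((t0 + 8 * tau) * fs))
    if i1 <= i0:
        return
    t = np.arange(i0, i1) / fs - t0
    t = np.clip(t, 0.0, None)
    v[i0:i1] += amp * (t / tau) * np.exp(1.0 - t / tau)


def _step_response(
    v: np.ndarray, fs: float, step: CurrentStep, r_mohm: float, tau_ms: float
) -> None:
    dv = step.amplitude_pa * r_mohm * 1e-3  # pA * MOhm -> mV
    tau = tau_ms * 1e-3
    i0 = int(step.onset * fs)
    i1 = min(v.size, int((step.onset + step.duration) * fs))
    t = np.arange(i0, i1) / fs - step.onset
    v[i0:i1] += dv * (1.0 - np.exp(-t / tau))
    # relaxation after step offset
    i2 = min(v.size, i1 + int(5 * tau * fs))
    if i2 > i1:
        t2 = np.arange(i1, i2) / fs - (step.onset + step.duration)
        v[i1:i2] += dv * (1.0 - math.exp(-step.duration / tau)) * np.exp(-t2 / tau)


def _light_profile(
    n: int, fs: float, pulses: tuple[LightPulse, ...], cfg: SimulationConfig, tau_ms: float = 20.0
) -> np.ndarray:
    """Hyperpolarization time course in mV (positive values = shift downward)."""
    prof = np.zeros(n)
    tau = tau_ms * 1e-3
    t = np.arange(n) / fs
    for p in pulses:
        dv = hyperpolarization_mv(p.intensity, cfg.dv_max_mv, cfg.i_half_pct)
        on = (t >= p.onset) & (t < p.offset)
        prof[on] += dv * (1.0 - np.exp(-(t[on] - p.onset) / tau))
        after = t >= p.offset
        level = dv * (1.0 - math.exp(-(p.offset - p.onset) / tau))
        prof[after] += level * np.exp(-(t[after] - p.offset) / tau)
    return prof


def default_step_protocol(start_s: float = 0.5) -> tuple[CurrentStep, ...]:
    """Three depolarizing steps (50/100/150 pA, 0.5 s) for classification."""
    return tuple(
        CurrentStep(onset=start_s + i * 1.0, duration=0.5, amplitude_pa=a)
        for i, a in enumerate((50.0, 100.0, 150.0))
    )


def generate_intracellular(
    cfg: SimulationConfig,
    role: str,
    index: int = 0,
    light_pulses: tuple[LightPulse, ...] = (),
    burst_onsets: np.ndarray | None = None,
    relay_spike_times: np.ndarray | None = None,
    duration_s: float | None = None,
    current_steps: tuple[CurrentStep, ...] | None = None,
    noise_mv: float = 0.5,
    input_slice: str = "left",
) -> tuple[IntracellularTrace, dict]:
    """Render a current-clamp trace for one simulated cell.

    Roles: ``mature`` / ``immature`` / ``glia`` render the three-step
    classification protocol; ``relay`` renders an opsin-expressing graft
    neuron — EPSPs (alpha-shaped, ~4 mV) time-locked to the assigned slice's
    bursts, action potentials at the relay spike times, light-evoked
    hyperpolarization per the intensity map, and spike suppression while the
    hyperpolarization exceeds the silencing threshold.

    ``index`` selects an independent random stream per cell under the same
    config seed. Returns the trace and a ground-truth dict.
    """
    if role not in _ROLE_PARAMS:
        raise ValueError(f"unknown role {role!r}")
    p = _ROLE_PARAMS[role]
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 7, index)))
    fs = _IC_FS
    rest = float(rng.uniform(-70.0, -50.0))

    if role != "relay" and current_steps is None:
        current_steps = default_step_protocol()
    current_steps = current_steps or ()
    if duration_s is None:
        parts = [0.5]
        parts += [s.onset + s.duration + 0.5 for s in current_steps]
        parts += [pl.offset + 0.5 for pl in light_pulses]
        if burst_onsets is not None and len(burst_onsets):
            parts.append(float(np.max(burst_onsets)) + 1.0)
        if relay_spike_times is not None and len(relay_spike_times):
            parts.append(float(np.max(relay_spike_times)) + 0.5)
        duration_s = max(parts)
    n = int(round(duration_s * fs))
    v = np.full(n, rest)
    v += rng.normal(0.0, noise_mv, n)

    for s in current_steps:
        _step_response(v, fs, s, p["r_mohm"], p["tau_ms"])

    light = _light_profile(n, fs, light_pulses, cfg)
    v -= light

    spike_times: list[float] = []
    epsp_times: list[float] = []
    if role in ("mature", "immature"):
        for s in (st for st in current_steps if st.amplitude_pa > 0):
            if role == "mature":
                times = np.arange(s.onset + 0.02, s.onset + s.duration - 0.01, 0.04)
            else:
                times = np.array([s.onset + 0.05])
            spike_times.extend(float(t) for t in times)
    elif role == "relay":
        if burst_onsets is not None:
            for b in np.asarray(burst_onsets, dtype=float):
                t_e = b + 0.02 + rng.normal(0.0, 0.003)
                epsp_times.append(float(t_e))
        if relay_spike_times is not None:
            spike_times.extend(float(t) for t in np.asarray(relay_spike_times, dtype=float))

    for t_e in epsp_times:
        _alpha_bump(v, fs, t_e, amp=4.0, tau_ms=10.0)

    kept_spikes = []
    for t_s in spike_times:
        i = min(n - 1, max(0, int(t_s * fs)))
        if light[i] >= cfg.silencing_threshold_mv:
            continue  # relay silenced: no action potential
        _gauss_bump(v, fs, t_s, p["spike_amp"], p["spike_width_ms"])
        kept_spikes.append(t_s)

    trace = IntracellularTrace(
        v_mv=v,
        sampling_rate=fs,
        resting_potential_mv=rest,
        current_steps=current_steps,
        light_pulses=light_pulses,
    )
    truth = {
        "role": role,
        "resting_potential_mv": rest,
        "spike_times": np.asarray(kept_spikes),
        "suppressed_spike_times": np.asarray(
            [t for t in spike_times if t not in kept_spikes]
        ),
        "epsp_times": np.asarray(epsp_times),
        "input_slice": input_slice,
        "hyperpolarization_mv": {
            pl.intensity: hyperpolarization_mv(pl.intensity, cfg.dv_max_mv, cfg.i_half_pct)
            for pl in light_pulses
        },
    }
    return trace, truth
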