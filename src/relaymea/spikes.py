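"""Threshold-based multiunit event detection and artifact blanking.

Detection follows the classic MEA recipe: per channel, events are the samples
where ``|v|`` exceeds ``k`` times a robust estimate of the noise standard
deviation, thinned by a per-channel refractory dead time. No spike sorting is
performed — each threshold crossing is a multiunit event.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .recording import EventRaster, LightPulse, RawRecording

#: MAD -> SD conversion for Gaussian noise.
_MAD_SCALE = 0.6745


def robust_noise_sd(x: np.ndarray) -> float:
    """Noise SD estimated as median(|x|)/0.6745.

    The median of the rectified trace is nearly insensitive to the sparse
    large-amplitude spikes that inflate the plain standard deviation.
    """
    x = np.asarray(x)
    if x.size == 0:
        raise ValueError("empty channel")
    return float(np.median(np.abs(x)) / _MAD_SCALE)


def _thin_refractory(idx: np.ndarray, dead_samples: int) -> list[int]:
    """Greedy dead-time thinning over suprathreshold sample indices."""
    kept: list[int] = []
    last = -dead_samples - 1
    for i in idx:
        if i - last >= dead_samples:
            kept.append(int(i))
            last = i
    return kept


def detect_events(
    rec: RawRecording,
    threshold_k: float = 5.0,
    refractory_ms: float = 1.0,
) -> EventRaster:
    """Detect multiunit events on every channel of a raw recording.

    Parameters
    ----------
    rec
        Raw recording; all channels must be finite and non-empty.
    threshold_k
        Threshold in units of the per-channel robust noise SD (default 5).
    refractory_ms
        Per-channel dead time after each event (default 1 ms). The dead time
        is enforced in integer samples, so a deflection staying above
        threshold longer than the refractory period yields repeated events.

    Returns
    -------
    EventRaster sorted by time.
    """
    if threshold_k <= 0:
        raise ValueError("threshold_k must be positive")
    if refractory_ms < 0:
        raise ValueError("refractory must be non-negative")
    if not np.isfinite(rec.signals).all():
        raise ValueError("non-finite samples in recording")
    dead = max(1, int(round(refractory_ms * 1e-3 * rec.sampling_rate)))
    all_ids: list[np.ndarray] = []
    all_idx: list[np.ndarray] = []
    for row, eid in enumerate(rec.layout.electrode_ids):
        x = rec.signals[row]
        thr = threshold_k * robust_noise_sd(x)
        if thr == 0.0:
            # all-zero channel: nothing can exceed a zero threshold strictly
            continue
        idx = np.flatnonzero(np.abs(x) > thr)
        kept = _thin_refractory(idx, dead)
        if kept:
            all_idx.append(np.asarray(kept, dtype=np.int64))
            all_ids.append(np.full(len(kept), eid, dtype=np.int64))
    if all_idx:
        ids = np.concatenate(all_ids)
        times = np.concatenate(all_idx) / rec.sampling_rate
    else:
        ids = np.empty(0, dtype=np.int64)
        times = np.empty(0)
    return EventRaster(ids, times, rec.duration, rec.layout)


def bandpass_filter(
    rec: RawRecording,
    low_hz: float = 300.0,
    high_hz: float = 3000.0,
    order: int = 2,
) -> RawRecording:
    """Zero-phase Butterworth band-pass of every channel.

    A configurable pre-filter for recordings that arrive broadband; the
    threshold detector itself does not require it (synthetic traces are
    rendered band-limited).
    """
    from scipy.signal import butter, sosfiltfilt

    if not (0 < low_hz < high_hz < rec.sampling_rate / 2):
        raise ValueError("band edges must satisfy 0 < low < high < Nyquist")
    sos = butter(order, [low_hz, high_hz], btype="band", fs=rec.sampling_rate, output="sos")
    return RawRecording(
        signals=sosfiltfilt(sos, rec.signals, axis=1),
        sampling_rate=rec.sampling_rate,
        layout=rec.layout,
        stim_times=rec.stim_times,
        light_pulses=rec.light_pulses,
    )


def blank_artifacts(
    raster: EventRaster,
    stim_times: Iterable[float] = (),
    light_pulses: Sequence[LightPulse] = (),
    stim_window_ms: float = 2.0,
    light_window_ms: float = 5.0,
) -> EventRaster:
    """Remove events within ±window of stimulation times and light-pulse edges.

    Electrical stimulation and LED on/off switching both induce electrical
    artifacts on the array that the threshold detector picks up as events.
    Windows are closed: an event exactly at ``center ± window`` is removed.
    Idempotent.
    """
    if stim_window_ms < 0 or light_window_ms < 0:
        raise ValueError("blank window must be non-negative")
    keep = np.ones(raster.n_events, dtype=bool)
    if stim_window_ms > 0:
        w = stim_window_ms * 1e-3
        for t in stim_times:
            keep &= np.abs(raster.times - t) > w
    if light_window_ms > 0:
        w = light_window_ms * 1e-3
        for p in light_pulses:
            keep &= np.abs(raster.times - p.onset) > w
            keep &= np.abs(raster.times - p.offset) > w
    return raster.subset(keep)
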