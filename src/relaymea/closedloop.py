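"""Closed-loop burst-triggered optogenetic silencing: online detection,
pulse scheduling, block quantification and the half-block-delay extrapolation.

The online detector emulates the acquisition-side logic: one hand-picked
trigger electrode per slice, event counts in 10 ms windows, a threshold over
the running standard deviation of a trailing burst-free history, immediate
LED on-switching on trigger, then a lockout (>= 5 s by default) to protect
the LED and culture from heating.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bursts import PropagationRecord
from .recording import LightPulse


@dataclass(frozen=True)
class ClosedLoopConfig:
    """Trigger/pulse semantics of the burst-triggered LED controller.

    ``pulse_delay_ms`` is referenced to the online trigger for spontaneous
    bursts and to the stimulation time for stimulated trials.
    """

    trigger_electrodes: dict = field(default_factory=dict)
    detection_window_ms: float = 10.0
    threshold_sd: float = 5.0
    min_count: int = 3
    history_s: float = 2.0
    pulse_duration_s: float = 1.0
    lockout_s: float = 5.0
    light_intensity: float = 94.0
    pulse_delay_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.detection_window_ms <= 0 or self.threshold_sd <= 0:
            raise ValueError("detection window and threshold must be positive")
        if self.pulse_duration_s <= 0 or self.lockout_s < 0:
            raise ValueError("invalid pulse duration or lockout")
        if not (0.0 <= self.light_intensity <= 100.0):
            raise ValueError("light intensity must be in [0, 100] %")
        if self.history_s <= 0:
            raise ValueError("history must be positive")


@dataclass(frozen=True)
class BlockCurve:
    """Blocked fraction (relative to no-light control) per light-pulse delay."""

    pulse_delays_ms: np.ndarray
    fraction_blocked: np.ndarray
    n_trials: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.pulse_delays_ms, dtype=float)
        f = np.asarray(self.fraction_blocked, dtype=float)
        n = np.asarray(self.n_trials, dtype=np.int64)
        if not (d.size == f.size == n.size):
            raise ValueError("curve arrays must have equal length")
        if d.size and (np.diff(d) <= 0).any():
            raise ValueError("delays must be strictly increasing")
        if ((f < 0) | (f > 1)).any():
            raise ValueError("fractions must lie in [0, 1]")
        object.__setattr__(self, "pulse_delays_ms", d)
        object.__setattr__(self, "fraction_blocked", f)
        object.__setattr__(self, "n_trials", n)


@dataclass(frozen=True)
class BlockResult:
    fraction_blocked: float
    propagation_light: float
    propagation_control: float
    n_leading_light: int
    n_leading_control: int

    @property
    def percent_unpropagated_light(self) -> float:
        return 100.0 * (1.0 - self.propagation_light)


def online_burst_detector(
    stream: Sequence[int],
    cfg: ClosedLoopConfig,
    start_time: float = 0.0,
) -> np.ndarray:
    """Causal burst-onset detection on a per-bin event-count stream.

    Processes the trigger electrode's counts bin by bin. A trigger is emitted
    at the end of the first bin whose count exceeds ``threshold_sd`` times the
    running SD of the trailing burst-free history (and is at least
    ``min_count`` events — a bare SD rule on near-empty count bins would fire
    on any stray background event). Triggers within the lockout of a previous
    trigger are suppressed, as is everything before the history window has
    filled. A zero-variance history suppresses triggering with a warning.

    Returns trigger times in seconds (bin-end times, so no trigger precedes
    the activity that caused it).
    """
    counts = np.asarray(stream, dtype=float)
    w = cfg.detection_window_ms * 1e-3
    hist_len = max(2, int(round(cfg.history_s / w)))
    history: list[float] = []
    triggers: list[float] = []
    warned = False
    last_trigger = -np.inf
    for i, c in enumerate(counts):
        t_end = start_time + (i + 1) * w
        ready = len(history) >= hist_len
        is_quiet = c < cfg.min_count
        if ready and not is_quiet and t_end - last_trigger >= cfg.lockout_s:
            sd = float(np.std(history))
            if sd == 0.0:
                if not warned:
                    warnings.warn(
                        "online detector: zero-variance history, trigger suppressed",
                        RuntimeWarning,
                        stacklevel=2,
                    )
                    warned = True
            elif c > cfg.threshold_sd * sd:
                triggers.append(t_end)
                last_trigger = t_end
        if is_quiet:
            history.append(float(c))
            if len(history) > hist_len:
                history.pop(0)
    return np.asarray(triggers)


def bin_electrode_stream(
    times: np.ndarray,
    duration: float,
    window_ms: float = 10.0,
) -> np.ndarray:
    """Event counts of one electrode in consecutive half-open windows."""
    w = window_ms * 1e-3
    n = max(1, int(np.ceil(duration / w - 1e-9)))
    counts, _ = np.histogram(np.asarray(times), bins=np.arange(n + 1) * w)
    return counts


def schedule_pulses(triggers: Sequence[float], cfg: ClosedLoopConfig) -> list[LightPulse]:
    """One light pulse per accepted trigger.

    Pulse onset is ``trigger + pulse_delay``; a trigger arriving before
    ``previous pulse offset + lockout`` is dropped (the controller is busy or
    cooling down).
    """
    pulses: list[LightPulse] = []
    last_off = -np.inf
    delay = cfg.pulse_delay_ms * 1e-3
    for t in sorted(triggers):
        if t < last_off + cfg.lockout_s:
            continue
        onset = t + delay
        pulses.append(LightPulse(onset, onset + cfg.pulse_duration_s, cfg.light_intensity))
        last_off = onset + cfg.pulse_duration_s
    return pulses


def quantify_block(
    records_light: Sequence[PropagationRecord],
    records_nolight: Sequence[PropagationRecord],
) -> BlockResult:
    """Fractional block of propagation under light, relative to control.

    ``fraction_blocked = 1 - (propagated fraction under light) /
    (propagated fraction without light)``, clipped to [0, 1].
    """
    if not records_light or not records_nolight:
        raise ValueError("both conditions need at least one leading burst")
    p_light = sum(r.propagated for r in records_light) / len(records_light)
    p_ctrl = sum(r.propagated for r in records_nolight) / len(records_nolight)
    if p_ctrl == 0.0:
        raise ValueError("control propagation rate is zero: block undefined")
    frac = float(np.clip(1.0 - p_light / p_ctrl, 0.0, 1.0))
    return BlockResult(
        fraction_blocked=frac,
        propagation_light=p_light,
        propagation_control=p_ctrl,
        n_leading_light=len(records_light),
        n_leading_control=len(records_nolight),
    )


def block_vs_delay_curve(
    trials: pd.DataFrame,
    control_propagation: float,
) -> BlockCurve:
    """Blocked fraction per light-pulse delay from a stimulated-trial table.

    ``trials`` needs columns ``pulse_delay_ms`` and ``propagated`` (bool);
    rows are sorted by delay internally. Requires >= 2 distinct delays and a
    positive control propagation rate.
    """
    required = {"pulse_delay_ms", "propagated"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    if control_propagation <= 0:
        raise ValueError("control propagation rate must be positive")
    grouped = trials.groupby("pulse_delay_ms")["propagated"]
    delays = np.array(sorted(grouped.groups))
    if delays.size < 2:
        raise ValueError("need at least two distinct pulse delays")
    frac, n = [], []
    for d in delays:
        v = grouped.get_group(d).to_numpy(dtype=bool)
        blocked = 1.0 - v.mean() / control_propagation
        frac.append(float(np.clip(blocked, 0.0, 1.0)))
        n.append(v.size)
    return BlockCurve(delays, np.array(frac), np.array(n))


def extrapolate_half_block_delay(curve: BlockCurve) -> float:
    """Light-pulse delay at which 50% of stimulated bursts are blocked.

    The measured curve is first made monotone non-increasing by isotonic
    regression (weighted by trials per delay) — block can only fall as the
    pulse is delayed — then the 50% point is read off by piecewise-linear
    interpolation. Raises if the curve never crosses 0.5, naming the side.
    """
    from sklearn.isotonic import IsotonicRegression

    d = curve.pulse_delays_ms
    if d.size < 2:
        raise ValueError("need at least two delays to extrapolate")
    iso = IsotonicRegression(increasing=False, y_min=0.0, y_max=1.0)
    f = iso.fit_transform(d, curve.fraction_blocked, sample_weight=curve.n_trials)
    if f.max() < 0.5:
        raise ValueError("curve never reaches 0.5: all fractions below 0.5")
    if f.min() > 0.5:
        raise ValueError("curve never falls to 0.5: all fractions above 0.5")
    # first crossing of 0.5, scanning in increasing delay
    for i in range(d.size):
        if f[i] == 0.5:
            return float(d[i])
        if i + 1 < d.size and f[i] > 0.5 >= f[i + 1]:
            if f[i] == f[i + 1]:
                return float(d[i + 1])
            return float(d[i] + (f[i] - 0.5) / (f[i] - f[i + 1]) * (d[i + 1] - d[i]))
    raise ValueError("curve never crosses 0.5")  # pragma: no cover


def exclude_cultures(
    sync_percent: Mapping[str, float],
    unreliable_detection: Sequence[str] = (),
    min_sync_percent: float = 50.0,
) -> tuple[list[str], dict[str, str]]:
    """Apply the culture exclusion rules of the silencing experiments.

    Cultures with synchronization strictly below ``min_sync_percent``
    (exactly 50% is kept) or flagged for unreliable online burst detection
    are discarded. Returns (kept ids, {discarded id: reason}).
    """
    unreliable = set(unreliable_detection)
    kept: list[str] = []
    discarded: dict[str, str] = {}
    for cid, pct in sync_percent.items():
        if cid in unreliable:
            discarded[cid] = "unreliable_online_detection"
        elif pct < min_sync_percent:
            discarded[cid] = "low_synchronization"
        else:
            kept.append(cid)
    return kept, discarded
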