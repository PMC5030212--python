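"""End-to-end orchestration: simulate -> detect -> bursts -> pairing ->
synchronization (-> closed loop) -> report."""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import bursts as ba
from . import simulate as sim
from .closedloop import ClosedLoopConfig, quantify_block
from .io import bursts_to_frame, records_to_frame, save_json
from .layout import SLICE_LABELS
from .recording import EventRaster


@dataclasses.dataclass(frozen=True)
class BurstParams:
    """Burst-detection and pairing parameters (times in ms)."""

    bin_width_ms: float = 10.0
    onset_thresh: int = 3
    min_electrodes: int = 4
    min_silent_ms: float = 300.0
    min_duration_ms: float = 30.0
    merge_gap_ms: float = 100.0
    max_delay_ms: float = 500.0


def analyze_raster(
    raster: EventRaster, params: BurstParams | None = None
) -> dict[str, Any]:
    """Run binning, burst detection, pairing and synchronization on a raster.

    Returns a dict with the per-slice activity traces and burst lists, the
    propagation records, the synchronization result (None if no bursts) and
    the delay summary (None if nothing propagated).
    """
    p = params or BurstParams()
    traces = ba.compute_network_activity(raster, bin_width_ms=p.bin_width_ms)
    bursts = {
        label: ba.detect_bursts(
            traces[label],
            raster,
            onset_thresh=p.onset_thresh,
            min_electrodes=p.min_electrodes,
            min_silent_ms=p.min_silent_ms,
            min_duration_ms=p.min_duration_ms,
            merge_gap_ms=p.merge_gap_ms,
        )
        for label in SLICE_LABELS
    }
    records = ba.pair_bursts(bursts["left"], bursts["right"], max_delay_ms=p.max_delay_ms)
    sync = ba.compute_synchronization(records) if records else None
    delays = (
        ba.compute_propagation_delays(records)
        if any(r.propagated for r in records)
        else None
    )
    return {
        "traces": traces,
        "bursts": bursts,
        "records": records,
        "synchronization": sync,
        "delays": delays,
    }


def _cfg_from_dict(section: Mapping[str, Any] | None, cls, **overrides):
    data = dict(section or {})
    data.update(overrides)
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{cls.__name__}: unknown parameter(s) {sorted(unknown)}")
    return cls(**data)


def run_pipeline(config: Mapping[str, Any], outdir: str | Path | None = None) -> dict:
    """Execute the configured stages and return (and optionally write) a report.

    ``config`` is the run-config mapping (see :func:`relaymea.io.load_run_config`):
    ``simulation`` and ``bursts`` parameter blocks, optional ``closed_loop``
    block with ``enabled: true``, top-level ``seed`` / ``duration_s``
    overrides, and ``report: {figures: bool}``. Deterministic given the seed.
    """
    sim_kwargs = dict(config.get("simulation") or {})
    if "seed" in config:
        sim_kwargs["seed"] = int(config["seed"])
    if "duration_s" in config:
        sim_kwargs["duration_s"] = float(config["duration_s"])
    if "envelope" in sim_kwargs:
        sim_kwargs["envelope"] = sim.BurstEnvelope(**sim_kwargs["envelope"])
    cfg = _cfg_from_dict(sim_kwargs, sim.SimulationConfig)
    params = _cfg_from_dict(config.get("bursts"), BurstParams)
    det = dict(config.get("detection") or {})
    mode = det.pop("mode", "events")
    unknown = set(det) - {"threshold_k", "refractory_ms"}
    if unknown:
        raise ValueError(f"detection: unknown parameter(s) {sorted(unknown)}")

    report: dict[str, Any] = {
        "parameters": {
            "simulation": _jsonable(dataclasses.asdict(cfg)),
            "bursts": dataclasses.asdict(params),
            "detection": {"mode": mode, **det},
            "seed": cfg.seed,
        }
    }

    if mode == "raw":
        raster, truth = sim.generate_detected_raster(cfg, **det)
    else:
        raster, truth = sim.generate_culture(cfg, mode="events")
    result = analyze_raster(raster, params)
    report["n_bursts_true"] = int(len(truth.bursts))
    report["n_bursts_detected"] = {
        k: len(v) for k, v in result["bursts"].items()
    }
    if result["synchronization"] is not None:
        s = result["synchronization"]
        report["synchronization"] = {
            "percent_propagated": s.percent_propagated,
            "n_leading_bursts": s.n_leading_bursts,
            "n_propagated": s.n_propagated,
            "by_direction": s.by_direction,
        }
    if result["delays"] is not None:
        d = result["delays"]
        report["propagation_delays_ms"] = {
            "mean": d.mean_ms,
            "sem": d.sem_ms,
            "max": d.max_ms,
            "n": int(d.delays_ms.size),
        }

    cl_section = dict(config.get("closed_loop") or {})
    if cl_section.pop("enabled", False):
        loop_cfg = _cfg_from_dict(cl_section, ClosedLoopConfig)
        raster_l, pulses, truth_l = sim.generate_closed_loop_session(cfg, loop_cfg)
        light_result = analyze_raster(raster_l, params)
        block = quantify_block(light_result["records"], result["records"])
        report["closed_loop"] = {
            "n_pulses": len(pulses),
            "fraction_blocked": block.fraction_blocked,
            "percent_unpropagated_light": block.percent_unpropagated_light,
            "propagation_light": block.propagation_light,
            "propagation_control": block.propagation_control,
        }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        save_json(report, outdir / "report.json")
        all_bursts = [b for v in result["bursts"].values() for b in v]
        bursts_to_frame(all_bursts).to_csv(outdir / "bursts.csv", index=False)
        records_to_frame(result["records"]).to_csv(outdir / "records.csv", index=False)
        if (config.get("report") or {}).get("figures", False):
            from .plots import network_activity_figure, raster_figure

            t_hi = min(60.0, raster.duration)
            fig = raster_figure(raster, t_range=(0.0, t_hi))
            fig.savefig(outdir / "raster.png", dpi=120)
            fig2 = network_activity_figure(
                result["traces"], result["bursts"], t_range=(0.0, t_hi)
            )
            fig2.savefig(outdir / "network_activity.png", dpi=120)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
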