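"""File formats: CSV and HDF5 round-trips for layouts, rasters, recordings,
burst/record/trial tables, plus YAML run configuration.

Every container carries a schema version; readers validate required columns
and raise :class:`SchemaError` naming the offending field.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from .bursts import Burst, PropagationRecord
from .layout import ElectrodeLayout
from .recording import EventRaster, LightPulse, RawRecording

SCHEMA_VERSION = "1"


class SchemaError(ValueError):
    """A file does not match the expected schema."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


# ------------------------------------------------------------------- layouts

LAYOUT_COLUMNS = ["electrode_id", "x_um", "y_um", "slice_label", "selected"]


def save_layout_csv(layout: ElectrodeLayout, path: str | Path) -> None:
    pd.DataFrame(
        {
            "electrode_id": layout.electrode_ids,
            "x_um": layout.x_um,
            "y_um": layout.y_um,
            "slice_label": layout.slice_labels,
            "selected": layout.selected.astype(int),
        }
    ).to_csv(path, index=False)


def load_layout_csv(path: str | Path) -> ElectrodeLayout:
    df = pd.read_csv(path)
    _require_columns(df, LAYOUT_COLUMNS, "layout CSV")
    return ElectrodeLayout(
        electrode_ids=df["electrode_id"].to_numpy(),
        x_um=df["x_um"].to_numpy(),
        y_um=df["y_um"].to_numpy(),
        slice_labels=df["slice_label"].to_numpy(dtype="U8"),
        selected=df["selected"].to_numpy(dtype=bool),
    )


# ------------------------------------------------------------------- rasters


def save_raster_csv(raster: EventRaster, path: str | Path) -> None:
    """Events as CSV; the header comment carries schema and duration."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# relaymea-raster schema={SCHEMA_VERSION} duration_s={raster.duration!r}\n")
        pd.DataFrame(
            {"electrode_id": raster.electrode_ids, "time_s": raster.times}
        ).to_csv(fh, index=False)


def load_raster_csv(path: str | Path, layout: ElectrodeLayout) -> EventRaster:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# relaymea-raster"):
            raise SchemaError("raster CSV: missing schema header line")
        fields = dict(tok.split("=", 1) for tok in header.split()[2:])
        if fields.get("schema") != SCHEMA_VERSION:
            raise SchemaError(f"raster CSV: unsupported schema {fields.get('schema')!r}")
        duration = float(fields["duration_s"])
        df = pd.read_csv(fh)
    _require_columns(df, ["electrode_id", "time_s"], "raster CSV")
    return EventRaster(
        electrode_ids=df["electrode_id"].to_numpy(),
        times=df["time_s"].to_numpy(),
        duration=duration,
        layout=layout,
    )


def _write_layout_group(g: h5py.Group, layout: ElectrodeLayout) -> None:
    g.create_dataset("electrode_id", data=layout.electrode_ids)
    g.create_dataset("x_um", data=layout.x_um)
    g.create_dataset("y_um", data=layout.y_um)
    g.create_dataset(
        "slice_label", data=np.array([s.encode() for s in layout.slice_labels])
    )
    g.create_dataset("selected", data=layout.selected)


def _read_layout_group(g: h5py.Group) -> ElectrodeLayout:
    for name in ("electrode_id", "x_um", "y_um", "slice_label", "selected"):
        if name not in g:
            raise SchemaError(f"HDF5 layout group: missing dataset {name!r}")
    return ElectrodeLayout(
        electrode_ids=g["electrode_id"][:],
        x_um=g["x_um"][:],
        y_um=g["y_um"][:],
        slice_labels=np.array([s.decode() for s in g["slice_label"][:]]),
        selected=g["selected"][:],
    )


def save_raster_h5(raster: EventRaster, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = SCHEMA_VERSION
        f.attrs["kind"] = "raster"
        f.attrs["duration_s"] = raster.duration
        f.create_dataset("electrode_id", data=raster.electrode_ids)
        f.create_dataset("time_s", data=raster.times)
        _write_layout_group(f.create_group("layout"), raster.layout)


def load_raster_h5(path: str | Path) -> EventRaster:
    with h5py.File(path, "r") as f:
        if f.attrs.get("schema") != SCHEMA_VERSION or f.attrs.get("kind") != "raster":
            raise SchemaError("HDF5 file is not a relaymea raster of a supported schema")
        return EventRaster(
            electrode_ids=f["electrode_id"][:],
            times=f["time_s"][:],
            duration=float(f.attrs["duration_s"]),
            layout=_read_layout_group(f["layout"]),
        )


# ---------------------------------------------------------------- recordings


def save_recording_h5(rec: RawRecording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = SCHEMA_VERSION
        f.attrs["kind"] = "recording"
        f.attrs["sampling_rate"] = rec.sampling_rate
        f.create_dataset("signals", data=rec.signals, compression="gzip", compression_opts=1)
        f.create_dataset("stim_times", data=rec.stim_times)
        pl = np.array([(p.onset, p.offset, p.intensity) for p in rec.light_pulses])
        f.create_dataset("light_pulses", data=pl if pl.size else np.empty((0, 3)))
        _write_layout_group(f.create_group("layout"), rec.layout)


def load_recording_h5(path: str | Path) -> RawRecording:
    with h5py.File(path, "r") as f:
        if f.attrs.get("schema") != SCHEMA_VERSION or f.attrs.get("kind") != "recording":
            raise SchemaError("HDF5 file is not a relaymea recording of a supported schema")
        pulses = tuple(
            LightPulse(float(a), float(b), float(c)) for a, b, c in f["light_pulses"][:]
        )
        return RawRecording(
            signals=f["signals"][:],
            sampling_rate=float(f.attrs["sampling_rate"]),
            layout=_read_layout_group(f["layout"]),
            stim_times=f["stim_times"][:],
            light_pulses=pulses,
        )


# -------------------------------------------------------------------- tables


def bursts_to_frame(bursts: Sequence[Burst]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "slice_label": [b.slice_label for b in bursts],
            "onset_s": [b.onset for b in bursts],
            "offset_s": [b.offset for b in bursts],
            "peak_rate": [b.peak_rate for b in bursts],
            "n_active_electrodes": [b.n_active_electrodes for b in bursts],
            "total_events": [b.total_events for b in bursts],
        }
    )


def records_to_frame(records: Sequence[PropagationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "onset_s": [r.leading.onset for r in records],
            "offset_s": [r.leading.offset for r in records],
            "slice": [r.leading.slice_label for r in records],
            "propagated": [r.propagated for r in records],
            "delay_ms": [r.delay_ms if r.propagated else np.nan for r in records],
            "direction": [r.direction for r in records],
        }
    )


def curve_to_frame(curve) -> pd.DataFrame:
    """Block-vs-delay curve as a tidy table."""
    return pd.DataFrame(
        {
            "pulse_delay_ms": curve.pulse_delays_ms,
            "fraction_blocked": curve.fraction_blocked,
            "n_trials": curve.n_trials,
        }
    )


# ------------------------------------------------------- intracellular traces


def save_trace_h5(trace, path: str | Path) -> None:
    """Current-clamp trace with protocol annotations."""
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = SCHEMA_VERSION
        f.attrs["kind"] = "trace"
        f.attrs["sampling_rate"] = trace.sampling_rate
        f.attrs["resting_potential_mv"] = trace.resting_potential_mv
        f.create_dataset("v_mv", data=trace.v_mv)
        steps = np.array([(s.onset, s.duration, s.amplitude_pa) for s in trace.current_steps])
        f.create_dataset("current_steps", data=steps if steps.size else np.empty((0, 3)))
        pl = np.array([(p.onset, p.offset, p.intensity) for p in trace.light_pulses])
        f.create_dataset("light_pulses", data=pl if pl.size else np.empty((0, 3)))


def load_trace_h5(path: str | Path):
    from .intracellular import CurrentStep, IntracellularTrace

    with h5py.File(path, "r") as f:
        if f.attrs.get("schema") != SCHEMA_VERSION or f.attrs.get("kind") != "trace":
            raise SchemaError("HDF5 file is not a relaymea trace of a supported schema")
        return IntracellularTrace(
            v_mv=f["v_mv"][:],
            sampling_rate=float(f.attrs["sampling_rate"]),
            resting_potential_mv=float(f.attrs["resting_potential_mv"]),
            current_steps=tuple(
                CurrentStep(float(a), float(b), float(c)) for a, b, c in f["current_steps"][:]
            ),
            light_pulses=tuple(
                LightPulse(float(a), float(b), float(c)) for a, b, c in f["light_pulses"][:]
            ),
        )


# ------------------------------------------------------------- configuration

_CONFIG_SECTIONS = {
    "simulation",
    "detection",
    "bursts",
    "pairing",
    "closed_loop",
    "report",
    "seed",
    "duration_s",
}


def load_run_config(path: str | Path) -> dict:
    """YAML run configuration with strict top-level key validation."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SchemaError("run config must be a mapping")
    unknown = set(cfg) - _CONFIG_SECTIONS
    if unknown:
        raise SchemaError(f"run config: unknown key(s) {sorted(unknown)}")
    return cfg


def save_json(obj: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
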