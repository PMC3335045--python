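"""Plain-text I/O: trip CSV dialects, ground-truth sidecars, YAML scenarios.

A trip is stored as two CSVs — ``<trip>_1hz.csv`` (``time_s, depth_m,
temp_c``) and ``<trip>_32hz.csv`` (``time_s, surge_ms2, heave_ms2``) —
plus a JSON ground-truth sidecar when simulated.  Scenario configuration
is YAML mirroring :class:`~divetherm.synthetic.TripScenario`.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dives import Dive, TripMetrics
from .synthetic import (
    GroundTruth,
    SensorSpec,
    TripRecording,
    TripScenario,
    WaterColumnSpec,
)

__all__ = [
    "write_trip",
    "read_trip",
    "write_ground_truth",
    "load_scenario",
    "write_dive_table",
    "write_metrics",
]


def write_trip(recording: TripRecording, out_dir, prefix: str | None = None) -> dict:
    """Write the two channel CSVs plus a small metadata JSON; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prefix = prefix or f"{recording.bird_id}_{recording.date.isoformat()}"
    p_slow = out / f"{prefix}_1hz.csv"
    p_fast = out / f"{prefix}_32hz.csv"
    p_meta = out / f"{prefix}_meta.json"
    recording.slow.to_csv(p_slow, index=False)
    recording.fast.to_csv(p_fast, index=False)
    p_meta.write_text(json.dumps({
        "bird_id": recording.bird_id,
        "date": recording.date.isoformat(),
        "start_seconds": recording.start_seconds,
    }, indent=1))
    return {"slow": p_slow, "fast": p_fast, "meta": p_meta}


def read_trip(out_dir, prefix: str) -> TripRecording:
    out = Path(out_dir)
    meta = json.loads((out / f"{prefix}_meta.json").read_text())
    return TripRecording(
        bird_id=meta["bird_id"],
        date=_dt.date.fromisoformat(meta["date"]),
        slow=pd.read_csv(out / f"{prefix}_1hz.csv"),
        fast=pd.read_csv(out / f"{prefix}_32hz.csv"),
        start_seconds=int(meta["start_seconds"]),
    )


def write_ground_truth(truth: GroundTruth, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps({
        "dive_intervals": np.asarray(truth.dive_intervals).tolist(),
        "dive_max_depths": np.asarray(truth.dive_max_depths).tolist(),
        "pursuit_segments": truth.pursuit_segments,
        "n_strokes": int(truth.stroke_times.size),
        "column": truth.true_column.spec.__dict__,
    }))
    return path


def _scenario_from_mapping(cfg: dict) -> TripScenario:
    cfg = dict(cfg)
    if "water_column" in cfg:
        cfg["water_column"] = WaterColumnSpec(**cfg["water_column"])
    if "sensors" in cfg:
        cfg["sensors"] = SensorSpec(**cfg["sensors"])
    if "date" in cfg and isinstance(cfg["date"], str):
        cfg["date"] = _dt.date.fromisoformat(cfg["date"])
    if "depth_modes" in cfg:
        cfg["depth_modes"] = tuple(tuple(m) for m in cfg["depth_modes"])
    if "pursuit_depth_range" in cfg:
        cfg["pursuit_depth_range"] = tuple(cfg["pursuit_depth_range"])
    return TripScenario(**cfg)


def load_scenario(path) -> TripScenario:
    """Read a YAML scenario file into a validated :class:`TripScenario`."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    scn = _scenario_from_mapping(cfg)
    scn.validate()
    return scn


def write_dive_table(dives: list[Dive], path) -> Path:
    rows = [{
        "dive_index": d.index,
        "start_s": d.start,
        "end_s": d.end,
        "max_depth_m": d.max_depth,
        "descent_s": d.descent.duration,
        "bottom_s": d.bottom.duration,
        "ascent_s": d.ascent.duration,
    } for d in dives]
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def write_metrics(metrics: TripMetrics, bird_id: str, date: _dt.date, path) -> Path:
    payload = {"bird_id": bird_id, "date": date.isoformat()}
    payload.update({
        k: getattr(metrics, k)
        for k in ("n_dives", "mean_dive_depth", "time_underwater",
                  "bottom_proportion", "deep_dive_fraction", "hunting_efficiency")
    })
    Path(path).write_text(json.dumps(payload, indent=1))
    return Path(path)
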