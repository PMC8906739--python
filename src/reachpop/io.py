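"""Plain-text readers and writers for session data.

Formats (all delimited text / JSON / YAML):

* trace CSV        -- columns ``t_s, x_mm, y_mm`` (1-kHz samples)
* spike CSV        -- columns ``unit_id, time_s``, sorted by (unit, time)
* events CSV       -- one row per reach: start_s, stop_s, amplitude_mm,
                      direction_rad, peak_speed_mm_s, duration_s,
                      rewarded, block_id
* ground-truth JSON -- per-unit planted parameters
* config YAML/JSON -- session / pipeline parameters
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .kinematics import JoystickTrace, ReachEvent
from .synthetic import GroundTruth, SessionConfig

__all__ = [
    "write_trace",
    "read_trace",
    "write_spikes",
    "read_spikes",
    "write_events",
    "read_events",
    "write_ground_truth",
    "read_ground_truth",
    "load_session_config",
    "dump_session_config",
]

PathLike = Union[str, Path]

EVENT_COLUMNS = [
    "start_s",
    "stop_s",
    "amplitude_mm",
    "direction_rad",
    "peak_speed_mm_s",
    "duration_s",
    "rewarded",
    "block_id",
]


def write_trace(trace: JoystickTrace, path: PathLike) -> None:
    pd.DataFrame({"t_s": trace.t, "x_mm": trace.x, "y_mm": trace.y}).to_csv(path, index=False)


def read_trace(path: PathLike) -> JoystickTrace:
    df = pd.read_csv(path)
    return JoystickTrace(t=df["t_s"].to_numpy(), x=df["x_mm"].to_numpy(), y=df["y_mm"].to_numpy())


def write_spikes(spikes: pd.DataFrame, path: PathLike) -> None:
    spikes[["unit_id", "time_s"]].to_csv(path, index=False)


def read_spikes(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


def write_events(events: Sequence[ReachEvent], path: PathLike) -> None:
    rows = [
        [ev.start_s, ev.stop_s, ev.amplitude, ev.direction, ev.peak_speed,
         ev.duration_s, ev.rewarded, ev.block_id]
        for ev in events
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def read_events(path: PathLike) -> list[ReachEvent]:
    df = pd.read_csv(path)
    events = []
    for _, row in df.iterrows():
        events.append(
            ReachEvent(
                start_s=float(row["start_s"]),
                stop_s=float(row["stop_s"]),
                amplitude=float(row["amplitude_mm"]),
                direction=float(row["direction_rad"]),
                peak_speed=float(row["peak_speed_mm_s"]),
                duration_s=float(row["duration_s"]),
                rewarded=None if pd.isna(row["rewarded"]) else bool(row["rewarded"]),
                block_id=None if pd.isna(row["block_id"]) else int(row["block_id"]),
            )
        )
    return events


def write_ground_truth(truth: GroundTruth, path: PathLike) -> None:
    payload = truth.units.reset_index().to_dict(orient="records")
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_ground_truth(path: PathLike) -> GroundTruth:
    records = json.loads(Path(path).read_text())
    units = pd.DataFrame.from_records(records).set_index("unit_id")
    return GroundTruth(units=units)


def _coerce_tuples(cfg: dict) -> dict:
    out = {}
    for k, v in cfg.items():
        if isinstance(v, list) and k != "unit_class_fractions":
            out[k] = tuple(v)
        else:
            out[k] = v
    return out


def load_session_config(path: PathLike) -> SessionConfig:
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    cfg = SessionConfig(**_coerce_tuples(data))
    cfg.validate()
    return cfg


def dump_session_config(config: SessionConfig, path: PathLike) -> None:
    data = dataclasses.asdict(config)
    data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in data.items()}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
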