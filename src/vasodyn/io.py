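"""File formats: trace/train/cell tables (CSV), volumes (TIFF), configs.

Write-then-read is an identity for every artifact the pipeline passes
between stages: wide trace CSVs with a JSON metadata sidecar, event-train
CSVs with a session sidecar, cell tables, multi-page TIFF masks/channels
with a voxel-size sidecar, and YAML/JSON run configurations.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .synthio import AnimalTrain, EventTrainSet, ImageStack, VesselTrace

__all__ = [
    "write_traces", "read_traces",
    "write_trains", "read_trains",
    "write_stack", "read_stack",
    "write_cells", "read_cells",
    "write_events", "read_events",
    "load_config", "save_config",
]


# --- traces ----------------------------------------------------------------

def write_traces(traces: list[VesselTrace], csv_path):
    """Wide CSV (time + one column per vessel) plus a JSON metadata sidecar."""
    csv_path = Path(csv_path)
    data = {"time_s": traces[0].time}
    meta = {}
    for tr in traces:
        data[tr.vessel_id] = tr.fluorescence
        meta[tr.vessel_id] = {"animal_id": tr.animal_id, "cohort": tr.cohort}
    pd.DataFrame(data).to_csv(csv_path, index=False)
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_traces(csv_path) -> list[VesselTrace]:
    csv_path = Path(csv_path)
    try:
        df = pd.read_csv(csv_path)
    except Exception as exc:
        raise ValueError(f"malformed trace CSV {csv_path}: {exc}") from exc
    if "time_s" not in df.columns or df.isna().any().any():
        raise ValueError(f"malformed trace CSV {csv_path}: missing time_s or values")
    sidecar = csv_path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    t = df["time_s"].to_numpy(dtype=float)
    out = []
    for col in df.columns:
        if col == "time_s":
            continue
        m = meta.get(col, {})
        out.append(VesselTrace(col, m.get("animal_id", "unknown"),
                               m.get("cohort", "unknown"), t,
                               df[col].to_numpy(dtype=float)))
    return out


# --- event trains ----------------------------------------------------------

def write_trains(trains: EventTrainSet, csv_path):
    """CSV (animal_id, kind, onset_s) plus a JSON sidecar of session bounds."""
    csv_path = Path(csv_path)
    rows, sessions = [], {}
    for a in trains:
        sessions[a.animal_id] = [a.session_start, a.session_end]
        rows += [{"animal_id": a.animal_id, "kind": "seizure", "onset_s": t}
                 for t in a.seizures]
        rows += [{"animal_id": a.animal_id, "kind": "spasm", "onset_s": t}
                 for t in a.spasms]
    pd.DataFrame(rows, columns=["animal_id", "kind", "onset_s"]).to_csv(
        csv_path, index=False)
    csv_path.with_suffix(".json").write_text(json.dumps(sessions, indent=1))


def read_trains(csv_path) -> EventTrainSet:
    csv_path = Path(csv_path)
    try:
        df = pd.read_csv(csv_path)
    except Exception as exc:
        raise ValueError(f"malformed train CSV {csv_path}: {exc}") from exc
    required = {"animal_id", "kind", "onset_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"train CSV {csv_path} missing columns "
                         f"{sorted(required - set(df.columns))}")
    sessions = json.loads(csv_path.with_suffix(".json").read_text())
    animals = []
    for aid, (s0, s1) in sessions.items():
        sub = df[df["animal_id"] == aid]
        sz = np.sort(sub.loc[sub["kind"] == "seizure", "onset_s"].to_numpy(float))
        sp = np.sort(sub.loc[sub["kind"] == "spasm", "onset_s"].to_numpy(float))
        animals.append(AnimalTrain(aid, float(s0), float(s1), sz, sp))
    return EventTrainSet(animals)


# --- volumes ---------------------------------------------------------------

def write_stack(stack: ImageStack, directory, prefix: str = "stack"):
    """One multi-page TIFF per channel plus a JSON voxel-size sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, arr in stack.channels.items():
        tifffile.imwrite(directory / f"{prefix}_{name}.tif", np.asarray(arr))
    sidecar = {"voxel_size_um": list(stack.voxel_size),
               "channels": sorted(stack.channels)}
    (directory / f"{prefix}.json").write_text(json.dumps(sidecar, indent=1))


def read_stack(directory, prefix: str = "stack") -> ImageStack:
    directory = Path(directory)
    sidecar = json.loads((directory / f"{prefix}.json").read_text())
    channels = {name: tifffile.imread(directory / f"{prefix}_{name}.tif")
                for name in sidecar["channels"]}
    return ImageStack(channels, tuple(sidecar["voxel_size_um"]))


# --- cells and events ------------------------------------------------------

def write_cells(cells: pd.DataFrame, csv_path):
    cells.to_csv(csv_path, index=False)


def read_cells(csv_path) -> pd.DataFrame:
    try:
        df = pd.read_csv(csv_path)
    except Exception as exc:
        raise ValueError(f"malformed cell CSV {csv_path}: {exc}") from exc
    for col in ("x_um", "y_um", "z_um"):
        if col not in df.columns:
            raise ValueError(f"cell CSV {csv_path} missing column {col}")
    return df


def write_events(events_by_vessel: dict, csv_path):
    """Events CSV: vessel_id, onset_t, trough_t, end_t, magnitude, duration."""
    rows = [{"vessel_id": vid, "onset_t": e.onset_t, "trough_t": e.trough_t,
             "end_t": e.end_t, "magnitude": e.magnitude, "duration": e.duration,
             "onset_time": e.onset_time, "termination_time": e.termination_time}
            for vid, evs in events_by_vessel.items() for e in evs]
    pd.DataFrame(rows, columns=["vessel_id", "onset_t", "trough_t", "end_t",
                                "magnitude", "duration", "onset_time",
                                "termination_time"]).to_csv(csv_path, index=False)


def read_events(csv_path) -> pd.DataFrame:
    return pd.read_csv(csv_path)


# --- configs ---------------------------------------------------------------

def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def save_config(config: dict, path):
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(config, sort_keys=True))
    else:
        path.write_text(json.dumps(config, indent=1, sort_keys=True))
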