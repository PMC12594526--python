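"""Delimited-text readers and writers for the pipeline's tables.

Tracks and decay curves are plain CSV. Cell geometries are one record per
cell with the outline and centerline vertex lists packed as
``x:y;x:y;...`` strings, so the whole dataset stays greppable text.
Simulation configs round-trip through YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import CellGeometry
from .kinetics import DecayTimeCourse
from .synthetic_data import GroundTruth, SimConfig

TRACK_COLUMNS = ["movie_id", "track_id", "frame", "x_px", "y_px"]


def write_tracks(tracks: pd.DataFrame, path):
    tracks[TRACK_COLUMNS].to_csv(path, index=False)


def read_tracks(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"tracks file missing columns: {sorted(missing)}")
    return df


def _pack(points: np.ndarray) -> str:
    return ";".join(f"{x:.6f}:{y:.6f}" for x, y in points)


def _unpack(s: str) -> np.ndarray:
    return np.array([[float(v) for v in p.split(":")] for p in s.split(";")])


def write_cells(cells: list[CellGeometry], path):
    rows = [{
        "cell_id": c.cell_id,
        "movie_id": c.movie_id,
        "vertices": _pack(c.outline),
        "centerline": _pack(c.centerline),
        "length_px": c.length_px,
        "width_px": c.width_px,
    } for c in cells]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cells(path) -> list[CellGeometry]:
    df = pd.read_csv(path)
    return [CellGeometry(cell_id=int(r.cell_id), movie_id=int(r.movie_id),
                         outline=_unpack(r.vertices),
                         centerline=_unpack(r.centerline),
                         length_px=float(r.length_px),
                         width_px=float(r.width_px))
            for r in df.itertuples()]


def write_ground_truth(gt: GroundTruth, directory):
    d = Path(directory)
    gt.molecules.to_csv(d / "ground_truth_molecules.csv", index=False)
    gt.positions.to_csv(d / "ground_truth_positions.csv", index=False)


def read_ground_truth(directory) -> GroundTruth:
    d = Path(directory)
    return GroundTruth(
        molecules=pd.read_csv(d / "ground_truth_molecules.csv"),
        positions=pd.read_csv(d / "ground_truth_positions.csv"))


def write_config(config: SimConfig, path):
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def read_config(path) -> SimConfig:
    with open(path) as fh:
        return SimConfig(**yaml.safe_load(fh))


def write_decay(timecourses: list[DecayTimeCourse], path):
    rows = []
    for tc in timecourses:
        for t, a in zip(tc.times, tc.abundance):
            rows.append({"replicate": tc.replicate_id, "time_s": t,
                         "abundance": a})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_decay(path) -> list[DecayTimeCourse]:
    df = pd.read_csv(path)
    return [DecayTimeCourse(replicate_id=int(rep),
                            times=grp["time_s"].to_numpy(),
                            abundance=grp["abundance"].to_numpy())
            for rep, grp in df.groupby("replicate")]


def write_histogram(hist, path):
    pd.DataFrame({"bin_lo": hist.edges[:-1], "bin_hi": hist.edges[1:],
                  "prob": hist.prob, "sem": hist.sem}).to_csv(path, index=False)


def write_json(obj: dict, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
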