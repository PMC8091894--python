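"""File formats: track/edge CSV dialects, TIFF stacks with sidecar JSON,
feature-trace CSV and JSON summaries."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MnkitError
from .features import FeatureTraces
from .types import (CellTrack, InputWaveform, MonolayerDataset,
                    SimulationParams)

TRACK_COLUMNS = ["cell_id", "t_min", "x_um", "y_um", "nuclear_area_um2",
                 "nfkb_au", "region_label"]


def tracks_to_frame(dataset: MonolayerDataset) -> pd.DataFrame:
    """Long-form track table: one row per cell per time point."""
    rows = []
    for tr in dataset.tracks:
        rows.append(pd.DataFrame({
            "cell_id": tr.cell_id,
            "t_min": tr.times,
            "x_um": tr.centroid_xy[:, 0],
            "y_um": tr.centroid_xy[:, 1],
            "nuclear_area_um2": tr.nuclear_area,
            "nfkb_au": tr.nfkb_nuclear,
            "region_label": tr.region_label,
        }))
    return pd.concat(rows, ignore_index=True) if rows else \
        pd.DataFrame(columns=TRACK_COLUMNS)


def write_tracks_csv(dataset: MonolayerDataset, path) -> None:
    tracks_to_frame(dataset).to_csv(path, index=False)


def read_tracks_csv(path, params: SimulationParams | None = None,
                    input_wf: InputWaveform | None = None
                    ) -> MonolayerDataset:
    """Rebuild a MonolayerDataset from the track CSV dialect.

    Neighbor edges are re-derived from frame-0 centroids; params/input fall
    back to defaults (a zero-amplitude stimulus) when not given.
    """
    from .simulate import delaunay_edges, make_input_waveform

    df = pd.read_csv(path)
    missing = set(TRACK_COLUMNS[:6]) - set(df.columns)
    if missing:
        raise MnkitError(f"track CSV missing columns: {sorted(missing)}")
    tracks = []
    for cid, sub in df.groupby("cell_id"):
        sub = sub.sort_values("t_min")
        tracks.append(CellTrack(
            cell_id=int(cid),
            times=sub["t_min"].to_numpy(),
            centroid_xy=sub[["x_um", "y_um"]].to_numpy(),
            nuclear_area=sub["nuclear_area_um2"].to_numpy(),
            nfkb_nuclear=sub["nfkb_au"].to_numpy(),
            region_label=(str(sub["region_label"].iloc[0])
                          if "region_label" in sub else "interior")))
    times = tracks[0].times if tracks else np.array([0.0, 1.0])
    dt = float(times[1] - times[0]) if len(times) > 1 else 1.0
    if params is None:
        params = SimulationParams(dt=dt, duration=dt * max(len(times), 64))
    if input_wf is None:
        input_wf = make_input_waveform(max(4 * dt, 20.0), 0.5, 0.0,
                                       dt * len(times), dt)
    pos0 = np.array([t.centroid_xy[0] for t in tracks])
    edges = delaunay_edges(pos0) if len(pos0) >= 3 else []
    edges = [(int(tracks[a].cell_id), int(tracks[b].cell_id))
             for a, b in edges]
    return MonolayerDataset(tracks=tracks, params=params, input=input_wf,
                            neighbor_edges=edges, preset_name="from_csv")


def write_edges_csv(dataset: MonolayerDataset, path,
                    long_form: bool = False) -> None:
    """Edge list; with ``long_form`` one row per edge per time point holding
    the junction intensity."""
    if long_form and dataset.junction_intensity:
        rows = []
        times = dataset.times
        for (a, b), trace in sorted(dataset.junction_intensity.items()):
            rows.append(pd.DataFrame({"cell_id_a": a, "cell_id_b": b,
                                      "t_min": times, "junction_au": trace}))
        pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    else:
        pd.DataFrame(dataset.neighbor_edges,
                     columns=["cell_id_a", "cell_id_b"]).to_csv(path,
                                                                index=False)


def write_stack(stack: np.ndarray, path, pixel_size: float,
                dt: float) -> None:
    """Multi-page TIFF (frame order = time order) plus a sidecar JSON with
    the physical calibration."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump({"pixel_size_um": pixel_size, "dt_min": dt,
                   "n_frames": int(len(stack))}, fh, indent=2)


def read_stack(path) -> tuple[np.ndarray, dict]:
    import tifffile

    path = Path(path)
    stack = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return stack, meta


def write_feature_csv(traces: FeatureTraces, path) -> None:
    """Wide CSV: entity_id x time."""
    df = pd.DataFrame(traces.values,
                      index=[str(e) for e in traces.entity_ids],
                      columns=[f"{t:g}" for t in traces.times])
    df.index.name = "entity_id"
    df.to_csv(path)


def write_velocity_csv(field, path) -> None:
    """PIV field as CSV: x_um, y_um, vx_um_min, vy_um_min, valid."""
    g = field.grid_xy.reshape(-1, 2)
    v = field.vectors.reshape(-1, 2)
    valid = (field.valid.reshape(-1) if field.valid is not None
             else np.ones(len(g), dtype=bool))
    pd.DataFrame({"x_um": g[:, 0], "y_um": g[:, 1],
                  "vx_um_min": v[:, 0], "vy_um_min": v[:, 1],
                  "valid": valid}).to_csv(path, index=False)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            v = float(o)
            return v if np.isfinite(v) else None
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return super().default(o)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, cls=_NumpyEncoder)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
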