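"""Morphological feature traces: Delaunay triangle areas, nuclear shape
fluctuation (NSF), trajectory-deviation vibration (Dl), junction events and
actin extension.

All "normalized" traces are divided by their own time mean, so each row of a
normalized :class:`FeatureTraces` matrix has mean 1.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import medfilt
from scipy.spatial import Delaunay, ConvexHull

from .errors import EmptyOutputWarning, MnkitError, TriangulationError
from .types import MonolayerDataset

FEATURE_NAMES = ("triangle_area", "nsf", "vibration", "junction",
                 "actin_extension", "cell_area")


@dataclass
class FeatureTraces:
    """Entities x time matrix of one named derived feature."""

    feature_name: str
    entity_ids: list
    times: np.ndarray
    values: np.ndarray                    # (n_entities, T)
    normalized: bool = False
    normalization_mode: str = "none"      # time_mean | initial_value | none
    valid: Optional[np.ndarray] = None    # (n_entities,) bool

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.feature_name not in FEATURE_NAMES:
            raise MnkitError(f"unknown feature {self.feature_name!r}")
        if self.values.shape[0] != len(self.entity_ids):
            raise MnkitError("values rows must match entity_ids")
        if self.valid is None:
            self.valid = np.ones(len(self.entity_ids), dtype=bool)

    def mean_trace(self) -> np.ndarray:
        """Population-average trace over valid entities."""
        return self.values[self.valid].mean(axis=0)


def normalize_by_time_mean(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Divide each row by its time mean; rows with non-positive mean are
    flagged invalid and left unnormalized."""
    means = values.mean(axis=1)
    ok = means > 1e-12
    out = values.copy()
    out[ok] = values[ok] / means[ok, None]
    return out, ok


# ---------------------------------------------------------------------------
# neighbor triangulation
# ---------------------------------------------------------------------------

@dataclass
class NeighborTriangulation:
    """Delaunay triangulation of nuclear centroids at a reference frame,
    frozen for the whole movie."""

    triangles: np.ndarray                 # (M, 3) indices into dataset order
    edges: list[tuple[int, int]]
    reference_frame_index: int = 0
    adjacent_pairs: list[tuple[int, int]] = field(default_factory=list)


def build_triangulation(dataset: MonolayerDataset,
                        reference_frame_index: int = 0
                        ) -> NeighborTriangulation:
    """Triangulate centroids at the reference frame.

    Triangles sharing an edge are recorded as adjacent pairs (the unit used
    for triangle-area cross-correlation).
    """
    pos = dataset.positions()[:, reference_frame_index, :]
    if len(pos) < 3:
        raise TriangulationError("need at least 3 cells to triangulate")
    try:
        dt = Delaunay(pos)
    except Exception as exc:
        raise TriangulationError(f"degenerate cell positions: {exc}") from exc
    if dt.simplices.size == 0:
        raise TriangulationError("collinear cells: no triangles")
    tris = np.sort(dt.simplices, axis=1)
    edge_map: dict[tuple[int, int], list[int]] = {}
    for ti, tri in enumerate(tris):
        for a, b in ((0, 1), (0, 2), (1, 2)):
            e = (int(tri[a]), int(tri[b]))
            edge_map.setdefault(e, []).append(ti)
    adjacent = sorted({(min(p), max(p)) for members in edge_map.values()
                       if len(members) == 2
                       for p in [tuple(members)]})
    return NeighborTriangulation(triangles=tris,
                                 edges=sorted(edge_map),
                                 reference_frame_index=reference_frame_index,
                                 adjacent_pairs=adjacent)


def triangle_areas(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Shoelace areas; ``points`` (..., N, 2), returns (..., M)."""
    p = points[..., triangles, :]         # (..., M, 3, 2)
    a, b, c = p[..., 0, :], p[..., 1, :], p[..., 2, :]
    cross = ((b[..., 0] - a[..., 0]) * (c[..., 1] - a[..., 1])
             - (b[..., 1] - a[..., 1]) * (c[..., 0] - a[..., 0]))
    return 0.5 * np.abs(cross)


def triangle_area_traces(dataset: MonolayerDataset,
                         triangulation: NeighborTriangulation,
                         normalize: bool = True) -> FeatureTraces:
    """Per-triangle shoelace area at every frame, normalized by each
    triangle's time mean; degenerate (zero-area) triangles are flagged."""
    pos = dataset.positions()             # (N, T, 2)
    areas = triangle_areas(np.moveaxis(pos, 1, 0), triangulation.triangles)
    values = areas.T                      # (M, T)
    valid = np.all(values > 1e-9, axis=1)
    mode = "none"
    if normalize:
        values, ok = normalize_by_time_mean(values)
        valid &= ok
        mode = "time_mean"
    # entity ids are triangle ordinals, matching triangulation.adjacent_pairs
    ids = list(range(len(triangulation.triangles)))
    return FeatureTraces("triangle_area", ids, dataset.times, values,
                         normalized=normalize, normalization_mode=mode,
                         valid=valid)


def hull_area(points: np.ndarray) -> float:
    return float(ConvexHull(points).volume)   # 2-D: volume is the area


# ---------------------------------------------------------------------------
# nuclear shape fluctuation
# ---------------------------------------------------------------------------

def nsf_traces(dataset: MonolayerDataset) -> FeatureTraces:
    """Nuclear-area traces normalized by each cell's time-averaged area."""
    values, ok = normalize_by_time_mean(dataset.areas())
    return FeatureTraces("nsf", list(dataset.cell_ids), dataset.times,
                         values, normalized=True,
                         normalization_mode="time_mean", valid=ok)


def nsf_amplitude(traces: FeatureTraces) -> np.ndarray:
    """Fluctuation amplitude per cell: half the peak-to-trough range of the
    3-point median-filtered normalized trace."""
    filt = np.stack([medfilt(row, 3) for row in traces.values])
    return (filt.max(axis=1) - filt.min(axis=1)) / 2.0


# ---------------------------------------------------------------------------
# vibration deviation (Dl)
# ---------------------------------------------------------------------------

def moving_average_trajectory(xy: np.ndarray, window_samples: int
                              ) -> np.ndarray:
    """Centered moving average with truncated windows at the edges.

    Cumulative-sum implementation; the brute-force equivalent averages
    xy[max(0, i-h) : min(T, i+h+1)] for half-width h.
    """
    t = len(xy)
    h = window_samples // 2
    cs = np.vstack([np.zeros((1, xy.shape[1])), np.cumsum(xy, axis=0)])
    idx = np.arange(t)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h + 1, t)
    return (cs[hi] - cs[lo]) / (hi - lo)[:, None]


def vibration_deviation(dataset: MonolayerDataset, window: float = 30.0
                        ) -> FeatureTraces:
    """Dl(t): deviation of each cell's position from its own time-averaged
    trajectory (centered moving average over ``window`` minutes)."""
    dt = dataset.params.dt
    if window < 3 * dt:
        raise MnkitError("window must span at least 3 samples")
    wlen = int(round(window / dt))
    pos = dataset.positions()
    dl = np.empty(pos.shape[:2])
    for i in range(pos.shape[0]):
        avg = moving_average_trajectory(pos[i], wlen)
        dl[i] = np.hypot(*(pos[i] - avg).T)
    return FeatureTraces("vibration", list(dataset.cell_ids), dataset.times,
                         dl, normalized=False, normalization_mode="none")


# ---------------------------------------------------------------------------
# junction events
# ---------------------------------------------------------------------------

def junction_event_count(junction_traces: dict | np.ndarray,
                         rel_threshold: float = 0.10):
    """Count excursions of junction fluorescence beyond ``rel_threshold``
    of the per-edge temporal median baseline.

    An event is a maximal contiguous run with |value - baseline|/baseline
    above threshold.  Returns (per-edge counts, mean, sd).
    """
    if isinstance(junction_traces, dict):
        keys = sorted(junction_traces)
        mat = np.stack([junction_traces[k] for k in keys]) if keys else \
            np.empty((0, 0))
    else:
        keys = list(range(len(junction_traces)))
        mat = np.atleast_2d(np.asarray(junction_traces, dtype=float))
    if mat.size and np.any(mat <= 0):
        raise MnkitError("junction traces must be strictly positive")
    counts = {}
    for k, trace in zip(keys, mat):
        baseline = np.median(trace)
        above = np.abs(trace - baseline) / baseline > rel_threshold
        # count rising edges of maximal runs
        starts = np.flatnonzero(above & ~np.concatenate([[False], above[:-1]]))
        counts[k] = int(len(starts))
    vals = np.array(list(counts.values()), dtype=float)
    mean = float(vals.mean()) if vals.size else 0.0
    sd = float(vals.std()) if vals.size else 0.0
    return counts, mean, sd


# ---------------------------------------------------------------------------
# actin extension
# ---------------------------------------------------------------------------

def actin_extension(endpoints: pd.DataFrame) -> FeatureTraces:
    """Per-cell mean actin-filament end-to-end extension, normalized to the
    value at t = 0.

    ``endpoints`` columns: filament_id, end ('a'|'b'), t_min, x_um, y_um and
    optionally cell_id.  Filaments with zero initial length are excluded.
    """
    df = endpoints.copy()
    if "cell_id" not in df.columns:
        df["cell_id"] = 0
    wide = df.pivot_table(index=["cell_id", "filament_id", "t_min"],
                          columns="end", values=["x_um", "y_um"])
    dx = wide[("x_um", "a")] - wide[("x_um", "b")]
    dy = wide[("y_um", "a")] - wide[("y_um", "b")]
    lengths = np.hypot(dx, dy).rename("length").reset_index()
    times = np.sort(lengths["t_min"].unique())
    cell_rows, ids = [], []
    for cell, sub in lengths.groupby("cell_id"):
        mat = sub.pivot(index="filament_id", columns="t_min",
                        values="length").reindex(columns=times)
        init = mat.iloc[:, 0]
        mat = mat[init > 1e-12]           # zero initial length -> excluded
        if mat.empty:
            continue
        ratio = mat.div(mat.iloc[:, 0], axis=0)
        cell_rows.append(ratio.mean(axis=0).to_numpy())
        ids.append(cell)
    if not cell_rows:
        warnings.warn("all filaments excluded", EmptyOutputWarning)
        return FeatureTraces("actin_extension", [], times,
                             np.empty((0, len(times))),
                             normalized=True,
                             normalization_mode="initial_value")
    return FeatureTraces("actin_extension", ids, times, np.stack(cell_rows),
                         normalized=True, normalization_mode="initial_value")


# ---------------------------------------------------------------------------
# positional return dynamics
# ---------------------------------------------------------------------------

def return_times(dataset: MonolayerDataset, pulse_onset: float,
                 k_sigma: float = 2.0, sustain_frames: int = 3
                 ) -> np.ndarray:
    """Per-cell time (min, from pulse onset) until the displacement from the
    pre-pulse mean position re-enters ``k_sigma`` times its pre-pulse sd and
    stays there for ``sustain_frames`` consecutive frames.

    Cells that never leave the envelope return 0; cells that never re-enter
    return NaN.
    """
    times = dataset.times
    pre = times < pulse_onset
    if not np.any(pre):
        raise MnkitError("no pre-pulse frames before the given onset")
    pos = dataset.positions()
    out = np.empty(len(pos))
    post = ~pre
    t_post = times[post] - pulse_onset
    for i, xy in enumerate(pos):
        mean_pre = xy[pre].mean(axis=0)
        disp_pre = np.hypot(*(xy[pre] - mean_pre).T)
        env = k_sigma * max(disp_pre.std(), 1e-9)
        disp_post = np.hypot(*(xy[post] - mean_pre).T)
        inside = disp_post <= env
        ok = np.array([inside[k:k + sustain_frames].all()
                       for k in range(len(inside) - sustain_frames + 1)])
        hits = np.flatnonzero(ok)
        out[i] = t_post[hits[0]] if hits.size else np.nan
    return out
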