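"""Correlation statistics: best-lag cross-correlation of neighboring cells
and of traces against the stimulus, PIV velocity fields, spatial correlation
length and the active-cell fraction.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import fftconvolve

from .errors import (BaselineWindowError, DegenerateFieldError,
                     EmptySummaryError, MnkitError,
                     UndefinedCorrelationError)
from .features import FeatureTraces
from .types import InputWaveform, VelocityField


@dataclass
class CorrelationSummary:
    """Population summary of best-lag cross-correlation coefficients."""

    pair_ids: list
    coefficients: np.ndarray      # signed, |c| <= 1
    best_lags: np.ndarray         # min
    mean: float
    sd: float
    max_lag: float                # min
    mode: str                     # "neighbor" | "vs_input"


@dataclass
class CorrelationLengthResult:
    """Azimuthally averaged spatial velocity autocorrelation."""

    separations: np.ndarray       # um, bin centers
    correlation_curve: np.ndarray
    length_1e: float              # um (nan when censored)
    censored: bool


# ---------------------------------------------------------------------------
# cross-correlation
# ---------------------------------------------------------------------------

def _lag_order(n_steps: int) -> list[int]:
    """Lag steps ordered by (|lag|, negative first): 0, -1, +1, -2, ..."""
    order = [0]
    for k in range(1, n_steps + 1):
        order.extend([-k, k])
    return order


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two (P, T) matrices."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((a * a).sum(axis=1) * (b * b).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, (a * b).sum(axis=1) / denom, np.nan)


def _best_lag_matrix(x: np.ndarray, y: np.ndarray, dt: float,
                     max_lag: float) -> tuple[np.ndarray, np.ndarray]:
    """Best-lag (max |Pearson|) coefficients for paired rows of x and y.

    A positive best lag means y is delayed relative to x.  Ties resolve to
    the smallest |lag|, then to the negative lag.
    """
    n_steps = int(round(max_lag / dt))
    t = x.shape[1]
    if t < 2 * n_steps + 8:
        raise MnkitError("traces too short for the requested max_lag")
    best_c = np.full(x.shape[0], np.nan)
    best_l = np.zeros(x.shape[0])
    for lag in _lag_order(n_steps):
        if lag >= 0:
            c = _pearson_rows(x[:, :t - lag or None], y[:, lag:])
        else:
            c = _pearson_rows(x[:, -lag:], y[:, :t + lag])
        take = np.isnan(best_c) | (np.abs(c) > np.abs(best_c))
        best_c = np.where(take, c, best_c)
        best_l = np.where(take, lag * dt, best_l)
    return best_c, best_l


def xcorr_coefficient(x: np.ndarray, y: np.ndarray, dt: float,
                      max_lag: float) -> tuple[float, float]:
    """Signed cross-correlation coefficient with maximal |value| over
    integer-step lags in [-max_lag, max_lag], and the lag achieving it."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise MnkitError("traces must have equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero-variance trace")
    c, lag = _best_lag_matrix(x[None, :], y[None, :], dt, max_lag)
    return float(c[0]), float(lag[0])


def neighbor_correlation(features: FeatureTraces,
                         adjacency: Sequence[tuple[int, int]],
                         dt: float, max_lag: float) -> CorrelationSummary:
    """Best-lag cross-correlation over all adjacent entity pairs."""
    index = {e: i for i, e in enumerate(features.entity_ids)}
    rows_i, rows_j, ids = [], [], []
    for a, b in adjacency:
        if a in index and b in index and features.valid[index[a]] \
                and features.valid[index[b]]:
            rows_i.append(index[a])
            rows_j.append(index[b])
            ids.append((a, b))
    if not ids:
        raise EmptySummaryError("no valid adjacent pairs")
    x = features.values[rows_i]
    y = features.values[rows_j]
    var_ok = (np.ptp(x, axis=1) > 0) & (np.ptp(y, axis=1) > 0)
    if not np.any(var_ok):
        raise EmptySummaryError("all pairs have zero-variance traces")
    c, lags = _best_lag_matrix(x[var_ok], y[var_ok], dt, max_lag)
    ids = [p for p, ok in zip(ids, var_ok) if ok]
    return CorrelationSummary(pair_ids=ids, coefficients=c, best_lags=lags,
                              mean=float(np.nanmean(c)),
                              sd=float(np.nanstd(c)),
                              max_lag=max_lag, mode="neighbor")


def input_correlation(features: FeatureTraces, input_wf: InputWaveform,
                      max_lag: float) -> CorrelationSummary:
    """Best-lag cross-correlation of each entity's trace vs the stimulus."""
    dt = input_wf.dt
    u = np.asarray(input_wf.values, dtype=float)
    if np.ptp(u) == 0:
        raise UndefinedCorrelationError("constant stimulus")
    rows = features.values[features.valid]
    ids = [e for e, v in zip(features.entity_ids, features.valid) if v]
    if not ids:
        raise EmptySummaryError("no valid entities")
    var_ok = np.ptp(rows, axis=1) > 0
    if not np.any(var_ok):
        raise EmptySummaryError("all traces constant")
    x = rows[var_ok]
    y = np.broadcast_to(u, x.shape)
    c, lags = _best_lag_matrix(x, y, dt, max_lag)
    ids = [e for e, ok in zip(ids, var_ok) if ok]
    return CorrelationSummary(pair_ids=ids, coefficients=c, best_lags=lags,
                              mean=float(np.nanmean(c)),
                              sd=float(np.nanstd(c)),
                              max_lag=max_lag, mode="vs_input")


# ---------------------------------------------------------------------------
# PIV
# ---------------------------------------------------------------------------

def _fill_invalid(vectors: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Replace invalid vectors by the mean of their valid 8-neighbors
    (iterated until filled; falls back to the global valid mean)."""
    out = vectors.copy()
    if valid.all() or not valid.any():
        return out
    global_mean = vectors[valid].mean(axis=0)
    todo = ~valid
    for _ in range(out.shape[0] * out.shape[1]):
        if not todo.any():
            break
        filled_any = False
        for iy, ix in zip(*np.nonzero(todo)):
            ys = slice(max(iy - 1, 0), iy + 2)
            xs = slice(max(ix - 1, 0), ix + 2)
            nb_valid = ~todo[ys, xs]
            nb_valid[min(iy, 1), min(ix, 1)] = False
            if nb_valid.any():
                out[iy, ix] = out[ys, xs][nb_valid].mean(axis=0)
                todo[iy, ix] = False
                filled_any = True
        if not filled_any:
            out[todo] = global_mean
            break
    return out


def piv(frame_a: np.ndarray, frame_b: np.ndarray, window_size: float,
        overlap: float = 0.0, pixel_size: float = 1.0,
        dt: float = 1.0) -> VelocityField:
    """Windowed cross-correlation velocimetry between two frames.

    Each interrogation window's displacement is the argmax of the
    cross-correlation of the mean-removed windows; featureless windows are
    flagged invalid and interpolated from their neighbors.
    """
    if frame_a.shape != frame_b.shape:
        raise MnkitError("frames must have equal shape")
    win_px = max(int(round(window_size / pixel_size)), 4)
    step = max(int(round(win_px * (1.0 - overlap))), 1)
    ny = (frame_a.shape[0] - win_px) // step + 1
    nx = (frame_a.shape[1] - win_px) // step + 1
    if ny < 1 or nx < 1:
        raise DegenerateFieldError("frames smaller than one PIV window")
    vectors = np.zeros((ny, nx, 2))
    valid = np.zeros((ny, nx), dtype=bool)
    grid = np.zeros((ny, nx, 2))
    for iy in range(ny):
        for ix in range(nx):
            y0, x0 = iy * step, ix * step
            a = frame_a[y0:y0 + win_px, x0:x0 + win_px].astype(float)
            b = frame_b[y0:y0 + win_px, x0:x0 + win_px].astype(float)
            grid[iy, ix] = ((x0 + win_px / 2.0) * pixel_size,
                            (y0 + win_px / 2.0) * pixel_size)
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue
            corr = fftconvolve(b - b.mean(), (a - a.mean())[::-1, ::-1],
                               mode="full")
            peak = np.unravel_index(np.argmax(corr), corr.shape)
            shift = (np.array(peak) - (win_px - 1))[::-1]   # (dx, dy)
            vectors[iy, ix] = shift * pixel_size / dt
            valid[iy, ix] = True
    vectors = _fill_invalid(vectors, valid)
    return VelocityField(grid_xy=grid, vectors=vectors, frame_pair=(0, 1),
                         window_size=win_px * pixel_size, valid=valid)


def piv_from_tracks(positions: np.ndarray, displacements: np.ndarray,
                    chamber: tuple[float, float], window_size: float,
                    dt: float = 1.0) -> VelocityField:
    """Bin per-cell displacements onto a regular grid (track-mode PIV)."""
    w, h = chamber
    nx = max(int(w // window_size), 1)
    ny = max(int(h // window_size), 1)
    sums = np.zeros((ny, nx, 2))
    counts = np.zeros((ny, nx))
    for p, d in zip(positions, displacements):
        ix = min(int(p[0] // window_size), nx - 1)
        iy = min(int(p[1] // window_size), ny - 1)
        sums[iy, ix] += d
        counts[iy, ix] += 1
    valid = counts > 0
    vectors = np.zeros_like(sums)
    vectors[valid] = sums[valid] / counts[valid][:, None] / dt
    vectors = _fill_invalid(vectors, valid)
    xs = (np.arange(nx) + 0.5) * window_size
    ys = (np.arange(ny) + 0.5) * window_size
    gx, gy = np.meshgrid(xs, ys)
    return VelocityField(grid_xy=np.stack([gx, gy], axis=-1),
                         vectors=vectors, window_size=window_size,
                         valid=valid)


# ---------------------------------------------------------------------------
# spatial correlation length
# ---------------------------------------------------------------------------

def correlation_length(field: VelocityField, bin_width: float = 10.0
                       ) -> CorrelationLengthResult:
    """1/e decay length of the normalized spatial velocity autocorrelation
    C(r) = <v(x).v(x+r)> / <|v|^2>, azimuthally averaged."""
    v = field.vectors
    ny, nx = v.shape[:2]
    if ny < 3 or nx < 3:
        raise DegenerateFieldError("need at least 3x3 vectors")
    if np.allclose(v, 0):
        raise MnkitError("all-zero field: correlation undefined")
    spacing = field.spacing
    # unnormalized autocorrelation via FFT convolution, per displacement
    num = np.zeros((2 * ny - 1, 2 * nx - 1))
    for c in range(2):
        num += fftconvolve(v[:, :, c], v[::-1, ::-1, c], mode="full")
    counts = fftconvolve(np.ones((ny, nx)), np.ones((ny, nx)), mode="full")
    corr2d = num / counts
    dy = (np.arange(2 * ny - 1) - (ny - 1)) * spacing
    dx = (np.arange(2 * nx - 1) - (nx - 1)) * spacing
    r = np.hypot(*np.meshgrid(dx, dy))
    c0 = corr2d[ny - 1, nx - 1]
    bins = np.arange(0.0, r.max() + bin_width, bin_width)
    idx = np.digitize(r.ravel(), bins) - 1
    wts = counts.ravel()
    curve = np.full(len(bins) - 1, np.nan)
    centers = np.full(len(bins) - 1, np.nan)
    for b in range(len(bins) - 1):
        sel = idx == b
        if np.any(sel):
            # pair-count weighting; the abscissa is the weighted mean
            # separation within the bin (not the bin center), removing the
            # convexity bias of the azimuthal average
            curve[b] = np.average(corr2d.ravel()[sel],
                                  weights=wts[sel]) / c0
            centers[b] = np.average(r.ravel()[sel], weights=wts[sel])
    ok = ~np.isnan(curve)
    centers, curve = centers[ok], curve[ok]
    # first crossing below 1/e, linearly interpolated
    thresh = 1.0 / np.e
    below = np.flatnonzero(curve < thresh)
    if below.size == 0:
        return CorrelationLengthResult(centers, curve, np.nan, True)
    k = below[0]
    if k == 0:
        length = centers[0]
    else:
        x0, x1 = centers[k - 1], centers[k]
        y0, y1 = curve[k - 1], curve[k]
        length = x0 + (thresh - y0) * (x1 - x0) / (y1 - y0)
    return CorrelationLengthResult(centers, curve, float(length), False)


def flow_correlation_length(params, grid_spacing: float = 10.0,
                            seeds=range(10), bin_width: float = 10.0
                            ) -> float:
    """1/e correlation length of the generator's collective flow.

    The azimuthally averaged autocorrelation curves of the sampled fields
    are averaged pointwise across seeds before the 1/e crossing is read
    off; a single 400-um window holds only ~30 independent correlation
    patches at the monolayer's ~70-um correlation length, so per-field
    crossings fluctuate strongly while the mean curve is stable.
    """
    from .simulate import sample_flow_field
    curves, grids = [], []
    for s in seeds:
        field = sample_flow_field(params, grid_spacing, seed=int(s))
        res = correlation_length(field, bin_width)
        curves.append(res.correlation_curve)
        grids.append(res.separations)
    n = min(len(c) for c in curves)
    curve = np.mean([c[:n] for c in curves], axis=0)
    seps = np.mean([g[:n] for g in grids], axis=0)
    thresh = 1.0 / np.e
    below = np.flatnonzero(curve < thresh)
    if below.size == 0:
        return float("nan")
    k = below[0]
    if k == 0:
        return float(seps[0])
    x0, x1 = seps[k - 1], seps[k]
    y0, y1 = curve[k - 1], curve[k]
    return float(x0 + (thresh - y0) * (x1 - x0) / (y1 - y0))


# ---------------------------------------------------------------------------
# activation
# ---------------------------------------------------------------------------

def active_fraction(nfkb: np.ndarray, times: np.ndarray,
                    stimulus_start: float, baseline_window: float = 60.0,
                    k_sigma: float = 2.0) -> float:
    """Fraction of cells whose post-stimulus NF-kB maximum exceeds their own
    pre-stimulus baseline mean + k_sigma x baseline sd."""
    nfkb = np.atleast_2d(np.asarray(nfkb, dtype=float))
    pre = (times >= stimulus_start - baseline_window) & \
        (times < stimulus_start)
    post = times >= stimulus_start
    if not np.any(pre):
        raise BaselineWindowError("empty pre-stimulus baseline window")
    base_mean = nfkb[:, pre].mean(axis=1)
    base_sd = nfkb[:, pre].std(axis=1)
    peak = nfkb[:, post].max(axis=1)
    return float(np.mean(peak > base_mean + k_sigma * base_sd))
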