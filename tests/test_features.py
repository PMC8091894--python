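"""Morphometric feature extraction: triangle areas, NSF, Dl, junction
events and actin extension."""
import numpy as np
import pandas as pd
import pytest

import mnkit as mk
from mnkit import features as ft
from mnkit.errors import MnkitError, TriangulationError
from mnkit.simulate import make_input_waveform
from mnkit.types import CellTrack, MonolayerDataset, SimulationParams


def _static_dataset(positions, areas=None, n_t=128, dt=2.0,
                    area_fn=None, pos_fn=None):
    """Dataset built from explicit geometry for measurement tests."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    times = np.arange(n_t) * dt
    params = SimulationParams(dt=dt, duration=n_t * dt, density=0.0)
    wf = make_input_waveform(20, 0.25, 0.0, n_t * dt, dt)
    tracks = []
    for i in range(n):
        if pos_fn is not None:
            xy = pos_fn(i, times)
        else:
            xy = np.tile(positions[i], (n_t, 1))
        if area_fn is not None:
            a = area_fn(i, times)
        elif areas is not None:
            a = np.full(n_t, float(areas[i]))
        else:
            a = np.full(n_t, 150.0)
        tracks.append(CellTrack(cell_id=i, times=times, centroid_xy=xy,
                                nuclear_area=a,
                                nfkb_nuclear=np.ones(n_t)))
    from mnkit.simulate import delaunay_edges
    edges = delaunay_edges(positions) if n >= 3 else []
    return MonolayerDataset(tracks=tracks, params=params, input=wf,
                            neighbor_edges=edges, preset_name="icm_default")


# ---------------------------------------------------------------------------
# triangulation and triangle areas
# ---------------------------------------------------------------------------

class TestTriangulation:
    def test_three_points_one_triangle(self):
        ds = _static_dataset([(0, 0), (10, 0), (0, 10)])
        tri = ft.build_triangulation(ds)
        assert len(tri.triangles) == 1

    def test_unit_square_two_half_triangles(self):
        ds = _static_dataset([(0, 0), (1, 0), (1, 1), (0, 1)])
        tri = ft.build_triangulation(ds)
        assert len(tri.triangles) == 2
        areas = ft.triangle_areas(ds.positions()[:, 0, :], tri.triangles)
        assert np.allclose(np.sort(areas), [0.5, 0.5])

    def test_partition_sums_to_hull_area(self, icm20):
        tri = ft.build_triangulation(icm20)
        pts = icm20.positions()[:, 0, :]
        total = ft.triangle_areas(pts, tri.triangles).sum()
        assert total == pytest.approx(ft.hull_area(pts), rel=1e-6)

    def test_partition_holds_at_every_frame(self, icm20):
        tri = ft.build_triangulation(icm20)
        tt = ft.triangle_area_traces(icm20, tri, normalize=False)
        pos = icm20.positions()
        for frame in (0, 150, 299):
            hull = ft.hull_area(pos[:, frame, :])
            # frame-0 triangulation does not partition later frames'
            # hulls exactly (cells move), but stays within the jitter
            tol = 1e-6 if frame == 0 else 5e-2
            assert tt.values[:, frame].sum() == pytest.approx(hull,
                                                              rel=tol)

    def test_too_few_cells_raises(self):
        ds = _static_dataset([(0, 0), (1, 1)])
        with pytest.raises(TriangulationError):
            ft.build_triangulation(ds)

    def test_collinear_cells_raise(self):
        ds = _static_dataset([(0, 0), (1, 0), (2, 0), (3, 0)])
        with pytest.raises(TriangulationError):
            ft.build_triangulation(ds)


class TestTriangleAreaTraces:
    def test_static_cells_normalized_traces_are_one(self):
        ds = _static_dataset([(0, 0), (10, 0), (0, 10), (12, 12)])
        tt = ft.triangle_area_traces(ds, ft.build_triangulation(ds))
        assert np.allclose(tt.values, 1.0)

    def test_uniform_scaling_gives_squared_factor(self):
        base = np.array([(0.0, 0.0), (10.0, 0.0), (0.0, 10.0)])

        def pos_fn(i, times):
            s = 1.0 + 0.1 * np.sin(2 * np.pi * times / 60.0)
            return np.outer(s, base[i])

        ds = _static_dataset(base, pos_fn=pos_fn)
        tt = ft.triangle_area_traces(ds, ft.build_triangulation(ds),
                                     normalize=False)
        s = 1.0 + 0.1 * np.sin(2 * np.pi * ds.times / 60.0)
        assert np.allclose(tt.values[0], 50.0 * s ** 2)

    def test_normalized_row_means_are_one(self, icm20):
        tt = ft.triangle_area_traces(icm20, ft.build_triangulation(icm20))
        assert np.allclose(tt.values[tt.valid].mean(axis=1), 1.0,
                           atol=1e-9)


# ---------------------------------------------------------------------------
# nuclear shape fluctuation
# ---------------------------------------------------------------------------

class TestNSF:
    def test_constant_area_zero_amplitude(self):
        ds = _static_dataset([(0, 0), (10, 0), (0, 10)])
        amp = ft.nsf_amplitude(ft.nsf_traces(ds))
        assert np.all(amp == 0)

    def test_sinusoidal_area_amplitude(self):
        # period >> dt so the 3-point median filter barely clips the peaks
        def area_fn(i, times):
            return 200.0 * (1 + 0.1 * np.sin(2 * np.pi * times / 80.0))

        ds = _static_dataset([(0, 0), (10, 0), (0, 10)], area_fn=area_fn)
        amp = ft.nsf_amplitude(ft.nsf_traces(ds))
        assert amp == pytest.approx(0.1, abs=0.005)

    def test_amplitude_scale_invariant(self):
        def area_fn(i, times):
            return 100.0 * (1 + 0.08 * np.sin(2 * np.pi * times / 40.0))

        ds1 = _static_dataset([(0, 0), (10, 0), (0, 10)], area_fn=area_fn)
        ds2 = _static_dataset(
            [(0, 0), (10, 0), (0, 10)],
            area_fn=lambda i, t: 7.3 * area_fn(i, t))
        a1 = ft.nsf_amplitude(ft.nsf_traces(ds1))
        a2 = ft.nsf_amplitude(ft.nsf_traces(ds2))
        assert np.allclose(a1, a2, atol=1e-12)


# ---------------------------------------------------------------------------
# vibration deviation (Dl)
# ---------------------------------------------------------------------------

def brute_force_dl(xy, window_samples):
    """Direct nested-loop oracle: truncated centered moving average."""
    t = len(xy)
    h = window_samples // 2
    out = np.empty(t)
    for i in range(t):
        lo, hi = max(0, i - h), min(t, i + h + 1)
        out[i] = np.linalg.norm(xy[i] - xy[lo:hi].mean(axis=0))
    return out


class TestVibrationDeviation:
    def test_uniform_linear_motion_interior_zero(self):
        v = np.array([0.3, -0.2])

        def pos_fn(i, times):
            return np.outer(times, v) + i

        ds = _static_dataset([(0, 0), (50, 0), (0, 50)], pos_fn=pos_fn)
        dl = ft.vibration_deviation(ds, window=30.0)
        h = int(round(30.0 / ds.params.dt)) // 2
        interior = dl.values[:, h:-h]
        assert np.allclose(interior, 0.0, atol=1e-9)

    def test_streaming_equals_brute_force(self, rng):
        """Cumulative-sum implementation vs the nested-loop oracle on 50
        random trajectories, exact to 1e-9."""
        n_t, w = 200, 15
        for _ in range(50):
            xy = np.cumsum(rng.normal(size=(n_t, 2)), axis=0)
            avg = ft.moving_average_trajectory(xy, w)
            stream = np.hypot(*(xy - avg).T)
            assert np.allclose(stream, brute_force_dl(xy, w), atol=1e-9)

    def test_line_plus_sinusoid_attenuation(self):
        """Interior Dl of line + sinusoid equals the brute-force
        moving-average oracle applied to the same trajectory."""
        times = np.arange(256) * 2.0
        a, period = 1.5, 24.0
        xy = np.stack([0.1 * times + a * np.sin(2 * np.pi * times / period),
                       np.zeros_like(times)], axis=1)

        def pos_fn(i, t):
            return xy

        ds = _static_dataset([(0, 0), (50, 0), (0, 50)], n_t=256,
                             pos_fn=pos_fn)
        dl = ft.vibration_deviation(ds, window=30.0)
        oracle = brute_force_dl(xy, int(round(30.0 / 2.0)))
        assert np.allclose(dl.values[0], oracle, atol=1e-9)

    def test_nonnegative(self, icm20):
        dl = ft.vibration_deviation(icm20)
        assert np.all(dl.values >= 0)

    def test_window_too_short_raises(self, icm20):
        with pytest.raises(MnkitError):
            ft.vibration_deviation(icm20, window=4.0)


# ---------------------------------------------------------------------------
# junction events
# ---------------------------------------------------------------------------

class TestJunctionEvents:
    def test_constant_trace_zero_events(self):
        counts, mean, sd = ft.junction_event_count(np.ones((1, 100)))
        assert counts[0] == 0 and mean == 0

    def test_threshold_run_counting(self):
        trace = np.ones(120)
        for k, depth in zip((10, 40, 70), (0.15, 0.2, 0.18)):
            trace[k:k + 5] = 1 - depth          # three supra-threshold dips
        for k in (25, 95):
            trace[k:k + 5] = 1 - 0.05           # two sub-threshold dips
        counts, _, _ = ft.junction_event_count(trace[None, :])
        assert counts[0] == 3

    def test_scale_invariance(self, rng):
        trace = 1 + 0.2 * np.abs(np.sin(np.linspace(0, 7, 200)))
        c1, _, _ = ft.junction_event_count(trace[None, :])
        c2, _, _ = ft.junction_event_count(17.3 * trace[None, :])
        assert c1 == c2

    def test_nonpositive_trace_rejected(self):
        with pytest.raises(MnkitError):
            ft.junction_event_count(np.zeros((1, 50)))

    def test_generator_junction_rate_higher_when_entrained(self):
        ds20 = mk.simulate_preset("icm_default", period=20.0, seed=0)
        ds90 = mk.simulate_preset("icm_default", period=90.0, seed=0)
        _, m20, _ = ft.junction_event_count(ds20.junction_intensity)
        _, m90, _ = ft.junction_event_count(ds90.junction_intensity)
        assert m20 > m90


# ---------------------------------------------------------------------------
# actin extension
# ---------------------------------------------------------------------------

def _endpoint_table(trajectories):
    """trajectories: {filament_id: (xy_a(t), xy_b(t))} at times 0..n-1."""
    rows = []
    for fid, (a, b) in trajectories.items():
        for t, (pa, pb) in enumerate(zip(a, b)):
            rows.append((fid, "a", float(t), pa[0], pa[1]))
            rows.append((fid, "b", float(t), pb[0], pb[1]))
    return pd.DataFrame(rows, columns=["filament_id", "end", "t_min",
                                       "x_um", "y_um"])


class TestActinExtension:
    def test_static_endpoints_ratio_one(self):
        a = [(0, 0)] * 5
        b = [(10, 0)] * 5
        tr = ft.actin_extension(_endpoint_table({0: (a, b)}))
        assert np.allclose(tr.values, 1.0)

    def test_uniform_contraction_to_60_percent(self):
        scale = np.linspace(1.0, 0.6, 5)
        a = [(0, 0)] * 5
        b = [(10 * s, 0) for s in scale]
        tr = ft.actin_extension(_endpoint_table({0: (a, b)}))
        assert tr.values[0, -1] == pytest.approx(0.6)
        assert tr.values[0, 0] == pytest.approx(1.0)

    def test_zero_initial_length_excluded(self):
        good = ([(0, 0)] * 3, [(5, 0)] * 3)
        degenerate = ([(1, 1)] * 3, [(1, 1)] * 3)
        tr = ft.actin_extension(_endpoint_table({0: good, 1: degenerate}))
        assert tr.values.shape[0] == 1


# ---------------------------------------------------------------------------
# positional return dynamics
# ---------------------------------------------------------------------------

class TestReturnTimes:
    def test_never_displaced_cell_returns_immediately(self):
        ds = _static_dataset([(0, 0), (50, 0), (0, 50)])
        rt = ft.return_times(ds, pulse_onset=100.0)
        assert np.all(rt == 0)

    def test_kicked_cell_returns_after_excursion(self):
        times = np.arange(256) * 2.0
        rng = np.random.default_rng(8)
        noise = 0.05 * rng.normal(size=(3, 256))

        def pos_fn(i, t):
            bump = 5.0 * np.exp(-np.clip(t - 100, 0, None) / 10.0) \
                * (t >= 100)
            return np.stack([bump + noise[i], np.zeros_like(t)], axis=1)

        ds = _static_dataset([(0, 0), (50, 0), (0, 50)], n_t=256,
                             pos_fn=pos_fn)
        rt = ft.return_times(ds, pulse_onset=100.0)
        assert np.all(rt > 0)
        assert np.all(rt < 80)
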