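"""Generator contracts: waveform, placement, oscillator physics, mixing,
gating, determinism and preset calibration."""
import numpy as np
import pytest

import mnkit as mk
from mnkit.errors import (AmbiguousCalibrationWarning,
                          DensityInfeasibleError, MnkitError,
                          UnknownPresetError, UnresolvableWaveformError)
from mnkit.presets import preset_params
from mnkit.simulate import (_integrate_oscillator, make_input_waveform,
                            modehop_wave, place_cells, pulse_onsets,
                            simulate_monolayer)


# ---------------------------------------------------------------------------
# stimulus waveform
# ---------------------------------------------------------------------------

class TestInputWaveform:
    def test_zero_amplitude_is_identically_zero(self):
        wf = make_input_waveform(20, 0.25, 0.0, 600, 2)
        assert np.all(wf.values == 0)

    def test_pulse_onset_count(self):
        wf = make_input_waveform(20, 0.25, 10.0, 600, 2)
        assert len(pulse_onsets(wf)) == 30          # 600 / 20 cycles

    @pytest.mark.parametrize("period", [20, 60, 90])
    def test_stimulation_presets_accepted(self, period):
        wf = make_input_waveform(period, 0.25, 10.0, 600, 2)
        assert wf.period == period
        assert wf.values.max() == 10.0

    def test_unresolvable_period_rejected(self):
        with pytest.raises(UnresolvableWaveformError):
            make_input_waveform(3.0, 0.5, 1.0, 600, 2)

    def test_pulse_value_is_amplitude_during_duty(self):
        wf = make_input_waveform(20, 0.5, 5.0, 200, 2)
        phase = np.mod(wf.times, 20)
        assert np.all(wf.values[phase < 10] == 5.0)
        assert np.all(wf.values[phase >= 10] == 0.0)

    def test_delayed_start_keeps_baseline_silent(self):
        wf = make_input_waveform(20, 0.25, 5.0, 600, 2, start=60)
        assert np.all(wf.values[wf.times < 60] == 0)
        assert wf.values[wf.times >= 60].max() == 5.0


# ---------------------------------------------------------------------------
# cell placement
# ---------------------------------------------------------------------------

class TestPlacement:
    def test_zero_density_gives_empty_set(self):
        assert len(place_cells(0, (400, 400), 15, seed=0)) == 0

    def test_reference_density_cell_count(self):
        pts = place_cells(700, (400, 400), 15, seed=0)
        assert len(pts) == 112                      # 700 / mm^2 x 0.16 mm^2

    def test_min_separation_respected(self):
        pts = place_cells(700, (400, 400), 15, seed=5)
        from scipy.spatial.distance import pdist
        assert pdist(pts).min() >= 15.0

    def test_deterministic_given_seed(self):
        a = place_cells(500, (300, 300), 15, seed=7)
        b = place_cells(500, (300, 300), 15, seed=7)
        assert np.array_equal(a, b)

    def test_infeasible_packing_raises(self):
        with pytest.raises(DensityInfeasibleError):
            place_cells(5000, (200, 200), 30, seed=0,
                        max_tries_per_cell=50)


# ---------------------------------------------------------------------------
# oscillator physics
# ---------------------------------------------------------------------------

def analytic_gain(period, t_n=90.0, zeta=0.1):
    r = t_n / period
    return 1.0 / np.hypot(1 - r * r, 2 * zeta * r)


class TestOscillator:
    @pytest.mark.parametrize("period", [20.0, 60.0, 90.0])
    def test_steady_state_gain_matches_closed_form(self, period):
        """Driven damped oscillator amplitude vs the analytic resonance
        curve, within 5% at each drive period."""
        dt, t_n, zeta = 2.0, 90.0, 0.1
        omega0 = 2 * np.pi / t_n
        t = np.arange(0, 1800, dt)
        forcing = np.sin(2 * np.pi * t / period)
        x = _integrate_oscillator(forcing[None, :], dt, omega0, zeta)[0]
        tail = x[len(x) // 2:]
        amp = np.sqrt(2.0) * tail.std()
        expected = analytic_gain(period, t_n, zeta) / omega0 ** 2
        assert amp == pytest.approx(expected, rel=0.05)

    def test_resonance_peak_at_natural_period(self):
        amps = {p: analytic_gain(p) for p in (20, 60, 90)}
        assert max(amps, key=amps.get) == 90
        assert mk.oscillator_gain(90, 90, 0.1) == pytest.approx(5.0)


# ---------------------------------------------------------------------------
# mode-hopping drive
# ---------------------------------------------------------------------------

class TestModeHop:
    def test_unit_amplitude_and_zero_mean(self, rng):
        t = np.arange(0, 600, 2.0)
        w = modehop_wave(t, rng)
        assert np.abs(w).max() <= 1.6       # equal-impulse amp <= h_mean/h_f
        assert abs(w.mean()) < 0.08

    def test_rate_tracked_carrier_at_schedule_mean(self, rng):
        """With phase tracking the dominant period stays at
        1 / (p 1/20 + (1-p) 1/30) time-weighted = 26 min."""
        from mnkit.spectral import dominant_frequency
        t = np.arange(0, 1200, 2.0)
        w = modehop_wave(t, rng, rate_tracking=True)
        assert 1.0 / dominant_frequency(w, 2.0) == pytest.approx(26.0,
                                                                 abs=0.8)

    def test_untracked_copies_decorrelate(self):
        t = np.arange(0, 600, 2.0)
        r1, r2 = np.random.default_rng(1), np.random.default_rng(2)
        a = modehop_wave(t, r1, rate_tracking=False)
        b = modehop_wave(t, r2, rate_tracking=False)
        assert abs(np.corrcoef(a, b)[0, 1]) < 0.45


# ---------------------------------------------------------------------------
# the simulation
# ---------------------------------------------------------------------------

NULL_OVERRIDES = dict(chem_gain=0.0, mech_gain=0.0, act_gain=0.0,
                      nsf_rel_amplitude=0.0, tri_amp=0.0, vib_amp=0.0,
                      drift_speed=0.0, position_noise_sd=0.0,
                      area_noise_sd=0.0, nfkb_noise_sd=0.0,
                      nfkb_basal_amp=0.0, junction_noise_sd=0.0,
                      junction_rate_base=0.0, junction_rate_active=0.0)


class TestSimulation:
    def test_null_dynamics_every_trace_constant(self):
        ds = mk.simulate_preset("icm_default", period=20.0, seed=0,
                                **NULL_OVERRIDES)
        for tr in ds.tracks:
            assert np.ptp(tr.nuclear_area) == 0
            assert np.ptp(tr.nfkb_nuclear) == 0
            assert np.ptp(tr.centroid_xy[:, 0]) == 0
            assert np.ptp(tr.centroid_xy[:, 1]) == 0

    def test_seed_determinism_bitwise(self):
        a = mk.simulate_preset("icm_default", period=20.0, seed=11)
        b = mk.simulate_preset("icm_default", period=20.0, seed=11)
        assert np.array_equal(a.positions(), b.positions())
        assert np.array_equal(a.areas(), b.areas())
        assert np.array_equal(a.nfkb(), b.nfkb())
        assert a.neighbor_edges == b.neighbor_edges
        for k in a.junction_intensity:
            assert np.array_equal(a.junction_intensity[k],
                                  b.junction_intensity[k])

    def test_different_seeds_differ(self):
        a = mk.simulate_preset("icm_default", period=20.0, seed=1)
        b = mk.simulate_preset("icm_default", period=20.0, seed=2)
        assert not np.array_equal(a.nfkb(), b.nfkb())

    def test_entrainment_gating_outside_window(self):
        """Stimulation at 60 min (outside [18, 22]) leaves nuclear area at
        the noise floor: with area noise disabled the traces are constant."""
        ds = mk.simulate_preset("icm_default", period=60.0, seed=0,
                                area_noise_sd=0.0, with_junctions=False)
        assert np.ptp(ds.areas(), axis=1).max() == 0

    def test_entrainment_engages_inside_window(self):
        ds = mk.simulate_preset("icm_default", period=20.0, seed=0,
                                area_noise_sd=0.0, with_junctions=False)
        rel = np.ptp(ds.areas(), axis=1) / ds.areas().mean(axis=1)
        assert np.median(rel) > 0.05

    def test_unknown_preset_raises(self):
        params = preset_params("icm_default")
        wf = make_input_waveform(20, 0.25, 10, params.duration, params.dt)
        with pytest.raises(UnknownPresetError):
            simulate_monolayer(params, wf, "no_such_preset")

    def test_misaligned_waveform_rejected(self):
        params = preset_params("icm_default")
        wf = make_input_waveform(20, 0.25, 10, 300, 2)
        with pytest.raises(MnkitError):
            simulate_monolayer(params, wf, "icm_default")

    def test_dataset_shape_contracts(self, icm20):
        assert icm20.n_cells == 112
        ids = set(icm20.cell_ids)
        for a, b in icm20.neighbor_edges:
            assert a != b and a in ids and b in ids
        assert np.all(icm20.areas() > 0)


# ---------------------------------------------------------------------------
# common-mode mixing closed form
# ---------------------------------------------------------------------------

class TestCommonModeMixing:
    @pytest.mark.parametrize("c,expected", [
        (0.0, 0.0),
        (1.0 / 3.0, 0.2),
        (0.45, 0.45 ** 2 / (0.45 ** 2 + 0.55 ** 2)),
        (1.0, 1.0),
    ])
    def test_pairwise_correlation_matches_closed_form(self, c, expected):
        """x_i = c F + (1-c) G_i with iid components gives pairwise
        correlation c^2 / (c^2 + (1-c)^2)."""
        rng = np.random.default_rng(42)
        n_cells, n_t = 30, 4000
        common = rng.normal(size=n_t)
        traces = c * common + (1 - c) * rng.normal(size=(n_cells, n_t))
        cors = []
        for i in range(n_cells):
            for j in range(i + 1, n_cells):
                cors.append(np.corrcoef(traces[i], traces[j])[0, 1])
        assert np.mean(cors) == pytest.approx(expected, abs=0.03)


# ---------------------------------------------------------------------------
# preset calibration
# ---------------------------------------------------------------------------

class TestCalibratePreset:
    def test_inverts_mixing_closed_form(self):
        grid = np.round(np.arange(0.05, 0.96, 0.05), 2).tolist() + [1 / 3]
        best = mk.calibrate_preset(
            0.2, "c", sorted(grid),
            lambda c: c ** 2 / (c ** 2 + (1 - c) ** 2))
        assert best == pytest.approx(1 / 3, abs=1e-9)

    def test_mode_frequency_calibration(self):
        """Count-weighted mean mode frequency p/20 + (1-p)/30 = 1/26
        inverts to p ~ 0.31."""
        grid = np.linspace(0.0, 1.0, 201)
        best = mk.calibrate_preset(1 / 26, "p20", grid,
                                   lambda p: p / 20 + (1 - p) / 30)
        assert best == pytest.approx(0.3077, abs=0.01)

    def test_exact_grid_point_returned(self):
        best = mk.calibrate_preset(4.0, "k", [1, 2, 3, 4, 5],
                                   lambda v: float(v))
        assert best == 4.0

    def test_non_monotone_warns_but_returns_argmin(self):
        with pytest.warns(AmbiguousCalibrationWarning):
            best = mk.calibrate_preset(0.9, "k", [0, 1, 2, 3],
                                       lambda v: (v - 2) ** 2)
        assert best in (1.0, 3.0)
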