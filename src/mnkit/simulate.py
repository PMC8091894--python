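"""Mechanically coupled stochastic oscillator model of a fibroblast monolayer.

The generator emulates the statistical structure of live-imaging data from a
confluent fibroblast sheet (an interconnected cell monolayer, ICM) under
periodic TNF-alpha stimulation:

* a shared mode-hopping mechanical oscillation (alternating ~20- and ~30-min
  half-cycles) drives collective nuclear-shape fluctuation (NSF) and, through
  a damped driven linear oscillator, entrains nuclear NF-kB dynamics;
* the mechano channel is gated by an entrainment window on the stimulus
  period (the RAC1 rule): only stimulation near a 20-min period converts the
  chemical input into intracellular mechanical cues;
* stimulus pulses trigger transient collective displacement "kicks" that
  relax back within ~20-30 min (the contractile deformation of the sheet);
* a slow coherent local spreading/contraction mode (~35-min period) makes
  Delaunay triangle areas fluctuate in a weakly correlated way at every
  input period;
* collective flow is a Gaussian-kernel-smoothed random vector field whose
  spatial autocorrelation has a closed-form 1/e length of twice the kernel
  width.

Every channel mixes a shared ("common-mode") component with an independent
per-cell copy; the mixing fractions set the pairwise correlations that the
measurement pipeline recovers.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import Delaunay
from scipy.signal import cont2discrete

from .errors import (AmbiguousCalibrationWarning, DegenerateFieldError,
                     DensityInfeasibleError, MnkitError,
                     UnresolvableWaveformError)
from .presets import preset_flags, preset_params
from .types import CellTrack, InputWaveform, MonolayerDataset, SimulationParams


# ---------------------------------------------------------------------------
# stimulus waveform
# ---------------------------------------------------------------------------

def make_input_waveform(period: float, duty_fraction: float, amplitude: float,
                        duration: float, dt: float,
                        start: float = 0.0) -> InputWaveform:
    """Square-pulse TNF-alpha train: pulse onset at t=0 of each cycle.

    ``start`` delays the whole train (concentration 0 before it), providing
    the pre-stimulus baseline used by activation statistics.
    """
    if period < 2 * dt:
        raise UnresolvableWaveformError(
            f"period {period} min not resolvable at dt={dt} min")
    if not 0.0 < duty_fraction <= 1.0:
        raise MnkitError("duty_fraction must lie in (0, 1]")
    times = np.arange(int(round(duration / dt))) * dt
    phase = np.mod(times - start, period)
    values = np.where((times >= start) & (phase < duty_fraction * period),
                      float(amplitude), 0.0)
    return InputWaveform(times=times, values=values, period=float(period),
                         duty_fraction=float(duty_fraction),
                         amplitude=float(amplitude), start=float(start))


def single_pulse_waveform(onset: float, width: float, amplitude: float,
                          duration: float, dt: float) -> InputWaveform:
    """A single TNF-alpha pulse (used for return-dynamics experiments)."""
    times = np.arange(int(round(duration / dt))) * dt
    values = np.where((times >= onset) & (times < onset + width),
                      float(amplitude), 0.0)
    return InputWaveform(times=times, values=values, period=float(duration),
                         duty_fraction=width / duration,
                         amplitude=float(amplitude), start=float(onset))


def pulse_onsets(input_wf: InputWaveform) -> np.ndarray:
    """Times at which the stimulus concentration rises from zero."""
    v = input_wf.values
    rising = (v[1:] > 0) & (v[:-1] == 0)
    onsets = input_wf.times[1:][rising]
    if len(v) and v[0] > 0:
        onsets = np.concatenate([[input_wf.times[0]], onsets])
    return onsets


# ---------------------------------------------------------------------------
# cell placement
# ---------------------------------------------------------------------------

def place_cells(density: float, chamber: tuple[float, float],
                min_separation: float = 15.0,
                seed: int | np.random.Generator = 0,
                max_tries_per_cell: int = 400) -> np.ndarray:
    """Poisson-disk-style placement of ``round(density x area)`` cells.

    Uniform random proposals are rejected when closer than
    ``min_separation`` to an accepted point.
    """
    if density < 0 or min_separation < 0:
        raise MnkitError("density and min_separation must be non-negative")
    w, h = chamber
    count = int(round(density * (w * h) / 1e6))   # density is per mm^2
    if count and min_separation > 0:
        # random sequential adsorption of hard discs jams near 54.7%
        # coverage; beyond ~60% the request cannot succeed — fail fast
        coverage = count * np.pi * (min_separation / 2.0) ** 2 / (w * h)
        if coverage > 0.6:
            raise DensityInfeasibleError(
                f"{count} cells at min_separation={min_separation} um "
                f"needs disc coverage {coverage:.2f} > jamming limit")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    pts: list[np.ndarray] = []
    accepted = np.empty((0, 2))
    tries = 0
    budget = max_tries_per_cell * max(count, 1)
    while len(pts) < count:
        if tries >= budget:
            raise DensityInfeasibleError(
                f"placed {len(pts)}/{count} cells after {tries} proposals at "
                f"min_separation={min_separation} um")
        p = rng.uniform((0.0, 0.0), (w, h))
        tries += 1
        if len(pts) == 0 or np.min(
                np.hypot(accepted[:, 0] - p[0], accepted[:, 1] - p[1])
        ) >= min_separation:
            pts.append(p)
            accepted = np.asarray(pts)
    return accepted.reshape(count, 2)


def delaunay_edges(positions: np.ndarray) -> list[tuple[int, int]]:
    """Symmetric, irreflexive Delaunay neighbor relation (a < b pairs)."""
    if len(positions) < 3:
        return []
    try:
        tri = Delaunay(positions)
    except Exception:
        return []
    edges = set()
    for simplex in tri.simplices:
        for i in range(3):
            a, b = int(simplex[i]), int(simplex[(i + 1) % 3])
            edges.add((min(a, b), max(a, b)))
    return sorted(edges)


# ---------------------------------------------------------------------------
# oscillation primitives
# ---------------------------------------------------------------------------

def _halfcycle_phase(times: np.ndarray, halves: np.ndarray,
                     phase0: float) -> np.ndarray:
    """Phase (rad) advancing by pi per half-cycle of the given durations."""
    edges = np.concatenate([[0.0], np.cumsum(halves)])
    phases = phase0 + np.pi * np.arange(len(edges))
    return np.interp(times, edges, phases)


def modehop_wave(times: np.ndarray, rng: np.random.Generator,
                 periods: tuple[float, float] = (20.0, 30.0),
                 p_fast: float = 0.4, phase0: float | None = None,
                 rate_tracking: bool = True,
                 tracking_gain: float = 0.08) -> np.ndarray:
    """Unit-amplitude oscillation hopping between two periods.

    Successive half-cycles take the duration of the fast period with
    probability ``p_fast`` (else the slow one).  With ``rate_tracking`` the
    draw probability is modulated by the accumulated time deficit so the
    long-run carrier frequency stays pinned at the schedule mean
    ``1 / (p_fast*T_fast + (1-p_fast)*T_slow)``; without it the phase
    performs a random walk and the wave decorrelates from any other copy —
    that is the regime used for the independent per-cell components.
    """
    hf, hs = periods[0] / 2.0, periods[1] / 2.0
    h_mean = p_fast * hf + (1 - p_fast) * hs
    total = float(times[-1]) if len(times) else 0.0
    halves = []
    elapsed = 0.0
    while elapsed <= total + hs:
        p = p_fast
        if rate_tracking:
            deficit = elapsed - h_mean * len(halves)   # >0: running slow
            p = float(np.clip(p_fast + tracking_gain * deficit, 0.02, 0.98))
        h = hf if rng.random() < p else hs
        halves.append(h)
        elapsed += h
    halves_arr = np.asarray(halves)
    if phase0 is None:
        phase0 = rng.uniform(0.0, 2 * np.pi)
    wave = np.sin(_halfcycle_phase(times, halves_arr, phase0))
    # equal-impulse half-cycles: amplitude ~ 1/duration, so alternating
    # half-cycles of unequal length carry no net low-frequency bias
    edges = np.concatenate([[0.0], np.cumsum(halves_arr)])
    idx = np.clip(np.searchsorted(edges, times, side="right") - 1,
                  0, len(halves_arr) - 1)
    return (h_mean / halves_arr[idx]) * wave


def band_wave(times: np.ndarray, rng: np.random.Generator,
              period_band: tuple[float, float] = (30.0, 40.0),
              phase0: float | None = None) -> np.ndarray:
    """Narrowband oscillation: half-cycle periods drawn uniformly in a band."""
    lo, hi = period_band
    total = float(times[-1]) if len(times) else 0.0
    halves = []
    elapsed = 0.0
    while elapsed <= total + hi / 2:
        h = rng.uniform(lo / 2.0, hi / 2.0)
        halves.append(h)
        elapsed += h
    if phase0 is None:
        phase0 = rng.uniform(0.0, 2 * np.pi)
    return np.sin(_halfcycle_phase(times, np.asarray(halves), phase0))


def relax_kernel(times: np.ndarray, tau_ret: float) -> np.ndarray:
    """Gamma-shaped rise-and-relax response, peak-normalized to 1.

    Shape-2 gamma with scale ``tau_ret/2``: rises over ~tau_ret/2, relaxes
    so the response has decayed to <10% of its peak by ~2.5 tau_ret.
    """
    theta = tau_ret / 2.0
    t = np.maximum(times, 0.0)
    return (t / theta) * np.exp(1.0 - t / theta)


def oscillator_gain(drive_period: float, natural_period: float,
                    damping_ratio: float) -> float:
    """Steady-state amplitude gain of x'' + 2 zeta w0 x' + w0^2 x = F sin(wt).

    Returned relative to the static gain 1/w0^2, i.e.
    ``1 / sqrt((1-r^2)^2 + (2 zeta r)^2)`` with ``r = w/w0``.
    """
    r = natural_period / drive_period
    return 1.0 / np.hypot(1.0 - r * r, 2.0 * damping_ratio * r)


def _integrate_oscillator(forcing: np.ndarray, dt: float, omega0: float,
                          zeta: float) -> np.ndarray:
    """Zero-state response of the damped oscillator to per-cell forcing.

    ``forcing`` has shape (n_cells, T); ZOH discretization is exact for the
    piecewise-constant stimulus and accurate to <2% for the sampled
    oscillatory drives (>=10 samples per cycle).
    """
    a = np.array([[0.0, 1.0], [-omega0 ** 2, -2.0 * zeta * omega0]])
    b = np.array([[0.0], [1.0]])
    ad, bd, *_ = cont2discrete((a, b, np.eye(2), np.zeros((2, 1))), dt)
    n_cells, n_t = forcing.shape
    x = np.zeros((2, n_cells))
    out = np.empty((n_cells, n_t))
    for k in range(n_t):
        out[:, k] = x[0]
        x = ad @ x + bd @ forcing[None, :, k]
    return out


def mech_forcing_filter(m: np.ndarray, dt: float,
                        cutoff_period: float = 50.0,
                        order: int = 3) -> np.ndarray:
    """Zero-phase high-pass applied to the mechanical drive before it forces
    the NF-kB oscillator.

    Mechano-transduction of nuclear shuttling is rate-sensitive: slow or
    static mechanical bias does not pump NF-kB.  Removing the (small)
    sub-1/50 min^-1 content of the mode-hopping drive keeps the resonant
    oscillator from amplifying spectral leakage at its 90-min natural
    period, which would otherwise mask the entrained ~1/26 min^-1 response.
    """
    from scipy.signal import butter, filtfilt
    if np.allclose(m, 0):
        return m
    b, a = butter(order, (1.0 / cutoff_period) / (0.5 / dt), "highpass")
    return filtfilt(b, a, m, axis=-1)


def _ou_noise(rng: np.random.Generator, shape: tuple[int, int], dt: float,
              tau: float, sd: float) -> np.ndarray:
    """Ornstein-Uhlenbeck noise with stationary sd and correlation time tau."""
    n, t = shape
    rho = np.exp(-dt / tau)
    innov_sd = sd * np.sqrt(1.0 - rho * rho)
    out = np.empty((n, t))
    out[:, 0] = rng.normal(0.0, sd, n)
    eps = rng.normal(0.0, innov_sd, (n, t))
    for k in range(1, t):
        out[:, k] = rho * out[:, k - 1] + eps[:, k]
    return out


# ---------------------------------------------------------------------------
# the monolayer simulation
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    return np.divide(v, n, out=np.zeros_like(v), where=n > 1e-12)


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    ang = rng.uniform(0, 2 * np.pi, n)
    return np.stack([np.cos(ang), np.sin(ang)], axis=1)


def mech_channel_active(params: SimulationParams, input_wf: InputWaveform,
                        preset_name: str) -> bool:
    """RAC1 gating rule: mechano channel on iff the preset is ICM-like and
    the stimulus period lies inside the entrainment window."""
    flags = preset_flags(preset_name)
    lo, hi = params.entrainment_window
    return bool(flags["mech_enabled"] and input_wf.amplitude > 0
                and lo <= input_wf.period <= hi)


def simulate_monolayer(params: SimulationParams, input_wf: InputWaveform,
                       preset_name: str = "icm_default",
                       with_junctions: bool = True,
                       external_mech: np.ndarray | None = None
                       ) -> MonolayerDataset:
    """Simulate a monolayer dataset; bitwise deterministic given the seed.

    ``external_mech`` (shape (T,)) imposes a mechanical drive on every cell
    directly, bypassing the entrainment-window gating — the on-chip
    experiment in which cytoskeletal deformation is induced by substrate
    stretching rather than by the monolayer's own feedback loop.
    """
    flags = preset_flags(preset_name)      # raises UnknownPresetError
    times = params.times
    n_t = len(times)
    if len(input_wf.times) != n_t or abs(input_wf.dt - params.dt) > 1e-9:
        raise MnkitError("input waveform not aligned with params dt/duration")

    ss = np.random.SeedSequence(params.seed)
    (s_place, s_common, s_cells, s_events, s_noise,
     s_junction) = [np.random.default_rng(c) for c in ss.spawn(6)]

    positions0 = place_cells(params.density, params.chamber,
                             params.min_separation, seed=s_place)
    n = len(positions0)
    edges = delaunay_edges(positions0)

    dose = input_wf.amplitude
    mech_on = mech_channel_active(params, input_wf, preset_name)
    mech_dose = dose / (dose + params.mech_dose_k_half) if dose > 0 else 0.0

    # --- shared (common-mode) processes -----------------------------------
    m_common = modehop_wave(times, s_common, params.modehop_periods,
                            params.modehop_p_fast, rate_tracking=True)
    tri_common = band_wave(times, s_common, params.tri_period_band)

    # --- per-cell mechanical drive m_i ------------------------------------
    if external_mech is not None:
        if len(external_mech) != n_t:
            raise MnkitError("external_mech must match the time grid")
        m = np.broadcast_to(np.asarray(external_mech, dtype=float),
                            (n, n_t)).copy()
        mech_on = True
    elif mech_on:
        eta = np.stack([
            modehop_wave(times, s_cells, params.modehop_periods,
                         params.modehop_p_fast, rate_tracking=False)
            for _ in range(n)])
        # the RAC1-mediated transition to dynamic cell-cell connections
        # establishes over ~mech_ramp_tau of periodic stimulation; the slow
        # onset avoids shock-exciting the NF-kB natural resonance
        ramp = 1.0 - np.exp(-np.maximum(times - input_wf.start, 0.0)
                            / max(params.mech_ramp_tau, 1e-9))
        m = (params.c_nsf * m_common[None, :]
             + (1.0 - params.c_nsf) * eta) * mech_dose * ramp[None, :]
    else:
        m = np.zeros((n, n_t))

    # --- region labels ----------------------------------------------------
    w, h = params.chamber
    margin = params.margin_width
    marginal = ((positions0[:, 0] < margin) | (positions0[:, 0] > w - margin)
                | (positions0[:, 1] < margin) | (positions0[:, 1] > h - margin))

    # --- nuclear area (NSF channel) ---------------------------------------
    a0 = np.clip(s_cells.normal(params.nuclear_area_mean,
                                params.nuclear_area_sd, n), 60.0, None)
    boost = np.where(marginal, 1.0 + params.marginal_boost, 1.0)
    area = a0[:, None] * (1.0 - params.nsf_rel_amplitude
                          * boost[:, None] * m)
    area = area + a0[:, None] * params.area_noise_sd * s_noise.normal(
        size=(n, n_t))
    area = np.clip(area, 30.0, None)

    # --- NF-kB channel ----------------------------------------------------
    omega0 = 2.0 * np.pi / params.natural_period_nfkb
    gamma = np.exp(s_cells.normal(-params.response_gain_sigma ** 2 / 2.0,
                                  params.response_gain_sigma, n))
    m_forcing = mech_forcing_filter(m, params.dt) if mech_on else m
    forcing = gamma[:, None] * (params.chem_gain * input_wf.values[None, :]
                                + params.mech_gain * m_forcing)
    x = _integrate_oscillator(forcing, params.dt, omega0,
                              params.damping_ratio)
    # slow activation envelope: low-passed stimulus, saturating in dose
    env = np.zeros(n_t)
    if dose > 0:
        rho = np.exp(-params.dt / params.act_tau)
        u_norm = input_wf.values / dose
        for k in range(1, n_t):
            env[k] = rho * env[k - 1] + (1 - rho) * u_norm[k]
        env *= params.act_gain * dose / (dose + params.act_k_half)
    act = gamma[:, None] * env[None, :]
    nfkb_noise = _ou_noise(s_noise, (n, n_t), params.dt,
                           params.nfkb_noise_tau, params.nfkb_noise_sd)
    # basal nucleus-cytoplasm shuttling: a bounded per-cell oscillation that
    # sets the pre-stimulus variability of nuclear NF-kB
    basal_phase = s_cells.uniform(0, 2 * np.pi, n)
    # saturated (quasi-square) waveform: its peak-to-rms ratio ~1.2 keeps
    # the baseline-plus-2-sigma activation statistic from firing on the
    # basal oscillation itself
    basal = params.nfkb_basal_amp * np.tanh(2.0 * np.sin(
        2 * np.pi * times[None, :] / params.nfkb_basal_period
        + basal_phase[:, None])) / np.tanh(2.0)
    nfkb = np.clip(params.nfkb_baseline + basal + act + x + nfkb_noise,
                   0.0, None)

    # --- centroid channel -------------------------------------------------
    # directed slow drift
    ang = s_cells.uniform(0, 2 * np.pi, n)
    drift_dir = np.stack([np.cos(ang), np.sin(ang)], axis=1)
    drift = params.drift_speed * drift_dir[:, None, :] * times[None, :, None]

    # triangle-area channel: coherent breathing of the sheet (global
    # dilation about the chamber center — Delaunay areas partition the
    # hull, so only boundary-moving modes change them coherently) mixed
    # with independent per-cell jitter at the same ~35-min timescale
    # The common mode is a breathing deformation of the actin sheet driven
    # by one shared ~35-min oscillation E(t): a weak uniform dilation about
    # the chamber center (net expansion/contraction, which survives in the
    # population-mean triangle-area trace) superposed with a long-wavelength
    # longitudinal wave (locally coherent divergence of useful amplitude at
    # bounded, sub-um displacement).  Displacements stay small enough not to
    # contaminate the Dl (trajectory-deviation) channel.
    center = np.array([w / 2.0, h / 2.0])
    radial = positions0 - center
    r_scale = max(np.mean(np.hypot(*radial.T)), 1e-9)
    k_hat = _random_unit_vectors(s_common, 1)[0]
    psi = s_common.uniform(0, 2 * np.pi)
    wave_phase = (2 * np.pi * (positions0 @ k_hat) / params.tri_wavelength
                  + psi)
    wf_ = params.tri_wave_fraction
    profile = ((1.0 - wf_) * radial / r_scale
               + wf_ * np.sin(wave_phase)[:, None] * k_hat[None, :])
    tri_indep = np.stack([band_wave(times, s_cells, params.tri_period_band)
                          for _ in range(n)])
    indep_dirs = _random_unit_vectors(s_cells, n)
    tri_disp = (params.c_tri * params.tri_amp
                * tri_common[None, :, None] * profile[:, None, :]
                + (1.0 - params.c_tri) * params.tri_amp
                * tri_indep[:, :, None] * indep_dirs[:, None, :])

    # stimulus-triggered collective kicks (vibration channel)
    vib_disp = np.zeros((n, n_t, 2))
    if dose > 0 and params.vib_amp > 0:
        onsets = pulse_onsets(input_wf)
        kern_t = np.arange(0.0, 6.0 * params.return_tau, params.dt)
        kern = relax_kernel(kern_t, params.return_tau)
        lk = len(kern)
        mag_mu = -0.125                         # lognormal(mu, 0.5): mean ~1
        for t_k in onsets:
            k0 = int(round(t_k / params.dt))
            sl = slice(k0, min(k0 + lk, n_t))
            kk = kern[:sl.stop - sl.start]
            # shared component: one direction and magnitude for all cells;
            # every pulse elicits some collective contraction (lognormal
            # magnitude), while individual cells participate intermittently
            ang_k = s_events.uniform(0, 2 * np.pi)
            d_shared = np.array([np.cos(ang_k), np.sin(ang_k)])
            a_shared = s_events.lognormal(-0.045, 0.3)
            # independent per-cell components
            ang_i = s_events.uniform(0, 2 * np.pi, n)
            d_i = np.stack([np.cos(ang_i), np.sin(ang_i)], axis=1)
            a_i = (s_events.random(n) < params.vib_participation) * \
                s_events.lognormal(mag_mu, 0.5, n) / params.vib_participation
            amp = (params.c_vib * a_shared * d_shared[None, :]
                   + (1.0 - params.c_vib) * a_i[:, None] * d_i)
            vib_disp[:, sl, :] += (params.vib_amp * mech_dose
                                   * amp[:, None, :] * kk[None, :, None])
    pos_noise = params.position_noise_sd * s_noise.normal(size=(n, n_t, 2))
    centroid = (positions0[:, None, :] + drift + tri_disp + vib_disp
                + pos_noise)

    # --- junction traces --------------------------------------------------
    junction: dict[tuple[int, int], np.ndarray] = {}
    if with_junctions and flags.get("junctions", True):
        rate = (params.junction_rate_active if mech_on
                else params.junction_rate_base)
        if not flags.get("junction_dynamic", True):
            rate = min(rate, params.junction_rate_base / 2.0)
        for e in edges:
            trace = np.ones(n_t)
            n_ev = s_junction.poisson(rate * params.duration / 60.0)
            for _ in range(n_ev):
                t0 = s_junction.uniform(0, params.duration)
                depth = s_junction.uniform(*params.junction_event_depth)
                width = s_junction.uniform(*params.junction_event_width)
                trace -= depth * np.exp(-0.5 * ((times - t0)
                                                / (width / 4.0)) ** 2)
            trace += params.junction_noise_sd * s_junction.normal(size=n_t)
            junction[e] = np.clip(trace, 0.05, None)

    tracks = [CellTrack(cell_id=i, times=times, centroid_xy=centroid[i],
                        nuclear_area=area[i], nfkb_nuclear=nfkb[i],
                        region_label="marginal" if marginal[i]
                        else "interior")
              for i in range(n)]
    return MonolayerDataset(tracks=tracks, params=params, input=input_wf,
                            neighbor_edges=edges, preset_name=preset_name,
                            seed=params.seed, junction_intensity=junction)


def simulate_preset(preset_name: str, period: float = 20.0,
                    duty_fraction: float = 0.25, amplitude: float = 10.0,
                    seed: int = 0, start: float = 0.0,
                    with_junctions: bool = True,
                    **param_overrides) -> MonolayerDataset:
    """Convenience wrapper: preset parameters + waveform + simulation."""
    params = preset_params(preset_name, seed=seed, **param_overrides)
    wf = make_input_waveform(period, duty_fraction, amplitude,
                             params.duration, params.dt, start=start)
    return simulate_monolayer(params, wf, preset_name,
                              with_junctions=with_junctions)


# ---------------------------------------------------------------------------
# preset calibration
# ---------------------------------------------------------------------------

def calibrate_preset(target_statistic: float, parameter_name: str,
                     search_grid, evaluator) -> float:
    """Brute-force calibration: grid value whose statistic is nearest target.

    ``evaluator`` maps a parameter value to the emergent statistic and is
    expected to be monotone on the grid; if it is not, an
    AmbiguousCalibrationWarning is issued and the argmin is still returned.
    Ties resolve to the smaller parameter value.
    """
    grid = np.asarray(list(search_grid), dtype=float)
    if grid.size == 0:
        raise MnkitError("empty calibration grid")
    stats = np.array([evaluator(v) for v in grid])
    diffs = np.diff(stats)
    if len(diffs) and not (np.all(diffs >= 0) or np.all(diffs <= 0)):
        warnings.warn(
            f"evaluator for {parameter_name!r} is not monotone on the grid",
            AmbiguousCalibrationWarning)
    err = np.abs(stats - target_statistic)
    best = int(np.argmin(err))        # argmin takes the first (smaller) tie
    return float(grid[best])


# ---------------------------------------------------------------------------
# collective flow field
# ---------------------------------------------------------------------------

def sample_flow_field(params: SimulationParams, grid_spacing: float,
                      seed: int | np.random.Generator = 0):
    """Spatially correlated random velocity field of the actin layer.

    White-noise vectors smoothed with an isotropic Gaussian kernel of width
    ``flow_kernel_sigma``; the normalized spatial autocorrelation of such a
    field is exp(-r^2 / (4 sigma^2)), so the 1/e correlation length is
    exactly 2 sigma.  Periodic smoothing keeps the field stationary.
    """
    from scipy.ndimage import gaussian_filter
    from .types import VelocityField

    if grid_spacing <= 0:
        raise MnkitError("grid_spacing must be positive")
    w, h = params.chamber
    nx = int(round(w / grid_spacing))
    ny = int(round(h / grid_spacing))
    if nx < 3 or ny < 3:
        raise DegenerateFieldError("flow grid smaller than 3x3")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    sigma_px = params.flow_kernel_sigma / grid_spacing
    # synthesize on a padded domain and crop, so the returned field is a
    # stationary sample of the Gaussian-kernel process without periodic or
    # edge artifacts
    pad = int(np.ceil(4 * sigma_px))
    vec = rng.normal(size=(ny + 2 * pad, nx + 2 * pad, 2))
    if sigma_px > 0:
        for c in range(2):
            vec[:, :, c] = gaussian_filter(vec[:, :, c], sigma_px,
                                           mode="constant")
    vec = vec[pad:pad + ny, pad:pad + nx]
    rms = np.sqrt(np.mean(np.sum(vec ** 2, axis=2)))
    if rms > 0:
        vec *= params.flow_speed_scale / rms
    xs = (np.arange(nx) + 0.5) * grid_spacing
    ys = (np.arange(ny) + 0.5) * grid_spacing
    gx, gy = np.meshgrid(xs, ys)
    return VelocityField(grid_xy=np.stack([gx, gy], axis=-1), vectors=vec,
                         frame_pair=(0, 1), window_size=grid_spacing)
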