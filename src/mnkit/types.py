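"""Core domain types: simulation parameters, stimulus waveform, cell tracks.

Units are minutes (time), micrometres (length), cells/mm^2 (density) and
arbitrary fluorescence units (a.u.) throughout.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional

import numpy as np

from .errors import MnkitError


@dataclass
class SimulationParams:
    """Parameters of the mechanically coupled stochastic oscillator model.

    The model couples three per-cell channels — nuclear area (NSF), nuclear
    NF-kB level and centroid position — through a shared mechanical drive
    that is active only when the stimulus period falls inside the
    entrainment window (the RAC1 gating rule) and the preset represents a
    mechanically coupled monolayer.
    """

    # sampling / geometry
    dt: float = 2.0                      # min
    duration: float = 600.0              # min
    density: float = 700.0               # cells / mm^2
    chamber: tuple[float, float] = (400.0, 400.0)   # um x um
    min_separation: float = 15.0         # um, nuclear packing constraint

    # NF-kB oscillator
    natural_period_nfkb: float = 90.0    # min, T_N
    damping_ratio: float = 0.1           # zeta, dimensionless
    chem_gain: float = 6e-5              # beta_c, forcing per (ng/mL)
    mech_gain: float = 0.02              # beta_m, forcing per unit mech drive
    nfkb_baseline: float = 1.0           # a.u.
    response_gain_sigma: float = 0.9     # lognormal sd of per-cell gain
    act_gain: float = 0.12               # slow activation-envelope gain
    act_tau: float = 30.0                # min, activation low-pass timescale
    act_k_half: float = 0.1              # ng/mL, activation dose half-saturation
    mech_dose_k_half: float = 1.0        # ng/mL, mechano-channel dose half-sat.

    # mechano channel (NSF drive)
    entrainment_window: tuple[float, float] = (18.0, 22.0)  # min
    modehop_periods: tuple[float, float] = (20.0, 30.0)     # min (fast, slow)
    modehop_p_fast: float = 0.4          # probability of the fast half-cycle
    nsf_rel_amplitude: float = 0.06      # relative nuclear-area modulation
    mech_ramp_tau: float = 60.0          # min, entrainment build-up time

    # common-mode fractions per feature channel (c_tri / c_vib pinned by
    # the pipeline-level calibration described in docs/methods.md)
    c_tri: float = 0.6
    c_vib: float = 0.68
    c_nsf: float = 0.7

    # triangle-area (local spreading) channel
    tri_period_band: tuple[float, float] = (30.0, 40.0)  # min, half-cycle draw
    tri_amp: float = 1.2                 # um, breathing/jitter amplitude
    tri_wavelength: float = 250.0        # um, longitudinal wave length
    tri_wave_fraction: float = 0.5       # wave vs uniform-dilation weight

    # vibration (stimulus-kick) channel
    vib_amp: float = 2.5                 # um, kick displacement scale
    vib_participation: float = 0.5       # per-event response probability
    return_tau: float = 8.0              # min, tau_ret of the relax kernel
    drift_speed: float = 0.001           # um/min, directed slow drift

    # collective flow field
    flow_kernel_sigma: float = 35.0      # um, sigma_v (1/e length = 2 sigma_v)
    flow_speed_scale: float = 0.15       # um/min rms

    # noise (per channel, per frame)
    position_noise_sd: float = 0.15      # um
    area_noise_sd: float = 0.015         # relative to A0
    nfkb_noise_sd: float = 0.004         # a.u.
    nfkb_noise_tau: float = 10.0         # min, OU correlation time
    nfkb_basal_amp: float = 0.03         # a.u., basal shuttling oscillation
    nfkb_basal_period: float = 40.0      # min
    junction_noise_sd: float = 0.02      # a.u.

    # nuclear geometry
    nuclear_area_mean: float = 180.0     # um^2
    nuclear_area_sd: float = 20.0        # um^2

    # junction events
    junction_rate_base: float = 0.2      # events / edge / h, mechano inactive
    junction_rate_active: float = 1.0    # events / edge / h, mechano active
    junction_event_depth: tuple[float, float] = (0.12, 0.35)  # relative drop
    junction_event_width: tuple[float, float] = (6.0, 16.0)   # min

    marginal_boost: float = 0.0          # optional NSF boost of marginal cells
    margin_width: float = 40.0           # um, marginal-region depth

    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise MnkitError("dt must be positive")
        if self.duration / self.dt < 64:
            raise MnkitError("duration/dt must be at least 64 samples")
        for name in ("c_tri", "c_vib", "c_nsf", "vib_participation",
                     "modehop_p_fast"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise MnkitError(f"{name} must lie in [0, 1], got {v}")
        lo, hi = self.entrainment_window
        if not lo < hi:
            raise MnkitError("entrainment_window must satisfy lo < hi")
        pf, ps = self.modehop_periods
        if pf <= 0 or ps <= 0 or pf == ps:
            raise MnkitError("modehop_periods must be positive and distinct")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    def to_dict(self) -> dict:
        return asdict(self)

    def with_overrides(self, **kw) -> "SimulationParams":
        return replace(self, **kw)


@dataclass
class InputWaveform:
    """Periodic TNF-alpha stimulus u(t): a square pulse train."""

    times: np.ndarray        # min
    values: np.ndarray       # ng/mL
    period: float            # min
    duty_fraction: float
    amplitude: float         # ng/mL
    start: float = 0.0       # min, stimulus onset (0 before)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise MnkitError("times and values must have equal length")
        if np.any(self.values < 0):
            raise MnkitError("stimulus concentrations must be non-negative")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class CellTrack:
    """One cell's sampled time series."""

    cell_id: int
    times: np.ndarray                     # min, strictly increasing, step dt
    centroid_xy: np.ndarray               # (T, 2) um
    nuclear_area: np.ndarray              # (T,) um^2, > 0
    nfkb_nuclear: np.ndarray              # (T,) a.u.
    region_label: str = "interior"        # "marginal" | "interior"
    interpolated: Optional[np.ndarray] = None   # (T,) bool, gap-filled frames

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if len(t) >= 2:
            steps = np.diff(t)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
                raise MnkitError("track times must increase with constant step")
        if np.any(np.asarray(self.nuclear_area) <= 0):
            raise MnkitError("nuclear_area must be positive everywhere")
        n = len(t)
        if len(self.centroid_xy) != n or len(self.nuclear_area) != n \
                or len(self.nfkb_nuclear) != n:
            raise MnkitError("all trace lengths must match times")


@dataclass
class MonolayerDataset:
    """A simulated (or reconstructed) population of cell tracks.

    ``neighbor_edges`` is the symmetric, irreflexive Delaunay neighbor
    relation on frame-0 centroids.  ``junction_intensity`` maps each edge
    (a, b) with a < b to a per-frame actin fluorescence trace at that
    cell-cell connection.
    """

    tracks: list[CellTrack]
    params: SimulationParams
    input: InputWaveform
    neighbor_edges: list[tuple[int, int]]
    preset_name: str = "icm_default"
    seed: int = 0
    junction_intensity: dict[tuple[int, int], np.ndarray] = field(
        default_factory=dict)

    def __post_init__(self) -> None:
        ids = {t.cell_id for t in self.tracks}
        for a, b in self.neighbor_edges:
            if a == b:
                raise MnkitError("neighbor relation must be irreflexive")
            if a not in ids or b not in ids:
                raise MnkitError(f"edge ({a},{b}) references unknown cell")

    # -- convenience array views -------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.tracks)

    @property
    def times(self) -> np.ndarray:
        return self.tracks[0].times if self.tracks else self.params.times

    @property
    def cell_ids(self) -> np.ndarray:
        return np.array([t.cell_id for t in self.tracks])

    def positions(self) -> np.ndarray:
        """Centroid positions, shape (n_cells, T, 2) um."""
        if not self.tracks:
            return np.empty((0, len(self.times), 2))
        return np.stack([t.centroid_xy for t in self.tracks])

    def areas(self) -> np.ndarray:
        """Nuclear areas, shape (n_cells, T) um^2."""
        if not self.tracks:
            return np.empty((0, len(self.times)))
        return np.stack([t.nuclear_area for t in self.tracks])

    def nfkb(self) -> np.ndarray:
        """Nuclear NF-kB levels, shape (n_cells, T) a.u."""
        if not self.tracks:
            return np.empty((0, len(self.times)))
        return np.stack([t.nfkb_nuclear for t in self.tracks])


@dataclass
class VelocityField:
    """Velocity vectors on a regular spatial grid (PIV output or synthetic
    flow sample)."""

    grid_xy: np.ndarray          # (ny, nx, 2) um
    vectors: np.ndarray          # (ny, nx, 2) um/min
    frame_pair: tuple[int, int] = (0, 1)
    window_size: float = 0.0     # um
    valid: Optional[np.ndarray] = None   # (ny, nx) bool

    @property
    def spacing(self) -> float:
        g = self.grid_xy
        if g.shape[1] >= 2:
            return float(g[0, 1, 0] - g[0, 0, 0])
        return float(g[1, 0, 1] - g[0, 0, 1])
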