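"""End-to-end experiment orchestration: condition sweeps, the
phase-mismatch sweep and the drug-perturbation panel, with machine-readable
per-condition reports.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from . import correlation as co
from . import features as ft
from . import spectral as sp
from .errors import MnkitError
from .presets import available_presets, preset_params
from .simulate import make_input_waveform, simulate_monolayer
from .types import MonolayerDataset


@dataclass
class PipelineConfig:
    """Configuration of a sweep: conditions x analysis parameters."""

    preset_names: list[str] = field(default_factory=lambda: ["icm_default"])
    periods: list[float] = field(default_factory=lambda: [20.0, 60.0, 90.0])
    duty_fraction: float = 0.25
    amplitude: float = 10.0              # ng/mL
    stimulus_start: float = 0.0          # min
    seeds: list[int] = field(default_factory=lambda: [0, 1, 2, 3, 4])
    max_lag: float | None = None         # min; None -> half the input period
    nsf_band: tuple[float, float] = (1.0 / 35.0, 1.0 / 18.0)   # min^-1
    baseline_window: float = 60.0        # min
    k_sigma: float = 2.0
    dl_window: float = 30.0              # min
    param_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.preset_names) - set(available_presets())
        if unknown:
            raise MnkitError(f"unknown presets: {sorted(unknown)}")
        if not self.seeds:
            raise MnkitError("need at least one seed")

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PhaseSweepSpec:
    """Phase offsets between the induced mechanical forcing and the
    chemical input; Dt = Dphi * period_mech / (2 pi), referenced to the
    mechanical forcing period."""

    period: float = 20.0                     # min (chem and mech)
    phase_offsets: tuple = (0.0, np.pi / 3, 2 * np.pi / 3)
    mech_amplitude: float | None = None      # None -> matched to chem

    def __post_init__(self) -> None:
        for dphi in self.phase_offsets:
            if not 0.0 <= dphi < 2 * np.pi:
                raise MnkitError("phase offsets must lie in [0, 2 pi)")

    def dt_offsets(self) -> list[float]:
        return [dphi * self.period / (2 * np.pi)
                for dphi in self.phase_offsets]


# ---------------------------------------------------------------------------
# per-condition analysis
# ---------------------------------------------------------------------------

def analyze_dataset(dataset: MonolayerDataset, config: PipelineConfig
                    ) -> dict:
    """All figure-level statistics of one simulated condition."""
    dt = dataset.params.dt
    period = dataset.input.period
    max_lag = config.max_lag if config.max_lag is not None else period / 2.0
    out: dict = {}

    nsf = ft.nsf_traces(dataset)
    out["nsf_amplitude_mean"] = float(np.mean(ft.nsf_amplitude(nsf)))
    out["nsf_dominant_frequency"] = sp.spectral_summary(
        nsf, dt).population_dominant_frequency
    s = co.neighbor_correlation(nsf, dataset.neighbor_edges, dt, max_lag)
    out["nsf_neighbor_corr"] = {"mean": s.mean, "sd": s.sd}

    nf = dataset.nfkb()
    norm = nf / nf.mean(axis=1, keepdims=True)
    nft = ft.FeatureTraces("cell_area", list(dataset.cell_ids),
                           dataset.times, norm, normalized=True,
                           normalization_mode="time_mean")
    out["nfkb_dominant_frequency"] = sp.spectral_summary(
        nft, dt).population_dominant_frequency
    band = (1.0 / (1.3 * period), min(1.0 / (0.77 * period), 0.5 / dt))
    out["nfkb_amplitude_at_input"] = sp.oscillation_amplitude(
        norm.mean(axis=0), dt, band)
    s = co.neighbor_correlation(nft, dataset.neighbor_edges, dt, max_lag)
    out["nfkb_neighbor_corr"] = {"mean": s.mean, "sd": s.sd}

    tri = ft.build_triangulation(dataset)
    tt = ft.triangle_area_traces(dataset, tri)
    s = co.neighbor_correlation(tt, tri.adjacent_pairs, dt,
                                min(max_lag, 10.0))
    out["triangle_neighbor_corr"] = {"mean": s.mean, "sd": s.sd}
    out["triangle_dominant_frequency"] = sp.spectral_summary(
        tt, dt).population_dominant_frequency

    dl = ft.vibration_deviation(dataset, window=config.dl_window)
    s = co.neighbor_correlation(dl, dataset.neighbor_edges, dt,
                                min(max_lag, 10.0))
    out["dl_neighbor_corr"] = {"mean": s.mean, "sd": s.sd}
    if dataset.input.amplitude > 0:
        s = co.input_correlation(dl, dataset.input, min(max_lag, 10.0))
        out["dl_input_corr"] = {"mean": s.mean, "sd": s.sd}
        out["dl_dominant_frequency"] = sp.spectral_summary(
            dl, dt).population_dominant_frequency
    if dataset.input.start > 0:
        out["active_fraction"] = co.active_fraction(
            nf, dataset.times, dataset.input.start,
            config.baseline_window, config.k_sigma)
    if dataset.junction_intensity:
        _, mean, sd = ft.junction_event_count(dataset.junction_intensity)
        out["junction_events_per_edge"] = {"mean": mean, "sd": sd}
    return out


def _aggregate(per_seed: list[dict]) -> dict:
    """Mean +/- sd across seeds for every numeric leaf."""
    out = {}
    for key in per_seed[0]:
        vals = [r[key] for r in per_seed]
        if isinstance(vals[0], dict):
            means = [v["mean"] for v in vals]
            out[key] = {"mean": float(np.mean(means)),
                        "sd": float(np.std(means))}
        else:
            out[key] = {"mean": float(np.mean(vals)),
                        "sd": float(np.std(vals))}
    return out


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

def validate_report(report: dict) -> None:
    """Structural check applied before a report is written: every
    successful condition names its preset, period and seed list, and all
    aggregated metrics are finite numbers."""
    if "conditions" not in report:
        raise MnkitError("report missing 'conditions'")
    for key, cond in report["conditions"].items():
        if "failed" in cond:
            continue
        for field_ in ("preset", "period_min", "seeds", "metrics"):
            if field_ not in cond:
                raise MnkitError(f"condition {key!r} missing {field_!r}")
        for name, stat in cond["metrics"].items():
            if not (np.isfinite(stat["mean"]) and np.isfinite(stat["sd"])):
                raise MnkitError(f"non-finite metric {name!r} in {key!r}")


def run_condition_sweep(config: PipelineConfig) -> dict:
    """Simulate -> features -> spectra -> correlations for every
    (preset x period x seed); failures are recorded per condition and the
    sweep continues."""
    report = {"config_digest": config.digest(), "conditions": {}}
    for preset in config.preset_names:
        for period in config.periods:
            key = f"{preset}@{period:g}min"
            per_seed = []
            try:
                for seed in config.seeds:
                    params = preset_params(preset, seed=seed,
                                           **config.param_overrides)
                    wf = make_input_waveform(
                        period, config.duty_fraction, config.amplitude,
                        params.duration, params.dt,
                        start=config.stimulus_start)
                    ds = simulate_monolayer(params, wf, preset)
                    per_seed.append(analyze_dataset(ds, config))
                report["conditions"][key] = {
                    "preset": preset, "period_min": period,
                    "seeds": list(config.seeds),
                    "metrics": _aggregate(per_seed)}
            except Exception as exc:   # noqa: BLE001 - sweep must continue
                report["conditions"][key] = {
                    "preset": preset, "period_min": period,
                    "failed": f"{type(exc).__name__}: {exc}"}
    validate_report(report)
    return report


def run_phase_sweep(spec: PhaseSweepSpec, config: PipelineConfig | None
                    = None) -> dict:
    """Stand-alone cells with externally imposed mechanical forcing
    phase-shifted by each Dphi relative to the chemical input.

    The mechanical sinusoid is matched in effective forcing amplitude to
    the fundamental of the chemical pulse train (and sampled at midpoints
    to compensate the zero-order-hold phase lag), so in the linear regime
    the response amplitude follows the two-phasor form
    |F_c + F_m e^{-i Dphi}| ~ |cos(Dphi/2)|.  The slow activation envelope
    is disabled here to isolate the oscillatory pathway.
    """
    from .types import SimulationParams

    config = config or PipelineConfig()
    period = spec.period
    report = {"period_min": period, "phase_offsets": list(spec.phase_offsets),
              "dt_offsets_min": spec.dt_offsets(), "amplitudes": {}}
    omega = 2 * np.pi / period

    def _mean_trace(ds):
        nf = ds.nfkb()
        return (nf / nf.mean(axis=1, keepdims=True)).mean(axis=0)

    def _demod(trace, times):
        x = trace - trace.mean()
        return np.sum(x * np.exp(-1j * omega * times))

    for seed in config.seeds:
        # the SA preset zeroes mech_gain (no intrinsic mechano channel);
        # restore the default coupling so the externally imposed forcing
        # can reach the oscillator
        overrides = {"mech_gain": SimulationParams().mech_gain,
                     **config.param_overrides}
        params = preset_params("sa_default", seed=seed, act_gain=0.0,
                               **overrides)
        wf = make_input_waveform(period, config.duty_fraction,
                                 config.amplitude, params.duration,
                                 params.dt)
        t_mid = params.times + params.dt / 2.0     # zero-order-hold midpoint
        # calibration runs: chemical-only and mechanical-only response
        # phasors at the drive frequency, so the imposed forcing can be
        # matched in amplitude and aligned in phase (Dphi = 0 means the
        # mechanical response phasor coincides with the chemical one)
        ds_c = simulate_monolayer(params, wf, "sa_default",
                                  with_junctions=False,
                                  external_mech=np.zeros(params.n_samples))
        z_c = _demod(_mean_trace(ds_c), params.times)
        params_m = params.with_overrides(chem_gain=0.0)
        probe = np.cos(omega * t_mid)
        ds_m = simulate_monolayer(params_m, wf, "sa_default",
                                  with_junctions=False, external_mech=probe)
        z_m = _demod(_mean_trace(ds_m), params.times)
        if spec.mech_amplitude is None:
            mech_amp = abs(z_c) / abs(z_m) if abs(z_m) > 0 else 0.0
        else:
            mech_amp = spec.mech_amplitude
        phase0 = np.angle(z_m) - np.angle(z_c)
        amps = []
        for dphi in spec.phase_offsets:
            m_ext = mech_amp * np.cos(omega * t_mid - phase0 - dphi)
            ds = simulate_monolayer(params, wf, "sa_default",
                                    with_junctions=False,
                                    external_mech=m_ext)
            band = (1.0 / (1.3 * period),
                    min(1.0 / (0.77 * period), 0.5 / params.dt))
            amps.append(sp.oscillation_amplitude(_mean_trace(ds),
                                                 params.dt, band))
        report["amplitudes"][f"seed{seed}"] = amps
    arr = np.array(list(report["amplitudes"].values()))
    report["amplitude_mean"] = arr.mean(axis=0).tolist()
    report["amplitude_sd"] = arr.std(axis=0).tolist()
    return report


def run_perturbation_panel(config: PipelineConfig | None = None,
                           drugs: list[str] | None = None) -> dict:
    """ICM at 20- and 90-min inputs under each drug preset; NSF and NF-kB
    neighbor correlations reported relative to the untreated ICM."""
    config = config or PipelineConfig()
    drugs = drugs if drugs is not None else [
        "rock_inhibitor", "cytochalasin", "blebbistatin", "ml141", "jasp",
        "ecad_antibody", "nocodazole"]
    base = PipelineConfig(preset_names=["icm_default"] + list(drugs),
                          periods=[20.0, 90.0], seeds=config.seeds,
                          duty_fraction=config.duty_fraction,
                          amplitude=config.amplitude,
                          param_overrides=config.param_overrides)
    sweep = run_condition_sweep(base)
    report = {"config_digest": base.digest(), "relative": {}}
    for period in (20.0, 90.0):
        ref = sweep["conditions"][f"icm_default@{period:g}min"]
        if "failed" in ref:
            continue
        ref_nsf = ref["metrics"]["nsf_neighbor_corr"]["mean"]
        ref_nf = ref["metrics"]["nfkb_neighbor_corr"]["mean"]
        for preset in ["icm_default"] + list(drugs):
            cond = sweep["conditions"][f"{preset}@{period:g}min"]
            if "failed" in cond:
                report["relative"][f"{preset}@{period:g}min"] = cond
                continue
            m = cond["metrics"]
            report["relative"][f"{preset}@{period:g}min"] = {
                "nsf_corr_rel": (m["nsf_neighbor_corr"]["mean"] / ref_nsf
                                 if ref_nsf else float("nan")),
                "nfkb_corr_rel": (m["nfkb_neighbor_corr"]["mean"] / ref_nf
                                  if ref_nf else float("nan")),
            }
    report["sweep"] = sweep
    return report
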