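"""Condition presets: monolayer vs stand-alone cells and drug perturbations.

Each preset is a set of coupling switches and parameter overrides applied on
top of the default :class:`~mnkit.types.SimulationParams`:

* ``icm_default`` — confluent interconnected monolayer (ICM): all coupling
  channels on, mechano channel gated by the entrainment window.
* ``sa_default`` — stand-alone cells: identical geometry and single-cell
  dynamics but no cell-cell coupling (all common-mode fractions zero, no
  mechano channel, higher migratory drift).
* drug presets — coupling switches emulating the perturbation panel:
  actin-contractility and cell-cell-connection drugs remove the mechano
  channel and the corresponding common modes; the microtubule drug
  (nocodazole) changes nothing.

``c_tri``/``c_vib`` defaults (in SimulationParams) were pinned with the
package's own calibration routine so that the measured adjacent-triangle and
neighbor-Dl correlations land on their target values of 0.2 and 0.4 (see
docs/methods.md).
"""
from __future__ import annotations

import json
from dataclasses import asdict

from .errors import UnknownPresetError
from .types import SimulationParams

# flags: mech_enabled  -> mechano (NSF) channel may engage inside the
#                         entrainment window
#        junction_dynamic -> TNF can raise the junction-event rate
_PRESETS: dict[str, dict] = {
    "icm_default": {
        "flags": {"mech_enabled": True, "junction_dynamic": True},
        "params": {},
    },
    "icm_low_noise": {   # diagnostic preset for closed-form checks
        "flags": {"mech_enabled": True, "junction_dynamic": True},
        "params": {"position_noise_sd": 0.0, "area_noise_sd": 0.0,
                   "nfkb_noise_sd": 0.0, "drift_speed": 0.0},
    },
    "sa_default": {
        "flags": {"mech_enabled": False, "junction_dynamic": False},
        "params": {"c_tri": 0.0, "c_vib": 0.0, "c_nsf": 0.0,
                   "mech_gain": 0.0, "drift_speed": 0.08},
    },
    # --- drug perturbations on the ICM ------------------------------------
    # ROCK inhibition removes contractility-driven NSF coupling but leaves
    # the collective movement of the actin layer intact.
    "rock_inhibitor": {
        "flags": {"mech_enabled": False, "junction_dynamic": True},
        "params": {"c_nsf": 0.0, "mech_gain": 0.0},
    },
    # actin depolymerization / myosin or Cdc42 block: NSF coupling and the
    # collective movement are both lost.
    "cytochalasin": {
        "flags": {"mech_enabled": False, "junction_dynamic": True},
        "params": {"c_nsf": 0.0, "mech_gain": 0.0, "c_vib": 0.0,
                   "c_tri": 0.0, "flow_kernel_sigma": 10.0},
    },
    "blebbistatin": {
        "flags": {"mech_enabled": False, "junction_dynamic": True},
        "params": {"c_nsf": 0.0, "mech_gain": 0.0, "c_vib": 0.0,
                   "c_tri": 0.0, "flow_kernel_sigma": 10.0},
    },
    "ml141": {
        "flags": {"mech_enabled": False, "junction_dynamic": True},
        "params": {"c_nsf": 0.0, "mech_gain": 0.0, "c_vib": 0.0,
                   "c_tri": 0.0, "flow_kernel_sigma": 10.0},
    },
    # JASP stabilizes connections; E-cadherin antibody removes them: either
    # way the on-off process of cell-cell contacts — and with it the mechano
    # channel and junction events — is suppressed.
    "jasp": {
        "flags": {"mech_enabled": False, "junction_dynamic": False},
        "params": {"c_nsf": 0.0, "mech_gain": 0.0},
    },
    "ecad_antibody": {
        "flags": {"mech_enabled": False, "junction_dynamic": False},
        "params": {"c_nsf": 0.0, "mech_gain": 0.0, "c_vib": 0.0,
                   "c_tri": 0.0, "flow_kernel_sigma": 10.0},
    },
    # microtubule depolymerization: no effect on the collective responses
    "nocodazole": {
        "flags": {"mech_enabled": True, "junction_dynamic": True},
        "params": {},
    },
}

#: TNF-alpha concentration of the low-dose stimulation preset (ng/mL)
LOW_DOSE_AMPLITUDE = 0.08


def available_presets() -> list[str]:
    return sorted(_PRESETS)


def _lookup(name: str) -> dict:
    try:
        return _PRESETS[name]
    except KeyError:
        raise UnknownPresetError(
            f"unknown preset {name!r}; available: {available_presets()}"
        ) from None


def preset_flags(name: str) -> dict:
    return dict(_lookup(name)["flags"])


def preset_params(name: str, **overrides) -> SimulationParams:
    """SimulationParams for a preset, with optional field overrides."""
    kw = dict(_lookup(name)["params"])
    kw.update(overrides)
    return SimulationParams(**kw)


def registry_to_json(path) -> None:
    """Write the full preset registry (every parameter field) to JSON."""
    out = {}
    for name, entry in _PRESETS.items():
        params = SimulationParams(**entry["params"])
        out[name] = {"flags": entry["flags"], "params": asdict(params)}
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2)


def register_preset(name: str, flags: dict, params: dict) -> None:
    """Add or replace a preset (e.g. loaded from a user JSON config)."""
    SimulationParams(**params)   # validate
    _PRESETS[name] = {"flags": dict(flags), "params": dict(params)}
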