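"""Run configuration: YAML parsing, defaults, fail-closed validation.

Configuration is a nested key-value document (YAML).  Unknown keys are
rejected with the offending key named (fail-closed), defaults are filled
in, and every run writes the fully resolved config — seeds included — next
to its outputs so it can be re-run bit-identically.

Units: mm, MPa throughout.  The wall base thickness default of 0.5 mm is
an assumption (the specimens' wall thickness was not reported) and is
deliberately exposed here.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import yaml

from .geometry import HelixSpec, ThinPatchSpec, TubeSpec
from .growth import PRESSURE_RANGES_MPA, PressureProtocol
from .materials import DamagePlasticParams, PolymerParams
from .scenarios import SCENARIO_NAMES, ScenarioPreset, _POLYMERS, _snap_patch, build_model

__all__ = ["DEFAULTS", "RunConfig", "load_config"]

DEFAULTS: dict = {
    "scenario": "control",
    "seed": 0,
    "mesh": {"n_axial": 80, "n_circ": 40},
    "geometry": {
        "inner_diameter": 5.0,
        "length": 60.0,
        "base_thickness": 0.5,  # assumed; not reported for the specimens
    },
    "patch": {
        "enabled": True,
        "axial_center": None,  # None -> mid-span, snapped to an element center
        "circ_center": 0.0,
        "axial_halfwidth": 6.0,
        "circ_halfwidth": 1.2,
        "min_thickness": 0.06,
        "transition": 1.0,
    },
    "noise": {"amplitude": 0.02, "corr_length": 5.0},
    "bio": {"E0": 1.0, "eps_y": 0.6, "floor": 0.1, "PE_ref": 0.0055, "nu": 0.45},
    "helix": {
        "pitch": None,  # None -> polymer default (2.25 PVDF / 2.15 PCL)
        "thread_diameter": None,
        "n_layers": 2,
        "phase": 0.0,
        "handedness": 1,
    },
    "polymer": {"E": None, "nu": 0.35},  # E None -> 458 PVDF / 321 PCL
    "pressure": {
        "range": "normo",
        "p_min": None,  # explicit MPa values override the named range
        "p_max": None,
        "n_cycles": 150,
        "unload_target": "zero",
    },
    "solver": {"tol": 1.0e-9, "max_iter": 50, "clamped_length": 5.0},
    "ring": {"pin_diameter": 2.0},
    "output": {"dir": "runs"},
}


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in user.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ValueError(f"unknown config key: {here!r}")
        if isinstance(defaults[key], dict):
            if not isinstance(val, dict):
                raise ValueError(f"config key {here!r} must be a mapping")
            out[key] = _merge(defaults[key], val, here)
        else:
            out[key] = val
    return out


@dataclass
class RunConfig:
    """Resolved configuration with typed accessors for the model pieces."""

    resolved: dict

    @property
    def scenario(self) -> str:
        return self.resolved["scenario"]

    @property
    def seed(self) -> int:
        return int(self.resolved["seed"])

    def tube(self, length: float | None = None) -> TubeSpec:
        g, m = self.resolved["geometry"], self.resolved["mesh"]
        L = g["length"] if length is None else length
        n_axial = max(4, round(m["n_axial"] * L / g["length"]))
        return TubeSpec(
            inner_diameter=g["inner_diameter"],
            length=L,
            base_thickness=g["base_thickness"],
            n_axial=n_axial,
            n_circ=m["n_circ"],
        )

    def damage_params(self) -> DamagePlasticParams:
        b = self.resolved["bio"]
        return DamagePlasticParams(
            E0=b["E0"], eps_y=b["eps_y"], floor=b["floor"], PE_ref=b["PE_ref"]
        )

    def protocol(self) -> PressureProtocol:
        p = self.resolved["pressure"]
        if p["p_min"] is not None and p["p_max"] is not None:
            return PressureProtocol(
                p_min=p["p_min"], p_max=p["p_max"],
                n_cycles=p["n_cycles"], unload_target=p["unload_target"],
            )
        if p["range"] not in PRESSURE_RANGES_MPA:
            raise ValueError(
                f"unknown pressure.range {p['range']!r}; valid: "
                f"{sorted(PRESSURE_RANGES_MPA)}"
            )
        lo, hi = PRESSURE_RANGES_MPA[p["range"]]
        return PressureProtocol(
            p_min=lo, p_max=hi, n_cycles=p["n_cycles"], unload_target=p["unload_target"]
        )

    def preset(self, scenario: str | None = None, length: float | None = None) -> ScenarioPreset:
        name = scenario or self.scenario
        if name not in SCENARIO_NAMES:
            raise ValueError(f"unknown scenario {name!r}; valid: {list(SCENARIO_NAMES)}")
        tube = self.tube(length)
        pc = self.resolved["patch"]
        patches: tuple = ()
        if pc["enabled"]:
            center = pc["axial_center"]
            patch = ThinPatchSpec(
                axial_center=tube.length / 2.0 if center is None else center,
                circ_center=pc["circ_center"],
                axial_halfwidth=pc["axial_halfwidth"],
                circ_halfwidth=pc["circ_halfwidth"],
                min_thickness=pc["min_thickness"],
                transition=pc["transition"],
            )
            patches = (_snap_patch(tube, patch),)
        helix = None
        polymer = None
        if name in _POLYMERS:
            hdef = _POLYMERS[name]
            hc, poc = self.resolved["helix"], self.resolved["polymer"]
            helix = HelixSpec(
                pitch=hc["pitch"] if hc["pitch"] is not None else hdef["pitch"],
                thread_diameter=(
                    hc["thread_diameter"]
                    if hc["thread_diameter"] is not None
                    else hdef["thread"]
                ),
                n_layers=hc["n_layers"],
                polymer_id=name.upper(),
                phase=hc["phase"],
                handedness=hc["handedness"],
            )
            polymer = PolymerParams(
                E=poc["E"] if poc["E"] is not None else hdef["E"],
                id=name.upper(),
                nu=poc["nu"],
            )
        noise = self.resolved["noise"]
        return ScenarioPreset(
            name=name,
            tube=tube,
            patches=patches,
            helix=helix,
            damage=self.damage_params(),
            polymer=polymer,
            protocol=self.protocol(),
            noise_amplitude=noise["amplitude"],
            noise_corr_length=noise["corr_length"],
            nu_bio=self.resolved["bio"]["nu"],
        )

    def build_model(self, scenario: str | None = None, length: float | None = None):
        return build_model(self.preset(scenario, length), seed=self.seed)

    def dump(self, file) -> None:
        """Write the resolved config (seeds included) as YAML."""
        if hasattr(file, "write"):
            yaml.safe_dump(self.resolved, file, sort_keys=False)
        else:
            with open(file, "w") as fh:
                yaml.safe_dump(self.resolved, fh, sort_keys=False)


def load_config(file=None) -> RunConfig:
    """Read a YAML config; missing file or empty document means all defaults."""
    user: dict = {}
    if file is not None:
        if hasattr(file, "read"):
            user = yaml.safe_load(file.read()) or {}
        else:
            with open(file) as fh:
                user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError("config document must be a mapping")
    return RunConfig(resolved=_merge(DEFAULTS, user))
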