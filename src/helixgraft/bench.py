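"""Virtual bench protocols: compliance, tension with stop criterion, ratios.

Compliance replicates the saline pressurization bench: the 60 mm specimen
with fully fixed ("encastre") end bands is solved at the two endpoints of a
pressure range (hypo 50-90, normo 80-120, hyper 110-150 mmHg; the printed
MPa presets are used), and the compliance is the systolic-diastolic outer
diameter difference as a percentage of the smaller (diastolic) diameter,
measured at mid-span where the camera saw the widest profile.

Tension tests wrap the longitudinal-bar and transverse-ring solvers and
terminate when the force drops 30% below its running maximum — the bench
stop criterion associated with helix or scaffold rupture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ScaffoldModel
from .growth import PRESSURE_RANGES_MPA
from .materials import MaterialState, initial_modulus
from .solver import (
    BoundaryCondition,
    solve_longitudinal_tension,
    solve_pressure,
    solve_transverse_ring,
)

__all__ = [
    "ComplianceResult",
    "StressStrainCurve",
    "compliance_test",
    "tension_test",
    "apply_stop_criterion",
    "stiffness_ratio",
]


@dataclass(frozen=True)
class ComplianceResult:
    """Outcome of one pressure-range compliance measurement."""

    range_label: str
    diastolic_diameter_mm: float
    systolic_diameter_mm: float
    compliance_pct: float
    flags: tuple = ()

    def __post_init__(self) -> None:
        if self.systolic_diameter_mm < self.diastolic_diameter_mm:
            raise ValueError("systolic diameter below diastolic")


@dataclass
class StressStrainCurve:
    """Strain/stress series from a virtual (or synthetic bench) test."""

    strain: np.ndarray
    stress: np.ndarray
    direction: str = "longitudinal"
    stop_index: int | None = None

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain.size > 1 and not np.all(np.diff(self.strain) > 0):
            raise ValueError("strains must be strictly increasing")
        if not np.all(np.isfinite(self.stress)):
            raise ValueError("stress must be finite")

    def __len__(self) -> int:
        return self.strain.size


def _midspan_outer_diameter(
    model: ScaffoldModel, U1: np.ndarray, measure: str = "midspan"
) -> float:
    """Deformed outer diameter: widest profile at mid-span (or span average)."""
    tube = model.tube
    n_c = tube.n_circ
    w = U1.reshape(tube.n_axial + 1, n_c)
    if measure == "midspan":
        mid_row = tube.n_axial // 2
        w_meas = w[mid_row].max()
    elif measure == "span_average":
        w_meas = w.max(axis=1).mean()
    else:
        raise ValueError("measure must be 'midspan' or 'span_average'")
    return 2.0 * (tube.outer_radius + float(w_meas))


def compliance_test(
    model: ScaffoldModel,
    range_name: str,
    states: MaterialState | None = None,
    bc: BoundaryCondition = BoundaryCondition(),
    measure: str = "midspan",
) -> ComplianceResult:
    """Two endpoint pressure solves; compliance = (D_sys - D_dia)/D_dia * 100."""
    if range_name not in PRESSURE_RANGES_MPA:
        raise ValueError(
            f"unknown pressure range {range_name!r}; valid: "
            f"{sorted(PRESSURE_RANGES_MPA)}"
        )
    tube = model.tube
    if states is None:
        states = MaterialState.virgin((tube.n_axial, tube.n_circ))
    p_dia, p_sys = PRESSURE_RANGES_MPA[range_name]
    flags: list[str] = []
    diams = []
    for p in (p_dia, p_sys):
        res = solve_pressure(model, states, p, bc)
        flags.extend(res.flags)
        if not res.converged:
            flags.append(f"solver failure at p={p}")
        diams.append(_midspan_outer_diameter(model, res.U1, measure))
    d_dia, d_sys = diams
    return ComplianceResult(
        range_label=range_name,
        diastolic_diameter_mm=d_dia,
        systolic_diameter_mm=d_sys,
        compliance_pct=(d_sys - d_dia) / d_dia * 100.0,
        flags=tuple(flags),
    )


def apply_stop_criterion(force: np.ndarray, drop_fraction: float = 0.30) -> int | None:
    """Index of the first sample whose force falls below (1-drop)*running max.

    Returns None when the criterion never triggers (monotone curves).
    """
    force = np.asarray(force, dtype=float)
    running_max = np.maximum.accumulate(force)
    below = force < (1.0 - drop_fraction) * running_max
    idx = np.flatnonzero(below)
    return int(idx[0]) if idx.size else None


def tension_test(
    model: ScaffoldModel,
    direction: str,
    max_strain: float,
    stop_on_force_drop: float = 0.30,
    n_steps: int = 60,
    pin_diameter: float = 2.0,
) -> StressStrainCurve:
    """Virtual uniaxial tension with the 30%-force-drop stop criterion.

    Longitudinal: 60 mm bar pull, nominal strain = displacement / length,
    nominal stress = force / annular wall area.  Transverse: 15 mm ring
    between two lumen pins, nominal strain = pin travel / lumen diameter,
    nominal stress = force / (2 * t * L) (two wall cross-sections resist).
    """
    if max_strain <= 0:
        raise ValueError("max_strain must be positive")
    tube = model.tube
    if direction == "longitudinal":
        disp, force = solve_longitudinal_tension(
            model, max_strain * tube.length, n_steps=n_steps
        )
        area = np.pi * (tube.outer_radius**2 - tube.inner_radius**2)
        strain = disp / tube.length
        stress = force / area
    elif direction == "transverse":
        disp, force = solve_transverse_ring(
            model, max_strain * tube.inner_diameter,
            pin_diameter=pin_diameter, n_steps=n_steps,
        )
        t_mean = float(model.thickness.values.mean())
        strain = disp / tube.inner_diameter
        stress = force / (2.0 * t_mean * tube.length)
    else:
        raise ValueError("direction must be 'longitudinal' or 'transverse'")
    stop = apply_stop_criterion(force, stop_on_force_drop)
    if stop is not None:
        strain, stress = strain[: stop + 1], stress[: stop + 1]
    return StressStrainCurve(
        strain=strain, stress=stress, direction=direction, stop_index=stop
    )


def stiffness_ratio(
    curve_reinforced: StressStrainCurve,
    curve_control: StressStrainCurve,
    strain_window: float = 0.01,
) -> float:
    """Ratio of initial moduli (reinforced / control) over the window."""
    e_r = initial_modulus(curve_reinforced.strain, curve_reinforced.stress, strain_window)
    e_c = initial_modulus(curve_control.strain, curve_control.stress, strain_window)
    return e_r / e_c
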