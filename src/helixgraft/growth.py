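"""Cyclic-pressure aneurysm growth simulation.

The vessel is loaded and unloaded repeatedly (default 150 cycles of the
normotensive 80-120 mmHg range).  At each cycle peak the shell equilibrium
is solved with the current damaged moduli; elements whose hoop strain
exceeds the yield strain accumulate plastic strain, which degrades their
modulus through the damage law.  Every subsequent cycle therefore loads the
damaged region at reduced stiffness, strains it further, and deepens the
damage — the positive feedback that turns a locally thin wall patch into an
aneurysm-like residual bulge.  Once all yielded elements reach the damage
floor the per-cycle increments vanish and the trace saturates.

Residual (unloaded) geometry is reconstructed from the accumulated plastic
hoop strain (w_residual = PE * R per element, averaged to nodes) rather
than by a second plastic-equilibrium solve; this is consistent with the
scalar-hoop plasticity model and cheap.  Cycles that change no state are
not re-solved: the remaining trace rows are replicated, which is exact for
this rate-independent, history-monotone model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import ScaffoldModel
from .materials import DamagePlasticParams, MaterialState, stress_update_field
from .solver import BoundaryCondition, solve_pressure

__all__ = [
    "MMHG_TO_MPA",
    "PRESSURE_RANGES_MPA",
    "mmhg_to_mpa",
    "PressureProtocol",
    "GrowthTrace",
    "run_cycles",
    "growth_metrics",
    "save_trace",
    "load_trace",
]

MMHG_TO_MPA = 133.322e-6

# The study's printed MPa presets for the three bench pressure ranges.
PRESSURE_RANGES_MPA = {
    "hypo": (0.007, 0.012),    # 50-90 mmHg
    "normo": (0.011, 0.016),   # 80-120 mmHg
    "hyper": (0.015, 0.020),   # 110-150 mmHg
}


def mmhg_to_mpa(p_mmhg: float) -> float:
    """Generic converter, 1 mmHg = 133.322 Pa."""
    return p_mmhg * MMHG_TO_MPA


@dataclass(frozen=True)
class PressureProtocol:
    """Cyclic load definition (MPa)."""

    p_min: float = PRESSURE_RANGES_MPA["normo"][0]
    p_max: float = PRESSURE_RANGES_MPA["normo"][1]
    n_cycles: int = 150
    unload_target: str = "zero"  # 'zero' (relaxed state) or 'p_min'

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_min < self.p_max:
            raise ValueError("require 0 <= p_min < p_max")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.unload_target not in ("zero", "p_min"):
            raise ValueError("unload_target must be 'zero' or 'p_min'")

    @classmethod
    def from_range(cls, name: str, n_cycles: int = 150) -> "PressureProtocol":
        if name not in PRESSURE_RANGES_MPA:
            raise ValueError(
                f"unknown pressure range {name!r}; valid: {sorted(PRESSURE_RANGES_MPA)}"
            )
        lo, hi = PRESSURE_RANGES_MPA[name]
        return cls(p_min=lo, p_max=hi, n_cycles=n_cycles)


_TRACE_COLUMNS = [
    "cycle",
    "max_residual_u1_mm",
    "min_modulus_fraction",
    "max_plastic_strain",
    "loaded_diameter_mm",
    "unloaded_diameter_mm",
]


@dataclass
class GrowthTrace:
    """Per-cycle record of the growth simulation plus final state fields."""

    per_cycle: pd.DataFrame
    final_f: np.ndarray | None = None
    final_PE: np.ndarray | None = None
    final_residual_u1: np.ndarray | None = None
    flags: list = field(default_factory=list)
    truncated_at: int | None = None

    @property
    def n_cycles(self) -> int:
        return len(self.per_cycle)


def _nodal_plastic_displacement(model: ScaffoldModel, PE: np.ndarray) -> np.ndarray:
    """Residual radial displacement per node from the plastic strain field."""
    tube = model.tube
    n_z, n_c = tube.n_axial + 1, tube.n_circ
    acc = np.zeros((n_z, n_c))
    cnt = np.zeros((n_z, n_c))
    for di in (0, 1):
        rows = np.arange(tube.n_axial) + di
        for dj in (0, 1):
            for j in range(n_c):
                jj = (j + dj) % n_c
                acc[rows, jj] += PE[:, j]
                cnt[rows, jj] += 1.0
    return (acc / cnt).ravel() * tube.mid_radius


def run_cycles(
    model: ScaffoldModel,
    params: DamagePlasticParams,
    protocol: PressureProtocol,
    bc: BoundaryCondition = BoundaryCondition(),
    state: MaterialState | None = None,
) -> GrowthTrace:
    """Run the cyclic load/unload protocol and record the growth trace.

    Deterministic for fixed inputs.  On solver non-convergence the trace is
    truncated at the failing cycle and flagged, never silently continued.
    """
    tube = model.tube
    shape = (tube.n_axial, tube.n_circ)
    if state is None:
        state = MaterialState.virgin(shape)
    rows = []
    flags: list[str] = []
    truncated_at = None
    w_res = np.zeros((tube.n_axial + 1) * tube.n_circ)
    cycle = 0
    while cycle < protocol.n_cycles:
        cycle += 1
        res = solve_pressure(model, state, protocol.p_max, bc)
        for fl in res.flags:
            tagged = f"cycle {cycle}: {fl}"
            if tagged not in flags and not any(fl in f for f in flags):
                flags.append(tagged)
        if not res.converged:
            truncated_at = cycle
            rows.append(_cycle_row(cycle, w_res, state, model, res))
            break
        eps = np.maximum(res.hoop_strain, 0.0)
        _sigma, new_state = stress_update_field(eps, state, params)
        w_res = _nodal_plastic_displacement(model, new_state.PE_acc)
        if protocol.unload_target == "p_min" and protocol.p_min > 0:
            res_min = solve_pressure(model, new_state, protocol.p_min, bc)
            w_res = w_res + res_min.U1
        row = _cycle_row(cycle, w_res, new_state, model, res)
        rows.append(row)
        steady = np.array_equal(new_state.PE_acc, state.PE_acc)
        state = new_state
        if steady and cycle < protocol.n_cycles:
            # no further state change possible: replicate the steady cycle
            for extra in range(cycle + 1, protocol.n_cycles + 1):
                r = dict(row)
                r["cycle"] = extra
                rows.append(r)
            cycle = protocol.n_cycles
    trace = GrowthTrace(
        per_cycle=pd.DataFrame(rows, columns=_TRACE_COLUMNS),
        final_f=state.f.copy(),
        final_PE=state.PE_acc.copy(),
        final_residual_u1=w_res.copy(),
        flags=flags,
        truncated_at=truncated_at,
    )
    return trace


def _cycle_row(cycle, w_res, state, model, res) -> dict:
    tube = model.tube
    return {
        "cycle": cycle,
        "max_residual_u1_mm": float(w_res.max(initial=0.0)),
        "min_modulus_fraction": float(state.f.min()),
        "max_plastic_strain": float(state.PE_acc.max()),
        "loaded_diameter_mm": 2.0 * (tube.inner_radius + float(res.U1.max(initial=0.0))),
        "unloaded_diameter_mm": 2.0 * (tube.inner_radius + float(w_res.max(initial=0.0))),
    }


def growth_metrics(trace: GrowthTrace) -> dict:
    """Summary of the trace: the quantities the study reports per model."""
    if trace.n_cycles == 0:
        raise ValueError("empty trace has no metrics")
    last = trace.per_cycle.iloc[-1]
    return {
        "max_residual_u1_mm": float(trace.per_cycle["max_residual_u1_mm"].max()),
        "min_modulus_fraction": float(trace.per_cycle["min_modulus_fraction"].min()),
        "max_plastic_strain_pct": float(trace.per_cycle["max_plastic_strain"].max()) * 100.0,
        "final_loaded_diameter_mm": float(last["loaded_diameter_mm"]),
        "final_unloaded_diameter_mm": float(last["unloaded_diameter_mm"]),
        "n_cycles": int(trace.n_cycles),
        "flags": list(trace.flags),
        "truncated_at": trace.truncated_at,
    }


def save_trace(trace: GrowthTrace, file, fields_file=None) -> None:
    """Write the per-cycle trace as CSV (and, optionally, final fields as JSON)."""
    trace.per_cycle.to_csv(file, index=False)
    if fields_file is not None:
        import json

        payload = {
            "final_f": None if trace.final_f is None else trace.final_f.tolist(),
            "final_PE": None if trace.final_PE is None else trace.final_PE.tolist(),
            "final_residual_u1": (
                None if trace.final_residual_u1 is None
                else trace.final_residual_u1.tolist()
            ),
            "flags": trace.flags,
            "truncated_at": trace.truncated_at,
        }
        if hasattr(fields_file, "write"):
            json.dump(payload, fields_file)
        else:
            with open(fields_file, "w") as fh:
                json.dump(payload, fh)


def load_trace(file) -> GrowthTrace:
    """Read a per-cycle trace CSV back; rejects files with a wrong schema."""
    df = pd.read_csv(file)
    if list(df.columns) != _TRACE_COLUMNS:
        raise ValueError(
            f"trace schema mismatch: expected columns {_TRACE_COLUMNS}, "
            f"got {list(df.columns)}"
        )
    return GrowthTrace(per_cycle=df)
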