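"""Study-condition presets and synthetic bench-data generation.

Three scenario presets mirror the bench subgroups: an unreinforced Control,
and the same biological tube wrapped with a double PVDF or PCL helix.  All
three share the control's bio geometry exactly (same tube, same thickness
field for equal seeds).  The control wall carries one locally thin patch
(default minimum 0.06 mm in a 0.5 mm wall) sized so that the first-cycle
hoop stress at 120 mmHg, p*r/t ~ 0.67 MPa, marginally exceeds the yield
stress E0*eps_y = 0.6 MPa — the minimal construction that activates the
plasticity/damage mechanism in a desk-scale geometry.

The bench-curve generator emulates the J-shaped stress-strain response of
the decellularized wall with replicate-to-replicate spread: each replicate
perturbs the polynomial coefficients (normal, relative sd) and adds point
noise.  Only the qualitative structure (J-shape plus variability) is
emulated; bench interquartile ranges are not matched numerically.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .bench import StressStrainCurve
from .geometry import (
    HelixSpec,
    ScaffoldModel,
    ThinPatchSpec,
    TubeSpec,
    assemble_scaffold,
    build_thickness_field,
)
from .growth import PressureProtocol
from .materials import DamagePlasticParams, LinearLaw, PolymerParams

__all__ = [
    "SCENARIO_NAMES",
    "ScenarioPreset",
    "CurveEnsemble",
    "make_preset",
    "build_model",
    "gen_bench_curves",
]

SCENARIO_NAMES = ("control", "pvdf", "pcl")

# Extruded-polymer moduli and measured helix geometry (medians).
_POLYMERS = {
    "pvdf": dict(E=458.0, pitch=2.25, thread=0.33),
    "pcl": dict(E=321.0, pitch=2.15, thread=0.30),
}


@dataclass(frozen=True)
class ScenarioPreset:
    """Everything needed to build and load one scenario model."""

    name: str
    tube: TubeSpec
    patches: tuple  # of ThinPatchSpec
    helix: HelixSpec | None
    damage: DamagePlasticParams
    polymer: PolymerParams | None
    protocol: PressureProtocol
    noise_amplitude: float = 0.02
    noise_corr_length: float = 5.0
    nu_bio: float = 0.45


def _snap_patch(tube: TubeSpec, patch: ThinPatchSpec) -> ThinPatchSpec:
    """Move the patch center onto the nearest element center.

    Guarantees that one element attains exactly the patch minimum
    thickness, so damage localization is unambiguous.
    """
    z_c, phi_c = tube.element_centers()
    z = z_c[np.argmin(np.abs(z_c - patch.axial_center))]
    dphi = np.angle(np.exp(1j * (phi_c - patch.circ_center)))
    phi = phi_c[np.argmin(np.abs(dphi))]
    return replace(patch, axial_center=float(z), circ_center=float(phi))


def make_preset(
    name: str,
    length: float = 60.0,
    n_axial: int = 80,
    n_circ: int = 40,
    n_cycles: int = 150,
    patch_min_thickness: float = 0.06,
) -> ScenarioPreset:
    """Build the named study preset ('control', 'pvdf' or 'pcl')."""
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; valid: {list(SCENARIO_NAMES)}")
    tube = TubeSpec(
        inner_diameter=5.0,
        length=length,
        base_thickness=0.5,
        n_axial=n_axial,
        n_circ=n_circ,
    )
    patch = _snap_patch(
        tube,
        ThinPatchSpec(
            axial_center=length / 2.0,
            circ_center=0.0,
            axial_halfwidth=6.0,
            circ_halfwidth=1.2,
            min_thickness=patch_min_thickness,
            transition=1.0,
        ),
    )
    helix = None
    polymer = None
    if name in _POLYMERS:
        spec = _POLYMERS[name]
        helix = HelixSpec(
            pitch=spec["pitch"],
            thread_diameter=spec["thread"],
            n_layers=2,
            polymer_id=name.upper(),
        )
        polymer = PolymerParams(E=spec["E"], id=name.upper())
    return ScenarioPreset(
        name=name,
        tube=tube,
        patches=(patch,),
        helix=helix,
        damage=DamagePlasticParams(),
        polymer=polymer,
        protocol=PressureProtocol.from_range("normo", n_cycles=n_cycles),
    )


def build_model(preset: ScenarioPreset, seed: int = 0, bio_law=None) -> ScaffoldModel:
    """Instantiate the preset into a solvable ScaffoldModel (seeded)."""
    thickness = build_thickness_field(
        preset.tube,
        list(preset.patches),
        noise_amplitude=preset.noise_amplitude,
        noise_corr_length=preset.noise_corr_length,
        seed=seed,
    )
    if bio_law is None:
        bio_law = LinearLaw(preset.damage.E0)
    return assemble_scaffold(
        preset.tube,
        thickness,
        bio_law,
        helix=preset.helix,
        polymer=preset.polymer,
        nu_bio=preset.nu_bio,
        name=preset.name,
    )


@dataclass
class CurveEnsemble:
    """n replicate J-shaped curves plus the generating parameters."""

    curves: list
    a1: float
    a3: float
    noise_sd: float
    coef_rel_sd: float
    seed: int | None

    @property
    def n(self) -> int:
        return len(self.curves)

    def pooled_coefficients(self, degree: int = 3) -> tuple[float, float]:
        """Mean of per-replicate polynomial fits (a1, a3)."""
        from .materials import fit_polynomial

        fits = [fit_polynomial(c.strain, c.stress, degree=degree) for c in self.curves]
        return (
            float(np.mean([f.a1 for f in fits])),
            float(np.mean([f.a3 for f in fits])),
        )

    def to_frame(self) -> pd.DataFrame:
        """Multi-column table: strain plus one stress column per replicate."""
        data = {"strain": self.curves[0].strain}
        for i, c in enumerate(self.curves, start=1):
            data[f"stress_{i}"] = c.stress
        return pd.DataFrame(data)


def gen_bench_curves(
    a1: float = 1.0,
    a3: float = 2.0,
    noise_sd: float = 0.02,
    n: int = 5,
    seed: int | None = 0,
    coef_rel_sd: float = 0.1,
    eps_max: float = 0.6,
    n_points: int = 30,
) -> CurveEnsemble:
    """Seeded ensemble of noisy J-curves sigma_i = (a1+d_i)e + (a3+g_i)e^3 + noise.

    d_i ~ N(0, coef_rel_sd*a1) and g_i ~ N(0, coef_rel_sd*|a3|) are
    replicate-level coefficient perturbations; point noise is
    N(0, noise_sd) MPa.  The default a1 of 1 MPa matches the wall's
    small-strain modulus; a3 sets the collagen-recruitment upturn.
    """
    if a1 <= 0:
        raise ValueError("a1 must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    eps = np.linspace(0.0, eps_max, n_points + 1)[1:]  # strictly increasing, no 0/0
    curves = []
    for _ in range(n):
        d = rng.normal(0.0, coef_rel_sd * a1)
        g = rng.normal(0.0, coef_rel_sd * abs(a3)) if a3 != 0 else 0.0
        sigma = (a1 + d) * eps + (a3 + g) * eps**3
        if noise_sd > 0:
            sigma = sigma + rng.normal(0.0, noise_sd, size=eps.shape)
        curves.append(StressStrainCurve(strain=eps, stress=sigma, direction="transverse"))
    return CurveEnsemble(
        curves=curves, a1=a1, a3=a3, noise_sd=noise_sd,
        coef_rel_sd=coef_rel_sd, seed=seed,
    )
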