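"""Material models for the scaffold wall and the reinforcement polymers.

The biological wall follows a damage-coupled elastoplastic law: linear
elastic (modulus E0 = 1 MPa) up to a yield strain of 0.6 mm/mm; beyond it,
irreversible (plastic) strain accumulates and the elastic modulus degrades
linearly with accumulated plastic strain down to a floor of 10% of the
initial value.  The degradation ramp is calibrated so the floor is reached
at PE_ref = 0.0055 mm/mm of plastic strain — the level at which the
full-geometry study observed the modulus bottom out.  There is no healing:
both the plastic strain and the damage are monotone over any load history.

The extruded reinforcement polymers (PVDF 458 MPa, PCL 321 MPa) are purely
linear elastic, with no plasticity or degradation.

Bench-style stress-strain curves are summarized two ways: an odd polynomial
sigma = a1*eps + a3*eps^3 (+ higher odd terms if requested) constrained
through the origin, and the initial modulus — the slope of a through-origin
line over the small-strain window (default up to 1% strain), the quantity
the study used to set the 1 MPa wall modulus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DamagePlasticParams",
    "PolymerParams",
    "MaterialState",
    "PolyFit",
    "LinearLaw",
    "PolynomialLaw",
    "damage_factor",
    "stress_update",
    "stress_update_field",
    "fit_polynomial",
    "initial_modulus",
]


@dataclass(frozen=True)
class DamagePlasticParams:
    """Damage-plasticity parameters of the biological wall.

    E0      initial elastic modulus, MPa
    eps_y   yield strain, mm/mm
    floor   minimal modulus fraction retained at full damage
    PE_ref  accumulated plastic strain at which the floor is reached, mm/mm
    """

    E0: float = 1.0
    eps_y: float = 0.6
    floor: float = 0.1
    PE_ref: float = 0.0055

    def __post_init__(self) -> None:
        if not 0.0 < self.floor < 1.0:
            raise ValueError("floor must be in (0, 1)")
        if self.eps_y <= 0:
            raise ValueError("eps_y must be positive")
        if self.PE_ref <= 0:
            raise ValueError("PE_ref must be positive")
        if self.E0 <= 0:
            raise ValueError("E0 must be positive")


@dataclass(frozen=True)
class PolymerParams:
    """Linear elastic reinforcement polymer (E in MPa)."""

    E: float
    id: str = "PVDF"
    nu: float = 0.35

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("polymer modulus E must be positive")

    @property
    def G(self) -> float:
        """Shear modulus from E and nu."""
        return self.E / (2.0 * (1.0 + self.nu))


@dataclass
class MaterialState:
    """Evolving per-element state: accumulated plastic strain and damage.

    ``f`` is the modulus fraction (1 = virgin, floor = fully damaged);
    ``PE_acc`` never decreases, ``f`` never increases.
    """

    PE_acc: np.ndarray
    f: np.ndarray

    @classmethod
    def virgin(cls, shape) -> "MaterialState":
        return cls(PE_acc=np.zeros(shape), f=np.ones(shape))

    def copy(self) -> "MaterialState":
        return MaterialState(PE_acc=self.PE_acc.copy(), f=self.f.copy())


def damage_factor(PE_acc, params: DamagePlasticParams):
    """Modulus fraction as a function of accumulated plastic strain.

    f = max(floor, 1 - (1 - floor) * PE_acc / PE_ref): a linear ramp from 1
    at zero plastic strain to the floor at PE_ref, clamped below.
    """
    PE_acc = np.asarray(PE_acc, dtype=float)
    f = 1.0 - (1.0 - params.floor) * PE_acc / params.PE_ref
    return np.maximum(params.floor, f)


def stress_update(eps_total, state_PE: float, params: DamagePlasticParams):
    """One-point damage-plastic stress update (scalar, tension only).

    Returns (sigma, PE_new, f_new).  Below the yield strain all deformation
    is reversible and the state is untouched; above it the plastic strain
    jumps to the excess over yield (monotone: never decreases), the damage
    factor follows, and the stress is f * E0 * (eps - PE).
    """
    if eps_total < 0:
        raise ValueError("compression (eps_total < 0) is not modelled")
    PE_new = state_PE
    if eps_total > params.eps_y:
        PE_new = max(state_PE, eps_total - params.eps_y)
    f_new = float(damage_factor(PE_new, params))
    sigma = f_new * params.E0 * (eps_total - PE_new)
    return sigma, PE_new, f_new


def stress_update_field(
    eps_total: np.ndarray, state: MaterialState, params: DamagePlasticParams
) -> tuple[np.ndarray, MaterialState]:
    """Vectorized stress_update over an element field."""
    eps_total = np.asarray(eps_total, dtype=float)
    if np.any(eps_total < 0):
        raise ValueError("compression (eps_total < 0) is not modelled")
    excess = np.maximum(0.0, eps_total - params.eps_y)
    PE_new = np.maximum(state.PE_acc, excess)
    f_new = damage_factor(PE_new, params)
    sigma = f_new * params.E0 * (eps_total - PE_new)
    return sigma, MaterialState(PE_acc=PE_new, f=f_new)


class LinearLaw:
    """sigma = E * eps; the study's linear wall and polymer model."""

    def __init__(self, E: float):
        if E <= 0:
            raise ValueError("modulus must be positive")
        self.E = float(E)

    def stress(self, eps):
        return self.E * np.asarray(eps, dtype=float)

    def tangent(self, eps):
        return np.full_like(np.asarray(eps, dtype=float), self.E)

    def initial_modulus(self) -> float:
        return self.E


@dataclass(frozen=True)
class PolyFit:
    """Odd polynomial sigma(eps) = a1*eps + a3*eps^3 (+ ...), through origin."""

    coeffs: tuple  # (a1, a3, a5, ...) ascending odd powers
    residual: float = 0.0

    def __post_init__(self) -> None:
        if self.coeffs[0] <= 0:
            raise ValueError("PolyFit leading coefficient a1 must be positive")

    @property
    def a1(self) -> float:
        return self.coeffs[0]

    @property
    def a3(self) -> float:
        return self.coeffs[1] if len(self.coeffs) > 1 else 0.0

    def __call__(self, eps):
        eps = np.asarray(eps, dtype=float)
        out = np.zeros_like(eps)
        for k, a in enumerate(self.coeffs):
            out = out + a * eps ** (2 * k + 1)
        return out

    def to_json(self, file) -> None:
        payload = {"coeffs": list(self.coeffs), "residual": self.residual}
        if hasattr(file, "write"):
            json.dump(payload, file)
        else:
            with open(file, "w") as fh:
                json.dump(payload, fh)

    @classmethod
    def from_json(cls, file) -> "PolyFit":
        if hasattr(file, "read"):
            payload = json.load(file)
        else:
            with open(file) as fh:
                payload = json.load(fh)
        return cls(coeffs=tuple(payload["coeffs"]), residual=payload["residual"])


class PolynomialLaw:
    """Material law backed by a PolyFit (J-shaped wall response)."""

    def __init__(self, fit: PolyFit):
        self.fit = fit

    def stress(self, eps):
        return self.fit(eps)

    def tangent(self, eps):
        eps = np.asarray(eps, dtype=float)
        out = np.zeros_like(eps)
        for k, a in enumerate(self.fit.coeffs):
            out = out + (2 * k + 1) * a * eps ** (2 * k)
        return out

    def initial_modulus(self) -> float:
        return self.fit.a1


def fit_polynomial(strain, stress, degree: int = 3) -> PolyFit:
    """Least-squares odd polynomial through the origin.

    degree is the highest odd power kept (3 -> a1*eps + a3*eps^3).
    Requires at least 5 points with strictly increasing strains.
    """
    strain = np.asarray(strain, dtype=float)
    stress = np.asarray(stress, dtype=float)
    if strain.size < 5:
        raise ValueError("need at least 5 points to fit")
    if not np.all(np.diff(strain) > 0):
        raise ValueError("strains must be strictly increasing")
    if np.allclose(stress, 0.0):
        raise ValueError("degenerate all-zero stress curve")
    if degree < 1 or degree % 2 == 0:
        raise ValueError("degree must be a positive odd integer")
    powers = np.arange(1, degree + 1, 2)
    A = strain[:, None] ** powers[None, :]
    coef, res, _, _ = np.linalg.lstsq(A, stress, rcond=None)
    residual = float(np.sqrt(res[0] / strain.size)) if res.size else float(
        np.sqrt(np.mean((A @ coef - stress) ** 2))
    )
    return PolyFit(coeffs=tuple(coef), residual=residual)


def initial_modulus(strain, stress, strain_window: float = 0.01) -> float:
    """Slope of a through-origin line over strains in [0, strain_window].

    This is the 'near-physiological' small-strain modulus the study used
    (window default 1% strain).
    """
    strain = np.asarray(strain, dtype=float)
    stress = np.asarray(stress, dtype=float)
    if strain_window > strain.max():
        raise ValueError("strain_window exceeds the curve's maximum strain")
    mask = (strain >= 0) & (strain <= strain_window)
    if mask.sum() < 2:
        raise ValueError("fewer than 2 points in the strain window")
    x, y = strain[mask], stress[mask]
    return float(x @ y / (x @ x))
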