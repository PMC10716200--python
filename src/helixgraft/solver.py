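"""Quasi-static structural solvers for the reduced scaffold model.

The pressurized vessel is solved with reduced kinematics: a single radial
displacement field w(z, phi) on the structured mid-surface grid.  Each wall
element resists hoop membrane stretch with stiffness f*E*t (the degraded
secant wall law; axial load is carried by the end fixtures, so the hoop
state is treated as uniaxial) plus the homogenized helix hoop stiffness;
neighbor support enters through a bending term built from the local
flexural rigidity f*E*t^3/(12*(1-nu^2)), so locally thin patches are
bridged rather than free-ballooning.  Equilibrium is found by Newton
iteration (one step suffices for linear wall laws).

Tension tests use dedicated reduced models: the 60 mm longitudinal pull is
a composite bar (annular wall cross-section with its material law, plus a
coil-spring axial stiffness for each helix layer), and the 15 mm transverse
ring pull is a closed planar curved-beam finite-element ring with a
composite bending/stretching section, loaded by two opposed lumen pins
(frozen wrap, no sliding).

Closed-form oracles: Laplace's thin-wall law for the uniform pressurized
tube, and the classical curved-beam result for a slender elastic ring under
opposed point loads, delta = F*R^3/(E*I) * (pi/4 - 2/pi).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .geometry import ScaffoldModel, TubeSpec
from .materials import MaterialState

__all__ = [
    "BoundaryCondition",
    "SolveResult",
    "solve_pressure",
    "laplace_reference",
    "solve_longitudinal_tension",
    "solve_transverse_ring",
    "ring_compliance_reference",
    "coil_spring_stiffness",
]

RING_SHAPE_FACTOR = np.pi / 4.0 - 2.0 / np.pi  # opposed-point-load ring bending


@dataclass(frozen=True)
class BoundaryCondition:
    """End restraint of the tube: fully fixed ('encastre') bands or free."""

    end_constraint: str = "encastre"
    clamped_length: float = 5.0

    def __post_init__(self) -> None:
        if self.end_constraint not in ("encastre", "free"):
            raise ValueError("end_constraint must be 'encastre' or 'free'")
        if self.clamped_length < 0:
            raise ValueError("clamped_length must be non-negative")

    def validate_for(self, tube: TubeSpec) -> None:
        if self.end_constraint == "encastre" and self.clamped_length >= tube.length / 2:
            raise ValueError(
                f"clamped_length {self.clamped_length} must be below half the "
                f"specimen length {tube.length / 2}"
            )


@dataclass
class SolveResult:
    """Equilibrium fields of one pressure solve.

    U1 is the radial nodal displacement (mm); strains/stresses are
    per-element.  ``flags`` collects non-fatal validity warnings
    ('model validity exceeded' when strains pass 50%).
    """

    U1: np.ndarray
    hoop_strain: np.ndarray
    axial_strain: np.ndarray
    hoop_stress: np.ndarray
    iterations: int
    converged: bool
    residual_norm: float = 0.0
    flags: list = field(default_factory=list)


def laplace_reference(p: float, r: float, t: float, E: float) -> float:
    """Thin-wall hoop strain of a pressurized tube: p*r/(t*E).

    Warns outside the thin-wall regime (t >= r/5).
    """
    if t >= r / 5.0:
        warnings.warn(
            f"thick-wall input (t={t}, r={r}): Laplace estimate is approximate",
            stacklevel=2,
        )
    return p * r / (t * E)


def _hoop_incidence(tube: TubeSpec) -> sp.csr_matrix:
    """Element-mean operator B: eps_hoop = (B @ w) / R_mid."""
    n_c = tube.n_circ
    n_el = tube.n_axial * n_c
    rows = np.repeat(np.arange(n_el), 4)
    cols = np.empty(4 * n_el, dtype=np.int64)
    for i in range(tube.n_axial):
        for j in range(n_c):
            e = i * n_c + j
            jn = (j + 1) % n_c
            cols[4 * e: 4 * e + 4] = (
                i * n_c + j, i * n_c + jn, (i + 1) * n_c + jn, (i + 1) * n_c + j
            )
    data = np.full(4 * n_el, 0.25)
    n_nodes = (tube.n_axial + 1) * n_c
    return sp.csr_matrix((data, (rows, cols)), shape=(n_el, n_nodes))


def _laplacian(tube: TubeSpec) -> sp.csr_matrix:
    """Discrete surface Laplacian on the (z, arc-length) node grid.

    Periodic in phi; mirror (symmetry) closure at the end rows, which keeps
    a uniform inflation curvature-free.
    """
    n_z, n_c = tube.n_axial + 1, tube.n_circ
    hz = tube.dz
    hc = tube.mid_radius * tube.dphi
    n = n_z * n_c
    L = sp.lil_matrix((n, n))
    for i in range(n_z):
        for j in range(n_c):
            k = i * n_c + j
            jp, jm = (j + 1) % n_c, (j - 1) % n_c
            L[k, i * n_c + jp] += 1.0 / hc**2
            L[k, i * n_c + jm] += 1.0 / hc**2
            L[k, k] += -2.0 / hc**2
            if 0 < i < n_z - 1:
                L[k, (i + 1) * n_c + j] += 1.0 / hz**2
                L[k, (i - 1) * n_c + j] += 1.0 / hz**2
                L[k, k] += -2.0 / hz**2
            else:
                im = (i + 1) if i == 0 else (i - 1)
                L[k, im * n_c + j] += 2.0 / hz**2
                L[k, k] += -2.0 / hz**2
    return L.tocsr()


def _nodal_average(tube: TubeSpec, elem_field: np.ndarray) -> np.ndarray:
    """Average a per-element field onto nodes (area-weighted, uniform grid)."""
    n_z, n_c = tube.n_axial + 1, tube.n_circ
    acc = np.zeros((n_z, n_c))
    cnt = np.zeros((n_z, n_c))
    # element (i, j) touches nodes (i+di, (j+dj) mod n_c), di/dj in {0, 1}
    for di in (0, 1):
        rows = np.arange(tube.n_axial) + di
        for dj in (0, 1):
            for j in range(n_c):
                jj = (j + dj) % n_c
                acc[rows, jj] += elem_field[:, j]
                cnt[rows, jj] += 1.0
    return (acc / cnt).ravel()


def _free_mask(tube: TubeSpec, bc: BoundaryCondition) -> np.ndarray:
    n_z, n_c = tube.n_axial + 1, tube.n_circ
    z = np.repeat(np.arange(n_z) * tube.dz, n_c)
    if bc.end_constraint == "free":
        return np.ones(n_z * n_c, dtype=bool)
    eps = 1e-9
    clamped = (z <= bc.clamped_length + eps) | (z >= tube.length - bc.clamped_length - eps)
    return ~clamped


def solve_pressure(
    model: ScaffoldModel,
    states: MaterialState,
    p: float,
    bc: BoundaryCondition = BoundaryCondition(),
    tol: float = 1e-9,
    max_iter: int = 50,
) -> SolveResult:
    """Equilibrium of the (possibly reinforced) shell under inner pressure p (MPa).

    Wall hoop resultant per element: N(eps) = f * sigma_bio(eps) * t +
    C_helix * eps, with eps = mean nodal w / R_mid.  Bending couples
    neighbors through the degraded local flexural rigidity.  Newton
    iterations run until the residual drops below tol * ||load||.
    """
    if p < 0:
        raise ValueError("pressure must be non-negative")
    tube = model.tube
    bc.validate_for(tube)
    n_el_shape = (tube.n_axial, tube.n_circ)
    n_nodes = (tube.n_axial + 1) * tube.n_circ
    if p == 0.0:
        zeros_el = np.zeros(n_el_shape)
        return SolveResult(
            U1=np.zeros(n_nodes), hoop_strain=zeros_el, axial_strain=zeros_el,
            hoop_stress=zeros_el, iterations=0, converged=True,
        )

    t_el = model.thickness.values
    f_el = states.f
    R = tube.mid_radius
    el_area = tube.dz * R * tube.dphi
    C_hel = model.helix_hoop_stiffness()
    law = model.bio_law

    B = _hoop_incidence(tube)
    L = _laplacian(tube)
    E_init = law.initial_modulus()
    D_el = f_el * E_init * t_el**3 / (12.0 * (1.0 - model.nu_bio**2))
    D_node = _nodal_average(tube, D_el)
    # nodal tributary area: half-height strip at the end rows
    n_z, n_c = tube.n_axial + 1, tube.n_circ
    hz_node = np.full(n_z, tube.dz)
    hz_node[0] = hz_node[-1] = tube.dz / 2.0
    A_node = np.repeat(hz_node, n_c) * (R * tube.dphi)
    K_bend = (L.T @ sp.diags(D_node * A_node) @ L).tocsr()

    F_ext = p * tube.inner_radius * tube.dphi * np.repeat(hz_node, n_c)

    free = _free_mask(tube, bc)
    w = np.zeros(n_nodes)
    ref = max(np.linalg.norm(F_ext[free]), 1e-12)

    converged = False
    res_norm = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        eps = (B @ w).reshape(n_el_shape) / R
        N_el = f_el * law.stress(eps) * t_el + C_hel * eps
        Q = B.T @ (N_el.ravel() * el_area / R)
        resid = K_bend @ w + Q - F_ext
        res_norm = np.linalg.norm(resid[free])
        if res_norm <= tol * ref:
            converged = True
            break
        dN = f_el * law.tangent(eps) * t_el + C_hel
        K_hoop = B.T @ sp.diags(dN.ravel() * el_area / R**2) @ B
        K = (K_bend + K_hoop).tocsr()
        Kff = K[free][:, free]
        dw = spsolve(Kff.tocsc(), -resid[free])
        w[free] += dw
    # final fields
    eps = (B @ w).reshape(n_el_shape) / R
    N_el = f_el * law.stress(eps) * t_el + C_hel * eps
    sigma_bio = f_el * law.stress(eps)
    flags = []
    if not converged:
        flags.append(f"non-convergence: residual {res_norm:.3e} after {it} iterations")
    if np.max(np.abs(eps)) > 0.5:
        flags.append("model validity exceeded: hoop strain above 50%")
    return SolveResult(
        U1=w,
        hoop_strain=eps,
        axial_strain=np.zeros(n_el_shape),
        hoop_stress=sigma_bio,
        iterations=it,
        converged=converged,
        residual_norm=float(res_norm),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Longitudinal tension (60 mm bar + coil springs)


def coil_spring_stiffness(G: float, d: float, D_coil: float, n_turns: float) -> float:
    """Axial stiffness of a helical coil spring: G*d^4/(8*D^3*n) (N/mm)."""
    if n_turns <= 0:
        raise ValueError("n_turns must be positive")
    return G * d**4 / (8.0 * D_coil**3 * n_turns)


def solve_longitudinal_tension(
    model: ScaffoldModel, displacement: float, n_steps: int = 60
) -> tuple[np.ndarray, np.ndarray]:
    """Force-displacement curve of the axial pull on the 60 mm specimen.

    The wall acts as a bar of annular cross-section with the model's
    material law; each helix layer adds a coil-spring axial stiffness
    (negligible next to the bar for the study's geometries, matching the
    bench observation that the helix leaves longitudinal behavior
    unchanged).  Lower end encastre, displacement applied at the top.
    """
    if displacement < 0:
        raise ValueError("displacement must be non-negative")
    tube = model.tube
    if displacement > tube.length:
        raise ValueError("displacement exceeds specimen length")
    A = np.pi * (tube.outer_radius**2 - tube.inner_radius**2)
    disp = np.linspace(0.0, displacement, n_steps + 1)
    eps = disp / tube.length
    force = model.bio_law.stress(eps) * A
    if model.helix is not None and model.polymer is not None and model.helix.n_layers:
        d = model.helix.thread_diameter
        D_coil = 2.0 * model.helix.winding_radius(tube)
        n_turns = tube.length / model.helix.pitch
        k = coil_spring_stiffness(model.polymer.G, d, D_coil, n_turns)
        force = force + model.helix.n_layers * k * disp
    return disp, force


# ---------------------------------------------------------------------------
# Transverse ring test (15 mm specimen between two lumen pins)


def ring_compliance_reference(F: float, R: float, E: float, I: float) -> float:
    """Diametral deflection of a slender ring under opposed point loads."""
    return F * R**3 / (E * I) * RING_SHAPE_FACTOR


def _ring_stiffness_matrix(R: float, EA: float, EI: float, n: int) -> sp.csr_matrix:
    """Planar frame FE of a closed ring (3 DOF/node), polygon approximation."""
    angles = 2.0 * np.pi * np.arange(n) / n
    pts = np.column_stack([R * np.cos(angles), R * np.sin(angles)])
    K = sp.lil_matrix((3 * n, 3 * n))
    for e in range(n):
        a, b = e, (e + 1) % n
        dx, dy = pts[b] - pts[a]
        Le = np.hypot(dx, dy)
        c, s = dx / Le, dy / Le
        EA_L = EA / Le
        k = np.array(
            [
                [EA_L, 0, 0, -EA_L, 0, 0],
                [0, 12 * EI / Le**3, 6 * EI / Le**2, 0, -12 * EI / Le**3, 6 * EI / Le**2],
                [0, 6 * EI / Le**2, 4 * EI / Le, 0, -6 * EI / Le**2, 2 * EI / Le],
                [-EA_L, 0, 0, EA_L, 0, 0],
                [0, -12 * EI / Le**3, -6 * EI / Le**2, 0, 12 * EI / Le**3, -6 * EI / Le**2],
                [0, 6 * EI / Le**2, 2 * EI / Le, 0, -6 * EI / Le**2, 4 * EI / Le],
            ]
        )
        T = np.array(
            [
                [c, s, 0, 0, 0, 0],
                [-s, c, 0, 0, 0, 0],
                [0, 0, 1, 0, 0, 0],
                [0, 0, 0, c, s, 0],
                [0, 0, 0, -s, c, 0],
                [0, 0, 0, 0, 0, 1],
            ]
        )
        ke = T.T @ k @ T
        dofs = [3 * a, 3 * a + 1, 3 * a + 2, 3 * b, 3 * b + 1, 3 * b + 2]
        for ii in range(6):
            for jj in range(6):
                K[dofs[ii], dofs[jj]] += ke[ii, jj]
    return K.tocsr()


def ring_point_load_compliance(R: float, EA: float, EI: float, n: int = 128) -> float:
    """Diametral compliance delta/F of the FE ring under opposed point loads.

    Loads act at the two nodes on the vertical diameter (frozen pin wrap:
    no sliding, pure point transfer).  n must be a multiple of 4.
    """
    if n % 4:
        raise ValueError("n must be a multiple of 4")
    K = _ring_stiffness_matrix(R, EA, EI, n)
    top, bottom = n // 4, 3 * n // 4
    F = np.zeros(3 * n)
    F[3 * top + 1] = 1.0
    fixed = [3 * bottom, 3 * bottom + 1, 3 * top]  # kill rigid modes
    free = np.ones(3 * n, dtype=bool)
    free[fixed] = False
    u = np.zeros(3 * n)
    u[free] = spsolve(K[free][:, free].tocsc(), F[free])
    return float(u[3 * top + 1])


def ring_composite_section(model: ScaffoldModel) -> tuple[float, float, float]:
    """(EA, EI, t) of the composite ring cross-section.

    Bio wall: width = specimen length, thickness = mean wall thickness,
    modulus = initial bio modulus.  Helix threads crossing the section:
    n_layers * n_turns threads of the polymer at the outer wall surface
    (parallel-axis offset (t + d)/2 from the wall mid-line).
    """
    tube = model.tube
    t = float(model.thickness.values.mean())
    Lw = tube.length
    E_b = model.bio_law.initial_modulus()
    EA = E_b * Lw * t
    EI = E_b * Lw * t**3 / 12.0
    if model.helix is not None and model.polymer is not None and model.helix.n_layers:
        h = model.helix
        n_threads = h.n_layers * tube.length / h.pitch
        A_th = h.thread_area
        I_th = np.pi * h.thread_diameter**4 / 64.0
        offset = (t + h.thread_diameter) / 2.0
        EA += model.polymer.E * n_threads * A_th
        EI += model.polymer.E * n_threads * (I_th + A_th * offset**2)
    return EA, EI, t


def solve_transverse_ring(
    model: ScaffoldModel,
    pin_displacement: float,
    pin_diameter: float = 2.0,
    n_steps: int = 60,
    n_ring: int = 128,
) -> tuple[np.ndarray, np.ndarray]:
    """Force-displacement curve of the 15 mm ring pulled apart by two pins.

    The ring is a closed planar curved beam (bending + stretching) with the
    composite bio+helix section; pin contact is a frozen wrap (opposed
    point transfer, no sliding).  Linear in the initial-modulus regime, so
    the curve is a ray whose slope is the composite ring stiffness.
    """
    if pin_displacement < 0:
        raise ValueError("pin_displacement must be non-negative")
    tube = model.tube
    if pin_diameter >= tube.inner_diameter:
        raise ValueError(
            f"pin diameter {pin_diameter} must be below the lumen "
            f"diameter {tube.inner_diameter}"
        )
    EA, EI, _t = ring_composite_section(model)
    compliance = ring_point_load_compliance(tube.mid_radius, EA, EI, n=n_ring)
    disp = np.linspace(0.0, pin_displacement, n_steps + 1)
    force = disp / compliance
    return disp, force
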