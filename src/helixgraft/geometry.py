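"""Synthetic scaffold geometry: tube meshes, thickness fields, helix paths.

The study specimens are decellularized bovine internal mammary arteries
(inner diameter 5 mm, segment lengths 15 and 60 mm) wrapped externally with
a double polymer helix (pitch ~2.15-2.25 mm, thread ~0.30-0.33 mm).  Here
they are idealized as structured cylindrical shell meshes with a per-element
wall-thickness field (locally thinned patches emulate the weak regions of
real scaffolds) and an analytic double-helix polyline whose path length is
distributed over the shell elements ("coverage") for homogenized
reinforcement stiffness.

Units are mm throughout; angles in radians.  Elements are indexed
(axial row, circumferential column), 0-based; z runs along the vessel axis,
phi from a fixed generator line.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
import trimesh

__all__ = [
    "TubeSpec",
    "ThinPatchSpec",
    "ThicknessField",
    "HelixSpec",
    "SurfaceMesh",
    "ScaffoldModel",
    "make_tube_mesh",
    "build_thickness_field",
    "make_helix_path",
    "helix_coverage",
    "assemble_scaffold",
    "import_stl",
    "export_stl",
    "ScaffoldIOError",
]


class ScaffoldIOError(ValueError):
    """Raised for malformed mesh files (carries a byte/line offset hint)."""


@dataclass(frozen=True)
class TubeSpec:
    """Idealized cylindrical scaffold segment.

    The mesh lives on the wall mid-surface, radius inner_diameter/2 +
    base_thickness/2.
    """

    inner_diameter: float = 5.0
    length: float = 60.0
    base_thickness: float = 0.5
    n_axial: int = 60
    n_circ: int = 32

    def __post_init__(self) -> None:
        for name in ("inner_diameter", "length", "base_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"TubeSpec.{name} must be positive, got {getattr(self, name)}")
        if self.n_axial < 4:
            raise ValueError(f"TubeSpec.n_axial must be >= 4, got {self.n_axial}")
        if self.n_circ < 8:
            raise ValueError(f"TubeSpec.n_circ must be >= 8, got {self.n_circ}")
        if self.n_circ % 2:
            raise ValueError(f"TubeSpec.n_circ must be even, got {self.n_circ}")

    @property
    def inner_radius(self) -> float:
        return self.inner_diameter / 2.0

    @property
    def mid_radius(self) -> float:
        return self.inner_radius + self.base_thickness / 2.0

    @property
    def outer_radius(self) -> float:
        return self.inner_radius + self.base_thickness

    @property
    def dz(self) -> float:
        return self.length / self.n_axial

    @property
    def dphi(self) -> float:
        return 2.0 * np.pi / self.n_circ

    def element_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(z, phi) centers of the n_axial x n_circ element grid."""
        z = (np.arange(self.n_axial) + 0.5) * self.dz
        phi = (np.arange(self.n_circ) + 0.5) * self.dphi
        return z, phi


@dataclass(frozen=True)
class ThinPatchSpec:
    """A locally thinned, smoothly blended region of the wall.

    Thickness at the patch center equals ``min_thickness``; the blend is
    exp(-rho^(2*transition)) with rho the elliptic distance normalized by
    the halfwidths (transition=1 is a Gaussian bump).
    """

    axial_center: float
    circ_center: float
    axial_halfwidth: float
    circ_halfwidth: float
    min_thickness: float
    transition: float = 1.0

    def __post_init__(self) -> None:
        if self.min_thickness <= 0:
            raise ValueError("ThinPatchSpec.min_thickness must be positive")
        if self.axial_halfwidth <= 0 or self.circ_halfwidth <= 0:
            raise ValueError("ThinPatchSpec halfwidths must be positive")
        if self.transition <= 0:
            raise ValueError("ThinPatchSpec.transition must be positive")


@dataclass(frozen=True)
class ThicknessField:
    """Per-element wall thickness on the TubeSpec grid (mm)."""

    values: np.ndarray  # shape (n_axial, n_circ)
    seed: int | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if not np.all(vals > 0):
            raise ValueError("ThicknessField must be positive everywhere")

    @property
    def min(self) -> float:
        return float(self.values.min())


@dataclass(frozen=True)
class HelixSpec:
    """Double-helix reinforcement winding.

    pitch is axial advance per turn; the paper's measured medians are
    2.25 mm (PVDF) and 2.15 mm (PCL), thread diameters 0.33 and 0.30 mm.
    n_layers=2 gives the fused double helix (layer 1 advances +z, layer 2
    returns -z with a half-turn phase offset so crossings coincide).
    """

    pitch: float
    thread_diameter: float
    n_layers: int = 2
    polymer_id: str = "PVDF"
    phase: float = 0.0
    handedness: int = 1

    def __post_init__(self) -> None:
        if self.pitch <= 0:
            raise ValueError("HelixSpec.pitch must be positive")
        if self.pitch <= self.thread_diameter:
            raise ValueError("HelixSpec.pitch must exceed thread_diameter")
        if self.n_layers not in (0, 1, 2):
            raise ValueError("HelixSpec.n_layers must be 0, 1 or 2")
        if self.handedness not in (1, -1):
            raise ValueError("HelixSpec.handedness must be +1 or -1")

    @property
    def thread_area(self) -> float:
        """Cross-section area of one thread (mm^2)."""
        return np.pi * (self.thread_diameter / 2.0) ** 2

    def winding_radius(self, tube: TubeSpec) -> float:
        """Thread centerline radius: outer wall surface + half thread."""
        return tube.inner_radius + tube.base_thickness + self.thread_diameter / 2.0

    def helix_angle(self, tube: TubeSpec) -> float:
        """Angle of the thread from the hoop direction (radians)."""
        return float(np.arctan(self.pitch / (np.pi * 2.0 * self.winding_radius(tube))))


@dataclass
class SurfaceMesh:
    """Shell surface mesh.

    Native meshes are structured quadrilateral grids on the mid-surface
    cylinder with a (z, phi) parameterization; meshes imported from STL are
    triangular and flagged ``external`` (no parameterization; usable for
    geometry statistics).
    """

    points: np.ndarray          # (n_nodes, 3)
    faces: np.ndarray           # quads (n_el, 4) native, triangles (n_el, 3) external
    z: np.ndarray | None = None     # per-node axial coordinate (native only)
    phi: np.ndarray | None = None   # per-node angle (native only)
    tube: TubeSpec | None = None
    external: bool = False

    @property
    def n_nodes(self) -> int:
        return self.points.shape[0]

    @property
    def n_elements(self) -> int:
        return self.faces.shape[0]

    def node_index(self, row: int, col: int) -> int:
        assert self.tube is not None
        return row * self.tube.n_circ + (col % self.tube.n_circ)

    def surface_area(self) -> float:
        """Total facet area (triangulating quads for native meshes)."""
        tris = self.faces
        if tris.shape[1] == 4:
            tris = np.vstack([tris[:, [0, 1, 2]], tris[:, [0, 2, 3]]])
        p = self.points
        a = p[tris[:, 1]] - p[tris[:, 0]]
        b = p[tris[:, 2]] - p[tris[:, 0]]
        return float(0.5 * np.linalg.norm(np.cross(a, b), axis=1).sum())


def make_tube_mesh(spec: TubeSpec) -> SurfaceMesh:
    """Structured n_axial x n_circ quad mesh on the mid-surface cylinder.

    The circumferential seam is closed: column n_circ-1 shares its second
    edge with column 0, so phi=0 and phi=2*pi are the same nodes.
    """
    n_z, n_c = spec.n_axial + 1, spec.n_circ
    rows = np.arange(n_z)
    cols = np.arange(n_c)
    z_nodes = np.repeat(rows * spec.dz, n_c)
    phi_nodes = np.tile(cols * spec.dphi, n_z)
    r = spec.mid_radius
    points = np.column_stack(
        [r * np.cos(phi_nodes), r * np.sin(phi_nodes), z_nodes]
    )
    faces = np.empty((spec.n_axial * n_c, 4), dtype=np.int64)
    for i in range(spec.n_axial):
        for j in range(n_c):
            jn = (j + 1) % n_c
            faces[i * n_c + j] = (
                i * n_c + j,
                i * n_c + jn,
                (i + 1) * n_c + jn,
                (i + 1) * n_c + j,
            )
    return SurfaceMesh(points=points, faces=faces, z=z_nodes, phi=phi_nodes, tube=spec)


def _patch_bump(patch: ThinPatchSpec, z: np.ndarray, phi: np.ndarray) -> np.ndarray:
    dphi = np.angle(np.exp(1j * (phi - patch.circ_center)))  # wrapped
    rho2 = ((z - patch.axial_center) / patch.axial_halfwidth) ** 2 + (
        dphi / patch.circ_halfwidth
    ) ** 2
    return np.exp(-(rho2 ** patch.transition))


def build_thickness_field(
    spec: TubeSpec,
    patches: list[ThinPatchSpec] | None = None,
    noise_amplitude: float = 0.0,
    noise_corr_length: float = 5.0,
    seed: int | None = None,
) -> ThicknessField:
    """Smooth per-element thickness field: base wall, thin patches, noise.

    Thickness at each patch center equals its min_thickness exactly (the
    noise is modulated to vanish there — the patch minimum is a controlled
    parameter); far from patches the field is base_thickness plus
    (optional) correlated noise.  Deterministic for a fixed seed.
    """
    patches = patches or []
    z_c, phi_c = spec.element_centers()
    zz, pp = np.meshgrid(z_c, phi_c, indexing="ij")
    t = np.full_like(zz, spec.base_thickness)
    bump_total = np.zeros_like(zz)
    for patch in patches:
        if patch.min_thickness >= spec.base_thickness:
            raise ValueError(
                f"patch min_thickness {patch.min_thickness} must be below "
                f"base_thickness {spec.base_thickness}"
            )
        if not (0.0 <= patch.axial_center <= spec.length):
            raise ValueError(
                f"patch axial_center {patch.axial_center} outside mesh span "
                f"[0, {spec.length}]"
            )
        depth = spec.base_thickness - patch.min_thickness
        bump = _patch_bump(patch, zz, pp)
        t = t - depth * bump
        bump_total = np.maximum(bump_total, bump)
    if noise_amplitude > 0.0:
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(seed)
        white = rng.standard_normal(t.shape)
        sig_z = noise_corr_length / spec.dz
        sig_p = noise_corr_length / (spec.mid_radius * spec.dphi)
        smooth = gaussian_filter(white, sigma=(sig_z, sig_p), mode=("nearest", "wrap"))
        sd = smooth.std()
        if sd > 0:
            t = t + noise_amplitude * (smooth / sd) * (1.0 - bump_total)
    # multiple overlapping patches could drive t negative; that is a user error
    if not np.all(t > 0):
        raise ValueError("thickness field non-positive; patches/noise too aggressive")
    return ThicknessField(values=t, seed=seed)


def make_helix_path(
    h: HelixSpec,
    t: TubeSpec,
    points_per_turn: int = 72,
    pitch_jitter_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """3D polyline of the (double) helix thread centerline, shape (n, 3).

    Layer 1 winds from z=0 to z=length advancing +z; layer 2 returns from
    z=length to 0 with the opposite winding sense and a half-turn phase
    offset, so the two layers cross and fuse periodically as on the real
    specimens.  The polyline is continuous (layer 2 starts where layer 1
    ends).  Optional seeded pitch jitter perturbs the turn spacing.
    """
    if h.n_layers == 0:
        return np.empty((0, 3))
    r = h.winding_radius(t)
    n_turns = t.length / h.pitch
    n_pts = max(2, int(np.ceil(n_turns * points_per_turn)))
    s = np.linspace(0.0, 1.0, n_pts)  # normalized axial coordinate
    z1 = s * t.length
    if pitch_jitter_sd > 0.0:
        rng = np.random.default_rng(seed)
        wobble = np.cumsum(rng.standard_normal(n_pts)) / np.sqrt(n_pts)
        wobble -= s * wobble[-1]  # keep endpoints exact
        z1 = np.clip(z1 + pitch_jitter_sd * wobble, 0.0, t.length)
        z1.sort()
    ang1 = h.phase + h.handedness * 2.0 * np.pi * z1 / h.pitch
    layers = [np.column_stack([r * np.cos(ang1), r * np.sin(ang1), z1])]
    if h.n_layers == 2:
        z2 = z1[::-1]
        ang2 = h.phase + np.pi - h.handedness * 2.0 * np.pi * z2 / h.pitch
        # turn-around: a surface arc along the far end ring joins the layers
        # (the extruder reverses on the scaffold, not through it)
        d_ang = float(np.angle(np.exp(1j * (ang2[0] - ang1[-1]))))
        if abs(d_ang) > 1e-12:
            n_arc = max(2, int(np.ceil(abs(d_ang) / (2.0 * np.pi / points_per_turn))))
            arc = ang1[-1] + d_ang * np.linspace(0.0, 1.0, n_arc + 1)[1:-1]
            layers.append(
                np.column_stack(
                    [r * np.cos(arc), r * np.sin(arc), np.full(arc.size, z1[-1])]
                )
            )
        layers.append(np.column_stack([r * np.cos(ang2), r * np.sin(ang2), z2]))
    return np.vstack(layers)


def helix_coverage(
    path: np.ndarray, mesh: SurfaceMesh, thread_diameter: float | None = None
) -> np.ndarray:
    """Assign helix path length to shell elements, shape (n_axial, n_circ).

    Each polyline segment's length goes to the element whose (z, phi)
    footprint contains the segment midpoint; the sum over elements equals
    the path length (0.1% conservation is the contract, exact here up to
    floating point).  Warns if any path point sits more than two thread
    diameters off the outer wall surface (geometry mismatch).
    """
    tube = mesh.tube
    if tube is None or mesh.external:
        raise ValueError("helix_coverage requires a native parameterized mesh")
    cov = np.zeros((tube.n_axial, tube.n_circ))
    if len(path) < 2:
        return cov
    a, b = path[:-1], path[1:]
    seg_vec = b - a
    # unwrap angle across each segment so mid-angle and length are right
    ang_a = np.arctan2(a[:, 1], a[:, 0])
    d_ang = np.angle(np.exp(1j * (np.arctan2(b[:, 1], b[:, 0]) - ang_a)))
    mid_phi = np.mod(ang_a + 0.5 * d_ang, 2.0 * np.pi)
    mid = 0.5 * (a + b)
    mid_z = np.clip(mid[:, 2], 0.0, tube.length - 1e-12)
    lengths = np.linalg.norm(seg_vec, axis=1)
    radial = np.hypot(mid[:, 0], mid[:, 1])
    if thread_diameter is None:
        # estimate the thread clearance from the path itself
        thread_diameter = max(2.0 * (radial.mean() - tube.outer_radius), 0.1)
    if np.any(np.abs(radial - tube.outer_radius) > 2.0 * thread_diameter):
        warnings.warn(
            "helix path is radially distant from the scaffold surface; "
            "geometry mismatch", stacklevel=2,
        )
    rows = np.minimum((mid_z / tube.dz).astype(int), tube.n_axial - 1)
    cols = np.minimum((mid_phi / tube.dphi).astype(int), tube.n_circ - 1)
    np.add.at(cov, (rows, cols), lengths)
    return cov


def path_length(path: np.ndarray) -> float:
    if len(path) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(path, axis=0), axis=1).sum())


@dataclass
class ScaffoldModel:
    """A scaffold ready for structural analysis.

    Bundles the shell mesh, the thickness field, the (optional) helix and
    its per-element coverage, and the material handles that the solver and
    the growth driver consume.  ``bio_law`` is any object with
    ``stress(eps)`` / ``tangent(eps)`` (see helixgraft.materials); the
    default is the 1 MPa linear wall.
    """

    mesh: SurfaceMesh
    thickness: ThicknessField
    bio_law: object
    nu_bio: float = 0.45
    helix: HelixSpec | None = None
    polymer: object | None = None  # PolymerParams
    coverage: np.ndarray | None = None
    name: str = "scaffold"

    @property
    def tube(self) -> TubeSpec:
        assert self.mesh.tube is not None
        return self.mesh.tube

    def helix_hoop_stiffness(self) -> np.ndarray:
        """Homogenized helix hoop membrane stiffness per element (N/mm).

        E_p * A_thread * cos^2(theta) * coverage / element_area, with the
        coverage of each axial row smeared uniformly over its circumference
        (the tied helix restrains the whole ring it wraps, projected per
        unit axial length).
        """
        tube = self.tube
        shape = (tube.n_axial, tube.n_circ)
        if self.helix is None or self.polymer is None or self.coverage is None:
            return np.zeros(shape)
        theta = self.helix.helix_angle(tube)
        el_area = tube.dz * tube.mid_radius * tube.dphi
        row_cov = self.coverage.sum(axis=1) / tube.n_circ  # mm path per element slot
        per_row = (
            self.polymer.E * self.helix.thread_area * np.cos(theta) ** 2
            * row_cov / el_area
        )
        return np.repeat(per_row[:, None], tube.n_circ, axis=1)


def assemble_scaffold(
    tube: TubeSpec,
    thickness: ThicknessField,
    bio_law,
    helix: HelixSpec | None = None,
    polymer=None,
    nu_bio: float = 0.45,
    name: str = "scaffold",
    seed: int | None = None,
    pitch_jitter_sd: float = 0.0,
) -> ScaffoldModel:
    """Build mesh + helix path + coverage into a solvable ScaffoldModel."""
    mesh = make_tube_mesh(tube)
    coverage = None
    if helix is not None and helix.n_layers > 0:
        path = make_helix_path(helix, tube, pitch_jitter_sd=pitch_jitter_sd, seed=seed)
        coverage = helix_coverage(path, mesh, thread_diameter=helix.thread_diameter)
    return ScaffoldModel(
        mesh=mesh,
        thickness=thickness,
        bio_law=bio_law,
        nu_bio=nu_bio,
        helix=helix,
        polymer=polymer,
        coverage=coverage,
        name=name,
    )


# ---------------------------------------------------------------------------
# STL I/O


def _validate_stl_bytes(data: bytes) -> None:
    """Structural sanity check with byte/line offsets for malformed files."""
    if len(data) < 15:
        raise ScaffoldIOError(f"STL too short ({len(data)} bytes) at byte 0")
    is_ascii = data[:6].strip().lower().startswith(b"solid") and b"facet" in data[:2048]
    if is_ascii:
        text = data.decode("ascii", errors="replace")
        n_facet = text.count("facet normal")
        n_end = text.count("endfacet")
        if n_facet != n_end:
            off = text.rfind("facet normal")
            raise ScaffoldIOError(
                f"ASCII STL facet/endfacet mismatch ({n_facet} vs {n_end}); "
                f"last facet starts at byte {off}"
            )
        if "endsolid" not in text:
            raise ScaffoldIOError(f"ASCII STL missing endsolid (file ends at byte {len(data)})")
        return
    if len(data) < 84:
        raise ScaffoldIOError(f"binary STL header truncated at byte {len(data)}")
    n_tri = int.from_bytes(data[80:84], "little")
    expected = 84 + 50 * n_tri
    if len(data) != expected:
        raise ScaffoldIOError(
            f"binary STL declares {n_tri} triangles ({expected} bytes) but file "
            f"has {len(data)}; truncation at byte {min(expected, len(data))}"
        )


def import_stl(file) -> SurfaceMesh:
    """Read an STL surface (ASCII or binary) as an external triangle mesh.

    Imported meshes carry no (z, phi) parameterization and are flagged
    ``external``; they serve geometry statistics and coarse checks, e.g. on
    the authors' deposited micro-CT facets.
    """
    if hasattr(file, "read"):
        data = file.read()
    else:
        with open(file, "rb") as fh:
            data = fh.read()
    _validate_stl_bytes(data)
    try:
        tm = trimesh.load(io.BytesIO(data), file_type="stl", process=False)
    except Exception as exc:  # pragma: no cover - trimesh internals
        raise ScaffoldIOError(f"STL parse failed: {exc}") from exc
    return SurfaceMesh(
        points=np.asarray(tm.vertices, dtype=float),
        faces=np.asarray(tm.faces, dtype=np.int64),
        external=True,
    )


def export_stl(mesh: SurfaceMesh, file) -> None:
    """Write a mesh as binary STL (quads are split into two triangles)."""
    faces = mesh.faces
    if faces.shape[1] == 4:
        faces = np.vstack([faces[:, [0, 1, 2]], faces[:, [0, 2, 3]]])
    tm = trimesh.Trimesh(vertices=mesh.points, faces=faces, process=False)
    tm.export(file, file_type="stl")
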