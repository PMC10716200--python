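"""Scaffold geometry: tube meshes, thickness fields, helix paths, STL I/O."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import helixgraft as hg
from helixgraft.geometry import ScaffoldIOError, path_length


class TestTubeMesh:
    def test_grid_dimensions_and_mid_surface_radius(self):
        tube = hg.TubeSpec(inner_diameter=5.0, length=60.0, base_thickness=0.5,
                           n_axial=60, n_circ=32)
        mesh = hg.make_tube_mesh(tube)
        assert mesh.n_elements == 60 * 32
        assert mesh.n_nodes == 61 * 32
        radii = np.hypot(mesh.points[:, 0], mesh.points[:, 1])
        assert np.allclose(radii, 2.75)

    def test_axial_span_matches_transverse_specimen_length(self):
        mesh = hg.make_tube_mesh(hg.TubeSpec(length=15.0, n_axial=15))
        assert mesh.points[:, 2].max() == pytest.approx(15.0)
        assert mesh.points[:, 2].min() == 0.0

    def test_circumferential_seam_is_closed(self):
        tube = hg.TubeSpec(n_axial=4, n_circ=8)
        mesh = hg.make_tube_mesh(tube)
        # the last column's elements reuse column-0 nodes: every node id in
        # faces is a valid grid node and each interior node is shared by 4 quads
        assert mesh.faces.max() == mesh.n_nodes - 1
        counts = np.bincount(mesh.faces.ravel(), minlength=mesh.n_nodes)
        interior = counts.reshape(5, 8)[1:-1, :]
        assert np.all(interior == 4)

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(inner_diameter=-1.0), "inner_diameter"),
            (dict(length=0.0), "length"),
            (dict(base_thickness=-0.5), "base_thickness"),
            (dict(n_circ=9), "even"),
            (dict(n_axial=2), "n_axial"),
        ],
    )
    def test_invalid_spec_rejected_naming_field(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            hg.TubeSpec(**kwargs)

    def test_refinement_changes_surface_area_below_one_percent(self):
        coarse = hg.make_tube_mesh(hg.TubeSpec(n_axial=30, n_circ=16))
        fine = hg.make_tube_mesh(hg.TubeSpec(n_axial=30, n_circ=32))
        a0, a1 = coarse.surface_area(), fine.surface_area()
        assert abs(a1 - a0) / a1 < 0.01


class TestThicknessField:
    def test_no_patches_zero_noise_is_constant(self):
        tube = hg.TubeSpec()
        field = hg.build_thickness_field(tube)
        assert np.all(field.values == tube.base_thickness)

    def test_patch_minimum_attained_at_center(self):
        tube = hg.TubeSpec(n_axial=60, n_circ=32)
        z_c, phi_c = tube.element_centers()
        patch = hg.ThinPatchSpec(
            axial_center=float(z_c[30]), circ_center=float(phi_c[5]),
            axial_halfwidth=4.0, circ_halfwidth=0.8, min_thickness=0.06,
        )
        field = hg.build_thickness_field(tube, [patch])
        assert field.min == pytest.approx(0.06)
        assert field.values[30, 5] == pytest.approx(0.06)

    def test_patch_center_exact_even_with_noise(self):
        tube = hg.TubeSpec(n_axial=60, n_circ=32)
        z_c, phi_c = tube.element_centers()
        patch = hg.ThinPatchSpec(
            axial_center=float(z_c[30]), circ_center=float(phi_c[5]),
            axial_halfwidth=4.0, circ_halfwidth=0.8, min_thickness=0.06,
        )
        field = hg.build_thickness_field(tube, [patch], noise_amplitude=0.05, seed=3)
        assert field.values[30, 5] == pytest.approx(0.06)

    def test_seeded_fields_are_bit_reproducible(self):
        tube = hg.TubeSpec()
        a = hg.build_thickness_field(tube, noise_amplitude=0.03, seed=7)
        b = hg.build_thickness_field(tube, noise_amplitude=0.03, seed=7)
        assert np.array_equal(a.values, b.values)
        c = hg.build_thickness_field(tube, noise_amplitude=0.03, seed=8)
        assert not np.array_equal(a.values, c.values)

    def test_patch_outside_span_rejected(self):
        tube = hg.TubeSpec(length=60.0)
        patch = hg.ThinPatchSpec(
            axial_center=70.0, circ_center=0.0, axial_halfwidth=3.0,
            circ_halfwidth=0.5, min_thickness=0.06,
        )
        with pytest.raises(ValueError, match="outside"):
            hg.build_thickness_field(tube, [patch])


class TestHelixPath:
    def test_turn_count_matches_span_over_pitch(self):
        tube = hg.TubeSpec(length=15.0, n_axial=15)
        helix = hg.HelixSpec(pitch=2.25, thread_diameter=0.33, n_layers=1)
        path = hg.make_helix_path(helix, tube)
        angles = np.unwrap(np.arctan2(path[:, 1], path[:, 0]))
        turns = abs(angles[-1] - angles[0]) / (2 * np.pi)
        assert turns == pytest.approx(15.0 / 2.25, rel=1e-3)

    def test_helix_angle_closed_form(self):
        # atan(pitch / (pi * winding diameter)); pitch 2.25 on ~6 mm tube -> ~6.8 deg
        tube = hg.TubeSpec(inner_diameter=5.0, base_thickness=0.5)
        helix = hg.HelixSpec(pitch=2.25, thread_diameter=0.33)
        expected = np.arctan(2.25 / (np.pi * 2 * helix.winding_radius(tube)))
        assert helix.helix_angle(tube) == pytest.approx(expected)
        assert np.degrees(expected) == pytest.approx(6.8, abs=0.5)

    def test_zero_layers_gives_empty_path(self):
        path = hg.make_helix_path(
            hg.HelixSpec(pitch=2.25, thread_diameter=0.33, n_layers=0), hg.TubeSpec()
        )
        assert path.shape == (0, 3)

    def test_double_helix_is_continuous(self):
        tube = hg.TubeSpec(length=15.0, n_axial=15)
        helix = hg.HelixSpec(pitch=2.25, thread_diameter=0.33, n_layers=2)
        path = hg.make_helix_path(helix, tube)
        steps = np.linalg.norm(np.diff(path, axis=0), axis=1)
        # no jump larger than a few sampling steps anywhere (incl. turn-around)
        assert steps.max() < 5 * np.median(steps)

    def test_invalid_pitch_rejected(self):
        with pytest.raises(ValueError, match="pitch"):
            hg.HelixSpec(pitch=-1.0, thread_diameter=0.3)
        with pytest.raises(ValueError, match="pitch"):
            hg.HelixSpec(pitch=0.2, thread_diameter=0.3)


class TestHelixCoverage:
    def test_empty_path_gives_zero_coverage(self):
        mesh = hg.make_tube_mesh(hg.TubeSpec())
        cov = hg.helix_coverage(np.empty((0, 3)), mesh)
        assert np.all(cov == 0)

    def test_hoop_ring_limit_concentrates_in_one_row(self):
        # a closed circle at one z: coverage confined to that row, sum = pi*D
        tube = hg.TubeSpec(n_axial=10, length=10.0)
        mesh = hg.make_tube_mesh(tube)
        r_w = 3.165
        ang = np.linspace(0, 2 * np.pi, 721)
        ring = np.column_stack(
            [r_w * np.cos(ang), r_w * np.sin(ang), np.full(ang.size, 4.5)]
        )
        cov = hg.helix_coverage(ring, mesh, thread_diameter=0.33)
        assert cov[4].sum() == pytest.approx(cov.sum())
        assert cov.sum() == pytest.approx(2 * np.pi * r_w, rel=1e-3)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        pitch=st.floats(1.5, 4.0),
        phase=st.floats(0.0, 2 * np.pi),
        n_layers=st.sampled_from([1, 2]),
    )
    def test_coverage_conserves_path_length(self, pitch, phase, n_layers):
        tube = hg.TubeSpec(length=30.0, n_axial=30, n_circ=16)
        helix = hg.HelixSpec(
            pitch=pitch, thread_diameter=0.3, n_layers=n_layers, phase=phase
        )
        mesh = hg.make_tube_mesh(tube)
        path = hg.make_helix_path(helix, tube)
        cov = hg.helix_coverage(path, mesh, thread_diameter=0.3)
        assert cov.sum() == pytest.approx(path_length(path), rel=1e-3)

    def test_per_row_coverage_nearly_uniform(self, models):
        cov = models["pvdf"].coverage
        rows = cov.sum(axis=1)
        assert rows.std() / rows.mean() < 0.15

    def test_distant_path_warns(self):
        tube = hg.TubeSpec()
        mesh = hg.make_tube_mesh(tube)
        far_ring = np.column_stack(
            [10 * np.cos(np.linspace(0, 6, 50)), 10 * np.sin(np.linspace(0, 6, 50)),
             np.full(50, 30.0)]
        )
        with pytest.warns(UserWarning, match="radially distant"):
            hg.helix_coverage(far_ring, mesh, thread_diameter=0.33)


class TestStlIO:
    def test_round_trip_preserves_vertices(self, tmp_path):
        mesh = hg.make_tube_mesh(hg.TubeSpec(n_axial=10, n_circ=8))
        f = tmp_path / "tube.stl"
        hg.export_stl(mesh, f)
        back = hg.import_stl(f)
        assert back.external
        # match vertex sets (trimesh may reorder)
        orig = np.unique(np.round(mesh.points, 6), axis=0)
        got = np.unique(np.round(back.points, 6), axis=0)
        assert orig.shape == got.shape
        assert np.max(np.abs(orig - got)) < 1e-4

    def test_unit_tetrahedron_reads_four_triangles(self):
        verts = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float
        )
        faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
        tet = hg.SurfaceMesh(points=verts, faces=faces, external=True)
        buf = io.BytesIO()
        hg.export_stl(tet, buf)
        buf.seek(0)
        back = hg.import_stl(buf)
        assert back.faces.shape[0] == 4

    def test_truncated_binary_stl_rejected_with_offset(self):
        data = b"\x00" * 80 + (1000).to_bytes(4, "little") + b"\x00" * 100
        with pytest.raises(ScaffoldIOError, match="byte"):
            hg.import_stl(io.BytesIO(data))

    def test_malformed_ascii_stl_rejected(self):
        text = b"solid junk\nfacet normal 0 0 1\nouter loop\n"  # never closed
        with pytest.raises(ScaffoldIOError):
            hg.import_stl(io.BytesIO(text))
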