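"""Pressure, longitudinal and ring solvers against closed-form oracles."""

import numpy as np
import pytest

import helixgraft as hg
from helixgraft.solver import (
    coil_spring_stiffness,
    ring_composite_section,
    ring_point_load_compliance,
)

FREE = hg.BoundaryCondition("free")


class TestLaplaceReference:
    def test_closed_form_value(self):
        with pytest.warns(UserWarning, match="thick-wall"):
            assert hg.laplace_reference(0.016, 2.5, 0.5, 1.0) == pytest.approx(0.08)

    def test_zero_pressure_and_thickness_proportionality(self):
        assert hg.laplace_reference(0.0, 2.5, 0.1, 1.0) == 0.0
        a = hg.laplace_reference(0.012, 2.5, 0.1, 1.0)
        b = hg.laplace_reference(0.012, 2.5, 0.2, 1.0)
        assert a == pytest.approx(2.0 * b)


class TestSolvePressure:
    def test_uniform_tube_matches_laplace_within_one_percent(
        self, uniform_tube, virgin_state_uniform
    ):
        res = hg.solve_pressure(uniform_tube, virgin_state_uniform, 0.012, FREE)
        expected = 0.012 * 2.5 / (0.5 * 1.0)  # p*r/(t*E) = 0.06
        assert res.converged
        assert np.max(np.abs(res.hoop_strain - expected)) / expected < 0.01

    def test_zero_pressure_returns_zero_without_iterating(
        self, uniform_tube, virgin_state_uniform
    ):
        res = hg.solve_pressure(uniform_tube, virgin_state_uniform, 0.0, FREE)
        assert res.iterations == 0
        assert np.all(res.U1 == 0.0)

    def test_helix_cuts_hoop_strain_by_over_tenfold(self, virgin_state_uniform):
        tube = hg.TubeSpec(n_axial=60, n_circ=32)
        th = hg.build_thickness_field(tube)
        bare = hg.assemble_scaffold(tube, th, hg.LinearLaw(1.0))
        reinforced = hg.assemble_scaffold(
            tube, th, hg.LinearLaw(1.0),
            helix=hg.HelixSpec(pitch=2.25, thread_diameter=0.33),
            polymer=hg.PolymerParams(E=458.0),
        )
        s0 = hg.solve_pressure(bare, virgin_state_uniform, 0.012, FREE)
        s1 = hg.solve_pressure(reinforced, virgin_state_uniform, 0.012, FREE)
        assert s0.hoop_strain.max() / s1.hoop_strain.max() > 10.0
        # homogenized helix stiffness dwarfs the bio wall's E*t = 0.5 N/mm
        assert reinforced.helix_hoop_stiffness().max() > 20.0

    def test_helix_never_increases_displacement(self, virgin_state_uniform):
        tube = hg.TubeSpec(n_axial=60, n_circ=32)
        th = hg.build_thickness_field(tube)
        bare = hg.assemble_scaffold(tube, th, hg.LinearLaw(1.0))
        reinforced = hg.assemble_scaffold(
            tube, th, hg.LinearLaw(1.0),
            helix=hg.HelixSpec(pitch=2.15, thread_diameter=0.30),
            polymer=hg.PolymerParams(E=321.0, id="PCL"),
        )
        s0 = hg.solve_pressure(bare, virgin_state_uniform, 0.016, FREE)
        s1 = hg.solve_pressure(reinforced, virgin_state_uniform, 0.016, FREE)
        assert np.all(s1.U1 <= s0.U1 + 1e-12)

    def test_encastre_bands_stay_fixed(self, models):
        model = models["control"]
        tube = model.tube
        state = hg.MaterialState.virgin((tube.n_axial, tube.n_circ))
        res = hg.solve_pressure(model, state, 0.016, hg.BoundaryCondition())
        w = res.U1.reshape(tube.n_axial + 1, tube.n_circ)
        z = np.arange(tube.n_axial + 1) * tube.dz
        clamped = (z <= 5.0) | (z >= tube.length - 5.0)
        assert np.all(w[clamped] == 0.0)
        assert w[~clamped].max() > 0.0

    def test_mesh_convergence_on_control_preset(self):
        """Halving the element size changes the peak radial displacement
        by under 2% for the first pressurization of the control scenario."""
        peaks = []
        for n_axial, n_circ in [(80, 40), (160, 80)]:
            pre = hg.make_preset("control", n_axial=n_axial, n_circ=n_circ)
            model = hg.build_model(pre, seed=1)
            state = hg.MaterialState.virgin((n_axial, n_circ))
            res = hg.solve_pressure(model, state, pre.protocol.p_max)
            peaks.append(res.U1.max())
        assert abs(peaks[1] - peaks[0]) / peaks[1] < 0.02

    def test_negative_pressure_rejected(self, uniform_tube, virgin_state_uniform):
        with pytest.raises(ValueError):
            hg.solve_pressure(uniform_tube, virgin_state_uniform, -0.01, FREE)

    def test_overload_flags_model_validity(self, uniform_tube, virgin_state_uniform):
        res = hg.solve_pressure(uniform_tube, virgin_state_uniform, 0.15, FREE)
        assert any("validity" in f for f in res.flags)


class TestLongitudinalTension:
    def test_bar_force_at_ten_percent_strain(self, uniform_tube):
        # F = E * eps * A_annulus; A = pi*(3^2 - 2.5^2) = 8.64 mm^2
        disp, force = hg.solve_longitudinal_tension(uniform_tube, 6.0)
        area = np.pi * (3.0**2 - 2.5**2)
        assert force[-1] == pytest.approx(1.0 * 0.1 * area, rel=1e-6)

    def test_helix_changes_axial_force_under_five_percent(self, models):
        d0, f0 = hg.solve_longitudinal_tension(models["control"], 6.0)
        d1, f1 = hg.solve_longitudinal_tension(models["pvdf"], 6.0)
        assert abs(f1[-1] - f0[-1]) / f0[-1] < 0.05

    def test_zero_displacement_gives_zero_force(self, uniform_tube):
        disp, force = hg.solve_longitudinal_tension(uniform_tube, 0.0)
        assert np.all(force == 0.0)

    def test_negative_displacement_rejected(self, uniform_tube):
        with pytest.raises(ValueError):
            hg.solve_longitudinal_tension(uniform_tube, -1.0)

    def test_coil_spring_closed_form(self):
        # G*d^4/(8*D^3*n)
        assert coil_spring_stiffness(100.0, 0.4, 6.0, 10.0) == pytest.approx(
            100.0 * 0.4**4 / (8 * 216.0 * 10.0)
        )


class TestTransverseRing:
    def test_slender_ring_matches_curved_beam_closed_form(self):
        # bending-only oracle: delta = F R^3/(EI) (pi/4 - 2/pi)
        R, EI = 10.0, 50.0
        compliance = ring_point_load_compliance(R, EA=1e9, EI=EI, n=128)
        ref = hg.ring_compliance_reference(1.0, R, 1.0, EI)
        assert compliance == pytest.approx(ref, rel=0.02)

    def test_composite_ring_stiffer_than_bio_only(self, models):
        ctrl = hg.build_model(hg.make_preset("control", length=15.0, n_axial=20), seed=1)
        pvdf = hg.build_model(hg.make_preset("pvdf", length=15.0, n_axial=20), seed=1)
        assert ring_composite_section(pvdf)[1] > ring_composite_section(ctrl)[1]
        d0, f0 = hg.solve_transverse_ring(ctrl, 1.0)
        d1, f1 = hg.solve_transverse_ring(pvdf, 1.0)
        assert f1[-1] > f0[-1]

    def test_zero_displacement_gives_zero_force(self):
        ctrl = hg.build_model(hg.make_preset("control", length=15.0, n_axial=20), seed=1)
        disp, force = hg.solve_transverse_ring(ctrl, 0.0)
        assert np.all(force == 0.0)

    def test_pin_wider_than_lumen_rejected(self):
        ctrl = hg.build_model(hg.make_preset("control", length=15.0, n_axial=20), seed=1)
        with pytest.raises(ValueError, match="pin diameter"):
            hg.solve_transverse_ring(ctrl, 1.0, pin_diameter=6.0)
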