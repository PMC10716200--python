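# helixgraft

Desk-scale simulator of **externally helix-reinforced decellularized
vascular scaffolds**.

Decellularized arteries (here: 5 mm inner-diameter vessels) are promising
small-caliber graft substrates, but decellularization weakens the wall and
the grafts tend to fail by aneurysmal dilation under blood pressure.  One
proposed remedy is to wind a double polymer helix (PVDF or PCL, extruded
directly onto the vessel) around the outside: it should lock the hoop
(radial) response without stiffening the vessel axially or destroying its
pressure-diameter compliance.  `helixgraft` models that system end to end:

- **Geometry** — structured cylindrical shell meshes with a heterogeneous
  wall-thickness field (locally thin patches emulate weak regions of real
  scaffolds) and an analytic double-helix winding whose path length is
  distributed over the shell elements; STL import/export for scanned
  surfaces.
- **Constitutive model** — the biological wall is linear elastic
  (E₀ = 1 MPa) up to a yield strain ε_y = 0.6 mm/mm.  Beyond yield,
  plastic strain accumulates, `PE ← max(PE, ε − ε_y)`, and the modulus
  degrades linearly with it,

  f(PE) = max(0.1, 1 − 0.9·PE/PE_ref),  PE_ref = 0.0055,

  so the wall bottoms out at 10 % of its initial stiffness.  There is no
  healing: f and PE are monotone over any load history.  The polymers are
  linear elastic (PVDF 458 MPa, PCL 321 MPa), without damage.
- **Structural solver** — a reduced radial-displacement shell (hoop
  membrane stiffness f·E₀·t plus homogenized helix hoop stiffness
  E_p·A·cos²θ·coverage/area, with bending coupling bridging thin patches),
  validated against Laplace's law; a composite-bar model for longitudinal
  tension and a curved-beam ring FE for the transverse pin test, validated
  against δ = F·R³/(E·I)(π/4 − 2/π).
- **Aneurysm growth** — 150 load/unload cycles of 80–120 mmHg: elements
  that yield degrade, soften, strain further next cycle, and degrade more,
  until the damage floor saturates the feedback; residual bulge is
  reconstructed from the accumulated plastic hoop strain.
- **Virtual bench** — pressure-diameter compliance in three ranges
  (50–90 / 80–120 / 110–150 mmHg), tension tests with the 30 %-force-drop
  stop criterion, odd-polynomial (σ = a₁ε + a₃ε³) wall fits, stiffness
  ratios, and a seeded generator of J-shaped synthetic bench curves.

## Worked example

```python
import helixgraft as hg

for name in hg.SCENARIO_NAMES:          # control, pvdf, pcl
    preset = hg.make_preset(name)       # study geometry + protocol
    model = hg.build_model(preset, seed=1)
    trace = hg.run_cycles(model, preset.damage, preset.protocol)
    m = hg.growth_metrics(trace)
    print(name, m["min_modulus_fraction"], m["max_residual_u1_mm"])
```

prints (see `examples/03_aneurysm_growth.py`):

```
scenario     min f  max PE %  resid U1 mm  loaded D mm
control       0.10    650.49       15.247       42.106
pvdf          1.00      0.00        0.000        5.008
pcl           1.00      0.00        0.000        5.013
```

Reading it: after 150 cycles the unreinforced control's thin patch has
degraded to the 10 % modulus floor (`min f = 0.10`) and holds a permanent
bulge, while both reinforced walls never yield — the helix carries the
hoop load, so no plastic strain and no residual dilation at all.  (With a
purely linear damage law the floored patch balloons freely, so the
*absolute* control bulge is far larger than a real vessel's; it is the
orderings and the damage levels that are meaningful — see
`docs/methods.md`.)  The anisotropy of the design shows up in the bench
suite (`examples/04_tension_tests.py`): the helix changes longitudinal
stiffness by ≈ 0.1 % yet multiplies transverse ring stiffness by
hundreds.

More narrative walk-throughs live in `examples/` (geometry, compliance,
growth, tension, curve fitting); a thin CLI mirrors them:

```bash
helixgraft growth --scenario control --cycles 150 --out runs/control
helixgraft compliance --scenario pvdf --range normo
```

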