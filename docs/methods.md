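# Methods

## The model

`helixgraft` simulates a decellularized arterial scaffold (a thin-walled
cylinder of soft collagenous tissue) optionally wrapped in a double
polymer helix, under quasi-static internal pressure and bench-style
tension.  The guiding physical picture: at physiological pressures the
wall works in its compliant toe regime; where the wall is locally thin,
hoop stress p·r/t can exceed the tissue's yield threshold, triggering a
coupled plasticity/degradation process that manifests as an aneurysm-like
permanent bulge.  An external helix adds hoop stiffness orders of
magnitude above the wall's own, so reinforced walls never reach yield.

### Damage-coupled elastoplastic wall

Scalar, hoop-strain-driven, tension-only:

- elastic below the yield strain ε_y: σ = f·E₀·ε, fully reversible;
- above yield, plastic strain jumps to the excess and never decreases:
  PE ← max(PE, ε − ε_y);
- damage (modulus fraction) follows the accumulated plastic strain as a
  linear ramp clamped at a floor:
  f = max(floor, 1 − (1 − floor)·PE/PE_ref);
- reported stress: σ = f·E₀·(ε − PE).

Defaults: E₀ = 1 MPa (small-strain modulus of the decellularized wall,
measured below 1 % strain), ε_y = 0.6 mm/mm, floor = 0.1, PE_ref =
0.0055 mm/mm.  Only the endpoints of the degradation (100 % → 10 %) and
its trigger (yield at 0.6) are empirically grounded; the *shape* of the
ramp is this package's calibration choice, with PE_ref set so that the
floor coincides with the plastic-strain level (0.55 %) at which
full-geometry simulations observed the modulus bottom out.  The ramp is
config-exposed.  Plasticity is isotropic and monotonic (no kinematic
hardening): the load is repeated same-sign cycling, so reverse plasticity
never engages.  Compression is rejected rather than modelled.  The
reported "max plastic strain" is the scalar hoop PE (a principal-strain
measure is not available in the reduced kinematics).

Reinforcement polymers are purely linear elastic (PVDF 458 MPa, PCL
321 MPa, as extruded), with no plasticity or degradation.

### Reduced shell solver

Kinematics are reduced to one radial displacement field w(z, φ) on the
structured mid-surface grid (radius r_in + t/2):

- hoop membrane: each element resists with resultant N(ε) =
  f·σ_bio(ε)·t + C_helix·ε, ε = mean nodal w / R_mid.  The bio term uses
  the *degraded secant* law (σ_bio(ε) = E₀·ε for the linear wall), i.e.
  the current damage field is frozen within a solve; the plastic offset
  enters the reported stress and the residual geometry, not the
  equilibrium stiffness.  This choice makes the cyclic feedback
  *saturate* once damaged elements reach the floor — the strain at peak
  pressure stops growing, so PE stops growing — rather than ratcheting
  without bound.
- hoop state is treated as uniaxial (σ_axial ≈ 0: the end fixtures carry
  the axial load), so the uniform-tube solution reproduces Laplace's law
  ε = p·r_in/(t·E) exactly for any Poisson ratio; ν enters only the
  flexural rigidity D = f·E·t³/(12(1 − ν²)).
- bending: energy ½·D·(∇²w)² with a finite-difference surface Laplacian
  (periodic in φ, mirror closure at free ends so uniform inflation is
  curvature-free).  This is what bridges locally thin patches instead of
  letting them balloon freely, with a decay length λ = (D·R²/C)^¼.
- load: p on the inner surface, nodal force p·r_in·dφ·dz.
- Newton iterations to a relative residual of 1e-9 (one step for linear
  walls; a handful for polynomial J-shaped walls); non-convergence is
  flagged, never silent, and hoop strains above 50 % raise a
  "model validity exceeded" flag while the run continues.

Helix coupling is **tied and homogenized**: the winding "embraces" the
wall and engages immediately in hoop, so frictional sliding is neglected
(the friction coefficient of the full contact formulation is therefore
intentionally unused here).  Per-element coverage (mm of thread path per
element) is computed by footprint-midpoint assignment and then smeared
over each axial row — the thread restrains the whole ring it wraps,
projected per unit axial length — giving C_helix = E_p·A_thread·cos²θ ×
row coverage / element area ≈ 38 N/mm for the PVDF preset versus the
wall's E₀·t = 0.5 N/mm.  Without the row smearing, elements falling
between turns at desk-scale element sizes would spuriously balloon, an
artifact of the assignment rather than of the physics.

### Growth protocol

Default: 150 cycles of 80–120 mmHg (the normotensive preset, in the
printed MPa values 0.011–0.016).  One equilibrium solve per cycle peak;
quasi-static cycling of a rate-independent law makes the intra-cycle
waveform irrelevant.  Unloading defaults to zero pressure (the relaxed
state); residual geometry is reconstructed as w_res = PE·R_mid per
element, averaged to nodes, instead of a second plastic-equilibrium
solve — consistent with the scalar-hoop plasticity and cheap, but an
approximation (no self-equilibration of the residual field).  Reference
geometry stays fixed across cycles (small-strain bookkeeping even when
the damaged patch strains far beyond; see Limitations).  Cycles that
change no state are not re-solved; the remaining rows are replicated,
which is exact for this history-monotone model.

### Virtual bench

- **Compliance**: two endpoint solves per range (hypo 0.007–0.012, normo
  0.011–0.016, hyper 0.015–0.020 MPa), encastre end bands of 5 mm;
  compliance = (D_sys − D_dia)/D_dia·100 with the outer diameter taken at
  mid-span (the widest camera profile; a span-average option exists).
- **Longitudinal tension**: composite bar — annular wall cross-section
  with the wall's material law plus a coil-spring axial stiffness
  G_p·d⁴/(8·D_coil³·n_turns) per helix layer.  The 20 mm/min bench rate
  is treated as quasi-static.
- **Transverse ring**: closed planar curved-beam FE (3 DOF/node frame
  elements on the ring polygon) with a composite section: bio wall
  (15 mm × t at the initial modulus) plus n_layers·n_turns polymer
  threads at the outer surface (parallel-axis offset (t + d)/2).  Pin
  contact is a frozen wrap: opposed point loads, no sliding.  Pin
  diameter defaults to 2 mm (unreported; config-exposed).  Nominal
  transverse stress is F/(2·t·L) — the specimen resists with two wall
  cross-sections — and nominal transverse strain is pin travel over the
  lumen diameter; both are conventions, flagged as such.
- **Stop criterion**: curves terminate at the first sample whose force
  falls below 70 % of the running maximum.
- **Polynomial fit**: least-squares odd polynomial through the origin
  (σ = a₁ε + a₃ε³ by default); the initial modulus is the through-origin
  slope over a small-strain window (default 1 %).

## Synthetic study conditions

The scenario presets encode the study conditions on an idealized
geometry: tube ID 5 mm, length 60 mm (15 mm transverse rings), base wall
0.5 mm — the wall thickness was not reported and 0.5 mm is an assumption,
flagged in the config.  Mesh 80 × 40 elements (halving the element size
changes the peak pressurized displacement by < 1 %, within the 2 %
convergence contract).

One Gaussian thin patch (minimum 0.06 mm, halfwidths 6 mm axially /
1.2 rad circumferentially, snapped to an element center) represents the
locally weak region.  The minimum is chosen so the first-cycle hoop
stress at 120 mmHg, p·r/t ≈ 0.67 MPa, marginally exceeds the yield
stress E₀·ε_y = 0.6 MPa; the halfwidths are chosen wide enough that
bending bridging does not suppress the activation (with 3 mm / 0.6 rad
the first-cycle peak strain stays at 0.42 < 0.6 and the mechanism never
starts; at the default size it reaches 0.64–0.65 across mesh
resolutions).  Correlated thickness noise (amplitude 0.02 mm, correlation
length 5 mm, seeded) emulates the uneven scaffold surface; it is
modulated to vanish at patch centers so the controlled minimum is exact
for every seed.

The double helix uses the measured median geometry: pitch 2.25 mm /
thread 0.33 mm (PVDF), 2.15 / 0.30 mm (PCL), two layers winding opposite
axial directions with a half-turn phase offset so crossings fuse; both
layers share one winding radius (outer wall + half thread), and fusion is
modelled purely as shared coverage, with no joint mechanics.  Optional
seeded pitch jitter (off by default) emulates winding irregularity.

The bench-curve generator produces J-shaped replicates
σ_i = (a₁+δ_i)ε + (a₃+γ_i)ε³ + noise with normal replicate-level
coefficient perturbations (relative sd 10 %) and point noise
(0.02 MPa).  Defaults a₁ = 1 MPa (matching the wall's small-strain
modulus) and a₃ = 2 give a visible collagen-recruitment upturn.  Only the
qualitative structure — J-shape plus spread — is emulated; measured
interquartile ranges are not matched.

## What passing tests do and do not show

The synthetic geometry reproduces the *mechanism* and the *orderings*:
the control's thin region degrades to the 10 % floor and holds a residual
bulge; reinforced walls stay elastic; PVDF confines the loaded diameter
at least as tightly as PCL; the helix is transversely stiffening but
longitudinally neutral.  Absolute magnitudes on the damaged control are
**not** transferable to real vessels: with a linear secant law, a floored
0.06 mm patch balloons to strains far beyond 50 % (the run is flagged
"model validity exceeded" and continues), producing a residual bulge of
~15 mm where full-geometry simulations of real scanned scaffolds show
~0.7 mm.  The bulge magnitude depends directly on the stand-in patch
(real thin-region thickness distributions are unknown here), the linear
law's lack of large-strain stiffening, and the fixed reference geometry.
Conversely, the reinforced presets show *zero* degradation, a stronger
protection than the ~13–23 % modulus decrease seen on real scanned
geometries, because the idealized uniform winding leaves no weakly
covered region at all.

## Numerical choices

- Units mm / N / MPa; angles in radians; elements (axial row,
  circumferential column), 0-based; z along the axis, φ from a fixed
  generator line.
- Poisson ratios are not empirically constrained: ν_bio = 0.45,
  ν_polymer = 0.35, config-exposed; with the uniaxial hoop treatment
  ν_bio affects only bending.
- Solver tolerance 1e-9 (relative residual), max 50 Newton iterations;
  p = 0 returns immediately with zero iterations.
- Damage-localization tie-break: ties in minimum modulus fraction resolve
  to the first element in row-major order.
- Degenerate inputs rejected loudly: negative pressures/displacements,
  compressive strains, pins wider than the lumen, patches outside the
  span, all-zero stress curves, non-increasing strain grids.
- mmHg → MPa uses 1 mmHg = 133.322 Pa, but the three named pressure
  ranges use the study's printed MPa values verbatim.
- Seeded randomness (thickness noise, pitch jitter, curve ensembles) uses
  `numpy.random.default_rng`; equal seeds give bit-identical fields.

## Limitations

Reduced radial-only shell kinematics instead of 3D continuum FE; no
frictional contact (tied helix); no fiber-orientation anisotropy,
viscoelasticity, or enzymatic degradation kinetics; no hemodynamic
(wall-shear or inflammation-driven) remodelling; no polymer fatigue; the
residual geometry is not re-equilibrated; tensile *strength* magnitudes
of real tissue are outside the model (rupture is not encoded, only the
force-drop stop criterion on computed curves).  Imported STL meshes are
supported for geometry statistics and round-tripping, not for the full
shell solve, which requires the native parameterized grid.
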