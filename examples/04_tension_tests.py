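"""Virtual tension bench: longitudinal null effect, transverse stiffening.

Pulls the 60 mm specimens axially (composite bar + coil spring) and the
15 mm rings transversely (curved-beam ring between two lumen pins), then
prints the initial-stiffness ratios reinforced/control for both
directions, reproducing the study's anisotropy: the helix barely changes
longitudinal behavior but multiplies transverse stiffness.
"""

import helixgraft as hg

models60 = {n: hg.build_model(hg.make_preset(n), seed=1) for n in hg.SCENARIO_NAMES}
models15 = {
    n: hg.build_model(hg.make_preset(n, length=15.0, n_axial=20), seed=1)
    for n in hg.SCENARIO_NAMES
}

long_curves = {n: hg.tension_test(m, "longitudinal", 0.10) for n, m in models60.items()}
ring_curves = {n: hg.tension_test(m, "transverse", 0.20) for n, m in models15.items()}

print("longitudinal stress at 10% strain (MPa):")
for n, c in long_curves.items():
    print(f"  {n:8s} {c.stress[-1]:.4f}")

print("\ninitial stiffness ratio vs control (strain window 1%):")
for n in ("pvdf", "pcl"):
    r_long = hg.stiffness_ratio(long_curves[n], long_curves["control"])
    r_ring = hg.stiffness_ratio(ring_curves[n], ring_curves["control"])
    print(f"  {n:8s} longitudinal {r_long:7.3f}   transverse {r_ring:8.1f}")

# stop criterion demo on a synthetic softening record
import numpy as np

force = np.array([0.0, 1.0, 2.0, 3.0, 2.5, 2.0, 1.2])
idx = hg.apply_stop_criterion(force, 0.30)
print(f"\n30%-force-drop stop criterion on {force.tolist()}: stop at index {idx}")
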