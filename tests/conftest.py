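"""Shared fixtures: study presets, built models, and full growth traces.

Growth traces are session-scoped because the 150-cycle runs are the most
expensive objects in the suite and several tests (orderings, localization,
saturation, acceptance) interrogate the same runs.
"""

import numpy as np
import pytest

import helixgraft as hg

SEED = 1


@pytest.fixture(scope="session")
def presets():
    return {name: hg.make_preset(name) for name in hg.SCENARIO_NAMES}


@pytest.fixture(scope="session")
def models(presets):
    return {name: hg.build_model(p, seed=SEED) for name, p in presets.items()}


@pytest.fixture(scope="session")
def traces(presets, models):
    out = {}
    for name in hg.SCENARIO_NAMES:
        pre = presets[name]
        out[name] = hg.run_cycles(models[name], pre.damage, pre.protocol)
    return out


@pytest.fixture(scope="session")
def uniform_tube():
    """Patch-free, noise-free 5 mm ID tube with the 1 MPa wall."""
    tube = hg.TubeSpec(n_axial=60, n_circ=32)
    thickness = hg.build_thickness_field(tube)
    return hg.assemble_scaffold(tube, thickness, hg.LinearLaw(1.0))


@pytest.fixture(scope="session")
def virgin_state_uniform(uniform_tube):
    tube = uniform_tube.tube
    return hg.MaterialState.virgin((tube.n_axial, tube.n_circ))
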