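"""Shared fixtures: small simulated data sets reused across test modules.

Everything is generated at run time from fixed seeds; no binary fixtures.
"""

from __future__ import annotations

import numpy as np
import pytest

from pseudotomo.geometry import FourierReference, matrix_to_euler
from pseudotomo.likelihood import PoseHypothesis
from pseudotomo.simulate import SimulationConfig, make_phantom, simulate_tilt_series
from pseudotomo.workflow import ProjectState


def state_from_truth(stack, truth, box, apply_damage=True):
    """Working state initialised at the ground-truth alignment."""
    return ProjectState(
        stack=stack,
        align=truth.align,
        positions=np.array([p.position for p in truth.poses]),
        poses=[
            PoseHypothesis(np.array(matrix_to_euler(p.rotation))) for p in truth.poses
        ],
        ctf=list(truth.ctf),
        box=box,
        apply_damage=apply_damage,
    )


@pytest.fixture(scope="session")
def phantom32():
    return make_phantom(32, seed=1, pixel_size=4.0)


@pytest.fixture(scope="session")
def ref32(phantom32):
    return FourierReference.from_map(phantom32.data)


@pytest.fixture(scope="session")
def sim_five_tilts(phantom32):
    """Six particles, five tilts (+-40 deg, 20 deg step), moderate noise."""
    cfg = SimulationConfig(
        box=32, n_particles=6, field_size=200, noise_sigma=1.0,
        max_tilt=40, tilt_step=20, apply_damage=True, seed=3,
    )
    stack, truth = simulate_tilt_series(phantom32, cfg)
    return stack, truth


@pytest.fixture(scope="session")
def sim_full_scheme(phantom32):
    """Four particles under the default dose-symmetric +-60/3 scheme."""
    cfg = SimulationConfig(
        box=32, n_particles=4, field_size=200, noise_sigma=1.0,
        max_tilt=60, tilt_step=3, apply_damage=True, seed=5,
    )
    stack, truth = simulate_tilt_series(phantom32, cfg)
    return stack, truth


@pytest.fixture(scope="session")
def sim_noiseless(phantom32):
    cfg = SimulationConfig(
        box=32, n_particles=4, field_size=200, noise_sigma=0.0,
        max_tilt=40, tilt_step=20, apply_damage=False, seed=7,
    )
    stack, truth = simulate_tilt_series(phantom32, cfg)
    return stack, truth
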