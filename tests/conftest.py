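"""Shared fixtures: expensive field solutions solved once per session."""

import numpy as np
import pytest

from electrotick import build_parallel_plate_scene, build_rig_scene
from electrotick.scenes import Conductor, FieldScene
from electrotick.shapes import Sphere
from electrotick.solver import GridSpec, rig_solution, solve_axisymmetric


@pytest.fixture(scope="session")
def rig_fine():
    """Rig at the experimental condition (+750 V, 3 mm gap), fine grid."""
    return rig_solution(gap=0.003, voltage=750.0, h_fine=5e-5)


@pytest.fixture(scope="session")
def rig_pair():
    """Rig at +750 V and -750 V on a lighter grid, for polarity contracts."""
    pos = rig_solution(gap=0.003, voltage=750.0, h_fine=1e-4)
    neg = rig_solution(gap=0.003, voltage=-750.0, h_fine=1e-4)
    return pos, neg


@pytest.fixture(scope="session")
def parallel_plate():
    """Ideal capacitor solution (3 mm gap, 750 V): |E| = 250 kV/m exactly."""
    scene = build_parallel_plate_scene(0.003, 750.0)
    return solve_axisymmetric(scene, GridSpec(h=1e-4))


@pytest.fixture(scope="session")
def mini_scene():
    """Small 3-D scene (charged ball over a grounded floor) for nested-solver
    property tests at tractable cost."""
    return FieldScene(
        domain_lo=(0.0, 0.0, 0.0),
        domain_hi=(0.1, 0.1, 0.1),
        conductors=[
            Conductor(Sphere(center=(0.05, 0.05, 0.06), radius=0.012), 100.0, "ball")
        ],
        symmetry="cartesian3d",
        name="mini ball",
    )


@pytest.fixture(scope="session")
def mini_grids():
    coarse = GridSpec(h=2.5e-3)
    fine = GridSpec(h=5e-4, refinement_box=((0.03, 0.03, 0.03), (0.075, 0.075, 0.078)))
    return coarse, fine
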