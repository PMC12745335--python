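"""Shared fixtures: small synthetic geometries and expensive solves.

Session-scoped fixtures cache the pieces several test modules need
(the Laplace cylinder solve, the dissected-tube solid mesh) so the
suite performs each expensive solve once.
"""

import numpy as np
import pytest

import aortagrow as ag
from aortagrow import stress as st


@pytest.fixture(scope="session")
def straight_tube_scene():
    """Plain tube: radius 15 mm, length 200 mm, no flap."""
    return ag.make_dissected_aorta(
        ag.AortaSpec(shape="straight", radius=15.0, length=200.0,
                     flap_angle=None))


@pytest.fixture(scope="session")
def straight_tube_structured(straight_tube_scene):
    return ag.parameterize_surface(straight_tube_scene)


@pytest.fixture(scope="session")
def dissected_scene():
    """Straight dissected tube with flap, two tears and mural thrombus."""
    return ag.make_dissected_aorta(
        ag.AortaSpec(shape="straight", radius=15.0, length=200.0,
                     n_axial=40, n_circ=24,
                     thrombus=ag.ThrombusSpec(start=110.0, end=160.0,
                                              depth=5.0)))


@pytest.fixture(scope="session")
def dissected_solid(dissected_scene):
    return ag.build_solid_mesh(dissected_scene)


@pytest.fixture(scope="session")
def dissected_tractions(dissected_solid):
    """Two-lumen systolic loading: 120 mmHg TL, 111 mmHg FL (kPa)."""
    return np.where(dissected_solid.facet_lumen == 0, 16.0, 14.8)


@pytest.fixture(scope="session")
def cylinder_fixture():
    """Laplace benchmark shell: inner radius 14 mm, thickness 2 mm."""
    return ag.make_cylinder_fixture(r=14.0, t=2.0, L=100.0, n_layers=4,
                                    n_circ=32, n_axial=24)


@pytest.fixture(scope="session")
def laplace_solution(cylinder_fixture):
    """Penalty solve of the cylinder at 120 mmHg with axial end restraint."""
    p_kpa = 120.0 * st.MMHG_TO_KPA
    tractions = np.full(len(cylinder_fixture.load_facets), p_kpa)
    field = st.forward_penalty_stress(cylinder_fixture, tractions,
                                      fixed_ends="axial")
    return {"field": field, "pressure_kpa": p_kpa}
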