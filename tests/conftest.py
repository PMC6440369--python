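"""Shared fixtures: exact tube anatomies and precomputed centrelines.

Expensive objects (heat-field solves, the marching-cubes atrial anatomy) are
session-scoped; every consumer treats them as read-only.
"""

from __future__ import annotations

import numpy as np
import pytest

import laaoplan as lp

CYL_RADIUS = 10.0
CYL_LENGTH = 40.0


@pytest.fixture(scope="session")
def cylinder():
    """Straight 20 mm-diameter, 40 mm-long LAA with labeled ostium cap."""
    return lp.make_cylinder_laa(radius=CYL_RADIUS, length=CYL_LENGTH)


@pytest.fixture(scope="session")
def cylinder_centreline(cylinder):
    mesh, ostium = cylinder
    fld = lp.solve_heat_field(mesh, ostium, pitch=1.0)
    return lp.march_centreline(fld, ostium)


@pytest.fixture(scope="session")
def straight_centreline():
    """Analytic centreline of the cylinder fixture (exact +z axis)."""
    s = np.linspace(0.0, CYL_LENGTH, 81)
    pts = np.column_stack([np.zeros_like(s), np.zeros_like(s), s])
    tans = np.tile([0.0, 0.0, 1.0], (len(s), 1))
    return lp.Centreline(points=pts, tangents=tans, arc_length=s)


@pytest.fixture(scope="session")
def anatomy():
    """Default bent/tapered synthetic LA + LAA with ground truth."""
    return lp.make_la_with_laa()


@pytest.fixture(scope="session")
def anatomy_centreline(anatomy):
    fld = lp.solve_heat_field(
        anatomy.mesh, anatomy.ostium, pitch=1.0,
        seed_point=anatomy.laa_seed_point,
    )
    return lp.march_centreline(fld, anatomy.ostium)
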