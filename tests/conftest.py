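"""Shared fixtures: small meshes and chamber problems reused across the
suite (session scope; everything is generated programmatically)."""

import numpy as np
import pytest

from pulseloop.fe import ChamberProblem
from pulseloop.geometry import (
    AortaGeometry,
    LVGeometry,
    assign_aorta_fiber_families,
    assign_lv_fibers,
    build_aorta_mesh,
    build_lv_mesh,
)
from pulseloop.materials import AortaMaterial, LVMaterial


@pytest.fixture(scope="session")
def lv_geom():
    return LVGeometry(n_circ=8, n_long=4, n_trans=1)


@pytest.fixture(scope="session")
def lv_mesh(lv_geom):
    return build_lv_mesh(lv_geom)


@pytest.fixture(scope="session")
def lv_frame(lv_mesh):
    return assign_lv_fibers(lv_mesh)


@pytest.fixture(scope="session")
def lv_problem(lv_mesh, lv_frame):
    return ChamberProblem(lv_mesh, lv_frame, LVMaterial())


@pytest.fixture(scope="session")
def tube_geom():
    # straight elastin-dominated verification tube
    return AortaGeometry(
        r_inner=1.0, thickness=0.2, arch_radius=None, length_asc=2.0,
        length_desc=3.0, taper_ratio=1.0, n_circ=8, n_axial=3, n_trans=1,
    )


@pytest.fixture(scope="session")
def tube_mesh(tube_geom):
    return build_aorta_mesh(tube_geom)


@pytest.fixture(scope="session")
def elastin_material():
    # collagen/SMC switched off (negligible moduli): neo-Hookean matrix only
    return AortaMaterial(c2=1e-9, c4=1e-9, S_m=0.0)


@pytest.fixture(scope="session")
def tube_problem(tube_mesh, elastin_material):
    frame = assign_aorta_fiber_families(tube_mesh)
    return ChamberProblem(tube_mesh, frame, elastin_material, active=False)


@pytest.fixture(scope="session")
def aorta_mesh():
    return build_aorta_mesh(AortaGeometry(), resolution=2.0 / 3.0)


@pytest.fixture(scope="session")
def aorta_problem(aorta_mesh):
    frame = assign_aorta_fiber_families(aorta_mesh)
    return ChamberProblem(aorta_mesh, frame, AortaMaterial(), active=True)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
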