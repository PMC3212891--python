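"""Shared fixtures: default geometry, meshes and operators are expensive
enough to build once per session."""

import numpy as np
import pytest

import embryoelast as ee


@pytest.fixture(scope="session")
def geometry():
    return ee.build_default_geometry(4)


@pytest.fixture(scope="session")
def geometry3():
    return ee.build_default_geometry(3)


@pytest.fixture(scope="session")
def materials():
    return ee.MaterialParams(dict(ee.DEFAULT_MODULI_PA), 0.3)


@pytest.fixture(scope="session")
def mesh3000(geometry):
    return ee.generate_mesh(
        geometry, target_nodes=3000, refine_points=[(0.0, 0.0), (0.665, 0.0)]
    )


@pytest.fixture(scope="session")
def midline_op(geometry, mesh3000):
    return ee.PlaneStressOperator(
        mesh3000, geometry, 0.3, ee.midline_load(190.0),
        lattice=ee.default_lattice(),
    )


@pytest.fixture(scope="session")
def homogeneous_disc():
    """Single-material 50-um disc used for the analytic comparisons."""
    regions = list(ee.REGIONS_4)
    geom = ee.RegionGeometry(
        midline_semi_axes=(0.18, 2.2),
        pellucida_semi_axes=(1.15, 2.8),
        outer_radius=5.0,
        thicknesses={r: 50.0 for r in regions},
        intermediate_semi_axes=(0.23, 2.25),
    )
    moduli = {r: 2000.0 for r in regions}
    return geom, moduli


@pytest.fixture(scope="session")
def speckle():
    return ee.make_speckle_image(grain_px=2.0, seed=3)
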