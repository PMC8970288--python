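import numpy as np
import pytest
import trimesh

from varishell.scene import SurfaceMesh


@pytest.fixture(scope="session")
def sphere_cell():
    """Radius-5 um spherical cell at the origin (fine icosphere)."""
    mesh = trimesh.creation.icosphere(subdivisions=4, radius=5.0)
    return SurfaceMesh.from_trimesh("SPH", mesh, repair=False)


@pytest.fixture(scope="session")
def ellipsoid_cell():
    """Ellipsoid with semi-axes (8, 5, 4) um at the origin."""
    mesh = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
    mesh.apply_scale([8.0, 5.0, 4.0])
    return SurfaceMesh.from_trimesh("ELL", mesh, repair=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scenes():
    """Two-subject synthetic dataset small enough for fast end-to-end runs."""
    from varishell.synthetic import GeneratorParams, generate

    params = GeneratorParams(
        n_subjects=2,
        ganglia_per_subject=1,
        cells_per_ganglion=6,
        slab=(200.0, 200.0, 40.0),
        background_intensity=5e-5,
    )
    return generate(params, seed=42)
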