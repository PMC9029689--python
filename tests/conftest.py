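import numpy as np
import pytest

from hybridsurf import extract_boundary_points, phantom_suite
from hybridsurf.synth import standard_specs


@pytest.fixture(scope="session")
def suite():
    """The four standard phantoms: list of (name, SegmentationVolume, SDF)."""
    return phantom_suite()


@pytest.fixture(scope="session")
def sphere_phantom(suite):
    return next(item for item in suite if item[0] == "sphere")


@pytest.fixture(scope="session")
def torus_phantom(suite):
    return next(item for item in suite if item[0] == "torus")


@pytest.fixture(scope="session")
def two_spheres_phantom(suite):
    return next(item for item in suite if item[0] == "two_spheres")


@pytest.fixture(scope="session")
def sphere_center():
    spec = standard_specs()[0]
    return np.asarray(spec.params["center"], dtype=float)


@pytest.fixture(scope="session")
def sphere_boundary(sphere_phantom):
    """Boundary point cloud of the sphere phantom, with normals."""
    _, vol, _ = sphere_phantom
    return extract_boundary_points(vol)


@pytest.fixture(scope="session")
def sphere_surface_cloud(sphere_boundary, sphere_center):
    """Boundary voxel centers projected radially onto the analytic sphere,
    with exact radial normals — points lying exactly on the ground truth."""
    radius = 10.0
    d = sphere_boundary.points - sphere_center
    r = np.linalg.norm(d, axis=1)
    normals = d / r[:, None]
    return sphere_center + radius * normals, normals
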