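import numpy as np
import pytest

from ctsurf import (classify_implicit, extract_surface, make_sphere, mesh_stats,
                    vertex_normals, voxelize)
from ctsurf.core import TriMesh

SPHERE_RADIUS = 12.0
DOMAIN_HALF = 16.0  # sphere grids span [-16, 16] mm per axis


def sphere_field(n: int, radius: float = SPHERE_RADIUS):
    """Tri-state field of a centred sphere sampled on an n^3 grid over [-16, 16]."""
    h = 2 * DOMAIN_HALF / (n - 1)
    grid = voxelize(make_sphere(radius), (n, n, n), (h, h, h),
                    (-DOMAIN_HALF, -DOMAIN_HALF, -DOMAIN_HALF))
    return classify_implicit(grid)


@pytest.fixture(scope="session")
def sphere_field_64():
    return sphere_field(64)


@pytest.fixture(scope="session")
def sphere_mesh_64(sphere_field_64):
    return extract_surface(sphere_field_64)


@pytest.fixture(scope="session")
def sphere_mesh_64_normals(sphere_field_64, sphere_mesh_64):
    return vertex_normals(sphere_field_64, sphere_mesh_64)


@pytest.fixture(scope="session")
def sphere_mesh_5k():
    """~5000-face sphere mesh (33^3 sampling), the decimation test substrate."""
    return extract_surface(sphere_field(33))


def octahedron(scale: float = 0.5) -> TriMesh:
    """Octahedron with apexes at +/-scale on each axis, outward orientation."""
    v = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                  [0, 0, 1], [0, 0, -1]], dtype=float) * scale
    f = np.array([[0, 2, 4], [2, 1, 4], [1, 3, 4], [3, 0, 4],
                  [2, 0, 5], [1, 2, 5], [3, 1, 5], [0, 3, 5]])
    return TriMesh(v, f)


@pytest.fixture
def octa():
    return octahedron()


def signed_volume(mesh: TriMesh) -> float:
    return mesh_stats(mesh).enclosed_volume
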