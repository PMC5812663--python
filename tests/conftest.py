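import numpy as np
import pytest

from mtcortex import (TriangulatedSurface, make_cube, make_sphere)


@pytest.fixture(scope="session")
def tetra_surface() -> TriangulatedSurface:
    """Regular tetrahedron with unit edge length."""
    verts = np.array([
        [1.0, 1.0, 1.0],
        [1.0, -1.0, -1.0],
        [-1.0, 1.0, -1.0],
        [-1.0, -1.0, 1.0],
    ]) / np.sqrt(8.0)   # edge length 1
    faces = np.array([[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
    return TriangulatedSurface(verts, faces)


@pytest.fixture(scope="session")
def cube_surface() -> TriangulatedSurface:
    return make_cube(15.0)


@pytest.fixture(scope="session")
def small_sphere() -> TriangulatedSurface:
    return make_sphere(6.0, 320)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260101)
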