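import numpy as np
import pytest

from cardiogrowth.fem import FESpace
from cardiogrowth.fibers import assign_fibers
from cardiogrowth.geometry import biventricle, sphere_shell
from cardiogrowth.mesh import TetMesh


@pytest.fixture(scope="session")
def bv_mesh():
    return biventricle()


@pytest.fixture(scope="session")
def bv_space(bv_mesh):
    return FESpace(bv_mesh)


@pytest.fixture(scope="session")
def bv_frame(bv_mesh, bv_space):
    return assign_fibers(bv_mesh, space=bv_space)


@pytest.fixture(scope="session")
def shell_mesh():
    """Small truncated spherical shell for cheap FE solves."""
    return sphere_shell(n_l=6, n_c=10)


@pytest.fixture(scope="session")
def slab_mesh():
    """Thin structured slab (one cell thick in y, z) for 1D wave propagation."""
    L, n = 60.0, 60
    x = np.linspace(0.0, L, n + 1)
    y = np.array([0.0, 1.0])
    z = np.array([0.0, 1.0])
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    verts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def vid(i, j, k):
        return (i * 2 + j) * 2 + k

    cells = []
    for i in range(n):
        corners = np.array(
            [
                [vid(i, 0, 0), vid(i, 1, 0), vid(i, 0, 1), vid(i, 1, 1)],
                [vid(i + 1, 0, 0), vid(i + 1, 1, 0), vid(i + 1, 0, 1), vid(i + 1, 1, 1)],
            ]
        )
        a, b, c, d = corners[0]
        e, f, g, h = corners[1]
        # split the hexahedron into 6 tets
        cells += [
            [a, b, d, h], [a, d, c, h], [a, c, g, h],
            [a, g, e, h], [a, e, f, h], [a, f, b, h],
        ]
    cells = np.array(cells)
    region = np.ones(len(cells), dtype=int)  # LVFW
    return TetMesh(verts, cells, region)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240613)
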