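import numpy as np
import pytest

from needlefield.head import BregmaFrame, HeadModel, icosphere, make_nested_head
from needlefield.surfaces import TriSurface


def sphere_head(radii, sigmas, subdiv) -> HeadModel:
    comps = [(icosphere(subdiv, r), s) for r, s in zip(radii, sigmas)]
    return HeadModel(comps, BregmaFrame(origin=np.array([0.0, 0.0, radii[0]])))


def square_grid(n: int = 41, L: float = 10.0) -> TriSurface:
    """Flat triangulated square (open mesh) with a corner at the origin."""
    x, y = np.meshgrid(np.linspace(0, L, n), np.linspace(0, L, n))
    verts = np.c_[x.ravel(), y.ravel(), np.zeros(n * n)]
    tris = []
    for i in range(n - 1):
        for j in range(n - 1):
            v00 = i * n + j
            v01 = i * n + j + 1
            v10 = (i + 1) * n + j
            v11 = (i + 1) * n + j + 1
            tris += [[v00, v01, v11], [v00, v11, v10]]
    return TriSurface(verts, np.array(tris), "square")


@pytest.fixture(scope="session")
def ico3():
    return icosphere(3, 10.0)


@pytest.fixture(scope="session")
def ico4():
    return icosphere(4, 10.0)


@pytest.fixture(scope="session")
def small_head():
    """Default mouse geometry at a coarse, fast resolution."""
    return make_nested_head(subdivisions=3)


@pytest.fixture(scope="session")
def default_head():
    """The default synthetic mouse head (study conditions)."""
    return make_nested_head(subdivisions=4)
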