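import numpy as np
import pytest
import trimesh

from torsofit.mesh import SurfaceMesh
from torsofit.phantoms import TorsoParams, generate_torso


@pytest.fixture(scope="session", autouse=True)
def warm_kernels():
    """Compile the numba kernels once on a tiny mesh so individual tests
    measure computation, not JIT latency."""
    from torsofit import _geometry
    from torsofit._bvh import AABBTree

    box = trimesh.creation.box(extents=[1, 1, 1])
    tree = AABBTree(box.vertices, box.faces)
    tree.query(np.array([[0.0, 0.0, 2.0]]))
    _geometry.winding_numbers(box.vertices, box.faces, np.zeros((1, 3)))


@pytest.fixture
def unit_cube() -> SurfaceMesh:
    box = trimesh.creation.box(extents=[1.0, 1.0, 1.0])
    box.apply_translation([0.5, 0.5, 0.5])  # span [0, 1]^3
    return SurfaceMesh(box.vertices, box.faces)


@pytest.fixture
def icosphere():
    def _make(radius: float, subdivisions: int = 3) -> SurfaceMesh:
        s = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
        return SurfaceMesh(s.vertices, s.faces)

    return _make


@pytest.fixture(scope="session")
def symmetric_torso() -> SurfaceMesh:
    return generate_torso(TorsoParams())


@pytest.fixture(scope="session")
def scoliotic_torso() -> SurfaceMesh:
    return generate_torso(
        TorsoParams(lateral_offset_amplitude=15.0, hump_amplitude=10.0)
    )
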