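import numpy as np
import pytest

from memtube.energy import MembraneParams
from memtube.mesh import build_flat_patch


@pytest.fixture()
def flat_mesh():
    return build_flat_patch(120.0, 120.0, 9.5)


@pytest.fixture()
def params():
    return MembraneParams(kappa=20.0, gamma=0.0, z=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def sphere_mesh():
    """Fine triangulated sphere (R = 50 nm) in a huge periodic box."""
    import trimesh

    from memtube.mesh import TriMesh

    ico = trimesh.creation.icosphere(subdivisions=3, radius=50.0)
    return TriMesh(np.asarray(ico.vertices) + 500.0,
                   np.asarray(ico.faces, np.int32), 1e6, 1e6)
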