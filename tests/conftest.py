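import numpy as np
import pytest

from skulladapt import meshforge, viewsphere
from skulladapt.meshforge import TriMesh


@pytest.fixture(scope="session")
def cube():
    """Unit cube as 12 triangles."""
    v = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)],
                 dtype=float)
    f = np.array([
        [0, 1, 3], [0, 3, 2], [4, 6, 7], [4, 7, 5],
        [0, 4, 5], [0, 5, 1], [2, 3, 7], [2, 7, 6],
        [0, 2, 6], [0, 6, 4], [1, 5, 7], [1, 7, 3],
    ])
    return TriMesh(v, f, name="cube")


@pytest.fixture(scope="session")
def tetrahedron():
    v = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0],
                  [0.0, 0.0, 1.0]])
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriMesh(v, f, name="tetra")


@pytest.fixture(scope="session")
def small_bank():
    """3 species x 4 specimens, deterministic."""
    return meshforge.generate_species_bank(3, 4, seed=7)


@pytest.fixture(scope="session")
def rendered_specimen(small_bank):
    """One clean 64 px render of the first specimen."""
    rec = small_bank[0]
    pose = viewsphere.CameraPose(yaw=40.0, pitch=20.0, distance=2.5)
    return viewsphere.render(rec.mesh, pose, viewsphere.RenderConfig(),
                             rec.species_id, rec.specimen_id)
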