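import numpy as np
import pytest

from crowngen import CrownParams, generate_case, generate_crown
from crowngen.depth import DepthEncoding


@pytest.fixture(scope="session")
def crown_params():
    return CrownParams(n_cusps=4, cusp_height=2.0, seed=7)


@pytest.fixture(scope="session")
def crown_mesh(crown_params):
    return generate_crown(crown_params)


@pytest.fixture(scope="session")
def encoding_96():
    return DepthEncoding(alpha=2.0, h=6.0, mm_per_pixel=0.12, width=96, height=96)


@pytest.fixture(scope="session")
def case64():
    return generate_case(3, image_size=64, local_size=32)


@pytest.fixture(scope="session")
def tiny_cases():
    """Eight small conditioned cases (48x48 global, 24x24 local)."""
    return [generate_case(100 + s, image_size=48, local_size=24) for s in range(8)]


def plane_mesh(z=0.0, half=4.0, step=0.5, standardized=True):
    """A flat square height-field mesh at height z."""
    from crowngen.mesh import ToothMesh

    g = np.arange(-half, half + step / 2, step)
    xx, yy = np.meshgrid(g, g)
    n = len(g)
    verts = np.column_stack([xx.ravel(), yy.ravel(), np.full(xx.size, float(z))])
    idx = np.arange(n * n).reshape(n, n)
    v00 = idx[:-1, :-1].ravel()
    v01 = idx[:-1, 1:].ravel()
    v10 = idx[1:, :-1].ravel()
    v11 = idx[1:, 1:].ravel()
    faces = np.concatenate(
        [np.column_stack([v00, v01, v10]), np.column_stack([v01, v11, v10])]
    )
    return ToothMesh(verts, faces, pose_standardized=standardized)
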