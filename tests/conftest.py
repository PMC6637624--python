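import numpy as np
import pytest

from bivatlas.mesh import ControlMesh
from bivatlas.synthetic import (
    PopulationSpec,
    Template,
    make_template_pair,
)


@pytest.fixture(scope="session")
def template() -> Template:
    return make_template_pair()


@pytest.fixture(scope="session")
def unit_cube() -> ControlMesh:
    V = np.array(
        [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
         [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]],
        float,
    )
    F = np.array(
        [[0, 3, 2, 1], [4, 5, 6, 7], [0, 1, 5, 4],
         [1, 2, 6, 5], [2, 3, 7, 6], [3, 0, 4, 7]]
    )
    return ControlMesh(V, F)


def cube_sphere(radius=10.0, level=4):
    """Subdivided-cube sphere approximation: subdivide, then project every
    vertex onto the sphere."""
    from bivatlas.mesh import catmull_clark

    V = np.array(
        [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
         [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]],
        float,
    )
    F = np.array(
        [[0, 3, 2, 1], [4, 5, 6, 7], [0, 1, 5, 4],
         [1, 2, 6, 5], [2, 3, 7, 6], [3, 0, 4, 7]]
    )
    s = catmull_clark(ControlMesh(V, F), level)
    P = s.vertices - 0.5
    P = radius * P / np.linalg.norm(P, axis=1, keepdims=True)
    return s.with_vertices(P)


@pytest.fixture(scope="session")
def clean_population(template):
    """Small noiseless, shiftless population with planted variation."""
    from bivatlas.synthetic import sample_population

    spec = PopulationSpec(
        n_subjects=4, seed=7, noise_sd_mm=0.0, shift_sd_mm=0.0
    )
    return sample_population(template, spec)
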