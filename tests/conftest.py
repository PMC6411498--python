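import logging

import numpy as np
import pytest
import trimesh

from tubemorph.correspondence import (OpenMesh, compute_cuts,
                                      conformal_parameterize,
                                      resample_to_grid)
from tubemorph.synthetic import CohortSpec, make_cohort, make_template_tube

logging.getLogger("tubemorph").setLevel(logging.ERROR)


def open_cylinder(n_rings=40, n_around=36, radius=5.0, length=30.0,
                  ry=None) -> OpenMesh:
    """Uncapped right (optionally elliptic) cylinder as an OpenMesh."""
    ry = radius if ry is None else ry
    z = np.linspace(0, length, n_rings)
    th = 2 * np.pi * np.arange(n_around) / n_around
    verts = np.array([[radius * np.cos(t), ry * np.sin(t), zz]
                      for zz in z for t in th])
    idx = lambda i, j: i * n_around + (j % n_around)  # noqa: E731
    faces = []
    for i in range(n_rings - 1):
        for j in range(n_around):
            faces.append((idx(i, j), idx(i + 1, j + 1), idx(i, j + 1)))
            faces.append((idx(i, j), idx(i + 1, j), idx(i + 1, j + 1)))
    faces = np.array(faces)
    return OpenMesh(vertices=verts, faces=faces,
                    anterior_loop=np.arange((n_rings - 1) * n_around,
                                            n_rings * n_around),
                    posterior_loop=np.arange(n_around),
                    principal_axis=np.array([0.0, 0.0, 1.0]))


@pytest.fixture(scope="session")
def template_tube():
    return make_template_tube(50, 30, length=40.0, radius_profile=5.0,
                              bend=0.3)


@pytest.fixture(scope="session")
def template_grid(template_tube):
    ps = conformal_parameterize(compute_cuts(template_tube, 0.02))
    return resample_to_grid(ps, 30, 50)


@pytest.fixture(scope="session")
def small_cohort():
    """A small dose-graded cohort shared by the slower integration tests."""
    spec = CohortSpec(group_sizes={"NC": 6, "HT": 5, "HM": 5}, seed=202)
    return make_cohort(spec)


@pytest.fixture(scope="session")
def icosphere():
    return trimesh.creation.icosphere(subdivisions=4, radius=1.0)
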