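import logging

import numpy as np
import pytest
import trimesh

from femurssm.mesh import TriangleMesh
from femurssm.pipeline import PipelineConfig, standardize_mesh
from femurssm.synthetic import make_femur

logging.getLogger("femurssm.mesh").setLevel(logging.ERROR)


def icosphere(subdivisions: int = 3, radius: float = 1.0) -> TriangleMesh:
    ico = trimesh.creation.icosphere(subdivisions=subdivisions)
    return TriangleMesh(
        np.asarray(ico.vertices) * radius, np.asarray(ico.faces)
    )


def tetrahedron() -> TriangleMesh:
    v = np.array(
        [[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float
    )
    # outward-wound closed tetrahedron
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriangleMesh(v, f)


@pytest.fixture(scope="session")
def femur():
    """One synthetic femur at default parameters (raw marching cubes)."""
    return make_femur(seed=0)


@pytest.fixture(scope="session")
def femur_mesh(femur):
    """The same femur standardised to the 10,000-face budget."""
    return standardize_mesh(femur.mesh, PipelineConfig())


@pytest.fixture(scope="session")
def femur_pdm(femur_mesh):
    """A PDM over analytically deformed copies of one femur mesh.

    Cheap stand-in for a registered population: four size/bend
    variations of the same topology, so the mean is femur-shaped and
    partial-correspondence logic sees realistic geometry.
    """
    from femurssm.mesh import TriangleMesh
    from femurssm.ssm import build_pdm

    base = femur_mesh.vertices
    c = base.mean(axis=0)
    meshes = []
    for k, scale in enumerate((0.97, 0.99, 1.01, 1.03)):
        v = c + scale * (base - c)
        bend = 2e-5 * (k - 1.5) * (v[:, 2] - c[2]) ** 2
        v = v + np.stack(
            [bend, np.zeros(len(v)), np.zeros(len(v))], axis=1
        )
        meshes.append(TriangleMesh(v, femur_mesh.faces))
    return build_pdm(meshes)


@pytest.fixture(scope="session")
def small_pdm():
    """A tiny random PDM with a known basis (3 modes, 40 vertices)."""
    from femurssm.ssm import PointDistributionModel

    rng = np.random.default_rng(11)
    pts = rng.normal(scale=15.0, size=(40, 3))
    basis, _ = np.linalg.qr(rng.normal(size=(120, 3)))
    return PointDistributionModel(
        faces=np.array([[0, 1, 2]]),
        mean=pts.ravel(),
        basis=basis,
        variances=np.array([25.0, 9.0, 1.0]),
    )
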