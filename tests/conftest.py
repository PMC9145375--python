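"""Shared fixtures: canonical meshes and phantoms, all generated in-process."""

import numpy as np
import pytest
import trimesh

from stairsmooth import TriangleMesh, extract_surface, generate_phantom

# unit cube [0,1]^3 as 12 outward-oriented triangles
CUBE_VERTICES = np.array([
    [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
    [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
], dtype=float)
CUBE_FACES = np.array([
    [0, 2, 1], [0, 3, 2],          # bottom (z=0, normal -z)
    [4, 5, 6], [4, 6, 7],          # top (z=1, normal +z)
    [0, 1, 5], [0, 5, 4],          # y=0, normal -y
    [2, 3, 7], [2, 7, 6],          # y=1, normal +y
    [1, 2, 6], [1, 6, 5],          # x=1, normal +x
    [3, 0, 4], [3, 4, 7],          # x=0, normal -x
])


def make_icosphere(subdivisions: int = 3, radius: float = 1.0) -> TriangleMesh:
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def make_convex_mesh(n_points: int, seed: int) -> TriangleMesh:
    """Convex hull of seeded random points, oriented outward."""
    from scipy.spatial import ConvexHull

    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n_points, 3))
    hull = ConvexHull(pts)
    verts = pts[hull.vertices]
    remap = {old: new for new, old in enumerate(hull.vertices)}
    faces = np.array([[remap[i] for i in simplex]
                      for simplex in hull.simplices])
    centroid = verts.mean(axis=0)
    fixed = []
    for tri in faces:
        a, b, c = verts[tri]
        if np.dot(np.cross(b - a, c - a), a - centroid) < 0:
            tri = tri[::-1]
        fixed.append(tri)
    return TriangleMesh(verts, np.array(fixed))


@pytest.fixture
def cube() -> TriangleMesh:
    return TriangleMesh(CUBE_VERTICES.copy(), CUBE_FACES.copy())


@pytest.fixture
def tetrahedron() -> TriangleMesh:
    v = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
    f = np.array([[0, 1, 2], [0, 2, 3], [0, 3, 1], [1, 3, 2]])
    return TriangleMesh(v, f)


@pytest.fixture
def octahedron() -> TriangleMesh:
    """All edges equal: the exact uniform-edge limit case."""
    v = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                  [0, 0, 1], [0, 0, -1]], dtype=float)
    f = np.array([[0, 2, 4], [2, 1, 4], [1, 3, 4], [3, 0, 4],
                  [2, 0, 5], [1, 2, 5], [3, 1, 5], [0, 3, 5]])
    return TriangleMesh(v, f)


@pytest.fixture(scope="session")
def icosphere() -> TriangleMesh:
    return make_icosphere(3, 1.0)


@pytest.fixture(scope="session")
def ellipsoid_phantom():
    return generate_phantom("ellipsoid", seed=0)


@pytest.fixture(scope="session")
def ellipsoid_mesh(ellipsoid_phantom) -> TriangleMesh:
    return extract_surface(ellipsoid_phantom, "voxel-faces")


@pytest.fixture(scope="session")
def ridged_phantoms():
    return [generate_phantom("ridged-blob", seed=s) for s in (1, 2, 3)]
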