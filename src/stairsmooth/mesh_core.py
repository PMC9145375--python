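"""Triangle-mesh container, topology queries and geometric primitives.

Every smoother and metric in the package operates on :class:`TriangleMesh`,
a closed oriented 2-manifold triangle mesh in millimetre coordinates.
:func:`build_adjacency` derives the one-ring structure (cyclically ordered
neighbours, edge lengths, and the two angles opposite each edge) that the
discrete Laplacian operators consume.

Volume is computed with the divergence theorem — exact for polyhedra and
independent of any voxel resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, InputError, MeshStructureError

# Faces with area below this (mm^2) are considered degenerate slivers and
# rejected at validation: cotangent weights blow up on them.
DEGENERATE_AREA = 1e-12


@dataclass
class TriangleMesh:
    """A closed, consistently oriented triangle mesh.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex positions in millimetres.
    faces : (m, 3) int array
        Vertex-index triples, counter-clockwise when viewed from outside,
        so the signed volume of a valid mesh is positive.
    provenance : dict
        Free-form load/processing notes (weld counts, orientation flips).
    """

    vertices: np.ndarray
    faces: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise InputError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise InputError("faces must be an (m, 3) array")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(),
                            dict(self.provenance))

    def with_vertices(self, vertices: np.ndarray) -> "TriangleMesh":
        """Same topology, new positions."""
        return TriangleMesh(np.asarray(vertices, dtype=np.float64),
                            self.faces.copy(), dict(self.provenance))

    def bounding_box_diagonal(self) -> float:
        return float(np.linalg.norm(self.vertices.max(axis=0)
                                    - self.vertices.min(axis=0)))


@dataclass
class OneRingAdjacency:
    """One-ring neighbourhood structure of a closed manifold mesh.

    For every vertex ``i``: ``neighbors[i]`` is the cyclic (fan) ordering of
    N1(i) obtained by walking the incident triangles; ``edge_lengths[i][k]``
    is |e_ij| for ``j = neighbors[i][k]``; ``opposite_angles[i][k]`` holds
    the two angles (alpha, beta) opposite edge e_ij in the two triangles
    sharing it.  The cyclic convention: for the counter-clockwise ring
    ``n_0 .. n_{m-1}``, the face (i, n_k, n_{k+1}) is a mesh triangle.
    """

    neighbors: list[np.ndarray]
    edge_lengths: list[np.ndarray]
    opposite_angles: list[np.ndarray]  # per vertex: (m, 2) array

    @property
    def n_vertices(self) -> int:
        return len(self.neighbors)

    def degree(self, i: int) -> int:
        return len(self.neighbors[i])


def face_cross_products(mesh: TriangleMesh) -> np.ndarray:
    """Unnormalised face normals (cross product of two edges); |.| = 2*area."""
    v = mesh.vertices
    f = mesh.faces
    return np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])


def face_areas(mesh: TriangleMesh) -> np.ndarray:
    return 0.5 * np.linalg.norm(face_cross_products(mesh), axis=1)


def face_normals(mesh: TriangleMesh) -> np.ndarray:
    """Unit outward face normals; degenerate faces raise."""
    c = face_cross_products(mesh)
    n = np.linalg.norm(c, axis=1)
    if np.any(n < 2.0 * DEGENERATE_AREA):
        bad = int(np.argmin(n))
        raise GeometryError(f"face {bad} has near-zero area; repair the mesh "
                            "(remove slivers) before processing")
    return c / n[:, None]


def vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    """Per-vertex unit normals as area-weighted averages of face normals."""
    c = face_cross_products(mesh)  # area-weighted: |c| = 2*area
    acc = np.zeros_like(mesh.vertices)
    for k in range(3):
        np.add.at(acc, mesh.faces[:, k], c)
    norms = np.linalg.norm(acc, axis=1)
    if np.any(norms < 1e-300):
        bad = int(np.argmin(norms))
        raise GeometryError(f"vertex {bad}: all incident faces degenerate; "
                            "cannot define a normal")
    return acc / norms[:, None]


def mesh_volume(mesh: TriangleMesh) -> float:
    """Signed enclosed volume (mm^3) by the divergence theorem.

    ``V = (1/6) * sum over faces det(a, b, c)``; positive for a closed mesh
    oriented outward, negated if all faces are flipped.
    """
    v = mesh.vertices
    f = mesh.faces
    a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


def _edge_face_incidence(mesh: TriangleMesh) -> dict:
    """Map undirected edge -> list of (face index, local edge slot)."""
    edges: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for fi, (p, q, r) in enumerate(mesh.faces):
        for slot, (u, w) in enumerate(((p, q), (q, r), (r, p))):
            key = (u, w) if u < w else (w, u)
            edges.setdefault(key, []).append((fi, slot))
    return edges


def validate_mesh(mesh: TriangleMesh, require_positive_volume: bool = True) -> None:
    """Check all TriangleMesh invariants; raise on the first violation.

    Checks: index bounds, no topologically degenerate faces, closed
    2-manifold (every edge in exactly two faces), consistent orientation
    (each edge traversed once per direction), no geometrically degenerate
    faces, and (optionally) positive signed volume.
    """
    f = mesh.faces
    if len(f) == 0:
        raise InputError("mesh has no faces")
    if f.min() < 0 or f.max() >= mesh.n_vertices:
        raise MeshStructureError("face index out of range")
    if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
        bad = int(np.where((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2])
                           | (f[:, 0] == f[:, 2]))[0][0])
        raise MeshStructureError(f"face {bad} repeats a vertex")

    areas = face_areas(mesh)
    if np.any(areas < DEGENERATE_AREA):
        bad = int(np.argmin(areas))
        raise MeshStructureError(
            f"face {bad} is geometrically degenerate (area {areas[bad]:.3e} "
            "mm^2 < 1e-12); remove slivers or re-extract the surface")

    # directed-edge multiset: closed + consistently oriented <=> every
    # directed edge appears exactly once and its reverse exactly once
    directed = {}
    for fi, (p, q, r) in enumerate(f):
        for u, w in ((p, q), (q, r), (r, p)):
            if (u, w) in directed:
                raise MeshStructureError(
                    f"edge ({u},{w}) traversed twice in the same direction: "
                    "inconsistent orientation or non-manifold")
            directed[(u, w)] = fi
    for (u, w) in directed:
        if (w, u) not in directed:
            raise MeshStructureError(
                f"edge ({u},{w}) has no partner: open boundary or "
                "non-manifold edge (closed meshes only)")

    if require_positive_volume and mesh_volume(mesh) <= 0.0:
        raise MeshStructureError("signed volume is non-positive; mesh is "
                                 "oriented inward or self-inverted")


def build_adjacency(mesh: TriangleMesh) -> OneRingAdjacency:
    """Build cyclically ordered one-ring adjacency for a closed manifold mesh.

    Neighbour order is the counter-clockwise fan obtained by walking the
    incident triangles, which pairs the two opposite angles of each edge
    deterministically.
    """
    edges = _edge_face_incidence(mesh)
    for (u, w), inc in edges.items():
        if len(inc) != 2:
            raise MeshStructureError(
                f"edge ({u},{w}) borders {len(inc)} faces (expected 2): "
                + ("open boundary" if len(inc) < 2 else "non-manifold edge"))

    v = mesh.vertices
    f = mesh.faces
    n = mesh.n_vertices

    # successor map per vertex: in face (i, a, b) CCW, ring step a -> b
    succ: list[dict[int, int]] = [dict() for _ in range(n)]
    for p, q, r in f:
        succ[p][q] = r
        succ[q][r] = p
        succ[r][p] = q

    neighbors: list[np.ndarray] = []
    lengths: list[np.ndarray] = []
    angles: list[np.ndarray] = []

    for i in range(n):
        s = succ[i]
        m = len(s)
        if m < 3:
            raise MeshStructureError(f"vertex {i} has degree {m} < 3")
        start = next(iter(s))
        ring = [start]
        cur = s[start]
        while cur != start:
            ring.append(cur)
            if len(ring) > m:
                raise MeshStructureError(
                    f"vertex {i}: one-ring does not close into a single fan "
                    "(non-manifold vertex)")
            cur = s[cur]
        if len(ring) != m:
            raise MeshStructureError(
                f"vertex {i}: one-ring fan visits {len(ring)} of {m} "
                "neighbours (non-manifold vertex)")

        ring_arr = np.asarray(ring, dtype=np.int64)
        d = v[ring_arr] - v[i]
        ln = np.linalg.norm(d, axis=1)
        if np.any(ln <= 0.0):
            raise GeometryError(f"vertex {i}: zero-length edge in one-ring")

        # edge (i, ring[k]) lies in faces (i, ring[k-1], ring[k]) and
        # (i, ring[k], ring[k+1]); opposite vertices are ring[k-1], ring[k+1]
        prv = np.roll(ring_arr, 1)
        nxt = np.roll(ring_arr, -1)
        ab = np.empty((m, 2))
        for col, opp in enumerate((prv, nxt)):
            u1 = v[i] - v[opp]
            u2 = v[ring_arr] - v[opp]
            crossn = np.linalg.norm(np.cross(u1, u2), axis=1)
            dot = np.einsum("ij,ij->i", u1, u2)
            ab[:, col] = np.arctan2(crossn, dot)
        neighbors.append(ring_arr)
        lengths.append(ln)
        angles.append(ab)

    return OneRingAdjacency(neighbors, lengths, angles)


def vertex_mixed_areas(mesh: TriangleMesh) -> np.ndarray:
    """Mixed Voronoi vertex areas (mm^2) in the sense of Meyer et al.

    The "small region around the vertex" over which the discrete mean
    curvature is averaged: the Voronoi cell restricted to each non-obtuse
    incident triangle, with the standard fallback (area/2 if the triangle
    is obtuse at the vertex, area/4 otherwise).
    """
    v = mesh.vertices
    f = mesh.faces
    areas = face_areas(mesh)
    out = np.zeros(mesh.n_vertices)
    p, q, r = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]

    def cots_and_obtuse(a, b, c):
        # angle at a, between b and c
        u1, u2 = b - a, c - a
        dot = np.einsum("ij,ij->i", u1, u2)
        crs = np.linalg.norm(np.cross(u1, u2), axis=1)
        return dot / np.maximum(crs, 1e-300), dot < 0.0

    cot = np.empty((len(f), 3))
    obtuse = np.empty((len(f), 3), dtype=bool)
    cot[:, 0], obtuse[:, 0] = cots_and_obtuse(p, q, r)
    cot[:, 1], obtuse[:, 1] = cots_and_obtuse(q, r, p)
    cot[:, 2], obtuse[:, 2] = cots_and_obtuse(r, p, q)
    any_obtuse = obtuse.any(axis=1)

    edge_sq = np.empty((len(f), 3))
    edge_sq[:, 0] = np.einsum("ij,ij->i", q - r, q - r)  # opposite vertex 0
    edge_sq[:, 1] = np.einsum("ij,ij->i", r - p, r - p)
    edge_sq[:, 2] = np.einsum("ij,ij->i", p - q, p - q)

    for k in range(3):
        idx = f[:, k]
        k1, k2 = (k + 1) % 3, (k + 2) % 3
        # Voronoi: (1/8)(|e_{k,k1}|^2 cot(angle at k2) + |e_{k,k2}|^2 cot(at k1))
        voro = 0.125 * (edge_sq[:, k2] * cot[:, k2] + edge_sq[:, k1] * cot[:, k1])
        fallback = np.where(obtuse[:, k], 0.5 * areas, 0.25 * areas)
        contrib = np.where(any_obtuse, fallback, voro)
        np.add.at(out, idx, contrib)
    return out
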