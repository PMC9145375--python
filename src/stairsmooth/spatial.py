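"""Nearest-surface queries: exact point-to-triangle distances with a
KD-tree candidate filter, plus pseudonormal-signed distances.

Used by the Hausdorff metric (exact directed maxima over vertices) and by
the pre-dilation smoother's contact rule (has any vertex crossed strictly
inside the original surface?).

The candidate filter is provably complete: the nearest mesh VERTEX gives an
upper bound d_up on the true surface distance, and any triangle containing
the closest surface point has its centroid within d_up + r_max of the query
(r_max = largest centroid-to-corner distance over all triangles), so
querying centroids inside that ball never misses the optimum.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree
from trimesh.triangles import closest_point as _tri_closest_point
from trimesh.triangles import points_to_barycentric

from .errors import InputError
from .mesh_core import TriangleMesh, face_cross_products

_BARY_EPS = 1e-9


class NearestSurface:
    """Spatial index over a triangle mesh answering nearest-point queries."""

    def __init__(self, mesh: TriangleMesh):
        if mesh.n_faces == 0:
            raise InputError("empty mesh")
        self.mesh = mesh
        v, f = mesh.vertices, mesh.faces
        self.triangles = v[f]  # (m, 3, 3)
        self.centroids = self.triangles.mean(axis=1)
        corner_d = np.linalg.norm(
            self.triangles - self.centroids[:, None, :], axis=2)
        self.r_max = float(corner_d.max())
        self._vtree = cKDTree(v)
        self._ctree = cKDTree(self.centroids)

        cx = face_cross_products(mesh)
        self._face_normals = cx / np.linalg.norm(cx, axis=1)[:, None]
        self._build_pseudonormals()

    def _build_pseudonormals(self) -> None:
        mesh = self.mesh
        v, f = mesh.vertices, mesh.faces
        fn = self._face_normals

        # angle-weighted vertex pseudonormals
        vp = np.zeros_like(v)
        for k in range(3):
            a = v[f[:, k]]
            b = v[f[:, (k + 1) % 3]]
            c = v[f[:, (k + 2) % 3]]
            u1, u2 = b - a, c - a
            ang = np.arctan2(np.linalg.norm(np.cross(u1, u2), axis=1),
                             np.einsum("ij,ij->i", u1, u2))
            np.add.at(vp, f[:, k], ang[:, None] * fn)
        self._vertex_pseudo = vp

        # edge pseudonormal = sum of the two adjacent face normals; stored
        # per (face, local slot opposite vertex k): edge (f[k1], f[k2])
        edge_acc: dict[tuple[int, int], np.ndarray] = {}
        for fi, (p, q, r) in enumerate(f):
            for u, w in ((p, q), (q, r), (r, p)):
                key = (u, w) if u < w else (w, u)
                edge_acc[key] = edge_acc.get(key, 0.0) + fn[fi]
        ep = np.zeros((len(f), 3, 3))
        for fi, (p, q, r) in enumerate(f):
            for k, (u, w) in enumerate(((q, r), (r, p), (p, q))):
                key = (u, w) if u < w else (w, u)
                ep[fi, k] = edge_acc[key]
        self._edge_pseudo = ep

    def closest(self, points: np.ndarray):
        """Exact closest surface points.

        Returns ``(distances, closest_points, triangle_indices)``.
        """
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        npts = len(points)
        d_up, _ = self._vtree.query(points)
        radii = d_up + self.r_max + 1e-12
        groups = self._ctree.query_ball_point(points, radii)

        counts = np.fromiter((len(g) for g in groups), dtype=np.int64,
                             count=npts)
        tri_idx = np.concatenate([np.asarray(g, dtype=np.int64)
                                  for g in groups])
        pt_idx = np.repeat(np.arange(npts), counts)
        cand = _tri_closest_point(self.triangles[tri_idx], points[pt_idx])
        dist = np.linalg.norm(cand - points[pt_idx], axis=1)

        best = np.full(npts, np.inf)
        np.minimum.at(best, pt_idx, dist)
        is_best = dist <= best[pt_idx] + 0.0
        # first best candidate per point
        order = np.lexsort((~is_best, pt_idx))
        first = order[np.searchsorted(pt_idx[order], np.arange(npts))]
        closest_pts = cand[first]
        closest_tri = tri_idx[first]
        return best, closest_pts, closest_tri

    def distance(self, points: np.ndarray) -> np.ndarray:
        """Exact unsigned point-to-surface distances (mm)."""
        return self.closest(points)[0]

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distances: negative strictly inside the closed surface.

        The sign comes from the angle-weighted pseudonormal of the closest
        feature (face interior, edge, or vertex), which is the standard
        robust sign test for closed meshes.
        """
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        dist, cp, tri = self.closest(points)
        bary = points_to_barycentric(self.triangles[tri], cp)
        # classify the closest feature from barycentric coordinates
        small = bary < _BARY_EPS
        n_small = small.sum(axis=1)
        normal = self._face_normals[tri].copy()

        on_edge = n_small == 1
        if np.any(on_edge):
            slot = np.argmax(small[on_edge], axis=1)  # zero bary at slot k
            normal[on_edge] = self._edge_pseudo[tri[on_edge], slot]
        on_vertex = n_small >= 2
        if np.any(on_vertex):
            slot = np.argmax(bary[on_vertex], axis=1)
            vid = self.mesh.faces[tri[on_vertex], slot]
            normal[on_vertex] = self._vertex_pseudo[vid]

        sign = np.sign(np.einsum("ij,ij->i", points - cp, normal))
        return dist * np.where(sign == 0.0, 1.0, sign)

    def any_inside(self, points: np.ndarray) -> bool:
        """True if any query point lies strictly inside the surface."""
        return bool(np.any(self.signed_distance(points) < 0.0))
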