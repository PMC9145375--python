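"""The five smoothing algorithms for stair-stepped surface meshes.

All methods share the explicit update rule

    p_i(t+1) = p_i(t) + lambda * U(p_i(t))

applied simultaneously to every vertex (Jacobi-style: displacements are
computed from iterate t and applied together), differing only in the
local operator U:

* M1 ``laplacian`` — uniform umbrella operator (mean of one-ring minus
  the vertex); the classic diffusion that shrinks volume fastest.
* M2 ``predilate`` — M1 preceded by a global normal-direction dilation
  that inflates the enclosed volume by a configured fraction; iteration
  stops when the volume returns to within a threshold of the original,
  when the surface first contacts (crosses inside) the original surface,
  or at an iteration cap.
* M3 ``scaledep`` — scale-dependent umbrella: neighbours weighted by
  inverse edge length, normalised by 2/E with E the total ring edge
  length.  The operator has units 1/mm, so the stable step size depends
  on the edge-length scale (see :func:`scale_dependent_stable_lambda`).
* M4 ``curvflow`` — mean-curvature flow via the cotangent formula,
  either as the normalised explicit update (cotangent weights normalised
  to sum to one per ring) or as a backward-Euler implicit solve
  ``(I - lambda*dt*K) P(t+1) = P(t)``.
* M5 ``invdist`` — umbrella with inverse-distance neighbour weights
  normalised to sum to one.

Degenerate cotangents are controlled by clamping opposite angles to
[1 deg, 179 deg] before taking the cotangent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import GeometryError, InputError, MeshStructureError, NumericalError
from .mesh_core import (OneRingAdjacency, TriangleMesh, build_adjacency,
                        mesh_volume, vertex_mixed_areas, vertex_normals)
from .spatial import NearestSurface

METHOD_ALIASES = {
    "M1": "M1", "laplacian": "M1",
    "M2": "M2", "predilate": "M2",
    "M3": "M3", "scaledep": "M3",
    "M4": "M4", "curvflow": "M4",
    "M5": "M5", "invdist": "M5",
}

#: Default diffusion coefficient per method.  M1/M2/M5 updates are convex
#: combinations of ring positions, unconditionally stable for lambda <= 1.
#: M3's operator carries units 1/mm; for submillimetre edge lengths the
#: explicit step is only stable for lambda below roughly (min edge)^2 / 2
#: (see scale_dependent_stable_lambda).  M4's normalised cotangent weights
#: are not a convex combination (clamped cotangents can be negative and
#: large relative to the ring sum), so its explicit update likewise needs a
#: small step; both default to 0.1.
DEFAULT_LAMBDA = {"M1": 0.5, "M2": 0.5, "M3": 0.1, "M4": 0.1, "M5": 0.5}

ANGLE_CLAMP = (np.deg2rad(1.0), np.deg2rad(179.0))


@dataclass
class SmoothingConfig:
    """All scalar controls for the five smoothers.

    ``lam`` left as None resolves to the per-method default in
    ``DEFAULT_LAMBDA``.  ``iterations`` is the fixed round count for
    M1/M3/M4/M5 and the non-convergence cap for M2 (default 10000 there;
    set ``m2_cap`` explicitly to override).
    """

    method: str = "M1"
    lam: float | None = None
    dt: float = 0.1
    iterations: int = 30
    dilation_fraction: float = 0.05
    volume_threshold: float = 0.005
    curvature_mode: str = "explicit"
    m2_cap: int = 10000

    def __post_init__(self) -> None:
        if self.method not in METHOD_ALIASES:
            raise InputError(f"unknown method {self.method!r}; expected one of "
                             f"{sorted(set(METHOD_ALIASES))}")
        self.method = METHOD_ALIASES[self.method]
        if self.lam is None:
            self.lam = DEFAULT_LAMBDA[self.method]
        if not (0.0 <= self.lam <= 1.0):
            raise InputError("lambda must lie in [0, 1] for explicit updates")
        if self.dt <= 0.0:
            raise InputError("dt must be positive")
        if self.iterations < 0 or (self.method != "M2" and self.iterations < 1):
            raise InputError("iterations must be >= 1")
        if self.m2_cap < 1:
            raise InputError("m2_cap must be >= 1")
        if self.curvature_mode not in ("explicit", "explicit-normalized",
                                       "implicit"):
            raise InputError("curvature_mode must be 'explicit' or 'implicit'")
        if self.curvature_mode == "explicit-normalized":
            self.curvature_mode = "explicit"
        if self.method == "M2":
            if not (0.0 < self.dilation_fraction < 1.0):
                raise InputError("dilation_fraction must lie in (0, 1) for M2")
            if not (0.0 < self.volume_threshold < 1.0):
                raise InputError("volume_threshold must lie in (0, 1)")
            if self.volume_threshold >= self.dilation_fraction:
                raise InputError("volume_threshold must be smaller than "
                                 "dilation_fraction for M2 to be meaningful")
        elif self.dilation_fraction < 0.0:
            raise InputError("dilation_fraction must be non-negative")


@dataclass
class SmoothingResult:
    """Outcome of a smoothing run.

    ``termination_reason`` is ``"iterations"`` for the fixed-count methods
    and one of ``"threshold" | "contact" | "cap"`` for M2.  ``volume_log``
    holds the signed mesh volume after every iteration (index 0 = input, or
    the dilated mesh for M2).
    """

    mesh: TriangleMesh
    method: str
    config: SmoothingConfig
    termination_reason: str
    iterations_run: int
    volume_log: list[float] = field(default_factory=list)
    alpha: float | None = None
    converged: bool = True


# ---------------------------------------------------------------------------
# per-vertex operators (reference API; the drivers use vectorised equivalents)

def umbrella(p_i: np.ndarray, neighbors: np.ndarray) -> np.ndarray:
    """Uniform umbrella operator: (mean of one-ring) - p_i."""
    neighbors = np.atleast_2d(np.asarray(neighbors, dtype=np.float64))
    if len(neighbors) < 3:
        raise MeshStructureError("umbrella needs at least 3 neighbours")
    return neighbors.mean(axis=0) - np.asarray(p_i, dtype=np.float64)


def scale_dependent_umbrella(p_i: np.ndarray, neighbors: np.ndarray,
                             edge_lengths: np.ndarray | None = None
                             ) -> np.ndarray:
    """Scale-dependent umbrella: (2/E) * sum_j (p_j - p_i)/|e_ij|."""
    p_i = np.asarray(p_i, dtype=np.float64)
    neighbors = np.atleast_2d(np.asarray(neighbors, dtype=np.float64))
    if len(neighbors) < 3:
        raise MeshStructureError("operator needs at least 3 neighbours")
    d = neighbors - p_i
    if edge_lengths is None:
        edge_lengths = np.linalg.norm(d, axis=1)
    edge_lengths = np.asarray(edge_lengths, dtype=np.float64)
    if np.any(edge_lengths <= 0.0):
        raise GeometryError("zero-length edge in one-ring")
    E = edge_lengths.sum()
    return (2.0 / E) * (d / edge_lengths[:, None]).sum(axis=0)


def clamped_cot(angles: np.ndarray) -> np.ndarray:
    """Cotangent with angles clamped to [1 deg, 179 deg] first."""
    return 1.0 / np.tan(np.clip(angles, *ANGLE_CLAMP))


def cotangent_curvature_normal(p_i: np.ndarray, neighbors: np.ndarray,
                               opposite_angles: np.ndarray,
                               area: float) -> np.ndarray:
    """Discrete mean-curvature normal estimate (the displacement -kappa*n).

    ``-kappa_bar * n = (1/4A) * sum_j (cot(alpha_j) + cot(beta_j)) (p_j - p_i)``

    with ``opposite_angles[j] = (alpha_j, beta_j)`` the two angles opposite
    edge e_ij and ``area`` the vertex's local averaging region (the mixed
    Voronoi cell; see :func:`stairsmooth.mesh_core.vertex_mixed_areas`).
    On a sphere of radius r this points inward with magnitude ~1/r.
    """
    if area <= 0.0:
        raise GeometryError("one-ring area must be positive")
    p_i = np.asarray(p_i, dtype=np.float64)
    neighbors = np.atleast_2d(np.asarray(neighbors, dtype=np.float64))
    w = clamped_cot(np.asarray(opposite_angles, dtype=np.float64)).sum(axis=1)
    return (w[:, None] * (neighbors - p_i)).sum(axis=0) / (4.0 * area)


def inverse_distance_weights(p_i: np.ndarray,
                             neighbors: np.ndarray) -> np.ndarray:
    """Inverse-distance weights 1/|p_i - Q_j|, normalised to sum to one."""
    p_i = np.asarray(p_i, dtype=np.float64)
    neighbors = np.atleast_2d(np.asarray(neighbors, dtype=np.float64))
    d = np.linalg.norm(neighbors - p_i, axis=1)
    if np.any(d <= 0.0):
        raise GeometryError("coincident neighbour: inverse distance undefined")
    w = 1.0 / d
    return w / w.sum()


# ---------------------------------------------------------------------------
# ring topology in flat-array form (constant across iterations)

class _RingTopology:
    """Flattened one-ring arrays for vectorised per-iteration operators."""

    def __init__(self, adjacency: OneRingAdjacency):
        counts = np.array([len(nb) for nb in adjacency.neighbors],
                          dtype=np.int64)
        self.counts = counts
        self.indptr = np.concatenate([[0], np.cumsum(counts)])
        self.center = np.repeat(np.arange(len(counts)), counts)
        self.nbr = np.concatenate(adjacency.neighbors)
        # cyclic predecessors/successors: opposite vertices of each ring edge
        self.prv = np.concatenate([np.roll(nb, 1)
                                   for nb in adjacency.neighbors])
        self.nxt = np.concatenate([np.roll(nb, -1)
                                   for nb in adjacency.neighbors])

    def ring_sum(self, values: np.ndarray) -> np.ndarray:
        """Sum per-ring-entry values over each ring."""
        return np.add.reduceat(values, self.indptr[:-1], axis=0)


def _ring_topology(mesh: TriangleMesh) -> _RingTopology:
    return _RingTopology(build_adjacency(mesh))


def _uniform_displacements(P: np.ndarray, top: _RingTopology) -> np.ndarray:
    return top.ring_sum(P[top.nbr]) / top.counts[:, None] - P


def _scale_dependent_displacements(P: np.ndarray,
                                   top: _RingTopology) -> np.ndarray:
    d = P[top.nbr] - P[top.center]
    ln = np.linalg.norm(d, axis=1)
    if np.any(ln <= 0.0):
        raise GeometryError("zero-length edge during scale-dependent step")
    E = top.ring_sum(ln)
    return 2.0 / E[:, None] * top.ring_sum(d / ln[:, None])


def _inverse_distance_displacements(P: np.ndarray,
                                    top: _RingTopology) -> np.ndarray:
    d = P[top.nbr] - P[top.center]
    ln = np.linalg.norm(d, axis=1)
    if np.any(ln <= 0.0):
        raise GeometryError("coincident neighbour during inverse-distance step")
    w = 1.0 / ln
    wsum = top.ring_sum(w)
    return top.ring_sum(w[:, None] * d) / wsum[:, None]


def _ring_cot_weights(P: np.ndarray, top: _RingTopology) -> np.ndarray:
    """Per ring entry: cot(alpha) + cot(beta) for the edge (center, nbr)."""
    out = np.zeros(len(top.nbr))
    for opp in (top.prv, top.nxt):
        u1 = P[top.center] - P[opp]
        u2 = P[top.nbr] - P[opp]
        ang = np.arctan2(np.linalg.norm(np.cross(u1, u2), axis=1),
                         np.einsum("ij,ij->i", u1, u2))
        out += clamped_cot(ang)
    return out


def _curvature_explicit_displacements(P: np.ndarray,
                                      top: _RingTopology) -> np.ndarray:
    # normalised cotangent weights (sum to one per ring, sign preserved)
    w = _ring_cot_weights(P, top)
    wsum = top.ring_sum(w)
    if np.any(np.abs(wsum) < 1e-300):
        raise GeometryError("cotangent weights sum to zero on a ring")
    wn = w / wsum[top.center]
    return top.ring_sum(wn[:, None] * (P[top.nbr] - P[top.center]))


def _curvature_operator_matrix(mesh: TriangleMesh, P: np.ndarray,
                               top: _RingTopology) -> sp.csr_matrix:
    """Sparse K with (K P)_i = (1/4A_i) sum_j (cot a + cot b)(p_j - p_i)."""
    areas = vertex_mixed_areas(mesh.with_vertices(P))
    if np.any(areas <= 0.0):
        raise GeometryError("non-positive mixed vertex area")
    w = _ring_cot_weights(P, top) / (4.0 * areas[top.center])
    diag = -top.ring_sum(w)
    n = len(areas)
    rows = np.concatenate([top.center, np.arange(n)])
    cols = np.concatenate([top.nbr, np.arange(n)])
    vals = np.concatenate([w, diag])
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


# ---------------------------------------------------------------------------
# drivers

def _run_fixed(mesh: TriangleMesh, config: SmoothingConfig, step) -> SmoothingResult:
    top = _ring_topology(mesh)
    P = mesh.vertices.copy()
    log = [mesh_volume(mesh)]
    for _ in range(config.iterations):
        P = P + config.lam * step(P, top)
        log.append(mesh_volume(mesh.with_vertices(P)))
    return SmoothingResult(mesh.with_vertices(P), config.method, config,
                           "iterations", config.iterations, log)


def smooth_laplacian(mesh: TriangleMesh, config: SmoothingConfig | None = None
                     ) -> SmoothingResult:
    """M1: uniform Laplacian (umbrella) smoothing."""
    config = _coerce(config, "M1")
    return _run_fixed(mesh, config, _uniform_displacements)


def smooth_scale_dependent(mesh: TriangleMesh,
                           config: SmoothingConfig | None = None
                           ) -> SmoothingResult:
    """M3: scale-dependent umbrella smoothing (edge lengths recomputed
    from the current iterate each round)."""
    config = _coerce(config, "M3")
    return _run_fixed(mesh, config, _scale_dependent_displacements)


def smooth_inverse_distance(mesh: TriangleMesh,
                            config: SmoothingConfig | None = None
                            ) -> SmoothingResult:
    """M5: inverse-distance weighted umbrella smoothing."""
    config = _coerce(config, "M5")
    return _run_fixed(mesh, config, _inverse_distance_displacements)


def smooth_curvature_flow(mesh: TriangleMesh,
                          config: SmoothingConfig | None = None
                          ) -> SmoothingResult:
    """M4: mean-curvature flow, explicit-normalised or implicit."""
    config = _coerce(config, "M4")
    if config.curvature_mode == "explicit":
        return _run_fixed(mesh, config, _curvature_explicit_displacements)

    top = _ring_topology(mesh)
    P = mesh.vertices.copy()
    log = [mesh_volume(mesh)]
    n = len(P)
    for it in range(config.iterations):
        K = _curvature_operator_matrix(mesh, P, top)
        A = (sp.identity(n, format="csc") - config.lam * config.dt * K.tocsc())
        try:
            lu = spla.splu(A)
            P = np.column_stack([lu.solve(P[:, k]) for k in range(3)])
        except RuntimeError as exc:  # singular factorisation
            raise NumericalError(
                f"implicit curvature-flow solve failed at iteration {it}: "
                f"{exc}") from exc
        if not np.all(np.isfinite(P)):
            raise NumericalError(
                f"implicit curvature-flow solve diverged at iteration {it}")
        log.append(mesh_volume(mesh.with_vertices(P)))
    return SmoothingResult(mesh.with_vertices(P), "M4", config,
                           "iterations", config.iterations, log)


def dilate(mesh: TriangleMesh, dilation_fraction: float
           ) -> tuple[TriangleMesh, float]:
    """Offset every vertex by alpha along its unit vertex normal so the
    enclosed volume grows by ``dilation_fraction``; returns the solved alpha.

    alpha is found by bisection on the signed volume, to 1e-6 relative.
    """
    if dilation_fraction < 0.0:
        raise InputError("dilation_fraction must be non-negative")
    if dilation_fraction == 0.0:
        return mesh.copy(), 0.0
    v0 = mesh_volume(mesh)
    if v0 <= 0.0:
        raise InputError("dilate requires a positive-volume mesh")
    target = (1.0 + dilation_fraction) * v0
    normals = vertex_normals(mesh)

    def vol(alpha: float) -> float:
        return mesh_volume(mesh.with_vertices(mesh.vertices + alpha * normals))

    lo, hi = 0.0, 2.0 * mesh.bounding_box_diagonal()
    if vol(hi) < target:
        raise GeometryError("dilation bisection failed to bracket the target "
                            "volume (pathological normals)")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        vm = vol(mid)
        if abs(vm - target) <= 1e-6 * target:
            return mesh.with_vertices(mesh.vertices + mid * normals), mid
        if vm < target:
            lo = mid
        else:
            hi = mid
    raise GeometryError("dilation bisection did not converge")


def smooth_predilated(mesh: TriangleMesh, config: SmoothingConfig | None = None
                      ) -> SmoothingResult:
    """M2: Laplacian smoothing with pre-dilation and volume-aware stopping.

    Dilates the input by ``dilation_fraction`` (volume-wise), then applies
    uniform Laplacian steps until (a) the volume has returned to within
    ``volume_threshold`` of the original volume, (b) any vertex falls
    strictly inside the original surface, or (c) the iteration cap is hit
    (reported as non-convergence).
    """
    config = _coerce(config, "M2")
    v0 = mesh_volume(mesh)
    if v0 <= 0.0:
        raise InputError("M2 requires a positive-volume input mesh")
    original = NearestSurface(mesh)
    dilated, alpha = dilate(mesh, config.dilation_fraction)

    top = _ring_topology(dilated)
    P = dilated.vertices.copy()
    log = [mesh_volume(dilated)]
    cap = config.m2_cap  # M2 converges by volume, not by a fixed round count
    reason = "cap"
    it = 0
    for it in range(1, cap + 1):
        P = P + config.lam * _uniform_displacements(P, top)
        v = mesh_volume(mesh.with_vertices(P))
        log.append(v)
        if abs(v - v0) <= config.volume_threshold * v0:
            reason = "threshold"
            break
        if original.any_inside(P):
            reason = "contact"
            break
    return SmoothingResult(mesh.with_vertices(P), "M2", config, reason, it,
                           log, alpha=alpha, converged=reason != "cap")


def scale_dependent_stable_lambda(mesh: TriangleMesh) -> float:
    """Largest lambda for which the explicit M3 step is a contraction.

    Gershgorin bound: the update matrix I + lambda*W has spectrum inside
    the unit disc when lambda * max_i sum_j w_ij <= 1, with
    w_ij = (2/E_i)/|e_ij|.
    """
    top = _ring_topology(mesh)
    P = mesh.vertices
    ln = np.linalg.norm(P[top.nbr] - P[top.center], axis=1)
    E = top.ring_sum(ln)
    row = top.ring_sum(1.0 / ln) * 2.0 / E
    return float(1.0 / row.max())


_DRIVERS = {
    "M1": smooth_laplacian,
    "M2": smooth_predilated,
    "M3": smooth_scale_dependent,
    "M4": smooth_curvature_flow,
    "M5": smooth_inverse_distance,
}


def smooth(mesh: TriangleMesh, config: SmoothingConfig) -> SmoothingResult:
    """Dispatch to the configured method's driver."""
    return _DRIVERS[config.method](mesh, config)


def _coerce(config: SmoothingConfig | None, method: str) -> SmoothingConfig:
    if config is None:
        return SmoothingConfig(method=method)
    if config.method != method:
        config = replace(config, method=method, lam=config.lam)
    return config
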