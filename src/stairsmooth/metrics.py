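"""Quantitative validation metrics.

Relative Volume Difference (RVD, %, signed — negative means shrinkage)

    RVD(G, S) = (V_S - V_G) / V_G * 100

and the symmetric Hausdorff distance (HD, mm)

    HD(G, S) = max( max_{x in G} d(x, S), max_{y in S} d(y, G) )

where d is the exact point-to-triangle distance and the outer maxima are
taken over the vertices of the source mesh (vertex-sampled symmetric
Hausdorff).  Per-vertex distance fields are retained for heat-map export;
summary statistics (mean, population SD, RMS, max) pool both directions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .mesh_core import TriangleMesh, mesh_volume
from .spatial import NearestSurface


@dataclass
class RVDReport:
    volume_ground: float
    volume_smoothed: float
    rvd: float  # percent, signed

    def as_dict(self) -> dict:
        return {"volume_ground_mm3": self.volume_ground,
                "volume_smoothed_mm3": self.volume_smoothed,
                "rvd_percent": self.rvd}


@dataclass
class DistanceReport:
    """Directed and symmetric Hausdorff distances with per-vertex fields.

    ``field_ground`` holds d(x, S) for every vertex x of G; ``field_smoothed``
    holds d(y, G) for every vertex y of S.  Summary statistics are over the
    pooled fields.
    """

    directed_max_ground_to_smoothed: float
    directed_max_smoothed_to_ground: float
    hausdorff: float
    field_ground: np.ndarray
    field_smoothed: np.ndarray
    mean: float
    sd: float
    rms: float
    max: float

    def as_dict(self) -> dict:
        return {
            "hausdorff_mm": self.hausdorff,
            "directed_max_ground_to_smoothed_mm":
                self.directed_max_ground_to_smoothed,
            "directed_max_smoothed_to_ground_mm":
                self.directed_max_smoothed_to_ground,
            "mean_mm": self.mean,
            "sd_mm": self.sd,
            "rms_mm": self.rms,
            "max_mm": self.max,
        }


def relative_volume_difference(ground: TriangleMesh,
                               smoothed: TriangleMesh) -> RVDReport:
    """Signed percentage volume change of ``smoothed`` relative to ``ground``."""
    vg = mesh_volume(ground)
    vs = mesh_volume(smoothed)
    if vg <= 0.0:
        raise InputError("ground-truth mesh must have positive volume")
    return RVDReport(vg, vs, (vs - vg) / vg * 100.0)


def pooled_statistics(values: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, population SD, RMS, max) of a nonempty distance field."""
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise InputError("empty distance field")
    mean = float(values.mean())
    sd = float(values.std())  # population SD
    rms = float(np.sqrt(np.mean(values ** 2)))
    return mean, sd, rms, float(values.max())


def distance_statistics(report: DistanceReport) -> tuple[float, float, float, float]:
    """Summary statistics over the pooled per-vertex fields of a report."""
    pooled = np.concatenate([report.field_ground, report.field_smoothed])
    return pooled_statistics(pooled)


def hausdorff_distance(ground: TriangleMesh,
                       smoothed: TriangleMesh) -> DistanceReport:
    """Vertex-sampled symmetric Hausdorff distance with per-vertex fields."""
    if ground.n_faces == 0 or smoothed.n_faces == 0:
        raise InputError("empty mesh")
    d_g = NearestSurface(smoothed).distance(ground.vertices)
    d_s = NearestSurface(ground).distance(smoothed.vertices)
    gmax = float(d_g.max())
    smax = float(d_s.max())
    mean, sd, rms, mx = pooled_statistics(np.concatenate([d_g, d_s]))
    return DistanceReport(gmax, smax, max(gmax, smax), d_g, d_s,
                          mean, sd, rms, mx)


def export_heatmap(mesh: TriangleMesh, field: np.ndarray, path) -> tuple:
    """Write the mesh with a per-vertex scalar (ASCII PLY ``quality``
    property) and a vertex-index -> distance CSV next to it.

    Returns the two paths written.  Values round-trip bit-exactly through
    :func:`stairsmooth.io_formats.load_heatmap`.
    """
    from . import io_formats  # local import: io layer depends on core, not vice versa

    field = np.asarray(field, dtype=np.float64).ravel()
    if field.size != mesh.n_vertices:
        raise InputError(f"field length {field.size} != vertex count "
                         f"{mesh.n_vertices}")
    path = str(path)
    ply_path = path if path.endswith(".ply") else path + ".ply"
    csv_path = ply_path[:-4] + ".csv"
    io_formats.save_mesh(mesh, ply_path, scalar=field)
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["vertex_index", "distance_mm"])
        for i, val in enumerate(field):
            writer.writerow([i, repr(float(val))])
    return ply_path, csv_path
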