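"""Mesh and mask readers/writers with strict validation at the boundary.

STL/PLY/OBJ meshes go through trimesh; masks are NIfTI volumes via nibabel
with the voxel spacing taken from the header.  Loaded meshes are welded
(exact duplicates within 1e-9 mm merged — STL stores every facet's corners
independently) and validated; an inward-oriented mesh is flipped to
positive volume with the flip recorded in ``mesh.provenance``.

Heat-map meshes (a per-vertex scalar alongside the geometry) are written
as ASCII PLY with a ``quality`` vertex property plus a CSV table; the
scalar round-trips bit-exactly.
"""

from __future__ import annotations

import os

import numpy as np
import trimesh

from .errors import InputError, MeshStructureError
from .mesh_core import TriangleMesh, mesh_volume, validate_mesh
from .phantoms import VoxelPhantom

WELD_TOLERANCE = 1e-9  # mm; exact-duplicate welding only

_MESH_FORMATS = {".stl": "stl", ".ply": "ply", ".obj": "obj"}


def _weld(vertices: np.ndarray, faces: np.ndarray):
    """Merge vertices coincident within WELD_TOLERANCE; returns counts too."""
    quant = np.round(vertices / WELD_TOLERANCE).astype(np.int64)
    _, first, inverse = np.unique(quant, axis=0, return_index=True,
                                  return_inverse=True)
    # keep first-occurrence order so duplicate-free meshes round-trip exactly
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    welded_v = vertices[first[order]]
    welded_f = rank[inverse][faces]
    return welded_v, welded_f, len(vertices) - len(welded_v)


def load_mesh(path) -> TriangleMesh:
    """Load, weld and validate a closed mesh; orient outward.

    ``mesh.provenance`` records the source format, the number of vertices
    removed by welding, and whether the orientation had to be flipped.
    """
    path = str(path)
    if not os.path.exists(path):
        raise InputError(f"no such file: {path}")
    ext = os.path.splitext(path)[1].lower()
    if ext not in _MESH_FORMATS:
        raise InputError(f"unrecognised mesh format {ext!r} "
                         f"(expected one of {sorted(_MESH_FORMATS)})")
    try:
        tm = trimesh.load(path, file_type=_MESH_FORMATS[ext], process=False,
                          force="mesh")
    except Exception as exc:
        raise InputError(f"unreadable mesh file {path}: {exc}") from exc
    if tm.vertices.size == 0 or tm.faces.size == 0:
        raise InputError(f"mesh file {path} contains no triangles")

    vertices, faces, n_welded = _weld(np.asarray(tm.vertices, dtype=np.float64),
                                      np.asarray(tm.faces, dtype=np.int64))
    mesh = TriangleMesh(vertices, faces,
                        provenance={"path": path, "format": ext.lstrip("."),
                                    "welded_vertices": n_welded,
                                    "orientation_flipped": False})
    if mesh_volume(mesh) < 0.0:
        mesh.faces = mesh.faces[:, ::-1].copy()
        mesh.provenance["orientation_flipped"] = True
    validate_mesh(mesh)
    return mesh


def save_mesh(mesh: TriangleMesh, path, scalar: np.ndarray | None = None) -> str:
    """Write a mesh as STL/PLY/OBJ; an optional per-vertex scalar requires
    PLY (stored as a ``quality`` property)."""
    path = str(path)
    ext = os.path.splitext(path)[1].lower()
    if ext not in _MESH_FORMATS:
        raise InputError(f"unrecognised mesh format {ext!r}")
    if scalar is not None:
        scalar = np.asarray(scalar, dtype=np.float64).ravel()
        if scalar.size != mesh.n_vertices:
            raise InputError(f"scalar length {scalar.size} != vertex count "
                             f"{mesh.n_vertices}")
        if ext != ".ply":
            raise InputError("per-vertex scalars are only supported for PLY "
                             f"output, not {ext}")
        _write_scalar_ply(mesh, scalar, path)
        return path
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces,
                         process=False)
    tm.export(path)
    return path


def _write_scalar_ply(mesh: TriangleMesh, scalar: np.ndarray, path: str) -> None:
    # ASCII PLY with a double 'quality' property; %r floats round-trip exactly
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write("property double quality\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for (x, y, z), q in zip(mesh.vertices, scalar):
            fh.write(f"{float(x)!r} {float(y)!r} {float(z)!r} {float(q)!r}\n")
        for a, b, c in mesh.faces:
            fh.write(f"3 {a} {b} {c}\n")


def load_heatmap(path) -> tuple[TriangleMesh, np.ndarray]:
    """Read back a scalar-carrying ASCII PLY written by :func:`save_mesh`."""
    path = str(path)
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise InputError(f"{path} is not a PLY file")
        n_vert = n_face = None
        props: list[str] = []
        element = None
        while True:
            line = fh.readline()
            if not line:
                raise InputError(f"{path}: truncated PLY header")
            tok = line.split()
            if tok[0] == "format" and tok[1] != "ascii":
                raise InputError("scalar PLY reader handles ASCII only")
            if tok[0] == "element":
                element = tok[1]
                if element == "vertex":
                    n_vert = int(tok[2])
                elif element == "face":
                    n_face = int(tok[2])
            elif tok[0] == "property" and element == "vertex" \
                    and tok[1] != "list":
                props.append(tok[2])
            elif tok[0] == "end_header":
                break
        if n_vert is None or n_face is None:
            raise InputError(f"{path}: missing vertex or face element")
        if "quality" not in props:
            raise InputError(f"{path}: no 'quality' vertex property")
        cols = {name: i for i, name in enumerate(props)}
        data = np.array([fh.readline().split() for _ in range(n_vert)],
                        dtype=np.float64)
        vertices = data[:, [cols["x"], cols["y"], cols["z"]]]
        scalar = data[:, cols["quality"]]
        faces = np.array([fh.readline().split()[1:4] for _ in range(n_face)],
                         dtype=np.int64)
    return TriangleMesh(vertices, faces, {"path": path}), scalar


def load_mask(path, label: int | None = None, pad: int = 2) -> VoxelPhantom:
    """Load a binary/labelled NIfTI mask as a :class:`VoxelPhantom`.

    Nonzero voxels (or the chosen ``label``) become the occupancy grid;
    spacing comes from the header; empty padding is added if the occupied
    region touches the grid border.  The returned phantom carries no
    analytic descriptor.
    """
    import nibabel as nib

    path = str(path)
    if not os.path.exists(path):
        raise InputError(f"no such file: {path}")
    img = nib.load(path)
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise InputError(f"{path}: header has non-positive voxel spacing")
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise InputError(f"{path}: expected a 3D volume, got {data.ndim}D")
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise InputError(f"{path}: mask voxels must be integers")
        data = np.round(data).astype(np.int64)
    grid = (data == label) if label is not None else (data != 0)
    if not grid.any():
        raise InputError(f"{path}: selected label occupies no voxel")

    occ = np.argwhere(grid)
    lo = occ.min(axis=0)
    hi = np.array(grid.shape) - 1 - occ.max(axis=0)
    extra = np.maximum(pad - np.minimum(lo, hi), 0)
    if extra.any():
        grid = np.pad(grid, [(int(e), int(e)) for e in extra])
    origin = -0.5 * np.array(grid.shape) * np.array(zooms, dtype=np.float64)
    return VoxelPhantom(grid, tuple(float(z) for z in zooms), origin,
                        descriptor=None, seed=None)


def save_mask(phantom: VoxelPhantom, path) -> str:
    """Write the occupancy grid as a NIfTI volume with spacing in the header."""
    import nibabel as nib

    affine = np.diag(list(phantom.spacing) + [1.0])
    affine[:3, 3] = phantom.origin
    img = nib.Nifti1Image(phantom.grid.astype(np.uint8), affine)
    img.header.set_zooms(phantom.spacing)
    nib.save(img, str(path))
    return str(path)
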