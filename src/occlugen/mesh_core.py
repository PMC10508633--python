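"""Mesh data model, file I/O and discrete differential-geometry primitives.

Crown geometry is carried as :class:`trimesh.Trimesh` in millimetre
coordinates, right-handed with the occlusal surface facing +Z.  This module
adds the pieces the downstream stages need: validated loading, a cotangent
discrete mean-curvature estimator, and plain-text point-cloud export.
"""

from __future__ import annotations

import os
from collections import deque

import numpy as np
import trimesh

__all__ = [
    "MeshValidationError",
    "read_mesh",
    "write_mesh",
    "bounding_box",
    "vertex_curvature",
    "write_xyz",
    "read_xyz",
]

_SUPPORTED = {".obj", ".ply", ".stl"}

#: tolerance (mm) for welding duplicate vertices on STL load
WELD_TOL = 1e-6


class MeshValidationError(ValueError):
    """Raised when a mesh violates the contracts of this package."""


def _validate(mesh: trimesh.Trimesh, source: str = "<mesh>") -> trimesh.Trimesh:
    if len(mesh.vertices) == 0 or len(mesh.faces) == 0:
        raise MeshValidationError(f"empty mesh: {source}")
    if mesh.faces.max() >= len(mesh.vertices):
        raise MeshValidationError(f"face index out of range: {source}")
    if not np.isfinite(mesh.vertices).all():
        raise MeshValidationError(f"non-finite vertex coordinates: {source}")
    return mesh


def read_mesh(path: str | os.PathLike, file_type: str | None = None) -> trimesh.Trimesh:
    """Load an OBJ/PLY/STL triangle mesh (millimetres, passed through).

    STL stores loose triangles; duplicate vertices are welded at
    :data:`WELD_TOL` so that vertex adjacency is well defined.  Zero-area
    faces are dropped.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"mesh file not found: {path}")
    ext = (file_type or os.path.splitext(path)[1].lstrip(".")).lower()
    if f".{ext}" not in _SUPPORTED:
        raise MeshValidationError(f"unsupported mesh format '{ext}' for {path}")
    try:
        mesh = trimesh.load(path, file_type=ext, force="mesh", process=False)
    except Exception as exc:  # pragma: no cover - trimesh error text varies
        raise IOError(f"unreadable mesh file {path}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise MeshValidationError(f"no triangle geometry in {path}")
    if ext == "stl":
        mesh.merge_vertices(merge_tex=True, merge_norm=True, digits_vertex=6)
    mesh.update_faces(mesh.nondegenerate_faces())
    mesh.remove_unreferenced_vertices()
    return _validate(mesh, path)


def write_mesh(mesh: trimesh.Trimesh, path: str | os.PathLike) -> None:
    """Write a mesh; format chosen from the extension (OBJ/PLY/STL)."""
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext not in _SUPPORTED:
        raise MeshValidationError(f"unsupported mesh format '{ext}' for {path}")
    mesh.export(path)


def bounding_box(mesh: trimesh.Trimesh) -> tuple[np.ndarray, np.ndarray]:
    """Axis-aligned bounding box of the mesh as (min corner, max corner), mm."""
    _validate(mesh)
    v = np.asarray(mesh.vertices, dtype=float)
    return v.min(axis=0), v.max(axis=0)


def _interior_mask(mesh: trimesh.Trimesh) -> np.ndarray:
    """True for vertices not on an open boundary edge."""
    interior = np.ones(len(mesh.vertices), dtype=bool)
    # edges that belong to exactly one face lie on the boundary
    edges = mesh.edges_sorted
    unique, counts = np.unique(edges, axis=0, return_counts=True)
    boundary_edges = unique[counts == 1]
    if len(boundary_edges):
        interior[np.unique(boundary_edges)] = False
    return interior


def vertex_curvature(mesh: trimesh.Trimesh) -> np.ndarray:
    """Discrete mean-curvature magnitude per vertex (1/mm).

    Uses the cotangent Laplace–Beltrami operator with barycentric vertex
    areas: the mean-curvature normal at vertex i is

        K_i = (1/(2 A_i)) * sum_j (cot a_ij + cot b_ij) (v_i - v_j)

    and |K_i| = 2 H_i, so the unsigned mean curvature is |K_i| / 2.  The
    estimate is undefined on open boundaries; boundary vertices inherit the
    value of their nearest interior neighbour (graph distance).
    """
    _validate(mesh)
    v = np.asarray(mesh.vertices, dtype=float)
    f = np.asarray(mesh.faces, dtype=np.int64)
    nv = len(v)

    lap = np.zeros((nv, 3))
    area = np.zeros(nv)

    for k in range(3):
        i = f[:, k]
        j = f[:, (k + 1) % 3]
        o = f[:, (k + 2) % 3]  # vertex opposite edge (i, j)
        e1 = v[i] - v[o]
        e2 = v[j] - v[o]
        cross = np.cross(e1, e2)
        cross_norm = np.linalg.norm(cross, axis=1)
        cross_norm = np.where(cross_norm < 1e-300, 1e-300, cross_norm)
        cot = (e1 * e2).sum(axis=1) / cross_norm
        half = 0.5 * cot
        # edge (i, j) gets the cotangent of the opposite angle from this face
        np.add.at(lap, i, half[:, None] * (v[i] - v[j]))
        np.add.at(lap, j, half[:, None] * (v[j] - v[i]))

    # mixed Voronoi vertex areas: exact Voronoi cell on non-obtuse triangles,
    # half / quarter triangle area at and opposite an obtuse corner
    tri_area = 0.5 * np.linalg.norm(
        np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]]), axis=1
    )
    cots = np.empty((len(f), 3))
    for k in range(3):
        i, j, o = f[:, k], f[:, (k + 1) % 3], f[:, (k + 2) % 3]
        e1 = v[i] - v[o]
        e2 = v[j] - v[o]
        cn = np.linalg.norm(np.cross(e1, e2), axis=1)
        cn = np.where(cn < 1e-300, 1e-300, cn)
        cots[:, k] = (e1 * e2).sum(axis=1) / cn  # cot of angle at o, opposite (i, j)
    obtuse = cots < 0  # column k: angle at vertex opposite edge k is obtuse
    any_obtuse = obtuse.any(axis=1)
    for k in range(3):
        i, j, o = f[:, k], f[:, (k + 1) % 3], f[:, (k + 2) % 3]
        ln2 = ((v[i] - v[j]) ** 2).sum(axis=1)
        vor = 0.125 * cots[:, k] * ln2  # (1/8)|ij|^2 cot(opposite), to each endpoint
        contrib_i = np.where(
            any_obtuse,
            np.where(obtuse[:, (k + 1) % 3], tri_area / 2.0, tri_area / 4.0) / 2.0,
            vor,
        )
        np.add.at(area, i, contrib_i)
        contrib_j = np.where(
            any_obtuse,
            np.where(obtuse[:, (k + 2) % 3], tri_area / 2.0, tri_area / 4.0) / 2.0,
            vor,
        )
        np.add.at(area, j, contrib_j)

    area = np.where(area < 1e-300, 1e-300, area)
    # lap already carries (cot a + cot b)/2 per edge, so |lap| / (2 A) = H
    h = np.linalg.norm(lap / (2.0 * area)[:, None], axis=1)

    interior = _interior_mask(mesh)
    if interior.any() and not interior.all():
        h = _fill_boundary(mesh, h, interior)
    return h


def _fill_boundary(mesh: trimesh.Trimesh, values: np.ndarray, interior: np.ndarray) -> np.ndarray:
    """BFS from interior vertices: boundary vertices copy the nearest interior value."""
    out = values.copy()
    neighbors = mesh.vertex_neighbors
    todo = deque(np.nonzero(interior)[0].tolist())
    done = interior.copy()
    while todo:
        i = todo.popleft()
        for j in neighbors[i]:
            if not done[j]:
                out[j] = out[i]
                done[j] = True
                todo.append(j)
    return out


def write_xyz(points: np.ndarray, path: str | os.PathLike) -> None:
    """Write a point cloud as plain text, one ``x y z`` triple per line (mm)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if not np.isfinite(pts).all():
        raise MeshValidationError("non-finite point coordinates")
    np.savetxt(os.fspath(path), pts, fmt="%.6f")


def read_xyz(path: str | os.PathLike) -> np.ndarray:
    pts = np.loadtxt(os.fspath(path), dtype=float)
    return pts.reshape(-1, 3)
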