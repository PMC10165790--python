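"""Triangulated surface meshes and the geometric primitives built on them.

The :class:`SurfaceMesh` is the carrier for torso scans and brace models
throughout the pipeline.  Coordinates are always millimetres, with the
anatomical convention +x = patient left, +y = anterior, +z = superior.
File I/O (STL/PLY/OBJ) is delegated to :mod:`trimesh`; the exact
nearest-point, inside/outside and slab-clipping kernels live in
:mod:`torsofit._geometry`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import trimesh

from . import _geometry
from ._bvh import AABBTree

MERGE_TOL_MM = 1e-6
DEGENERATE_AREA_MM2 = 1e-12
ON_SURFACE_TOL_MM = 1e-6


class InvalidMeshError(ValueError):
    """Raised when an input mesh violates a precondition (empty, open, ...)."""


@dataclass(frozen=True)
class Plane:
    """Oriented plane given by a point on it and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.point, dtype=np.float64).reshape(3)
        n = np.asarray(self.normal, dtype=np.float64).reshape(3)
        norm = np.linalg.norm(n)
        if abs(norm - 1.0) > 1e-9:
            if norm == 0:
                raise ValueError("plane normal must be non-zero")
            n = n / norm
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "normal", n)

    def signed_distance(self, pts: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(pts) - self.point) @ self.normal


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion: rotation (det +1 orthonormal) then translation, mm."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation has negative determinant (reflection)")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return np.atleast_2d(pts) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass
class CleaningReport:
    merged_vertices: int = 0
    dropped_faces: int = 0


class SurfaceMesh:
    """Triangulated surface: ``vertices`` (n, 3) mm and ``faces`` (m, 3)."""

    def __init__(self, vertices, faces, cleaning: Optional[CleaningReport] = None):
        self.vertices = np.asarray(vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise InvalidMeshError("face index exceeds vertex count")
        if len(self.faces) and self.faces.min() < 0:
            raise InvalidMeshError("negative face index")
        self.cleaning = cleaning or CleaningReport()
        self._tm: Optional[trimesh.Trimesh] = None
        self._index: Optional[AABBTree] = None

    # -- derived views ------------------------------------------------------
    @property
    def trimesh(self) -> trimesh.Trimesh:
        if self._tm is None:
            self._tm = trimesh.Trimesh(
                vertices=self.vertices, faces=self.faces, process=False
            )
        return self._tm

    @property
    def surface_index(self) -> AABBTree:
        if self._index is None:
            if len(self.faces) == 0:
                raise InvalidMeshError("mesh has no faces")
            self._index = AABBTree(self.vertices, self.faces)
        return self._index

    @property
    def is_watertight(self) -> bool:
        return bool(self.trimesh.is_watertight)

    @property
    def open_edge_count(self) -> int:
        edges = self.trimesh.edges_sorted
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return int((counts != 2).sum())

    @property
    def area(self) -> float:
        return float(self.trimesh.area)

    @property
    def z_range(self) -> tuple[float, float]:
        z = self.vertices[:, 2]
        return float(z.min()), float(z.max())

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices.copy(), self.faces.copy())

    def __repr__(self) -> str:  # pragma: no cover
        return f"SurfaceMesh({len(self.vertices)} vertices, {len(self.faces)} faces)"


# ---------------------------------------------------------------------------
# construction / cleaning


def clean_mesh(vertices, faces) -> SurfaceMesh:
    """Merge vertices closer than 1e-6 mm and drop zero-area faces."""
    v = np.asarray(vertices, dtype=np.float64).reshape(-1, 3)
    f = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
    report = CleaningReport()
    if len(v):
        key = np.round(v / MERGE_TOL_MM).astype(np.int64)
        _, first, inv = np.unique(key, axis=0, return_index=True, return_inverse=True)
        report.merged_vertices = len(v) - len(first)
        v = v[np.sort(first)]
        # remap through the sorted-unique ordering
        order = np.argsort(first)
        rank = np.empty_like(order)
        rank[order] = np.arange(len(order))
        f = rank[inv][f] if len(f) else f
    if len(f):
        tri = v[f]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )
        degenerate = (
            (areas < DEGENERATE_AREA_MM2)
            | (f[:, 0] == f[:, 1])
            | (f[:, 1] == f[:, 2])
            | (f[:, 2] == f[:, 0])
        )
        report.dropped_faces = int(degenerate.sum())
        f = f[~degenerate]
    if len(v) == 0 or len(f) == 0:
        raise InvalidMeshError("mesh is empty after cleaning")
    # drop unreferenced vertices
    used = np.unique(f)
    remap = np.full(len(v), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return SurfaceMesh(v[used], remap[f], cleaning=report)


_FORMATS = {"stl", "ply", "obj"}


def read_mesh(path, fmt: str = "auto") -> SurfaceMesh:
    """Read an STL/PLY/OBJ surface, merging duplicate vertices (1e-6 mm)."""
    path = Path(path)
    file_type = path.suffix.lstrip(".").lower() if fmt == "auto" else fmt.lower()
    if file_type not in _FORMATS:
        raise ValueError(f"unsupported mesh format: {file_type!r}")
    if not path.exists():
        raise IOError(f"mesh file not found: {path}")
    try:
        loaded = trimesh.load(str(path), file_type=file_type, process=False, force="mesh")
    except Exception as exc:
        raise IOError(f"could not read {path}: {exc}") from exc
    if not isinstance(loaded, trimesh.Trimesh) or len(loaded.faces) == 0:
        raise InvalidMeshError(f"no triangles found in {path}")
    return clean_mesh(loaded.vertices, loaded.faces)


def write_mesh(mesh: SurfaceMesh, path, fmt: str = "auto") -> None:
    """Write to STL (binary), PLY (binary little-endian) or OBJ."""
    if len(mesh.vertices) == 0 or len(mesh.faces) == 0:
        raise InvalidMeshError("refusing to write an empty mesh")
    path = Path(path)
    file_type = path.suffix.lstrip(".").lower() if fmt == "auto" else fmt.lower()
    if file_type not in _FORMATS:
        raise ValueError(f"unsupported mesh format: {file_type!r}")
    try:
        mesh.trimesh.export(str(path), file_type=file_type)
    except Exception as exc:
        raise IOError(f"could not write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# rigid geometry


def reflect(mesh: SurfaceMesh, plane: Plane) -> SurfaceMesh:
    """Mirror across a plane (Householder map), reversing winding so the
    surface stays outward-oriented and the signed volume keeps its sign."""
    d = mesh.vertices @ plane.normal - plane.point @ plane.normal
    v = mesh.vertices - 2.0 * np.outer(d, plane.normal)
    return SurfaceMesh(v, mesh.faces[:, ::-1])


def apply_rigid(mesh: SurfaceMesh, t: RigidTransform) -> SurfaceMesh:
    return SurfaceMesh(t.apply(mesh.vertices), mesh.faces)


def enclosed_volume(mesh: SurfaceMesh, allow_negative: bool = False) -> float:
    """Signed (divergence-theorem) volume in mm³ of a watertight surface."""
    if not mesh.is_watertight:
        raise InvalidMeshError(
            f"volume undefined for open mesh ({mesh.open_edge_count} "
            "non-manifold/open edges)"
        )
    vol = float(mesh.trimesh.volume)
    if vol < 0 and not allow_negative:
        raise InvalidMeshError(
            "mesh is inward-oriented (negative signed volume); "
            "fix winding or pass allow_negative=True"
        )
    return vol


def nearest_point_on_surface(mesh: SurfaceMesh, query) -> tuple[np.ndarray, float, int]:
    """Exact closest point on the triangle set to a single query point."""
    pts, dist, fid = mesh.surface_index.query(np.asarray(query, dtype=np.float64))
    return pts[0], float(dist[0]), int(fid[0])


def nearest_points_on_surface(mesh: SurfaceMesh, queries):
    """Batched exact closest-point query; returns (points, distances, face ids)."""
    return mesh.surface_index.query(queries)


def winding_number(mesh: SurfaceMesh, queries) -> np.ndarray:
    return _geometry.winding_numbers(mesh.vertices, mesh.faces, queries)


def point_inside(mesh: SurfaceMesh, query) -> str:
    """Classify a point as 'inside' / 'outside' / 'on-surface'.

    Uses the generalised winding number with a 0.5 threshold; points within
    1e-6 mm of the surface are reported on-surface.
    """
    if not mesh.is_watertight:
        raise InvalidMeshError(
            f"inside/outside undefined for open mesh ({mesh.open_edge_count} open edges)"
        )
    q = np.asarray(query, dtype=np.float64)
    _, dist, _ = mesh.surface_index.query(q[None, :])
    if dist[0] <= ON_SURFACE_TOL_MM:
        return "on-surface"
    w = _geometry.winding_numbers(mesh.vertices, mesh.faces, q[None, :])[0]
    return "inside" if abs(w) > 0.5 else "outside"


def slice_z(mesh: SurfaceMesh, zmin: float, zmax: float, cap: bool = True) -> SurfaceMesh:
    """Clip to the slab ``zmin <= z <= zmax``; with ``cap`` the result is
    closed with planar caps, otherwise it is an open shell."""
    if not zmin < zmax:
        raise ValueError("zmin must be < zmax")
    lo, hi = mesh.z_range
    if zmax <= lo or zmin >= hi:
        raise InvalidMeshError(
            f"slab [{zmin}, {zmax}] does not intersect mesh z-range [{lo}, {hi}]"
        )
    v, f = _geometry.clip_mesh_to_slab(mesh.vertices, mesh.faces, zmin, zmax, cap=cap)
    if len(f) == 0:
        raise InvalidMeshError("slab clipping produced an empty mesh")
    return SurfaceMesh(v, f)
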