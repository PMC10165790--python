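"""Torso / brace asymmetry index.

The index quantifies mirror asymmetry of a closed surface: estimate (or
accept) a mid-sagittal plane, mirror the surface across it, register the
mirror back onto the original with rigid ICP, trim both to a common
z-extent, and report the volume lying between the two solids (Boolean
symmetric difference) as a percentage of the trimmed original's volume.
A perfectly mirror-symmetric shape scores 0; larger lateral offsets and
rib humps push the score up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _geometry
from .mesh import (
    InvalidMeshError,
    Plane,
    RigidTransform,
    SurfaceMesh,
    apply_rigid,
    enclosed_volume,
    reflect,
    slice_z,
)

DEFAULT_VOXEL_PITCH_MM = 2.0
MAX_GRID_CELLS = 200_000_000


@dataclass(frozen=True)
class IcpConfig:
    """Parameters of the rigid iterative-closest-point registration.

    ``sample_size`` surface points are drawn area-weighted from the source
    mesh (seeded, so runs are reproducible); iteration stops when the RMS
    residual changes by less than ``convergence_tol`` mm.
    """

    max_iterations: int = 100
    convergence_tol: float = 1e-4
    sample_size: int = 5000
    seed: int = 0

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")
        if self.sample_size < 100:
            raise ValueError("sample_size must be >= 100")


@dataclass
class IcpResult:
    transform: RigidTransform
    rms_residual: float
    iterations: int
    converged: bool
    warning: Optional[str] = None


@dataclass
class AsymmetryResult:
    """Full output of the asymmetry pipeline, intermediates included."""

    asymmetry_percent: float
    inter_surface_volume: float
    total_volume: float
    mirror_plane: Plane
    icp_transform: RigidTransform
    icp_rms_residual: float
    trim_interval: tuple[float, float]
    voxel_pitch: float
    icp_iterations: int = 0

    def as_dict(self) -> dict:
        return {
            "asymmetry_percent": self.asymmetry_percent,
            "inter_surface_volume_mm3": self.inter_surface_volume,
            "total_volume_mm3": self.total_volume,
            "mirror_plane_point": self.mirror_plane.point.tolist(),
            "mirror_plane_normal": self.mirror_plane.normal.tolist(),
            "icp_rotation": self.icp_transform.rotation.tolist(),
            "icp_translation": self.icp_transform.translation.tolist(),
            "icp_rms_residual_mm": self.icp_rms_residual,
            "icp_iterations": self.icp_iterations,
            "trim_interval_mm": list(self.trim_interval),
            "voxel_pitch_mm": self.voxel_pitch,
        }


def estimate_midsagittal_plane(mesh: SurfaceMesh) -> Plane:
    """Mid-sagittal plane from principal axes of the vertex cloud.

    The dominant principal direction is taken as the longitudinal axis; of
    the remaining directions the one most aligned with the left-right (x)
    axis, re-signed to +x, is the plane normal.  The plane passes through
    the vertex centroid.  Raises for near-isotropic clouds (e.g. a sphere)
    where the lateral axes are not identifiable.
    """
    v = mesh.vertices
    if len(v) < 4:
        raise InvalidMeshError("too few vertices for plane estimation")
    centroid = v.mean(axis=0)
    cov = np.cov((v - centroid).T)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[2] <= 0 or evals[0] / evals[2] > 1.0 - 1e-6:
        raise InvalidMeshError("degenerate (isotropic) vertex distribution")
    # lateral candidates: the two minor principal directions
    lateral = evecs[:, :2]
    align = np.abs(lateral[0, :])  # |x component|
    if abs(align[0] - align[1]) < 1e-9 and abs(evals[0] - evals[1]) / evals[2] < 1e-9:
        raise InvalidMeshError("lateral principal directions are degenerate")
    normal = lateral[:, int(np.argmax(align))]
    if normal[0] < 0:
        normal = -normal
    return Plane(centroid, normal)


def sample_surface(mesh: SurfaceMesh, n: int, seed: int) -> np.ndarray:
    """Area-weighted uniform surface samples (deterministic for a seed)."""
    rng = np.random.default_rng(seed)
    tri = mesh.vertices[mesh.faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    probs = areas / areas.sum()
    fidx = rng.choice(len(tri), size=n, p=probs)
    r1 = np.sqrt(rng.random(n))
    r2 = rng.random(n)
    a, b, c = tri[fidx, 0], tri[fidx, 1], tri[fidx, 2]
    return (1 - r1)[:, None] * a + (r1 * (1 - r2))[:, None] * b + (r1 * r2)[:, None] * c


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping src onto dst (SVD solution)."""
    cs = src.mean(axis=0)
    cd = dst.mean(axis=0)
    h = (src - cs).T @ (dst - cd)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(r, cd - r @ cs)


def icp_register(
    source: SurfaceMesh, target: SurfaceMesh, cfg: IcpConfig = IcpConfig()
) -> IcpResult:
    """Point-to-point rigid ICP of ``source`` onto ``target``.

    Matches seeded area-weighted source samples to their exact nearest
    points on the target surface, solves the Kabsch least-squares rigid
    fit, and iterates until the RMS residual stabilises.
    """
    if len(source.faces) == 0 or len(target.faces) == 0:
        raise InvalidMeshError("ICP requires non-empty meshes")
    samples = sample_surface(source, cfg.sample_size, cfg.seed)
    index = target.surface_index
    current = samples.copy()
    cumulative = RigidTransform.identity()
    prev_rms = np.inf
    rms = np.inf
    non_decreasing = 0
    warning = None
    iterations = 0
    for iterations in range(1, cfg.max_iterations + 1):
        matches, dists, _ = index.query(current)
        step = _kabsch(current, matches)
        cumulative = step.compose(cumulative)
        current = step.apply(current)
        rms = float(np.sqrt(np.mean(np.sum((current - matches) ** 2, axis=1))))
        if rms >= prev_rms - 1e-15:
            non_decreasing += 1
            if non_decreasing >= 5:
                warning = "residual stopped decreasing for 5 iterations"
                break
        else:
            non_decreasing = 0
        if abs(prev_rms - rms) < cfg.convergence_tol:
            break
        prev_rms = rms
    return IcpResult(
        transform=cumulative,
        rms_residual=rms,
        iterations=iterations,
        converged=warning is None,
        warning=warning,
    )


def trim_to_equal_length(
    original: SurfaceMesh, registered_mirror: SurfaceMesh, min_overlap: float = 0.10
) -> tuple[SurfaceMesh, SurfaceMesh, tuple[float, float]]:
    """Slice both meshes (capped) to the intersection of their z-ranges."""
    lo_a, hi_a = original.z_range
    lo_b, hi_b = registered_mirror.z_range
    zmin, zmax = max(lo_a, lo_b), min(hi_a, hi_b)
    larger = max(hi_a - lo_a, hi_b - lo_b)
    if zmax - zmin < min_overlap * larger:
        raise InvalidMeshError(
            f"z-overlap {max(zmax - zmin, 0.0):.2f} mm is below "
            f"{min_overlap:.0%} of the larger extent ({larger:.2f} mm)"
        )
    eps = 1e-9 * max(1.0, larger)
    same_a = abs(zmin - lo_a) < eps and abs(zmax - hi_a) < eps
    same_b = abs(zmin - lo_b) < eps and abs(zmax - hi_b) < eps
    a = original if same_a else slice_z(original, zmin, zmax, cap=True)
    b = registered_mirror if same_b else slice_z(registered_mirror, zmin, zmax, cap=True)
    return a, b, (zmin, zmax)


def inter_surface_volume(
    a: SurfaceMesh,
    b: SurfaceMesh,
    voxel_pitch: float = DEFAULT_VOXEL_PITCH_MM,
    max_cells: int = MAX_GRID_CELLS,
) -> float:
    """Volume (mm³) of the Boolean symmetric difference of two solids.

    Both solids are rasterised on one shared grid; a cell counts when
    exactly one solid contains its centre.  Converges to the exact
    symmetric-difference volume as the pitch shrinks.
    """
    if voxel_pitch <= 0:
        raise ValueError("voxel_pitch must be > 0")
    for name, m in (("first", a), ("second", b)):
        if not m.is_watertight:
            raise InvalidMeshError(
                f"{name} mesh is not watertight ({m.open_edge_count} open edges)"
            )
    lo = np.minimum(a.vertices.min(axis=0), b.vertices.min(axis=0)) - voxel_pitch
    hi = np.maximum(a.vertices.max(axis=0), b.vertices.max(axis=0)) + voxel_pitch
    shape = tuple(np.maximum(np.ceil((hi - lo) / voxel_pitch).astype(int), 1))
    if int(np.prod(shape)) > max_cells:
        raise MemoryError(
            f"grid {shape} exceeds the {max_cells} cell budget; "
            "increase voxel_pitch"
        )
    occ_a = _geometry.column_parity_occupancy(a.vertices, a.faces, lo, voxel_pitch, shape)
    occ_b = _geometry.column_parity_occupancy(b.vertices, b.faces, lo, voxel_pitch, shape)
    return float((occ_a ^ occ_b).sum()) * voxel_pitch**3


def asymmetry_index(
    mesh: SurfaceMesh,
    cfg: IcpConfig = IcpConfig(),
    voxel_pitch: float = DEFAULT_VOXEL_PITCH_MM,
    plane_override: Optional[Plane] = None,
) -> AsymmetryResult:
    """Run the full mirror → ICP → trim → volume-ratio chain.

    The mirrored copy is the ICP source and the original the target; the
    denominator is the enclosed volume of the trimmed original.
    """
    if not mesh.is_watertight:
        raise InvalidMeshError(
            f"asymmetry index requires a watertight mesh "
            f"({mesh.open_edge_count} open edges)"
        )
    plane = plane_override if plane_override is not None else estimate_midsagittal_plane(mesh)
    mirrored = reflect(mesh, plane)
    icp = icp_register(mirrored, mesh, cfg)
    registered = apply_rigid(mirrored, icp.transform)
    orig_t, mirr_t, interval = trim_to_equal_length(mesh, registered)
    inter = inter_surface_volume(orig_t, mirr_t, voxel_pitch)
    total = enclosed_volume(orig_t)
    return AsymmetryResult(
        asymmetry_percent=100.0 * inter / total,
        inter_surface_volume=inter,
        total_volume=total,
        mirror_plane=plane,
        icp_transform=icp.transform,
        icp_rms_residual=icp.rms_residual,
        trim_interval=interval,
        voxel_pitch=voxel_pitch,
        icp_iterations=icp.iterations,
    )
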