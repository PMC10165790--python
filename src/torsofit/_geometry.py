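"""Low-level vectorised geometry kernels.

Everything here operates on raw ``(n, 3)`` float64 vertex arrays and
``(m, 3)`` integer face arrays so the public mesh layer stays thin.
Kernels are numpy, with numba-compiled fast paths where the point x face
product dominates; all are deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "closest_point_on_triangles",
    "winding_numbers",
    "column_parity_occupancy",
    "clip_mesh_to_slab",
]


def closest_point_on_triangles(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on each triangle ``tri[i]`` to each query ``points[i]``.

    Implements the region-based point/triangle projection (Voronoi-region
    case analysis) fully vectorised; ``points`` is ``(n, 3)`` and ``tri``
    is ``(n, 3, 3)``.
    """
    p = np.asarray(points, dtype=np.float64)
    a, b, c = tri[:, 0, :], tri[:, 1, :], tri[:, 2, :]
    ab = b - a
    ac = c - a
    ap = p - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def settle(mask, value):
        m = mask & ~done
        if m.any():
            out[m] = value[m] if value.ndim == 2 else value
            done[m] = True

    settle((d1 <= 0.0) & (d2 <= 0.0), a)  # vertex A
    settle((d3 >= 0.0) & (d4 <= d3), b)  # vertex B

    denom_ab = d1 - d3
    t_ab = np.divide(d1, denom_ab, out=np.zeros_like(d1), where=denom_ab != 0.0)
    settle((vc <= 0.0) & (d1 >= 0.0) & (d3 <= 0.0), a + t_ab[:, None] * ab)

    settle((d6 >= 0.0) & (d5 <= d6), c)  # vertex C

    denom_ac = d2 - d6
    t_ac = np.divide(d2, denom_ac, out=np.zeros_like(d2), where=denom_ac != 0.0)
    settle((vb <= 0.0) & (d2 >= 0.0) & (d6 <= 0.0), a + t_ac[:, None] * ac)

    denom_bc = (d4 - d3) + (d5 - d6)
    t_bc = np.divide(d4 - d3, denom_bc, out=np.zeros_like(d4), where=denom_bc != 0.0)
    settle(
        (va <= 0.0) & ((d4 - d3) >= 0.0) & ((d5 - d6) >= 0.0),
        b + t_bc[:, None] * (c - b),
    )

    # interior
    rest = ~done
    if rest.any():
        s = va + vb + vc
        inv = np.divide(1.0, s, out=np.zeros_like(s), where=s != 0.0)
        v = vb * inv
        w = vc * inv
        out[rest] = (a + v[:, None] * ab + w[:, None] * ac)[rest]
    return out


try:  # numba speeds the O(points x faces) solid-angle sum up ~30x
    from numba import njit as _njit

    @_njit(cache=True, fastmath=False)
    def _winding_kernel(tri, pts):  # pragma: no cover - exercised via wrapper
        n = pts.shape[0]
        m = tri.shape[0]
        out = np.empty(n)
        for q in range(n):
            px, py, pz = pts[q, 0], pts[q, 1], pts[q, 2]
            acc = 0.0
            for f in range(m):
                ax = tri[f, 0, 0] - px
                ay = tri[f, 0, 1] - py
                az = tri[f, 0, 2] - pz
                bx = tri[f, 1, 0] - px
                by = tri[f, 1, 1] - py
                bz = tri[f, 1, 2] - pz
                cx = tri[f, 2, 0] - px
                cy = tri[f, 2, 1] - py
                cz = tri[f, 2, 2] - pz
                la = np.sqrt(ax * ax + ay * ay + az * az)
                lb = np.sqrt(bx * bx + by * by + bz * bz)
                lc = np.sqrt(cx * cx + cy * cy + cz * cz)
                det = (
                    ax * (by * cz - bz * cy)
                    - ay * (bx * cz - bz * cx)
                    + az * (bx * cy - by * cx)
                )
                denom = (
                    la * lb * lc
                    + (ax * bx + ay * by + az * bz) * lc
                    + (bx * cx + by * cy + bz * cz) * la
                    + (cx * ax + cy * ay + cz * az) * lb
                )
                acc += np.arctan2(det, denom)
            out[q] = acc / (2.0 * np.pi)
        return out

except ImportError:  # pragma: no cover
    _winding_kernel = None


def winding_numbers(
    vertices: np.ndarray,
    faces: np.ndarray,
    points: np.ndarray,
    chunk: int = 1_000_000,
) -> np.ndarray:
    """Generalised winding number of each query point w.r.t. the surface.

    Sums the signed solid angle of every triangle (van Oosterom–Strackee
    formula) and divides by 4π; ~1 inside a watertight outward-oriented
    surface, ~0 outside.  Chunked over the points × faces product to bound
    memory.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    tri = np.asarray(vertices, dtype=np.float64)[np.asarray(faces, dtype=np.int64)]
    m = len(tri)
    n = len(pts)
    if m == 0 or n == 0:
        return np.zeros(n)
    if _winding_kernel is not None:
        return _winding_kernel(np.ascontiguousarray(tri), np.ascontiguousarray(pts))
    rows = max(1, int(chunk // max(m, 1)))
    w = np.empty(n)
    for s in range(0, n, rows):
        p = pts[s : s + rows]
        a = tri[None, :, 0, :] - p[:, None, :]
        b = tri[None, :, 1, :] - p[:, None, :]
        c = tri[None, :, 2, :] - p[:, None, :]
        la = np.linalg.norm(a, axis=2)
        lb = np.linalg.norm(b, axis=2)
        lc = np.linalg.norm(c, axis=2)
        det = np.einsum("pfi,pfi->pf", a, np.cross(b, c))
        denom = (
            la * lb * lc
            + np.einsum("pfi,pfi->pf", a, b) * lc
            + np.einsum("pfi,pfi->pf", b, c) * la
            + np.einsum("pfi,pfi->pf", c, a) * lb
        )
        w[s : s + rows] = np.arctan2(det, denom).sum(axis=1) / (2.0 * np.pi)
    return w


def column_parity_occupancy(
    vertices: np.ndarray,
    faces: np.ndarray,
    origin: np.ndarray,
    pitch: float,
    shape: tuple[int, int, int],
) -> np.ndarray:
    """Cell-centre occupancy of a watertight mesh on a regular grid.

    Casts a vertical ray through the centre of every (x, y) grid column,
    records the z of each triangle crossing, and fills cells by crossing
    parity.  Triangles parallel to z (zero projected area) never cross a
    vertical ray and are skipped.  Returns a boolean ``shape`` array.
    """
    nx, ny, nz = shape
    v = np.asarray(vertices, dtype=np.float64)
    tri = v[np.asarray(faces, dtype=np.int64)]
    ox, oy, oz = float(origin[0]), float(origin[1]), float(origin[2])
    # tiny distinct irrational-ish offsets keep ray samples off projected
    # triangle edges (e.g. the shared diagonal of a quad), whose exact hits
    # would double-count crossings and break parity
    xs = ox + (np.arange(nx) + 0.5 + 2.718281828e-5) * pitch
    ys = oy + (np.arange(ny) + 0.5 + 3.141592653e-5) * pitch

    cols: list[np.ndarray] = []
    zs: list[np.ndarray] = []
    for t in tri:
        (x0, y0, z0), (x1, y1, z1), (x2, y2, z2) = t
        denom = (x1 - x0) * (y2 - y0) - (x2 - x0) * (y1 - y0)
        if abs(denom) < 1e-14:
            continue
        i0 = np.searchsorted(xs, min(x0, x1, x2))
        i1 = np.searchsorted(xs, max(x0, x1, x2), side="right")
        j0 = np.searchsorted(ys, min(y0, y1, y2))
        j1 = np.searchsorted(ys, max(y0, y1, y2), side="right")
        if i0 >= i1 or j0 >= j1:
            continue
        gx, gy = np.meshgrid(xs[i0:i1], ys[j0:j1], indexing="ij")
        u = ((gx - x0) * (y2 - y0) - (gy - y0) * (x2 - x0)) / denom
        w = ((x1 - x0) * (gy - y0) - (y1 - y0) * (gx - x0)) / denom
        inside = (u >= 0.0) & (w >= 0.0) & (u + w <= 1.0)
        if not inside.any():
            continue
        zc = z0 + u[inside] * (z1 - z0) + w[inside] * (z2 - z0)
        ii, jj = np.nonzero(inside)
        cols.append((ii + i0) * ny + (jj + j0))
        zs.append(zc)

    occ = np.zeros((nx * ny, nz), dtype=np.int32)
    if cols:
        col = np.concatenate(cols)
        z = np.concatenate(zs)
        # first cell whose centre lies above the crossing
        k = np.floor((z - oz) / pitch - 0.5).astype(np.int64) + 1
        keep = k < nz
        k = np.clip(k[keep], 0, nz - 1)
        np.add.at(occ, (col[keep], k), 1)
    occ = np.cumsum(occ, axis=1) % 2
    return occ.astype(bool).reshape(nx, ny, nz)


# ---------------------------------------------------------------------------
# slab clipping with planar caps


def _clip_polygon_halfspace(poly: np.ndarray, z_cut: float, keep_below: bool):
    """Sutherland–Hodgman clip of a 3D polygon against z<=z_cut or z>=z_cut."""
    sign = -1.0 if keep_below else 1.0
    d = sign * (poly[:, 2] - z_cut)
    out = []
    n = len(poly)
    for i in range(n):
        j = (i + 1) % n
        pi, pj = poly[i], poly[j]
        di, dj = d[i], d[j]
        if di >= 0.0:
            out.append(pi)
            if dj < 0.0:
                t = di / (di - dj)
                out.append(pi + t * (pj - pi))
        elif dj >= 0.0:
            t = di / (di - dj)
            out.append(pi + t * (pj - pi))
    return np.asarray(out) if out else np.empty((0, 3))


def _weld(vertices: np.ndarray, decimals: int = 6):
    key = np.round(vertices, decimals)
    _, idx, inv = np.unique(key, axis=0, return_index=True, return_inverse=True)
    return vertices[idx], inv


def _boundary_loops(faces: np.ndarray):
    """Directed boundary edges (used by exactly one face) assembled into loops."""
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    und = np.sort(edges, axis=1)
    _, inv, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
    boundary = edges[counts[inv] == 1]
    nxt = {int(a): int(b) for a, b in boundary}
    loops = []
    seen: set[int] = set()
    for start in list(nxt):
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        cur = nxt.get(start)
        while cur is not None and cur != start and cur not in seen:
            loop.append(cur)
            seen.add(cur)
            cur = nxt.get(cur)
        if cur == start and len(loop) >= 3:
            loops.append(loop)
    return loops


def clip_mesh_to_slab(
    vertices: np.ndarray,
    faces: np.ndarray,
    zmin: float,
    zmax: float,
    cap: bool = True,
):
    """Clip a triangle mesh to ``zmin <= z <= zmax``; optionally add planar caps.

    Caps are centroid fans over the cut boundary loops, which is exact for
    star-shaped cross sections (all torso/brace/primitive fixtures here).
    Returns ``(vertices, faces)``.
    """
    v = np.asarray(vertices, dtype=np.float64)
    f = np.asarray(faces, dtype=np.int64)
    zt = v[f][:, :, 2]
    inside = (zt >= zmin) & (zt <= zmax)
    full = inside.all(axis=1)
    out = (zt < zmin).all(axis=1) | (zt > zmax).all(axis=1)
    crossing = ~full & ~out

    tris = [v[f[full]].reshape(-1, 3, 3)] if full.any() else []
    for t in v[f[crossing]]:
        poly = _clip_polygon_halfspace(t, zmin, keep_below=False)
        if len(poly) >= 3:
            poly = _clip_polygon_halfspace(poly, zmax, keep_below=True)
        if len(poly) >= 3:
            fan = np.stack(
                [
                    np.repeat(poly[0][None, :], len(poly) - 2, axis=0),
                    poly[1:-1],
                    poly[2:],
                ],
                axis=1,
            )
            tris.append(fan)
    if not tris:
        return np.empty((0, 3)), np.empty((0, 3), dtype=np.int64)
    tri_soup = np.concatenate(tris)
    flat = tri_soup.reshape(-1, 3)
    new_v, inv = _weld(flat)
    new_f = inv.reshape(-1, 3)
    # drop degenerate faces produced by clipping
    keep = (
        (new_f[:, 0] != new_f[:, 1])
        & (new_f[:, 1] != new_f[:, 2])
        & (new_f[:, 2] != new_f[:, 0])
    )
    new_f = new_f[keep]
    if not cap:
        return new_v, new_f

    cap_faces = []
    cap_verts = [new_v]
    n_v = len(new_v)
    for loop in _boundary_loops(new_f):
        pts = new_v[loop]
        z_med = np.median(pts[:, 2])
        centroid = pts.mean(axis=0)
        centroid[2] = z_med
        ci = n_v
        cap_verts.append(centroid[None, :])
        n_v += 1
        idx = np.asarray(loop)
        nxt = np.roll(idx, -1)
        # shell boundary edge runs idx->nxt; the cap must traverse it
        # nxt->idx so shared edges have opposite directions (consistent winding)
        cap_faces.append(np.stack([np.full(len(idx), ci), nxt, idx], axis=1))
    if cap_faces:
        new_v = np.concatenate(cap_verts)
        new_f = np.concatenate([new_f] + cap_faces)
    return new_v, new_f
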