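"""Axis-aligned bounding-box tree for exact nearest-point-on-surface queries.

A static median-split AABB tree over triangles, built once per mesh in
numpy, traversed per query with branch-and-bound in a numba kernel (or a
pure-numpy fallback).  Distances are exact point-to-triangle (vertex,
edge or interior), so results match a brute-force scan over all faces.
"""

from __future__ import annotations

import numpy as np

LEAF_SIZE = 8


def build(tri: np.ndarray):
    """Build the tree over ``(m, 3, 3)`` triangles.

    Returns ``(node_min, node_max, node_left, node_right, node_start,
    node_count, order)``; internal nodes have ``count == -1``, leaves
    index ``order[start:start+count]``.
    """
    m = len(tri)
    lo = tri.min(axis=1)
    hi = tri.max(axis=1)
    centroids = tri.mean(axis=1)

    node_min, node_max = [], []
    node_left, node_right = [], []
    node_start, node_count = [], []
    order = np.arange(m, dtype=np.int64)

    def new_node():
        node_min.append(np.zeros(3))
        node_max.append(np.zeros(3))
        node_left.append(-1)
        node_right.append(-1)
        node_start.append(-1)
        node_count.append(-1)
        return len(node_min) - 1

    # iterative construction to avoid recursion limits on skinny meshes
    root = new_node()
    stack = [(root, 0, m)]
    while stack:
        node, start, end = stack.pop()
        idx = order[start:end]
        node_min[node] = lo[idx].min(axis=0)
        node_max[node] = hi[idx].max(axis=0)
        n = end - start
        if n <= LEAF_SIZE:
            node_start[node] = start
            node_count[node] = n
            continue
        c = centroids[idx]
        axis = int(np.argmax(c.max(axis=0) - c.min(axis=0)))
        half = n // 2
        part = np.argpartition(c[:, axis], half)
        order[start:end] = idx[part]
        left = new_node()
        right = new_node()
        node_left[node] = left
        node_right[node] = right
        stack.append((left, start, start + half))
        stack.append((right, start + half, end))

    return (
        np.asarray(node_min),
        np.asarray(node_max),
        np.asarray(node_left, dtype=np.int64),
        np.asarray(node_right, dtype=np.int64),
        np.asarray(node_start, dtype=np.int64),
        np.asarray(node_count, dtype=np.int64),
        order,
    )


def _closest_on_tri_py(p, a, b, c):  # scalar reference used by the fallback
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = ab @ ap
    d2 = ac @ ap
    if d1 <= 0 and d2 <= 0:
        return a
    bp = p - b
    d3 = ab @ bp
    d4 = ac @ bp
    if d3 >= 0 and d4 <= d3:
        return b
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        return a + ab * (d1 / (d1 - d3))
    cp = p - c
    d5 = ab @ cp
    d6 = ac @ cp
    if d6 >= 0 and d5 <= d6:
        return c
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        return a + ac * (d2 / (d2 - d6))
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        return b + (c - b) * ((d4 - d3) / ((d4 - d3) + (d5 - d6)))
    denom = va + vb + vc
    v = vb / denom
    w = vc / denom
    return a + ab * v + ac * w


try:
    from numba import njit

    @njit(cache=True)
    def _query_kernel(
        nmin, nmax, nleft, nright, nstart, ncount, order, tri, pts
    ):  # pragma: no cover - exercised via query()
        n = pts.shape[0]
        out_pt = np.empty((n, 3))
        out_d = np.empty(n)
        out_f = np.empty(n, dtype=np.int64)
        stack = np.empty(128, dtype=np.int64)
        for q in range(n):
            px, py, pz = pts[q, 0], pts[q, 1], pts[q, 2]
            best = 1e300
            bx = by = bz = 0.0
            bf = -1
            top = 0
            stack[top] = 0
            top += 1
            while top > 0:
                top -= 1
                node = stack[top]
                # squared distance to node box
                dx = max(nmin[node, 0] - px, 0.0, px - nmax[node, 0])
                dy = max(nmin[node, 1] - py, 0.0, py - nmax[node, 1])
                dz = max(nmin[node, 2] - pz, 0.0, pz - nmax[node, 2])
                if dx * dx + dy * dy + dz * dz >= best:
                    continue
                if ncount[node] >= 0:  # leaf
                    for i in range(nstart[node], nstart[node] + ncount[node]):
                        f = order[i]
                        ax, ay, az = tri[f, 0, 0], tri[f, 0, 1], tri[f, 0, 2]
                        vbx, vby, vbz = tri[f, 1, 0], tri[f, 1, 1], tri[f, 1, 2]
                        cx, cy, cz = tri[f, 2, 0], tri[f, 2, 1], tri[f, 2, 2]
                        abx, aby, abz = vbx - ax, vby - ay, vbz - az
                        acx, acy, acz = cx - ax, cy - ay, cz - az
                        apx, apy, apz = px - ax, py - ay, pz - az
                        d1 = abx * apx + aby * apy + abz * apz
                        d2 = acx * apx + acy * apy + acz * apz
                        if d1 <= 0.0 and d2 <= 0.0:
                            qx, qy, qz = ax, ay, az
                        else:
                            bpx, bpy, bpz = px - vbx, py - vby, pz - vbz
                            d3 = abx * bpx + aby * bpy + abz * bpz
                            d4 = acx * bpx + acy * bpy + acz * bpz
                            if d3 >= 0.0 and d4 <= d3:
                                qx, qy, qz = vbx, vby, vbz
                            else:
                                vc = d1 * d4 - d3 * d2
                                if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
                                    t = d1 / (d1 - d3)
                                    qx = ax + abx * t
                                    qy = ay + aby * t
                                    qz = az + abz * t
                                else:
                                    cpx, cpy, cpz = px - cx, py - cy, pz - cz
                                    d5 = abx * cpx + aby * cpy + abz * cpz
                                    d6 = acx * cpx + acy * cpy + acz * cpz
                                    if d6 >= 0.0 and d5 <= d6:
                                        qx, qy, qz = cx, cy, cz
                                    else:
                                        vb = d5 * d2 - d1 * d6
                                        if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
                                            t = d2 / (d2 - d6)
                                            qx = ax + acx * t
                                            qy = ay + acy * t
                                            qz = az + acz * t
                                        else:
                                            va = d3 * d6 - d5 * d4
                                            if (
                                                va <= 0.0
                                                and (d4 - d3) >= 0.0
                                                and (d5 - d6) >= 0.0
                                            ):
                                                t = (d4 - d3) / (
                                                    (d4 - d3) + (d5 - d6)
                                                )
                                                qx = vbx + (cx - vbx) * t
                                                qy = vby + (cy - vby) * t
                                                qz = vbz + (cz - vbz) * t
                                            else:
                                                denom = va + vb + vc
                                                v = vb / denom
                                                w = vc / denom
                                                qx = ax + abx * v + acx * w
                                                qy = ay + aby * v + acy * w
                                                qz = az + abz * v + acz * w
                        ddx, ddy, ddz = px - qx, py - qy, pz - qz
                        d2q = ddx * ddx + ddy * ddy + ddz * ddz
                        if d2q < best:
                            best = d2q
                            bx, by, bz = qx, qy, qz
                            bf = f
                else:
                    # push farther child first so the nearer one pops first
                    l = nleft[node]
                    r = nright[node]
                    dlx = max(nmin[l, 0] - px, 0.0, px - nmax[l, 0])
                    dly = max(nmin[l, 1] - py, 0.0, py - nmax[l, 1])
                    dlz = max(nmin[l, 2] - pz, 0.0, pz - nmax[l, 2])
                    dl = dlx * dlx + dly * dly + dlz * dlz
                    drx = max(nmin[r, 0] - px, 0.0, px - nmax[r, 0])
                    dry = max(nmin[r, 1] - py, 0.0, py - nmax[r, 1])
                    drz = max(nmin[r, 2] - pz, 0.0, pz - nmax[r, 2])
                    dr = drx * drx + dry * dry + drz * drz
                    if dl <= dr:
                        stack[top] = r
                        top += 1
                        stack[top] = l
                        top += 1
                    else:
                        stack[top] = l
                        top += 1
                        stack[top] = r
                        top += 1
            out_pt[q, 0], out_pt[q, 1], out_pt[q, 2] = bx, by, bz
            out_d[q] = np.sqrt(best)
            out_f[q] = bf
        return out_pt, out_d, out_f

except ImportError:  # pragma: no cover
    _query_kernel = None


class AABBTree:
    """Exact nearest-point-on-surface queries against a fixed triangle set."""

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        self.tri = np.ascontiguousarray(
            np.asarray(vertices, dtype=np.float64)[np.asarray(faces, dtype=np.int64)]
        )
        (
            self.nmin,
            self.nmax,
            self.nleft,
            self.nright,
            self.nstart,
            self.ncount,
            self.order,
        ) = build(self.tri)

    def query(self, points: np.ndarray):
        pts = np.ascontiguousarray(np.atleast_2d(np.asarray(points, dtype=np.float64)))
        if _query_kernel is not None:
            return _query_kernel(
                self.nmin,
                self.nmax,
                self.nleft,
                self.nright,
                self.nstart,
                self.ncount,
                self.order,
                self.tri,
                pts,
            )
        return self._query_py(pts)

    def _query_py(self, pts):  # slow but dependency-free fallback
        n = len(pts)
        out_pt = np.empty((n, 3))
        out_d = np.empty(n)
        out_f = np.empty(n, dtype=np.int64)
        for q in range(n):
            p = pts[q]
            best = np.inf
            stack = [0]
            while stack:
                node = stack.pop()
                d = np.maximum(
                    np.maximum(self.nmin[node] - p, 0.0), p - self.nmax[node]
                )
                if d @ d >= best:
                    continue
                if self.ncount[node] >= 0:
                    for i in range(
                        self.nstart[node], self.nstart[node] + self.ncount[node]
                    ):
                        f = self.order[i]
                        c = _closest_on_tri_py(p, *self.tri[f])
                        dd = (p - c) @ (p - c)
                        if dd < best:
                            best = dd
                            out_pt[q] = c
                            out_f[q] = f
                else:
                    stack.extend((self.nleft[node], self.nright[node]))
            out_d[q] = np.sqrt(best)
        return out_pt, out_d, out_f
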