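"""Exact geometric primitives: point/segment/triangle distances and
ray-triangle intersection, plus a KD-tree-accelerated point-to-mesh
distance query.

All routines are pure numpy; the accelerated paths are exact (the
KD-tree only prunes candidates with conservative bounds).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "closest_point_on_segment",
    "closest_point_on_triangles",
    "point_triangle_distance",
    "segment_segment_distance",
    "ray_triangles_hit",
    "triangle_triangle_distance",
    "MeshDistance",
]


def closest_point_on_segment(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Closest point(s) on segment(s) ``ab`` to point(s) ``p`` (broadcasting)."""
    ab = b - a
    denom = np.sum(ab * ab, axis=-1)
    t = np.where(denom > 0, np.sum((p - a) * ab, axis=-1) / np.where(denom > 0, denom, 1.0), 0.0)
    t = np.clip(t, 0.0, 1.0)
    return a + t[..., None] * ab


def closest_point_on_triangles(p: np.ndarray, tri: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closest point on each triangle to each paired query point.

    ``p``: (n, 3) points; ``tri``: (n, 3, 3) triangles (paired). Returns
    ``(distances (n,), closest_points (n, 3))``. The candidate set is the
    in-plane projection (when its barycentric coordinates are interior)
    and the three edge closest points, which covers all cases exactly.
    """
    p = np.atleast_2d(p)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    n = np.cross(b - a, c - a)
    nn = np.sum(n * n, axis=-1)
    safe = nn > 0
    # projection onto the triangle plane
    dist_plane = np.sum((p - a) * n, axis=-1) / np.where(safe, nn, 1.0)
    proj = p - dist_plane[:, None] * n
    # interior test via barycentric coordinates
    v0, v1, v2 = c - a, b - a, proj - a
    d00 = np.sum(v0 * v0, axis=-1)
    d01 = np.sum(v0 * v1, axis=-1)
    d11 = np.sum(v1 * v1, axis=-1)
    d20 = np.sum(v2 * v0, axis=-1)
    d21 = np.sum(v2 * v1, axis=-1)
    denom = d00 * d11 - d01 * d01
    denom_safe = np.where(np.abs(denom) > 0, denom, 1.0)
    u = (d11 * d20 - d01 * d21) / denom_safe
    v = (d00 * d21 - d01 * d20) / denom_safe
    interior = safe & (np.abs(denom) > 0) & (u >= 0) & (v >= 0) & (u + v <= 1)

    cands = [closest_point_on_segment(p, a, b),
             closest_point_on_segment(p, b, c),
             closest_point_on_segment(p, c, a)]
    d2 = [np.sum((p - q) ** 2, axis=-1) for q in cands]
    best = np.argmin(d2, axis=0)
    idx = np.arange(p.shape[0])
    pts = np.stack(cands, axis=0)[best, idx]
    dmin2 = np.min(d2, axis=0)

    proj_d2 = np.sum((p - proj) ** 2, axis=-1)
    use_proj = interior & (proj_d2 <= dmin2)
    pts = np.where(use_proj[:, None], proj, pts)
    dmin2 = np.where(use_proj, proj_d2, dmin2)
    return np.sqrt(dmin2), pts


def point_triangle_distance(p, a, b, c) -> float:
    """Scalar convenience wrapper."""
    d, _ = closest_point_on_triangles(
        np.asarray(p, dtype=float)[None, :],
        np.asarray([a, b, c], dtype=float)[None, :, :],
    )
    return float(d[0])


def segment_segment_distance(p1, q1, p2, q2) -> tuple[float, np.ndarray, np.ndarray]:
    """Minimum distance between segments p1q1 and p2q2 (Ericson's method)."""
    p1, q1, p2, q2 = (np.asarray(v, dtype=float) for v in (p1, q1, p2, q2))
    d1, d2, r = q1 - p1, q2 - p2, p1 - p2
    a = float(d1 @ d1)
    e = float(d2 @ d2)
    f = float(d2 @ r)
    eps = 1e-15
    if a <= eps and e <= eps:
        s = t = 0.0
    elif a <= eps:
        s, t = 0.0, np.clip(f / e, 0.0, 1.0)
    else:
        c = float(d1 @ r)
        if e <= eps:
            t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
        else:
            b = float(d1 @ d2)
            denom = a * e - b * b
            s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > eps else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
            elif t > 1.0:
                t, s = 1.0, np.clip((b - c) / a, 0.0, 1.0)
    c1 = p1 + s * d1
    c2 = p2 + t * d2
    return float(np.linalg.norm(c1 - c2)), c1, c2


def ray_triangles_hit(
    orig: np.ndarray,
    direction: np.ndarray,
    tri: np.ndarray,
    t_min: float = 1e-9,
    t_max: float = np.inf,
) -> tuple[np.ndarray, np.ndarray]:
    """Moller-Trumbore intersection of one ray against many triangles.

    ``tri``: (m, 3, 3). Returns ``(hit_mask (m,), t_values (m,))`` with
    hits restricted to ``t in (t_min, t_max)``.
    """
    orig = np.asarray(orig, dtype=float)
    d = np.asarray(direction, dtype=float)
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1, e2 = v1 - v0, v2 - v0
    pvec = np.cross(d, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > 1e-14
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    tvec = orig - v0
    u = np.einsum("ij,ij->i", tvec, pvec) * inv
    qvec = np.cross(tvec, e1)
    v = np.einsum("j,ij->i", d, qvec) * inv
    t = np.einsum("ij,ij->i", e2, qvec) * inv
    hit = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > t_min) & (t < t_max)
    return hit, t


def rays_first_hit(
    orig: np.ndarray,
    dirs: np.ndarray,
    tri: np.ndarray,
    t_min: float = 1e-9,
    chunk_elems: int = 4_000_000,
) -> tuple[np.ndarray, np.ndarray]:
    """First-hit of many rays from one origin against many triangles.

    Returns ``(tri_index (n,), t (n,))`` with index -1 and t = inf for
    misses. Chunked over rays to bound memory.
    """
    dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
    orig = np.asarray(orig, dtype=float)
    v0 = tri[:, 0]
    e1 = tri[:, 1] - v0
    e2 = tri[:, 2] - v0
    tvec = orig - v0                                  # (m, 3)
    qvec = np.cross(tvec, e1)                         # (m, 3)
    t_base = np.einsum("mj,mj->m", e2, qvec)          # det * t numerator part
    n_rays, m = dirs.shape[0], len(tri)
    out_idx = np.full(n_rays, -1, dtype=int)
    out_t = np.full(n_rays, np.inf)
    if m == 0:
        return out_idx, out_t
    step = max(1, chunk_elems // m)
    for s in range(0, n_rays, step):
        d = dirs[s:s + step]                          # (r, 3)
        pvec = np.cross(d[:, None, :], e2[None, :, :])            # (r, m, 3)
        det = np.einsum("mj,rmj->rm", e1, pvec)
        ok = np.abs(det) > 1e-14
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        u = np.einsum("mj,rmj->rm", tvec, pvec) * inv
        v = np.einsum("rj,mj->rm", d, qvec) * inv
        t = t_base[None, :] * inv
        hit = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > t_min)
        t_masked = np.where(hit, t, np.inf)
        j = np.argmin(t_masked, axis=1)
        rows = np.arange(len(d))
        tbest = t_masked[rows, j]
        found = np.isfinite(tbest)
        out_idx[s:s + step][found] = j[found]
        out_t[s:s + step][found] = tbest[found]
    return out_idx, out_t


def _segment_intersects_triangle(p, q, tri) -> bool:
    hit, _ = ray_triangles_hit(p, q - p, tri[None, :, :], t_min=0.0, t_max=1.0)
    return bool(hit[0])


def triangle_triangle_distance(t1: np.ndarray, t2: np.ndarray) -> float:
    """Exact minimum distance between two triangles (0 if intersecting).

    Minimum over the 9 edge-edge pairs and 6 vertex-face pairs, with an
    explicit edge-through-face intersection test for the touching case.
    """
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    for i in range(3):
        if _segment_intersects_triangle(t1[i], t1[(i + 1) % 3], t2):
            return 0.0
        if _segment_intersects_triangle(t2[i], t2[(i + 1) % 3], t1):
            return 0.0
    best = np.inf
    for i in range(3):
        for j in range(3):
            d, _, _ = segment_segment_distance(
                t1[i], t1[(i + 1) % 3], t2[j], t2[(j + 1) % 3]
            )
            best = min(best, d)
    d1, _ = closest_point_on_triangles(t1, np.broadcast_to(t2, (3, 3, 3)))
    d2, _ = closest_point_on_triangles(t2, np.broadcast_to(t1, (3, 3, 3)))
    return float(min(best, d1.min(), d2.min()))


class MeshDistance:
    """Exact point-to-mesh distance with KD-tree candidate pruning."""

    def __init__(self, vertices: np.ndarray, triangles: np.ndarray):
        self.vertices = np.asarray(vertices, dtype=float)
        self.triangles = np.asarray(triangles, dtype=int)
        self.tri_pts = self.vertices[self.triangles]          # (m, 3, 3)
        self.centroids = self.tri_pts.mean(axis=1)
        self.radii = np.linalg.norm(
            self.tri_pts - self.centroids[:, None, :], axis=2
        ).max(axis=1)
        self.r_max = float(self.radii.max()) if len(self.radii) else 0.0
        self.tree = cKDTree(self.centroids)

    def query(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Distances, closest points and triangle ids for query points."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        n = points.shape[0]
        d_c, i_c = self.tree.query(points)
        upper = d_c + self.radii[i_c]          # guaranteed reachable distance
        dists = np.empty(n)
        closest = np.empty((n, 3))
        tri_id = np.empty(n, dtype=int)
        for k in range(n):
            cand = self.tree.query_ball_point(points[k], upper[k] + self.r_max + 1e-12)
            cand = np.asarray(cand, dtype=int)
            d, pts = closest_point_on_triangles(
                np.broadcast_to(points[k], (cand.size, 3)), self.tri_pts[cand]
            )
            j = int(np.argmin(d))
            dists[k] = d[j]
            closest[k] = pts[j]
            tri_id[k] = cand[j]
        return dists, closest, tri_id

    def query_brute(self, points: np.ndarray) -> np.ndarray:
        """No-acceleration scan over every triangle (oracle path)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.empty(points.shape[0])
        m = len(self.tri_pts)
        for k, p in enumerate(points):
            d, _ = closest_point_on_triangles(
                np.broadcast_to(p, (m, 3)), self.tri_pts
            )
            out[k] = d.min()
        return out
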