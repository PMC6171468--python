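"""Morphometric operations on labeled meshes: nearest-element granule
tallies, contact surface areas, organelle minimum distances and planar
cross sections."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import triangle_triangle_distance
from .mesh import GranuleSet, SurfaceMesh

__all__ = [
    "nearest_element_tally",
    "contact_area",
    "min_distance",
    "cross_section_area",
    "TallyResult",
]


@dataclass
class TallyResult:
    assignment: pd.DataFrame       # per-granule audit table
    per_class: pd.Series           # counts by mesh class
    per_object: pd.Series          # counts by object id


def nearest_element_tally(granules: GranuleSet, meshes: list[SurfaceMesh]) -> TallyResult:
    """Assign each granule to the mesh with minimum point-to-surface
    distance (exact point-triangle distance; ties break to the lowest
    object id)."""
    if not meshes:
        raise ValueError("at least one mesh is required")
    order = np.argsort([m.object_id for m in meshes], kind="stable")
    meshes_sorted = [meshes[i] for i in order]
    dists = np.stack([
        m.distance_query.query(granules.centers)[0] for m in meshes_sorted
    ])                                              # (n_mesh, n_gran)
    winner = np.argmin(dists, axis=0)               # first minimum = lowest id
    rows = []
    for g in range(len(granules)):
        m = meshes_sorted[winner[g]]
        rows.append({
            "granule": g,
            "object_id": m.object_id,
            "mesh_class": m.mesh_class,
            "distance": float(dists[winner[g], g]),
            "host_id": int(granules.host_ids[g]),
        })
    table = pd.DataFrame(rows)
    per_class = table["mesh_class"].value_counts()
    per_object = table["object_id"].value_counts()
    return TallyResult(table, per_class, per_object)


def contact_area(
    mesh_a: SurfaceMesh,
    mesh_b: SurfaceMesh,
    epsilon: float,
    brute: bool = False,
) -> float:
    """Sum of ``mesh_a`` triangle areas whose centroid lies within
    ``epsilon`` of ``mesh_b``'s surface (measured on A by convention;
    not symmetric)."""
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    centroids = mesh_a.tri_pts.mean(axis=1)
    if brute:
        d = mesh_b.distance_query.query_brute(centroids)
    else:
        d, _, _ = mesh_b.distance_query.query(centroids)
    return float(mesh_a.triangle_areas[d <= epsilon].sum())


def min_distance(mesh_a: SurfaceMesh, mesh_b: SurfaceMesh) -> tuple[float, np.ndarray, np.ndarray]:
    """Exact minimum surface-to-surface distance (0 if intersecting).

    A vertex-based KD-tree bound prunes triangle pairs, then exact
    triangle-triangle distances settle the remainder. Returns
    ``(distance, point_on_a, point_on_b)``.
    """
    if len(mesh_a.triangles) == 0 or len(mesh_b.triangles) == 0:
        raise ValueError("both meshes must be non-empty")
    qa = mesh_b.distance_query
    d_ab, p_ab, _ = qa.query(mesh_a.vertices)
    k = int(np.argmin(d_ab))
    upper = float(d_ab[k])
    best = (upper, mesh_a.vertices[k].copy(), p_ab[k].copy())

    ca, cb = mesh_a.tri_pts.mean(axis=1), mesh_b.tri_pts.mean(axis=1)
    ra = np.linalg.norm(mesh_a.tri_pts - ca[:, None, :], axis=2).max(axis=1)
    rb = np.linalg.norm(mesh_b.tri_pts - cb[:, None, :], axis=2).max(axis=1)
    from scipy.spatial import cKDTree

    tree_b = cKDTree(cb)
    reach = upper + ra + float(rb.max())
    pairs = tree_b.query_ball_point(ca, reach)
    for i, cand in enumerate(pairs):
        for j in cand:
            lower = np.linalg.norm(ca[i] - cb[j]) - ra[i] - rb[j]
            if lower >= best[0]:
                continue
            d = triangle_triangle_distance(mesh_a.tri_pts[i], mesh_b.tri_pts[j])
            if d < best[0]:
                # recover witness points via a fine check
                best = (d, *_witness_points(mesh_a.tri_pts[i], mesh_b.tri_pts[j]))
            if best[0] == 0.0:
                return best
    return best


def _witness_points(t1: np.ndarray, t2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    from .geometry import closest_point_on_triangles, segment_segment_distance

    best = (np.inf, t1[0], t2[0])
    for i in range(3):
        for j in range(3):
            d, c1, c2 = segment_segment_distance(
                t1[i], t1[(i + 1) % 3], t2[j], t2[(j + 1) % 3]
            )
            if d < best[0]:
                best = (d, c1, c2)
    d_v, p_v = closest_point_on_triangles(t1, np.broadcast_to(t2, (3, 3, 3)))
    for i in range(3):
        if d_v[i] < best[0]:
            best = (float(d_v[i]), t1[i], p_v[i])
    d_v, p_v = closest_point_on_triangles(t2, np.broadcast_to(t1, (3, 3, 3)))
    for i in range(3):
        if d_v[i] < best[0]:
            best = (float(d_v[i]), p_v[i], t2[i])
    return best[1], best[2]


def cross_section_area(
    mesh: SurfaceMesh,
    plane_point,
    plane_normal,
) -> tuple[float, float]:
    """Area and perimeter of the planar section of a watertight mesh.

    Triangle-plane intersection segments are chained into closed loops
    using mesh-edge identity (robust to coordinate noise); loop
    orientation induced by triangle winding makes hole areas subtract.
    Returns ``(0.0, 0.0)`` when the plane misses the mesh.
    """
    mesh.validate(require_watertight=True)
    p0 = np.asarray(plane_point, dtype=float)
    n = np.asarray(plane_normal, dtype=float)
    n = n / np.linalg.norm(n)

    d = (mesh.vertices - p0) @ n
    # nudge vertices exactly on the plane to one side (deterministic)
    d = np.where(np.abs(d) < 1e-12, 1e-12, d)

    tri = mesh.triangles
    td = d[tri]                                     # (m, 3)
    crossing = ~(np.all(td > 0, axis=1) | np.all(td < 0, axis=1))
    if not crossing.any():
        return 0.0, 0.0

    # in-plane orthonormal basis (u, v) with u x v = n
    a = np.array([1.0, 0.0, 0.0])
    if abs(n @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    u = np.cross(a, n)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)

    segments = []                                   # (edge_key_start, edge_key_end, p2d_start, p2d_end)
    for ti in np.flatnonzero(crossing):
        ids = tri[ti]
        dd = d[ids]
        # the lone vertex sits on the opposite side of the other two
        signs = dd > 0
        lone = int(np.flatnonzero(signs == (signs.sum() == 1))[0])
        others = [(lone + 1) % 3, (lone + 2) % 3]
        pts = []
        keys = []
        for o in others:
            i1, i2 = int(ids[lone]), int(ids[o])
            t = d[i1] / (d[i1] - d[i2])
            pt = mesh.vertices[i1] + t * (mesh.vertices[i2] - mesh.vertices[i1])
            pts.append(pt)
            keys.append((min(i1, i2), max(i1, i2)))
        # orient the segment so loops wind consistently: direction along
        # cross(tri_normal, plane_normal)
        tdir = np.cross(mesh.triangle_normals[ti], n)
        if (pts[1] - pts[0]) @ tdir < 0:
            pts.reverse()
            keys.reverse()
        p2d = [np.array([(p - p0) @ u, (p - p0) @ v]) for p in pts]
        segments.append((keys[0], keys[1], p2d[0], p2d[1]))

    # chain loops by edge identity (watertight: each key appears twice)
    start_of = {}
    for si, seg in enumerate(segments):
        start_of.setdefault(seg[0], []).append(si)
    used = np.zeros(len(segments), dtype=bool)
    area2 = 0.0
    perimeter = 0.0
    for si in range(len(segments)):
        if used[si]:
            continue
        loop = [si]
        used[si] = True
        cur = segments[si]
        while True:
            nxt_candidates = [k for k in start_of.get(cur[1], []) if not used[k]]
            if not nxt_candidates:
                break
            nxt = nxt_candidates[0]
            used[nxt] = True
            loop.append(nxt)
            cur = segments[nxt]
            if cur[1] == segments[si][0]:
                break
        pts2d = [segments[k][2] for k in loop]
        pts2d.append(segments[loop[-1]][3])
        P = np.asarray(pts2d)
        x, y = P[:, 0], P[:, 1]
        area2 += float(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))
        # close the polygon for the last edge of the shoelace
        area2 += float(x[-1] * y[0] - x[0] * y[-1])
        perimeter += float(np.sum(np.linalg.norm(np.diff(P, axis=0), axis=1)))
        perimeter += float(np.linalg.norm(P[0] - P[-1]))
    return abs(area2) / 2.0, perimeter
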