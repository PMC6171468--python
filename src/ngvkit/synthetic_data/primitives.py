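"""Watertight procedural mesh primitives (icosphere, capped tube, box,
metaball blob via marching cubes). All generators are deterministic pure
functions of their arguments."""

from __future__ import annotations

import numpy as np

from ..glam_morphometrics.mesh import SurfaceMesh

__all__ = ["icosphere", "capped_tube", "box_mesh", "metaball_blob", "flat_patch"]


def icosphere(radius: float = 1.0, center=(0.0, 0.0, 0.0), subdivisions: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Subdivided icosahedron; 20 * 4^subdivisions outward-wound faces."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array([
        (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
        (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
        (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
    ], dtype=float)
    verts /= np.linalg.norm(verts[0])
    faces = np.array([
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ], dtype=int)
    for _ in range(subdivisions):
        cache: dict[tuple[int, int], int] = {}
        vlist = list(verts)

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in cache:
                m = vlist[i] + vlist[j]
                m = m / np.linalg.norm(m)
                cache[key] = len(vlist)
                vlist.append(m)
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        verts = np.asarray(vlist)
        faces = np.asarray(new_faces, dtype=int)
    return verts * radius + np.asarray(center, dtype=float), faces


def capped_tube(
    p0,
    p1,
    radius: float,
    n_seg: int = 12,
    n_len: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed cylinder from ``p0`` to ``p1`` with triangle-fan caps."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    axis = p1 - p0
    length = np.linalg.norm(axis)
    if length <= 0:
        raise ValueError("tube endpoints coincide")
    w = axis / length
    a = np.array([1.0, 0.0, 0.0])
    if abs(w @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    u = np.cross(w, a)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)

    theta = 2 * np.pi * np.arange(n_seg) / n_seg
    circle = radius * (np.cos(theta)[:, None] * u + np.sin(theta)[:, None] * v)
    verts = []
    for i in range(n_len + 1):
        c = p0 + (i / n_len) * axis
        verts.extend(c + circle)
    i_bot = len(verts)
    verts.append(p0)
    i_top = len(verts)
    verts.append(p1)
    verts = np.asarray(verts)

    faces = []
    for i in range(n_len):
        for j in range(n_seg):
            j2 = (j + 1) % n_seg
            a0, b0 = i * n_seg + j, i * n_seg + j2
            a1, b1 = (i + 1) * n_seg + j, (i + 1) * n_seg + j2
            faces += [(a0, b0, a1), (b0, b1, a1)]
    for j in range(n_seg):
        j2 = (j + 1) % n_seg
        faces.append((i_bot, j2, j))                          # bottom cap
        faces.append((i_top, n_len * n_seg + j, n_len * n_seg + j2))  # top cap
    faces = np.asarray(faces, dtype=int)
    # orient outward
    mesh = SurfaceMesh(verts, faces)
    if mesh.signed_volume < 0:
        faces = faces[:, ::-1]
    return verts, faces


def box_mesh(lo, hi) -> tuple[np.ndarray, np.ndarray]:
    """Axis-aligned box with 12 outward-wound triangles."""
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    x0, y0, z0 = lo
    x1, y1, z1 = hi
    verts = np.array([
        (x0, y0, z0), (x1, y0, z0), (x1, y1, z0), (x0, y1, z0),
        (x0, y0, z1), (x1, y0, z1), (x1, y1, z1), (x0, y1, z1),
    ])
    faces = np.array([
        (0, 2, 1), (0, 3, 2),          # bottom (z0)
        (4, 5, 6), (4, 6, 7),          # top (z1)
        (0, 1, 5), (0, 5, 4),          # y0
        (1, 2, 6), (1, 6, 5),          # x1
        (2, 3, 7), (2, 7, 6),          # y1
        (3, 0, 4), (3, 4, 7),          # x0
    ], dtype=int)
    return verts, faces


def flat_patch(
    size: float,
    n: int,
    center=(0.0, 0.0, 0.0),
    normal_up: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Square grid patch in the z-plane, (n+1)^2 vertices, normals +z."""
    xs = np.linspace(-size / 2, size / 2, n + 1)
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    verts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
    verts += np.asarray(center, dtype=float)
    faces = []
    for i in range(n):
        for j in range(n):
            a = i * (n + 1) + j
            b = (i + 1) * (n + 1) + j
            faces += [(a, b, a + 1), (a + 1, b, b + 1)]
    faces = np.asarray(faces, dtype=int)
    if not normal_up:
        faces = faces[:, ::-1]
    return verts, faces


def metaball_blob(
    centers: np.ndarray,
    radii: np.ndarray,
    resolution: float,
    level: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Watertight union-of-spheres surface via marching cubes on the
    metaball field ``sum_i (r_i / d_i)^2``."""
    from skimage.measure import marching_cubes

    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    radii = np.asarray(radii, dtype=float)
    pad = radii.max() * 2.0
    lo = centers.min(axis=0) - pad
    hi = centers.max(axis=0) + pad
    shape = np.maximum(((hi - lo) / resolution).astype(int) + 1, 8)
    grids = [np.linspace(lo[k], hi[k], shape[k]) for k in range(3)]
    gx, gy, gz = np.meshgrid(*grids, indexing="ij")
    field = np.zeros(gx.shape)
    for c, r in zip(centers, radii):
        d2 = (gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2
        field += r ** 2 / np.maximum(d2, 1e-12)
    spacing = tuple((hi[k] - lo[k]) / (shape[k] - 1) for k in range(3))
    verts, faces, _, _ = marching_cubes(field, level=level, spacing=spacing)
    verts = verts + lo
    mesh = SurfaceMesh(verts, faces)
    if mesh.signed_volume < 0:
        faces = faces[:, ::-1].copy()
    return verts, np.asarray(faces, dtype=int)
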