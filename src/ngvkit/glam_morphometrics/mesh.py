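"""Labeled triangle surface meshes and glycogen granule sets.

Coordinates are um, 0-based, right-handed. A valid mesh has finite
vertices, in-range indices, no zero-area triangles and consistent
winding; watertightness (every edge shared by exactly two opposite-
orientation triangles) is tracked as a flag because only the
cross-section operation requires it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .geometry import MeshDistance

__all__ = ["MESH_CLASSES", "SurfaceMesh", "GranuleSet", "MeshValidationError"]

MESH_CLASSES = (
    "axon", "bouton", "spine", "dendrite", "astrocyte",
    "ER", "mitochondrion", "synapse", "vessel",
)


class MeshValidationError(ValueError):
    pass


@dataclass
class SurfaceMesh:
    vertices: np.ndarray          # (n, 3) um
    triangles: np.ndarray         # (m, 3) int
    mesh_class: str = "axon"
    object_id: int = 0
    name: str = ""

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError("vertices must be (n, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise MeshValidationError("triangles must be (m, 3)")

    # -- validation -----------------------------------------------------

    def validate(self, require_watertight: bool = False) -> None:
        if not np.all(np.isfinite(self.vertices)):
            bad = np.flatnonzero(~np.all(np.isfinite(self.vertices), axis=1))
            raise MeshValidationError(f"non-finite vertex coordinates at {bad[:5]}")
        if self.mesh_class not in MESH_CLASSES:
            raise MeshValidationError(
                f"unknown mesh class {self.mesh_class!r}; allowed: {MESH_CLASSES}"
            )
        n = len(self.vertices)
        if self.triangles.size and (self.triangles.min() < 0 or self.triangles.max() >= n):
            raise MeshValidationError("triangle vertex index out of range")
        areas = self.triangle_areas
        degenerate = np.flatnonzero(areas <= 0)
        if degenerate.size:
            raise MeshValidationError(
                f"zero-area triangle(s) at indices {degenerate[:10].tolist()}"
            )
        if not self.consistent_winding:
            raise MeshValidationError("inconsistent triangle winding")
        if require_watertight and not self.watertight:
            raise MeshValidationError(
                f"mesh {self.name or self.object_id} is not watertight"
            )

    # -- derived geometry ----------------------------------------------

    @cached_property
    def tri_pts(self) -> np.ndarray:
        return self.vertices[self.triangles]

    @cached_property
    def triangle_normals_raw(self) -> np.ndarray:
        t = self.tri_pts
        return 0.5 * np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])

    @cached_property
    def triangle_areas(self) -> np.ndarray:
        return np.linalg.norm(self.triangle_normals_raw, axis=1)

    @cached_property
    def area(self) -> float:
        return float(self.triangle_areas.sum())

    @cached_property
    def triangle_normals(self) -> np.ndarray:
        return self.triangle_normals_raw / self.triangle_areas[:, None]

    @cached_property
    def vertex_normals(self) -> np.ndarray:
        """Area-weighted vertex normals."""
        vn = np.zeros_like(self.vertices)
        np.add.at(vn, self.triangles[:, 0], self.triangle_normals_raw)
        np.add.at(vn, self.triangles[:, 1], self.triangle_normals_raw)
        np.add.at(vn, self.triangles[:, 2], self.triangle_normals_raw)
        norms = np.linalg.norm(vn, axis=1)
        norms[norms == 0] = 1.0
        return vn / norms[:, None]

    @cached_property
    def vertex_ring_areas(self) -> np.ndarray:
        """One third of each vertex's incident triangle area sum."""
        va = np.zeros(len(self.vertices))
        for k in range(3):
            np.add.at(va, self.triangles[:, k], self.triangle_areas / 3.0)
        return va

    @cached_property
    def _edge_counts(self):
        e = np.concatenate([
            self.triangles[:, [0, 1]],
            self.triangles[:, [1, 2]],
            self.triangles[:, [2, 0]],
        ])
        directed = {}
        for a, b in e:
            directed[(int(a), int(b))] = directed.get((int(a), int(b)), 0) + 1
        return directed

    @cached_property
    def consistent_winding(self) -> bool:
        # consistent orientation: no directed edge repeated
        return all(c == 1 for c in self._edge_counts.values())

    @cached_property
    def watertight(self) -> bool:
        if not self.consistent_winding:
            return False
        directed = self._edge_counts
        return all((b, a) in directed for (a, b) in directed)

    @cached_property
    def signed_volume(self) -> float:
        t = self.tri_pts
        return float(np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0)

    @cached_property
    def distance_query(self) -> MeshDistance:
        return MeshDistance(self.vertices, self.triangles)

    def flipped(self) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices.copy(), self.triangles[:, ::-1].copy(),
                           self.mesh_class, self.object_id, self.name)


@dataclass
class GranuleSet:
    """Glycogen granules: centers (um), radii (um), host object id."""

    centers: np.ndarray            # (n, 3)
    radii: np.ndarray              # (n,)
    host_ids: np.ndarray = field(default=None)  # (n,) int

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.radii = np.asarray(self.radii, dtype=float)
        if self.host_ids is None:
            self.host_ids = np.full(len(self.radii), -1, dtype=int)
        self.host_ids = np.asarray(self.host_ids, dtype=int)
        if self.centers.shape != (len(self.radii), 3):
            raise ValueError("centers must be (n, 3) matching radii length")
        if len(self.host_ids) != len(self.radii):
            raise ValueError("host_ids length mismatch")
        if not np.all(np.isfinite(self.centers)):
            raise ValueError("granule centers must be finite")
        if np.any(self.radii <= 0):
            bad = int(np.flatnonzero(self.radii <= 0)[0])
            raise ValueError(f"granule {bad} has non-positive radius")

    def __len__(self) -> int:
        return len(self.radii)
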