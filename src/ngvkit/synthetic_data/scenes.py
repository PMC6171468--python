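"""Procedural neuropil scene generation.

A :class:`SceneRecipe` plus a seed deterministically produces a list of
labeled watertight meshes: tubes for axons and dendrites, spheres for
boutons (placed en passant on axons) and spines (attached to
dendrites), and a blobby union-of-spheres astrocyte. Object ids are
assigned in generation order starting at 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..glam_morphometrics.mesh import SurfaceMesh
from .primitives import capped_tube, icosphere, metaball_blob

__all__ = ["SceneRecipe", "make_neuropil"]


@dataclass(frozen=True)
class SceneRecipe:
    n_axons: int = 2
    n_dendrites: int = 1
    n_boutons: int = 3
    n_spines: int = 2
    n_astro_blobs: int = 1
    box: tuple[float, float, float] = (12.0, 12.0, 12.0)
    mesh_resolution: int = 2        # icosphere subdivisions / tube density
    seed: int = 0

    def validate(self) -> None:
        counts = (self.n_axons, self.n_dendrites, self.n_boutons,
                  self.n_spines, self.n_astro_blobs)
        if any(c < 0 for c in counts):
            raise ValueError("recipe counts must be >= 0")
        if any(b <= 0 for b in self.box):
            raise ValueError("bounding box must be positive")
        if self.n_boutons > 0 and self.n_axons == 0:
            raise ValueError("boutons require at least one axon")
        if self.n_spines > 0 and self.n_dendrites == 0:
            raise ValueError("spines require at least one dendrite")
        # crude capacity check: each tube needs a lane of ~2 um
        if (self.n_axons + self.n_dendrites) * 2.0 > min(self.box[:2]) * 2:
            raise ValueError("bounding box too small for the requested counts")


def make_neuropil(recipe: SceneRecipe) -> tuple[list[SurfaceMesh], pd.DataFrame]:
    """Generate the scene; returns ``(meshes, manifest)``.

    The manifest has columns ``(name, mesh_class, object_id)`` and one
    row per mesh, in object-id order.
    """
    recipe.validate()
    rng = np.random.default_rng(recipe.seed)
    box = np.asarray(recipe.box, dtype=float)
    meshes: list[SurfaceMesh] = []
    axon_axes = []
    dend_axes = []
    next_id = 0

    def add(verts, faces, cls, name):
        nonlocal next_id
        m = SurfaceMesh(verts, faces, mesh_class=cls, object_id=next_id, name=name)
        m.validate()
        meshes.append(m)
        next_id += 1
        return m

    n_tubes = recipe.n_axons + recipe.n_dendrites
    for k in range(recipe.n_axons):
        # parallel-ish lanes through the box to avoid tangling
        frac = (k + 1) / (n_tubes + 1)
        y = frac * box[1]
        z = (0.25 + 0.5 * rng.random()) * box[2]
        r = 0.25 + 0.15 * rng.random()
        p0 = np.array([0.5, y, z])
        p1 = np.array([box[0] - 0.5, y, z])
        v, f = capped_tube(p0, p1, r, n_seg=10 + 2 * recipe.mesh_resolution,
                           n_len=max(3, int(box[0] / 3)))
        add(v, f, "axon", f"axon_{k}")
        axon_axes.append((p0, p1, r))
    for k in range(recipe.n_dendrites):
        frac = (recipe.n_axons + k + 1) / (n_tubes + 1)
        y = frac * box[1]
        z = (0.25 + 0.5 * rng.random()) * box[2]
        r = 0.5 + 0.2 * rng.random()
        p0 = np.array([0.5, y, z])
        p1 = np.array([box[0] - 0.5, y, z])
        v, f = capped_tube(p0, p1, r, n_seg=12 + 2 * recipe.mesh_resolution,
                           n_len=max(3, int(box[0] / 3)))
        add(v, f, "dendrite", f"dendrite_{k}")
        dend_axes.append((p0, p1, r))

    for k in range(recipe.n_boutons):
        p0, p1, r = axon_axes[int(rng.integers(len(axon_axes)))]
        t = 0.15 + 0.7 * rng.random()
        center = p0 + t * (p1 - p0)
        radius = r + 0.25 + 0.2 * rng.random()     # swells past the axon
        v, f = icosphere(radius, center, subdivisions=recipe.mesh_resolution)
        add(v, f, "bouton", f"bouton_{k}")
    for k in range(recipe.n_spines):
        p0, p1, r = dend_axes[int(rng.integers(len(dend_axes)))]
        t = 0.15 + 0.7 * rng.random()
        theta = 2 * np.pi * rng.random()
        radius = 0.2 + 0.1 * rng.random()
        offset = np.array([0.0, np.cos(theta), np.sin(theta)]) * (r + radius * 0.8)
        center = p0 + t * (p1 - p0) + offset
        v, f = icosphere(radius, center, subdivisions=recipe.mesh_resolution)
        add(v, f, "spine", f"spine_{k}")

    for k in range(recipe.n_astro_blobs):
        n_balls = 3 + int(rng.integers(3))
        c0 = box * (0.3 + 0.4 * rng.random(3))
        centers = c0 + rng.normal(scale=1.2, size=(n_balls, 3))
        radii = 0.8 + 0.5 * rng.random(n_balls)
        v, f = metaball_blob(centers, radii, resolution=0.35)
        add(v, f, "astrocyte", f"astrocyte_{k}")

    manifest = pd.DataFrame({
        "name": [m.name for m in meshes],
        "mesh_class": [m.mesh_class for m in meshes],
        "object_id": [m.object_id for m in meshes],
    })
    return meshes, manifest
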