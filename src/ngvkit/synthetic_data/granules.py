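"""Planted glycogen granule distributions with known nearest-class truth."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..glam_morphometrics.mesh import GranuleSet, SurfaceMesh

__all__ = ["scatter_granules"]


def scatter_granules(
    meshes: list[SurfaceMesh],
    n: int,
    p_bouton: float,
    seed: int,
    radius_range: tuple[float, float] = (0.01, 0.04),
    offset_range: tuple[float, float] = (0.02, 0.25),
    margin: float = 1e-6,
    max_tries: int = 400,
) -> tuple[GranuleSet, pd.DataFrame]:
    """Scatter ``n`` granules, each strictly nearest a planted target class.

    With probability ``p_bouton`` the target class is ``bouton``,
    otherwise a uniformly chosen other class present in the scene.
    Placement is rejection-sampled: a random surface point of a random
    target-class mesh, offset outward, accepted only if its distance to
    every other mesh exceeds the distance to the target by ``margin``.

    Returns the granule set and a truth table with columns
    ``(granule, planted_class, planted_object_id)``.
    """
    if not 0.0 <= p_bouton <= 1.0:
        raise ValueError("p_bouton must be in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    classes = sorted({m.mesh_class for m in meshes})
    if p_bouton > 0 and "bouton" not in classes:
        raise ValueError("scene has no bouton meshes")
    other_classes = [c for c in classes if c != "bouton"]
    if p_bouton < 1 and not other_classes:
        raise ValueError("scene has only boutons; cannot plant other classes")

    rng = np.random.default_rng(seed)
    by_class: dict[str, list[SurfaceMesh]] = {}
    for m in meshes:
        by_class.setdefault(m.mesh_class, []).append(m)

    centers = np.empty((n, 3))
    radii = rng.uniform(*radius_range, size=n)
    truth_rows = []
    astro = by_class.get("astrocyte", [])
    host_default = astro[0].object_id if astro else -1

    for g in range(n):
        target_class = "bouton" if rng.random() < p_bouton else (
            other_classes[int(rng.integers(len(other_classes)))]
        )
        target_meshes = by_class[target_class]
        placed = False
        for _ in range(max_tries):
            tm = target_meshes[int(rng.integers(len(target_meshes)))]
            # area-weighted random surface point
            w = tm.triangle_areas / tm.area
            ti = int(rng.choice(len(w), p=w))
            r1, r2 = rng.random(), rng.random()
            if r1 + r2 > 1:
                r1, r2 = 1 - r1, 1 - r2
            a, b, c = tm.tri_pts[ti]
            pt = a + r1 * (b - a) + r2 * (c - a)
            pt = pt + tm.triangle_normals[ti] * rng.uniform(*offset_range)
            d_target = float(tm.distance_query.query(pt[None, :])[0][0])
            ok = True
            for other in meshes:
                if other is tm:
                    continue
                d_o = float(other.distance_query.query(pt[None, :])[0][0])
                if d_o <= d_target + margin:
                    ok = False
                    break
            if ok:
                centers[g] = pt
                truth_rows.append({
                    "granule": g,
                    "planted_class": target_class,
                    "planted_object_id": tm.object_id,
                })
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"rejection budget exhausted placing granule {g} "
                f"(target class {target_class!r}, {max_tries} tries)"
            )
    granules = GranuleSet(centers, radii,
                          np.full(n, host_default, dtype=int))
    return granules, pd.DataFrame(truth_rows)
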