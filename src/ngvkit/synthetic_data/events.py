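"""Poisson synaptic-event streams on a voxel grid."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..voxel_sim.grid import EventStream, VoxelGrid

__all__ = ["make_event_stream"]


def make_event_stream(
    grid: VoxelGrid,
    rate_field: np.ndarray,
    q: float,
    t_span: tuple[float, float],
    seed: int,
) -> EventStream:
    """Homogeneous Poisson events per voxel, uniform positions in-cell.

    ``rate_field`` is (nx, ny, nz) in Hz per voxel; every event carries
    quanta ``q``. The combined stream is sorted by time and is a
    deterministic function of the seed.
    """
    rate_field = np.asarray(rate_field, dtype=float)
    if rate_field.shape != tuple(grid.dims):
        raise ValueError(
            f"rate_field shape {rate_field.shape} != grid dims {grid.dims}"
        )
    if np.any(rate_field < 0):
        raise ValueError("rates must be >= 0")
    if q <= 0:
        raise ValueError("q must be > 0")
    rng = np.random.default_rng(seed)
    t0, t1 = t_span
    dur = t1 - t0
    rows = []
    origin = np.asarray(grid.origin)
    for idx in np.ndindex(rate_field.shape):
        lam = rate_field[idx] * dur
        if lam == 0:
            continue
        k = rng.poisson(lam)
        if k == 0:
            continue
        t = np.sort(rng.uniform(t0, t1, size=k))
        lo = origin + grid.h * np.asarray(idx)
        pos = lo + grid.h * rng.random((k, 3))
        rows.append(pd.DataFrame({
            "t": t, "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2],
            "q": np.full(k, q),
        }))
    if rows:
        table = pd.concat(rows, ignore_index=True)
        table = table.sort_values("t", kind="stable").reset_index(drop=True)
    else:
        table = pd.DataFrame({c: pd.Series(dtype=float) for c in EventStream.COLUMNS})
    return EventStream(table)
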