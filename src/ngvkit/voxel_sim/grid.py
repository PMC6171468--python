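"""Cubic voxel grid and synaptic-event binning.

Voxel cells are half-open: a point belongs to voxel
``floor((pos - origin)/h)`` per axis, with the cell spanning
``[origin + i*h, origin + (i+1)*h)``. Events exactly on the upper world
boundary are outside the grid and rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["VoxelGrid", "EventStream", "assign_events"]


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned grid of cubic voxels (edge ``h`` um, default 50)."""

    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    h: float = 50.0
    dims: tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self):
        if self.h <= 0:
            raise ValueError("voxel edge h must be > 0")
        if any(int(d) < 1 for d in self.dims):
            raise ValueError("grid dims must be >= 1 on every axis")

    @property
    def extent(self) -> np.ndarray:
        """World-space upper corner, ``origin + h * dims``."""
        return np.asarray(self.origin) + self.h * np.asarray(self.dims)

    @property
    def n_voxels(self) -> int:
        d = self.dims
        return int(d[0]) * int(d[1]) * int(d[2])

    @property
    def voxel_volume(self) -> float:
        return self.h ** 3

    def voxel_index(self, pos: np.ndarray) -> np.ndarray:
        """Half-open floor indexing; no bounds check."""
        pos = np.atleast_2d(np.asarray(pos, dtype=float))
        return np.floor((pos - np.asarray(self.origin)) / self.h).astype(int)

    def contains(self, pos: np.ndarray) -> np.ndarray:
        idx = self.voxel_index(pos)
        return np.all((idx >= 0) & (idx < np.asarray(self.dims)), axis=1)


@dataclass
class EventStream:
    """Synaptic release events: ``(t [s], x, y, z [um], q [mM um^3])``."""

    table: pd.DataFrame

    COLUMNS = ("t", "x", "y", "z", "q")

    def __post_init__(self):
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"event stream missing column(s): {sorted(missing)}")
        t = self.table["t"].to_numpy()
        if t.size > 1 and np.any(np.diff(t) < 0):
            raise ValueError("event times must be non-decreasing")
        q = self.table["q"].to_numpy()
        if np.any(q <= 0):
            row = int(np.flatnonzero(q <= 0)[0])
            raise ValueError(f"event row {row} has non-positive quanta q={q[row]}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def positions(self) -> np.ndarray:
        return self.table[["x", "y", "z"]].to_numpy(dtype=float)

    @property
    def times(self) -> np.ndarray:
        return self.table["t"].to_numpy(dtype=float)

    @property
    def quanta(self) -> np.ndarray:
        return self.table["q"].to_numpy(dtype=float)


def assign_events(
    events: EventStream,
    grid: VoxelGrid,
    dt_bin: float,
    t_span: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Bin events into per-voxel release-rate time series.

    Each event deposits ``q / (dt_bin * h^3)`` mM/s into the bin holding
    its time, in the voxel holding its position, so the total quanta
    ``sum(rate) * dt_bin * h^3`` is conserved exactly.

    Returns ``(rates, bin_edges)`` with ``rates`` of shape
    ``(n_bins, nx, ny, nz)``.
    """
    if dt_bin <= 0:
        raise ValueError("dt_bin must be > 0")
    t = events.times
    if t_span is None:
        t_span = (0.0, float(t.max()) + dt_bin) if t.size else (0.0, dt_bin)
    t0, t1 = t_span
    n_bins = int(np.ceil((t1 - t0) / dt_bin - 1e-12))
    edges = t0 + dt_bin * np.arange(n_bins + 1)

    rates = np.zeros((n_bins,) + tuple(int(d) for d in grid.dims))
    if t.size == 0:
        return rates, edges

    inside = grid.contains(events.positions)
    if not np.all(inside):
        bad = np.flatnonzero(~inside)
        rows = ", ".join(str(int(b)) for b in bad[:10])
        raise ValueError(
            f"{bad.size} event(s) outside the grid extent (rows: {rows})"
        )
    in_time = (t >= t0 - 1e-12) & (t < t1 - 1e-12)
    if not np.all(in_time):
        bad = np.flatnonzero(~in_time)
        raise ValueError(
            f"event row(s) outside the time span: {[int(b) for b in bad[:10]]}"
        )
    vox = grid.voxel_index(events.positions)
    tbin = np.clip(((t - t0) / dt_bin).astype(int), 0, n_bins - 1)
    w = events.quanta / (dt_bin * grid.voxel_volume)
    np.add.at(rates, (tbin, vox[:, 0], vox[:, 1], vox[:, 2]), w)
    return rates, edges
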