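"""Voxel grid: binning partition/conservation, per-voxel independence,
snapshot counting, normalization and NRRD round trips."""

import numpy as np
import pandas as pd
import pytest

from ngvkit.metabolic_core import RESTING_DRIVE, integrate_unit
from ngvkit.synthetic_data import make_event_stream
from ngvkit.voxel_sim import (
    EventStream,
    VoxelGrid,
    assign_events,
    denormalize_field,
    drives_from_rates,
    export_snapshots,
    normalize_field,
    read_nrrd,
    simulate_grid,
    write_nrrd,
)


def _events(rows):
    return EventStream(pd.DataFrame(rows, columns=list(EventStream.COLUMNS)))


class TestGridIndexing:
    def test_floor_rule(self):
        grid = VoxelGrid(h=50.0, dims=(3, 3, 3))
        idx = grid.voxel_index([[75.0, 10.0, 120.0]])
        np.testing.assert_array_equal(idx[0], [1, 0, 2])

    def test_half_open_boundary(self):
        grid = VoxelGrid(h=50.0, dims=(3, 3, 3))
        idx = grid.voxel_index([[100.0, 0.0, 0.0]])
        assert idx[0, 0] == 2

    def test_upper_world_boundary_outside(self):
        grid = VoxelGrid(h=50.0, dims=(2, 2, 2))
        assert not grid.contains([[100.0, 50.0, 50.0]])[0]

    def test_invalid_grid(self):
        with pytest.raises(ValueError):
            VoxelGrid(h=0.0)
        with pytest.raises(ValueError):
            VoxelGrid(dims=(0, 1, 1))


class TestAssignEvents:
    def test_quanta_conserved(self):
        grid = VoxelGrid(h=50.0, dims=(2, 2, 1))
        ev = _events([(0.005, 10, 10, 10, 100.0),
                      (0.012, 60, 10, 10, 250.0),
                      (0.013, 60, 60, 10, 50.0)])
        rates, edges = assign_events(ev, grid, 0.01, (0.0, 0.02))
        total = rates.sum() * 0.01 * grid.voxel_volume
        assert total == pytest.approx(400.0, rel=1e-12)

    def test_partition_single_voxel_each(self):
        grid = VoxelGrid(h=50.0, dims=(2, 2, 2))
        ev = make_event_stream(grid, np.full((2, 2, 2), 30.0), 10.0, (0, 0.5), 11)
        rates, _ = assign_events(ev, grid, 0.01, (0.0, 0.5))
        count_rate = (rates > 0).sum()
        assert rates.sum() * 0.01 * grid.voxel_volume == pytest.approx(
            ev.quanta.sum(), rel=1e-9)

    def test_outside_event_rejected_with_row(self):
        grid = VoxelGrid(h=50.0, dims=(1, 1, 1))
        ev = _events([(0.0, 10, 10, 10, 1.0), (0.01, 60.0, 10, 10, 1.0)])
        with pytest.raises(ValueError, match="rows: 1"):
            assign_events(ev, grid, 0.01, (0.0, 0.02))

    def test_unsorted_events_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            _events([(0.5, 1, 1, 1, 1.0), (0.1, 1, 1, 1, 1.0)])

    def test_nonpositive_quanta_rejected(self):
        with pytest.raises(ValueError, match="quanta"):
            _events([(0.1, 1, 1, 1, -1.0)])


class TestSimulateGrid:
    def test_zero_drive_equals_rest(self, params, rest):
        grid = VoxelGrid(h=50.0, dims=(2, 1, 1))
        rates = np.zeros((1,) + tuple(grid.dims))
        drives = drives_from_rates(rates, np.array([0.0, 0.2]))
        fields = simulate_grid(grid, drives, params, (0.0, 0.2), 0.05,
                               species=("ATP_n", "LAC_e"), state0=rest)
        for sp in ("ATP_n", "LAC_e"):
            ref = getattr(rest, sp)
            np.testing.assert_allclose(fields[sp].values, ref, rtol=1e-6)

    def test_single_voxel_drive_localized(self, params, rest):
        grid = VoxelGrid(h=50.0, dims=(2, 1, 1))
        rates = np.zeros((2, 2, 1, 1))
        rates[:, 1, 0, 0] = 0.4          # mM/s release in voxel (1,0,0) only
        drives = drives_from_rates(rates, np.array([0.0, 0.25, 0.5]))
        fields = simulate_grid(grid, drives, params, (0.0, 0.5), 0.05,
                               species=("GLU_e",), state0=rest)
        glu = fields["GLU_e"].values
        assert np.allclose(glu[:, 0, 0, 0], rest.GLU_e, atol=1e-9)
        assert glu[:, 1, 0, 0].max() > 1e-3

    def test_grid_matches_independent_unit_runs_bitwise(self, params, rest):
        grid = VoxelGrid(h=50.0, dims=(2, 2, 2))
        rng = np.random.default_rng(5)
        rates = rng.uniform(0.0, 0.5, size=(2, 2, 2, 2))
        edges = np.array([0.0, 0.1, 0.2])
        drives = drives_from_rates(rates, edges)
        fields = simulate_grid(grid, drives, params, (0.0, 0.2), 0.02,
                               species=("ATP_n", "GLU_e"), state0=rest)
        for idx in np.ndindex((2, 2, 2)):
            traj = integrate_unit(rest, params, drives[idx], (0.0, 0.2), 0.02)
            for sp in ("ATP_n", "GLU_e"):
                np.testing.assert_array_equal(
                    fields[sp].values[(slice(None),) + idx], traj.series(sp)
                )

    def test_snapshot_count_formula(self, params, rest):
        grid = VoxelGrid(dims=(1, 1, 1))
        drives = drives_from_rates(np.zeros((1, 1, 1, 1)), np.array([0.0, 1.0]))
        for t_end, dt_snap, expect in ((1.0, 0.010, 101), (0.5, 0.25, 3),
                                       (0.3, 0.1, 4)):
            fields = simulate_grid(grid, drives, params, (0.0, t_end), dt_snap,
                                   species=("ATP_n",), state0=rest)
            assert fields["ATP_n"].values.shape[0] == expect

    def test_missing_drive_rejected(self, params, rest):
        grid = VoxelGrid(dims=(2, 1, 1))
        with pytest.raises(ValueError, match="missing drive"):
            simulate_grid(grid, {}, params, (0.0, 0.1), 0.05, state0=rest)


class TestNormalize:
    @pytest.fixture()
    def series(self, params, rest):
        grid = VoxelGrid(dims=(1, 1, 1))
        drives = drives_from_rates(np.full((1, 1, 1, 1), 0.3), np.array([0.0, 0.5]))
        fields = simulate_grid(grid, drives, params, (0.0, 0.5), 0.1,
                               species=("ATP_n",), state0=rest)
        return fields["ATP_n"]

    def test_resting_series_all_ones(self, params, rest):
        grid = VoxelGrid(dims=(1, 1, 1))
        drives = drives_from_rates(np.zeros((1, 1, 1, 1)), np.array([0.0, 0.2]))
        fields = simulate_grid(grid, drives, params, (0.0, 0.2), 0.1,
                               species=("ATP_n",), state0=rest)
        norm = normalize_field(fields["ATP_n"])
        np.testing.assert_allclose(norm.values, 1.0, rtol=1e-6)

    def test_round_trip(self, series):
        norm = normalize_field(series)
        back = denormalize_field(norm)
        np.testing.assert_allclose(back.values, series.values, rtol=1e-14)

    def test_minmax_range(self, series):
        norm = normalize_field(series, mode="minmax")
        assert norm.values.min() == 0.0
        assert norm.values.max() == 1.0

    def test_zero_reference_rejected(self, series):
        series.meta["resting_value"] = 0.0
        with pytest.raises(ValueError, match="resting value"):
            normalize_field(series)


class TestNrrd:
    def test_header_sizes(self, tmp_path, params, rest):
        grid = VoxelGrid(dims=(4, 4, 4))
        data = np.arange(64, dtype=float).reshape(4, 4, 4)
        p = tmp_path / "vol.nrrd"
        write_nrrd(p, data, spacing=50.0)
        back, hdr = read_nrrd(p)
        assert hdr["sizes"] == "4 4 4"
        np.testing.assert_array_equal(back, data)

    @pytest.mark.parametrize("encoding", ["raw", "text"])
    def test_round_trip_exact(self, tmp_path, encoding):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(3, 5, 2))
        p = tmp_path / "v.nrrd"
        write_nrrd(p, data, spacing=1.5, origin=(1, 2, 3), encoding=encoding)
        back, _ = read_nrrd(p)
        np.testing.assert_array_equal(back, data)

    def test_export_per_snapshot_count(self, tmp_path, params, rest):
        grid = VoxelGrid(dims=(1, 1, 1))
        drives = drives_from_rates(np.zeros((1, 1, 1, 1)), np.array([0.0, 1.0]))
        fields = simulate_grid(grid, drives, params, (0.0, 1.0), 0.010,
                               species=("ATP_n",), state0=rest)
        paths = export_snapshots(fields["ATP_n"], tmp_path / "out")
        nrrds = [p for p in paths if str(p).endswith(".nrrd")]
        assert len(nrrds) == 101
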