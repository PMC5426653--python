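"""Occupancy grids, pore connectivity, and the pore-radius profile."""

import numpy as np
import pytest
from scipy.stats import chisquare

from poreflux.accessibility import (
    OccupancyGrid,
    accessible_mask,
    accumulate_occupancy,
    pore_exists,
    pore_radius_profile,
    write_dx,
)
from poreflux.model import AtomRecord, AtomSelection, AxialRegion, Frame, Role, Topology, Trajectory
from poreflux.select import select
from poreflux.synthetic import (
    dark_like_spec,
    detector_benchmark_spec,
    generate_pore_trajectory,
    meta2_like_spec,
)

from conftest import trajectory_from_z


class TestAccumulateOccupancy:
    def test_static_water_fills_one_voxel(self):
        traj = trajectory_from_z(np.full((100, 1), 3.3))
        grid = accumulate_occupancy(traj, AtomSelection([0]), spacing=1.0,
                                    bounds=((-5, -5, 0), (5, 5, 10)))
        assert grid.counts.max() == 100
        assert (grid.counts > 0).sum() == 1
        assert grid.overflow == 0

    def test_conservation_with_overflow(self):
        rng = np.random.default_rng(0)
        traj = trajectory_from_z(rng.uniform(-30, 30, size=(50, 8)))
        grid = accumulate_occupancy(traj, AtomSelection(range(8)), spacing=1.0,
                                    bounds=((-5, -5, -10), (5, 5, 10)))
        assert grid.counts.sum() + grid.overflow == 50 * 8
        assert grid.overflow > 0  # waters outside the bounds are tallied

    def test_uniform_sampling_is_multinomial(self):
        rng = np.random.default_rng(1)
        n = 10_000
        coords = rng.uniform(0, 4, size=(n, 1, 3))
        topo = trajectory_from_z(np.zeros((1, 1))).topology
        frames = [Frame(coords[i], np.array([40.0, 40.0, 60.0]), 0.01 * i)
                  for i in range(n)]
        traj = Trajectory(topo, frames)
        grid = accumulate_occupancy(traj, AtomSelection([0]), spacing=1.0,
                                    bounds=((0, 0, 0), (4, 4, 4)))
        _, p = chisquare(grid.counts.ravel())
        assert p > 0.001

    def test_zero_volume_bounds_rejected(self):
        traj = trajectory_from_z(np.zeros((2, 1)))
        with pytest.raises(ValueError):
            accumulate_occupancy(traj, AtomSelection([0]), bounds=((0, 0, 0), (0, 5, 5)))


class TestAccessibleMask:
    def _grid(self):
        counts = np.zeros((3, 3, 3), dtype=np.int64)
        counts[1, 1, 1] = 7
        counts[0, 0, 0] = 2
        return OccupancyGrid(np.zeros(3), 1.0, counts, n_frames=7, n_tracked=2)

    def test_threshold_semantics(self):
        g = self._grid()
        assert accessible_mask(g, 1).sum() == 2
        assert accessible_mask(g, 3).sum() == 1
        assert accessible_mask(g, 8).sum() == 0

    def test_monotone_in_threshold(self):
        g = self._grid()
        for lo, hi in [(1, 2), (2, 5), (5, 9)]:
            assert not (accessible_mask(g, hi) & ~accessible_mask(g, lo)).any()


def _grid_from_mask(mask):
    return OccupancyGrid(np.array([0.0, 0.0, -10.0]), 1.0,
                         mask.astype(np.int64), n_frames=1, n_tracked=1)


class TestPoreExists:
    BULK = AxialRegion("bulk", -10.0, -6.0)
    POCKET = AxialRegion("pocket", 6.0, 10.0)

    def test_spanning_cylinder_connects(self):
        mask = np.zeros((9, 9, 20), dtype=bool)
        mask[4, 4, :] = True
        ok, comp = pore_exists(_grid_from_mask(mask), self.BULK, self.POCKET)
        assert ok
        assert comp.sum() == 20

    def test_split_blobs_do_not_connect(self):
        mask = np.zeros((9, 9, 20), dtype=bool)
        mask[4, 4, :8] = True
        mask[4, 4, 12:] = True
        ok, comp = pore_exists(_grid_from_mask(mask), self.BULK, self.POCKET)
        assert not ok
        assert not comp.any()

    def test_diagonal_touch_needs_corner_connectivity(self):
        mask = np.zeros((9, 9, 20), dtype=bool)
        mask[4, 4, :10] = True
        mask[5, 5, 10:] = True  # corner contact at the midplane
        grid = _grid_from_mask(mask)
        ok_face, _ = pore_exists(grid, self.BULK, self.POCKET, connectivity="face")
        ok_corner, _ = pore_exists(grid, self.BULK, self.POCKET,
                                   connectivity="face+edge+corner")
        assert not ok_face
        assert ok_corner

    def test_superset_of_connected_mask_stays_connected(self):
        rng = np.random.default_rng(3)
        mask = np.zeros((9, 9, 20), dtype=bool)
        mask[4, 4, :] = True
        extra = rng.uniform(size=mask.shape) < 0.2
        ok, _ = pore_exists(_grid_from_mask(mask | extra), self.BULK, self.POCKET)
        assert ok

    def test_region_outside_grid_errors(self):
        mask = np.ones((4, 4, 4), dtype=bool)
        with pytest.raises(ValueError):
            pore_exists(_grid_from_mask(mask), AxialRegion("bulk", 50, 60), self.POCKET)

    def test_open_and_blocked_fixtures(self):
        specs = {
            "open": detector_benchmark_spec(seed=31, n_steps=30000),
            "blocked": dark_like_spec(seed=31, n_steps=30000, save_stride=1,
                                      include_walls=False, dt=0.5,
                                      reservoir_fraction=0.6),
        }
        results = {}
        for name, spec in specs.items():
            traj, _ = generate_pore_trajectory(spec)
            grid = accumulate_occupancy(
                traj, AtomSelection(range(spec.n_waters)), spacing=1.0,
                bounds=((-22, -22, spec.reservoir_bottom - 1),
                        (22, 22, spec.pocket_top + 1)))
            bulk = AxialRegion("bulk", spec.reservoir_bottom - 0.5, spec.z_lo)
            pocket = AxialRegion("pocket", spec.z_hi, spec.pocket_top + 0.5)
            results[name], _ = pore_exists(grid, bulk, pocket)
        assert results == {"open": True, "blocked": False}


def _ring_trajectory(ring_radius=6.5, vdw=1.5, n_atoms=24, n_frames=3):
    records = [
        AtomRecord(i, "WA", "X", "WAL", 1 + i // 100, "X", vdw, Role.WALL)
        for i in range(n_atoms)
    ]
    ang = 2 * np.pi * np.arange(n_atoms) / n_atoms
    coords = np.column_stack(
        [ring_radius * np.cos(ang), ring_radius * np.sin(ang), np.zeros(n_atoms)])
    topo = Topology(records)
    frames = [Frame(coords, np.array([40.0, 40.0, 40.0]), 0.01 * i)
              for i in range(n_frames)]
    return Trajectory(topo, frames)


class TestPoreRadiusProfile:
    def test_analytic_ring(self):
        traj = _ring_trajectory()
        prof = pore_radius_profile(traj, AtomSelection(range(24)),
                                   axis_xy=(0.0, 0.0), z_range=(-0.25, 0.25),
                                   bin_width=0.5)
        assert len(prof.z_centers) == 1
        assert abs(prof.mean_radius[0] - 5.0) < 1e-12
        assert prof.sd_radius[0] == 0.0

    def test_hourglass_wall_recovery(self):
        spec = meta2_like_spec(seed=2, n_steps=100, save_stride=50, n_waters=5)
        traj, _ = generate_pore_trajectory(spec)
        obstacles = select(traj.topology, "wall")
        # bins of 0.1 Å placed so every control point is a bin centre
        prof = pore_radius_profile(traj, obstacles, axis_xy=(0.0, 0.0),
                                   z_range=(-10.05, 5.05), bin_width=0.1)
        for zc, r in spec.radius_profile:
            i = int(np.argmin(np.abs(prof.z_centers - zc)))
            assert abs(prof.z_centers[i] - zc) < 1e-6
            assert abs(prof.mean_radius[i] - r) < 0.3
        assert np.all(prof.sd_radius < 1e-9)  # static walls
        # narrowest point of the open profile is the constriction radius
        valid = ~prof.capped
        assert abs(prof.mean_radius[valid].min() - 1.5) < 0.3

    def test_blocked_profile_reaches_zero(self):
        spec = dark_like_spec(seed=2, n_steps=100, save_stride=50, n_waters=5)
        traj, _ = generate_pore_trajectory(spec)
        obstacles = select(traj.topology, "wall")
        prof = pore_radius_profile(traj, obstacles, axis_xy=(0.0, 0.0),
                                   z_range=(-10.05, 5.05), bin_width=0.1)
        i = int(np.argmin(np.abs(prof.z_centers - spec.blocked_z)))
        assert prof.mean_radius[i] < 0.15

    def test_empty_slab_is_capped_and_flagged(self):
        traj = _ring_trajectory()
        prof = pore_radius_profile(traj, AtomSelection(range(24)),
                                   axis_xy=(0.0, 0.0), z_range=(-10, 10),
                                   bin_width=0.5, cap_radius=12.0)
        assert prof.capped.any()
        far = np.abs(prof.z_centers) > 2
        assert np.all(prof.mean_radius[far] == 12.0)


def test_dx_export_round_numbers(tmp_path):
    counts = np.arange(27, dtype=np.int64).reshape(3, 3, 3)
    grid = OccupancyGrid(np.zeros(3), 1.0, counts, n_frames=27, n_tracked=1)
    path = tmp_path / "grid.dx"
    write_dx(path, grid)
    text = path.read_text()
    assert "counts 3 3 3" in text
    assert "items 27" in text
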