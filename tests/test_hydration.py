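"""Internal-water census, hydration sites, hydrogen-bond geometry."""

import numpy as np
import pytest

from poreflux.accessibility import accumulate_occupancy
from poreflux.hydration import (
    detect_hbonds,
    find_hydration_sites,
    internal_water_census,
    site_hbond_profile,
    HydrationSite,
)
from poreflux.model import AtomRecord, AtomSelection, Frame, Role, Topology, Trajectory
from poreflux.synthetic import (
    generate_pore_trajectory,
    meta2_like_spec,
    two_trap_spec,
)

from conftest import make_water_topology, trajectory_from_z


def _census_system(water_xyz, ref_xyz, box=(50.0, 50.0, 50.0)):
    """Waters plus single-atom reference residues (GLY CA)."""
    n_w, n_r = len(water_xyz), len(ref_xyz)
    records = [
        AtomRecord(i, "O", "O", "HOH", i + 1, "W", 1.52, Role.WATER_OXYGEN)
        for i in range(n_w)
    ] + [
        AtomRecord(n_w + j, "CA", "C", "GLY", j + 1, "A", 1.7, Role.PROTEIN)
        for j in range(n_r)
    ]
    topo = Topology(records)
    coords = np.vstack([water_xyz, ref_xyz])
    traj = Trajectory(topo, [Frame(coords, np.asarray(box, dtype=float), 0.0)])
    tokens = [f"G{j + 1}" for j in range(n_r)]
    return traj, tokens


from conftest import brute_force_census as _brute_force_census


class TestCensus:
    def test_inclusive_cutoff(self):
        waters = np.array([[3.0, 0, 0], [6.9, 0, 0], [7.1, 0, 0]]) + 25.0
        ref = np.array([[25.0, 25.0, 25.0]])
        traj, tokens = _census_system(waters, ref)
        series = internal_water_census(traj, tokens, cutoff=7.0)
        assert series.counts[0] == 2
        exactly = np.array([[32.0, 25.0, 25.0]])  # exactly 7.000 away
        traj2, tokens2 = _census_system(exactly, ref)
        assert internal_water_census(traj2, tokens2, cutoff=7.0).counts[0] == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_exhaustive_minimum_image_oracle(self, seed):
        rng = np.random.default_rng(seed)
        box = (22.0, 18.0, 25.0)
        # spread beyond the box so minimum-image wrapping matters
        waters = rng.uniform(-10, 30, size=(100, 3))
        ref = rng.uniform(0, 20, size=(10, 3))
        traj, tokens = _census_system(waters, ref, box=box)
        series = internal_water_census(traj, tokens, cutoff=7.0)
        assert series.counts[0] == _brute_force_census(waters, ref, box, 7.0)

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(3)
        waters = rng.uniform(0, 30, size=(50, 3))
        ref = rng.uniform(10, 20, size=(5, 3))
        traj, tokens = _census_system(waters, ref, box=(30, 30, 30))
        counts = [
            internal_water_census(traj, tokens, cutoff=c).counts[0]
            for c in (2.0, 4.0, 7.0, 12.0)
        ]
        assert counts == sorted(counts)

    def test_unknown_residue_token_errors(self):
        traj, _ = _census_system(np.zeros((1, 3)) + 10, np.ones((1, 3)))
        with pytest.raises(ValueError, match="Y306"):
            internal_water_census(traj, ["Y306"], cutoff=7.0)

    def test_channel_sites_always_occupied(self):
        """Census near the trapped sites stays >= 2 in almost every frame."""
        spec = two_trap_spec(seed=13, n_steps=60000, include_walls=True)
        traj, _ = generate_pore_trajectory(spec)
        topo = traj.topology
        wall_idx = np.flatnonzero(topo.roles == Role.WALL.value)
        coords = traj.frames[0].coordinates
        near = wall_idx[np.abs(coords[wall_idx, 2] + 3.75) < 3.0]
        series = internal_water_census(
            traj, AtomSelection(near), cutoff=7.0,
            waters=AtomSelection(range(spec.n_waters)))
        assert (series.counts >= 2).mean() >= 0.95


@pytest.fixture(scope="module")
def two_trap_grid():
    spec = two_trap_spec(seed=5, n_steps=60000)
    traj, _ = generate_pore_trajectory(spec)
    return accumulate_occupancy(
        traj, AtomSelection(range(spec.n_waters)), spacing=0.5,
        bounds=((-8.25, -8.25, -12.25), (8.25, 8.25, 6.25)))


class TestFindSites:
    def test_two_trap_run_recovers_both_sites(self, two_trap_grid):
        sites = find_hydration_sites(two_trap_grid, 0.5)
        assert len(sites) == 2
        for site, target in zip(sites, (-5.0, -2.5)):
            assert abs(site.z - target) < 1.0
            assert site.occupancy_fraction >= 0.95

    def test_trap_free_run_has_no_sites(self):
        spec = meta2_like_spec(seed=6, trap_sites=(), n_waters=50, n_steps=5000,
                               save_stride=10, include_walls=False)
        traj, _ = generate_pore_trajectory(spec)
        grid = accumulate_occupancy(
            traj, AtomSelection(range(spec.n_waters)), spacing=0.5,
            bounds=((-8.25, -8.25, -12.25), (8.25, 8.25, 6.25)))
        assert find_hydration_sites(grid, 0.9) == []

    def test_threshold_monotonicity(self, two_trap_grid):
        n_sites = [len(find_hydration_sites(two_trap_grid, t))
                   for t in (0.2, 0.5, 0.8, 1.5)]
        assert all(a >= b for a, b in zip(n_sites, n_sites[1:]))


def _hbond_frame(d, angle_deg, donor_is_a=True):
    """Water donor O–H aimed at a serine OG acceptor: D–A distance ``d``,
    D–H–A angle ``angle_deg``, O–H bond length 0.96 Å."""
    oh = 0.96
    theta = np.deg2rad(180.0 - angle_deg)
    acceptor = np.array([oh + (d - oh) * np.cos(theta), (d - oh) * np.sin(theta), 0.0])
    # recompute donor-acceptor distance from construction to place exactly
    records = [
        AtomRecord(0, "O", "O", "HOH", 1, "W", 1.52, Role.WATER_OXYGEN),
        AtomRecord(1, "H1", "H", "HOH", 1, "W", 1.2, Role.WATER_HYDROGEN),
        AtomRecord(2, "H2", "H", "HOH", 1, "W", 1.2, Role.WATER_HYDROGEN),
        AtomRecord(3, "OG", "O", "SER", 10, "A", 1.52, Role.PROTEIN),
    ]
    topo = Topology(records)
    coords = np.array([
        [0.0, 0.0, 0.0],
        [oh, 0.0, 0.0],
        [-0.24, 0.93, 0.0],
        acceptor,
    ])
    # scale acceptor so that |O - acceptor| == d exactly
    coords[3] *= d / np.linalg.norm(coords[3]) if np.linalg.norm(coords[3]) else 1.0
    frame = Frame(coords, np.array([50.0, 50.0, 50.0]), 0.0)
    return topo, frame


class TestHBonds:
    def test_ideal_water_donor(self):
        topo, frame = _hbond_frame(2.8, 180.0)
        bonds = detect_hbonds(frame, topo, AtomSelection([0, 1, 2]), AtomSelection([3]))
        assert len(bonds) == 1
        b = bonds[0]
        assert (b.donor_atom, b.hydrogen_atom, b.acceptor_atom) == (0, 1, 3)
        assert abs(b.distance - 2.8) < 1e-6
        assert b.angle > 179.0

    def test_distance_cutoff(self):
        topo, frame = _hbond_frame(5.0, 180.0)
        assert detect_hbonds(frame, topo, AtomSelection([0, 1, 2]), AtomSelection([3])) == []

    def test_symmetric_under_set_swap(self):
        topo, frame = _hbond_frame(2.9, 170.0)
        a, b = AtomSelection([0, 1, 2]), AtomSelection([3])
        fwd = detect_hbonds(frame, topo, a, b)
        rev = detect_hbonds(frame, topo, b, a)
        assert [(x.donor_atom, x.acceptor_atom) for x in fwd] == [
            (x.donor_atom, x.acceptor_atom) for x in rev]

    def test_grid_of_geometries_matches_predicate(self):
        """Detection over a (distance, angle) grid equals direct evaluation of
        the two-condition criterion."""
        a_sel, b_sel = AtomSelection([0, 1, 2]), AtomSelection([3])
        for d in np.linspace(2.0, 5.0, 31):
            for ang in np.linspace(90.0, 180.0, 31):
                topo, frame = _hbond_frame(float(d), float(ang))
                got = len(detect_hbonds(frame, topo, a_sel, b_sel,
                                        d_max=3.5, angle_min=150.0))
                # measure the realised geometry directly
                xyz = frame.coordinates
                dd = np.linalg.norm(xyz[3] - xyz[0])
                v1, v2 = xyz[0] - xyz[1], xyz[3] - xyz[1]
                realised = np.degrees(np.arccos(
                    np.clip(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1)))
                expected = int(dd <= 3.5 and realised >= 150.0)
                assert got == expected, (d, ang)


class TestSiteHbondProfile:
    def _held_water_trajectory(self, bond_every_other=False, n_frames=10):
        topo, frame0 = _hbond_frame(2.8, 180.0)
        far = frame0.coordinates.copy()
        far[3] = [20.0, 20.0, 20.0]  # acceptor moved out of range
        frames = []
        for f in range(n_frames):
            coords = far.copy() if (bond_every_other and f % 2) else frame0.coordinates
            frames.append(Frame(coords, frame0.box, 0.01 * f))
        return Trajectory(topo, frames)

    def _site(self):
        return HydrationSite(mean_position=np.zeros(3), z=0.0, occupancy_fraction=1.0)

    def test_permanent_bond_frequency_one(self):
        traj = self._held_water_trajectory()
        table = site_hbond_profile(traj, self._site(), capture_radius=1.5)
        assert table == {("S10:OG", "donor"): 1.0}

    def test_alternating_bond_frequency_half(self):
        traj = self._held_water_trajectory(bond_every_other=True)
        table = site_hbond_profile(traj, self._site(), capture_radius=1.5)
        assert table[("S10:OG", "donor")] == 0.5

    def test_empty_site_empty_table(self):
        traj = self._held_water_trajectory()
        site = HydrationSite(mean_position=np.array([30.0, 30.0, 30.0]),
                             z=30.0, occupancy_fraction=0.0)
        assert site_hbond_profile(traj, site, capture_radius=1.5) == {}
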