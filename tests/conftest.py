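"""Shared fixtures: all inputs are generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from poreflux.model import AtomRecord, Frame, Role, Topology, Trajectory


def make_water_topology(n_waters: int) -> Topology:
    """Topology of bare water oxygens (one residue each)."""
    return Topology(
        [
            AtomRecord(i, "O", "O", "HOH", i + 1, "W", 1.52, Role.WATER_OXYGEN)
            for i in range(n_waters)
        ]
    )


def trajectory_from_z(z_matrix, box=(40.0, 40.0, 60.0), dt_ns=0.01) -> Trajectory:
    """Scripted trajectory: waters at x = y = 0, z per (frame, water) matrix."""
    z = np.asarray(z_matrix, dtype=float)
    if z.ndim == 1:
        z = z.reshape(-1, 1)  # one water, many frames
    n_frames, n_waters = z.shape
    topo = make_water_topology(n_waters)
    frames = []
    for f in range(n_frames):
        coords = np.zeros((n_waters, 3))
        coords[:, 2] = z[f]
        frames.append(Frame(coords, np.asarray(box, dtype=float), time=f * dt_ns))
    return Trajectory(topo, frames)


TINY_WATER_PDB = """\
CRYST1   40.000   40.000   60.000  90.00  90.00  90.00 P 1           1
HETATM    1  O   HOH A   1       1.000   2.000   3.000  1.00  0.00           O
HETATM    1  H1  HOH A   1       1.800   2.300   3.200  1.00  0.00           H
HETATM    3  H2  HOH A   1       0.400   2.700   3.400  1.00  0.00           H
END
"""


@pytest.fixture
def tiny_water_pdb(tmp_path):
    """Three-atom water PDB; note the deliberately duplicated atom serial."""
    path = tmp_path / "water.pdb"
    path.write_text(TINY_WATER_PDB)
    return path


def make_helix(n_residues: int = 10, noise_sd: float = 0.0, seed: int = 0):
    """Synthetic poly-alanine-style helix: N, CA, C, O backbone per residue.

    Ideal-helix parameters (1.5 Å rise, 100° twist per residue) around the z
    axis; optional Gaussian coordinate noise.
    """
    rng = np.random.default_rng(seed)
    records, coords = [], []
    i = 0
    offsets = {"N": (2.2, -30.0, -0.8), "CA": (2.3, 0.0, 0.0),
               "C": (2.0, 25.0, 0.7), "O": (2.9, 35.0, 0.9)}
    for res in range(n_residues):
        base_angle = np.deg2rad(100.0 * res)
        for name, (r, dphi, dz) in offsets.items():
            ang = base_angle + np.deg2rad(dphi)
            xyz = np.array([r * np.cos(ang), r * np.sin(ang), 1.5 * res + dz])
            records.append(
                AtomRecord(i, name, name[0], "ALA", res + 1, "A",
                           1.7 if name[0] == "C" else 1.55, Role.PROTEIN)
            )
            coords.append(xyz)
            i += 1
    coords = np.asarray(coords)
    if noise_sd > 0:
        coords = coords + noise_sd * rng.standard_normal(coords.shape)
    return Topology(records), Frame(coords, np.array([40.0, 40.0, 60.0]), 0.0)


@pytest.fixture(scope="session")
def helix():
    return make_helix()


def brute_force_census(water_xyz, ref_xyz, box, cutoff) -> int:
    """Exhaustive all-pairs census with explicit periodic image shifts."""
    box = np.asarray(box, dtype=float)
    # fold everything into the primary cell first so +/-1 images suffice
    water_xyz = np.mod(np.asarray(water_xyz, dtype=float), box)
    ref_xyz = np.mod(np.asarray(ref_xyz, dtype=float), box)
    count = 0
    for w in water_xyz:
        best = np.inf
        for r in np.asarray(ref_xyz, dtype=float):
            for ix in (-1, 0, 1):
                for iy in (-1, 0, 1):
                    for iz in (-1, 0, 1):
                        shift = box * np.array([ix, iy, iz])
                        best = min(best, float(np.linalg.norm(w - r + shift)))
        if best <= cutoff:
            count += 1
    return count
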