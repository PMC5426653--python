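"""Internal-water census, hydration-site identification, hydrogen bonds.

The census follows the residue-proximity definition of an internal water: a
water whose oxygen lies within a cutoff (7 Å by default) of any atom of a
designated set of helix-core residues, with minimum-image distances so waters
wrapped across the periodic box are counted. The boundary is inclusive
(distance == cutoff counts).

Hydrogen bonds use the common geometric criterion: donor–acceptor distance
≤ 3.5 Å and donor–H–acceptor angle ≥ 150°, both configurable. Donor hydrogens
are resolved through a bundled bonding table for water and the standard
amino-acid polar groups (no distance-based bond perception).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .model import AtomSelection, Frame, Role, Topology, Trajectory
from .io import THREE_TO_ONE
from .select import residue_token_mask

logger = logging.getLogger(__name__)

__all__ = [
    "CensusSeries",
    "HydrationSite",
    "HBond",
    "internal_water_census",
    "find_hydration_sites",
    "detect_hbonds",
    "site_hbond_profile",
]


@dataclass
class CensusSeries:
    times: np.ndarray  # ns
    counts: np.ndarray  # internal waters per frame
    cutoff: float  # Å
    reference_residues: tuple[str, ...]


@dataclass
class HydrationSite:
    """A localized, persistently occupied water position."""

    mean_position: np.ndarray  # count-weighted, Å
    z: float
    occupancy_fraction: float  # peak-voxel visits / n_frames
    donor_partners: list[str] = field(default_factory=list)
    acceptor_partners: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class HBond:
    donor_atom: int
    hydrogen_atom: int
    acceptor_atom: int
    distance: float  # donor–acceptor, Å
    angle: float  # donor–H–acceptor, degrees


# hydrogen name → donor heavy-atom name, per residue type (water + standard
# polar groups; backbone amide applies to all amino acids)
_WATER_DONORS = {"H1": "O", "H2": "O", "HW1": "OW", "HW2": "OW"}
_SIDECHAIN_DONORS: dict[str, dict[str, str]] = {
    "SER": {"HG": "OG"},
    "THR": {"HG1": "OG1"},
    "TYR": {"HH": "OH"},
    "CYS": {"HG": "SG"},
    "LYS": {"HZ1": "NZ", "HZ2": "NZ", "HZ3": "NZ"},
    "ARG": {"HE": "NE", "HH11": "NH1", "HH12": "NH1", "HH21": "NH2", "HH22": "NH2"},
    "HIS": {"HD1": "ND1", "HE2": "NE2"},
    "HSD": {"HD1": "ND1"},
    "HSE": {"HE2": "NE2"},
    "TRP": {"HE1": "NE1"},
    "ASN": {"HD21": "ND2", "HD22": "ND2"},
    "GLN": {"HE21": "NE2", "HE22": "NE2"},
}
_BACKBONE_DONORS = {"H": "N", "HN": "N"}
_WATER_RESNAMES = {"HOH", "TIP3", "SOL", "WAT"}
_ACCEPTOR_ELEMENTS = {"O", "N", "S"}


def _min_image_distances(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """All-pairs minimum-image distance matrix for an orthorhombic box."""
    from MDAnalysis.lib.distances import distance_array

    mda_box = np.array([box[0], box[1], box[2], 90.0, 90.0, 90.0], dtype=np.float32)
    return distance_array(
        np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64), box=mda_box
    )


def internal_water_census(
    trajectory: Trajectory,
    reference: list[str] | AtomSelection,
    cutoff: float = 7.0,
    waters: AtomSelection | None = None,
) -> CensusSeries:
    """Count waters within ``cutoff`` of any reference atom, per frame.

    ``reference`` is either a list of residue tokens (e.g. the helix-core
    lists ``["G51", "I123", ...]``) or a pre-built atom selection.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    topo = trajectory.topology
    if isinstance(reference, AtomSelection):
        ref_idx = reference.indices
        tokens: tuple[str, ...] = ()
    else:
        masks = []
        for token in reference:
            m = residue_token_mask(topo, token)
            if not m.any():
                raise ValueError(f"reference residue {token!r} not found")
            masks.append(m)
        ref_idx = np.flatnonzero(np.logical_or.reduce(masks))
        tokens = tuple(reference)
    if len(ref_idx) == 0:
        raise ValueError("reference selection is empty")
    if waters is None:
        waters = AtomSelection(np.flatnonzero(topo.roles == Role.WATER_OXYGEN.value))
    counts = np.empty(trajectory.n_frames, dtype=np.int64)
    for f, frame in enumerate(trajectory.frames):
        d = _min_image_distances(
            frame.coordinates[waters.indices], frame.coordinates[ref_idx], frame.box
        )
        counts[f] = int((d.min(axis=1) <= cutoff).sum())
    return CensusSeries(
        times=trajectory.times, counts=counts, cutoff=float(cutoff),
        reference_residues=tokens,
    )


def find_hydration_sites(
    grid, occupancy_fraction_min: float = 0.5
) -> list[HydrationSite]:
    """Cluster persistently visited voxels into hydration sites.

    Voxels with ``counts / n_frames >= occupancy_fraction_min`` are clustered
    by face connectivity; each cluster yields one site at the count-weighted
    mean voxel-centre position, with occupancy fraction = the cluster's peak
    voxel count / n_frames. Raising the threshold never increases the number
    of sites.
    """
    frac = grid.counts / max(grid.n_frames, 1)
    mask = frac >= occupancy_fraction_min
    labels, n = ndimage.label(mask, structure=ndimage.generate_binary_structure(3, 1))
    sites: list[HydrationSite] = []
    centers = [grid.voxel_centers(a) for a in range(3)]
    for lab in range(1, n + 1):
        sel = labels == lab
        w = grid.counts[sel].astype(float)
        ijk = np.argwhere(sel)
        pos = np.column_stack([centers[a][ijk[:, a]] for a in range(3)])
        mean_pos = (pos * w[:, None]).sum(axis=0) / w.sum()
        sites.append(
            HydrationSite(
                mean_position=mean_pos,
                z=float(mean_pos[2]),
                occupancy_fraction=float(w.max() / grid.n_frames),
            )
        )
    sites.sort(key=lambda s: s.z)
    return sites


def _donor_pairs(topology: Topology, indices: np.ndarray) -> list[tuple[int, int]]:
    """(donor_heavy, hydrogen) atom-index pairs within a candidate set."""
    by_residue: dict[tuple, dict[str, int]] = {}
    for i in indices:
        key = (topology.chain_ids[i], topology.residue_numbers[i], topology.residue_names[i])
        by_residue.setdefault(key, {})[topology.atom_names[i]] = int(i)
    pairs: list[tuple[int, int]] = []
    for (chain, resnum, resname), atoms in by_residue.items():
        rn = resname.upper()
        table: dict[str, str] = {}
        if rn in _WATER_RESNAMES:
            table = _WATER_DONORS
        else:
            table = {**_BACKBONE_DONORS, **_SIDECHAIN_DONORS.get(rn, {})}
        for hname, idx in atoms.items():
            heavy_name = table.get(hname)
            if heavy_name is None:
                continue
            heavy = atoms.get(heavy_name)
            if heavy is None:
                logger.warning(
                    "donor hydrogen %s of %s%s has no attached %s atom; skipped",
                    hname, resname, resnum, heavy_name,
                )
                continue
            pairs.append((heavy, idx))
    return pairs


def detect_hbonds(
    frame: Frame,
    topology: Topology,
    candidates_a: AtomSelection,
    candidates_b: AtomSelection,
    d_max: float = 3.5,
    angle_min: float = 150.0,
) -> list[HBond]:
    """Geometric hydrogen bonds between two candidate sets, with roles.

    Bonds are reported in both directions (A donating to B and B donating to
    A), so the result is symmetric under swapping the two sets.
    """
    xyz = frame.coordinates
    bonds: list[HBond] = []
    for donors_from, acceptors_from in (
        (candidates_a, candidates_b),
        (candidates_b, candidates_a),
    ):
        pairs = _donor_pairs(topology, donors_from.indices)
        acc = [
            int(i)
            for i in acceptors_from.indices
            if topology.elements[i] in _ACCEPTOR_ELEMENTS
        ]
        if not pairs or not acc:
            continue
        acc_xyz = xyz[acc]
        for heavy, h in pairs:
            d_vec = acc_xyz - xyz[heavy]
            dist = np.linalg.norm(d_vec, axis=1)
            close = (dist <= d_max) & (dist > 1e-6)
            for k in np.flatnonzero(close):
                a_idx = acc[k]
                if a_idx == heavy or a_idx == h:
                    continue
                v1 = xyz[heavy] - xyz[h]
                v2 = xyz[a_idx] - xyz[h]
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                if angle >= angle_min:
                    bonds.append(HBond(heavy, h, a_idx, float(dist[k]), angle))
    return bonds


def _residue_atom_token(topology: Topology, atom_index: int) -> str:
    rn = topology.residue_names[atom_index].upper()
    one = THREE_TO_ONE.get(rn, rn)
    return f"{one}{topology.residue_numbers[atom_index]}:{topology.atom_names[atom_index]}"


def site_hbond_profile(
    trajectory: Trajectory,
    site: HydrationSite,
    capture_radius: float = 1.5,
    partners: AtomSelection | None = None,
    d_max: float = 3.5,
    angle_min: float = 150.0,
) -> dict[tuple[str, str], float]:
    """Occupancy-normalised donor/acceptor partner frequencies for one site.

    For every frame in which a water oxygen sits within ``capture_radius`` of
    the site, hydrogen bonds between that water molecule and the partner
    selection (protein atoms by default) are tallied per partner residue-atom
    and per role of the *water* ("donor"/"acceptor"); frequencies divide by
    the number of occupied frames. Empty dict when the site is never occupied.
    """
    topo = trajectory.topology
    ox = np.flatnonzero(topo.roles == Role.WATER_OXYGEN.value)
    if partners is None:
        partners = AtomSelection(np.flatnonzero(topo.roles == Role.PROTEIN.value))
    tallies: dict[tuple[str, str], int] = {}
    occupied = 0
    for frame in trajectory.frames:
        d = np.linalg.norm(frame.coordinates[ox] - site.mean_position, axis=1)
        k = int(np.argmin(d)) if len(d) else -1
        if k < 0 or d[k] > capture_radius:
            continue
        occupied += 1
        o_idx = int(ox[k])
        water_atoms = np.flatnonzero(
            (topo.residue_numbers == topo.residue_numbers[o_idx])
            & (topo.chain_ids == topo.chain_ids[o_idx])
            & (topo.residue_names == topo.residue_names[o_idx])
        )
        bonds = detect_hbonds(
            frame, topo, AtomSelection(water_atoms), partners, d_max, angle_min
        )
        seen = set()
        for b in bonds:
            if b.donor_atom in water_atoms:
                key = (_residue_atom_token(topo, b.acceptor_atom), "donor")
            else:
                key = (_residue_atom_token(topo, b.donor_atom), "acceptor")
            if key not in seen:
                seen.add(key)
                tallies[key] = tallies.get(key, 0) + 1
    if occupied == 0:
        return {}
    return {k: v / occupied for k, v in sorted(tallies.items())}
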