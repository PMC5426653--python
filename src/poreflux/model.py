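"""Core domain types: atoms, topology, frames, trajectories, selections, axial regions.

Conventions used throughout the package:

* lengths in Å, times in ns;
* ``z`` is the membrane normal and ``z = 0`` is the membrane center;
* atom order in a :class:`Topology` matches the coordinate row order of every
  :class:`Frame` of an associated :class:`Trajectory`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Role",
    "AtomRecord",
    "Topology",
    "Frame",
    "Trajectory",
    "AtomSelection",
    "AxialRegion",
    "slice_frames",
]


class Role(str, enum.Enum):
    """Coarse functional role of an atom, assigned at read time."""

    PROTEIN = "protein"
    WATER_OXYGEN = "water_oxygen"
    WATER_HYDROGEN = "water_hydrogen"
    LIPID_PHOSPHORUS = "lipid_phosphorus"
    WALL = "wall"
    OTHER = "other"


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the (static) topology.

    ``residue_number`` is taken verbatim from the source file (1-based,
    crystal-structure numbering); ``atom_index`` is the 0-based position in
    the topology and in every coordinate array.
    """

    atom_index: int
    atom_name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    vdw_radius: float
    role: Role = Role.OTHER

    def __post_init__(self) -> None:
        if not self.vdw_radius > 0:
            raise ValueError(f"vdw_radius must be > 0, got {self.vdw_radius}")


class Topology:
    """Ordered collection of :class:`AtomRecord` shared by all frames.

    Exposes vectorised per-atom attribute arrays for fast selection.
    """

    def __init__(self, atoms: Sequence[AtomRecord]):
        self.atoms: list[AtomRecord] = list(atoms)
        idx = [a.atom_index for a in self.atoms]
        if idx != list(range(len(self.atoms))):
            raise ValueError("atom_index values must be 0..n_atoms-1 in order")
        self.atom_names = np.array([a.atom_name for a in self.atoms], dtype=object)
        self.elements = np.array([a.element for a in self.atoms], dtype=object)
        self.residue_names = np.array([a.residue_name for a in self.atoms], dtype=object)
        self.residue_numbers = np.array([a.residue_number for a in self.atoms], dtype=np.int64)
        self.chain_ids = np.array([a.chain_id for a in self.atoms], dtype=object)
        self.vdw_radii = np.array([a.vdw_radius for a in self.atoms], dtype=float)
        self.roles = np.array([a.role.value for a in self.atoms], dtype=object)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def __len__(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Topology(n_atoms={self.n_atoms})"


@dataclass
class Frame:
    """Coordinates of one snapshot plus its periodic box and time stamp."""

    coordinates: np.ndarray  # (n_atoms, 3), Å
    box: np.ndarray  # (3,), Å, orthorhombic (Lx, Ly, Lz)
    time: float  # ns

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (n_atoms, 3)")
        if self.box.shape != (3,) or not np.all(self.box > 0):
            raise ValueError("box must be three positive lengths")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")


class Trajectory:
    """A topology plus an ordered, strictly time-increasing list of frames."""

    def __init__(self, topology: Topology, frames: Sequence[Frame]):
        self.topology = topology
        self.frames: list[Frame] = list(frames)
        n = topology.n_atoms
        for i, f in enumerate(self.frames):
            if f.coordinates.shape[0] != n:
                raise ValueError(
                    f"frame {i} has {f.coordinates.shape[0]} atoms, topology has {n}"
                )
        t = self.times
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames], dtype=float)

    @property
    def boxes(self) -> np.ndarray:
        return np.array([f.box for f in self.frames], dtype=float)

    def coordinates_array(self, selection: "AtomSelection | None" = None) -> np.ndarray:
        """Stack coordinates into an (n_frames, n_sel, 3) array."""
        if selection is None:
            return np.array([f.coordinates for f in self.frames], dtype=float)
        idx = selection.indices
        return np.array([f.coordinates[idx] for f in self.frames], dtype=float)

    def __len__(self) -> int:
        return len(self.frames)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Trajectory(n_atoms={self.topology.n_atoms}, n_frames={self.n_frames})"


@dataclass(frozen=True)
class AtomSelection:
    """An ordered, duplicate-free set of atom indices into a topology."""

    indices: np.ndarray

    def __init__(self, indices: Iterable[int]):
        arr = np.unique(np.asarray(list(indices), dtype=np.int64))
        object.__setattr__(self, "indices", arr)

    def __len__(self) -> int:
        return len(self.indices)

    def validate(self, topology: Topology) -> None:
        if len(self.indices) and (
            self.indices.min() < 0 or self.indices.max() >= topology.n_atoms
        ):
            raise IndexError("selection indices out of range for topology")

    def union(self, other: "AtomSelection") -> "AtomSelection":
        return AtomSelection(np.union1d(self.indices, other.indices))

    def intersection(self, other: "AtomSelection") -> "AtomSelection":
        return AtomSelection(np.intersect1d(self.indices, other.indices))


@dataclass(frozen=True)
class AxialRegion:
    """A slab along the membrane normal, optionally laterally restricted.

    Membership along z is half-open, ``z_min <= z < z_max``, so adjacent
    regions tile the axis without overlap and a boundary value belongs to the
    higher-z region.
    """

    label: str
    z_min: float
    z_max: float
    lateral: tuple[float, float, float] | None = None  # (x, y, max radial distance)

    def __post_init__(self) -> None:
        if not self.z_min < self.z_max:
            raise ValueError(f"z_min must be < z_max for region {self.label!r}")

    def contains_z(self, z) -> np.ndarray | bool:
        z = np.asarray(z)
        return (z >= self.z_min) & (z < self.z_max)

    def contains_point(self, xyz) -> np.ndarray | bool:
        xyz = np.asarray(xyz, dtype=float)
        inside = self.contains_z(xyz[..., 2])
        if self.lateral is not None:
            x0, y0, rmax = self.lateral
            r2 = (xyz[..., 0] - x0) ** 2 + (xyz[..., 1] - y0) ** 2
            inside = inside & (r2 <= rmax**2)
        return inside


def slice_frames(trajectory: Trajectory, t_start: float, t_end: float) -> Trajectory:
    """Restrict a trajectory to frames with ``t_start <= time <= t_end`` (ns).

    Mirrors the usual practice of discarding an initial equilibration window
    before analysis. Raises ``ValueError`` when the window is empty or
    contains no frames.
    """
    if not t_start < t_end:
        raise ValueError("t_start must be < t_end")
    t = trajectory.times
    keep = [f for f, ti in zip(trajectory.frames, t) if t_start <= ti <= t_end]
    if not keep:
        raise ValueError(
            f"analysis window [{t_start}, {t_end}] ns contains no frames"
        )
    return Trajectory(trajectory.topology, keep)
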