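"""Structure and trajectory readers/writers.

PDB files are parsed and written with :mod:`gemmi`. Trajectories use an
extended XYZ convention where the comment line carries the orthorhombic box
and the frame time::

    4
    box=80.0 80.0 116.0 time=0.010
    O   1.0000   2.0000   3.0000
    ...

DCD trajectories are read through MDAnalysis when requested.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .model import AtomRecord, Frame, Role, Topology, Trajectory
from .vdw import TABLE_NAME, vdw_radius

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_WATER_RESNAMES",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory_xyz",
    "load_config",
]

DEFAULT_WATER_RESNAMES = frozenset({"HOH", "TIP3", "SOL", "WAT"})
DEFAULT_WALL_RESNAMES = frozenset({"WAL"})
DEFAULT_LIPID_RESNAMES = frozenset({"POPC", "POPE", "POPS", "DPPC", "DOPC", "LIP"})

STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS HSD HSE HSP ILE LEU LYS MET PHE PRO "
    "SER THR TRP TYR VAL".split()
)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "HSD": "H",
    "HSE": "H", "HSP": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T",
    "TRP": "W", "TYR": "Y", "VAL": "V",
}


def _guess_element(atom_name: str, explicit: str = "") -> str:
    if explicit and explicit.strip() and explicit.strip() not in ("X", ""):
        return explicit.strip().upper()
    name = atom_name.strip()
    # strip leading digits (e.g. 1HG1) then take the leading letter(s)
    while name and name[0].isdigit():
        name = name[1:]
    if not name:
        return "X"
    two = name[:2].upper()
    if two in ("CL", "BR", "NA", "MG", "ZN") and len(name) >= 2:
        return two
    return name[0].upper()


def assign_role(
    atom_name: str,
    element: str,
    residue_name: str,
    water_resnames: frozenset[str] = DEFAULT_WATER_RESNAMES,
    wall_resnames: frozenset[str] = DEFAULT_WALL_RESNAMES,
    lipid_resnames: frozenset[str] = DEFAULT_LIPID_RESNAMES,
) -> Role:
    rn = residue_name.strip().upper()
    if rn in water_resnames:
        if element == "O":
            return Role.WATER_OXYGEN
        if element == "H":
            return Role.WATER_HYDROGEN
        return Role.OTHER
    if rn in wall_resnames:
        return Role.WALL
    if rn in lipid_resnames:
        return Role.LIPID_PHOSPHORUS if element == "P" else Role.OTHER
    if rn in STANDARD_AMINO_ACIDS:
        return Role.PROTEIN
    return Role.OTHER


def read_structure(
    path: str | Path,
    format: str = "pdb",
    water_resnames: Iterable[str] | None = None,
) -> tuple[Topology, Frame]:
    """Read a PDB structure into a :class:`Topology` and first :class:`Frame`.

    One :class:`AtomRecord` is produced per ATOM/HETATM record, in file order,
    with ``atom_index`` reassigned sequentially (duplicate serials in the file
    are therefore harmless). Water atoms are flagged by residue name
    (configurable; default HOH/TIP3/SOL/WAT) and van-der-Waals radii come from
    the bundled element table.
    """
    if format != "pdb":
        raise ValueError(f"unsupported structure format {format!r}")
    import gemmi

    waters = frozenset(s.upper() for s in water_resnames) if water_resnames else DEFAULT_WATER_RESNAMES
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"failed to parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"PDB file {path} contains no model")
    model = st[0]
    records: list[AtomRecord] = []
    coords: list[tuple[float, float, float]] = []
    i = 0
    for chain in model:
        for residue in chain:
            for atom in residue:
                element = _guess_element(atom.name, atom.element.name)
                records.append(
                    AtomRecord(
                        atom_index=i,
                        atom_name=atom.name,
                        element=element,
                        residue_name=residue.name,
                        residue_number=residue.seqid.num,
                        chain_id=chain.name,
                        vdw_radius=vdw_radius(element),
                        role=assign_role(atom.name, element, residue.name, waters),
                    )
                )
                coords.append((atom.pos.x, atom.pos.y, atom.pos.z))
                i += 1
    if not records:
        raise ValueError(f"PDB file {path} contains no atoms")
    cell = st.cell
    if cell.a > 1 and cell.b > 1 and cell.c > 1:
        box = np.array([cell.a, cell.b, cell.c])
    else:
        box = np.array([1e3, 1e3, 1e3])  # effectively non-periodic
    topo = Topology(records)
    frame = Frame(np.array(coords, dtype=float), box, time=0.0)
    logger.info("read %d atoms from %s (vdW table: %s)", len(records), path, TABLE_NAME)
    return topo, frame


def write_structure(path: str | Path, topology: Topology, frame: Frame) -> None:
    """Write a topology + frame as a PDB file (CRYST1 carries the box)."""
    import gemmi

    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(frame.box[0], frame.box[1], frame.box[2], 90, 90, 90)
    st.spacegroup_hm = "P 1"
    model = gemmi.Model("1")
    chain_map: dict[str, gemmi.Chain] = {}
    cur_res = None
    cur_key = None
    for rec, xyz in zip(topology.atoms, frame.coordinates):
        cid = rec.chain_id or "A"
        if cid not in chain_map:
            chain_map[cid] = gemmi.Chain(cid)
            model.add_chain(chain_map[cid])
            chain_map[cid] = model[len(model) - 1]
        key = (cid, rec.residue_number, rec.residue_name)
        if key != cur_key:
            res = gemmi.Residue()
            res.name = rec.residue_name
            res.seqid = gemmi.SeqId(rec.residue_number, " ")
            res.het_flag = "A" if rec.residue_name in STANDARD_AMINO_ACIDS else "H"
            chain_map[cid].add_residue(res)
            cur_res = chain_map[cid][len(chain_map[cid]) - 1]
            cur_key = key
        atom = gemmi.Atom()
        atom.name = rec.atom_name
        atom.element = gemmi.Element(rec.element.capitalize())
        atom.pos = gemmi.Position(float(xyz[0]), float(xyz[1]), float(xyz[2]))
        cur_res.add_atom(atom)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def write_trajectory_xyz(path: str | Path, trajectory: Trajectory) -> None:
    """Write all frames in the extended XYZ convention (box + time on line 2)."""
    names = trajectory.topology.atom_names
    with open(path, "w") as fh:
        for frame in trajectory.frames:
            fh.write(f"{trajectory.topology.n_atoms}\n")
            fh.write(
                "box=%.6f %.6f %.6f time=%.9f\n"
                % (frame.box[0], frame.box[1], frame.box[2], frame.time)
            )
            for name, (x, y, z) in zip(names, frame.coordinates):
                fh.write(f"{name:<4s} {x:12.4f} {y:12.4f} {z:12.4f}\n")


def _parse_xyz_comment(line: str) -> tuple[np.ndarray | None, float | None]:
    toks = line.split()
    box = None
    time = None
    i = 0
    while i < len(toks):
        tok = toks[i]
        if tok.startswith("box="):
            try:
                box = np.array(
                    [float(tok[4:]), float(toks[i + 1]), float(toks[i + 2])]
                )
            except (IndexError, ValueError):
                box = None
            i += 3
            continue
        if tok.startswith("time="):
            try:
                time = float(tok[5:])
            except ValueError:
                time = None
        i += 1
    return box, time


def read_trajectory(
    path: str | Path,
    topology: Topology,
    format: str = "xyz",
    box: Sequence[float] | None = None,
    dt_ns: float | None = None,
) -> Trajectory:
    """Read a coordinate trajectory against an existing topology.

    ``box``/``dt_ns`` supply the periodic box and frame interval when the
    format does not carry them. Atom-count mismatches and truncated final
    frames raise errors naming the frame index (nothing is dropped silently).
    """
    if format == "xyz":
        return _read_xyz(path, topology, box, dt_ns)
    if format == "dcd":
        return _read_dcd(path, topology, box, dt_ns)
    raise ValueError(f"unsupported trajectory format {format!r}")


def _read_xyz(path, topology, box, dt_ns) -> Trajectory:
    frames: list[Frame] = []
    default_box = np.asarray(box, dtype=float) if box is not None else None
    n = topology.n_atoms
    with open(path) as fh:
        frame_idx = 0
        while True:
            header = fh.readline()
            if not header.strip():
                break
            try:
                count = int(header)
            except ValueError as exc:
                raise ValueError(
                    f"frame {frame_idx}: malformed atom-count line {header!r}"
                ) from exc
            if count != n:
                raise ValueError(
                    f"frame {frame_idx}: file has {count} atoms, topology has {n}"
                )
            comment = fh.readline()
            fbox, ftime = _parse_xyz_comment(comment)
            coords = np.empty((n, 3), dtype=float)
            for i in range(n):
                line = fh.readline()
                if not line:
                    raise ValueError(
                        f"frame {frame_idx}: truncated at atom {i} of {n}"
                    )
                parts = line.split()
                if len(parts) < 4:
                    raise ValueError(
                        f"frame {frame_idx}: malformed coordinate line {line!r}"
                    )
                coords[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
            if fbox is None:
                if default_box is None:
                    raise ValueError(
                        f"frame {frame_idx}: no box in file and none configured"
                    )
                fbox = default_box
            if ftime is None:
                ftime = frame_idx * (dt_ns if dt_ns is not None else 1.0)
            frames.append(Frame(coords, fbox, ftime))
            frame_idx += 1
    return Trajectory(topology, frames)


def _read_dcd(path, topology, box, dt_ns) -> Trajectory:
    from MDAnalysis.coordinates.DCD import DCDReader

    frames: list[Frame] = []
    default_box = np.asarray(box, dtype=float) if box is not None else None
    reader = DCDReader(str(path))
    if reader.n_atoms != topology.n_atoms:
        raise ValueError(
            f"DCD has {reader.n_atoms} atoms, topology has {topology.n_atoms}"
        )
    for i, ts in enumerate(reader):
        dims = ts.dimensions
        if dims is not None and dims[0] > 0:
            fbox = np.array(dims[:3], dtype=float)
        elif default_box is not None:
            fbox = default_box
        else:
            raise ValueError(f"frame {i}: no box in DCD and none configured")
        t = i * dt_ns if dt_ns is not None else ts.time / 1000.0  # ps → ns
        frames.append(Frame(ts.positions.astype(float), fbox, t))
    reader.close()
    return Trajectory(topology, frames)


def load_config(path: str | Path) -> dict:
    """Load a YAML run-configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"configuration file {path} must map keys to values")
    return cfg
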