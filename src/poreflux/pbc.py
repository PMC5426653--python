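"""Periodic-boundary helpers: wrapping, unwrapping, and membrane-centred z.

Unwrapping makes a single molecule's z-series continuous across periodic
images: any frame-to-frame jump larger than half the box is shifted by the
appropriate number of box lengths. The first frame keeps its wrapped value.
"""

from __future__ import annotations

import numpy as np

from .model import AtomSelection, Trajectory

__all__ = [
    "unwrap_series",
    "wrap_series",
    "unwrap_molecule_z",
    "unwrap_selection_z",
    "axial_offsets",
]


def unwrap_series(z: np.ndarray, box_length) -> np.ndarray:
    """Unwrap a 1-D (or columns of a 2-D) wrapped coordinate series.

    ``box_length`` is a scalar or a per-frame array. The correction applied
    between consecutive samples is the multiple of the box length that brings
    the jump below half a box.
    """
    z = np.asarray(z, dtype=float)
    L = np.broadcast_to(np.asarray(box_length, dtype=float), z.shape[:1]).copy()
    diffs = np.diff(z, axis=0)
    Ld = L[1:] if L.ndim == 1 else L
    if z.ndim == 2:
        Ld = Ld[:, None]
    shifts = -np.round(diffs / Ld) * Ld
    out = z.copy()
    out[1:] = z[1:] + np.cumsum(shifts, axis=0)
    return out


def wrap_series(z: np.ndarray, box_length, origin: float = 0.0) -> np.ndarray:
    """Wrap coordinates into ``[origin, origin + box_length)``."""
    z = np.asarray(z, dtype=float)
    L = np.asarray(box_length, dtype=float)
    if L.ndim == 1 and z.ndim == 2:
        L = L[:, None]
    return origin + np.mod(z - origin, L)


def unwrap_molecule_z(trajectory: Trajectory, molecule: AtomSelection) -> np.ndarray:
    """Continuous z-series (Å) of a single water oxygen across the trajectory."""
    if len(molecule) != 1:
        raise ValueError("unwrap_molecule_z expects a single-atom selection")
    z = trajectory.coordinates_array(molecule)[:, 0, 2]
    Lz = trajectory.boxes[:, 2]
    return unwrap_series(z, Lz)


def unwrap_selection_z(trajectory: Trajectory, selection: AtomSelection) -> np.ndarray:
    """Per-atom unwrapped z, shape (n_frames, n_atoms_in_selection)."""
    z = trajectory.coordinates_array(selection)[:, :, 2]
    Lz = trajectory.boxes[:, 2]
    return unwrap_series(z, Lz)


def axial_offsets(trajectory: Trajectory, membrane: AtomSelection) -> np.ndarray:
    """Per-frame mean z (Å) of a membrane selection.

    Subtracting this series from z-coordinates realises the membrane-centred
    convention (z = 0 at the membrane center).
    """
    if len(membrane) == 0:
        raise ValueError("membrane selection is empty")
    z = trajectory.coordinates_array(membrane)[:, :, 2]
    return z.mean(axis=1)
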