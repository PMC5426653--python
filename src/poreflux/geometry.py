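"""Rigid-body superposition, RMSD series, membrane metrics, residue distances.

Superposition is the least-squares optimal rotation + translation (Kabsch
with reflection correction, computed through
``scipy.spatial.transform.Rotation.align_vectors``); RMSD is evaluated after
applying the transform. No mass weighting is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .model import AtomSelection, Frame, Trajectory
from .select import residue_token_mask

__all__ = [
    "RigidTransform",
    "DistanceDistribution",
    "superpose",
    "rmsd_series",
    "membrane_metrics",
    "residue_pair_distances",
    "count_modes",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation (det = +1) plus translation, in Å."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz) @ self.rotation.T + self.translation


@dataclass
class DistanceDistribution:
    """Per-frame nearest-atom distances between two residues, plus histogram."""

    pair: tuple[str, str]
    samples: np.ndarray  # Å, one per frame
    bin_edges: np.ndarray
    counts: np.ndarray
    n_modes: int


def _check_points(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3 or x.shape[0] < 3:
        raise ValueError(f"{name} must be (n >= 3, 3) coordinates")
    centered = x - x.mean(axis=0)
    # collinear (or coincident) point sets have rank < 2
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise ValueError(f"{name} points are degenerate (collinear)")
    return x


def superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns the transform and the post-fit RMSD in Å.
    """
    mobile = _check_points(mobile, "mobile")
    reference = _check_points(reference, "reference")
    if mobile.shape != reference.shape:
        raise ValueError("point counts differ")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    rot, rssd = Rotation.align_vectors(reference - rc, mobile - mc)
    R = rot.as_matrix()
    t = rc - R @ mc
    transform = RigidTransform(R, t)
    moved = transform.apply(mobile)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return transform, rmsd


def rmsd_series(
    trajectory: Trajectory, selection: AtomSelection, reference: Frame
) -> np.ndarray:
    """Per-frame RMSD (Å) of a selection after optimal superposition.

    The reference coordinates are taken from the same selection of the
    reference frame (e.g. the helical backbone of the starting structure).
    """
    ref = reference.coordinates[selection.indices]
    coords = trajectory.coordinates_array(selection)
    return np.array([superpose(c, ref)[1] for c in coords])


def membrane_metrics(
    trajectory: Trajectory,
    top_leaflet: AtomSelection,
    bottom_leaflet: AtomSelection,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame membrane area (Lx·Ly, Å²) and thickness (Å).

    Thickness is the difference between the mean z of the phosphorus markers
    in the two leaflets; swapping the leaflets negates it.
    """
    if len(top_leaflet) == 0 or len(bottom_leaflet) == 0:
        raise ValueError("leaflet selections must be non-empty")
    boxes = trajectory.boxes
    area = boxes[:, 0] * boxes[:, 1]
    zt = trajectory.coordinates_array(top_leaflet)[:, :, 2].mean(axis=1)
    zb = trajectory.coordinates_array(bottom_leaflet)[:, :, 2].mean(axis=1)
    return area, zt - zb


def count_modes(counts: np.ndarray, smooth_bins: float = 2.0, rel_floor: float = 0.05) -> int:
    """Count strict local maxima of a kernel-smoothed histogram.

    The histogram is smoothed with a Gaussian kernel of width
    ``smooth_bins`` bins (bandwidth 2x the bin width by default) and maxima
    below ``rel_floor`` of the global maximum are ignored — a reproducible,
    parameter-light surrogate for judging unimodality by eye.
    """
    y = gaussian_filter1d(counts.astype(float), smooth_bins, mode="constant")
    if y.max() <= 0:
        return 0
    floor = rel_floor * y.max()
    ypad = np.concatenate([[-np.inf], y, [-np.inf]])
    is_max = (ypad[1:-1] > ypad[:-2]) & (ypad[1:-1] > ypad[2:]) & (ypad[1:-1] >= floor)
    return int(is_max.sum())


def residue_pair_distances(
    trajectory: Trajectory, res_a: str, res_b: str, bin_width: float = 0.1
) -> DistanceDistribution:
    """Nearest-atom distance between two residues, per frame.

    The sample for each frame is the minimum over all atom pairs (one atom
    from each residue) of the Euclidean distance, as used for judging whether
    a constriction has one conformational state (unimodal distribution).
    """
    topo = trajectory.topology
    masks = []
    for token in (res_a, res_b):
        m = residue_token_mask(topo, token)
        if not m.any():
            raise ValueError(f"residue {token!r} not found in topology")
        masks.append(np.flatnonzero(m))
    ia, ib = masks
    samples = np.empty(trajectory.n_frames)
    for f, frame in enumerate(trajectory.frames):
        samples[f] = cdist(frame.coordinates[ia], frame.coordinates[ib]).min()
    lo = np.floor(samples.min() / bin_width) * bin_width
    hi = np.ceil(samples.max() / bin_width) * bin_width
    n_bins = max(1, int(round((hi - lo) / bin_width)))
    counts, edges = np.histogram(samples, bins=n_bins, range=(lo, lo + n_bins * bin_width))
    return DistanceDistribution(
        pair=(res_a, res_b),
        samples=samples,
        bin_edges=edges,
        counts=counts,
        n_modes=count_modes(counts),
    )
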