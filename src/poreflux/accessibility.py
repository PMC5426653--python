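"""Water-accessibility occupancy grids, pore connectivity, pore-radius profile.

The occupancy grid voxelises where water oxygens have been over a trajectory
(1 Å spacing by default); thresholding it at ``min_visits = 1`` reproduces the
"anywhere water reached" accessibility-surface semantics. Pore existence is a
flood-fill question: does one connected component of accessible voxels touch
both the bulk region and the internal pocket region?

The radius profile is a fixed-axis variant of the HOLE procedure: at each
z-bin centre, the radius is the clearance from the axis point to the nearest
obstacle-atom surface within the slab. Per-slice centre optimisation (full
HOLE) is deliberately not done; the axis (x, y) is supplied or defaulted to
the obstacle centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .model import AtomSelection, AxialRegion, Trajectory

__all__ = [
    "OccupancyGrid",
    "RadiusProfile",
    "accumulate_occupancy",
    "accessible_mask",
    "pore_exists",
    "pore_radius_profile",
    "write_dx",
]


@dataclass
class OccupancyGrid:
    """Per-voxel visit counts over ``n_frames`` frames.

    ``counts[i, j, k]`` covers the half-open cube
    ``origin + spacing*[i, j, k]`` to ``origin + spacing*[i+1, j+1, k+1]``.
    Positions outside the bounds are tallied in ``overflow``, never dropped
    silently, so ``counts.sum() + overflow == n_frames * n_tracked``.
    """

    origin: np.ndarray  # (3,) Å
    spacing: float  # Å
    counts: np.ndarray  # (nx, ny, nz) int64
    n_frames: int
    n_tracked: int
    overflow: int = 0

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.counts.shape

    def voxel_centers(self, axis: int) -> np.ndarray:
        n = self.counts.shape[axis]
        return self.origin[axis] + self.spacing * (np.arange(n) + 0.5)

    def region_mask(self, region: AxialRegion) -> np.ndarray:
        """Boolean voxel mask of an axial region (by voxel-centre position)."""
        zc = self.voxel_centers(2)
        mz = region.contains_z(zc)
        mask = np.zeros(self.counts.shape, dtype=bool)
        mask[:, :, mz] = True
        if region.lateral is not None:
            x0, y0, rmax = region.lateral
            xc = self.voxel_centers(0)[:, None]
            yc = self.voxel_centers(1)[None, :]
            lat = (xc - x0) ** 2 + (yc - y0) ** 2 <= rmax**2
            mask &= lat[:, :, None]
        if not mask.any():
            raise ValueError(f"region {region.label!r} lies outside the grid")
        return mask


def accumulate_occupancy(
    trajectory: Trajectory,
    waters: AtomSelection,
    spacing: float = 1.0,
    bounds: tuple | None = None,
) -> OccupancyGrid:
    """Increment each water oxygen's containing voxel, every frame.

    ``bounds`` is ``((xmin, ymin, zmin), (xmax, ymax, zmax))``; when omitted it
    is taken from the data extent padded by one voxel.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    pos = trajectory.coordinates_array(waters)  # (F, n, 3)
    flat = pos.reshape(-1, 3)
    if bounds is None:
        lo = flat.min(axis=0) - spacing
        hi = flat.max(axis=0) + spacing
    else:
        lo = np.asarray(bounds[0], dtype=float)
        hi = np.asarray(bounds[1], dtype=float)
    if np.any(hi <= lo):
        raise ValueError("bounds describe a zero or negative volume")
    dims = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    idx = np.floor((flat - lo) / spacing).astype(np.int64)
    inside = np.all((idx >= 0) & (idx < dims), axis=1)
    counts = np.zeros(tuple(dims), dtype=np.int64)
    np.add.at(counts, tuple(idx[inside].T), 1)
    return OccupancyGrid(
        origin=lo,
        spacing=float(spacing),
        counts=counts,
        n_frames=pos.shape[0],
        n_tracked=pos.shape[1],
        overflow=int((~inside).sum()),
    )


def accessible_mask(grid: OccupancyGrid, min_visits: int = 1) -> np.ndarray:
    """Voxels visited at least ``min_visits`` times."""
    if min_visits < 1:
        raise ValueError("min_visits must be >= 1")
    return grid.counts >= min_visits


_STRUCTURES = {
    "face": ndimage.generate_binary_structure(3, 1),
    "face+edge+corner": ndimage.generate_binary_structure(3, 3),
}


def pore_exists(
    grid: OccupancyGrid,
    bulk_region: AxialRegion,
    pocket_region: AxialRegion,
    mask: np.ndarray | None = None,
    min_visits: int = 1,
    connectivity: str = "face",
) -> tuple[bool, np.ndarray]:
    """Is there one connected accessible component joining bulk and pocket?

    Flood-fills the accessible mask (6-neighbour by default) and reports
    whether any component has voxels in both regions, returning that
    component's voxel mask (empty mask when no pore exists).
    """
    if mask is None:
        mask = accessible_mask(grid, min_visits)
    structure = _STRUCTURES[connectivity]
    labels, _n = ndimage.label(mask, structure=structure)
    bulk_mask = grid.region_mask(bulk_region)
    pocket_mask = grid.region_mask(pocket_region)
    bulk_labels = np.unique(labels[bulk_mask & mask])
    pocket_labels = np.unique(labels[pocket_mask & mask])
    common = np.intersect1d(bulk_labels, pocket_labels)
    common = common[common > 0]
    if common.size == 0:
        return False, np.zeros_like(mask)
    return True, np.isin(labels, common)


@dataclass
class RadiusProfile:
    """Mean ± SD channel radius versus axial position (membrane-centred z)."""

    z_centers: np.ndarray
    mean_radius: np.ndarray
    sd_radius: np.ndarray
    n_frames: int
    capped: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))


def pore_radius_profile(
    trajectory: Trajectory,
    obstacles: AtomSelection,
    axis_xy: tuple[float, float] | None = None,
    z_range: tuple[float, float] | None = None,
    bin_width: float = 0.5,
    cap_radius: float = 15.0,
) -> RadiusProfile:
    """Axial pore-radius profile against a fixed (x, y) axis.

    At each bin centre ``c`` and frame, the radius is::

        max(0, min over obstacle atoms with |z_atom - c| <= bin_width of
               (|atom - (axis_x, axis_y, c)| - vdw_radius))

    i.e. the largest probe sphere centred on the axis that touches no atom in
    the slab. Bins whose slab holds no obstacle atom in some frame report the
    configured ``cap_radius`` and are flagged in ``capped``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if len(obstacles) == 0:
        raise ValueError("obstacle selection is empty")
    coords = trajectory.coordinates_array(obstacles)  # (F, m, 3)
    vdw = trajectory.topology.vdw_radii[obstacles.indices]
    if axis_xy is None:
        cx, cy = coords[0, :, 0].mean(), coords[0, :, 1].mean()
    else:
        cx, cy = axis_xy
    if z_range is None:
        z_range = (coords[:, :, 2].min(), coords[:, :, 2].max())
    n_bins = max(1, int(round((z_range[1] - z_range[0]) / bin_width)))
    centers = z_range[0] + bin_width * (np.arange(n_bins) + 0.5)
    radii = np.empty((coords.shape[0], n_bins))
    capped = np.zeros(n_bins, dtype=bool)
    for f in range(coords.shape[0]):
        xyz = coords[f]
        dx = xyz[:, 0] - cx
        dy = xyz[:, 1] - cy
        for b, c in enumerate(centers):
            slab = np.abs(xyz[:, 2] - c) <= bin_width
            if not slab.any():
                radii[f, b] = cap_radius
                capped[b] = True
                continue
            d = np.sqrt(dx[slab] ** 2 + dy[slab] ** 2 + (xyz[slab, 2] - c) ** 2)
            radii[f, b] = max(0.0, float((d - vdw[slab]).min()))
    return RadiusProfile(
        z_centers=centers,
        mean_radius=radii.mean(axis=0),
        sd_radius=radii.std(axis=0),
        n_frames=coords.shape[0],
        capped=capped,
    )


def write_dx(path, grid: OccupancyGrid) -> None:
    """Export the grid as an OpenDX scalar field (readable by VMD/PyMOL)."""
    nx, ny, nz = grid.dims
    s = grid.spacing
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(
            "origin %.4f %.4f %.4f\n"
            % (grid.origin[0] + s / 2, grid.origin[1] + s / 2, grid.origin[2] + s / 2)
        )
        fh.write(f"delta {s:.4f} 0 0\ndelta 0 {s:.4f} 0\ndelta 0 0 {s:.4f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n"
        )
        flat = grid.counts.astype(float).ravel()
        for i in range(0, len(flat), 3):
            fh.write(" ".join("%g" % v for v in flat[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')
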