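"""Permeation-event detection, position classification, pathway labelling.

A permeation event is a *committed* transit of one water between the bulk
region and the internal pocket: the water must leave one region and reach the
other without returning to its origin in between. Re-entering the origin
region aborts the attempt (no event). The per-water state machine therefore
has three states — in bulk, in transit, in pocket — and an event is committed
at the first frame the far region is entered, with the event span starting at
the last frame the origin region was occupied.

"Inward" is bulk → pocket (cytoplasm toward the retinal-binding pocket).
Transits are counted in both directions; water flux through such pores is
bi-directional.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .model import AtomSelection, AxialRegion, Trajectory
from .pbc import unwrap_selection_z

logger = logging.getLogger(__name__)

__all__ = [
    "Direction",
    "RegionSet",
    "PermeationEvent",
    "default_positions",
    "detect_events",
    "classify_position",
    "event_z_series",
    "classify_pathway",
]


class Direction(str, enum.Enum):
    INWARD = "inward"    # bulk → pocket
    OUTWARD = "outward"  # pocket → bulk


def default_positions() -> list[AxialRegion]:
    """The three canonical axial positions between the pore constrictions:
    position 1 in [−10, −5), position 2 in [−5, 0), position 3 in [0, 5) Å."""
    return [
        AxialRegion("position1", -10.0, -5.0),
        AxialRegion("position2", -5.0, 0.0),
        AxialRegion("position3", 0.0, 5.0),
    ]


@dataclass(frozen=True)
class RegionSet:
    """Bulk and pocket regions plus the ordered intermediate positions."""

    bulk: AxialRegion
    pocket: AxialRegion
    positions: tuple[AxialRegion, ...] = ()

    def __post_init__(self) -> None:
        if not (self.bulk.z_max <= self.pocket.z_min or self.pocket.z_max <= self.bulk.z_min):
            raise ValueError("bulk and pocket regions must be disjoint in z")
        zs = [r.z_min for r in self.positions]
        if zs != sorted(zs):
            raise ValueError("positions must be ordered by z")

    @classmethod
    def with_default_positions(cls, bulk: AxialRegion, pocket: AxialRegion) -> "RegionSet":
        return cls(bulk, pocket, tuple(default_positions()))


@dataclass
class PermeationEvent:
    """One committed bulk↔pocket transit of one water."""

    water_id: int  # atom index of the water oxygen
    direction: Direction
    start_frame: int
    end_frame: int
    z_series: np.ndarray  # unwrapped z, start_frame..end_frame inclusive
    pathway: str = "unassigned"

    def __post_init__(self) -> None:
        if not self.start_frame < self.end_frame:
            raise ValueError("start_frame must be < end_frame")
        if len(self.z_series) != self.end_frame - self.start_frame + 1:
            raise ValueError("z_series length must equal the frame span")


def anchored_pocket_region(
    trajectory: Trajectory, anchor_token: str, radius: float = 7.0
) -> AxialRegion:
    """Pocket region anchored on a residue (e.g. the retinal-linked lysine).

    Built as a capture cylinder of the given radius around the anchor
    residue's centroid in the first frame: z span ``centroid_z ± radius``,
    lateral constraint ``(centroid_x, centroid_y, radius)``. The 7 Å default
    reuses the internal-water census cutoff.
    """
    from .select import residue_token_mask

    mask = residue_token_mask(trajectory.topology, anchor_token)
    if not mask.any():
        raise ValueError(f"anchor residue {anchor_token!r} not found")
    centroid = trajectory.frames[0].coordinates[mask].mean(axis=0)
    return AxialRegion(
        label=f"pocket@{anchor_token}",
        z_min=float(centroid[2] - radius),
        z_max=float(centroid[2] + radius),
        lateral=(float(centroid[0]), float(centroid[1]), float(radius)),
    )


def _region_codes(z: np.ndarray, regions: RegionSet) -> np.ndarray:
    """0 = bulk, 2 = pocket, 1 = transit, elementwise."""
    codes = np.ones(z.shape, dtype=np.int8)
    codes[regions.bulk.contains_z(z)] = 0
    codes[regions.pocket.contains_z(z)] = 2
    return codes


def detect_events(
    trajectory: Trajectory,
    waters: AtomSelection,
    regions: RegionSet,
    z_offsets: np.ndarray | None = None,
) -> list[PermeationEvent]:
    """Run the permeation state machine over every selected water.

    z-series are unwrapped across periodic images first; ``z_offsets``
    (per-frame, e.g. from a membrane-centring selection) is subtracted when
    given. Events per water are chronological and alternate in direction.
    """
    z = unwrap_selection_z(trajectory, waters)  # (F, n)
    if z_offsets is not None:
        z = z - np.asarray(z_offsets, dtype=float)[:, None]
    codes = _region_codes(z, regions)
    events: list[PermeationEvent] = []
    for col, atom_index in enumerate(waters.indices):
        c = codes[:, col]
        onside = np.flatnonzero(c != 1)
        if onside.size < 2:
            continue
        sides = c[onside]
        changes = np.flatnonzero(sides[1:] != sides[:-1])
        for j in changes:
            start = int(onside[j])       # last frame in the origin region
            end = int(onside[j + 1])     # commitment frame
            direction = Direction.INWARD if sides[j] == 0 else Direction.OUTWARD
            events.append(
                PermeationEvent(
                    water_id=int(atom_index),
                    direction=direction,
                    start_frame=start,
                    end_frame=end,
                    z_series=z[start : end + 1, col].copy(),
                )
            )
    events.sort(key=lambda e: (e.end_frame, e.water_id))
    return events


def classify_position(z: float, regions: RegionSet) -> str:
    """Label of the axial position containing ``z`` (half-open intervals).

    Below the lowest position: ``bulk-side``; at or above the highest:
    ``beyond``.
    """
    positions = regions.positions or tuple(default_positions())
    if z < positions[0].z_min:
        return "bulk-side"
    for region in positions:
        if region.contains_z(z):
            return region.label
    return "beyond"


def event_z_series(
    trajectory: Trajectory,
    event: PermeationEvent,
    pad_frames: int = 0,
    regions: RegionSet | None = None,
    z_offsets: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(times ns, unwrapped z Å, position labels) over the padded event span.

    Padding is truncated (with a log message) at the trajectory ends.
    """
    n = trajectory.n_frames
    if not (0 <= event.start_frame < event.end_frame < n):
        raise ValueError("event frames outside trajectory")
    lo = event.start_frame - pad_frames
    hi = event.end_frame + pad_frames
    if lo < 0 or hi > n - 1:
        logger.info("padding truncated at trajectory ends for water %d", event.water_id)
        lo, hi = max(0, lo), min(n - 1, hi)
    sel = AtomSelection([event.water_id])
    z = unwrap_selection_z(trajectory, sel)[:, 0]
    if z_offsets is not None:
        z = z - np.asarray(z_offsets, dtype=float)
    times = trajectory.times[lo : hi + 1]
    zs = z[lo : hi + 1]
    rs = regions or RegionSet(
        AxialRegion("bulk", -1e9, -10.0), AxialRegion("pocket", 5.0, 1e9),
        tuple(default_positions()),
    )
    labels = [classify_position(float(v), rs) for v in zs]
    return times, zs, labels


def classify_pathway(
    event: PermeationEvent,
    trajectory: Trajectory,
    pathway_gates: list[tuple[str, AxialRegion]],
) -> str:
    """Label the gate capturing the majority of the event's in-membrane frames.

    Gates are lateral capture volumes spanning the membrane (an axial region
    with a lateral (x, y, radius) constraint). Frames inside the membrane span
    (the union of gate z-ranges) vote for the gate containing them; a gate
    wins with > 50% of those frames, otherwise the event is ``unassigned``.
    """
    if not pathway_gates:
        return "unassigned"
    idx = np.arange(event.start_frame, event.end_frame + 1)
    xyz = np.array(
        [trajectory.frames[i].coordinates[event.water_id] for i in idx]
    )
    z_lo = min(r.z_min for _, r in pathway_gates)
    z_hi = max(r.z_max for _, r in pathway_gates)
    in_membrane = (xyz[:, 2] >= z_lo) & (xyz[:, 2] < z_hi)
    total = int(in_membrane.sum())
    if total == 0:
        return "unassigned"
    best_label, best_frac = "unassigned", 0.0
    for label, region in pathway_gates:
        frac = float(region.contains_point(xyz[in_membrane]).sum()) / total
        if frac > best_frac:
            best_label, best_frac = label, frac
    return best_label if best_frac > 0.5 else "unassigned"
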