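"""Synthetic membrane-pore water trajectories with ground-truth transit logs.

The generator emulates the situation the analysis pipeline is built for: a
cytoplasmic water reservoir connected to a small internal pocket through a
narrow channel whose radius profile has an hourglass entrance and two
constrictions, with optional deep hydration-site traps between the
constrictions, and a blocked variant in which an impassable wall severs the
channel (the inactive, closed-pore analogue).

Water oxygens follow overdamped Brownian dynamics::

    x(t+dt) = x(t) + (D/kT) F dt + sqrt(2 D dt) ξ,   ξ ~ N(0, 1) per axis

with energies in kT units, hard reflection off the channel/reservoir walls,
and Gaussian attractive wells for the traps. Waters do not interact with each
other. Because the generator integrates its own dynamics, it knows every
committed reservoir↔pocket transit exactly; that log is the oracle against
which the permeation detector is tested.

Geometry convention (membrane-centred z, matching the analysis modules): the
bulk reservoir lies *below* ``channel_z_range[0]`` and the pocket *above*
``channel_z_range[1]``, so "inward" permeation moves toward positive z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

from .model import AtomRecord, Frame, Role, Topology, Trajectory

__all__ = [
    "PoreSpec",
    "TransitEvent",
    "SiteVisit",
    "GroundTruthLog",
    "generate_pore_trajectory",
    "generate_membrane_slab",
    "meta2_like_spec",
    "dark_like_spec",
    "detector_benchmark_spec",
    "two_trap_spec",
    "write_ground_truth",
    "read_ground_truth",
]

WALL_VDW = 1.5  # Å, radius of wall pseudo-atoms; rings sit at R(z) + WALL_VDW


@dataclass(frozen=True)
class PoreSpec:
    """Full description of one synthetic pore system and its run."""

    reservoir_half_height: float = 10.0  # Å; reservoir spans 2x this below the channel
    reservoir_radius: float = 15.0  # Å
    channel_z_range: tuple[float, float] = (-10.0, 5.0)  # Å
    radius_profile: tuple[tuple[float, float], ...] = (
        (-10.0, 5.0),  # hourglass mouth
        (-7.5, 1.5),   # first constriction
        (-5.0, 3.0),   # cavity holding the lower hydration site
        (-3.2, 1.5),   # second constriction
        (-1.0, 3.0),
        (5.0, 4.0),
    )
    constriction_centers: tuple[float, ...] = (-7.5, -3.2)
    trap_sites: tuple[tuple[float, float], ...] = ((-5.0, 8.0), (-2.5, 8.0))  # (z Å, depth kT)
    trap_width: float = 1.0  # Å, Gaussian well width
    n_waters: int = 200
    diffusion_coefficient: float = 0.23  # Å²/ps (bulk water at ~310 K)
    dt: float = 0.1  # ps
    n_steps: int = 100_000
    save_stride: int = 100  # saved-frame interval 10 ps at the default dt
    seed: int = 0
    blocked: bool = False
    # geometry of the internal pocket (not part of the channel profile)
    pocket_radius: float = 6.0
    pocket_height: float = 8.0
    # fraction of waters initially placed in the reservoir; the rest go to the
    # channel/pocket (plus one water seeded per trap site)
    reservoir_fraction: float = 0.8
    include_walls: bool = True
    # half-thickness (Å) of the impassable slab around the zero-radius point
    # of a blocked channel; a closed gate has finite thickness, and a slab
    # thinner than the analysis voxel size would be invisible to occupancy
    # connectivity
    plug_half_width: float = 1.5

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.n_waters < 1:
            raise ValueError("n_waters must be >= 1")
        radii = [r for _, r in self.radius_profile]
        if self.blocked:
            if min(radii) > 0:
                raise ValueError("blocked spec needs a zero-radius control point")
        elif min(radii) <= 0:
            raise ValueError("radius_profile radii must be > 0 unless blocked")
        for z, depth in self.trap_sites:
            if depth > 25.0:
                raise ValueError(
                    f"trap at z={z} Å is {depth} kT deep; depths > 25 kT give "
                    "numerically meaningless residence times"
                )

    # ---- derived geometry -------------------------------------------------
    @property
    def z_lo(self) -> float:
        return self.channel_z_range[0]

    @property
    def z_hi(self) -> float:
        return self.channel_z_range[1]

    @property
    def reservoir_bottom(self) -> float:
        return self.z_lo - 2.0 * self.reservoir_half_height

    @property
    def pocket_top(self) -> float:
        return self.z_hi + self.pocket_height

    @property
    def box(self) -> np.ndarray:
        L = 2.0 * (self.reservoir_radius + WALL_VDW + 3.0)
        Lz = (self.pocket_top - self.reservoir_bottom) + 2.0 * (WALL_VDW + 3.0)
        return np.array([L, L, Lz])

    @property
    def blocked_z(self) -> float | None:
        for z, r in self.radius_profile:
            if r <= 0:
                return z
        return None

    def radius_at(self, z) -> np.ndarray:
        """Accessible (water-centre) radius as a function of z."""
        z = np.asarray(z, dtype=float)
        zs = np.array([p[0] for p in self.radius_profile])
        rs = np.array([p[1] for p in self.radius_profile])
        r = np.interp(z, zs, rs)
        r = np.where(z < self.z_lo, self.reservoir_radius, r)
        r = np.where(z >= self.z_hi, self.pocket_radius, r)
        return r


class TransitEvent(NamedTuple):
    water_id: int          # atom index of the water oxygen
    direction: str         # "in" (reservoir→pocket) or "out"
    start_step: int        # last step the water occupied the origin region
    end_step: int          # step at which the transit commits


class SiteVisit(NamedTuple):
    water_id: int
    site_index: int
    entry_step: int
    exit_step: int


@dataclass
class GroundTruthLog:
    """Events and site visits recorded by the generator itself."""

    events: list[TransitEvent] = field(default_factory=list)
    site_visits: list[SiteVisit] = field(default_factory=list)
    save_stride: int = 1

    def count(self, direction: str | None = None) -> int:
        if direction is None:
            return len(self.events)
        return sum(1 for e in self.events if e.direction == direction)


# ---------------------------------------------------------------------------
# wall-atom placement
# ---------------------------------------------------------------------------

def _ring(x0: float, y0: float, z: float, radius: float, arc: float = 1.0) -> np.ndarray:
    n = max(8, int(math.ceil(2 * math.pi * max(radius, 1.0) / arc)))
    ang = 2 * math.pi * np.arange(n) / n
    return np.column_stack(
        [x0 + radius * np.cos(ang), y0 + radius * np.sin(ang), np.full(n, z)]
    )


def _disk(z: float, r_outer: float, r_inner: float = 0.0, spacing: float = 2.0) -> np.ndarray:
    g = np.arange(-r_outer, r_outer + spacing / 2, spacing)
    X, Y = np.meshgrid(g, g)
    rho = np.hypot(X, Y)
    m = (rho <= r_outer) & (rho >= r_inner)
    return np.column_stack([X[m], Y[m], np.full(m.sum(), z)])


def build_wall_atoms(spec: PoreSpec, ring_spacing: float = 0.25) -> np.ndarray:
    """Static wall-atom positions tracing the accessible surface.

    Channel rings are spaced 0.25 Å in z (4 rings per Å) at radial distance
    ``R(z) + WALL_VDW`` so the accessible radius seen by a profile scan equals
    the PoreSpec radius profile to within the ring discretisation (< 0.2 Å).
    """
    pieces: list[np.ndarray] = []
    rv = WALL_VDW
    # channel surface
    zs = np.arange(spec.z_lo, spec.z_hi + ring_spacing / 2, ring_spacing)
    for z in zs:
        r = float(spec.radius_at(np.clip(z, spec.z_lo, spec.z_hi - 1e-9)))
        if r <= 0:  # blocked point: plug handled below
            continue
        pieces.append(_ring(0.0, 0.0, z, r + rv))
    if spec.blocked_z is not None:
        zb = spec.blocked_z
        near = spec.radius_at(np.array([zb - 1.0, zb + 1.0]))
        pieces.append(_disk(zb, float(near.max()) + rv, spacing=0.7))
    # reservoir: side wall, floor, ceiling annulus around the channel mouth
    for z in np.arange(spec.reservoir_bottom, spec.z_lo + 0.5, 1.0):
        pieces.append(_ring(0.0, 0.0, z, spec.reservoir_radius + rv))
    pieces.append(_disk(spec.reservoir_bottom - rv, spec.reservoir_radius))
    mouth = float(np.interp(spec.z_lo, [p[0] for p in spec.radius_profile],
                            [p[1] for p in spec.radius_profile]))
    pieces.append(_disk(spec.z_lo - 1e-3 + rv, spec.reservoir_radius, r_inner=mouth + rv))
    # pocket: side wall and ceiling
    for z in np.arange(spec.z_hi, spec.pocket_top + 0.5, 1.0):
        pieces.append(_ring(0.0, 0.0, z, spec.pocket_radius + rv))
    pieces.append(_disk(spec.pocket_top + rv, spec.pocket_radius))
    return np.vstack(pieces)


def _build_topology(spec: PoreSpec, wall_xyz: np.ndarray | None) -> Topology:
    records: list[AtomRecord] = []
    i = 0
    for w in range(spec.n_waters):
        records.append(
            AtomRecord(i, "O", "O", "HOH", w + 1, "W", 1.52, Role.WATER_OXYGEN)
        )
        i += 1
    if wall_xyz is not None:
        for j in range(len(wall_xyz)):
            records.append(
                AtomRecord(
                    i, "WA", "X", "WAL", 1 + j // 100, "X", WALL_VDW, Role.WALL
                )
            )
            i += 1
    return Topology(records)


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def _initial_positions(spec: PoreSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_waters
    pos = np.empty((n, 3))
    n_trap = min(len(spec.trap_sites), n)
    n_res = min(n - n_trap, int(round(spec.reservoir_fraction * n)))
    n_rest = n - n_trap - n_res

    k = 0
    for (zt, _), _i in zip(spec.trap_sites, range(n_trap)):
        pos[k] = (0.0, 0.0, zt)
        k += 1
    # reservoir: uniform in the cylinder
    z = rng.uniform(spec.reservoir_bottom, spec.z_lo, n_res)
    rho = (spec.reservoir_radius - 0.5) * np.sqrt(rng.uniform(0, 1, n_res))
    ang = rng.uniform(0, 2 * math.pi, n_res)
    pos[k : k + n_res] = np.column_stack([rho * np.cos(ang), rho * np.sin(ang), z])
    k += n_res
    # remainder: channel + pocket, proportional to their volumes
    zs = np.linspace(spec.z_lo, spec.z_hi, 64)
    v_channel = 0.0 if spec.blocked else float(
        np.trapezoid(np.pi * spec.radius_at(zs) ** 2, zs)
    )
    v_pocket = math.pi * spec.pocket_radius**2 * spec.pocket_height
    for i in range(n_rest):
        if rng.uniform() < v_channel / (v_channel + v_pocket):
            zz = rng.uniform(spec.z_lo, spec.z_hi)
            rmax = max(float(spec.radius_at(zz)) - 0.2, 0.05)
        else:
            zz = rng.uniform(spec.z_hi, spec.pocket_top)
            rmax = spec.pocket_radius - 0.5
        rr = rmax * math.sqrt(rng.uniform())
        aa = rng.uniform(0, 2 * math.pi)
        pos[k + i] = (rr * math.cos(aa), rr * math.sin(aa), zz)
    return pos


def generate_pore_trajectory(spec: PoreSpec) -> tuple[Trajectory, GroundTruthLog]:
    """Run the Brownian-dynamics generator.

    Returns the saved trajectory (waters first, wall atoms after when
    ``spec.include_walls``) and the step-resolution ground-truth log of
    committed reservoir↔pocket transits and trap-site visits. Deterministic
    given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_waters
    D, dt = spec.diffusion_coefficient, spec.dt
    noise_sd = math.sqrt(2.0 * D * dt)
    z_lo, z_hi = spec.z_lo, spec.z_hi
    zbot, ztop = spec.reservoir_bottom, spec.pocket_top
    zb = spec.blocked_z
    sigma2 = spec.trap_width**2
    trap_centers = np.array([[0.0, 0.0, z] for z, _ in spec.trap_sites])
    trap_depths = np.array([d for _, d in spec.trap_sites])
    capture2 = 1.0  # Å², trap-visit logging radius

    pos = _initial_positions(spec, rng)

    n_saved = spec.n_steps // spec.save_stride + 1
    saved = np.empty((n_saved, n, 3))
    saved[0] = pos
    saved_times = np.empty(n_saved)
    saved_times[0] = 0.0

    # ground-truth machinery (step resolution)
    side = np.full(n, -1, dtype=np.int8)  # -1 unknown/transit, 0 bulk, 1 pocket
    code0 = np.where(pos[:, 2] < z_lo, 0, np.where(pos[:, 2] >= z_hi, 1, -1)).astype(np.int8)
    side[code0 >= 0] = code0[code0 >= 0]
    last_side_step = np.zeros(n, dtype=np.int64)
    events: list[TransitEvent] = []
    in_site = np.zeros((len(trap_centers), n), dtype=bool)
    site_entry = np.zeros((len(trap_centers), n), dtype=np.int64)
    visits: list[SiteVisit] = []

    def _update_sites(p: np.ndarray, step: int) -> None:
        for t in range(len(trap_centers)):
            d2 = np.einsum("ij,ij->i", p - trap_centers[t], p - trap_centers[t])
            now = d2 < capture2
            entered = now & ~in_site[t]
            left = ~now & in_site[t]
            site_entry[t, entered] = step
            for w in np.flatnonzero(left):
                visits.append(SiteVisit(int(w), t, int(site_entry[t, w]), step))
            in_site[t] = now

    if len(trap_centers):
        _update_sites(pos, 0)

    isave = 1
    for step in range(1, spec.n_steps + 1):
        # drift from trap wells + diffusion
        drift = np.zeros_like(pos)
        for t in range(len(trap_centers)):
            d = pos - trap_centers[t]
            r2 = np.einsum("ij,ij->i", d, d)
            w = (trap_depths[t] / sigma2) * np.exp(-r2 / (2.0 * sigma2))
            drift -= (D * dt) * w[:, None] * d
        new = pos + drift + noise_sd * rng.standard_normal((n, 3))

        # hard walls: outer z, blocked plane, radial
        zc = new[:, 2]
        zc = np.where(zc < zbot, 2 * zbot - zc, zc)
        zc = np.where(zc > ztop, 2 * ztop - zc, zc)
        if zb is not None:
            lo_plane, hi_plane = zb - spec.plug_half_width, zb + spec.plug_half_width
            from_below = (pos[:, 2] <= lo_plane) & (zc > lo_plane)
            from_above = (pos[:, 2] >= hi_plane) & (zc < hi_plane)
            zc = np.where(from_below, 2 * lo_plane - zc, zc)
            zc = np.where(from_above, 2 * hi_plane - zc, zc)
        new[:, 2] = zc
        R = spec.radius_at(new[:, 2])
        rho = np.hypot(new[:, 0], new[:, 1])
        bad = rho > R
        if bad.any():
            rho_ref = 2 * R - rho
            ok = bad & (rho_ref >= 0) & (rho_ref <= R) & (rho > 1e-12)
            scale = rho_ref / np.maximum(rho, 1e-12)
            new[ok, 0] *= scale[ok]
            new[ok, 1] *= scale[ok]
        # final check: anything still outside the walls (or inside the plug
        # slab) reverts to its previous, valid position — at the channel
        # mouths this acts as a rejecting wall
        rem = np.hypot(new[:, 0], new[:, 1]) > spec.radius_at(new[:, 2]) + 1e-9
        if zb is not None:
            rem |= (new[:, 2] > zb - spec.plug_half_width) & (
                new[:, 2] < zb + spec.plug_half_width
            )
        if rem.any():
            new[rem] = pos[rem]
        pos = new

        # ground truth update
        z = pos[:, 2]
        code = np.where(z < z_lo, 0, np.where(z >= z_hi, 1, -1)).astype(np.int8)
        onside = code >= 0
        commit = onside & (side >= 0) & (code != side)
        for w in np.flatnonzero(commit):
            events.append(
                TransitEvent(
                    int(w),
                    "in" if code[w] == 1 else "out",
                    int(last_side_step[w]),
                    step,
                )
            )
        side[onside] = code[onside]
        last_side_step[onside] = step
        if len(trap_centers):
            _update_sites(pos, step)

        if step % spec.save_stride == 0:
            saved[isave] = pos
            saved_times[isave] = step * dt
            isave += 1

    # close out open site visits at the final step
    for t in range(len(trap_centers)):
        for w in np.flatnonzero(in_site[t]):
            visits.append(SiteVisit(int(w), t, int(site_entry[t, w]), spec.n_steps))

    wall_xyz = build_wall_atoms(spec) if spec.include_walls else None
    topo = _build_topology(spec, wall_xyz)
    box = spec.box
    frames = []
    for i in range(isave):
        coords = saved[i] if wall_xyz is None else np.vstack([saved[i], wall_xyz])
        frames.append(Frame(coords, box, time=saved_times[i] / 1000.0))  # ps → ns
    traj = Trajectory(topo, frames)
    log = GroundTruthLog(events=events, site_visits=visits, save_stride=spec.save_stride)
    return traj, log


# ---------------------------------------------------------------------------
# membrane slab fixture
# ---------------------------------------------------------------------------

def generate_membrane_slab(
    n_markers: int,
    z_top: float,
    z_bottom: float,
    jitter_sd: float,
    n_frames: int,
    box=(80.0, 80.0, 116.0),
    seed: int = 0,
) -> Trajectory:
    """Two planes of phosphorus-like markers with Gaussian z-jitter per frame.

    Top-leaflet markers have atom name ``PT``, bottom ``PB``, so leaflets can
    be selected by atom name.
    """
    if not z_top > z_bottom:
        raise ValueError("z_top must be > z_bottom")
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    records = []
    for i in range(2 * n_markers):
        top = i < n_markers
        records.append(
            AtomRecord(
                i, "PT" if top else "PB", "P", "LIP", i + 1, "T" if top else "B",
                1.80, Role.LIPID_PHOSPHORUS,
            )
        )
    topo = Topology(records)
    xy = rng.uniform(0, box[0], size=(2 * n_markers, 2))
    base_z = np.concatenate([np.full(n_markers, z_top), np.full(n_markers, z_bottom)])
    frames = []
    for f in range(n_frames):
        z = base_z + (jitter_sd * rng.standard_normal(2 * n_markers) if jitter_sd > 0 else 0.0)
        coords = np.column_stack([xy[:, 0], xy[:, 1], z])
        frames.append(Frame(coords, box, time=f * 0.01))
    return Trajectory(topo, frames)


# ---------------------------------------------------------------------------
# canonical specs
# ---------------------------------------------------------------------------

def meta2_like_spec(seed: int = 0, **overrides) -> PoreSpec:
    """Open-pore system: hourglass entrance, two constrictions, two trap sites."""
    return replace(PoreSpec(seed=seed), **overrides) if overrides else PoreSpec(seed=seed)


def dark_like_spec(seed: int = 0, **overrides) -> PoreSpec:
    """Blocked-pore system: zero-radius wall at the first constriction."""
    base = PoreSpec(
        seed=seed,
        blocked=True,
        radius_profile=(
            (-10.0, 5.0),
            (-7.5, 0.0),
            (-5.0, 3.0),
            (-3.2, 1.5),
            (-1.0, 3.0),
            (5.0, 4.0),
        ),
        trap_sites=(),
    )
    return replace(base, **overrides) if overrides else base


def detector_benchmark_spec(seed: int = 0, n_steps: int = 100_000, **overrides) -> PoreSpec:
    """Open pore without traps, sized so many transits occur per run.

    Used for detector-vs-ground-truth equivalence: no wells, a wider (2.2 Å)
    constriction, a 0.5 ps step and stride-1 saving so the detector sees every
    integration step.
    """
    base = PoreSpec(
        seed=seed,
        radius_profile=(
            (-10.0, 5.0),
            (-7.5, 2.2),
            (-5.0, 3.5),
            (-3.2, 2.2),
            (-1.0, 3.5),
            (5.0, 4.0),
        ),
        trap_sites=(),
        dt=0.5,
        n_steps=n_steps,
        save_stride=1,
        include_walls=False,
        reservoir_fraction=0.6,
    )
    return replace(base, **overrides) if overrides else base


def two_trap_spec(seed: int = 0, **overrides) -> PoreSpec:
    """Deep, narrow wells at z = −5 and −2.5 Å for hydration-site recovery.

    18 kT deep, 0.4 Å wide: the equilibrium spread in the well core is
    σ/sqrt(depth) ≈ 0.09 Å and the core Boltzmann weight dwarfs the
    surrounding cavity volume, so the occupied voxel of a 0.5 Å grid aligned
    with the trap coordinates is visited in essentially every frame. The fine
    0.0015 ps step keeps the overdamped integration stable in the stiff wells.
    """
    base = PoreSpec(
        seed=seed,
        trap_sites=((-5.0, 18.0), (-2.5, 18.0)),
        trap_width=0.4,
        dt=0.0015,
        n_steps=200_000,
        save_stride=10,
        include_walls=False,
        # one water is seeded per site; keeping the rest in the reservoir
        # emulates singly-occupied hydration sites, which the generator's
        # non-interacting waters cannot enforce by excluded volume
        reservoir_fraction=1.0,
    )
    return replace(base, **overrides) if overrides else base


# ---------------------------------------------------------------------------
# ground-truth text I/O (one event per line)
# ---------------------------------------------------------------------------

def write_ground_truth(path, log: GroundTruthLog) -> None:
    with open(path, "w") as fh:
        fh.write("# kind\twater_id\tlabel\tstart_step\tend_step\n")
        fh.write(f"# save_stride={log.save_stride}\n")
        for e in log.events:
            fh.write(f"event\t{e.water_id}\t{e.direction}\t{e.start_step}\t{e.end_step}\n")
        for v in log.site_visits:
            fh.write(f"site\t{v.water_id}\t{v.site_index}\t{v.entry_step}\t{v.exit_step}\n")


def read_ground_truth(path) -> GroundTruthLog:
    log = GroundTruthLog()
    with open(path) as fh:
        for line in fh:
            if line.startswith("# save_stride="):
                log.save_stride = int(line.split("=", 1)[1])
            if line.startswith("#") or not line.strip():
                continue
            kind, a, b, c, d = line.split("\t")
            if kind == "event":
                log.events.append(TransitEvent(int(a), b, int(c), int(d)))
            else:
                log.site_visits.append(SiteVisit(int(a), int(b), int(c), int(d)))
    return log
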