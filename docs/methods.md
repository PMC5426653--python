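# Methods

`poreflux` analyses trajectories of a membrane protein–water system for the
signatures of a cytoplasmic water channel ("solvent pore"): where water has
been, whether the visited volume connects the bulk to the internal pocket,
how narrow the channel is, how often waters complete bulk↔pocket transits,
which hydration sites are stably occupied, and who hydrogen-bonds to them.
Because the μs-scale all-atom MD trajectories that motivate these analyses
are far beyond desk scale (and rarely deposited), the package ships a
Brownian-dynamics pore generator that produces trajectories with *known*
ground truth; every analysis stage is validated against that oracle.

## Coordinate and unit conventions

* Lengths in Å, times in ns (readers convert; the generator integrates in ps).
* `z` is the membrane normal with `z = 0` at the membrane centre. For real
  data `poreflux.pbc.axial_offsets` recentres each frame on the mean z of a
  membrane selection; synthetic data is generated in centred coordinates.
* Axial regions are half-open, `z_min ≤ z < z_max`, so adjacent regions tile
  the axis and a boundary value belongs to the higher-z region. The default
  intermediate positions are position 1 `[−10, −5)`, position 2 `[−5, 0)` and
  position 3 `[0, 5)` Å, with `bulk-side` below −10 Å and `beyond` at ≥ 5 Å.
* Residue tokens are one-letter code + file residue number (`L128`, `Y306`);
  numbering is taken verbatim from the input file.
* van-der-Waals radii come from the bundled Bondi (1964) element table;
  unknown elements fall back to 1.5 Å with a logged warning, and the table
  name is recorded in every run manifest.

## Permeation events

A permeation event is a *committed* transit: per water, a three-state machine
(in bulk / in transit / in pocket) commits an event at the first frame the
water enters the far region after last occupying the near region; returning
to the origin region first aborts the attempt. The event span runs from the
last origin-region frame to the commitment frame; "inward" is bulk → pocket.
z-series are unwrapped across periodic images before classification
(frame-to-frame jumps larger than half the box are folded back). The pocket
may be given as an axial region (synthetic data) or built as a 7 Å capture
cylinder around an anchor residue's centroid (`anchored_pocket_region`),
reusing the census cutoff.

Consequences of the definition worth knowing:

* events per water alternate in direction, so |inward − outward| ≤ 1 per
  water and the net flux of an equilibrium run is statistically zero;
* reversing the frame order maps inward events one-to-one onto outward ones;
* subsampling frames can only merge or drop events (missed fast
  recrossings), never create them — the detected count at stride k is ≤ the
  stride-1 count.

## Occupancy, connectivity, hydration sites

Occupancy grids voxelise water-oxygen positions (default 1 Å spacing);
positions outside the grid go to an overflow tally so the sum rule
`counts.sum() + overflow = n_frames × n_waters` holds exactly. The
accessibility surface is the mask of voxels visited at least `min_visits`
times (default 1 — "anywhere water reached"). Pore existence is decided by
flood-filling that mask (face/6-neighbour connectivity by default, stricter
than 26-neighbour and free of corner-touching artifacts at 1 Å spacing) and
asking whether one component holds voxels in both the bulk and the pocket
region.

Hydration sites are face-connected clusters of voxels whose visit fraction
is ≥ 0.5 (configurable); each cluster is summarised by its count-weighted
mean position and an occupancy fraction defined as the cluster's *peak voxel*
count over `n_frames`. Two caveats follow directly from that definition:
the peak-voxel fraction depends on how the grid aligns with the density peak
(analyses of known site positions should align voxel centres with them, as
the bundled fixtures do), and it can exceed 1 when several waters occupy the
voxel in the same frame — values near or above 1 mean "always occupied".
Per-site hydrogen-bond tables tally, over the frames in which a water sits
within 1.5 Å of the site, the partners the site water binds and whether the
water acts as donor or acceptor, normalised by occupied-frame count.

## Pore-radius profile

A fixed-axis variant of the HOLE procedure: at each z-bin centre the radius
is the largest probe sphere centred on the (x, y) axis that touches no
obstacle atom in the slab — min over atoms within one bin width in z of
(distance − vdW radius), clamped at 0. Mean and SD are taken over frames;
slabs with no atoms report a configured cap radius and are flagged rather
than silently interpolated. Per-slice centre optimisation (full HOLE) is
deliberately out of scope: with a user-supplied axis the profile is
deterministic, cheap, and adequate for a roughly straight channel; a strongly
kinked channel would need the full algorithm and its bottleneck radii can be
underestimated by a fixed axis.

## Superposition, RMSD, distances, membrane

Superposition is the least-squares optimal rigid transform (Kabsch with
reflection correction, via SciPy's `Rotation.align_vectors`), no mass
weighting; RMSD is evaluated after applying the fit. Correctness is checked
against an independent quaternion-search minimiser in the tests. Nearest-atom
residue-pair distances are the per-frame minimum over all atom pairs; the
number of modes of their histogram is counted on a kernel-smoothed histogram
(Gaussian, bandwidth 2 bins, maxima below 5% of the global peak ignored) — a
reproducible surrogate for the by-eye unimodality judgement. Membrane metrics
are the box area Lx·Ly and the difference of mean phosphorus z between
leaflets.

## The synthetic generator

Water oxygens follow overdamped Brownian dynamics,
`dx = D F dt + sqrt(2 D dt) ξ` with energies in kT, `D = 0.23 Å²/ps` (bulk
water near 310 K), inside a rigid geometry: a cytoplasmic reservoir cylinder
below the channel, a channel whose radius profile is linearly interpolated
between control points (hourglass mouth, two ~1.5 Å constrictions, cavities
between them), and a small internal pocket above. Trap sites are isotropic
Gaussian wells (depth in kT, width σ); depths above 25 kT are rejected as
numerically meaningless. Walls act by radial reflection with a
reject-and-stay fallback at the channel mouths; the blocked (closed-pore)
variant adds an impassable slab of half-width 1.5 Å at the zero-radius
control point — finite thickness, because a zero-width wall would be
invisible to voxel-grid connectivity. Wall pseudo-atoms (rings every 0.25 Å
at radial distance R(z) + 1.5 Å, vdW 1.5 Å) are placed on the accessible
surface so the radius profiler and the accessibility map run on the same
fixture; runs that only need water positions can omit them
(`include_walls=False`), which keeps stride-1 trajectories in memory.

The generator logs every committed reservoir↔pocket transit at integration-
step resolution with the same commitment rule the detector uses, plus
entry/exit intervals for each trap site. At stride-1 saving the detector
must therefore reproduce the log exactly — the two implementations are
independent code paths over the same definition.

What the generator does *not* emulate: water–water interactions (no excluded
volume, so several waters can share a trap), hydrogen-bond dynamics
(hydrogens are placed rigidly only in constructed h-bond fixtures), lipids,
electrostatics, and conformational gating. Passing tests therefore establish
the correctness of the *analysis* operations, not the realism of any
particular force field.

### Fixture parameter choices

* **Canonical open pore** (defaults): channel z ∈ (−10, 5) Å matching the
  region between the pore entrance and the pocket; constrictions at −7.5 and
  −3.2 Å; traps (8 kT, σ = 1 Å) at −5 and −2.5 Å where the two stable
  hydration sites sit; 200 waters; dt = 0.1 ps; 10⁵ steps; saved every 10 ps.
* **Detector benchmark**: no traps, 2.2 Å constrictions, dt = 0.5 ps,
  stride 1 — sized so a 10⁵-step run yields hundreds of committed transits,
  giving the exact-equality check real statistical power while staying near
  a minute of runtime on one core.
* **Two-trap site fixture**: 18 kT, σ = 0.4 Å wells at −5 and −2.5 Å with a
  0.0015 ps step (stability limit of the stiff wells). The equilibrium spread
  in a well core is σ/√depth ≈ 0.09 Å, so on a 0.5 Å grid aligned with the
  trap coordinates the peak voxel is occupied in ≳ 97% of frames; shallower
  or wider wells leak enough probability into the surrounding cavity to break
  the "always occupied" property the fixture is meant to exhibit.
* **Blocked (dark-state analogue)**: zero-radius control point at the first
  constriction, no traps.

## Numerical and design notes

* Event boundaries, census cutoff (≤, inclusive) and region membership use
  documented tie-breaks; all thresholds are configurable.
* H-bond criterion: donor–acceptor ≤ 3.5 Å and donor–H–acceptor ≥ 150°, the
  commonest geometric convention; donor hydrogens resolve through a bonding
  table (water + standard polar groups), never by distance-based perception.
* The census uses MDAnalysis minimum-image distances; tests compare it
  against an exhaustive 27-image brute-force count.
* Degenerate inputs error loudly: < 3 or collinear points for superposition,
  empty leaflets, empty analysis windows, truncated trajectory frames,
  regions outside the grid.
* Determinism: a single integer seed fixes the generator bit-for-bit, and a
  pipeline rerun with the same configuration + seed reproduces every tabular
  output byte-identically (manifests carry wall-clock timings and are
  excluded from that comparison).

## Problem sizes used in validation

Detector-equivalence runs use 5 seeds × 10⁵ steps × 200 waters at stride 1;
connectivity contrasts use 3×10⁴-step runs; the site fixture runs 2×10⁵
steps of 0.0015 ps. These sizes were chosen so each property is tested with
ample statistics while the whole suite remains a desk-scale computation.

## Known limitations

* The fixed-axis radius profile underestimates bottlenecks of strongly bent
  channels (see above).
* `classify_pathway` votes frame-by-frame with cylindrical gates; genuinely
  interleaved pathways (a water wandering between two gates) fall to
  `unassigned` by the > 50% majority rule.
* The XYZ trajectory convention (box + time on the comment line) is this
  package's own; DCD and PDB follow the standard formats.
* Hydration-site occupancy is a voxel statistic, not a first-passage or
  residence-time analysis; kinetic modelling of permeation is out of scope.
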