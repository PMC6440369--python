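# Methods

This note documents the models and numerical choices behind `laaoplan`, the
defaults a user may want to change, and what the synthetic-data tests do and
do not demonstrate.  All geometry is in millimetres; shear stresses in Pa;
times in seconds.

## Mesh model

A `SurfaceMesh` is a triangle mesh with one integer label per face
(`wall=0, ostium=1, pv_inlet=2, mv_outlet=3, device=4`); the code table is
embedded in every exported file.  Anatomical meshes may carry the ostium as
a triangulated membrane overlaid on the closed wall surface — the same way
segmentation-derived meshes carry a labeled ostium plane region.  The
`shell()` accessor returns the closed flow boundary: it drops the membrane
when the remaining surface is still edge-2-closed and keeps it when the cap
is structural (e.g. the proximal cap of a tube fixture).  Watertightness,
enclosed volume, voxelization and point-containment all operate on the
shell.  Non-watertight input: the planner and CFD export refuse; smoothing
proceeds with a warning.

File formats: STL/PLY via trimesh (geometry only; STL is read as a triangle
soup and re-welded); VTK legacy, VTP/VTU (ASCII XML) and MSH v2.2 are
written and parsed directly as small text subsets with labels as the
`label` cell array / physical tag.  Output uses fixed field order and
`%.9e` floats, so identical inputs give byte-identical files.

## Taubin smoothing

Uniform-umbrella Taubin smoothing with the classic anti-shrink pair
λ = 0.6, μ = −0.53 and 10 iterations by default.  Vertices incident to
non-wall faces (ostium ring, inlet/outlet rims) are held fixed by default
(`preserve_labeled`), so anatomical landmarks survive; the flag exists
because the right choice depends on how the labels were produced.  On a
noisy sphere the default pair reduces radial noise while changing enclosed
volume by only a few percent (measured by the acceptance script).

## Centreline

**Field.**  The LAA region (the half-space on the appendage side of the
ostium plane, intersected with the lumen) is voxelized at `pitch` (default
0.5 mm; 1 mm is adequate for ≥ 8 mm lumens and ~4× faster) and the steady
problem  ∇²u − σu = 0  is solved with u = 1 on ostium-plane voxels and
natural (insulated) walls.  A pure Laplace problem with one Dirichlet
boundary would be constant; the uniform sink σ makes the field decay with
depth.  σ is set so the solution spans ~3 orders of magnitude across the
region extent (decay length ≈ extent / 6.9), giving a well-conditioned
gradient everywhere.  On a full atrial mesh the distal half-space can also
clip parts of the atrial body; a `seed_point` inside the appendage selects
the right component (otherwise the component with the most ostium voxels is
used, and sizeable strays raise an error listing component sizes).

**Tracing.**  The marching start is the most interior voxel (largest
distance-to-boundary) of the *deep front* — the voxels within one decay
length of the field minimum.  The raw argmin itself is reported as the tip
voxel but is not used as the start: on a flat-capped or bent tube it sits
at a wall-hugging cap corner, and a line started there cuts the corner.
From the start point the tracer ascends the normalized gradient to the
ostium plane (the crossing is interpolated exactly onto the plane) and
descends it to the tip surface, with direction inertia (½ previous + ½
gradient) bridging the near-flat field across the tip cap.  After each step
the point is recentred at the barycentre of the voxel-connected isovalue
front through it — the level set of u is a transversal front whose
barycentre lies on the lumen axis even in bends, where a geometric plane
normal to the gradient tilts inward.  The recentring shift is projected
laterally (perpendicular to travel) and clamped to one step, which bounds
consecutive spacing at √2 × step ≤ 1.5 × step.  The polyline is finished
with two passes of endpoint-preserving (¼, ½, ¼) smoothing — a straight
line is a fixed point, so exact fixtures are unaffected.  The whole
procedure is deterministic.

Measured accuracy: on a 20 mm × 40 mm cylinder the line stays within
0.25 mm of the axis with length error < 2 %; on a quarter-torus (bend
radius 20 mm) the arc length is within ~3 %; on the blended marching-cubes
LA anatomy the length error is ~9 %, dominated by the funnel-shaped
ostium junction and the rounded tip cap, while mid-tube deviation is
≈ 0.3 mm.  Recovery tests on the implicit anatomy therefore use wider
tolerances than the analytic-fixture tests.

## Morphometry

Cross-sections are mesh/plane intersections chained into closed polygons
(CCW about the plane normal; components below 1e-9 mm² discarded); the
component enclosing the centreline point is kept, which makes slicing
lobe-safe.  Contours are resampled to ≤ 0.2 mm segments, then D1 is the
maximum Feret diameter and D2 the minimum Feret width.  Both are evaluated
on the convex hull — projection extents depend only on the hull, so this is
exact for the Feret definition while keeping cost low; brute-force pairwise
and directional-sweep oracles confirm it in the tests.  D1/D2 are measured
on the contour as-is (not a convexified lumen): device sizing concerns the
lumen boundary.  Area is the planar shoelace of the raw contour.

Ostium metrics come from the labeled patch: area as the triangle-area sum,
perimeter as the boundary-ring length, and principal axes as extreme-point
extents along the 2D PCA directions of the boundary ring (a pure-PCA
variant, 4√λ per axis, is available via `axes_method="pca"`).

A sensitivity harness (`station_sensitivity`) reports how D1 responds to
shifting the cutting plane by ±1 mm — on tapered anatomies small station
shifts change D1 by millimetres, which is why the landing-zone station is
fixed by rule rather than eyeballed.  The harness logs and returns the
spread; no bound is asserted.

## Devices

Both families are closed surfaces of revolution about +z with the proximal
face at z = 0 and axis pointing into the appendage.  Watchman-like: a
cylinder of the nominal diameter with an elliptic-profile distal cap,
depth = 0.8 × nominal.  Amulet-like: proximal disc (nominal + 6 mm for
sizes ≤ 22 mm, + 7 mm above; 2 mm thick), a 3 mm-radius waist across a
4 mm disc–lobe gap, and a shoulder-rounded lobe (10 mm long) of the nominal
diameter.  These proportions follow public product documentation; every
parameter is overridable per `DeviceSpec`, and the 4 mm gap in particular
is a package default, not a published value.  Devices are impermeable
closed walls — no fabric porosity, struts or anchors, and no deployment
mechanics.  Meshes are watertight genus-0 by construction; resolutions
coarser than nominal/8 are refused.  Default catalogs: watchman
{21, 24, 27, 30, 33} mm with the public D1 interval chart
(17–19.9 → 21, …, 29–31.9 → 33); amulet {16, 18, 20, 22, 25, 28, 31, 34} mm.
Both are YAML-overridable.

## Planner

"Orientation perpendicular to the centreline" is read as: the device's
transversal plane is perpendicular to the centreline, i.e. the device axis
is parallel to the centreline tangent.  The compression denominator is the
nominal size — compression = 100 × (nominal − mean(D1, D2)) / nominal —
and the landing diameter is mean(D1, D2), consistent with the sizing rule
using the same mean.  The modality offset is a range (2–5 mm CT, 3–6 mm
TEE); the range midpoint ranks candidates and the full range is echoed in
the sizing note, because a scalar is needed to rank but the range is the
actual rule.  Candidate sizes are chosen nearest-above the target (the
safe side); this is a package choice where the rule itself is silent.
When no catalog size achieves 10 % compression the planner returns an empty
list with a structured warning — the in-silico analogue of needing a
different device.

Scenarios: `smaller_20` scales the whole device (nominal and geometry) to
80 % without snapping back to the catalog, because it models the same
device shrunk, not a different catalog choice (snapping is available via a
flag).  `misplaced` defaults to +5 mm depth and 15° tilt about a
deterministic perpendicular — package defaults for "sub-optimal", both
configurable.  The `ostium_flush` override preset centres the device on
the ostium plane with its axis along the inward normal, modeling uniform
coverage of the LA/LAA junction.

Implantation produces the two-surface domain (atrium + posed device) with
interference diagnostics: the count of atrial faces with a vertex inside
the device.  Radial interference is expected under compression and is
reported, not forbidden; only a proximal face centred outside the lumen is
an error.  Point containment uses a fixed-direction ray-parity test
(Möller–Trumbore), deterministic and dependency-free.

CFD export writes a solver-agnostic bundle — labeled VTP surface plus a
YAML manifest (phases, blood constants, waveform, label table) — rather
than any proprietary solver case; the solve itself is explicitly out of
scope.

## Hemodynamic indices

TAWSS, OSI and ECAP use the standard definitions (see README) with
trapezoidal time integration on the solver's own sampling.  Nodes with
zero shear over the whole cycle get OSI = 0 and are flagged invalid for
ECAP (finite histograms beat infinities; the invalid count is reported).
Node areas are lumped as one third of incident face areas.  One cycle is
assumed; no multi-cycle averaging.

The ROI "between the ostium and the device" selects wall nodes on the
appendage side of the ostium plane whose nearest-point arc-length
projection onto the centreline lies in [0, device proximal station],
excluding device-surface nodes; without a device the ROI is the whole
distal appendage.  Histograms default to surface-area weighting (the
physically meaningful reading) with node-count weighting behind a flag —
both conventions appear in practice and they differ whenever node areas
are skewed.  Default bin edges (0, 0.5, 1, 2, 3, ∞) Pa⁻¹ keep 3 as an
edge so the high-risk "> 3" summary is a bin sum; the edges are a package
default, configurable.  The velocity probe sits on the reversed centreline
tangent 5 mm into the atrial body by default (the direction is principled,
the distance is a package default) and uses nearest-sample lookup.

The report writes per-scenario VTP surfaces (`TAWSS_Pa`, `OSI`,
`ECAP_invPa` point data), CSV histograms and probes, and a summary ranking
scenarios by % ROI area with ECAP > 3 Pa⁻¹ (lower is better).  Fixed
formatting makes regeneration byte-identical.

## Synthetic data

Two generator tiers serve different tolerances:

* **Parametric tubes** (`make_tube`, `make_cylinder_laa`,
  `make_elliptic_cylinder`) are exact surfaces with twist-minimizing
  frames, used wherever 1 % analytic tolerances apply.
* **Implicit-union anatomies** (`make_la_with_laa`, `make_two_lobe_laa`)
  take the signed-distance minimum of an ellipsoidal body
  (30 × 27 × 24 mm semi-axes), four 12 mm pulmonary-vein cylinders, one
  24 mm mitral cylinder and the LAA tube (default: 22 → 14 mm taper over
  40 mm, 40° bend, attached at 45°; optional neck and lobes), sampled at
  `pitch_mm` (default 1.2) and extracted with marching cubes.  Vessel end
  caps are labeled by proximity to the cap planes; the ostium membrane is
  triangulated from the slice at the junction plane, 3 mm clear of the
  body surface.  A ground-truth record (true spine, per-station diameters,
  ostium plane, an interior seed point) rides along.  Generation is
  seed-deterministic; optional surface noise is the only randomized
  element.

The closed-form shear generator composes per-node steady and oscillatory
amplitudes: unidirectional nodes (a ≥ c) have TAWSS = a, OSI = 0; fully
oscillatory nodes have TAWSS = 2c/π, OSI = ½, ECAP = π/(4c).  An odd
sample count keeps T/2 on the grid so the |sin| kink does not degrade the
trapezoidal O(Δt²) convergence.  The inlet waveform is two half-sines
phase-aligned with the 0.40 s / 0.65 s partition; its amplitude scale
(peak 0.4 m/s in `make_probe_flow`) is a generator default, since only
the sinusoidal shape and phase split are prescribed.

**What passing tests show — and don't.**  Synthetic anatomies are smooth,
single-ostium, convex-bodied idealizations: they exercise every algorithm
(bends, tapers, necks, lobes, label plumbing, index identities) but not
segmentation noise, trabeculated appendage walls, extreme morphologies
(chicken-wing kinks), or real CFD fields with spatial correlation.
Geometric tolerances met on analytic fixtures (sub-percent) degrade to
several percent on the blended implicit anatomy and should be expected to
degrade further on patient data.  The index engine, by contrast, is exact
up to time-integration error regardless of data origin.

## Problem sizes and tolerances

Default test and acceptance runs use: cylinder fixtures with 64 × 41
surface samplings (~2.6 k vertices), the implicit anatomy at 1.2 mm pitch
(~15 k vertices), heat solves at 1 mm pitch (~26 k voxels), device meshes
at 0.6–1 mm edge length, 33–4001 time samples per cycle, and 1000
random-field trials for the OSI bound — sizes chosen so the full suite and
the acceptance script each complete in about a minute on one CPU while
keeping every tolerance comfortably resolved.  Degenerate inputs are
handled explicitly: tangent slices are suppressed (area < 1e-9 mm²), the
profile's tip station is evaluated 1 µm inside the lumen, zero-shear nodes
are flagged rather than divided by, and flat field minima are tie-broken
deterministically.
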