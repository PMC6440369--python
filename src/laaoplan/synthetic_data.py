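"""Synthetic anatomies and closed-form flow fields.

Every pipeline stage is testable without patient data through two kinds of
generators:

* **Parametric tubes** (:func:`make_tube`, :func:`make_cylinder_laa`,
  :func:`make_elliptic_cylinder`) — exact surfaces of extrusion with a
  labeled ostium cap, used where analytic tolerances are tight (diameters,
  areas, centreline recovery).
* **Implicit-union anatomies** (:func:`make_la_with_laa`) — an ellipsoidal
  LA body, four pulmonary-vein inlet cylinders, one mitral-valve outlet
  cylinder and a tubular, optionally bent/tapered/multi-lobed LAA, unioned
  as a signed-distance minimum and extracted with marching cubes into a
  single watertight labeled surface.  A ground-truth record (true
  centreline, true per-station diameters) rides along for recovery tests.

Closed-form wall-shear series (:func:`make_wss_series`) carry their analytic
TAWSS/OSI/ECAP so the index engine can be checked end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .errors import LaaoError, TopologyError
from .geometry_core import FACE_LABELS, OstiumPlane, SurfaceMesh
from .hemodynamics import FlowSeries, WSSTimeSeries
from .planner import BoundaryConditionSpec


# ---------------------------------------------------------------------------
# parametric tube surfaces (exact)


def _transport_frames(spine: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Twist-minimizing (tangent, normal, binormal) frames along a polyline."""
    seg = np.diff(spine, axis=0)
    tangents = np.empty_like(spine)
    tangents[0], tangents[-1] = seg[0], seg[-1]
    if len(spine) > 2:
        tangents[1:-1] = spine[2:] - spine[:-2]
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    normals = np.empty_like(spine)
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(tangents[0])))] = 1.0
    n0 = np.cross(tangents[0], helper)
    normals[0] = n0 / np.linalg.norm(n0)
    for i in range(1, len(spine)):
        # parallel transport: rotate previous normal into the new tangent plane
        v = np.cross(tangents[i - 1], tangents[i])
        c = float(np.dot(tangents[i - 1], tangents[i]))
        if np.linalg.norm(v) < 1e-12:
            normals[i] = normals[i - 1]
        else:
            vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
            rot = np.eye(3) + vx + vx @ vx / (1.0 + c)
            normals[i] = rot @ normals[i - 1]
        normals[i] -= np.dot(normals[i], tangents[i]) * tangents[i]
        normals[i] /= np.linalg.norm(normals[i])
    binormals = np.cross(tangents, normals)
    return tangents, normals, binormals


def make_tube(
    spine: np.ndarray,
    radii: np.ndarray,
    n_theta: int = 64,
    cap_start_label: str = "ostium",
    radii_minor: np.ndarray | None = None,
) -> SurfaceMesh:
    """Closed tube around a spine polyline; both ends capped with fans.

    ``radii`` may vary per spine point (taper, neck); ``radii_minor`` makes
    the section elliptic (major axis along the transported normal).  The
    start cap's faces are labeled ``cap_start_label`` (the ostium by
    default); everything else is wall.  Watertight by construction.
    """
    spine = np.asarray(spine, dtype=float)
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (len(spine),))
    minor = (radii if radii_minor is None
             else np.broadcast_to(np.asarray(radii_minor, dtype=float),
                                  (len(spine),)))
    _, normals, binormals = _transport_frames(spine)
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    rings = (
        spine[:, None, :]
        + radii[:, None, None] * np.cos(theta)[None, :, None] * normals[:, None, :]
        + minor[:, None, None] * np.sin(theta)[None, :, None] * binormals[:, None, :]
    )  # (k, n_theta, 3)
    k = len(spine)
    verts = np.vstack([rings.reshape(-1, 3), spine[0][None], spine[-1][None]])
    c0, c1 = k * n_theta, k * n_theta + 1

    faces, labels = [], []
    lab_cap = FACE_LABELS[cap_start_label]
    for j in range(n_theta):
        jn = (j + 1) % n_theta
        faces.append([c0, jn, j])
        labels.append(lab_cap)
    for i in range(k - 1):
        a, b = i * n_theta, (i + 1) * n_theta
        for j in range(n_theta):
            jn = (j + 1) % n_theta
            faces.append([a + j, a + jn, b + jn])
            faces.append([a + j, b + jn, b + j])
            labels.extend([0, 0])
    last = (k - 1) * n_theta
    for j in range(n_theta):
        jn = (j + 1) % n_theta
        faces.append([c1, last + j, last + jn])
        labels.append(0)

    mesh = SurfaceMesh(verts, np.array(faces, dtype=np.int64),
                       np.array(labels, dtype=np.int64))
    if mesh.to_trimesh(shell_only=True).volume < 0:
        # flipping all faces preserves labels
        mesh.faces = mesh.faces[:, ::-1].copy()
    return mesh


def make_cylinder_laa(
    radius: float = 10.0,
    length: float = 40.0,
    n_theta: int = 64,
    n_axial: int = 41,
    axis=(0.0, 0.0, 1.0),
    origin=(0.0, 0.0, 0.0),
) -> tuple[SurfaceMesh, OstiumPlane]:
    """Straight circular-cylinder LAA with the ostium cap at the origin.

    The ostium plane normal points away from the tube (toward where the LA
    body would be), per the orientation convention.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    origin = np.asarray(origin, dtype=float)
    s = np.linspace(0.0, length, n_axial)
    spine = origin[None] + s[:, None] * axis[None]
    mesh = make_tube(spine, np.full(n_axial, radius), n_theta=n_theta)
    return mesh, OstiumPlane(origin=origin, normal=-axis)


def make_elliptic_cylinder(
    semi_major: float,
    semi_minor: float,
    length: float,
    n_theta: int = 96,
    n_axial: int = 21,
) -> tuple[SurfaceMesh, OstiumPlane]:
    """Elliptic cylinder along +z with the ostium cap at z = 0."""
    s = np.linspace(0.0, length, n_axial)
    spine = np.column_stack([np.zeros_like(s), np.zeros_like(s), s])
    mesh = make_tube(
        spine, np.full(n_axial, semi_major), n_theta=n_theta,
        radii_minor=np.full(n_axial, semi_minor),
    )
    return mesh, OstiumPlane(origin=(0.0, 0.0, 0.0), normal=(0.0, 0.0, -1.0))


# ---------------------------------------------------------------------------
# implicit-union LA + LAA anatomy


@dataclass
class LobeSpec:
    """A secondary LAA lobe branching off the main tube."""

    branch_station: float  # mm along the main tube from the ostium
    length: float  # mm
    diameter: float  # mm
    direction_deg: float = 55.0  # angle off the main tube direction


@dataclass
class SyntheticLAASpec:
    """Parameters of the synthetic LA + LAA anatomy.

    Defaults describe a mid-sized appendage: a 40 mm tube tapering from
    22 mm at the ostium to 14 mm at the tip, bent by 40 degrees, attached to
    the atrial body at 45 degrees — sized to the anatomies the planning
    rules address.  ``pitch_mm`` is the marching-cubes edge length; the seed
    fixes any randomized detail (currently surface noise, default off).
    """

    tube_length: float = 40.0
    proximal_diameter: float = 22.0
    distal_diameter: float = 14.0
    bend_angle_deg: float = 40.0
    attachment_angle_deg: float = 45.0
    lobes: tuple[LobeSpec, ...] = ()
    neck_station: float | None = None  # mm from the ostium
    neck_diameter: float | None = None
    pitch_mm: float = 1.2
    noise_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.proximal_diameter, self.distal_diameter) <= 0:
            raise ValueError("diameters must be positive")
        if self.neck_station is not None and not (
            0 < self.neck_station < self.tube_length
        ):
            raise ValueError("neck_station must lie within the tube length")
        for lobe in self.lobes:
            if not 0 < lobe.branch_station < self.tube_length:
                raise ValueError("lobe branch_station must lie within the tube")


@dataclass
class SyntheticAnatomy:
    """Generated anatomy plus its ground truth for recovery tests."""

    mesh: SurfaceMesh
    ostium: OstiumPlane
    spec: SyntheticLAASpec
    true_centreline_points: np.ndarray  # (k, 3), index 0 at the ostium plane
    true_arc_length: np.ndarray  # (k,)
    true_stations: np.ndarray  # (m,) mm
    true_d1: np.ndarray  # (m,) mm
    true_d2: np.ndarray  # (m,) mm
    laa_seed_point: np.ndarray = field(default=None)  # interior LAA point

    def truth_sidecar(self) -> dict:
        return {
            "tube_length_mm": self.spec.tube_length,
            "centreline_xyz_mm": self.true_centreline_points.tolist(),
            "arc_length_mm": self.true_arc_length.tolist(),
            "stations_mm": self.true_stations.tolist(),
            "d1_mm": self.true_d1.tolist(),
            "d2_mm": self.true_d2.tolist(),
            "ostium_origin_mm": self.ostium.origin.tolist(),
            "ostium_normal": self.ostium.normal.tolist(),
        }


# LA body semi-axes (mm) and attachment directions; fixed anatomy layout.
_BODY_SEMI_AXES = np.array([30.0, 27.0, 24.0])
_PV_DIRS = np.array(
    [[0.55, 0.70, 0.45], [0.62, 0.62, -0.48], [-0.60, 0.68, 0.42],
     [-0.64, 0.60, -0.46]]
)
_PV_RADIUS, _PV_LENGTH = 6.0, 16.0
_MV_DIR = np.array([0.0, -1.0, 0.0])
_MV_RADIUS, _MV_LENGTH = 12.0, 14.0
_LAA_ANCHOR_DIR = np.array([0.80, -0.25, 0.55])
_OSTIUM_OFFSET = 3.0  # mm from the body surface to the ostium plane


def _ellipsoid_surface_point(direction: np.ndarray) -> np.ndarray:
    d = direction / np.linalg.norm(direction)
    scale = 1.0 / np.sqrt(np.sum((d / _BODY_SEMI_AXES) ** 2))
    return scale * d


def _capsule_sdf(points: np.ndarray, a: np.ndarray, b: np.ndarray,
                 radius: float) -> np.ndarray:
    """Signed distance to a finite capped cylinder approximated as a capsule."""
    ab = b - a
    t = np.clip((points - a) @ ab / float(ab @ ab), 0.0, 1.0)
    foot = a[None] + t[:, None] * ab[None]
    return np.linalg.norm(points - foot, axis=1) - radius


def _cylinder_sdf(points: np.ndarray, a: np.ndarray, b: np.ndarray,
                  radius: float) -> np.ndarray:
    """Signed distance to a flat-capped finite cylinder."""
    ab = b - a
    L = float(np.linalg.norm(ab))
    w = ab / L
    h = (points - a) @ w
    radial = np.linalg.norm(points - a[None] - h[:, None] * w[None], axis=1)
    dr = radial - radius
    dh = np.maximum(-h, h - L)
    inside = np.maximum(dr, dh)
    out = np.hypot(np.maximum(dr, 0.0), np.maximum(dh, 0.0))
    return np.where((dr <= 0) & (dh <= 0), inside, out)


def _tube_sdf(points: np.ndarray, spine: np.ndarray,
              radii: np.ndarray) -> np.ndarray:
    """Distance to a varying-radius tube, via its dense spine sampling."""
    best = np.full(len(points), np.inf)
    for i in range(len(spine) - 1):
        a, b = spine[i], spine[i + 1]
        ab = b - a
        den = float(ab @ ab) or 1.0
        t = np.clip((points - a) @ ab / den, 0.0, 1.0)
        foot = a[None] + t[:, None] * ab[None]
        r = radii[i] + t * (radii[i + 1] - radii[i])
        best = np.minimum(best, np.linalg.norm(points - foot, axis=1) - r)
    return best


def _laa_spine_and_radii(spec: SyntheticLAASpec):
    """Dense spine (1 mm sampling) from inside the body to the tip.

    Returns (spine points, radii, sigma) where sigma is the arc coordinate
    with 0 at the ostium plane; the spine starts at sigma = -(offset + 4 mm)
    inside the atrial body so the implicit union blends smoothly.
    """
    anchor = _ellipsoid_surface_point(_LAA_ANCHOR_DIR)
    outward = anchor / np.linalg.norm(anchor)
    perp = np.cross(outward, [0.0, 0.0, 1.0])
    perp /= np.linalg.norm(perp)
    ang = np.deg2rad(spec.attachment_angle_deg)
    d0 = np.cos(ang) * outward + np.sin(ang) * perp
    d0 /= np.linalg.norm(d0)

    # the implicit tube ends in a rounded cap of the distal radius, so the
    # spine stops one end-radius short of tube_length; the cap apex then sits
    # exactly at geodesic tube_length from the ostium plane
    r_end = 0.5 * spec.distal_diameter
    start_inset = _OSTIUM_OFFSET + 4.0
    total = start_inset + spec.tube_length - r_end
    n = int(np.ceil(total)) + 1
    ds = total / (n - 1)
    bend_axis = np.cross(d0, perp)
    if np.linalg.norm(bend_axis) < 1e-9:
        bend_axis = np.array([0.0, 0.0, 1.0])
    bend_axis /= np.linalg.norm(bend_axis)

    pts = [anchor - start_inset * d0]
    sigma = [-start_inset]
    direction = d0.copy()
    bend_start, bend_span = 0.3 * spec.tube_length, 0.5 * spec.tube_length
    dtheta_total = np.deg2rad(spec.bend_angle_deg)
    for _ in range(n - 1):
        s_here = sigma[-1]
        if bend_start < s_here < bend_start + bend_span:
            dtheta = dtheta_total * ds / bend_span
            c, s_ = np.cos(dtheta), np.sin(dtheta)
            k = bend_axis
            direction = (
                direction * c + np.cross(k, direction) * s_
                + k * float(k @ direction) * (1 - c)
            )
            direction /= np.linalg.norm(direction)
        pts.append(pts[-1] + ds * direction)
        sigma.append(s_here + ds)
    spine = np.array(pts)
    sigma = np.array(sigma)

    r_prox, r_dist = 0.5 * spec.proximal_diameter, 0.5 * spec.distal_diameter
    frac = np.clip(sigma / spec.tube_length, 0.0, 1.0)
    radii = r_prox + frac * (r_dist - r_prox)
    if spec.neck_station is not None and spec.neck_diameter is not None:
        dip = radii - 0.5 * spec.neck_diameter
        width = 4.0  # mm gaussian neck width
        radii = radii - np.maximum(dip, 0.0) * np.exp(
            -0.5 * ((sigma - spec.neck_station) / width) ** 2
        )
    return spine, radii, sigma


def make_la_with_laa(spec: SyntheticLAASpec | None = None) -> SyntheticAnatomy:
    """Watertight labeled LA + LAA surface with attached ground truth.

    The anatomy is the implicit union of an ellipsoidal body, four
    pulmonary-vein cylinders, one mitral-valve cylinder and the LAA tube,
    extracted by marching cubes at ``pitch_mm``.  Faces on the vessel end
    caps are labeled ``pv_inlet`` / ``mv_outlet``; the ostium cross-section
    is appended as a triangulated membrane labeled ``ostium``.  Generation
    is seed-deterministic.
    """
    from .geometry_core import slice_with_plane, _plane_basis

    spec = spec or SyntheticLAASpec()
    spine, radii, sigma = _laa_spine_and_radii(spec)

    # collision checks: lobes and appendage must clear the body
    tip = spine[-1]
    if np.sum((tip / _BODY_SEMI_AXES) ** 2) < 1.0:
        raise LaaoError("LAA tip falls inside the atrial body; adjust the spec")

    lobe_tubes = []
    for lobe in spec.lobes:
        i = int(np.argmin(np.abs(sigma - lobe.branch_station)))
        base, d_main = spine[i], spine[min(i + 1, len(spine) - 1)] - spine[i]
        d_main /= np.linalg.norm(d_main)
        perp = np.cross(d_main, _LAA_ANCHOR_DIR)
        perp /= np.linalg.norm(perp)
        ang = np.deg2rad(lobe.direction_deg)
        d_lobe = np.cos(ang) * d_main + np.sin(ang) * perp
        n_l = max(2, int(np.ceil(lobe.length)))
        s_l = np.linspace(0.0, lobe.length, n_l)
        lspine = base[None] + s_l[:, None] * d_lobe[None]
        lradii = np.full(n_l, 0.5 * lobe.diameter)
        if np.sum((lspine[-1] / _BODY_SEMI_AXES) ** 2) < 1.0:
            raise LaaoError("lobe collides with the atrial body; adjust the spec")
        lobe_tubes.append((lspine, lradii))

    pv_caps, cyl_defs = [], []
    for d in _PV_DIRS:
        p0 = _ellipsoid_surface_point(d)
        w = d / np.linalg.norm(d)
        p0_in = p0 - 3.0 * w
        p1 = p0 + _PV_LENGTH * w
        cyl_defs.append((p0_in, p1, _PV_RADIUS))
        pv_caps.append((p1, w, _PV_RADIUS))
    mv0 = _ellipsoid_surface_point(_MV_DIR) - 3.0 * _MV_DIR
    mv1 = _ellipsoid_surface_point(_MV_DIR) + _MV_LENGTH * _MV_DIR
    cyl_defs.append((mv0, mv1, _MV_RADIUS))
    mv_cap = (mv1, _MV_DIR, _MV_RADIUS)

    # grid over the union's bounding box
    all_pts = np.vstack(
        [spine + radii[:, None], spine - radii[:, None],
         [a for a, _, _ in cyl_defs], [b for _, b, _ in cyl_defs]]
        + [ls for ls, _ in lobe_tubes]
    )
    lo = np.minimum(all_pts.min(axis=0), -_BODY_SEMI_AXES) - 3 * spec.pitch_mm
    hi = np.maximum(all_pts.max(axis=0), _BODY_SEMI_AXES) + 3 * spec.pitch_mm
    h = spec.pitch_mm
    xs = np.arange(lo[0], hi[0] + h, h)
    ys = np.arange(lo[1], hi[1] + h, h)
    zs = np.arange(lo[2], hi[2] + h, h)
    shape = (len(xs), len(ys), len(zs))
    vol = np.empty(shape, dtype=np.float32)

    rng = np.random.default_rng(spec.seed)
    chunk = 200_000
    grid = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1).reshape(-1, 3)
    for start in range(0, len(grid), chunk):
        pts = grid[start : start + chunk]
        body = (
            np.sqrt(np.sum((pts / _BODY_SEMI_AXES) ** 2, axis=1)) - 1.0
        ) * float(_BODY_SEMI_AXES.min())
        sdf = body
        for a, b, r in cyl_defs:
            sdf = np.minimum(sdf, _cylinder_sdf(pts, a, b, r))
        sdf = np.minimum(sdf, _tube_sdf(pts, spine, radii))
        for lspine, lradii in lobe_tubes:
            sdf = np.minimum(sdf, _tube_sdf(pts, lspine, lradii))
        vol.reshape(-1)[start : start + chunk] = sdf
    if spec.noise_mm > 0:
        vol += rng.normal(0.0, spec.noise_mm, size=vol.shape).astype(np.float32)

    verts, faces, _, _ = measure.marching_cubes(vol, level=0.0, spacing=(h, h, h))
    verts = verts + lo
    mesh = SurfaceMesh(verts, faces.astype(np.int64))
    if mesh.to_trimesh(shell_only=True).volume < 0:
        mesh.faces = mesh.faces[:, ::-1].copy()

    # label vessel end caps
    cent = mesh.face_centroids()
    labels = mesh.face_labels
    for (cap_p, cap_w, cap_r), code in (
        [(c, FACE_LABELS["pv_inlet"]) for c in pv_caps]
        + [(mv_cap, FACE_LABELS["mv_outlet"])]
    ):
        on_plane = np.abs((cent - cap_p) @ cap_w) < 0.9 * h
        radial = np.linalg.norm(
            cent - cap_p[None] - ((cent - cap_p) @ cap_w)[:, None] * cap_w[None],
            axis=1,
        )
        labels[on_plane & (radial < cap_r + h)] = code

    # ostium plane and membrane
    i0 = int(np.argmin(np.abs(sigma)))
    ost_origin = spine[i0]
    ost_dir = spine[min(i0 + 1, len(spine) - 1)] - spine[i0 - 1]
    ost_dir /= np.linalg.norm(ost_dir)
    ostium = OstiumPlane(origin=ost_origin, normal=-ost_dir)
    mesh = _append_ostium_membrane(mesh, ostium, near_point=ost_origin)

    # ground truth: spine inside the lumen plus the rounded-cap apex
    gt_keep = sigma >= 0.0
    end_dir = spine[-1] - spine[-2]
    end_dir /= np.linalg.norm(end_dir)
    apex = spine[-1] + (spec.tube_length - sigma[-1]) * end_dir
    gt_points = np.vstack([spine[gt_keep], apex[None]])
    gt_sigma = np.concatenate([sigma[gt_keep], [spec.tube_length]])
    # diameter truth only on the tubular part (the rounded cap has no
    # cylinder-like cross-section)
    stations = np.arange(0.0, sigma[-1] + 1e-9, 2.5)
    r_at = np.interp(stations, gt_sigma[:-1], radii[gt_keep])
    seed_pt = gt_points[int(np.argmin(np.abs(gt_sigma - 5.0)))]
    return SyntheticAnatomy(
        mesh=mesh, ostium=ostium, spec=spec,
        true_centreline_points=gt_points,
        true_arc_length=gt_sigma,
        true_stations=stations,
        true_d1=2.0 * r_at, true_d2=2.0 * r_at,
        laa_seed_point=seed_pt,
    )


def _append_ostium_membrane(
    mesh: SurfaceMesh, ostium: OstiumPlane, near_point: np.ndarray
) -> SurfaceMesh:
    """Triangulate the ostium cross-section and append it labeled ``ostium``."""
    from .geometry_core import _plane_basis, slice_with_plane

    polys = slice_with_plane(mesh, ostium)
    if not polys:
        raise TopologyError("ostium plane does not intersect the mesh")
    dists = [np.linalg.norm(p.mean(axis=0) - near_point) for p in polys]
    poly = polys[int(np.argmin(dists))]
    centroid = poly.mean(axis=0)
    n0 = mesh.n_vertices
    verts = np.vstack([mesh.vertices, poly, centroid[None]])
    k = len(poly)
    fan = np.array(
        [[n0 + k, n0 + j, n0 + (j + 1) % k] for j in range(k)], dtype=np.int64
    )
    faces = np.vstack([mesh.faces, fan])
    labels = np.concatenate(
        [mesh.face_labels, np.full(k, FACE_LABELS["ostium"], dtype=np.int64)]
    )
    return SurfaceMesh(verts, faces, labels)


def make_two_lobe_laa(
    main_length: float = 40.0,
    main_diameter: float = 18.0,
    lobe_length: float = 18.0,
    lobe_diameter: float = 10.0,
    branch_station: float = 15.0,
    pitch_mm: float = 0.8,
) -> tuple[SurfaceMesh, OstiumPlane]:
    """Standalone bifurcated LAA (no atrial body) for lobe-handling tests.

    Straight main tube along +z with a side lobe branching at
    ``branch_station``; the ostium cap sits at z = 0.  Built by implicit
    union + marching cubes, membrane labeled at the proximal plane.
    """
    r_main, r_lobe = 0.5 * main_diameter, 0.5 * lobe_diameter
    d_lobe = np.array([np.sin(np.deg2rad(50.0)), 0.0, np.cos(np.deg2rad(50.0))])
    base = np.array([0.0, 0.0, branch_station])
    lobe_tip = base + lobe_length * d_lobe
    lo = np.array([-r_main - 3, -r_main - 3, -3.0])
    hi = np.array(
        [max(r_main, lobe_tip[0] + r_lobe) + 3, r_main + 3, main_length + 3]
    )
    h = pitch_mm
    xs = np.arange(lo[0], hi[0] + h, h)
    ys = np.arange(lo[1], hi[1] + h, h)
    zs = np.arange(lo[2], hi[2] + h, h)
    grid = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
    pts = grid.reshape(-1, 3)
    sdf = _cylinder_sdf(
        pts, np.array([0.0, 0.0, 0.0]), np.array([0.0, 0.0, main_length]), r_main
    )
    sdf = np.minimum(sdf, _capsule_sdf(pts, base, lobe_tip, r_lobe))
    vol = sdf.reshape(grid.shape[:3]).astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(vol, level=0.0, spacing=(h, h, h))
    mesh = SurfaceMesh(verts + lo, faces.astype(np.int64))
    if mesh.to_trimesh(shell_only=True).volume < 0:
        mesh.faces = mesh.faces[:, ::-1].copy()
    ostium = OstiumPlane(origin=(0.0, 0.0, 0.5), normal=(0.0, 0.0, -1.0))
    mesh = _append_ostium_membrane(mesh, ostium, near_point=np.zeros(3))
    return mesh, ostium


# ---------------------------------------------------------------------------
# closed-form flow / wall-shear fields


@dataclass
class SyntheticFlowSpec:
    """Per-node steady + oscillatory wall-shear composition over one cycle.

    tau_w(x, t) = [a(x) + c(x) sin(2 pi t / T)] d(x) where a >= c
    (unidirectional regime), else tau_w = c(x) sin(2 pi t / T) d(x)
    (fully oscillatory).  ``samples`` should keep T/2 on the grid (odd
    sample count) so the trapezoidal |sin| integral converges at O(dt^2).
    """

    steady: float | np.ndarray = 1.0  # a(x), Pa
    oscillatory: float | np.ndarray = 0.0  # c(x), Pa
    direction: np.ndarray | str = (1.0, 0.0, 0.0)  # d(x) or 'random'
    cycle_length: float = 1.05  # s
    samples: int = 33
    seed: int = 0

    def __post_init__(self) -> None:
        if self.samples < 8:
            raise ValueError("need at least 8 samples per cycle")
        if self.cycle_length <= 0:
            raise ValueError("cycle_length must be positive")


def make_wss_series(
    mesh: SurfaceMesh, spec: SyntheticFlowSpec | None = None
) -> tuple[WSSTimeSeries, dict]:
    """Closed-form wall-shear series plus its analytic index ground truth.

    Returns ``(series, truth)`` where ``truth`` holds per-node arrays
    ``tawss`` (a, or 2c/pi), ``osi`` (0, or 1/2) and ``ecap`` (0, or
    pi/(4c)) for the regime active at each node.
    """
    spec = spec or SyntheticFlowSpec()
    n = mesh.n_vertices
    a = np.broadcast_to(np.asarray(spec.steady, dtype=float), (n,)).copy()
    c = np.broadcast_to(np.asarray(spec.oscillatory, dtype=float), (n,)).copy()
    if np.any(a < 0) or np.any(c < 0):
        raise ValueError("steady and oscillatory amplitudes must be >= 0")
    if isinstance(spec.direction, str) and spec.direction == "random":
        rng = np.random.default_rng(spec.seed)
        d = rng.normal(size=(n, 3))
    else:
        d = np.broadcast_to(np.asarray(spec.direction, dtype=float), (n, 3)).copy()
    d = d / np.linalg.norm(d, axis=1, keepdims=True)

    T = spec.cycle_length
    times = np.linspace(0.0, T, spec.samples)
    sin_t = np.sin(2 * np.pi * times / T)
    oscillatory = a < c  # regime per node
    amp = np.where(
        oscillatory[None, :], c[None, :] * sin_t[:, None],
        a[None, :] + c[None, :] * sin_t[:, None],
    )  # (T, n)
    vectors = amp[:, :, None] * d[None, :, :]
    series = WSSTimeSeries(surface_ref=mesh, times=times, vectors=vectors)

    tawss = np.where(oscillatory, 2.0 * c / np.pi, a)
    osi = np.where(oscillatory, 0.5, 0.0)
    with np.errstate(divide="ignore"):
        ecap = np.where(
            oscillatory, np.pi / (4.0 * np.where(c > 0, c, np.inf)), 0.0
        )
    truth = {"tawss": tawss, "osi": osi, "ecap": ecap,
             "oscillatory_mask": oscillatory}
    return series, truth


def make_inlet_waveform(
    bc: BoundaryConditionSpec | None = None, samples: int = 64
) -> tuple[np.ndarray, np.ndarray]:
    """One-cycle sinusoidal inlet multiplier aligned with the phase partition.

    Systole carries a nonnegative half-sine peaking mid-phase; diastole a
    second half-sine over its own duration.  Returns (times_s, multiplier).
    """
    bc = bc or BoundaryConditionSpec()
    if samples < 8:
        raise ValueError("need at least 8 samples")
    T, Ts = bc.cycle_duration, bc.systole_duration
    times = np.linspace(0.0, T, samples)
    mult = np.where(
        times <= Ts,
        np.sin(np.pi * times / Ts),
        np.sin(np.pi * (times - Ts) / bc.diastole_duration),
    )
    return times, np.abs(mult)


def make_probe_flow(
    points: np.ndarray,
    bc: BoundaryConditionSpec | None = None,
    peak_velocity: float = 0.4,
    samples: int = 64,
    direction=(1.0, 0.0, 0.0),
) -> FlowSeries:
    """Uniform-in-space sampled velocity field following the inlet waveform.

    ``peak_velocity`` defaults to 0.4 m/s — a typical healthy-cycle inlet
    peak, chosen here as the generator's own default.
    """
    bc = bc or BoundaryConditionSpec()
    times, mult = make_inlet_waveform(bc, samples)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    vel = peak_velocity * mult[:, None, None] * d[None, None, :]
    vel = np.broadcast_to(vel, (len(times), len(pts), 3)).copy()
    return FlowSeries(points=pts, times=times, velocities=vel)
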