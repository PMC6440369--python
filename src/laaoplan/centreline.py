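"""LAA centreline extraction.

The centreline runs from the ostium plane to the appendage tip.  A steady
heat-propagation field is solved on a voxelization of the LAA region with the
ostium held at value 1 (Dirichlet), insulated walls (natural Neumann) and a
uniform volumetric sink so the field decays monotonically with depth; the tip
is the field minimum.  The centreline is traced by marching along the field
gradient from a deep interior point near the minimum — up to the ostium plane
and down to the tip surface — recentring each step at the barycentre of the
local isovalue front, which keeps the line on the lumen axis even in bent or
tapered appendages.

A pure Laplace solve with one Dirichlet boundary and insulated walls would be
constant; the sink regularization makes the field span several orders of
magnitude across the appendage depth, which is what gives the gradient its
direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ConvergenceError, RangeError, TopologyError
from .geometry_core import OstiumPlane, SurfaceMesh

#: Default voxel pitch (mm) for the internal finite-difference discretization.
DEFAULT_PITCH = 0.5
#: Default marching step (mm) and iteration cap.
DEFAULT_STEP = 0.5
MAX_STEPS = 10_000
#: The sink constant is set so the field spans ~3 decades over the region size.
_DECADES = 3.0


@dataclass
class ScalarField:
    """Heat-propagation field on a voxel grid restricted to the LAA region."""

    origin: np.ndarray  # corner of voxel (0,0,0) centre, mm
    pitch: float  # voxel edge, mm
    values: np.ndarray  # (nx, ny, nz) float, NaN outside region
    mask: np.ndarray  # (nx, ny, nz) bool, True inside LAA region
    ostium_mask: np.ndarray  # Dirichlet voxels (subset of mask)
    surface_ref: SurfaceMesh | None = None
    _filled: np.ndarray | None = field(default=None, repr=False)

    def _nearest_filled(self) -> np.ndarray:
        """Values with the exterior filled from the nearest interior voxel."""
        if self._filled is None:
            idx = ndi.distance_transform_edt(
                ~self.mask, return_distances=False, return_indices=True
            )
            self._filled = self.values[tuple(idx)]
        return self._filled

    def _to_index(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.origin) / self.pitch

    def value_at(self, points: np.ndarray) -> np.ndarray:
        filled = self._nearest_filled()
        return ndi.map_coordinates(
            filled, self._to_index(points).T, order=1, mode="nearest"
        )

    def gradient_at(self, points: np.ndarray) -> np.ndarray:
        """Central-difference gradient (per mm) by trilinear sampling."""
        pts = np.atleast_2d(points)
        h = 0.5 * self.pitch
        grad = np.empty_like(pts)
        for ax in range(3):
            e = np.zeros(3)
            e[ax] = h
            grad[:, ax] = (self.value_at(pts + e) - self.value_at(pts - e)) / (2 * h)
        return grad

    def tip_point(self) -> np.ndarray:
        """Voxel centre of the field minimum (the LAA tip).

        The minimum can sit on a flat plateau (e.g. the end cap of a
        cylindrical appendage, where the field is constant across the cap);
        the plateau voxel closest to the plateau centroid is chosen, with
        remaining ties broken by (value, flat index) for determinism.
        """
        vals = np.where(self.mask, self.values, np.inf)
        vmin = vals.min()
        plateau = np.argwhere(vals <= vmin + 1e-6)
        centroid = plateau.mean(axis=0)
        d2 = ((plateau - centroid) ** 2).sum(axis=1)
        flat = np.ravel_multi_index(tuple(plateau.T), vals.shape)
        order = np.lexsort((flat, vals[tuple(plateau.T)], d2))
        ijk = plateau[order[0]]
        return self.origin + self.pitch * ijk.astype(float)


@dataclass
class Centreline:
    """Ordered polyline from the ostium-plane crossing (index 0) to the tip."""

    points: np.ndarray  # (k, 3) mm
    tangents: np.ndarray  # (k, 3) unit, pointing from ostium toward tip
    arc_length: np.ndarray  # (k,) cumulative mm from the ostium

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        self.tangents = np.asarray(self.tangents, dtype=np.float64)
        self.arc_length = np.asarray(self.arc_length, dtype=np.float64)
        if np.any(np.diff(self.arc_length) <= 0):
            raise ValueError("arc_length must be strictly increasing")

    @property
    def length(self) -> float:
        return float(self.arc_length[-1])

    def write_table(self, path) -> None:
        """Plain-text 4-column table: x, y, z, s (mm)."""
        data = np.column_stack([self.points, self.arc_length])
        header = "x_mm y_mm z_mm s_mm"
        np.savetxt(path, data, fmt="%.9e", header=header)

    def write_vtk(self, path) -> None:
        """VTK legacy polyline with arc_length point data."""
        n = len(self.points)
        lines = ["# vtk DataFile Version 3.0", "laaoplan centreline", "ASCII",
                 "DATASET POLYDATA", f"POINTS {n} double"]
        lines += [" ".join(f"{x:.9e}" for x in p) for p in self.points]
        lines.append(f"LINES 1 {n + 1}")
        lines.append(" ".join([str(n)] + [str(i) for i in range(n)]))
        lines.append(f"POINT_DATA {n}")
        lines.append("SCALARS arc_length double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{s:.9e}" for s in self.arc_length]
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def point_at_geodesic_distance(cl: Centreline, d: float) -> tuple[np.ndarray, np.ndarray]:
    """Point and unit tangent at geodesic station ``d`` mm from the ostium."""
    if d < 0 or d > cl.length:
        raise RangeError(
            f"station {d} mm outside centreline range [0, {cl.length:.3f}] mm"
        )
    pt = np.array([np.interp(d, cl.arc_length, cl.points[:, i]) for i in range(3)])
    tan = np.array([np.interp(d, cl.arc_length, cl.tangents[:, i]) for i in range(3)])
    tan /= np.linalg.norm(tan)
    return pt, tan


# ---------------------------------------------------------------------------
# heat field


def _voxelize_region(
    mesh: SurfaceMesh, ostium: OstiumPlane, pitch: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxelize the LAA side of the ostium plane; returns origin, mask, ostium mask."""
    import trimesh.voxel.creation as vox

    tm = mesh.to_trimesh(shell_only=True)
    grid = vox.voxelize(tm, pitch).fill()
    # voxel centres in world coordinates
    idx = np.argwhere(grid.matrix)
    centres = grid.indices_to_points(idx)
    sd = ostium.signed_distance(centres)
    laa = sd < 0.5 * pitch  # LAA side, plus a one-voxel band at the plane
    mask_shape = grid.matrix.shape
    mask = np.zeros(mask_shape, dtype=bool)
    mask[tuple(idx[laa].T)] = True
    ost = np.zeros(mask_shape, dtype=bool)
    at_plane = laa & (np.abs(sd) <= 0.75 * pitch)
    ost[tuple(idx[at_plane].T)] = True
    origin = grid.indices_to_points(np.zeros((1, 3), dtype=int))[0]
    return origin, mask, ost


def solve_heat_field(
    laa_region: SurfaceMesh,
    ostium: OstiumPlane,
    pitch: float = DEFAULT_PITCH,
    on_disconnected: str = "error",
    seed_point: np.ndarray | None = None,
) -> ScalarField:
    """Steady sink-regularized diffusion on the voxelized LAA region.

    Dirichlet value 1 on ostium-plane voxels, natural (insulated) walls, and a
    uniform sink chosen so the solution spans about three orders of magnitude
    across the region extent.  Values are normalized to [0, 1]; the tip is the
    field argmin.

    On a full atrial mesh the half-space distal to the ostium plane can also
    clip parts of the atrial body; ``seed_point`` (an interior LAA point)
    selects the appendage component directly.  Otherwise the component with
    the most ostium-plane voxels is kept — with ``on_disconnected='error'``
    (default) any sizeable stray component raises instead, listing component
    sizes.
    """
    origin, mask, ost = _voxelize_region(laa_region, ostium, pitch)
    if not mask.any():
        raise TopologyError("ostium plane leaves no voxels on the LAA side")
    if not ost.any():
        raise TopologyError("no voxels found on the ostium plane; check the plane")

    labels, ncomp = ndi.label(mask, structure=ndi.generate_binary_structure(3, 1))
    if ncomp > 1:
        sizes = ndi.sum_labels(mask, labels, index=range(1, ncomp + 1)).astype(int)
        if seed_point is not None:
            ijk = np.round(
                (np.asarray(seed_point, dtype=float) - origin) / pitch
            ).astype(int)
            if np.any(ijk < 0) or np.any(ijk >= np.array(mask.shape)):
                raise TopologyError(f"seed point {seed_point} outside the grid")
            main = int(labels[tuple(ijk)])
            if main == 0:
                raise TopologyError(
                    f"seed point {seed_point} is not inside the LAA region"
                )
        else:
            ost_counts = ndi.sum_labels(
                ost, labels, index=range(1, ncomp + 1)
            ).astype(int)
            main = int(np.argmax(ost_counts)) + 1
            stray = sizes[np.arange(1, ncomp + 1) != main]
            if on_disconnected == "error" and np.any(
                stray > max(10, 0.01 * mask.sum())
            ):
                raise TopologyError(
                    f"LAA region is disconnected; component sizes (voxels): "
                    f"{sorted(sizes.tolist(), reverse=True)}"
                )
        mask = labels == main
        ost = ost & mask
        if not ost.any():
            raise TopologyError(
                "selected LAA component does not touch the ostium plane"
            )

    # decay length from the region extent: exp(-L/l) ~ 10^-_DECADES
    idx = np.argwhere(mask)
    extent = float(np.linalg.norm((idx.max(axis=0) - idx.min(axis=0)) * pitch))
    extent = max(extent, pitch)
    sigma = (_DECADES * np.log(10.0) / extent) ** 2  # 1/mm^2

    n = int(mask.sum())
    num = -np.ones(mask.shape, dtype=np.int64)
    num[mask] = np.arange(n)
    free = mask & ~ost

    rows, cols, vals = [], [], []
    h2 = pitch * pitch
    diag = np.zeros(n)
    for ax in range(3):
        for sign in (1, -1):
            shifted = np.roll(mask, sign, axis=ax)
            # roll wraps; kill wrapped layer
            sl = [slice(None)] * 3
            sl[ax] = 0 if sign == 1 else -1
            shifted[tuple(sl)] = False
            pair = mask & shifted
            i = num[pair]
            j_idx = np.argwhere(pair)
            j_idx[:, ax] -= sign
            j = num[tuple(j_idx.T)]
            rows.append(i)
            cols.append(j)
            vals.append(np.full(len(i), -1.0 / h2))
            diag[i] += 1.0 / h2

    diag += sigma
    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )

    # impose Dirichlet rows: u = 1 on ostium voxels
    dir_idx = num[ost]
    free_idx = num[free]
    u = np.zeros(n)
    u[dir_idx] = 1.0
    if len(free_idx):
        A_ff = A[free_idx][:, free_idx]
        rhs = -A[free_idx][:, dir_idx] @ u[dir_idx]
        try:
            u_f = spla.spsolve(A_ff.tocsc(), rhs)
        except Exception as exc:  # noqa: BLE001
            raise ConvergenceError(
                "heat-field system could not be solved; try a finer pitch"
            ) from exc
        if not np.all(np.isfinite(u_f)):
            raise ConvergenceError(
                "singular heat-field system; try a finer discretization pitch"
            )
        u[free_idx] = u_f

    values = np.full(mask.shape, np.nan)
    values[mask] = u
    vmax = np.nanmax(values)
    if vmax <= 0:
        raise ConvergenceError("degenerate heat field (non-positive maximum)")
    values /= vmax
    values = np.clip(values, 0.0, 1.0)
    values[ost] = 1.0
    return ScalarField(
        origin=origin, pitch=pitch, values=values, mask=mask,
        ostium_mask=ost, surface_ref=laa_region,
    )


# ---------------------------------------------------------------------------
# marching


def _recentre(
    fld: ScalarField,
    point: np.ndarray,
    direction: np.ndarray,
    grad_mag: float,
    max_shift: float,
) -> np.ndarray:
    """Move ``point`` toward the barycentre of its local isovalue front.

    The level set of the heat field through the point is a transversal
    front; its barycentre lies on the lumen axis even in bends (where a
    geometric plane normal to the gradient would be tilted inward).  Only
    the voxel-connected front component containing the point is used, which
    keeps the recentring lobe-safe.  The shift is clamped to ``max_shift``.
    """
    u0 = float(fld.value_at(point[None])[0])
    band = max(grad_mag * fld.pitch, 1e-12)
    ijk = np.round((point - fld.origin) / fld.pitch).astype(int)
    ijk = np.clip(ijk, 0, np.array(fld.values.shape) - 1)
    structure = ndi.generate_binary_structure(3, 1)
    for widen in (1.0, 2.0, 4.0):
        sel = fld.mask & (np.abs(fld.values - u0) <= widen * band)
        if not sel.any():
            continue
        labels, _ = ndi.label(sel, structure=structure)
        lab = labels[tuple(ijk)]
        if lab == 0:
            # point voxel not in the band; take the nearest banded voxel
            cand = np.argwhere(sel)
            d2 = ((cand - ijk) ** 2).sum(axis=1)
            if d2.min() > 9:  # more than ~3 voxels away: widen instead
                continue
            lab = labels[tuple(cand[int(np.argmin(d2))])]
        voxels = np.argwhere(labels == lab)
        target = fld.origin + fld.pitch * voxels.mean(axis=0)
        shift = target - point
        # lateral component only: axial pull toward the band barycentre
        # (e.g. into a rounded tip cap) must not fight the marching step
        shift -= float(shift @ direction) * direction
        norm = np.linalg.norm(shift)
        if norm > max_shift:
            shift *= max_shift / norm
        return point + shift
    return point


def _smooth_polyline(points: np.ndarray, iterations: int) -> np.ndarray:
    """Endpoint-preserving (1/4, 1/2, 1/4) smoothing of a polyline.

    Damps the lateral zigzag the marcher picks up from voxel-scale surface
    bumps; a straight polyline is a fixed point, so exact fixtures are
    unaffected.
    """
    pts = points.copy()
    for _ in range(iterations):
        if len(pts) < 3:
            break
        pts[1:-1] = 0.25 * pts[:-2] + 0.5 * pts[1:-1] + 0.25 * pts[2:]
    return pts


def _deep_start(fld: ScalarField) -> np.ndarray:
    """Interior marching start: the most interior voxel of the deep front.

    The raw field argmin sits at the geodesically farthest voxel, which on a
    flat-capped or bent appendage is a wall-hugging cap corner.  Among the
    voxels within one decay length of the minimum (field value up to e times
    the minimum, connected to the argmin), the voxel with the largest
    distance to the region boundary lies on the lumen axis near the tip —
    marching then runs along the axis in both directions from there.  Ties
    are broken by (value, flat index).
    """
    p = fld.tip_point()
    u0 = float(fld.value_at(p[None])[0])
    sel = fld.mask & (fld.values <= np.e * max(u0, 1e-300))
    labels, _ = ndi.label(sel, structure=ndi.generate_binary_structure(3, 1))
    ijk = np.clip(
        np.round((p - fld.origin) / fld.pitch).astype(int),
        0, np.array(fld.values.shape) - 1,
    )
    lab = labels[tuple(ijk)]
    if lab == 0:
        return p
    region = labels == lab
    edt = ndi.distance_transform_edt(fld.mask)
    voxels = np.argwhere(region)
    flat = np.ravel_multi_index(tuple(voxels.T), fld.mask.shape)
    order = np.lexsort((flat, fld.values[region], -edt[region]))
    return fld.origin + fld.pitch * voxels[order[0]].astype(float)


def march_centreline(
    fld: ScalarField,
    ostium: OstiumPlane,
    step_size: float = DEFAULT_STEP,
    max_steps: int = MAX_STEPS,
    smooth_iters: int = 2,
) -> Centreline:
    """Trace the centreline between the ostium plane and the tip surface.

    From an interior start point near the field minimum, the tracer ascends
    the normalized field gradient toward the ostium (terminating exactly on
    the ostium plane) and descends it toward the tip (terminating at the
    tip surface).  After every step the point is recentred at the barycentre
    of the isovalue-front component containing it, projected laterally so
    recentring never fights the direction of travel; this keeps the line on
    the lumen axis in bends, tapers and lobes.  Index 0 of the result sits
    on the ostium plane.  Deterministic: no randomness is involved.
    """
    if step_size <= 0:
        raise ValueError("step_size must be positive")

    start = _deep_start(fld)

    def _voxel_inside(point: np.ndarray) -> bool:
        ijk = np.round((point - fld.origin) / fld.pitch).astype(int)
        if np.any(ijk < 0) or np.any(ijk >= np.array(fld.mask.shape)):
            return False
        return bool(fld.mask[tuple(ijk)])

    # ascend toward the ostium (u increases)
    up: list[np.ndarray] = []
    p = start.copy()
    crossed = False
    for _ in range(max_steps):
        g = fld.gradient_at(p)[0]
        gn = np.linalg.norm(g)
        if gn == 0:
            raise ConvergenceError(
                f"zero gradient at {p}; marching stalled before the ostium"
            )
        direction = g / gn
        p_new = p + step_size * direction
        sd_prev = float(ostium.signed_distance(p)[0])
        sd_new = float(ostium.signed_distance(p_new)[0])
        if sd_new >= 0.0:
            # interpolate the exact plane crossing
            t = sd_prev / (sd_prev - sd_new) if sd_new != sd_prev else 1.0
            up.append(p + t * (p_new - p))
            crossed = True
            break
        p_new = _recentre(fld, p_new, direction, gn, max_shift=1.0 * step_size)
        if float(ostium.signed_distance(p_new)[0]) >= 0.0:
            up.append(p_new)
            crossed = True
            break
        up.append(p_new.copy())
        p = p_new
    if not crossed:
        raise ConvergenceError(
            f"marching did not reach the ostium plane within {max_steps} steps; "
            f"last point {up[-1] if up else start}"
        )

    # descend toward the tip surface (u decreases) until leaving the lumen;
    # direction inertia bridges the near-flat field across the tip cap
    down: list[np.ndarray] = []
    p = start.copy()
    prev_dir: np.ndarray | None = None
    for _ in range(max_steps):
        g = fld.gradient_at(p)[0]
        gn = np.linalg.norm(g)
        if gn == 0:
            break
        direction = -g / gn
        if prev_dir is not None:
            direction = 0.5 * direction + 0.5 * prev_dir
            direction /= np.linalg.norm(direction)
        prev_dir = direction
        p_new = p + step_size * direction
        if not _voxel_inside(p_new):
            break
        p_new = _recentre(fld, p_new, direction, gn, max_shift=1.0 * step_size)
        if not _voxel_inside(p_new):
            break
        down.append(p_new.copy())
        p = p_new

    # assemble ostium -> tip and reverse: up runs start->ostium
    pts = up[::-1] + [start] + down
    points = np.array(pts)
    points = _smooth_polyline(points, smooth_iters)
    # drop consecutive duplicates
    keep = np.concatenate(
        [[True], np.linalg.norm(np.diff(points, axis=0), axis=1) > 1e-12]
    )
    points = points[keep]
    seg = np.diff(points, axis=0)
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(seg, axis=1))])
    # tangents by central differences along the polyline, toward the tip
    tangents = np.empty_like(points)
    tangents[0] = seg[0]
    tangents[-1] = seg[-1]
    if len(points) > 2:
        tangents[1:-1] = points[2:] - points[:-2]
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    return Centreline(points=points, tangents=tangents, arc_length=arc)


def extract_centreline(
    mesh: SurfaceMesh,
    ostium: OstiumPlane,
    pitch: float = DEFAULT_PITCH,
    step_size: float = DEFAULT_STEP,
) -> Centreline:
    """Convenience wrapper: heat-field solve followed by marching."""
    fld = solve_heat_field(mesh, ostium, pitch=pitch)
    return march_centreline(fld, ostium, step_size=step_size)
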