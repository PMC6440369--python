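"""Mesh data model and geometry utilities.

All geometry is expressed in millimetres.  A :class:`SurfaceMesh` carries an
integer label per triangular face; the label code table is published as
:data:`FACE_LABELS`.  Anatomical meshes may additionally carry the ostium as a
triangulated membrane (faces labeled ``ostium``) overlaid on the watertight
wall/inlet/outlet shell; watertightness checks and volume computations operate
on the shell only and ignore the membrane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .errors import TopologyError

#: Face-label code table, embedded as field data in exported files.
FACE_LABELS: dict[str, int] = {
    "wall": 0,
    "ostium": 1,
    "pv_inlet": 2,
    "mv_outlet": 3,
    "device": 4,
}

LABEL_NAMES: dict[int, str] = {v: k for k, v in FACE_LABELS.items()}

#: Slice components with enclosed area below this (mm^2) are discarded.
DEGENERATE_AREA = 1e-9


@dataclass
class SurfaceMesh:
    """Triangulated surface with per-face anatomical labels (units: mm)."""

    vertices: np.ndarray  # (n, 3) float64
    faces: np.ndarray  # (m, 3) int64
    face_labels: np.ndarray | None = None  # (m,) int64, defaults to wall

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("vertex coordinates must be finite")
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of range")
        if self.face_labels is None:
            self.face_labels = np.zeros(len(self.faces), dtype=np.int64)
        else:
            self.face_labels = np.ascontiguousarray(self.face_labels, dtype=np.int64)
            if self.face_labels.shape != (len(self.faces),):
                raise ValueError("face_labels must have one entry per face")

    # -- basic derived quantities -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_areas(self) -> np.ndarray:
        tri = self.vertices[self.faces]
        return 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )

    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def faces_with_label(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.face_labels == FACE_LABELS[label])

    def label_mask(self, label: str) -> np.ndarray:
        return self.face_labels == FACE_LABELS[label]

    @staticmethod
    def _edges_closed(faces: np.ndarray) -> bool:
        if len(faces) == 0:
            return False
        edges = np.sort(faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def shell(self) -> "SurfaceMesh":
        """The closed flow boundary.

        When the ostium faces form a redundant membrane overlaid on an
        already-closed wall surface they are dropped; when they structurally
        close the surface (e.g. the proximal cap of a tube fixture) they are
        kept.
        """
        keep = self.face_labels != FACE_LABELS["ostium"]
        if keep.all() or not self._edges_closed(self.faces[keep]):
            return SurfaceMesh(self.vertices, self.faces, self.face_labels)
        return SurfaceMesh(self.vertices, self.faces[keep], self.face_labels[keep])

    def to_trimesh(self, shell_only: bool = False) -> trimesh.Trimesh:
        src = self.shell() if shell_only else self
        return trimesh.Trimesh(
            vertices=src.vertices.copy(), faces=src.faces.copy(), process=False
        )

    def is_watertight(self) -> bool:
        """True when every shell edge is shared by exactly two faces."""
        shell = self.shell()
        if shell.n_faces == 0:
            return False
        edges = np.sort(
            shell.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
        )
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def enclosed_volume(self) -> float:
        """Signed volume of the shell by the divergence theorem (mm^3)."""
        tm = self.to_trimesh(shell_only=True)
        return abs(float(tm.volume))

    def vertex_labels(self) -> np.ndarray:
        """Per-vertex label: the maximum label code of incident faces.

        Device (4) wins over anatomical labels so that nodes on the occluder
        surface are unambiguously excluded from wall regions of interest.
        """
        out = np.full(self.n_vertices, -1, dtype=np.int64)
        for lab in sorted(set(self.face_labels.tolist())):
            idx = np.unique(self.faces[self.face_labels == lab])
            out[idx] = np.maximum(out[idx], lab)
        return out

    def vertex_areas(self) -> np.ndarray:
        """Lumped nodal area: one third of each incident face area (mm^2)."""
        fa = self.face_areas()
        out = np.zeros(self.n_vertices)
        np.add.at(out, self.faces.ravel(), np.repeat(fa / 3.0, 3))
        return out


@dataclass
class VolumeMesh:
    """Tetrahedral mesh with labeled boundary triangles (units: mm)."""

    vertices: np.ndarray  # (n, 3)
    tets: np.ndarray  # (m, 4)
    boundary_faces: np.ndarray | None = None  # (k, 3)
    boundary_labels: np.ndarray | None = None  # (k,)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        if self.boundary_faces is not None:
            self.boundary_faces = np.ascontiguousarray(
                self.boundary_faces, dtype=np.int64
            )
            if self.boundary_labels is None:
                self.boundary_labels = np.zeros(
                    len(self.boundary_faces), dtype=np.int64
                )
            else:
                self.boundary_labels = np.ascontiguousarray(
                    self.boundary_labels, dtype=np.int64
                )

    def tet_volumes(self) -> np.ndarray:
        t = self.vertices[self.tets]
        return (
            np.einsum(
                "ij,ij->i",
                np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]),
                t[:, 3] - t[:, 0],
            )
            / 6.0
        )

    def fix_orientation(self) -> None:
        """Reorder tet vertices so all signed volumes are positive."""
        vol = self.tet_volumes()
        flip = vol < 0
        self.tets[flip] = self.tets[flip][:, [0, 2, 1, 3]]
        if np.any(self.tet_volumes() == 0):
            raise TopologyError("degenerate (zero-volume) tetrahedra present")


@dataclass
class SmoothingParams:
    """Taubin lambda/mu smoothing parameters.

    Defaults are the standard anti-shrink pair lambda = 0.6, mu = -0.53 with
    10 iterations, suitable for segmentation-derived cardiac surfaces.
    """

    lambda_factor: float = 0.6
    mu_factor: float = -0.53
    iterations: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.lambda_factor < 1.0:
            raise ValueError("lambda_factor must lie in (0, 1)")
        if self.mu_factor >= 0.0:
            raise ValueError("mu_factor must be negative")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")


@dataclass
class OstiumPlane:
    """The ostium plane; ``normal`` points from the LAA toward the LA body."""

    origin: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        n = np.asarray(self.normal, dtype=np.float64).reshape(3)
        nrm = np.linalg.norm(n)
        if nrm == 0:
            raise ValueError("normal must be nonzero")
        self.normal = n / nrm

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Positive on the LA-body side, negative on the LAA side."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return (pts - self.origin) @ self.normal


def contains_points(mesh: SurfaceMesh, points: np.ndarray,
                    chunk: int = 256) -> np.ndarray:
    """Ray-parity inside test against the mesh shell.

    Casts one fixed, irrationally-oriented ray per point and counts
    Moller-Trumbore triangle crossings; odd parity means inside.  Intended
    for closed shells; results on open surfaces are undefined.
    """
    shell = mesh.shell()
    tri = shell.vertices[shell.faces]  # (f, 3, 3)
    v0 = tri[:, 0]
    e1 = tri[:, 1] - v0
    e2 = tri[:, 2] - v0
    d = np.array([0.2397181, 0.6034586, 0.7606694])
    d /= np.linalg.norm(d)
    h = np.cross(d, e2)  # (f, 3)
    a = np.einsum("fj,fj->f", e1, h)
    ok = np.abs(a) > 1e-12
    inv_a = np.zeros_like(a)
    inv_a[ok] = 1.0 / a[ok]

    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    inside = np.zeros(len(pts), dtype=bool)
    for lo in range(0, len(pts), chunk):
        o = pts[lo : lo + chunk]  # (p, 3)
        s = o[:, None, :] - v0[None, :, :]  # (p, f, 3)
        u = np.einsum("pfj,fj->pf", s, h) * inv_a[None]
        q = np.cross(s, e1[None])  # (p, f, 3)
        v = np.einsum("pfj,j->pf", q, d) * inv_a[None]
        t = np.einsum("pfj,fj->pf", q, e2) * inv_a[None]
        hit = (
            ok[None]
            & (u >= 0.0) & (u <= 1.0)
            & (v >= 0.0) & (u + v <= 1.0)
            & (t > 1e-9)
        )
        inside[lo : lo + chunk] = hit.sum(axis=1) % 2 == 1
    return inside


# -- smoothing ---------------------------------------------------------------------


def _vertex_adjacency(mesh: SurfaceMesh) -> tuple[np.ndarray, np.ndarray]:
    """CSR-style (indptr, indices) of unique vertex neighbours."""
    e = mesh.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
    e = np.unique(np.sort(e, axis=1), axis=0)
    both = np.concatenate([e, e[:, ::-1]])
    order = np.lexsort((both[:, 1], both[:, 0]))
    both = both[order]
    counts = np.bincount(both[:, 0], minlength=mesh.n_vertices)
    indptr = np.concatenate([[0], np.cumsum(counts)])
    return indptr, both[:, 1]


def taubin_smooth(
    mesh: SurfaceMesh,
    params: SmoothingParams | None = None,
    preserve_labeled: bool = True,
) -> SurfaceMesh:
    """Taubin lambda|mu smoothing with the uniform umbrella operator.

    Each iteration applies an inflating step ``v += lambda * (mean(neigh) - v)``
    followed by a deflating step with ``mu``; connectivity is untouched.  With
    ``preserve_labeled`` (default) vertices incident to non-wall faces — the
    ostium ring, inlet/outlet rims, device — are held fixed so anatomical
    landmarks survive smoothing.
    """
    params = params or SmoothingParams()
    if mesh.n_vertices < 4:
        raise ValueError("mesh must have at least 4 vertices")
    if params.iterations == 0:
        return SurfaceMesh(
            mesh.vertices.copy(), mesh.faces.copy(), mesh.face_labels.copy()
        )

    indptr, indices = _vertex_adjacency(mesh)
    degree = np.diff(indptr).astype(np.float64)
    isolated = degree == 0
    if np.any(isolated):
        warnings.warn(
            f"{int(isolated.sum())} isolated vertices left unmoved", stacklevel=2
        )

    movable = ~isolated
    if preserve_labeled:
        non_wall = np.unique(mesh.faces[mesh.face_labels != FACE_LABELS["wall"]])
        movable[non_wall] = False

    verts = mesh.vertices.copy()
    deg_safe = np.where(degree > 0, degree, 1.0)[:, None]

    def _umbrella_step(v: np.ndarray, factor: float) -> None:
        sums = np.add.reduceat(v[indices], indptr[:-1], axis=0)
        sums[degree == 0] = 0.0
        delta = sums / deg_safe - v
        v[movable] += factor * delta[movable]

    for _ in range(params.iterations):
        _umbrella_step(verts, params.lambda_factor)
        _umbrella_step(verts, params.mu_factor)

    return SurfaceMesh(verts, mesh.faces.copy(), mesh.face_labels.copy())


# -- plane slicing -----------------------------------------------------------------


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal in-plane basis (u, v) with u x v = normal."""
    n = np.asarray(normal, dtype=np.float64)
    n = n / np.linalg.norm(n)
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(n)))] = 1.0
    u = np.cross(helper, n)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def polygon_area_2d(pts2d: np.ndarray) -> float:
    """Signed shoelace area of a closed 2D polygon (last vertex != first)."""
    x, y = pts2d[:, 0], pts2d[:, 1]
    return 0.5 * float(
        np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    )


def slice_with_plane(
    mesh: SurfaceMesh,
    plane: OstiumPlane,
    merge_tol: float = 1e-6,
) -> list[np.ndarray]:
    """Intersect the mesh with a plane; return closed polygons as (k, 3) arrays.

    Each polygon is ordered counter-clockwise about the plane normal and does
    not repeat its first vertex.  Separate intersection components (e.g. LAA
    lobes) are returned as separate polygons; open chains and components with
    in-plane area < 1e-9 mm^2 are discarded.  No intersection yields an empty
    list.
    """
    tm = mesh.to_trimesh()
    segments = trimesh.intersections.mesh_plane(
        tm, plane_normal=plane.normal, plane_origin=plane.origin
    )
    if len(segments) == 0:
        return []

    # Weld segment endpoints on a tolerance grid, then walk closed loops.
    pts = segments.reshape(-1, 3)
    keys = np.round(pts / merge_tol).astype(np.int64)
    _, first_idx, inverse = np.unique(
        keys, axis=0, return_index=True, return_inverse=True
    )
    welded = pts[first_idx]
    seg_ids = inverse.reshape(-1, 2)
    seg_ids = seg_ids[seg_ids[:, 0] != seg_ids[:, 1]]  # drop degenerate segments

    adjacency: dict[int, list[int]] = {}
    for a, b in seg_ids:
        adjacency.setdefault(int(a), []).append(int(b))
        adjacency.setdefault(int(b), []).append(int(a))

    visited_edges: set[tuple[int, int]] = set()
    polygons: list[np.ndarray] = []
    u, v = _plane_basis(plane.normal)

    for start in sorted(adjacency):
        for nxt in adjacency[start]:
            if (start, nxt) in visited_edges:
                continue
            loop = [start]
            prev, cur = start, nxt
            visited_edges.add((start, nxt))
            visited_edges.add((nxt, start))
            closed = False
            while True:
                loop.append(cur)
                candidates = [w for w in adjacency[cur] if w != prev]
                if not candidates:
                    break
                nxt2 = candidates[0]
                if nxt2 == loop[0]:
                    closed = True
                    visited_edges.add((cur, nxt2))
                    visited_edges.add((nxt2, cur))
                    break
                if (cur, nxt2) in visited_edges:
                    break
                visited_edges.add((cur, nxt2))
                visited_edges.add((nxt2, cur))
                prev, cur = cur, nxt2
            if not closed or len(loop) < 3:
                continue
            poly = welded[np.array(loop)]
            pts2d = np.column_stack([(poly - plane.origin) @ u, (poly - plane.origin) @ v])
            area = polygon_area_2d(pts2d)
            if abs(area) < DEGENERATE_AREA:
                continue
            if area < 0:  # enforce CCW about the plane normal
                poly = poly[::-1]
            polygons.append(np.ascontiguousarray(poly))

    return polygons


def polygon_perimeter(poly: np.ndarray) -> float:
    """Perimeter of a closed polygon given without repeated first vertex."""
    return float(np.linalg.norm(np.roll(poly, -1, axis=0) - poly, axis=1).sum())


def polygon_plane_area(poly: np.ndarray, normal: np.ndarray) -> float:
    """Unsigned in-plane area of a closed 3D polygon."""
    u, v = _plane_basis(normal)
    origin = poly[0]
    pts2d = np.column_stack([(poly - origin) @ u, (poly - origin) @ v])
    return abs(polygon_area_2d(pts2d))


def resample_polygon(poly: np.ndarray, max_seg: float) -> np.ndarray:
    """Insert vertices so no polygon edge exceeds ``max_seg`` (mm)."""
    out = []
    n = len(poly)
    for i in range(n):
        a, b = poly[i], poly[(i + 1) % n]
        length = np.linalg.norm(b - a)
        k = max(1, int(np.ceil(length / max_seg)))
        for j in range(k):
            out.append(a + (b - a) * (j / k))
    return np.asarray(out)
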