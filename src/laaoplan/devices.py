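"""Parametric occluder models and size catalogs.

Two device families are modeled as closed surfaces of revolution about +z
with the proximal face (the side facing the left atrium) at z = 0:

* ``amulet`` — an Amplatzer-Amulet-like lobe-and-disc occluder: a flat
  proximal disc, a narrow waist, and a rounded-cylinder lobe whose diameter
  is the nominal size.
* ``watchman`` — a Watchman-like single convex plug: a cylinder of the
  nominal diameter capped distally by a spherical cap.

Exact manufacturer dimensions are not public in citable form; the default
geometry parameters encode the product-manual proportions (amulet disc =
lobe + 6 mm for sizes <= 22 mm, + 7 mm above; watchman depth = 0.8 x
nominal) and every one of them can be overridden per spec or via the YAML
catalog config.  Devices are impermeable closed walls — no fabric porosity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import LaaoError
from .geometry_core import FACE_LABELS, SurfaceMesh

FAMILIES = ("amulet", "watchman")

_DEFAULT_SIZES = {
    "watchman": [21.0, 24.0, 27.0, 30.0, 33.0],
    "amulet": [16.0, 18.0, 20.0, 22.0, 25.0, 28.0, 31.0, 34.0],
}

#: Watchman landing-diameter (D1) interval -> nominal size, public sizing chart.
_DEFAULT_WATCHMAN_MAP = [
    (17.0, 19.9, 21.0),
    (20.0, 22.9, 24.0),
    (23.0, 25.9, 27.0),
    (26.0, 28.9, 30.0),
    (29.0, 31.9, 33.0),
]


@dataclass
class DeviceSpec:
    """One occluder: family, nominal (lobe/frame) diameter, geometry params."""

    family: str
    nominal_size: float
    geometry_params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise LaaoError(
                f"unknown device family {self.family!r}; known: {FAMILIES}"
            )
        if self.nominal_size <= 0:
            raise ValueError("nominal_size must be positive")
        defaults = default_geometry(self.family, self.nominal_size)
        self.geometry_params = {**defaults, **self.geometry_params}
        if any(v <= 0 for v in self.geometry_params.values()):
            raise ValueError("all geometry parameters must be positive")

    @property
    def depth(self) -> float:
        """Axial extent of the device (mm)."""
        g = self.geometry_params
        if self.family == "watchman":
            return g["plug_depth"]
        return g["disc_thickness"] + g["disc_offset"] + g["lobe_length"]


def default_geometry(family: str, nominal: float) -> dict[str, float]:
    if family == "watchman":
        return {"plug_depth": 0.8 * nominal, "cap_radius": 0.5 * nominal}
    disc_extra = 6.0 if nominal <= 22.0 else 7.0
    return {
        "lobe_length": 10.0,
        "disc_diameter": nominal + disc_extra,
        "disc_offset": 4.0,  # axial disc-lobe gap; not stated publicly
        "disc_thickness": 2.0,
        "waist_radius": 3.0,
        "shoulder_radius": 1.5,
    }


@dataclass
class SizeCatalog:
    """Ordered nominal sizes for a family; watchman also maps D1 -> size."""

    family: str
    sizes: list[float]
    landing_map: list[tuple[float, float, float]] | None = None

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.sizes, self.sizes[1:])):
            raise ValueError("catalog sizes must be strictly increasing")

    def size_for_landing_diameter(self, d1: float) -> float | None:
        """Mapped size for a landing D1 (watchman chart); None if out of range."""
        if not self.landing_map:
            return None
        for lo, hi, size in self.landing_map:
            if lo <= d1 <= hi:
                return size
        return None

    def next_size_up(self, size: float) -> float | None:
        bigger = [s for s in self.sizes if s > size + 1e-9]
        return min(bigger) if bigger else None


def catalog(family: str, config: dict | str | None = None) -> SizeCatalog:
    """Default size catalog for a family, optionally overridden by config.

    ``config`` may be a dict or a path to a YAML file with optional keys
    ``sizes`` and (watchman) ``landing_map`` (list of [lo, hi, size]).
    """
    if family not in FAMILIES:
        raise LaaoError(f"unknown device family {family!r}; known: {FAMILIES}")
    cfg: dict = {}
    if isinstance(config, (str, bytes)) or hasattr(config, "read_text"):
        with open(config) as fh:
            cfg = yaml.safe_load(fh) or {}
    elif isinstance(config, dict):
        cfg = config
    sizes = [float(s) for s in cfg.get("sizes", _DEFAULT_SIZES[family])]
    lmap = None
    if family == "watchman":
        lmap = [tuple(map(float, row)) for row in
                cfg.get("landing_map", _DEFAULT_WATCHMAN_MAP)]
    return SizeCatalog(family=family, sizes=sizes, landing_map=lmap)


def catalog_to_yaml(cat: SizeCatalog, path) -> None:
    data = {"family": cat.family, "sizes": cat.sizes}
    if cat.landing_map:
        data["landing_map"] = [list(row) for row in cat.landing_map]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# meshing


def _profile(spec: DeviceSpec) -> np.ndarray:
    """Generating (z, r) polyline, r = 0 at both ends, z increasing overall."""
    g = spec.geometry_params
    if spec.family == "watchman":
        R = 0.5 * spec.nominal_size
        depth = g["plug_depth"]
        cap = min(g["cap_radius"], R, depth - 1e-6)  # cap height
        z_cap = depth - cap  # cylinder ends, cap begins
        pts = [(0.0, 0.0), (0.0, R), (z_cap, R)]
        # elliptical-profile cap from (z_cap, R) down to the axis at z = depth
        for a in np.linspace(0.0, np.pi / 2, 9)[1:]:
            pts.append((z_cap + cap * np.sin(a), R * np.cos(a)))
        return np.array(pts)

    lobe_R = 0.5 * spec.nominal_size
    disc_R = 0.5 * g["disc_diameter"]
    t, gap, L = g["disc_thickness"], g["disc_offset"], g["lobe_length"]
    w = min(g["waist_radius"], 0.8 * lobe_R)
    s = min(g["shoulder_radius"], 0.45 * L, 0.9 * (lobe_R - w))
    z_a = t + gap  # lobe proximal face
    z_b = z_a + L  # lobe distal face
    pts = [(0.0, 0.0), (0.0, disc_R), (t, disc_R), (t, w), (z_a, w)]
    # proximal shoulder: quarter arc up to the lobe radius
    for a in np.linspace(np.pi, np.pi / 2, 5)[1:]:
        pts.append((z_a + s + s * np.cos(a), (lobe_R - s) + s * np.sin(a)))
    # distal shoulder
    for a in np.linspace(np.pi / 2, 0.0, 5):
        pts.append((z_b - s + s * np.cos(a), (lobe_R - s) + s * np.sin(a)))
    pts.append((z_b, 0.0))
    return np.array(pts)


def _refine_profile(pts: np.ndarray, max_seg: float) -> np.ndarray:
    out = [pts[0]]
    for a, b in zip(pts[:-1], pts[1:]):
        length = float(np.hypot(*(b - a)))
        k = max(1, int(np.ceil(length / max_seg)))
        for j in range(1, k + 1):
            out.append(a + (b - a) * (j / k))
    res = np.array(out)
    keep = np.concatenate([[True], np.linalg.norm(np.diff(res, axis=0), axis=1) > 1e-12])
    return res[keep]


def build_device_mesh(spec: DeviceSpec, resolution: float = 1.0) -> SurfaceMesh:
    """Closed watertight surface of revolution for a device spec.

    The device axis is +z with the proximal face at z = 0.  ``resolution`` is
    the target edge length in mm; values coarser than nominal/8 are refused
    (self-intersection risk on the revolved shoulders).
    """
    if resolution > spec.nominal_size / 8.0:
        raise LaaoError(
            f"resolution {resolution} mm too coarse for a {spec.nominal_size} mm "
            f"device; need <= nominal/8 = {spec.nominal_size / 8.0:.2f} mm"
        )
    prof = _refine_profile(_profile(spec), resolution)
    r_max = prof[:, 1].max()
    n_theta = max(16, int(np.ceil(2 * np.pi * r_max / resolution)))
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)

    interior = prof[1:-1]  # r > 0 rows between the two axis poles
    verts = [np.array([0.0, 0.0, prof[0, 0]])]
    for z, r in interior:
        verts.extend(
            np.column_stack([r * np.cos(theta), r * np.sin(theta),
                             np.full(n_theta, z)])
        )
    verts.append(np.array([0.0, 0.0, prof[-1, 0]]))
    verts = np.vstack([np.atleast_2d(v) for v in verts])

    def ring(i: int) -> np.ndarray:  # vertex ids of interior ring i
        return 1 + i * n_theta + np.arange(n_theta)

    faces = []
    r0 = ring(0)
    for j in range(n_theta):  # proximal pole fan (outward normal at z=0-)
        faces.append([0, r0[(j + 1) % n_theta], r0[j]])
    for i in range(len(interior) - 1):
        a, b = ring(i), ring(i + 1)
        for j in range(n_theta):
            jn = (j + 1) % n_theta
            faces.append([a[j], a[jn], b[jn]])
            faces.append([a[j], b[jn], b[j]])
    last = ring(len(interior) - 1)
    tip = len(verts) - 1
    for j in range(n_theta):
        faces.append([tip, last[j], last[(j + 1) % n_theta]])

    mesh = SurfaceMesh(
        verts, np.array(faces, dtype=np.int64),
        np.full(len(faces), FACE_LABELS["device"], dtype=np.int64),
    )
    # orient outward: enclosed volume must be positive under the convention
    tm = mesh.to_trimesh()
    if tm.volume < 0:
        mesh.faces = mesh.faces[:, ::-1].copy()
    return mesh
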