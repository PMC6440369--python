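"""Automatic device configuration, scenario generation and CFD-ready export.

The automatic proposal places the device centre on the centreline at a fixed
geodesic depth from the ostium — 10 mm for the amulet family, 13 mm for the
watchman — with the device axis along the centreline tangent, i.e. the
device's transversal plane perpendicular to the centreline.  Sizing follows
the clinical rules: for the amulet, the target diameter is the mean of the
landing-section D1 and D2 plus a modality-dependent oversizing offset
(2–5 mm for CT, 3–6 mm for TEE; the range midpoint ranks candidates and the
full range is reported), escalated by a further 2–5 mm when the target falls
below D1; for the watchman, the nominal size comes from the D1 sizing chart.
Only devices achieving at least 10% compression of their nominal size at the
landing section are retained — the anchoring criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh
import yaml

from .centreline import Centreline, point_at_geodesic_distance
from .devices import DeviceSpec, SizeCatalog, build_device_mesh, catalog as _catalog
from .errors import LabelError, PlacementError
from .geometry_core import FACE_LABELS, OstiumPlane, SurfaceMesh, contains_points
from .morphometry import CrossSection, cross_section_at

#: Geodesic landing depth of the device centre from the ostium, per family (mm).
LANDING_DEPTH_MM = {"amulet": 10.0, "watchman": 13.0}

SCENARIO_TAGS = ("no_laao", "vidaa_init", "smaller_20", "misplaced", "vidaa_end")


class PlannerWarning(UserWarning):
    """Structured warning for planner edge cases (e.g. no admissible size)."""


@dataclass
class DevicePose:
    """Rigid placement: device origin at ``centre``, +z along ``axis``."""

    centre: np.ndarray
    axis: np.ndarray
    depth: float  # geodesic mm from the ostium to the centre

    def __post_init__(self) -> None:
        self.centre = np.asarray(self.centre, dtype=np.float64).reshape(3)
        a = np.asarray(self.axis, dtype=np.float64).reshape(3)
        self.axis = a / np.linalg.norm(a)
        if self.depth < 0:
            raise ValueError("depth must be >= 0")


@dataclass
class DeviceConfiguration:
    """One virtual implantation: device, pose, landing section, compression."""

    spec: DeviceSpec
    pose: DevicePose
    landing_section: CrossSection | None
    compression_pct: float
    scenario_tag: str = "vidaa_init"
    sizing_note: str = ""

    def __post_init__(self) -> None:
        if self.scenario_tag not in SCENARIO_TAGS:
            raise ValueError(f"unknown scenario tag {self.scenario_tag!r}")


@dataclass
class SizingRule:
    """Modality-dependent oversizing rule with the compression filter."""

    modality: str = "CT"
    offset_range: tuple[float, float] = (2.0, 5.0)
    undersize_escalation: tuple[float, float] = (2.0, 5.0)
    min_compression_pct: float = 10.0

    def __post_init__(self) -> None:
        if self.offset_range[0] > self.offset_range[1]:
            raise ValueError("offset_range lower bound exceeds upper")
        if self.min_compression_pct < 0:
            raise ValueError("min_compression_pct must be >= 0")

    @classmethod
    def for_modality(cls, modality: str) -> "SizingRule":
        ranges = {"CT": (2.0, 5.0), "TEE": (3.0, 6.0)}
        if modality not in ranges:
            raise ValueError(f"modality must be one of {sorted(ranges)}")
        return cls(modality=modality, offset_range=ranges[modality])


@dataclass
class MisplaceOpts:
    """Magnitudes of the deliberately sub-optimal 'misplaced' scenario."""

    extra_depth: float = 5.0  # mm deeper than the optimal landing zone
    tilt_deg: float = 15.0  # axis tilt off the centreline tangent


@dataclass
class BoundaryConditionSpec:
    """Solver-agnostic boundary conditions for one cardiac cycle.

    Defaults model a healthy-cycle rigid-wall atrium: systole (mitral valve
    closed, pulmonary veins as velocity inlets) lasting 0.40 s, diastole
    (mitral valve open as a pressure outlet at 8 mmHg) lasting 0.65 s, blood
    as an incompressible Newtonian fluid (rho = 1060 kg/m^3, mu = 0.0035
    Pa*s), and all walls — including the occluder — rigid with no slip.
    """

    systole_duration: float = 0.40  # s
    diastole_duration: float = 0.65  # s
    mv_outlet_pressure: float = 8.0  # mmHg
    blood_density: float = 1060.0  # kg/m^3
    blood_viscosity: float = 0.0035  # Pa*s (dynamic)
    rigid_no_slip_walls: bool = True
    inlet_waveform: dict | None = None  # {"times_s": [...], "multiplier": [...]}

    def __post_init__(self) -> None:
        if self.systole_duration <= 0 or self.diastole_duration <= 0:
            raise ValueError("phase durations must be positive")
        if self.blood_density <= 0 or self.blood_viscosity <= 0:
            raise ValueError("blood constants must be positive")

    @property
    def cycle_duration(self) -> float:
        return self.systole_duration + self.diastole_duration


def compression_pct(nominal: float, section: CrossSection) -> float:
    """Compression as % of nominal: 100 * (nominal - mean(D1, D2)) / nominal."""
    return 100.0 * (nominal - section.mean_diameter()) / nominal


# ---------------------------------------------------------------------------
# automatic proposal


def propose_configuration(
    mesh: SurfaceMesh,
    cl: Centreline,
    family: str,
    modality: str = "CT",
    rules: SizingRule | None = None,
    size_catalog: SizeCatalog | None = None,
) -> list[DeviceConfiguration]:
    """Automatically proposed device configurations (the vidaa_init set).

    Returns up to three candidates for the amulet and two for the watchman,
    ordered by closeness to the sizing target; an empty list (with a
    :class:`PlannerWarning`) means no catalog size passed the >= 10%
    compression filter — the in-silico analogue of needing a second device.
    """
    if family not in LANDING_DEPTH_MM:
        raise ValueError(f"family must be one of {sorted(LANDING_DEPTH_MM)}")
    rules = rules or SizingRule.for_modality(modality)
    cat = size_catalog or _catalog(family)
    depth = LANDING_DEPTH_MM[family]
    if cl.length <= depth:
        raise PlacementError(
            f"centreline ({cl.length:.1f} mm) shorter than the {family} "
            f"landing depth {depth} mm"
        )
    section = cross_section_at(mesh, cl, depth)
    origin, tangent = point_at_geodesic_distance(cl, depth)
    pose = DevicePose(centre=origin, axis=tangent, depth=depth)
    d1, d2 = section.d1_max_diameter, section.d2_min_diameter
    mean_d = section.mean_diameter()

    if family == "amulet":
        offset_mid = 0.5 * sum(rules.offset_range)
        target = mean_d + offset_mid
        note = (f"target = mean(D1,D2) {mean_d:.1f} + {modality} offset "
                f"{rules.offset_range[0]:.0f}-{rules.offset_range[1]:.0f} mm "
                f"(mid {offset_mid:.1f})")
        if target < d1:
            esc_mid = 0.5 * sum(rules.undersize_escalation)
            target += esc_mid
            note += f"; escalated +{esc_mid:.1f} mm (target < D1 {d1:.1f})"
        candidates = [s for s in cat.sizes if s >= target]
        candidates = [
            s for s in candidates
            if compression_pct(s, section) >= rules.min_compression_pct
        ]
        candidates = sorted(candidates, key=lambda s: abs(s - target))[:3]
    else:
        mapped = cat.size_for_landing_diameter(d1)
        target = d1
        note = f"watchman chart lookup for D1 = {d1:.1f} mm"
        candidates = []
        if mapped is not None:
            candidates.append(mapped)
            nxt = cat.next_size_up(mapped)
            if nxt is not None:
                candidates.append(nxt)
        candidates = [
            s for s in candidates
            if compression_pct(s, section) >= rules.min_compression_pct
        ][:2]

    if not candidates:
        warnings.warn(
            f"no {family} catalog size satisfies >= "
            f"{rules.min_compression_pct:.0f}% compression at the landing zone "
            f"(D1={d1:.1f}, D2={d2:.1f} mm); a second device or manual "
            f"repositioning would be needed",
            PlannerWarning, stacklevel=2,
        )
        return []

    configs = []
    for size in sorted(candidates, key=lambda s: abs(s - target)):
        spec = DeviceSpec(family=family, nominal_size=float(size))
        configs.append(
            DeviceConfiguration(
                spec=spec,
                pose=replace(pose),
                landing_section=section,
                compression_pct=compression_pct(size, section),
                scenario_tag="vidaa_init",
                sizing_note=note,
            )
        )
    return configs


# ---------------------------------------------------------------------------
# scenarios and overrides


def _perpendicular(axis: np.ndarray) -> np.ndarray:
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(axis)))] = 1.0
    p = np.cross(axis, helper)
    return p / np.linalg.norm(p)


def _tilt(axis: np.ndarray, tilt_deg: float) -> np.ndarray:
    """Rotate ``axis`` by ``tilt_deg`` about a deterministic perpendicular."""
    perp = _perpendicular(axis)
    rot = trimesh.transformations.rotation_matrix(np.deg2rad(tilt_deg), perp)
    return (rot[:3, :3] @ axis).astype(float)


def make_scenarios(
    base: DeviceConfiguration,
    misplace_opts: MisplaceOpts | None = None,
    mesh: SurfaceMesh | None = None,
    cl: Centreline | None = None,
    snap_to_catalog: bool = False,
    size_catalog: SizeCatalog | None = None,
) -> list[DeviceConfiguration]:
    """Derive the simulation scenarios from a vidaa_init configuration.

    Emits the base itself plus ``smaller_20`` (the whole device scaled to 80%
    of nominal — kept un-snapped by default, since it is the device that
    shrinks, not the catalog choice) and ``misplaced`` (deeper by
    ``extra_depth`` and tilted by ``tilt_deg``).  The no-device scenario is
    represented by the absence of a configuration.  When ``mesh`` and ``cl``
    are given, landing sections and compression are recomputed at the moved
    depth.
    """
    if base.scenario_tag != "vidaa_init":
        raise ValueError("scenarios derive from a vidaa_init configuration")
    opts = misplace_opts or MisplaceOpts()

    small_nominal = 0.8 * base.spec.nominal_size
    if snap_to_catalog:
        cat = size_catalog or _catalog(base.spec.family)
        small_nominal = min(cat.sizes, key=lambda s: abs(s - small_nominal))
    small_spec = DeviceSpec(
        family=base.spec.family,
        nominal_size=small_nominal,
        geometry_params={
            k: 0.8 * v for k, v in base.spec.geometry_params.items()
        } if not snap_to_catalog else {},
    )
    smaller = DeviceConfiguration(
        spec=small_spec,
        pose=replace(base.pose),
        landing_section=base.landing_section,
        compression_pct=compression_pct(small_nominal, base.landing_section),
        scenario_tag="smaller_20",
    )

    new_depth = base.pose.depth + opts.extra_depth
    if mesh is not None and cl is not None and new_depth < cl.length:
        centre, tangent = point_at_geodesic_distance(cl, new_depth)
        section = cross_section_at(mesh, cl, new_depth)
    else:
        centre = base.pose.centre + opts.extra_depth * base.pose.axis
        tangent = base.pose.axis
        section = base.landing_section
    mis_pose = DevicePose(
        centre=centre, axis=_tilt(tangent, opts.tilt_deg), depth=new_depth
    )
    misplaced = DeviceConfiguration(
        spec=base.spec,
        pose=mis_pose,
        landing_section=section,
        compression_pct=compression_pct(base.spec.nominal_size, section),
        scenario_tag="misplaced",
    )
    return [base, smaller, misplaced]


def apply_override(
    cfg: DeviceConfiguration,
    new_pose: DevicePose | None = None,
    new_size: float | None = None,
    preset: str | None = None,
    mesh: SurfaceMesh | None = None,
    cl: Centreline | None = None,
    ostium: OstiumPlane | None = None,
) -> DeviceConfiguration:
    """Interactive-style override of pose and/or size, tagged ``vidaa_end``.

    The ``ostium_flush`` preset centres the device on the ostium plane with
    its axis along the inward plane normal, so the proximal face lies in the
    plane and the device uniformly covers the LA/LAA junction.  Compression
    is recomputed against the cross-section at the new depth when ``mesh``
    and ``cl`` are available; a size below the landing D2 yields negative
    compression and a warning.
    """
    pose = new_pose or replace(cfg.pose)
    if preset == "ostium_flush":
        if ostium is None:
            raise ValueError("ostium_flush preset requires the ostium plane")
        pose = DevicePose(centre=ostium.origin, axis=-ostium.normal, depth=0.0)
    elif preset is not None:
        raise ValueError(f"unknown preset {preset!r}")

    spec = cfg.spec
    if new_size is not None:
        spec = DeviceSpec(family=cfg.spec.family, nominal_size=float(new_size))

    section = cfg.landing_section
    if mesh is not None and cl is not None and 0 <= pose.depth <= cl.length:
        section = cross_section_at(mesh, cl, pose.depth)
        if not bool(contains_points(mesh, pose.centre[None])[0]):
            raise PlacementError(
                f"override centre {pose.centre} lies outside the lumen"
            )
    comp = compression_pct(spec.nominal_size, section)
    if comp < 0:
        warnings.warn(
            f"nominal {spec.nominal_size:.1f} mm is below the landing mean "
            f"diameter; compression is negative ({comp:.1f}%)",
            PlannerWarning, stacklevel=2,
        )
    return DeviceConfiguration(
        spec=spec, pose=pose, landing_section=section,
        compression_pct=comp, scenario_tag="vidaa_end",
        sizing_note=cfg.sizing_note,
    )


# ---------------------------------------------------------------------------
# implantation and CFD export


def pose_transform(pose: DevicePose) -> np.ndarray:
    """Homogeneous transform taking the canonical +z device to its pose."""
    rot = trimesh.geometry.align_vectors([0.0, 0.0, 1.0], pose.axis)
    t = np.eye(4)
    t[:3, 3] = pose.centre
    return t @ rot


def implant(
    mesh: SurfaceMesh,
    cfg: DeviceConfiguration,
    resolution: float = 1.0,
) -> tuple[SurfaceMesh, dict]:
    """Two-surface CFD domain: the LA shell plus the posed device surface.

    The device is rigid-transformed from its canonical frame (+z axis,
    proximal face at the origin) into the pose.  Radial interference with the
    LA wall is expected under compression; the returned diagnostics report
    the number of LA faces with at least one vertex inside the device rather
    than forbidding contact.  A proximal face centred outside the lumen is a
    placement error.
    """
    if not bool(contains_points(mesh, cfg.pose.centre[None])[0]):
        raise PlacementError(
            f"device proximal face centre {cfg.pose.centre} is outside the lumen"
        )
    dev = build_device_mesh(cfg.spec, resolution=resolution)
    xform = pose_transform(cfg.pose)
    dev_pts = (dev.vertices @ xform[:3, :3].T) + xform[:3, 3]
    dev = SurfaceMesh(dev_pts, dev.faces, dev.face_labels)

    dev_tm = dev.to_trimesh()
    bb_lo, bb_hi = dev_tm.bounds
    near = np.all((mesh.vertices >= bb_lo - 1e-9) & (mesh.vertices <= bb_hi + 1e-9),
                  axis=1)
    inside = np.zeros(mesh.n_vertices, dtype=bool)
    if near.any():
        inside[near] = contains_points(dev, mesh.vertices[near])
    interference = int(np.count_nonzero(inside[mesh.faces].any(axis=1)))

    combined = SurfaceMesh(
        np.vstack([mesh.vertices, dev.vertices]),
        np.vstack([mesh.faces, dev.faces + mesh.n_vertices]),
        np.concatenate([mesh.face_labels, dev.face_labels]),
    )
    diagnostics = {
        "interference_faces": interference,
        "device_volume_mm3": dev.enclosed_volume(),
        "scenario_tag": cfg.scenario_tag,
    }
    return combined, diagnostics


def export_cfd_case(
    domain: SurfaceMesh,
    bc: BoundaryConditionSpec,
    out_dir,
    waveform_samples: int = 64,
) -> Path:
    """Write a solver-agnostic CFD case bundle; returns the manifest path.

    The bundle holds the labeled domain surface (``domain.vtp``) and a YAML
    manifest with two phases: systole — pulmonary veins as velocity inlets
    scaled by the (default sinusoidal) waveform, mitral valve as a wall — and
    diastole — mitral valve as a pressure outlet.  All walls and the device
    are rigid no-slip.  Output is bit-stable for identical inputs.
    """
    from .io import write_mesh  # local import: io depends on geometry only

    present = set(domain.face_labels.tolist())
    required = {"wall", "pv_inlet", "mv_outlet"}
    missing = [name for name in sorted(required)
               if FACE_LABELS[name] not in present]
    if missing:
        raise LabelError(f"domain is missing label class(es): {', '.join(missing)}")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_mesh(domain, out_dir / "domain.vtp", "vtp")

    if bc.inlet_waveform is None:
        from .synthetic_data import make_inlet_waveform

        times, mult = make_inlet_waveform(bc, waveform_samples)
        waveform = {
            "times_s": [round(float(t), 9) for t in times],
            "multiplier": [round(float(m), 9) for m in mult],
        }
    else:
        waveform = bc.inlet_waveform

    manifest = {
        "units": {"length": "mm", "pressure": "mmHg", "time": "s"},
        "blood": {
            "density_kg_m3": bc.blood_density,
            "dynamic_viscosity_Pa_s": bc.blood_viscosity,
        },
        "cycle": {
            "systole_duration_s": bc.systole_duration,
            "diastole_duration_s": bc.diastole_duration,
            "period_s": round(bc.cycle_duration, 9),
        },
        "phases": [
            {
                "name": "systole",
                "duration_s": bc.systole_duration,
                "pv_inlet": {"type": "velocity_inlet",
                             "waveform": "inlet_waveform"},
                "mv_outlet": {"type": "wall"},
            },
            {
                "name": "diastole",
                "duration_s": bc.diastole_duration,
                "pv_inlet": {"type": "velocity_inlet",
                             "waveform": "inlet_waveform"},
                "mv_outlet": {"type": "pressure_outlet",
                              "pressure_mmHg": bc.mv_outlet_pressure},
            },
        ],
        "walls": {"model": "rigid_no_slip",
                  "applies_to": ["wall", "device"]},
        "inlet_waveform": waveform,
        "labels": dict(FACE_LABELS),
        "mesh_file": "domain.vtp",
    }
    manifest_path = out_dir / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path


def read_cfd_manifest(path) -> dict:
    """Round-trip reader for the manifest written by :func:`export_cfd_case`."""
    with open(path) as fh:
        return yaml.safe_load(fh)
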