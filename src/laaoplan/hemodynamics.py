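"""Thrombus-risk indices from time-resolved wall-shear-stress data.

For the wall-shear-stress vector tau_w(x, t) over one cardiac cycle of
length T the standard indices are

* TAWSS  = (1/T) * int_0^T |tau_w| dt                       [Pa]
* OSI    = 1/2 * (1 - |int_0^T tau_w dt| / int_0^T |tau_w| dt)   [-]
* ECAP   = OSI / TAWSS                                      [1/Pa]

OSI is 0 for perfectly unidirectional shear and 1/2 for fully oscillatory
shear; high ECAP marks slow (low TAWSS) and complex (high OSI) flow — the
regions where thrombus is likely to form.  Time integrals use the
trapezoidal rule on the solver's own sampling.  Nodes with zero shear over
the whole cycle get OSI = 0 and are flagged invalid for ECAP, keeping
downstream histograms finite.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .centreline import Centreline
from .errors import LaaoError, RangeError, TopologyError
from .geometry_core import FACE_LABELS, OstiumPlane, SurfaceMesh
from .planner import DeviceConfiguration

#: Default ECAP histogram bin edges (1/Pa); the last bin is open-ended and 3
#: is an edge so the ">3" high-risk summary is a bin sum.
DEFAULT_ECAP_EDGES = (0.0, 0.5, 1.0, 2.0, 3.0, np.inf)

#: High-risk ECAP threshold used in the scenario-ranking summary (1/Pa).
ECAP_RISK_THRESHOLD = 3.0

#: Default probe offset into the LA body from the ostium (mm).
DEFAULT_PROBE_OFFSET = 5.0


@dataclass
class WSSTimeSeries:
    """Per-node wall-shear-stress vectors (Pa) over one cycle [0, T]."""

    surface_ref: SurfaceMesh
    times: np.ndarray  # (T,), s, strictly increasing
    vectors: np.ndarray  # (T, n, 3), Pa

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if len(self.times) < 3:
            raise ValueError("need at least 3 time samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.vectors.shape != (
            len(self.times), self.surface_ref.n_vertices, 3
        ):
            raise ValueError("vectors must be (n_times, n_nodes, 3)")


@dataclass
class HemoIndexField:
    """Per-wall-node TAWSS (Pa), OSI (-), ECAP (1/Pa) with lumped node areas."""

    surface_ref: SurfaceMesh
    tawss: np.ndarray
    osi: np.ndarray
    ecap: np.ndarray
    node_area: np.ndarray  # mm^2
    valid: np.ndarray  # bool; False where ECAP is undefined (TAWSS = 0)


@dataclass
class EcapHistogram:
    bin_edges: np.ndarray  # 1/Pa, last edge may be inf
    percentages: np.ndarray  # % per bin, sums to 100
    weighting: str  # 'node_count' or 'surface_area'
    n_invalid: int = 0

    def pct_above(self, threshold: float) -> float:
        """Summed percentage of bins whose lower edge is >= threshold."""
        idx = np.flatnonzero(self.bin_edges[:-1] >= threshold - 1e-12)
        return float(self.percentages[idx].sum())


@dataclass
class VelocityProbe:
    location: np.ndarray  # mm
    times: np.ndarray  # s
    speed: np.ndarray  # m/s


@dataclass
class FlowSeries:
    """Sampled velocity field: probe points (mm) and velocities (m/s)."""

    points: np.ndarray  # (p, 3)
    times: np.ndarray  # (T,)
    velocities: np.ndarray  # (T, p, 3)


def compute_indices(wss: WSSTimeSeries) -> HemoIndexField:
    """TAWSS, OSI and ECAP by trapezoidal integration over the cycle."""
    t = wss.times
    T = t[-1] - t[0]
    mag = np.linalg.norm(wss.vectors, axis=2)  # (T, n)
    int_mag = np.trapezoid(mag, t, axis=0)  # (n,)
    int_vec = np.trapezoid(wss.vectors, t, axis=0)  # (n, 3)
    tawss = int_mag / T
    with np.errstate(divide="ignore", invalid="ignore"):
        osi = 0.5 * (1.0 - np.linalg.norm(int_vec, axis=1) / int_mag)
    zero = int_mag <= 0.0
    osi[zero] = 0.0
    osi = np.clip(osi, 0.0, 0.5)
    valid = ~zero
    ecap = np.zeros_like(tawss)
    ecap[valid] = osi[valid] / tawss[valid]
    return HemoIndexField(
        surface_ref=wss.surface_ref,
        tawss=tawss, osi=osi, ecap=ecap,
        node_area=wss.surface_ref.vertex_areas(),
        valid=valid,
    )


def _project_arclength(points: np.ndarray, cl: Centreline) -> np.ndarray:
    """Arc-length station of the closest centreline point for each input point."""
    a = cl.points[:-1]  # (m, 3) segment starts
    d = cl.points[1:] - a  # (m, 3)
    seg_len2 = (d**2).sum(axis=1)
    seg_len2[seg_len2 == 0] = 1.0
    # (n, m) parameter of the foot of the perpendicular on each segment
    w = points[:, None, :] - a[None, :, :]
    tpar = np.clip((w * d[None]).sum(axis=2) / seg_len2[None], 0.0, 1.0)
    foot = a[None] + tpar[..., None] * d[None]
    dist2 = ((points[:, None, :] - foot) ** 2).sum(axis=2)
    best = np.argmin(dist2, axis=1)
    n = len(points)
    return cl.arc_length[best] + tpar[np.arange(n), best] * np.sqrt(
        seg_len2[best]
    )


def roi_between_ostium_and_device(
    fld: HemoIndexField,
    ostium: OstiumPlane,
    cfg: DeviceConfiguration | None,
    cl: Centreline,
) -> np.ndarray:
    """Wall-node mask of the region between the ostium and the device.

    Selects nodes on the LAA side of the ostium plane whose arc-length
    projection onto the centreline lies in [0, device proximal station];
    device-surface nodes are excluded.  Without a device (the no-occluder
    scenario) the mask covers the whole LAA distal to the ostium.
    """
    mesh = fld.surface_ref
    vlab = mesh.vertex_labels()
    on_device = vlab == FACE_LABELS["device"]
    laa_side = ostium.signed_distance(mesh.vertices) < 0.0
    s = _project_arclength(mesh.vertices, cl)
    if cfg is None:
        mask = laa_side & ~on_device
    else:
        mask = laa_side & ~on_device & (s >= 0.0) & (s <= cfg.pose.depth)
    return mask


def ecap_histogram(
    fld: HemoIndexField,
    mask: np.ndarray,
    bin_edges=DEFAULT_ECAP_EDGES,
    weighting: str = "surface_area",
) -> EcapHistogram:
    """ECAP distribution over the masked nodes as percentages per bin.

    ``weighting='surface_area'`` (default) weights each node by its lumped
    area — the physically meaningful reading; ``'node_count'`` counts nodes.
    Invalid nodes (undefined ECAP) are excluded and counted.
    """
    if weighting not in ("surface_area", "node_count"):
        raise ValueError("weighting must be 'surface_area' or 'node_count'")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise LaaoError("empty node mask: no region of interest")
    use = mask & fld.valid
    n_invalid = int(np.count_nonzero(mask & ~fld.valid))
    if not use.any():
        raise LaaoError("all nodes in the mask have undefined ECAP")
    edges = np.asarray(bin_edges, dtype=float)
    weights = fld.node_area[use] if weighting == "surface_area" else None
    hist, _ = np.histogram(fld.ecap[use], bins=edges, weights=weights)
    pct = 100.0 * hist / hist.sum()
    return EcapHistogram(
        bin_edges=edges, percentages=pct, weighting=weighting,
        n_invalid=n_invalid,
    )


def probe_velocity(
    flow: FlowSeries,
    cl: Centreline,
    ostium: OstiumPlane,
    offset: float = DEFAULT_PROBE_OFFSET,
    max_distance: float | None = None,
) -> VelocityProbe:
    """Speed-over-cycle at a point outside the device, toward the LA body.

    The probe sits at the centreline's ostium crossing displaced by
    ``offset`` mm along the reversed centreline tangent (into the LA cavity).
    The nearest flow sample is used; ``max_distance`` (mm) guards against
    probing outside the sampled domain.
    """
    if offset < 0:
        raise RangeError("offset must be >= 0")
    location = cl.points[0] - offset * cl.tangents[0]
    dist = np.linalg.norm(flow.points - location, axis=1)
    nearest = int(np.argmin(dist))
    if max_distance is not None and dist[nearest] > max_distance:
        raise TopologyError(
            f"probe at {location} is {dist[nearest]:.2f} mm from the nearest "
            f"flow sample (limit {max_distance} mm); outside the domain?"
        )
    speed = np.linalg.norm(flow.velocities[:, nearest, :], axis=1)
    return VelocityProbe(
        location=location, times=np.asarray(flow.times, dtype=float),
        speed=speed,
    )


# ---------------------------------------------------------------------------
# reporting


def render_report(
    scenarios: dict[str, tuple[HemoIndexField, EcapHistogram, VelocityProbe | None]],
    out_dir,
) -> Path:
    """Write per-scenario index surfaces, histograms, probes and a summary.

    ``scenarios`` maps a scenario tag to (index field, ROI histogram,
    optional probe).  Per scenario the labeled surface goes out as VTP with
    point-data arrays ``TAWSS_Pa``, ``OSI`` and ``ECAP_invPa``; histograms
    and probes go out as CSV.  ``summary.csv`` ranks scenarios by the
    percentage of ROI area with ECAP above the high-risk threshold (lower is
    better).  Regeneration is bit-identical for identical inputs.
    """
    from .io import _write_vtp  # shared bit-stable VTP writer

    if not scenarios:
        raise LaaoError("at least one scenario is required")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    summary_rows = []
    for tag in sorted(scenarios):
        fld, hist, probe = scenarios[tag]
        point_data = {
            "TAWSS_Pa": fld.tawss, "OSI": fld.osi, "ECAP_invPa": fld.ecap,
        }
        (out_dir / f"{tag}_indices.vtp").write_text(
            _write_vtp(fld.surface_ref, point_data=point_data)
        )
        with open(out_dir / f"{tag}_ecap_histogram.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["bin_lo_invPa", "bin_hi_invPa", f"pct_{hist.weighting}"])
            for lo, hi, pct in zip(
                hist.bin_edges[:-1], hist.bin_edges[1:], hist.percentages
            ):
                w.writerow([f"{lo:g}", f"{hi:g}", f"{pct:.6f}"])
        if probe is not None:
            with open(out_dir / f"{tag}_probe.csv", "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["time_s", "speed_m_s"])
                for t, v in zip(probe.times, probe.speed):
                    w.writerow([f"{t:.9e}", f"{v:.9e}"])
        summary_rows.append((tag, hist.pct_above(ECAP_RISK_THRESHOLD)))

    summary_rows.sort(key=lambda row: (row[1], row[0]))
    summary_path = out_dir / "summary.csv"
    with open(summary_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["rank", "scenario", "pct_roi_ecap_above_3"])
        for rank, (tag, pct) in enumerate(summary_rows, start=1):
            w.writerow([rank, tag, f"{pct:.6f}"])
    return summary_path


def read_wss_csv(path, surface: SurfaceMesh) -> WSSTimeSeries:
    """Long-format CSV reader: columns node_id, t, taux, tauy, tauz."""
    raw = np.loadtxt(path, delimiter=",", skiprows=1)
    nodes = raw[:, 0].astype(int)
    times = np.unique(raw[:, 1])
    n = surface.n_vertices
    vectors = np.zeros((len(times), n, 3))
    t_index = {t: i for i, t in enumerate(times)}
    for row in raw:
        vectors[t_index[row[1]], int(row[0])] = row[2:5]
    return WSSTimeSeries(surface_ref=surface, times=times, vectors=vectors)
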