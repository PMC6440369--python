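"""Mesh file I/O: STL, PLY, VTK legacy, VTU/VTP (ASCII XML) and MSH v2.2.

STL and PLY carry geometry only and go through trimesh.  The VTK-family and
MSH dialects are written and parsed here directly as small ASCII subsets:
face labels travel as an integer cell-data array named ``label`` (VTK) or as
the physical tag (MSH), using the :data:`~laaoplan.geometry_core.FACE_LABELS`
code table.  Output is bit-stable: fixed field order and fixed ``%.9e``
float formatting.
"""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import trimesh

from .errors import MeshFormatError, UnsupportedElementError
from .geometry_core import FACE_LABELS, SurfaceMesh, VolumeMesh

_FLOAT_FMT = "{:.9e}"
_SUPPORTED = ("stl", "ply", "vtk", "vtp", "vtu", "msh")
_LABEL_COMMENT = "labels " + " ".join(f"{k}={v}" for k, v in FACE_LABELS.items())


def _fmt_floats(arr: np.ndarray) -> str:
    return " ".join(_FLOAT_FMT.format(x) for x in arr)


def _detect_format(path: Path, format_hint: str | None) -> str:
    fmt = (format_hint or path.suffix.lstrip(".")).lower()
    if fmt not in _SUPPORTED:
        raise MeshFormatError(
            f"unknown format {fmt!r}; supported: {', '.join(_SUPPORTED)}"
        )
    return fmt


# ---------------------------------------------------------------------------
# public API


def read_mesh(path, format_hint: str | None = None) -> SurfaceMesh | VolumeMesh:
    """Read a surface or volume mesh; labels recovered when the format has them.

    Coordinates are assumed to be millimetres and are not rescaled.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format_hint)
    try:
        if fmt in ("stl", "ply"):
            tm = trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
            if fmt == "stl":
                tm.merge_vertices()  # STL stores triangle soup
            return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
        text = path.read_text()
        if fmt == "vtk":
            return _read_vtk_legacy(text)
        if fmt == "vtp":
            return _read_vtp(text)
        if fmt == "vtu":
            return _read_vtu(text)
        return _read_msh(text)
    except (MeshFormatError, UnsupportedElementError):
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap with location info
        raise MeshFormatError(f"cannot parse {path} as {fmt}: {exc}") from exc


def write_mesh(mesh: SurfaceMesh | VolumeMesh, path, format: str | None = None) -> Path:
    """Write a mesh; returns the path written.

    STL/PLY drop labels (a warning is issued when non-wall labels exist);
    VTK-family and MSH preserve them.
    """
    path = Path(path)
    fmt = _detect_format(path, format)
    is_surface = isinstance(mesh, SurfaceMesh)
    if fmt in ("stl", "ply"):
        if not is_surface:
            raise UnsupportedElementError(f"{fmt} cannot store tetrahedra")
        if np.any(mesh.face_labels != 0):
            warnings.warn(f"{fmt} does not carry labels; they are dropped",
                          stacklevel=2)
        tm = mesh.to_trimesh()
        path.write_bytes(trimesh.exchange.export.export_mesh(tm, None, file_type=fmt))
        return path
    if fmt == "vtk":
        path.write_text(_write_vtk_legacy(mesh))
    elif fmt == "vtp":
        if not is_surface:
            raise UnsupportedElementError("vtp stores surfaces only; use vtu")
        path.write_text(_write_vtp(mesh))
    elif fmt == "vtu":
        path.write_text(_write_vtu(mesh))
    else:
        path.write_text(_write_msh(mesh))
    return path


# ---------------------------------------------------------------------------
# VTK legacy ASCII


def _write_vtk_legacy(mesh: SurfaceMesh | VolumeMesh) -> str:
    lines = ["# vtk DataFile Version 3.0", f"laaoplan mesh; {_LABEL_COMMENT}", "ASCII"]
    if isinstance(mesh, SurfaceMesh):
        lines.append("DATASET POLYDATA")
        lines.append(f"POINTS {mesh.n_vertices} double")
        lines += [_fmt_floats(v) for v in mesh.vertices]
        lines.append(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}")
        lines += [f"3 {a} {b} {c}" for a, b, c in mesh.faces]
        lines.append(f"CELL_DATA {mesh.n_faces}")
        lines.append("SCALARS label int 1")
        lines.append("LOOKUP_TABLE default")
        lines += [str(x) for x in mesh.face_labels]
    else:
        lines.append("DATASET UNSTRUCTURED_GRID")
        lines.append(f"POINTS {len(mesh.vertices)} double")
        lines += [_fmt_floats(v) for v in mesh.vertices]
        n = len(mesh.tets)
        lines.append(f"CELLS {n} {5 * n}")
        lines += [f"4 {a} {b} {c} {d}" for a, b, c, d in mesh.tets]
        lines.append(f"CELL_TYPES {n}")
        lines += ["10"] * n
    return "\n".join(lines) + "\n"


def _read_vtk_legacy(text: str) -> SurfaceMesh | VolumeMesh:
    tokens = text.split()
    lower = [t.lower() for t in tokens]

    def _find(word: str) -> int:
        try:
            return lower.index(word.lower())
        except ValueError as exc:
            offset = text.lower().find(word.lower())
            raise MeshFormatError(
                f"missing {word} section (searched to byte {len(text)}, "
                f"found at {offset})"
            ) from exc

    i = _find("POINTS")
    npts = int(tokens[i + 1])
    pts = np.array(tokens[i + 3 : i + 3 + 3 * npts], dtype=float).reshape(npts, 3)

    if "polygons" in lower:
        i = _find("POLYGONS")
        ncells = int(tokens[i + 1])
        total = int(tokens[i + 2])
        raw = np.array(tokens[i + 3 : i + 3 + total], dtype=np.int64)
        faces = []
        j = 0
        for _ in range(ncells):
            k = int(raw[j])
            if k != 3:
                raise UnsupportedElementError("only triangles supported in POLYGONS")
            faces.append(raw[j + 1 : j + 4])
            j += k + 1
        faces = np.array(faces, dtype=np.int64)
        labels = None
        if "cell_data" in lower and "label" in lower:
            i = lower.index("label")
            # SCALARS label int 1 / LOOKUP_TABLE default / values...
            i = lower.index("default", i) + 1
            labels = np.array(tokens[i : i + ncells], dtype=np.int64)
        return SurfaceMesh(pts, faces, labels)

    if "cells" in lower:
        i = _find("CELLS")
        ncells = int(tokens[i + 1])
        total = int(tokens[i + 2])
        raw = np.array(tokens[i + 3 : i + 3 + total], dtype=np.int64)
        tets = []
        j = 0
        for _ in range(ncells):
            k = int(raw[j])
            if k != 4:
                raise UnsupportedElementError("only tetrahedra supported in CELLS")
            tets.append(raw[j + 1 : j + 5])
            j += k + 1
        return VolumeMesh(pts, np.array(tets, dtype=np.int64))

    raise MeshFormatError("no POLYGONS or CELLS section found")


# ---------------------------------------------------------------------------
# VTK XML (ASCII appended-free)


def _xml_data_array(name: str, arr: np.ndarray, dtype: str, ncomp: int) -> str:
    if dtype == "Float64":
        body = " ".join(_FLOAT_FMT.format(x) for x in arr.ravel())
    else:
        body = " ".join(str(int(x)) for x in arr.ravel())
    comp = f' NumberOfComponents="{ncomp}"' if ncomp > 1 else ""
    return (
        f'<DataArray type="{dtype}" Name="{name}"{comp} format="ascii">'
        f"{body}</DataArray>"
    )


def _write_vtp(mesh: SurfaceMesh, point_data: dict | None = None) -> str:
    n, m = mesh.n_vertices, mesh.n_faces
    conn = mesh.faces.ravel()
    offs = 3 * (np.arange(m, dtype=np.int64) + 1)
    pd = ""
    if point_data:
        arrays = "".join(
            _xml_data_array(name, np.asarray(arr, dtype=float), "Float64", 1)
            for name, arr in point_data.items()
        )
        pd = f"<PointData>{arrays}</PointData>\n"
    return (
        '<?xml version="1.0"?>\n'
        f"<!-- {_LABEL_COMMENT} -->\n"
        '<VTKFile type="PolyData" version="0.1" byte_order="LittleEndian">\n'
        "<PolyData>\n"
        f'<Piece NumberOfPoints="{n}" NumberOfPolys="{m}">\n'
        "<Points>" + _xml_data_array("Points", mesh.vertices, "Float64", 3)
        + "</Points>\n"
        "<Polys>" + _xml_data_array("connectivity", conn, "Int64", 1)
        + _xml_data_array("offsets", offs, "Int64", 1) + "</Polys>\n"
        + pd
        + "<CellData>" + _xml_data_array("label", mesh.face_labels, "Int64", 1)
        + "</CellData>\n"
        "</Piece>\n</PolyData>\n</VTKFile>\n"
    )


def _write_vtu(mesh: SurfaceMesh | VolumeMesh) -> str:
    if isinstance(mesh, SurfaceMesh):
        cells, ctype, labels = mesh.faces, 5, mesh.face_labels
    else:
        cells, ctype = mesh.tets, 10
        labels = np.zeros(len(cells), dtype=np.int64)
    n, m = len(mesh.vertices), len(cells)
    k = cells.shape[1]
    offs = k * (np.arange(m, dtype=np.int64) + 1)
    types = np.full(m, ctype, dtype=np.int64)
    return (
        '<?xml version="1.0"?>\n'
        f"<!-- {_LABEL_COMMENT} -->\n"
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">\n'
        "<UnstructuredGrid>\n"
        f'<Piece NumberOfPoints="{n}" NumberOfCells="{m}">\n'
        "<Points>" + _xml_data_array("Points", mesh.vertices, "Float64", 3)
        + "</Points>\n"
        "<Cells>" + _xml_data_array("connectivity", cells.ravel(), "Int64", 1)
        + _xml_data_array("offsets", offs, "Int64", 1)
        + _xml_data_array("types", types, "Int64", 1) + "</Cells>\n"
        "<CellData>" + _xml_data_array("label", labels, "Int64", 1)
        + "</CellData>\n"
        "</Piece>\n</UnstructuredGrid>\n</VTKFile>\n"
    )


def _xml_find_array(piece: ET.Element, section: str, name: str) -> np.ndarray | None:
    sec = piece.find(section)
    if sec is None:
        return None
    for da in sec.iter("DataArray"):
        if da.get("Name") == name:
            vals = (da.text or "").split()
            if da.get("type", "").startswith("Float"):
                return np.array(vals, dtype=float)
            return np.array(vals, dtype=np.int64)
    return None


def _read_vtp(text: str) -> SurfaceMesh:
    root = ET.fromstring(text)
    piece = root.find(".//Piece")
    if piece is None:
        raise MeshFormatError("no <Piece> element")
    pts = _xml_find_array(piece, "Points", "Points").reshape(-1, 3)
    conn = _xml_find_array(piece, "Polys", "connectivity")
    offs = _xml_find_array(piece, "Polys", "offsets")
    if np.any(np.diff(np.concatenate([[0], offs])) != 3):
        raise UnsupportedElementError("only triangle polys supported")
    faces = conn.reshape(-1, 3)
    labels = _xml_find_array(piece, "CellData", "label")
    return SurfaceMesh(pts, faces, labels)


def _read_vtu(text: str) -> SurfaceMesh | VolumeMesh:
    root = ET.fromstring(text)
    piece = root.find(".//Piece")
    if piece is None:
        raise MeshFormatError("no <Piece> element")
    pts = _xml_find_array(piece, "Points", "Points").reshape(-1, 3)
    conn = _xml_find_array(piece, "Cells", "connectivity")
    types = _xml_find_array(piece, "Cells", "types")
    labels = _xml_find_array(piece, "CellData", "label")
    uniq = set(types.tolist())
    if uniq == {5}:
        return SurfaceMesh(pts, conn.reshape(-1, 3), labels)
    if uniq == {10}:
        return VolumeMesh(pts, conn.reshape(-1, 4))
    raise UnsupportedElementError(
        f"mixed or unsupported VTU cell types {sorted(uniq)}; need all 5 or all 10"
    )


# ---------------------------------------------------------------------------
# Gmsh MSH v2.2 ASCII


def _write_msh(mesh: SurfaceMesh | VolumeMesh) -> str:
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes",
             str(len(mesh.vertices))]
    for i, v in enumerate(mesh.vertices, start=1):
        lines.append(f"{i} {_fmt_floats(v)}")
    lines += ["$EndNodes", "$Elements"]
    if isinstance(mesh, SurfaceMesh):
        lines.append(str(mesh.n_faces))
        for i, (f, lab) in enumerate(zip(mesh.faces, mesh.face_labels), start=1):
            # elm-type 2 = 3-node triangle; physical + geometrical tag = label
            lines.append(f"{i} 2 2 {lab} {lab} {f[0]+1} {f[1]+1} {f[2]+1}")
    else:
        lines.append(str(len(mesh.tets)))
        for i, t in enumerate(mesh.tets, start=1):
            lines.append(f"{i} 4 2 0 0 {t[0]+1} {t[1]+1} {t[2]+1} {t[3]+1}")
    lines.append("$EndElements")
    return "\n".join(lines) + "\n"


def _read_msh(text: str) -> SurfaceMesh | VolumeMesh:
    lines = text.splitlines()

    def _section(name: str) -> tuple[int, int]:
        try:
            a = lines.index(f"${name}")
            b = lines.index(f"$End{name}")
        except ValueError as exc:
            raise MeshFormatError(f"missing ${name} section") from exc
        return a, b

    a, _ = _section("MeshFormat")
    version = lines[a + 1].split()[0]
    if not version.startswith("2."):
        raise MeshFormatError(f"only MSH v2.x supported, got {version}")

    a, b = _section("Nodes")
    nn = int(lines[a + 1])
    node_rows = [ln.split() for ln in lines[a + 2 : a + 2 + nn]]
    ids = np.array([int(r[0]) for r in node_rows])
    pts = np.array([[float(r[1]), float(r[2]), float(r[3])] for r in node_rows])
    id_map = {int(i): k for k, i in enumerate(ids)}

    a, b = _section("Elements")
    ne = int(lines[a + 1])
    tris, tri_labels, tets = [], [], []
    for ln in lines[a + 2 : a + 2 + ne]:
        parts = ln.split()
        etype, ntags = int(parts[1]), int(parts[2])
        tags = parts[3 : 3 + ntags]
        nodes = [id_map[int(x)] for x in parts[3 + ntags :]]
        if etype == 2:
            tris.append(nodes)
            tri_labels.append(int(tags[0]) if tags else 0)
        elif etype == 4:
            tets.append(nodes)
        else:
            raise UnsupportedElementError(f"MSH element type {etype} unsupported")
    if tets and tris:
        vm = VolumeMesh(pts, np.array(tets, dtype=np.int64),
                        np.array(tris, dtype=np.int64),
                        np.array(tri_labels, dtype=np.int64))
        return vm
    if tets:
        return VolumeMesh(pts, np.array(tets, dtype=np.int64))
    return SurfaceMesh(pts, np.array(tris, dtype=np.int64),
                       np.array(tri_labels, dtype=np.int64))
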