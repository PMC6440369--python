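"""Mesh model, file round trips, Taubin smoothing and plane slicing."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

import laaoplan as lp
from laaoplan.errors import MeshFormatError, UnsupportedElementError
from laaoplan.geometry_core import (
    contains_points,
    polygon_perimeter,
    polygon_plane_area,
)
from laaoplan.io import read_mesh, write_mesh


@pytest.fixture()
def labeled_tube():
    mesh, _ = lp.make_cylinder_laa(radius=5.0, length=10.0, n_theta=16,
                                   n_axial=5)
    return mesh


# ---------------------------------------------------------------------------
# I/O


def test_unit_cube_stl_roundtrip(tmp_path):
    """A unit-cube STL reads back as 8 welded vertices and 12 faces."""
    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    mesh = lp.SurfaceMesh(np.asarray(box.vertices), np.asarray(box.faces))
    path = tmp_path / "cube.stl"
    write_mesh(mesh, path)
    back = read_mesh(path)
    assert isinstance(back, lp.SurfaceMesh)
    # STL stores triangle soup; the reader welds duplicates back together
    assert back.n_faces == 12
    assert back.n_vertices == 8
    assert back.enclosed_volume() == pytest.approx(1.0, rel=1e-9)


@pytest.mark.parametrize("fmt", ["vtk", "vtp", "vtu", "msh"])
def test_label_formats_roundtrip_exact(labeled_tube, tmp_path, fmt):
    """Label-carrying formats preserve geometry and the label array."""
    path = tmp_path / f"tube.{fmt}"
    write_mesh(labeled_tube, path)
    back = read_mesh(path)
    np.testing.assert_allclose(back.vertices, labeled_tube.vertices, atol=1e-6)
    np.testing.assert_array_equal(back.faces, labeled_tube.faces)
    np.testing.assert_array_equal(back.face_labels, labeled_tube.face_labels)


@pytest.mark.parametrize("fmt", ["ply", "stl"])
def test_geometry_only_formats_roundtrip(labeled_tube, tmp_path, fmt):
    path = tmp_path / f"tube.{fmt}"
    with pytest.warns(UserWarning, match="labels"):
        write_mesh(labeled_tube, path)
    back = read_mesh(path)
    assert back.enclosed_volume() == pytest.approx(
        labeled_tube.enclosed_volume(), rel=1e-6
    )


def test_write_is_bit_stable(labeled_tube, tmp_path):
    a, b = tmp_path / "a.vtp", tmp_path / "b.vtp"
    write_mesh(labeled_tube, a)
    write_mesh(labeled_tube, b)
    assert a.read_bytes() == b.read_bytes()


def test_handwritten_vtu_labels_recovered(tmp_path):
    """A VTU with cell array 'label' in {0=wall, 1=ostium} maps onto face_labels."""
    vtu = """<?xml version="1.0"?>
<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">
<UnstructuredGrid><Piece NumberOfPoints="4" NumberOfCells="2">
<Points><DataArray type="Float64" Name="Points" NumberOfComponents="3" format="ascii">
0 0 0 1 0 0 1 1 0 0 1 0</DataArray></Points>
<Cells><DataArray type="Int64" Name="connectivity" format="ascii">0 1 2 0 2 3</DataArray>
<DataArray type="Int64" Name="offsets" format="ascii">3 6</DataArray>
<DataArray type="Int64" Name="types" format="ascii">5 5</DataArray></Cells>
<CellData><DataArray type="Int64" Name="label" format="ascii">0 1</DataArray></CellData>
</Piece></UnstructuredGrid></VTKFile>
"""
    path = tmp_path / "quad.vtu"
    path.write_text(vtu)
    mesh = read_mesh(path)
    np.testing.assert_array_equal(mesh.face_labels, [0, 1])
    assert mesh.n_vertices == 4


def test_volume_mesh_msh_v2_grammar(tmp_path):
    """MSH v2.2 output follows the section grammar and round-trips."""
    verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
                      [1, 1, 1.0]])
    tets = np.array([[0, 1, 2, 3], [1, 2, 3, 4]])
    vm = lp.VolumeMesh(verts, tets)
    path = tmp_path / "two.msh"
    write_mesh(vm, path)
    text = path.read_text()
    lines = text.splitlines()
    assert lines[0] == "$MeshFormat"
    assert lines[1].split() == ["2.2", "0", "8"]
    for section in ("$EndMeshFormat", "$Nodes", "$EndNodes",
                    "$Elements", "$EndElements"):
        assert section in lines
    assert lines[lines.index("$Nodes") + 1] == "5"
    back = read_mesh(path)
    assert isinstance(back, lp.VolumeMesh)
    np.testing.assert_allclose(back.vertices, verts, atol=1e-6)
    np.testing.assert_array_equal(back.tets, tets)


def test_unknown_format_lists_supported(labeled_tube, tmp_path):
    with pytest.raises(MeshFormatError, match="supported"):
        write_mesh(labeled_tube, tmp_path / "tube.obj")


def test_unreadable_file_names_location(tmp_path):
    path = tmp_path / "junk.vtk"
    path.write_text("# vtk DataFile Version 3.0\njunk\nASCII\nDATASET POLYDATA\n")
    with pytest.raises(MeshFormatError, match="POINTS"):
        read_mesh(path)


def test_mixed_vtu_cells_rejected(tmp_path):
    vtu = """<?xml version="1.0"?>
<VTKFile type="UnstructuredGrid"><UnstructuredGrid>
<Piece NumberOfPoints="5" NumberOfCells="2">
<Points><DataArray type="Float64" Name="Points" NumberOfComponents="3" format="ascii">
0 0 0 1 0 0 1 1 0 0 1 0 0 0 1</DataArray></Points>
<Cells><DataArray type="Int64" Name="connectivity" format="ascii">0 1 2 0 1 2 4</DataArray>
<DataArray type="Int64" Name="offsets" format="ascii">3 7</DataArray>
<DataArray type="Int64" Name="types" format="ascii">5 10</DataArray></Cells>
</Piece></UnstructuredGrid></VTKFile>
"""
    path = tmp_path / "mixed.vtu"
    path.write_text(vtu)
    with pytest.raises(UnsupportedElementError, match="mixed"):
        read_mesh(path)


# ---------------------------------------------------------------------------
# Taubin smoothing


def _noisy_sphere(sigma: float, seed: int = 7):
    sph = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
    rng = np.random.default_rng(seed)
    verts = np.asarray(sph.vertices)
    radial = verts / np.linalg.norm(verts, axis=1, keepdims=True)
    verts = verts + sigma * rng.standard_normal((len(verts), 1)) * radial
    return lp.SurfaceMesh(verts, np.asarray(sph.faces))


def test_zero_iterations_is_identity(labeled_tube):
    out = lp.taubin_smooth(labeled_tube, lp.SmoothingParams(iterations=0))
    np.testing.assert_array_equal(out.vertices, labeled_tube.vertices)
    np.testing.assert_array_equal(out.faces, labeled_tube.faces)


def test_noisy_sphere_noise_reduced_volume_kept():
    """The default lambda|mu pair denoises without shrinking the sphere."""
    mesh = _noisy_sphere(sigma=0.02)
    vol_before = mesh.enclosed_volume()
    radii_before = np.linalg.norm(mesh.vertices, axis=1)
    out = lp.taubin_smooth(mesh, lp.SmoothingParams())  # (0.6, -0.53, 10)
    radii_after = np.linalg.norm(out.vertices, axis=1)
    assert np.std(radii_after) < np.std(radii_before)
    assert out.enclosed_volume() == pytest.approx(vol_before, rel=0.05)
    np.testing.assert_array_equal(out.faces, mesh.faces)  # connectivity kept


def test_umbrella_step_moves_toward_neighbour_centroid():
    """One lambda-step pulls a fan's interior vertex toward its neighbours."""
    centre = np.array([0.0, 0.0, 0.5])  # lifted above the fan plane
    ring = np.array(
        [[np.cos(a), np.sin(a), 0.0] for a in np.linspace(0, 2 * np.pi, 6,
                                                          endpoint=False)]
    )
    verts = np.vstack([centre, ring])
    faces = np.array([[0, 1 + i, 1 + (i + 1) % 6] for i in range(6)])
    mesh = lp.SurfaceMesh(verts, faces)
    lam = 0.6
    out = lp.taubin_smooth(
        mesh, lp.SmoothingParams(lambda_factor=lam, mu_factor=-1e-12,
                                 iterations=1),
        preserve_labeled=False,
    )
    expected = centre + lam * (ring.mean(axis=0) - centre)
    np.testing.assert_allclose(out.vertices[0], expected, atol=1e-9)


def test_labeled_vertices_held_fixed(labeled_tube):
    out = lp.taubin_smooth(labeled_tube, lp.SmoothingParams(iterations=3))
    ost_verts = np.unique(
        labeled_tube.faces[labeled_tube.label_mask("ostium")]
    )
    np.testing.assert_array_equal(
        out.vertices[ost_verts], labeled_tube.vertices[ost_verts]
    )


# ---------------------------------------------------------------------------
# plane slicing


def test_cylinder_slice_perimeter(cylinder):
    mesh, _ = cylinder
    plane = lp.OstiumPlane(origin=(0, 0, 20.0), normal=(0, 0, 1.0))
    polys = lp.slice_with_plane(mesh, plane)
    assert len(polys) == 1
    # inscribed 64-gon: within mesh-resolution tolerance of 2*pi*r
    assert polygon_perimeter(polys[0]) == pytest.approx(2 * np.pi * 10.0,
                                                        rel=2e-3)


def test_no_intersection_returns_empty(cylinder):
    mesh, _ = cylinder
    polys = lp.slice_with_plane(
        mesh, lp.OstiumPlane(origin=(0, 0, 100.0), normal=(0, 0, 1.0))
    )
    assert polys == []


def test_tangent_plane_degenerate_suppressed():
    sph = trimesh.creation.icosphere(subdivisions=2, radius=5.0)
    mesh = lp.SurfaceMesh(np.asarray(sph.vertices), np.asarray(sph.faces))
    polys = lp.slice_with_plane(
        mesh, lp.OstiumPlane(origin=(0, 0, 4.9999999), normal=(0, 0, 1.0))
    )
    for poly in polys:
        assert polygon_plane_area(poly, np.array([0, 0, 1.0])) >= 1e-9


def test_two_disjoint_lobes_give_two_polygons():
    m1, _ = lp.make_cylinder_laa(radius=4.0, length=30.0, n_theta=24,
                                 origin=(0, 0, 0))
    m2, _ = lp.make_cylinder_laa(radius=4.0, length=30.0, n_theta=24,
                                 origin=(20.0, 0, 0))
    combined = lp.SurfaceMesh(
        np.vstack([m1.vertices, m2.vertices]),
        np.vstack([m1.faces, m2.faces + m1.n_vertices]),
    )
    polys = lp.slice_with_plane(
        combined, lp.OstiumPlane(origin=(0, 0, 15.0), normal=(0, 0, 1.0))
    )
    assert len(polys) == 2


def test_slice_perimeter_matches_per_face_clipping_oracle(cylinder):
    """Total polygon perimeter equals the brute-force per-triangle segment sum."""
    mesh, _ = cylinder
    plane = lp.OstiumPlane(origin=(0.3, -0.2, 17.0), normal=(0.1, 0.2, 1.0))
    polys = lp.slice_with_plane(mesh, plane)
    total = sum(polygon_perimeter(p) for p in polys)

    # oracle: clip each triangle against the plane independently
    oracle = 0.0
    tri = mesh.vertices[mesh.faces]
    sd = (tri - plane.origin) @ plane.normal  # (m, 3)
    for t, d in zip(tri, sd):
        pts = []
        for i in range(3):
            j = (i + 1) % 3
            if d[i] == 0.0:
                pts.append(t[i])
            if d[i] * d[j] < 0:
                w = d[i] / (d[i] - d[j])
                pts.append(t[i] + w * (t[j] - t[i]))
        if len(pts) == 2:
            oracle += np.linalg.norm(pts[1] - pts[0])
    assert total == pytest.approx(oracle, abs=1e-9)


def test_polygons_are_ccw_about_plane_normal(cylinder):
    mesh, _ = cylinder
    plane = lp.OstiumPlane(origin=(0, 0, 12.0), normal=(0, 0, 1.0))
    (poly,) = lp.slice_with_plane(mesh, plane)
    signed = 0.5 * np.sum(
        poly[:, 0] * np.roll(poly[:, 1], -1) - np.roll(poly[:, 0], -1) * poly[:, 1]
    )
    assert signed > 0


# ---------------------------------------------------------------------------
# containment


def test_contains_points_on_closed_tube(labeled_tube):
    inside = contains_points(
        labeled_tube, np.array([[0, 0, 5.0], [0, 0, -1.0], [10.0, 0, 5.0]])
    )
    np.testing.assert_array_equal(inside, [True, False, False])
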