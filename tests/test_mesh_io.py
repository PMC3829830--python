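import gzip
import struct

import numpy as np
import pytest
import trimesh

from mesh2u3d import (
    MaskVolume,
    MeshParseError,
    isosurface_from_mask,
    load_mask_volume,
    make_fixture,
    read_mesh,
    validate_mesh,
    write_off,
    write_stl_binary,
)

ASCII_STL = """solid minimal
facet normal 0 0 1
  outer loop
    vertex 0 0 0
    vertex 1 0 0
    vertex 0 1 0
  endloop
endfacet
endsolid minimal
"""

OFF_ONE_TRI = "OFF\n3 1 0\n0 0 0\n1 0 0\n0 1 0\n3 0 1 2\n"
OBJ_ONE_TRI = "v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1 2 3\n"
PLY_ONE_TRI = (
    "ply\nformat ascii 1.0\nelement vertex 3\nproperty float x\nproperty float y\n"
    "property float z\nelement face 1\nproperty list uchar int vertex_indices\n"
    "end_header\n0 0 0\n1 0 0\n0 1 0\n3 0 1 2\n"
)


def _binary_stl(triangles) -> bytes:
    out = bytearray(b"\0" * 80)
    out += struct.pack("<I", len(triangles))
    for tri in triangles:
        out += struct.pack("<3f", 0, 0, 1)
        for v in tri:
            out += struct.pack("<3f", *v)
        out += struct.pack("<H", 0)
    return bytes(out)


class TestReaders:
    def test_minimal_ascii_stl(self, tmp_path):
        p = tmp_path / "t.stl"
        p.write_text(ASCII_STL)
        mesh = read_mesh(p)
        assert mesh.n_vertices == 3 and mesh.n_faces == 1

    def test_binary_stl_dedup(self, tmp_path):
        # two triangles sharing an edge: brute-force coordinate dedup says
        # 4 distinct vertices remain
        tris = [
            [(0, 0, 0), (1, 0, 0), (0, 1, 0)],
            [(1, 0, 0), (1, 1, 0), (0, 1, 0)],
        ]
        p = tmp_path / "two.stl"
        p.write_bytes(_binary_stl(tris))
        mesh = read_mesh(p)
        distinct = {tuple(v) for tri in tris for v in tri}
        assert mesh.n_vertices == len(distinct) == 4
        assert mesh.n_faces == 2
        # faces still reference the original coordinates
        for tri, face in zip(tris, mesh.faces):
            assert np.allclose(mesh.positions[face], tri)

    def test_cross_format_identity(self, tmp_path):
        meshes = []
        for name, text in [
            ("t.stl", ASCII_STL),
            ("t.off", OFF_ONE_TRI),
            ("t.obj", OBJ_ONE_TRI),
            ("t.ply", PLY_ONE_TRI),
        ]:
            p = tmp_path / name
            p.write_text(text)
            meshes.append(read_mesh(p))
        for m in meshes[1:]:
            assert np.array_equal(m.positions, meshes[0].positions)
            assert np.array_equal(m.faces, meshes[0].faces)

    def test_format_hint_overrides_extension(self, tmp_path):
        p = tmp_path / "mesh.dat"
        p.write_text(OFF_ONE_TRI)
        mesh = read_mesh(p, format_hint="off")
        assert mesh.n_faces == 1

    def test_quads_fan_triangulated(self, tmp_path):
        p = tmp_path / "q.obj"
        p.write_text("v 0 0 0\nv 1 0 0\nv 1 1 0\nv 0 1 0\nf 1 2 3 4\n")
        mesh = read_mesh(p)
        assert mesh.n_faces == 2
        assert np.array_equal(mesh.faces, [(0, 1, 2), (0, 2, 3)])

    def test_reading_twice_is_deterministic(self, tmp_path):
        ico = make_fixture("icosphere", level=2)
        p = tmp_path / "i.stl"
        write_stl_binary(ico, p)
        a, b = read_mesh(p), read_mesh(p)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.faces, b.faces)

    def test_reader_outputs_are_valid(self, tmp_path):
        ico = make_fixture("icosphere", level=2)
        off_p, stl_p = tmp_path / "i.off", tmp_path / "i.stl"
        write_off(ico, off_p)
        write_stl_binary(ico, stl_p)
        for p in (off_p, stl_p):
            assert validate_mesh(read_mesh(p)) == []

    def test_roundtrip_against_trimesh_oracle(self, tmp_path):
        ico = make_fixture("icosphere", level=2)
        p = tmp_path / "i.stl"
        write_stl_binary(ico, p)
        ours = read_mesh(p)
        oracle = trimesh.load(str(p), process=True)
        assert len(oracle.vertices) == ours.n_vertices
        assert len(oracle.faces) == ours.n_faces
        # identical vertex sets (ordering may differ)
        def key(verts):
            return {tuple(np.round(np.asarray(v, dtype=np.float64), 5)) for v in verts}

        assert key(oracle.vertices) == key(ours.positions)

    def test_trimesh_written_ply_and_obj_parse(self, tmp_path):
        ico = make_fixture("icosphere", level=1)
        tm = trimesh.Trimesh(vertices=ico.positions, faces=ico.faces, process=False)
        for name in ("i.ply", "i.obj"):  # PLY exports binary-little-endian
            p = tmp_path / name
            tm.export(str(p))
            mesh = read_mesh(p)
            assert mesh.n_faces == ico.n_faces
            assert np.allclose(
                np.sort(mesh.positions, axis=0), np.sort(ico.positions, axis=0), atol=1e-6
            )


class TestReaderErrors:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.stl"
        p.write_text("")
        with pytest.raises(MeshParseError, match="empty"):
            read_mesh(p)

    def test_garbled_ascii_stl_names_line(self, tmp_path):
        p = tmp_path / "g.stl"
        p.write_text("solid x\nfacet normal 0 0 1\nouter loop\nvertex 0 0\nendloop\nendfacet\n")
        with pytest.raises(MeshParseError, match="line 4"):
            read_mesh(p)

    def test_truncated_binary_stl_names_bytes(self, tmp_path):
        p = tmp_path / "t.stl"
        p.write_bytes(_binary_stl([[(0, 0, 0), (1, 0, 0), (0, 1, 0)]])[:-10])
        with pytest.raises(MeshParseError, match="truncated"):
            read_mesh(p)

    def test_obj_line_records_rejected(self, tmp_path):
        p = tmp_path / "l.obj"
        p.write_text("v 0 0 0\nv 1 0 0\nl 1 2\n")
        with pytest.raises(MeshParseError, match="non-polygonal"):
            read_mesh(p)

    def test_unknown_extension(self, tmp_path):
        p = tmp_path / "m.xyz"
        p.write_text("boo")
        with pytest.raises(MeshParseError, match="unknown mesh format"):
            read_mesh(p)

    def test_off_count_mismatch(self, tmp_path):
        p = tmp_path / "b.off"
        p.write_text("OFF\n5 1 0\n0 0 0\n1 0 0\n")
        with pytest.raises(MeshParseError, match="end of file"):
            read_mesh(p)


def _edge_incidence(mesh):
    edges = {}
    for f in mesh.faces:
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            k = (min(a, b), max(a, b))
            edges[k] = edges.get(k, 0) + 1
    return edges


class TestIsosurface:
    def test_all_zero_volume_empty_mesh(self):
        mesh = isosurface_from_mask(MaskVolume(np.zeros((3, 3, 3))), 0.5)
        assert mesh.n_faces == 0

    def test_single_voxel_closed_euler_two(self):
        vol = np.zeros((3, 3, 3))
        vol[1, 1, 1] = 1
        mesh = isosurface_from_mask(MaskVolume(vol), 0.5)
        edges = _edge_incidence(mesh)
        V, E, F = mesh.n_vertices, len(edges), mesh.n_faces
        assert all(c == 2 for c in edges.values()), "surface not closed"
        assert V - E + F == 2

    def test_border_touching_mask_still_closed(self):
        # zero padding closes surfaces of masks touching the volume border
        vol = np.ones((4, 4, 4))
        mesh = isosurface_from_mask(MaskVolume(vol), 0.5)
        assert mesh.n_faces > 0
        assert all(c == 2 for c in _edge_incidence(mesh).values())

    def test_sphere_mask_area_near_analytic(self):
        n = 32
        idx = np.indices((n, n, n))
        c = (n - 1) / 2
        r2 = ((idx[0] - c) ** 2 + (idx[1] - c) ** 2 + (idx[2] - c) ** 2)
        mesh = isosurface_from_mask(MaskVolume((r2 <= 10.0**2).astype(float)), 0.5)
        p = mesh.positions.astype(np.float64)
        f = mesh.faces
        area = 0.5 * np.linalg.norm(
            np.cross(p[f[:, 1]] - p[f[:, 0]], p[f[:, 2]] - p[f[:, 0]]), axis=1
        ).sum()
        assert abs(area - 4 * np.pi * 100) / (4 * np.pi * 100) < 0.15

    def test_world_coordinates_spacing_and_origin(self):
        vol = np.zeros((3, 3, 3))
        vol[1, 1, 1] = 1
        spacing, origin = (2.0, 3.0, 4.0), (10.0, 20.0, 30.0)
        mesh = isosurface_from_mask(MaskVolume(vol, spacing=spacing, origin=origin), 0.5)
        center = mesh.positions.mean(axis=0)
        expected = np.asarray(origin) + np.asarray(spacing) * 1  # voxel (1,1,1)
        assert np.allclose(center, expected, atol=1e-5)

    def test_threshold_outside_range_empty(self):
        vol = np.zeros((3, 3, 3))
        vol[1, 1, 1] = 1
        assert isosurface_from_mask(MaskVolume(vol), 2.0).n_faces == 0

    def test_non_3d_volume_rejected(self):
        with pytest.raises(ValueError, match="3-D"):
            MaskVolume(np.zeros((3, 3)))


class TestFixtures:
    @pytest.mark.parametrize("level, faces, verts", [(0, 20, 12), (3, 1280, 642)])
    def test_icosphere_counts(self, level, faces, verts):
        m = make_fixture("icosphere", level=level)
        assert m.n_faces == faces and m.n_vertices == verts
        assert np.allclose(np.linalg.norm(m.positions.astype(np.float64), axis=1), 1, atol=1e-6)

    def test_plane_grid_counts_and_planarity(self):
        m = make_fixture("plane_grid", rows=8, cols=8)
        assert m.n_faces == 128
        assert np.all(m.positions[:, 2] == 0)

    def test_two_shells_scene(self):
        scene = make_fixture("two_shells")
        assert len(scene.patches) == 2
        labels = {p.label for p in scene.patches}
        assert len(labels) == 2
        assert all(p.description for p in scene.patches)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            make_fixture("icosphere", level=-1)
        with pytest.raises(ValueError):
            make_fixture("plane_grid", rows=0, cols=4)
        with pytest.raises(ValueError):
            make_fixture("klein_bottle")


class TestVolumes:
    def test_nifti_roundtrip(self, tmp_path):
        import nibabel as nib

        vol = np.zeros((5, 6, 7), dtype=np.uint8)
        vol[2, 3, 4] = 1
        affine = np.diag([2.0, 2.0, 2.5, 1.0])
        affine[:3, 3] = (1.0, -2.0, 3.0)
        p = tmp_path / "mask.nii.gz"
        nib.save(nib.Nifti1Image(vol, affine), str(p))
        loaded = load_mask_volume(p)
        assert np.array_equal(loaded.voxels, vol)
        assert loaded.spacing == (2.0, 2.0, 2.5)
        assert loaded.origin == (1.0, -2.0, 3.0)

    @pytest.mark.parametrize("encoding", ["raw", "gzip"])
    def test_nrrd_minimal(self, tmp_path, encoding):
        vol = np.arange(24, dtype=np.uint8).reshape(2, 3, 4)
        payload = vol.transpose(2, 1, 0).tobytes()  # fastest-axis-first
        if encoding == "gzip":
            payload = gzip.compress(payload)
        header = (
            "NRRD0004\n"
            "type: uint8\n"
            "dimension: 3\n"
            "sizes: 2 3 4\n"
            f"encoding: {encoding}\n"
            "spacings: 1.5 2.0 2.5\n"
            "space origin: (5.0,6.0,7.0)\n"
            "\n"
        ).encode()
        p = tmp_path / "m.nrrd"
        p.write_bytes(header + payload)
        loaded = load_mask_volume(p)
        assert np.array_equal(loaded.voxels, vol)
        assert loaded.spacing == (1.5, 2.0, 2.5)
        assert loaded.origin == (5.0, 6.0, 7.0)

    def test_nrrd_truncated(self, tmp_path):
        p = tmp_path / "m.nrrd"
        p.write_bytes(b"NRRD0004\ntype: uint8\ndimension: 3\nsizes: 4 4 4\nencoding: raw\n\nxx")
        with pytest.raises(MeshParseError, match="truncated"):
            load_mask_volume(p)
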