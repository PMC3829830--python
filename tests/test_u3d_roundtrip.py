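import struct

import numpy as np
import pytest

from conftest import assert_scene_roundtrip
from mesh2u3d import (
    Patch,
    Scene,
    TriangleMesh,
    make_fixture,
    random_scene,
    read_u3d,
    write_u3d,
)
from mesh2u3d.u3d import BlockType, U3DFormatError
from mesh2u3d.u3d.blocks import iter_blocks

TRI = TriangleMesh(positions=[(0, 0, 0), (1, 0, 0), (0, 1, 0)], faces=[(0, 1, 2)])


def _single_triangle_scene():
    return Scene(patches=[Patch(mesh=TRI, label="Tri")])


class TestWriter:
    def test_file_starts_with_u3d_magic(self, tmp_path):
        p = tmp_path / "tri.u3d"
        write_u3d(_single_triangle_scene(), p)
        first = struct.unpack("<I", p.read_bytes()[:4])[0]
        assert first == 0x00443355
        assert struct.pack("<I", first)[:3] == b"U3D"

    def test_summary_counts(self, tmp_path):
        p = tmp_path / "s.u3d"
        summary = write_u3d(make_fixture("two_shells", level=1), p)
        assert summary.object_count == 2
        assert summary.bytes_written == p.stat().st_size

    def test_empty_scene_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="empty scene"):
            write_u3d(Scene(), tmp_path / "x.u3d")

    def test_patch_without_faces_rejected_by_name(self, tmp_path):
        scene = Scene(
            patches=[Patch(mesh=TriangleMesh(positions=[(0, 0, 0)], faces=[]), label="Hollow")]
        )
        with pytest.raises(ValueError, match="Hollow"):
            write_u3d(scene, tmp_path / "x.u3d")

    def test_blocks_are_four_byte_aligned(self, tmp_path):
        p = tmp_path / "a.u3d"
        write_u3d(make_fixture("two_shells", level=1), p)
        buf = p.read_bytes()
        offsets = [off for off, _ in iter_blocks(buf)]
        assert all(off % 4 == 0 for off in offsets)
        assert len(buf) % 4 == 0

    def test_byte_determinism(self, tmp_path):
        a, b = tmp_path / "a.u3d", tmp_path / "b.u3d"
        write_u3d(make_fixture("two_shells", level=1), a)
        write_u3d(make_fixture("two_shells", level=1), b)
        assert a.read_bytes() == b.read_bytes()


class TestRoundtrip:
    def test_two_shells(self, tmp_path):
        p = tmp_path / "ts.u3d"
        scene = make_fixture("two_shells", level=2)
        write_u3d(scene, p)
        u3d = read_u3d(p)
        assert_scene_roundtrip(make_fixture("two_shells", level=2), u3d)
        assert u3d.scene.model_name == "TwoShells"

    def test_object_count_equals_patch_count(self, tmp_path, rng):
        for i in range(5):
            scene = random_scene(rng)
            n = len(scene.patches)
            p = tmp_path / f"s{i}.u3d"
            write_u3d(scene, p)
            u3d = read_u3d(p)
            assert len(u3d.scene.patches) == n
            assert [pp.label for pp in u3d.scene.patches] == [
                pp.label for pp in scene.patches
            ]

    def test_randomized_scenes(self, tmp_path, rng):
        for i in range(10):
            scene = random_scene(rng)
            p = tmp_path / f"r{i}.u3d"
            write_u3d(scene, p)
            assert_scene_roundtrip(random_scene_copy(scene), read_u3d(p))

    def test_duplicate_labels_uniquified_in_file(self, tmp_path):
        scene = Scene(
            patches=[
                Patch(mesh=TRI, label="A"),
                Patch(mesh=TRI, label="A"),
                Patch(mesh=TRI, label=""),
            ]
        )
        p = tmp_path / "dup.u3d"
        write_u3d(scene, p)
        labels = [pp.label for pp in read_u3d(p).scene.patches]
        assert labels == ["A", "A_1", "Object_3"]
        assert len(set(labels)) == 3 and all(labels)

    def test_shared_color_shares_material(self, tmp_path):
        scene = Scene(
            patches=[
                Patch(mesh=TRI, label="A", description="ObjectColor=1,0,0,1"),
                Patch(mesh=make_fixture("cube"), label="B", description="ObjectColor=1,0,0,1"),
            ]
        )
        p = tmp_path / "shared.u3d"
        write_u3d(scene, p)
        u3d = read_u3d(p)
        assert len(u3d.layout.shaders) == 1
        assert len(u3d.layout.materials) == 1

    def test_group_color_travels_on_group_node(self, tmp_path):
        scene = Scene(
            patches=[
                Patch(mesh=TRI, label="A", description="GroupName=G;GroupColor=0.1,0.2,0.3,0.4"),
                Patch(mesh=make_fixture("cube"), label="B", description="GroupName=G"),
            ]
        )
        p = tmp_path / "gc.u3d"
        write_u3d(scene, p)
        u3d = read_u3d(p)
        for props in u3d.properties:
            assert props.group_name == "G"
            assert props.group_rgba is not None
            assert np.allclose(props.group_rgba, (0.1, 0.2, 0.3, 0.4))

    def test_same_segment_under_two_parents(self, tmp_path):
        scene = Scene(
            patches=[
                Patch(mesh=TRI, label="A", description="GroupName=Left/Bone"),
                Patch(mesh=make_fixture("cube"), label="B", description="GroupName=Right/Bone"),
            ]
        )
        p = tmp_path / "seg.u3d"
        write_u3d(scene, p)
        u3d = read_u3d(p)
        assert u3d.properties[0].group_name == "Left/Bone"
        assert u3d.properties[1].group_name == "Right/Bone"

    def test_declaration_size_field_checked(self, tmp_path):
        p = tmp_path / "ok.u3d"
        write_u3d(_single_triangle_scene(), p)
        buf = bytearray(p.read_bytes())
        # declaration size lives at offset 20 inside the header block data
        struct.pack_into("<I", buf, 20, 12345)
        bad = tmp_path / "bad.u3d"
        bad.write_bytes(bytes(buf))
        with pytest.raises(U3DFormatError, match="declaration size"):
            read_u3d(bad)


def random_scene_copy(scene):
    """Rebuild an equal scene (write_u3d finalizes a copy, input unchanged)."""
    return Scene(
        patches=[Patch(mesh=p.mesh, label=p.label, description=p.description)
                 for p in scene.patches],
        model_name=scene.model_name,
    )


class TestReaderErrors:
    def test_bad_magic(self, tmp_path):
        p = tmp_path / "x.u3d"
        p.write_bytes(b"XXXX" + b"\0" * 32)
        with pytest.raises(U3DFormatError, match="not a U3D file"):
            read_u3d(p)

    def test_header_only_truncated(self, tmp_path):
        good = tmp_path / "good.u3d"
        write_u3d(_single_triangle_scene(), good)
        trunc = tmp_path / "trunc.u3d"
        trunc.write_bytes(good.read_bytes()[:40])
        with pytest.raises(U3DFormatError, match="offset"):
            read_u3d(trunc)

    def test_unknown_block_listed_and_skipped(self, tmp_path, caplog):
        import logging

        good = tmp_path / "good.u3d"
        write_u3d(_single_triangle_scene(), good)
        buf = bytearray(good.read_bytes())
        # append an unknown block and patch the header's file size
        unknown = struct.pack("<III", 0xFFFFFFAA, 4, 0) + b"\xde\xad\xbe\xef"
        buf += unknown
        struct.pack_into("<Q", buf, 24, len(buf))  # file size field
        mutant = tmp_path / "mutant.u3d"
        mutant.write_bytes(bytes(buf))
        with caplog.at_level(logging.WARNING):
            u3d = read_u3d(mutant)
        assert any("unknown block" in r.message for r in caplog.records)
        assert any(b.block_type == 0xFFFFFFAA for b in u3d.blocks)
        assert len(u3d.scene.patches) == 1  # scene still recovered
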