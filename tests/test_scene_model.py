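import logging

import numpy as np
import pytest

from mesh2u3d import (
    Patch,
    Scene,
    TriangleMesh,
    U3DProperties,
    build_group_tree,
    compute_vertex_normals,
    make_fixture,
    uniquify_labels,
    validate_mesh,
)

TRI = TriangleMesh(positions=[(0, 0, 0), (1, 0, 0), (0, 1, 0)], faces=[(0, 1, 2)])


class TestValidateMesh:
    def test_minimal_valid_triangle(self):
        assert validate_mesh(TRI) == []

    def test_repeated_index_is_degenerate(self):
        mesh = TriangleMesh(positions=[(0, 0, 0), (1, 0, 0)], faces=[(0, 0, 1)])
        violations = validate_mesh(mesh)
        assert len(violations) == 1
        assert "degenerate" in violations[0] and "face 0" in violations[0]

    def test_out_of_range_index(self):
        mesh = TriangleMesh(positions=TRI.positions, faces=[(0, 1, 5)])
        violations = validate_mesh(mesh)
        assert len(violations) == 1
        assert "out of range" in violations[0]

    def test_nonfinite_coordinate(self):
        mesh = TriangleMesh(positions=[(0, 0, 0), (np.nan, 0, 0), (0, 1, 0)], faces=[(0, 1, 2)])
        assert any("non-finite" in v for v in validate_mesh(mesh))

    def test_bad_normals_reported(self):
        mesh = TriangleMesh(
            positions=TRI.positions, faces=TRI.faces, normals=[(0, 0, 2)] * 3
        )
        assert any("unit length" in v for v in validate_mesh(mesh))


class TestVertexNormals:
    def test_cube_corner_normals_are_diagonals(self):
        # three orthogonal faces meet at equal angles at each corner, so
        # the angle-weighted average is the corner diagonal
        cube = compute_vertex_normals(make_fixture("cube"))
        expected = cube.positions / np.linalg.norm(cube.positions, axis=1)[:, None]
        assert np.allclose(cube.normals, expected, atol=1e-6)

    def test_flat_square_all_up(self):
        mesh = TriangleMesh(
            positions=[(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)],
            faces=[(0, 1, 2), (0, 2, 3)],
        )
        out = compute_vertex_normals(mesh)
        assert np.allclose(out.normals, [(0, 0, 1)] * 4, atol=1e-7)

    def test_icosphere_normals_near_radial(self):
        sphere = make_fixture("icosphere", level=3)
        out = compute_vertex_normals(sphere)
        radial = sphere.positions / np.linalg.norm(sphere.positions, axis=1)[:, None]
        cosang = np.clip(np.einsum("ij,ij->i", out.normals, radial), -1, 1)
        assert np.arccos(cosang).max() < 1e-2  # radians

    def test_isolated_vertex_gets_placeholder(self, caplog):
        mesh = TriangleMesh(
            positions=[(0, 0, 0), (1, 0, 0), (0, 1, 0), (5, 5, 5)], faces=[(0, 1, 2)]
        )
        with caplog.at_level(logging.WARNING):
            out = compute_vertex_normals(mesh)
        assert np.allclose(out.normals[3], (0, 0, 1))
        assert any("incident" in r.message for r in caplog.records)

    def test_unit_norm_invariant_on_random_meshes(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 40))
            positions = rng.normal(size=(n, 3))
            m = int(rng.integers(2, 60))
            faces = []
            while len(faces) < m:
                f = rng.choice(n, size=3, replace=False)
                faces.append(tuple(f))
            out = compute_vertex_normals(
                TriangleMesh(positions=positions, faces=np.asarray(faces))
            )
            assert validate_mesh(out) == []
            assert np.abs(np.linalg.norm(out.normals, axis=1) - 1).max() < 1e-5


def _scene(labels):
    return Scene(patches=[Patch(mesh=TRI, label=lb) for lb in labels])


class TestUniquifyLabels:
    @pytest.mark.parametrize(
        "labels, expected",
        [
            (["Femur", "Tibia"], ["Femur", "Tibia"]),
            (["A", "A", ""], ["A", "A_1", "Object_3"]),
            (["A", "A_1", "A"], ["A", "A_1", "A_2"]),
        ],
    )
    def test_scheme(self, labels, expected):
        out = uniquify_labels(_scene(labels))
        assert [p.label for p in out.patches] == expected

    def test_minimal_suffixes_brute_force(self, rng):
        # oracle: output labels unique + non-empty, unchanged labels kept,
        # and every suffixed label uses the smallest free k at its turn
        pool = ["A", "A_1", "B", "", "A"]
        for _ in range(50):
            labels = [pool[i] for i in rng.integers(0, len(pool), size=6)]
            out = [p.label for p in uniquify_labels(_scene(labels)).patches]
            assert len(set(out)) == len(out)
            assert all(out)
            taken = set()
            for i, (src, got) in enumerate(zip(labels, out), start=1):
                base = src or f"Object_{i}"
                if base not in taken:
                    assert got == base
                else:
                    k = 1
                    while f"{base}_{k}" in taken:
                        k += 1
                    assert got == f"{base}_{k}"
                taken.add(got)

    def test_idempotent(self, rng):
        labels = ["A", "A", "", "B", "A_1"]
        once = uniquify_labels(_scene(labels))
        twice = uniquify_labels(once)
        assert [p.label for p in once.patches] == [p.label for p in twice.patches]


class TestGroupTree:
    def test_single_group(self):
        scene = _scene(["P1", "P2"])
        props = [U3DProperties(group_name="Skeleton")] * 2
        tree = build_group_tree(scene, props)
        assert list(tree.root.children) == ["Skeleton"]
        assert tree.root.children["Skeleton"].patch_labels == ["P1", "P2"]

    def test_path_semantics(self):
        scene = _scene(["P1", "P2"])
        props = [U3DProperties(group_name="A/B"), U3DProperties(group_name="A")]
        tree = build_group_tree(scene, props)
        a = tree.root.children["A"]
        assert a.patch_labels == ["P2"]
        assert a.children["B"].patch_labels == ["P1"]

    def test_random_paths_conservation_and_node_count(self, rng):
        paths = ["X", "X/Y", "X/Y/Z", "W", "W/V"]
        scene = _scene([f"P{i}" for i in range(20)])
        chosen = [paths[i] for i in rng.integers(0, len(paths), size=20)]
        props = [U3DProperties(group_name=p) for p in chosen]
        tree = build_group_tree(scene, props)
        assert sorted(tree.all_patch_labels()) == sorted(p.label for p in scene.patches)
        prefixes = set()
        for p in chosen:
            parts = p.split("/")
            for k in range(1, len(parts) + 1):
                prefixes.add(tuple(parts[:k]))
        assert tree.node_count() == len(prefixes) + 1

    def test_ungrouped_patches_attach_to_root(self):
        scene = _scene(["P1"])
        tree = build_group_tree(scene, [U3DProperties()])
        assert tree.root.patch_labels == ["P1"]

    def test_group_name_equal_to_patch_label_rejected(self):
        scene = _scene(["P1", "P2"])
        props = [U3DProperties(group_name="P2"), U3DProperties()]
        with pytest.raises(ValueError, match="collides"):
            build_group_tree(scene, props)
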