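import numpy as np
import pytest

from mesh2u3d import parse_description
from mesh2u3d.u3d import finalize_scene


@pytest.fixture
def rng():
    return np.random.default_rng(20250928)


def assert_scene_roundtrip(scene, u3d_file):
    """Assert the reader recovered the finalized scene exactly.

    Positions and normals must match bitwise as float32, faces and labels
    exactly, group paths exactly, colors within 1/255 (they pass through
    float32 material fields).
    """
    fin_scene, fin_props, model_name, _tree = finalize_scene(scene)
    got = u3d_file.scene
    assert len(got.patches) == len(fin_scene.patches)
    assert got.model_name == model_name

    # expected group color: first patch (in order) that supplies one wins
    expected_group_color = {}
    for props in fin_props:
        if props.group_name and props.group_rgba is not None:
            expected_group_color.setdefault(props.group_name, props.group_rgba)

    for want, have, props_in, props_out in zip(
        fin_scene.patches, got.patches, fin_props, u3d_file.properties
    ):
        assert have.label == want.label
        assert np.array_equal(
            have.mesh.positions.view(np.uint32), want.mesh.positions.view(np.uint32)
        ), f"positions differ for {want.label}"
        assert np.array_equal(have.mesh.faces, want.mesh.faces)
        assert np.array_equal(
            have.mesh.normals.view(np.uint32), want.mesh.normals.view(np.uint32)
        )
        for a, b in zip(props_out.object_rgba, props_in.object_rgba):
            assert abs(a - b) <= 1 / 255
        for a, b in zip(props_out.specular_rgb, props_in.specular_rgb):
            assert abs(a - b) <= 1 / 255
        assert props_out.group_name == props_in.group_name
        want_gc = expected_group_color.get(props_in.group_name)
        if want_gc is None:
            assert props_out.group_rgba is None
        else:
            for a, b in zip(props_out.group_rgba, want_gc):
                assert abs(a - b) <= 1 / 255
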