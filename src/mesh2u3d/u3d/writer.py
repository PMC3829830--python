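"""Serialize a Scene into an ECMA-363 Universal 3D file.

The file layout is: File Header Block; a declaration area with one
modifier chain per scene-graph node (a root group node named after the
model, one group node per group-tree entry, one model node + shading
modifier per patch, one ambient light node), the light resource, one
lit-texture-shader + material resource pair per distinct resolved
color/specular combination (shared between patches), and one CLOD mesh
generator declaration per patch; then a continuation area with one base
mesh continuation block per patch carrying all geometry.

Level-of-detail is fixed at the base mesh: the CLOD declaration's
minimum and final maximum resolution both equal the vertex count and no
progressive resolution updates are written, which every mainstream PDF
viewer renders as-is.  Colors are per-object (material diffuse +
opacity), not per-vertex.  Group colors, which have no U3D material of
their own, ride on the group node's modifier-chain block as a key/value
metadata pair.  Two serialization passes back-patch the header's
declaration-size and file-size fields.  The writer is deterministic:
identical scenes produce byte-identical files.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ..metadata import resolve_scene_properties
from ..scene_model import (
    GroupTree,
    Patch,
    Scene,
    TriangleMesh,
    U3DProperties,
    build_group_tree,
    compute_vertex_normals,
    uniquify_labels,
    validate_mesh,
)
from .bitstream import BitWriter, Context
from .blocks import BlockType, U3DBlock, encode_metadata, serialize_block

logger = logging.getLogger(__name__)

__all__ = ["SceneLayout", "WriteSummary", "finalize_scene", "build_layout", "write_u3d"]

PROFILE_IDENTIFIER = 0
CHARACTER_ENCODING_UTF8 = 106
GROUP_COLOR_METADATA_KEY = "GroupColor"
GROUP_SEGMENT_METADATA_KEY = "GroupSegment"

#: dynamic compression context for per-face shading ids in base meshes
SHADING_ID_CONTEXT = Context.dynamic(1)

# lit-texture-shader constants
ALPHA_TEST_ALWAYS = 0x00000617
BLEND_FB_ADD = 0x00000604
BLEND_FB_ALPHA_BLEND = 0x00000606

_IDENTITY = tuple(float(x) for x in np.eye(4).T.ravel())  # column-major


@dataclass
class SceneLayout:
    """Derived export plan: who is in which palette, under which name."""

    model_name: str
    root_group: str
    #: (palette name, parent palette name, group color, true path segment)
    group_nodes: List[Tuple[str, str, Optional[tuple], str]]
    model_nodes: List[Tuple[str, str]]  # (patch label, parent node)
    light_node: str
    shaders: List[str]
    materials: List[str]
    patch_shader: Dict[str, str]  # patch label -> shader name
    mesh_resources: List[str]


@dataclass
class WriteSummary:
    bytes_written: int
    block_count: int
    object_count: int


def finalize_scene(scene: Scene):
    """Uniquify labels, parse descriptions, attach normals, build groups.

    Returns ``(scene, per_patch_properties, model_name, group_tree)`` —
    the finalized inputs :func:`write_u3d` serializes.
    """
    if not scene.patches:
        raise ValueError("cannot export an empty scene (at least one patch required)")
    scene = uniquify_labels(scene)
    for patch in scene.patches:
        if patch.mesh.n_faces == 0:
            raise ValueError(f"patch {patch.label!r} has no faces")
        problems = validate_mesh(patch.mesh)
        if problems:
            raise ValueError(f"patch {patch.label!r}: invalid mesh: {problems[0]}")
    props, model_name = resolve_scene_properties(scene)
    patches = []
    for patch in scene.patches:
        if patch.mesh.normals is None:
            patch = Patch(
                mesh=compute_vertex_normals(patch.mesh),
                label=patch.label,
                description=patch.description,
            )
        patches.append(patch)
    scene = Scene(patches=patches, model_name=scene.model_name)
    tree = build_group_tree(scene, props)
    return scene, props, model_name, tree


def build_layout(
    scene: Scene,
    props: Sequence[U3DProperties],
    model_name: str,
    tree: GroupTree,
) -> SceneLayout:
    """Plan palettes and node names for a finalized scene.

    Shader/material resources are shared: patches with identical resolved
    RGBA + specular reference one material.  Palette names are assigned in
    first-use order, so the layout — and the file — is deterministic.
    """
    labels = [p.label for p in scene.patches]
    taken = set(labels)

    def unique_node_name(base: str) -> str:
        name = base
        k = 1
        while name in taken:
            name = f"{base}_{k}"
            k += 1
        taken.add(name)
        return name

    root_group = unique_node_name(model_name)
    if root_group != model_name:
        logger.warning(
            "model name %r collides with a patch label; root group named %r",
            model_name, root_group,
        )

    # group nodes in breadth-first order, root first
    group_colors: Dict[tuple, tuple] = {}
    for patch_props in props:
        if patch_props.group_name and patch_props.group_rgba is not None:
            path = tuple(s for s in patch_props.group_name.split("/") if s)
            group_colors.setdefault(path, patch_props.group_rgba)  # first wins

    # node-palette names must be unique; the true path segment is kept
    # alongside (and written as metadata when the palette name differs)
    group_nodes: List[Tuple[str, str, Optional[tuple], str]] = []
    path_to_name: Dict[tuple, str] = {(): root_group}
    for path, node in tree.root.walk():
        if not path:
            continue
        parent = path_to_name[path[:-1]]
        name = unique_node_name(node.name)
        path_to_name[path] = name
        group_nodes.append((name, parent, group_colors.get(path), node.name))

    # model nodes: parent = deepest group of the patch's path
    patch_parent: Dict[str, str] = {}
    for path, node in tree.root.walk():
        for label in node.patch_labels:
            patch_parent[label] = path_to_name[path]
    model_nodes = [(label, patch_parent[label]) for label in labels]

    light_node = unique_node_name("AmbientLight")

    shaders: List[str] = []
    materials: List[str] = []
    patch_shader: Dict[str, str] = {}
    color_key_to_shader: Dict[tuple, str] = {}
    for patch, patch_props in zip(scene.patches, props):
        key = (tuple(patch_props.object_rgba), tuple(patch_props.specular_rgb))
        shader = color_key_to_shader.get(key)
        if shader is None:
            shader = f"Shader_{len(shaders) + 1}"
            color_key_to_shader[key] = shader
            shaders.append(shader)
            materials.append(f"Material_{len(materials) + 1}")
        patch_shader[patch.label] = shader
    return SceneLayout(
        model_name=model_name,
        root_group=root_group,
        group_nodes=group_nodes,
        model_nodes=model_nodes,
        light_node=light_node,
        shaders=shaders,
        materials=materials,
        patch_shader=patch_shader,
        mesh_resources=list(labels),
    )


# ---------------------------------------------------------------------------
# individual blocks


def _write_parent_list(w: BitWriter, parent: str) -> None:
    w.write_u32(1)
    w.write_string(parent)
    for x in _IDENTITY:
        w.write_f32(x)


def _modifier_chain(
    name: str, chain_type: int, blocks: List[U3DBlock], metadata: bytes = b""
) -> U3DBlock:
    w = BitWriter()
    w.write_string(name)
    w.write_u32(chain_type)
    w.write_u32(0)  # attributes: no bounding info
    head = len(w.getvalue())
    w.write_bytes(b"\0" * ((4 - head % 4) % 4))  # align the modifier count
    w.write_u32(len(blocks))
    for b in blocks:
        w.write_bytes(serialize_block(b))
    return U3DBlock(BlockType.MODIFIER_CHAIN, w.getvalue(), metadata)


def _group_node_block(name: str, parent: str) -> U3DBlock:
    w = BitWriter()
    w.write_string(name)
    _write_parent_list(w, parent)
    return U3DBlock(BlockType.GROUP_NODE, w.getvalue())


def _model_node_block(name: str, parent: str, resource: str) -> U3DBlock:
    w = BitWriter()
    w.write_string(name)
    _write_parent_list(w, parent)
    w.write_string(resource)
    w.write_u32(3)  # visibility: front and back faces
    return U3DBlock(BlockType.MODEL_NODE, w.getvalue())


def _shading_modifier_block(name: str, shader: str) -> U3DBlock:
    w = BitWriter()
    w.write_string(name)
    w.write_u32(1)  # chain index
    w.write_u32(1)  # attributes: apply to mesh
    w.write_u32(1)  # shader list count
    w.write_u32(1)  # shaders in list
    w.write_string(shader)
    return U3DBlock(BlockType.SHADING_MODIFIER, w.getvalue())


def _light_node_block(name: str, resource: str) -> U3DBlock:
    w = BitWriter()
    w.write_string(name)
    _write_parent_list(w, "")
    w.write_string(resource)
    return U3DBlock(BlockType.LIGHT_NODE, w.getvalue())


def _light_resource_block(name: str) -> U3DBlock:
    w = BitWriter()
    w.write_string(name)
    w.write_u32(1)  # attributes: light enabled
    w.write_u8(0x00)  # type: ambient
    for c in (1.0, 1.0, 1.0, 1.0):  # color + reserved
        w.write_f32(c)
    for a in (1.0, 0.0, 0.0):  # attenuation constant/linear/quadratic
        w.write_f32(a)
    w.write_f32(0.0)  # spot angle
    w.write_f32(1.0)  # intensity
    return U3DBlock(BlockType.LIGHT_RESOURCE, w.getvalue())


def _shader_block(name: str, material: str, alpha_blended: bool) -> U3DBlock:
    w = BitWriter()
    w.write_string(name)
    w.write_u32(1)  # attributes: lighting enabled
    w.write_f32(0.0)  # alpha test reference
    w.write_u32(ALPHA_TEST_ALWAYS)
    w.write_u32(BLEND_FB_ALPHA_BLEND if alpha_blended else BLEND_FB_ADD)
    w.write_u32(1)  # render pass enabled flags
    w.write_u32(0)  # shader channels (no texture layers)
    w.write_u32(0)  # alpha texture channels
    w.write_string(material)
    return U3DBlock(BlockType.LIT_TEXTURE_SHADER, w.getvalue())


def _material_block(name: str, rgba: tuple, specular: tuple) -> U3DBlock:
    r, g, b, a = rgba
    w = BitWriter()
    w.write_string(name)
    w.write_u32(0x3F)  # ambient | diffuse | specular | emissive | reflectivity | opacity
    for c in (0.25 * r, 0.25 * g, 0.25 * b):  # ambient: dimmed diffuse
        w.write_f32(c)
    for c in (r, g, b):
        w.write_f32(c)
    for c in specular:
        w.write_f32(c)
    for c in (0.0, 0.0, 0.0):  # emissive
        w.write_f32(c)
    w.write_f32(0.1)  # reflectivity (shininess)
    w.write_f32(a)  # opacity
    return U3DBlock(BlockType.MATERIAL_RESOURCE, w.getvalue())


def _mesh_declaration_block(name: str, mesh: TriangleMesh) -> U3DBlock:
    n_pos = mesh.n_vertices
    w = BitWriter()
    w.write_string(name)
    w.write_u32(0)  # chain index
    # max mesh description
    w.write_u32(0)  # attributes: per-vertex normals included
    w.write_u32(mesh.n_faces)
    w.write_u32(n_pos)
    w.write_u32(n_pos)  # normal count (one per vertex)
    w.write_u32(0)  # diffuse colors
    w.write_u32(0)  # specular colors
    w.write_u32(0)  # texture coordinates
    w.write_u32(1)  # shading descriptions
    w.write_u32(0)  # shading attributes: no per-vertex colors
    w.write_u32(0)  # texture layer count
    w.write_u32(0)  # original shading id
    # CLOD description: base mesh only
    w.write_u32(n_pos)  # minimum resolution
    w.write_u32(n_pos)  # final maximum resolution
    # resource description: quality factors, inverse quantization, parameters
    for q in (1000, 1000, 1000):
        w.write_u32(q)
    for iq in (1.0, 1.0, 1.0, 1.0, 1.0):
        w.write_f32(iq)
    for p in (0.9, 0.5, 0.985):
        w.write_f32(p)
    w.write_u32(0)  # skeleton bone count
    return U3DBlock(BlockType.CLOD_MESH_DECLARATION, w.getvalue())


def _base_mesh_continuation_block(name: str, mesh: TriangleMesh) -> U3DBlock:
    positions = mesh.positions.astype("<f4")
    normals = mesh.normals.astype("<f4")
    faces = mesh.faces
    n_pos = mesh.n_vertices
    w = BitWriter()
    w.write_string(name)
    w.write_u32(0)  # chain index
    w.write_u32(len(faces))
    w.write_u32(n_pos)
    w.write_u32(n_pos)  # normals
    w.write_u32(0)  # diffuse colors
    w.write_u32(0)  # specular colors
    w.write_u32(0)  # texture coordinates
    w.write_bytes(positions.tobytes())
    w.write_bytes(normals.tobytes())
    pos_ctx = Context.static(n_pos)
    for face in faces.tolist():
        w.write_compressed_u32(SHADING_ID_CONTEXT, 0)
        for v in face:
            w.write_compressed_u32(pos_ctx, v)  # position index
            w.write_compressed_u32(pos_ctx, v)  # normal index (per-vertex)
    return U3DBlock(BlockType.CLOD_BASE_MESH_CONTINUATION, w.getvalue())


def _header_block(declaration_size: int, file_size: int) -> bytes:
    w = BitWriter()
    w.write_i16(0)  # major version
    w.write_i16(0)  # minor version
    w.write_u32(PROFILE_IDENTIFIER)
    w.write_u32(declaration_size)
    w.write_u64(file_size)
    w.write_u32(CHARACTER_ENCODING_UTF8)
    return serialize_block(U3DBlock(BlockType.FILE_HEADER, w.getvalue()))


# ---------------------------------------------------------------------------


def write_u3d(scene: Scene, path) -> WriteSummary:
    """Export a scene to ``path`` as a U3D file; one object per patch.

    The scene is finalized first (labels uniquified, descriptions parsed,
    normals computed where missing), so any valid scene with at least one
    non-empty patch can be passed directly.
    """
    scene, props, model_name, tree = finalize_scene(scene)
    layout = build_layout(scene, props, model_name, tree)

    declaration_blocks: List[U3DBlock] = []
    continuation_blocks: List[U3DBlock] = []

    declaration_blocks.append(
        _modifier_chain(layout.root_group, 0, [_group_node_block(layout.root_group, "")])
    )
    for name, parent, color, segment in layout.group_nodes:
        pairs = []
        if segment != name:
            pairs.append((GROUP_SEGMENT_METADATA_KEY, segment))
        if color is not None:
            pairs.append(
                (GROUP_COLOR_METADATA_KEY, ",".join(repr(float(c)) for c in color))
            )
        declaration_blocks.append(
            _modifier_chain(name, 0, [_group_node_block(name, parent)], encode_metadata(pairs))
        )
    for label, parent in layout.model_nodes:
        declaration_blocks.append(
            _modifier_chain(
                label,
                0,
                [
                    _model_node_block(label, parent, label),
                    _shading_modifier_block(label, layout.patch_shader[label]),
                ],
            )
        )
    declaration_blocks.append(
        _modifier_chain(
            layout.light_node, 0, [_light_node_block(layout.light_node, layout.light_node)]
        )
    )
    declaration_blocks.append(_light_resource_block(layout.light_node))

    color_of_shader = {}
    for patch, patch_props in zip(scene.patches, props):
        shader = layout.patch_shader[patch.label]
        color_of_shader.setdefault(shader, (patch_props.object_rgba, patch_props.specular_rgb))
    for shader, material in zip(layout.shaders, layout.materials):
        rgba, specular = color_of_shader[shader]
        declaration_blocks.append(_shader_block(shader, material, alpha_blended=rgba[3] < 1.0))
        declaration_blocks.append(_material_block(material, rgba, specular))

    for patch in scene.patches:
        declaration_blocks.append(
            _modifier_chain(patch.label, 1, [_mesh_declaration_block(patch.label, patch.mesh)])
        )
        continuation_blocks.append(_base_mesh_continuation_block(patch.label, patch.mesh))

    declaration_bytes = b"".join(serialize_block(b) for b in declaration_blocks)
    continuation_bytes = b"".join(serialize_block(b) for b in continuation_blocks)
    header = _header_block(0, 0)
    declaration_size = len(header) + len(declaration_bytes)
    file_size = declaration_size + len(continuation_bytes)
    header = _header_block(declaration_size, file_size)  # back-patch pass

    payload = header + declaration_bytes + continuation_bytes
    with open(path, "wb") as fh:
        fh.write(payload)
    return WriteSummary(
        bytes_written=len(payload),
        block_count=1 + len(declaration_blocks) + len(continuation_blocks),
        object_count=len(scene.patches),
    )
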