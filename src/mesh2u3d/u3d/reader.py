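"""Parse U3D files produced by this writer (or any base-mesh-only
producer within the same feature subset) back into a Scene.

The reader is the writer's verification oracle: it re-checks the file
header fields (magic, declaration size, file size), walks the block
sequence, reassembles meshes, names, colors and the group tree, and
lists every block — unknown block types are reported and skipped with a
warning rather than failing the parse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from ..metadata import compose_description
from ..scene_model import Patch, Scene, TriangleMesh, U3DProperties
from .bitstream import BitReader, Context
from .blocks import BlockType, U3DBlock, U3DFormatError, decode_metadata, iter_blocks
from .writer import (
    GROUP_COLOR_METADATA_KEY,
    GROUP_SEGMENT_METADATA_KEY,
    SHADING_ID_CONTEXT,
    SceneLayout,
)

logger = logging.getLogger(__name__)

__all__ = ["BlockInfo", "U3DFile", "read_u3d"]


@dataclass
class BlockInfo:
    offset: int
    block_type: int
    type_name: str
    data_size: int
    metadata_size: int
    name: str = ""


@dataclass
class HeaderInfo:
    major_version: int
    minor_version: int
    profile: int
    declaration_size: int
    file_size: int
    character_encoding: int


@dataclass
class U3DFile:
    """Everything recovered from one U3D file."""

    scene: Scene
    layout: SceneLayout
    blocks: List[BlockInfo]
    header: HeaderInfo
    properties: List[U3DProperties] = field(default_factory=list)


def _parse_parent(r: BitReader) -> str:
    count = r.read_u32()
    parent = ""
    for i in range(count):
        name = r.read_string()
        for _ in range(16):
            r.read_f32()
        if i == 0:
            parent = name
    return parent


def read_u3d(path) -> U3DFile:
    """Read a U3D file and reconstruct its scene, layout and block list."""
    with open(path, "rb") as fh:
        buf = fh.read()
    if len(buf) < 4:
        raise U3DFormatError(f"{path}: not a U3D file (only {len(buf)} bytes)")
    magic = int.from_bytes(buf[:4], "little")
    if magic != BlockType.FILE_HEADER:
        raise U3DFormatError(
            f"{path}: not a U3D file (first block type 0x{magic:08X}, "
            f"expected 0x{BlockType.FILE_HEADER:08X})"
        )

    blocks: List[BlockInfo] = []
    header: Optional[HeaderInfo] = None
    group_nodes: Dict[str, Tuple[str, List[Tuple[str, str]]]] = {}  # name -> (parent, meta)
    group_order: List[str] = []
    model_nodes: List[Tuple[str, str, str]] = []  # (name, parent, resource)
    patch_shader: Dict[str, str] = {}
    light_nodes: List[str] = []
    shaders: Dict[str, str] = {}  # shader -> material
    shader_order: List[str] = []
    materials: Dict[str, Tuple[tuple, tuple, float]] = {}  # name -> (rgb, specular, opacity)
    material_order: List[str] = []
    mesh_decls: Dict[str, Tuple[int, int]] = {}  # name -> (faces, positions)
    base_meshes: Dict[str, TriangleMesh] = {}
    first_continuation_offset: Optional[int] = None
    unknown_types = set()

    def parse_node_block(block: U3DBlock, chain_meta: List[Tuple[str, str]]) -> str:
        nonlocal header
        r = BitReader(block.data)
        bt = block.block_type
        if bt == BlockType.GROUP_NODE:
            name = r.read_string()
            parent = _parse_parent(r)
            group_nodes[name] = (parent, chain_meta)
            group_order.append(name)
            return name
        if bt == BlockType.MODEL_NODE:
            name = r.read_string()
            parent = _parse_parent(r)
            resource = r.read_string()
            model_nodes.append((name, parent, resource))
            return name
        if bt == BlockType.LIGHT_NODE:
            name = r.read_string()
            _parse_parent(r)
            r.read_string()
            light_nodes.append(name)
            return name
        if bt == BlockType.SHADING_MODIFIER:
            name = r.read_string()
            r.read_u32()  # chain index
            r.read_u32()  # attributes
            lists = r.read_u32()
            for li in range(lists):
                count = r.read_u32()
                for si in range(count):
                    shader = r.read_string()
                    if li == 0 and si == 0:
                        patch_shader[name] = shader
            return name
        if bt == BlockType.LIT_TEXTURE_SHADER:
            name = r.read_string()
            r.read_u32()
            r.read_f32()
            r.read_u32()
            r.read_u32()
            r.read_u32()
            r.read_u32()
            r.read_u32()
            shaders[name] = r.read_string()
            shader_order.append(name)
            return name
        if bt == BlockType.MATERIAL_RESOURCE:
            name = r.read_string()
            r.read_u32()  # attribute flags
            for _ in range(3):
                r.read_f32()  # ambient
            diffuse = tuple(r.read_f32() for _ in range(3))
            specular = tuple(r.read_f32() for _ in range(3))
            for _ in range(3):
                r.read_f32()  # emissive
            r.read_f32()  # reflectivity
            opacity = r.read_f32()
            materials[name] = (diffuse, specular, opacity)
            material_order.append(name)
            return name
        if bt == BlockType.LIGHT_RESOURCE:
            return r.read_string()
        if bt == BlockType.CLOD_MESH_DECLARATION:
            name = r.read_string()
            r.read_u32()  # chain index
            r.read_u32()  # attributes
            n_faces = r.read_u32()
            n_pos = r.read_u32()
            mesh_decls[name] = (n_faces, n_pos)
            return name
        if bt == BlockType.CLOD_BASE_MESH_CONTINUATION:
            name = r.read_string()
            r.read_u32()  # chain index
            n_faces = r.read_u32()
            n_pos = r.read_u32()
            n_norm = r.read_u32()
            for _ in range(3):
                r.read_u32()  # diffuse / specular / texcoord counts
            positions = np.frombuffer(r.read_bytes(12 * n_pos), dtype="<f4").reshape(-1, 3)
            normals = np.frombuffer(r.read_bytes(12 * n_norm), dtype="<f4").reshape(-1, 3)
            pos_ctx = Context.static(n_pos) if n_pos else Context.static(1)
            faces = np.empty((n_faces, 3), dtype=np.int64)
            for fi in range(n_faces):
                r.read_compressed_u32(SHADING_ID_CONTEXT)
                for corner in range(3):
                    faces[fi, corner] = r.read_compressed_u32(pos_ctx)
                    r.read_compressed_u32(pos_ctx)  # normal index
            base_meshes[name] = TriangleMesh(
                positions=positions.copy(), faces=faces, normals=normals.copy()
            )
            return name
        unknown_types.add(bt)
        logger.warning("skipping unknown block type 0x%08X", bt)
        return ""

    for offset, block in iter_blocks(buf):
        name = ""
        if block.block_type == BlockType.FILE_HEADER:
            r = BitReader(block.data)
            header = HeaderInfo(
                major_version=r.read_i16(),
                minor_version=r.read_i16(),
                profile=r.read_u32(),
                declaration_size=r.read_u32(),
                file_size=r.read_u64(),
                character_encoding=r.read_u32(),
            )
        elif block.block_type == BlockType.MODIFIER_CHAIN:
            r = BitReader(block.data)
            chain_name = r.read_string()
            r.read_u32()  # chain type
            r.read_u32()  # attributes
            consumed = 2 + len(chain_name.encode("utf-8")) + 8
            r.read_bytes((4 - consumed % 4) % 4)
            count = r.read_u32()
            # nested blocks start right after the (aligned) count field
            inner_offset = consumed + (4 - consumed % 4) % 4 + 4
            meta = decode_metadata(block.metadata)
            parsed = 0
            for _, inner in iter_blocks(block.data, inner_offset):
                parse_node_block(inner, meta)
                parsed += 1
            if parsed != count:
                raise U3DFormatError(
                    f"modifier chain {chain_name!r} declares {count} modifiers, found {parsed}"
                )
            name = chain_name
        elif block.block_type in BlockType.CONTINUATION_TYPES:
            if first_continuation_offset is None:
                first_continuation_offset = offset
            name = parse_node_block(block, [])
        else:
            name = parse_node_block(block, [])
        blocks.append(
            BlockInfo(
                offset=offset,
                block_type=block.block_type,
                type_name=BlockType.name(block.block_type),
                data_size=len(block.data),
                metadata_size=len(block.metadata),
                name=name,
            )
        )

    if header is None:
        raise U3DFormatError(f"{path}: missing file header block")
    if header.file_size != len(buf):
        raise U3DFormatError(
            f"{path}: header file size {header.file_size} != actual {len(buf)}"
        )
    if not unknown_types:
        decl_end = first_continuation_offset if first_continuation_offset is not None else len(buf)
        if header.declaration_size != decl_end:
            raise U3DFormatError(
                f"{path}: header declaration size {header.declaration_size} != "
                f"actual declaration span {decl_end}"
            )

    # -- reassemble the scene ----------------------------------------------
    def segment_of(node_name: str) -> str:
        _, meta = group_nodes[node_name]
        for key, value in meta:
            if key == GROUP_SEGMENT_METADATA_KEY:
                return value
        return node_name

    def color_of(node_name: str) -> Optional[tuple]:
        _, meta = group_nodes[node_name]
        for key, value in meta:
            if key == GROUP_COLOR_METADATA_KEY:
                return tuple(float(c) for c in value.split(","))
        return None

    root_group = ""
    for name in group_order:
        if group_nodes[name][0] == "":
            root_group = name
            break
    model_name = segment_of(root_group) if root_group else ""

    patches: List[Patch] = []
    properties: List[U3DProperties] = []
    group_layout: List[Tuple[str, str, Optional[tuple], str]] = [
        (name, group_nodes[name][0], color_of(name), segment_of(name))
        for name in group_order
        if name != root_group
    ]
    for name, parent, resource in model_nodes:
        mesh = base_meshes.get(resource)
        if mesh is None:
            raise U3DFormatError(f"{path}: model node {name!r} references missing mesh {resource!r}")
        props = U3DProperties()
        shader = patch_shader.get(name)
        if shader and shader in shaders and shaders[shader] in materials:
            diffuse, specular, opacity = materials[shaders[shader]]
            props.object_rgba = tuple(diffuse) + (opacity,)
            props.specular_rgb = tuple(specular)
        # group path: walk up the parent chain to (but excluding) the root
        segments: List[str] = []
        cursor = parent
        while cursor and cursor != root_group and cursor in group_nodes:
            segments.append(segment_of(cursor))
            cursor = group_nodes[cursor][0]
        if segments:
            props.group_name = "/".join(reversed(segments))
            # color of the patch's own (deepest) group node only
            props.group_rgba = color_of(parent) if parent in group_nodes else None
        patches.append(Patch(mesh=mesh, label=name, description=compose_description(props)))
        properties.append(props)

    scene = Scene(patches=patches, model_name=model_name)
    layout = SceneLayout(
        model_name=model_name,
        root_group=root_group,
        group_nodes=group_layout,
        model_nodes=[(n, p) for n, p, _ in model_nodes],
        light_node=light_nodes[0] if light_nodes else "",
        shaders=shader_order,
        materials=material_order,
        patch_shader=patch_shader,
        mesh_resources=list(base_meshes),
    )
    return U3DFile(
        scene=scene, layout=layout, blocks=blocks, header=header, properties=properties
    )
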