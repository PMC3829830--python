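"""U3D block framing and block-type constants.

A U3D file is a sequence of blocks, each ``(type, data size, metadata
size)`` as unsigned little-endian 32-bit values followed by the data and
metadata payloads, each zero-padded to a 32-bit boundary.  The declared
sizes are the unpadded byte counts.  The first block of a file is always
the File Header Block, type 0x00443355 ("U3D\\0" read as ASCII bytes).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from typing import Iterator, List, Tuple

from .bitstream import BitReader, BitWriter

__all__ = [
    "U3DBlock",
    "U3DFormatError",
    "BlockType",
    "serialize_block",
    "iter_blocks",
    "encode_metadata",
    "decode_metadata",
]


class U3DFormatError(ValueError):
    """Raised when a byte stream is not a readable U3D file."""


class BlockType:
    """ECMA-363 block type codes (the subset this toolkit touches)."""

    FILE_HEADER = 0x00443355
    FILE_REFERENCE = 0xFFFFFF12
    MODIFIER_CHAIN = 0xFFFFFF14
    PRIORITY_UPDATE = 0xFFFFFF15
    GROUP_NODE = 0xFFFFFF21
    MODEL_NODE = 0xFFFFFF22
    LIGHT_NODE = 0xFFFFFF23
    VIEW_NODE = 0xFFFFFF24
    CLOD_MESH_DECLARATION = 0xFFFFFF31
    CLOD_BASE_MESH_CONTINUATION = 0xFFFFFF3B
    CLOD_PROGRESSIVE_MESH_CONTINUATION = 0xFFFFFF3C
    POINT_SET_DECLARATION = 0xFFFFFF36
    LINE_SET_DECLARATION = 0xFFFFFF37
    SHADING_MODIFIER = 0xFFFFFF45
    CLOD_MODIFIER = 0xFFFFFF46
    LIGHT_RESOURCE = 0xFFFFFF51
    VIEW_RESOURCE = 0xFFFFFF52
    LIT_TEXTURE_SHADER = 0xFFFFFF53
    MATERIAL_RESOURCE = 0xFFFFFF54
    TEXTURE_DECLARATION = 0xFFFFFF55
    MOTION_RESOURCE = 0xFFFFFF56
    TEXTURE_CONTINUATION = 0xFFFFFF5C

    #: block types that belong to the continuation area of a file
    CONTINUATION_TYPES = frozenset(
        {0xFFFFFF3B, 0xFFFFFF3C, 0xFFFFFF5C}
    )

    _NAMES = {}

    @classmethod
    def name(cls, code: int) -> str:
        if not cls._NAMES:
            cls._NAMES = {
                v: k for k, v in vars(cls).items()
                if isinstance(v, int) and not k.startswith("_")
            }
        return cls._NAMES.get(code, f"UNKNOWN_0x{code:08X}")


@dataclass
class U3DBlock:
    """One serialized block: type code plus data and metadata payloads."""

    block_type: int
    data: bytes = b""
    metadata: bytes = b""


def _pad4(n: int) -> int:
    return (4 - n % 4) % 4


def serialize_block(block: U3DBlock) -> bytes:
    out = bytearray()
    out += struct.pack("<III", block.block_type, len(block.data), len(block.metadata))
    out += block.data
    out += b"\0" * _pad4(len(block.data))
    out += block.metadata
    out += b"\0" * _pad4(len(block.metadata))
    return bytes(out)


def iter_blocks(buf: bytes, offset: int = 0) -> Iterator[Tuple[int, U3DBlock]]:
    """Yield ``(offset, block)`` for each block in ``buf`` starting at
    ``offset``; raises :class:`U3DFormatError` on a truncated payload."""
    pos = offset
    total = len(buf)
    while pos < total:
        if pos + 12 > total:
            raise U3DFormatError(f"truncated block header at offset {pos}")
        block_type, dsize, msize = struct.unpack_from("<III", buf, pos)
        start = pos + 12
        end = start + dsize + _pad4(dsize) + msize + _pad4(msize)
        if end > total:
            raise U3DFormatError(
                f"truncated block payload at offset {pos} "
                f"(type 0x{block_type:08X} needs {end - pos} bytes, {total - pos} left)"
            )
        data = buf[start : start + dsize]
        mstart = start + dsize + _pad4(dsize)
        metadata = buf[mstart : mstart + msize]
        yield pos, U3DBlock(block_type=block_type, data=data, metadata=metadata)
        pos = end


def encode_metadata(pairs: List[Tuple[str, str]]) -> bytes:
    """Serialize key/value metadata pairs into a block metadata payload."""
    if not pairs:
        return b""
    w = BitWriter()
    w.write_u32(len(pairs))
    for key, value in pairs:
        w.write_u32(0)  # attributes: string value
        w.write_string(key)
        w.write_string(value)
    return w.getvalue()


def decode_metadata(payload: bytes) -> List[Tuple[str, str]]:
    if not payload:
        return []
    r = BitReader(payload)
    count = r.read_u32()
    pairs = []
    for _ in range(count):
        r.read_u32()
        pairs.append((r.read_string(), r.read_string()))
    return pairs
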