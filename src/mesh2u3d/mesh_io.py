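"""Mesh and volume input: STL/OFF/OBJ/PLY readers, isosurface extraction,
fixture generators and the OFF / binary-STL writers used by the CLI.

Readers return validated :class:`~mesh2u3d.scene_model.TriangleMesh`
objects.  STL facets are deduplicated by exact coordinate equality (no
tolerance welding); polygonal OFF/OBJ/PLY faces are fan-triangulated from
their first vertex.
"""

from __future__ import annotations

import gzip
import io
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

from .scene_model import Patch, Scene, TriangleMesh, validate_mesh

__all__ = [
    "MeshParseError",
    "MaskVolume",
    "read_mesh",
    "load_mask_volume",
    "isosurface_from_mask",
    "make_fixture",
    "random_scene",
    "write_off",
    "write_stl_binary",
]


class MeshParseError(ValueError):
    """Raised when a mesh or volume file cannot be parsed; the message
    names the offending line or byte offset."""


@dataclass
class MaskVolume:
    """A 3-D scalar volume (typically a binary/label segmentation mask).

    ``spacing`` is the world-length step per voxel along each axis and
    ``origin`` the world position of the center of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"mask volume must be 3-D, got {self.voxels.ndim}-D")
        if any(s < 1 for s in self.voxels.shape):
            raise ValueError(f"all volume dimensions must be >= 1: {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0: {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)


# ---------------------------------------------------------------------------
# mesh readers


def read_mesh(path, format_hint: Optional[str] = None) -> TriangleMesh:
    """Read a triangle mesh from STL, OFF, OBJ or PLY.

    The format is taken from ``format_hint`` ("stl"/"off"/"obj"/"ply") or
    the file extension.  STL may be ASCII or binary; PLY may be ASCII or
    binary-little-endian.  Polygons are fan-triangulated; STL vertices are
    deduplicated by exact coordinate equality and re-indexed.
    """
    path = Path(path)
    fmt = (format_hint or path.suffix.lstrip(".")).lower()
    readers = {"stl": _read_stl, "off": _read_off, "obj": _read_obj, "ply": _read_ply}
    if fmt not in readers:
        raise MeshParseError(f"{path}: unknown mesh format {fmt!r} (expected stl/off/obj/ply)")
    data = path.read_bytes()
    if not data.strip():
        raise MeshParseError(f"{path}: empty file")
    mesh = readers[fmt](path, data)
    problems = validate_mesh(mesh)
    if problems:
        raise MeshParseError(f"{path}: invalid mesh: " + "; ".join(problems[:5]))
    return mesh


def _dedup_vertices(tri_coords: np.ndarray) -> TriangleMesh:
    """Weld exactly-equal vertices of an (m, 3, 3) triangle-soup array."""
    flat = tri_coords.reshape(-1, 3).astype(np.float32)
    index = {}
    remap = np.empty(flat.shape[0], dtype=np.int64)
    verts = []
    for i, row in enumerate(flat):
        key = (float(row[0]), float(row[1]), float(row[2]))
        j = index.get(key)
        if j is None:
            j = len(verts)
            index[key] = j
            verts.append(row)
        remap[i] = j
    positions = np.asarray(verts, dtype=np.float32).reshape(-1, 3)
    faces = remap.reshape(-1, 3)
    return TriangleMesh(positions=positions, faces=faces)


def _read_stl(path: Path, data: bytes) -> TriangleMesh:
    if _stl_is_ascii(data):
        return _read_stl_ascii(path, data)
    return _read_stl_binary(path, data)


def _stl_is_ascii(data: bytes) -> bool:
    if not data.lstrip().startswith(b"solid"):
        return False
    head = data[:4096]
    try:
        head.decode("ascii")
    except UnicodeDecodeError:
        return False
    # binary files may start with "solid" in the 80-byte header; require a facet
    return b"facet" in data[:4096] or (b"endsolid" in data and b"facet" not in data)


def _read_stl_ascii(path: Path, data: bytes) -> TriangleMesh:
    tris = []
    current: list = []
    for lineno, raw in enumerate(data.decode("ascii", errors="replace").splitlines(), 1):
        tokens = raw.split()
        if not tokens:
            continue
        kw = tokens[0].lower()
        if kw == "vertex":
            if len(tokens) != 4:
                raise MeshParseError(f"{path}: line {lineno}: vertex needs 3 coordinates")
            try:
                current.append([float(t) for t in tokens[1:4]])
            except ValueError:
                raise MeshParseError(f"{path}: line {lineno}: non-numeric vertex coordinate")
        elif kw == "endfacet":
            if len(current) != 3:
                raise MeshParseError(
                    f"{path}: line {lineno}: facet has {len(current)} vertices (need 3)"
                )
            tris.append(current)
            current = []
        elif kw in ("solid", "endsolid", "facet", "outer", "endloop"):
            continue
        else:
            raise MeshParseError(f"{path}: line {lineno}: unexpected token {tokens[0]!r}")
    if current:
        raise MeshParseError(f"{path}: unterminated facet at end of file")
    if not tris:
        raise MeshParseError(f"{path}: no facets found")
    return _dedup_vertices(np.asarray(tris, dtype=np.float32))


def _read_stl_binary(path: Path, data: bytes) -> TriangleMesh:
    if len(data) < 84:
        raise MeshParseError(f"{path}: binary STL truncated at byte {len(data)} (header needs 84)")
    (count,) = struct.unpack_from("<I", data, 80)
    expected = 84 + 50 * count
    if len(data) < expected:
        raise MeshParseError(
            f"{path}: binary STL truncated at byte {len(data)}, "
            f"{count} triangles need {expected} bytes"
        )
    if count == 0:
        raise MeshParseError(f"{path}: binary STL declares 0 triangles")
    records = np.frombuffer(
        data, dtype=np.dtype([("n", "<3f4"), ("v", "<(3,3)f4"), ("attr", "<u2")]),
        count=count, offset=84,
    )
    return _dedup_vertices(np.ascontiguousarray(records["v"]))


def _tokenize_text(path: Path, data: bytes):
    try:
        text = data.decode("utf-8")
    except UnicodeDecodeError as exc:
        raise MeshParseError(f"{path}: not a text file (bad byte at offset {exc.start})")
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if line:
            yield lineno, line.split()


def _fan_triangulate(poly: list) -> list:
    return [[poly[0], poly[k], poly[k + 1]] for k in range(1, len(poly) - 1)]


def _read_off(path: Path, data: bytes) -> TriangleMesh:
    tokens = _tokenize_text(path, data)
    try:
        lineno, first = next(tokens)
    except StopIteration:
        raise MeshParseError(f"{path}: empty OFF file")
    if first == ["OFF"]:
        try:
            lineno, first = next(tokens)
        except StopIteration:
            raise MeshParseError(f"{path}: OFF header without counts line")
    elif first[0] == "OFF" and len(first) == 4:
        first = first[1:]  # counts on the same line as the keyword
    if len(first) != 3:
        raise MeshParseError(f"{path}: line {lineno}: OFF counts line needs 3 integers")
    try:
        nv, nf, _ne = (int(t) for t in first)
    except ValueError:
        raise MeshParseError(f"{path}: line {lineno}: non-integer OFF counts")
    verts = np.empty((nv, 3), dtype=np.float32)
    for i in range(nv):
        try:
            lineno, tok = next(tokens)
        except StopIteration:
            raise MeshParseError(f"{path}: unexpected end of file reading vertex {i}")
        if len(tok) < 3:
            raise MeshParseError(f"{path}: line {lineno}: vertex needs 3 coordinates")
        try:
            verts[i] = [float(t) for t in tok[:3]]
        except ValueError:
            raise MeshParseError(f"{path}: line {lineno}: non-numeric coordinate")
    faces = []
    for i in range(nf):
        try:
            lineno, tok = next(tokens)
        except StopIteration:
            raise MeshParseError(f"{path}: unexpected end of file reading face {i}")
        try:
            k = int(tok[0])
            poly = [int(t) for t in tok[1 : 1 + k]]
        except ValueError:
            raise MeshParseError(f"{path}: line {lineno}: non-integer face record")
        if k < 3 or len(poly) != k:
            raise MeshParseError(f"{path}: line {lineno}: face record count mismatch")
        faces.extend(_fan_triangulate(poly))
    if not faces:
        raise MeshParseError(f"{path}: OFF file has no faces")
    return TriangleMesh(positions=verts, faces=np.asarray(faces, dtype=np.int64))


def _read_obj(path: Path, data: bytes) -> TriangleMesh:
    verts = []
    faces = []
    for lineno, tok in _tokenize_text(path, data):
        kw = tok[0]
        if kw == "v":
            if len(tok) < 4:
                raise MeshParseError(f"{path}: line {lineno}: 'v' needs 3 coordinates")
            try:
                verts.append([float(t) for t in tok[1:4]])
            except ValueError:
                raise MeshParseError(f"{path}: line {lineno}: non-numeric coordinate")
        elif kw == "f":
            poly = []
            for ref in tok[1:]:
                idx_txt = ref.split("/", 1)[0]
                try:
                    idx = int(idx_txt)
                except ValueError:
                    raise MeshParseError(f"{path}: line {lineno}: bad face index {ref!r}")
                if idx < 0:
                    idx = len(verts) + idx  # relative reference
                else:
                    idx -= 1  # OBJ is 1-based
                poly.append(idx)
            if len(poly) < 3:
                raise MeshParseError(f"{path}: line {lineno}: face needs >= 3 vertices")
            faces.extend(_fan_triangulate(poly))
        elif kw in ("l", "p"):
            raise MeshParseError(
                f"{path}: line {lineno}: non-polygonal record {kw!r} is not supported"
            )
        # vn/vt/usemtl/o/g/s/mtllib are ignored
    if not faces:
        raise MeshParseError(f"{path}: OBJ file has no faces")
    return TriangleMesh(
        positions=np.asarray(verts, dtype=np.float32),
        faces=np.asarray(faces, dtype=np.int64),
    )


_PLY_TYPES = {
    "char": "i1", "int8": "i1", "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2", "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4", "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4", "double": "f8", "float64": "f8",
}


def _read_ply(path: Path, data: bytes) -> TriangleMesh:
    stream = io.BytesIO(data)

    def header_line():
        raw = stream.readline()
        if not raw:
            raise MeshParseError(f"{path}: unexpected end of PLY header at byte {stream.tell()}")
        return raw.decode("ascii", errors="replace").strip()

    if header_line() != "ply":
        raise MeshParseError(f"{path}: missing 'ply' magic on line 1")
    fmt = None
    elements = []  # (name, count, [(prop_name, dtype, list_count_dtype|None)])
    while True:
        line = header_line()
        tok = line.split()
        if not tok or tok[0] == "comment":
            continue
        if tok[0] == "format":
            if tok[1] not in ("ascii", "binary_little_endian"):
                raise MeshParseError(f"{path}: unsupported PLY format {tok[1]!r}")
            fmt = tok[1]
        elif tok[0] == "element":
            elements.append((tok[1], int(tok[2]), []))
        elif tok[0] == "property":
            if not elements:
                raise MeshParseError(f"{path}: property before any element in header")
            if tok[1] == "list":
                elements[-1][2].append((tok[4], _PLY_TYPES.get(tok[3]), _PLY_TYPES.get(tok[2])))
            else:
                elements[-1][2].append((tok[2], _PLY_TYPES.get(tok[1]), None))
        elif tok[0] == "end_header":
            break
    if fmt is None:
        raise MeshParseError(f"{path}: PLY header missing 'format' line")

    verts = None
    faces: list = []
    ascii_tokens = None
    if fmt == "ascii":
        ascii_tokens = data[stream.tell():].split()
        cursor = [0]

        def take(n):
            if cursor[0] + n > len(ascii_tokens):
                raise MeshParseError(f"{path}: PLY data truncated (token {cursor[0]})")
            out = ascii_tokens[cursor[0] : cursor[0] + n]
            cursor[0] += n
            return out

    for name, count, props in elements:
        if any(t is None for _, t, _ in props) or any(
            lc is None for _, _, lc in props if lc == ""
        ):
            raise MeshParseError(f"{path}: PLY element {name!r} has an unsupported property type")
        if name == "vertex":
            idx = {p[0]: k for k, p in enumerate(props)}
            if not {"x", "y", "z"} <= set(idx):
                raise MeshParseError(f"{path}: PLY vertex element lacks x/y/z properties")
            rows = np.empty((count, len(props)), dtype=np.float64)
            if fmt == "ascii":
                for i in range(count):
                    vals = take(len(props))
                    try:
                        rows[i] = [float(v) for v in vals]
                    except ValueError:
                        raise MeshParseError(f"{path}: PLY vertex {i}: non-numeric value")
            else:
                dt = np.dtype([(p[0], "<" + p[1]) for p in props])
                buf = stream.read(dt.itemsize * count)
                if len(buf) < dt.itemsize * count:
                    raise MeshParseError(f"{path}: PLY data truncated at byte {stream.tell()}")
                rec = np.frombuffer(buf, dtype=dt, count=count)
                for k, p in enumerate(props):
                    rows[:, k] = rec[p[0]]
            verts = rows[:, [idx["x"], idx["y"], idx["z"]]].astype(np.float32)
        else:
            for i in range(count):
                for pname, ptype, list_type in props:
                    if list_type is not None:
                        if fmt == "ascii":
                            k = int(take(1)[0])
                            poly = [int(v) for v in take(k)]
                        else:
                            k = int(_read_scalar(path, stream, list_type))
                            poly = [int(_read_scalar(path, stream, ptype)) for _ in range(k)]
                        if pname in ("vertex_indices", "vertex_index") and name == "face":
                            if k < 3:
                                raise MeshParseError(
                                    f"{path}: PLY face {i} has {k} vertices (need >= 3)"
                                )
                            faces.extend(_fan_triangulate(poly))
                    else:
                        if fmt == "ascii":
                            take(1)
                        else:
                            _read_scalar(path, stream, ptype)
    if verts is None:
        raise MeshParseError(f"{path}: PLY file has no vertex element")
    if not faces:
        raise MeshParseError(f"{path}: PLY file has no faces")
    return TriangleMesh(positions=verts, faces=np.asarray(faces, dtype=np.int64))


def _read_scalar(path, stream, dtype_code: str):
    dt = np.dtype("<" + dtype_code)
    buf = stream.read(dt.itemsize)
    if len(buf) < dt.itemsize:
        raise MeshParseError(f"{path}: PLY data truncated at byte {stream.tell()}")
    return np.frombuffer(buf, dtype=dt)[0]


# ---------------------------------------------------------------------------
# volumes and isosurfaces


def load_mask_volume(path) -> MaskVolume:
    """Load a 3-D volume from NIfTI (.nii/.nii.gz) or NRRD (.nrrd).

    Spacing comes from the NIfTI zooms or the NRRD ``spacings`` / diagonal
    ``space directions``; the origin from the affine translation or
    ``space origin``.  Axis rotations in the NIfTI affine are ignored — the
    volume is treated in its stored voxel order.
    """
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim > 3:
            data = np.squeeze(data)
        zooms = img.header.get_zooms()[:3]
        origin = tuple(float(x) for x in img.affine[:3, 3])
        return MaskVolume(voxels=data, spacing=tuple(float(z) for z in zooms), origin=origin)
    if name.endswith(".nrrd"):
        return _read_nrrd(path)
    raise MeshParseError(f"{path}: unknown volume format (expected .nii, .nii.gz or .nrrd)")


_NRRD_DTYPES = {
    "signed char": "i1", "int8": "i1", "uchar": "u1", "unsigned char": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2", "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4", "uint": "u4", "uint32": "u4",
    "float": "f4", "double": "f8",
}


def _read_nrrd(path: Path) -> MaskVolume:
    """Minimal NRRD reader: ASCII header, raw or gzip encoding, the common
    spacing/origin fields.  Covers detached-free single-file NRRDs only."""
    data = path.read_bytes()
    end = data.find(b"\n\n")
    sep = 2
    if end == -1:
        end = data.find(b"\r\n\r\n")
        sep = 4
    if end == -1 or not data.startswith(b"NRRD"):
        raise MeshParseError(f"{path}: not a NRRD file (missing magic or header terminator)")
    header = {}
    for lineno, line in enumerate(data[:end].decode("ascii", errors="replace").splitlines(), 1):
        if lineno == 1 or line.startswith("#") or not line.strip():
            continue
        if ":" not in line:
            raise MeshParseError(f"{path}: header line {lineno}: missing ':'")
        key, _, value = line.partition(":")
        header[key.strip().lower()] = value.lstrip("=").strip()
    try:
        dim = int(header["dimension"])
        sizes = [int(s) for s in header["sizes"].split()]
        dtype_code = _NRRD_DTYPES[header["type"].strip()]
        encoding = header["encoding"].strip().lower()
    except KeyError as exc:
        raise MeshParseError(f"{path}: NRRD header missing field {exc}")
    if dim != 3 or len(sizes) != 3:
        raise MeshParseError(f"{path}: only 3-D NRRD volumes are supported (dimension={dim})")
    endian = header.get("endian", "little").strip().lower()
    if endian == "big":
        raise MeshParseError(f"{path}: big-endian NRRD is not supported")
    payload = data[end + sep :]
    if encoding in ("gzip", "gz"):
        payload = gzip.decompress(payload)
    elif encoding != "raw":
        raise MeshParseError(f"{path}: unsupported NRRD encoding {encoding!r}")
    dt = np.dtype("<" + dtype_code)
    n = sizes[0] * sizes[1] * sizes[2]
    if len(payload) < n * dt.itemsize:
        raise MeshParseError(
            f"{path}: NRRD data truncated ({len(payload)} bytes, need {n * dt.itemsize})"
        )
    # NRRD data is fastest-axis-first; store with sizes[0] as axis 0
    voxels = np.frombuffer(payload, dtype=dt, count=n).reshape(sizes[::-1]).transpose(2, 1, 0)
    spacing = (1.0, 1.0, 1.0)
    if "spacings" in header:
        spacing = tuple(float(s) for s in header["spacings"].split()[:3])
    elif "space directions" in header:
        vecs = [v for v in header["space directions"].split(")") if "(" in v]
        diag = []
        for v in vecs[:3]:
            comps = [float(c) for c in v.split("(")[1].split(",")]
            diag.append(float(np.linalg.norm(comps)))
        if len(diag) == 3:
            spacing = tuple(diag)
    origin = (0.0, 0.0, 0.0)
    if "space origin" in header:
        inner = header["space origin"].strip().lstrip("(").rstrip(")")
        origin = tuple(float(c) for c in inner.split(","))[:3]
    return MaskVolume(voxels=np.ascontiguousarray(voxels), spacing=spacing, origin=origin)


def isosurface_from_mask(volume: MaskVolume, threshold: float) -> TriangleMesh:
    """Extract the marching-cubes isosurface of a volume at ``threshold``.

    The volume is implicitly zero-padded by one voxel layer on every side
    so that masks touching the border still yield closed surfaces.  Vertex
    positions are linearly interpolated along cell edges and returned in
    world coordinates (``origin + index * spacing``).  A threshold at or
    outside the global value range yields an empty mesh.
    """
    from skimage import measure

    vox = np.asarray(volume.voxels, dtype=np.float64)
    if vox.ndim != 3:
        raise ValueError(f"volume must be 3-D, got {vox.ndim}-D")
    padded = np.pad(vox, 1, mode="constant", constant_values=0.0)
    if not (padded.min() < threshold < padded.max()):
        return TriangleMesh(
            positions=np.empty((0, 3), np.float32), faces=np.empty((0, 3), np.int64)
        )
    verts, faces, _normals, _values = measure.marching_cubes(
        padded, level=threshold, spacing=volume.spacing
    )
    # undo the one-voxel pad, then shift to world coordinates
    verts = verts - np.asarray(volume.spacing) + np.asarray(volume.origin)
    return TriangleMesh(positions=verts.astype(np.float32), faces=faces.astype(np.int64))


# ---------------------------------------------------------------------------
# fixtures


def _icosahedron() -> TriangleMesh:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
            (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
            (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
        ],
        dtype=np.float64,
    )
    verts /= np.linalg.norm(verts, axis=1)[:, None]
    faces = np.array(
        [
            (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
            (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
            (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
            (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
        ],
        dtype=np.int64,
    )
    return TriangleMesh(positions=verts, faces=faces)


def icosphere(level: int = 0, radius: float = 1.0, center=(0.0, 0.0, 0.0)) -> TriangleMesh:
    """Subdivided icosahedron projected onto a sphere: 20 * 4**level faces."""
    if level < 0:
        raise ValueError("subdivision level must be >= 0")
    base = _icosahedron()
    verts = [tuple(v) for v in base.positions.astype(np.float64)]
    faces = [tuple(f) for f in base.faces]
    for _ in range(level):
        cache = {}

        def midpoint(a, b):
            key = (min(a, b), max(a, b))
            if key in cache:
                return cache[key]
            m = np.asarray(verts[a]) + np.asarray(verts[b])
            m /= np.linalg.norm(m)
            verts.append(tuple(m))
            cache[key] = len(verts) - 1
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces
    pos = np.asarray(verts, dtype=np.float64) * radius + np.asarray(center, dtype=np.float64)
    return TriangleMesh(positions=pos.astype(np.float32), faces=np.asarray(faces, dtype=np.int64))


def cube(size: float = 1.0, center=(0.0, 0.0, 0.0)) -> TriangleMesh:
    """Axis-aligned cube of edge length ``size``; 12 outward-CCW triangles."""
    h = size / 2.0
    c = np.asarray(center, dtype=np.float64)
    corners = np.array(
        [(sx, sy, sz) for sx in (-h, h) for sy in (-h, h) for sz in (-h, h)]
    ) + c
    # index bit layout: x*4 + y*2 + z
    quads = [
        (0, 1, 3, 2),  # -x
        (4, 6, 7, 5),  # +x
        (0, 4, 5, 1),  # -y
        (2, 3, 7, 6),  # +y
        (0, 2, 6, 4),  # -z
        (1, 5, 7, 3),  # +z
    ]
    faces = []
    for a, b, cc, d in quads:
        faces += [(a, b, cc), (a, cc, d)]
    return TriangleMesh(positions=corners.astype(np.float32), faces=np.asarray(faces, np.int64))


def plane_grid(rows: int, cols: int, spacing: float = 1.0) -> TriangleMesh:
    """A rows x cols grid of squares in the z=0 plane, 2*rows*cols CCW (+z)
    triangles."""
    if rows < 1 or cols < 1:
        raise ValueError("plane_grid needs at least a 1x1 grid")
    xs, ys = np.meshgrid(np.arange(cols + 1), np.arange(rows + 1), indexing="xy")
    verts = np.column_stack(
        [xs.ravel() * spacing, ys.ravel() * spacing, np.zeros(xs.size)]
    )
    faces = []
    stride = cols + 1
    for r in range(rows):
        for c in range(cols):
            v00 = r * stride + c
            v10 = v00 + 1
            v01 = v00 + stride
            v11 = v01 + 1
            faces += [(v00, v10, v11), (v00, v11, v01)]
    return TriangleMesh(positions=verts.astype(np.float32), faces=np.asarray(faces, np.int64))


def two_shells(level: int = 2) -> Scene:
    """Two concentric icospheres with distinct labels and colors — a small
    stand-in for multi-surface anatomy (outer surface + inner shell)."""
    outer = Patch(
        mesh=icosphere(level=level, radius=1.0),
        label="OuterShell",
        description="ModelName=TwoShells;GroupName=Shells;ObjectColor=0.8,0.1,0.1,0.4",
    )
    inner = Patch(
        mesh=icosphere(level=level, radius=0.6),
        label="InnerShell",
        description="GroupName=Shells;ObjectColor=0.1,0.2,0.8,1;SpecularColor=0.3,0.3,0.3",
    )
    return Scene(patches=[outer, inner], model_name="TwoShells")


def random_scene(rng, max_patches: int = 8) -> Scene:
    """A randomized multi-patch scene for exercising the export pipeline.

    Draws 1..``max_patches`` patches from the deterministic fixture shapes,
    randomly scaled and shifted, with random colors (sometimes
    transparent), specular colors, group paths (flat and nested, one color
    per group path) and an occasional model name.  ``rng`` is a
    ``numpy.random.Generator``; the same state always yields the same
    scene.
    """
    from .metadata import compose_description
    from .scene_model import U3DProperties

    group_pool = [None, "GroupA", "GroupA/Sub1", "GroupB", "Deep/Nest/Leaf"]
    n = int(rng.integers(1, max_patches + 1))
    group_color: dict = {}
    scene = Scene(model_name="")
    for i in range(n):
        kind = int(rng.integers(0, 3))
        if kind == 0:
            mesh = icosphere(level=int(rng.integers(0, 2)))
        elif kind == 1:
            mesh = cube(size=float(rng.uniform(0.5, 2.0)))
        else:
            mesh = plane_grid(int(rng.integers(1, 4)), int(rng.integers(1, 4)))
        scale = float(rng.uniform(0.5, 3.0))
        offset = rng.uniform(-5, 5, size=3)
        positions = (mesh.positions.astype(np.float64) * scale + offset).astype(np.float32)
        mesh = TriangleMesh(positions=positions, faces=mesh.faces)
        alpha = 1.0 if rng.random() < 0.6 else float(np.round(rng.uniform(0.2, 0.9), 3))
        props = U3DProperties(
            object_rgba=tuple(np.round(rng.uniform(0, 1, size=3), 4)) + (alpha,),
            specular_rgb=tuple(np.round(rng.uniform(0, 1, size=3), 4))
            if rng.random() < 0.5
            else None,
            group_name=group_pool[int(rng.integers(0, len(group_pool)))],
        )
        if props.group_name and rng.random() < 0.5:
            if props.group_name not in group_color:
                group_color[props.group_name] = tuple(
                    np.round(rng.uniform(0, 1, size=4), 4)
                )
            props.group_rgba = group_color[props.group_name]
        if i == 0 and rng.random() < 0.5:
            props.model_name = "RandomModel"
        scene.add(
            Patch(mesh=mesh, label=f"Patch_{i + 1}", description=compose_description(props))
        )
    return scene


def make_fixture(kind: str, **params):
    """Deterministic test/demo geometry.

    ``kind`` is one of ``icosphere`` (param ``level``, ``radius``),
    ``cube`` (``size``), ``plane_grid`` (``rows``, ``cols``) or
    ``two_shells`` (``level``); the first three return a
    :class:`TriangleMesh`, ``two_shells`` returns a two-patch
    :class:`Scene`.
    """
    makers = {
        "icosphere": icosphere,
        "cube": cube,
        "plane_grid": plane_grid,
        "two_shells": two_shells,
    }
    if kind not in makers:
        raise ValueError(f"unknown fixture kind {kind!r} (expected {sorted(makers)})")
    return makers[kind](**params)


# ---------------------------------------------------------------------------
# writers


def write_off(mesh: TriangleMesh, path) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {mesh.n_faces} 0\n")
        for v in mesh.positions:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def write_stl_binary(mesh: TriangleMesh, path) -> None:
    faces = mesh.faces
    tri = mesh.positions[faces].astype(np.float32)  # (m, 3, 3)
    normals, _ = _face_normals_areas_f32(mesh.positions, faces)
    with open(path, "wb") as fh:
        fh.write(b"mesh2u3d binary STL".ljust(80, b"\0"))
        fh.write(struct.pack("<I", len(faces)))
        rec = np.zeros(
            len(faces), dtype=np.dtype([("n", "<3f4"), ("v", "<(3,3)f4"), ("attr", "<u2")])
        )
        rec["n"] = normals
        rec["v"] = tri
        fh.write(rec.tobytes())


def _face_normals_areas_f32(positions, faces):
    from .scene_model import _face_normals_areas

    unit, area = _face_normals_areas(positions.astype(np.float64), faces)
    return unit.astype(np.float32), area
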