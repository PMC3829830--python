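"""Core domain model: triangle meshes, patches, scenes and group trees.

A *patch* is one named surface (the unit that becomes a single U3D object);
a *scene* is the ordered collection of patches that is exported into one
U3D file.  All geometry is plain indexed triangle soup: an ``(n, 3)`` float
array of vertex positions, an ``(m, 3)`` integer array of 0-based vertex
triples, and optionally one unit normal per vertex.  Counter-clockwise
winding (seen from outside) is the outward convention throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TriangleMesh",
    "Patch",
    "U3DProperties",
    "Scene",
    "GroupNode",
    "GroupTree",
    "validate_mesh",
    "compute_vertex_normals",
    "uniquify_labels",
    "build_group_tree",
]

_NORMAL_TOL = 1e-5


@dataclass(frozen=True)
class TriangleMesh:
    """Indexed triangle mesh.

    Parameters
    ----------
    positions : (n, 3) float32 array
        Vertex positions in arbitrary spatial units.
    faces : (m, 3) int array
        0-based vertex index triples, counter-clockwise = outward.
    normals : (n, 3) float32 array, optional
        Per-vertex unit normals.
    """

    positions: np.ndarray
    faces: np.ndarray
    normals: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        pos = np.ascontiguousarray(np.asarray(self.positions, dtype=np.float32))
        pos = pos.reshape(-1, 3) if pos.size else np.empty((0, 3), np.float32)
        fac = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        fac = fac.reshape(-1, 3) if fac.size else np.empty((0, 3), np.int64)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "faces", fac)
        if self.normals is not None:
            nrm = np.ascontiguousarray(np.asarray(self.normals, dtype=np.float32))
            nrm = nrm.reshape(-1, 3) if nrm.size else np.empty((0, 3), np.float32)
            object.__setattr__(self, "normals", nrm)

    @property
    def n_vertices(self) -> int:
        return int(self.positions.shape[0])

    @property
    def n_faces(self) -> int:
        return int(self.faces.shape[0])

    def with_normals(self, normals: np.ndarray) -> "TriangleMesh":
        return replace(self, normals=normals)


@dataclass
class Patch:
    """A named, described mesh — the unit converted to one U3D object."""

    mesh: TriangleMesh
    label: str = ""
    description: str = ""


@dataclass
class U3DProperties:
    """Parsed per-patch export properties.

    ``object_rgba`` is the diffuse color plus opacity; ``specular_rgb`` the
    reflective color; ``group_name`` a "/"-separated path in the scene's
    group tree; ``group_rgba`` a color attached to that group node;
    ``model_name`` names the overall model.
    """

    object_rgba: Optional[tuple] = None
    specular_rgb: Optional[tuple] = None
    group_name: Optional[str] = None
    group_rgba: Optional[tuple] = None
    model_name: Optional[str] = None

    def __post_init__(self) -> None:
        for name, val, n in (
            ("object_rgba", self.object_rgba, 4),
            ("specular_rgb", self.specular_rgb, 3),
            ("group_rgba", self.group_rgba, 4),
        ):
            if val is None:
                continue
            val = tuple(float(c) for c in val)
            if len(val) != n:
                raise ValueError(f"{name} needs {n} components, got {len(val)}")
            if any(not (0.0 <= c <= 1.0) for c in val):
                raise ValueError(f"{name} components must lie in [0, 1]: {val}")
            setattr(self, name, val)


@dataclass
class Scene:
    """Ordered patches plus the overall model name; the unit of export."""

    patches: list = field(default_factory=list)
    model_name: str = ""

    def add(self, patch: Patch) -> None:
        self.patches.append(patch)


@dataclass
class GroupNode:
    """One node of the group hierarchy; the root carries an empty name."""

    name: str = ""
    children: dict = field(default_factory=dict)  # name -> GroupNode
    patch_labels: list = field(default_factory=list)

    def walk(self):
        """Yield (path_segments, node) depth-first, root first."""
        stack = [((), self)]
        while stack:
            path, node = stack.pop(0)
            yield path, node
            for name, child in node.children.items():
                stack.append((path + (name,), child))


@dataclass
class GroupTree:
    root: GroupNode = field(default_factory=GroupNode)

    def node_count(self) -> int:
        return sum(1 for _ in self.root.walk())

    def all_patch_labels(self) -> list:
        out = []
        for _, node in self.root.walk():
            out.extend(node.patch_labels)
        return out


# ---------------------------------------------------------------------------
# operations


def validate_mesh(mesh: TriangleMesh) -> list:
    """Check every mesh invariant; return one message per violation.

    An empty list means the mesh is valid.  Checks: finite coordinates,
    face indices in range, no degenerate (repeated-index) triangles, and —
    when normals are present — one unit normal per vertex.
    """
    violations = []
    pos, faces = mesh.positions, mesh.faces
    if pos.size and not np.all(np.isfinite(pos)):
        for idx in np.unique(np.nonzero(~np.isfinite(pos))[0]):
            violations.append(f"vertex {idx}: non-finite coordinate")
    n = mesh.n_vertices
    if faces.size:
        bad = np.nonzero((faces < 0) | (faces >= n))[0]
        for idx in np.unique(bad):
            violations.append(
                f"face {idx}: vertex index out of range [0, {n}): {tuple(faces[idx])}"
            )
        degen = np.nonzero(
            (faces[:, 0] == faces[:, 1])
            | (faces[:, 1] == faces[:, 2])
            | (faces[:, 0] == faces[:, 2])
        )[0]
        for idx in degen:
            violations.append(f"face {idx}: degenerate (repeated vertex index) {tuple(faces[idx])}")
    if mesh.normals is not None:
        if mesh.normals.shape[0] != n:
            violations.append(
                f"normals: {mesh.normals.shape[0]} normals for {n} vertices"
            )
        else:
            norms = np.linalg.norm(mesh.normals, axis=1)
            for idx in np.nonzero(np.abs(norms - 1.0) > _NORMAL_TOL)[0]:
                violations.append(f"vertex {idx}: normal is not unit length ({norms[idx]:.6f})")
    return violations


def _face_normals_areas(positions: np.ndarray, faces: np.ndarray):
    p0 = positions[faces[:, 0]]
    e1 = positions[faces[:, 1]] - p0
    e2 = positions[faces[:, 2]] - p0
    cross = np.cross(e1, e2)
    norm = np.linalg.norm(cross, axis=1)
    unit = np.zeros_like(cross)
    ok = norm > 0
    unit[ok] = cross[ok] / norm[ok][:, None]
    return unit, 0.5 * norm


def compute_vertex_normals(mesh: TriangleMesh) -> TriangleMesh:
    """Attach angle-weighted per-vertex unit normals.

    Each vertex normal is the average of the unit normals of its incident
    faces, weighted by the interior angle of the face at that vertex; face
    normals follow counter-clockwise-is-outward winding.  A vertex with no
    incident face gets the placeholder normal (0, 0, 1) and a logged
    warning.
    """
    pos = mesh.positions.astype(np.float64)
    faces = mesh.faces
    accum = np.zeros_like(pos)
    if faces.size:
        face_n, _ = _face_normals_areas(pos, faces)
        for corner in range(3):
            i = faces[:, corner]
            a = pos[faces[:, (corner + 1) % 3]] - pos[i]
            b = pos[faces[:, (corner + 2) % 3]] - pos[i]
            na = np.linalg.norm(a, axis=1)
            nb = np.linalg.norm(b, axis=1)
            denom = np.where(na * nb > 0, na * nb, 1.0)
            cosang = np.clip(np.einsum("ij,ij->i", a, b) / denom, -1.0, 1.0)
            angle = np.arccos(cosang)
            np.add.at(accum, i, face_n * angle[:, None])
    lengths = np.linalg.norm(accum, axis=1)
    isolated = lengths < 1e-12
    if np.any(isolated):
        logger.warning(
            "%d vertex/vertices without incident faces; normal set to (0, 0, 1)",
            int(isolated.sum()),
        )
        accum[isolated] = (0.0, 0.0, 1.0)
        lengths[isolated] = 1.0
    normals = (accum / lengths[:, None]).astype(np.float32)
    # renormalise in float32 so the unit invariant holds at storage precision
    n32 = np.linalg.norm(normals.astype(np.float64), axis=1)
    normals = (normals / np.where(n32 > 0, n32, 1.0)[:, None]).astype(np.float32)
    return mesh.with_normals(normals)


def uniquify_labels(scene: Scene) -> Scene:
    """Return a scene whose patch labels are all non-empty and unique.

    Processing in patch order: an empty label at (1-based) position *i*
    becomes ``Object_i``; a label colliding with an earlier finalized one
    gets the ``_k`` suffix with the smallest integer k >= 1 that restores
    uniqueness.  Idempotent: a scene with unique non-empty labels is
    returned unchanged.
    """
    taken = set()
    new_patches = []
    for i, patch in enumerate(scene.patches, start=1):
        label = patch.label or f"Object_{i}"
        if label in taken:
            k = 1
            while f"{label}_{k}" in taken:
                k += 1
            label = f"{label}_{k}"
        taken.add(label)
        if label != patch.label:
            patch = Patch(mesh=patch.mesh, label=label, description=patch.description)
        new_patches.append(patch)
    return Scene(patches=new_patches, model_name=scene.model_name)


def build_group_tree(scene: Scene, properties: Sequence[U3DProperties]) -> GroupTree:
    """Build the group hierarchy from per-patch "/"-separated group paths.

    Patches without a group attach to the (unnamed) root; identical paths
    share one node and intermediate nodes are created on demand.  A group
    segment that equals a patch label is rejected, because U3D group and
    model nodes share one node-palette namespace.
    """
    if len(properties) != len(scene.patches):
        raise ValueError("one U3DProperties per patch required")
    labels = {p.label for p in scene.patches}
    tree = GroupTree()
    for patch, props in zip(scene.patches, properties):
        node = tree.root
        if props.group_name:
            segments = [s for s in props.group_name.split("/") if s]
            for seg in segments:
                if seg in labels:
                    raise ValueError(
                        f"group name {seg!r} collides with a patch label "
                        "(shared U3D node palette)"
                    )
                node = node.children.setdefault(seg, GroupNode(name=seg))
        node.patch_labels.append(patch.label)
    return tree
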