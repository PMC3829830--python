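"""Quadric-error-metric edge-collapse decimation.

Each vertex accumulates a symmetric 4x4 quadric — the sum of outer
products ``p p^T`` of the (unit-normal) plane equations of its incident
faces — so that ``v^T Q v`` is the sum of squared distances of a point to
those planes.  Edges are collapsed cheapest-first from a priority queue
with lazy invalidation.  Placement uses the *subset* (half-edge) policy:
the merged vertex is whichever endpoint of the edge has the lower
accumulated-quadric error, so every output vertex is one of the input
vertices and the decimated surface never drifts off the original
geometry (free quadric-optimal placement, by contrast, systematically
inflates convex anatomy like spherical organ surfaces).  Collapses that
would flip or geometrically degenerate a surviving triangle are
rejected.  Because flat regions have (near-)zero quadric error,
triangles on plane surfaces are always the first to be replaced by a
coarser mesh.

Boundary edges receive an extra high-weight constraint plane through the
edge and perpendicular to the adjacent face, which pins the decimated
boundary to the original one.
"""

from __future__ import annotations

import heapq
import logging

import numpy as np

from .scene_model import TriangleMesh, compute_vertex_normals

logger = logging.getLogger(__name__)

__all__ = ["decimate", "vertex_quadrics", "BOUNDARY_WEIGHT", "MIN_FACES"]

BOUNDARY_WEIGHT = 1000.0
MIN_FACES = 4


def _plane_quadric(normal: np.ndarray, point: np.ndarray) -> np.ndarray:
    d = -float(np.dot(normal, point))
    p = np.array([normal[0], normal[1], normal[2], d], dtype=np.float64)
    return np.outer(p, p)


def vertex_quadrics(mesh: TriangleMesh) -> np.ndarray:
    """Per-vertex 4x4 quadrics: face planes plus weighted boundary planes."""
    pos = mesh.positions.astype(np.float64)
    faces = mesh.faces
    Q = np.zeros((mesh.n_vertices, 4, 4), dtype=np.float64)
    edge_count: dict = {}
    edge_face: dict = {}
    for fi, (a, b, c) in enumerate(faces):
        p0, p1, p2 = pos[a], pos[b], pos[c]
        n = np.cross(p1 - p0, p2 - p0)
        norm = np.linalg.norm(n)
        if norm <= 0:
            continue
        n /= norm
        K = _plane_quadric(n, p0)
        Q[a] += K
        Q[b] += K
        Q[c] += K
        for u, v in ((a, b), (b, c), (c, a)):
            key = (min(u, v), max(u, v))
            edge_count[key] = edge_count.get(key, 0) + 1
            edge_face[key] = fi
    # boundary constraint: a plane through the edge, perpendicular to the face
    for key, count in edge_count.items():
        if count != 1:
            continue
        u, v = key
        fi = edge_face[key]
        a, b, c = faces[fi]
        p0, p1, p2 = pos[a], pos[b], pos[c]
        fn = np.cross(p1 - p0, p2 - p0)
        fnorm = np.linalg.norm(fn)
        if fnorm <= 0:
            continue
        fn /= fnorm
        edge_dir = pos[v] - pos[u]
        en = np.linalg.norm(edge_dir)
        if en <= 0:
            continue
        cn = np.cross(edge_dir / en, fn)
        cnorm = np.linalg.norm(cn)
        if cnorm <= 0:
            continue
        K = BOUNDARY_WEIGHT * _plane_quadric(cn / cnorm, pos[u])
        Q[u] += K
        Q[v] += K
    return Q


def _quadric_error(Q: np.ndarray, point: np.ndarray) -> float:
    h = np.append(point, 1.0)
    return max(float(h @ Q @ h), 0.0)


def _placement(Q: np.ndarray, pa: np.ndarray, pb: np.ndarray):
    """Subset placement: the endpoint with the lower quadric error.

    Ties (within 1e-15) keep the first endpoint, i.e. the smaller vertex
    index, which keeps the collapse order deterministic.
    """
    err_a = _quadric_error(Q, pa)
    err_b = _quadric_error(Q, pb)
    if err_b < err_a - 1e-15:
        return pb, err_b
    return pa, err_a


def _edge_error(Q: np.ndarray, pa, pb):
    point, err = _placement(Q, pa, pb)
    return err, point


def decimate(mesh: TriangleMesh, reduction_rate: float) -> TriangleMesh:
    """Reduce a mesh to ``max(4, round((1 - reduction_rate) * F))`` faces.

    ``reduction_rate`` is the fraction of triangles to remove (0.95 removes
    95% of them).  The collapse order is deterministic: queue ties are
    broken by the sorted vertex-index pair.  If no legal collapse remains
    before the target is reached the current mesh is returned with a
    logged warning.  Vertex normals, when present on the input, are
    recomputed on the result.
    """
    if not (0.0 <= reduction_rate < 1.0):
        raise ValueError(f"reduction_rate must lie in [0, 1): {reduction_rate}")
    n_faces = mesh.n_faces
    target = max(MIN_FACES, int(round((1.0 - reduction_rate) * n_faces)))
    if target >= n_faces:
        return mesh

    pos = [p.astype(np.float64) for p in mesh.positions]
    quadrics = list(vertex_quadrics(mesh))
    faces = [list(f) for f in mesh.faces]
    alive = [True] * len(faces)
    vertex_faces = [set() for _ in range(len(pos))]
    for fi, f in enumerate(faces):
        for v in f:
            vertex_faces[v].add(fi)
    version = [0] * len(pos)
    alive_count = n_faces

    heap: list = []

    def push_edge(a: int, b: int) -> None:
        a, b = (a, b) if a < b else (b, a)
        err, _ = _edge_error(quadrics[a] + quadrics[b], pos[a], pos[b])
        heapq.heappush(heap, (err, a, b, version[a], version[b]))

    seen = set()
    for f in faces:
        for u, v in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            key = (min(u, v), max(u, v))
            if key not in seen:
                seen.add(key)
                push_edge(*key)
    del seen

    def face_normal(fi: int, override: int = -1, new_pos=None):
        a, b, c = faces[fi]
        pa = new_pos if a == override else pos[a]
        pb = new_pos if b == override else pos[b]
        pc = new_pos if c == override else pos[c]
        n = np.cross(pb - pa, pc - pa)
        return n

    while alive_count > target and heap:
        err, a, b, va, vb = heapq.heappop(heap)
        if version[a] != va or version[b] != vb:
            continue  # stale entry
        shared = vertex_faces[a] & vertex_faces[b]
        if not shared:
            continue  # edge no longer exists
        Q = quadrics[a] + quadrics[b]
        new_pos, _ = _placement(Q, pos[a], pos[b])

        # legality: no surviving incident face may flip or degenerate
        affected = (vertex_faces[a] | vertex_faces[b]) - shared
        legal = True
        for fi in affected:
            if not alive[fi]:
                continue
            before = face_normal(fi)
            f2 = [a if v == b else v for v in faces[fi]]
            pa_, pb_, pc_ = (
                new_pos if v == a else pos[v] for v in f2
            )
            after = np.cross(pb_ - pa_, pc_ - pa_)
            if np.linalg.norm(after) < 1e-14:
                legal = False
                break
            nb = np.linalg.norm(before)
            if nb > 0 and float(np.dot(before / nb, after / np.linalg.norm(after))) < 0.0:
                legal = False
                break
        if not legal:
            continue

        # commit: merge b into a
        for fi in shared:
            if alive[fi]:
                alive[fi] = False
                alive_count -= 1
            for v in faces[fi]:
                vertex_faces[v].discard(fi)
        for fi in list(vertex_faces[b]):
            faces[fi] = [a if v == b else v for v in faces[fi]]
            vertex_faces[a].add(fi)
        vertex_faces[b] = set()
        pos[a] = np.asarray(new_pos, dtype=np.float64)
        quadrics[a] = Q
        version[a] += 1
        version[b] += 1

        neighbors = set()
        for fi in vertex_faces[a]:
            neighbors.update(faces[fi])
        neighbors.discard(a)
        for n in sorted(neighbors):
            push_edge(a, n)

    if alive_count > target:
        logger.warning(
            "decimation stopped at %d faces (target %d): no legal collapse remains",
            alive_count, target,
        )

    # compact: keep alive faces and referenced vertices, preserving order
    out_faces = [faces[fi] for fi in range(len(faces)) if alive[fi]]
    used = sorted({v for f in out_faces for v in f})
    remap = {v: i for i, v in enumerate(used)}
    new_positions = np.asarray([pos[v] for v in used], dtype=np.float32)
    new_faces = np.asarray([[remap[v] for v in f] for f in out_faces], dtype=np.int64)
    result = TriangleMesh(positions=new_positions, faces=new_faces)
    if mesh.normals is not None:
        result = compute_vertex_normals(result)
    return result
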