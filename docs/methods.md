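# Methods

This note documents the models, algorithms and design choices behind
`mesh2u3d`, in the spirit of a methods section: what is computed, under
which assumptions, which knobs exist and why their defaults are what
they are, and what the synthetic fixtures do and do not demonstrate.

## Scene model

The unit of conversion is the *patch*: one indexed triangle mesh plus a
label and a description string. A *scene* is an ordered patch list; on
export every patch becomes exactly one U3D object carrying the patch
label. Geometry is float32 (the precision U3D stores), faces are
0-based vertex triples, and counter-clockwise winding seen from outside
is the outward convention — the dominant convention of the supported
input formats.

Label uniquification runs in patch order: an empty label at 1-based
position *i* becomes `Object_i`; a label equal to an earlier finalized
one gets the suffix `_k` with the smallest `k ≥ 1` that restores
uniqueness. The scheme is deterministic, readable and idempotent
(uniquifying an already-unique scene is the identity). Because it is
order-based, a later patch whose original label happens to equal an
earlier patch's generated name is itself renamed — global uniqueness
always wins over preserving an input label.

Vertex normals (required for U3D shading) are angle-weighted averages
of incident-face normals: each face contributes its unit normal scaled
by the interior angle at the vertex. Angle weighting is insensitive to
how a polygon happened to be triangulated and gives the exact corner
diagonal on a cube and near-radial normals on a sphere. Vertices with
no incident face get the placeholder (0, 0, 1) and a logged warning.

Group membership is a `/`-separated path ("Skeleton/Left"); the group
tree is a strict tree rooted at an unnamed node, intermediate nodes are
created on demand, and a group segment equal to a patch label is
rejected because U3D keeps group and model nodes in one name-keyed node
palette.

## Description grammar

Per-patch properties are string-encoded as `Key=Value` entries joined
by `;`, with keys `ModelName`, `GroupName`, `GroupColor`, `ObjectColor`,
`SpecularColor`. Colors are comma-separated decimals in [0, 1] — RGBA
(4 components) for object and group colors, RGB (3) for specular. `;`
and `=` are reserved everywhere; `/` is reserved except in `GroupName`
where it separates path levels. Composition is canonical (fixed key
order, shortest-round-trip float formatting), so compose∘parse and
parse∘compose are identities on their respective domains, and parsing
never silently drops an entry — anything unrecognized raises.

Scene-level resolution: the model name is the first non-empty
`ModelName` in patch order (later conflicting values are logged and
ignored), defaulting to `"Model"`. Unset object color defaults to
mid-gray opaque (0.7, 0.7, 0.7, 1.0) and unset specular to a dim
(0.1, 0.1, 0.1) — neutral on-screen appearance for unannotated
surfaces. When several patches of one group supply a `GroupColor`, the
first wins.

## Mesh input

The four readers are deliberately strict: parse errors name the line
(text formats) or byte offset (binary) of the failure; empty files,
non-polygonal records (OBJ `l`/`p`) and count mismatches are errors.
Polygons with more than three vertices are fan-triangulated from their
first vertex. STL carries no connectivity, so facets are welded by
*exact* coordinate equality (tolerance 0) — near-duplicate vertices are
never silently merged; if welding is wanted at a tolerance, it should
be an explicit upstream step. PLY support covers ASCII and
binary-little-endian with arbitrary scalar vertex properties (x/y/z
extracted) and a list-typed face property.

Volume masks load from NIfTI (via nibabel; spacing from the header
zooms, origin from the affine translation — axis rotations in the
affine are ignored, the volume is processed in stored voxel order) or
from NRRD through a small built-in reader covering the common
single-file subset (ASCII header; raw or gzip encoding; little-endian;
`spacings`/diagonal `space directions`; `space origin`).

## Isosurface extraction

`isosurface_from_mask` zero-pads the volume by one voxel layer on every
side, so a mask touching the volume border still produces a *closed*
surface, then runs scikit-image's marching cubes (Lewiner variant,
which resolves the ambiguous cube cases and guarantees watertight
output — every undirected edge incident to exactly two faces). Vertices
are linearly interpolated along cell edges and mapped to world
coordinates as `origin + index · spacing`. A threshold at or outside
the padded volume's value range yields an empty mesh. On a binary
single-voxel mask the result is the expected octahedron (V−E+F = 2); on
a rasterized ball of radius 10 voxels the summed triangle area lands
within a few percent of 4πr² (the residual is voxelization error, not
mesh error).

## Decimation

Quadric-error-metric edge collapse. Per-vertex quadrics sum the outer
products of incident-face plane equations (unit normals); boundary
edges add a constraint plane through the edge and perpendicular to the
adjacent face, weighted ×1000, which pins open-sheet outlines. Edge
candidates live in a binary heap with lazy invalidation (entries are
stamped with per-vertex version counters); ties are broken by the
sorted vertex-index pair, so decimation is deterministic. A collapse is
rejected if any surviving face would flip its normal (negative dot of
before/after) or become geometrically degenerate. The target is
`max(4, round((1−r)·F))` faces; if no legal collapse remains earlier,
the current mesh is returned with a warning.

Placement policy: the merged vertex is the edge endpoint with the lower
accumulated-quadric error (*subset placement*, the policy of half-edge
decimaters such as OpenMesh's). We measured the alternatives on the
level-3 icosphere reduced by 95% (1280 → 64 faces): solving the 4×4
system for the free optimal position inflates convex surfaces — the
accumulated planes of a merged spherical cap place the minimizer
outside the sphere, up to 5.4% radial overshoot at this coarseness —
while constraining the optimum to the collapsing segment undershoots
comparably (−5.5%), and recomputing quadrics from the current mesh
("memoryless") drifts worst (+8.9%). Subset placement keeps every
output vertex on the original vertex set, i.e. zero radial drift on
curved anatomy, at the cost of slightly higher mean in-plane error —
the right trade-off for surfaces whose silhouette and volume must stay
trustworthy in a publication figure. Flat regions are unaffected by the
policy: coplanar collapses carry zero error, so plane-dominated meshes
coarsen first and stay exactly in their plane.

A reduction rate of 0.95 (remove 95% of triangles) is a practical
default for voxel-precise anatomy meshes destined for illustration;
the rate is exposed as `--reduce` and per-call.

## U3D serialization

File layout: File Header Block (type `0x00443355`; version fields 0,
profile 0, UTF-8 string encoding code 106), then the declaration area,
then the continuation area. Two serialization passes back-patch the
header's declaration-size and file-size fields; the reader re-verifies
both. All multi-byte values are little-endian; strings are
length-prefixed (u16) UTF-8; every block's data and metadata payloads
are zero-padded to 32-bit boundaries while the declared sizes stay
unpadded.

Scene graph: one modifier chain per node. The root group node is named
after the model — that is how the model name travels in the file — and
everything else parents under it: group nodes per group-tree entry,
one model node + shading modifier per patch, plus one ambient light
node (white, intensity 1) with its light resource, so exported objects
are lit in viewers that honor scene lights. Node-palette names must be
unique, so a group segment that collides with another node keeps its
true segment name in a `GroupSegment` metadata pair while the palette
name gets a suffix; group colors, which have no U3D material of their
own, ride as a `GroupColor` metadata pair on the group's chain block
(U3D blocks carry first-class key/value metadata payloads). Readers
that ignore metadata simply see a plain group tree.

Appearance: one lit-texture-shader + material resource pair per
distinct (RGBA, specular) combination, shared across patches in
first-use order — equal-colored patches reference one material.
Material: diffuse = RGB, opacity = alpha, specular from the reflective
color, ambient = 0.25·diffuse, emissive 0, reflectivity 0.1. Alpha < 1
additionally switches the shader's framebuffer blend to alpha blending.

Geometry: one CLOD mesh generator declaration per patch with minimum
resolution = final maximum resolution = vertex count, and a single base
mesh continuation block carrying all geometry — no progressive
resolution updates. The continuous-level-of-detail structures required
by the format are present, but the mesh is complete at base resolution,
which every mainstream PDF viewer renders directly; progressive
streaming adds nothing for document-embedded models. Positions and
per-vertex normals are raw float32 triples; faces are written through
the compression contexts: the shading id in a dynamic context, position
and normal indices in static contexts sized by the vertex count.
Colors are per-object via materials, so base-mesh color pools stay
empty. Out of scope by design: textures, 2D glyph labels, point sets,
line sets, animations, views/cameras (viewers supply a default view),
and PDF generation itself.

## The bit coder

ECMA-363 block payloads mix plain values with compressed unsigned
integers driven by a 16-bit arithmetic coder over per-context symbol
histograms. Dynamic contexts (ids 1..0x3FF) adapt: a value `v` is coded
as symbol `v+1`; a symbol unseen in that context escapes (symbol 0) and
is followed by a raw literal, after which the histogram learns it.
Histogram totals halve at 0x1FFF ("elephant" cap) and symbols ≥ 0xFFFF
are never tracked (always escaped). Static contexts `0x400 + r` encode
a uniform range of `r` values; ranges beyond the coder's 16-bit
precision (≥ 0x3FFF) fall back to raw little-endian writes, as do all
floats. Bits pack least-significant-first into bytes with coder bits
emitted most-significant-first, which makes byte-aligned plain data
appear verbatim in the payload (both ends exploit this with a bulk
fast path whose output is bit-identical to the coded path). At block
end the writer emits the quarter-disambiguation bits (the classic
arithmetic-coding flush) and zero-pads to a byte; each block gets a
fresh coder, so blocks decode independently.

Conformance of the coder is established by exhaustive self-round-trip
testing (mixed plain/compressed streams, escape paths, skewed
distributions — which also verify real compression, ~10× on geometric
data); rendering exported files in an external PDF viewer remains a
manual check, as no installable independent U3D parser exists to
automate it.

## Synthetic data and what the tests show

All fixtures are generated programmatically: icospheres (20·4^level
faces, analytically unit radius), cubes, planar grids (2·rows·cols
faces), a two-shell scene emulating nested anatomy surfaces (e.g. an
outer bone surface over an inner shell) with distinct colors and a
shared group, rasterized ball masks for isosurfacing, and randomized
multi-patch scenes (1–8 patches, random transforms, colors with and
without transparency, flat and nested group paths, occasional model
names) for the round-trip suite. These cover the format mechanics and
the geometry pipeline end to end, including bitwise geometry recovery
and byte determinism.

What they do not show: real segmentation masks are noisier and more
topologically complex than rasterized balls (handles, cavities,
staircase aliasing), real meshes can be non-manifold or self-
intersecting (the validator rejects only indexing-level defects), and
on-screen appearance in a specific PDF viewer is outside automated
reach. Problem sizes in the default test run (icosphere level ≤ 3,
32³ volumes, 50 random scenes, 10⁴ coded values) were chosen so the
full suite completes in seconds while still exercising every code
path; all properties checked are size-independent invariants, not
fitted constants.

## Known limitations

* Writer and reader support the base-mesh subset of ECMA-363 this
  package emits; the reader lists and skips unknown block types rather
  than failing, but does not reconstruct progressive meshes, textures
  or animation data.
* NIfTI affines are reduced to zooms + translation; oblique
  acquisitions should be resampled upstream.
* Patches are decimated independently; shared boundaries between
  adjacent patches may drift apart at high reduction rates.
* Non-triangle input faces are fan-triangulated, which is correct for
  convex polygons only.
* The exact byte stream of other U3D writers is not reproduced (the
  standard leaves freedom in block ordering and context usage); files
  are standard-conforming but byte-level comparison with third-party
  exporters is not meaningful.
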