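# mesh2u3d

Convert biomedical surface meshes into **Universal 3D (U3D)** files —
the ECMA-363 binary scene-graph format that PDF authoring tools embed
into interactive 3D PDF documents.

Publishing segmented anatomy (organ surfaces, bone shells, vessel trees)
as an interactive 3D model inside an ordinary PDF is one of the most
accessible ways to share volumetric results with readers, clinicians and
students: the reader only needs a PDF viewer with 3D support. The
bottleneck is producing a *valid, well-annotated* U3D file: the format
is binary, bit-packed and scene-graph structured, and the authoring tool
needs object names, colors, transparency and grouping to come along with
the geometry. `mesh2u3d` fills exactly that gap:

* **read** triangle meshes from STL (ASCII + binary), OFF, Wavefront OBJ
  and PLY (ASCII + binary little-endian), or **extract** isosurfaces
  from volumetric segmentation masks (NIfTI, NRRD) by marching cubes;
* **annotate** each surface patch with a name, diffuse color + opacity,
  specular (reflective) color, group path and overall model name via a
  compact `Key=Value;...` description grammar;
* **decimate** heavy meshes with quadric-error-metric edge collapse to
  meet a target triangle-reduction rate (e.g. remove 95% of triangles —
  usually plenty for illustration while keeping file sizes small);
* **write** a standard-conforming U3D file: one U3D object per patch,
  a monohierarchic group tree, shared shader/material resources for
  patches of equal color, an ambient light, and base-mesh CLOD geometry
  serialized through the standard's context-based arithmetic bit coder;
* **read back / inspect** any file it writes — the bundled parser is
  the round-trip oracle for the test suite and powers `mesh2u3d inspect`.

The U3D file is the 3D payload; assembling the final PDF remains the job
of an authoring tool (Adobe Acrobat, LaTeX `media9`, iText, ...), which
imports `.u3d` files directly.

## The core machinery in brief

**Quadric-error decimation.** Every vertex accumulates the 4×4 quadric
`Q = Σ p pᵀ` over the plane equations `p = (n, d)` of its incident
triangles, so `vᵀQv` is the summed squared distance to those planes.
Edges are collapsed cheapest-first; the merged vertex is the edge
endpoint with the lower accumulated error (subset placement), so the
decimated surface never drifts off the original geometry. Flat regions
cost nothing to collapse and go first; boundary edges get a heavily
weighted (×1000) constraint plane so open sheets keep their outline.
A reduction rate *r* targets `max(4, round((1−r)·F))` faces.

**U3D serialization.** A U3D file is a File Header Block
(type `0x00443355`, "U3D" in ASCII) followed by declaration blocks (the
scene graph: group/model/light nodes as modifier chains, shader +
material + light resources, one CLOD mesh declaration per patch) and
continuation blocks (one base mesh per patch with raw float32 positions
and normals, and face indices compressed by the standard's adaptive
context arithmetic coder). Writing is two-pass so the header's
declaration-size and file-size fields are exact, and byte-deterministic:
the same scene always produces the identical file.

## Worked example

```bash
mesh2u3d fixture two_shells --level 2 -o demo   # two concentric spheres
mesh2u3d convert --config demo.yaml -o demo.u3d
mesh2u3d inspect demo.u3d
```

prints

```
U3D file: demo.u3d
model name: TwoShells
  offset        type      data    meta  name
       0  0x00443355        24       0  FILE_HEADER
      36  0xFFFFFF14       120       0  MODIFIER_CHAIN TwoShells
     168  0xFFFFFF14       120       0  MODIFIER_CHAIN Shells
     300  0xFFFFFF14       192       0  MODIFIER_CHAIN OuterShell
     504  0xFFFFFF14       192       0  MODIFIER_CHAIN InnerShell
     708  0xFFFFFF14       140       0  MODIFIER_CHAIN AmbientLight
     860  0xFFFFFF51        55       0  LIGHT_RESOURCE AmbientLight
     928  0xFFFFFF53        50       0  LIT_TEXTURE_SHADER Shader_1
     992  0xFFFFFF54        72       0  MATERIAL_RESOURCE Material_1
    1076  0xFFFFFF53        50       0  LIT_TEXTURE_SHADER Shader_2
    1140  0xFFFFFF54        72       0  MATERIAL_RESOURCE Material_2
    1224  0xFFFFFF14       152       0  MODIFIER_CHAIN OuterShell
    1388  0xFFFFFF14       152       0  MODIFIER_CHAIN InnerShell
    1552  0xFFFFFF3B      5695       0  CLOD_BASE_MESH_CONTINUATION OuterShell
    7260  0xFFFFFF3B      5695       0  CLOD_BASE_MESH_CONTINUATION InnerShell
objects:
  OuterShell: 320 faces, 162 vertices, color 0.800,0.100,0.100,0.400, group Shells
  InnerShell: 320 faces, 162 vertices, color 0.100,0.200,0.800,1.000, group Shells
```

Reading the listing: the header block is followed by the scene graph —
the root group node carries the model name (`TwoShells`), a `Shells`
group holds both objects, each patch contributes a model-node chain
(node + shading modifier) and a mesh-declaration chain, and all
geometry sits in the two base-mesh continuation blocks. The semi-
transparent red outer shell (alpha 0.4) lets the opaque blue inner
shell show through in a 3D-PDF viewer. Colors, names and grouping came
from `demo.yaml`, which the `fixture` command wrote next to the meshes.

Direct flags work too — convert a segmented mask and an STL into one
model, removing 95% of the triangles:

```bash
mesh2u3d convert \
    --mask liver.nii.gz --threshold 0.5 --label Liver --color 0.6,0.2,0.2,1 \
    --in implant.stl --label Implant --color 0.8,0.8,0.9,0.7 \
    --group Abdomen --group Abdomen \
    --model-name Patient042 --reduce 0.95 -o patient042.u3d
```

The library mirrors the CLI one-to-one
(`read_mesh`, `isosurface_from_mask`, `decimate`, `write_u3d`,
`read_u3d`, ...); see the module docstrings.

Opening an exported file in a 3D-capable PDF viewer (drag the `.u3d`
into a PDF via an authoring tool) and checking names, colors and the
group tree is a useful manual sanity check; the automated round trip
covers everything except the final on-screen rendering.

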