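# insecthull

Natural-colour 3D digitization of pinned insect specimens from turntable
photography — as a library and command-line pipeline, with a bundled
analytic renderer standing in for the physical camera rig so everything
runs (and is tested against ground truth) on one CPU.

Museum and collection specimens from roughly 3–30 mm are traditionally
documented with text and 2D photographs, which cannot show a specimen
"from all angles"; precious holotypes still get shipped between
institutions for re-examination.  A cost-effective alternative is to
photograph the pinned specimen on a two-axis turntable from many pan/tilt
angles (and, for millimetre-scale specimens, at many focus distances per
angle, because macro optics have sub-millimetre depth of field) and
reconstruct a textured, watertight 3D surface model from the images.

## Method

The reconstruction core is **shape from silhouette** (the visual hull).
Each calibrated view *i* contributes a binary silhouette *S_i*; the
visual hull is the intersection of the back-projected silhouette cones

    VH = ∩_i  π_i⁻¹(S_i),

the maximal shape consistent with every silhouette — always a superset of
the true object, unable to represent concavities.  The pipeline realizes
it by **volume carving**: a voxel of an axis-aligned grid survives iff,
in every view, at least one of its sample points projects inside the
(conservatively 1 px dilated) silhouette; voxels a view cannot see
(outside its frame, or behind the camera — e.g. the underside occluded by
the mounting mat) are never carved by that view.  An octree variant
(`carve_octree`) prunes provably-interior/exterior nodes and is
bit-identical to the dense rule.  The surface is extracted by marching
cubes at iso-level 0.5 and textured per face from the single view that
sees the face most nearly head-on (depth-buffer visibility, then maximal
|cos| between face normal and viewing direction), since colour fidelity
is best where surface normals are parallel to the camera axis.

Around that core:

* **Acquisition plans** (`insecthull.plan`) — normal mode: 24 pan × 6
  tilt = 144 captures; macro mode adds an inner loop of 31 focus
  positions 0.25 mm apart: 4,464 captures per specimen.
* **Focus stacking** (`insecthull.stacking`) — per-pixel variance of
  Laplacian sharpness, argmax frame selection with median smoothing,
  hard (colour-conserving) compositing.
* **Camera poses** (`insecthull.camera`) — from turntable kinematics, or
  estimated from a printed fiducial mat (a ring of colour-coded dots) by
  homography decomposition plus nonlinear reprojection refinement.
* **Pin removal** (`insecthull.texturing.remove_pin`) — either delete
  secondary mesh components (a pin separated from the body carves to its
  own component) or delete faces inside a user-given cylinder around the
  pin axis; alternatively mask the pin in 2D before carving
  (`apply_exclusions`), which removes it from the hull at the cost of
  possible texture contamination where it crossed the body.
* **Export** — OBJ (+MTL+PNG atlas), binary PLY, binary STL, X3D.
* **Synthetic rig** (`insecthull.render`) — exact ray-cast renders of
  quadric/box scenes with ground-truth mattes, depths, poses and
  closed-form volumes, plus a circle-of-confusion defocus model for
  macro-rail simulation.

## Worked example

Digitize the stock synthetic specimen (a ~3 mm weevil: ellipsoid body,
sphere head, six cylinder legs, 0.2 mm mounting pin) in macro mode —
5 focus positions per view here, 8 pans × 4 tilts:

```yaml
# weevil.yaml
mode: macro
pan_steps: 8
tilt_angles_deg: [-40.0, -15.0, 15.0, 40.0]
focus_count: 5
focus_step_mm: 1.0
scene: weevil
export_formats: [obj, x3d]
```

```sh
insecthull run --config weevil.yaml --out model
```

prints the per-stage manifest:

```json
{
  "plan":        {"views": 32, "total_captures": 160},
  "acquire":     {"source": "synthetic", "views": 32, "captures": 160},
  "silhouettes": {"views": 32, "mean_area_px": 55302.3},
  "carve":       {"resolution": 96, "occupied_voxels": 19078,
                  "volume_mm3": 5.6527},
  "mesh":        {"vertices": 8628, "faces": 17172},
  "texture":     {"faces_textured": 17168, "faces_unseen": 4},
  "export":      {"files": ["model/model.obj", "model/model.mtl",
                            "model/model.png", "model/model.x3d"]}
}
```

160 simulated captures were stacked to 32 all-in-focus views, segmented,
and carved on a 96³ grid (6.4 mm box, 0.067 mm voxels): 19,078 occupied
voxels ≈ 5.65 mm³ of hull, meshed to 17,172 triangles of which all but 4
were assigned a source photograph for texture.  The exported OBJ encloses
5.59 mm³, +5.4% over the scene's closed-form volume of 5.30 mm³ — the
visual hull is a slight superset by construction, and the 1 px
conservative silhouette dilation adds a thin shell.

Every stage is also available separately (`insecthull plan / simulate /
stack / mask / pose / carve / texture / editpin / export`), reading and
writing plain files so intermediate results can be inspected.

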