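# Methods

This note records the models, conventions, numerical choices and known
limitations behind `insecthull`, in the order the pipeline runs.

## Coordinate and camera conventions

One convention is used everywhere: a right-handed, specimen-centred
world frame with +Z up along the pin axis; all lengths in millimetres;
angles in degrees at API boundaries and radians internally.  Cameras are
distortion-free pinholes with square pixels: `x_cam = R x_world + t`,
camera +z forward, +x image-right, +y image-down, pixel origin top-left,
`u = f·x/z + cx`.  The rig camera sits on the world +X axis looking at
the origin; turntable pan rotates the specimen about +Z and tilt about
+Y, so a capture at (pan, tilt) is equivalent to a virtual camera whose
extrinsics compose the fixed rig pose with the specimen rotation
`R_y(tilt)·R_z(pan)`.  Lens distortion and intrinsics self-calibration
are out of scope; images are assumed rectified.

## Acquisition schedules

Normal mode enumerates `pan_steps` uniform pan angles at each tilt,
pan-major.  The stock schedule is 24 pans × 6 tilts (±45°, ±27°, ±9°) =
144 captures; only the product is fixed by the rig design this emulates,
so the factorization is configurable.  Macro mode attaches an inner loop
of uniformly spaced focus-rail positions — stock 31 positions 0.25 mm
apart, hence 4,464 captures.  The 10 mm normal-vs-macro specimen-size
rule of thumb is advisory; the mode is an explicit flag.  File ingestion
follows the `view{i:04d}_focus{j:03d}.png` convention (this package's
convention, not the rig's).

## Fiducial mat and pose estimation

The commercial reconstruction software this pipeline replaces calibrates
from a proprietary printed mat whose pattern is unpublished.  The
substitute here is fully documented: `marker_count` circular dots evenly
spaced on a ring (default 12 dots of 3 mm on a 40 mm ring) in the mat
plane Z = 0, each dot filled with a colour that encodes its 6-bit id —
two bits per RGB channel over four intensity levels {40, 100, 160, 220}.
Colour is invariant to viewing angle, so ids decode at steep tilts
without unwarping a perspective-distorted code ring; decoding rejects a
channel more than 28 (half the level gap) from every level.  Detection
segments pixels within Euclidean RGB distance 35 of any code colour,
takes connected components ≥ 12 px, and reports sub-pixel centroids.

Pose from ≥ 4 identified markers: a normalized-DLT homography of the mat
plane is decomposed with the known intrinsics (the two in-plane columns
orthonormalized by SVD, sign fixed so the mat lies in front of the
camera), then refined by Levenberg–Marquardt on reprojection error
(rotation parameterized as a rotation vector; tolerances 1e-10 on cost,
≤ 100 iterations).  Collinear image points are rejected as degenerate
(second singular value < 1e-6 of the first).  Because intrinsics and mat
geometry are fixed and no parameters are shared across views, the joint
multi-view refinement decomposes into independent per-view solves; each
refined pose is kept only if its RMS does not increase, so the total RMS
is non-increasing by construction.  When detection fails for a view the
turntable kinematics (always known) provide the fallback pose.

## Focus stacking

Sharpness is the local variance of the Laplacian of ITU-R 601 luminance
over a 9 px window — non-negative, zero on constant regions, invariant
to DC offset.  Depth selection is the per-pixel argmax across frames
(ties to the lower index), median-filtered with radius 5 px so isolated
misselections in textureless regions inherit their neighbourhood's
index.  Compositing is hard per-pixel selection, which conserves colours
exactly (every output pixel is an input pixel) and returns an
identical-frame stack bit-exactly.  Laplacian-pyramid blending would
hide seams better and is a possible extension; it was deliberately not
used because hard selection is testable to the bit.  Frames are assumed
aligned (a macro rail translates the camera rather than refocusing the
lens, so magnification change between frames is negligible at these
reproduction ratios).

## Silhouette extraction

Segmentation is chroma-key style: foreground = pixels whose RGB distance
(normalized to [0,1]) from the background model exceeds 0.12.  The
background model is a uniform key colour for synthetic captures or a
per-pixel empty-rig reference image for real ones.  A morphological
close (disk 3 px) bridges thin gaps, components under 16 px are dropped
as dust.  By default the largest component (plus whatever the close
merged into it) is retained; the pipeline instead keeps *all*
above-floor components (`keep_components="all"`), because specimen parts
— head, legs, the pin — can project as disjoint 2D blobs in side views,
and a single view whose mask omits a part is enough to carve that part
out of the hull entirely.  Masks are finally dilated by 1 px before
carving: silhouette errors must inflate, never truncate, the hull, since
carving is irreversible.  2D pin masking (`apply_exclusions`) forces
polygon interiors to background; the carved model then lacks the pin but
faces it occluded may pick up contaminated texture, which is why 3D mesh
editing is offered as the alternative.

## Carving

The grid default is 96³–128³ over a user-set box (resolution is bounded
by memory and the silhouette pixel footprint, not by the algorithm).
Sampling is one point per voxel (the centre); the 1 px mask dilation
supplies the conservatism that makes the superset property hold despite
nearest-pixel rounding.  8-corner sampling is available where a stricter
per-voxel guarantee is wanted (a voxel survives a view if *any* sample
lands inside the silhouette).  Unseen voxels (outside a view's frame or
behind its camera) are not carved by that view — the physical mat
occludes the underside, and carving on no evidence would destroy real
volume.  The octree variant certifies whole nodes from the pixel
bounding box of their 8 projected corners against an integral image of
the mask, padded ±1 px to cover centre-rounding, and falls back to the
exact per-voxel rule at leaves; its occupancy is therefore identical to
dense carving, which the tests assert bitwise.  Photo-consistency
(space-carving) refinement of concavities is deliberately out of scope:
on specimens with strong specular reflection and fine structures its
benefit is limited, and the visual hull alone is the method under test.

Meshing is marching cubes at iso 0.5 on the 0/1 occupancy field, zero-
padded by one voxel so occupancy touching the grid boundary still closes
to a watertight surface; vertex coordinates map lattice point *i* to the
centre of voxel *i* in mm.  Meshes are kept at marching-cubes resolution
(no decimation).

## Texturing

Per-face single-view assignment, no blending: visible seams are accepted
in exchange for texels that are traceable to one photograph.  Visibility
in a view is "the face owns at least one pixel of the rasterized face-id
buffer", with a centroid depth-buffer test (tolerance 2× median edge
length) as fallback for sub-pixel faces; the id-buffer criterion is
robust to the z-fighting that tiny marching-cubes facets exhibit when
several share one pixel.  Scoring uses neighbourhood-smoothed normals
(mean of trimesh vertex normals per face) because raw facet normals
alternate at the voxel scale and would favour views that graze the
underlying surface.  Ties break to the lower view id.  The atlas packs
one face per square cell as an axis-aligned right triangle (default
2048² atlas); each texel maps barycentrically to the surface and
bilinearly samples the assigned photograph, so every atlas texel is a
bilinear combination of source pixels from its one assigned view.
Faces visible in no view are flagged with magenta (255, 0, 255),
recorded in metadata.

## Pin removal (3D)

Component mode deletes every face-connected component except the largest
(ties to the component containing the lowest vertex index) — suited to a
pin that carves to its own component.  Cylinder mode deletes faces whose
centroids lie within a radius of an axis line, then keeps the largest
remainder — for pins fused to the body — and reports the hole as its
boundary-edge count (no hole filling is attempted).  Both warn rather
than fail when nothing matches.  Note that component mode removes *all*
secondary components; on the stock synthetic weevil, whose head and legs
are deliberately disjoint primitives, it removes those too — on a real
specimen the body is one connected component.

## Synthetic rig

The renderer ray-casts sphere/ellipsoid/cylinder/box scenes with flat
shading — no lighting, shadows, speculars or transparency — so mattes,
depths and colours are analytic ground truth.  Defocus is simulated as a
Gaussian blur with sigma = `blur_gain`·|depth − focal plane| px
(a linear circle-of-confusion model), applied per depth bin (16 uniform
bins by default) rather than per pixel: orders of magnitude faster, with
error bounded by the bin width.  Background pixels carry no depth and
are treated as in-focus; a uniform backdrop blurs to itself, so this is
exact for the chroma-key scenes used.  All randomness is caller-seeded;
renders are bit-deterministic.

The stock "weevil" test specimen matches the smallest specimens such
rigs target: 3 mm ellipsoid body + 0.5 mm-radius head + six 0.09 mm
cylinder legs + a 0.2 mm-diameter pin, with small gaps between parts so
all primitives are disjoint and the closed-form scene volume
(≈ 5.30 mm³) is a valid oracle; a `pin_attached` variant fuses the pin
into the body for cylinder-mode removal tests (and is correctly rejected
by the volume oracle as overlapping).  What the generator does *not*
emulate — lighting variation, specular cuticle, translucent wings, setae
and antennae below voxel scale, sensor noise, calibration error — bounds
what passing tests show: they validate the geometry/texture machinery,
not robustness to real photographic nuisance factors.

## Problem sizes and defaults

The default pipeline rig is 600² images at ~100 px/mm on the specimen, a
desk-scale stand-in for the 18-megapixel frames of the physical rig;
at this scale the 1 px conservative dilation costs a few percent of
volume on a 3 mm specimen (it is the dominant, one-sided term in the
hull volume error; thin legs inflate relatively most).  Tests and the
acceptance script use 240–320² images, 32–128³ grids and 18–72 views —
sizes chosen so each property is exercised at meaningful scale while a
full run stays in minutes on one CPU.  Determinism: a pipeline run is a
pure function of (config, seed); the manifest records both plus
per-stage counts, and re-running a config reproduces the exported
geometry byte-for-byte.

## Known limitations

* Concavities are unrecoverable in principle (visual hull).
* Structures thinner than both a voxel and the silhouette's pixel
  footprint (fine setae, antennae tips) vanish or inflate.
* Single-view texturing shows seams at view-assignment boundaries.
* The fiducial decoder assumes reasonably colour-faithful rendering or
  printing; heavy white-balance error would break id decoding before
  detection fails.
* PLY/STL export stores float32 coordinates (≈ 1e-6 relative), fine at
  specimen scale but below OBJ's text precision.
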