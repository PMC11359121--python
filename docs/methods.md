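# Methods

This note documents the models, defaults and numerical choices behind the
`herdscan` pipeline, and what the synthetic validation experiments do and
do not demonstrate.

## Geometry conventions

Pixel `(u, v)` refers to the pixel centre; the image origin is top-left,
the camera looks down +z with x right and y down.  Depth maps store
**z-depth** (projection of the surface point onto the optical axis), not
ray range, so the pinhole backprojection `x=(u−c_x)z/f_x, y=(v−c_y)z/f_y,
z=d` inverts rendering exactly.  Depth on disk is 16-bit PNG millimetres
with 0 = invalid (quantization ≤ 0.5 mm); in memory it is float64 metres
with non-positive/NaN marking invalid pixels.  Rigid poses are 4×4
homogeneous matrices with the rotation block orthonormal to 1e-9.

## Scene simulator

Scenes are unions of posed, textured primitives (box, cylinder, sphere)
plus an optional infinite ground plane.  Depth is the nearest positive
analytic ray intersection per pixel; colour is unlit procedural albedo
(3-D checker, or multi-octave value noise hashed from the scene seed)
evaluated at the local-frame hit point, so texture is exactly consistent
across viewpoints — the property the photometric ICP term relies on.

The noise model mimics a ToF sensor at three levels, all reproducible from
a seed:

* **Gaussian depth noise** — per-pixel, default σ = 3 mm (typical of ToF
  depth repeatability at ~2 m range).
* **Flying pixels** — at pixels where an opposite-neighbour second
  difference of depth exceeds 0.1 m (a true edge, as opposed to a smooth
  steep ramp), a Bernoulli(rate) subset is replaced by a uniform draw
  between the nearest and farthest neighbouring depth — the mixed-pixel
  signature.  Default rate 0.2.
* **Interference dropout** — a Bernoulli fraction of valid pixels is
  invalidated, emulating unsynchronized multi-camera capture.  Default 0
  (synchronized); the pipeline logs per-camera point counts so the dropout
  effect is observable when enabled.

The default study rig is a ring of 10 cameras at radius 1.9 m with
**alternating elevations ±0.55 m**, all aimed at the rig centre, 320×240
images with f = 260 px.  Alternating elevations play the role of the top
and bottom camera placements of a physical frame: with all cameras above
the target, the underside is never observed and the reconstruction closes
it with an inward bulge (about −6% volume on a 0.5 m cube).  The image
size gives a surface sampling pitch of ~7 mm at the target, which sets
several defaults below.  Initial camera poses handed to registration are
the true extrinsics perturbed by exactly 2° / 2 cm (random axis and
direction), standing in for fiducial-based calibration error.

The validation objects are a cylinder of radius 0.088 m and length
1.233 m — closed-form surface area 2πr(r+h) ≈ 0.730 m², volume
πr²h ≈ 0.030 m³ — and cubes of side 0.3 / 0.4 / 0.5 m (the 0.5 m cube:
1.5 m², 0.125 m³).  Validation scenes suspend the object at the rig
centre with the ground plane off: the low cameras must see the underside
unobstructed, and an infinite ground sweeps every z-depth from their
viewpoint so no depth band could separate it per view.  Scenes exercising
segmentation and the flying-pixel filter use the ground plane and clutter
bars with upper cameras only.

## Flying-pixel filter

A valid pixel survives iff at least `min_support` (default 0.5) of its
valid 8-neighbours lie within a depth tolerance of it; surviving depths are
never modified, and a valid pixel with no valid neighbour is removed.  The
tolerance is `0.029 m + 0.025·d`: the absolute part covers noise
(3σ + 2 cm), the depth-proportional part covers the legitimate per-pixel
depth step of obliquely viewed surfaces (the pixel footprint grows with
depth; at ~10° grazing incidence the step reaches 5–7 cm at 2 m).  Without
the proportional term the filter deletes entire grazing-incidence faces.
Filtering is strictly removal — no smoothing of kept depths.  Applying the
filter twice can only shrink the kept set (neighbour removal can orphan
further pixels), which is asserted as a property test.

## Segmentation

The deployment design assumes learned per-modality segmenters; the package
defines the mask-provider contract (any callable `frame → Mask`, registered
per modality) and ships a deterministic geometric stand-in: the largest
8-connected component of valid depth inside a configured depth band,
rejected if smaller than `min_component_px`.  Fusion modes are RGB-only,
depth-only, OR, AND.  Scoring reports IOU, and FP/FN percentages with FP
referenced to ground-truth-negative pixels and FN to ground-truth-positive
pixels; the denominators are isolated in one place because other
conventions exist.  Under these definitions OR-fusion can only lower the
false-negative rate and AND-fusion the false-positive rate relative to
either modality — a theorem on the definitions, asserted over random mask
pairs.

## Registration

Pairwise colored ICP minimizes `E(T) = (1−δ)E_C + δE_G` with δ = 0.968 on
the geometric term, following the original colored-ICP formulation.  The
photometric residual uses grayscale intensity (RGB mean) and the target
point's tangent-plane linearization `C_p(x) = I(p) + g_p·(x−p)`; the
gradients `g_p` are least-squares fits over k=16 neighbours projected onto
the tangent plane, with the normal component pinned by penalty (so
`g_p·n_p = 0` and the tangent-plane projection in the residual is
absorbed).  Minimization is Gauss–Newton on a left-multiplied se(3)
parametrization with exact Rodrigues rotation per step; steps are halved
(up to 8 times) until the objective on the current correspondence set does
not increase, which makes the per-iteration objective provably
non-increasing.  Correspondences are source→target nearest neighbours
gated by a per-scale distance, with two rejections: pairs beyond the gate,
and pairs whose normals disagree by more than 60° — the latter is
essential with partially overlapping views, where top surfaces otherwise
latch onto bottom surfaces.  Fewer than 6 correspondences raises.

The scale schedule is coarse-to-fine voxel pyramids of 0.04 / 0.02 / 0.01 /
0.005 m (50/30/30/30 iterations, gate = 3× voxel).  The finest scale is
deliberately at the sensor sampling pitch: on surfaces with a continuous
symmetry (a cylinder's azimuth) only texture pins the free mode, and
stopping at 0.01 m leaves a ~2° tangential slide (a fine-scale local
minimum) that chains into a few-millimetre surface inflation after
merging.  Colour gradients are re-estimated per scale on the downsampled
target.

Pairs are adjacent cameras in rig order, arranged as a two-armed tree
rooted at camera 1 (1–2–3–… and 1–10–9–…), which halves the chain length
relative to a single chain; camera 1's frame is the world frame and chains
are composed exactly.  Cycles are rejected, not averaged — no pose-graph
relaxation.  Merging transforms every per-view cloud (normals rotated),
concatenates, and consolidates with a 5 mm voxel-centroid downsample.

## Cleanup

DBSCAN (full core/border/noise semantics; sklearn's implementation with
index-ordered expansion) labels the merged cloud and only the largest
cluster survives.  Defaults: eps = 5× merge voxel = 25 mm, min_pts = 10.
The eps multiple is chosen above the worst-case sampling anisotropy of the
rig: grazing-incidence faces backproject as rows up to ~60 mm apart from a
single view but interleave across views; at 2.5× the merge voxel those
faces disconnect and the largest-cluster rule would delete them.  Border
points reachable from two clusters go to the first-expanded cluster
(ascending index), so the labelling is deterministic for a given point
order; the largest-cluster point set is permutation invariant.

## Poisson reconstruction and traits

The implicit function is computed on a regular `resolution³` node lattice
(default 128) over the cloud's bounding box padded 10% per side — a
deliberate simplification of the classical octree formulation, adequate
for desk-scale targets.  Oriented normals are splatted trilinearly into a
vector field V; V and a parallel scalar density field are smoothed with a
Gaussian of physical width 5 mm (the splat kernel, resolution
independent); V is divided by the density where the density exceeds 5% of
its mean at the samples (unit-magnitude transition regardless of local
sampling density — otherwise sparsely seen patches are cut at an offset
iso position); the divergence is taken by central differences; and
`ΔX = ∇·V` is solved with zero-Dirichlet boundaries by a type-I discrete
sine transform, which diagonalizes the 7-point Laplacian exactly (verified
against a manufactured solution to 1e-6 RMS).  The isosurface at the mean
of X sampled at the input points is extracted by marching cubes, welded,
cleared of degenerate faces, and oriented so the enclosed volume is
positive.  An open result raises with the boundary-edge count rather than
returning silently wrong traits.

Surface area is the triangle-area sum; volume is the divergence-theorem
sum `|Σ a·(b×c)|/6`, which requires watertightness (checked: every
undirected edge on exactly two faces, all directed edges unique) and is
invariant under rigid motion to 1e-9 relative.

## Validation experiments and their scope

* **Pose sweep** — 8 uniformly random orientations/translations of the
  cylinder, full pipeline under default noise: mean surface area within
  3% of 0.730 m², mean volume within 3% of 0.030 m³, pose-wise coefficient
  of variation ≤ 2%.  (Measured: ≈ −0.3% SA, +1% V, CV ≈ 0.1–0.3%.)
* **Cube recovery** — 0.5 m cube, one scan: within 3% of 1.5 m² /
  0.125 m³.
* **Multi-object regression** — cylinder + three cubes, 10 noisy scans
  each, per-object means regressed on analytic values; the acceptance
  script reports R² for surface area and volume.  A 3-repetition smoke
  version must reach R² ≥ 0.99.

Problem sizes (320×240 frames, 10 cameras, 128³ grid, ≈ 5–7 s per scan)
are the package defaults and were chosen as the smallest configuration
that resolves the validation objects' surfaces at the rig distance.

What passing these experiments shows: the geometry chain — filtering,
backprojection, registration from perturbed initials, meshing, trait
integration — is unbiased to a few percent under Gaussian + mixed-pixel
noise and miscalibrated initial poses.  What it does not show: performance
on real animals (articulated, moving, specular hide), real ToF physics
(multipath, intensity-dependent noise), or learned-segmenter quality; the
live-animal segmentation metrics of the original deployment require a
trained network and hand-labelled data and are out of scope here.

## Known limitations

* The regular-grid Poisson solver holds the full `resolution³` lattice in
  memory (~16 MB at 128³ per field component); very elongated objects get
  anisotropic node spacing rather than octree adaptivity.
* Edge rounding from normal smoothing and the splat kernel biases surface
  area low by 1–4% on sharp-edged objects, growing as the object shrinks
  relative to the sampling pitch; volumes are much less affected.
* On texture-symmetric surfaces the azimuthal degree of freedom is pinned
  only photometrically and can retain a few tenths of a degree of error.
* The pairwise chain accumulates drift; without loop closure the two arms
  can disagree where they meet at the back of the ring.  At the default
  noise and perturbation levels the disagreement is sub-millimetre.
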