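# Methods

## Pipeline model

Each endoscopic frame is segmented into background / tool / catheter; the
catheter silhouette then determines four overlay parameters. The underlying
assumptions are those of the clinical setting: the catheter is a rigid,
near-vertical, elongated cylinder whose apex (upper tip) is visible; its
real-world diameter is known; in-plane rotation (`rotZ`) is moderate;
rotation about the vertical axis (`rotY`) is negligible and fixed to 0.

**Anchor.** The overlay apex is pinned at the central point of the upper
edge of the catheter's bounding geometry. Two conventions are implemented:

- `anchor_mode="hull"` (default): the midpoint of the *upper edge of the
  convex hull* of the main contour — the maximal chain of hull edges
  inclined less than `hull_edge_max_deg` (default 45°) from horizontal that
  contains the topmost hull vertex. For a tilted elongated silhouette this
  edge is the physical tip cap, so the anchor stays attached to the tip for
  any in-plane rotation, and the scale (upper-edge extent / diameter) stays
  tilt-invariant.
- `anchor_mode="bbox"`: the midpoint of the top edge of the axis-aligned
  bounding box. This is the more literal reading of "bounding box", but for
  a rigid silhouette tilted by rotZ the box's x-centre approaches the
  silhouette's overall x-centre: the anchor drifts from the tip by roughly
  `L·sin(rotZ)/2` and, because the centroid's x also sits near that centre,
  the anchor→centroid angle collapses toward 0. The bbox variant is
  therefore only equivalent for upright catheters; the hull variant is the
  default because it is the convention under which the measurement model is
  self-consistent.

**rotZ** is the angle of the anchor→centroid vector, `atan2(cx − p1,
cy − p2)` in degrees — 0° when the centroid is straight below the anchor,
positive rightward, range (−180°, 180°]. For any silhouette symmetric about
its axis the centroid lies on the axis, so with the hull anchor the angle
equals the geometric tilt exactly (up to rasterization).

**rotX** (toward/away from camera) uses the area-asymmetry cue: split the
region at the centroid row, `s = (A_lower − A_upper)/(A_lower + A_upper)`
(pixels exactly on the row count half to each side), and report
`rotX = rotx_gain · s`. A cylinder tipped toward the camera presents a
nearer, wider lower end, so `s > 0` ⇔ toward the camera. No principled
mapping from `s` to degrees exists without camera calibration, so the gain
(default 60°/unit) is an explicit linear convention: *only the sign and the
monotonicity of rotX are calibrated claims; its magnitude is not.* The
recovery study asserts sign accuracy and monotonicity only.

**Scale** is apparent width / `catheter_diameter_mm` (default 6.0 mm, an
18 Fr urinary catheter), in px/mm: the hull upper-edge extent (+1 px for
inclusive width) in hull mode, the bbox width `xmax − xmin + 1` in bbox
mode.

**Numerical exactness.** The centroid-relative quantities are computed from
exact integer pixel sums (`n·y ≶ Σy` instead of `y ≶ Σy/n`; the atan2
numerators are `2Σx − n·2p1`, with `2p1` integral for both anchor
conventions). Consequently integer translation shifts `(p1, p2)` exactly
and leaves rotZ/rotX/scale bit-identical, and a horizontal mirror negates
rotZ bit-exactly while preserving rotX and scale. Tie-breaks: the main
contour is the largest-area region, ties resolved by scan order of the
topmost-then-leftmost start pixel; degenerate inputs (area below
`min_region_px`, default 50 px, or centroid coincident with the anchor)
yield `valid=False` rather than an exception.

## Contours and hull

Foreground is 8-connected, background 4-connected (the standard pairing
that avoids topological paradoxes). Outer boundaries are traced with
Moore-neighbour border following, terminating when the trace re-enters the
start pixel and is about to repeat its initial transition; enclosed
background pockets produce hole-border chains (the *region* pixels around
the pocket). The reconstruction identity — filling outer chains and carving
hole interiors reproduces the region pixel-exactly — is tested on random
blob masks and is the module's correctness oracle.

The convex hull uses Andrew's monotone chain rather than Sklansky's
polygon scan: Sklansky's algorithm is known to be incorrect for some simple
polygons, and the contract (hull of the contour point set) is unchanged.
Output is counter-clockwise as seen on screen (y down) with collinear
points excluded.

## Rotation-error metric

Poses are compared by composing `q = qZ(rotZ) ⊗ qX(rotX)` (X applied first
in the fixed frame; the composition order is a convention — any fixed order
yields a valid error metric) and measuring the relative rotation
`Q = q2⁻¹ ⊗ q1`. The reported distance is the geodesic arc length
`2·atan2(‖(Qx,Qy,Qz)‖, |Qw|)` ∈ [0, π] radians, which agrees with the
rotation-matrix angle `arccos((tr R − 1)/2)` to ~1e−12 and is symmetric and
left-invariant. The naive "L2 norm of Q" formula is provably the constant 1
on unit quaternions; it is kept as `variant="paper_literal"` purely so the
degeneracy is inspectable.

Mean IoU averages per-class IoU over the classes whose union is nonempty;
a class absent from both masks is excluded (scoring it 1.0 would reward
trivially empty predictions). Aggregate tables report mean and population
standard deviation (σ); a `sample_sigma` flag switches to the sample
estimator.

## Synthetic scenes

The generator's job is to make every downstream claim testable with exact
ground truth, not to be photorealistic. The catheter is an isosceles
trapezoid: apex edge (width `diameter_px`) centred at the anchor, axis
tilted rotZ from vertical, projected length `length_px·cos(rotX)`, base
width `diameter_px·(1 + β·sin(rotX))` with weak-perspective taper β = 0.35.
Because the trapezoid is symmetric about its axis, the anchor→centroid
angle is exactly rotZ and the taper makes the area-asymmetry cue
informative (continuous asymmetry `s ≈ β·sin(rotX)/12`). Appearance —
smooth reddish tissue texture, pale shaded catheter, grey metallic tool
quadrilaterals entering from frame edges — is driven by `params.seed`;
tool *layout* (which changes the mask) has its own `layout_seed`, so
"different seed" means identical mask with different texture. Failure
modes: `highlight` saturates an elliptical patch to near-white (image only;
confusable with the pale catheter), `blood` paints dark red over the lowest
`coverage` (default 30%) of catheter pixels and relabels them background in
the *observed* mask while the clean mask remains ground truth.

Dataset sampling draws parameters uniformly: rotZ ∈ [−30°, 30°],
rotX ∈ [−40°, 40°], diameter 0.10–0.15 and length 0.55–0.75 of the smaller
frame side, with the anchor window tightened per-draw so the whole
silhouette stays in frame (clipping would corrupt the ground-truth
centroid). These ranges match the intended deployment: a near-vertical
catheter occupying a substantial fraction of a 416×608 frame.

What the generator does **not** emulate: real tissue appearance and motion
blur, camera intrinsics/distortion, perspective beyond the linear taper,
catheter curvature, specular reflections other than the stylized highlight,
and annotation noise. Passing tests therefore validate the geometry and
learning machinery, not clinical performance on surgical video.

## Study sizes and defaults

- **Pose recovery**: 500 clean scenes at the reference 416×608 resolution
  (catheter ≈ 42–62 px wide). At that scale rasterization jitter in `s`
  (~1e−3) sits an order of magnitude below the 10°-taper signal
  (`s ≈ 0.005`), so sign accuracy for |rotX| ≥ 10° is a fair claim; at
  96×96 the same claim would be noise-limited. The monotonicity sweep uses
  an even larger raster (≈1500×830, 10° steps) for the same reason.
- **Desk-scale end-to-end**: 64 training / 16 test scenes at 96×96,
  trained with the reference recipe — batch 4, Adam (lr 0.001, β₁ 0.9,
  β₂ 0.999), categorical cross-entropy, 20 epochs, seeded shuffling. The
  network is a one-conv-per-stage U-Net (base 16 channels, depth 3,
  ≈1.1×10⁵ parameters, bottleneck 12×12 for 96×96 input), float32 im2col
  GEMM convolutions; training runs in ~2 minutes on one CPU. This exercises
  the full train→segment→pose chain; it is an analogue of the original
  training protocol at desk scale, not a reproduction of its published
  IoUs, which depend on private surgical videos.
- **Degradation study**: 50 scenes; blood occlusion is evaluated on
  observed masks (sign accuracy of rotX for |rotX| ≥ 10°), highlight on
  predicted-mask catheter IoU.

## Known limitations

- The rotX magnitude is uncalibrated by design (see above); only its sign
  and ordering carry meaning.
- The hull upper-edge detector assumes the tip cap is the most horizontal
  boundary section; it would mis-select for |rotZ| approaching
  `hull_edge_max_deg`.
- Hole borders are extracted and used in reconstruction tests but not in
  pose estimation (real catheter silhouettes are simply connected).
- The segmentation net has no augmentation and a deliberately small
  capacity; it memorizes the synthetic appearance distribution and is not
  transferable to real frames.
- Throughput numbers are machine-dependent; only the measurement machinery
  (n iterations / wall-clock seconds, threshold flag at 10 it/s) is part of
  the contract.
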