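# Methods

This note documents the segmentation model implemented by `pelviseg`, the
reasoning behind its numerical choices and defaults, what the synthetic
phantom does and does not emulate, and the known limitations.

## The segmentation pipeline

`pelviseg` segments bone in pelvic CT volumes with a five-stage classical
pipeline. The target definition of "bone" is marrow-inclusive: enclosed
cavities inside the cortical shell are labelled as bone interior (code 2),
because downstream material decomposition assigns them marrow composition.
Compact bone keeps its own code (1); a `--binary` flag collapses the two.

1. **Histogram matching + table removal.** The volume's intensity
   distribution is mapped onto a stored reference by classical monotone
   CDF/quantile matching (1-HU bins over [−1024, 3072) HU, piecewise-linear
   inverse CDF). Matching is estimated from body voxels only (above the air
   threshold, default −500 HU) but applied to every voxel; both CDFs are
   anchored at (−1024 HU, 0) so air maps near air rather than collapsing
   onto the body minimum. This removes global intensity differences between
   scanners/tube voltages so that fixed HU thresholds are meaningful. The
   patient table is removed by keeping the largest 26-connected component
   of above-air voxels after one morphological closing pass (ball, radius
   2 voxels) that bridges thin skin gaps; everything else is set to
   −1000 HU. The component is chosen as the one containing the most
   above-air voxels, so the largest raw component is never discarded.
2. **Dual-threshold segmentation.** `bone_mask = {v ≥ t_bone}` captures
   most of the compact bone; `seed_mask = {v ≥ t_seed}` (with
   `t_seed > t_bone`) captures high-confidence seed regions.
3. **Seeded 3D region growing, 26-connectivity.** A voxel joins the region
   iff (a) its intensity strictly exceeds the mean of its n×n×n box
   neighbourhood (n = 9 by default) — the *local-maximum* criterion — and
   (b) its intensity lies in the acceptance range `[accept_low,
   accept_high]` (open above by default). Both criteria are precomputed
   before growth, which makes growing a pure reachability problem on the
   admissible voxel graph: the result is provably independent of growth
   order, and the implementation reduces to connected-component labelling.
4. **Combination.** Voxelwise union of the threshold and region-growing
   masks.
5. **Merging + 3D hole filling.** Bone parts closer than roughly twice the
   merge radius are merged by morphological closing with a spacing-aware
   ellipsoidal structuring element of physical radius `merge_radius_mm`
   (identical behaviour on anisotropic grids). Then every background voxel
   that cannot reach the volume border through a 6-connected background
   path is labelled interior/marrow. Using 6-connectivity for background —
   the complement-dual of the 26-connected foreground — prevents filling
   from leaking diagonally through the shell. Filling is global, not
   per-component. A slice-wise 2D fill (4-connected, per axial slice) is
   kept solely as a baseline to demonstrate why 3D filling is needed.

## Parameter defaults and the half-maximum rule

All parameters live in `PipelineParams` and can be set from YAML or CLI
flags (flag > config file > default).

| parameter         | default | unit | meaning |
|-------------------|--------:|------|---------|
| `t_bone`          |     600 | HU   | lower threshold, compact bone |
| `t_seed`          |     900 | HU   | seed threshold (> `t_bone`) |
| `box_n`           |       9 | vox  | box-filter side, local-max criterion |
| `accept_low`      |     450 | HU   | lower edge of growing acceptance |
| `accept_high`     |      +∞ | HU   | upper edge (dense bone never excluded) |
| `merge_radius_mm` |     3.0 | mm   | bone-part merging radius |
| `air_threshold`   |    −500 | HU   | body/air split for matching & table removal |

The HU defaults follow a *partial-volume half-maximum* argument. Under the
scanner's point-spread blur, the iso-contour that estimates a tissue
interface without bias lies at the midpoint of the two tissue intensities.
With nominal cortical bone around 1200 HU against soft tissue around
0–50 HU, that midpoint is ≈600 HU, which is `t_bone`. Thresholds far below
the midpoint (e.g. the 150–300 HU values often quoted for trabecular bone
on sharp reconstructions) displace the segmented surface outward by close
to a millimetre at typical blur, and the integrated halo over the whole
pelvic surface costs several Dice points. Seeds sit at 900 HU, well inside
compact bone. `accept_low` = 450 HU is the half-maximum for
reduced-density cortical bone (~900 HU): region growing is the stage meant
to recover weak-boundary bone that the main threshold misses, so its
acceptance reaches deliberately below `t_bone`, at the price of a small
outward bias where boundaries are smooth (see Limitations).

`merge_radius_mm` = 3.0 bridges cortical perforations (foramina, ~1–2 mm)
without routinely bridging a healthy hip-joint space; closing can merge
parts separated by a little under twice the radius, so gaps below ~6 mm
are at risk — which is precisely the documented hip-bridging failure mode,
reproducible with the `kissing_joint` phantom.

## Numerical choices

- **Box-filter boundary rule.** Near the volume border the neighbourhood
  mean is taken over the intersection of the box with the volume
  (shrinking window). Zero-padding would depress border means and create
  spurious local maxima. The filter is computed with exact cumulative-sum
  arithmetic and the comparison is evaluated as `v·count > sum`, so the
  strict inequality ("ties are not maxima") is exact for integer-valued HU
  data; a constant volume yields an empty mask, and the mask is invariant
  under adding a constant to all intensities.
- **Degenerate matching inputs.** A constant body maps entirely to the
  reference value at quantile 0.5, with a warning. An all-air volume is
  returned unchanged (there is no body distribution to estimate), so that
  table removal can fail with its proper "empty body" error.
- **Closing at the border.** Masks are padded with background before
  closing so the outside of the volume behaves as open space; closing is
  then genuinely extensive and never removes foreground.
- **Determinism.** No stage draws random numbers; identical inputs give
  bit-identical label volumes.
- **Geometry.** Internal axis order is (x, y, z); all readers convert into
  it and all stages preserve spacing/origin/direction untouched.
  Non-axis-aligned orientation matrices are stored and round-tripped but
  never resampled.

## The synthetic phantom

Patient CT data cannot ship with the package, so every stage is exercised
on a synthetic pelvic phantom with exact ground truth (`PhantomSpec`,
`generate_phantom`). The phantom emulates the features that make pelvic
bone segmentation hard: high-intensity cortical shells around
lower-intensity marrow; cortical perforations (foramina) that defeat naive
hole filling; a femoral head sitting `joint_gap_mm` from an acetabular
cup; a detached patient table; Gaussian partial-volume blur; additive
Gaussian noise.

Default intensities and corruption: body 0 HU, muscle 50 HU, cortical
1200 HU, marrow 150 HU, table −300 HU, cortical thickness 2 mm, blur
σ = 0.8 mm, noise 15 HU, 96³ voxels at 1 mm isotropic — representative CT
tissue values in the clinical voxel-size regime. The geometry (body
ellipsoid, sphere-plus-shaft femurs, a torus arch carrying two eccentric
cup shells) scales with the volume extent so presets also generate at
64³; absolute quantities (thicknesses, gaps, blur) stay in mm. The cup is
deliberately eccentric: the head–cup gap equals `joint_gap_mm` at the cup
rim and widens toward the pole, so a narrow gap lets closing seal the rim
while an enclosed pocket of joint space remains — reproducing the
real-world failure where the sealed joint space is then mislabelled as
marrow. The default gap is 8 mm, safely above twice the default merge
radius so the default phantom's joints stay open.

Ground truth (1 = cortical, 2 = marrow) is computed from the pre-blur,
pre-noise geometry: Dice against it measures the algorithm, not the
corruption. Two independent RNG streams derive from the single seed — one
for geometry (foramina placement), one for noise — so the truth is
invariant to the noise draw.

What the phantom does **not** emulate: real anatomy (sacrum, coccyx,
lumbar spine, realistic bone shapes), heterogeneous trabecular texture,
beam hardening, scatter, metal or contrast agent, and inter-patient
variability in tissue fractions. Passing phantom tests therefore shows the
pipeline's operators behave as specified and that recovery works under
controlled blur/noise; it does not certify clinical accuracy.

Presets: `default`; `osteoporosis` (cortical intensity ×0.5, the
low-contrast case); `kissing_joint` (1 mm joint gap, the bridging
fixture); `perforated` (8 foramina); `canal` (an axially open tube that a
2D slice-wise fill wrongly fills and a 3D fill correctly leaves open).

## Evaluation

Dice = 2|A∩B| / (|A|+|B|), computed by default on pooled labels {1, 2}
(bone versus background, matching the marrow-inclusive bone definition);
restriction to single labels is available. Two empty segmentations give
Dice 1.0 with a warning (agreement on absence), avoiding 0/0. Summaries
report mean/min/max and a fixed-range histogram over [0, 1].

## Known limitations

- **Outward boundary bias from region growing.** The local-maximum
  criterion admits the upper half of any smooth blurred boundary, so with
  `accept_low` below `t_bone` the grown region extends a fraction of a
  millimetre beyond the half-maximum surface. On the default phantom this
  is the dominant residual error (final Dice ≈ 0.93 instead of the ≈ 0.98
  achievable with `accept_low = t_bone`, which would, however, make the
  growing stage vacuous).
- **Degradation is not monotone in the mild regime.** Because the residual
  error is bias-dominated, mild corruption (moderate extra noise, moderate
  cortical-intensity reduction) acts as dither that randomly removes halo
  voxels and can *raise* Dice by ~0.01; degradation becomes monotone only
  under strong corruption (noise ≳ 80 HU, cortical scaling ≲ 0.25).
  Relatedly, quantile matching against a reference with identical tissue
  fractions almost exactly inverts a global cortical-intensity scaling, so
  the pipeline is by construction insensitive to the phantom's
  osteoporosis model; real osteoporosis is not a global monotone intensity
  transform and does degrade threshold-based pipelines.
- **Joint bridging under partial volume.** End-to-end, a 1 mm joint gap is
  not only sealed at the rim but filled solid by closing (the blur halo
  narrows it further), so the bridged joint space is labelled compact bone
  rather than marrow; on exact geometry (ground-truth masks) the
  merge-then-fill behaviour labels it marrow, as documented.
- **Thin or faint cortex.** Where the shell is thinner than the blur
  kernel or its intensity falls below `accept_low`, the shell breaks and
  enclosed interiors leak; merging repairs gaps only up to ~2× the merge
  radius. This is the classical failure of intensity-based bone
  segmentation and the reason learning-based methods overtake it.
- No resampling or reorientation; anisotropic voxels are handled by
  physical-distance morphology only. DECT mixing, bias-field correction
  and multi-bone labelling are out of scope.
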