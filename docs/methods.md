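# Methods

This note documents the models and numerical choices behind soypod: what
the synthetic generators emulate, how the counting pipeline works, which
parameters matter, and where the design was genuinely open.

## Scene synthesis under occlusion control

**Model.** A scene is an ordered stack of pod instances on a canvas.
Placement order defines the z-order; a pod is occluded only by pods
placed later (on top). For pod *j*, the occluded region is the union of
its intersections with higher-z amodal masks; the occlusion ratio δⱼ is
that area divided by the amodal area; the visible mask is the amodal
mask minus the same union. A tentative placement (uniform rotation in
[0°, 360°), uniform in-canvas translation) is accepted only if every
already-placed pod would keep δⱼ ≤ α. The newly placed pod sits on top
and is itself unoccluded at the moment of placement.

This z-ordered reading is a deliberate choice over a symmetric one (both
overlapping pods losing the shared pixels): symmetric subtraction would
delete the overlap from every mask, so the visible masks would no longer
tile the rendered foreground. With z-order, three invariants hold by
construction and are asserted in tests: δⱼ ≤ α for all pods, visible
masks are pairwise disjoint, and their union equals the union of the
amodal masks.

**Parameters.** α ∈ {0.1, 0.3, 0.5} are the standard operating points;
the attempt budget is 100 resamples per pod (a pod that cannot be placed
is skipped and logged — rejection is a normal outcome, not an error);
the default pod count per image is drawn uniformly from [5, 15].
Determinism comes from one seed per scene; dataset commands derive
per-image streams as `seed + image_index` so parallel generation would
not change results.

**On-branch variant.** The branch silhouette's vertical extent
[h_min, h_max] is split into 7 even bands; band lines get a vertical
jitter of ±0.15 band heights (the jitter magnitude and the 3 candidate
x-positions per line are package choices; only "small jitter" is
inherent to the model). Pods attach by their tip vertex: the minimum-area
rotated rectangle is split into four equal strips along the long axis,
the terminal strip with the smaller mask overlap is the tip side (ties
resolve to the low-x end), and the tip is the centroid of boundary
points within 1 px of that strip's outer edge. The pod is rotated so the
tip-to-centroid axis points within ±60° of straight down (pods hang),
translated so the tip lands on a growth point consumed without
replacement, and then submitted to the same α acceptance. The branch is
rendered below all pods and deliberately does not occlude them: the
occlusion model is pod-vs-pod, and in the imaging setup pods hang in
front of the stem.

## The counting pipeline

All stage parameters live in `PipelineConfig`; defaults are the
operating point of the method: κ = 0.4, ρ = 0.8, τ_abs = 0.15, density
weights (0.45, 0.40, 0.15), η = 1.0, λ₁ = 0.8, λ₂ = 0.6, e_max = 0.98.

1. **Pose normalization.** Components smaller than
   max(20 px², 0.5 % of the foreground) are removed, the largest
   component is kept, and the mask is rotated so the long side of its
   minimum-area rectangle is horizontal (one corrective pass if
   discretization leaves it > 1° off), then cropped.
2. **Axial width.** w(x) = 2 · column maximum of the Euclidean distance
   transform; w̄ = median of nonzero w; standard radius r = κ·w̄. Note
   that for a single convex lobe this profile is tent-shaped (the column
   maximum of the distance field decays linearly from the lobe centre),
   so w̄ sits near *half* the true lobe width — see the area-gate choice
   below.
3. **Fused density.** N_D is the min–max-normalized distance field
   (normalization always within the mask); N_M is the pixelwise maximum
   of the distance field smoothed at σ ∈ {0.5r, 0.75r, 1.0r} — tying the
   scale set to r makes the operator size-adaptive; N_E is one minus the
   normalized Sobel gradient magnitude of the σ=1-smoothed mask. The
   fusion F = 0.45·N_D + 0.40·N_M + 0.15·N_E is clipped to [0, 1] and
   zeroed outside the mask. Because the components are normalized, the
   absolute floor τ_abs = 0.15 is meaningful.
4. **Peaks.** A candidate must be the strongest response within a disk
   of radius d_min = ρ·r and exceed τ_abs. Plateaus of equal response
   yield one candidate each (lexicographic (y, x) representative), and
   the set is greedily thinned in descending response so pairwise
   distances stay ≥ d_min. A pure greedy sweep without the local-maximum
   test would tile every above-floor ridge with candidates at d_min
   spacing; the local-maximum condition is what makes candidates
   seed-like.
5. **Watershed.** Candidates are foreground markers; the background
   marker is everything outside the mask plus a 2-px inner boundary
   band (the high-gradient rim). Flooding runs on −F, so basins grow
   from density peaks; the mask gradient supplies background markers
   only. Each candidate seeds exactly one region.
6. **Morphology gate.** Regions survive if their area lies in
   [π(0.5r)², π(3r)²] and their moment-based eccentricity is ≤ 0.98.
   The upper gate is 3r rather than 2r: with the tent-shaped width
   profile of step 2, r underestimates the seed radius by roughly a
   factor of two for single-seed pods, and a 2r gate would reject the
   (correct) whole-pod region of every 1-seed pod. Rejected regions are
   kept with reason tags for inspection.
7. **DP refinement.** Candidates are sorted by x. The expected spacing
   is δ̄ = η · mean of w at the candidate columns. A candidate's score is
   sᵢ − λ₁·((δᵢ−δ̄)/δ̄)² − λ₂·oᵢ, where δᵢ is the gap to its *selected*
   predecessor (no spacing penalty for the first of a chain — skipping a
   candidate must update the spacing), and oᵢ is the largest fractional
   overlap of the candidate's radius-r disk with any other candidate's
   disk (watershed regions are disjoint by construction, so disk overlap
   operationalizes "crowding"). The spacing penalty is normalized by δ̄²
   so λ₁ acts on a dimensionless quantity — raw squared pixels would
   dwarf sᵢ ∈ [0, 1]. The recursion cost[i] = max(startᵢ, maxⱼ<ᵢ cost[j]
   + Sᵢ(j)) with backtracking yields the optimal ordered subset
   (selected x strictly increasing); its size is the main count. The
   implementation is checked against exhaustive subset enumeration for
   up to 12 candidates.
8. **Auxiliary count and fusion.** Bulges of w(x) (valleys of 1−w) with
   prominence ≥ 0.1·max(w) and separation ≥ 0.8r are counted; a nonempty
   profile always counts at least one, and a flat plateau counts once.
   The fused SPP keeps the DP count unless the profile count differs by
   exactly one *and* its mean prominence reaches 0.2·max(w), in which
   case the profile evidence wins. The "sufficiently confident" fusion
   criterion is a package choice; only the preference order is inherent
   to the method.

## Trait extraction

Pod length is the long side of the minimum-area rotated rectangle;
width is twice the maximum of the Euclidean distance transform (maximal
inscribed circle diameter); area is the foreground pixel count. All are
computed on the pose-normalized largest component, in pixels (physical
calibration is out of scope).

Two numerical choices make these measurements stable to ±1 px under
re-rasterization (masks that have been rotated and resampled):

- Rectangles are fitted by rotating calipers to the sub-pixel 0.5-level
  contour rather than to pixel centres, masks are warped bilinearly with
  a 0.5 threshold rather than nearest-neighbour, and length/width are
  measured on a σ = 1.25 px Gaussian-regularized boundary. The inscribed
  circle is capped by the single deepest boundary nick and the hull is
  stretched by the single tallest bump, so sub-pixel jaggies otherwise
  bias width low and length high by 1–2 px. The width EDT runs on a 4×
  upsampled field (1/8-px quantization).
- For near-circular pods the min-area orientation is ill-conditioned:
  rasterization shrinks diagonal extents by up to ~0.7 px, which can
  make a diagonal rectangle beat the axis-aligned one by ~2 % in area
  and flip the reported "length" between 2a and intermediate diagonals.
  Among orientations within 5 % of the minimal area, the rectangle whose
  long axis is closest to the PCA principal axis is reported; the PCA
  candidate angle is always included (a coarse hull may lack an edge
  along the symmetry axis). For elongated shapes a 5 % area band confines
  the orientation to ≲1°, so this coincides with the true minimum.

## The fixture generator

A pod is a union of `num_seeds` elliptical lobes placed along a chain
(a circular arc; curvature 0 = straight) with centre spacing < 2× the
lobe radius so lobes overlap. Lobe minor/major axis ratios are sampled
in [0.85, 1.0]; each junction is pinched so the waist is at most 0.85×
the narrower neighbouring lobe's width, guaranteeing the width-profile
valleys the counting pipeline relies on. Constructed truth is exact:
seed centres are lobe centres; true length is the chain (chord) extent
plus the terminal semi-axes — (n−1)·spacing + r_first + r_last for
straight chains; true width is twice the largest lobe minor semi-axis,
which is exactly the maximal-inscribed-circle diameter the extractor
measures. Branches are smooth random-walk trunks spanning the canvas
height with a couple of slanted side branchlets.

The default library conditions — 1–4 seeds per pod, nominal lobe radius
18 ± 3 px, spacing 1.5× the radius, straight chains — are the study
conditions for all accuracy checks. The library defaults to straight
chains because the length truth is exact there; curved chains are
supported (truth then uses the chord extent, an under-approximation of
the rasterized rectangle length for strong bends).

**What the fixtures do and do not show.** The generator reproduces the
bulge/pinch morphology, size variation and arbitrary pose of real pod
masks, so passing tests demonstrate that the counting and trait
machinery is correct on cleanly segmented amodal masks. It does not
model texture, illumination, segmentation noise beyond small specks,
boundary uncertainty of predicted (as opposed to annotated) amodal
masks, or biological shape irregularity (asymmetric lobes, twisted
pods). Accuracy on real imagery is bounded by upstream mask quality and
should be expected to be worse than on fixtures.

## Evaluation

Mask AP follows the COCO convention: greedy confidence-descending
one-to-one matching at IoU ≥ τ, 101-point interpolated precision–recall
integration; AP50 and AP75 are reported (the 0.50:0.95 average is out of
scope). Trait agreement uses MAE, RMSE and R² (R² is refused for
constant ground truth). Seed counts are discretized into classes 1–4
(counts above 4 clip into class 4) for a confusion matrix with overall
accuracy and adjacent-class accuracy (Acc@±1).

## Problem sizes

The test suite and the acceptance script run at desk scale as the
package's reference conditions: 200-pod batches for accuracy metrics,
50 scenes per α on ~260×320 canvases for the occlusion-control property,
500 random candidate sets for the DP-vs-enumeration equivalence, 100
scenes for serialization round trips, and 25 pods × 8 angles for
rotation invariance. Scene canvases in the CLI default to 1920×1080.

## Known limitations

- Counting assumes seeds lie along a single axial chain; forked or
  strongly twisted pods violate the DP's ordering model.
- The occlusion model is binary-mask-based; no illumination, shadow or
  contact deformation is simulated.
- Pixel units only; scale calibration to physical units is explicitly
  out of scope.
- Very heavily occluded amodal masks with missing interior evidence can
  still merge adjacent seeds; the auxiliary profile count only corrects
  off-by-one disagreements.
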