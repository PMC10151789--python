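# Methods

This note documents the models and procedures `harvestkp` implements, the
parameters that matter, the synthetic data the tests run on, and the design
choices made where the design was genuinely open.

## Coordinate and rasterisation conventions

All public APIs use `(row, col)` with row 0 at the image top. Annotation
dialects that store `(x, y) = (col, row)` (Labelme, COCO) are converted at
the file boundary. A polygon fills a pixel iff the pixel center is strictly
inside under the even-odd rule or lies on the boundary within 1e-9 px; the
rule is orientation- and start-index-independent and is verified against an
independent point-in-polygon oracle. Masks without a source polygon are
exported to Labelme as their exact pixel-boundary polygon (vertices on pixel
corners), which round-trips bit-identically; multi-component or holey masks
cannot be one simple polygon and must use the COCO dialect (uncompressed
column-major RLE, also exact).

## Fruit–stem matching

The matcher encodes three priors of dome-type cultivation: attachment,
gravity, and uniqueness.

*Adjacency* is the number of stem **boundary** pixels whose Euclidean
distance to the nearest fruit pixel is strictly below `dis_thr`. Scanning
the stem boundary against a distance transform of the fruit makes the count
a resolution-stable measure of the contact zone at O(perimeter) cost; the
roles of the two masks are deliberately asymmetric. Defaults `dis_thr = 2.0`
px and `num_thr = 5` (the gate is `count > num_thr`) mean a contact segment
of at least six boundary pixels within a one-pixel gap — diagonal contact at
√2 still counts. Both are exposed in `MatchConfig` and on the CLI; on
higher-resolution imagery they should be scaled with the mask perimeter.

*Gravity* requires the stem centroid row to be strictly smaller than the
fruit centroid row. *Uniqueness* is enforced globally: all gated candidates
are sorted by ascending matching degree `D = arctan(|Δcol|/|Δrow|)` — ties
broken by larger adjacency count, then smaller indices, for determinism —
and accepted greedily while both instances are free. Greedy ascending-`D`
selection realises "the candidate with minimum D wins" while guaranteeing a
one-to-one result and `K ≤ min(M, N)` even in many-to-many conflicts. A lone
candidate is accepted regardless of how large its degree is; no absolute
degree gate is applied. The degenerate horizontal case (Δrow = 0) returns
the limit value π/2 with a logged warning; the gravity gate keeps it out of
`match_scene` results.

Unmatched fruits and stems are returned alongside the pairs: a pumpkin whose
stem (or fruit) is entirely hidden produces a lone instance, and reporting it
separately is the occlusion filter downstream consumers need.

## Keypoint geometry

The centroid line `l_p` through C_F and C_S is stored in two exact forms:
`col = c` when the centroid columns coincide (within 1e-9), else
`row = k·col + b`. Fruit pixels are partitioned by the sign of the signed
line evaluation; pixels within 1e-9 of the line belong to neither side.
(A one-sided ≤/> split would assign on-line pixels arbitrarily; the
symmetric exclusion cannot change a maximiser in non-degenerate scenes.) On
each side the pixel of maximum distance — `|col − c|` in the vertical case,
perpendicular distance otherwise — is the grasping point; among equidistant
pixels the smallest row, then column wins (the first maximiser in row-major
order), which makes the output bit-reproducible and oracle-checkable. Grasp
points are necessarily boundary pixels of the fruit mask. They are reported
as pixel coordinates without gripper-clearance offsetting; end-effector
geometry is out of scope.

The cutting point is the stem's center of mass. A curved stem can place its
centroid off-mask, which is physically uncuttable, so by default the point is
snapped to the nearest stem pixel and the snap distance reported; callers can
disable snapping. An error is raised per pair (and the pair skipped with a
log entry) when geometry degenerates: coincident centroids, or a side of the
line containing no fruit pixel.

## Point-rendering refinement

Inference-time refinement of a coarse instance probability map: each of 5
steps upsamples ×2 (align-corners-false bilinear, separable, values stay in
[0, 1]) and re-predicts the `N = 28² = 784` cells with smallest |p − 0.5|
(ties in row-major order). The default schedule takes 7×7 to 224×224. When a
level holds fewer than `N` cells — the 14×14 level has 196 — every cell is
re-predicted, so a full default run issues 196 + 4·784 = 3332 predictor
queries. The trained point head (an MLP over concatenated coarse and fine
features) is not re-implemented: no weights or dataset exist to drive it, and
the deterministic selection/subdivision schedule is the part that benefits
from desk verification. The predictor is a contract taking normalized
(row, col) cell centers in [0, 1]² plus the current interpolated values; an
identity predictor (refinement degenerates to pure upsampling, bit-level) and
a ground-truth oracle predictor (for sharpening experiments) ship with the
package.

## Metrics

Precision = TP/(TP+FP) and recall = TP/(TP+FN); a zero denominator yields an
explicit `None`, never a silent 0. Matching confusion is counted per
ground-truth pair identity `(fruit_index, stem_index)` within each scene. AP
uses COCO-style greedy score-descending matching at each of the 10 IoU
thresholds 0.50–0.95 and all-point interpolation of the precision–recall
curve; per-image prediction caps are not applied since scenes here hold a
handful of instances.

## Synthetic scenes

The generator emulates mask-level phenomena of unstructured fields so every
algorithm is testable without a dataset download:

- **Fruits** are ellipses with column semi-axis 12–22 px and row semi-axis
  0.72× that (dome-grown pumpkins are wider than tall), on a 192×256 canvas.
- **Stems** are 4–6 px wide, 9–16 px long ribbons whose base is carved
  against the fruit's top arc, tilted up to `stem_angle_jitter` (default
  0.15 rad) off vertical. Construction guarantees the pair passes the
  default attachment gate and the gravity constraint.
- **Distractors** (lone fruits, lone stems) are placed at least 8 px from
  everything else, well beyond the adjacency threshold.
- **Occluders** model foliage partially covering an instance: a disk whose
  radius scales with the instance (0.2–0.45 × equivalent radius) bites into
  the boundary. A bite must keep ≥ 40 % of the instance's pixels, must not
  split it, and on a paired instance must leave the contact zone above the
  attachment gate: occlusion shifts centroids, areas and keypoints, but a
  leaf blotting out the entire junction would turn the pumpkin into two
  unrelated objects — identity-deleting occlusion, excluded at default
  settings just like instance-splitting bites. The `occluder_prob` setting
  is the per-instance probability of attempting a bite.

Ground-truth pairs and keypoints are derived by independent exhaustive
scans (`_bruteforce`): explicit coordinate sums for centroids, all-pairs
distances for adjacency, per-pixel loops for grasp maximisation. Generator
and detector therefore cross-validate rather than sharing code paths; on
integer pixel coordinates both arithmetic routes are exact, so agreement is
asserted bit-level.

What passing tests on these scenes show — and what they do not: the
geometry, the assignment logic and the evaluation arithmetic are exact, and
matching is robust to moderate identity-preserving mask erosion. They say
nothing about segmentation quality on real imagery: real failure modes are
missing or hallucinated instances and grossly wrong masks, which enter this
pipeline only through the confusion counts of its evaluation layer.

## Study sizes and numerical choices

The matching study uses 200 scenes per condition (clean and
`occluder_prob = 0.3`), with 1–4 pumpkins and 0–2 lone distractors of each
class per scene; grasp-oracle checks use 100 random fruits up to 64×64;
selection checks use 50 random 224×224 maps. Line-membership and
vertical-form tolerances are 1e-9 px. All randomness flows through
`numpy.random.default_rng` seeds carried in `SceneSpec`/function arguments;
identical seeds give bit-identical scenes, manifests and results.

## Known limitations

- Matching relies on the gravity prior; images not oriented upright (or
  ground-trailing vines) violate it.
- Grasp points are 2-D pixel locations; 3-D localisation and robot-frame
  transforms are out of scope.
- The refinement module is the inference schedule only; without a trained
  point head its practical ceiling is the quality of the supplied predictor.
- Thresholds `dis_thr`/`num_thr` are in absolute pixels and should be
  rescaled for image resolutions far from the generator's 192×256 default.
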