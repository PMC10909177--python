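# Methods

This note documents the models and procedures implemented in `traymetry`,
the assumptions behind them, the parameters that matter, and the numerical
and design choices made where the design was genuinely open. It states no
empirical result that the test-suite or `scripts/acceptance.py` does not
itself compute.

## Homography metrology

The tray-handle rectangle has known metric dimensions (configured;
default 60 × 40 cm, an explicitly arbitrary placeholder — real deployments
must set their tray size). Its four labelled image corners determine the
plane-to-plane projective map exactly (8 degrees of freedom from 4 point
correspondences). We solve by the **normalized DLT**: both point sets are
translated to their centroid and isotropically scaled to RMS radius √2
before building the 8×9 linear system, whose null vector (smallest
singular vector) gives the map. Normalization is unnecessary for a perfect
solve but keeps the system well-conditioned for the near-degenerate quads
that human corner clicks can produce. Numerical contract:

* corner residual must be below **1e−6 cm**, else the configuration is
  rejected as degenerate;
* a condition estimate (ratio of first to penultimate singular value)
  above **1e8** attaches an *ill-conditioned* warning to the result rather
  than failing — corner labels are approximate by nature, and the caller
  decides what to do;
* mapped points with homogeneous coordinate |w| ≤ 1e−12 raise a
  horizon-point error naming the offending point.

**Corner correspondence.** Canonical corner order is purely visual: the
convex cycle starts at the image top-left. Under in-plane camera rotation
the cycle can start on either tray side, and pairing a short image side
with the long tray side would stretch every measurement by the tray aspect
ratio. The estimator therefore chooses between the two cyclic pairings by
matching the *longer pair of observed opposite edges* to `width_cm`. This
is exact whenever perspective does not invert which tray side appears
longer (safe for the mild tilts of hand-held tray photography given the
3:2 tray aspect). The residual 180° ambiguity maps the tray plane onto
itself by a rotation — an isometry, so no length, area or box extent can
be affected. For square trays the tie defaults to the canonical pairing.

**Sizes.** Fish length is the *full arc length* of the mouth-to-tail
polyline mapped into the tray plane — bent fish are traced, not chorded.
Mask area is the shoelace area of the mapped polygon vertices, holes
subtracted via ring nesting; segments between mapped vertices are treated
as straight, which a projective map only guarantees approximately between
distant vertices. This is a documented limitation, validated in the tests
against a dense rasterization oracle (0.1 cm grid, 1% tolerance) — polygon
vertices in practice are dense enough that the discrepancy is far smaller.

## Size regression

Feature layout (fixed, enforced by the fitted model):

```
[bbox_x, bbox_y, bbox_w, bbox_h | mask_area_px | one-hot species | corners(8)?]
```

The box enters as all four numbers, not just width/height: instance
*position* is what lets an uncalibrated model absorb the position-dependent
scale that perspective induces. Species is one-hot, avoiding a false
ordinal structure. The optional trailing block is the 8 tray-corner pixel
coordinates — available only for corner-labelled images, included to
quantify how much explicit calibration information would help.

Normalization schemes: `none`, `standard_input` (z-score),
`minmax_input` (train min→0, max→1 per column; the default), and
`minmax_io` (additionally scales the target, predictions inverse-
transformed before metrics). Degenerate columns (zero or denormally tiny
span) map to 0. Parameters are fitted on training folds only.

Models are a registry delegating to scikit-learn: `gbr` (default),
`extra_trees`, `random_forest`, `svm_radial`, `svm_linear`, `knn`, and the
`dummy` constant-mean baseline whose R² is 0 by construction. The
evaluation protocol is **10 repeats of 10-fold cross-validation**; repeat
*i* reshuffles rows with seed `base_seed + i`. Reports pool all
out-of-fold predictions and carry two dispersion numbers — the std of
pooled per-instance absolute errors and the std across fold-mean MAEs —
because a single "±" is ambiguous between the two. Predictions are floored
at 0.1 cm (lengths are physically positive). Biomass uses the allometric
law W = a·L^b with per-species coefficients supplied by the user; no
default coefficient table ships with the package.

A practical note from validation: boosted shallow trees approximate the
smooth area→length relationship rather coarsely (held-out MAE plateaus
near 0.35 cm on noiseless synthetic scenes regardless of boosting depth or
rounds), while extremely randomized trees interpolate it to ~0.13 cm under
identical conditions. The pipeline-closure tests therefore use the
`extra_trees` spec; all comparative results keep the gradient-boosting
default.

## Detection evaluation

IoU is computed on polygon geometry (resolution-independent; the tests
cross-check against pixel-grid counting at 0.05 px). Matching is greedy in
descending confidence, each prediction taking its highest-IoU eligible
unmatched ground truth at or above the threshold; all ties (confidence,
IoU) break toward the lowest index so results are deterministic.

Two matching flavours serve two questions. AP, mAP and F1 use
**class-aware** matching. Confusion matrices use **class-agnostic**
matching at IoU 0.5, so a detected-but-misclassified fish lands in an
off-diagonal cell; ground truths no prediction matched fill the trailing
**Missed (FN)** column. Rows are normalized to percentages (sum 100);
species with zero ground-truth instances yield all-zero rows and are
flagged. AP uses 101-point interpolated precision over the recall grid
{0, 0.01, …, 1} — the dominant convention for mask AP — pooling class
predictions over images; mAP is the unweighted mean over classes with at
least one ground-truth instance. The exact matching rule behind
detected-vs-missed accounting is this package's documented choice (0.5,
class-agnostic); nothing in the evaluation depends on score calibration.

## Augmentation planning

Ops are rigid motions — rotation about the image centre from a configured
set (default 0°, 15°, 45° and the 45°-multiples up to 315°) followed by a
translation of 5–50 px magnitude — applied to masks, polylines, corners
and boxes (boxes recomputed as the transformed mask's hull). Instances
retaining less than a **visibility fraction** (default 0.5) of their mask
area inside the canvas are dropped. Range validation applies only when an
`OpCatalog` is passed: a bare `apply_op` performs any rigid motion, which
is what the off-canvas-drop semantics need.

Balancing replaces the manual curation such datasets usually get with an
explicit objective: while the max/min species-count ratio exceeds the
target and budget remains, duplicate (as an augmentation op) the image
whose addition yields the smallest new ratio. Steps that would worsen the
ratio are never taken, so the achieved ratio is monotonically
non-increasing in the budget. Because one image rarely contains every
scarce species, the minimum is often attained by several species at once
and no single step can strictly reduce the ratio; ties are therefore
broken by preferring the candidate whose sorted count vector is
lexicographically largest (raising the scarcest counts first), then the
lowest image index. Candidate contributions are obtained by actually
applying the op, so clipped-away instances are never counted and replaying
the plan reproduces the claimed counts exactly. Species present in zero
images are reported as unbalanceable warnings and excluded from the ratio.

## Synthetic scenes

The generator builds everything on the metric tray plane first, then
pushes it through a known projective map, so the truth channel is exact by
construction. Design choices:

* **Fish are capsules** (rectangle plus semicircular caps along the length
  axis): the simplest shape with unambiguous length, area and hull. The
  size polyline is the straight centerline (3 collinear points), so its
  arc length equals the capsule length exactly.
* **Camera is the homography itself** — scale, out-of-plane tilt
  (foreshortening 1/(1 − y·sinφ/d) with viewing distance d = 120 cm),
  in-plane rotation and principal offset; no 3D pose is decomposed because
  only the plane-to-plane map matters to any consumer. Defaults emulate a
  hand-held capture from a similar distance and angle for every tray:
  scale 9.5–10.5 px/cm, tilt 5–15°, rotation ±10°.
* **Species defaults**: 13 Mediterranean market labels (one species split
  by sexual dimorphism), log-normal lengths clipped per species and to a
  global 5–83 cm envelope, typical fish near 17 cm, one elongated
  large-bodied outlier species (*Sphyraena sphyraena*, 25–83 cm,
  aspect 0.12). Aspect ratios (width/length, 0.12–0.45) set the capsule
  width. Placement rejects capsules whose rotated extent exceeds the tray;
  after bounded retries the length is redrawn, and a placement error names
  the fish if the tray genuinely cannot hold the species.
* **Noise channels**, each independently switchable (defaults: corner and
  polyline jitter σ = 1 px, detection dropout 0.10, misclassification
  0.05, confidence ~ Beta(8, 2)); `SceneConfig.noiseless()` zeroes them.

What the generator does *not* emulate: occlusion (overlapping fish emit
full masks), pixel texture/photometry, lens distortion, bent fish, and
annotation biases of real labellers beyond isotropic jitter. Passing tests
therefore demonstrate the correctness of the geometry, the evaluation
machinery and the learning protocol — not real-image segmentation quality.

## Problem sizes and determinism

Test-suite and acceptance-script runs use: 1,000 random quads (×10
interior points) for the homography oracle; 200 noiseless scenes
(~1,100 fish) for metric closure and for the repeated 10-fold regression
comparison; 300 trays for detection scoring; 500 trays for the
missed-detection calibration (3σ binomial check against the 20% dropout
rate); 60 trays with a skewed 8:4:2:1 species mixture for the balancing
planner. These sizes give tight binomial/multinomial bounds while keeping
a full run in the low minutes on one CPU. Every random draw flows from an
explicit seed (per-tray seeds are `seed + index`); reruns are
bit-identical, and the test-suite asserts this for the generator, the
cross-validation report and the planner.

## Known limitations

* Tray dimensions are a config value; nothing checks them against reality.
* The long-edge correspondence rule can mis-pair under extreme perspective
  (when a short tray side projects longer than a long one) — far outside
  the capture conditions the pipeline targets.
* Shoelace-on-vertices area is exact only for dense polygons (see above).
* The uncalibrated regressor learns the *training* capture geometry; its
  error grows with camera variability between trays, which is exactly the
  gap the calibrated-variant comparison quantifies.
* One homography per image: multi-tray images are out of scope.
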