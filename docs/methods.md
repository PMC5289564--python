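# Methods

This note documents the models, conventions and design choices behind
`tunasonar`, in the order the pipeline runs.

## Synthetic scenes: what they emulate and what they do not

The generator reproduces the *structure* of a medium-range-sonar screen
dump, not its acoustics: a circular echogram on a black or blue
background, overlay graphics (range circumferences, a cursor cross, a
short vessel-track polyline) drawn from a dedicated palette, surface-noise
speckle, a menu panel with text-like filler, and echo blobs rendered as
filled rotated ellipses.  Ellipses were chosen because the downstream
descriptors are themselves elliptical (moments ellipse, aspect ratio),
which gives closed-form expectations for every measured quantity.

Class-conditional morphology is uniform over configurable ranges.  The
defaults encode the qualitative contrast reported for real schools — tuna
blobs larger, more elongated and more horizontally aligned than clutter:

| parameter | tuna | clutter | unit |
|---|---|---|---|
| area | U(1500, 8000) | U(100, 600) | px |
| aspect ratio | U(2, 5) | U(1, 2) | – |
| orientation | N(0°, 12°) mod 180 | U(0°, 180°) | deg from horizontal |

The tuna area floor (1500 px) sits well above both the 100-px segmentation
floor and the 415-px smallest school seen by experts in real imagery, and
the ranges make the two classes cleanly separable by construction.  That
is deliberate: the synthetic study validates that the *pipeline* (cleaning,
segmentation, measurement, CV protocol) loses essentially no class
information between rendered pixels and the feature table.  It does not
show that real tuna and clutter are this separable — on survey imagery the
class-conditional distributions overlap, real echoes have intensity
texture, blobs touch and occlude, and annotation is imperfect.  Perfect
synthetic scores are therefore a statement about the machinery, not about
at-sea performance.

Speckle arcs (3–6 px) are placed on a jittered angular grid in the outer
15% of the disc radius so they never merge into clutter-sized components;
blobs are placed in the upper half-disc, clear of the rim, with disjoint
bounding boxes, because the recovery tests require non-touching blobs.
Overlays are drawn beneath blobs so the per-pixel ground truth is exact.
All randomness in a scene flows through one seeded generator and every
artifact records its seed.

`make_feature_table` emits labelled descriptor rows directly from the same
morphology distributions, deriving each descriptor from (area, AR, angle)
with small multiplicative noise standing in for rasterisation error.  The
rows satisfy every schema invariant (AR = Major/Minor, Roundness = 1/AR,
MinFeret ≤ Feret, Width·Height ≥ Area, Solidity ∈ (0,1]) but carry no
pixel-level information; they exist so the balancing and evaluation layers
can be tested at full dataset scale (22 501 rows) in seconds.

## Preprocessing

Screen layout (disc centre/radius, menu box, overlay palette) comes from a
per-sonar-model config file; the display geometry of a given sonar model is
fixed, so estimating it per frame would add noise for no benefit.
Coordinates are 0-based, x rightward, y downward, pixel-centre convention.

Cleaning order is overlays → speckle → upper-half mask.  Overlay removal
matches palette colours within ±10 per RGB channel (analog capture
jitter), then applies a morphological opening with a (t+1)×(t+1) square
(t = maximum overlay line thickness, default 2 px) to remove unmatched
thin structures, then a closing with the same element to reconnect blob
bodies severed by a removed line.  Using the same structuring element for
both makes the open–close composition idempotent, so cleaning an already
clean frame is a no-op; reconnected pixels take the colour of the nearest
surviving foreground pixel.  Speckle suppression drops 8-connected
components strictly smaller than 8 px — far below both the 100-px blob
floor and any real school — and 0 disables it.  The upper-half mask keeps
pixels with y ≤ centre row, matching how skippers read the display (the
vessel's forward sector is at the top; the wake corrupts the bottom).

## Segmentation

Background is, by default, the dominant colour inside the valid mask
("auto"), which handles both black and blue display backgrounds with one
rule; an explicit colour list can be given instead.  Foreground pixels are
grouped under 8-adjacency (`scipy.ndimage.label`), blobs are ordered
row-major by their topmost-leftmost pixel for reproducibility, and blobs
under `min_area` (default 100 px) are dropped, with the threshold kept
strict: a 100-px blob survives, a 99-px blob does not.

## Morphological descriptors

Pixels are unit squares centred on integer coordinates.  Conventions, each
chosen so the corresponding invariant is exactly testable:

- **Centroid, moments, Feret and MinFeret** use pixel *centres*.  Each
  pixel contributes its own square's second moment (the +1/12 term), so an
  axis-aligned w×h rectangle measures AR = w/h exactly.
- **Convex (hull) area** uses pixel *corners*, so Solidity ≤ 1 with
  equality for convex shapes.
- **Perimeter** is the outer 8-connected boundary chain through pixel
  centres — axial steps 1, diagonal steps √2 — minus 0.10765 per
  axial↔diagonal direction change.  The correction constant is fixed by
  requiring a digital straight line at 22.5° (the worst angle for the
  1/√2 weighting) to be measured exactly; with it, a 10×10 square measures
  exactly 36 and a radius-30 digital disk comes out within 0.4% of 2πr.
  An uncorrected chain overestimates smooth curves by ~5%, which would
  push disk circularity down to 0.91.
- **Circularity** is 4πA/P², clipped to 1 for reporting (digital disks can
  exceed 1 slightly); a single pixel (P = 0) reports 1 by convention.
- **MinFeret** is the rotating-calipers minimum width of the pixel-centre
  hull, floored at 1 px.  Computing both calipers on the same point cloud
  makes MinFeret ≤ Feret structural for any multi-pixel blob (a
  corner-cloud MinFeret would exceed the centre Feret for compact blobs,
  e.g. a 2×2 square), and the floor preserves the convention that a
  1-px-wide line has width 1.
- **Angles** (ellipse Angle, FeretAngle) are measured counter-clockwise
  from +x with the y axis flipped from raster order, reported in [0, 180);
  isotropic shapes report 0 by convention.
- **Roundness = 1/AR**, following the dataset schema this package targets;
  note that some particle-analysis tools instead define roundness as
  4·Area/(π·Major²).  The two differ for non-elliptical shapes.
- Degenerate inputs never crash: a single pixel yields Perimeter 0,
  Feret 0, MinFeret 1, Circularity 1; collinear blobs floor the minor axis
  at 1 px.

Pixel areas convert to m² by a per-pixel scale that depends on the sonar
gain setting; the 0.69–0.92 m²/px range of the reference instrument is
validated by default and can be overridden for other sonars.

## Imbalance handling

SMOTE: neighbour search runs on z-scored minority features (the
descriptors span four orders of magnitude; unstandardised Euclidean
distance would be dominated by Area), k = 5 neighbours, interpolation
uniform along the segment in the original feature space.  `percent` = 100
spawns one synthetic row per minority row; other multiples spawn
percent/100 each, and fractional parts use a random minority subset.
Majority rows are never modified or reordered, synthetic ids carry a
`_syn<i>` suffix, and the id/class columns are excluded from distances.
Interpolated rows are convex combinations per feature, so derived-column
consistency (e.g. AR = Major/Minor) no longer holds exactly on synthetic
rows; the table reader reports such violations as warnings rather than
rejecting the file.

Spread subsampling keeps every minority row and a uniform random
half (default) of the majority; a `max_ratio` mode caps the
majority:minority ratio instead.  With the reference counts these rules
reproduce the three canonical dataset constructions exactly: 1497/21004
(ratio 14.03), 2994/21004 after SMOTE (ratio 7.02, 23 998 rows), and
1497/10502 after subsampling (11 999 rows).

Balancing is applied **inside training folds** by default: synthetic
minority points interpolated from the whole table would leak test-fold
information into training.  A `whole_table_balance` flag in
`run_experiment2` rebalances the whole table up front instead, for
comparison with whole-table constructions.

## Evaluation machinery

AUC is computed as the Mann–Whitney probability with ties counted ½
(rank formula), which equals the trapezoidal area under the empirical ROC
exactly.  Kappa follows (p_o − p_e)/(1 − p_e) with the expected agreement
from the confusion-matrix margins; degenerate agreement (p_e = 1) reports
0 with a warning, and undefined sensitivity/specificity/AUC (a class
absent) report NaN with a warning and are NaN-skipped in aggregates.

5×2cv draws, per replication, a stratified half/half split (fold sizes
differ by at most one, both overall and per class; a split leaving a class
empty in either half is resampled and logged).  Repeated k-fold uses
stratified folds built by per-class round-robin with a rotating offset, so
class remainders do not accumulate in one fold.  The corrected resampled
t-test uses t = d̄ / √((1/J + n_test/n_train)·s²_d) with J−1 degrees of
freedom; all-equal differences short-circuit to (0, 1) for zero mean and
(±∞, 0) otherwise.

Attribute filters: features are discretised by Fayyad–Irani MDL-stopped
entropy partitioning (a split must buy more information than its
description cost), so an uninformative feature yields a single bin and a
score of exactly 0 for both the Pearson χ² and the information-gain
filter.  The SVM filter ranks by |weight| of a linear max-margin
classifier on standardised features.  Stepwise selection is greedy
forward–backward on a mildly regularised logistic model scored by BIC;
the subset size is data-dependent by design.  Classifier backends are thin
scikit-learn adapters (random forest 100 trees; RBF SVM with scaling,
scored by decision margin; one-hidden-layer MLP; entropy decision tree;
5-NN with scaling), each deterministic given its seed — the bespoke,
tested surface is the protocol around them, not the learners.

`run_experiment1` evaluates each filter at sizes 3–19 (step 2) plus the
stepwise subset against the full 20-feature run: all subsets share the
same 5×2 partitions (same seed), so per-fold accuracy differences are
paired, and the comparison uses the corrected resampled t-test at
two-sided α = 0.05.  `run_experiment2` crosses the three dataset
constructions with the five backends under repeated k-fold.

## Problem sizes used in the checked studies

The committed studies use 200 rendered scenes (~750 blobs) for the
end-to-end recovery check, a 260-row 20-feature table for the
feature-reduction grid, and full 22 501-row tables for the dataset
constructions (which are cheap).  These sizes give the stochastic
assertions comfortable margins at default settings while keeping a full
run of the suite around a minute.

## Known limitations

- The generator has no acoustic physics: no beam pattern, no
  target-strength model, no range-dependent intensity, no interference
  between echoes; blob interiors are flat colour.
- Overlay/blob colour ambiguity — real overlays can share colours with
  echoes — is out of the generator by construction (disjoint palettes);
  the preprocessing path handles it only via the thin-structure opening.
- Menu-panel OCR, temporal school tracking across consecutive frames,
  echosounder fusion and abundance-index (detections-per-unit-effort)
  standardisation are out of scope.
- The exact perimeter and roundness conventions of the original Java
  measurement software are unknown; the conventions above are declared and
  tested on their own terms, with tolerance bands wide enough to absorb
  reasonable alternatives.
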