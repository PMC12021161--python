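# Methods

## Problem and model

`herdscan` locates active nomadic pastoralist settlements in satellite
imagery.  The region of interest is partitioned into square tiles with a
128 m ground footprint, and a binary classifier estimates, per tile, the
probability that it contains an active settlement:

    P(y = 1 | x) = h(x) = f(E(x)),

where `E` is a CNN encoder mapping the H×W×C tile to a d-dimensional
embedding (global average pooling over the last feature map) and `f` is a
fully-connected head ending in a sigmoid.  Training minimizes the mean
unweighted binary cross entropy with Adam (batch size 16, learning rate
0.001, at most 40 epochs).  After every epoch, validation AUPRC and
precision at 0.95 recall are computed; the weights of the best epoch under
the configured selection metric are kept.  There is no early stopping and no
class weighting.  Augmentation is off by default; an `augment` flag adds one
randomly shifted (up to ±0.35 tile) and flipped/rotated copy of each
training tile.

Active settlements are visually distinctive: dark circular livestock
enclosures (kraals), hut blobs, and grazed bare ground.  Abandoned
settlements show burn marks and vegetation overgrowth and act as hard
negatives.

### Infrastructure-distance fusion (GDA)

Active settlements sit systematically closer to roads and waterways.  For
each infrastructure kind, the nearest-distance covariate D is modeled
generatively:

    y ~ Bernoulli(ξ),   D | y=0 ~ N(μ₀, σ₀²),   D | y=1 ~ N(μ₁, σ₁²),

fit by maximum likelihood (class sample means; variances divided by n_c,
floored at 1 m² because the MLE is degenerate on constant fitting sets; ξ is
the label-1 fraction).  The fitting subset is a stratified 20% hold-out of
the training split and is excluded from classifier training, so the
auxiliary features seen by the classifier are out-of-sample.  Bayes' rule
converts a distance into a posterior P(y=1 | d); the posterior is evaluated
through log-density differences and the logistic function so it is exact to
machine precision arbitrarily far into the tails.

Per kind, the auxiliary feature vector is (p(d|y=0), p(d|y=1), P(y=1|d)).
Three fusion strategies wire these k features into the classifier:

* **aux2** — concatenate to the embedding; head input dimension d+k.
* **aux1** — concatenate to the pre-sigmoid class logit and map through a
  learned linear combiner back to a scalar logit.  "Adding features to the
  class logit" is implemented as concatenation + linear combiner rather than
  arithmetic addition, because the auxiliary features are probabilities and
  densities, not logits; arithmetic addition would be scale-incoherent.
* **aux12** — both insertion points simultaneously.

A raw-distance mode (min-max-normalized distance, no generative modeling)
shares the same interface, which is what makes the "GDA vs raw distance"
ablation a one-flag change.  ξ is taken from the fitting subset's prevalence;
the mismatch with deployment-time prevalence is a documented approximation,
not corrected.  Distances are nonnegative but are modeled with untruncated
normals, matching the generative formulation above.

### Evaluation machinery

The decision rule is `score > α` throughout.  The PR curve has one operating
point per distinct score (ties enter or leave the predicted-positive set
together); the lowest distinct score yields the recall = 1 endpoint.  AUPRC
is right-continuous step integration (Σ precision · Δrecall), which avoids
the optimism of trapezoidal interpolation; precision at recall r* is the
maximum precision over operating points with recall ≥ r*, with no
interpolation between points.  The deployment threshold α is calibrated on
labeled validation data as the largest threshold retaining ≥ 95% of known
positives: with n₊ positives, α must lie strictly below the
⌈0.95·n₊⌉-th largest positive score; we return the midpoint between that
score and the next distinct score below it.

### Deployment

Every tile of the region grid is scored once (resumable via a checkpoint
written every 1,000 tiles).  Tiles with score > α are flagged; flagged tiles
that are adjacent under 8-connectivity are merged into one detection —
8-connectivity because a settlement straddling a tile corner should not
split into two candidates.  The detection location is the area centroid of
the union polygon of member tiles (identical to the mean of tile centers for
rectangular blocks; documented because it differs for L-shaped components).
The search-space reduction is (tiles scanned) / (merged candidates); at the
reference regional scale, 300,000 tiles merging to ~1,100 candidates is a
~273-fold reduction in manual review volume.

Labeled datasets center each tile on its settlement or negative point, while
a deployment grid cuts tiles wherever they fall, so settlements appear at
arbitrary offsets and may straddle tile corners.  The deployment recipe
therefore (a) trains with the shift/flip augmentation and (b) calibrates α
on the grid-tile scores of known settlement locations rather than on the
centered validation tiles.  On the packaged synthetic set this yields ≥ 95%
recall of known locations and comparable recall on held-out settlements,
with a ~30-fold review reduction (recomputed by `scripts/acceptance.py`).

### Resolution degradation protocol

To emulate coarser satellite products from fine imagery, a tile at source
resolution s m/px targeted to t ≥ s m/px is downsampled to
round_half_up(H·s/t) pixels per side with area averaging (modeling sensor
footprint integration), then upsampled back to H×H bilinearly.  This
isolates the resolution change from every other image parameter.  Targets
finer than the source are rejected — detail is never fabricated.

## Synthetic scenes

No study imagery is distributed, so the package ships a seeded scene
generator that reproduces the statistical structure the method relies on:

* **Imagery.** A semi-arid background (low-frequency noise + speckle),
  waterways drawn as sinuous west–east polylines through the central band of
  the region, roads tracking them with an independent lateral wander (roads
  follow rivers, so the road–water gap sweeps continuously through
  0–800 m — important so that arbitrary joint distance draws are
  geometrically realizable), plus one north–south road.  Active settlements
  are rendered as dark annuli with interior bare ground and 1–3 hut blobs;
  inactive settlements as burn-mark blotches with green overgrowth texture
  and no intact annulus.  Settlement geometry is defined in meters
  (enclosure radius default 16 m) so appearance scales correctly with
  resolution.
* **Distance structure.** Active settlements realize road and water
  distances drawn from N(μ₁, σ₁²) truncated at zero (defaults μ₁ = 200 m,
  σ₁ = 100 m); inactive settlements and random negatives from N(μ₀, σ₀²)
  (defaults μ₀ = 2000 m, σ₀ = 800 m).  Placement is rejection sampling
  against the realized polyline network: a distance pair is drawn, candidate
  locations are proposed from a coarse distance-transform grid, and a
  candidate is accepted only when its exact polyline distances match the
  draw within 6 m — so image content and the distance covariate are always
  consistent.  Truncation at zero shifts the class-1 mean from 200 m to
  ≈ 205.5 m; the generator's tests compare against the truncated mean
  computed by numerical integration.  Joint draws that the realized geometry
  cannot host (e.g. beyond the maximum distance the region affords) are
  redrawn, which mildly truncates the far tail of the class-0 distribution.
* **Strata.**  Negatives come in three strata mirroring a realistic
  collection protocol: `near_settlement` (uniform within 1 km of an active
  settlement — these inherit small infrastructure distances and are the hard
  negatives that the image model, not the GDA prior, must reject),
  `random_national` (background terrain, class-0 distances) and
  `random_continental` (class-0 distances on visually distinct terrain
  palettes, emulating geographic diversity).
* **Separation.**  Point centers are kept ≥ tile size + 4 m apart, so the
  half-open 128 m tile windows of any two labeled points — in particular
  across train/validation/test splits — never share pixels (no label
  leakage).  Splits are stratified with largest-remainder rounding, making
  split sizes exact per stratum.

What the generator does **not** emulate: real sensor radiometry, clouds and
shadows, terrain-correlated settlement appearance, seasonal change, or
correlated infrastructure errors.  Passing the packaged trend tests
therefore demonstrates that the pipeline's machinery is correct and that its
comparisons are wired fairly (paired seeds, identical splits), not that the
printed performance levels would transfer to real imagery.

## Problem sizes and defaults

Chosen so the full pipeline runs comfortably on one CPU core:

* Main synthetic study set: 10.24 × 10.24 km at 2.0 m/px, 200 active
  settlements, 100 inactive, 150 + 150 + 300 stratified negatives,
  70/15/15 split.
* Resolution-ablation scene: 3.07 × 3.07 km at 0.5 m/px (256 px tiles),
  60 actives, distance parameters scaled to the compact region
  (μ₀ = 600 m, μ₁ = 80 m) — that experiment measures the resolution trend,
  not the distance structure.
* Transfer scene ("second region"): 6.14 × 6.14 km, 60 actives, 40
  inactives used as negatives, no continental stratum, different distance
  scale (μ₀ = 1200 m, μ₁ = 150 m).
* Encoder: 4-block CNN (8–16–32–32 channels, 3×3 kernels, max-pool), d = 32,
  ~15k parameters, 64 px model input (tiles at other sizes are resized
  bilinearly).  Larger backbones can be registered in `ENCODERS`; nothing in
  the tests depends on one.
* Training runs in the packaged experiments use 6–8 epochs (the smoke
  benchmark reaches validation AUPRC > 0.9 in ≤ 8); the `TrainingConfig`
  default remains 40.

## Numerical choices and edge cases

* Variance floor 1 m² in the GDA fit; both classes must have ≥ 2 samples.
* Posterior evaluated via logistic(log p₁ − log p₀ + logit ξ); saturates to
  exactly 0/1 only where a float cannot represent the difference.
* Ties in model selection resolve to the earliest epoch; ties in score
  thresholds are grouped; the intermediate pixel size in degradation uses
  round-half-up.
* Tile grids cover the region with ceil-division; overhanging boundary tiles
  are zero-padded and flagged rather than discarded so deployment counts
  refer to the full region.
* Scene determinism is byte-level: identical config + seed give identical
  checksums over raster, polylines, and manifest.
* Distances are planar Euclidean meters.  Real inputs must be supplied in a
  projected CRS; geodesic and along-network distances are out of scope.

## Known limitations

* The synthetic classification task is easier than real imagery; several
  trend comparisons saturate at 1.0 and hold as equalities.
* The class-0 distance distribution is truncated by region geometry
  (realized mean slightly below μ₀); only the class-1 parameters are
  asserted against their generative targets.
* Deployment-level precision against a full manual review cannot be
  replicated without the original imagery; deployment behavior is validated
  through structural invariants (coverage, conservation, idempotence,
  centroid geometry) and the synthetic end-to-end scan.
* The numpy CNN is intentionally small; it is a faithful, testable stand-in
  for the training strategy, not a competitive backbone.
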