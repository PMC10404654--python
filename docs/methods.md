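# Methods

## The modelling problem

`ensdm` implements a multi-model ensemble species distribution modelling
(SDM) workflow for a rare, wide-ranging terrestrial species in a
mountainous, human-dominated region, together with the downstream
conservation analyses that such models feed: habitat reclassification,
human-disturbance masking, conservation-priority ranking by multi-model
intersection, range-shift quantification under climate/land-use scenarios,
protected-area (PA) threat assessment in eco-sensitive zones (ESZ), and the
evaluation of expert range polygons against model output.

Three nested predictor sets drive three independent models:

* **HLCAm** — habitat (NDVI, tree canopy, forest type) + land cover +
  climate + anthropogenic pressure + topography; the baseline, fitted only
  to the current period because its habitat layers have no credible future
  analogue.
* **LCAm** — land cover + climate + anthropogenic + topography; projected to
  future scenarios with land-cover change and constant human pressure.
* **Cm** — climate + topography only; projected to future scenarios.

Comparing the three reveals how much each block of predictors shapes the
projected habitat, and their intersection defines conservation priorities.

## Occurrence preparation

Presence-only records are de-duplicated exactly and then spatially thinned
to a minimum pairwise separation (default 5 km — a home-range-scale distance
for a large territorial carnivore). Thinning maximizes retention by
randomized greedy selection over shuffled visiting orders (default 100
restarts), with ties between equal-size solutions broken by the
lexicographically smallest id set so results are reproducible. For point
sets of ≤ 12 records this strategy attains the exhaustive
maximum-independent-set optimum (verified by enumeration in the test suite).
One-record-per-grid-cell thinning (cell area 5 km²) is available as
`method="grid"`; the two readings of "one point per cell / minimum buffer"
differ and both are provided. Distances are Euclidean in projected km;
great-circle distances are used when coordinates are tagged lon/lat.

## Collinearity screening

The variance inflation factor VIF_j = 1/(1 − R²_j) is computed from the OLS
regression (with intercept) of each continuous predictor on all others.
Stepwise elimination drops the single worst predictor and recomputes until
every VIF falls below the threshold (default 10). Ties on the maximum VIF
are broken by layer-name order. VIF is computed on a seeded region-wide
subsample of valid cells (default 10,000) rather than at presences only:
collinearity is a property of the predictor field over the model's
projection domain. Categorical layers (land cover, forest type) are excluded
from VIF and passed through. The `VIFSelector` estimator exposes the same
elimination as a scikit-learn feature selector.

## The ensemble protocol

Five learner families are fitted: a native IRLS logistic regression (GLM), a
hinge-spline logistic model with L1 term selection (the adaptive
regression-splines style learner), gradient-boosted trees (BRT), random
forest (RF), and a maximum-entropy-style model realized as penalized
logistic regression of presences against a large background sample (the
weighted-logistic equivalence of MaxEnt).

Presence–absence families train against pseudo-absences drawn uniformly
from cells at least 5 km from every presence, in equal number to the
presences; the background family additionally sees a 10,000-point
unconstrained background sample appended to its training rows. Evaluation
rows are identical across families (held-out presences vs. buffered
pseudo-absences) so family metrics are comparable.

Each family runs 10 replicates. A replicate takes a fresh stratified 70/30
train/test split and a fresh pseudo-absence draw from an eligible-cell pool,
runs 5-fold cross-validation inside the training portion, then refits on the
full training portion and is scored on the held-out 30%. Both the CV means
and the held-out means are reported, labelled, since they answer different
questions (model-selection stability vs. generalization).

Families whose mean held-out AUC falls below 0.8 are excluded from the
ensemble. The remaining replicate fits are combined as a weighted mean with
weights proportional to each fit's held-out TSS (AUC weighting is a config
switch), clipped at zero and normalized to sum to one. Weighting is per fit,
not per family mean, so a family's internal spread is preserved. Ensemble
scores are convex combinations of member scores and therefore stay in
[0, 1].

Continuous predictors are z-scored with statistics frozen on the baseline
stack and reused for scenario stacks, so a shifted climate layer is seen as
shifted. Categorical layers are one-hot encoded against the categories
observed at fit time.

## Evaluation

* **AUC** — rank-based (Mann–Whitney) with tie correction.
* **TSS** — max over observed score thresholds of sensitivity +
  specificity − 1, returned with its operating threshold. The search is over
  observed scores only, so the returned threshold exactly attains the
  returned TSS.
* **Continuous Boyce index** — 101 overlapping windows of width 1/10 of the
  background score range; for each window the predicted-to-expected ratio
  P/E compares presence and background mass; the index is the Spearman
  correlation of P/E against window midpoint over windows with non-zero
  expectation. Windows and width are configurable. The index is invariant
  under common shifts of all scores (rank-based over windows).
* **Null-model significance** — the observed AUC is compared with the 95th
  percentile (one-sided, type-7 interpolation) of AUCs from the same
  protocol re-run on uniformly random points (default 99 iterations).
  n = 99 matters: with the type-7 rule the nominal type-I rate is ≈5–6% at
  n = 99 but ≈9–10% at n = 19, an order-statistics property independent of
  the data.
* **Permutation variable importance** — mean drop in AUC (or TSS) over
  permutations of one variable's column, floored at zero.
* **Marginal response curves** — one predictor varied over its observed
  range with the others held at regional means (mode for categorical).

## Post-processing

Suitability is reclassified at 0.2 / 0.4 / 0.6 into unsuitable / low /
medium / high. Intervals are half-open at the lower edge with the top class
closed at 1.0; the boundary convention is configurable because interval
notation in the source thresholds is ambiguous at the edges.

The disturbance ensemble is the arithmetic mean of human footprint and human
modification; each layer is min–max normalized only when its values leave
[0, 1] (layers already on the unit scale pass through unchanged, so a cell
at footprint 0.2 / modification 0.3 has ensemble pressure 0.25). Cells above
0.3 are high disturbance and are removed from all conservation products.

Priorities on low-disturbance cells: **very high** where HLCAm is high and
both LCAm and Cm are at least medium currently; **high** where HLCAm is
medium under the same agreement (the strict triple intersection — the
intersection arity was an open design point; provenance strings on the
priority map record the rule used); **possible future** where a cell not
already ranked is at least medium in every future map of both scenarios
(requiring both scenarios is the conservative reading; an any-scenario mode
is a config switch); **none** otherwise. The categories are mutually
exclusive and exhaustive over low-disturbance cells.

Area reports give class areas (cell count × cell area) and percent of zone,
rounded half-up to two decimals, with raw percents alongside. The "suitable
percent" of a report is the sum of the *rounded* medium and high percents —
the components-then-sum convention used in published accounting tables —
and this arithmetic is what the acceptance checks reproduce exactly.

Range shift between two class maps counts gain/loss/stable cells of
suitable (≥ medium) habitat and reports the vector between area-weighted
suitable centroids (+y is north).

PA threat: the high-pressure mask is the disturbance rule OR road distance
< 3 km. Per PA, the fraction of high-pressure cells inside the polygon and
inside its 1 km ESZ ring (buffer minus polygon, mitre joins so toy ring
areas are closed-form) is computed with the cell-center-in-polygon rule; a
PA is flagged threatened above a 0.3 fraction. That flag threshold parallels
the disturbance cut-off but is a package convention — no established
standard defines "threatened" here, and reports say so.

## The synthetic landscape and virtual species

`synthgeo`-style generation replaces real geodata with a seeded, fully
reproducible landscape: two smooth climate gradients (N–S and E–W with
gentle curvature), three (or more) autocorrelated Gaussian-field climate
layers (white noise filtered at a stated range, default 15 cells),
elevation as ridge-plus-relief with slope derived by finite differences,
meandering river and road polylines with exact Euclidean distance rasters,
categorical land cover whose anthropogenic class tracks a human-pressure
latent field, human footprint/modification in [0, 1] correlated with that
class, and habitat layers (NDVI, canopy, elevation-band forest type).
Futures shift/scale climate layers, convert a stated fraction of natural
land cover to anthropogenic frontier-first (adjacent to existing
anthropogenic cells before interior cells), and hold human layers constant.

The virtual species is a known logistic niche over standardized layers.
Defaults: coefficients (+4.0, −4.0, −2.5) on (bio18, elevation,
human footprint), intercept −4.0 — a sharply contrasted habitat specialist
with regional mean suitability ≈ 0.18. The sharp contrast is deliberate: a
weak-contrast niche (coefficients ≈ ±1.5, mean suitability ≈ 0.34) has a
discrimination ceiling near AUC 0.70 under probability-proportional presence
sampling, i.e. *no* model could meet the 0.8 quality bar, whereas a
low-prevalence specialist is both recoverable and closer to a rare large
carnivore whose suitable habitat is a small fraction of the region.
Presences are drawn without replacement at cell level with probability
proportional to suitability (optionally × a detectability bias raster; a
road-proximity bias helper is provided, default off = uniform
detectability).

What the generator does *not* emulate: real spatial sampling bias along
survey routes, positional error, temporal nonstationarity, mass effects /
dispersal limitation, and interactions among predictors beyond the additive
logistic truth. Passing the recovery tests therefore shows the pipeline can
recover a knowable niche under clean conditions, not that it would be
equally accurate on real occurrence data.

## Problem sizes and numerical choices

The acceptance runs use a 200×200 grid of 1 km cells, 3 active predictors,
≈800 sampled → 200 thinned presences, 10 replicates × 5 folds × 5 families
(the full protocol); null-model calibration runs 200 nested trials of a
lightweight single-replicate GLM protocol (30 presences on a small noise
landscape, 99 null iterations each); the range-shift direction check uses
20 seeded 80×80 landscapes. These sizes were chosen as the package's
standard validation workloads.

Seeds: every stochastic step takes an explicit seed; the pipeline derives
per-stage seeds from the master seed and stage name (crc32 mixing), records
them in the run manifest, and reruns of a config are bit-identical.

Degenerate inputs: empty occurrence sets thin to empty; zero river/road
counts yield a sentinel max-distance raster flagged degenerate; constant
predictors are rejected by VIF with a named error; perfect collinearity is
reported as +inf; a Boyce background concentrated in one window triggers a
degeneracy warning; empty zones produce zero-area rows, not failures.

## Known limitations

* The MaxEnt-style learner is the penalized-logistic equivalence, not a
  feature-class MaxEnt; its raw scores are relative indices rather than
  calibrated probabilities (rank metrics are unaffected).
* The hinge-spline learner approximates adaptive spline regression with
  fixed quantile knots plus lasso selection; it does not prune interactions.
* No connectivity or corridor modelling; priorities are cellwise.
* Geographic I/O is plain-text (ASCII grid, GeoJSON, CSV); coordinate
  systems are treated as planar km except for great-circle thinning
  distances on lon/lat inputs.
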