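# Methods

## The model

`extrisk` models the probability that a species is assessed as threatened
from its intrinsic biological traits and summaries of the environment
across its geographic range.  The response is the dichotomized Red List
status: VU/EN/CR/EW/EX are "at risk" (y = 1), NT/LC are "not at risk"
(y = 0), and Data Deficient (DD) species are unlabeled — they never enter
training but are scored by the fitted model, which is the main practical
use of a threat-status classifier.

The classifier is a forest of **conditional inference trees**.  At each
node, the split *variable* is chosen by a permutation-test association
p-value between each candidate feature and the labels, not by exhaustive
impurity search.  For feature x with influence g(x) (raw values for
numeric features, indicator coding for categorical ones), binary labels
y and case weights w, the linear statistic is T = Σᵢ wᵢ g(xᵢ) yᵢ with
permutation-null moments

    μ = E_w(y) · Σ wᵢ g(xᵢ),
    Σ = V_w(y) · (W·Σ wᵢ g gᵀ − (Σ wᵢ g)(Σ wᵢ g)ᵀ) / (W − 1),

and the standardized quadratic form c = (T−μ)ᵀ Σ⁺ (T−μ) is referred to
χ² with df = rank(Σ).  Selecting by p-value removes the classical bias
of CART-style search toward variables with many distinct split points;
the acceptance suite verifies this directly (uniform root-selection
frequencies under pure noise for two numeric features against a
10-level categorical one).  Within the selected variable, the cutpoint
(numeric) or binary level partition (categorical; exhaustive up to 12
observed levels, class-rate-ordered scan above) maximizes the analogous
two-sample statistic.

Numerical choices worth knowing:

* **Small nodes.**  The χ² reference is unreliable below ~15 cases, so
  for unweighted nodes with ≤ 14 cases the permutation null is
  enumerated exactly (all C(n, n₁) label placements).  Tests confirm
  agreement with a 100,000-draw Monte-Carlo permutation oracle within
  0.02 at n ≤ 12.
* **Degenerate features** (constant after removing missing values) get
  the sentinel p = 1 and are never selected.
* **Ties** in variable selection break toward the smallest feature
  index; tied cutpoint statistics take the smallest cutpoint; tied
  categorical modes and profile levels take the smallest code.
* **Stopping.**  A node splits only if the winner's Bonferroni-adjusted
  p (over the mtry candidates) is ≤ α.

### Missing data

No imputation anywhere.  Cases with a missing value of the tested
feature are excluded from that node's statistic.  At a fitted split,
a case missing the split feature is sent to *both* children during
training with weights proportional to the observed split proportions,
and to the heavier child (ties left) at prediction.  This reproduces a
documented side effect: features with many missing values have fewer
usable cases per node, hence weaker statistics and deflated importance.

### Forest defaults

500 trees; α = 0.05; mtry = 5; per-tree subsamples of fraction 0.632
drawn **without** replacement; minimum 20 (weighted) cases to attempt a
split and 7 per child.  These are the conventional defaults of
permutation-test forests; all are configurable (`ForestConfig`).
Forest probabilities are plain averages of per-tree leaf at-risk
proportions and are invariant to tree order.

## Classification and evaluation

Scores become binary calls at the **max-kappa threshold**: candidate
thresholds are midpoints between consecutive distinct scores plus
below-min/above-max sentinels; the smallest candidate maximizing
Cohen's kappa wins, and the rule is strict (score > threshold → at
risk).  Skill is summarised by stratified 10-fold cross-validation:
folds are class-stratified with sizes differing by at most one; pooled
holdout scores give the ROC AUC (computed by the rank/concordance
formula, ties counted half) and the threshold; accuracy, sensitivity,
specificity and kappa are reported at that threshold.  The threshold
from a full-data refit is reported alongside, but the pooled-holdout
one is canonical.

## Interpretation and geography

*Partial dependence* substitutes each grid value (1st–99th percentile
grid for numeric features, every level for categorical ones) into a
single **reference profile** — numeric means, categorical modes — and
scores it.  We deliberately use this single-profile construction rather
than data-averaged partial dependence because the geographic
attribution maps reuse the identical construction: each species is
scored with only its observed focal value substituted into the profile,
and the *attribution map* is the per-cell mean of those scores over the
species covering the cell.  *Permutation importance* is the mean drop
in out-of-subsample accuracy (0.5 cut) when a feature is permuted among
a tree's out-of-subsample rows; the loss and cut are recorded in the
output metadata since no canonical choice exists.

Risk sets nest by construction — DD-predicted ⊆ latent ⊆ predicted ⊆
actual-or-potential — with the latent membership statuses defaulting to
{LC, NT, DD}; a narrower reading ({LC, NT} only) is available via
configuration, in which case the first inclusion is not guaranteed and
is not asserted.  Richness maps count subset species per cell; both map
types satisfy exact conservation identities (cell sums equal
species-side sums) that the tests check.  Climate exposure is the zonal
mean velocity (km/yr) over each range, with exceedance fractions at
≥ 0.5 and ≥ 1.0 km/yr per risk set, and a tercile-by-tercile
velocity × richness overlay.

## Zonal extraction conventions

Continuous layers are summarised by their mean over a range's
non-no-data cells (min/max are available behind a flag but do not enter
the default feature set); categorical layers by the modal category
(ties to the smallest code); positions by median latitude and median
longitude of cell centers, the longitude computed circularly when the
range spans more than 180° so antimeridian ranges summarise near ±180.
Cells are weighted equally within a range; a cos(latitude) area
weighting exists but is off by default.  Body mass and range size enter
the model as log₁₀ values (the base only rescales axes; it cannot change
any split).  Rasters are ESRI ASCII grids (row 0 northernmost, values at
cell centers, NaN no-data, `%.17g` formatting so round trips are
bit-exact); range atlases are per-species cell lists or GeoJSON polygons
rasterized by cell-center inclusion with boundary ties resolved toward
+lon/−lat.

## The synthetic world

The generator emulates the statistical structure of a global mammal
risk dataset on a quarter-degree grid (75°S–75°N by default):

* cumulative annual productivity ∝ cos²(latitude) with smooth
  multiplicative noise; seasonality (CV of productivity) rising with
  |latitude|; minimum productivity = cumulative × (1 − min(CV, 1));
* human density as a background (2 km⁻²) plus 12 Gaussian hotspots with
  log-normal peak amplitudes (median ≈ 800 km⁻²) and 4–14° decay
  scales; night lights ∝ log(1 + human density) plus smooth noise;
* an 8-category land cover from argmax of smoothed Gaussian fields
  (spatially autocorrelated, as real land cover is);
* a smooth log-normal climate-velocity field (median ≈ 0.45 km/yr,
  σ_log = 0.8), which puts roughly 40–50% of cells above 0.5 km/yr and
  ~15% above 1 km/yr — the order of magnitude reported for mid-century
  temperature-velocity rasters.

Species (n = 2,000 by default, 8 taxonomic orders) get log-normal body
masses (ln-median 100 g, σ = 2.3, order offsets σ = 1.2) and disc-shaped
ranges around sphere-uniform centroids with log-normal areas (ln-median
≈ 1.6 × 10⁵ km², σ = 2); `range_size` is cell count × cell area at the
centroid latitude.  Secondary traits follow standard allometries
(production ∝ mass⁻⁰·²⁵, Damuth-style density ∝ mass⁻⁰·⁷⁵, home range
increasing with mass) with log-normal noise.

True risk is logistic in four standardized features — log range size
(−2.4, the dominant driver), log body mass (+1.2), mean human density
(+1.2), mean seasonality (−0.9) — with the intercept bisected so mean
probability matches the target prevalence of 0.25 (the realized class
balance of the motivating analyses is unpublished; 0.25 is a realistic
threatened fraction for mammals).  These magnitudes give a Bayes AUC of
≈ 0.93, so a well-fitted forest reaches holdout AUC ≈ 0.90 —
representative of published trait-based threat classifiers.  After
labeling, statuses are drawn uniformly within the at-risk ({VU, EN, CR})
and not-at-risk ({LC, NT}) groups (the model only consumes the
dichotomy), 10% of species are masked DD, and per-trait missingness
(10–40%, PanTHERIA-like) is applied to the public table only.  The
generating truth (labels, linear predictor, coefficients) is returned
separately and never enters the table handed to the pipeline; a test
asserts the column sets are disjoint.

What the generator does **not** emulate: phylogenetic covariance beyond
order-level mass offsets, range-shape realism (discs only), habitat
suitability inside ranges, spatial covariance between land cover and
productivity, and threat processes with explicit mechanisms.  Passing
recovery tests therefore demonstrate that the pipeline recovers a known
signal of this statistical shape — not that any particular real-world
covariate ranking is correct.

## Problem sizes used in checks

The test suite and `scripts/acceptance.py` run the full default world
(2,000 species, 500 trees, 10-fold CV) once for the headline skill
metrics; repeated-seed recovery checks (importance rank, partial-
dependence slope signs: 10 seeds; hotspot attribution contrast: 20
seeds) use the same generating structure with smaller forests (120 and
40 trees) or smaller worlds (300 species at 2°), since rank/sign/contrast
recovery is insensitive to ensemble size while wall time is not.
Monte-Carlo oracles use 100,000 permutation draws; unbiasedness and
type-I checks use 1,000 replicates.

## Known limitations

* Surrogate splits and conditional (correlation-adjusted) importance
  are out of scope; proportional missing routing is simpler and
  testable but can dilute signal when missingness is informative.
* The χ²/exact hybrid p-value is exact only for unweighted nodes;
  fractionally weighted nodes (created by missing routing) always use
  the asymptotic reference.
* Ordered categorical traits are treated as unordered unless the
  feature dictionary marks an order.
* Latitude/longitude geographic handling is plate carrée throughout;
  no projections.
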