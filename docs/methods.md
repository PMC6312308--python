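# Methods

This note documents the models, the synthetic world, the numerical choices,
and what the test suite does and does not establish.

## Spatial data model

All computation happens on a north-up WGS84 geographic grid with square
cells; a point belongs to the cell whose half-open box
`[x_min + c·res, x_min + (c+1)·res) × (y_max − (r+1)·res, y_max − r·res]`
contains it, so thinning and extraction are deterministic even for records
on cell edges. Area is counted in cells, not km²: every area statistic the
pipeline reports is a ratio (percent change, proportional coverage), which
is invariant to that choice, and it avoids a latitude-weighting convention
the products do not need. Ocean/unanalyzed cells are nodata supplied by the
input stack and excluded from every statistic. GeoTIFF I/O writes the
standard georeferencing tags (ModelPixelScale, ModelTiepoint, a GeoKey
directory declaring EPSG:4326, GDAL_NODATA); continuous layers are float32,
categorical layers uint8 with 255 as nodata.

## Occurrence cleaning

The cascade is precision filter → exact deduplication → one-record-per-cell
thinning → random 50/50 calibration/evaluation split. Records are
low-precision when both coordinates carry at most one decimal place
(coarser than a 2.5-arcmin pixel); with a `precision` column that metadata
is used directly, otherwise decimals are counted from the coordinate text.
Thinning is grid-cell uniqueness rather than pairwise great-circle
distance: it is the literal "one per pixel" criterion and is deterministic.
Ties (which record a cell keeps) go to the first record in input order. The
split assigns `ceil(f·n)` records to calibration. All stage counts are kept
in a `counts_log` so the cascade can be reported as a table.

## Dimension reduction

PCA is fitted on the correlation matrix (per-layer z-scores over all
non-nodata cells of the present-day stack): bioclimatic layers carry
incommensurate units, and covariance PCA would be dominated by
precipitation-scale layers. Loadings' signs are fixed (largest-magnitude
entry of each column positive) so the decomposition is reproducible across
linear-algebra backends. Future stacks are centered and scaled with the
*present-day* means and standard deviations and projected on the
present-day loadings — the mapping applied per cell is frozen at fit time,
which the tests assert directly. The default keeps 8 components;
`select_components` picks the smallest count reaching a cumulative variance
target (interpreted as ≥ target) for worlds where 8 is meaningless.

## Maximum-entropy model

The model is the estimand of MaxEnt's raw output: a Gibbs density over
background cells, not a port of any particular MaxEnt release. Features are
linear + quadratic terms of the components by default, with pairwise
products optional; hinge/threshold features are omitted because the inputs
are already smooth principal components, and an exponentiated quadratic
already represents any Gaussian response surface. The objective is convex
and solved exactly by splitting each weight into positive and negative
parts, turning the L1 penalty into smooth bound-constrained minimization
(L-BFGS-B, 10 000 iteration cap, projected-gradient check at the solution).

Regularization follows MaxEnt's design: feature *j* pays
`β · s_j / √m` per unit weight, where `s_j` is the feature's standard
deviation over the *presence sample* and `m` the presence count. This
scaling is what lets the model discriminate signal from noise when
near-zero-variance components are standardized up to unit scale: features
whose presence distribution is tightly concentrated (a genuine response)
are penalized little, while features as dispersed at presences as at
background are shrunk to exactly zero. The default multiplier is `β = 2.0`
— roughly two standard errors of each presence constraint, the point where
pure-noise features are reliably excluded while the default world's true
response features (≈6 standard errors) are untouched. A flat-penalty
variant (penalty independent of presence spread) was measured to either
pass noise features through (small β) or zero out genuine quadratic
responses (large β); the presence-sd scaling removed that trade-off.

Output is `exp(η)` rescaled by its maximum over valid in-range cells, so
the best cell scores exactly 1. Every downstream product — the E%
threshold, pROC, D/I after re-normalization — is invariant to monotone
rescaling, so the logistic transform's extra constant is unnecessary.
"Extrapolation deactivated" is a hard rectangular rule: any cell with a
component value outside the training (presence + background) range gets
suitability 0 and a novelty flag; values are never clamped into range.
Background is 10 000 cells drawn uniformly without replacement from the
accessible area (a latitude band, optionally bounded in longitude, judged
by cell centers). Replicates bootstrap `ceil(0.5·n)` calibration points
with replacement under per-replicate subseeds and share one background
sample, so replicate spread reflects occurrence resampling only.

## Thresholding and ensembles

The E=5% threshold is the largest calibration-point suitability value whose
omission (fraction of calibration points strictly below it) stays ≤ E;
binary maps use ≥ τ, so points exactly at the cutoff count as predicted
present. Future binaries reuse the present-day τ (future scenarios have no
calibration points of their own). Per (RCP, period), the ensemble is the
per-cell median across GCM medians; uncertainty is the per-cell max−min
across GCM medians (and across the 10 replicates for the present day).
Stability codes partition valid cells exhaustively: stable (1), loss (4),
gain agreed by all GCMs (2), partial agreement (3), unsuitable throughout
(0); the loss class is kept even where a display might merge it into 0,
because the partition must be exhaustive. Area change is reported under
both conventions — relative to present suitable area and relative to all
analyzed cells — since percent-increase statements are ambiguous about the
base.

## Evaluation

Partial ROC uses 101 equal-width cutoffs on [0, 1]; sensitivity comes from
a with-replacement resample of half the test points per iteration, and
proportional predicted area (PPA) from all valid cells of the full
prediction extent. The curve is restricted to sensitivity ≥ 1−E, the
partial AUC is trapezoidal, the null is the area under the identity line
over the same PPA range, and the p-value is the fraction of iterations with
ratio ≤ 1. A constant map yields ratio 1 identically (the degenerate
single-point region is scored by height). Under a random map the p-value is
approximately uniform — it is a calibrated p-value, not a statistic
concentrated near 1 — so calibration checks are run over an ensemble of
random maps (median p, rejection rate) rather than on a single draw. The
binomial test is the exact tail `P(X ≥ s)` for `X ~ Binomial(n, p)` with
`p` the proportional suitable coverage of the valid area, recomputed per
run.

## Niche overlap

D and I are computed over the union of the two maps' valid cells, each
surface normalized to sum 1 on that shared mask; I is evaluated as the
Bhattacharyya coefficient and cross-checked against the Hellinger form at
1e−12. The background similarity test draws, per replicate, as many uniform
random points from species B's accessible area as B has real occurrences,
fits a model with the same background, features and β as the real fits
(isolating the randomization to the occurrence points), and compares it to
species A's surface; similarity is rejected one-tailed when the observed D
(or I) falls below the 5th percentile (linear interpolation of order
statistics) of the null. The empirical percentile rank of the observed
statistic is reported as an auxiliary quantity; the boolean decision is
primary.

## The synthetic world

The generator emulates the statistical structure of a global bioclimatic
analysis at desk scale. Latent environmental gradients are white noise
convolved with a Gaussian kernel (σ = 8 cells) and standardized — the
simplest surface with controllable spatial autocorrelation. The observed
stack mixes 2 latent gradients into 15 layers through a fixed random
matrix, adds independent noise (sd 0.05 of a unit gradient), and gives each
layer its own scale and offset so that correlation-matrix PCA is the
appropriate reduction. Species' true suitability is an axis-aligned
Gaussian in latent space (default width 1.0 latent sd, isotropic; the
second species' center shifted by 0.5): smooth, unimodal, and exactly
representable by quadratic features, giving a clean recovery benchmark.
Occurrences are drawn with probability proportional to true suitability,
placed uniformly within their cell, then contaminated with 10% exact
duplicates and 10% coordinate-rounded low-precision records — the
artifacts the cleaning cascade removes. Pseudo-GCM futures shift every
latent gradient along the equal-weight direction by
`rcp_shift × period_multiplier` (0.25/0.50/0.75/1.00 latent sd for
RCP 2.6/4.5/6.0/8.5; multipliers 1.0 for 2050, 1.5 for 2070) plus smooth
GCM-specific perturbations (amplitude 0.15) from per-GCM subseeds, and mix
through the *same* observation model as the present stack — 9 GCMs × 4
RCPs × 2 periods = 72 stacks.

What the world does *not* emulate: real marginal distributions or units of
bioclimatic variables, GCM physics, spatial sampling bias, or detection
error. Passing tests therefore demonstrate that the machinery is correct
and well-calibrated under a known smooth unimodal niche, not that any
particular real-world map is right.

## Problem sizes and determinism

The default study conditions are a 100×120 grid, 400 occurrences per
species, 10 bootstrap replicates, 10 000 background cells, 1000 pROC
iterations and 100 overlap replicates; the discrimination study for the
similarity test uses a 60×70 world with 50 replicates over 20 seeds, and
the end-to-end determinism check runs the full 72-combination pipeline at
48×60. Every random draw descends from one master seed through named
`SeedSequence` spawns, so a configuration + seed pair reproduces every
output bit-for-bit; subseeds stay below 2³¹.

## Known limitations

- The latitude-band accessible area is judged by cell centers; regions
  narrower than a cell can select no cells.
- The rectangular novelty rule is conservative: a cell barely outside one
  layer's training range is zeroed even if all other layers are typical.
- The E-threshold is defined on calibration-point suitabilities only; with
  very few points τ is coarse.
- The background similarity test fits one model per replicate; at 100
  replicates per direction this dominates pipeline runtime.
- p-values from the pROC bootstrap are granular at 1/n_iterations; report
  them with n.
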