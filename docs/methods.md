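# Methods

This note records the modelling choices in `pollmap`, their defaults, and
what the synthetic experiments do and do not demonstrate.

## Data model

All layers live on one projected planar grid of square cells (default
1 km²), indexed `(row, col)` with half-open cell intervals
`[x, x+1) × [y, y+1)`, so every point belongs to exactly one cell and
re-gridding cell centres is idempotent. Rasters are serialized as ESRI ASCII
grids at float32 precision with nodata −9999; the package neither reprojects
nor aligns grids — inputs must share one grid, and mismatches are rejected
naming both layers.

## Occurrence processing

Records with spatial accuracy coarser than 1000 m are dropped; within a cell
only one record of a species counts ("records" vs "occurrences"). A species'
spatial extent is summarized by the longest pairwise distance within the
third quartile of all pairwise occurrence distances — the third rather than
the fourth quartile so isolated outlying records do not inflate the extent.
Percentiles everywhere in the package use linear interpolation between order
statistics (numpy's default); this convention matters and is deliberately
uniform across the Q3 distance, the training-presence threshold, and the
honey-bee absence cut-off.

Calibration species are chosen by Ward-linkage agglomerative clustering
(Euclidean distance on z-scored occurrence count, bounding-box coordinates
and Q3 distance; 4 clusters by default — the cluster count is configuration,
not doctrine), taking ceil(1/3 of each cluster) with round-robin selection
across genera. Modified prevalence: commonality is the geometric mean of
min-max-normalized record count, occurrence count and years-with-records;
species are quintile-binned by commonality rank onto τ ∈ {0.1, …, 0.5}
(ties share a bin, so the mapping is permutation-equivariant). This mapping
uses exactly the three commonality quantities but is otherwise a design
choice; any explicit species→τ table can be supplied instead.

## Bioclim derivation

Monthly mean temperature is (tmin+tmax)/2 (the standard bioclim
convention). Quarters are all 12 circular 3-month windows, so Dec–Jan–Feb is
admissible and relabelling months leaves outputs unchanged. Isothermality is
100·MDR/TAR, which lies in (0, 100] for 12-month data because the mean of
monthly ranges cannot exceed the overall range; a cell with TAR = 0 gets
nodata with a warning. Precipitation seasonality uses the sample standard
deviation (ddof = 1). Collinearity reduction is the backward Jolliffe
variant: discard the variable loading most heavily on the last principal
component while the smallest correlation-matrix eigenvalue is below 0.70,
then screen remaining pairs at |r| > 0.7, dropping the member with the
larger mean absolute correlation. Both thresholds are configuration.

## MaxEnt core

The Gibbs distribution is fitted by minimizing the negative penalized
log-likelihood in the exact split-variable form (λ = u − v, u, v ≥ 0, L1
penalty β·(u+v)) with L-BFGS-B; convergence at penalized-likelihood
improvement < 1e-8 or 500 iterations, non-convergence returned flagged. The
fitted q is asserted to sum to 1 over the background to 1e-8 after every
fit. Default per-column regularization is β_j = β₀ · sd_j(background
features) / √n_presence with β₀ = 1 — a single global multiplier in the
spirit of published maxent practice, exposed in configuration rather than
the feature-class-specific tables of the original program.

Hinge features use 50 knots per layer (20 in the pipeline defaults, for
speed at desk scale) at equally spaced interior quantiles of the background
values; each knot contributes a forward and a reverse hinge, both scaled to
[0, 1]. Columns are clipped to [0, 1] for values outside the background
range. The minimum sample size is 12 presences.

The logistic output is the entropy-offset form
p = σ(logit τ + η + H): exact by construction at a typical site (η = −H,
p = τ), strictly increasing in η, and evaluated in log space so it cannot
overflow. τ defaults to 0.5 and is replaced by the species' modified
prevalence when profiles are available.

Cross-validation partitions presences uniformly at random into k = 10
near-equal folds (no stratification). Training AUC scores training
presences against the model's own background; test AUC scores held-out
presences against a freshly drawn background of the same size and origin —
re-drawing is the default because reusing the training background lets the
test set see fitted noise. Permutation importance permutes each source
predictor jointly across pooled presence + background rows, re-evaluates
without refitting, floors AUC drops at zero and normalizes to 100% (one
permutation per predictor per fold by default; both the count and the
flooring are configuration). With all drops zero the importance is spread
uniformly so it still sums to 100.

The null-model test fits models to uniformly random pseudo-records of equal
sample size and reports p = (1 + #{null ≥ observed})/(n_null + 1); with
n_null = 19 the α = 0.05 decision is exactly resolvable (observed must beat
every null), and below 19 a warning is raised. The TGB bias test compares
mean cross-validated AUC of models whose "presences" are draws from the
target-group cell pool against the 95th percentile of the same statistic
under uniform draws.

## Ensemble

Run surfaces are binarized at the 10th linear-interpolated percentile of
predictions at that run's training presences, comparing with ≥ so presences
at the threshold count as present. Under this convention the "≥ 90% of
training presences retained" guarantee is exact whenever the training-set
size is a multiple of 10 and can fall short by at most one presence
otherwise (e.g. 202/225 = 89.8%); the bundled experiments use k = 10 folds
on 100 presences, where it is exact. The consensus mask requires all k runs
by default (min_agree configurable; 9-of-10 is the shipped sensitivity
setting); the final map is the plain cellwise mean of all run surfaces
masked to the consensus area — masking after averaging, since per-run
absences are already encoded in the consensus.

## Service kernel

The service of a species to a crop cell is the exponentially
distance-weighted proportion of surrounding cells occupied by the species,
with the species' mean foraging distance a_s as e-folding scale. Cells of
zero suitability count in the denominator — the statistic is a proportion of
the local landscape, not a mean over occupied cells. The kernel is truncated
at 3·a_s: the exponential alone never reaches zero, and the truncation is
what produces the exact zeros that mark crop fields beyond foraging reach;
the factor 3 (where the weight has fallen to e⁻³ ≈ 5%) is configuration.
The implementation is a direct 2-D convolution, which matches a literal
double loop over (crop cell, map cell) to 1e-10 and preserves exact zeros
(no FFT). Default foraging distances for the field-bean pollinator set are
1 km, doubled to 2 km for the three wide-ranging *Bombus* species.

The managed honey-bee layer divides each 4 km² forager count by four into
its 1 km² children, min-max rescales to [0, 1], and zeroes cells below the
5th percentile of the nonzero scores (taken over nonzero rather than all
cells, since the zero mass would otherwise collapse the percentile). Wild
and managed surfaces are reported separately and never summed: one is a
probability of occurrence, the other a relative forager density.

## Synthetic data: what it emulates, what it does not

Landscapes are Gaussian random fields (white noise smoothed at a stated
length-scale, standardized to mean 0, variance 1; periodic boundary), the
simplest field with controllable spatial autocorrelation. Virtual species
combine per-layer Gaussian/ramp/flat responses multiplicatively and rescale
by the field maximum, so true suitability is in [0, 1] without clipping and
the occupied fraction against any threshold is known exactly. Occurrence
records are drawn cell-wise with replacement with probability ∝ suitability
× effort, jittered within the cell, with accuracy ≤ 1000 m — duplicates are
intended and exercise the deduplication stage. Recorder effort is uniform,
quadrant-concentrated, a spatial gradient, or proportional to
exp(strength · layer); the environment-correlated form is the regime in
which the TGB test has power, because an SDM sees only environmental
predictors and a purely spatial restriction of a periodic landscape carries
no environmental signal. Real recording schemes differ in ways not
emulated — temporal autocorrelation of visits, list-length effects,
detectability differences between species — so passing tests demonstrate
correctness of the machinery and statistical calibration under known bias,
not fidelity to any particular national recording scheme.

Default experiment sizes (15×15 to 25×25 grids, 120–800 background cells,
100–400 records per species, 19–20 null models) were chosen once as the
smallest landscapes on which the statistical behaviours of interest —
null-model calibration, the 1 − a/2 AUC ceiling, parameter recovery, bias
detection — are stable and readable.

## Known limitations

* No reprojection, no GeoTIFF (ASCII grids only), no cartography.
* The apiary→forager dispersal model is a testing aid (per-apiary
  exponential redistribution), not a calibrated forager model; real forager
  layers should be supplied as rasters.
* Land-cover and pesticide-risk layers are accepted as pre-built inputs,
  not derived.
* Product/threshold/categorical features get their basic expansion only.
* The prevalence mapping and Jolliffe thresholds are explicit, documented
  assumptions wherever the choice is genuinely open.
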