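# Methods

This note documents the models, defaults and numerical choices in
`climniche`, and what the synthetic-data generator does and does not emulate.

## Occurrence handling

Records are read from delimited text (comma or tab) with columns `species`,
`lon`, `lat` and optional `year`, `source`; coordinates are WGS84 decimal
degrees. Rows with malformed or out-of-range coordinates are rejected with a
log entry; exact duplicate coordinates collapse to one record, keeping the
most recent year.

**Spatial thinning.** Records are ordered by year descending (unknown years
last, file order breaking ties — or pure file order with `prefer="first"`)
and scanned greedily: a record is kept iff it lies more than
`min_distance_km` (default 50 km) from every record already kept, by
great-circle distance on a sphere of radius 6371 km. The result is
deterministic, maximal under that order, idempotent, and every retained pair
is separated by more than the minimum distance. Because the rule is
order-sensitive among equal years, retained *counts* on real data can differ
by a record or two from other implementations of the same rule.

**Bias surface.** Collecting effort is estimated as a Gaussian-product
kernel density of the (deduplicated) record coordinates evaluated at cell
centers, in unprojected lon/lat degrees. Per-axis bandwidths follow the
normal-reference rule h = 4 · 1.06 · min(sd, IQR/1.34) · n^(−1/5) with kernel
standard deviation h/4 (the convention of the classic two-dimensional KDE
implementations); if the rule degenerates (records aligned on an axis) the
kernel falls back to one cell width. The surface is renormalized to sum to 1
over non-missing cells and background points (default n = 10 000) are drawn
from it with replacement at cell centers, so the model contrasts presences
against effort, not area.

## Maximum-entropy model

Variables are min–max scaled to [0, 1] by their background range (constant
variables scale to 0 and contribute no nonlinear features). Feature classes:
L (identity), Q (square), P (all pairwise products), H (forward and reverse
hinges) and T (step indicators), with hinge/threshold knots evenly spaced
strictly inside (0, 1); the default is 50 knots per variable, reduced to 8 in
the packaged desk-scale experiments (see *Problem sizes* below).

Coefficients maximize
(1/m) Σ_pres η − log Σ_bg e^η − Σ_j β_j |λ_j| with
β_j = rm · base(class, m) · max(sd_j(presence features), 10⁻³), where the
class bases are 0.5 (hinge), 1.0 (threshold) and an interpolation over
presence counts m ∈ {0, 10, 30, 100} → {1, 1, 0.2, 0.05} for
linear/quadratic/product. (Some MaxEnt implementations additionally divide
by √m; the construction here keeps the stated product form throughout, so
multipliers are comparable across this package's own runs.)

The objective is concave. It is solved by accelerated proximal gradient
(FISTA) with backtracking line search and function-value restarts
(soft-threshold prox, λ₀ = 0, relative-objective tolerance 10⁻⁷, iteration
cap 5 000), then polished by an active-set damped-Newton refinement with KKT
screening: on the current support the penalty is smooth, Newton steps
converge quadratically, coefficients that cross zero are pruned, and
excluded features violating |∂f/∂λ_j| ≤ β_j are admitted between rounds.
The polished solutions agree with a generic bound-constrained convex solver
(split λ = a − b) to ~10⁻¹⁰ in the tests — far inside the 10⁻⁴ documented
contract — and carry exact zeros, which matters because AICc counts nonzero
coefficients.

Prediction scales: `raw` = e^{η − log Z} with Z the sum over the *training*
background (so raw sums to 1 there and is invariant to duplicating
background rows), and `cloglog` = 1 − exp(−e^H · raw) with H the entropy of
the fitted raw distribution. A fully shrunk model therefore outputs
1 − e⁻¹ ≈ 0.6321 everywhere, a useful analytic fingerprint. Projection onto
a layer stack clamps scaled features to the training [0, 1] range by default
and logs how many cells extrapolated.

**Variable importance.** Percent contribution allocates |λ_j| · sd_j
(background features) to each feature's variable (products split evenly) and
normalizes to 100 — a coefficient-magnitude allocation, deliberately simpler
than the path-dependent accounting of the original MaxEnt implementation,
which depends on the optimizer trajectory. Permutation importance permutes
one variable across presences + background (single permutation, fixed seed)
and normalizes the non-negative training-AUC drops to 100. Variables with
either measure ≥ 10% carry a "highly contributing" flag.

## Evaluation and selection

**Replicates.** "Bootstrap" replicates hold out a random 25% of presences as
test and resample the remaining pool with replacement to its own size for
training; 10 replicates by default, all driven by one seed.

**Thresholds and omission.** The maxSSS threshold maximizes sensitivity
(training presences ≥ t) plus specificity (background < t) over the union of
observed scores, taking the smallest threshold among maximizers (with a
10⁻¹² tolerance so float noise cannot flip a tie). Test omission is the
fraction of test presences below the threshold; rates above 0.1 carry an
overfitting flag. Candidate configurations are ranked lexicographically:
lowest mean test omission, then smallest mean |train − test| AUC gap, then
highest mean test AUC.

**Partial ROC.** The curve plots sensitivity against the proportion of
background scoring at or above each threshold. The integration region — the
thresholds where the full test set's omission is ≤ E (default 0.05) — is
fixed once from the observed curve; each of 500 iterations then resamples
half the test presences *without replacement* and computes the ratio of the
resampled curve's area to the chance diagonal's over that region; the
p-value is the share of ratios ≤ 1. Two choices here are deliberate and
differ from some field tools: a per-resample region conditions on the
resampled curve being high and biases the null ratio upward, and a half-size
bootstrap *with* replacement doubles the statistic's variance relative to
its sampling distribution, making the p-values conservative. With the fixed
region and without-replacement half-samples (whose variance matches the
full-sample statistic — the classic subsampling argument), the null
p-values are approximately uniform at moderate sizes (verified over 200 null
datasets of 400 presences / 2 000 background). The bootstrap flavor remains
available via `replace=True`.

**AICc.** Raw predictions are renormalized over all complete cells of the
study grid (not the background sample); lnL is the sum of log probabilities
at the occurrence cells; k counts nonzero coefficients; AICc = 2k − 2 lnL +
2k(k+1)/(n−k−1), invalid (excluded from comparisons) when k ≥ n − 1. The
tuning loop fits all class-set × multiplier combinations (36 by default) and
marks the per-class and overall minima.

**Variable selection.** Iterative filtering to a fixed point: fit a
reference model (LQ, rm = 1 by default), drop variables contributing less
than 5%, and among pairs with |r| ≥ 0.9 drop the lower-contribution member;
then run the full AICc tuning on the survivors. Both thresholds are
configurable (the correlation flag threshold is configurable precisely
because published conventions vary between 0.8 and 0.9).

## Areas and regions

Cell areas are analytic on the R = 6371 km sphere, A = R²·Δλ·(sin φ_top −
sin φ_bot); a global 5-arc-minute grid sums to 4πR² to ~10⁻¹³ relative
error. Cells are assigned by center with half-open boundaries: center lon <
60° E is Europe, otherwise Asia (so europe + asia = total exactly); center
lat ≥ 66.562° N is polar. Suitability maps for area accounting are the mean
of the per-replicate projections, thresholded at the mean per-replicate
maxSSS threshold. The analytic route replaces GIS raster calculation; at
5-arc-minute resolution the two agree to well under the precision at which
such areas are usually reported.

## Niche differentiation

PCA is computed from the correlation matrix (variables standardized), since
bioclimatic variables mix °C and mm; loadings carry a deterministic sign
(largest-magnitude entry positive). The broken-stick rule retains the
leading run of components whose variance proportion exceeds
b_k = (1/p) Σ_{i=k}^p 1/i. ANOVA and Tukey HSD run per retained component;
non-significant components are reported, not hidden, and pair significance
is flagged at p < 0.001.

Subset selection enumerates all variable subsets exactly; the condition
number of the standardized column matrix is computed from the eigenvalues of
the subset's correlation matrix (κ = √(λ_max/λ_min)), and VIFs as the
diagonal of its inverse — both algebraically identical to the regression
definitions but thousands of times cheaper, which keeps the full 2¹⁹ − 1
enumeration feasible. Exactly collinear subsets have infinite κ and can
never be selected. The final set is the largest size whose best subset
passes VIF ≤ 10.

The pair classifier minimizes mean log-loss + λ_pen‖w‖² (intercept
unpenalized) with λ_pen chosen from 100 evenly spaced values on
[0.001, 0.5] by mean out-of-fold ROC-AUC over 5 stratified folds; the 80/20
split is stratified by species. (Internally this maps to the scikit-learn
parameterization via C = 1/(2nλ_pen).) "Larger λ_pen = stronger shrinkage"
is the adopted reading of the penalty grid; the grid itself is configurable.
For a linear model the Shapley values under a mean-imputation value function
have the closed form φ_ij = w_j (z_ij − ref_j), which satisfies local
accuracy exactly and matches exhaustive coalition enumeration to machine
precision; partial-dependence curves sweep one variable over a grid while
averaging predictions over the data.

## Synthetic data

The generator emulates the *shapes* of the real inputs, not their physics.
Each variable is a planar gradient plus smooth noise: white noise smoothed
by a separable moving average (correlation length 8 cells), standardized,
then linearly mixed through the matrix square root of a target correlation
matrix (default AR(1)-style, ρ = 0.6 between adjacent variable indices).
Defaults split variables 11:8 into temperature-like (cooling poleward, 0.5
units/degree, noise amplitude 2) and precipitation-like (drying eastward, 5
units/degree, amplitude 60), echoing the bio1–bio19 family. The default grid
(100 × 100 cells, 0.25°, 40–65° E × 50–75° N) deliberately straddles the
Ural meridian and the Arctic Circle so regional accounting is exercised.
"Periods" are additive offsets (e.g. +2 on temperature-like variables) —
uniform shifts, not GCM fields.

Virtual species have Gaussian (bell) responses on named driver variables —
suitability = Π_v exp(−(z_v − μ_v)²/2σ_v²) — so both "too cold" and "too
hot" limits exist; a rising logistic response is available. Presences are
drawn with probability ∝ suitability × collecting bias, at cell centers with
sub-cell jitter and random years, and every species carries a truth record
(drivers, cutoff, true occupied area).

**The recovery scenario** (`synthetic.recovery_scenario`) is the package's
standard validation problem: 6 variables, one latitudinal and one
longitudinal driver with tolerance 0.25 grid standard deviations (the
species occupies roughly 15% of the grid — a localized optimum; wider
niches make the problem information-limited, with the *true* suitability's
AUC falling below 0.9), 200 presences under uniform effort, 2 000 uniform
background points. Its truth cutoff is the grid-mean suitability: under
suitability-proportional sampling against uniform background, that is the
population optimum of the sensitivity-plus-specificity rule, which makes the
maxSSS-thresholded model area directly comparable to the true occupied area.

**What passing these tests does and does not show.** The synthetic surfaces
are stationary, the niches are exactly Gaussian in the measured variables,
sampling bias is known, and scenario change is a uniform offset. Real
occurrence data violate all four (detection varies, niches involve
unmeasured factors, effort is unknown, climate change is spatially
structured), so recovery here validates the *machinery* — optimization,
thresholds, area arithmetic, selection logic — not the ecological fidelity
of any particular real-data model.

## Problem sizes

The packaged experiments are sized for a single CPU: the recovery scenario
uses 6 variables and 8 hinge/threshold knots (so the 10-seed × 36-combination
tuning study completes in well under a minute), the partial-ROC null
calibration uses 200 datasets of 400 presences / 2 000 background, and the
exhaustive subset-selection oracle comparisons run at p ≤ 8 (255 subsets;
the implementation itself handles p = 19). Generator defaults
(`make_climate_stack`) remain 19 variables and 50 knots in the modeling
layer.

## Known limitations

- Percent contribution is a coefficient-magnitude allocation, not the
  original tool's path accounting; numbers are comparable within this
  package, not across tools.
- The thinning rule's retained counts are order-sensitive among equal years.
- No categorical features, no GeoTIFF reader (ESRI ASCII is the canonical
  format), no reprojection or resampling between resolutions.
- The partial ROC test is calibrated in its default (fixed-region,
  subsampling) form at moderate test sizes; at very small test sizes
  (< ~100 presences) the sensitivity curve's granularity still biases the
  ratio upward, as it does in all implementations of this statistic.
- Bootstrap-replicate training resamples can drop records; this is the
  intended semantics of the replicate design, not a bug.
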