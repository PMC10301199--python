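# Methods

## The estimation problem

Presence-only records tell us where a species was found, not where it
was absent. The maximum-entropy approach treats the species'
distribution as an unknown probability distribution over the cells of
an accessible region and picks, among all distributions whose feature
expectations match the presence sample, the one closest to uniform.
Equivalently (the formulation implemented here) it fits a Gibbs
density q(x) ∝ exp(η·f(x)) over the background cells by maximizing the
penalized presence log-likelihood

    ℓ(η) = (1/m) Σᵢ η·f(xᵢ) − log Σ_b exp(η·f(b)) + log N − Σⱼ βⱼ|ηⱼ|.

ℓ(0) = 0, so ℓ(η̂) is the regularized training gain and is always
non-negative. With the penalty at zero and linear features the
optimum satisfies exact moment matching: E_q[fⱼ] equals the presence
mean of fⱼ (a test asserts this to 1e-4).

Assumptions worth keeping in mind: presences are an unbiased sample of
occupied cells within the background region; the background sample
represents available environment; features capture the response shape
(only linear, quadratic and product classes exist here — no hinge or
threshold features, so sharply stepped responses are approximated by
smooth ones).

## Regularization

βⱼ = RM · sⱼ/√m, where sⱼ is the presence-sample standard deviation of
feature j (floored at 1e-4) and RM is the regularization multiplier
from the candidate grid (1–10). This single rule is applied to every
feature class. The canonical Maxent implementation instead
interpolates class-specific tuning tables from empirical studies; the
single rule preserves the multiplier's role (larger RM → sparser,
smoother models; a property test checks the nonzero count is
non-increasing in RM) while remaining fully documented and
reproducible. Coefficient counts and AICc values are therefore not
numerically interchangeable with those of other Maxent
implementations.

## Optimization

The objective is convex. Fits run deterministic FISTA (proximal
gradient with soft-thresholding and adaptive restart, backtracking
Lipschitz estimate), then an L-BFGS-B polish on the split form
η = η⁺ − η⁻ (where the penalty is linear), then one exact proximal
step so that inactive coefficients are hard zeros — the parameter
count k used by AICc needs exact zeros, not small residuals.
Convergence is declared when the proximal-gradient residual falls
below `tol` (default 1e-7, sup-norm); non-convergence raises an error
carrying the last iterate and residual. No stochastic steps anywhere:
identical inputs give bit-identical fits.

## Outputs

Raw output is q itself (sums to 1 over the fitting background).
Logistic output is L = τe^H·raw/(1 + τe^H·raw) with H the entropy of q
and τ = 0.5 the default prevalence, giving values in (0, 1) with the
conventional interpretation that a cell with "typical" presence
conditions scores about 0.5. Projection onto scenario layers rebuilds
features with the stored background min-max scaling; with clamping on
(default) scaled features are truncated to [0, 1], so projections
never extrapolate a feature beyond its calibration range — range-edge
conditions get range-edge suitability.

## Selection statistics

**Partial ROC.** Thresholds sweep the distinct background
suitabilities; sensitivity (fraction of test presences at/above) is
plotted against proportional predicted area (fraction of background
at/above), the curve is restricted to sensitivity ≥ 1 − E/100, and the
AUC ratio divides the restricted trapezoidal area by the area of the
1:1 line over the same interval. The crossing point of the
sensitivity limit is linearly interpolated; without that the discrete
restricted curve systematically over-covers the null line and the test
rejects far too often. Bootstrap: 500 resamples of half the test
points; p = fraction of bootstrap ratios ≤ 1. The statistic retains a
small positive bias that shrinks with test-set size (a selection
effect: thresholds enter the restricted region exactly when their
empirical sensitivity fluctuates high), so the type-I calibration
check runs at 300 test presences, where the empirical rejection rate
sits near the nominal 5%.

**Omission.** The least-training-presence threshold at error level E
is the largest threshold keeping ≥ (100−E)% of calibration
suitabilities at/above it (computed by exhaustive scan over observed
values; E = 0 gives the training minimum). Omission of the test set
uses strict inequality (below threshold = omitted). Because the
threshold is tuned to sit at E% training omission, test omission
concentrates near E% — on unlucky splits every candidate can exceed
the nominal 5% cut. The sweep therefore relaxes, with a logged
warning, to the minimum observed omission among significant candidates
when the strict cut empties the selection; this mirrors the behaviour
of the kuenm model evaluator and matches how published best models can
report omission slightly above the cut.

**AICc.** lnL = Σᵢ log raw(xᵢ) with raw renormalized over the
background; k counts nonzero coefficients; AICc is undefined (and the
candidate invalid) when m − k − 1 ≤ 0. ΔAICc is computed within the
significant, low-omission subset, not across all candidates, following
the two-stage ordering (significance first, information criterion
second). Ties at ΔAICc ≤ 2 are all kept; the lowest-AICc one is
marked primary.

## Preprocessing

Thinning is the randomized-greedy maximum-independent-set heuristic of
the spThin family: repeatedly delete one random record among those
with the most neighbours closer than the minimum distance (5 km
default, haversine with R = 6371.0088 km), restart with independent
substreams (100 by default), keep the largest survivor set. On small
instances an exhaustive bitmask search provides the optimum; the
heuristic matches it on ≥ 95% of random 10-point instances.

The accessible region M is the union of whole ecoregion polygons
intersecting the dissolved 100-km buffers around occurrences (buffers
are 64-vertex circles with local degree scaling). Whole-polygon
inclusion (rather than clipping to the buffers) follows the standard
reading of the buffer-overlay construction. The 70/30
calibration/test split is a single uniform random partition.

## Variable sets

Set1 and Set2 are configured lists (for bioclim-named stacks the
shipped defaults are the 15-variable list after dropping the four
anomalous layers Bio8/9/18/19, and a 9-variable literature list; for
synthetic stacks they default to the full list and its first half).
Set3 ranks variables by jackknife contribution — each variable's
single-variable regularized gain, normalized to sum to 100 — takes the
smallest prefix exceeding 90% cumulative contribution, then prunes
pairs with |Pearson r| ≥ 0.8 (contribution as the tie-break; the
pruning runs after the cut). Set4 drops the largest-VIF variable
until max VIF ≤ 10. Correlation and VIF use the background sample of
M cells.

## Synthetic worlds

The generator emulates what the pipeline needs from real geodata, at
desk scale: a 120×120-cell grid over a 3°×3° extent (cells in the same
1-km size class as real bioclim products), 8 layers by default.
Layers are Gaussian white noise smoothed with a Gaussian kernel
(σ = 8 cells), empirically whitened across layers and then mixed to a
target correlation matrix — whitening first, because smoothing leaves
few effective degrees of freedom and chance correlations would
otherwise swamp the target. Truth is a logistic of a sparse linear
predictor on z-scored layers (defaults: +1.5 on env1, −1.0 on env2,
six noise layers) with the intercept solved so mean suitability is
0.2 — a realistic regional prevalence. Presences sample cells without
replacement with probability proportional to truth, at cell centers
("unique occurrence sites"; no observation error in v1). Futures are
additive per-layer shifts (default +1 standardized unit on the two
informative layers — a strong but plausible climate signal).
Ecoregions are a rectangular tiling (k = 9) and migration routes are
jittered south-north polylines.

What the synthetic world does *not* emulate: sampling bias, coordinate
error, spatially structured absence of effort, non-additive climate
change, irregular ecoregion shapes, and nodata structure. Passing
recovery tests therefore demonstrates correctness of the machinery,
not robustness to the observational pathologies of real occurrence
data.

## Scenario products and overlay

One threshold — derived from current-period suitability at the
calibration occurrences — binarizes every scenario of a run. Change
between two binary maps is reported as conserved = |A∩B|,
gained = |B\A|, lost = |A\B| pixels. Published percentage conventions
for these quantities are often ambiguous, so the summary defines its
bases explicitly (union for conserved, current area for gained and
lost) and always carries the raw counts and denominators so any
convention can be recomputed. Between-scenario variation is the
binomial variance p̂(1−p̂) of per-cell presence across scenarios,
classed low/medium/high by equal intervals on [0, 0.25].

Risk classes cut suitability at (0.15, 0.385, 0.525, 0.86): the
published class ranges (0.15–0.38, 0.39–0.52, 0.53–0.86) leave gaps
between printed bounds, so the interior boundaries sit at the
midpoints of the touching ranges, making the classification a true
partition; values above the top break clamp into "high" with a
warning. Routes are buffered to 10-km-half-width corridors (a bare
polyline would intersect almost no 1-km cells); cells are assigned by
center-in-polygon, and each route reports per-class tallies plus both
the modal and the maximal non-outside class (ties to the higher
risk).

## Problem sizes and numerical choices

Defaults chosen for minutes-scale runs: background capped at a seeded
uniform sample of 10,000 cells (5,000 in the pipeline harness),
partial-ROC bootstrap 500 (200 in the sweep), 10 final-model
replicates, fit tolerance 1e-6 in sweeps and 1e-7 for single fits.
The end-to-end harness runs three variable sets (the configured full
list, Set3 and Set4) × RM {1, 2, 5} × classes {l, lq, lqp} — a
representative 27-candidate slice of the full 280-candidate grid,
which remains available by passing explicit grids. Degenerate inputs
are handled explicitly: constant features are dropped before fitting,
constant variables before pruning, perfect collinearity gives infinite
VIF and is eliminated first, and an all-constant suitability surface
raises a degenerate-curve error rather than a silent ROC.

## Known limitations

- The simplified β rule means coefficient paths, parameter counts and
  AICc values differ from table-tuned Maxent implementations.
- No hinge/threshold/categorical features; no cloglog output.
- Geometry is geographic (WGS84) throughout: buffers and corridors use
  local-degree approximations, adequate at regional scale and mid
  latitudes, not near the poles.
- The omission-cut relaxation keeps calibration runs from dying on
  unlucky splits but means a reported "selected" model can carry test
  omission slightly above the nominal cut (always visible in the
  results table).
- Percentages in range-change tables depend on the declared bases;
  compare against other software via the raw pixel counts.
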