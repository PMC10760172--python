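# Methods

This note documents the models and procedures nichekit implements, the
numerical choices behind them, what the synthetic study system does and
does not emulate, and the package's known limitations.

## Occurrence preparation

**Checklist filtering.** Semi-structured citizen-science checklists vary in
effort, and the standard hygiene for presence-only modelling is to restrict
to comparable surveys. The default `FilterConfig` keeps Stationary and
Traveling protocols, duration strictly under 360 minutes, distance
travelled strictly under 10 km, start times from 06:00 to 21:00 inclusive,
at most 10 observers, complete checklists only, June–July records from
2010–2023, inside the north-east Pacific extent 175–114°W, 31–62°N. The
duration and distance bounds are exclusive and the observer bound inclusive
because that is how the thresholds are conventionally stated; boundary
records (duration exactly 360) are rejected. Each dropped row is attributed
to its *first* failing criterion in the fixed order protocol, duration,
distance, time, observers, completeness, month, year, bbox — the order
affects only the rejection bookkeeping, never the retained set. Outlier
removal is supported only as an explicit id blacklist; no automatic rule is
guessed.

**Spatial thinning.** Sampling density mirrors observer density, so records
are pruned until every retained pair is at least `min_distance` apart
(default 0.5 km). Although the procedure is often described as a thinning
*grid*, distance-based thinning dominates grid thinning (any grid-feasible
set is distance-feasible at the grid spacing) and matches the behaviour of
the standard thinning tools, so the distance rule is the implementation; a
planar-Euclidean metric is available for synthetic km-unit grids.
Great-circle distances use the haversine form with mean Earth radius
6371.0088 km; candidate conflicts are found with a KD-tree on 3-D
chord coordinates, which is exact for the great-circle threshold because
chord length is strictly monotone in arc length. The maximum-retention
problem is NP-hard in general (maximum independent set on the conflict
graph), so the solver is a randomized greedy heuristic — repeatedly delete
a point with the most conflicting neighbours, ties broken uniformly at
random — repeated `n_repeats` times keeping the largest result. On small
instances (≤ 15 points) the tests verify it attains the brute-force
optimum; the ≥ `min_distance` guarantee is asserted on every output.

**Balancing and background.** Groups are downsampled independently and
uniformly without replacement to a common size (1,500 at study scale). The
background is a uniform subsample (10,000 at study scale) of the
*all-species* occurrence pool: because that pool was collected by the same
survey process, its spatial density carries the same effort bias as the
focal groups, and contrasting presences against it cancels effort bias to
first order (the target-group background device).

## Variable selection

The variance inflation factor of variable j is VIF_j = 1/(1 − R²_j), with
R²_j from OLS of j on the other continuous variables plus an intercept;
R² ≥ 1 − 1e−12 is reported as +inf (exact collinearity). Two screens are
provided: *stepwise* (drop the largest VIF while it exceeds the threshold,
default 10, recomputing after each drop) and *pairwise* (while any
|Pearson r| exceeds the threshold, default 0.9, drop the pair member with
the larger VIF). Ties break alphabetically so reports are reproducible.
When both are requested the retained set is their intersection, with each
pure result still available. Categorical variables are excluded from VIF
arithmetic — linear VIF is undefined for unordered class codes — but are
always carried into the model. VIF is scale-invariant, so columns are not
standardized.

## The maximum-entropy model

Features are built from the pooled presence+background sample: continuous
variables are min-max scaled to [0,1] and expanded into the requested
classes (linear; quadratic = square of the scaled value; optional products
and hinges with knots at presence-value quantiles); categorical variables
become one-hot indicators. Out-of-range values at prediction time are
clamped to the training interval.

The fit maximizes J(λ) = (1/m) Σ_presence λ·f − log Σ_background exp(λ·f)
− Σ_j β_j|λ_j| with β_j = β·s_j/√m, where s_j is the feature's presence
standard deviation (floored at 1e−3 so no feature is accidentally
penalty-free) and β defaults to 1. The default feature set is
linear + quadratic + indicators — rich enough for the Gaussian niches of
the synthetic system while keeping the optimum cheaply verifiable against
a generic convex solver; hinge features are off by default.

The optimizer is cyclic coordinate ascent: for each coordinate a quadratic
approximation (gradient b_j − E_q[f_j], curvature Var_q[f_j]) gives a
soft-threshold step, which is backtracked (halved up to 40 times) against
the *exact* objective and rejected if it cannot improve it, so the
penalized gain is non-decreasing by construction. Convergence is declared
when a full sweep improves the objective by less than `tol` (default
1e−7); a model that exhausts `max_iter` is returned flagged
`converged=False`. Each accepted update's gain increment is recorded
against the updated feature's source variable; *percent contribution* is
the normalized sum of positive increments per variable. This accounting is
path-dependent (it depends on the update order), which is inherent to the
measure as conventionally defined, and it is therefore reported alongside
the path-independent *permutation importance*: the AUC drop after shuffling
a variable's values across all presence+background rows and recomputing its
features with the frozen scaling constants, floored at zero and normalized
to 100%.

Predictions: `raw` is exp(λ·f)/Z with Z fixed by the training background —
it sums to 1 over the background and is the operand of the overlap
statistics; `cloglog` is 1 − exp(−e^H · raw) with H the entropy of the
fitted background distribution, a strictly monotone rescaling used for
mapping and response curves. Response curves vary one variable over its
observed range (class set if categorical) holding other continuous
variables at their presence mean and categorical ones at their presence
mode; bands are normal-theory 95% intervals over replicate models.

Validation is replicated random subsampling, not disjoint k-fold: 10
replicates of an 80/20 presence split, background never split, AUC of
held-out presences against the full background. AUC is the rank statistic
(Mann–Whitney with mid-rank ties), so it is invariant under monotone
transforms of the scores; 0.7 is used as the conventional reliability bar.

## Overlap statistics

Suitability surfaces are renormalized to probability distributions over the
*intersection* of the two models' valid cells before comparison, since the
statistics are defined over a common space. D = 1 − ½Σ|p_X − p_Y|,
H = √(Σ(√p_X − √p_Y)²), I = 1 − H²/2 (equivalently the Bhattacharyya
coefficient Σ√(p_X p_Y)). The canonical square-root forms are used; they
yield the provable ordering D ≤ I (total variation ≥ H²/2), checked
property-style on random distribution pairs. Overlap always consumes the
raw (normalized) model output, never cloglog.

## Permutation tests

Both tests share one engine. The observed statistic pair (D, I) comes from
models fitted to the two groups against a shared background; each null
replicate re-partitions the pooled occurrences into pseudo-groups of the
original sizes, re-extracts their environments, refits both models with
identical settings and the same background, and recomputes D and I — the
nulls must vary with the relabeling, not merely resample fixed predictions.
Holding the background fixed across observed and null fits isolates the
occurrence-label effect. The *identity* test partitions uniformly at
random; the *blob range-breaking* test picks one pooled point as origin and
assigns the |A| nearest points (great-circle or planar per configuration,
ties broken by point id) to pseudo-A, producing spatially contiguous
pseudo-ranges. p-values use the add-one convention
p = (1 + #{null ≤ observed})/(n_iter + 1), ties counting toward the tail,
so p ∈ [1/(n_iter+1), 1]; the observed value is not inserted into its own
null beyond that correction. The lower tail is the divergence/boundary
direction, but both tails are always reported. A replicate whose model
fails to converge is redrawn once, then excluded with a reported count.
The default n_iter is 100 with α = 0.05; the test-bed and acceptance runs
use 99 replicates so the attainable minimum p is exactly 1/100.

## The synthetic study system

The generator produces what the analysis assumes and nothing more:

- **Landscapes** are standardized Gaussian random fields — white noise
  smoothed by a Gaussian kernel (`autocorr_length` cells, wrap-around
  boundary), then centered and scaled to unit variance — so layer units are
  standard deviations and the effective correlation length is of the order
  of the kernel bandwidth. Kernel smoothing was chosen over spectral
  synthesis for simplicity; it gives adequate autocorrelation control.
  Inter-layer correlation is induced by mixing the independent latent
  fields through an eigen-factor of the target correlation matrix; the
  achieved correlations are approximate by design (within ±0.05 at
  200×200 cells with short correlation lengths) and layers with different
  smoothing lengths blend their spectra when mixed. Categorical layers are
  quantile-thresholded latent fields, giving near-equal class areas.
- **Niches** are products of independent Gaussian responses per continuous
  layer times a weight per categorical class — no interactions, so the
  ground truth stays analytically checkable. Stock scenarios: `identical`
  (the null), `divergent` (optima `separation`·σ apart on one layer), and
  `three_group` (parents at ±separation/2 on layer 1, hybrid displaced on
  layer 2 — a transitional niche of its own, not an intermediate).
- **Occurrences** are multinomial draws over cells with probability
  proportional to suitability (conditioned on n, not an inhomogeneous
  Poisson process — downstream methods use only point locations), with
  optional uniform within-cell jitter.
- **Checklist metadata** attaches protocol, duration, distance, start
  time, observer count, completeness, and date to each record, planting a
  known, ledgered subset of violations of each filter criterion just
  outside its bound, so filter behaviour can be verified record-by-record.
- The **all-species pool** that feeds target-group background sampling is
  uniform over valid cells, i.e. effort is spatially unbiased in the
  synthetic system.

What this validates — and what it does not: passing tests show the
machinery is correct under spatially autocorrelated predictors, correlated
layers, Gaussian niches, and known metadata contamination. Real checklist
data add ingredients deliberately absent here: spatially *biased* effort
(the target-group device is carried through but exercised only under
unbiased effort), species misidentification, non-Gaussian and interacting
niche responses, temporal nonstationarity, and detection probability below
one. Results on the synthetic system bound correctness, not field
performance.

## Problem sizes and calibration choices

Simulation-based checks run at desk scale as the package's own test-bed
conditions: 40–50-cell square landscapes, 100–150 presences per group,
200–300 background points, 99 permutation replicates, coordinate-ascent
tolerance 1e−5 inside permutation replicates (1e−7 elsewhere). Type-I
error of the identity test is assessed over 200 same-niche simulations
(rejection rate at α = 0.05 expected in [0.01, 0.12] by binomial
tolerance) and power over 50 simulations at 4σ separation. The
"strongly informative" specialist niche used for AUC checks has breadth
0.2–0.5 layer-sd: against a uniform background, discrimination is governed
by niche breadth relative to landscape variance, not by the separation
between groups, and breadths near 1 sd cap achievable AUC near 0.8. The
monotone-power check (rejection frequency non-decreasing over 0, 2, 4σ)
runs 12 simulations per level in the module suite.

## Numerical details and degenerate inputs

- Exactly collinear variable sets: VIF reported as +inf; the stepwise
  screen drops one member (alphabetical tie-break) and recovers finite
  VIFs.
- A categorical variable with a single observed class contributes no
  indicator (warning), since the indicator would be constant.
- All-zero fitted models (heavy regularization) predict the uniform
  background distribution; percent contribution warns and reports zeros.
- Probability grids assert unit mass to 1e−9; suitability must be finite
  and nonnegative on unmasked cells.
- Cell assignment is floor((coord − origin)/cell_size): boundary points
  deterministically join the greater-coordinate cell.
- Per-stage seeds are (master ⊕ CRC-32(stage name)) mod 2³¹, so inserting
  a stage never perturbs another stage's randomness and every run is
  byte-reproducible from the master seed.

## Limitations

- The optimizer handles the default linear/quadratic/indicator feature
  sets well; very large hinge expansions would favour a specialized
  sequential-update implementation.
- Raster I/O is ESRI ASCII grid only; no GeoTIFF or CRS transformation —
  inputs must already be in WGS84 degrees (or a planar km grid).
- The blob test implements only the blob null; linear and ribbon
  range-breaking variants, and environment-space background/similarity
  tests, are out of scope.
- Percent contribution inherits the path-dependence of its definition;
  compare across models only with identical feature sets and update
  schedules.
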