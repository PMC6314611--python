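# Methods

This note documents the statistical procedures, parameter choices and
numerical conventions used throughout the package, and what validation
on synthetic data does and does not establish.

## Occurrence cleaning

Records arrive as lon/lat (WGS84 decimal degrees) with a
georeferencing uncertainty radius in meters. Cleaning runs in a fixed
order enforced by the pipeline driver:

1. rows with unparseable or out-of-range coordinates are dropped (count
   logged);
2. records lacking uncertainty or with uncertainty above
   `max_uncertainty_m` (default 10,000 m, matching a ~17 km modeling
   resolution) are removed — the boundary is inclusive, so exactly
   10,000 m is kept;
3. optional expert exclusion lists (supplied as data, never hard-coded)
   remove individually flagged records;
4. coordinate duplicates are dropped;
5. spatial rarefaction ("thinning") enforces a minimum great-circle
   separation (default 50 km; the synthetic demo uses 25 km because its
   grid spans only ~900 km);
6. the survivors are split randomly into equal calibration and
   evaluation halves (odd counts favor calibration).

**Thinning algorithm.** Greedy deletion: repeatedly remove the record
with the most neighbors closer than `min_km`, breaking ties by larger
summed inverse-distance crowding and then by later input position;
afterwards a re-add pass (input order) restores any removed record that
no longer conflicts. The re-add pass makes the result *maximal* — no
removed point could be re-added — which greedy deletion alone does not
guarantee. The procedure is fully deterministic. All great-circle
distances use the haversine formula with Earth radius 6,371.0088 km.

## Accessible area (M)

Model calibration is restricted to cells whose centers lie within
`buffer_deg` degrees of great-circle arc (default 7°, ~770 km) of any
occurrence, intersected with the raster validity mask and an optional
region mask. The buffer is spherical, not planar, so the km scale is
latitude-consistent.

## Maximum-entropy model

Variables are min–max scaled to [0, 1] using the background sample;
constant variables are excluded with a warning. Feature classes:
linear `x`, quadratic `x²`, pairwise products `x_i x_j`, threshold
steps `1[x > t]` at 10 evenly spaced knots per variable, and
forward/reverse hinges at 15 presence-quantile knots per variable
(both hinge arms rescaled to [0, 1]). Per-feature penalties follow the
published MaxEnt class defaults interpolated by presence count, scaled
by `s_j/√n` with the presence sd floored at 0.01 so features absent
from the presences stay penalized.

**Solver.** The penalized objective — convex in λ — is what defines
the model; no attempt is made to mirror any particular sequential
update scheme. Each coefficient is split into positive and negative
parts (λ = u − v, u, v ≥ 0), turning the L1 penalty into a linear term
under bound constraints, and the per-presence-scaled problem is solved
with L-BFGS-B (ftol 1e−15, gtol 1e−8, up to 4,000 iterations; 10,000
along regularization paths). Convergence is declared when the KKT
residual of the original L1 subdifferential falls below 1e−5 on the
per-presence scale; failures are logged and flagged on the model but
the fit is still returned and evaluated, since the selection stage
must see every candidate.

**Coefficient pruning and k.** With [0, 1]-scaled features the
per-presence penalties can be as small as ~1e−6, which leaves the
lasso active set numerically undetermined near zero: solver dust and
genuine micro-coefficients cannot be distinguished at the achievable
tolerance. Coefficients with |λ| ≤ 1e−3 are therefore pruned to exact
zero after fitting (each pruned feature moves the linear predictor by
at most 0.1%), normalizers are recomputed from the pruned vector, and
`k` — the AICc parameter count — counts the surviving nonzeros. Path
refits warm-start from the unpruned solution of the previous
multiplier (fitted in descending-penalty order), which keeps weakly
penalized fits well converged and the active-set count stable.

**Outputs.** Raw output is the density itself (summing to 1 over the
training background; verified to 1e−6 after every fit). Cloglog
output is `1 − exp(−e^H · raw)` with `H` the entropy of the fitted
background distribution; all downstream thresholding uses cloglog.
Projection clamps each variable into its training range before feature
expansion (cells affected are recorded in a clamped mask); raw scores
on projections remain normalized against the training background.

## Candidate evaluation and selection

Candidates are the Cartesian product of feature-class combinations,
regularization multipliers (a grid-spec parser handles range
expressions such as `0.1-1 by 0.1; 1-6 by 1; 8; 10`, deduplicating
overlapping endpoints → 17 values) and nested variable sets, evaluated
in a stable (variable set, combination, multiplier) order.

**Partial ROC.** The ROC curve plots sensitivity of the evaluation
records against fractional predicted area, sweeping thresholds over
the grid suitability values; the partial AUC integrates the region
with sensitivity ≥ 1 − E. Each of 500 iterations forms an AUC ratio
whose denominator is the partial AUC of a random-prediction sample of
the same size drawn i.i.d. from the grid suitabilities, over the same
clipped domain; the p-value is the fraction of ratios ≤ 1. Estimating
the null from matched-size draws (rather than the analytic diagonal)
makes numerator and denominator exchangeable under the null
hypothesis, so the test behaves as a Monte-Carlo rank test: in a
200-dataset null simulation the rejection rate at α = 0.05 measures
0.04–0.06 for evaluation sets of 30–90 points, while analytic-null
variants we piloted rejected 13–43% because the clipped-domain partial
AUC is a tail statistic whose finite-sample staircase bias has no
counterpart in the analytic reference. Setting `boot_frac < 1`
additionally subsamples the evaluation records per iteration (the
traditional construction; conservative). A constant suitability grid
has no ROC and is reported non-significant.

**Omission rate.** The threshold is the ⌈E·n⌉-th smallest calibration
suitability (E = 5% default); the omission rate is the fraction of
evaluation suitabilities strictly below it (ties retained). Note that
for a perfectly calibrated model the *expected* evaluation omission is
⌈E·n⌉/(n+1) ≈ E, so the ≤ E filter passes roughly half of all
well-specified candidates per split — strictness is inherent to the
protocol, not a defect (the original study retained 1% of its
candidates at this stage).

**AICc.** `ln L = Σ ln(raw_i / Σ_grid raw)` over the occurrence
records (calibration + evaluation by default, switchable), `k` =
nonzero coefficients, `AICc = 2k − 2 ln L + 2k(k+1)/(n−k−1)`,
with +∞ when `k ≥ n − 1` or any occurrence has zero raw score.

**Selection.** Three sequential filters: keep p < α (0.05); keep
omission ≤ 0.05; compute ΔAICc within the survivors and keep ΔAICc ≤ 2
(ties kept). An empty outcome at any stage produces an explicit
empty-selection report, never an exception, and is order-invariant.

## Variable sets

Variable contribution = drop in regularized training gain (mean
presence log-density relative to uniform, minus the per-presence
penalty) when the variable is left out and the model refit with
linear+quadratic features. The sequential reduction removes the
lowest-contribution variables (ties broken alphabetically; failed
refits rank lowest) down to each target size, recording strictly
nested snapshots. On synthetic data with two known response variables,
both survive to a final set of two in ≥ 90% of seeded replications.

## Final models, transfer, agreement

Selected configurations are refit on the full occurrence set as 10
bootstrap replicates (replicate seeds derived deterministically from
the master seed; bootstrap is switchable to plain refits). The
replicate-median cloglog surface is the estimate; max − min the
uncertainty surface. The E = 5% adjusted-training-presence threshold
is computed once from the consensus median at the calibration records
and reused for every epoch and GCM (which present-day surface anchors
the loss comparison is otherwise ambiguous). Per scenario, each GCM's
median transfer is binarized and compared with the present binary map:
gain = newly suitable, loss = no longer suitable; the agreement map
stores gain counts as classes 1–4 and loss counts as 5–8. Because both
comparisons use the same present map, a cell can never be gain and
loss at once; a precedence rule (gain wins, logged) guards
caller-mixed inputs. Scenario outputs are never pooled across RCPs.

## MOP extrapolation risk

Variables are standardized by calibration mean/sd; each projection
cell's distance is the mean Euclidean distance to its nearest
⌈f·n⌉ calibration cells (reference fraction f = 0.1 by default — the
source protocol does not state its percentage, so the value is
declared, not inferred). Similarity = 1 − distance/max distance; a
zero maximum (possible only for degenerate clouds or reference k = 1
on identical regions) is reported as similarity 1 everywhere. Strict
extrapolation is tested on the raw variable ranges, not the
standardized ones. Calibration clouds above 10,000 cells are
subsampled with a recorded seed; an exact mode covers testing. The
identity property (projection region = calibration region ⇒ similarity
≡ 1, empty strict mask) holds exactly at reference k = 1, where every
cell's nearest calibration cell is itself; at larger k the relative
rescaling necessarily spreads similarity over [0, 1].

## Synthetic study system

`generate_climate` builds each variable as Gaussian-filtered white
noise (kernel sd = `smoothness` cells; the filtered field is
normalized by its theoretical asymptotic sd `1/(2σ√π)` so the noise
term vanishes smoothly in the high-smoothness limit) blended with a
north–south gradient whose sign alternates between variables,
standardized to mean 0, sd 1, on a 1/6° (~10 arc-minute) grid. The
virtual species multiplies independent Gaussian responses
(`exp(−(x−opt)²/2b²)`) over 2 response variables and rescales to max
1. Occurrences are drawn with probability proportional to truth,
jittered uniformly within their cell, and tagged with lognormal
uncertainty radii (median 5,000 m, ~10% above 10,000 m, so the
uncertainty filter is exercised in both directions). Futures add a
scenario-wide mean shift per variable plus a smooth zero-mean
pseudo-GCM perturbation field (sd 0.3, shared across scenarios within
a GCM), giving 4 GCM × 2 scenario transfer stacks in the demo.

What the generator does *not* emulate: real bioclim covariance
structure, anisotropic spatial autocorrelation, sampling bias
correlated with accessibility, temporal nonstationarity, or any tick
biology (hosts, phenology). Passing tests therefore establish that the
pipeline's statistics behave as specified on data meeting the model's
assumptions — not that the model is adequate for any particular real
dataset.

**Demo study conditions.** 50×50 grid, 6 variables, species responding
to 2 of them (optima 0.5/−0.3, breadths 0.8), 1,000 occurrence
samples, 25 km thinning (~320 survivors, ~160 per half), variable sets
{6, 4}, 8 mid-complexity feature-class combinations × 3 multipliers ×
2 variable sets = 48 candidates, 2 pseudo-GCMs × 2 scenarios, 500
pROC iterations, 10 replicates. These sizes keep a full study around
20–30 s on one CPU. Because the omission filter passes a calibrated
candidate only about half the time per split (see above), the demo
protocol generates up to 5 independent synthetic studies from seeds
derived from the master seed and analyzes the first with a non-empty
selection; the attempt count is part of the run report. Measured over
10 master seeds, 70% of single studies succeed, and every successful
study selected the linear+quadratic configuration with truth-recovery
Spearman ρ ≥ 0.97 (occasionally a monotone linear±product
approximation wins instead, with lower but still substantial ρ).

## Determinism

Every stochastic stage (thinning tie-breaks, the half split,
background subsampling, pROC draws, bootstrap replicates, MOP
subsampling, synthetic generation) consumes a named substream fanned
out from the single master seed, so stages can be re-run in isolation
and a full rerun is byte-identical. Fixture data shipped with the
repository (`data/s1_occurrences_synthetic.csv`) are a synthetic
stand-in generated by the package's own sampler and 50 km thinning,
truncated to 181 records; the generating script is
`scripts/make_s1_standin.py`.

## Known limitations

- The solver flags (but does not reject) fits whose KKT residual
  misses 1e−5; this occurs for weakly penalized hinge-rich models
  whose conditioning is poor. Their suitability surfaces are accurate
  to far tighter than any downstream tolerance, but their `k` is less
  certain — such models are in practice eliminated by AICc.
- Active-set counts along a regularization path can jitter by ±1–2 on
  some datasets despite pruning; the monotone-path property is exact
  on the frozen validation dataset but not guaranteed universally
  (it is not a theorem of the lasso).
- No reprojection: all rasters must already be WGS84 lon/lat and
  co-registered.
- Categorical predictors and MESS-type similarity surfaces are out of
  scope.
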