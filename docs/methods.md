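# Methods

This note documents the models, algorithmic choices and synthetic-data
assumptions behind `cogmap`, in enough detail to reproduce or audit every
numerical decision.

## Batch self-organizing map

**Model.** Nodes live on an `grid_rows × grid_cols` lattice (default 8×8,
64 nodes, row-major indexing); node i carries a weight vector m_i with the
dimensionality of the assessment battery.  Inputs are used on their
original standardized scale (mean 100, SD 15); no feature standardization
is applied because all tasks already share a common scale.

**Initialization.** Kohonen-style linear initialization: node (r, c)
starts at `mean + a_r·√λ₁·u₁ + b_c·√λ₂·u₂`, with (λᵢ, uᵢ) the two leading
eigenpairs of the data covariance and a_r, b_c linearly spaced over
[−2, +2] (i.e. the grid spans ±2 SD along the two leading principal
components).  Eigenvector signs are fixed by making the largest-magnitude
component positive, so initialization is fully deterministic.  If the data
have rank < 2 the initialization falls back to the mean plus a seeded
jitter of magnitude 10⁻³ of each task's SD (with a warning); this is the
only place the SOM seed can matter.

**Training.** Classic batch updates: each cycle assigns every input to its
Best Matching Unit (Euclidean; ties broken toward the lowest row-major node
index, which makes training deterministic), then replaces each node's
weight by the mean of all inputs whose BMU lies within the current
neighbourhood radius of that node.  Nodes whose buffers are empty keep
their weights (the batch map is otherwise undefined for them).  Membership
is hard (boxcar), matching the buffer/neighbourhood-set formulation rather
than a Gaussian kernel.  The radius shrinks linearly,
`ND(t) = 1 + INS·(1 − t/n)`, evaluated at t = 1..n over the n ordering
cycles so the final ordering cycle uses radius exactly 1 (evaluating from
t = 0 would start at 1 + INS and never reach 1).  Fine-tuning cycles use
the neighbourhood {BMU only}, implemented as radius 0 — the same semantics
as "radius < 1" without a magic constant.

**Lattice.** Default rectangular topology with Chebyshev grid distance;
4-connected ("link", Manhattan) distance and a hexagonal lattice (odd-r
offset coordinates, axial distance) are available through the
configuration.  The rectangular/Chebyshev default makes every
neighbourhood set exactly enumerable in tests.

**Fit.** Quantization error = mean Euclidean distance between inputs and
their BMUs.  On study-sized synthetic cohorts (N = 616, 4 tasks) the 8×8
map lands around 8.3–8.7, i.e. roughly half a marginal SD in 4-D distance.

## Prediction validation

`knn_predict` ranks nodes by Euclidean distance in the observed-task
subspace and returns the inverse-distance-weighted mean of the k = 3
nearest nodes' target elements (w_i ∝ 1/d_i, so the closest node has the
highest weight; uniform and inverse-squared weightings are available).  If
a node matches the observed sub-vector exactly, the prediction is the
unweighted mean of the zero-distance nodes among the selected k.

Cross-validation holds out `floor(0.2·N)` participants per repetition
(independent seeded re-split each time), trains a fresh map on the rest,
and accumulates absolute errors per task.  Null distributions come from
shuffling the predicted scores against the true scores (100 shuffles per
repetition, pooled across repetitions).  All permutation p-values use the
add-one convention p = (1 + #{null ≤ observed})/(1 + B), so p is never 0
and small p means prediction beats chance.  The error-set comparison
between two cohorts permutes pooled group labels and uses the two-sided
statistic |mean(a) − mean(b)|; the pooled sample is canonicalized (sorted,
smaller group drawn first) so the result is exactly invariant under
swapping the groups.

Under a cohort with mutually independent tasks the per-repetition p is
uniform on its attainable grid; the empirical rejection rate at α = 0.05
sits inside the exact binomial band (verified in the acceptance suite at
300 participants × 50 repetitions × 100 shuffles).

## Component-plane similarity and change testing

Column k of the weight matrix is task k's component plane; plane-pair
Pearson correlations form the task-similarity matrix (clipped to [−1, 1],
diagonal exactly 1, symmetrized).  A constant plane is an error naming the
task rather than a silent NaN.

To test whether a pair's correlation changed between two maps, node
indices are drawn with replacement B = 10,000 times *within each map*
(jointly for the two tasks of a pair, preserving their pairing; node
identities do not correspond across separately trained maps, so indices
are never paired across maps).  Each map's resampling stream is keyed to a
digest of its own weight matrix, which makes the test exactly antisymmetric
under swapping the two maps and identically zero when a map is compared
with itself.  Resamples that produce a constant plane are redrawn (bounded
retries).  The default decision rule is two-sided at α = 0.05: reject when
zero falls outside the nearest-rank 2.5th–97.5th percentile interval of
the post-minus-pre differences.  The literal bottom-or-top-5% rule (a 10%
test) is available as `tail_rule="paper"`; the self-consistent two-sided
rule is the default.

Under a no-change null (two maps trained on independent cohorts from one
distribution) the empirical rejection rate is at or slightly below the
nominal 5% — the node bootstrap is mildly conservative relative to
cohort-level sampling variation, which is the safe direction for claiming
training-induced change.

## Clustering and stability

K-means (k-means++ initialization, 100 restarts, seeded) runs on the 64
node-weight vectors, unweighted by node occupancy; an occupancy-weighted
variant was considered and rejected as the default because the method
clusters the map's representation, not the sample density (weighting can
be emulated by clustering participants directly).  Labels are renumbered
so centroid grand means descend with the cluster label — cluster 1 is
always the highest-performing profile — making solutions comparable across
runs and seeds.  Participants inherit the cluster of their BMU.

Silhouette widths over a k-range use the standard (b − a)/max(a, b) per
node; singleton clusters score 0, and the all-singleton solution
k = n_nodes scores 0 by the same convention.

Retrain stability: the map-training algorithm here is deterministic given
the data (PCA initialization), so "retraining with a new random seed"
would reproduce the identical map.  Each stability repetition therefore
retrains on a bootstrap resample of the cohort (participants drawn with
replacement), reclusters, and allocates the full original cohort; the
adjusted Rand index between repetition partitions measures robustness.
This makes stability reflect sampling variability of the cohort rather
than optimizer noise.  On well-separated four-profile cohorts the mean ARI
exceeds 0.99; on the realistic calibrated mixture (whose middle profiles
genuinely overlap) it is around 0.6–0.7, an honest reflection of how
sensitive boundary participants are to resampling.

## Trajectories and group statistics

Transition tables pair each participant's pre and post cluster labels with
per-task gain scores (exactly post − pre).  Interest groups follow the
mover/stayer definitions: movers into clusters 1–3 must arrive from a
different cluster; stayers in 4 were in cluster 4 at both timepoints;
everything else — including children already in a target cluster who stay
there, and children who fall into cluster 4 — is `other` and excluded from
the group comparisons.  Groups with fewer than two members are excluded
with a warning.

Gains and the external covariate are compared across interest groups with
classical one-way ANOVA (explicit sum-of-squares decomposition, so the
fully degenerate no-variation case yields F = 0 rather than NaN) and Tukey
HSD (studentized-range distribution).  The treatment × time interaction of
the two-way mixed ANOVA (between = treatment, within = time, two levels)
is computed via the exact algebraic equivalence with the one-way ANOVA on
gain scores, giving F with (g − 1, N − g) degrees of freedom; this is
cross-checked against an independent mixed-ANOVA implementation in the
test suite.  No sphericity correction is needed with a two-level within
factor.

Effect sizes use the pooled-two-timepoint formula
d = (m_post − m_pre)/√((s_pre² + s_post²)/2), which reproduces all four
published training effect sizes from the published summary rows to within
0.002.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes,
because the original cohorts are unavailable:

- **Baseline mixture** (`default_baseline_spec`): four equal-weight
  Gaussian profiles at offsets (+19/+11 high-all, 0 mid-flat, −8/+8
  visuospatial-above-verbal, −11/−19 low-all; first value verbal, second
  visuospatial) around the published combined-cohort means
  (93.86, 93.46, 92.81, 98.64).  Offsets sum to zero per task, so the
  mixture mean equals the target exactly; within-profile variances are the
  published variances minus the between-profile variance, so marginal SDs
  (15.84, 15.41, 14.00, 15.26) are matched too.  Within-profile inter-task
  correlation defaults to 0.3 — no cohort-level inter-task correlations
  were published, so this is a package choice representing the moderate
  positive manifold typical of ability batteries.
- **Training cohort** (`default_training_spec`): pre-training profiles
  calibrated the same way to the adaptive-group pre rows; gains are the
  published mean gains (6.59, 19.78, 15.43, 12.80) plus per-profile
  offsets (−2, −2, +6, −2) — the visuospatial-tilted profile benefits
  most, consistent with visuospatial training content — plus i.i.d.
  Gaussian noise (SD 7.9).  With shared verbal/visuospatial profile
  offsets the four published post-training variances cannot all be matched
  simultaneously; the gain parameters solve the least-compromise moment
  system, leaving every expected pooled-SD effect size within ~0.03 of the
  published values (realized values at N = 179 scatter within ±0.14).
  A Gf covariate is drawn per profile (means 96/96/111/96, SD 10),
  ordered with the gain offsets so fluid intelligence predicts
  improvement (implied population correlation with mean gain ≈ 0.36).
- **Separated variants** (`separated_*_spec`): four roughly equidistant
  (simplex-like) centroids with tight within-profile spread (SD 5),
  used where ground-truth recovery must be achievable.  Early designs
  with one very distant profile left a band of interpolating map nodes
  that soaked up a K-means cluster; near-equal pairwise separation avoids
  that artifact.  Their gains differ strongly by profile (+10/+4/−4/−10)
  with Gf means 112/102/95/85.

What the generator does *not* emulate: recruitment heterogeneity of the
constituent studies, age structure, missing data (rows with missing scores
are rejected, never imputed — no imputation rule was published),
task-relationship *changes* from pre to post (gains are additive, so the
correlation structure is approximately preserved; a pipeline run on the
default training cohort correctly finds few or no significant similarity
changes), floor/ceiling effects, or non-Gaussian score tails.  Passing
tests on these cohorts therefore demonstrate algorithmic correctness and
calibration, not that real training data contain four profiles.

## Problem sizes and tolerances

The test suite and `scripts/acceptance.py` run the resampling stages at
reduced but statistically meaningful sizes chosen so Monte-Carlo error is
small relative to every tolerance tested: cross-validation at 50–300
repetitions × 100 shuffles, bootstrap difference tests at B = 1,000–10,000,
stability at 25–100 repetitions, null-calibration checks against exact
binomial 99% bands, and Monte-Carlo-vs-exhaustive permutation agreement
within 3 Monte-Carlo standard errors.  Full-scale settings (1,000 CV
repetitions, 1,000 stability retrains, B = 10,000) remain the pipeline
defaults.

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; stage seeds derive deterministically from one
master seed, and two pipeline runs with the same master seed produce
byte-identical artifacts.

## Known limitations

- The SOM neighbourhood is hard (boxcar) and the lattice metric
  configurable; results are not intended to be numerically identical to
  any particular legacy toolbox implementation.
- Bootstrap change tests treat node weights as the units of resampling;
  with 64 nodes the similarity estimates are based on a modest sample and
  the test is mildly conservative under the null.
- Interest-group analyses condition on the baseline cluster solution; no
  uncertainty in the cluster boundaries is propagated into the trajectory
  statistics.
- Regression-to-the-mean corrections and latent change-score models are
  out of scope.
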