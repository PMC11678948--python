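# Methods

## Model and procedure

`spiralfs` treats feature selection as continuous minimization over the
unit hypercube. A position `x ∈ [0,1]^d` binarizes to the subset
`S = {j : x_j > 0.5}` (strictly greater, so a component at exactly 0.5 is
*not* selected), scored by

    fitness(S) = α · ErrorRate(S) + (1 − α) · |S|/d,     α = 0.99.

`ErrorRate` is the mean misclassification rate of a Euclidean k-NN (k = 5)
over stratified 5-fold cross-validation on the 80% training partition of a
stratified 80/20 split. An empty subset is assigned fitness 1.0 — the worst
attainable value — rather than being repaired, so the optimizer is pushed
away from it without position bias. The held-out 20% is used exactly once,
to report test accuracy of the final mask; both the CV accuracy of the best
mask and the test accuracy are reported and labelled, since protocols in
this literature are often ambiguous about which one their tables show.

### Optimizer schedules and branches

The envelope is `a(t) = 2 − 2t/MaxIter` with 0-based `t`, so it starts
exactly at 2 and reaches 0 after the last update. Per agent and step one
scalar `A = 2a·u − a` is drawn (the branch test `|A| ≥ 1` is defined on a
scalar; the coefficient is broadcast over dimensions), one per-dimension
vector `C = 2·u⃗`, and scalars `p ∈ U[0,1]`, `l ∈ U[−1,1]`. `p = 0.5`
falls to the spiral branch. Boundary handling is clamping to `[lb, ub]`.
All draws come from one seeded `numpy` Generator in a fixed documented
order, so runs replay bit-identically.

### AMS partitioning

`K(t) = ⌊(N/2)·exp(−ln(N/2)·t/MaxIter) + γ⌋` with γ = 0.8 by default;
`M = ⌊N/K⌋`. Agents are ordered by the fitness–distance score
`FD = (1 − fit_norm) + dis_norm` (min–max normalization over the current
population; 0/0 defined as 0; distances are Euclidean to the incumbent
global best) descending, ties broken by lower agent index, and cut into
contiguous blocks of `M`; the `N − K·M` remainder joins the last block.
Every `R` iterations (default `R = 10`, a value not fixed by the method's
description; configurable) the ordering is replaced by a uniformly random
permutation to exchange information between subswarms. Leaders are the
minimum-fitness members, recomputed after each full update sweep and again
before refinement.

### DSS exploration

The exploration branch (`p < 0.5`, `|A| ≥ 1`) becomes
`x ← r·e^{θ}cos(2πθ) + x` with `r = |W ⊙ x_rand − x|`, `W ∈ U[0,1]^d`
per-dimension and `θ` a single scalar per step. The distribution of `θ` is
not prescribed by the method; we use `θ ~ U[−1,1]`, mirroring the spiral
parameter `l`, which spans spiral factors in roughly `[−2.7, +2.7]` and
therefore both inward and outward moves. `x_rand` is drawn from another
subpopulation when `K > 1` and from any other agent when `K = 1`.

### BES refinement

While `t/MaxIter < 0.2` (strict, 0-based), each subpopulation leader `g` is
refined once per member `m`: a third agent `r` is drawn uniformly from the
whole population, the per-dimension quadratic-interpolation vertex

    q_j = [(m_j²−r_j²)F_g + (r_j²−g_j²)F_m + (g_j²−m_j²)F_r]
          / (2[(m_j−r_j)F_g + (r_j−g_j)F_m + (g_j−m_j)F_r])

is computed with a per-dimension fallback to `g_j` when the denominator is
below 1e−12 in magnitude (coincident or collinear abscissae), a uniform
per-dimension crossover keeps `q_j` when a fresh draw is ≥ 0.5 and `g_j`
otherwise, and the crossed candidate replaces the leader only if strictly
fitter. Each candidate costs one extra objective evaluation, so the total
budget is `N·MaxIter + N` plus `N` per gated iteration.

The recorded global best is elitist (replaced only by strictly better
solutions), so convergence histories are non-increasing by construction
even though the population itself may move away from the best point.

## Fitness-evaluation details

* k-NN ties (possible with even votes in multiclass data) are broken by the
  nearest neighbour's class; the vote is implemented over a
  `scipy.spatial.distance.cdist` neighbour ranking because library k-NN
  classifiers do not expose this tie-break. With two classes and odd k the
  rule is inert and the implementation agrees exactly with
  scikit-learn's classifier (tested).
* Features are min–max scaled using training-fold statistics only;
  constant columns scale to zero. Fold assignment is stratified and seeded
  once per selection run, so a mask's fitness is a pure function of the
  mask and the run seed — which also enables an exact per-mask cache that
  removes repeated CV evaluations without changing any result.
* If a training fold has fewer than k samples, k is reduced to
  `n_train − 1` with a warning.
* The fall-detection pipeline swaps the k-NN for an RBF-kernel SVM with
  library-default regularization (C = 1), features scaled the same way.

## Synthetic data: what it emulates and what it does not

### Classification generator

Informative columns are unit-variance Gaussians whose class means differ by
`effect_size`; redundant columns are random linear mixes of the informative
block plus 20% noise; remaining columns are class-independent noise.
Defaults: 200 samples, 30 features, 3 informative, effect size 2.5,
balanced classes.

The effect size was calibrated on an identifiability requirement, not on
optimizer behaviour: a parameter-recovery experiment is only well-posed if
the ground-truth mask is itself the fitness optimum. Too weak a separation
(≲1.5) lets noise columns reduce the finite-sample CV error below the
informative mask (the optimum then genuinely contains noise); too strong a
separation (≳3) makes two of three informative columns sufficient for zero
error, so the penalty correctly drops the third. At effect 2.5 with 200
samples, the ground-truth mask strictly beat every drop-one mask in 20/20
fresh draws, each feature's marginal error contribution (~3–4% absolute)
comfortably exceeding both the CV quantization (1/160) and the per-feature
penalty (0.033%).

What a green recovery test establishes: the optimizer finds
individually-necessary features and prunes most noise under the stated
fitness. What it does not establish: behaviour on real omics data, whose
features are correlated, heavy-tailed and batch-confounded; absolute
accuracy numbers on the published benchmark datasets are out of reach
without those datasets.

### IMU generator

Recordings are 9 channels × 200 samples (10 s at 20 Hz): acceleration
(g), angular velocity (deg/s), pitch/yaw/roll (deg), clipped to the sensor
ranges ±16 g, ±2000 deg/s, ±90°/±180°. Daily activities are band-limited
periodic gait or smooth posture-transition templates around 1 g vertical;
falls are a gait prefix, a ~160 ms multi-g impact burst with a
several-hundred-deg/s gyroscope transient, and a sustained post-impact
pitch/roll change whose sign encodes the fall direction. Channel noise is
Gaussian with per-channel scales (0.05 g, 3 deg/s, 0.5 deg).

These templates reproduce the *discriminative structure* real fall data
shows (impact magnitude, orientation change, post-impact quiescence); they
do not reproduce inter-subject variability, sensor drift, misaligned
mounting, or near-fall confusers, so pipeline F1 values on synthetic data
overstate what a deployed system would achieve and stand in only as a
functional test of the pipeline.

### Feature extractor

The 13 time-domain features are mean, std, variance, RMS, min, max, range,
median, IQR, skewness, kurtosis, mean absolute deviation and the
zero-crossing rate of the mean-centred signal (skewness/kurtosis defined as
0 for constant signals). The 6 frequency-domain features come from the
DC-excluded magnitude spectrum: total spectral energy, dominant frequency,
magnitude-weighted centroid and bandwidth, normalized spectral entropy,
and the power-weighted mean frequency. The 8 time-frequency features are
the relative energies of the 8 leaf sub-bands of a 3-level Daubechies-4
wavelet packet with periodized orthonormal filters (implemented in-package;
the transform preserves energy, so the relative energies sum to 1). The
13/6/8 counts are fixed by the protocol; the concrete lists are this
package's documented choice. Channel-major concatenation gives the fixed
243-column layout in `FEATURE_NAMES`.

## Benchmark harness

Runs are paired: run `r` of every algorithm uses seed `base_seed + r`,
which fixes the 80/20 split, CV folds and initial-population draws, so
between-algorithm differences are not confounded by data partitioning.
Significance labels use the two-sided Wilcoxon rank-sum test at α = 0.05
(the customary choice in this literature; the exact test is configurable),
with '~' forced for identical samples and for fewer than 3 runs. Runtime
is recorded but never asserted on — it is hardware-dependent.

## Numerical choices and degenerate inputs

* QI denominator tolerance 1e−12 with per-dimension leader fallback.
* Min–max 0/0 (constant fitness or distances) defined as 0, making all FD
  scores 1 for an identical population.
* Remainder agents attach to the last subpopulation so every agent is
  always active.
* Significance labels replace the '≈' glyph with ASCII '~'.
* Test-suite experiments that mirror full-scale protocols (30 runs, 100
  iterations) run at reduced scale where the check is directional or
  structural (for example the fall-pipeline F1 property uses 10-iteration
  optimizer runs); tolerance-bearing acceptance checks run at their stated
  scale.

## Known limitations

* The subset encoding is continuous with threshold binarization; no
  S-/V-shaped transfer functions are provided.
* Only k-NN (fitness) and SVM (fall demo) are wired into the wrapper;
  other classifiers would need a one-line extension of the fold scorer.
* The multipopulation scheme is a logical partition in one process; there
  is no island-model parallelism.
* Real UCI/microarray and real fall datasets are not downloaded or bundled;
  the loaders accept any delimited matrix.
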