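# Methods

## Data model

The unit of analysis is one participant's trial-space matrix: n_trials rows,
each the electrode-major concatenation of one epoch's per-electrode time
courses (electrode e's samples occupy columns [e·T, (e+1)·T) for T samples
per epoch). The reference design is 124 electrodes × 32 samples at 62.5 Hz
(16 ms/sample, 496 ms of stimulus-locked post-onset response), 72 image
exemplars × 72 repetitions = 5,184 trials, with exemplars grouped into six
categories of twelve and categories into two superordinates (Animate =
{Human Body, Human Face, Animal Body, Animal Face}, Inanimate = {Fruit
Vegetable, Inanimate Object}). All sizes are free parameters; every analysis
works on any balanced design.

Epoch-time bookkeeping: sample windows are half-open and 0-based internally;
display labels in ms span the first to the last sample inclusively, so a
6-sample window starting at sample 9 is "144–224 ms" at 62.5 Hz. This
reconciles "80 ms" windows with 6 × 16 ms samples.

## Decoding

Principal components are obtained from a thin SVD of X₁ without mean
centering, X₁ = UΣVᵀ, and classification operates on UΣ. By default the SVD
is computed once on the full matrix before cross-validation partitioning.
This is deliberate — it reproduces the reference procedure and is cheap —
but it lets unsupervised structure of the test trials inform the basis; the
`fold_safe_svd` flag recomputes the SVD on each outer training partition and
projects the test fold onto that basis. Basis-sign indeterminacy is fixed by
making the largest-magnitude entry of each V column positive.

The classifier is one-against-all LDA. For each class c, a binary
discriminant is fit between class c and the pooled remainder using the
pooled within-group covariance of the two groups (n − 2 denominator), score
s_c(z) = wᵀz − wᵀ(μ_c + μ_rest)/2 with w = Σ̂⁻¹(μ_c − μ_rest); prediction is
argmax_c s_c, ties broken toward the lowest class index. No prior term is
included: all designs here are balanced, and the same omission applies to
every class so cross-class comparisons are unaffected. A nonnegative
`shrinkage` ridge can be added to the covariance diagonal; the default is 0,
and rank-deficient fits raise an error that points to it rather than
silently regularizing.

Cross-validation uses a uniform random permutation partitioned into
n_folds_outer ≈ equal folds (the n mod folds leftover trials go to the first
folds); each fold is the test set exactly once. A stratified option assigns
each class round-robin to folds with a per-class rotating start fold, so
that classes smaller than the fold count still cover all folds. Within each
outer fold, a nested inner cross-validation (same partition rules, RNG
streams spawned per fold from the master seed) evaluates every candidate
component count k on the training rows only; k* maximizes mean inner
accuracy with exact ties resolved toward the smallest k (parsimony). The
candidate grid defaults to every integer in [3, min(200, K)] when that range
is small (≤ 30 values or K ≤ 32) and to a 24-point log-spaced grid
otherwise; the search strategy is not dictated by the procedure being
reproduced, so it is configurable (`k_grid`), and exhaustive search is a
config away. The grid is truncated to the usable rank — min(rows, columns,
smallest inner-training size − 2) — because the pooled covariance of a
two-group split of n rows has n − 2 degrees of freedom; truncation is
logged.

Confusion matrices accumulate counts over all outer folds (rows = actual,
columns = predicted); the row-normalized matrix is row-stochastic and its
diagonal mean is the accuracy. Balanced class counts are asserted unless
explicitly waived.

## Confusion-derived RDMs

The normalized confusion matrix is converted to dissimilarities in three
steps: divide each row by its diagonal (unit self-similarity; a zero
diagonal makes this undefined and raises an error naming the class),
symmetrize by the *elementwise* geometric mean S_ij = √(CM′_ij · CM′_ji),
and vectorize D = ℒ(1 − S) over the lower triangle (row-major over i > j).
The elementwise reading of the geometric mean is the only one that
guarantees a unit diagonal and is the standard confusion-symmetrization; a
matrix-product reading would not. When an off-diagonal confusion exceeds its
row's diagonal, S_ij > 1 and the raw distance is negative; such entries are
clipped to 0 and the similarity object records a `clipped` flag, since MDS
and UPGMA downstream require nonnegative dissimilarities.

## Embedding and clustering

Classical (Torgerson) MDS double-centers the squared distances,
B = −½·J·D²·J, and eigendecomposes B. Eigenpairs with eigenvalue
≤ 1e-10 × λ_max are dropped; negative eigenvalues (non-Euclidean D, which
clipping and confusion noise can produce) are dropped and logged rather than
imputed. Coordinates are eigenvector × √eigenvalue, dimensions sorted by
descending eigenvalue, sign fixed by making each dimension's
largest-magnitude coordinate positive. An all-zero D returns a 0-dimensional
embedding rather than erroring.

UPGMA merges the closest cluster pair under size-weighted average linkage;
exact ties break toward the lexicographically smallest cluster-id pair
(leaves are ids 0..n−1, so all-equal distances merge (0, 1) first). The
merge height is the inter-cluster distance at merge — the convention used
across scientific-computing linkage implementations — not the half-distance
sometimes used for ultrametric trees; cophenetic distances are computed from
the same heights, and the in-package implementation is cross-checked against
both a brute-force O(N³) enumeration and scipy's average linkage in the
test suite. Newick export uses branch length = parent height − child height.

## Inference

All accuracy inference is exact-binomial at the single-fold scale, following
the floored-mean convention: fold size n = ⌊n_trials/n_folds⌋, observed
correct C_obs = ⌊total correct/n_folds⌋, chance p₀ = 1/N. The p-value is the
upper tail P(X ≥ C_obs); the effect size d = (C_obs − n·p₀)/√(n·p₀(1−p₀));
the α-level threshold is the exact upper quantile — the smallest count k
with CDF(k) ≥ 1 − α — reported as 100·k/n rounded to two decimals. For the
reference designs this rule gives 20.66% (n = 518, p₀ = 1/6), 16.28%
(n = 86, p₀ = 1/12) and 58.72% (n = 172, p₀ = 1/2) at α = 0.01. A boundary
subtlety follows from the quantile definition: the threshold count itself is
the last one *inside* the null's 1 − α mass (P(X > k*) ≤ α < P(X > k*−1)),
so the upper-tail p at exactly k* can slightly exceed α. Searchlight maps
receive no multiple-comparison correction by default, matching the design
they reproduce; a Bonferroni option is available. scipy.stats.binom provides
the exact distributions; the suite verifies it against a direct log-space
pmf summation.

Rank-sum separability of categories along MDS dimensions uses the two-tailed
Wilcoxon rank-sum (Mann–Whitney) test, exact when both groups have ≤ 12
members and no ties, normal approximation with tie correction otherwise;
degenerate all-equal inputs return p = 1. Groups of fewer than 6 members
cannot reach p < 0.01 two-tailed, which bounds what small synthetic cohorts
can show. Cross-participant dispersion is the unbiased (n − 1) sample SD.

## Synthetic data

The generator emulates the *statistical design* of the reference study, not
its physics: per-exemplar expected patterns are sums of independent
superordinate, category and exemplar templates (n_electrodes ×
n_time_samples each), drawn as white Gaussians, moving-average-smoothed
along time (width `temporal_smoothness`, default 3 samples — evoked
responses are band-limited; the exact kernel is immaterial) and rescaled to
the configured per-entry variances (arbitrary squared voltage units). Trials
add i.i.d. Gaussian noise of variance `var_noise`; an optional AR(1)-in-time
(lag-1 correlation `noise_ar1_rho`) with uniform spatial correlation
`noise_spatial_rho` mode provides more realistic searchlight noise.
Templates can be confined to a `signal_electrodes` × `signal_window` mask
(exactly zero outside), giving known ground truth for localization tests.
One call generates one participant; cohorts vary the seed.

Defaults mirror the reference design (124 × 32 at 62.5 Hz, 6 × 12 × 72
trials) with variance components (1, 1, 0.5) over noise 4 — signal-dominant,
since no SNR is specified by the emulated design and strong structure is the
useful default for verification. The bundled cohort drivers instead use a
scaled design (16 electrodes, 6 × 6 × 24 = 864 trials) with noise variance
80, chosen so that decoding sits mid-range rather than at ceiling, the
regime where the method's behavior is informative.

What the generator does **not** emulate: volume-conducted forward-model
topographies, 1/f and oscillatory background spectra, eye/muscle artifacts,
trial-order and session effects, or the low-level image-feature structure of
the actual photographs. Passing tests therefore certify the *pipeline* —
that it recovers structure that is present and stays calibrated when none is
— not that real EEG contains such structure.

## Problem sizes and determinism

The test and acceptance workloads are sized for quick desk runs as a design
choice: null calibration uses 50 zero-signal participants of 120 trials × 32
features; planted-structure recovery uses 240 trials × 96 features with
category variance 8× noise; searchlight localization uses a 5-electrode ×
12-sample grid with the signal in electrodes {1,2} × samples [6,12) and
*disjoint* 6-sample windows, so the planted block is a single unambiguous
cell — with half-overlapping windows the neighbor window genuinely contains
half the signal and can legitimately win the argmax. These constructions
were sized by checking recovery reliability across ≥ 40 generator seeds
before being frozen. Every stochastic step (template draws, noise, fold
permutations, per-cell searchlight streams) derives from explicit seeds via
`numpy.random.SeedSequence` spawning, so identical configurations reproduce
byte-identical results.

## Known limitations

- The default whole-matrix SVD leaks test-set covariance into the basis (an
  intentional reproduction choice; `fold_safe_svd` avoids it).
- Self-normalization is undefined for classes never classified correctly;
  the pipeline skips the representational chain for such classifications and
  records the cause, leaving merging/dropping classes to the analyst.
- Exact printed effect sizes from multi-participant studies are not
  recoverable when the cross-participant aggregation of C_obs is
  underdetermined; this package floors the mean total correct across
  participants and states so in its outputs.
- MAT import requires the caller to supply the container's key names and the
  epoch layout; deposited-repository internals vary.
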