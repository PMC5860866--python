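# Methods

This note documents the models and procedures the package implements, the
defaults it chooses where the methodology is genuinely open, and what the
synthetic-data generators do and do not emulate.

## RDM conventions

An RDM is square, symmetric within an absolute tolerance of 1e-10, with a
zero diagonal; inputs inside tolerance are symmetrized by averaging with
the transpose. The package-wide vectorization canon is the lower triangle
in row-major order — pairs (1,0), (2,0), (2,1), … — used consistently by
every module, so vectors from different modules can be correlated or
regressed directly. Spearman correlations average tied ranks. A
rank-transform utility exists for display only and never feeds inference;
rank-scaling compresses the dissimilarity metric and would bias
ratio-scale comparisons.

## Stimulus-set selection

The selector searches for a fixed-size category set (default 30, equal
thirds from the indoor / outdoor man-made / outdoor natural superordinate
classes) whose three model sub-RDMs are minimally inter-correlated. A
candidate's score is the **maximum** of its three pairwise Spearman
correlations; the stopping rule rejects a learning batch of candidates
(default 10,000), records the minimum score seen, and accepts the first
later candidate scoring **strictly** below that record (ties continue the
search). Scoring by the per-candidate maximum is a deliberate reading of
"minimize the inter-model correlations": it turns three numbers into one
stopping criterion and directly bounds the worst collinearity the
downstream regressions will face. A `max_iterations` guard (default 10 ×
the learning batch) prevents non-termination; when it trips, the best
candidate seen anywhere is returned with `exhausted_ = True`, and that
summary may equal (not beat) the learning record. No global optimality is
claimed.

## Behavioral RDMs

Category dissimilarity is the mean squared Euclidean on-screen distance
over all between-category exemplar pairs, in pixels². Within-category
distances are discarded (diagonal fixed at zero). Per-participant RDMs are
not normalized before group averaging; correlations are scale-invariant,
so leaving raw pixel units does not affect inference. An arena-radius
check validates that all thumbnails lie inside the circle.

## Crossnobis distances

Noise covariance: per-run sample covariances of the run-demeaned residual
time courses are averaged into one pooled estimate and shrunk toward its
diagonal, `Σ̂ = (1−λ)S + λ·diag(S)`. The automatic intensity is the
analytic (Schäfer–Strimmer) estimator for the diagonal target — the ratio
of summed sampling variances of the off-diagonal entries to their summed
squares, clipped to [0, 1]. The whitener is the symmetric eigendecomposed
inverse square root (order-free, unlike Cholesky) and satisfies
`WᵀΣ̂W = I` to 1e-6.

Distances use the leave-one-run-out cross-validated inner product of
whitened pattern differences, averaged over folds. Two parameterized
choices, both defaults documented as implementation decisions rather than
attributed to any source: (1) distances are divided by the voxel count, so
values are per-voxel and comparable across ROI and searchlight sizes
(switch with `normalize_by_voxels=False`); (2) one pooled covariance is
shared across folds rather than re-estimated per fold, keeping all folds
in a common whitened space (the searchlight can instead re-estimate per
sphere, its default, or share a whole-mask covariance via
`shared_noise=True`).

## Inference

- **Partial correlation**: Pearson correlation of the residuals of y and x
  after least-squares regression (with intercept) on the covariates.
- **Variance partitioning**: all seven subset OLS regressions, decomposed
  by the commonality identities; components sum to the full r² at machine
  precision. Negative components (suppression) are reported as-is in the
  raw decomposition and clipped at zero only in the percentage view, with
  the clipped keys recorded — Euler-style areas cannot be negative, but
  silently suppressing the raw numbers would hide suppression effects.
  Group-level partitions run on the participant-average RDM by default;
  per-participant partitions can be averaged as a robustness check.
- **Wilcoxon signed-rank**: W is the sum of positive signed ranks; zero
  differences are dropped (Wilcoxon's original prescription). p is exact
  for n ≤ 25 with no tied absolute differences, otherwise from the
  tie-corrected normal approximation; the z-ratio is always reported from
  the normal approximation. One-sided means "greater than the null".
- **FDR**: Benjamini–Hochberg step-up within each declared family.
- **Noise ceiling**: upper bound = mean correlation of each participant's
  RDM with the group average (overfits, hence an upper bound); lower bound
  = leave-one-out version.
- **Reproducibility**: Pearson r between two group-average RDM vectors;
  the null jointly permutes the category labels (rows and columns) of one
  average RDM. All n! permutations are enumerated when that is no larger
  than `n_perm`; otherwise `n_perm` random permutations are drawn. p uses
  the add-one convention (1+k)/(1+N), which can never return zero and
  equals 1/(N+1) when no permutation reaches the observed value. The CI
  is a percentile bootstrap over participants within each group, default
  95% with 10,000 resamples. Because resampling duplicates participants'
  noise, bootstrap correlations are slightly attenuated and the interval
  can sit marginally below a very high observed r; violations are
  reported, never adjusted away.

## Searchlight and group inference

Sphere offsets are all integer offsets with Euclidean norm ≤ radius,
boundary inclusive; at the default radius 3.0 this is exactly 123 voxels.
The radius convention was resolved in favor of the voxel count: a literal
"diameter 3" cube could never exceed 27 voxels. Centers whose in-mask
sphere falls below `min_voxels` are skipped and counted. Each analyzed
sphere gets its own shrinkage covariance from its residuals (default),
a crossnobis RDM, and per-model partial correlations written to the
center voxel.

Group inference: one-sample t over participants, converted to z through
the t CDF with n−1 degrees of freedom, then TFCE

    TFCE(v) = Σ_h e_v(h)^E · h^H · dh

with defaults E = 0.5, H = 2, dh = 0.1, 18-connectivity — the conventional
parameterization of the TFCE literature and of the major MVPA toolboxes;
all configurable. Negative values are enhanced by transforming the negated
map and negating back. Familywise correction takes the maximum TFCE over
the mask per sign-flip permutation; corrected p = (1+k)/(1+N), one-sided
for positive effects, with a z ≥ 1.64 display overlay (one-sided p < .05).
Sign assignments are drawn antithetically — each random assignment is
immediately followed by its negation — a balanced scheme that halves null
variance and makes the null distribution exactly invariant under global
negation of the input maps. Group analysis is volumetric; surface
projection and surface smoothing are out of scope, so cluster geometry is
not comparable to surface-based maps.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of their arguments including the seed,
and return a `GroundTruth` record.

- **Model RDM triplets**: each model's item × feature matrix is
  `w·(shared latent) + √(1−w²)·(independent part)`; the covariance between
  two models' dissimilarity entries is carried only by the shared factor,
  giving an expected RDM-vector correlation of `w⁴`, so `w = target^(1/4)`.
  Achieved correlations fluctuate with finite items (typically ±0.08 at 30
  items, the documented tolerance). Linear common-factor mixing cannot
  produce negative RDM correlations; negative targets are rejected.
- **Pattern datasets**: category base patterns come from the classical
  distance-to-Gram embedding `G = −½·C·D·C`, eigen-clipped at zero (a
  substantially negative eigenvalue raises an error; the
  `inflate_to_embeddable` helper adds the minimal off-diagonal constant,
  which shifts all centered-Gram eigenvalues by half that constant and
  leaves correlations untouched). Coordinates are spread over voxels by a
  random orthonormal mixing scaled so squared distances / voxel count hit
  the target exactly in the noiseless limit. Per-run betas and residual
  series share a known noise covariance (identity or random SPD).
- **Arrangements**: category anchors from classical 2-D scaling of the
  target, rescaled into the arena, exemplars jittered isotropically and
  radially clamped to the boundary. The 2-D bottleneck is faithful to the
  paradigm — a single arrangement can only express rank-2 structure — so
  recovered RDMs are proportional to the target only when the target is
  2-D embeddable; for higher-rank targets the projection redistributes
  variance among correlated models, which is a genuine limitation of
  multi-arrangement data, not of the estimator.
- **Searchlight volumes**: a planted region carries the embedding of a
  target RDM; all voxels receive i.i.d. noise betas and residuals. One
  geometric fact matters for recovery tests: a sphere sees only a subset
  of the region's embedding coordinates, which distorts sub-distances by a
  random projection factor. For a near-constant target (e.g. a 1−r RDM
  over many features, modulation ≈ 7% of the mean) that distortion
  dominates the signal and caps voxelwise recovery AUC around 0.87
  regardless of noise level; recovery tests therefore plant high-contrast
  targets (few-feature RDMs, modulation ≈ 23%), where AUC exceeds 0.95.

Not emulated: hemodynamics, temporal autocorrelation, spatial noise
correlation beyond the supplied covariance, image content, DNN activation
statistics, exemplar-level behavior. Passing tests therefore certify the
estimators and their statistical calibration, not robustness to those
real-data properties.

## Problem sizes and numerical choices

The test suite and acceptance script scale simulations to what the
statistics need rather than to study scale: selection uses learning
batches of 30–300 candidates (study-scale 10,000 is a parameter, not a
different code path), calibration simulations use 100–200 replicates,
permutation nulls 200 draws where a binomial bound is being checked and
10,000 where a p-value is being quoted. Degenerate inputs (constant
vectors, rank-deficient designs, zero-variance voxels, empty masks,
infeasible quotas) raise errors naming the offender rather than producing
NaNs. Stopping-rule ties continue the search; FDR families are adjusted
independently; bootstrap and permutation seeds derive from a single
user-supplied seed.
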