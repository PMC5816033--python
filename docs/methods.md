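# Methods

`voxelopt` implements Bayesian optimization of two image pre-processing
parameters — the isotropic resampling voxel size and the FWHM of the
Gaussian smoothing kernel — for brain-age prediction from normalized
gray-matter maps, together with the synthetic cohort generator used to
exercise and validate the pipeline end to end.

## The optimization problem

A cohort of subjects with gray-matter volume maps `x_i` and ages `y_i` is
pre-processed with candidate parameters θ = (v, F): each map is resampled to
an isotropic v mm grid (trilinear, with a Gaussian anti-alias pre-filter of
sd 0.42 × the downsampling factor when coarsening), smoothed with a Gaussian
kernel of F mm FWHM (σ = F / (2√(2 ln 2)), applied at the resampled
resolution with reflective boundaries), and flattened to a feature vector
(voxels that are zero in every subject are dropped). A linear-kernel SVM
(young/old classification) or ε-SVR (age regression) is trained on those
features, and the objective f(θ) is its 10-fold cross-validated error —
misclassification rate, or MAE in years. Both tasks minimize.

SVM hyper-parameters stay at defaults throughout (C = 1, linear kernel;
SVR ε = 0.1 × the training-label sd; features unscaled, with a config
switch for standardization). The search is over pre-processing only.

### Order of operations

Resampling precedes smoothing, and the FWHM is interpreted in mm at the
resampled resolution (so the kernel sd in voxels depends on the candidate
voxel size). This matches pipelines in which smoothing is part of the
normalization write-out step; the reverse order is a plausible alternative
but is not implemented.

### Sub-sampling

Each objective evaluation must see fresh data, so differing parameter
settings are never compared on the same subjects. The cohort is partitioned
into ⌊N/n⌋ disjoint subsets of exactly n subjects (default n = 80 at full
scale; 32 on the desk-scale benchmark), each approximately reproducing the
cohort's age distribution:

- classification mode draws exactly n/2 per group, age-stratified within
  group (members are dealt from age-sorted blocks, one per subset, after a
  seeded shuffle);
- regression mode allocates draws across 8 contiguous age strata by largest
  remainder and deals within strata the same way, rotating the remainder
  across subsets so every subset has exactly n members.

The N mod n remainder stays unassigned — never silently recycled. Plans are
deterministic in (inputs, seed) and serialize to JSON for audit.

## The surrogate and acquisition layer

The Gaussian-process surrogate uses an anisotropic Matérn-5/2 kernel with a
constant prior mean and a fitted white-noise term, on inputs affinely mapped
to the unit square; objective values are z-scored before fitting and
predictions un-standardized on output. Hyper-parameters maximize the
marginal likelihood from multiple restarts (scikit-learn's GP machinery),
with length scales bounded to [0.1, 2] of the unit square: the objective is
smooth at the search-box scale, and unconstrained maximum likelihood on a
dozen noisy points has spurious modes — noise-interpolating spikes, or a
surface flat in one dimension — that these bounds exclude. Predictions
report the noise-free latent objective: the fitted noise variance is
subtracted from the predictive variance.

Six acquisition functions are available, all phrased for minimization and
maximized over a seeded scrambled-Sobol candidate set (default 2048 points,
ties broken by candidate order) followed by a bounded local polish:

- **EI** — expected improvement E[max(0, y* − Y)];
- **PI** — probability of improvement P(Y < y*);
- **LCB** — rank by μ − κσ with κ = 2 × exploration ratio (the mapping is a
  declared package choice; the ratio's native definition does not fix one);
- **EI per second** — EI divided by the predicted evaluation time from a
  second GP fitted to log wall time (tests inject a deterministic time
  model);
- **EI+** and **EI per second +** — as EI(-per-second), plus an escape rule:
  when the posterior sd at the incumbent falls below the fitted noise sd ×
  exploration ratio, the region counts as over-exploited and the surrogate's
  predictive sd is inflated (default factor 5) for the next proposal,
  pushing it toward unexplored territory. The "noise sd" here is the fitted
  GP noise hyper-parameter; a user-supplied constant would be an
  alternative reading, but the fitted level is self-calibrating.

Because evaluations are noisy, the improvement target ("best so far") is
the posterior-mean plug-in incumbent — the sampled point with the lowest
posterior mean — rather than the raw best observation, which is the
luckiest draw and deflates improvement-based acquisitions.

A run performs a burn-in of seeded scrambled-Sobol draws (default 5):
marginally uniform over the box and independent of any objective value,
but space-filling, so every run covers the box even at five points (iid
draws leave the coarse third of the voxel range unsampled in about one run
in nine). Guided iterations follow until the plan's subsets are exhausted
(12 subsets and burn-in 5 give 5 + 7 evaluations). The reported optimum is the minimizer of
the posterior-mean surface (dense grid scan plus local refinement; observed
points join the candidate set and win exact ties, so a flat posterior from
a single observation returns that observation).

## Final-model evaluation and statistics

`train_final_and_holdout` retrains at chosen parameters on an age-stratified
training split and reports metrics on the untouched hold-out (2003 subjects
with a 200-subject hold-out reproduce a 1803/200 split). **R² is reported as
the square of the Pearson correlation** between predicted and true age, not
as 1 − SSE/SST — the convention is applied consistently everywhere.

Paired comparisons: McNemar's χ² on discordant counts
(χ² = (|b−c| − corr)²/(b+c), continuity correction off by default, flagged
degenerate when b + c = 0) and Steiger's z for dependent correlations
sharing one variable (Fisher transforms with the Dunn–Clark covariance
term). Note that comparing two models evaluated on *different* test subsets
is outside the standard dependent-correlation setting; the package computes
the standard test and leaves that caveat to the caller.

Stability analysis: posterior-mean surfaces from several runs sampled on a
shared grid, flattened and pairwise Pearson-correlated (unit-diagonal,
symmetric matrix, heat-map ready).

Cross-dataset generalization (regression) follows three cases: (1) source
parameters and source model applied to the target cohort; (2) the full
optimization re-run inside the target's training portion with a new target
model (train:test ≈ 9.8:1); (3) source parameters, fresh target model on
the same split. Reports carry an audit of which subject ids each stage
consumed.

## The synthetic cohort generator

The generator emulates normalized gray-matter maps, not raw MRI: per
subject, intensity = baseline − effect × (age/10) × template + noise,
clipped to [0, 1], on a 32³ grid of 2 mm voxels by default.

- **Atrophy template**: 12 isotropic Gaussian bumps at seeded positions,
  max-normalized. Bump sd = signal_scale/2, so the field's autocorrelation
  is Gaussian with 1/e distance exactly signal_scale (default 8 mm).
- **Age effect**: 0.04 intensity per decade at full-weight loci (≈ 4–8% of
  baseline per decade, the order reported for adult gray-matter decline),
  linear in age — a monotone proxy for aging-related atrophy.
- **Fine noise**: sd 0.30, Gaussian correlation 1 mm — scan/registration
  noise that smoothing and coarsening can average away.
- **Anatomical variability**: a second noise field, sd 0.08 at 16 mm
  correlation — smooth between-subject differences that smoothing cannot
  remove, so over-coarsening and over-smoothing are penalized.

These defaults were calibrated once so the optimization problem is
non-trivial: classification error on 32-subject subsets spans roughly 0.25
(matched pre-processing) to 0.55 (16+ mm voxels), with real curvature in
both parameters. The generator does not model registration error, field
inhomogeneity, site effects, sex differences or non-linear aging; passing
tests therefore demonstrate that the optimization machinery works on a
controlled analogue, not that any particular voxel size is optimal for real
cohorts.

A structural property of the analogue (and arguably of the real problem):
voxel size and FWHM jointly set one effective spatial resolution, so the
objective has a ridge of near-equivalent settings rather than a sharp
point minimum. On 32-subject subsets the evaluation noise (sd ≈ 0.08 of
classification error, roughly double that of an 80-subject protocol) is
comparable to the depth of that ridge, so optima recovered from 12
evaluations are uncertain along it: localizing the exhaustive-grid oracle's
best 10% of cells from one run is not statistically achievable at this
scale, and the package reports that recovery rate honestly rather than
claiming point-optimum recovery. Treat any recovered optimum as
indicative, not definitive.

For analyses of the *optimizer's* reproducibility — the surface-stability
protocol across seeds and acquisition functions — the package provides an
analytic noisy benchmark objective (`benchmark.synthetic_error_surface`)
with the same landscape shape (fine-voxel penalty, coarse-voxel cliff,
shallow smoothing bowl) and controllable Gaussian evaluation noise
(sd 0.05). On it, posterior-mean surfaces from independent runs correlate
strongly (median pairwise r ≈ 0.95), isolating the machinery's stability
from the image pipeline's sampling noise; the same statistic on the
image-cohort runs is lower (~80% of pairs above a pure-noise null) for the
noise reasons above, and both are reported.

## Numerical choices

- Evaluations on a degenerate (zero-column) feature matrix report the
  worst-case objective (1.0, or the subset's age range) flagged, instead of
  crashing the loop.
- The linear-kernel Gram matrix is computed once per evaluation and sliced
  per CV fold (`kernel="precomputed"`); this is algebraically identical to
  refitting on raw features.
- Duplicate sampled points are absorbed by the GP noise term (no
  singular-matrix failures); revisits during guided sampling are permitted.
- Per-run randomness derives from one `SeedSequence`: burn-in draws,
  candidate sets, CV splits and plan shuffles all reproduce bit-identically
  for a fixed seed and configuration.
- Benchmark problem sizes (400-subject cohort, 32³ grid, 32-subject
  subsets, 10×10 oracle grid) are the package's desk-scale defaults; all
  scale upward through `CohortSpec` and the function arguments.

## Known limitations

- Only 2-D search spaces (voxel size × FWHM) are supported.
- Orientation metadata in NIfTI headers is not interpreted; volumes must
  share a grid and orientation.
- The un-optimized reference (1.5 mm, 4 mm) and all statistical
  conventions target the VBM-style analysis this package emulates; other
  feature types (surface-based, deep representations) are out of scope.
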