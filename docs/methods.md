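# Methods

This note records the statistical model, the defaults and why they were
chosen, what the synthetic generator does and does not emulate, and the
numerical conventions that make results reproducible bit for bit.

## Gaussian process classification

**Model.** Subjects are rows of a beta-value matrix `X` (one column per
in-mask voxel, row-major voxel order).  A zero-mean GP prior with linear
covariance `K = Xc Xcᵀ + jitter·I` is combined with a probit likelihood
`p(y_i|f_i) = Φ(y_i f_i)`, `y_i ∈ {±1}` (+1 = at-risk).  `Xc` is `X` minus
the *training-fold* column means; the same means are subtracted from test
data, so no test information leaks into centring.  There are no kernel
hyperparameters and none are optimized — with far fewer subjects than
voxels a parameter-free linear covariance is the standard, stable choice,
and it keeps every fit deterministic.

**Inference.** The latent posterior is approximated by expectation
propagation (EP; sequential site updates with rank-1 downdates, posterior
recomputed from site parameters after every sweep for numerical hygiene) or,
optionally, by a Laplace approximation (Newton iteration on the latent
mode).  Both yield a Gaussian latent predictive `N(μ*, σ*²)` and the
closed-form predictive probability `Φ(μ*/√(1+σ*²))`.  Convergence is
declared when the largest site-parameter change (EP) or latent-mode change
(Laplace) falls below `convergence_tol` (default 1e-8); non-convergence
within `max_iterations` (default 200) raises an error rather than returning
a half-converged model.  The EP inner loop is compiled with numba; fits on
desk-scale problems take tens of microseconds, which is what makes
permutation studies that rerun the entire nested pipeline thousands of
times affordable.

**Approximation quality.** EP posterior moments match importance-sampling
ground truth to high accuracy on small problems.  The predictive
*probability* of any Gaussian approximation can still deviate from the
fully Bayesian value when the exact posterior is strongly non-Gaussian: on
a two-point toy with a rank-1 kernel the gap is ≈ 0.03 (EP 0.78 vs exact
0.75), and no Gaussian-family approximation can close it — even a
moment-exact Gaussian fit gives 0.78.  Laplace additionally shrinks
probabilities toward 0.5 relative to EP; the shrinkage grows with class
separation (measured up to ≈ 0.2 on well-separated toys) while the implied
decisions coincide.  EP is therefore the default; Laplace is retained as a
cross-check.  The test suite verifies the closed-form link integral against
dense 1-D quadrature (agreement ~1e-12, asserted at 1e-4) and bounds the
EP-vs-exact gap on the toy at 0.05.

**Conventions.** `jitter` is relative to the mean kernel diagonal (default
1e-6) and enters the predictive variance as a white-noise kernel component.
Weights `w = Xcᵀα` satisfy primal/dual equivalence `w·(x−x̄) = μ*(x)` to
machine precision; positive weight pushes toward at-risk.  A probability
exactly equal to the 0.5 threshold is classified as control — an explicit,
if measure-zero, tie rule.

## RFE and nested cross-validation

The voxel-count grid starts at the mask size and descends in steps of
`step` (default 5000, matching whole-brain scale) with a final partial
removal to `level_floor` (default 1; a zero-voxel classifier is undefined).
At each level the classifier is refitted on the surviving voxels and voxels
are ranked by `|w|`, ties broken by voxel index, so paths are deterministic
and nested.

The outer loop holds out each matched pair in turn (lexicographic pair-id
order).  The inner loop holds out each remaining pair as a validation set,
recomputes a full RFE path on the rest, and pools validation accuracy per
level across inner folds (all folds share one level grid).  The level with
maximal mean validation accuracy — ties toward the *larger* level, i.e.
toward removing less — is then used for the outer fold, where RFE is
*recomputed* on all non-test pairs rather than reusing inner-fold rankings:
this spends all available training data on the final model.  The held-out
pair influences nothing upstream of its own prediction; a sentinel test
corrupts a test pair by +1e6 and checks the selected level is unchanged.

Accuracy, sensitivity and specificity are percentages over all test
subjects, at-risk subjects, and controls respectively; with the balanced
paired design `accuracy = (sensitivity + specificity)/2` holds exactly.

## Permutation testing

Significance of the cross-validated accuracy is assessed by rerunning the
**entire** nested RFE cross-validation under relabelled data.  Two
relabelling schemes are provided: `within_pair_flip` (labels swapped or not
within each matched pair; the default, since it respects the exchangeability
structure of a matched design) and `free_relabel` (random permutation of
the label vector).  Randomness is counter-based: permutation `b` draws from
`numpy.random.default_rng([seed, b])`, so results are reproducible and
independent of evaluation order.

Three p-value rules are available.  `strictly_greater` divides the count of
permuted statistics strictly above the observed one by `N` — the classical
estimator, kept as the default.  `greater_or_equal` uses `(count≥ + 1)/(N+1)`,
which is never anticonservative.  `mid_p` counts ties as half.  The choice
matters because cross-validated accuracy on small cohorts is heavily
discrete: in a calibration study on zero-effect synthetic data (200
datasets × 99 permutations) the strict rule rejected true nulls at 12% for
a nominal 5% and the ≥ rule at 0%, while the mid-p rule rejected at 4% —
the only rule whose realized level tracks the nominal one under heavy
ties.  Calibration tests therefore use `mid_p`; analyses of real data at
study scale (1000 permutations, 32 subjects) are far less tie-dominated and
any rule is reasonable there.

The AUC permutation test relabels outcomes freely (outcome labels are not
paired).

## Outcome analysis

Risk scores are the cross-validated predictive probabilities of the at-risk
subjects whose follow-up outcome is known.  Developers vs non-developers
are compared with a pooled-variance two-sample t-test, one-tailed for
"developers score higher", `df = n₁ + n₂ − 2` (6 and 7 subjects give
df = 11).  Note that `t = 1.82` at `df = 11` corresponds to a one-tailed
p of 0.048, not 0.04 as sometimes printed in this literature; the package
reports the honestly computed value.  The ROC curve sweeps thresholds over
the unique scores; the trapezoidal AUC equals the tie-corrected pairwise
probability `P(score_dev > score_nondev) + ½P(tie)`, which the tests verify
against brute-force enumeration.

## Synthetic data

`simulate(spec)` draws, per subject: a shared baseline offset
`N(0, subject_offset_sd²)`; per condition, white Gaussian noise smoothed
with a Gaussian kernel (`smoothing_fwhm` voxels) and rescaled to
`noise_sd` exactly (the kernel L2 norm is computed once per grid); and, for
at-risk subjects in the signal condition only, an added cluster effect
`effect_size · noise_sd · a_s` on the voxels within `cluster_radius` of
`cluster_center`, where `a_s ~ lognormal(0, 0.25)` is the subject's private
amplitude.  Developer labels for followed at-risk subjects are Bernoulli
with probability logistic in the standardized log-amplitude, slope
`outcome_coupling` and intercept solved (Gauss–Hermite quadrature) so the
expected developer fraction equals `outcome_fraction`.  Everything is drawn
from one seeded generator in a fixed order; identical specs produce
byte-identical files.

Presets: `null` (8 pairs, 500 voxels, zero effect — the exchangeable-label
setting used for calibration), `easy` (8 pairs, 2000 voxels, a 57-voxel
cluster at 3 noise-SD per voxel, strong outcome coupling — the
signal-recovery setting), and `paperlike` (16 pairs, 12³ grid, three
conditions with the effect in `neutral` only, follow-up for 13/16 at-risk
subjects, expected developer fraction 6/13).

What the generator does *not* emulate: hemodynamics and task timing, GLM
estimation, motion and scanner artifacts, anatomically structured
covariance, and between-pair demographic matching effects.  Passing tests
show the pipeline's bookkeeping, calibration and signal recovery are
correct under the assumed statistical structure — they do not certify
accuracy levels on real scans.

## Problem sizes used in the shipped studies

Calibration and recovery suites run at desk scale, chosen as the smallest
sizes at which the checked properties are statistically meaningful: null
mean-accuracy calibration uses 50 datasets of 8 pairs × 500 voxels (800
Bernoulli trials; 95% band ±3.5 points around 50%); permutation-test
calibration uses 200 datasets of 5 pairs × 60 voxels with 99 permutations
each (20 000 nested-CV runs); signal recovery uses the `easy` preset.  The
acceptance script reruns the two headline quantities (mean null AUC over
2000 replicates; mean null nested-CV accuracy over 50 datasets) from
scratch with a user-supplied seed.

## Known limitations

* Only binary, balanced, matched-pair designs; no multi-class or unmatched
  variants.
* Linear kernel only; no hyperparameter learning.  Whether per-fold
  covariance optimization would change results is untested here.
* Images are never resampled; grids must match the mask exactly (affine
  tolerance 1e-4).
* Permutation p-values at 99 permutations have granularity 1/99; study-scale
  analyses should use 1000 as in the defaults.
* The discrimination map is a decision-boundary representation; it supports
  no voxelwise inference and is deliberately unthresholded.
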