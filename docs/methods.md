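# Methods

This note documents the statistical procedures implemented in `lesionnet`,
the design choices made where several reasonable options existed, the
synthetic-data generator's model, and the package's known limitations.

## Volumetric data model

All volumes in one analysis share a single grid (shape + 4×4 voxel-to-world
affine, agreement tolerance 1e-4 on the affine). No resampling is performed
anywhere: a mask on a different grid is an error, not a warning. Masks
binarize at strictly > 0. Lesion volume is voxel count × voxel volume (mm³).
Regional damage defaults to the fraction of the *lesion* inside a named
atlas region — the per-lesion covariate meaning of "damaged more of the
cortex" — with the fraction of the region damaged available as a secondary
metric. Region fractions over an atlas that partitions the brain sum to 1
for any lesion inside the brain mask.

Peak lesion overlap is reported as a percentage rounded to the nearest
integer (18/76 → 24%), matching how such figures are conventionally printed.

## Lesion network maps

The seed signal of a lesion is the unweighted mean time series over
seed ∩ brain voxels; unweighted because no principled voxel weighting is
available for binary masks and the mean is robust to lesion size. Per
subject, the seed signal is Pearson-correlated with every brain voxel;
voxels with zero temporal variance get r = 0 and are flagged. Correlations
are clamped to |r| ≤ 1 − 1e-7 before the Fisher transform so a voxel inside
its own seed maps to a finite z ≈ 8.4. Across subjects the default
aggregate is the voxelwise mean z; a one-sample t aggregate is available
behind a flag (both are in circulation for normative-connectome pipelines
and the choice is not identifiable from summary statistics alone).
ROI-to-ROI connectivity applies the same recipe between two mask-mean
signals and averages z across subjects; it is symmetric in its arguments.

## Voxelwise permutation inference

The voxelwise statistic is the Aspin–Welch V (Welch's unequal-variance
two-sample statistic) with Welch–Satterthwaite degrees of freedom. Nuisance
covariates are handled by Freedman–Lane permutation: residualize the data on
the nuisance model (intercept always included), permute residual rows,
re-add the nuisance fit, re-residualize, recompute V. The observed statistic
is likewise computed on nuisance-adjusted values.

Design and numerical choices:

- **Permutation unit.** With nuisance covariates the statistic depends on
  the full row permutation, not just the induced group partition, so the
  number of distinct permutations is n!. When n! ≤ the requested
  permutation count the space is enumerated exhaustively and
  p = (#{at least as extreme})/n! (the identity is part of the
  enumeration); otherwise p = (1 + #extreme)/(1 + n_perm) over random
  permutations, which is a valid p-value by construction and never smaller
  than 1/(1 + n_perm).
- **Tie handling.** Permutation statistics within a relative 1e-9 of the
  observed one count as ties. Without this, mathematically identical
  statistics computed from rows in a different order can flip a strict
  comparison by ~1e-16 and make p-values depend on subject ordering;
  with it, exhaustive p-values are bit-reproducible against independent
  enumeration.
- **Sidedness.** Two-sided tests use |V| (discovery); one-sided tests must
  declare their direction (validation and DBS analyses use one-sided
  conventions).
- **FWE** comes from the max-statistic null distribution over the analysis
  mask, which guarantees p_fwe ≥ p_unc voxelwise. **FDR** is
  Benjamini–Hochberg step-up, computed within the supplied ROI when one is
  given. A supplied ROI restricts the entire analysis (statistic, FWE
  maximum, FDR family) to ROI ∩ mask, which is the meaning of an a-priori
  region-of-interest test.
- **Degenerate voxels.** Both group variances zero: V = 0 when the means
  agree (p = 1), ±inf when they differ; df is NaN in either case.
- **Default n_perm = 5000**; analyses in this repository's tests use
  199–499 permutations, which resolves FWE thresholds at α = 0.05 while
  keeping simulation suites fast. Fixing the seed fixes every output bit.

Univariate VLSM reuses the same engine with roles swapped: at each voxel
lesioned in ≥ `min_lesioned` patients (default 5; unstated in the source
analyses, chosen as the customary floor) and spared in ≥ 2, nuisance-
adjusted epilepsy status is contrasted between lesioned and spared patients.
Voxelwise outcome correlation computes partial Pearson r per voxel after
residualizing both sides on the nuisance model and permutes outcome
residuals.

Calibration, not numeric identity to any particular neuroimaging toolbox,
is the contract: under exchangeable-null simulations the uncorrected
rejection rate at α = 0.05 stays within [0.04, 0.06] and whole-run FWE false
positives occur at ≈ 5%, which the acceptance checks measure.

## Risk model

Lesion network nodes are voxels with corrected p < α (default α = 0.05,
FWE) and the defining contrast's sign (negative: epilepsy lesions are
anticorrelated with the nodes). The node map records that sign. The risk
score of a lesion is sign × z(lesion, nodes), i.e. the negated connectivity
for anticorrelated nodes, so that **larger score = higher epilepsy risk**;
this orientation is stated everywhere because the defining contrast is
negative while the DBS benefit score (below) is deliberately unflipped.

Leave-one-dataset-out scoring derives nodes from the other datasets'
contrast (adjusted for lesion volume and dataset indicators) and scores each
held-out lesion against them; per-fold provenance is recorded and audited by
tests (a lesion's own dataset never contributes to its nodes). A fold whose
contrast yields no significant voxel reports the failure and leaves its
lesions unscored rather than silently re-thresholding.

Odds ratios are reported per 1 SD of the score (scale-free, matches the
±1 SD stratification; the original unit is not recoverable from summary
statistics). Perfect separation is flagged and no OR is reported.
Stratification: high = score > mean + SD, low = score < mean − SD, exact
boundaries fall in the moderate stratum; cutoffs are pooled across datasets
by default with a within-dataset mode provided. The χ² test is Pearson's
without continuity correction; AUC is the Mann–Whitney probability with
ties credited 0.5.

A note on attainable discrimination: a true odds ratio of 2.8 per SD bounds
the achievable AUC near 0.75 even for perfect scores, so out-of-sample AUCs
in the low 0.7s are the expected behavior of a well-calibrated pipeline at
that effect size, not a shortfall of the scoring.

## Mediation

Paths: a from linear M ~ X; c from logistic Y ~ X; b and c′ from logistic
Y ~ M + X, all on standardized X and M (binary-outcome mediation on the
logit scale; counterfactual estimators are out of scope). The indirect
effect a·b gets a percentile bootstrap CI (default 5000 resamples; no BCa),
resampling subjects and refitting both paths per draw. The verdict rule —
"full" if the CI excludes 0 and the direct path c′ has Wald p > 0.05,
"partial" if both are significant, "none" otherwise — is this package's
operationalization of "fully mediated". Bootstrap refits use an internal
Newton/IRLS logistic solver for speed; headline estimates and p-values come
from statsmodels. Non-convergence, separation, or > 50% degenerate bootstrap
draws flag the result and suppress the verdict.

## DBS analysis

Stimulation sites (volumes of tissue activated) are consumed as binary
masks; electrode localization and field modelling are out of scope. The
benefit score is site-to-node connectivity with **positive** orientation:
the clinical logic is inverted relative to lesions (lesions anticorrelated
with the nodes cause seizures; stimulation positively connected to the
nodes relieves them). Outcomes code improvement as positive percent change
in seizure frequency, making the expected association a positive r. The
outcome correlation uses a one-sided (positive) permutation p by default
(10 000 permutations), partial correlation via residualization when controls
(stimulation amplitude, VTA volume) are supplied — constant control columns
are dropped, so they cannot change the estimate — and an optional
leave-one-out sensitivity table for outlier checks.

## Synthetic data generator

The generator is factor-structured. Voxel v of every subject carries

    x_v(t) = lam(v)·f(t) + eta·sin(theta_v)·g(t) + eta·cos(theta_v)·h(t) + sigma·eps_v(t)

with f, g, h, eps iid standard normal, sigma = 1 by default. The brain is a
radius-8 sphere in an 18³ grid of 2 mm voxels; the primary loading `lam` is
a linear gradient spanning [−1, +1] along x, overridden to +1 inside the
planted node (radius-2 sphere at the positive end of the gradient, so the
high-loading cap is a single coherent region). Two voxels with loadings
l_a, l_b on the primary latent alone correlate at
l_a·l_b/√((l_a²+σ²)(l_b²+σ²)) — 0.5 for two node voxels at σ = 1 — which the
tests verify against sample correlations.

The quadrature nuisance pair (g, h) deserves explanation because it is what
makes node recovery a real test. Its loadings have constant power η² = 1 at
every voxel outside the node (zero inside), with phase θ winding four full
periods along y. Consequences: (i) every non-node voxel carries
epilepsy-irrelevant connectivity variance, which suppresses the group
contrast there and makes the nuisance-free node the unique peak — without
it, the contrast is nearly flat across the loading gradient and the peak
voxel is an extreme-value lottery; (ii) the phase period (≈ 4 voxels, a
typical lesion diameter) keeps nuisance loadings coherent within single
lesions but averages them out over extended ROIs, so mask-mean signals are
not dominated by a single nuisance mode. The closed-form two-voxel
correlations above apply to nuisance-free voxel pairs; tests of the pure
gradient (e.g. the −0.5 anticorrelation of opposite-end voxels) set η = 0.

Lesions are random spheres (radius uniform on 1–3 voxels) centered at
uniform brain voxels, intersected with the brain; dataset labels rotate
round-robin over five etiologies with per-dataset radius multipliers
(0.6, 0.8, 1.0, 1.3, 1.6) that plant a lesion-size-by-dataset confound, so
covariate adjustment is actually exercised. A lesion's true node
connectivity is its mean primary loading c_i; the standardized, sign-flipped
s_i = −standardize(c_i) enters the label model
epilepsy ~ Bernoulli(logistic(β₀ + β₁·s_i)) with β₀ = −0.619 (baseline
prevalence 0.35) and β₁ = ln 2.8 (planted odds ratio per SD). The DBS
cohort places 30 VTA spheres near a fixed locus on the gradient with ±3
voxel jitter; outcome = 30 + 25·z_i + 31·noise truncated to [−100, 100]%,
where z_i is the standardized true site loading, so the planted population
correlation is 25/√(25² + 31²) = 0.628 (truncation attenuates it mildly).
One master seed drives named substreams for connectome, cohort and DBS
stages; identical configurations reproduce bit-identical data.

What the generator does *not* emulate: hemodynamics, temporal and spatial
autocorrelation of real fMRI, realistic lesion geometry, registration
error, or between-subject connectome variability beyond iid noise. Passing
recovery tests therefore demonstrates that the pipeline's statistics are
correct and well calibrated under a known factor model — not that the
method's anatomical claims hold in real patients.

## Problem sizes used by the test and acceptance suites

Chosen to exercise every stage at desk scale: the default study is a
20-subject connectome (150 time points, ≈ 2100 brain voxels) with 120
lesions across 5 datasets; recovery suites run 20 seeded replicates with
499 permutations. Null-calibration suites use a 12³ grid, 8 subjects, 40
lesions and 199 permutations across 100 replicates (≥ 50 000 voxel-tests).
Mediation recovery uses n = 1000 with 400 bootstrap draws; DBS recovery
uses 200 replicates of the 30-patient cohort.

## Known limitations

- Exhaustive enumeration is only feasible for small n (n! permutations);
  larger designs rely on Monte Carlo p-values with the add-one estimator.
- The permutation engine targets calibration, not numeric identity with any
  specific neuroimaging toolbox's covariate-aware statistic.
- LODO folds with no significant voxels leave their dataset unscored; with
  few datasets this can remove a substantial fraction of the cohort from
  downstream OR/AUC estimates.
- The mediation verdict rule is a conventional operationalization, not a
  causal identification result.
- Percentile bootstrap CIs are first-order accurate only; BCa is not
  implemented.
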