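# Methods

This note records the models, conventions and numerical choices behind
`trusrad`, and what the synthetic experiments do and do not demonstrate.

## Problem and data model

The task is binary prediction of prostate-cancer status from radiomic
descriptors of a segmented gland in grayscale TRUS volumes, with a
radiologist's MRI-based verdict available as a third information source.
A video clip is treated as a single 3D stack (frames along the third
axis); per-frame 2D extraction is deliberately out of scope. The unit of
extraction is an `ROIVolume`: a float intensity grid, an aligned binary
mask with at least two foreground voxels, and a purely descriptive voxel
spacing (no resampling or intensity normalisation is performed).

## Texture features

**Catalog.** The descriptor catalog enumerates shape (14), first-order
(18), GLCM (24), GLDM (14), GLRLM (16), GLSZM (16) and NGTDM (5) on the
original image — 107 descriptors — and the seven non-shape classes over
eight wavelet sub-bands (93 × 8 = 744), 851 in total. Only the
14-descriptor signature has numeric implementations; requesting any other
catalogued descriptor raises `NotImplementedError` rather than silently
returning a number.

**Wavelet transform.** Single-level undecimated (stationary) separable
3D transform: each axis is filtered circularly (periodic extension) with
the decomposition low- or high-pass filter, with no downsampling, so
every sub-band keeps the input extents and the original mask applies.
The filter is placed so that output sample n uses taps x[n], x[n+1], …
— a pure phase convention, consistent across sub-bands and irrelevant to
mask-aggregated statistics. Default family is Coiflet-1; any PyWavelets
family name is accepted, and grids smaller than the filter length are
rejected with the offending axis named (tiny test phantoms therefore use
Haar). `pywt` supplies only the filter coefficients; the transform itself
is implemented here because the library's stationary transform requires
even extents, which the small-phantom oracle grids do not have.

**Discretisation.** Fixed bin width (default 25 intensity units — about
ten levels over an 8-bit ultrasound dynamic range), anchored at the
masked minimum: level(v) = floor((v − min)/w) + 1. Anchoring makes the
levels invariant to global intensity shifts. Each wavelet sub-band is
discretised independently against its own masked minimum. A flat region
yields a single level; texture features then take their documented
closed-form values (GLCM shade/prominence 0, correlation 1; GLSZM of one
zone; GLDM of full dependence) instead of raising, so batch extraction
never aborts.

**Matrices.** GLCM: one symmetric co-occurrence matrix per direction over
the 13 unique distance-1 offsets, features averaged over directions with
at least one masked pair; a direction with vanishing marginal SD has
Correlation defined as 1 (degenerate perfect dependence). GLSZM: zones
are 26-connected components of constant level inside the mask
(6-connectivity available). GLDM: dependence is 1 + the number of
26-neighbours inside the mask within level tolerance α (default 0); the
centre voxel counts itself, so d ≥ 1. First-order Skewness uses
population moments with the zero-variance case defined as 0.

All texture values are verified against independent brute-force
enumeration (explicit pair loops, BFS flood fill, per-voxel neighbour
counts) on random masked grids up to 5×5×5.

## Selection chain

The order is fixed — reproducibility filter, univariate screen, variance
filter, LASSO — and each stage's survivors are a subset of its input.

**ICC.** Two-way random effects, absolute agreement, single rater
(ICC(2,1)), computed per feature from the two-way ANOVA mean squares;
its expectation under the shared-subject-effect model is
σ²subject/(σ²subject + σ²noise), which is exactly what the rater-pair
generator prescribes. Zero-variance features have an undefined ICC,
reported as missing and failing the ≥ 0.8 filter (boundary inclusive).

**Screen.** Welch's (unequal-variance) t-test and the Mann–Whitney U per
feature; retention by default requires significance on *either* test at
α = 0.05 (the lenient reading — the LASSO prunes downstream), with a
strict-AND flag. Welch rather than pooled variance because no per-feature
homogeneity check is part of the design.

**LASSO.** L1-penalised logistic regression (squared-error loss on the
0/1 labels available as a flag). The penalty grid is log-spaced from the
data-derived λ_max = max_j |x_jᵀ(y − ȳ)|/n (the smallest penalty with an
all-zero solution when the intercept is unpenalised) down to
λ_max·10⁻⁴ over 100 points by default. For each repeat an independent
stratified 10-fold partition is drawn; the full path is fitted on each
training fold (features standardised within the fold, warm starts along
the path) and held-out deviance accumulated; λ* minimises the mean
deviance (plain minimum, not the 1-SE rule, since the design reports a
single precise λ). The final model is refitted on all rows at λ*;
features with nonzero coefficients are the selection. The default of 50
CV repeats is a deliberate scale-down of the design's 100,000: λ*
stabilises (SD below half a log-grid step across independent runs) by
about 20 repeats on synthetic cohorts, so further repeats only burn CPU.
Solver: liblinear coordinate descent via scikit-learn with a large
`intercept_scaling` so the intercept penalty is negligible; it produces
exact zeros and, at λ → 0 on well-conditioned n ≫ p data, matches the
unpenalised logistic fit to ~10⁻³.

## Classifiers

Both models tune by stratified 10-fold CV on training rows only, scored
by mean accuracy by default (AUC by configuration), over decade-spaced
grids (C ∈ 10⁻²…10³, γ ∈ 10⁻⁴…10¹, trees ∈ {10, 10², 10³, 10⁴}); an
optional refinement pass searches a finer multiplicative grid around the
winning decade. The standardising scaler lives inside the CV pipeline,
so held-out rows never leak into tuning (pinned by a perturbation test).
SVM probabilities are sigmoid (Platt) calibrations of the decision values
fitted on internal CV folds; RF probabilities are the fraction of trees
voting malignant.

## Fusion rule and threshold

The fused score is the nested convex combination given in the README.
Inputs are validated, never clamped — calibrating upstream probabilities
is the caller's contract. Binary calls use threshold 0.5 with ties called
malignant (the conservative direction for a cancer screen). The rule is
*not* monotone in P_RF: the sub-model contribution 2|0.5 − p|·p peaks
inside (0, 0.5). That is a property of the published rule and is pinned
by a test so it cannot be "fixed" away. Each reader tier is a single
verdict column; aggregating multiple readers per tier is out of scope.

## Evaluation statistics

AUC is computed by the rank (Mann–Whitney) identity with ties counted
half and verified against exhaustive pair counting. Proportion CIs are
Clopper–Pearson exact beta quantiles by default (guaranteed ≥ nominal
coverage; Wilson optional) because the printed intervals of small
cohorts cannot be reverse-engineered to a unique method. Paired AUC
comparisons use the DeLong structural-components test (two-sided normal
approximation; identical scores give p = 1, degenerate variance with a
nonzero difference is reported missing); a case-swap permutation test is
provided for contrasts against binary verdicts. The cohort summary gates
the continuous-variable test on Shapiro–Wilk normality per group (Welch t
if all normal, otherwise Mann–Whitney) — note this deliberately uses a
normality test where the original description names the Levene
variance-homogeneity test for that role — and chi-square for categorical
variables.

## Synthetic data: what it emulates and what it does not

Feature tables are Gaussian within class (log-normal via a flag to
exercise the rank-based screen), with features in equicorrelated blocks
(one-factor construction, default ρ = 0.3, block size 10) and the first
k features shifted by the effect size (in within-class SD units) in the
malignant class. Rater pairs share per-subject effects and add
independent per-rater noise, so the true ICC is exactly the
variance-ratio. Reader verdicts are independent Bernoulli draws at the
stated sensitivity/specificity; the default junior (0.71, 0.60) and
senior (0.63, 0.87) profiles are the two tiers' test-set operating
points. Volumes are smooth correlated Gaussian fields (Gaussian-kernel
smoothing, SD 2 voxels) in an 8-bit-like range with an ellipsoidal mask;
the malignant class adds unsmoothed high-frequency noise (SD 25 gray
levels) so texture, not mean intensity, separates classes. None of this
models prostate anatomy, speckle physics or temporal dynamics — passing
tests demonstrate the *pipeline machinery* (recovery, calibration,
ordering), not clinical performance on real TRUS data.

Cohort class counts are free configuration rather than fixed study
numbers, because the source cohort description is internally
inconsistent (231 total vs. per-split counts summing to 265); nothing in
the pipeline depends on the totals.

## Problem sizes used by tests and the acceptance script

The test suite and `scripts/acceptance.py` run the simulations at sizes
chosen to make each property measurable with comfortable margin on a
single CPU: ICC recovery at n = 500 subjects; LASSO recovery at
n = 200, p = 100, k = 10, 1 SD effect, over 20 seeds with one 10-fold CV
repeat and a 25-point grid truncated at λ_max·10⁻² (the CV minimum sits
well above the truncation; the near-unpenalised tail of the default grid
adds nothing but solver iterations); Clopper–Pearson coverage at
n ∈ {15, 19, 30} with 10⁴ draws; DeLong null size with 10⁴ replicate
pairs of noisy copies of one latent score at n = 120; and the
fusion-benefit simulation at 300-patient cohorts with effect size 0.75,
where the tuned models land near AUC 0.78, the senior-reader verdict near
0.75, and the fused arm near 0.85, reproducing the expected ordering
fused > model > reader across 20 seeds.

## Known limitations

- Only the 14-signature descriptors are computed numerically; the other
  837 catalog entries are enumerable but not evaluable.
- No spacing-aware resampling, gray-level normalisation or 2D
  (per-frame) extraction.
- The fusion rule's weights are fixed by construction, not learned, and
  a single verdict stands in for each reader tier.
- DeLong is a large-sample approximation; for very small cohorts or
  binary-verdict arms prefer the permutation variant.
- NIfTI is the only volume container (images + masks as pairs); tables
  are plain CSV.
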