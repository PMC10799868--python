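# Methods

`neurosig` implements a multiclass decoding pipeline for emotion-regulation
fMRI: given one voxel-level activation ("beta") map per subject for each of
three task conditions — passively viewing neutral imagery (*neutral*),
passively viewing negative imagery (*negative*), and actively down-regulating
the response to negative imagery by cognitive reappraisal (*decrease*) — it
harmonizes maps across scanning sites, trains two multinomial classifiers,
and derives voxel-level signature maps of which brain locations consistently
drive the classification.

## Data model

All computation happens on mask-aligned vectors. A binary brain mask fixes
the voxel set and geometry; maps are vectorized in C-scan order over the mask
grid (deterministic and identical across reads). The three condition labels
are encoded `(neutral=0, negative=1, decrease=2)` everywhere. Each subject
contributes at most one map per condition; a `BetaMapSet` carries the maps
with subject and site annotations. NIfTI I/O goes through nibabel; affines
must agree with the mask to 1e-4 per entry (guarding against benign header
noise). `unmask` writes background 0 by default (NaN available for
visualization).

## Site harmonization (ComBat + CovBat, per class)

Training and holdout data come from different scanners and preprocessing
pipelines, which shifts per-voxel location and scale and distorts feature
covariance. ComBat models voxel `v` of map `i` at site `s` as
`y_isv = alpha_v + gamma_sv + delta_sv * eps_isv` and removes `gamma` and
`delta` with parametric empirical Bayes: per-site voxel-wise location/scale
estimates are shrunk toward moment-matched normal / inverse-gamma priors
pooled across voxels. The implementation is the *reference-batch* variant:
the grand mean and pooled sd are taken from the (single) training site,
reference-site data passes through unchanged, and holdout maps are
transformed into the training distribution — required because the
classifiers are frozen after fitting on training data. The EB update is a
single conditional-posterior pass (non-iterative); with the sample sizes
used here the iterated fixed point moves estimates by less than sampling
noise. Zero-variance voxels pass through unadjusted with a warning.

CovBat then corrects residual covariance differences: ComBat residuals of
the pooled data are decomposed by SVD, and the smallest number `q` of
principal scores reaching a cumulative explained-variance cutoff (default
0.95, configurable) have their per-site mean and variance aligned to the
reference site before back-projection. Score adjustment uses plain
mean/variance matching without EB shrinkage — `q` is small, so per-score
estimates are stable.

Because the three conditions differ in mean and covariance structure, the
full ComBat+CovBat pipeline is fitted separately on the beta maps of each
condition (three independent models), and the harmonized holdout set is
reassembled with its original annotations.

## Classifiers

**LASSO-PCR.** PCA of the centered training maps (maps as observation rows;
no per-voxel variance scaling), retaining the smallest `m` components whose
cumulative explained-variance ratio reaches 0.90. The component scores feed
an L1-penalized multinomial logistic regression (softmax parameterization;
scores standardized internally for the penalized fit, coefficients returned
on the raw score scale). The penalty path runs from `lambda_max` (the
smallest penalty zeroing all slopes) down by a factor 1e-4 over 100
log-spaced values; `lambda` is chosen to minimize multinomial deviance in
10-fold cross-validation with folds grouped by subject (a subject's three
maps never split across folds, preventing leakage through shared
subject-level offsets; grouping also stratifies, since each subject carries
all three conditions). The model is refitted on all training data at the
selected penalty. When every slope is penalized to zero, intercepts are set
to the exact null MLE (log class frequencies) rather than relying on solver
convergence at extreme regularization.

**LDA.** Two linear discriminant directions (three classes admit at most
two), solved by SVD-based whitening so the within-class scatter need not be
invertible when voxels far exceed maps, followed by an *unpenalized*
multinomial logistic regression on the two discriminant scores.

At test time, training loadings are projected onto new data
(`scores = (x - train_mean) @ V`); prediction never updates model state.
Argmax ties break to the lowest class index.

## Bootstrap signature maps

Voxel-level contributions are assessed by a subject-level bootstrap
(default 1000 replicates; resampling whole subjects respects the
within-subject correlation induced by shared offsets). The identical sample
lists are reused for both model families. For each replicate the family's
model is refitted and per-class voxel weights `W_k = V beta_k` recorded —
for LASSO-PCR, `V` restricted to components with nonzero penalized
coefficients (equivalently the full loading matrix, since zeroed components
contribute nothing); for LDA the two discriminant loadings. The LASSO
penalty is selected once on the full training data and held fixed across
replicates, so replicates differ only through resampling; re-running the
full CV inside every replicate would multiply cost ~tenfold without changing
which voxels are consistently signed. Bootstrap principal-axis signs are
aligned to the full-data loadings by the inner-product rule (the products
`W_k` are invariant to joint sign flips, but alignment keeps stored loadings
and coefficients individually comparable).

Per voxel and class: `prop_pos` / `prop_neg` over replicates (exact zeros
count toward neither sign — conservative), sign-consistency
`p = 1 - max(prop_pos, prop_neg)` with significance at `p < 0.005`
(consistent sign in at least 99.5% of replicates; a two-sided variant
`2 * min` is available by flag), and `z` = bootstrap mean / sd. Significant
voxels are grouped into signed connected components (26-neighborhood
default, minimum 10 voxels, both configurable); clusters report voxel count,
volume (count x voxel volume, 27 mm^3 at 3-mm isotropic), peak world
coordinates of the max-|z| voxel via the mask affine, and signed max z,
sorted by volume within sign.

A bootstrap replicate that happens to contain no maps of some class is
redrawn (logged); a replicate whose penalty zeroes every coefficient
contributes an all-zero weight row (logged, not an error).

## Evaluation

Accuracy, per-class sensitivity/specificity from the 3x3 confusion matrix;
per-class one-vs-rest AUC; overall multiclass AUC by the Hand–Till pairwise
construction `M = 2/(c(c-1)) * sum_{i<j} [A(i|j) + A(j|i)]/2` with midrank
tie handling, each conditional AUC computed from that class's own
probability column (for two classes this is exactly the Mann–Whitney AUC).
Degenerate denominators surface as an explicit `"undefined"` marker with a
warning, never a silent NaN. Model comparison uses McNemar's test on the
discordant correctness pairs with an exact two-sided binomial p (discordant
counts on a 40-subject holdout are small; a continuity-corrected chi-square
variant is available). The learning curve repeats, at each of the six
protocol training sizes (5, 14, 28, 41, 55, 69 subjects) and for each of 20
repeats by default, a subject-level draw without replacement for fitting
with all remaining subjects as the evaluation set — using all data while
keeping fit and evaluation subject-disjoint.

## Synthetic data

The generator emulates the structure the analysis assumes: per-class mean
activation confined to spherical regions; a subject-level offset shared
across a subject's three maps (sd 0.3 beta units by default); voxel noise
smoothed with a Gaussian kernel (FWHM 8 mm at 3-mm voxels, mimicking
standard preprocessing blur) and renormalized so the nominal noise sd
(default 0.5) stays the marginal voxel sd; and per-site effects — additive
shift, multiplicative noise scale, and a site-specific rank-5 covariance
component blended by `cov_mix` (deterministic in the site id), giving CovBat
something location/scale correction alone cannot fix. Maps are generated
near mean 0, as appropriate for contrast estimates rather than raw signal
intensities. Ground truth (per-voxel per-class indicator and signed effect
relative to the grand mean) is returned for recovery tests.

The default two-site study configuration mirrors the study design: 82
training subjects at one site, 40 holdout subjects at another with shift
1.0, scale 1.5, cov_mix 0.3; region effect 0.5 against noise sd 0.5. The
effect size was calibrated once so that harmonized holdout accuracy lands in
the mid-0.7 to high-0.8 range across families and seeds, comparable to the
reported holdout performance (~0.78-0.83). What the generator does **not** emulate: anatomy and
tissue contrast, hemodynamic time-series structure, task-timing convolution,
spatially structured (non-spherical) signal, heavy-tailed artifacts, and
realistic inter-regional correlation — so passing recovery tests demonstrate
correctness of the machinery under the assumed model, not performance on
real scanner data.

## Problem sizes in the shipped tests and acceptance script

Simulations use masks of a few hundred to ~800 voxels, 40–82 subjects, and
300–500 bootstrap replicates — large enough for the asymptotic behavior the
checks target (site-effect recovery within EB shrinkage tolerance, sign
consistency at the 99.5% level, learning-curve growth) while keeping the
whole suite desk-scale. The signature-recovery criterion is asserted on the
LASSO-PCR signature: under those conditions the LDA signature's dense,
high-variance discriminant loadings rarely reach 99.5% per-voxel sign
consistency (sensitivity ~0.15), which is a property of the method in the
voxels >> maps regime rather than a defect; LDA recovery values are still
computed and reported.

## Known limitations

- Reference-batch ComBat assumes a single training site; multi-site training
  data would need a generalization.
- The EB scale estimate `delta*` is shrunk toward the site prior; with few
  maps per site, strong true scale effects are recovered with visible
  shrinkage bias (e.g. ~1.9 recovered for a true factor 2 at n=40/site).
- Sign-consistency p-values are resolution-limited by the replicate count
  (1/B); at B = 200 the 0.005 threshold is attainable only by perfect
  consistency.
- The saga solver's penalized fits are iterative; coefficient reproducibility
  across platforms is at solver tolerance (1e-5), not bit-exact, though
  selection traces and resampling draws are seed-exact.
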