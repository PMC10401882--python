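# Methods

## The problem and the model

Feature maps pooled over S scanners follow, per subject i and feature
(voxel) v,

    Y[i,v] = alpha[v] + X_signal[i,:] beta[:,v] + gamma[site(i),v]
             + delta[site(i),v] * eps[i,v]

where X_signal holds the biological covariates (age in years, sex and
diagnosis as 0/1 indicators), gamma/delta are additive/multiplicative site
effects and eps is residual noise. The package provides three estimators of
"Y without gamma and delta" and the tooling to judge them.

### Dual-projection ICA (the core method)

Spatial ICA factorizes the feature-wise-centered matrix, Y − mean = A·S,
with S rows independent across features. Each mixing course A[:,c] is
tested against every signal variable (Pearson correlation; point-biserial
for binary) and against site (one-way ANOVA). All C × (n_signal_vars + 1)
tests of one run form a single Bonferroni family. Labels follow the
significance pattern: signal-only → *signal*, site-only → *noise*, both →
*mixed*, neither → *unclassified*. Unclassified components are always
retained: removing structure that is significant for nothing would discard
unexplained variance with no justification, and the count is logged.

Single projection removes only the pure noise courses; dual projection
first replaces each mixed course by its residual after regression on the
signal design (with intercept), then removes pure-noise and purged-mixed
courses together. Both are least-squares projections realized by
`numpy.linalg.lstsq` with a relative singular-value cutoff of 1e-10·σ_max,
so rank-deficient bases (duplicated or collinear courses) fall back to the
minimum-norm projection without error.

**Intercept convention.** The bare projection equations would also remove
any grand-mean component that overlaps the course columns. By default every
projection basis is augmented with the all-ones column and the per-feature
means are restored afterwards, so harmonized data keeps its original grand
mean and stays directly comparable to ComBat's restore step; `raw_eq=True`
reproduces the literal equations. With an empty basis both modes are the
exact identity.

**What the projections do not do.** SP/DP are linear operations in subject
space: they remove additive site structure expressible in the span of the
selected courses, but multiplicative (variance) site effects are untouched.
ComBat handles those through delta*.

### ICA details

Whitening is done in-package: feature-wise centering, SVD, projection onto
the top C right-singular vectors scaled to unit variance across features.
The seeded fixed-point rotation (logcosh contrast, symmetric/parallel
decorrelation, tol 1e-6, max 1000 iterations) is scikit-learn's `fastica`
run with `whiten=False`; doing the whitening ourselves avoids sklearn's
extra per-sample centering, which would otherwise break the exact
reconstruction Y − mean = A·S at full rank. Components are ordered by
explained variance and sign-fixed (largest-|value| map element positive) so
runs are bit-reproducible given the seed. Non-convergence is a warning plus
a `converged=False` flag, never an exception — the partially converged
rotation is still an orthogonal basis of the PCA subspace and the
projection algebra downstream does not depend on full ICA convergence. No
attempt is made to reproduce any particular ICA toolbox's output; the
contract is a valid seeded ICA factorization.

### ComBat

The classical parametric empirical-Bayes procedure: per-feature least
squares on [site one-hot | signal covariates], grand intercept as the
site-size-weighted mean of site intercepts (which enforces the weighted
sum-to-zero constraint on the naive additive estimates), standardization by
the pooled residual variance, then per-site shrinkage — normal prior for
the location, inverse-gamma for the scale, hyperparameters by method of
moments across features, fixed-point iteration to tol 1e-8 (max 500; the
update order and stopping rule follow the standard implementation, only
tighter). Sites need ≥ 2 subjects; a design in which a site perfectly
predicts a covariate is rejected as confounded. The restore step divides by
sqrt(delta*) in standardized space — the published equation's typesetting
is ambiguous about that grouping, and the standard ComBat restore is used.

The environment provides no reference ComBat implementation, so the test
suite carries an independently written naive oracle (explicit per-feature
loops, per-feature fixed points iterated to 1e-12) and requires 1e-6
relative agreement of the harmonized matrices.

## Feature measures

**ALFF.** Per voxel: linear detrend, real FFT, one-sided amplitude
2|F_k|/t per positive-frequency bin, summed over bins with frequency in
[low, high] (default 0.01–0.1 Hz, closed band edges; the DC bin is always
excluded). The "total power" of the ALFF literature is implemented as a sum
of amplitudes, the convention of the standard toolboxes; `stat=` switches
to mean amplitude or summed squared amplitude, and every downstream
harmonization step is invariant to that choice up to scale. Band-edge
inclusivity is controlled by `closed=` so ALFF is exactly additive over
abutting bands.

**ReHo.** Kendall's coefficient of concordance over the 7/19/27-voxel
neighborhood, mid-ranks for ties and the tie-corrected denominator. Voxels
near the mask boundary use whatever in-mask neighbors exist (variable K);
isolated voxels (K = 1) emit W = 0 and are counted in a log line.

**Smoothing order.** Spatial Gaussian smoothing (σ = FWHM/(2√(2 ln 2)),
mask-aware renormalization) is applied to every 3-D frame *before* ALFF but
to the map *after* ReHo — smoothing a series before rank-transforming it
changes neighbor concordance, so the order is part of the definition.

## Synthetic generator

The generator emits exactly the generative model above. `abide_like_spec`
calibrates it to the packaged 16-site demographics table: per-site subject
counts (summing to 795), age ~ truncated-normal (site mean ± sd, floor 5
years), sex and diagnosis ~ Bernoulli with the site's observed proportions.
`confound_strength` interpolates every site's covariate parameters between
the pooled cohort values (0: covariates independent of site) and the
per-site values (1: the fully confounded real cohort); the calibrated spec
defaults to 1. Site effects default to additive offsets gamma ~ N(0, 0.5²)
per site × feature (weight-centered across sites, matching ComBat's
identifiability constraint) and delta = exp(N(0, 0.2²)), against unit
noise — site offsets comparable to the noise sd, which at n = 795 makes
virtually every feature site-significant before harmonization, the regime
the method targets. Signal effects sit on contiguous random feature blobs
(defaults: age −0.02 per year on 30% of features, sex and diagnosis +0.3 on
20%): weak enough per-subject to be maskable, localized so that detection
tests have ground truth. `age_masking_spec` is the signal-preservation
scenario: a broad (60% of features) negative age effect of −0.02/year under
moderate confounding (0.5), where between-site offsets attenuate the
age–summary correlation until the site variance is removed.

Noise is Gaussian — deliberately matching ComBat's parametric assumptions
so that EB recovery is testable — and the generator does not emulate
spatial autocorrelation, motion or hemodynamics; a green end-to-end test
establishes the estimators' statistical behavior under the stated model,
not robustness to real-scanner artifact structure. The time-series
generator (sinusoids + white noise, per-site in-band amplitude scaling) is
a fixture for the spectral/concordance measures, not a hemodynamic model.

## Evaluation

Site and signal tests are partial F-tests by extra sum of squares between
nested OLS fits, vectorized across features; the site factor is
reference-coded on top of intercept + covariates. FWE control is Bonferroni
across features by default (the conservative choice when the correction
method is unspecified), with a max-statistic permutation alternative.
"Factor: age" is a linear term's 1-df partial F — a one-way ANOVA on a
continuous variable is not otherwise defined. Age-effect analyses can be
restricted to healthy controls. The median-ROI summary is median within
each ROI, then median across ROIs (a pooled-median alternative is a flag),
against a synthetic parcellation of 100 contiguous equal blocks — the
summary only needs ROIs to be fixed disjoint feature groups, not an
anatomical atlas. t-SNE embeddings (perplexity 30, fixed seed, PCA init)
are diagnostics; only silhouette bounds on constructed data are asserted.

## Known limitations

* When site and signal variables are nearly confounded (canonical
  correlation of site indicators vs signal design > 0.95) the intersection
  variance cannot be attributed; `harmonize` warns and the purged courses
  carry away shared signal. This is the method's documented failure regime.
* Multiplicative site effects pass through SP/DP (see above).
* Classification inherits the power of its univariate tests: at small n or
  weak site effects, noise components can land in *unclassified* and
  survive denoising.
* The cohort-calibrated generator reproduces site structure and covariate
  confounding, not spatial or temporal autocorrelation; effect sizes on
  real data will differ.
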