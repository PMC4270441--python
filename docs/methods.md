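# Methods

This note records the models, conventions and numerical choices behind
`repbench`, and what its synthetic validation does and does not establish.

## Kernel analysis

Given a representation X (n images × d features) and category labels, we form
the Gaussian kernel K_ij = exp(−‖x_i−x_j‖²/2σ²) and solve kernel ridge
regression at each regularization λ. The leave-one-out residual of example i
is computed in closed form as α_i / (K+λI)⁻¹_ii with α = (K+λI)⁻¹y; with the
eigendecomposition K = VΛVᵀ both quantities are O(n²) per λ, so one
eigendecomposition per σ serves the entire λ grid. The closed form is exact
(validated against explicit retrain-without-i to 1e−8 in the test suite);
eigenvalues are clipped at zero to absorb −1e−15-scale numerical negatives.

**Labels.** Multiclass problems use one-vs-all squared-loss regressions. Each
category's 0/1 indicator is centered (y_c = 1{c} − p_c, p_c the category
fraction) and its LOO mean-squared error is divided by mean(y_c²) =
p_c(1−p_c). This normalization is what gives the stated conventions: a
predictor pinned at zero — equivalently at the base rate — scores a
normalized error of exactly 1 in every class (precision 0), and perfect
prediction scores precision 1. Per-class normalized errors are averaged over
categories before subtracting from 1. With raw (uncentered) indicators an
uninformative representation could still predict the base rate and score
1/C; centering removes that offset.

**Grids.** σ is scanned as 2^c·σ_med for 32 exponents c evenly spaced in
[−3, 3] (σ_med = median pairwise Euclidean distance; observed optima sit well
inside this range), and λ over 56 log-spaced values in [1e−6, 1e3], stored
descending so complexity 1/λ ascends. Both grids are configurable; the
desk-scale experiments below use 12 σ × 20 λ, which changes KA-AUC values by
less than the bootstrap spread. Per λ the σ minimizing LOO error is kept;
because σ re-optimization itself regularizes, curves plateau at high
complexity rather than collapsing.

**KA-AUC.** Area under precision vs log10(complexity) by the trapezoid rule,
divided by the log10 span, so a constant curve of precision p scores exactly
p and AUC reads as mean precision over the complexity range.

**Bootstrap.** Ten image subsets are drawn per analysis, each sampling
floor(0.8·n_min) images per category *with replacement* (n_min the smallest
category count, equalizing categories). Duplicated rows are kept and treated
as distinct examples by the LOO computation. The subset index sets are a
function of the seed alone and are reused across representations, so
representation differences are never image-subset differences.

## Neural-style preprocessing

Trial tensors (sites × images × trials) become feature matrices by
subtracting each site's background (blank) rate, dividing by the site's
response standard deviation, and averaging over trials. The normalizing
standard deviation is computed over all images × trials of the site unless an
explicit per-site scale is supplied — the recording-block structure that the
original normalization referenced is not reconstructible, and the full-data
standard deviation preserves the scale-equalization intent. Background
subtraction precedes normalization. Zero or negative scales raise rather
than silently producing infinities.

Site screening uses split-half consistency: trials are split into random
halves, image-response vectors averaged per half, and the Pearson correlation
recorded (mean over 20 random splits by default). Constant response vectors
yield an undefined (NaN) consistency, reported as missing, never as 0. The
Spearman-Brown prophecy formula 2r/(1+r) estimates full-data reliability.
Top-k selection ranks by split-half r with ties broken toward the lower site
index. A separate screening stimulus set may be passed; by default screening
runs on the evaluation set.

## Noise model and matching

After centering and scaling the population response to unit grand variance,
each site's trial variance is regressed on its trial mean across images and
the coefficients (a, b) averaged over sites with equal weight. The regressor
(a T-trial sample mean) carries sampling noise of variance Var(trial)/T that
would attenuate a naive least-squares slope and leak the lost slope into the
intercept — at desk scale (500 images, 50 trials) the bias exceeds 10% of a.
The fit therefore uses the standard measurement-error-corrected moment
estimator: slope = Cov(m̂, s²) / (Var(m̂) − mean(s²)/T). Sites whose mean
spread does not exceed their sampling noise are excluded with a warning.

The observed (trial-averaged) variance splits as σ²_total = σ²_signal +
σ²_noise with σ²_noise = mean over sites and images of max(0, a·μ+b)/T — the
standard error of a T-trial mean, not single-trial variability. T defaults to
47 when matching multi-unit samples and 6 for single units. σ²_signal is
floored just above zero; recordings where the SEM term exceeds the total
variance are rejected as carrying no resolvable signal.

Matching a model representation proceeds: subsample features (80 by default),
center and rescale globally so total variance equals σ²_signal (a single
multiplier, preserving all pairwise distance ratios), then add independent
zero-mean Gaussian noise of variance max(0, a·m+b)/T per entry. Negative
predicted variances at negative normalized entries clip to 0. Ten
independent noise draws are produced and downstream metrics reported as
mean ± std. The procedure is conservative by construction when applied to
neural data: the base representation retains its own residual trial noise on
top of the injection (verified in the conservativeness experiment below).

## Decoding and encoding

The linear-SVM protocol uses stratified 80/20 train/test splits (stratification
keeps chance exactly 1/C), 10 randomizations, and selects the penalty C per
split by stratified 5-fold grid search over 7 log-spaced values in
[1e−4, 1e2] on the training rows only. One-vs-rest LinearSVC (primal, squared
hinge) is the base classifier.

Encoding models are ridge regressions from model features to each site's
trial-averaged response, with the penalty chosen per site by generalized
cross-validation (21 log-spaced values in [1e−4, 1e6]) on training rows.
Performance per site is the Pearson correlation of held-out predictions with
the observed responses; the noise ceiling is the site's Spearman-Brown
corrected split-half trial consistency computed on the training images; the
summary is 100·r²_pred/r²_ceiling, median over sites within a split, mean
over splits. The squared-correlation ratio is the percentage-of-explainable-
variance convention; sites with non-positive ceilings are excluded with a
warning, and values above 100% are flagged rather than clipped. A raw per-site
r is also exposed for users preferring the un-normalized metric.

## Representational similarity

Object-level RDMs average feature vectors over each object's image
variations (49 objects in the default task) and take 1 − Pearson correlation
between object vectors; similarity between RDMs is the Spearman rank
correlation of strictly-upper-triangle entries (1176 values at 49 objects),
with average ranks for ties. RDMs are computed on held-out 20% image splits
(object-stratified, identical subsets across all representations). Because
the correlation distance centers each object vector, the exact invariance
class is global scalings, per-object additive shifts, and orthogonal
transformations of the *centered* feature space (rotations fixing the
all-ones direction); unrestricted feature rotations are preserved only
approximately, improving with dimensionality. Site split-half consistency
(50 random half-splits of sites × the image splits) bounds the similarity a
model could attain. The "+IT-fit" variant predicts site responses by ridge
encoding on the 80% training images and computes RDMs from the held-out
predictions only — fitting images never enter an RDM.

## Synthetic generator

The generator emulates the statistical structure the analyses assume. The
default geometry is the full study structure: 7 categories × 7 object
exemplars × 40 images = 1960 stimuli. Latent representations compose a
category centroid, an object offset and an image-level nuisance draw,
isotropic Gaussians with variances (1.0, 0.5, 0.5) by default in 20
dimensions — category structure strong relative to within-category
variation. Sites mix latent dimensions through fixed nonnegative uniform
weights on a positive background rate (2.0), and trials add Gaussian noise
with variance a·rate + b (defaults a=1, b=0.1 — Poisson-like variance ≈ mean
with a small floor), at T=47 trials and 168 sites. The Gaussian
linear-variance noise makes the estimation pipeline exactly well-specified;
a true-Poisson option exists for robustness checks (the mean–variance fit
recovers a≈1 there too). Multi-unit-like sites are sums of disjoint pools of
single-unit sites.

What the generator does *not* emulate: correlated (site × site) noise,
temporal spike dynamics, session/electrode drift, non-Gaussian count
statistics beyond the Poisson option, and any actual image computation.
Passing tests therefore establish internal correctness and well-specified
recovery, not performance claims about real recordings.

## Validation experiments and desk-scale choices

Repeated kernel analyses are run at reduced size: a 7-category × 2-object ×
10-image task (140 images; 280 for the experiments below) with 12 σ × 20 λ
grids. These sizes keep the full validation suite around a minute while
leaving bootstrap spreads small relative to the effects tested.

**Conservativeness.** For T ∈ {2, 6, 12, 47} and 10 simulation seeds, the
*empirical* condition averages a random subset of T of the 47 simulated
trials; the *injected* condition takes the full 47-trial average, rescales to
the estimated signal variance and injects model noise at trial count T. The
signal variance is estimated once at the full trial count — it is a property
of the recording, while only the injected noise level depends on T. This
experiment uses 280 images and 80 sites: at T=2 the trial averages are noisy
enough that smaller designs leave the AUC comparison within Monte-Carlo
error. The injected condition scores lower mean KA-AUC at every T (margins
≈ 0.02–0.03 AUC), confirming injection penalizes at least as hard as real
trial noise.

**Ranking agreement.** Five representations of graded quality share one draw
of category centroids, object offsets and nuisance; grade i scales only the
category component by √ratio, ratios (0.05, 0.15, 0.4, 1.0, 2.5). Nesting
the signal guarantees a true ordering — independently generated grades would
add cross-grade structural noise that can swap adjacent members. The family
uses stronger nuisance (4.0) and object (1.5) variances than the generator
default so the strongest grade stays below the linear decoder's 100%
ceiling; ties at perfect accuracy carry no ordering information. Under these
conditions kernel-analysis AUC and SVM accuracy order all five grades
identically (Spearman ρ = 1 per seed). The weakest two grades are separated
by only a few accuracy points, so ordering agreement there is near the
resolution limit of 5 decoding splits; occasional single-seed swaps appear
at other random seeds.

## Known limitations

- The σ and λ grid endpoints are package defaults; analyses of
  very high- or low-scale feature spaces may need wider grids.
- The noise model is independent across features/sites; correlated neural
  noise would require a different injection scheme.
- Explainable-variance normalization is undefined for sites with non-positive
  ceilings; such sites are dropped from medians rather than imputed.
- The "+IT-fit" RDMs inherit the encoding model's ridge bias on small
  training sets.
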