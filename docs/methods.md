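# Methods

This note documents the models, algorithms and numerical choices behind
`rnc`, and what the synthetic-data tests do and do not establish about
real data.

## Data model and preprocessing

Responses live in two containers.  `TrialBetas` holds trial-level beta
estimates `(trials × voxels)` with image and session labels;
`ResponseSet` holds image-level responses `(images × voxels)` with
unique image ids and per-voxel metadata (NCSNR, optional visual-field
tag).  All downstream selections are expressed in image ids — never
positional indices — with the `ResponseSet` image order as the canonical
order, so solutions remain valid across stores.

Betas are z-scored per voxel within each acquisition session.  The
divisor convention is configurable (`ddof=0`, population sd, is the
default; `ddof=1` for sample sd): published pipelines rarely state which
is used, and the two differ by a factor √(n/(n−1)) that is immaterial
for every downstream quantity except exact unit checks.  Voxel selection
keeps voxels with NCSNR *strictly* above the threshold (default 0.5,
with the conventional fallback of retrying at 0.4 surfaced in the error
message when nothing survives).

## Noise ceiling

For each voxel, the across-repeat variance (unbiased, n−1 estimator) is
averaged over images and rooted to give σ̂_noise; because z-scored betas
have unit total variance, σ̂_signal = √max(1 − σ̂_noise², 0) (positive
half-wave rectification), NCSNR = σ̂_signal/σ̂_noise (defined +∞ when
σ̂_noise = 0), and the noise ceiling for n averaged trials is
NC(n) = 100·NCSNR²/(NCSNR² + 1/n), in percent.  Model evaluation
computes per-voxel Pearson r across stimuli, sets negative r to zero,
squares, and divides by NC(n)/100 to give noise-ceiling-normalized
explained variance (NNEV).  Two conventions are ours: NNEV is capped at
100% (estimation noise can push r² above the estimated ceiling), and
zero-variance prediction or target columns yield r = 0 rather than an
exception, because constant in-silico voxels are legitimate degenerate
cases.  The three-predictor noise analysis (single trial / mean of two
trials / model output predicting held-out single trials, with the n = 1
ceiling; 6, 3 and 3 sub-predictions respectively) is implemented for
exactly three repeats.

## Univariate control

The baseline for an area is built by scoring random batches (default 25
images, drawn without replacement within batch) by their mean response
and taking the sampled batch whose score is closest to the null mean;
the null size defaults to 10⁶ (tests and the demo use 10³–10⁵ through
the identical code path).  Selection filters images by the margin
constraints (driven area: value > baseline + margin; suppressed:
value < baseline − margin; margin default 0.04 z-units) and ranks by sum
or difference.  Filtering before ranking is equivalent to the joint
statement of the procedure but remains well defined when fewer than 25
images qualify: the solution is returned short and flagged, not raised.
Ranking ties break by image id for determinism.  Cross-validation is
participant-wise leave-one-out: baseline construction and selection run
on the training-average profile (the margin therefore applies at
selection time only), and the held-out participant's mean responses over
the selected and baseline images evaluate the fold.

## Multivariate control

RSMs are image-by-image Pearson correlations of voxel patterns; RSA is
the Pearson r over the strictly-lower triangles (the constant unit
diagonal would inflate r).  The genetic search is elitist: each
generation keeps the `n_elite` best batches untouched (align: highest r;
disentangle: lowest |r|), adds one mutated copy per (elite, mutation
count) — that many images replaced by uniform draws from the pool,
rejecting within-batch duplicates — plus fresh random batches.  Elitism
makes the best score monotone, and on enumerable instances the search
provably reaches the exhaustive optimum when run long enough; the test
suite checks both.  Ranking ties break by an order-insensitive batch
hash.  Cross-participant aggregation averages RSMs entry-wise (not
patterns) both in the search objective and in the baseline null; NaN
scores (possible only for degenerate batches) rank last.

## Generative control

The two-phase global score is: `objective + 10¹⁰` while either area
misses its threshold (baseline ± 0.6 z-units; strict inequality), else
the PNG byte size of the image at a fixed compression level (default 9,
recorded in the config, since byte counts depend on it).  The objective
term is condition-signed so that *lower is always better* (−(u_A+u_B)
for drive-both, +(u_A+u_B) for suppress-both, −(u_A−u_B) when A is
driven, +(u_A−u_B) when B is driven); this single ordering reproduces
the verbal description of the algorithm in all four conditions.
Selection probabilities are softmax(z-scored negated score × 0.5), so
equal scores give the uniform distribution.  Children mix two parents
component-wise, taking each component from the higher-probability
parent with probability 0.75, then mutate each component independently
with probability 0.25 by *adding* a draw from N(0, 0.75²) (the additive
form was chosen where add-vs-replace was unstated).  The population is
re-evaluated every generation; since generator and models are
deterministic this is behaviourally identical to caching elite scores.

## Statistics

Permutation tests take the statistic and the exchange scheme as explicit
callables, so each analysis's exchangeability assumption (across image
conditions, areas, voxels, predictors) is a named preset rather than
hard-coded.  The p value is the plain proportion of randomized
statistics at least as extreme as the observed one ((b+1)/(m+1)
smoothing is available by flag but off by default, matching the plain
proportion definition); two-sided extremeness is measured around the
permutation mean.  Benjamini–Hochberg adjustment delegates to
statsmodels; the test suite checks it against an independently written
step-up rule.  Population prevalence is P = 1 − BinomCDF(k; n, α),
i.e. the probability of *more than* k significant participants under
the global null — the printed form of the formula, which reproduces all
the quoted significance bounds for cohorts of 8, whereas the alternative
tail P(X ≥ k) does not.  Bootstrap CIs resample participants with
replacement and take the 2.5/97.5 percentiles of the resampled means.

**Known limitation.**  The plain percentile bootstrap undercovers for
small cohorts: for the mean of n = 8 Normal values its interval is
approximately mean ± 1.96·σ̂₀/√8, which covers ≈ 89% rather than 95%
(P(|t₇| < 1.83) ≈ 0.891; our simulation measures ≈ 88–89%).  The method
is implemented as defined; consumers needing calibrated small-sample
intervals should prefer t-based or BCa intervals.

## Network embedding

Areas are embedded in 2-D by metric MDS on Euclidean distances between
their feature vectors (participant-averaged univariate profiles, or
vectorized strictly-lower RSM triangles), with 10 restarts and 1,000
max iterations.  The convergence tolerance is 1e-6 on scikit-learn's
current normalized-stress scale (equivalent in effect to the historical
1e-3 tolerance on raw stress).  MDS coordinates are defined only up to
rotation/reflection, so every quantitative statement uses pairwise
distances; reported coordinates are canonically aligned (first area at
angle 0) purely for plotting.  Proximity-to-opacity maps the smallest
pairwise distance to 1.0 and the largest to 0.1, linearly, per
embedding.

## Synthetic cortex

The simulator plants the structure the analyses are designed to detect.
Each area at hierarchy position p receives a scalar univariate factor
and a latent pattern factor, both following a first-order
autoregressive chain over positions with per-step correlation
ρ = 1 − share_decay, so the planted cross-area profile correlation is
ρ^distance — shared content decays geometrically with hierarchy
distance, and at share_decay 0 or 1 the areas are identical or
independent.  The pattern factor is projected through a per-area random
loading matrix and centred across voxels so it carries the
representational geometry without contaminating the univariate profile
(per-voxel standardization reintroduces a ≲10⁻³ residue at finite voxel
counts).  Participants share the signal and differ by additive Gaussian
voxel noise whose per-voxel scale is drawn from Uniform(0.5, 1.5)×
noise_sd, giving NCSNR heterogeneity.  Defaults — 8 participants, 4
areas, 80 voxels per area, 2,000 images, share_decay 0.35, noise sd 0.3,
3 repeats in trial simulation — were chosen once to mirror a
small-cohort, repeat-scanned visual fMRI setting with moderate
between-area sharing; the grouped variant places two category pairs at
positions (0, 1) and (5, 6) so within-group distance is small and
between-group distance large.

The toy image-computable encoders score 4×4 subwindows of 64×64 images:
"freq" by mean absolute forward-difference gradient magnitude (forward
differences, so single-pixel alternation registers), "blob" by the count
of thresholded connected components with area in [5, 200] (a filled
window does not count as one giant blob).  Both standardize against a
frozen 256-image reference set of toy-generator outputs regenerated
deterministically at construction.  The toy generator maps the first
half of its latent to a grid of blob amplitudes/sizes and the second
half to a sinusoid's frequencies, contrast and phase; the zero latent is
a uniform mid-gray image.

**What passing tests show — and do not.**  The synthetic cortex is
linear, Gaussian, stationary and voxelwise-independent in its noise; it
has no retinotopy beyond subwindow tags, no category semantics, and its
generator spans a tiny parametric image family.  Green tests therefore
establish that the algorithms are implemented correctly (oracle
equivalence, monotonicity, calibration) and that they recover planted
relational structure under realistic noise levels — not that any
particular real cortical hierarchy will show the same effect sizes.

## Problem sizes

Tests and the acceptance script scale the study defaults down to keep
runs in minutes while exercising identical code paths: nulls of 300–10⁵
samples instead of 10⁶, genetic searches of 15–30 generations with
populations of 120–200 instead of 2,000 × 2,400, generative runs of
100 generations × 200 latents on 64×64 images instead of 500 × 1,000,
and 10,000-image simulations for NCSNR recovery.  All defaults remain
the full-scale values on the public interfaces.
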