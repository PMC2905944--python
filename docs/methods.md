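# Methods

## Data model and conventions

A run is stored as a `t x v` matrix over the voxels of a boolean brain
mask; columns are ordered by ascending linear voxel index with the
first (fastest-varying) axis first, i.e. Fortran ravel order of the
spatial grid.  This ordering is part of the public contract so that a
seed reported as "voxel 1731" is reproducible, and every seed report
also carries 0-based (i, j, k) indices and world-mm coordinates through
the NIfTI affine.  When no mask is supplied, voxels with zero temporal
standard deviation are excluded automatically.

Voxelwise normalization removes the temporal mean and optionally scales
temporal variance to 1; zero-variance voxels map to all-zero columns
rather than erroring so degenerate phantom voxels stay usable.  The
highpass filter subtracts a Gaussian-weighted running-line fit: at each
time point a straight line is fit by weighted least squares with
weights `exp(-(k-i)^2 / 2 sigma^2)` and its fitted value subtracted.
`sigma` is specified in seconds of kernel width (converted to samples
via the TR), not as a cutoff period; the kernel formula above is the
definition.  The filter output is demeaned per voxel — the downstream
ICA/GLM normalization demeans anyway, so retaining the mean would only
add a pass-through constant.

## PCA, model order and ICA

The temporal covariance (`t x t`, over voxels) is eigendecomposed; the
top-N eigenvectors whiten the data into N spatial scores with identity
row covariance.  The discarded eigenvalue share is reported as the
residual (noise) variance fraction.  Signs are fixed so each
dewhitening column's largest-magnitude entry is positive, making the
PCA deterministic.

Model order selection offers AIC, BIC and MDL computed from the
eigen-spectrum of the voxelwise-normalized data, with the v voxels as
observations.  The log-likelihood term is the sphericity statistic of
the trailing eigenvalues (`n (p-k) ln(geometric/arithmetic mean)`);
temporal demeaning removes one degree of freedom, so the resulting
near-zero eigenvalue is dropped before the computation (it would
otherwise drive the tail geometric mean to zero and force the maximal
order).  AIC and MDL use the classic signal-array parameter count
`k(2p-k)+1` with penalties `2m` and `0.5 m ln n`; BIC uses the
probabilistic-PCA parameter count `pk - k(k-1)/2 + k + 1` with the full
`m ln n` penalty, so BIC selects orders at or below MDL's on noisy
data.  Ties break toward the smaller order.

ICA is the symmetric fixed-point iteration with the logcosh contrast
(`g = tanh`), estimating all components simultaneously with symmetric
decorrelation.  Convergence requires the maximum row realignment
`| |<w_new, w>| - 1 |` to fall below epsilon = 1e-8 within 500
iterations; on failure the estimation restarts up to 3 times with
deterministically derived seeds and, if none converges, returns the
tightest iterate with `converged=False` (long iteration counts were
not observed to rescue non-converging cases, so restarting is the
better use of the budget).  Component sign is normalized so each map's
skewness is nonnegative, resolving ICA's sign indeterminacy
deterministically; components are ordered by descending explained
variance with stable ties.  Maps are z-scored to mean 0, variance 1
across the mask.

Group decomposition concatenates normalized runs in time and applies
the same PCA + ICA.  Back-reconstruction of subject s takes the rows of
the group mixing matrix belonging to s as the subject's time courses
and solves the least-squares fit of s's demeaned data on them for the
subject's maps.  This is the single-stage equivalent of the two-stage-
PCA "regular" method: on noise-free data the two coincide; with noise
the two-stage variant additionally projects through a per-subject PCA
whose retention policy is a free parameter, so exact numerical
equivalence with that variant is not claimed.

## Seeds and the GLM

The SV seed is the map's maximum (ties to the lowest linear index); FV
keeps voxels strictly above `max - 1.0` on the z scale ("one less than
the highest", read strictly); MV scans integer thresholds 1..ceil(max)
and keeps the one whose strict suprathreshold count is closest to the
target, ties going to the lower threshold (more voxels).  ROI time
courses are unweighted voxel averages, normalized to zero mean and unit
variance so GLM betas are comparable across seed flavours; a seed whose
series cancel exactly returns a flagged all-zero course.  Dual
regression stage 1 demeans each seed map over the mask, adds an
intercept per time point, and solves the joint spatial regression for
all time points at once; a design condition number above 1e8 is
rejected as collinear.

The GLM is ordinary least squares per voxel with `dof = t - s`.
t statistics map to z through the t cumulative probability and the
standard-normal quantile, computed in the survival tail for precision
and capped at |z| = 38 so noise-free fixtures stay finite.  An optional
one-step Cochrane-Orcutt AR(1) prewhitening flag exists for temporally
correlated noise (one further dof is spent on the AR coefficient); it
is off by default because the phantom noise is white, where OLS is
exact.  Thresholding is one-tailed throughout: fixed z (default 3.1),
Bonferroni (`z > Phi^-1(1 - alpha/v)`), or Benjamini-Hochberg FDR via
statsmodels.  Gaussian-random-field maximum-height and cluster-extent
corrections are out of scope; Bonferroni serves as the conservative
surrogate for max-height correction.

## Evaluation metrics

Spatial correlation is Pearson r over masked voxels with Fisher z
(`atanh`) for averaging and confidence intervals; |r| is clipped to
1 - 1e-12 before the transform so perfect maps give a large finite z.
Threshold-adjusted overlap takes the FC map's k highest voxels, where k
is the reference's suprathreshold count, which makes false positives
equal false negatives by construction; ties at the boundary value are
admitted in ascending linear-index order until exactly k voxels are
kept, so FP = FN holds exactly.  The ROC sweeps a threshold with tied
values grouped (scikit-learn's curve construction) and integrates
trapezoidally on [0, LFPR] with linear interpolation at the right edge;
`pauc_adjusted = area / LFPR` scales the maximum to 1, and the default
LFPR of 0.05 reflects that false-positive counts beyond ~5% of the
mask exceed the size of any plausible reference map.  Sensitivity and
specificity are plain percentages against a ground-truth mask.
Between-method comparisons are summarized descriptively (means and 95%
CIs on the Fisher-z scale, back-transformed).

## The phantom generator

The generator emulates a signal-injection study: components are voxel
sets (boxes, spheres, single-slice rasterized triangles, plus explicit
extra voxels) carrying zero-mean unit-peak waveforms — square waves or
block designs convolved with a Gaussian haemodynamic response (peak lag
5 s, sigma 2.8 s, truncated at 4 sigma, sampled on the TR grid) — at
amplitudes expressed as percent of the per-voxel baseline mean, plus
white Gaussian noise scaled the same way (an AR(1) temporal-correlation
knob is available).  The baseline defaults to a spatial constant with
an optional linear gradient.  All randomness flows from one integer
seed; groups derive per-subject seeds, amplitude multipliers
(`1 + N(0, sd)` floored at 0) and rigid integer spatial shifts
deterministically from the group seed.

The default injection fixture uses a 24 x 24 x 8 grid (3 mm voxels),
TR 2 s, 190 volumes, baseline 1000: a 33-voxel spherical "natural"
component at 1% amplitude driven by ten 19 s-on/19 s-off blocks, and a
64-voxel "artificial" component — three 21-voxel triangles in one axial
slice plus the natural component's centre voxel — carrying a 60 s
square wave (30 volumes per period) at 0.5% amplitude, in 0.25% noise.
These sizes put the artificial component at ~4.5% of total variance
with triangles covering ~1.4% of the grid, matching the variance-share
and spatial-compactness regime of injection studies on real data, where
spatial smoothing gives individual voxels a favourable effective SNR.
The injection experiment decomposes demeaned (not variance-normalized)
data: with a spatially constant baseline, variance normalization would
only shrink signal voxels toward the background and bound the
achievable map-truth correlation; for real data with heteroscedastic
voxels the variance-normalization step is available and recommended.

What passing phantom tests does not show: the generator has no
physiological noise spectra, scanner drift beyond AR(1), motion, or
spatial autocorrelation, so absolute sensitivity/specificity values on
real data will be lower than the phantom's, and the phantom cannot
adjudicate preprocessing choices (smoothing, registration) that are out
of scope here.

## Pipelines

`experiment1` generates the fixture, runs ICA at order 6 (comfortably
above the two sources), matches components to the truth masks by
maximal |r|, thresholds the artificial IC z map at z > 3.1, and derives
single-voxel-seed FC maps from the overlap voxel and the two IC peaks,
thresholded by one-tailed Bonferroni at alpha 0.05.  `experiment_group`
simulates subjects (default amplitude sd 15%, jitter 1 voxel), takes
each subject's own task-regressor GLM z map as that subject's
reference, matches the group IC of interest against the voxelwise mean
of the subject z maps (a simple stand-in for a mixed-effects group
map), and scores SV/FV/MV/DRS/DRA (and optionally back-reconstruction)
per subject.  Both drivers are reproducible end-to-end from (config,
seed).  Desk-scale defaults (4608 voxels, 190 volumes, 10 replicates)
keep a full injection-recovery sweep to a few seconds.

## Known limitations

Back-reconstruction is the single-stage form (see above).  Infomax ICA,
mixture-model map thresholding, the Laplace evidence model-order
criterion, GRFT corrections and prewhitening beyond one AR(1) step are
not implemented.  The MV rule takes a voxel-count target directly;
converting a volume target between voxel sizes is the caller's job.
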