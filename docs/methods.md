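# Methods

## Scope and model

`smncent` computes voxel-wise network centrality of resting-state fMRI
data restricted to a binary network mask (e.g. a sensorimotor-network
template), and carries the resulting per-subject maps through group
inference with Monte-Carlo cluster-size correction and cluster-level
clinical regression.  The package assumes its 4D inputs are already
slice-time corrected, realigned and resampled to a common grid (3 mm
isotropic by default); registration is deliberately out of scope.

Two centrality metrics are computed on the voxel-wise Pearson correlation
graph of the N in-mask time courses:

* **Degree centrality (DC).**  For voxel i,
  `DC(i) = sum_{j != i} r_ij * [r_ij > r0]` (weighted positive form) or
  the analogous count (binary form).  The threshold r0 suppresses weak,
  noise-dominated correlations; the primary threshold is 0.25 and a sweep
  over {0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4} supports robustness
  checks.  The sum as printed in the defining equation runs over all j;
  we exclude the self-term j = i, which otherwise adds a constant 1 to
  every voxel, so that uncorrelated data yields DC near 0.
* **Eigenvector centrality (EC).**  The principal eigenvector of
  A = (C + 1)/2, where C is the in-mask correlation matrix.  The affine
  shift maps correlations into [0, 1], making A entrywise nonnegative so
  that Perron–Frobenius guarantees a unique nonnegative principal
  eigenvector; the raw eigen-equation alone permits signed matrices for
  which that uniqueness fails.  The eigenvector is found matrix-free by
  power iteration using
  `A v = (Z (Z^T v)/(T-1) + 1 * sum(v))/2`
  with Z the row-standardised time-series matrix, so the N x N matrix is
  never materialised (the same applies to DC, which is accumulated over
  column blocks of the correlation matrix; results are identical across
  block sizes to 1e-10).

Power iteration uses the deterministic uniform start `1/sqrt(N)`,
tolerance 1e-12 on the Euclidean difference of successive unit vectors,
and at most 1000 iterations; non-convergence returns a flagged partial
result with a warning.  Because A is PSD with a spectral gap driven by
the rank-one all-ones term, convergence is typically reached in tens of
iterations.

### Normalisation for group analysis

Subject DC maps are divided by their in-mask global mean (k/k0) and then
converted for group comparison.  Centrality toolboxes conventionally
label this conversion "Fisher's Z", but globally normalised DC routinely
exceeds 1, where atanh is undefined, so the default conversion is
z-standardisation over the mask, with literal `atanh` available for maps
confined to (-1, 1).
EC maps are rank-Gaussianised (tied ranks, Blom positions
`(rank - 3/8)/(N + 1/4)`, normal quantiles) and then z-standardised;
global-mean division (u/u0) is retained as an alternative path.  Every
map carries its normalisation provenance as an ordered list.

## Preprocessing

Stage order: discard the first 10 volumes, Gaussian smoothing (FWHM 6 mm,
applied volume-wise on the full grid, sigma = FWHM/(2 sqrt(2 ln 2))
converted to voxels per axis), ideal band-pass 0.01–0.08 Hz, nuisance
regression on [intercept, WM signal, CSF signal, 6 motion parameters].
Conventions differ on whether smoothing precedes filtering;
smooth-then-filter was chosen and is applied consistently.

The band-pass retains discrete-spectrum bins inside the band (DC always
removed) after linear detrending.  A finite-sample line fit does not
commute with bin selection, so a single detrend-then-filter pass leaves
an O(1e-3) trend residue and is not idempotent.  Alternating the two
steps is a linear contraction whose fixed point is an oblique projection
onto band-limited, trend-free signals; because detrending is a rank-one
update within the band, the fixed point has a closed form (project the
filtered data along `F(r_hat)` until it is orthogonal to the ramp) and is
applied directly.  The resulting operator is idempotent to machine
precision, annihilates linear trends exactly, and preserves the RMS
amplitude of an in-band tone to ~0.5% (time-domain peaks can show Gibbs
ringing at the series boundaries, inherent to ideal filters).

Head-motion QC follows the 2 mm / 2 degree rule on maximum absolute
translation/rotation.  "Mean head motion" is summarised as the mean
Euclidean norm of volume-to-volume translation differences — one of
several formulas in circulation; rotations are reported separately.

## Group statistics

Per-voxel OLS with a design shared across voxels: two-sample contrasts
with age (centred) and gender (0/1) covariates; paired comparisons as a
one-sample t on within-pair differences (dof n-1, equivalent to a
subject-fixed-effects GLM); a multi-level group factor as the partial F
from model comparison against the covariate-only model.  Voxels with
numerically zero residual variance are flagged non-finite rather than
reported.

Cluster formation uses the rmm neighbourhood: all voxel offsets with
centre-to-centre distance at most rmm mm (18-connectivity for 3 mm voxels
at rmm = 5).  Positive and negative tails are thresholded separately at
the one-tailed quantile for the per-voxel p (default 0.01); the reported
tail convention of the original AlphaSim program varies between
implementations, and the one-tailed-per-direction choice used here is
internally consistent between the data path and the null simulation.

The Monte-Carlo correction fills the mask's bounding box with unit white
noise, smooths to the nominal analysis FWHM, restricts to the mask,
re-standardises the in-mask values (so kernel-edge variance loss cannot
deflate the threshold), thresholds at the one-tailed z, and records the
maximum cluster extent; the critical size k at level alpha is the
smallest extent whose exceedance rate across iterations is at most
alpha (1000 iterations by default).  Residual-based smoothness estimation
is out of scope; the nominal applied FWHM is used.

## Clinical measures

BPF = (GM + WM)/(GM + WM + CSF) from binary masks or tissue-probability
volumes (probability mass is integrated rather than thresholded at 0.5);
TWMLL = lesion voxel count x voxel volume / 1000 (ml).  For clusters
with significant group differences, the mean converted centrality per
subject is regressed on each clinical metric with age and gender as
covariates; the partial correlation is derived from the metric's t
statistic.  Bonferroni correction is applied over the declared family —
(number of clusters) x (number of metrics) by default — and the family
size is reported with every result so users can re-scope it.  Regression
is run on cluster means rather than voxel-wise to keep the family
interpretable.

## Synthetic-data generator

Each in-mask voxel's time course is a weighted sum of unit-variance
white community latent signals plus stationary AR(1) noise (lag-1
coefficient 0.3, stationary SD 1.0 by default).  Two voxels sharing one
latent with weight w have expected correlation w^2/(w^2 + sd^2), giving
closed forms for all planted quantities; `expected_dc` evaluates the
population DC implied by any loading configuration.  Hub voxels load on
several latents.  Group effects add a loading increment at a designated
voxel set in affected sessions; paired sessions share a subject-level
loading scale (Gaussian, SD 0.1 around 1), which induces the within-pair
dependence a paired design exploits.  Clinical covariates are linear in
each subject's true effect-cluster centrality with Gaussian noise; EDSS
is rounded to 0.5 steps and clipped to [0, 10].  Masks are seeded
randomised breadth-first blobs (always 6-connected); segmentations are
concentric WM/GM/CSF shells of exact voxel-rounded volume with the
lesion nested innermost in WM; motion traces are seeded random walks.

What the generator does **not** emulate: hemodynamic response shape,
physiological (cardiac/respiratory) noise, scanner drift and spikes,
registration error, lesion geometry, and the long-range non-community
dependence of real BOLD data.  Passing tests therefore demonstrate that
the pipeline measures what it claims under its own assumptions — not
that those assumptions hold in any particular patient cohort.

## Validation design and problem sizes

The study-scale validation uses desk-scale stand-ins chosen once: a
1000-voxel connected mask on a 12x12x12 grid of 3 mm voxels, 60–120
volumes at TR 2 s, 8 subjects per group for two-sample calibration, 11
pairs for the paired design, and 200 Monte-Carlo iterations for the
null-calibration correction (1000 remains the analysis default).

* Kernel correctness is checked against dense-matrix oracles (full
  correlation matrix; `numpy.linalg.eigh`) on 20 random fixtures plus a
  hand-solved 3-voxel case.
* Family-wise error is estimated over 200 seeded null studies.  The
  null fields are smoothed AR(1) noise; community latent signals are
  deliberately absent because shared latents induce long-range
  between-subject dependence in DC maps that violates the
  stationary-smooth-Gaussian-field assumption of cluster-extent
  inference (a known failure mode of such corrections), which would be a
  property of the null model rather than of the code under test.
* Power uses a planted 30-voxel contiguous effect (loading increment
  3.0) whose standardized within-pair magnitude, measured on unsmoothed
  DC differences, is ~2.5; smoothing dilutes the realised per-voxel
  effect but the corrected analysis recovers an overlapping cluster in
  >= 90% of seeds at n = 11.
* Clinical-regression recovery is run at the cluster-mean level
  (generator coupling matches the regression direction: cluster mean
  linear in the metric), 200 seeds at n = 34, SNR 1.

## Known limitations

* The correction calibrates cluster extent only against its own
  smooth-Gaussian null; data with strong non-Gaussian spatial
  dependence (including the generator's community structure) can exceed
  the nominal family-wise rate.
* The ideal band-pass assumes regular sampling and shows boundary
  ringing; a Butterworth alternative is not currently wired into the
  pipeline configuration.
* EC sign/normalisation choices (rank-Gaussian then z-standardise) are
  one defensible reading of an ambiguous description; both the
  global-mean and rank paths are implemented and recorded in map
  provenance.
* Voxel-wise inference assumes identical designs across voxels; missing
  data per voxel is not supported.
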