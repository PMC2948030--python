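# Methods

`restparc` implements a resting-state functional-connectivity analysis of a
cortical target region in two complementary branches — seed-based
connectivity mapping and connectivity-based voxelwise parcellation — plus
the split-half reliability machinery used to judge the stability of the
resulting group maps, all exercised against a synthetic BOLD cohort
generator with known planted structure.  This note documents the models,
the defaults and their rationale, the numerical choices, and what the
synthetic data can and cannot certify.

## Synthetic cohort generator

The generator emulates a 16-subject resting-state cohort, 200 volumes at
TR = 2 s, on a 24×24×18 grid with 4×4×5 mm voxels (a desk-scale analogue
of a 64×64×19 EPI acquisition).  Four spatial networks are planted as
contiguous Gaussian blobs (weights in [0, 1], truncated at 0.05) centred
on the corners of a square in the central axial slab:

- **TPN / TNN** — an anticorrelated pair (task-positive / task-negative
  analogue) on one diagonal, so their supports are disjoint;
- **MOT / VIS** — sensorimotor- and visual-like networks on the other
  diagonal, mutually near-orthogonal.

A rectangular *target band* runs through all four blob centres; moving
along the band the dominant network changes smoothly, emulating a cortical
region whose subregions belong to different networks with gradual
transitions.  This band is what the parcellation branch segments.

**Time courses.** Each network course is unit-variance white noise
restricted to 0.01–0.1 Hz by a hard DFT mask (so band confinement is exact
by construction, and the band-pass stage of the pipeline preserves the
signal).  The anticorrelated pair is built as
`s_TNN = −0.7·s_TPN + sqrt(1−0.49)·r` with `r` an orthogonal band-limited
residual, giving a Pearson correlation of exactly −0.7; the remaining
courses are orthogonalized against everything built before them, so all
other pairwise correlations are numerically zero.

**Forward model.** Voxel signal =
`snr · Σ_k w_k(v) s_k(t)` + global/WM/CSF nuisance courses (amplitudes
0.5 each, added brain-wide / within tissue masks) + motion leakage
(amplitude 0.3; six smooth bounded random walks, ≤ 0.9 mm / 0.9°, coupled
into voxels through a per-subject random spatial pattern) + AR(1) noise
(ρ = 0.3, unit marginal variance) + a per-voxel linear drift (≤ ±2 units
over the run) + a baseline of 100.  `snr` is therefore the planted-signal
to noise standard-deviation ratio at a weight-1 voxel; the default
`snr = 1` gives raw voxel–network correlations of ≈ 0.55–0.65 at planted
peaks before filtering.  Effect sizes at the voxel level are not reported
quantities for this kind of data, so the snr default is a calibration
choice, stated here once and used unchanged everywhere.

Noise is AR(1) rather than white so that the prewhitening stage has a real
job; motion and drift exist so that the motion regressors and the
detrending stage are consequential.

**What the generator does not emulate:** anatomical realism (no cortical
folding, no stereotactic space), cardiac/respiratory waveforms beyond
band-limited nuisance courses, susceptibility dropout, and — importantly —
the *spatial* correlation of real scanner noise (noise here is independent
across voxels).  Passing tests on this cohort therefore demonstrates the
correctness and calibration of the algorithms under known truth, not
performance on real BOLD data.

## Preprocessing

Per-voxel linear detrend (least squares, intercept included), then a
zero-phase order-2 Butterworth band-pass at 0.01–0.1 Hz applied
forward-and-backward (`sosfiltfilt`, even-symmetric padding — the
odd-symmetric default leaks stop-band energy through edge transients on
200-sample runs).  The filter family and order are declared defaults: only
the band itself is a fixed analysis parameter.  Detrending precedes
filtering to keep ramp energy out of the low band edge.

Spatial smoothing is an 8 mm FWHM Gaussian (σ per axis =
FWHM/(2√(2 ln 2))/voxel size, so anisotropic voxels are correct),
mask-renormalized (smoothed data divided by the smoothed mask) to avoid
signal dilution at the brain edge.  Smoothing is applied **only in the
seed-connectivity branch**; the parcellation branch clusters unsmoothed
voxel time courses so that neighbouring voxels keep independent
information.

## Seed connectivity

Seeds are 125 mm³ cubes (5 mm edge, rounded per axis to the nearest odd
voxel count); a bilateral seed averages the cube and its x-mirror.  Seed
placement is validated against across-subject mean gray-matter coverage
with an inclusive 70% threshold.  Seed courses are voxel averages,
z-normalized and *sequentially orthogonalized* in ROI order
(Gram–Schmidt), so each regressor carries the variance unique to its ROI
given the earlier ones; the non-orthogonalized variant (one model per
seed) is available and produces closely similar maps on the synthetic
cohort (Dice ≥ 0.7 of supra-threshold positives).

The nuisance block contains 15 columns: the global-mean, white-matter and
CSF courses each expanded into the course, its first temporal derivative
and its centred square (9 covariates — the expansion is a declared
convention, `mode="plain"` keeps just the 3 courses), plus the 6 motion
parameters.  All columns are mean-centred; all-zero motion columns are
dropped with a warning.

**Prewhitened GLM.** All orthogonalized seeds enter one joint model with
intercept and nuisance block.  Per voxel, the lag-1 autocorrelation ρ of
the OLS residuals is estimated (clipped to ±0.95) and the model is
quasi-differenced: `y'_t = y_t − ρ y_{t−1}` with the first row scaled by
`sqrt(1−ρ²)`, so ρ = 0 is exactly the identity and the row count (hence
dof = T − p) is preserved.  The whole-brain fit is vectorized by noting
that X'X(ρ), X'y(ρ) and y'y(ρ) are quadratic polynomials in ρ with
precomputable coefficients, reducing the voxel loop to one batched
(n, p, p) solve; the batch path is tested against the scalar path to
1e−8.  A voxel fit with numerically zero residual (e.g. the seed's own
voxel) reports a capped, flagged t of ±1e6.

**Cluster-extent correction.** The minimum cluster size K is calibrated by
Monte-Carlo simulation: Gaussian null volumes on the brain mask, smoothed
to the analysis FWHM, z-scored within the mask, thresholded two-tailed at
the voxel-level p (default 0.01, configurable — the voxelwise p underlying
published K values is rarely stated, so K is treated as data-geometry
dependent, not a reproduction target), 6-connectivity components, K = the
smallest size whose max-cluster exceedance probability is ≤ α (default
0.05).  Observed maps are thresholded the same way with positive and
negative clusters kept separately (labels +1, +2, … / −1, −2, …), so
positively and negatively correlated networks are reported as distinct
clusters.

**Group level.** Random-effects: per voxel the subject betas are regressed
on intercept + mean-centred age + sex; the reported t is the intercept's,
dof = n − 3; voxels with zero between-subject variance are flagged
undefined (NaN).  Probability maps are voxelwise percentages of subjects
whose thresholded map is positive.

## Fuzzy parcellation

Input: the target region's unsmoothed, temporally filtered voxel time
courses, z-scored per voxel, PCA-reduced to the smallest subspace holding
≥ 90% of the variance (constant voxels are dropped with a warning).

**Fuzzy c-means.**  Standard Bezdek alternating updates
(`u_cn = 1/Σ_j (d_cn/d_jn)^(2/(m−1))`, centroid = u^m-weighted mean),
initialization from seeded distinct data rows, convergence when the max
membership change < 1e−5 (max 300 iterations), 10 restarts keeping the
lowest objective.  Coincident voxel/centroid pairs receive crisp
membership.  The objective `J = Σ u^m d²` is recorded per iteration and is
nonincreasing on every run.

*Distance metric.*  The default metric for time-course clustering is
**cosine** (spherical FCM: rows length-normalized, `d² = 1 − cos`,
centroids renormalized after the weighted-mean update, which preserves the
descent property).  Correlation/cosine similarity is the natural measure
for z-scored BOLD courses: it is scale invariant, and — decisive here — it
is not swamped by each voxel's own noise energy.  With Euclidean distance
in the ≥ 90%-variance subspace (≈ 50 dimensions on the default cohort,
mostly a flat noise tail), every voxel is nearly equidistant from every
denoised centroid; the fuzzifier then has a single stable fixed point with
all centroids at the grand mean, and the partition degenerates (this was
observed directly: memberships uniform at 1/c for any m ≤ 2.5).  The
classical Euclidean variant remains available (`metric="euclidean"`) and
is the one for which the small-sample equivalence with exhaustive 2-means
holds.

*Fuzziness.*  Published fMRI fuzzy-clustering work sometimes quotes the
fuzziness on a reciprocal scale where 0.4 corresponds to the standard
exponent m = 1/0.4 = 2.5.  The package uses the standard exponent
(m > 1), default **m = 2.5**; the mapping is a declared assumption and is
logged once per session.

*Cluster count.*  Unsupervised search over c ∈ [2, 8] minimizing the
Xie–Beni index (compactness over minimal squared centroid separation, in
the partition's own metric; coincident centroids ⇒ index = ∞, which
naturally disqualifies over-fitted c).  The per-c best-of-10-restarts
partition is scored and the full index table is returned for audit.  At
the cohort level the per-subject winners are combined by modal vote.  On
the default cohort the search selects c = 4, one cluster per planted
network.

**Cross-subject aggregation.**  Per-subject hardened labelings (argmax
membership, ties to the lowest index) are aligned by exact Dice-optimal
linear assignment against a reference (first subject), then re-aligned
against the consensus (voxelwise modal label) in a second pass.  The
assignment is brute-force-verifiable at small c and is tested against
exhaustive permutation search at c = 3.  Aligned labels are summarized as
per-cluster probability maps (percent of subjects assigning each voxel to
the cluster); the reporting layer blanks values below 10% so displayed
probabilities lie in [10, 100], while raw values are retained.

Clusters are named after networks by correlating each cluster's
membership-weighted mean time course with the candidate network courses
(injective assignment when c equals the number of networks; a top-2
correlation gap < 0.05 flags the label as ambiguous without failing).

## Reliability

For each of `n_splits` (default 100; the acceptance computation uses 50)
random equal halves of the cohort, the group map is rebuilt per half and
compared with the Sørensen (Dice) index — binary `2C/(A+B)` on
thresholded maps, fuzzy `2 Σ min(a,b)/(Σa+Σb)` on probability/membership
maps (exactly the binary form on 0/1 maps).  Two empty maps count as
perfect agreement (1.0, warned).  The half-cohort similarity r_h is
projected to full-cohort reliability with the Spearman–Brown formula
`R_SB = 2 r_h/(1+r_h)`, and the mean across maps and splits is reported.
Averaging over many random splits (rather than one) removes
split-selection variance; single-split mode is a parameter choice.

## Problem sizes and determinism

The default demonstration configuration — 16 subjects, 24×24×18 grid,
200 volumes — runs the complete pipeline in well under a minute on one
CPU; Monte-Carlo calibration uses 500–1000 iterations and the reliability
stage 50–100 splits at these sizes.  Every stochastic component (cohort
noise, centroid initialization, null simulations, split selection) draws
from seeds derived via `numpy.random.SeedSequence` from a single
configuration seed, so identical configurations reproduce bit-identical
cohorts and identical maps, manifests and reports.

## Known limitations

- Voxel noise is spatially independent; real BOLD noise is spatially
  correlated, which would loosen cluster-extent calibration transfers and
  make parcellation harder than it is here.
- The AR(1) prewhitening model is the simplest autocorrelation correction;
  higher-order or spatially regularized models are out of scope.
- The 9-covariate nuisance expansion and the fuzziness-scale mapping are
  declared conventions, both configurable and logged.
- The unsupervised cluster-count criterion (Xie–Beni) and the Dice/
  consensus cluster matching are documented replacements for
  tool-specific procedures whose details are not publicly specified; they
  are validated against brute-force oracles, not claimed to be faithful
  re-implementations of those tools.
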