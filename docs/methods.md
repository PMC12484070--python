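# Methods

This note documents the models, estimators and design choices behind the
package, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Windowed spectral amplitude

ALFF of a length-N series at repetition time TR is the mean, over the
one-sided DFT frequencies k/(N·TR) inside the closed band
[f_lo, f_hi] (default 0.01–0.1 Hz; some toolboxes use 0.01–0.08 Hz, so the
band is configurable), of the square-root power spectrum. Power is
expressed on the single-sinusoid amplitude scale 2|F_k|/N, so a pure
in-band sinusoid of amplitude A at an exact DFT frequency contributes A to
its bin; any fixed scale convention cancels in the CV. The periodogram
uses a rectangular window (no taper) with per-segment linear detrending —
the classical ALFF convention. If a window length admits no in-band DFT
bin, the sliding computation refuses with the achievable resolution rather
than returning zeros.

Sliding windows of length L TR step by s TR give n = ⌊(T−L)/s⌋+1 windows;
window w covers timepoints [w·s, w·s+L). The dynamic map is the temporal
coefficient of variation of the windowed amplitudes, CV = SD/mean with the
n−1 SD denominator (the convention is not universal; it only rescales CV
by a constant factor per window count). CV is invariant to positive
rescaling of the raw signal, which is why per-window maps are *not*
individually standardized before the CV; the subject-level CV map is
z-scored within the analysis mask before group statistics to guard
residual scale differences between subjects (a mean-division mode also
exists, and the unstandardized path is selectable).

## Preprocessing

The orchestrated order is discard initial volumes → motion QC → spatial
smoothing → nuisance regression; temporal band-pass filtering is not a
separate step because the band restriction lives inside the ALFF
definition. Each operation is independently callable.

- Motion QC fails a subject only on *strictly* greater motion than the
  limits (default 2 mm translation, 2° rotation), so a subject exactly at
  the limit is retained.
- The 24-regressor motion model is [R(t), R(t−1), R(t)², R(t−1)²] for the
  six realignment parameters, with a zero first row for the lag block
  (the lag convention at t=0 is not standardized; zero is the common
  choice).
- Nuisance regression is voxelwise OLS on
  [intercept | linear trend | global mean | regressors]; the global
  signal is the per-frame mean over the supplied analysis mask. Residuals
  are exactly orthogonal to the design (checked to 1e-8 relative).
- Smoothing is an isotropic Gaussian specified as FWHM in world mm
  (σ = FWHM/2.355), converted to voxel units per axis, so anisotropic
  voxels are handled per-axis.
- The head-motion summary entering the group model is the mean
  Power-style framewise displacement (50 mm head radius); the choice of
  summary (mean FD vs maxima) is a convention, not derivable from first
  principles.

## Group inference

The group model is per-voxel OLS of the subject map on
[intercept, group, mean-centered covariates]; t is the group coefficient
over its standard error, df = n − rank(design). With no covariates this
reproduces the pooled-variance two-sample t exactly (tested to 1e-10
relative). Voxels constant across subjects are undefined and leave the
mask.

Smoothness is estimated from the spatial first differences of the
voxelwise-normalized residuals: for unit-variance fields the mean squared
difference λ along an axis estimates 2(1−ρ), giving
FWHM = √(4 ln 2)·d/√λ per axis and
resels = |mask|·∏(d_i/FWHM_i). On white noise this returns
≈ 1.18× the voxel size (the estimator's intrinsic resolution floor); a
field smoothed at 6 mm on 3 mm voxels is recovered within a few percent of
√(6² + intrinsic²).

Cluster correction Gaussianizes the t-field by the probit transform of
its tail probabilities, thresholds each tail at voxel_p/2 (two-tailed
default), extracts 26-connected components, and assigns each cluster
p = 1 − exp(−E[m]·P(extent ≥ k)) with the expected cluster count E[m]
from the 3-D Euler-characteristic density at the threshold times the
resel count, and the classical exp(−βk^{2/3}) extent distribution. The
lower-dimensional EC terms are omitted; at the thresholds used here the
3-D term dominates and the measured family-wise error on smooth null data
is below nominal (0–0.5% at nominal 1% over 200 datasets). The
permutation alternative uses Freedman–Lane residual permutation under the
reduced (covariates-only) model and the null distribution of the maximum
cluster extent over both tails; with 100 permutations its family-wise
error is 1/101 by construction (ties make it conservative). Cluster peaks
are reported at the maximum |t| voxel, ties broken by lowest linear voxel
index.

Demographics statistics use the pooled-variance two-sample t from summary
numbers and the Pearson chi-square without continuity correction — the
variants that reproduce printed cohort tables of this literature.

## Expression preprocessing

The donor pipeline is: pooled intensity-based probe filter (retain a
probe when ≥ 50% of samples across donors flag above background) →
per-gene probe selection by maximal Pearson correlation with a reference
expression vector (ties to the first probe in annotation order;
zero-variance probes skipped) → sample-to-region assignment (containing
voxel, else nearest labeled voxel within 2 mm) → per-donor region
averaging → scaled robust sigmoid per gene within donor
(1/(1+exp(−(x−median)/(IQR/1.35))), min-max rescaled; invariant to
positive affine transforms of the input) → differential-stability filter
(mean inter-donor Pearson correlation of regional profiles, threshold
0.1) → donor averaging. Only left-hemisphere parcels are used by default,
mirroring the hemispheric coverage of postmortem expression atlases.

## PLS and gene screening

The PLS is univariate-response NIPALS with deflation on column-z-scored X
and y; component k's share of response variance is q_k²·‖t_k‖²/‖y‖²
(scores are orthogonal, so shares are additive), and the Pearson r of
each score with the response is reported alongside. The component to
interpret is always an explicit caller parameter — shares need not be
monotone and the interesting component is a scientific choice, never
auto-selected. "Cross-modal variance explained" is reported as the
response-variance share (headline) with the score–response r as the
companion number, because the literature uses the phrase both ways.

Component significance uses spin permutations: each trial draws a
uniformly random 3-D rotation (the right hemisphere receives the
x-mirrored rotation), reassigns every region to the nearest rotated
centroid (duplicates allowed; a strict-permutation mode solves the
assignment problem instead), and
p = (1+#{|r_null| ≥ |r_obs|})/(1+n_spins), two-tailed, never zero.

Per-gene screening bootstraps regions with replacement and refits the
PLS. Three numerical choices matter and were made after measuring the
naive alternatives on synthetic data:

1. The per-gene statistic is the component's **salience** — the
   unnormalized cross-covariance of the gene with the component's
   response residual — not the unit-norm weight. The unit-norm constraint
   couples all genes through ‖X'y‖, whose bootstrap replicates are
   inflated by the summed resampling variances of p genes (an O(p/n)
   effect); with 200 genes and 90 regions this shrank bootstrap SEs by
   ~10% and made null Z-scores anticonservative.
2. The bootstrap error is the RMS deviation of the sign-aligned
   replicates **about the original estimate**, so resampling bias inflates
   the error term instead of being discounted.
3. The two-tailed p uses a **t(n_regions − 2)** reference; the weight is a
   covariance-type statistic and the normal reference is too thin-tailed
   at n = 90.

After these choices the marginal null-Z distribution is calibrated to
slightly conservative (empirical sd 0.99, tails below the t reference).

FDR across genes defaults to the **Benjamini–Yekutieli** variant. The
reason is dependence, not marginal calibration: with spatially
autocorrelated expression noise, entire blocks of null genes co-align
with a given response realization, the Benjamini–Hochberg step-up
amplifies these bursts, and the measured false-discovery proportion was
≈ 0.10 at nominal 0.05 over 100 simulations even with calibrated
marginals. Benjamini–Yekutieli guarantees FDR control under arbitrary
dependence at the cost of a log(m) factor in power — immaterial here,
because genuinely contributing genes have |Z| an order of magnitude above
the threshold. Plain BH remains available (`correction="bh"`).

## Receptor association

Each density map gets a Pearson r with the regional t profile, a
parametric two-tailed p (t transform, n−2 df), and a spin p from a shared
spatial null. Both p families are FDR-corrected across the panel with the
same dependence-robust variant (receptor densities within a real PET
panel share strong spatial gradients), and a map is significant only when
both corrected families clear the threshold. Corollary: the spin count
sets a resolution floor — the smallest attainable corrected spin q is
roughly (1/(n_spins+1))·(m/rank)·H(m), so a 20-map panel at threshold
0.05 needs at least ~1,000 spins (the component-level spin test in the
published workflow this mirrors uses 10,000 trials).

## Synthetic data: what it emulates, and what it does not

Every input is generated from a seed, bit-reproducibly.

- **BOLD**: each voxel is baseline + A(t)·sin(2πft+φ) + white noise with
  a single band-interior carrier (0.05 Hz, an exact DFT frequency of all
  three window lengths at TR 2 s) and a blockwise-constant random
  envelope A(t) = A₀(1 + m·s(t)), s ~ U(−1,1) per 10-TR block. Patients
  get a larger modulation depth m (0.7 vs 0.2) inside three mutually
  adjacent left-hemisphere parcels; both groups share the control depth
  elsewhere, so group means are identical everywhere and only amplitude
  *variability* differs. The envelope is recorded as ground truth, making
  windowed ALFF analytically predictable: with windows matched to the
  modulation blocks the computed CV equals the CV of the per-window
  envelope means to ~1e-14. The planted regions are adjacent because
  6 mm smoothing on ~2.8-voxel-wide parcels would wash out isolated
  effects. Defaults: 240 volumes (10 discarded → 230 analyzed), TR 2 s,
  12×14×12 grid of 3 mm voxels, 90 parcels, 10 subjects per group.
- **Atlas**: mirrored Voronoi parcellation — seed voxels drawn in the
  left x-half and mirrored right, so hemispheres are exactly symmetric
  (45/45), labels are nearest-seed in world mm with no cross-midline
  ties, and unit-sphere centroid coordinates support spin nulls.
- **Expression**: a planted fraction of genes follows ±z(target map) +
  noise; noise genes and the planted-gene noise are white fields smoothed
  over parcel centroids with a Gaussian kernel. The default correlation
  length (6 mm) sits below the ~8.5 mm inter-centroid spacing so that
  parcels remain approximately exchangeable sampling units — the
  assumption the regional bootstrap rests on; longer correlation lengths
  are available and demonstrably break bootstrap-based error control
  (see the FDR discussion above). Donor tables add per-donor affine
  distortions, good and noisy probes, above-background flags and a
  reference expression vector, so the probe-level pipeline is exercised.
- **Receptors**: maps at chosen indices have exact population correlation
  ρ with the target map; the rest are independent; all maps are shifted
  strictly positive (an affine change, invisible to Pearson r).
- **Motion**: bounded random walks; exclusion-violating subjects are
  injected explicitly at a configured fraction rather than by chance.

Not emulated: hemodynamic response functions, physiological noise
spectra (cardiac/respiratory), scanner artifacts, spatial normalization
error, hemispheric asymmetries of expression, or realistic receptor
covariance. Passing tests therefore demonstrate the *statistical
machinery* — calibration, recovery, invariances — under controlled
conditions, not robustness to the full noise structure of real scans.

## Problem sizes used in validation

The validation suite runs at the toy scale above: cluster-correction
calibration uses 200 null datasets of 20 subjects on the 12×14×12 grid;
spin calibration 500 replicates at 199 spins; gene recovery 20
simulations of 200 genes × 90 regions with 1,000 bootstraps;
receptor recovery 50 panels of 20 maps at 10,000 spins; strong-effect
cluster recovery uses 20 subjects per group with maximal modulation
contrast, where between-subject sampling noise of the CV (only ~5–8
independent windows fit in 230 volumes) still permits voxelwise
detection. At the default 10-per-group scale the planted effect is
deliberately *not* reliably detectable at voxel p < 0.005 — mirroring
the power reality that motivates larger cohorts.

## Known limitations

- GRF cluster p-values use only the 3-D EC term and the asymptotic extent
  distribution; they are accurate for smooth fields and high thresholds
  and conservative on the toy grid.
- The CV of windowed ALFF is a quasi-static summary; overlapping windows
  make neighbouring amplitudes strongly dependent, and the effective
  number of independent windows — not the window count — governs its
  sampling error.
- Bootstrap gene screening treats regions as exchangeable; under spatial
  autocorrelation at or above the parcel scale its marginal error
  estimates degrade, which is precisely why the dependence-robust FDR
  variant is the default and why the spin test, not the bootstrap,
  carries the component-level inference.
- The spin null with nearest-centroid reassignment allows duplicated
  regions; the strict-permutation mode avoids this at the cost of the
  assignment solve.
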