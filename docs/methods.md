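# Methods

## Input model and conventions

The pipeline consumes a 3D T2-weighted intensity volume and an aligned
integer label mask (NIfTI-1/2). A label map names up to five regions —
IVD, NP, AF, CSF, BONE — with the convention `{"IVD":1, "NP":2, "AF":3,
"CSF":4, "BONE":5}` (configurable). Because a voxel carries a single code,
region membership is hierarchical: NP voxels are NP *and* disc, AF voxels
are AF *and* disc, and the IVD region is the union of the three codes. When
a mask has no AF code, the AF is derived as IVD∖NP. This guarantees
NP ⊆ IVD and n(IVD) = n(NP) + n(AF).

Voxel index (i,j,k) maps to world millimetres through the image affine at
the index itself (0-based voxel centers). Voxels are treated as point
samples weighted by physical voxel volume; thick-slice acquisitions are not
interpolated across gaps. Multiple disconnected components under one label
are accepted silently.

## Normalization

Two steps decouple the indices from disc size and scanner settings:

1. every voxel of a region carries weight `voxel_volume / region_volume`
   (1/n on a uniform grid), so histogram indices are Riemann-sum estimates
   of integrals over the region rather than voxel-count statistics;
2. intensities are divided by the volume-weighted mean of a reference
   region: CSF or cancellous bone. On a uniform grid the weighted mean
   equals the plain mean. A NONE mode (divide by 1) exists for phantom
   debugging only.

Dividing by a reference measured in the same acquisition cancels a global
multiplicative gain exactly; this invariance is asserted end-to-end in the
test suite at 1e-10. Negative raw intensities (possible with synthetic
additive noise) are clipped to zero with a logged warning, since magnitude
MR images are non-negative. Bias-field correction and cross-scanner
histogram matching are out of scope.

## Histogram indices

All moments use the population convention on volume weights:
μ = Σwᵢxᵢ, σ = √(Σwᵢ(xᵢ−μ)²), g₁ = Σwᵢ(xᵢ−μ)³/σ³.

* **Standard error** is σ/√n with n the voxel count — the one index that
  deliberately keeps a sample-size dependence.
* **Sum of squared values** is volume-weighted (Σwᵢxᵢ²); the unweighted
  variant is available behind a flag but would reintroduce the voxel-count
  dependence step 1 removes.
* **Quantiles** (median, p75) interpolate the weighted empirical CDF with
  plotting positions pᵢ = (cᵢ − wᵢ)/(1 − wᵢ) over sorted values, where cᵢ
  is the cumulative weight. This reduces exactly to the standard
  linear-interpolation sample quantile (positions (i−1)/(n−1)) at equal
  weights, is monotone for arbitrary positive weights, and maps q=0/q=1 to
  min/max. Weighted-quantile conventions differ between packages, hence the
  explicit formula; a midpoint-position convention was considered and
  rejected because it disagrees with the standard unweighted quantile on
  equal weights.
* **Maximal bin weight** is the largest volume fraction in a histogram bin;
  default bin width 0.01 normalized-intensity units, range (0, max). This
  is the only binned index.
* **KS distance** is the supremum of |F_w(x) − Φ((x−μ)/σ)| with μ, σ
  fitted from the same region (population σ). The supremum over a step
  function minus a continuous CDF is attained at a jump, so both sides of
  every distinct-value step are evaluated — no grid, no approximation. It
  is computed on raw voxel values, not on binned histograms; coarse binning
  would change the statistic.
* Zero-variance regions return NaN for skewness and KS distance (not 0),
  and the NaNs propagate as missing values into cohort tables.

## Center geometry and volume ratio

W = ΣIᵢPᵢ/ΣIᵢ uses normalized intensities (W is invariant to the
normalization scale either way); G is the unweighted centroid; d = |W−G|/N.
The division by the voxel count N is deliberate and literal: it suppresses
disc-size effects but gives d units of mm/voxel, so d is only comparable
across images on matched grids. Positions in voxel-index units are
available (`extract_region(..., units="voxel")`) for resolution-independent
reporting. The weighted center accepts an optional volume-fraction
weighting for anisotropic grids; the default follows the plain n-point sum.
The NP/IVD volume ratio is a voxel-count ratio, integer-exact on one grid.

## Group statistics

For each (normalization, region, index) cell:

* **Three-group comparison** (control / scoliosis / spondylolisthesis):
  Shapiro–Wilk per group and Levene (median-centered) across groups, both
  at α = 0.05, gate between one-way ANOVA (+ Tukey HSD post-hoc) and
  Kruskal–Wallis (+ Dunn's post-hoc). Dunn's test uses midranks with the
  tie-corrected variance (N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/nᵢ+1/nⱼ) and
  two-sided normal p-values. Pairwise stars appear only when the omnibus
  test rejects.
* **Severity contrast**: pathology × severity factorial on the pathologic
  subjects (control excluded), type-II sums of squares. When the per-cell
  normality/homogeneity gates fail, values are replaced by their global
  midranks and the same linear model is fitted — the Conover rank-transform
  ANOVA, the standard reading of "ANOVA on ranks" for a factorial design.
* Stars: `*` p < 0.05, `**` p < 0.01 (configurable). No multiple-testing
  correction is applied across the grid by default, matching common
  practice for exploratory index screens; Benjamini–Hochberg is available
  behind a flag.

Every group (or design cell) needs at least 3 observations — the minimum
for Shapiro–Wilk — otherwise the comparison raises an insufficient-data
error and its grid cell stays empty.

## Synthetic phantom

The generator emulates the structures the pipeline consumes, not spine
anatomy: an ellipsoidal disc (default semi-axes 18×14×6 mm on a 64×64×32
grid at 1 mm isotropic) containing a concentric NP ellipsoid scaled to a
27% volume ratio by default, plus two constant-composition reference
blocks (CSF 1000, bone 320 arbitrary units; NP 800, AF 200) and additive
Gaussian noise (sd 20). All randomness flows from a single integer seed;
volumes are bit-identical across runs.

Three structural choices make the phantom informative rather than trivially
symmetric:

* a **radial T2 attenuation** toward the outer annulus (35% loss at the
  disc surface, quadratic in elliptic radius), anchored to the *disc*
  frame. A displaced nucleus is therefore attenuated asymmetrically, which
  is what makes the weighted center — and d — respond monotonically to the
  imposed displacement; a homogeneous NP would carry its own weighted
  center along with it and d(NP) would ignore the displacement entirely;
* a thin **NP/AF partial-volume rim** (Gaussian blur, 0.7 mm) so a healthy
  annulus histogram carries a small, far, concentrated bright tail;
* **degeneration** in [0,1] widens that rim (1.5 mm per unit, via
  normalized convolution restricted to the disc interior so no exterior
  signal bleeds in) and fades the NP toward the AF intensity (20% of the
  full blend at degeneration 1). Spreading the concentrated bright mass
  through the annulus raises its std and sum of squares while making the
  histogram smoother and closer to its own fitted Gaussian, so the KS
  distance falls — the qualitative signature of degeneration on
  T2-weighted images. The fade is kept partial because a full NP→AF blend
  removes the contrast faster than the blur can spread it, reversing the
  std trend at high degeneration.

Noise is additive Gaussian, a documented simplification of Rician magnitude
noise that is adequate at the simulated SNR (≥10). The reference blocks are
noise-bearing but composition-constant.

The default cohort reproduces the five-group study layout — low/high
scoliosis (n=16 each), low/high spondylolisthesis (n=16 each), control
(n=15), 79 subjects — with per-group distributions chosen to mirror the
clinical cohort's volume-ratio means and spreads (control 27.0 ± 6.3%,
scoliosis 18.9–19.9%, spondylolisthesis 18.0–22.2%), larger nucleus
displacement in scoliosis (2.0 mm mean vs 0.7–1.0 mm), and degeneration
rising with severity. Group parameters are sampled per subject from
truncated normal draws; displacement direction is uniform in-plane; each
subject gets an independent child seed from the master seed.

What passing tests on phantoms do **not** show: robustness to real
segmentation variability, partial-volume effects of thick sagittal slices
with gaps, Rician noise at low SNR, susceptibility or bias-field artifacts,
or anatomically realistic disc shapes. The phantom validates the *method's
mechanics* (invariances, monotone responses, statistical calibration), not
clinical sensitivity.

## Numerical choices and degenerate inputs

* Region weights always sum to 1 within 1e-9 by construction; extraction
  fails loudly on empty regions or misaligned masks.
* Assumption gates treat constant groups as non-normal (Shapiro p := 0).
* All-constant data across groups returns F = 0, p = 1 rather than NaN.
* Ellipsoid containment of the displaced NP is checked on 400 sampled
  surface directions (deterministic sampling), a practical surrogate for
  the exact ellipsoid-in-ellipsoid criterion.
* Problem sizes in the test suite and acceptance script (reduced 32×32×16
  phantom grids for repeated-simulation studies, 100–2000 replicates for
  calibration estimates) were chosen to keep simulation studies quick while
  leaving Monte-Carlo error well inside the asserted margins.

## Known limitations

* d has resolution-dependent units by construction (see above); compare
  only within one acquisition protocol.
* The severity contrast pools both pathologies, so a severity effect in one
  pathology only is diluted.
* Dunn p-values are unadjusted for the number of pairs, following the
  two-level star convention of the reporting grid.
* DICOM input, registration, and segmentation are out of scope; masks are
  inputs.
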