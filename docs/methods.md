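# Methods

This note documents the models implemented in `hncpipe`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical choices that affect results.

## PET segmentation and metabolic indices

The lesion mask is `{voxel ∈ seed ROI : SUV ≥ threshold}` with the threshold
fixed at 2.5, the long-standing head-and-neck convention. When the
thresholded set is disconnected, the largest 26-connected component is kept:
the contract assumes a single primary lesion, and 26-connectivity is the
permissive 3-D standard. An empty candidate set raises an explicit
"no avid lesion" error rather than returning an empty mask, and a seed ROI
touching the grid boundary sets a provenance flag. SUV values are taken as
given (body-weight normalization assumed upstream); MTV is voxel count ×
voxel volume with no partial-volume surface correction, matching
threshold-based volumetry, so TLG = MTV × SUVmean holds as an exact
algebraic identity and is asserted as such in the tests.

## Texture features

Quantization is equal-width min–max binning *within the tumor mask* into 64
levels by default. The bin count is a genuine degree of freedom in this
literature; 64 is the common choice of the co-occurrence era and keeps
entropy magnitudes in the single-digit-bit range typical of reported values.
Because binning is min–max within the mask, every feature is invariant under
monotone affine rescaling of SUV. The top bin is right-closed so the
maximum voxel is always assigned level 64; a constant tumor degenerates to
one occupied level and is flagged.

The co-occurrence matrix pools counts over all 13 unique 3-D directions at
distance 1 voxel, in both orderings (symmetric by construction), skipping
pairs that leave the mask, then normalizes once after pooling.
Direction-summed pooling (rather than per-direction feature averaging) is
the default because the tumors are volumetric and small; no isotropic
resampling is applied before texture computation — voxels are used as
acquired and anisotropy is recorded in the feature metadata. Entropy uses
log base 2 (bits).

The gray-tone difference table follows Amadasun and King: for every masked
voxel with at least one masked 26-neighbor, the neighborhood mean excludes
the center and all out-of-mask voxels; s(i) accumulates |i − mean| per
level, p_i is the occupancy fraction. Coarseness is (ε + Σ p_i s_i)⁻¹ with
ε = 10⁻⁶, capping the perfectly homogeneous case at 10⁶; contrast and
busyness are undefined with a single occupied level and are returned as
explicit missing values, never silently as zero. All nine features are
cross-checked against independent brute-force pairwise/neighborhood
enumeration on random ≤8³ grids to 10⁻¹⁰.

## DCE-MRI chain

**T1 mapping.** The variable-flip-angle SPGR signal is linearized as
S/sin α = E1·(S/tan α) + M0(1 − E1), fitted by ordinary least squares per
voxel; T1 = −TR/ln(slope). Slopes outside (0, 1) are nonphysical and flag
the voxel as unfittable instead of being clamped, because clamping produces
plausible-looking but meaningless T1 values.

**Concentration.** The baseline signal (mean of the 4 pre-contrast frames)
calibrates M0 from the known T1₀; each frame is inverted for T1(t) and
C(t) = (1/r1)(1/T1(t) − 1/T1₀). Relaxivity defaults to r1 = 4.5 s⁻¹mM⁻¹
(Gd-DTPA at 3 T). Negative concentrations from noise are clipped at zero
with the clip count reported. TE decay is neglected (TE = 1.13 ms).

**AIF.** The reproducible default is the Parker population model — a
two-Gaussian-plus-sigmoidal-washout analytic plasma curve — shifted to the
detected bolus-arrival frame (first frame whose mean enhancement exceeds
5× the baseline noise SD, falling back to the first post-baseline frame for
noiseless data). A data-driven mode decomposes an arterial candidate
region's time courses into independent temporal sources (FastICA), selects
the most bolus-like source by peak amplitude and early arrival, rescales it
to concentration through its highest-loading voxels at the blood T1, and
divides by (1 − hematocrit), 0.42 by default, to convert whole-blood to
plasma concentration. If no source passes the arterial criteria the
population mode is returned with a warning flag.

**Extended Kety fit.** The convolution K^trans ∫C_p e^(−k_ep(t−τ))dτ is
evaluated by trapezoidal quadrature on the native frame grid via a
precomputed lower-triangular weight matrix; at 3.3-s resolution this is
accurate to well below the 1% recovery tolerance for physiological k_ep, so
no supersampling is applied by default. Parameters are bounded
(K^trans ∈ [0, 5] min⁻¹, v_e ∈ (0, 1], v_p ∈ [0, 0.5]) and fitted by
trust-region least squares from four starts crossing low/high K^trans with
low/high v_e; the lowest residual wins, ties resolving toward the smaller
K^trans. k_ep is always derived as K^trans/v_e, never fitted independently.
An all-zero curve short-circuits to the boundary solution. ROI values are
means over converged, unflagged voxels with the exclusion count reported
(median aggregation would also be defensible; the mean is documented as the
choice).

## DWI

ADC = ln(S₀/S_b)/b voxel-wise. Nonpositive signals and nonpositive ADCs
(S_b ≥ S₀, nonphysical for tissue) are flagged but the values are reported,
so diagnostic accounting is possible downstream. The tumor ROI for ADC may
differ from the PET-defined volume; the API accepts an independent mask.

## Synthetic data

The PET phantom is an ellipsoid of mean SUV 8 in an SUV-1 background on a
2-mm grid. Heterogeneity is a log-normal multiplicative field: white noise
Gaussian-smoothed to a correlation length (default 4 mm), normalized to
unit variance in the tumor, scaled by σ (default 0.3) and exponentiated.
This gives independent control of heterogeneity amplitude (σ) and spatial
scale (correlation length) — the paired-simulation tests verify that longer
correlation lengths yield higher coarseness. Background noise is kept
strictly below the 2.5 threshold so segmentation is well-posed by
construction. The generator emulates contrast and texture only: there is no
scanner point-spread function, scatter, reconstruction noise or anatomy, so
passing tests demonstrate correctness of the estimators, not robustness to
scanner physics.

The DCE generator runs the same extended Kety model forward under a chosen
AIF (a shared code path with the fitter — the round-trip tests therefore
validate inversion, while the quadrature itself is validated against the
analytic special cases: flat signal for no exchange, exact linearity in M0).
Timing defaults are 80 frames at 3.3 s with 4 pre-contrast frames, VFA
baselines at 4°/8°/15°/25°, TR/TE 3.5/1.13 ms, dynamic flip 15°; the bolus
arrives at the first post-baseline frame, mirroring injection immediately
after the baseline block. Noise, when requested, is additive Gaussian in
signal space at a stated SNR (a first-order stand-in for Rician noise,
adequate at the SNRs used). DWI is monoexponential decay at b = 800 s/mm².

The cohort generator draws imaging parameters from log-normal distributions
for volume-like quantities (MTV, TLG, SUVmax) and normal distributions for
entropy and the kinetic/diffusion parameters — matching the skewness these
quantities typically show; no public distributional summaries exist to
calibrate against, so the defaults are illustrative and fully configurable.
Response is Bernoulli with logit = intercept + Σβ·z, survival exponential
proportional-hazards on the same design; planted effects act on
above-threshold indicators when a dichotomization point is specified, so
cutoff-based analyses can recover them. Censoring is independent
exponential with its rate solved numerically so the expected censored
fraction matches the requested rate; a rate of zero disables censoring. All
generators are bit-reproducible given their seed.

## Statistical layer

ROC cutoffs maximize Youden's J over all midpoints between consecutive
observed values, in both orientations, ties broken toward higher
sensitivity then the smaller cutoff; the exhaustive-search property is
asserted against an independent oracle. Association uses the plain Pearson
chi-square (no continuity correction). The logistic response model reports
exponentiated coefficients as odds ratios — in parts of the clinical
literature these are labeled "hazard ratios", which is a misnomer this
package does not reproduce. Perfect separation triggers a ridge-penalized
IRLS refit (λ = 1) flagged `penalized`. Survival modeling uses Kaplan–Meier
with Greenwood variance, log-rank tests, and Cox regression with Efron tie
handling; multivariable models are built by a univariate screen at p < .05
(configurable) followed by joint adjustment, mirroring the
screen-then-adjust flow common in these studies. No multiple-testing
correction is applied by default (two-sided p < .05 convention);
Benjamini–Hochberg is left to the caller. OS is measured from diagnosis and
RFS from end of treatment; the cohort table carries both time origins as
separate columns.

The additive risk score assigns one point per satisfied high-risk rule; it
is permutation-invariant in the rules and bounded by the rule count.
Score-stratified outputs report complete-response rates per level with a
chi-square across levels, and per-level Kaplan–Meier curves with a
multi-stratum log-rank test.

On null cohorts the screen-then-adjust procedure's false-selection behavior
is surfaced by the test suite (confidence-interval coverage of OR = 1 and
HR = 1 at 50 replicates of n = 1000) rather than asserted below a bound.

## Pipeline and problem sizes

The orchestrated run generates per-patient phantoms (32³ grid), measures
them, fits the tumor-average DCE curve per patient (2×2×2 voxel series at
SNR 60), computes ADC (4³ at SNR 80), then plants logistic and
proportional-hazards effects on the *measured* parameters (dichotomized at
cohort medians) and runs the full statistical layer. Per-patient failures
are quarantined and logged without aborting; each output file is
checksummed into the manifest, and a fixed seed reproduces every report
byte-identically. Default sizes (40 patients; 50 replicates and n = 1000
for the coverage simulations; 100 replicates for the noisy-fit bias; 50
random ≤8³ grids for the texture oracle) were chosen to make the binomial
and Monte-Carlo error small relative to the tolerances being checked while
keeping a full validation run in the tens of seconds on one CPU.

## Known limitations

- No DICOM ingestion, motion correction, registration, B1 correction, or
  partial-volume modeling; inputs start at SUV/signal volumes.
- The data-driven AIF mode is a generic independent-source decomposition,
  not a specific published blind-source-separation algorithm; the
  population mode is the reproducible default.
- Texture conventions (bin count, direction pooling, no resampling) are
  documented assumptions, switchable via arguments, since the upstream
  toolchains of this literature do not fully specify them.
- Synthetic cohort distributions are illustrative; recovery results show
  estimator correctness under the stated models, not clinical effect sizes.
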