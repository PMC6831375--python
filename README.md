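# hncpipe

Multimodal tumor-imaging quantification and prognostic risk scoring for
head-and-neck cancer studies, validated end-to-end on synthetic phantoms and
cohorts with known ground truth.

Pretreatment imaging of head-and-neck squamous cell carcinoma commonly
combines three quantitative modalities: FDG-PET (metabolic burden and
intratumoral heterogeneity), dynamic contrast-enhanced MRI (microvascular
permeability) and diffusion-weighted MRI (cellularity). Studies of this kind
dichotomize each imaging parameter at a ROC-derived cutoff, identify
independent predictors of treatment response and survival, and combine them
into an additive risk score. `hncpipe` implements that whole chain as a
tested, reusable library; because no patient data from such studies are
publicly deposited, every estimator is exercised against synthetic data
whose ground truth is exact.

## What it computes

**PET** — the lesion is segmented inside an operator ROI at a fixed SUV
threshold of 2.5 (largest 26-connected component); from the mask:
SUVmax, metabolic tumor volume MTV (voxel count × voxel volume, mL) and
total lesion glycolysis TLG = MTV × SUVmean (g/mL × mL). Heterogeneity is
quantified after 64-level min–max quantization by five second-order features
of the normalized gray-level co-occurrence matrix (uniformity = Σp²,
entropy = −Σp log₂p, dissimilarity = Σp|i−j|, homogeneity = Σp/(1+|i−j|),
inverse difference moment = Σp/(1+(i−j)²)) and four Amadasun–King features
of the neighborhood gray-tone difference matrix (coarseness, contrast,
busyness, complexity).

**DCE-MRI** — baseline T1₀ by the linearized variable-flip-angle SPGR fit
(4°/8°/15°/25°); signal→gadolinium concentration via
R1(t) = 1/T1₀ + r1·C(t); arterial input from the Parker population model
(or a data-driven independent-source mode); voxel-wise extended Kety
(extended Tofts) fit

&nbsp;&nbsp;&nbsp;&nbsp;C_t(t) = v_p·C_p(t) + K^trans ∫₀ᵗ C_p(τ)·e^(−k_ep(t−τ)) dτ,&nbsp;&nbsp;k_ep = K^trans/v_e,

by bounded multi-start nonlinear least squares on the native 3.3-s frame
grid (80 frames, 4 pre-contrast).

**DWI** — ADC = ln(S₀/S_b)/b from a b = 0 / b = 800 s/mm² pair.

**Statistics** — Youden-optimal ROC cutoffs, Pearson chi-square screens,
multivariable logistic response models (odds ratios), Kaplan–Meier / log-rank
/ Cox survival models (Efron ties, univariate screen then multivariable
adjustment), and additive risk scores counting each patient's independent
adverse factors, with score-stratified response rates and survival curves.

## Worked example

```python
import numpy as np
from hncpipe import (PhantomSpec, generate_pet_phantom, segment_fixed_threshold,
                     metabolic_indices, texture_features, AcquisitionSpec,
                     KineticGroundTruth, generate_dce_series, fit_t1_vfa,
                     signal_to_concentration, fit_extended_kety, population_aif)

# PET: heterogeneous ellipsoidal tumor, SUV 8, in SUV-1 background
spec = PhantomSpec(grid_shape=(48, 48, 48), tumor_radii_mm=(14, 12, 11),
                   tumor_mean_suv=8.0, heterogeneity_sigma=0.3,
                   heterogeneity_correlation_mm=4.0, rng_seed=7)
volume, _ = generate_pet_phantom(spec)
seg = segment_fixed_threshold(volume, np.ones(spec.grid_shape, bool), threshold=2.5)
met = metabolic_indices(volume, seg)
feats = texture_features(volume, seg, n_bins=64)

# DCE: forward-generate at known kinetics, then recover them
acq = AcquisitionSpec()                       # 80 frames @ 3.3 s, TR/TE 3.5/1.13 ms
aif = population_aif(acq.bolus_arrival_s)
truth = KineticGroundTruth(ktrans_per_min=0.655, ve_fraction=0.40, vp_fraction=0.05)
series, vfa = generate_dce_series(truth, acq, aif)
t1 = fit_t1_vfa(vfa, acq.vfa_flips_deg, acq.tr_ms)
conc, _ = signal_to_concentration(series, t1, acq.relaxivity_per_s_per_mM)
fit = fit_extended_kety(conc[0, 0, 0], aif, series.frame_times_s)
```

prints (via the obvious `print` statements):

```
SUVmax 21.20  MTV 7.81 mL  TLG 61.24 g/mL x mL
entropy 8.927 bits  uniformity 0.00323  coarseness 0.02310
Ktrans 0.6550/min  ve 0.4000  vp 0.0500  kep 1.6375/min
```

The segmentation recovers the planted tumor (7.81 mL at 2-mm voxels), TLG
satisfies TLG = MTV × SUVmean exactly, and the extended-Kety fit recovers
the planted K^trans = 0.655 min⁻¹, v_e = 0.40, v_p = 0.05 to four decimal
places from a noiseless forward series — the fit's k_ep is K^trans/v_e by
construction.

A full synthetic study (40 patients, imaging → cohort → response and
survival scoring) runs with:

```bash
hncpipe run --out myrun --seed 99 --n-patients 40
```

writing `cohort.csv`, cutoff/model/score tables, Kaplan–Meier curves, a
markdown report and a manifest with per-file checksums.

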