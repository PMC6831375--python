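"""Digital phantoms and synthetic cohorts with known ground truth.

Every downstream estimator in this package (SUV-threshold volumetry, texture
features, VFA T1 mapping, extended-Kety fitting, ADC mapping, response and
survival modeling) is exercised against data generated here, where the truth
is known exactly:

* **PET phantom** — an FDG-avid ellipsoidal tumor in a low-uptake background.
  Intratumoral heterogeneity is a log-normal multiplicative field obtained by
  Gaussian-smoothing white noise, giving independent control of its amplitude
  (``heterogeneity_sigma``) and spatial scale (``heterogeneity_correlation_mm``).
* **DCE-MRI series** — spoiled gradient-echo dynamic signals driven by the
  extended Kety forward model under a known arterial input function, plus
  variable-flip-angle baseline volumes at 4°, 8°, 15° and 25° from the same
  T1_0.  The default timing (80 frames at 3.3 s, 4 pre-contrast baseline
  frames, TR/TE 3.5/1.13 ms, 15° dynamic flip) mirrors a typical 3-T
  head-and-neck protocol; the bolus arrives at the first post-baseline frame.
* **DWI pair** — monoexponential decay ``S_b = S_0 exp(-b·ADC)`` at
  b = 800 s/mm².
* **Cohort** — per-patient imaging parameters drawn from configurable
  distributions, a binary treatment response (complete vs non-complete)
  generated by a logistic model with planted log-odds, and survival times
  from an exponential-baseline proportional-hazards model with independent
  censoring.  The planted coefficients are returned alongside the table so
  recovery tests can compare estimates with truth.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq

from .mri_functional import AifModel, DynamicSeries, spgr_signal
from .pet_quant import SuvVolume

__all__ = [
    "PhantomSpec",
    "KineticGroundTruth",
    "AcquisitionSpec",
    "PredictorSpec",
    "CohortSpec",
    "generate_pet_phantom",
    "generate_dce_series",
    "generate_dwi_pair",
    "generate_cohort",
    "write_phantom",
]


# ---------------------------------------------------------------------------
# specifications


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity description of a PET phantom."""

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    tumor_center_mm: tuple[float, float, float] | None = None  # grid center
    tumor_radii_mm: tuple[float, float, float] = (15.0, 12.0, 10.0)
    tumor_mean_suv: float = 8.0
    background_suv: float = 1.0
    heterogeneity_sigma: float = 0.3
    heterogeneity_correlation_mm: float = 4.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.tumor_mean_suv <= 2.5:
            raise ValueError("tumor_mean_suv must exceed the 2.5 SUV threshold")
        if not (0 <= self.background_suv < 2.5):
            raise ValueError("background_suv must be below the 2.5 SUV threshold")
        if self.heterogeneity_sigma < 0:
            raise ValueError("heterogeneity_sigma must be nonnegative")
        if self.heterogeneity_correlation_mm <= 0:
            raise ValueError("heterogeneity_correlation_mm must be positive")
        if any(r <= 0 for r in self.tumor_radii_mm):
            raise ValueError("tumor radii must be positive")

    @property
    def center_mm(self) -> tuple[float, float, float]:
        if self.tumor_center_mm is not None:
            return self.tumor_center_mm
        return tuple(
            (n - 1) * s / 2.0 for n, s in zip(self.grid_shape, self.voxel_spacing_mm)
        )


@dataclass(frozen=True)
class KineticGroundTruth:
    """True pharmacokinetic / relaxometric / diffusion parameters."""

    ktrans_per_min: float | np.ndarray = 0.3
    ve_fraction: float | np.ndarray = 0.35
    vp_fraction: float | np.ndarray = 0.05
    t10_ms: float | np.ndarray = 1000.0
    adc_mm2_per_s: float = 1.0e-3

    def __post_init__(self) -> None:
        ve = np.asarray(self.ve_fraction, dtype=float)
        vp = np.asarray(self.vp_fraction, dtype=float)
        kt = np.asarray(self.ktrans_per_min, dtype=float)
        if np.any(kt < 0):
            raise ValueError("ktrans must be nonnegative")
        if np.any((ve <= 0) & (kt > 0)):
            raise ValueError("ve = 0 with ktrans > 0: k_ep undefined")
        if np.any(ve > 1) or np.any(vp < 0) or np.any(vp >= 1):
            raise ValueError("require 0 < ve <= 1 and 0 <= vp < 1")
        if np.any(ve + vp > 1):
            raise ValueError("ve + vp must not exceed 1")
        if np.any(np.asarray(self.t10_ms) <= 0) or self.adc_mm2_per_s <= 0:
            raise ValueError("t10 and ADC must be positive")


@dataclass(frozen=True)
class AcquisitionSpec:
    """DCE/VFA/DWI acquisition timing and physics constants."""

    tr_ms: float = 3.5
    te_ms: float = 1.13
    dynamic_flip_deg: float = 15.0
    vfa_flips_deg: tuple[float, ...] = (4.0, 8.0, 15.0, 25.0)
    n_frames: int = 80
    frame_interval_s: float = 3.3
    n_baseline_frames: int = 4
    b_value_s_per_mm2: float = 800.0
    relaxivity_per_s_per_mM: float = 4.5
    hematocrit: float = 0.42

    def __post_init__(self) -> None:
        if self.n_baseline_frames >= self.n_frames:
            raise ValueError("n_baseline_frames must be < n_frames")
        if len(self.vfa_flips_deg) < 2:
            raise ValueError("need at least two VFA flip angles")

    @property
    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    @property
    def bolus_arrival_s(self) -> float:
        """Injection immediately after the baseline block."""
        return self.n_baseline_frames * self.frame_interval_s


# ---------------------------------------------------------------------------
# PET phantom


def generate_pet_phantom(spec: PhantomSpec) -> tuple[SuvVolume, np.ndarray]:
    """Ellipsoidal FDG-avid tumor with log-normal multiplicative texture.

    Tumor voxels take ``tumor_mean_suv × exp(σ·G)`` where G is a unit-variance
    Gaussian random field smoothed to the requested correlation length;
    background voxels take ``background_suv`` plus small positive noise kept
    strictly below the 2.5 segmentation threshold.  Returns the volume and
    the exact ellipsoid mask used.
    """
    rng = np.random.default_rng(spec.rng_seed)
    shape = tuple(int(n) for n in spec.grid_shape)
    spacing = np.asarray(spec.voxel_spacing_mm, dtype=float)
    center = np.asarray(spec.center_mm, dtype=float)
    radii = np.asarray(spec.tumor_radii_mm, dtype=float)

    lo = center - radii
    hi = center + radii
    extent = (np.asarray(shape) - 1) * spacing
    if np.any(lo < 0) or np.any(hi > extent):
        raise ValueError("tumor ellipsoid exceeds the grid extent")

    coords = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    dist2 = sum(((c - mu) / r) ** 2 for c, mu, r in zip(coords, center, radii))
    mask = dist2 <= 1.0

    volume = np.full(shape, float(spec.background_suv))
    if spec.background_suv > 0:
        # small positive jitter, capped so background stays below threshold
        amp = min(0.05 * spec.background_suv, 0.5 * (2.5 - spec.background_suv))
        noise = rng.normal(0.0, amp / 3.0 if amp > 0 else 0.0, size=shape)
        volume = np.clip(volume + noise, 0.0, 2.5 - 1e-6)

    if spec.heterogeneity_sigma > 0:
        white = rng.standard_normal(shape)
        sigma_vox = spec.heterogeneity_correlation_mm / spacing
        smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="reflect")
        sd = smooth[mask].std()
        if sd > 0:
            smooth = smooth / sd  # unit variance inside the tumor
        tumor_vals = spec.tumor_mean_suv * np.exp(
            spec.heterogeneity_sigma * smooth[mask]
        )
    else:
        tumor_vals = np.full(int(mask.sum()), float(spec.tumor_mean_suv))

    volume[mask] = np.clip(tumor_vals, 1e-9, None)
    return (
        SuvVolume(values=volume, voxel_spacing_mm=tuple(spacing)),
        mask,
    )


# ---------------------------------------------------------------------------
# DCE forward model


def generate_dce_series(
    truth: KineticGroundTruth,
    acq: AcquisitionSpec,
    aif: AifModel,
    grid_shape: tuple[int, int, int] = (1, 1, 1),
    m0: float = 1000.0,
    snr: float | None = None,
    rng_seed: int = 0,
) -> tuple[DynamicSeries, np.ndarray]:
    """Forward-generate an SPGR dynamic series plus VFA baseline volumes.

    Per voxel the extended Kety model gives C_t(t) under the supplied AIF;
    concentration raises the relaxation rate linearly
    (``R1(t) = 1/T1_0 + r1·C_t``) and the SPGR equation turns R1 into signal.
    The first ``n_baseline_frames`` frames are pre-contrast.  Optional
    additive Gaussian noise in signal space with the given SNR (defined as
    baseline signal over noise SD).  Returns ``(series, vfa)`` where ``vfa``
    stacks one volume per flip angle on the last axis.
    """
    from .mri_functional import kety_forward

    t = acq.frame_times_s
    shape = tuple(int(n) for n in grid_shape)
    nvox = int(np.prod(shape))

    kt = np.broadcast_to(np.asarray(truth.ktrans_per_min, float), shape).ravel()
    ve = np.broadcast_to(np.asarray(truth.ve_fraction, float), shape).ravel()
    vp = np.broadcast_to(np.asarray(truth.vp_fraction, float), shape).ravel()
    t10 = np.broadcast_to(np.asarray(truth.t10_ms, float), shape).ravel()

    cp = aif(t)
    frames = np.empty((nvox, t.size))
    for v in range(nvox):
        ct = kety_forward(t, cp, kt[v], ve[v], vp[v])
        r1 = 1.0 / t10[v] + acq.relaxivity_per_s_per_mM * ct / 1000.0  # 1/ms
        frames[v] = spgr_signal(m0, 1.0 / r1, acq.tr_ms, acq.dynamic_flip_deg)

    frames = frames.reshape(shape + (t.size,))
    vfa = np.stack(
        [
            spgr_signal(m0, t10.reshape(shape), acq.tr_ms, a)
            for a in acq.vfa_flips_deg
        ],
        axis=-1,
    )

    if snr is not None and snr > 0:
        rng = np.random.default_rng(rng_seed)
        base = float(frames[..., : acq.n_baseline_frames].mean())
        sd = base / snr
        frames = np.clip(frames + rng.normal(0.0, sd, frames.shape), 0.0, None)
        vfa = np.clip(vfa + rng.normal(0.0, sd, vfa.shape), 0.0, None)

    series = DynamicSeries(
        frames=frames,
        frame_times_s=t,
        n_baseline_frames=acq.n_baseline_frames,
        tr_ms=acq.tr_ms,
        flip_deg=acq.dynamic_flip_deg,
        acquisition=acq,
    )
    return series, vfa


# ---------------------------------------------------------------------------
# DWI


def generate_dwi_pair(
    adc_mm2_per_s: float | np.ndarray,
    b: float = 800.0,
    s0: float | np.ndarray = 1000.0,
    grid_shape: tuple[int, int, int] | None = None,
    snr: float | None = None,
    rng_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Monoexponential DWI pair: ``S_b = S_0 exp(-b·ADC)`` voxel-wise."""
    adc = np.asarray(adc_mm2_per_s, dtype=float)
    if np.any(adc <= 0):
        raise ValueError("ADC must be positive")
    s0a = np.asarray(s0, dtype=float)
    if grid_shape is not None:
        adc = np.broadcast_to(adc, grid_shape).copy()
        s0a = np.broadcast_to(s0a, grid_shape).copy()
    sb = s0a * np.exp(-b * adc)
    if snr is not None and snr > 0:
        rng = np.random.default_rng(rng_seed)
        sd = float(np.mean(s0a)) / snr
        s0a = np.clip(s0a + rng.normal(0.0, sd, s0a.shape), 1e-9, None)
        sb = np.clip(sb + rng.normal(0.0, sd, sb.shape), 1e-9, None)
    return s0a, sb


# ---------------------------------------------------------------------------
# synthetic cohort


@dataclass(frozen=True)
class PredictorSpec:
    """Distribution and (optional) planted effect of one imaging parameter.

    ``distribution`` is "lognormal" (parameters are the log-scale mean/sd,
    the default for volume-like quantities) or "normal".  Planted effects act
    on the indicator ``x > dichotomize_at`` when a cutoff is given, otherwise
    on the standardized continuous value.
    """

    name: str
    distribution: str = "lognormal"
    loc: float = 0.0
    scale: float = 1.0
    response_log_odds: float = 0.0
    survival_log_hazard: float = 0.0
    dichotomize_at: float | None = None


#: default imaging-parameter distributions: log-normal for volume-like
#: quantities, normal for entropy and the kinetic/diffusion parameters
DEFAULT_PREDICTORS: tuple[PredictorSpec, ...] = (
    PredictorSpec("suvmax", "lognormal", loc=2.3, scale=0.4),
    PredictorSpec("mtv_ml", "lognormal", loc=2.5, scale=0.8),
    PredictorSpec("tlg", "lognormal", loc=4.6, scale=0.9),
    PredictorSpec("entropy_bits", "normal", loc=7.0, scale=0.2),
    PredictorSpec("uniformity", "normal", loc=0.01, scale=0.003),
    PredictorSpec("ktrans_per_min", "normal", loc=0.45, scale=0.15),
    PredictorSpec("ve_fraction", "normal", loc=0.35, scale=0.1),
    PredictorSpec("vp_fraction", "normal", loc=0.05, scale=0.02),
    PredictorSpec("kep_per_min", "normal", loc=1.3, scale=0.4),
    PredictorSpec("adc_mm2_per_s", "normal", loc=1.0e-3, scale=0.2e-3),
)


@dataclass(frozen=True)
class CohortSpec:
    """Synthetic patient cohort with planted response and survival effects."""

    n_patients: int = 61
    predictors: tuple[PredictorSpec, ...] = DEFAULT_PREDICTORS
    response_intercept: float = -1.0       # log-odds of non-complete response
    baseline_hazard_per_month: float = 0.02
    censoring_rate: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.censoring_rate < 1):
            raise ValueError("censoring_rate must be in [0, 1)")
        coefs = [self.response_intercept, self.baseline_hazard_per_month] + [
            c for p in self.predictors
            for c in (p.response_log_odds, p.survival_log_hazard)
        ]
        if not np.all(np.isfinite(coefs)):
            raise ValueError("model coefficients must be finite")


def _draw_predictor(p: PredictorSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if p.distribution == "lognormal":
        return rng.lognormal(mean=p.loc, sigma=p.scale, size=n)
    if p.distribution == "normal":
        return rng.normal(loc=p.loc, scale=p.scale, size=n)
    raise ValueError(f"unknown distribution {p.distribution!r}")


def _effect_design(p: PredictorSpec, x: np.ndarray) -> np.ndarray:
    if p.dichotomize_at is not None:
        return (x > p.dichotomize_at).astype(float)
    return (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Draw a synthetic cohort table plus the ground-truth effect record.

    Response: ``P(non-complete) = logistic(intercept + Σ β_k z_k)``.
    Survival: exponential baseline hazard with multiplicative per-predictor
    hazards; overall-survival and recurrence-free-survival times are drawn
    from the same linear predictor (RFS with a 1.5× hazard, reflecting that
    recurrence-or-death precedes death).  Censoring is independent
    exponential with its rate solved so the expected censored fraction
    matches ``censoring_rate``; zero disables censoring.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_patients

    df = pd.DataFrame({"patient_id": [f"P{i:04d}" for i in range(n)]})
    z_resp = np.full(n, float(spec.response_intercept))
    z_surv = np.zeros(n)
    for p in spec.predictors:
        x = _draw_predictor(p, n, rng)
        df[p.name] = x
        z = _effect_design(p, x)
        z_resp = z_resp + p.response_log_odds * z
        z_surv = z_surv + p.survival_log_hazard * z

    p_noncr = 1.0 / (1.0 + np.exp(-z_resp))
    non_complete = rng.random(n) < p_noncr
    df["response"] = np.where(non_complete, "non_complete", "complete")

    h0 = spec.baseline_hazard_per_month
    hazard_os = h0 * np.exp(z_surv)
    hazard_rfs = 1.5 * h0 * np.exp(z_surv)
    t_os = rng.exponential(1.0 / hazard_os)
    t_rfs = rng.exponential(1.0 / hazard_rfs)

    def censor(times: np.ndarray, hazards: np.ndarray, sub_rng) -> tuple:
        if spec.censoring_rate == 0:
            return times, np.ones_like(times, dtype=bool)
        # P(censored) = E[rc / (rc + h)]; solve rc for the requested rate
        def pc(rc):
            return float(np.mean(rc / (rc + hazards))) - spec.censoring_rate
        rc = brentq(pc, 1e-10, 1e4)
        c = sub_rng.exponential(1.0 / rc, size=times.size)
        return np.minimum(times, c), times <= c

    os_m, os_event = censor(t_os, hazard_os, rng)
    rfs_m, rfs_event = censor(t_rfs, hazard_rfs, rng)
    df["os_months"] = os_m
    df["death"] = os_event
    df["rfs_months"] = rfs_m
    df["recurrence_or_death"] = rfs_event

    # clinical covariates mimicking a head-and-neck staging table
    df["t_stage"] = rng.choice(["T2", "T3", "T4"], size=n, p=[0.25, 0.35, 0.4])
    df["n_stage"] = rng.choice(["N0", "N1", "N2", "N3"], size=n,
                               p=[0.15, 0.2, 0.5, 0.15])

    truth = {
        "response_intercept": spec.response_intercept,
        "response_log_odds": {p.name: p.response_log_odds for p in spec.predictors
                              if p.response_log_odds != 0},
        "survival_log_hazard": {p.name: p.survival_log_hazard for p in spec.predictors
                                if p.survival_log_hazard != 0},
        "dichotomize_at": {p.name: p.dichotomize_at for p in spec.predictors
                           if p.dichotomize_at is not None},
        "baseline_hazard_per_month": h0,
        "censoring_rate": spec.censoring_rate,
    }
    return df, truth


# ---------------------------------------------------------------------------
# sidecar output


def write_phantom(out_dir, spec: PhantomSpec, volume: SuvVolume,
                  mask: np.ndarray) -> None:
    """Write a phantom as NIfTI image + mask with a JSON ground-truth sidecar."""
    from pathlib import Path

    from .pet_quant import save_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_volume(out / "suv.nii.gz", volume.values, volume.voxel_spacing_mm)
    save_volume(out / "tumor_mask.nii.gz", mask, volume.voxel_spacing_mm)
    sidecar = {
        "grid_shape": list(spec.grid_shape),
        "voxel_spacing_mm": list(spec.voxel_spacing_mm),
        "tumor_radii_mm": list(spec.tumor_radii_mm),
        "tumor_mean_suv": spec.tumor_mean_suv,
        "background_suv": spec.background_suv,
        "heterogeneity_sigma": spec.heterogeneity_sigma,
        "heterogeneity_correlation_mm": spec.heterogeneity_correlation_mm,
        "rng_seed": spec.rng_seed,
    }
    (out / "ground_truth.json").write_text(json.dumps(sidecar, indent=2))
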