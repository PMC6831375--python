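"""End-to-end orchestration: phantom/cohort generation → image quantification
→ cohort assembly → outcome modeling, as one reproducible, seeded run.

Each synthetic patient gets a PET phantom (segmented and quantified), a DCE
acquisition (tumor-average curve fitted with the extended Kety model), and a
DWI pair (ADC).  Measured imaging parameters are assembled into a cohort
table; treatment response and survival outcomes are then generated from
planted logistic and proportional-hazards effects on selected measured
parameters, and the statistical layer (ROC cutoffs, logistic response model,
Cox survival models, additive risk scores) is run on the result.

A failure while processing one patient quarantines that patient (logged in
the manifest) without aborting the run.  Every output file is listed in the
run manifest with its SHA-256 checksum, and the resolved configuration is
written next to the outputs so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import mri_functional as mf
from . import outcome_analysis as oa
from . import pet_quant as pq
from . import pet_texture as pt
from . import synthetic_data as sd

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "load_config"]

logger = logging.getLogger("hncpipe")

PACKAGE_VERSION = "0.1.0"


@dataclass
class RunConfig:
    """Resolved configuration of a full synthetic pipeline run."""

    n_patients: int = 40
    seed: int = 0
    out_dir: str = "hncpipe_run"

    # stage toggles
    run_pet: bool = True
    run_dce: bool = True
    run_dwi: bool = True
    run_outcomes: bool = True

    # PET phantom / segmentation / texture
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    suv_threshold: float = 2.5
    n_bins: int = 64

    # DCE acquisition and fitting
    aif_mode: str = "population"
    relaxivity_per_s_per_mM: float = 4.5
    hematocrit: float = 0.42

    # outcome generation (planted effects on measured parameters)
    response_intercept: float = -1.2
    response_log_odds: dict = field(
        default_factory=lambda: {"tlg": 2.0, "entropy_bits": 1.5}
    )
    survival_log_hazard: dict = field(
        default_factory=lambda: {
            "ktrans_per_min": -0.8, "vp_fraction": 0.6,
            "suvmax": 0.6, "entropy_bits": 0.8,
        }
    )
    baseline_hazard_per_month: float = 0.03
    censoring_rate: float = 0.25

    # statistics
    univariate_alpha: float = 0.05

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("grid_shape", "voxel_spacing_mm"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["voxel_spacing_mm"] = list(self.voxel_spacing_mm)
        return d


def load_config(path) -> RunConfig:
    """Load a YAML run configuration, rejecting unknown keys."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config: dict
    software_version: str
    wall_clock_s: float
    outputs: dict[str, str]          # path -> sha256
    quarantined: list[dict]
    warnings: list[str]
    stage_seconds: dict[str, float]

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _patient_imaging(cfg: RunConfig, idx: int, seed: int) -> dict:
    """Measure one synthetic patient; returns a row of imaging parameters."""
    rng = np.random.default_rng(seed)
    row: dict = {"patient_id": f"P{idx:04d}"}

    # per-patient ground truth drawn around physiological centers
    mean_suv = float(np.exp(rng.normal(np.log(8.0), 0.3)))
    radii = tuple(float(r) for r in rng.uniform(8.0, 13.0, size=3))
    sigma = float(rng.uniform(0.1, 0.45))
    corr = float(rng.uniform(2.0, 6.0))
    ktrans = float(np.clip(rng.normal(0.45, 0.15), 0.05, 1.5))
    ve = float(np.clip(rng.normal(0.35, 0.08), 0.1, 0.7))
    vp = float(np.clip(rng.normal(0.05, 0.015), 0.005, 0.2))
    adc_true = float(np.clip(rng.normal(1.0e-3, 0.2e-3), 0.4e-3, 2.0e-3))

    if cfg.run_pet:
        spec = sd.PhantomSpec(
            grid_shape=cfg.grid_shape,
            voxel_spacing_mm=cfg.voxel_spacing_mm,
            tumor_radii_mm=radii,
            tumor_mean_suv=mean_suv,
            heterogeneity_sigma=sigma,
            heterogeneity_correlation_mm=corr,
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        )
        volume, true_mask = sd.generate_pet_phantom(spec)
        roi = np.zeros(cfg.grid_shape, dtype=bool)
        pad = 2
        idxs = np.nonzero(true_mask)
        lo = [max(0, int(i.min()) - pad) for i in idxs]
        hi = [min(s, int(i.max()) + pad + 1) for i, s in zip(idxs, cfg.grid_shape)]
        roi[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
        seg = pq.segment_fixed_threshold(volume, roi, threshold=cfg.suv_threshold)
        met = pq.metabolic_indices(volume, seg)
        row.update(suvmax=met.suvmax, mtv_ml=met.mtv_ml,
                   suvmean=met.suvmean, tlg=met.tlg)
        feats = pt.texture_features(volume, seg, n_bins=cfg.n_bins)
        row.update(feats.as_dict())

    if cfg.run_dce:
        acq = sd.AcquisitionSpec(
            relaxivity_per_s_per_mM=cfg.relaxivity_per_s_per_mM,
            hematocrit=cfg.hematocrit,
        )
        truth = sd.KineticGroundTruth(
            ktrans_per_min=ktrans, ve_fraction=ve, vp_fraction=vp,
        )
        aif = mf.population_aif(acq.bolus_arrival_s, cfg.hematocrit)
        series, vfa = sd.generate_dce_series(
            truth, acq, aif, grid_shape=(2, 2, 2),
            snr=60.0, rng_seed=int(rng.integers(0, 2**31 - 1)),
        )
        t1 = mf.fit_t1_vfa(vfa, acq.vfa_flips_deg, acq.tr_ms)
        conc, _ = mf.signal_to_concentration(series, t1, acq.relaxivity_per_s_per_mM)
        mean_curve = np.nanmean(conc.reshape(-1, conc.shape[-1]), axis=0)
        params = mf.fit_extended_kety(mean_curve, aif, series.frame_times_s)
        row.update(
            ktrans_per_min=params.ktrans_per_min,
            ve_fraction=params.ve_fraction,
            vp_fraction=params.vp_fraction,
            kep_per_min=params.kep_per_min,
            dce_converged=params.converged,
        )

    if cfg.run_dwi:
        s0, sb = sd.generate_dwi_pair(
            adc_true, b=800.0, s0=1000.0, grid_shape=(4, 4, 4),
            snr=80.0, rng_seed=int(rng.integers(0, 2**31 - 1)),
        )
        res = mf.adc_map(s0, sb, b=800.0, mask=np.ones((4, 4, 4), dtype=bool))
        row["adc_mm2_per_s"] = res.roi_mean
    return row


def _generate_outcomes(cfg: RunConfig, table: pd.DataFrame,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Plant logistic response and PH survival effects on measured parameters.

    Effects act on indicators of each parameter exceeding its cohort median,
    so the planted direction is recoverable by the downstream ROC/score
    analysis.
    """
    df = table.copy()
    z_resp = np.full(len(df), cfg.response_intercept)
    for name, beta in cfg.response_log_odds.items():
        ind = (df[name] > df[name].median()).astype(float)
        z_resp = z_resp + beta * ind
    p_noncr = 1.0 / (1.0 + np.exp(-z_resp))
    non_cr = rng.random(len(df)) < p_noncr
    df["response"] = np.where(non_cr, "non_complete", "complete")

    z_surv = np.zeros(len(df))
    for name, beta in cfg.survival_log_hazard.items():
        ind = (df[name] > df[name].median()).astype(float)
        z_surv = z_surv + beta * ind
    h_os = cfg.baseline_hazard_per_month * np.exp(z_surv)
    h_rfs = 1.5 * h_os
    t_os = rng.exponential(1.0 / h_os)
    t_rfs = rng.exponential(1.0 / h_rfs)
    if cfg.censoring_rate > 0:
        from scipy.optimize import brentq

        def solve_rc(h):
            return brentq(
                lambda rc: float(np.mean(rc / (rc + h))) - cfg.censoring_rate,
                1e-10, 1e4,
            )
        c_os = rng.exponential(1.0 / solve_rc(h_os), size=len(df))
        c_rfs = rng.exponential(1.0 / solve_rc(h_rfs), size=len(df))
    else:
        c_os = np.full(len(df), np.inf)
        c_rfs = np.full(len(df), np.inf)
    df["os_months"] = np.minimum(t_os, c_os)
    df["death"] = t_os <= c_os
    df["rfs_months"] = np.minimum(t_rfs, c_rfs)
    df["recurrence_or_death"] = t_rfs <= c_rfs
    return df


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Execute all enabled stages; returns the manifest (also written to disk)."""
    t_start = time.perf_counter()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    quarantined: list[dict] = []
    stage_seconds: dict[str, float] = {}

    (out / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))

    # --- per-patient imaging ---------------------------------------------
    t0 = time.perf_counter()
    ss = np.random.SeedSequence(cfg.seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
                   for s in ss.spawn(cfg.n_patients + 1)]
    rows = []
    for i in range(cfg.n_patients):
        try:
            rows.append(_patient_imaging(cfg, i, child_seeds[i]))
        except Exception as exc:  # quarantine, do not abort
            logger.warning("patient %d quarantined: %s", i, exc)
            quarantined.append({"patient_index": i, "error": str(exc)})
    if not rows:
        raise RuntimeError("all patients failed imaging quantification")
    table = pd.DataFrame(rows)
    stage_seconds["imaging"] = time.perf_counter() - t0

    # --- outcome generation + statistics ---------------------------------
    t0 = time.perf_counter()
    report_lines = [
        "# Synthetic multimodal imaging run",
        "",
        f"Patients quantified: {len(table)} "
        f"(quarantined: {len(quarantined)})",
        "",
    ]
    results_files: list[Path] = []
    if cfg.run_outcomes:
        rng = np.random.default_rng(child_seeds[-1])
        table = _generate_outcomes(cfg, table, rng)

        # response analysis: cutoffs -> logistic model -> score strata
        try:
            resp_pos = (table["response"] == "non_complete").to_numpy()
            rules = []
            for name in cfg.response_log_odds:
                rule = oa.roc_cutoff(table[name], resp_pos)
                rules.append(dataclasses.replace(rule, parameter=name))
            cutoff_df = pd.DataFrame(
                [
                    {"parameter": r.parameter, "cutoff": r.cutoff,
                     "direction": r.direction, "sensitivity": r.sensitivity,
                     "specificity": r.specificity, "youden_j": r.youden_j}
                    for r in rules
                ]
            )
            cutoff_df.to_csv(out / "cutoffs.csv", index=False,
                             float_format="%.6g")
            results_files.append(out / "cutoffs.csv")

            logit = oa.response_model(table, rules)
            logit.to_csv(out / "response_model.csv", index=False,
                         float_format="%.6g")
            results_files.append(out / "response_model.csv")

            score_res = oa.build_score(table, rules)
            score_tab = score_res["response_by_score"]
            score_tab.to_csv(out / "response_by_score.csv", index=False,
                             float_format="%.6g")
            results_files.append(out / "response_by_score.csv")
            report_lines += [
                "## Response",
                "",
                "Cutoffs (Youden): "
                + "; ".join(f"{r.parameter} {r.direction} {r.cutoff:.4g}"
                            for r in rules),
                "",
                score_tab.to_string(index=False),
                "",
            ]
        except ValueError as exc:
            warnings.append(f"response analysis skipped: {exc}")
            report_lines += ["## Response", "", f"skipped: {exc}", ""]

        # survival analysis: cutoffs -> Cox screen/adjust -> score strata
        try:
            surv_rules = []
            for name in cfg.survival_log_hazard:
                rule = oa.roc_cutoff(table[name], table["death"].to_numpy())
                surv_rules.append(dataclasses.replace(rule, parameter=name))
            surv = oa.survival_models(
                table, surv_rules, "os_months", "death",
                univariate_alpha=cfg.univariate_alpha,
            )
            surv["univariate"].to_csv(out / "os_cox_univariate.csv",
                                      index=False, float_format="%.6g")
            results_files.append(out / "os_cox_univariate.csv")
            if surv["multivariable"] is not None:
                surv["multivariable"].to_csv(out / "os_cox_multivariable.csv",
                                             index=False, float_format="%.6g")
                results_files.append(out / "os_cox_multivariable.csv")

            surv_score = oa.build_score(
                table, surv_rules, response_col=None,
                time_col="os_months", event_col="death",
            )
            km_rows = []
            for level, km in surv_score["km_by_score"].items():
                km = km.copy()
                km.insert(0, "score", level)
                km_rows.append(km)
            pd.concat(km_rows).to_csv(out / "os_km_by_score.csv", index=False,
                                      float_format="%.6g")
            results_files.append(out / "os_km_by_score.csv")
            report_lines += [
                "## Overall survival",
                "",
                "Retained in multivariable Cox: "
                + (", ".join(surv["retained"]) if surv["retained"] else "none"),
                f"Score-stratified log-rank p = "
                f"{surv_score['survival_logrank']['p_value']:.3g}",
                "",
            ]
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.append(f"survival analysis skipped: {exc}")
            report_lines += ["## Overall survival", "", f"skipped: {exc}", ""]

    table.to_csv(out / "cohort.csv", index=False, float_format="%.10g")
    results_files.append(out / "cohort.csv")
    (out / "report.md").write_text("\n".join(report_lines))
    results_files.append(out / "report.md")
    results_files.append(out / "config.yaml")
    stage_seconds["outcomes"] = time.perf_counter() - t0

    manifest = RunManifest(
        config=cfg.to_dict(),
        software_version=PACKAGE_VERSION,
        wall_clock_s=time.perf_counter() - t_start,
        outputs={str(p.relative_to(out)): _sha256(p) for p in results_files},
        quarantined=quarantined,
        warnings=warnings,
        stage_seconds=stage_seconds,
    )
    manifest.write(out / "manifest.json")
    return manifest
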