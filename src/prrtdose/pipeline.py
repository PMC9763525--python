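"""End-to-end orchestration: calibrate -> simulate -> quantify -> dose -> stats.

Each stage consumes and produces plain tables (pandas DataFrames, written as
CSV) or JSON, so that any stage can equally be fed real study data — e.g. a
transcribed per-tumour supplement table — in place of the synthetic cohort.
All randomness flows from a single integer seed recorded in the manifest.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from . import constants
from .cohort import (
    CohortSpec,
    PatientRecord,
    cohort_organ_table,
    cohort_tumour_table,
    make_cohort,
)
from .dosimetry import (
    dose_rate_local,
    fit_organ_curve,
    fit_tumour_curve,
    rescale_and_integrate,
)
from .images import LabelMask, VoxelImage
from .phantoms import blur_and_noise, make_sphere_phantom, nema_phantom_spec
from .predict import PredictionConfig, backpropagate_to_t0, predict_dose, prediction_error_table
from .quantify import (
    CalibrationConfig,
    apply_suv_calibration,
    pvc_organ,
    pvc_tumour_pet,
    pvc_tumour_spect,
    voi_stats,
)
from .recovery import (
    RCFitResult,
    SphereMeasurement,
    VolumeMapParams,
    estimate_psf_fwhm,
    fit_rc,
    fit_volume_map,
)
from .stats import (
    filter_tumours,
    kidney_average,
    log_ratio_bland_altman,
    loo_interval,
    pearson,
    rmcorr,
    weighted_pearson,
)

__all__ = [
    "CalibrationResult",
    "segment_threshold_volume",
    "run_calibration",
    "quantify_cohort",
    "dosimetry_cohort",
    "predict_cohort",
    "run_stats",
    "run_full",
]


@dataclass
class CalibrationResult:
    """Fitted recovery calibrations from the sphere-phantom set."""

    rc_pet: RCFitResult
    rc_spect: RCFitResult
    vol_map: VolumeMapParams
    psf_fwhm_mm: float
    measurements: pd.DataFrame
    seed: int = 0

    def to_json_dict(self) -> dict:
        return {
            "rc_pet": self.rc_pet.to_dict(),
            "rc_spect": self.rc_spect.to_dict(),
            "volume_map": self.vol_map.to_dict(),
            "psf_fwhm_mm": self.psf_fwhm_mm,
            "seed": self.seed,
            "n_measurements": int(len(self.measurements)),
        }


def segment_threshold_volume(
    measured: VoxelImage,
    mask: LabelMask,
    label: int,
    background: float,
    search_voxels: int = 6,
) -> float:
    """Half-contrast threshold segmentation of one sphere, in mL.

    Counts voxels above background + 50% of the local contrast inside a
    neighbourhood of the true region; a deliberately simple segmenter whose
    volume bias (with respect to size and background ratio) is what the
    affine volume map is calibrated to undo.
    """
    region = mask.region(label)
    if not region.any():
        raise ValueError(f"label {label} is empty")
    neighbourhood = ndimage.binary_dilation(region, iterations=search_voxels)
    local = measured.values[neighbourhood]
    threshold = background + 0.5 * (local.max() - background)
    n = int((local >= threshold).sum())
    return n * measured.voxel_volume_ml


def run_calibration(
    seed: int = 0,
    psf_fwhm_mm: float = constants.PET_PSF_FWHM_MM,
    noise_scale: float = 0.0,
    background_ratios=constants.PHANTOM_BACKGROUND_RATIOS,
    sphere_volumes_ml=constants.NEMA_SPHERE_VOLUMES_ML,
) -> CalibrationResult:
    """Calibrate the recovery models on simulated sphere phantoms.

    Generates one phantom per background ratio, images it (PSF blur plus
    optional counting noise), measures apparent concentrations and
    threshold-segmented volumes, and fits: the background-aware recovery
    model (all ratios), the volume-only model (background-free subset), the
    segmented-to-physical volume map, and the PSF FWHM by matched filtering.
    """
    rows = []
    psf_pair = None
    for i, eta in enumerate(background_ratios):
        spec = nema_phantom_spec(
            background_ratio=eta,
            sphere_volumes_ml=sphere_volumes_ml,
            psf_fwhm_mm=psf_fwhm_mm,
            noise_scale=noise_scale,
            seed=seed + i,
        )
        truth, mask = make_sphere_phantom(spec)
        measured = blur_and_noise(
            truth, psf_fwhm_mm, noise_scale, seed=seed + i,
            reference_concentration=spec.sphere_concentration,
        )
        if eta == 0:
            psf_pair = (measured, truth)
        bg_true = eta * spec.sphere_concentration
        for label, vp in mask.volumes_ml.items():
            mean, _, _, _ = voi_stats(measured, mask.region(label))
            vs = segment_threshold_volume(measured, mask, label, bg_true)
            rows.append(
                {
                    "eta": eta,
                    "v_physical_ml": vp,
                    "v_segmented_ml": vs,
                    "apparent": mean,
                    "true": spec.sphere_concentration,
                }
            )
    table = pd.DataFrame(rows)
    meas = [
        SphereMeasurement(
            v_physical_ml=r.v_physical_ml,
            eta=r.eta,
            apparent_concentration=r.apparent,
            true_concentration=r.true,
            v_segmented_ml=r.v_segmented_ml,
        )
        for r in table.itertuples()
    ]
    rc_pet = fit_rc(meas)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # degenerate-f path is intended here
        rc_spect = fit_rc([m for m in meas if m.eta == 0])
    vol_map = fit_volume_map(
        table[["v_segmented_ml", "eta", "v_physical_ml"]].to_numpy()
    )
    if psf_pair is None:
        fwhm = psf_fwhm_mm
    else:
        grid = np.linspace(max(psf_fwhm_mm - 3.0, 0.5), psf_fwhm_mm + 3.0, 13)
        fwhm = estimate_psf_fwhm(psf_pair[0], psf_pair[1], grid)
    return CalibrationResult(
        rc_pet=rc_pet,
        rc_spect=rc_spect,
        vol_map=vol_map,
        psf_fwhm_mm=float(fwhm),
        measurements=table,
        seed=seed,
    )


def quantify_cohort(
    patients: list[PatientRecord],
    calibration: CalibrationResult | None = None,
    cal_cfg: CalibrationConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify all regions of a cohort into tidy tumour and organ tables.

    Region concentrations in the records are decay-corrected to the
    administration time; this stage applies the Ga-68 cross-calibration,
    partial-volume corrections (when a calibration is supplied) and the
    injected-activity normalization.
    """
    cal_cfg = cal_cfg or CalibrationConfig()
    tumour_rows, organ_rows = [], []
    for p in patients:
        for t in p.tumours:
            ac68 = apply_suv_calibration(t.ac68_apparent, cal_cfg)
            bg68 = apply_suv_calibration(t.background68, cal_cfg)
            if calibration is not None:
                vp, ac68_corr, eta, n_iter = pvc_tumour_pet(
                    ac68,
                    t.volume_pet_ml,
                    bg68,
                    calibration.rc_pet.params,
                    calibration.vol_map,
                )
                ac177_corr = pvc_tumour_spect(
                    t.ac177_spect, t.volume_spect_ml, calibration.rc_spect.params
                )
            else:
                vp, ac68_corr, eta, n_iter = (
                    t.volume_pet_ml,
                    ac68,
                    bg68 / ac68 if ac68 > 0 else np.nan,
                    0,
                )
                ac177_corr = t.ac177_spect
            tumour_rows.append(
                {
                    "patient_id": p.patient_id,
                    "tumour_id": t.tumour_id,
                    "grade": p.grade,
                    "volume_pet_ml": vp,
                    "volume_spect_ml": t.volume_spect_ml,
                    "eta_hat": eta,
                    "pvc_iterations": n_iter,
                    "ac68_per_ia": ac68_corr / p.injected_activity_68_bq,
                    "ac177_per_ia": ac177_corr / p.injected_activity_177_bq,
                    "ac177_corrected": ac177_corr,
                    "suv_mean": t.suv_mean,
                    "suv_max": t.suv_max,
                    "ga_scan_time_h": p.ga_scan_time_h,
                    "spect_time_h": p.spect_time_h,
                    "ia177_bq": p.injected_activity_177_bq,
                    "truth_ad_per_ia": (
                        t.truth.ad_per_ia_gy_per_gbq if t.truth else np.nan
                    ),
                }
            )
        for o in p.organs.values():
            ac68 = apply_suv_calibration(o.ac68_apparent, cal_cfg)
            ac68_corr = pvc_organ(ac68, o.rc_pet)
            ac177_corr = pvc_organ(o.ac177_spect, o.rc_spect)
            organ_rows.append(
                {
                    "patient_id": p.patient_id,
                    "organ": o.name,
                    "ac68_per_ia": ac68_corr / p.injected_activity_68_bq,
                    "ac177_per_ia": ac177_corr / p.injected_activity_177_bq,
                    "ac177_corrected": ac177_corr,
                    "spect_time_h": p.spect_time_h,
                    "ia177_bq": p.injected_activity_177_bq,
                    "truth_ad_per_ia": (
                        o.truth.ad_per_ia_gy_per_gbq if o.truth else np.nan
                    ),
                }
            )
    return pd.DataFrame(tumour_rows), pd.DataFrame(organ_rows)


def dosimetry_cohort(
    patients: list[PatientRecord],
    tumour_q: pd.DataFrame,
    organ_q: pd.DataFrame,
    cal_cfg: CalibrationConfig | None = None,
) -> pd.DataFrame:
    """Hybrid planar-SPECT absorbed doses (Gy/GBq) for every region."""
    cal_cfg = cal_cfg or CalibrationConfig()
    t_idx = tumour_q.set_index("tumour_id")
    o_idx = organ_q.set_index(["patient_id", "organ"])
    rows = []
    for p in patients:
        for t in p.tumours:
            q = t_idx.loc[t.tumour_id]
            curve = fit_tumour_curve(t.planar)
            ac_per_gbq = q["ac177_corrected"] / (p.injected_activity_177_bq / 1e9)
            dr = dose_rate_local(
                ac_per_gbq,
                density_g_per_ml=cal_cfg.tissue_density_g_per_ml,
            )
            res = rescale_and_integrate(curve, dr, p.spect_time_h, t.tumour_id)
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "region_id": t.tumour_id,
                    "kind": "tumour",
                    "t_eff_h": res.t_eff_h,
                    "dose_rate_at_spect": res.dose_rate_at_spect_gy_per_h,
                    "ad_per_ia": res.ad_per_ia_gy_per_gbq,
                    "quadrature_rel_diff": res.diagnostics["quadrature_rel_diff"],
                }
            )
        for o in p.organs.values():
            q = o_idx.loc[(p.patient_id, o.name)]
            curve = fit_organ_curve(o.planar)
            ac_per_gbq = q["ac177_corrected"] / (p.injected_activity_177_bq / 1e9)
            dr = dose_rate_local(
                ac_per_gbq,
                density_g_per_ml=cal_cfg.tissue_density_g_per_ml,
            )
            res = rescale_and_integrate(curve, dr, p.spect_time_h, o.name)
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "region_id": o.name,
                    "kind": "organ",
                    "t_eff_h": res.t_eff_h,
                    "dose_rate_at_spect": res.dose_rate_at_spect_gy_per_h,
                    "ad_per_ia": res.ad_per_ia_gy_per_gbq,
                    "quadrature_rel_diff": res.diagnostics["quadrature_rel_diff"],
                }
            )
    return pd.DataFrame(rows)


def predict_cohort(
    patients: list[PatientRecord],
    tumour_q: pd.DataFrame,
    cfg: PredictionConfig | None = None,
    backprop_mode: str = "effective",
) -> pd.DataFrame:
    """Predicted Lu-177 tumour AD/IA from the Ga-68 snapshot."""
    cfg = cfg or PredictionConfig()
    grades = {p.patient_id: p.grade for p in patients}
    rows = []
    for q in tumour_q.itertuples():
        grade = grades[q.patient_id]
        t_eff = cfg.t_eff_h(grade)
        ac0 = backpropagate_to_t0(
            q.ac68_per_ia, q.ga_scan_time_h, t_eff, mode=backprop_mode
        )
        pred = predict_dose(ac0, q.ia177_bq, grade, cfg, tumour_id=q.tumour_id)
        rows.append(
            {
                "patient_id": q.patient_id,
                "tumour_id": q.tumour_id,
                "grade": grade,
                "ac68_per_ia_t0": pred.ac68_per_ia_t0,
                "predicted_ad_per_ia": pred.predicted_ad_per_ia_gy_per_gbq,
            }
        )
    return pd.DataFrame(rows)


def _corr_from_units(units):
    x = np.array([u[0] for u in units])
    y = np.array([u[1] for u in units])
    w = np.array([u[2] for u in units])
    return weighted_pearson(x, y, w)


def run_stats(
    tumour_q: pd.DataFrame,
    organ_q: pd.DataFrame,
    doses: pd.DataFrame,
    predictions: pd.DataFrame,
    volume_cutoff_ml: float = constants.TUMOUR_VOLUME_CUTOFF_ML,
) -> dict:
    """The statistical battery on quantified + dosed cohort tables.

    Organ correlations (kidneys averaged left/right) and tumour inter-/
    intra-patient correlations of Lu-177 AD/IA and AC/IA against Ga-68
    uptake metrics, leave-one-out intervals, and log-ratio Bland-Altman
    agreement of predicted vs measured tumour doses.
    """
    out: dict = {}

    dose_map = (
        doses[doses["kind"] == "tumour"].set_index("region_id")["ad_per_ia"]
    )
    tq = tumour_q.copy()
    tq["ad_per_ia"] = tq["tumour_id"].map(dose_map)
    kept, excluded = filter_tumours(tq, volume_cutoff_ml)
    out["n_tumours_total"] = int(len(tq))
    out["n_tumours_kept"] = int(len(kept))
    out["n_tumours_excluded"] = int(len(excluded))

    # --- organs: one point per patient, kidneys averaged
    oq = organ_q.copy()
    od = doses[doses["kind"] == "organ"].set_index(["patient_id", "region_id"])[
        "ad_per_ia"
    ]
    oq["ad_per_ia"] = [
        od.get((r.patient_id, r.organ), np.nan) for r in oq.itertuples()
    ]
    organ_results = {}
    for organ_name in ("kidneys", "spleen", "liver"):
        if organ_name == "kidneys":
            sub = oq[oq["organ"].isin(["kidney_left", "kidney_right"])]
            rows = []
            for pid, g in sub.groupby("patient_id"):
                vals = {}
                for col in ("ac68_per_ia", "ac177_per_ia", "ad_per_ia"):
                    d = dict(zip(g["organ"], g[col]))
                    vals[col] = kidney_average(
                        d.get("kidney_left"), d.get("kidney_right")
                    )
                rows.append({"patient_id": pid, **vals})
            sub = pd.DataFrame(rows)
        else:
            sub = oq[oq["organ"] == organ_name]
        res = {}
        for target in ("ad_per_ia", "ac177_per_ia"):
            x = sub["ac68_per_ia"].to_numpy()
            y = sub[target].to_numpy()
            c = pearson(x, y)
            units = list(zip(x, y))
            c.loo_interval = loo_interval(
                units, lambda u: pearson([a for a, _ in u], [b for _, b in u])
            )
            res[target] = c
        organ_results[organ_name] = res
    out["organs"] = organ_results

    # --- tumours: inter-patient (weighted means) and intra-patient (rmcorr)
    tumour_results = {}
    for xvar in ("ac68_per_ia", "suv_mean", "suv_max"):
        for target in ("ad_per_ia", "ac177_per_ia"):
            g = kept.groupby("patient_id").agg(
                x=(xvar, "mean"), y=(target, "mean"), w=(xvar, "size")
            )
            units = list(zip(g["x"], g["y"], g["w"]))
            inter = _corr_from_units(units)
            inter.loo_interval = loo_interval(units, _corr_from_units)
            import warnings as _warnings

            with _warnings.catch_warnings():
                # single-tumour patients cannot inform the common slope;
                # dropping them is expected in the intra-patient analysis
                _warnings.filterwarnings(
                    "ignore", message=".*single observation.*"
                )
                intra = rmcorr(
                    kept["patient_id"].to_numpy(),
                    kept[xvar].to_numpy(),
                    kept[target].to_numpy(),
                )
            tumour_results[(xvar, target)] = {"inter": inter, "intra": intra}
    out["tumours"] = tumour_results

    # --- agreement of predicted vs measured tumour doses
    pred_tbl = predictions.rename(columns={"predicted_ad_per_ia": "value"})[
        ["patient_id", "tumour_id", "value"]
    ]
    meas_tbl = kept.rename(columns={"ad_per_ia": "value"})[
        ["patient_id", "tumour_id", "value"]
    ]
    pred_tbl = pred_tbl[pred_tbl["tumour_id"].isin(meas_tbl["tumour_id"])]
    tumour_pairs, patient_pairs = prediction_error_table(pred_tbl, meas_tbl)
    out["agreement_tumour"] = log_ratio_bland_altman(
        tumour_pairs["value_pred"], tumour_pairs["value_meas"], level="tumour"
    )
    out["agreement_patient"] = log_ratio_bland_altman(
        tumour_pairs["value_pred"],
        tumour_pairs["value_meas"],
        level="patient",
        patient_ids=tumour_pairs["patient_id"],
    )
    return out


def run_full(
    seed: int = 0,
    outdir=None,
    cohort_spec: CohortSpec | None = None,
    calibration_noise_scale: float = 0.0,
    use_pvc_bias: bool = True,
) -> dict:
    """Complete synthetic study: calibration through statistics.

    When ``use_pvc_bias`` is true the cohort is generated with the fitted
    recovery calibrations as its measurement forward model, so the
    quantification stage has real partial-volume bias to undo.
    """
    calibration = run_calibration(seed=seed, noise_scale=calibration_noise_scale)
    if cohort_spec is None:
        cohort_spec = CohortSpec(seed=seed + 1000, suv_bias_68=constants.SUV_FACTOR_GA68)
    if use_pvc_bias:
        from dataclasses import replace

        cohort_spec = replace(
            cohort_spec,
            rc_params_pet=calibration.rc_pet.params,
            vol_map_pet=calibration.vol_map,
            rc_params_spect=calibration.rc_spect.params,
        )
    patients = make_cohort(cohort_spec)
    tumour_q, organ_q = quantify_cohort(patients, calibration)
    doses = dosimetry_cohort(patients, tumour_q, organ_q)
    predictions = predict_cohort(patients, tumour_q)
    stats = run_stats(tumour_q, organ_q, doses, predictions)

    bundle = {
        "calibration": calibration,
        "patients": patients,
        "tumour_quant": tumour_q,
        "organ_quant": organ_q,
        "doses": doses,
        "predictions": predictions,
        "stats": stats,
        "seed": seed,
    }
    if outdir is not None:
        _write_bundle(bundle, outdir)
    return bundle


def _corr_to_dict(c) -> dict:
    return {
        "r": c.r,
        "p": c.p,
        "slope": c.slope,
        "intercept": c.intercept,
        "n_effective": c.n_effective,
        "loo_interval": list(c.loo_interval) if c.loo_interval else None,
    }


def _write_bundle(bundle: dict, outdir) -> None:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle["tumour_quant"].to_csv(outdir / "tumour_quant.csv", index=False)
    bundle["organ_quant"].to_csv(outdir / "organ_quant.csv", index=False)
    bundle["doses"].to_csv(outdir / "doses.csv", index=False)
    bundle["predictions"].to_csv(outdir / "predictions.csv", index=False)
    cohort_tumour_table(bundle["patients"]).to_csv(
        outdir / "cohort_tumours.csv", index=False
    )
    cohort_organ_table(bundle["patients"]).to_csv(
        outdir / "cohort_organs.csv", index=False
    )
    stats = bundle["stats"]
    stats_json = {
        "n_tumours_total": stats["n_tumours_total"],
        "n_tumours_kept": stats["n_tumours_kept"],
        "n_tumours_excluded": stats["n_tumours_excluded"],
        "organs": {
            organ: {t: _corr_to_dict(c) for t, c in res.items()}
            for organ, res in stats["organs"].items()
        },
        "tumours": {
            f"{x}__{t}": {
                "inter": _corr_to_dict(v["inter"]),
                "intra": _corr_to_dict(v["intra"]),
            }
            for (x, t), v in stats["tumours"].items()
        },
        "agreement": {
            level: asdict(stats[f"agreement_{level}"])
            for level in ("tumour", "patient")
        },
    }
    manifest = {
        "seed": bundle["seed"],
        "calibration": bundle["calibration"].to_json_dict(),
    }
    (outdir / "stats.json").write_text(json.dumps(stats_json, indent=2))
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
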