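"""Synthetic patient-cohort generator with known ground truth.

Emulates the study population the pipeline is built for: a small cohort of
neuroendocrine-tumour patients, each with a pre-therapy Ga-68 PET snapshot
(~1 h p.i.), a Lu-177 planar series at nominally 1/24/96/168 h, and one
quantitative Lu-177 SPECT at ~22 h. Every region (tumour or organ) follows
mono-exponential kinetics: the initial activity concentration per injected
activity (AC/IA at t = 0) is shared between the two tracers, the Lu-177
curve decays with the region's effective half-life, and the Ga-68
measurement reflects the same uptake after ~1 h of biological turnover.

Each record carries a ground-truth block (A0 per IA, effective half-life,
closed-form AD/IA under local energy deposition) so that the quantification,
dosimetry and prediction stages can be validated end to end. Measurement
imperfections are opt-in: multiplicative log-normal noise on region values,
partial-volume bias through supplied recovery/volume-map parameters, the
Ga-68 cross-calibration bias (0.94), and an early-uptake bend on the first
planar sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import constants
from .dosimetry import PlanarSample
from .recovery import RCParams, VolumeMapParams, rc_full, rc_volume

__all__ = [
    "OrganSpec",
    "CohortSpec",
    "RegionTruth",
    "TumourRecord",
    "OrganRecord",
    "PatientRecord",
    "make_cohort",
    "make_planar_patch",
    "cohort_tumour_table",
    "cohort_organ_table",
]


@dataclass
class OrganSpec:
    """Population kinetics and recovery settings for one organ."""

    name: str
    ac0_per_ia: float  # 1/mL at t = 0
    t_eff_h: float
    rc_spect: float = 1.0
    rc_pet: float = 1.0


DEFAULT_ORGANS = (
    OrganSpec("kidney_left", 1.3e-4, 50.0, rc_spect=0.85, rc_pet=0.92),
    OrganSpec("kidney_right", 1.2e-4, 50.0, rc_spect=0.85, rc_pet=0.92),
    OrganSpec("spleen", 2.7e-4, 60.0, rc_spect=0.85, rc_pet=0.93),
    OrganSpec("liver", 7.0e-5, 70.0, rc_spect=1.0, rc_pet=1.0),
)


@dataclass
class CohortSpec:
    """Study conditions of the synthetic cohort (defaults mirror the study)."""

    n_patients: int = 18
    tumours_per_patient: tuple[int, int] = (2, 9)
    tumour_volume_range_ml: tuple[float, float] = (0.5, 80.0)  # log-uniform
    grade_mix: float = 0.5  # fraction grade 1
    half_life_means_h: dict[int, float] = field(
        default_factory=lambda: dict(constants.T_EFF_TUMOUR_H)
    )
    half_life_cv: float = 0.2
    uptake_median_per_ia: float = 2.0e-4  # tumour AC/IA at t=0, 1/mL
    uptake_sigma_ln: float = 0.8
    tumour_background_ratio_range: tuple[float, float] = (0.05, 0.4)
    organ_kinetics: tuple[OrganSpec, ...] = DEFAULT_ORGANS
    ga_scan_time_min: float = 64.0
    planar_times_h: tuple[float, ...] = (1.0, 24.0, 96.0, 168.0)
    spect_time_h: float = 21.9
    injected_activity_68_bq: float = 0.17e9
    injected_activity_177_bq: float = 7.45e9
    weight_range_kg: tuple[float, float] = (55.0, 95.0)
    noise_cv: float = 0.05
    organ_uptake_cv: float = 0.3  # inter-subject spread of organ uptake
    early_uptake_bend: float = 1.0  # <1 pulls the first planar sample down
    # Ga-68 PET cross-calibration bias baked into image-derived values;
    # the quantification stage divides it back out
    suv_bias_68: float = constants.SUV_FACTOR_GA68
    rc_params_pet: RCParams | None = None
    vol_map_pet: VolumeMapParams | None = None
    rc_params_spect: RCParams | None = None
    energy_per_decay_kev: float = constants.MEAN_ELECTRON_ENERGY_KEV
    density_g_per_ml: float = constants.TISSUE_DENSITY_G_PER_ML
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if not 0.0 <= self.grade_mix <= 1.0:
            raise ValueError("grade_mix must lie in [0, 1]")
        if any(h <= 0 for h in self.half_life_means_h.values()):
            raise ValueError("half-life means must be positive")
        if self.ga_scan_time_min <= 0 or self.spect_time_h <= 0:
            raise ValueError("imaging times must be positive")
        if any(t <= 0 for t in self.planar_times_h):
            raise ValueError("planar times must be positive")
        if self.noise_cv < 0 or self.half_life_cv < 0:
            raise ValueError("coefficients of variation must be non-negative")
        if not 0 < self.early_uptake_bend <= 1.0:
            raise ValueError("early_uptake_bend must lie in (0, 1]")


@dataclass
class RegionTruth:
    """Generating parameters of a region: exact AC/IA, kinetics and dose."""

    ac0_per_ia: float
    t_eff_h: float
    ad_per_ia_gy_per_gbq: float


@dataclass
class TumourRecord:
    tumour_id: str
    volume_true_ml: float
    volume_pet_ml: float
    volume_spect_ml: float
    ac68_apparent: float  # Bq/mL, decay-corrected to administration
    ac68_corrected: float  # PV-free truth at scan time (noise-free path)
    background68: float  # Bq/mL, as measured next to the tumour
    ac177_spect: float  # Bq/mL at the SPECT time, uncorrected
    suv_mean: float
    suv_max: float
    planar: list[PlanarSample] = field(default_factory=list)
    ad_per_ia: float | None = None  # filled by the dosimetry stage
    truth: RegionTruth | None = None


@dataclass
class OrganRecord:
    name: str
    ac68_apparent: float
    ac68_corrected: float
    ac177_spect: float
    rc_pet: float
    rc_spect: float
    planar: list[PlanarSample] = field(default_factory=list)
    ad_per_ia: float | None = None
    truth: RegionTruth | None = None


@dataclass
class PatientRecord:
    patient_id: str
    grade: int
    weight_kg: float
    injected_activity_68_bq: float
    injected_activity_177_bq: float
    spect_time_h: float
    ga_scan_time_h: float
    tumours: list[TumourRecord] = field(default_factory=list)
    organs: dict[str, OrganRecord] = field(default_factory=dict)


def closed_form_ad_per_ia(
    ac0_per_ia: float,
    t_eff_h: float,
    energy_per_decay_kev: float = constants.MEAN_ELECTRON_ENERGY_KEV,
    density_g_per_ml: float = constants.TISSUE_DENSITY_G_PER_ML,
) -> float:
    """Exact AD/IA (Gy/GBq) of a mono-exponential concentration curve.

    Integrates c(t) = ac0_per_ia * 1 GBq * exp(-ln2 t / T_eff) under local
    energy deposition; used as the ground truth attached to every synthetic
    region.
    """
    c0 = ac0_per_ia * 1e9  # Bq/mL for 1 GBq injected
    joules_per_s_per_g = c0 * energy_per_decay_kev * constants.JOULE_PER_KEV / density_g_per_ml
    dose_rate_gy_per_h = joules_per_s_per_g * 1000.0 * 3600.0
    return dose_rate_gy_per_h * t_eff_h / constants.LN2


def _noise_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative log-normal factor with unit mean and given CV."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


def _lambda_bio(t_eff_h: float) -> float:
    return constants.LN2 / t_eff_h - constants.LN2 / constants.HALF_LIFE_LU177_H


def _segmented_volume(vp: float, eta: float, vm: VolumeMapParams | None) -> float:
    """Invert the volume map: the Vs a segmentation would have reported."""
    if vm is None:
        return vp
    denom = vm.a1 + vm.a3 * eta
    if denom <= 0:
        raise ValueError("volume map is not invertible at this eta")
    return (vp - vm.a0 - vm.a2 * eta) / denom


def _region_measurements(
    rng: np.random.Generator,
    spec: CohortSpec,
    ac0_per_ia: float,
    t_eff_h: float,
):
    """Shared mono-exponential forward model for any region."""
    lam_eff = constants.LN2 / t_eff_h
    lam_bio = _lambda_bio(t_eff_h)
    t_ga_h = spec.ga_scan_time_min / 60.0
    # decay-corrected Ga-68 concentration at the scan: physical decay removed,
    # biological turnover remains
    ac68_true = (
        ac0_per_ia * spec.injected_activity_68_bq * np.exp(-lam_bio * t_ga_h)
    )
    ac177_true_spect = (
        ac0_per_ia
        * spec.injected_activity_177_bq
        * np.exp(-lam_eff * spec.spect_time_h)
    )
    planar_scale = 10.0 ** rng.uniform(-1.0, 1.0)
    planar = []
    for i, t in enumerate(spec.planar_times_h):
        y = planar_scale * np.exp(-lam_eff * t)
        if i == 0:
            y *= spec.early_uptake_bend
        y *= float(_noise_factor(rng, spec.noise_cv))
        planar.append(PlanarSample(time_h=float(t), signal=float(y)))
    return ac68_true, ac177_true_spect, planar


def make_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Draw a synthetic cohort; a single seeded generator drives all draws."""
    rng = np.random.default_rng(spec.seed)
    t_ga_h = spec.ga_scan_time_min / 60.0
    patients = []
    for p in range(spec.n_patients):
        grade = 1 if rng.random() < spec.grade_mix else 2
        weight = float(rng.uniform(*spec.weight_range_kg))
        # inter-subject kinetic spread, shared by the patient's tumours;
        # capped below the Lu-177 physical half-life (faster-than-physical
        # effective decay is required for a positive biological rate)
        t_eff_cap = 0.95 * constants.HALF_LIFE_LU177_H
        patient_factor = float(_noise_factor(rng, spec.half_life_cv))
        t_eff_tumour = min(spec.half_life_means_h[grade] * patient_factor, t_eff_cap)

        patient = PatientRecord(
            patient_id=f"P{p + 1:02d}",
            grade=grade,
            weight_kg=weight,
            injected_activity_68_bq=spec.injected_activity_68_bq,
            injected_activity_177_bq=spec.injected_activity_177_bq,
            spect_time_h=spec.spect_time_h,
            ga_scan_time_h=t_ga_h,
        )

        n_tum = int(rng.integers(spec.tumours_per_patient[0],
                                 spec.tumours_per_patient[1] + 1))
        lo, hi = spec.tumour_volume_range_ml
        for k in range(n_tum):
            vp = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            ac0 = float(
                spec.uptake_median_per_ia
                * np.exp(rng.normal(0.0, spec.uptake_sigma_ln))
            )
            eta = float(rng.uniform(*spec.tumour_background_ratio_range))
            ac68_true, ac177_true, planar = _region_measurements(
                rng, spec, ac0, t_eff_tumour
            )
            background_true = eta * ac68_true
            r_pet = (
                rc_full(vp, eta, spec.rc_params_pet)
                if spec.rc_params_pet is not None
                else 1.0
            )
            ac68_app = (
                ac68_true * r_pet * spec.suv_bias_68
                * float(_noise_factor(rng, spec.noise_cv))
            )
            vs_pet = _segmented_volume(vp, eta, spec.vol_map_pet)
            v_spect = vp * float(_noise_factor(rng, spec.noise_cv))
            r_spect = (
                rc_volume(v_spect, spec.rc_params_spect)
                if spec.rc_params_spect is not None
                else 1.0
            )
            ac177_app = ac177_true * r_spect * float(_noise_factor(rng, spec.noise_cv))
            suv_mean = ac68_app * weight * 1000.0 / spec.injected_activity_68_bq
            suv_max = suv_mean * float(rng.uniform(1.3, 2.2))
            patient.tumours.append(
                TumourRecord(
                    tumour_id=f"{patient.patient_id}_T{k + 1}",
                    volume_true_ml=vp,
                    volume_pet_ml=vs_pet,
                    volume_spect_ml=v_spect,
                    ac68_apparent=float(ac68_app),
                    ac68_corrected=float(ac68_true),
                    background68=float(
                        background_true * spec.suv_bias_68
                    ),
                    ac177_spect=float(ac177_app),
                    suv_mean=float(suv_mean),
                    suv_max=float(suv_max),
                    planar=planar,
                    truth=RegionTruth(
                        ac0_per_ia=ac0,
                        t_eff_h=t_eff_tumour,
                        ad_per_ia_gy_per_gbq=closed_form_ad_per_ia(
                            ac0,
                            t_eff_tumour,
                            spec.energy_per_decay_kev,
                            spec.density_g_per_ml,
                        ),
                    ),
                )
            )

        for organ in spec.organ_kinetics:
            t_eff = min(
                organ.t_eff_h * float(_noise_factor(rng, spec.half_life_cv)),
                0.95 * constants.HALF_LIFE_LU177_H,
            )
            ac0 = organ.ac0_per_ia * float(_noise_factor(rng, spec.organ_uptake_cv))
            ac68_true, ac177_true, planar = _region_measurements(rng, spec, ac0, t_eff)
            ac68_app = (
                ac68_true * organ.rc_pet * spec.suv_bias_68
                * float(_noise_factor(rng, spec.noise_cv))
            )
            ac177_app = (
                ac177_true * organ.rc_spect * float(_noise_factor(rng, spec.noise_cv))
            )
            patient.organs[organ.name] = OrganRecord(
                name=organ.name,
                ac68_apparent=float(ac68_app),
                ac68_corrected=float(ac68_true),
                ac177_spect=float(ac177_app),
                rc_pet=organ.rc_pet,
                rc_spect=organ.rc_spect,
                planar=planar,
                truth=RegionTruth(
                    ac0_per_ia=ac0,
                    t_eff_h=t_eff,
                    ad_per_ia_gy_per_gbq=closed_form_ad_per_ia(
                        ac0, t_eff, spec.energy_per_decay_kev, spec.density_g_per_ml
                    ),
                ),
            )
        patients.append(patient)
    return patients


def make_planar_patch(
    region_kind: str,
    mean_signal: float,
    n_pixels: int,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """2-D pixel patch with a given mean and relative spread.

    Tumour patches need at least 5 pixels (the five-highest-pixels rule is
    undefined below that).
    """
    if region_kind not in ("organ", "tumour"):
        raise ValueError(f"unknown region kind {region_kind!r}")
    if region_kind == "tumour" and n_pixels < 5:
        raise ValueError("tumour patches need at least 5 pixels")
    if n_pixels < 1:
        raise ValueError("n_pixels must be positive")
    rng = np.random.default_rng(seed)
    values = mean_signal * np.asarray(_noise_factor(rng, noise_cv, size=n_pixels))
    side = int(np.sqrt(n_pixels))
    if side * side == n_pixels:
        return values.reshape(side, side)
    return values.reshape(1, n_pixels)


def cohort_tumour_table(patients: list[PatientRecord]) -> pd.DataFrame:
    """Tidy per-tumour table (one row per tumour) for the pipeline stages."""
    rows = []
    for p in patients:
        for t in p.tumours:
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "tumour_id": t.tumour_id,
                    "grade": p.grade,
                    "weight_kg": p.weight_kg,
                    "ia68_bq": p.injected_activity_68_bq,
                    "ia177_bq": p.injected_activity_177_bq,
                    "ga_scan_time_h": p.ga_scan_time_h,
                    "spect_time_h": p.spect_time_h,
                    "volume_pet_ml": t.volume_pet_ml,
                    "volume_spect_ml": t.volume_spect_ml,
                    "ac68_apparent": t.ac68_apparent,
                    "background68": t.background68,
                    "ac177_spect": t.ac177_spect,
                    "suv_mean": t.suv_mean,
                    "suv_max": t.suv_max,
                    "truth_ac0_per_ia": t.truth.ac0_per_ia if t.truth else np.nan,
                    "truth_t_eff_h": t.truth.t_eff_h if t.truth else np.nan,
                    "truth_ad_per_ia": (
                        t.truth.ad_per_ia_gy_per_gbq if t.truth else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


def cohort_organ_table(patients: list[PatientRecord]) -> pd.DataFrame:
    rows = []
    for p in patients:
        for o in p.organs.values():
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "organ": o.name,
                    "grade": p.grade,
                    "weight_kg": p.weight_kg,
                    "ia68_bq": p.injected_activity_68_bq,
                    "ia177_bq": p.injected_activity_177_bq,
                    "spect_time_h": p.spect_time_h,
                    "ac68_apparent": o.ac68_apparent,
                    "ac177_spect": o.ac177_spect,
                    "rc_pet": o.rc_pet,
                    "rc_spect": o.rc_spect,
                    "truth_ac0_per_ia": o.truth.ac0_per_ia if o.truth else np.nan,
                    "truth_t_eff_h": o.truth.t_eff_h if o.truth else np.nan,
                    "truth_ad_per_ia": (
                        o.truth.ad_per_ia_gy_per_gbq if o.truth else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)
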