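"""Activity quantification: VOI statistics, decay correction, SUV and PVC.

Conventions follow routine clinical quantification of Ga-68 PET and Lu-177
SPECT:

* AC/IA — activity concentration decay-corrected to the administration time
  using the physical half-life, divided by the injected activity (1/mL).
* SUV — non-partial-volume-corrected concentration, decay-corrected to the
  injection time, normalized to injected activity and multiplied by body
  weight (g/mL); SUVmax uses the maximum voxel value in the VOI.
* PET concentrations are first divided by the cross-calibration factor
  (0.94) observed for Ga-68 on the camera system.
* Tumour PET concentrations are corrected for both spill-out and spill-in
  with the background-aware recovery model; because the background-to-object
  ratio eta depends on the corrected concentration itself, the correction is
  a small fixed-point iteration over (eta, Vp, corrected AC).
* Tumour SPECT concentrations are corrected for spill-out only with the
  volume-only recovery model; organ concentrations are divided by a fixed
  organ RC (0.85 for kidneys/spleen SPECT, mask-convolution RCs for PET,
  unity for liver parenchyma).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import constants
from .images import LabelMask, VoxelImage
from .recovery import RCParams, VolumeMapParams, apply_volume_map, rc_full, rc_volume

__all__ = [
    "CalibrationConfig",
    "VOIResult",
    "voi_stats",
    "decay_correct",
    "ac_per_ia",
    "suv",
    "apply_suv_calibration",
    "estimate_background",
    "pvc_tumour_pet",
    "pvc_tumour_spect",
    "pvc_organ",
]


@dataclass
class CalibrationConfig:
    """Scalar calibration constants of the quantification chain."""

    suv_factor_68ga: float = constants.SUV_FACTOR_GA68
    rc_organ_spect: float = constants.RC_ORGAN_SPECT
    half_life_68ga_min: float = constants.HALF_LIFE_GA68_MIN
    half_life_177lu_d: float = constants.HALF_LIFE_LU177_D
    tissue_density_g_per_ml: float = constants.TISSUE_DENSITY_G_PER_ML

    def __post_init__(self):
        for v in (
            self.suv_factor_68ga,
            self.rc_organ_spect,
            self.half_life_68ga_min,
            self.half_life_177lu_d,
            self.tissue_density_g_per_ml,
        ):
            if v <= 0:
                raise ValueError("all calibration constants must be positive")

    @property
    def half_life_177lu_h(self) -> float:
        return self.half_life_177lu_d * 24.0


@dataclass
class VOIResult:
    """Per-region quantification output row."""

    region_id: str
    volume_ml: float
    ac_apparent: float
    ac_corrected: float
    ac_per_ia: float
    suv_mean: float | None = None
    suv_max: float | None = None
    eta_hat: float | None = None
    rc_applied: float | None = None


def voi_stats(image: VoxelImage, mask_region: np.ndarray):
    """(mean, max, total activity, volume) of a VOI.

    mean is in Bq/mL, total in Bq, volume in mL; by construction
    mean = total / volume.
    """
    region = np.asarray(mask_region, dtype=bool)
    if region.shape != image.values.shape:
        raise ValueError("mask region must match image shape")
    n = int(region.sum())
    if n == 0:
        raise ValueError("empty VOI region")
    vals = image.values[region]
    volume = n * image.voxel_volume_ml
    total = float(vals.sum() * image.voxel_volume_ml)
    return float(vals.mean()), float(vals.max()), total, float(volume)


def decay_correct(value, t_elapsed, half_life):
    """Correct a measured value back to t=0: value * 2**(t / half_life)."""
    if half_life <= 0:
        raise ValueError("half_life must be positive")
    return value * 2.0 ** (np.asarray(t_elapsed, dtype=float) / half_life)


def ac_per_ia(ac_corrected_t0, injected_activity_bq):
    """Activity concentration per injected activity, 1/mL."""
    if injected_activity_bq <= 0:
        raise ValueError("injected activity must be positive")
    return ac_corrected_t0 / injected_activity_bq


def suv(ac_bq_per_ml, injected_activity_bq, weight_kg):
    """Standardized uptake value, g/mL.

    ``ac_bq_per_ml`` must already be decay-corrected to the injection time
    and not partial-volume corrected (clinical convention).
    """
    if weight_kg <= 0:
        raise ValueError("body weight must be positive")
    if injected_activity_bq <= 0:
        raise ValueError("injected activity must be positive")
    return ac_bq_per_ml * (weight_kg * 1000.0) / injected_activity_bq


def apply_suv_calibration(ac_bq_per_ml, cal: CalibrationConfig | None = None):
    """Divide a Ga-68 PET concentration by the cross-calibration factor."""
    factor = constants.SUV_FACTOR_GA68 if cal is None else cal.suv_factor_68ga
    return ac_bq_per_ml / factor


def estimate_background(
    image: VoxelImage,
    mask: LabelMask,
    label: int,
    shell_voxels: tuple[int, int] = (2, 4),
) -> float:
    """Mean concentration in a morphological shell around one VOI.

    The shell lies between the ``inner`` and ``outer`` binary dilations of
    the region; voxels belonging to any labelled region are excluded so that
    neighbouring lesions do not contaminate the estimate.
    """
    inner, outer = shell_voxels
    if not 0 < inner < outer:
        raise ValueError("shell must satisfy 0 < inner < outer")
    mask.check_aligned(image)
    region = mask.region(label)
    if not region.any():
        raise ValueError(f"label {label} is empty")
    dil_inner = ndimage.binary_dilation(region, iterations=inner)
    dil_outer = ndimage.binary_dilation(region, iterations=outer)
    shell = dil_outer & ~dil_inner & (mask.labels == 0)
    if not shell.any():
        raise ValueError("background shell is empty after excluding labelled voxels")
    return float(image.values[shell].mean())


def pvc_tumour_pet(
    ac_apparent: float,
    v_segmented_ml: float,
    background_ac: float,
    rc_params: RCParams,
    vol_params: VolumeMapParams,
    tol: float = 1e-6,
    max_iter: int = 100,
):
    """Joint PVC of a PET tumour: returns (Vp, corrected AC, eta, iterations).

    Solves the coupled system
    ``eta = background / corrected``, ``Vp = volume_map(Vs, eta)``,
    ``corrected = apparent / R(Vp, eta)`` by fixed-point iteration from
    ``corrected = apparent``. eta is clamped at 1 (with a warning) when the
    background persistently exceeds the corrected concentration, in which
    case the region is indistinguishable from its surroundings.
    """
    if ac_apparent <= 0 or v_segmented_ml <= 0:
        raise ValueError("apparent concentration and segmented volume must be positive")
    if background_ac < 0:
        raise ValueError("background concentration must be non-negative")

    clamp_seen = False

    def step(c: float) -> float:
        nonlocal clamp_seen
        eta = background_ac / c if c > 0 else 1.0
        if eta > 1.0:
            eta = 1.0
            clamp_seen = True
        vp = apply_volume_map(v_segmented_ml, eta, vol_params)
        return ac_apparent / rc_full(vp, eta, rc_params)

    # fixed-point iteration with Aitken acceleration (Steffensen's method);
    # n_evals counts plain fixed-point applications
    corrected = float(ac_apparent)
    n_evals = 0
    converged = False
    while n_evals < max_iter:
        c1 = step(corrected)
        n_evals += 1
        if abs(c1 - corrected) / corrected < tol:
            corrected = c1
            converged = True
            break
        c2 = step(c1)
        n_evals += 1
        denom = c2 - 2.0 * c1 + corrected
        accel = corrected - (c1 - corrected) ** 2 / denom if denom != 0 else c2
        if not np.isfinite(accel) or accel <= 0:
            accel = c2
        if abs(accel - corrected) / corrected < tol:
            corrected = accel
            converged = True
            break
        corrected = accel
    if not converged:
        raise RuntimeError(
            f"PET PVC fixed point did not converge in {max_iter} evaluations "
            f"(last corrected={corrected:.4g})"
        )
    eta = background_ac / corrected if corrected > 0 else 1.0
    if eta > 1.0:
        eta = 1.0
    vp = apply_volume_map(v_segmented_ml, eta, vol_params)
    if clamp_seen and eta >= 1.0:
        warnings.warn(
            "background >= apparent concentration: eta clamped to 1, "
            "corrected concentration equals apparent",
            stacklevel=2,
        )
    return float(vp), float(corrected), float(eta), n_evals


def pvc_tumour_spect(
    ac_apparent: float,
    v_segmented_spect_ml: float,
    rc_params_spect: RCParams,
    volume_floor_ml: float = 0.1,
) -> float:
    """Spill-out-only PVC of a SPECT tumour: apparent / R0(volume)."""
    if v_segmented_spect_ml < volume_floor_ml:
        raise ValueError(
            f"SPECT volume {v_segmented_spect_ml:.3g} mL below floor "
            f"{volume_floor_ml} mL"
        )
    return float(ac_apparent / rc_volume(v_segmented_spect_ml, rc_params_spect))


def pvc_organ(ac_apparent, rc: float):
    """Divide an organ concentration by its recovery coefficient."""
    if not 0.0 < rc <= 1.0:
        raise ValueError("organ RC must lie in (0, 1]")
    return ac_apparent / rc
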