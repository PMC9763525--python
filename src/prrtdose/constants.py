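"""Physical constants and published defaults used across the pipeline.

All half-lives are physical unless suffixed ``_eff``. Units are stated per
constant; the package convention is hours for kinetic times, mm for lengths,
Bq/mL for activity concentrations and Gy/GBq for absorbed dose per injected
activity.
"""

import numpy as np

#: Physical half-life of Ga-68 in minutes.
HALF_LIFE_GA68_MIN = 67.71

#: Physical half-life of Lu-177 in days.
HALF_LIFE_LU177_D = 6.647

#: Physical half-life of Lu-177 in hours.
HALF_LIFE_LU177_H = HALF_LIFE_LU177_D * 24.0

#: Mean electron (beta + conversion/Auger) energy emitted per Lu-177 decay,
#: keV; standard decay-data value used for local energy deposition.
MEAN_ELECTRON_ENERGY_KEV = 147.9

#: Soft-tissue mass density, g/mL.
TISSUE_DENSITY_G_PER_ML = 1.04

#: Ga-68 PET cross-calibration factor: measured SUV for a uniform phantom;
#: image concentrations are divided by this value.
SUV_FACTOR_GA68 = 0.94

#: Gaussian PSF FWHM of the PET reconstruction, mm (isotropic).
PET_PSF_FWHM_MM = 6.4

#: Recovery coefficient applied to kidney and spleen SPECT concentrations.
RC_ORGAN_SPECT = 0.85

#: Population effective half-lives (hours) of Lu-177 tumour retention for
#: grade-1 and grade-2 neuroendocrine tumours.
T_EFF_TUMOUR_H = {1: 103.0, 2: 81.0}

#: PET-volume cutoff (mL) below which tumours are excluded from statistics.
TUMOUR_VOLUME_CUTOFF_ML = 5.0

#: NEMA IEC body-phantom sphere inner diameters (mm) and volumes (mL).
NEMA_SPHERE_DIAMETERS_MM = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)
NEMA_SPHERE_VOLUMES_ML = tuple(
    float(np.pi / 6.0 * (d / 10.0) ** 3) for d in NEMA_SPHERE_DIAMETERS_MM
)

#: Background-to-sphere activity-concentration ratios of the calibration set.
PHANTOM_BACKGROUND_RATIOS = (0.0, 0.2, 0.4, 0.6, 0.8)

JOULE_PER_KEV = 1.602176634e-16

LN2 = float(np.log(2.0))


def fwhm_to_sigma(fwhm: float) -> float:
    """Convert a Gaussian FWHM to its standard deviation (same units)."""
    return fwhm / (2.0 * np.sqrt(2.0 * LN2))
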