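# prrtdose

Quantitative internal dosimetry tools for peptide receptor radionuclide
therapy (PRRT) of neuroendocrine tumours with [¹⁷⁷Lu]Lu-DOTA-TATE, and for
relating those doses to pre-therapeutic [⁶⁸Ga]Ga-DOTA-TATE PET uptake.

The package is written for medical physicists and methods researchers who
want a fully testable, self-contained version of this analysis chain:
every stage can run on synthetic sphere phantoms and synthetic patient
cohorts with known ground truth, or on real region-level tables supplied
as CSV.

## What it computes

**Partial-volume recovery calibration.** On simulated six-sphere body
phantoms (0.52–26.5 mL, background-to-sphere ratios η ∈ {0, 0.2, 0.4,
0.6, 0.8}) the package fits

- the volume-only recovery coefficient
  `R₀(Vₚ) = 1 / (1 + (α/Vₚ)^β)` (SPECT tumour spill-out),
- the background-aware recovery coefficient
  `R(Vₚ, η) = R₀ + (1−R₀)·f·η + (1−R₀)·(1−f)·η²` with `f ∈ [0, 1]`
  (PET tumours, spill-out and spill-in; `R(Vₚ,0)=R₀`, `R(Vₚ,1)=1`
  identically),
- an affine segmented-to-physical volume map
  `Vₚ = a₀ + a₁·Vₛ + a₂·η + a₃·Vₛ·η`,
- the Gaussian PSF FWHM by matched-filter analysis,
- per-VOI organ recovery coefficients by mask–PSF convolution.

**Activity quantification.** VOI statistics, decay correction, the
activity concentration per injected activity (AC/IA, 1/mL), SUVmean/SUVmax
(g/mL), the ⁶⁸Ga PET cross-calibration division by 0.94, and the coupled
(η, Vₚ, corrected-AC) fixed-point partial-volume correction for PET
tumours.

**Hybrid planar–SPECT dosimetry.** Planar region values (organ: ROI mean
minus thigh background; tumour: mean of the five highest pixels),
piecewise time-activity fits (mono-exponential tail through the last three
samples; linear or tangent-quadratic early segments), rescaling to the
absorbed-dose rate at the SPECT time (local energy deposition, 147.9
keV/decay, density 1.04 g/mL), analytical integration to the absorbed dose
per injected activity (AD/IA, Gy/GBq), and re-timing of off-schedule SPECT
data with planar-derived effective half-lives.

**Dose prediction from ⁶⁸Ga PET.** Predicted ¹⁷⁷Lu tumour doses from a
single ⁶⁸Ga AC/IA snapshot using grade-specific population effective
half-lives (103 h grade 1, 81 h grade 2).

**Statistics.** Pearson, tumour-count-weighted inter-patient correlation,
repeated-measures (common slope, patient intercepts) intra-patient
correlation, leave-one-out stability intervals, log-ratio Bland–Altman
agreement with 95% coverage intervals, and the strict 5 mL PET-volume
tumour filter.

## Worked example

```bash
prrtdose full --seed 1 --outdir run
```

runs the complete synthetic study — phantom calibration, an 18-patient
cohort with measurement noise (CV 5%) and partial-volume bias,
quantification, hybrid dosimetry, prediction and statistics — and prints

```
tumours kept/total: 54/104
inter-patient r = 0.81 (p = 0.000131)
intra-patient r = 0.98 (p = 4.28e-26)
prediction agreement: mean -1% [-32%, +43%]
outputs in run/
```

Reading: of 104 generated tumours, 54 have a PET volume above the 5 mL
cutoff and enter the statistics. Across patients, the mean tumour ⁶⁸Ga
AC/IA and the mean ¹⁷⁷Lu AD/IA correlate with r = 0.81 (tumour-count
weighted); within patients the repeated-measures correlation is r = 0.98
(the synthetic cohort shares grade-level kinetics, so intra-patient
scatter comes from measurement noise only). The grade-based dose
prediction is unbiased on average (−1%) with a 95% coverage interval of
−32% to +43% — in the synthetic cohort the spread comes from the
inter-subject half-life variation (CV 20%) that a single ⁶⁸Ga snapshot
cannot see. `run/` contains the per-region quantification, dose,
prediction and statistics tables (CSV/JSON) plus a manifest with the seed
and calibration parameters.

The same stages are available as a library (`prrtdose.pipeline`,
`prrtdose.recovery`, `prrtdose.dosimetry`, ...) and as the subcommands
`calibrate`, `simulate`, `filter` and `full`.

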