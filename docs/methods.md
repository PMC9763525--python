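# Methods

This note documents the models, conventions, numerical choices and
limitations of `prrtdose`. Units: hours for kinetic times, mm for lengths,
mL for volumes, Bq/mL for activity concentrations, Gy/GBq for absorbed
dose per injected activity (AD/IA).

## Partial-volume recovery models

Finite spatial resolution makes the apparent concentration of a small
object differ from the true one: signal spills out of the object and, when
the surroundings are radioactive, background spills in. Two recovery
models are calibrated on digital sphere phantoms:

- volume-only: `R₀(Vₚ) = 1 / (1 + (α/Vₚ)^β)`, with α (mL) the volume of
  half recovery and β the steepness. Used for ¹⁷⁷Lu SPECT tumours, whose
  background at 1 d post-injection is low.
- background-aware:
  `R(Vₚ, η) = R₀ + (1−R₀)·f·η + (1−R₀)·(1−f)·η²` with the
  background-to-object concentration ratio η and a mixing parameter
  `f ∈ [0, 1]`. The form interpolates between pure spill-out (η = 0,
  `R = R₀`) and the exact identity `R(Vₚ, 1) = 1` (an object at background
  level is indistinguishable, hence fully "recovered"). Used for ⁶⁸Ga PET
  tumours, where blood background is substantial ~1 h post-injection.

Fits minimize squared residuals of observed recoveries
(apparent/true concentration) with Levenberg–Marquardt least squares on
transformed parameters — log for α and β, a logistic map for f — which
enforces positivity and `f ∈ [0, 1]` without a constrained solver.
Defaults: α initialized at the median sphere volume, β = 1, f = 0.5;
these converge on every surface we generate. If the data contain a single
η (e.g. the background-free subset used for the SPECT model), f is
unidentifiable: the fit drops to the volume-only model and flags
`degenerate_f` rather than failing.

Segmentation volume bias is corrected by the affine map
`Vₚ = a₀ + a₁·Vₛ + a₂·η + a₃·Vₛ·η`, fitted by ordinary least squares and
exact on data generated from the model. Applied volumes are floored at
0.1 mL (the affine form can go non-positive outside its calibration
range); a floor hit emits a warning.

Organ recovery coefficients are computed per VOI as the volume average,
over the VOI, of the binary mask convolved with the Gaussian PSF. The
field is evaluated on a 3× supersampled grid with the exact Gaussian
transfer function in the Fourier domain: a sampled spatial kernel is
biased when σ is below one voxel, and voxel-centre sampling alone
overestimates the retained fraction by a few percent at PET resolutions.
The PSF FWHM itself is estimated by matched filtering — the FWHM
minimizing the squared difference between the blurred ground truth and
the measured phantom image over a search grid, refined parabolically; a
boundary minimum raises instead of returning a clipped value.

## Phantoms and the measurement forward model

`make_sphere_phantom` rasterizes six spheres (defaults: the standard
body-phantom volumes 0.52–26.5 mL) at 3.65 mm isotropic voxels with ≥5³
sub-voxel supersampling, so voxelized volumes track the analytic volumes
to well under 1%. Boundary voxels carry exact occupancy fractions; the
label mask covers each sphere's full support (so the VOI captures all
sphere activity) while the legend records the analytic volume. The
in-plane PET grid of the emulated system is 3.65 mm with 3.27 mm slices;
we use 3.65 mm isotropic, which simplifies the PSF with negligible effect
on recovery curves. Sphere positions are a fixed deterministic row —
positions are irrelevant to recovery.

Imaging is Gaussian blur (FWHM 6.4 mm for PET) plus optional
scaled-Poisson counting noise: the image is scaled so a voxel at the
sphere concentration has `noise_scale` expected counts, integer counts
are drawn, and the scale inverted. This matches camera counting
statistics at image level without simulating projections. Blur boundary
handling conserves total activity to <0.1% for interior objects.

The calibration stage measures each sphere's apparent concentration as
the mean over its support VOI and its segmented volume with a simple
half-contrast threshold segmenter; the volume map is calibrated to undo
precisely that segmenter's bias. Patient-style quantification then
estimates η from a morphological background shell (between the 2nd and
4th binary dilations of the VOI, excluding all labelled voxels — far
enough to escape spill-out at 6.4 mm FWHM, close enough to be local).

## Quantification conventions

- AC/IA: concentration decay-corrected to the administration time with
  the physical half-life (67.71 min ⁶⁸Ga, 6.647 d ¹⁷⁷Lu, configurable),
  divided by the injected activity.
- SUV: clinical convention — no partial-volume correction,
  decay-corrected to injection time, normalized to injected activity,
  multiplied by body weight; SUVmax uses the maximum voxel.
- ⁶⁸Ga PET concentrations are divided by the cross-calibration factor
  0.94 observed for ⁶⁸Ga on the camera system.
- PET tumour PVC solves the coupled system η = background/corrected,
  Vₚ = volume-map(Vₛ, η), corrected = apparent / R(Vₚ, η) by fixed-point
  iteration with Aitken (Steffensen) acceleration, tolerance 10⁻⁶,
  at most 100 evaluations; phantom cases converge in <10. When the
  background persistently exceeds the corrected concentration, η is
  clamped at 1 (the region is indistinguishable from its surroundings)
  and the result flagged with a warning.
- SPECT tumours: corrected = apparent / R₀(V_SPECT). Kidney and spleen
  SPECT concentrations are divided by a fixed RC of 0.85; liver
  parenchyma VOIs are small relative to the organ, so liver RC is unity.

## Hybrid planar–SPECT dosimetry

Planar whole-body series (nominally 1, 24, 96, 168 h p.i.) provide the
curve *shape*; one quantitative SPECT/CT (nominally ~22 h) provides the
absolute scale. Organ planar values are ROI means minus a thigh-ROI
background (floored at zero with a warning); tumour values are the mean
of the five highest ROI pixels, without background subtraction.

Curves are fitted by unweighted least squares: a mono-exponential tail
through the last three samples (initialized by log-linear regression; a
non-decaying tail is an error naming the region), switching at the second
sample time t₂. Before t₂:

- organs: straight lines (0,0) → (t₁,y₁) → (t₂,y₂);
- tumours: a straight line (0,0) → (t₁,y₁), then a quadratic through
  (t₁,y₁) and (t₂,y₂) whose slope at t₂ matches the fitted tail.

The tangent-quadratic construction deserves a note, because the obvious
alternative — a quadratic through (0,0), (t₁,y₁), (t₂,y₂) — is unusable
at this sampling schedule: with t₁ ≈ 1 h and t₂ ≈ 24 h it must rise from
the origin to y₁ within one hour and then stay near the data for a day,
which forces a vertex several times above the measurements (≈6× for a
103 h effective half-life) and corrupts both the early integral and the
curve value at the SPECT time by factors of order 3. The tangent form
keeps the segment bounded by the late kinetics and reproduces a
mono-exponential ground truth at the SPECT time to <0.1%. One can show
the quadratic cannot go negative between two positive samples with a
decaying tail slope; a defensive fallback to the linear construction
(with a warning) exists regardless. The tail is attached with its own
fitted amplitude, i.e. continuity of value at t₂ is not forced; the
discontinuity magnitude is logged in the curve diagnostics.

Absorbed-dose rates use local energy deposition: a concentration c
(Bq/mL) deposits `c · E / ρ` J/(s·g) with E = 147.9 keV mean electron
energy per ¹⁷⁷Lu decay (standard decay data, configurable) and
ρ = 1.04 g/mL. For ¹⁷⁷Lu's short electron range the difference from full
radiation-transport dose engines is small for the region sizes analysed.
The fitted curve is rescaled so its value at the SPECT time equals the
dose rate derived from the corrected SPECT concentration, and AD/IA is
the closed-form integral of the rescaled curve (polynomial antiderivatives
plus the exponential tail). Every integration is cross-checked against
adaptive quadrature; the relative difference (required <10⁻⁶) is stored
in the result diagnostics. AD/IA is invariant to the arbitrary planar
signal units — planar data contribute shape only. Off-schedule SPECT
values can be re-timed to the nominal time point with the planar-derived
effective half-life of the same tissue
(`value · 2^((t_actual − t_target)/T_eff)`).

## Dose prediction from a single ⁶⁸Ga snapshot

Tumour kinetics are assumed mono-exponential with grade-specific
population effective half-lives: 103 h (grade 1) and 81 h (grade 2). The
decay-corrected ⁶⁸Ga AC/IA is propagated back from the scan time (~64
min) to t = 0; by default the remaining biological turnover rate is taken
as λ_eff − λ_phys(¹⁷⁷Lu) ("effective" mode; a "none" mode applies no
correction — the two differ by <1% at 64 min, and the switch exposes the
ambiguity of what "propagated back" should undo). Scaling by the injected
¹⁷⁷Lu activity gives the predicted initial ¹⁷⁷Lu concentration, and the
predicted AD/IA follows from local energy deposition and the analytic
integral `c₀ · E/ρ · T_eff/ln 2`. The prediction is exactly linear in the
⁶⁸Ga uptake, the injected activity, and the assumed half-life (so a
half-life mis-specified by a factor k scales the dose by exactly k).
Grade comes from supplied metadata; nothing is imputed.

## Statistics

Tumour analyses first apply a strict volume filter: only tumours with PET
volume > 5 mL enter (structures near the system resolution carry
unreliable volumes and concentrations); the boundary value itself is
excluded, and both counts are reported. With a variable number of tumours
per patient, independence cannot be assumed, so inter- and intra-patient
questions are separated: the inter-patient correlation uses one point per
patient (the mean across its tumours) weighted by the tumour count; the
intra-patient correlation is a repeated-measures correlation — one common
slope, patient-specific intercepts — computed by within-subject centering
(equivalent to the dummy-variable ANCOVA regression, against which it is
tested to 10⁻¹⁰), with N − n_subjects − 1 degrees of freedom and subjects
contributing a single observation dropped with a warning. Kidney values
enter organ analyses as the left/right mean to keep points independent.
p-values are two-sided from the t-distribution; the weighted
correlation's p uses a t approximation with (n_patients − 2) degrees of
freedom. Stability is probed by leave-one-out intervals (min/max r over
single-unit deletions); degenerate subsets are skipped with a warning,
and the interval is reported alongside — not in place of — the full-data
r. Agreement of predicted vs measured doses uses log ratios (symmetric
relative deviations); the mean and mean ± 1.96·SD (sample SD, n−1) are
back-transformed as (eˣ − 1)·100%. The normal-based coverage interval is
the default because percentile intervals are meaningless at n ≈ 18; the
significance threshold 0.05 is configuration, not baked into the math.

## Synthetic cohort: what it emulates and what it does not

`make_cohort` draws an 18-patient cohort (defaults): 2–9 tumours per
patient with log-uniform volumes 0.5–80 mL (≈55% above the 5 mL cutoff),
grade mix 0.5, tumour effective half-lives 103/81 h with 20%
inter-subject coefficient of variation (capped just below the ¹⁷⁷Lu
physical half-life, since effective decay cannot be slower than physical),
tumour AC/IA(t=0) log-normal with median 2·10⁻⁴ mL⁻¹ (SUV ≈ 15 at
typical weights), organ kinetics (kidneys, spleen, liver) chosen so that
kidney AD/IA lands at ≈0.5–0.8 Gy/GBq, injected activities 0.17 GBq
(⁶⁸Ga) and 7.45 GBq (¹⁷⁷Lu), weights 55–95 kg, the 1/24/96/168 h planar
schedule, SPECT at 21.9 h, the ⁶⁸Ga scan at 64 min, and multiplicative
log-normal measurement noise with CV 5%. Both tracers share each region's
initial AC/IA — the same receptor binding imaged twice — and the ⁶⁸Ga
measurement reflects ~1 h of biological turnover. Measurement bias is
opt-in: recovery/volume-map parameters applied in the forward direction,
the 0.94 PET calibration factor (on by default), and an early-uptake bend
pulling the first planar sample below the back-extrapolated exponential.
Every record carries a ground-truth block (A0 per IA, T_eff, closed-form
AD/IA) for end-to-end validation; all draws come from one seeded
generator, so a seed fixes the cohort bit-for-bit.

The generator does **not** emulate: non-mono-exponential kinetics
(multi-compartment washout, flare), registration error between
modalities, reconstruction artifacts, scatter/attenuation residuals,
anatomical context (organs at risk adjacent to lesions), respiratory
motion, or inter-tracer affinity differences. Passing round-trip tests
therefore demonstrates the correctness of the computational chain under
its stated model — not the clinical accuracy of the method on real
images.

## Problem sizes and determinism

Default analyses are sized for interactive use: phantom grids of roughly
150×30×30 voxels, five background ratios, 18-patient cohorts, 100-replicate
fit-recovery checks and 10⁵-sample Monte-Carlo statistics checks; a full
synthetic study completes in seconds. All stages are deterministic under
a fixed seed, and stage outputs are plain CSV/JSON so any stage can be
re-run on externally supplied tables.

## Known limitations

- The fixed-point PET PVC assumes the coupled system is a contraction;
  this holds on phantom-realistic inputs but is not proven globally
  (non-convergence raises with the trajectory context).
- η for patient tumours comes from a background shell; real analyses may
  prefer a reference region, and the choice matters when neighbouring
  uptake crowds the shell (labelled neighbours are excluded, unlabelled
  ones are not).
- The early time-activity segment below the first planar sample is
  unobserved; anchoring at the origin underestimates any uptake already
  present during the first hour (sub-percent effect on AD/IA at the
  default schedule).
- The volume map is affine and calibrated on spheres; strongly
  non-spherical lesions fall outside its calibration family.
- Organ SPECT recovery uses a single literature-style RC (0.85) rather
  than per-patient mask convolution; the PET organ path does use per-VOI
  mask RCs.
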