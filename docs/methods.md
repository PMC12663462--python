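# Methods

This note documents the models, assumptions, parameters and numerical
choices behind `ntpet`. It is the package's own account of its science;
every number quoted here is computed by the test suite or by
`scripts/acceptance.py`.

## The two-step pipeline

**Step 1 — normal-twin synthesis.** A *normal twin PET* (ntPET) is a
synthetic PET volume depicting the tracer uptake expected for a given
patient if they were free of focal disease. Crucially, the twin is
predicted from the CT-derived anatomy and the study attributes only — never
from the observed PET — so anomalies present in the PET cannot leak into
its reference. Three predictors implement the common estimator contract
(`fit(studies)` / `predict(study) -> Grid3D`):

- **Constant organ map** (reference method): each organ mask is filled with
  the training cohort's mean per-organ SUVmean (unweighted mean of
  per-study means). Anatomy-aware, covariate-blind.
- **Organ regression**: per organ, ordinary least squares of the per-study
  organ SUVmean on the covariate design
  `[1, sex_F, age - 60, fat_body_mass, uptake_time - 63, sin(2πd/365),
  cos(2πd/365)]` (d = scan day of year). Prediction fills each organ with
  its fitted mean for the study's attributes, clamped at 0. This is the
  desk-scale attribute-conditioned twin and, when applied in-sample, makes
  the twin correction an exact OLS residualisation — which is what makes
  the correction's behaviour analytically checkable.
- **Convolutional translator**: a small patch-based CT→PET network (below),
  the scaled-down analogue of the clinical volume-to-volume model.

**Step 2 — twin correction and anomaly detection.** Organ measurements are
corrected as `tcSUV_mean = SUV_mean − ntSUV_mean + C`, with `C` the
per-organ training-cohort mean ntSUVmean, included only to keep corrected
values on the familiar SUV scale; it provably changes neither variances nor
any test statistic. This is the imaging analogue of the CUPED
covariate-adjustment estimator: if the twin equals the conditional mean of
SUV given the covariates, the corrected value is uncorrelated with every
covariate. Voxel-wise anomaly maps are `gaussian(PET − ntPET)`; tumour
masks are `map > threshold` inside the body and outside organs with highly
variable physiological uptake (kidneys, heart, bladder, brain, small and
large intestine); disease burden is scored as total lesion glycolysis
(TLG = segmented volume in mL × SUVmean).

## The digital phantom

The phantom emulates the *statistical* structure of a pseudo-normal
whole-body FDG PET/CT cohort, not scanner physics.

**Anatomy.** An elliptical torso with a subcutaneous-fat shell, a muscle
band, a visceral interior containing ellipsoidal organs (liver, heart,
kidneys, bladder, intestines), a spine, an aorta, and a head (skull +
brain) joined by a neck so the body is one connected component. The fat
shell thickness grows linearly with the patient's fat body mass, so body
composition is encoded in the anatomy (fat-compartment volume is strictly
increasing in fat mass — a tested invariant).

**Attributes.** Sampled from clipped normals with defaults matching a large
clinical referral population: age 60.5 ± 17.3 y, injected activity
256 ± 66 MBq, uptake time 63 ± 6 min, male fraction 0.58, a four-scanner
site mix, uniform scan time-of-day in [7, 17) h and uniform day-of-year.
Height is sampled with sex-specific means (1.78/1.64 m) because the James
lean-body-mass formula needs it. Fat body mass is defined as
`weight − James LBM` (M: `1.1W − 128(W/H_cm)²`; F: `1.07W − 148(W/H_cm)²`),
an assumption documented here because no standard clinical definition
exists.

**Uptake model.** Organ-mean SUV is additive-linear in the covariates:

```
E[SUV_o] = baseline_o + sex_o·1[F] + age_o·(age−60) + fat_o·FBM
           + upt_o·(uptake−63) + A_o·cos(2π(day−15)/365)
```

plus i.i.d. Gaussian voxel noise (SD 0.05 SUV) and clamping at 0. The
season surrogate is a cosine peaking on day 15 (mid-winter), which is
smooth, analyzable, and detectable by a seasonal-bin ANOVA. Additivity is a
modelling choice: it keeps twin-correction recovery exactly checkable
against the generator's coefficients. Default injected effects: +0.3 SUV
female offset and a 0.2 SUV seasonal amplitude on both fat compartments,
−0.005 SUV/kg fat-mass slope and −0.01 SUV/min uptake-time slope on the
liver — magnitudes of the order reported for real fat/liver confounders,
chosen once as the package's study conditions.

**CT.** Per-tissue Hounsfield means (fat ≈ −100/−90, muscle 45, liver 55,
bone 400, …) with 15 HU Gaussian noise; air at −1000 HU.

**Lesions.** Spheres of configurable count, radius (mm) and SUV contrast,
placed with the whole sphere inside the body (optionally confined entirely
within the allowed organs plus a margin). Lesion voxels also take a dense
soft-tissue CT value (150 HU by default): real malignancies are
CT-discernible, and this is precisely why disease masking matters during
training. Ground-truth lesion masks and in-plane-expanded disease exclusion
masks (dilated antero-posteriorly and latero-medially, never axially,
mimicking masks drawn on coronal/sagittal MIPs) are carried with each
study.

**What the phantom does not model** — and hence what passing tests do not
show about clinical data: scanner physics (attenuation, PSF, Poisson
sinogram noise, reconstruction artefacts), PET/CT misalignment, respiratory
motion, inter-patient anatomical variability beyond body composition,
physiological uptake variability within an organ (brown fat, ureters,
vocal cords), and non-spherical infiltrative disease. Clinical headline
numbers from large cohorts are therefore not reproduction targets here;
the tests verify the *mechanisms* (effect recovery, masking necessity,
exclusion guarantees, metric arithmetic) under known ground truth.

## Preprocessing

PET is in SUV units (`concentration × weight / injected activity`, 1 g/mL
density). CT is clamped to [−500, 600] HU and mapped affinely onto [0, 2]
(the rescale is linear; −500→0, 600→2). Volumes are resampled with linear
interpolation (nearest for labels/masks); the clinical reference grid is
2 mm isotropic, the phantom default 4 mm. Body masks are the largest
connected component above −300 HU with in-plane hole filling.

## The convolutional translator

A fully-convolutional network in plain numpy (the building blocks carry
finite-difference gradient tests): three 3×3×3 convolutions (12 channels,
ReLU) and a 1×1×1 output head — receptive field 7 voxels per axis. Inputs:
the rescaled CT centred by −1 (so soft tissue sits near 0 and first-layer
ReLUs stay active on all-positive CT) plus a Gaussian-smoothed copy
(σ = 2 voxels) as a cheap second scale — tissues that differ only in
neighbourhood mean (liver vs muscle, 10 HU apart under 15 HU noise) then
need no learned averaging filters. Optional inputs: a fixed 4-d embedding
of the organ label map as extra channels, and the 16-d study-attribute
encoding injected as a learned per-channel bias at the deepest convolution,
broadcast across space.

The attribute encoder is deterministic: sin–cos pairs for day-of-year and
time-of-day (continuous across the wrap), standardised continuous
attributes, fixed seeded 3-d embeddings per categorical with a reserved
"unknown" row, projected to length 16 by a fixed 3-layer feed-forward map.

**Training.** Random axial patches (full transaxial extent × 8 slices at
phantom scale; the clinical reference is 256×256×32), batch size 2, masked
L1 loss ignoring voxels outside the body or inside exclusion masks, Adam
with the learning rate decayed ×0.1 at 62.5 % of training. The clinical
reference schedule (80 000 steps at 1e-4) is kept as the documented default
in `TrainConfig`; the phantom-scale experiments use 2 000 steps at 1e-2,
which suffices for the ~10⁵-parameter network on 8 small volumes.

**Inference.** Patches are extracted with 66.6 % axial overlap
(stride = round-half-away-from-zero of `depth × (1 − overlap)`, min 1; at
depth 32 this gives 11 — the rounding rule is a documented decision, the
alternative reading gives 10) and blended with generalized-normal weights
`w(z) = exp(−(|z−c|/α)^β)`, β = 4, α = 0.4 × depth, renormalised per voxel.
An identity-predictor oracle test guarantees the blending reproduces any
volume to 1e-6 across a grid of (depth, overlap, β, α). Negative predicted
SUV is clamped to 0.

## Twin correction battery

For each organ (subcutaneous fat, visceral fat, skeletal muscle, liver,
aorta) and each measurement (SUVmean, tcSUVmean, SULmean = SUV·LBM/weight):
sex via Welch t-test; age and uptake time binarized at the cohort median
(ties to "low") and tested via Welch; fat body mass via a two-sided OLS
slope t-test; season via one-way ANOVA over meteorological bins (Dec–Feb
winter, Mar–May spring, Jun–Aug summer, Sep–Nov fall). All tests are
two-sided, p-values are reported raw (no multiple-testing correction),
degenerate covariates are flagged rather than dropped. The correction
constant `C` is computed on the fitting cohort and frozen.

The recovery experiment (n = 200 phantoms, organ-regression twin fitted and
applied in-sample) checks that every injected (organ, covariate) pair is
significant at p < 0.01 before correction and that ≥ 90 % are
non-significant (p > 0.05) after; because the regression twin residualises
exactly, the post-correction statistics hover near their null values. The
measured fat-organ variance reduction is compared with the analytic value
`Var(effects) / (Var(effects) + Var(residual))` computed from the
generator's own coefficients and the sampled covariates, with the residual
organ-mean variance `noise²/n_voxels`. On SUL, the additive fat-organ
effects are *not* removed (SUL rescales rather than subtracts), mirroring
the qualitative observation that single-factor normalisations leave other
covariate effects intact.

## Anomaly detection choices

- The "4 mm gaussian" smoothing parameter is interpreted as FWHM
  (σ = FWHM/2.355 per axis in voxel units); boundary handling is
  reflective, which conserves the global mean of the difference map (a
  tested invariant).
- Default threshold 1.8 SUV, the value a greedy dice search produces on
  clinical cancer cohorts; the package's greedy search is a deterministic
  coarse-to-fine 1-D grid (step 0.2 over [0.2, 6], then 0.05 within one
  coarse step of the best point, ties to the lower threshold) and is tested
  to match an exhaustive fine-grid optimum within one fine step. Optimising
  the threshold on the evaluation studies yields an optimistic
  best-achievable dice, and the search documents itself as such.
- Pure thresholding by default; a minimum connected-component size filter
  exists but is off by default.
- Dice for threshold selection is averaged per study (not pooled over
  voxels).
- Exclusion is a hard guarantee: no segmented voxel ever carries an
  excluded organ label, at any threshold.

## Experiment problem sizes

Statistical experiments run on 48×48×80 grids at 4 mm; convolutional
training runs on 28×28×40 grids at 6 mm with depth-8 patches. These sizes
keep the full experiment battery to a few minutes on one CPU while leaving
every organ resolvable. The disease-masking experiment uses 8 phantoms with
2–3 bulky lesions (radius 15–18 mm, contrast +6 SUV) and trains the
translator twice — with and without exclusion masks in the loss — for 2 000
steps each; lesions need to occupy a visible share of the loss for the
unmasked model to be able to learn them at this scale, which is the
behaviour the experiment exists to demonstrate. The translator runs CT-only
here: with organ labels as input, a label-only prediction is a strong local
optimum that lets the model ignore the CT, making the masking contrast
untestable.

## Known limitations

- The organ-regression twin shares its functional form with the phantom's
  generator; its exact-recovery behaviour is by construction and will not
  transfer to misspecified real-world effects (the conv translator makes no
  such assumption).
- The numpy conv net is desk-scale: single-threaded, no GPU, no
  encoder-decoder levels; it is not intended for 2 mm clinical volumes.
- Lesion "background" for contrast is the host-organ level; infiltrative or
  necrotic lesion profiles are out of scope.
- SUV computation assumes 1 g/mL tissue density and no decay correction.
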