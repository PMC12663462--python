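# ntpet

Normal-twin PET synthesis, confounder correction of organ SUV measurements,
and unsupervised anomaly detection for whole-body FDG PET/CT — exercised
end-to-end on digital phantoms with known ground truth.

## The problem

Whole-body FDG PET quantification is confounded: organ SUVmean values shift
with sex, body fat mass, ambient season, and tracer uptake time, which both
inflates variance in group studies and obscures disease effects. And most
of a whole-body volume is normal tissue, so flagging disease without
per-disease labelled data requires a patient-specific notion of *normal*.

The **normal twin PET** (ntPET) approach answers both with one object: a
synthesized PET volume depicting the uptake expected for this patient's
anatomy, demographics and acquisition parameters, predicted from the CT and
study attributes — never from the PET itself, so anomalies cannot leak into
their own reference. The twin is then used two ways:

**Twin correction** (a CUPED-style covariate adjustment):

```
tcSUV_mean = SUV_mean − ntSUV_mean + C
```

where `C` is the per-organ population-mean ntSUVmean, kept only so
corrected values stay on the SUV scale (it changes no variance and no test
statistic). When the twin captures the covariate effects, `tcSUV` is
decorrelated from them and organ-level variance collapses to the residual.

**Unsupervised anomaly detection**: smooth `PET − ntPET` with a 4 mm
Gaussian, threshold (default 1.8 SUV) inside the body while ignoring organs
with erratic physiological uptake (kidneys, heart, bladder, brain,
intestines), and score disease burden as total lesion glycolysis
(TLG = lesion volume × SUVmean).

Because clinical cohorts are not shippable, the package includes a
first-class digital phantom: procedural whole-body anatomy whose fat
compartment scales with fat body mass, CT with per-tissue Hounsfield
statistics, PET whose organ means follow a known additive covariate model,
and optional CT-discernible lesions with ground-truth masks. Every
downstream claim is tested against the generator's injected truth. See
`docs/methods.md` for the full model description and its limitations.

## Who is this for

Researchers in quantitative PET/CT methodology who want a tested,
desk-scale reference implementation of twin-based confounder correction and
reconstruction-difference anomaly detection, and a phantom harness to probe
when those mechanisms work and fail.

## Worked example

```python
from ntpet import (simulate_cohort, OrganRegressionPredictor,
                   evaluate_prediction, organ_stats_table,
                   run_covariate_battery)

cohort = simulate_cohort(60, seed=0, shape=(48, 48, 80), spacing=(4, 4, 4))
twin = OrganRegressionPredictor().fit(cohort)

study = cohort[0]
print(evaluate_prediction(study.pet, twin.predict(study), study.body_mask))
# {'explained_variance': 99.705, 'suv_mae': 0.04, 'mare': 5.284}

table = organ_stats_table(cohort, twin)
battery = run_covariate_battery(table)
liver = battery[(battery.organ == "liver") & (battery.covariate == "fat_body_mass")]
print(liver[["measurement", "test", "p_value"]].to_string(index=False))
# measurement    test      p_value
#    suv_mean slope_t 2.240574e-08
# tc_suv_mean slope_t 1.000000e+00
#    sul_mean slope_t 2.526293e-27
```

The twin explains 99.7 % of the in-body PET variance on this noise-regime
phantom (SUV MAE 0.04). The battery shows the injected −0.005 SUV/kg
fat-mass effect on the liver: strongly significant on raw SUVmean, gone
after twin correction (p = 1.0 — the regression twin residualises exactly),
and *still present* on lean-body-mass-normalised SUL, which rescales rather
than removes covariate structure.

Detection on a phantom with one 20 mm, +4 SUV liver lesion:

```python
from ntpet import (sample_attributes, simulate_study, LesionSpec,
                   default_effect_model, detect, dice)

spec = LesionSpec(count=(1, 1), radius_mm=(10, 10), contrast=(4, 4),
                  allowed_organs=("liver",))
attrs = sample_attributes(1, seed=3)[0]
lesioned = simulate_study(attrs, default_effect_model(), spec,
                          shape=(48, 48, 80), spacing=(4, 4, 4), seed=3)
result = detect(lesioned, twin, threshold=1.8)
print(result.tlg, dice(result.tumor_mask, lesioned.lesion_mask))
# TLG 31.61 mL*SUV;  dice vs ground truth 1.0
```

## Command line

A thin CLI wraps the library:

```bash
ntpet simulate --n 10 --seed 1 --out-dir cohort/        # phantom cohort as NIfTI
ntpet train --cohort-dir cohort/ --model regression --out model.pkl
ntpet predict --model-file model.pkl --study-dir cohort/phantom_0000 --out twin.nii.gz
ntpet correct --cohort-dir cohort/ --model-file model.pkl --out stats/
ntpet detect --study-dir cohort/phantom_0000 --model-file model.pkl --out det/
ntpet run --n 20 --seed 0 --out-dir full_run/           # whole pipeline + report.json
```

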