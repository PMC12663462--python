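"""Self-contained phantom experiments validating each pipeline stage.

Each function simulates its own cohort under the package's default study
conditions, runs the relevant stage(s), and returns plain-number summaries.
They power both the acceptance script and the heavier end of the test
suite.  Problem sizes (grid 48x48x80 at 4 mm for statistics, 32x32x48 at
6 mm for convolutional training) are chosen so every experiment runs on a
single CPU in minutes.
"""

from __future__ import annotations

import numpy as np

from . import anomaly as an
from . import twin_correction as tc
from .grid import Grid3D
from .labels import ANALYSIS_ORGANS, DEFAULT_LABELS
from .phantom import (
    LesionSpec,
    default_effect_model,
    organ_expected_suv,
    simulate_cohort,
)
from .twin_model import (
    ConstantOrganMapPredictor,
    ConvTranslatorPredictor,
    OracleTwinPredictor,
    OrganRegressionPredictor,
    PatchSpec,
    TrainConfig,
    evaluate_prediction,
)

__all__ = [
    "injected_pairs",
    "twin_correction_recovery",
    "disease_masking_experiment",
    "uad_experiment",
    "tlg_classification_experiment",
    "model_ordering_experiment",
    "greedy_threshold_oracle",
]

STATS_SHAPE = (48, 48, 80)
STATS_SPACING = (4.0, 4.0, 4.0)
CONV_SHAPE = (28, 28, 40)
CONV_SPACING = (6.0, 6.0, 6.0)


def _subseeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence([seed, 0xE1]).generate_state(n) % (2**31)]


def injected_pairs(effect_model=None,
                   organs: tuple[str, ...] = ANALYSIS_ORGANS) -> list[tuple[str, str]]:
    """(organ, covariate) pairs carrying a non-zero injected effect."""
    em = effect_model or default_effect_model()
    mapping = {
        "sex": em.sex_offset,
        "age": em.age_slope,
        "fat_body_mass": em.fatmass_slope,
        "uptake_time": em.uptaketime_slope,
        "season": em.season_amplitude,
    }
    return [
        (organ, covariate)
        for covariate, coeffs in mapping.items()
        for organ, value in coeffs.items()
        if value != 0 and organ in organs
    ]


def twin_correction_recovery(seed: int, n: int = 200) -> dict[str, float]:
    """Inject known covariate effects, correct with the organ-regression
    twin, and measure what survives.

    Returns the fraction of injected (organ, covariate) pairs significant
    before correction (p < 0.01) and non-significant after (p > 0.05), plus
    measured and analytic variance reductions for the fat compartments.  The
    analytic value is Var(effects)/(Var(effects) + Var(residual)) computed
    from the generator's own coefficients and the sampled covariates.
    """
    em = default_effect_model()
    cohort = simulate_cohort(n, seed, effect_model=em,
                             shape=STATS_SHAPE, spacing=STATS_SPACING)
    predictor = OrganRegressionPredictor().fit(cohort)
    table = tc.organ_stats_table(cohort, predictor)
    battery = tc.run_covariate_battery(table)

    pairs = injected_pairs(em)
    pre = battery[battery["measurement"] == "suv_mean"]
    post = battery[battery["measurement"] == "tc_suv_mean"]

    def lookup(frame, organ, covariate):
        row = frame[(frame["organ"] == organ) & (frame["covariate"] == covariate)]
        return float(row["p_value"].iloc[0])

    pre_sig = [lookup(pre, o, c) < 0.01 for o, c in pairs]
    post_ok = [lookup(post, o, c) > 0.05 for o, c in pairs]

    out = {
        "n_injected_pairs": len(pairs),
        "pre_significant_fraction": float(np.mean(pre_sig)),
        "post_nonsignificant_fraction": float(np.mean(post_ok)),
    }

    # measured and analytic variance reduction per fat organ
    expectations = {
        s.id: organ_expected_suv(s.attributes, em) for s in cohort
    }
    for organ in ("subcutaneous_fat", "visceral_fat"):
        sub = table[table["organ"] == organ]
        out[f"vr_{organ}"] = 100.0 * tc.variance_reduction(
            sub["suv_mean"].to_numpy(), sub["tc_suv_mean"].to_numpy()
        )
        mu = np.array([expectations[s.id][organ] for s in cohort])
        var_effects = mu.var(ddof=1)
        lab = DEFAULT_LABELS[organ]
        n_vox = np.mean([int((s.organ_labels.data == lab).sum()) for s in cohort])
        var_residual = em.voxel_noise_sd**2 / n_vox
        out[f"vr_{organ}_analytic"] = float(
            100.0 * var_effects / (var_effects + var_residual)
        )
    return out


def disease_masking_experiment(
    seed: int,
    n: int = 8,
    steps: int = 2000,
    contrast: float = 6.0,
) -> dict[str, float]:
    """Train the conv translator with and without exclusion masks in the loss.

    Lesions are CT-discernible (dense soft tissue) and bulky (15-18 mm
    radius), so an unmasked model can and does learn to reproduce their
    elevated uptake from the CT, while loss masking forces the model to
    predict the host organ's normal uptake there.  The translator runs
    CT-only (no label channels): with organ labels as input a label-only
    prediction is a strong local optimum that lets the model ignore the CT
    entirely, which would make the masking contrast untestable.  Reports the
    in-lesion suppression — (target mean - predicted mean) / injected
    contrast — for both variants: near 1 means the lesion is absent from the
    twin.
    """
    spec = LesionSpec(count=(2, 3), radius_mm=(15.0, 18.0),
                      contrast=(contrast, contrast),
                      allowed_organs=("liver", "visceral_fat"))
    cohort = simulate_cohort(
        n, seed, lesion_spec=spec, shape=CONV_SHAPE, spacing=CONV_SPACING,
        exclusion_expansion_mm=8.0,
    )
    patch = PatchSpec(depth=8)
    cfg = TrainConfig(steps=steps, lr=1e-2, lr_final=1e-3, seed=seed % (2**31))

    out = {}
    for masked in (True, False):
        model = ConvTranslatorPredictor(
            patch_spec=patch, train_config=cfg,
            use_exclusion_masks=masked,
        ).fit(cohort)
        deficits = []
        for study in cohort:
            lesion = study.lesion_mask.data.astype(bool)
            pred = model.predict(study)
            deficits.append(
                float(study.pet.data[lesion].mean() - pred.data[lesion].mean())
            )
        key = "masked" if masked else "unmasked"
        out[f"{key}_suppression_fraction"] = float(np.mean(deficits) / contrast)
    out["contrast"] = contrast
    out["steps"] = steps
    return out


_UAD_SPEC = LesionSpec(count=(1, 3), radius_mm=(10.0, 10.0), contrast=(4.0, 4.0),
                       allowed_organs=("liver", "visceral_fat"))


def uad_experiment(seed: int, n: int = 20,
                   threshold: float = an.DEFAULT_THRESHOLD) -> dict[str, float]:
    """Oracle-twin anomaly detection on phantoms with 20 mm, +4 SUV lesions.

    Measures mean dice against the ground-truth lesion masks, confirms zero
    TLG on lesion-free phantoms, and confirms that lesions confined to
    excluded organs never segment.
    """
    em = default_effect_model()
    oracle = OracleTwinPredictor(em).fit()
    s1, s2, s3 = _subseeds(seed, 3)

    lesioned = simulate_cohort(n, s1, effect_model=em, lesion_spec=_UAD_SPEC,
                               shape=STATS_SHAPE, spacing=STATS_SPACING)
    dices, tlgs = [], []
    for study in lesioned:
        result = an.detect(study, oracle, threshold=threshold)
        dices.append(an.dice(result.tumor_mask, study.lesion_mask))
        tlgs.append(result.tlg)

    free = simulate_cohort(max(4, n // 4), s2, effect_model=em,
                           shape=STATS_SHAPE, spacing=STATS_SPACING)
    free_tlgs = [an.detect(s, oracle, threshold=threshold).tlg for s in free]

    # lesions fully contained (with a smoothing margin) in excluded organs:
    # the exclusion policy must silence them at any threshold
    excluded_spec = LesionSpec(count=(1, 2), radius_mm=(6.0, 8.0),
                               contrast=(4.0, 4.0),
                               allowed_organs=("brain", "bladder"),
                               confine_to_organs=True, margin_mm=4.0)
    shielded = simulate_cohort(4, s3, effect_model=em, lesion_spec=excluded_spec,
                               shape=STATS_SHAPE, spacing=STATS_SPACING)
    shielded_voxels = 0
    for study in shielded:
        for thr in (0.5, threshold, 3.5):
            result = an.detect(study, oracle, threshold=thr)
            shielded_voxels += int(result.tumor_mask.data.sum())

    return {
        "mean_dice": float(np.mean(dices)),
        "mean_lesioned_tlg": float(np.mean(tlgs)),
        "max_lesion_free_tlg": float(np.max(free_tlgs)),
        "excluded_organ_segmented_voxels": float(shielded_voxels),
        "threshold": threshold,
    }


def tlg_classification_experiment(seed: int, n_per_class: int = 30) -> dict[str, float]:
    """TLG-based separation of lesioned vs lesion-free phantoms (oracle twin)."""
    em = default_effect_model()
    oracle = OracleTwinPredictor(em).fit()
    s1, s2 = _subseeds(seed, 2)
    lesioned = simulate_cohort(n_per_class, s1, effect_model=em,
                               lesion_spec=_UAD_SPEC,
                               shape=STATS_SHAPE, spacing=STATS_SPACING)
    free = simulate_cohort(n_per_class, s2, effect_model=em,
                           shape=STATS_SHAPE, spacing=STATS_SPACING)
    scores = [an.detect(s, oracle).tlg for s in lesioned + free]
    labels = [1] * n_per_class + [0] * n_per_class
    return {
        "tlg_auroc": an.auroc(np.array(scores), np.array(labels)),
        "n": 2 * n_per_class,
    }


def model_ordering_experiment(seed: int, n_train: int = 40,
                              n_test: int = 12) -> dict[str, float]:
    """Whole-body explained variance of constant-map vs regression twins.

    On a cohort with non-zero covariate effects the attribute-conditioned
    regression must rank above the covariate-blind constant organ map.
    """
    em = default_effect_model()
    s1, s2 = _subseeds(seed, 2)
    train = simulate_cohort(n_train, s1, effect_model=em,
                            shape=STATS_SHAPE, spacing=STATS_SPACING)
    test = simulate_cohort(n_test, s2, effect_model=em,
                           shape=STATS_SHAPE, spacing=STATS_SPACING)
    out = {}
    for name, predictor in (
        ("constant_organ_map", ConstantOrganMapPredictor()),
        ("organ_regression", OrganRegressionPredictor()),
    ):
        predictor.fit(train)
        evs = [
            evaluate_prediction(s.pet, predictor.predict(s), s.body_mask)[
                "explained_variance"
            ]
            for s in test
        ]
        out[f"explained_variance_{name}"] = float(np.mean(evs))
    return out


def greedy_threshold_oracle(seed: int, n_pairs: int = 10) -> dict[str, float]:
    """Greedy coarse-to-fine threshold search vs exhaustive fine-grid optimum
    on synthetic anomaly-map/mask pairs."""
    rng = np.random.default_rng(seed)
    shape = (24, 24, 24)
    spacing = (4.0, 4.0, 4.0)
    anomalies, gts, labels, bodies = [], [], [], []
    for _ in range(n_pairs):
        base = rng.normal(0.0, 0.3, shape)
        gt = np.zeros(shape, dtype=bool)
        cx = rng.integers(6, 18, 3)
        xi, yi, zi = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
        gt |= ((xi - cx[0]) ** 2 + (yi - cx[1]) ** 2 + (zi - cx[2]) ** 2) <= rng.integers(4, 16)
        base[gt] += rng.uniform(2.0, 4.0)
        anomalies.append(Grid3D(base, spacing))
        gts.append(Grid3D(gt.astype(np.uint8), spacing))
        labels.append(Grid3D(np.full(shape, DEFAULT_LABELS["liver"], dtype=np.int16), spacing))
        bodies.append(Grid3D(np.ones(shape, dtype=np.uint8), spacing))

    greedy_t, greedy_dice = an.greedy_threshold_search(anomalies, gts, labels, bodies)

    fine_grid = np.arange(0.2, 6.0 + 0.025, 0.05)
    best_t, best_dice = None, -1.0
    for t in fine_grid:
        scores = [
            an.dice(an.segment(a, t, lab, body_mask=b), g)
            for a, g, lab, b in zip(anomalies, gts, labels, bodies)
        ]
        m = float(np.mean(scores))
        if m > best_dice:
            best_t, best_dice = float(t), m
    return {
        "greedy_threshold": greedy_t,
        "greedy_dice": greedy_dice,
        "exhaustive_threshold": best_t,
        "exhaustive_dice": best_dice,
        "threshold_gap": abs(greedy_t - best_t),
        "dice_gap": abs(greedy_dice - best_dice),
    }
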