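"""Attribute encoding, patch blending, and the three twin predictors."""

import dataclasses
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ntpet import Grid3D, GridError
from ntpet.labels import DEFAULT_LABELS
from ntpet.phantom import LesionSpec, default_effect_model, inject_lesions, simulate_cohort
from ntpet.twin_model import (
    AttributeCodebook,
    ConstantOrganMapPredictor,
    ConvTranslatorPredictor,
    OracleTwinPredictor,
    OrganRegressionPredictor,
    PatchSpec,
    TrainConfig,
    assemble_volume,
    axial_offsets,
    axial_stride,
    blend_weights,
    cyclic_pair,
    design_matrix,
    encode_attributes,
    evaluate_prediction,
    masked_l1,
)

SPACING = (4.0, 4.0, 4.0)


class TestAttributeEncoding:
    def test_year_boundary_is_continuous(self, attrs_m):
        cb = AttributeCodebook()
        d365 = dataclasses.replace(attrs_m, scan_day_of_year=365)
        d1 = dataclasses.replace(attrs_m, scan_day_of_year=1)
        d183 = dataclasses.replace(attrs_m, scan_day_of_year=183)
        e365, e1, e183 = (encode_attributes(a, cb).raw for a in (d365, d1, d183))
        assert np.linalg.norm(e365 - e1) < np.linalg.norm(e1 - e183)

    def test_quarter_year_maps_to_sin_one_cos_zero(self):
        s, c = cyclic_pair(365.0 / 4.0, 365.0)
        assert (s, c) == pytest.approx((1.0, 0.0), abs=1e-12)

    def test_unit_circle_invariant(self, attrs_m):
        raw = AttributeCodebook().raw_features(attrs_m)
        assert raw[0] ** 2 + raw[1] ** 2 == pytest.approx(1.0)
        assert raw[2] ** 2 + raw[3] ** 2 == pytest.approx(1.0)

    def test_deterministic_and_length_16(self, attrs_m):
        cb = AttributeCodebook()
        a = encode_attributes(attrs_m, cb)
        b = encode_attributes(attrs_m, cb)
        assert a.vector.shape == (16,)
        np.testing.assert_array_equal(a.vector, b.vector)

    def test_unseen_scanner_warns_and_uses_reserved_embedding(self, attrs_m):
        cb = AttributeCodebook()
        odd = dataclasses.replace(attrs_m, scanner_model="prototype_9000")
        with pytest.warns(UserWarning, match="unseen"):
            enc = encode_attributes(odd, cb)
        assert np.all(np.isfinite(enc.vector))


class TestPatchGeometry:
    @pytest.mark.parametrize("depth,overlap,expected", [
        (32, 0.666, 11),   # 32 x 0.334 = 10.688, rounds half-away to 11
        (12, 2.0 / 3.0, 4),
        (8, 0.0, 8),
        (8, 0.99, 1),
    ])
    def test_stride_values(self, depth, overlap, expected):
        assert axial_stride(depth, overlap) == expected

    @settings(max_examples=40, derandomize=True)
    @given(st.integers(1, 64), st.floats(0, 0.99))
    def test_stride_bounds(self, depth, overlap):
        s = axial_stride(depth, overlap)
        assert 1 <= s <= depth

    def test_offsets_cover_axis_flush(self):
        offs = axial_offsets(50, 8, 5)
        assert offs[0] == 0 and offs[-1] == 42
        covered = np.zeros(50, bool)
        for z in offs:
            covered[z:z + 8] = True
        assert covered.all()


class TestBlendWeights:
    def test_centre_weight_is_one(self):
        w = blend_weights(9, beta=4.0, alpha=3.0)
        assert w[4] == pytest.approx(1.0)

    def test_symmetric_positive_maximal_at_centre(self):
        w = blend_weights(8, beta=4.0, alpha=3.2)
        np.testing.assert_allclose(w, w[::-1])
        assert np.all(w > 0)
        assert w.max() == pytest.approx(w[3])

    def test_large_beta_flattens_interior(self):
        w = blend_weights(32, beta=16.0, alpha=0.4 * 32)
        assert w[8:24].min() > 0.9
        assert w[0] < 0.1


class TestAssembleVolume:
    def test_identity_patches_reproduce_volume(self):
        rng = np.random.default_rng(0)
        vol = rng.random((12, 12, 30))
        spec = PatchSpec(depth=8, overlap=0.666)
        stride = axial_stride(spec.depth, spec.overlap)
        w = blend_weights(spec.depth, spec.beta, spec.alpha_value)
        patches = [(z, vol[:, :, z:z + spec.depth])
                   for z in axial_offsets(30, spec.depth, stride)]
        out = assemble_volume(patches, w, vol.shape)
        np.testing.assert_allclose(out, vol, atol=1e-6)

    def test_constant_patches_give_constant_output(self):
        patches = [(z, np.full((4, 4, 6), 2.5)) for z in (0, 3, 6, 10)]
        out = assemble_volume(patches, blend_weights(6, 4.0, 2.4), (4, 4, 16))
        np.testing.assert_allclose(out, 2.5)

    def test_single_patch_passthrough(self):
        rng = np.random.default_rng(1)
        patch = rng.random((5, 5, 10))
        out = assemble_volume([(0, patch)], blend_weights(10, 4.0, 4.0), (5, 5, 10))
        np.testing.assert_allclose(out, patch)

    def test_uncovered_slice_fails(self):
        with pytest.raises(GridError, match="not covered"):
            assemble_volume([(0, np.ones((4, 4, 4)))],
                            blend_weights(4, 4.0, 1.6), (4, 4, 10))


class TestMaskedL1:
    def _grids(self):
        rng = np.random.default_rng(0)
        target = Grid3D(rng.random((6, 6, 6)), SPACING)
        body = Grid3D(np.ones((6, 6, 6), np.uint8), SPACING)
        return target, body

    def test_zero_when_equal(self):
        target, body = self._grids()
        assert masked_l1(target, target, body) == 0.0

    def test_constant_offset_inside_body(self):
        target, body = self._grids()
        pred = target.like(target.data + 0.5)
        assert masked_l1(pred, target, body) == pytest.approx(0.5)

    def test_exclusion_mask_removes_voxels_from_loss(self):
        target, body = self._grids()
        excl = Grid3D(np.zeros((6, 6, 6), np.uint8), SPACING)
        excl.data[:3] = 1
        tampered = target.like(target.data.copy())
        tampered.data[:3] += 100.0
        assert masked_l1(target, tampered, body, excl) == 0.0

    def test_empty_mask_fails(self):
        target, body = self._grids()
        with pytest.raises(GridError, match="empty"):
            masked_l1(target, target, body.like(np.zeros((6, 6, 6), np.uint8)))


class TestEvaluatePrediction:
    def test_perfect_prediction(self, small_study):
        m = evaluate_prediction(small_study.pet, small_study.pet, small_study.body_mask)
        assert m["explained_variance"] == pytest.approx(100.0)
        assert m["suv_mae"] == 0.0 and m["mare"] == 0.0

    def test_scalar_mean_prediction_explains_nothing(self, small_study):
        body = small_study.body_mask
        mean = small_study.pet.data[body.data.astype(bool)].mean()
        flat = small_study.pet.like(np.full(small_study.pet.shape, mean))
        m = evaluate_prediction(small_study.pet, flat, body)
        assert m["explained_variance"] == pytest.approx(0.0, abs=1e-6)

    def test_constant_offset_mae_and_mare(self):
        pet = Grid3D(np.ones((5, 5, 5)), SPACING)
        nt = pet.like(np.full((5, 5, 5), 1.1))
        body = pet.like(np.ones((5, 5, 5), np.uint8))
        # add one differing voxel so PET variance is nonzero
        pet.data[0, 0, 0] = 1.0 + 1e-9
        m = evaluate_prediction(pet, nt, body)
        assert m["suv_mae"] == pytest.approx(0.1, abs=1e-6)
        assert m["mare"] == pytest.approx(10.0, abs=1e-3)


class TestConstantOrganMap:
    def test_single_study_roundtrip(self, small_study):
        from ntpet.twin_correction import organ_suv_mean

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred = ConstantOrganMapPredictor().fit([small_study])
        twin = pred.predict(small_study)
        for organ, lab in DEFAULT_LABELS.items():
            got = organ_suv_mean(twin, small_study.organ_labels, lab)
            assert got == pytest.approx(pred.organ_map_[organ], abs=1e-9)

    def test_mean_of_means_and_permutation_invariance(self, small_cohort):
        a = ConstantOrganMapPredictor().fit(small_cohort[:10])
        b = ConstantOrganMapPredictor().fit(small_cohort[:10][::-1])
        assert a.organ_map_.keys() == b.organ_map_.keys()
        for organ in a.organ_map_:
            assert a.organ_map_[organ] == pytest.approx(b.organ_map_[organ],
                                                        rel=1e-12)

    def test_output_piecewise_constant_per_organ(self, small_cohort, small_study):
        pred = ConstantOrganMapPredictor().fit(small_cohort[:5])
        twin = pred.predict(small_study)
        for lab in np.unique(small_study.organ_labels.data):
            vals = twin.data[small_study.organ_labels.data == lab]
            assert np.unique(vals).size == 1


class TestOrganRegression:
    def test_requires_ten_studies(self, small_cohort):
        with pytest.raises(GridError, match=">= 10"):
            OrganRegressionPredictor().fit(small_cohort[:5])

    def test_recovers_injected_liver_coefficients(self, small_cohort):
        """The fitted liver coefficients must agree with the generator's
        injected fat-mass and uptake-time slopes (checked against a
        statsmodels OLS confidence interval on the same data)."""
        import statsmodels.api as sm
        from ntpet.twin_correction import organ_suv_mean

        pred = OrganRegressionPredictor().fit(small_cohort)
        X = design_matrix([s.attributes for s in small_cohort])
        y = np.array([
            organ_suv_mean(s.pet, s.organ_labels, DEFAULT_LABELS["liver"])
            for s in small_cohort
        ])
        ols = sm.OLS(y, X).fit()
        np.testing.assert_allclose(pred.coef_["liver"], ols.params, atol=1e-8)
        lo, hi = ols.conf_int()[3]  # fat_body_mass column
        assert lo <= -0.005 <= hi
        lo, hi = ols.conf_int()[4]  # uptake-time column
        assert lo <= -0.01 <= hi

    def test_average_covariate_prediction_equals_cohort_mean(self, small_cohort):
        from ntpet.twin_correction import organ_suv_mean

        pred = OrganRegressionPredictor().fit(small_cohort)
        X = design_matrix([s.attributes for s in small_cohort])
        xbar = X.mean(axis=0)
        liver_means = [
            organ_suv_mean(s.pet, s.organ_labels, DEFAULT_LABELS["liver"])
            for s in small_cohort
        ]
        assert xbar @ pred.coef_["liver"] == pytest.approx(np.mean(liver_means))

    def test_zero_effect_cohort_reduces_to_constant_map(self):
        em = default_effect_model(voxel_noise_sd=0.02)
        em.sex_offset = {}
        em.fatmass_slope = {}
        em.uptaketime_slope = {}
        em.season_amplitude = {}
        cohort = simulate_cohort(25, seed=3, effect_model=em,
                                 shape=(48, 48, 80), spacing=SPACING)
        reg = OrganRegressionPredictor().fit(cohort)
        const = ConstantOrganMapPredictor().fit(cohort)
        means = reg.predict_organ_means(cohort[0].attributes)
        for organ in ("liver", "subcutaneous_fat", "skeletal_muscle"):
            assert means[organ] == pytest.approx(const.organ_map_[organ], abs=0.02)


class TestLesionInvariance:
    def test_prediction_identical_with_and_without_lesions(self, small_cohort):
        """The twin never sees the PET, so injected lesions cannot leak into
        the prediction."""
        study = small_cohort[0]
        spec = LesionSpec(count=(2, 2), radius_mm=(10.0, 10.0), contrast=(4.0, 4.0))
        pet2, lesion = inject_lesions(study.pet, study.organ_labels, spec, seed=4,
                                      body_mask=study.body_mask)
        lesioned = dataclasses.replace(study, pet=pet2, lesion_mask=lesion)
        for predictor in (ConstantOrganMapPredictor().fit(small_cohort[:10]),
                          OrganRegressionPredictor().fit(small_cohort)):
            a = predictor.predict(study)
            b = predictor.predict(lesioned)
            np.testing.assert_array_equal(a.data, b.data)


class TestOracleTwin:
    def test_matches_noise_free_render(self, small_study, effect_model):
        twin = OracleTwinPredictor(effect_model).fit().predict(small_study)
        from ntpet.phantom import organ_expected_suv

        mu = organ_expected_suv(small_study.attributes, effect_model)
        liver = small_study.organ_labels.data == DEFAULT_LABELS["liver"]
        assert np.allclose(twin.data[liver], mu["liver"])


class TestTrainConfig:
    def test_learning_rate_schedule_contract(self):
        cfg = TrainConfig()
        assert cfg.lr_at(0) == 1e-4
        assert cfg.lr_at(cfg.decay_step - 1) == 1e-4
        assert cfg.lr_at(cfg.decay_step) == 1e-5
        assert cfg.decay_step == int(0.625 * cfg.steps)


class TestConvTranslator:
    def test_smoke_training_halves_masked_l1(self):
        """A short run on a small homogeneous cohort must cut the masked L1
        to below half its starting level."""
        em = default_effect_model(voxel_noise_sd=0.02)
        cohort = simulate_cohort(4, seed=11, effect_model=em,
                                 shape=(28, 28, 40), spacing=(6.0, 6.0, 6.0))
        model = ConvTranslatorPredictor(
            patch_spec=PatchSpec(depth=8),
            train_config=TrainConfig(steps=300, lr=1e-2, lr_final=1e-3, seed=0),
        ).fit(cohort)
        hist = np.array(model.loss_history_)
        assert hist[-20:].mean() <= 0.5 * hist[:10].mean()
        twin = model.predict(cohort[0])
        assert twin.shape == cohort[0].pet.shape
        assert np.all(twin.data >= 0)

    def test_seed_reproducible(self):
        em = default_effect_model(voxel_noise_sd=0.02)
        cohort = simulate_cohort(2, seed=12, effect_model=em,
                                 shape=(28, 28, 40), spacing=(6.0, 6.0, 6.0))
        kwargs = dict(patch_spec=PatchSpec(depth=8),
                      train_config=TrainConfig(steps=30, lr=1e-2, lr_final=1e-3, seed=5))
        a = ConvTranslatorPredictor(**kwargs).fit(cohort).predict(cohort[0])
        b = ConvTranslatorPredictor(**kwargs).fit(cohort).predict(cohort[0])
        np.testing.assert_array_equal(a.data, b.data)


class TestSklearnProtocol:
    def test_get_set_params_roundtrip(self):
        pred = OrganRegressionPredictor(age_ref=50.0)
        params = pred.get_params()
        assert params["age_ref"] == 50.0
        pred.set_params(age_ref=65.0)
        assert pred.age_ref == 65.0

    def test_clone_compatible(self):
        from sklearn.base import clone

        pred = ConvTranslatorPredictor(channels=8, use_attributes=True)
        cloned = clone(pred)
        assert cloned.channels == 8 and cloned.use_attributes
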