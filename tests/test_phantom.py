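"""Phantom generator: attribute sampling, anatomy, rendering, lesions."""

import numpy as np
import pytest

from ntpet import Grid3D
from ntpet.labels import DEFAULT_LABELS
from ntpet.phantom import (
    LesionSpec,
    PhantomError,
    PopulationSpec,
    build_anatomy,
    fat_body_mass,
    inject_lesions,
    make_disease_mask,
    organ_expected_suv,
    render_ct,
    render_normal_pet,
    sample_attributes,
    simulate_study,
)

SHAPE = (48, 48, 80)
SPACING = (4.0, 4.0, 4.0)


class TestSampleAttributes:
    def test_marginal_age_matches_population(self):
        attrs = sample_attributes(1000, seed=0)
        ages = np.array([a.age for a in attrs])
        assert abs(ages.mean() - 60.5) < 2.0
        assert abs(ages.std() - 17.3) < 3.0

    def test_single_record_fully_populated(self):
        (a,) = sample_attributes(1, seed=123)
        assert a.sex in ("M", "F") and a.weight > 0 and 1 <= a.scan_day_of_year <= 365

    def test_deterministic_for_fixed_seed(self):
        assert sample_attributes(20, seed=9) == sample_attributes(20, seed=9)

    def test_negative_sd_rejected(self):
        with pytest.raises(PhantomError, match="negative SD"):
            sample_attributes(5, seed=0, population=PopulationSpec(age=(60.0, -1.0)))

    def test_n_zero_rejected(self):
        with pytest.raises(PhantomError):
            sample_attributes(0, seed=0)


class TestFatBodyMass:
    @pytest.mark.parametrize("sex,weight,height,expected", [
        ("M", 80.0, 1.80, 17.28),   # 80 - (1.1*80 - 128*(80/180)^2)
        ("F", 60.0, 1.65, 15.37),   # 60 - (1.07*60 - 148*(60/165)^2)
    ])
    def test_weight_minus_james_lbm(self, attrs_m, sex, weight, height, expected):
        import dataclasses
        a = dataclasses.replace(attrs_m, sex=sex, weight=weight, height=height)
        assert fat_body_mass(a) == pytest.approx(expected, abs=0.01)

    def test_floors_at_zero_with_warning(self, attrs_m):
        import dataclasses
        # extremely tall and light: James LBM exceeds weight
        a = dataclasses.replace(attrs_m, weight=30.0, height=2.05)
        with pytest.warns(UserWarning, match="flooring"):
            assert fat_body_mass(a) == 0.0


class TestBuildAnatomy:
    def test_all_organs_present(self, attrs_m):
        labels, body = build_anatomy(attrs_m, SHAPE, SPACING, seed=0)
        for organ, lab in DEFAULT_LABELS.items():
            assert np.any(labels.data == lab), organ
        assert np.all(body.data[labels.data > 0] == 1)

    def test_fat_shell_grows_with_weight(self, attrs_m):
        import dataclasses
        heavy = dataclasses.replace(attrs_m, weight=attrs_m.weight + 20)
        lab_a, _ = build_anatomy(attrs_m, SHAPE, SPACING, seed=0)
        lab_b, _ = build_anatomy(heavy, SHAPE, SPACING, seed=0)
        fat = DEFAULT_LABELS["subcutaneous_fat"]
        assert (lab_b.data == fat).sum() > (lab_a.data == fat).sum()

    def test_deterministic(self, attrs_m):
        a, _ = build_anatomy(attrs_m, SHAPE, SPACING, seed=3)
        b, _ = build_anatomy(attrs_m, SHAPE, SPACING, seed=3)
        np.testing.assert_array_equal(a.data, b.data)

    def test_too_small_grid_fails(self, attrs_m):
        with pytest.raises(PhantomError, match="too small"):
            build_anatomy(attrs_m, (8, 8, 8), SPACING, seed=0)


class TestRenderCT:
    def test_zero_noise_gives_exact_tissue_means(self, attrs_m, noise_free_model):
        labels, _ = build_anatomy(attrs_m, SHAPE, SPACING, seed=0)
        ct = render_ct(labels, noise_free_model, seed=0)
        for organ, lab in DEFAULT_LABELS.items():
            vals = ct.data[labels.data == lab]
            assert np.all(vals == noise_free_model.ct_mean[organ]), organ
        assert np.all(ct.data[labels.data == 0] == -1000.0)

    def test_unknown_label_fails(self, noise_free_model):
        bad = Grid3D(np.full((4, 4, 4), 99, dtype=np.int16), SPACING)
        with pytest.raises(PhantomError, match="label"):
            render_ct(bad, noise_free_model)


class TestRenderNormalPET:
    def test_zero_effects_zero_noise_gives_baselines(self, attrs_m, noise_free_model):
        em = noise_free_model
        em.sex_offset = {}
        em.fatmass_slope = {}
        em.uptaketime_slope = {}
        em.season_amplitude = {}
        labels, _ = build_anatomy(attrs_m, SHAPE, SPACING, seed=0)
        pet = render_normal_pet(labels, attrs_m, em, seed=0)
        for organ, lab in DEFAULT_LABELS.items():
            vals = pet.data[labels.data == lab]
            assert np.allclose(vals, em.baseline[organ]), organ

    def test_fatmass_slope_shifts_liver_linearly(self, attrs_m, noise_free_model):
        # -0.005 SUV/kg on the liver: 20 kg extra fat mass -> -0.1 SUV
        mu = organ_expected_suv(attrs_m, noise_free_model)
        fbm = fat_body_mass(attrs_m)
        base = (noise_free_model.baseline["liver"]
                + noise_free_model.uptaketime_slope["liver"]
                * (attrs_m.uptake_time - noise_free_model.uptake_ref))
        assert mu["liver"] == pytest.approx(base - 0.005 * fbm, abs=1e-9)

    def test_seasonal_peak_to_trough_is_twice_amplitude(self, attrs_m, noise_free_model):
        import dataclasses
        at_phase = dataclasses.replace(attrs_m, scan_day_of_year=15)
        opposite = dataclasses.replace(attrs_m, scan_day_of_year=15 + 183)
        mu_a = organ_expected_suv(at_phase, noise_free_model)
        mu_b = organ_expected_suv(opposite, noise_free_model)
        diff = mu_a["subcutaneous_fat"] - mu_b["subcutaneous_fat"]
        assert diff == pytest.approx(2 * 0.2, abs=1e-3)

    def test_negative_expectation_warns_and_clamps(self, attrs_m, noise_free_model):
        noise_free_model.fatmass_slope["subcutaneous_fat"] = -1.0  # drives SUV < 0
        labels, _ = build_anatomy(attrs_m, SHAPE, SPACING, seed=0)
        with pytest.warns(UserWarning, match="negative expected SUV"):
            pet = render_normal_pet(labels, attrs_m, noise_free_model, seed=0)
        assert np.all(pet.data >= 0)


class TestInjectLesions:
    def test_zero_count_is_identity(self, attrs_m, noise_free_model):
        labels, body = build_anatomy(attrs_m, SHAPE, SPACING, seed=0)
        pet = render_normal_pet(labels, attrs_m, noise_free_model, seed=0)
        spec = LesionSpec(count=(0, 0))
        pet2, mask = inject_lesions(pet, labels, spec, seed=0, body_mask=body)
        np.testing.assert_array_equal(pet.data, pet2.data)
        assert mask.data.sum() == 0

    def test_contrast_added_exactly_inside_mask_only(self, attrs_m, noise_free_model):
        labels, body = build_anatomy(attrs_m, SHAPE, SPACING, seed=0)
        pet = render_normal_pet(labels, attrs_m, noise_free_model, seed=0)
        spec = LesionSpec(count=(1, 1), radius_mm=(10.0, 10.0), contrast=(4.0, 4.0))
        pet2, mask = inject_lesions(pet, labels, spec, seed=1, body_mask=body)
        m = mask.data.astype(bool)
        assert m.sum() > 0
        np.testing.assert_allclose(pet2.data[m] - pet.data[m], 4.0)
        np.testing.assert_array_equal(pet2.data[~m], pet.data[~m])
        assert not np.any(m & ~body.data.astype(bool))

    def test_impossible_placement_fails(self, attrs_m, noise_free_model):
        labels, body = build_anatomy(attrs_m, SHAPE, SPACING, seed=0)
        pet = render_normal_pet(labels, attrs_m, noise_free_model, seed=0)
        spec = LesionSpec(count=(1, 1), radius_mm=(500.0, 500.0), contrast=(4.0, 4.0))
        with pytest.raises(PhantomError, match="no room"):
            inject_lesions(pet, labels, spec, seed=0, body_mask=body)

    def test_missing_allowed_organ_fails(self, attrs_m, noise_free_model):
        labels, body = build_anatomy(attrs_m, SHAPE, SPACING, seed=0)
        pet = render_normal_pet(labels, attrs_m, noise_free_model, seed=0)
        spec = LesionSpec(allowed_organs=("pancreas",))
        with pytest.raises(PhantomError, match="absent"):
            inject_lesions(pet, labels, spec, seed=0, body_mask=body)


class TestDiseaseMask:
    def test_zero_expansion_is_identity(self):
        rng = np.random.default_rng(0)
        mask = Grid3D((rng.random((10, 10, 6)) > 0.9).astype(np.uint8), SPACING)
        out = make_disease_mask(mask, 0.0)
        np.testing.assert_array_equal(out.data, mask.data)

    def test_single_voxel_becomes_in_plane_block(self):
        data = np.zeros((9, 9, 5), dtype=np.uint8)
        data[4, 4, 2] = 1
        out = make_disease_mask(Grid3D(data, SPACING), expansion_mm=2 * SPACING[0])
        assert out.data.sum() == 25  # 5 x 5 x 1
        assert np.all(out.data[:, :, [0, 1, 3, 4]] == 0)

    def test_matches_bruteforce_dilation(self):
        rng = np.random.default_rng(1)
        data = (rng.random((12, 12, 7)) > 0.93).astype(np.uint8)
        r = 1  # expansion of one voxel per in-plane axis
        out = make_disease_mask(Grid3D(data, SPACING), expansion_mm=SPACING[0])
        expected = np.zeros_like(data)
        for x, y, z in np.argwhere(data):
            expected[max(0, x - r):x + r + 1, max(0, y - r):y + r + 1, z] = 1
        np.testing.assert_array_equal(out.data, expected)

    def test_empty_input_empty_output(self):
        out = make_disease_mask(Grid3D(np.zeros((6, 6, 6), np.uint8), SPACING), 8.0)
        assert out.data.sum() == 0


class TestSimulateStudy:
    def test_confined_lesions_stay_inside_allowed_organs(self, attrs_m, effect_model):
        spec = LesionSpec(count=(1, 1), radius_mm=(6.0, 6.0), contrast=(4.0, 4.0),
                          allowed_organs=("brain",), confine_to_organs=True,
                          margin_mm=4.0)
        study = simulate_study(attrs_m, effect_model, spec, SHAPE, SPACING, seed=2)
        brain = study.organ_labels.data == DEFAULT_LABELS["brain"]
        assert np.all(brain[study.lesion_mask.data.astype(bool)])

    def test_cohort_reproducible(self, attrs_m, effect_model):
        a = simulate_study(attrs_m, effect_model, None, SHAPE, SPACING, seed=9)
        b = simulate_study(attrs_m, effect_model, None, SHAPE, SPACING, seed=9)
        np.testing.assert_array_equal(a.pet.data, b.pet.data)
        np.testing.assert_array_equal(a.ct.data, b.ct.data)
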