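import numpy as np
import pytest

from ntpet import (
    EffectModel,
    Grid3D,
    LesionSpec,
    StudyAttributes,
    default_effect_model,
    simulate_cohort,
    simulate_study,
)

SMALL_SHAPE = (48, 48, 80)
SMALL_SPACING = (4.0, 4.0, 4.0)


@pytest.fixture
def attrs_m():
    return StudyAttributes(
        sex="M", age=60.0, weight=80.0, height=1.80, injected_activity=256.0,
        scanner_model="vision_quadra", uptake_time=63.0, scan_time_of_day=10.0,
        scan_day_of_year=100,
    )


@pytest.fixture
def attrs_f():
    return StudyAttributes(
        sex="F", age=55.0, weight=60.0, height=1.65, injected_activity=200.0,
        scanner_model="mct_flow", uptake_time=60.0, scan_time_of_day=14.0,
        scan_day_of_year=220,
    )


@pytest.fixture
def effect_model():
    return default_effect_model()


@pytest.fixture
def noise_free_model():
    em = default_effect_model(voxel_noise_sd=0.0)
    em.ct_sd = {organ: 0.0 for organ in em.ct_sd}
    return em


@pytest.fixture
def small_study(attrs_m, effect_model):
    return simulate_study(attrs_m, effect_model, shape=SMALL_SHAPE,
                          spacing=SMALL_SPACING, seed=5, study_id="small")


@pytest.fixture
def lesioned_study(attrs_m, effect_model):
    spec = LesionSpec(count=(2, 2), radius_mm=(10.0, 10.0), contrast=(4.0, 4.0))
    return simulate_study(attrs_m, effect_model, lesion_spec=spec,
                          shape=SMALL_SHAPE, spacing=SMALL_SPACING, seed=6,
                          study_id="lesioned")


@pytest.fixture(scope="session")
def small_cohort():
    """Shared lesion-free cohort for predictor/correction tests."""
    return simulate_cohort(30, seed=42, shape=SMALL_SHAPE, spacing=SMALL_SPACING)
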