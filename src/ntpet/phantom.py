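"""Digital whole-body PET/CT phantoms with known covariate effects.

The generator produces a cohort of synthetic "studies" that mimic the
statistical structure of a pseudo-normal FDG PET/CT population: procedural
anatomy (fat, muscle, organs) whose subcutaneous-fat compartment scales with
the patient's fat body mass, a CT volume with per-tissue Hounsfield means, a
PET volume whose per-organ mean uptake follows an additive linear model in
the study attributes (sex, age, fat body mass, uptake time, season), and
optional focal high-uptake lesions standing in for metabolically active
disease.

Every covariate effect is injected explicitly through :class:`EffectModel`,
so downstream stages (twin prediction, twin correction, anomaly detection)
can be validated against exact ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import Grid3D, GridError
from .labels import BACKGROUND, DEFAULT_LABELS, invert

__all__ = [
    "StudyAttributes",
    "PopulationSpec",
    "EffectModel",
    "LesionSpec",
    "Study",
    "PhantomError",
    "sample_attributes",
    "build_anatomy",
    "render_ct",
    "render_normal_pet",
    "organ_expected_suv",
    "inject_lesions",
    "apply_lesions_to_ct",
    "make_disease_mask",
    "fat_body_mass",
    "default_effect_model",
    "simulate_study",
    "simulate_cohort",
]

SEASON_DAYS = 365.0


class PhantomError(ValueError):
    """Raised for invalid phantom parameters or impossible geometry."""


# ---------------------------------------------------------------------------
# attributes


@dataclass
class StudyAttributes:
    """One examination's demographic and acquisition covariates.

    Units: age in years, weight in kg, height in m, injected_activity in MBq,
    uptake_time in minutes, scan_time_of_day in hours [0, 24), and
    scan_day_of_year an integer in [1, 365].
    """

    sex: str
    age: float
    weight: float
    height: float
    injected_activity: float
    scanner_model: str
    uptake_time: float
    scan_time_of_day: float
    scan_day_of_year: int

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise PhantomError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.weight <= 0:
            raise PhantomError(f"weight must be positive, got {self.weight}")
        if self.height <= 0:
            raise PhantomError(f"height must be positive, got {self.height}")
        if self.injected_activity <= 0:
            raise PhantomError("injected_activity must be positive")
        if self.uptake_time <= 0:
            raise PhantomError("uptake_time must be positive")
        if not 0 <= self.scan_time_of_day < 24:
            raise PhantomError("scan_time_of_day must lie in [0, 24)")
        self.scan_day_of_year = int(self.scan_day_of_year)
        if not 1 <= self.scan_day_of_year <= 365:
            raise PhantomError("scan_day_of_year must lie in [1, 365]")


@dataclass
class PopulationSpec:
    """Marginal distributions for attribute sampling.

    Defaults emulate a large clinical lymphoma/oncology referral population:
    age 60.5 +- 17.3 years, injected activity 256 +- 66 MBq, uptake time
    around 63 minutes, and a four-scanner site mix.  Continuous attributes
    are sampled from clipped normals; ``sex`` is Bernoulli with male
    probability ``p_male``.
    """

    p_male: float = 0.58
    age: tuple[float, float] = (60.5, 17.3)
    weight_m: tuple[float, float] = (82.0, 13.0)
    weight_f: tuple[float, float] = (70.0, 14.0)
    height_m: tuple[float, float] = (1.78, 0.07)
    height_f: tuple[float, float] = (1.64, 0.07)
    injected_activity: tuple[float, float] = (256.0, 66.0)
    uptake_time: tuple[float, float] = (63.0, 6.0)
    scan_time_of_day: tuple[float, float] = (7.0, 17.0)  # uniform window
    scanner_models: dict[str, float] = field(
        default_factory=lambda: {
            "vision_quadra": 0.44,
            "vision_600": 0.17,
            "mct_flow": 0.33,
            "truepoint": 0.06,
        }
    )

    def validate(self) -> None:
        for name in ("age", "weight_m", "weight_f", "height_m", "height_f",
                     "injected_activity", "uptake_time"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise PhantomError(f"{name}: negative SD {sd}")
        if not 0 <= self.p_male <= 1:
            raise PhantomError("p_male must lie in [0, 1]")
        total = sum(self.scanner_models.values())
        if total <= 0:
            raise PhantomError("scanner_models probabilities must sum > 0")


_CLIPS = {
    "age": (18.0, 95.0),
    "weight": (40.0, 160.0),
    "height": (1.40, 2.05),
    "injected_activity": (50.0, 600.0),
    "uptake_time": (30.0, 120.0),
}


def _clipped_normal(rng: np.random.Generator, mean: float, sd: float,
                    lo: float, hi: float, size: int) -> np.ndarray:
    return np.clip(rng.normal(mean, sd, size), lo, hi)


def sample_attributes(
    n: int,
    seed: int,
    population: PopulationSpec | None = None,
) -> list[StudyAttributes]:
    """Draw ``n`` attribute records from the population distribution."""
    if n < 1:
        raise PhantomError(f"n must be >= 1, got {n}")
    pop = population or PopulationSpec()
    pop.validate()
    rng = np.random.default_rng(seed)

    male = rng.random(n) < pop.p_male
    age = _clipped_normal(rng, *pop.age, *_CLIPS["age"], n)
    weight = np.where(
        male,
        _clipped_normal(rng, *pop.weight_m, *_CLIPS["weight"], n),
        _clipped_normal(rng, *pop.weight_f, *_CLIPS["weight"], n),
    )
    height = np.where(
        male,
        _clipped_normal(rng, *pop.height_m, *_CLIPS["height"], n),
        _clipped_normal(rng, *pop.height_f, *_CLIPS["height"], n),
    )
    activity = _clipped_normal(rng, *pop.injected_activity, *_CLIPS["injected_activity"], n)
    uptake = _clipped_normal(rng, *pop.uptake_time, *_CLIPS["uptake_time"], n)
    lo, hi = pop.scan_time_of_day
    tod = rng.uniform(lo, hi, n)
    day = rng.integers(1, 366, n)
    models = list(pop.scanner_models)
    probs = np.array([pop.scanner_models[m] for m in models], dtype=float)
    probs /= probs.sum()
    scanner = rng.choice(models, size=n, p=probs)

    return [
        StudyAttributes(
            sex="M" if male[i] else "F",
            age=float(age[i]),
            weight=float(weight[i]),
            height=float(height[i]),
            injected_activity=float(activity[i]),
            scanner_model=str(scanner[i]),
            uptake_time=float(uptake[i]),
            scan_time_of_day=float(tod[i]),
            scan_day_of_year=int(day[i]),
        )
        for i in range(n)
    ]


def fat_body_mass(attributes: StudyAttributes) -> float:
    """Fat body mass in kg: total weight minus James lean body mass.

    Floored at 0 with a warning for implausibly lean inputs.
    """
    from .twin_correction import lean_body_mass  # one-way dependency

    fbm = attributes.weight - lean_body_mass(
        attributes.sex, attributes.weight, attributes.height
    )
    if fbm < 0:
        warnings.warn(
            f"fat body mass {fbm:.2f} kg < 0 for weight={attributes.weight}, "
            f"height={attributes.height}; flooring at 0",
            stacklevel=2,
        )
        return 0.0
    return float(fbm)


# ---------------------------------------------------------------------------
# effect model


def _zero_map() -> dict[str, float]:
    return {}


@dataclass
class EffectModel:
    """Additive linear model for per-organ mean SUV plus CT tissue statistics.

    The expected SUV of organ *o* for a study with attributes *a* is::

        baseline[o] + sex_offset[o] * 1[a.sex == F]
                    + age_slope[o] * (a.age - age_ref)
                    + fatmass_slope[o] * fat_body_mass(a)
                    + uptaketime_slope[o] * (a.uptake_time - uptake_ref)
                    + season_amplitude[o] * cos(2*pi*(day - season_phase_day)/365)

    Voxel values add zero-mean Gaussian noise with SD ``voxel_noise_sd`` and
    are clamped at 0.  CT voxels are ``ct_mean[o]`` plus Gaussian noise of
    SD ``ct_sd[o]``; air outside the body is -1000 HU.
    """

    baseline: dict[str, float]
    sex_offset: dict[str, float] = field(default_factory=_zero_map)
    age_slope: dict[str, float] = field(default_factory=_zero_map)
    fatmass_slope: dict[str, float] = field(default_factory=_zero_map)
    uptaketime_slope: dict[str, float] = field(default_factory=_zero_map)
    season_amplitude: dict[str, float] = field(default_factory=_zero_map)
    season_phase_day: float = 15.0
    age_ref: float = 60.0
    uptake_ref: float = 63.0
    voxel_noise_sd: float = 0.05
    ct_mean: dict[str, float] = field(default_factory=_zero_map)
    ct_sd: dict[str, float] = field(default_factory=_zero_map)
    labels: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_LABELS))

    def __post_init__(self) -> None:
        if self.voxel_noise_sd < 0:
            raise PhantomError("voxel_noise_sd must be >= 0")
        for organ, b in self.baseline.items():
            if b < 0:
                raise PhantomError(f"baseline SUV for {organ} must be >= 0")


def default_effect_model(voxel_noise_sd: float = 0.05) -> EffectModel:
    """The study-condition effect model used throughout the package.

    Injected effects: a +0.3 SUV female offset and a 0.2 SUV winter-peaked
    seasonal amplitude on both fat compartments, a -0.005 SUV/kg fat-body-mass
    slope and a -0.01 SUV/min uptake-time slope on the liver.
    """
    return EffectModel(
        baseline={
            "subcutaneous_fat": 0.35,
            "visceral_fat": 0.45,
            "skeletal_muscle": 0.70,
            "liver": 2.2,
            "aorta": 1.7,
            "kidneys": 2.5,
            "heart": 3.0,
            "bladder": 8.0,
            "brain": 6.0,
            "small_intestine": 1.8,
            "large_intestine": 1.5,
            "bone": 0.9,
        },
        sex_offset={"subcutaneous_fat": 0.3, "visceral_fat": 0.3},
        fatmass_slope={"liver": -0.005},
        uptaketime_slope={"liver": -0.01},
        season_amplitude={"subcutaneous_fat": 0.2, "visceral_fat": 0.2},
        voxel_noise_sd=voxel_noise_sd,
        ct_mean={
            "subcutaneous_fat": -100.0,
            "visceral_fat": -90.0,
            "skeletal_muscle": 45.0,
            "liver": 55.0,
            "aorta": 45.0,
            "kidneys": 40.0,
            "heart": 40.0,
            "bladder": 0.0,
            "brain": 35.0,
            "small_intestine": 25.0,
            "large_intestine": 15.0,
            "bone": 400.0,
        },
        ct_sd={organ: 15.0 for organ in DEFAULT_LABELS},
    )


def organ_expected_suv(
    attributes: StudyAttributes, effect_model: EffectModel
) -> dict[str, float]:
    """Noise-free expected mean SUV per organ for one study (before clamping)."""
    em = effect_model
    fbm = fat_body_mass(attributes)
    is_f = 1.0 if attributes.sex == "F" else 0.0
    season = np.cos(
        2.0 * np.pi * (attributes.scan_day_of_year - em.season_phase_day) / SEASON_DAYS
    )
    out: dict[str, float] = {}
    for organ, base in em.baseline.items():
        mu = (
            base
            + em.sex_offset.get(organ, 0.0) * is_f
            + em.age_slope.get(organ, 0.0) * (attributes.age - em.age_ref)
            + em.fatmass_slope.get(organ, 0.0) * fbm
            + em.uptaketime_slope.get(organ, 0.0) * (attributes.uptake_time - em.uptake_ref)
            + em.season_amplitude.get(organ, 0.0) * float(season)
        )
        out[organ] = float(mu)
    return out


# ---------------------------------------------------------------------------
# anatomy

#: organs that must be present in every generated label map
_REQUIRED_ORGANS = tuple(DEFAULT_LABELS)


def build_anatomy(
    attributes: StudyAttributes,
    shape: tuple[int, int, int] = (96, 96, 160),
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0),
    seed: int = 0,
) -> tuple[Grid3D, Grid3D]:
    """Procedural body: elliptical torso with fat/muscle shells, organs, head.

    The subcutaneous-fat shell thickness grows monotonically with the
    patient's fat body mass, so body composition is encoded in the anatomy.
    Returns ``(organ_labels, body_mask)``.  Raises :class:`PhantomError` when
    the grid is too small to place every organ.
    """
    nx, ny, nz = shape
    if min(nx, ny) < 24 or nz < 40:
        raise PhantomError(f"grid {shape} too small to place all organs (need >=24x24x40)")
    if any(s <= 0 for s in spacing):
        raise PhantomError("spacing must be positive")

    fbm = fat_body_mass(attributes)
    L = DEFAULT_LABELS

    xi, yi, zi = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0

    z0 = int(round(0.04 * nz))
    z1 = int(round(0.72 * nz))
    zspan = z1 - z0
    rx, ry = 0.42 * nx, 0.36 * ny
    e = np.sqrt(((xi - cx) / rx) ** 2 + ((yi - cy) / ry) ** 2)
    in_torso_z = (zi >= z0) & (zi < z1)
    torso = (e <= 1.0) & in_torso_z

    # subcutaneous fat shell: thickness (as a fraction of the torso radius)
    # increases with fat body mass
    fat_frac = float(np.clip(0.05 + 0.005 * fbm, 0.04, 0.30))
    muscle_frac = 0.12
    subq = torso & (e > 1.0 - fat_frac)
    muscle = torso & (e <= 1.0 - fat_frac) & (e > 1.0 - fat_frac - muscle_frac)
    interior = torso & (e <= 1.0 - fat_frac - muscle_frac)

    labels = np.zeros(shape, dtype=np.int16)
    labels[subq] = L["subcutaneous_fat"]
    labels[muscle] = L["skeletal_muscle"]
    labels[interior] = L["visceral_fat"]

    def ellipsoid(xc, yc, zc, ax, ay, az):
        return (
            ((xi - xc) / max(ax, 0.75)) ** 2
            + ((yi - yc) / max(ay, 0.75)) ** 2
            + ((zi - zc) / max(az, 0.75)) ** 2
        ) <= 1.0

    # organ ellipsoids in torso-relative coordinates; painted inside the
    # visceral interior so anatomy stays nested for any fat fraction
    organs = {
        "small_intestine": ellipsoid(cx - 0.05 * nx, cy - 0.08 * ny, z0 + 0.30 * zspan,
                                     0.11 * nx, 0.09 * ny, 0.09 * zspan),
        "large_intestine": ellipsoid(cx + 0.10 * nx, cy + 0.03 * ny, z0 + 0.28 * zspan,
                                     0.08 * nx, 0.07 * ny, 0.08 * zspan),
        "liver": ellipsoid(cx + 0.12 * nx, cy - 0.02 * ny, z0 + 0.60 * zspan,
                           0.13 * nx, 0.12 * ny, 0.10 * zspan),
        "heart": ellipsoid(cx - 0.08 * nx, cy - 0.05 * ny, z0 + 0.72 * zspan,
                           0.09 * nx, 0.09 * ny, 0.06 * zspan),
        "kidneys": (
            ellipsoid(cx - 0.14 * nx, cy + 0.12 * ny, z0 + 0.48 * zspan,
                      0.055 * nx, 0.055 * ny, 0.06 * zspan)
            | ellipsoid(cx + 0.14 * nx, cy + 0.12 * ny, z0 + 0.48 * zspan,
                        0.055 * nx, 0.055 * ny, 0.06 * zspan)
        ),
        "bladder": ellipsoid(cx, cy + 0.02 * ny, z0 + 0.12 * zspan,
                             0.07 * nx, 0.07 * ny, 0.05 * zspan),
    }
    for organ, mask in organs.items():
        labels[mask & interior] = L[organ]

    # aorta: thin anterior-of-spine cylinder over the upper torso
    r_aorta = max(1.0, 0.035 * min(nx, ny))
    aorta = (
        (((xi - cx) ** 2 + (yi - (cy + 0.10 * ny)) ** 2) <= r_aorta**2)
        & (zi >= z0 + 0.35 * zspan)
        & (zi < z1)
    )
    labels[aorta & interior] = L["aorta"]

    # spine: posterior bone column spanning the torso
    r_spine = max(1.0, 0.05 * min(nx, ny))
    spine = (
        (((xi - cx) ** 2 + (yi - (cy + 0.20 * ny)) ** 2) <= r_spine**2) & in_torso_z
    )
    labels[spine & interior] = L["bone"]

    # head: skull shell around the brain, joined to the torso by a neck so
    # the body is one connected component
    rh = min(0.29 * min(nx, ny), 0.12 * nz)
    zh = 0.85 * nz
    head = ((xi - cx) ** 2 + (yi - cy) ** 2 + (zi - zh) ** 2) <= rh**2
    inner = ((xi - cx) ** 2 + (yi - cy) ** 2 + (zi - zh) ** 2) <= (0.75 * rh) ** 2
    labels[head] = L["bone"]
    labels[inner] = L["brain"]

    r_neck = max(1.5, 0.10 * min(nx, ny))
    neck = (
        (((xi - cx) ** 2 + (yi - cy) ** 2) <= r_neck**2)
        & (zi >= z1) & (zi <= zh)
    ) & ~head
    labels[neck] = L["skeletal_muscle"]

    body = torso | head | neck
    missing = [o for o in _REQUIRED_ORGANS if not np.any(labels == L[o])]
    if missing:
        raise PhantomError(f"grid {shape} too small: could not place {missing}")

    organ_labels = Grid3D(labels, spacing)
    body_mask = Grid3D(body.astype(np.uint8), spacing)
    return organ_labels, body_mask


# ---------------------------------------------------------------------------
# rendering


def _label_lookup(values: dict[str, float], label_map: dict[str, int],
                  default: float, n_labels: int) -> np.ndarray:
    table = np.full(n_labels, default, dtype=np.float64)
    for organ, value in values.items():
        if organ not in label_map:
            raise PhantomError(f"unknown organ {organ!r} in effect model")
        table[label_map[organ]] = value
    return table


def render_ct(
    organ_labels: Grid3D, effect_model: EffectModel, seed: int = 0
) -> Grid3D:
    """CT volume: per-tissue HU mean plus Gaussian noise; air at -1000 HU."""
    labels = organ_labels.data
    present = np.unique(labels)
    name_of = invert(effect_model.labels)
    for lab in present:
        if lab == BACKGROUND:
            continue
        organ = name_of.get(int(lab))
        if organ is None or organ not in effect_model.ct_mean:
            raise PhantomError(f"no CT mean for label {lab} ({organ})")
    n_labels = int(labels.max()) + 1
    mean = _label_lookup(effect_model.ct_mean, effect_model.labels, -1000.0, n_labels)
    sd = _label_lookup(effect_model.ct_sd, effect_model.labels, 0.0, n_labels)
    rng = np.random.default_rng(seed)
    ct = mean[labels] + rng.standard_normal(labels.shape) * sd[labels]
    ct[labels == BACKGROUND] = -1000.0
    return organ_labels.like(ct)


def render_normal_pet(
    organ_labels: Grid3D,
    attributes: StudyAttributes,
    effect_model: EffectModel,
    seed: int = 0,
) -> Grid3D:
    """Normal (lesion-free) PET volume under the additive effect model.

    Voxel values are the organ's expected SUV plus Gaussian noise, clamped at
    zero.  A negative pre-clamp expectation triggers a warning.
    """
    labels = organ_labels.data
    mu = organ_expected_suv(attributes, effect_model)
    negative = [o for o, v in mu.items() if v < 0]
    if negative:
        warnings.warn(
            f"negative expected SUV clamped to 0 for organs {negative}", stacklevel=2
        )
        mu = {o: max(v, 0.0) for o, v in mu.items()}
    n_labels = int(labels.max()) + 1
    table = _label_lookup(mu, effect_model.labels, 0.0, n_labels)
    rng = np.random.default_rng(seed)
    pet = table[labels]
    if effect_model.voxel_noise_sd > 0:
        pet = pet + rng.standard_normal(labels.shape) * effect_model.voxel_noise_sd
    pet[labels == BACKGROUND] = 0.0
    return organ_labels.like(np.maximum(pet, 0.0))


# ---------------------------------------------------------------------------
# lesions


@dataclass
class LesionSpec:
    """Focal spherical high-uptake lesions.

    ``contrast`` is added on top of the local background SUV; ``ct_hu`` is the
    absolute Hounsfield value lesion tissue takes in the CT (dense soft
    tissue, so lesions are CT-discernible as real malignancies are).
    """

    count: tuple[int, int] = (1, 3)
    radius_mm: tuple[float, float] = (8.0, 15.0)
    contrast: tuple[float, float] = (3.0, 6.0)
    allowed_organs: tuple[str, ...] = ("liver", "visceral_fat")
    ct_hu: float = 150.0
    #: when True, the whole sphere plus ``margin_mm`` must lie inside the
    #: allowed organs (not merely inside the body)
    confine_to_organs: bool = False
    margin_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.radius_mm[0] <= 0:
            raise PhantomError("lesion radius must be positive")
        if self.contrast[0] <= 0:
            raise PhantomError("lesion contrast must be positive")


def inject_lesions(
    pet: Grid3D,
    organ_labels: Grid3D,
    spec: LesionSpec,
    seed: int = 0,
    body_mask: Grid3D | None = None,
    label_map: dict[str, int] | None = None,
) -> tuple[Grid3D, Grid3D]:
    """Add spherical lesions to a PET volume.

    Returns ``(pet_with_lesions, lesion_mask)``.  Lesion centres are sampled
    uniformly from the allowed organs' voxels; the whole sphere must lie
    inside the body.  Exactly the masked voxels are modified.
    """
    pet.assert_congruent(organ_labels, "pet/labels")
    label_map = label_map or DEFAULT_LABELS
    labels = organ_labels.data
    body = (labels != BACKGROUND) if body_mask is None else body_mask.data.astype(bool)
    rng = np.random.default_rng(seed)

    missing = [o for o in spec.allowed_organs if o not in label_map
               or not np.any(labels == label_map[o])]
    if missing:
        raise PhantomError(f"allowed organs absent from label map: {missing}")

    allowed = np.isin(labels, [label_map[o] for o in spec.allowed_organs])
    cand = np.argwhere(allowed)
    n = int(rng.integers(spec.count[0], spec.count[1] + 1))
    out = pet.data.astype(np.float64).copy()
    lesion = np.zeros(pet.shape, dtype=bool)
    if n == 0:
        return pet.like(out), pet.like(lesion.astype(np.uint8))

    xi, yi, zi = np.meshgrid(*(np.arange(s) for s in pet.shape), indexing="ij")
    sp = np.asarray(pet.spacing)
    placed = 0
    for _ in range(200 * n):
        if placed == n:
            break
        centre = cand[rng.integers(len(cand))]
        radius = rng.uniform(*spec.radius_mm)
        contrast = rng.uniform(*spec.contrast)
        dist2 = (
            ((xi - centre[0]) * sp[0]) ** 2
            + ((yi - centre[1]) * sp[1]) ** 2
            + ((zi - centre[2]) * sp[2]) ** 2
        )
        sphere = dist2 <= radius**2
        if not sphere.any() or np.any(sphere & ~body) or np.any(sphere & lesion):
            continue
        if spec.confine_to_organs:
            halo = dist2 <= (radius + spec.margin_mm) ** 2
            if np.any(halo & ~allowed):
                continue
        out[sphere] += contrast
        lesion |= sphere
        placed += 1
    if placed < n:
        raise PhantomError(
            f"placed only {placed}/{n} lesions: no room for radius range "
            f"{spec.radius_mm} mm inside organs {spec.allowed_organs}"
        )
    return pet.like(out), pet.like(lesion.astype(np.uint8))


def apply_lesions_to_ct(ct: Grid3D, lesion_mask: Grid3D, ct_hu: float = 150.0,
                        noise_sd: float = 15.0, seed: int = 0) -> Grid3D:
    """Overwrite lesion voxels in the CT with dense soft-tissue HU."""
    ct.assert_congruent(lesion_mask, "ct/lesion_mask")
    rng = np.random.default_rng(seed)
    out = ct.data.astype(np.float64).copy()
    mask = lesion_mask.data.astype(bool)
    out[mask] = ct_hu + rng.standard_normal(int(mask.sum())) * noise_sd
    return ct.like(out)


def make_disease_mask(lesion_mask: Grid3D, expansion_mm: float) -> Grid3D:
    """Coarse exclusion mask: lesions dilated only along the two in-plane axes.

    Mimics MIP-delineated disease masks expanded antero-posteriorly and
    latero-medially but not cranio-caudally.
    """
    if expansion_mm < 0:
        raise PhantomError("expansion_mm must be >= 0")
    mask = lesion_mask.data.astype(bool)
    rx = int(round(expansion_mm / lesion_mask.spacing[0]))
    ry = int(round(expansion_mm / lesion_mask.spacing[1]))
    if (rx == 0 and ry == 0) or not mask.any():
        return lesion_mask.like(mask.astype(np.uint8))
    structure = np.ones((2 * rx + 1, 2 * ry + 1, 1), dtype=bool)
    out = ndimage.binary_dilation(mask, structure=structure)
    return lesion_mask.like(out.astype(np.uint8))


# ---------------------------------------------------------------------------
# study assembly


@dataclass
class Study:
    """One synthetic examination with ground truth."""

    id: str
    ct: Grid3D
    pet: Grid3D
    body_mask: Grid3D
    organ_labels: Grid3D
    attributes: StudyAttributes
    exclusion_mask: Grid3D | None = None
    lesion_mask: Grid3D | None = None

    def __post_init__(self) -> None:
        for name in ("pet", "body_mask", "organ_labels"):
            self.ct.assert_congruent(getattr(self, name), f"ct/{name}")
        body = self.body_mask.data.astype(bool)
        if np.any((self.organ_labels.data != BACKGROUND) & ~body):
            raise GridError(f"study {self.id}: organ labels outside body mask")
        if self.lesion_mask is not None:
            self.ct.assert_congruent(self.lesion_mask, "ct/lesion_mask")
            if np.any(self.lesion_mask.data.astype(bool) & ~body):
                raise GridError(f"study {self.id}: lesion mask outside body mask")
        if self.exclusion_mask is not None:
            self.ct.assert_congruent(self.exclusion_mask, "ct/exclusion_mask")


def simulate_study(
    attributes: StudyAttributes,
    effect_model: EffectModel | None = None,
    lesion_spec: LesionSpec | None = None,
    shape: tuple[int, int, int] = (96, 96, 160),
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0),
    seed: int = 0,
    study_id: str = "study",
    exclusion_expansion_mm: float = 8.0,
) -> Study:
    """Full single-study simulation: anatomy, CT, PET, optional lesions.

    When ``lesion_spec`` is given, lesions are injected into the PET, written
    into the CT at ``lesion_spec.ct_hu``, and an in-plane-expanded disease
    exclusion mask is attached.
    """
    em = effect_model or default_effect_model()
    ss = np.random.SeedSequence([seed, 0x5EED])
    s_anat, s_ct, s_pet, s_les = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4))

    organ_labels, body_mask = build_anatomy(attributes, shape, spacing, seed=s_anat)
    ct = render_ct(organ_labels, em, seed=s_ct)
    pet = render_normal_pet(organ_labels, attributes, em, seed=s_pet)

    lesion_mask = None
    exclusion = None
    if lesion_spec is not None:
        pet, lesion_mask = inject_lesions(
            pet, organ_labels, lesion_spec, seed=s_les, body_mask=body_mask,
            label_map=em.labels,
        )
        ct = apply_lesions_to_ct(ct, lesion_mask, ct_hu=lesion_spec.ct_hu, seed=s_les)
        exclusion = make_disease_mask(lesion_mask, exclusion_expansion_mm)

    return Study(
        id=study_id,
        ct=ct,
        pet=pet,
        body_mask=body_mask,
        organ_labels=organ_labels,
        attributes=attributes,
        exclusion_mask=exclusion,
        lesion_mask=lesion_mask,
    )


def simulate_cohort(
    n: int,
    seed: int,
    effect_model: EffectModel | None = None,
    lesion_spec: LesionSpec | None = None,
    population: PopulationSpec | None = None,
    shape: tuple[int, int, int] = (96, 96, 160),
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0),
    **kwargs,
) -> list[Study]:
    """Simulate ``n`` independent studies with a shared effect model."""
    em = effect_model or default_effect_model()
    attrs = sample_attributes(n, seed=seed, population=population)
    seeds = np.random.SeedSequence([seed, 0xC0C0]).generate_state(n) % (2**31)
    return [
        simulate_study(
            attrs[i], em, lesion_spec, shape, spacing,
            seed=int(seeds[i]), study_id=f"phantom_{i:04d}", **kwargs,
        )
        for i in range(n)
    ]
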