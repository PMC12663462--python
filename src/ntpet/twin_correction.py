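"""Twin correction of organ SUV measurements and the covariate test battery.

The twin correction removes predictable patient-specific effects from organ
SUVmean measurements by subtracting the normal-twin prediction::

    tcSUV_mean = SUV_mean - ntSUV_mean + C

where ``C`` is a population-wide per-organ average ntSUVmean included only
so corrected values stay on the familiar SUV scale — it changes neither
variances nor test statistics.  The construction is the imaging analogue of
the CUPED covariate-adjustment estimator from A/B testing: when the twin is
the conditional mean of SUV given the covariates, the corrected measurement
is uncorrelated with every covariate.

The battery quantifies covariate associations per organ on SUVmean,
tcSUVmean, and lean-body-mass normalised SUL: Welch t-tests for sex and for
median-binarized age and uptake time, one-way ANOVA over meteorological
seasons, and a two-sided slope t-test for fat body mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grid import Grid3D, GridError
from .labels import ANALYSIS_ORGANS, DEFAULT_LABELS
from .phantom import Study, fat_body_mass

__all__ = [
    "organ_suv_mean",
    "twin_correct",
    "correction_reference",
    "lean_body_mass",
    "sul_mean",
    "season_of",
    "binarize_median",
    "welch_t_test",
    "one_way_anova",
    "slope_test",
    "variance_reduction",
    "organ_stats_table",
    "run_covariate_battery",
    "CovariateTestResult",
    "DEFAULT_COVARIATES",
]


def organ_suv_mean(pet: Grid3D, organ_labels: Grid3D, organ_id: int) -> float:
    """Arithmetic mean SUV over one organ's voxels."""
    pet.assert_congruent(organ_labels, "pet/labels")
    mask = organ_labels.data == organ_id
    if not mask.any():
        raise GridError(f"organ label {organ_id} has no voxels")
    return float(pet.data[mask].mean())


def twin_correct(suv_mean: float, nt_suv_mean: float, c: float) -> float:
    """tcSUV = SUV - ntSUV + C, exactly."""
    return suv_mean - nt_suv_mean + c


def correction_reference(table: pd.DataFrame) -> dict[str, float]:
    """Per-organ constant C: the cohort mean ntSUVmean."""
    return {
        organ: float(sub["nt_suv_mean"].mean())
        for organ, sub in table.groupby("organ", observed=True)
    }


def lean_body_mass(sex: str, weight_kg: float, height_m: float) -> float:
    """James-formula lean body mass (kg); height enters in cm.

    M: 1.1 W - 128 (W/H_cm)^2;  F: 1.07 W - 148 (W/H_cm)^2.
    """
    if weight_kg <= 0 or height_m <= 0:
        raise GridError("weight and height must be positive")
    h_cm = height_m * 100.0
    if sex == "M":
        lbm = 1.1 * weight_kg - 128.0 * (weight_kg / h_cm) ** 2
    elif sex == "F":
        lbm = 1.07 * weight_kg - 148.0 * (weight_kg / h_cm) ** 2
    else:
        raise GridError(f"sex must be 'M' or 'F', got {sex!r}")
    if lbm <= 0:
        raise GridError(
            f"non-positive lean body mass for sex={sex}, weight={weight_kg}, "
            f"height={height_m}: implausible inputs"
        )
    return float(lbm)


def sul_mean(suv_mean: float, lbm_kg: float, weight_kg: float) -> float:
    """Lean-body-mass normalised SUV: SUV x LBM / weight."""
    if weight_kg <= 0:
        raise GridError("weight must be positive")
    return suv_mean * lbm_kg / weight_kg


# meteorological seasons on a 365-day year: Mar 1 = 60, Jun 1 = 152,
# Sep 1 = 244, Dec 1 = 335
def season_of(day_of_year: int) -> str:
    day = int(day_of_year)
    if not 1 <= day <= 365:
        raise GridError(f"day_of_year must lie in [1, 365], got {day}")
    if day >= 335 or day < 60:
        return "winter"
    if day < 152:
        return "spring"
    if day < 244:
        return "summer"
    return "fall"


def binarize_median(values: np.ndarray) -> np.ndarray:
    """Split at the median: > median -> 'high', <= median (ties) -> 'low'."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise GridError("need at least two values to binarize")
    if np.all(values == values[0]):
        raise GridError("all values identical: degenerate median split")
    med = np.median(values)
    return np.where(values > med, "high", "low")


def welch_t_test(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float]:
    """Welch two-sample t with Satterthwaite df, two-sided p.

    Two zero-variance groups with equal means return (0, 1) by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise GridError("each group needs >= 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Standard one-way F test across >= 2 groups."""
    if len(groups) < 2:
        raise GridError("ANOVA needs >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 2 for g in arrays):
        raise GridError("each ANOVA group needs >= 2 values")
    if all(g.var(ddof=1) == 0 for g in arrays):
        means = [g.mean() for g in arrays]
        if np.ptp(means) == 0:
            return 0.0, 1.0
        return np.inf, 0.0
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def slope_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS slope of y on x with a two-sided t-test of slope = 0.

    Returns ``(slope, t, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise GridError("slope test needs n >= 3")
    if np.all(x == x[0]):
        raise GridError("constant x: slope undefined")
    if np.all(y == y[0]):
        return 0.0, 0.0, 1.0
    res = stats.linregress(x, y)
    if res.stderr == 0:  # y exactly linear in x
        slope = float(res.slope)
        if slope == 0:
            return 0.0, 0.0, 1.0
        return slope, np.sign(slope) * np.inf, 0.0
    t = res.slope / res.stderr
    return float(res.slope), float(t), float(res.pvalue)


def variance_reduction(before: np.ndarray, after: np.ndarray) -> float:
    """1 - Var(after)/Var(before); the fraction of variance removed."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    vb = before.var(ddof=1)
    if vb == 0:
        raise GridError("zero before-variance: reduction undefined")
    return float(1.0 - after.var(ddof=1) / vb)


# ---------------------------------------------------------------------------
# stats table and battery


def organ_stats_table(
    studies: list[Study],
    predictor,
    organs: tuple[str, ...] = ANALYSIS_ORGANS,
    label_map: dict[str, int] | None = None,
    reference: dict[str, float] | None = None,
) -> pd.DataFrame:
    """One row per (study, organ): SUVmean, ntSUVmean, tcSUVmean, SULmean
    plus all covariates.

    ``predictor`` must be a fitted normal-twin estimator.  When ``reference``
    is omitted, C is computed from this cohort's ntSUVmeans (and frozen in
    the returned frame's values).
    """
    label_map = label_map or DEFAULT_LABELS
    rows = []
    for study in studies:
        ntpet = predictor.predict(study)
        a = study.attributes
        lbm = lean_body_mass(a.sex, a.weight, a.height)
        fbm = fat_body_mass(a)
        for organ in organs:
            lab = label_map[organ]
            suv = organ_suv_mean(study.pet, study.organ_labels, lab)
            ntsuv = organ_suv_mean(ntpet, study.organ_labels, lab)
            rows.append({
                "study_id": study.id,
                "organ": organ,
                "suv_mean": suv,
                "nt_suv_mean": ntsuv,
                "sul_mean": sul_mean(suv, lbm, a.weight),
                "sex": a.sex,
                "age": a.age,
                "weight": a.weight,
                "height": a.height,
                "injected_activity": a.injected_activity,
                "scanner_model": a.scanner_model,
                "uptake_time": a.uptake_time,
                "scan_time_of_day": a.scan_time_of_day,
                "scan_day_of_year": a.scan_day_of_year,
                "fat_body_mass": fbm,
                "season": season_of(a.scan_day_of_year),
            })
    table = pd.DataFrame(rows)
    ref = reference or correction_reference(table)
    table["tc_suv_mean"] = [
        twin_correct(r.suv_mean, r.nt_suv_mean, ref[r.organ])
        for r in table.itertuples()
    ]
    return table


@dataclass
class CovariateTestResult:
    organ: str
    covariate: str
    measurement: str
    test: str
    statistic: float
    p_value: float
    degenerate: bool = False


DEFAULT_COVARIATES = ("sex", "age", "fat_body_mass", "uptake_time", "season")

_MEASUREMENT_COLUMNS = {
    "suv_mean": "suv_mean",
    "tc_suv_mean": "tc_suv_mean",
    "sul_mean": "sul_mean",
}


def _test_one(sub: pd.DataFrame, covariate: str, y: np.ndarray):
    if covariate == "sex":
        a = y[(sub["sex"] == "M").to_numpy()]
        b = y[(sub["sex"] == "F").to_numpy()]
        t, p = welch_t_test(a, b)
        return "welch_t", t, p
    if covariate == "season":
        groups = [y[(sub["season"] == s).to_numpy()]
                  for s in ("winter", "spring", "summer", "fall")]
        groups = [g for g in groups if g.size >= 2]
        f, p = one_way_anova(groups)
        return "anova", f, p
    if covariate == "fat_body_mass":
        slope, t, p = slope_test(sub["fat_body_mass"].to_numpy(), y)
        return "slope_t", t, p
    # continuous covariates binarized at their median
    split = binarize_median(sub[covariate].to_numpy())
    t, p = welch_t_test(y[split == "low"], y[split == "high"])
    return "welch_t", t, p


def run_covariate_battery(
    table: pd.DataFrame,
    organs: tuple[str, ...] = ANALYSIS_ORGANS,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    measurements: tuple[str, ...] = ("suv_mean", "tc_suv_mean", "sul_mean"),
) -> pd.DataFrame:
    """Full (organ x covariate x measurement) p-value matrix.

    Degenerate covariates (constant values, too-small groups) are flagged
    with ``degenerate=True`` and p = NaN rather than dropped.
    """
    results: list[CovariateTestResult] = []
    for organ in organs:
        sub = table[table["organ"] == organ]
        if sub.empty:
            raise GridError(f"no rows for organ {organ!r}")
        for measurement in measurements:
            y = sub[_MEASUREMENT_COLUMNS[measurement]].to_numpy(dtype=float)
            for covariate in covariates:
                try:
                    test, stat, p = _test_one(sub, covariate, y)
                    results.append(CovariateTestResult(
                        organ, covariate, measurement, test, stat, p))
                except GridError:
                    results.append(CovariateTestResult(
                        organ, covariate, measurement, "degenerate",
                        np.nan, np.nan, degenerate=True))
    return pd.DataFrame([r.__dict__ for r in results])
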