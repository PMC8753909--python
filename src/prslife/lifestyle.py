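"""Obesogenic lifestyle risk index: survey parsing, factor classification,
weight derivation and the standardized, median-dichotomized index.

Six binary risk indicators are derived from survey answers:

* ``alcohol_risk``   — anything other than "1-2 per day" (excessive *or*
  limited intake relative to the 1-2 drinks/day reference);
* ``education_risk`` — highest attainment below a masters/doctoral/professional
  degree;
* ``inactivity_risk``— < 2.5 h/week (150 min) of moderate-to-high-intensity
  recreational exercise, excluding walking/hiking (and the explicitly
  lower-intensity activity);
* ``sleep_risk``     — habitual sleep duration < 8 h or >= 10 h per night,
  where duration is (5/7) x weekday + (2/7) x weekend duration from reported
  bed and wake clock times;
* ``smoking_risk``   — former smoking (quit), vs never or current;
* ``shift_risk``     — night-shift work.

The index is raw = sum_k w_k X_k with weights w_k taken from one joint OLS of
BMI on all six indicators plus age and sex, fit in a weighting subset disjoint
from the analytic subset; it is then standardized (mean 0, SD 1) and
dichotomized at the population median (ties to "low").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .prs import standardize

log = logging.getLogger(__name__)

ALCOHOL_CATEGORIES = (
    "none",
    "less than 1 per month",
    "1-3 per month",
    "1 per week",
    "2-4 per week",
    "5-6 per week",
    "1-2 per day",
    "3-4 per day",
    "5-6 per day",
    "more than 6 per day",
)
ALCOHOL_REFERENCE = "1-2 per day"

EDUCATION_CATEGORIES = (
    "grade school (1-4 years)",
    "grade school (5-8 years)",
    "some high school (9-11 years)",
    "high school diploma or GED (finished high school)",
    "some college",
    "2-year college or vocational school",
    "4-year college",
    "masters, doctoral or professional degree",
)
EDUCATION_REFERENCE = "masters, doctoral or professional degree"

SMOKING_CATEGORIES = (
    "yes, currently smoke",
    "yes, smoked in past, but quit",
    "no, have not smoked more than 100 cigarettes",
)
SMOKING_RISK = "yes, smoked in past, but quit"

SHIFT_CATEGORIES = (
    "afternoon shift",
    "night shift",
    "irregular shift",
    "rotating shift",
    "split shift",
    "no shift (unemployed)",
)
SHIFT_RISK = "night shift"

#: survey activity columns; the first group counts toward the
#: moderate-to-high-intensity total, the second does not.
EXERCISE_COUNTED = (
    "hours_bicycling",
    "hours_higher_intensity",
    "hours_jogging",
    "hours_lap_swimming",
    "hours_running",
    "hours_tennis_squash_racquetball",
)
EXERCISE_NOT_COUNTED = ("hours_lower_intensity", "hours_walking_hiking")

SLEEP_COLUMNS = ("bed_weekday", "wake_weekday", "bed_weekend", "wake_weekend")

FACTOR_NAMES = (
    "alcohol_risk",
    "education_risk",
    "inactivity_risk",
    "sleep_risk",
    "smoking_risk",
    "shift_risk",
)

SURVEY_COLUMNS = (
    ("alcohol", "education", "smoking", "shift")
    + EXERCISE_COUNTED
    + EXERCISE_NOT_COUNTED
    + SLEEP_COLUMNS
)

INACTIVITY_THRESHOLD_HOURS = 2.5  # 150 min / week
SLEEP_SHORT_HOURS = 8.0
SLEEP_LONG_HOURS = 10.0


class SurveyError(ValueError):
    """Raised for survey answers outside the printed response options."""


def parse_clock(value) -> np.ndarray:
    """Parse 'HH:MM' clock strings (24-h dial) to fractional hours."""
    s = pd.Series(value).astype(str)
    parts = s.str.split(":", expand=True)
    if parts.shape[1] != 2:
        raise SurveyError(f"malformed clock time(s): {sorted(s[~s.str.contains(':')].unique())}")
    hours = pd.to_numeric(parts[0], errors="coerce")
    minutes = pd.to_numeric(parts[1], errors="coerce")
    bad = hours.isna() | minutes.isna() | (hours < 0) | (hours > 23) | (minutes < 0) | (minutes > 59)
    if bad.any():
        raise SurveyError(f"invalid clock time(s): {sorted(s[bad].unique())}")
    return (hours + minutes / 60.0).to_numpy(float)


def compute_sleep_duration(bed_wd, wake_wd, bed_we, wake_we) -> np.ndarray:
    """Weighted nightly sleep duration in hours: (5/7) weekday + (2/7) weekend.

    Per-day duration is (wake - bed) mod 24 so cross-midnight sleep works;
    identical bed and wake time is ambiguous (0 vs 24 h) and rejected.
    """
    durations = []
    for bed, wake in ((bed_wd, wake_wd), (bed_we, wake_we)):
        b, w = parse_clock(bed), parse_clock(wake)
        if np.any(b == w):
            raise SurveyError("bed time equal to wake time is ambiguous (0 vs 24 h)")
        durations.append(np.mod(w - b, 24.0))
    return (5.0 / 7.0) * durations[0] + (2.0 / 7.0) * durations[1]


def _check_categories(series: pd.Series, allowed, column: str) -> None:
    bad = ~series.isin(allowed)
    if bad.any():
        raise SurveyError(
            f"unknown {column} value(s): {sorted(series[bad].astype(str).unique())}"
        )


def complete_cases(survey: pd.DataFrame) -> pd.DataFrame:
    """Drop participants with any missing survey item (complete-case rule)."""
    cols = [c for c in SURVEY_COLUMNS if c in survey.columns]
    missing = [c for c in SURVEY_COLUMNS if c not in survey.columns]
    if missing:
        raise SurveyError(f"survey table is missing column(s): {missing}")
    kept = survey.dropna(subset=cols)
    n_dropped = len(survey) - len(kept)
    if n_dropped:
        log.info("complete-case filter dropped %d of %d participants", n_dropped, len(survey))
    return kept


def classify_risk_factors(survey: pd.DataFrame) -> pd.DataFrame:
    """Classify the six binary risk indicators from raw survey answers.

    Returns one row per participant with the six 0/1 indicator columns plus
    the derived ``sleep_hours`` and ``exercise_hours`` used for the sleep and
    inactivity indicators.  Unknown category strings raise, naming the field
    and the offending value; missing items must be handled upstream
    (`complete_cases`).
    """
    missing = [c for c in SURVEY_COLUMNS if c not in survey.columns]
    if missing:
        raise SurveyError(f"survey table is missing column(s): {missing}")
    if survey[list(SURVEY_COLUMNS)].isna().any().any():
        raise SurveyError("survey contains missing items; apply complete_cases first")

    _check_categories(survey["alcohol"], ALCOHOL_CATEGORIES, "alcohol")
    _check_categories(survey["education"], EDUCATION_CATEGORIES, "education")
    _check_categories(survey["smoking"], SMOKING_CATEGORIES, "smoking")
    _check_categories(survey["shift"], SHIFT_CATEGORIES, "shift")

    exercise = survey[list(EXERCISE_COUNTED)].astype(float)
    if (exercise < 0).any().any() or (survey[list(EXERCISE_NOT_COUNTED)].astype(float) < 0).any().any():
        raise SurveyError("negative weekly exercise hours")
    exercise_hours = exercise.sum(axis=1).to_numpy(float)

    sleep_hours = compute_sleep_duration(
        survey["bed_weekday"], survey["wake_weekday"], survey["bed_weekend"], survey["wake_weekend"]
    )

    out = pd.DataFrame(
        {
            "alcohol_risk": (survey["alcohol"] != ALCOHOL_REFERENCE).astype(int),
            "education_risk": (survey["education"] != EDUCATION_REFERENCE).astype(int),
            "inactivity_risk": (exercise_hours < INACTIVITY_THRESHOLD_HOURS).astype(int),
            "sleep_risk": ((sleep_hours < SLEEP_SHORT_HOURS) | (sleep_hours >= SLEEP_LONG_HOURS)).astype(int),
            "smoking_risk": (survey["smoking"] == SMOKING_RISK).astype(int),
            "shift_risk": (survey["shift"] == SHIFT_RISK).astype(int),
            "sleep_hours": sleep_hours,
            "exercise_hours": exercise_hours,
        },
        index=survey.index,
    )
    return out


@dataclass(frozen=True)
class FactorWeights:
    """Per-factor index weights from one joint BMI regression (kg/m^2)."""

    weights: pd.Series = field(repr=False)  # indexed by FACTOR_NAMES
    se: pd.Series = field(repr=False)
    n: int = 0
    covariates: tuple = ("age", "sex")


def derive_factor_weights(profiles: pd.DataFrame, bmi, age, sex) -> FactorWeights:
    """Fit BMI ~ X1..X6 + age + sex by OLS in the weighting subset.

    The six indicator coefficients, taken jointly from this single model, are
    the index weights.  A constant indicator makes the design rank-deficient
    and raises, naming the factor.
    """
    import statsmodels.api as sm

    X = profiles[list(FACTOR_NAMES)].astype(float).copy()
    n = len(X)
    if n <= 50:
        raise ValueError(f"weighting subset too small (n={n}, need > 50)")
    constant = [f for f in FACTOR_NAMES if X[f].nunique() < 2]
    if constant:
        raise ValueError(f"constant indicator(s) make the weight model rank-deficient: {constant}")
    X["age"] = np.asarray(age, dtype=float)
    X["sex"] = np.asarray(sex, dtype=float)
    design = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(np.asarray(bmi, dtype=float), design).fit()
    return FactorWeights(
        weights=fit.params[list(FACTOR_NAMES)].rename("weight"),
        se=fit.bse[list(FACTOR_NAMES)].rename("se"),
        n=n,
    )


def dichotomize_index(values) -> np.ndarray:
    """Median split: value <= population median -> 'low', else 'high'.

    With mass at the median the groups can be unequal; the partition is
    always exhaustive and the tie rule (ties to low) deterministic.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("median split needs at least 2 participants")
    med = np.median(x)
    return np.where(x <= med, "low", "high")


@dataclass(frozen=True)
class IndexResult:
    """Per-participant lifestyle index: raw, standardized and dichotomized."""

    frame: pd.DataFrame = field(repr=False)  # columns: raw, z, group
    weights: FactorWeights | None = None

    @property
    def z(self) -> pd.Series:
        return self.frame["z"]

    @property
    def group(self) -> pd.Series:
        return self.frame["group"]

    def to_csv(self, path) -> None:
        self.frame.rename_axis("participant_id").to_csv(path)


def compute_index(profiles: pd.DataFrame, weights: FactorWeights) -> IndexResult:
    """Build raw = sum_k w_k X_k, standardize it, and median-split."""
    X = profiles[list(FACTOR_NAMES)].astype(float).to_numpy()
    raw = X @ weights.weights.to_numpy(float)
    z = standardize(raw)  # raises on a constant index
    group = dichotomize_index(z)
    frame = pd.DataFrame({"raw": raw, "z": z, "group": group}, index=profiles.index)
    return IndexResult(frame=frame, weights=weights)
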