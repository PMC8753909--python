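"""Seeded synthetic EHR-biobank cohort generator and calibration solver.

The generator emulates the analytic cohort of a hospital biobank: genotype
dosages for a variant panel, raw lifestyle-survey answers, ICD-9/10 billing
events, covariates, and clinically measured BMI.  BMI follows

    BMI_i = mu + b_age*age_i + b_sex*sex_i
            + b_prs*Z_i + b_index*L_i + b_int*Z_i*L_i + eps_i ,

where Z is the standardized PRS computed from the generated dosages through
the actual scoring code, L is the standardized latent lifestyle index
(a weighted sum of six correlated binary risk factors), and eps is Gaussian
with variance chosen so the marginal SD of BMI matches the configured value.
Survey answers are emitted so that the lifestyle classifiers reproduce the
latent binary indicators exactly; disease case status follows a logistic
model in Z, and cases receive >= 2 mapped billing events on distinct dates.

`calibrate_preset` solves the PRS main-effect and interaction coefficients
that reproduce two target median-split stratified effects.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from . import lifestyle as ls
from .phecode import PhecodeMap, default_phecode_map
from .prs import VariantPanel, compute_scores, default_panel, standardize

log = logging.getLogger(__name__)

#: per-factor risk prevalences (alcohol, education, inactivity, sleep,
#: smoking, shift) — defaults documented in the methods note
DEFAULT_FACTOR_PREVALENCES = (0.85, 0.80, 0.50, 0.35, 0.30, 0.05)
#: relative generating weights of the latent index, kg/m^2 scale
DEFAULT_FACTOR_WEIGHTS = (0.5, 0.9, 1.2, 0.8, 0.6, 0.7)

AGE_MEAN, AGE_SD, AGE_RANGE = 60.0, 17.0, (18.0, 100.0)
FEMALE_FRACTION = 0.53
EVENT_WINDOW_DAYS = 3650  # billing events span ~10 years around enrollment


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class DiseaseModel:
    """Logistic disease model: baseline prevalence and log-OR per SD of PRS."""

    prevalence: float
    log_or_per_sd: float

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ConfigError(f"prevalence {self.prevalence} outside (0, 1)")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of one synthetic cohort."""

    n_participants: int
    panel: VariantPanel = field(default_factory=default_panel, repr=False)
    factor_prevalences: tuple = DEFAULT_FACTOR_PREVALENCES
    factor_correlation: float = 0.1
    factor_weights: tuple = DEFAULT_FACTOR_WEIGHTS
    bmi_mean: float = 28.3
    bmi_sd: float = 6.3
    beta_age: float = 0.02
    beta_sex: float = -0.5
    beta_prs_per_sd: float = 0.0
    beta_index_per_sd: float = 0.0
    beta_interaction: float = 0.0
    disease_models: dict = field(default_factory=dict)
    n_null_phecodes: int = 0
    one_code_fraction: float = 0.03
    exclusion_code_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ConfigError("need at least 2 participants")
        if len(self.factor_prevalences) != 6 or len(self.factor_weights) != 6:
            raise ConfigError("exactly six factor prevalences and weights are required")
        for p in self.factor_prevalences:
            if not 0 < p < 1:
                raise ConfigError(f"factor prevalence {p} outside (0, 1)")
        if not -0.3 <= self.factor_correlation <= 0.3:
            raise ConfigError("factor correlation must lie in [-0.3, 0.3]")
        if self.bmi_sd <= 0:
            raise ConfigError("bmi_sd must be positive")
        for frac in (self.one_code_fraction, self.exclusion_code_fraction):
            if not 0 <= frac < 1:
                raise ConfigError("event-injection fractions must lie in [0, 1)")
        # approximate feasibility of the residual variance (exact check at
        # generation time uses the realized systematic component)
        approx = (
            self.beta_age**2 * AGE_SD**2
            + self.beta_sex**2 * FEMALE_FRACTION * (1 - FEMALE_FRACTION)
            + self.beta_prs_per_sd**2
            + self.beta_index_per_sd**2
            + self.beta_interaction**2 * 1.2
        )
        if approx >= self.bmi_sd**2:
            raise ConfigError(
                f"coefficients imply systematic variance {approx:.2f} >= bmi_sd^2 "
                f"{self.bmi_sd ** 2:.2f}; residual variance would be non-positive"
            )


@dataclass(frozen=True)
class SyntheticCohort:
    """One generated cohort; every table shares the participant-id index."""

    covariates: pd.DataFrame = field(repr=False)
    bmi: pd.Series = field(repr=False)
    dosages: pd.DataFrame = field(repr=False)
    survey: pd.DataFrame = field(repr=False)
    icd_events: pd.DataFrame = field(repr=False)
    latent: pd.DataFrame = field(repr=False)  # ground truth for validation
    config: GeneratorConfig = field(repr=False, default=None)

    @property
    def participant_ids(self) -> pd.Index:
        return self.covariates.index

    def frame(self) -> pd.DataFrame:
        """Covariates plus BMI, the base analysis table."""
        return self.covariates.join(self.bmi.rename("bmi"))


COVARIATE_COLUMNS = ("age", "sex", "array", "pc1", "pc2", "pc3", "pc4", "pc5")


def generate_genotypes(n: int, panel: VariantPanel, seed, min_freq: float | None = None) -> pd.DataFrame:
    """Independent dosages d_ij ~ Binomial(2, f_j) (linkage equilibrium)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    f = panel.freqs
    if min_freq is not None and (np.any(f < min_freq) or np.any(f > 1 - min_freq)):
        bad = [v for v, fj in zip(panel.variant_ids, f) if fj < min_freq or fj > 1 - min_freq]
        raise ConfigError(f"variant(s) outside the MAF >= {min_freq} bound: {bad}")
    d = rng.binomial(2, f, size=(n, panel.n_variants)).astype(float)
    return pd.DataFrame(d, columns=panel.variant_ids)


def _generate_factors(n: int, prevalences, correlation: float, rng: np.random.Generator) -> np.ndarray:
    """Six correlated binaries via a Gaussian copula (exchangeable rho)."""
    k = len(prevalences)
    cov = np.full((k, k), correlation)
    np.fill_diagonal(cov, 1.0)
    z = rng.multivariate_normal(np.zeros(k), cov, size=n, method="cholesky")
    thresholds = stats.norm.ppf(prevalences)
    return (z < thresholds).astype(int)


_SLEEP_OK = np.arange(8.0, 10.0, 0.5)  # weighted duration in [8, 10)
_SLEEP_RISK = np.concatenate([np.arange(5.0, 8.0, 0.5), np.arange(10.0, 12.5, 0.5)])
_BED_GRID = np.array([21.0, 21.5, 22.0, 22.5, 23.0, 23.5, 0.0, 0.5, 1.0])


def _clock(hours: np.ndarray) -> np.ndarray:
    h = np.mod(hours, 24.0)
    whole = h.astype(int)
    minute = np.rint((h - whole) * 60).astype(int)
    return np.char.add(
        np.char.add(np.char.zfill(whole.astype(str), 2), ":"),
        np.char.zfill(minute.astype(str), 2),
    )


def _survey_from_factors(X: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Raw survey answers consistent with the latent indicators.

    Each answer is drawn from the legal categories on the correct side of its
    classifier threshold, so classification reproduces X exactly.
    """
    n = X.shape[0]
    alcohol_risk_cats = [c for c in ls.ALCOHOL_CATEGORIES if c != ls.ALCOHOL_REFERENCE]
    education_risk_cats = [c for c in ls.EDUCATION_CATEGORIES if c != ls.EDUCATION_REFERENCE]
    shift_other = [c for c in ls.SHIFT_CATEGORIES if c != ls.SHIFT_RISK]

    alcohol = np.where(X[:, 0] == 1, rng.choice(alcohol_risk_cats, n), ls.ALCOHOL_REFERENCE)
    education = np.where(X[:, 1] == 1, rng.choice(education_risk_cats, n), ls.EDUCATION_REFERENCE)
    smoking = np.where(
        X[:, 4] == 1,
        ls.SMOKING_RISK,
        rng.choice(
            ["no, have not smoked more than 100 cigarettes", "yes, currently smoke"], n, p=[0.8, 0.2]
        ),
    )
    shift = np.where(
        X[:, 5] == 1,
        ls.SHIFT_RISK,
        rng.choice(shift_other, n, p=[0.1, 0.05, 0.05, 0.05, 0.75]),
    )

    # exercise: counted moderate/high total on the right side of 2.5 h/week
    total = np.where(
        X[:, 2] == 1, rng.uniform(0.0, 2.4, n), rng.uniform(2.6, 12.0, n)
    )
    shares = rng.dirichlet(np.full(len(ls.EXERCISE_COUNTED), 0.6), size=n)
    exercise = {c: total * shares[:, j] for j, c in enumerate(ls.EXERCISE_COUNTED)}
    exercise["hours_walking_hiking"] = np.round(rng.uniform(0.0, 6.0, n), 2)
    exercise["hours_lower_intensity"] = np.round(rng.uniform(0.0, 3.0, n), 2)

    # sleep: equal weekday/weekend duration drawn on the half-hour grid from
    # the adequate or inadequate range, so the 5/7-2/7 weighting is exact
    duration = np.where(
        X[:, 3] == 1,
        rng.choice(_SLEEP_RISK, n),
        rng.choice(_SLEEP_OK, n),
    )
    bed_wd = rng.choice(_BED_GRID, n)
    bed_we = rng.choice(_BED_GRID, n)
    survey = pd.DataFrame(
        {
            "alcohol": alcohol,
            "education": education,
            "smoking": smoking,
            "shift": shift,
            **{c: np.round(v, 3) if c in ls.EXERCISE_COUNTED else v for c, v in exercise.items()},
            "bed_weekday": _clock(bed_wd),
            "wake_weekday": _clock(bed_wd + duration),
            "bed_weekend": _clock(bed_we),
            "wake_weekend": _clock(bed_we + duration),
        }
    )
    return survey


def _solve_intercept(prevalence: float, log_or: float, z: np.ndarray) -> float:
    """Intercept alpha with mean expit(alpha + log_or * z) = prevalence."""

    def gap(alpha: float) -> float:
        return float(np.mean(expit(alpha + log_or * z))) - prevalence

    return optimize.brentq(gap, -25.0, 25.0, xtol=1e-10)


def _distinct_dates(frame: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Make event day offsets distinct within participant (sort + cumcount)."""
    frame = frame.sort_values(["participant_id", "day_offset"], kind="stable").reset_index(drop=True)
    frame["day_offset"] += frame.groupby("participant_id").cumcount()
    return frame


def generate_icd_events(
    participant_ids,
    z_prs,
    enrollment_dates: pd.Series,
    disease_models: dict[str, DiseaseModel],
    pmap: PhecodeMap,
    seed,
    n_null_phecodes: int = 0,
    one_code_fraction: float = 0.03,
    exclusion_code_fraction: float = 0.02,
    null_prevalence_range: tuple[float, float] = (0.005, 0.06),
) -> pd.DataFrame:
    """ICD billing events realizing the configured disease models.

    Per modeled phecode: case status ~ Bernoulli(expit(alpha + logOR * Z))
    with alpha solved so the realized mean equals the target prevalence;
    cases get 2 + Poisson(1) mapped events on distinct dates inside a
    ``EVENT_WINDOW_DAYS`` window centred on enrollment.  A configurable small
    fraction of non-cases gets exactly one event (exercising the one-code
    exclusion) or one event from the phecode's exclusion range.  Null
    phecodes (logOR = 0) are added from the map to pad the phenome.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ids = pd.Index(participant_ids)
    z = np.asarray(z_prs, dtype=float)
    n = len(ids)

    models = dict(disease_models)
    if n_null_phecodes:
        blocked = set(models)
        ranges = [r for pc in models for r in pmap.exclusion_ranges(pc)]
        mapped = set(pmap.icd_map["phecode"])
        for pc in pmap.phecodes:
            if len(models) - len(disease_models) >= n_null_phecodes:
                break
            num = float(pc)
            if pc in blocked or pc not in mapped or any(lo <= num <= hi for lo, hi in ranges):
                continue
            models[pc] = DiseaseModel(
                prevalence=float(rng.uniform(*null_prevalence_range)), log_or_per_sd=0.0
            )

    enr = pd.to_datetime(pd.Series(enrollment_dates).reindex(ids))
    pieces = []
    for phecode, model in models.items():
        codes = pmap.codes_for(phecode)  # raises naming an unmapped phecode
        alpha = _solve_intercept(model.prevalence, model.log_or_per_sd, z)
        case = rng.random(n) < expit(alpha + model.log_or_per_sd * z)

        # exclusion-range donor codes: codes of *other* phecodes inside the range
        excl_codes = None
        if exclusion_code_fraction > 0:
            ranges = pmap.exclusion_ranges(phecode)
            if ranges:
                nums = pd.to_numeric(pmap.icd_map["phecode"], errors="coerce")
                in_range = np.zeros(len(pmap.icd_map), dtype=bool)
                for lo, hi in ranges:
                    in_range |= ((nums >= lo) & (nums <= hi)).to_numpy()
                donor = pmap.icd_map.loc[in_range & (pmap.icd_map["phecode"] != phecode)]
                if len(donor):
                    excl_codes = donor[["vocabulary", "code"]].reset_index(drop=True)

        case_ids = np.flatnonzero(case)
        n_events = 2 + rng.poisson(1.0, len(case_ids))
        rows_pid = np.repeat(case_ids, n_events)
        pick = rng.integers(0, len(codes), rows_pid.size)
        frame = pd.DataFrame(
            {
                "participant_id": ids[rows_pid],
                "day_offset": rng.integers(0, EVENT_WINDOW_DAYS - 30, rows_pid.size),
                "vocabulary": codes["vocabulary"].to_numpy()[pick],
                "code": codes["code"].to_numpy()[pick],
            }
        )
        pieces.append(_distinct_dates(frame, rng))

        noncase_ids = np.flatnonzero(~case)
        u = rng.random(len(noncase_ids))
        one = noncase_ids[u < one_code_fraction]
        pick = rng.integers(0, len(codes), one.size)
        pieces.append(
            pd.DataFrame(
                {
                    "participant_id": ids[one],
                    "day_offset": rng.integers(0, EVENT_WINDOW_DAYS - 30, one.size),
                    "vocabulary": codes["vocabulary"].to_numpy()[pick],
                    "code": codes["code"].to_numpy()[pick],
                }
            )
        )
        if excl_codes is not None:
            sel = (u >= one_code_fraction) & (u < one_code_fraction + exclusion_code_fraction)
            exc = noncase_ids[sel]
            pick = rng.integers(0, len(excl_codes), exc.size)
            pieces.append(
                pd.DataFrame(
                    {
                        "participant_id": ids[exc],
                        "day_offset": rng.integers(0, EVENT_WINDOW_DAYS - 30, exc.size),
                        "vocabulary": excl_codes["vocabulary"].to_numpy()[pick],
                        "code": excl_codes["code"].to_numpy()[pick],
                    }
                )
            )

    if not pieces:
        return pd.DataFrame(columns=["participant_id", "date", "vocabulary", "code"])
    events = pd.concat(pieces, ignore_index=True)
    start = events["participant_id"].map(enr) - pd.to_timedelta(EVENT_WINDOW_DAYS // 2, unit="D")
    events["date"] = start + pd.to_timedelta(events["day_offset"], unit="D")
    events = (
        events[["participant_id", "date", "vocabulary", "code"]]
        .sort_values(["participant_id", "date", "vocabulary", "code"], kind="stable")
        .reset_index(drop=True)
    )
    return events


def generate_cohort(config: GeneratorConfig, pmap: PhecodeMap | None = None) -> SyntheticCohort:
    """Generate a complete synthetic cohort under ``config`` (deterministic)."""
    n = config.n_participants
    rng = np.random.default_rng(config.seed)
    ids = pd.Index([f"P{i:06d}" for i in range(n)], name="participant_id")

    a, b = (AGE_RANGE[0] - AGE_MEAN) / AGE_SD, (AGE_RANGE[1] - AGE_MEAN) / AGE_SD
    age = stats.truncnorm.rvs(a, b, loc=AGE_MEAN, scale=AGE_SD, size=n, random_state=rng)
    covariates = pd.DataFrame(
        {
            "age": age,
            "sex": rng.binomial(1, FEMALE_FRACTION, n).astype(float),
            "array": rng.binomial(1, 0.5, n).astype(float),
            **{f"pc{k}": rng.standard_normal(n) for k in range(1, 6)},
        },
        index=ids,
    )
    covariates["enrollment_date"] = pd.Timestamp("2010-01-01") + pd.to_timedelta(
        rng.integers(0, 2192, n), unit="D"
    )
    covariates["morbidity"] = rng.choice(["low", "mid", "high"], n, p=[0.25, 0.5, 0.25])

    dosages = generate_genotypes(n, config.panel, rng)
    dosages.index = ids
    z_prs = compute_scores(dosages, config.panel).z.to_numpy()

    X = _generate_factors(n, config.factor_prevalences, config.factor_correlation, rng)
    raw_index = X @ np.asarray(config.factor_weights, dtype=float)
    l_true = standardize(raw_index)
    survey = _survey_from_factors(X, rng)
    survey.index = ids

    systematic = (
        config.beta_age * covariates["age"].to_numpy()
        + config.beta_sex * covariates["sex"].to_numpy()
        + config.beta_prs_per_sd * z_prs
        + config.beta_index_per_sd * l_true
        + config.beta_interaction * z_prs * l_true
    )
    resid_var = config.bmi_sd**2 - systematic.var(ddof=1)
    if resid_var <= 0:
        raise ConfigError(
            f"realized systematic variance {systematic.var(ddof=1):.2f} leaves "
            f"non-positive residual variance at bmi_sd={config.bmi_sd}"
        )
    bmi = pd.Series(
        config.bmi_mean + (systematic - systematic.mean()) + rng.normal(0.0, math.sqrt(resid_var), n),
        index=ids,
        name="bmi",
    )

    latent = pd.DataFrame(
        {f"true_{name}": X[:, j] for j, name in enumerate(ls.FACTOR_NAMES)}, index=ids
    )
    latent["l_true"] = l_true
    latent["z_prs"] = z_prs

    if config.disease_models:
        if pmap is None:
            pmap = default_phecode_map()
        events = generate_icd_events(
            ids,
            z_prs,
            covariates["enrollment_date"],
            config.disease_models,
            pmap,
            rng,
            n_null_phecodes=config.n_null_phecodes,
            one_code_fraction=config.one_code_fraction,
            exclusion_code_fraction=config.exclusion_code_fraction,
        )
    else:
        events = pd.DataFrame(columns=["participant_id", "date", "vocabulary", "code"])

    return SyntheticCohort(
        covariates=covariates,
        bmi=bmi,
        dosages=dosages,
        survey=survey,
        icd_events=events,
        latent=latent,
        config=config,
    )


@dataclass(frozen=True)
class CalibrationPreset:
    """Solved coefficients reproducing two target stratified PRS effects.

    Solving uses that, with Z independent of L, the median-split stratified
    per-SD PRS effect equals b_main + b_int * E[L | group]:

        b_int  = (target_high - target_low) / (cH - cL)
        b_main = target_high - b_int * cH .
    """

    beta_prs_main: float
    beta_interaction: float
    c_high: float
    c_low: float
    target_high: float
    target_low: float
    index_sd_raw: float
    logistic_intercepts: dict = field(default_factory=dict)
    notes: str = ""


def calibrate_preset(
    target_high: float,
    target_low: float,
    pilot_n: int = 200_000,
    seed: int = 97,
    factor_prevalences=DEFAULT_FACTOR_PREVALENCES,
    factor_weights=DEFAULT_FACTOR_WEIGHTS,
    factor_correlation: float = 0.1,
    index_distribution: str = "factors",
    disease_models: dict[str, DiseaseModel] | None = None,
) -> CalibrationPreset:
    """Solve generator coefficients from target stratified effects.

    ``index_distribution='factors'`` (default) simulates the discrete
    six-factor index in a pilot cohort to measure the conditional means
    cH/cL of the standardized index above/below the median;
    ``'normal'`` uses a Gaussian index, for which cH - cL approaches the
    half-normal value 2*sqrt(2/pi) ~ 1.5958.
    """
    if pilot_n < 10_000:
        raise ConfigError(f"pilot_n={pilot_n} too small (need >= 10,000)")
    rng = np.random.default_rng(seed)
    if index_distribution == "normal":
        l_std = rng.standard_normal(pilot_n)
        raw_sd = 1.0
    elif index_distribution == "factors":
        X = _generate_factors(pilot_n, factor_prevalences, factor_correlation, rng)
        raw = X @ np.asarray(factor_weights, dtype=float)
        raw_sd = float(raw.std(ddof=1))
        if raw_sd == 0:
            raise ConfigError("degenerate pilot index (constant)")
        l_std = standardize(raw)
    else:
        raise ConfigError(f"unknown index_distribution {index_distribution!r}")

    group = ls.dichotomize_index(l_std)
    c_high = float(l_std[group == "high"].mean())
    c_low = float(l_std[group == "low"].mean())
    if abs(c_high - c_low) < 1e-9:
        raise ConfigError("degenerate index: identical conditional means above/below the median")
    beta_int = (target_high - target_low) / (c_high - c_low)
    beta_main = target_high - beta_int * c_high

    intercepts = {}
    for pc, model in (disease_models or {}).items():
        z = rng.standard_normal(pilot_n)
        intercepts[pc] = _solve_intercept(model.prevalence, model.log_or_per_sd, z)

    return CalibrationPreset(
        beta_prs_main=beta_main,
        beta_interaction=beta_int,
        c_high=c_high,
        c_low=c_low,
        target_high=target_high,
        target_low=target_low,
        index_sd_raw=raw_sd,
        logistic_intercepts=intercepts,
        notes=f"pilot_n={pilot_n}, seed={seed}, index_distribution={index_distribution}",
    )


# ---------------------------------------------------------------------------
# study presets: the simulated analogues of the published analytic cohorts

#: obesity phecode anchors: 8349 cases of 33,511; OR 1.26 per SD of PRS
OBESITY_PHECODE = "278.1"
OBESITY_PREVALENCE = 8349 / 33511
OBESITY_LOG_OR = math.log(1.26)

MAIN_COHORT_N = 33511
SURVEY_SUBSET_N = 17040
WEIGHTING_SUBSET_N = 30045
PRS_EFFECT_PER_SD = 0.83
INDEX_EFFECT_PER_SD = 1.49
STRATIFIED_TARGETS = (0.98, 0.59)
_CALIBRATION_SEED = 97


def main_cohort_config(seed: int, n: int = MAIN_COHORT_N) -> GeneratorConfig:
    """Genetic-cohort preset: per-SD PRS effect 0.83 on BMI, obesity phecode
    at prevalence 8349/33,511 with OR 1.26 per SD, plus null phecodes."""
    if n < 20:
        raise ConfigError("decile-dependent preset requires n >= 20")
    return GeneratorConfig(
        n_participants=n,
        beta_prs_per_sd=PRS_EFFECT_PER_SD,
        disease_models={OBESITY_PHECODE: DiseaseModel(OBESITY_PREVALENCE, OBESITY_LOG_OR)},
        n_null_phecodes=8,
        seed=seed,
    )


def survey_cohort_config(
    seed: int,
    n_analytic: int = SURVEY_SUBSET_N,
    n_weighting: int = WEIGHTING_SUBSET_N,
    targets: tuple[float, float] = STRATIFIED_TARGETS,
) -> tuple[GeneratorConfig, CalibrationPreset]:
    """Survey-subset preset with the interaction calibration.

    One cohort of ``n_analytic + n_weighting`` participants is generated; the
    first ``n_analytic`` are the analytic survey subset, the rest the
    independent weighting subset (see `split_survey_cohort`).  The index main
    effect is 1.49 kg/m^2 per SD; PRS main and interaction coefficients are
    solved so the median-split stratified PRS effects hit ``targets``.
    """
    if n_analytic < 20:
        raise ConfigError("decile-dependent preset requires n >= 20")
    preset = calibrate_preset(*targets, seed=_CALIBRATION_SEED)
    config = GeneratorConfig(
        n_participants=n_analytic + n_weighting,
        beta_prs_per_sd=preset.beta_prs_main,
        beta_index_per_sd=INDEX_EFFECT_PER_SD,
        beta_interaction=preset.beta_interaction,
        seed=seed,
    )
    return config, preset


def split_survey_cohort(
    cohort: SyntheticCohort, n_analytic: int = SURVEY_SUBSET_N
) -> tuple[pd.Index, pd.Index]:
    """(analytic ids, weighting ids): disjoint, in generation order."""
    ids = cohort.participant_ids
    if len(ids) <= n_analytic:
        raise ConfigError(f"cohort of {len(ids)} cannot hold an analytic subset of {n_analytic}")
    return ids[:n_analytic], ids[n_analytic:]
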