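"""Study-condition batteries: simulate a calibrated cohort at the published
sample sizes and re-estimate the headline quantities through the full
pipeline (scoring, survey classification, weight derivation, phecode engine,
adjusted regressions).

These functions are the single source for both the acceptance checks and the
analysis drivers, so every reported number is recomputed from scratch.
"""

from __future__ import annotations

import numpy as np

from . import lifestyle as ls
from . import models, prs, simulate
from .phecode import build_case_control, dedupe_events, default_phecode_map, map_events

PRS_COVARIATES = ("age", "sex", "array", "pc1", "pc2", "pc3", "pc4", "pc5")
INDEX_COVARIATES = ("age", "sex")


def main_cohort_estimates(seed: int, n: int = simulate.MAIN_COHORT_N) -> dict:
    """Genetic-cohort battery at the published n.

    Simulates under the main preset (per-SD PRS effect 0.83 kg/m^2 on BMI,
    obesity phecode at prevalence 8349/33,511 with OR 1.26 per SD), rebuilds
    the PRS from dosages, and returns the covariate-adjusted per-SD effect,
    the decile-10-vs-1 BMI contrast, and the obesity-phecode OR per SD from
    the full billing-event -> phecode -> logistic path.
    """
    config = simulate.main_cohort_config(seed, n=n)
    cohort = simulate.generate_cohort(config)
    data = cohort.frame()
    data["z_prs"] = prs.compute_scores(cohort.dosages, config.panel).z

    prs_fit = models.fit_linear(data, "bmi", "z_prs", PRS_COVARIATES)
    contrast = models.decile_contrast(data, "bmi", "z_prs", PRS_COVARIATES)

    pmap = default_phecode_map()
    instances = map_events(dedupe_events(cohort.icd_events), pmap)
    ccset = build_case_control(instances, pmap, simulate.OBESITY_PHECODE, cohort.participant_ids)
    obesity = data.join(ccset.status().rename("case")).dropna(subset=["case"])
    or_fit = models.fit_logistic(obesity, "case", "z_prs", PRS_COVARIATES)

    return {
        "n": n,
        "prs_effect": prs_fit.effect,
        "prs_ci": (prs_fit.ci_low, prs_fit.ci_high),
        "prs_se": prs_fit.se,
        "decile_contrast": contrast.effect,
        "decile_contrast_se": contrast.se,
        "obesity_or": or_fit.effect,
        "obesity_n_cases": ccset.n_cases,
        "incremental_r2": models.incremental_r2(data, "bmi", "z_prs", PRS_COVARIATES),
    }


def survey_subset_estimates(
    seed: int,
    n_analytic: int = simulate.SURVEY_SUBSET_N,
    n_weighting: int = simulate.WEIGHTING_SUBSET_N,
) -> dict:
    """Survey-subset battery: index effect and median-split stratified effects.

    Simulates under the interaction calibration (index main effect 1.49 per
    SD; stratified PRS targets 0.98/0.59), classifies the six risk factors
    from raw survey answers, derives factor weights by OLS in the independent
    weighting subset, builds the standardized index in the analytic subset,
    and fits the index model and the interaction/stratified PRS models.
    """
    config, preset = simulate.survey_cohort_config(
        seed, n_analytic=n_analytic, n_weighting=n_weighting
    )
    cohort = simulate.generate_cohort(config)
    analytic_ids, weighting_ids = simulate.split_survey_cohort(cohort, n_analytic=n_analytic)

    survey = ls.complete_cases(cohort.survey)
    profiles = ls.classify_risk_factors(survey)
    covs = cohort.frame()
    w_ids = profiles.index.intersection(weighting_ids)
    weights = ls.derive_factor_weights(
        profiles.loc[w_ids], covs.loc[w_ids, "bmi"], covs.loc[w_ids, "age"], covs.loc[w_ids, "sex"]
    )
    a_ids = profiles.index.intersection(analytic_ids)
    index = ls.compute_index(profiles.loc[a_ids], weights)

    data = covs.loc[a_ids].copy()
    data["l_index"] = index.z
    data["z_prs"] = prs.compute_scores(cohort.dosages.loc[a_ids], config.panel).z

    index_fit = models.fit_linear(data, "bmi", "l_index", INDEX_COVARIATES)
    inter = models.fit_interaction(data, "bmi", "z_prs", "l_index", PRS_COVARIATES)
    high = inter.stratified["high"]
    low = inter.stratified["low"]
    return {
        "n": n_analytic,
        "index_effect": index_fit.effect,
        "index_ci": (index_fit.ci_low, index_fit.ci_high),
        "high_effect": high.effect,
        "high_ci": (high.ci_low, high.ci_high),
        "low_effect": low.effect,
        "low_ci": (low.ci_low, low.ci_high),
        "beta_interaction": inter.beta_interaction,
        "p_interaction": inter.p_interaction,
        "beta_interaction_true": preset.beta_interaction,
        "index_r2": models.incremental_r2(data, "bmi", "l_index", INDEX_COVARIATES),
        "factor_weights": weights.weights.to_dict(),
    }


def seed_battery(base_seed: int, n_seeds: int = 20) -> list[int]:
    """Deterministic per-replicate seeds spawned from one base seed."""
    state = np.random.SeedSequence(base_seed).generate_state(n_seeds)
    return [int(s) % (2**31) for s in state]
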