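#!/usr/bin/env python
"""Stage 5 — phenome-wide association scan of the obesity PRS.

On the genetic cohort (n=33,511; obesity phecode calibrated to 8,349 cases
and OR 1.26 per SD, plus null phecodes): the phecode engine, the 1%-case
filtered logistic scan with Bonferroni correction, the BMI-adjusted refit,
Q10-vs-Q1 ORs for significant outcomes, morbidity-stratified and
post-enrollment sensitivity scans, and the interaction PheWAS over
scan-significant outcomes in the survey subset.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from prslife import lifestyle as ls
from prslife import models, phewas, prs, simulate
from prslife.phecode import (
    build_all_case_controls,
    default_phecode_map,
    dedupe_events,
    map_events,
    restrict_post_enrollment,
)
from prslife.replication import PRS_COVARIATES

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SEED = 2024


def case_control_sets(cohort, pmap, ids, events=None):
    events = cohort.icd_events if events is None else events
    instances = map_events(dedupe_events(events), pmap)
    present = sorted(set(instances["phecode"]) & set(pmap.phecodes))
    return build_all_case_controls(instances, pmap, ids, phecodes=present)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    pmap = default_phecode_map()
    config = simulate.main_cohort_config(SEED)
    cohort = simulate.generate_cohort(config)
    data = cohort.frame()
    data["z_prs"] = prs.compute_scores(cohort.dosages, config.panel).z
    n = len(data)

    ccsets = case_control_sets(cohort, pmap, cohort.participant_ids)
    min_cases = phewas.min_case_threshold(n)
    print(f"phecode engine: {len(ccsets)} phecodes with billing events; "
          f"minimum-case filter {min_cases} (1% of {n:,})")

    table = phewas.run_phewas(
        ccsets, data, "z_prs", PRS_COVARIATES, min_cases=min_cases,
        adjust_bmi="bmi", pmap=pmap,
    )
    table.to_csv(RESULTS / "phewas.csv", index=False)
    phewas.manhattan_export(table).to_csv(RESULTS / "phewas_manhattan.csv", index=False)
    print(f"scan: {len(table)} phecodes tested, Bonferroni "
          f"{table.attrs['bonferroni_threshold']:.2e}; "
          f"{int(table.significant.sum())} significant")
    for _, row in table.iterrows():
        mark = " *" if row.significant else ""
        print(f"  {row.phecode:>6s} {row.label:24s} OR/SD={row.or_per_sd:.3f} "
              f"P={row.p:.2e} (BMI-adj OR={row.or_bmi_adjusted:.3f}){mark}")

    sig = table.loc[table.significant, "phecode"].tolist()
    q_rows = []
    for pc in sig:
        q = phewas.extreme_decile_or(ccsets[pc], data, "z_prs", PRS_COVARIATES)
        q_rows.append({"phecode": pc, "label": pmap.label(pc), "or_q10_vs_q1": q.effect,
                       "ci_low": q.ci_low, "ci_high": q.ci_high, "p": q.p})
        print(f"extreme-decile OR for {pc} ({pmap.label(pc)}): "
              f"{q.effect:.2f} ({q.ci_low:.2f}, {q.ci_high:.2f})")
    pd.DataFrame(q_rows).to_csv(RESULTS / "phewas_decile_or.csv", index=False)

    # sensitivity: morbidity strata and >=1-year-post-enrollment diagnoses
    for stratum in ("low", "high"):
        ids = data.index[data["morbidity"] == stratum]
        t = phewas.run_phewas(
            case_control_sets(cohort, pmap, ids), data.loc[ids], "z_prs",
            PRS_COVARIATES, min_cases=phewas.min_case_threshold(len(ids)), pmap=pmap,
        ).set_index("phecode")
        if simulate.OBESITY_PHECODE in t.index:
            row = t.loc[simulate.OBESITY_PHECODE]
            print(f"obesity OR/SD, morbidity {stratum:>4s}: {row.or_per_sd:.3f} "
                  f"({row.ci_low:.3f}, {row.ci_high:.3f})")
    late = restrict_post_enrollment(cohort.icd_events, cohort.covariates["enrollment_date"])
    t = phewas.run_phewas(
        case_control_sets(cohort, pmap, cohort.participant_ids, events=late),
        data, "z_prs", PRS_COVARIATES, min_cases=min_cases, pmap=pmap,
    ).set_index("phecode")
    if simulate.OBESITY_PHECODE in t.index:
        row = t.loc[simulate.OBESITY_PHECODE]
        print(f"obesity OR/SD, diagnoses >=1 y post-enrollment only: {row.or_per_sd:.3f} "
              f"({row.ci_low:.3f}, {row.ci_high:.3f}; {int(row.n_cases):,} cases)")

    # interaction PheWAS on the survey subset (no disease-level interaction
    # is generated, so the expectation is a null scan)
    sconfig, _ = simulate.survey_cohort_config(SEED + 1)
    sconfig = dataclasses.replace(
        sconfig,
        disease_models={simulate.OBESITY_PHECODE: simulate.DiseaseModel(
            simulate.OBESITY_PREVALENCE, simulate.OBESITY_LOG_OR)},
        n_null_phecodes=8,
    )
    scohort = simulate.generate_cohort(sconfig)
    aid, wid = simulate.split_survey_cohort(scohort)
    profiles = ls.classify_risk_factors(ls.complete_cases(scohort.survey))
    covs = scohort.frame()
    w = profiles.index.intersection(wid)
    weights = ls.derive_factor_weights(
        profiles.loc[w], covs.loc[w, "bmi"], covs.loc[w, "age"], covs.loc[w, "sex"]
    )
    a = profiles.index.intersection(aid)
    sdata = covs.loc[a].copy()
    sdata["l_index"] = ls.compute_index(profiles.loc[a], weights).z
    sdata["z_prs"] = prs.compute_scores(scohort.dosages.loc[a], sconfig.panel).z
    scc = case_control_sets(scohort, pmap, a)
    tested = {pc: cc for pc, cc in scc.items() if cc.n_cases >= phewas.min_case_threshold(len(a))}
    itab = phewas.run_interaction_phewas(tested, sdata, "z_prs", "l_index",
                                         PRS_COVARIATES, pmap=pmap)
    itab.to_csv(RESULTS / "phewas_interaction.csv", index=False)
    print(f"\ninteraction PheWAS over {len(itab)} outcomes "
          f"(threshold {itab.attrs['bonferroni_threshold']:.2e}): "
          f"{int(itab.significant.sum())} significant; min P_int={itab.p_int.min():.3g}")
    print(f"\ntables: {RESULTS/'phewas.csv'}, {RESULTS/'phewas_decile_or.csv'}, "
          f"{RESULTS/'phewas_interaction.csv'}")


if __name__ == "__main__":
    main()
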