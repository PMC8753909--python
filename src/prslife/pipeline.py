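"""End-to-end orchestration: simulate a cohort to disk, then run the full
analysis sequence (per-variant scan -> concordance -> PRS/index models ->
interaction -> stratified -> phecode engine -> PheWAS -> interaction PheWAS)
and assemble a report.

Every numeric quantity in the report is first written to a results CSV; the
report layer only formats.  All randomness flows from the single seed in the
run configuration.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import lifestyle as ls
from . import models, phewas, prs, simulate
from .phecode import (
    build_all_case_controls,
    default_phecode_map,
    dedupe_events,
    map_events,
    restrict_post_enrollment,
)

log = logging.getLogger(__name__)

PRS_COVARIATES = ("age", "sex", "array", "pc1", "pc2", "pc3", "pc4", "pc5")
INDEX_COVARIATES = ("age", "sex")


@dataclass
class RunConfig:
    """Single-file YAML configuration for simulate / run-all."""

    outdir: str = "runs/demo"
    seed: int = 0
    preset: str = "full"  # main | survey | full
    n_participants: int | None = None
    n_weighting: int = simulate.WEIGHTING_SUBSET_N
    post_enrollment_days: int | None = None
    adjust_bmi: bool = True
    min_case_prevalence: float = 0.01
    alpha: float = 0.05
    input_dir: str | None = None

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} is not a YAML mapping")
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


def _generator_config(cfg: RunConfig) -> simulate.GeneratorConfig:
    if cfg.preset == "main":
        n = cfg.n_participants or simulate.MAIN_COHORT_N
        return simulate.main_cohort_config(cfg.seed, n=n)
    if cfg.preset in ("survey", "full"):
        n = cfg.n_participants or simulate.SURVEY_SUBSET_N
        gen, _ = simulate.survey_cohort_config(cfg.seed, n_analytic=n, n_weighting=cfg.n_weighting)
        if cfg.preset == "full":
            gen = dataclasses.replace(
                gen,
                disease_models={
                    simulate.OBESITY_PHECODE: simulate.DiseaseModel(
                        simulate.OBESITY_PREVALENCE, simulate.OBESITY_LOG_OR
                    )
                },
                n_null_phecodes=8,
            )
        return gen
    raise ValueError(f"unknown preset {cfg.preset!r}")


def run_simulate(cfg: RunConfig) -> Path:
    """Generate a cohort and write all standard-format inputs to disk.

    Writes dosages as VCF (DS field) and wide TSV; survey, ICD events and
    covariates (incl. BMI and the analytic/weighting split) as CSV; the run
    configuration as YAML; and the latent ground truth for validation.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gen = _generator_config(cfg)
    log.info("simulating preset=%s n=%d seed=%d", cfg.preset, gen.n_participants, gen.seed)
    cohort = simulate.generate_cohort(gen)

    n_analytic = gen.n_participants - (cfg.n_weighting if cfg.preset in ("survey", "full") else 0)
    covs = cohort.frame().copy()
    covs["subset"] = ["analytic"] * n_analytic + ["weighting"] * (gen.n_participants - n_analytic)

    prs.write_dosages_vcf(cohort.dosages, gen.panel, outdir / "dosages.vcf")
    cohort.dosages.rename_axis("participant_id").to_csv(outdir / "dosages.tsv", sep="\t")
    covs.to_csv(outdir / "covariates.csv")
    cohort.survey.rename_axis("participant_id").to_csv(outdir / "survey.csv")
    cohort.icd_events.to_csv(outdir / "icd_events.csv", index=False)
    cohort.latent.rename_axis("participant_id").to_csv(outdir / "latent_truth_synthetic.csv")
    gen.panel.table.to_csv(outdir / "variant_panel.tsv", sep="\t", index=False)
    cfg.to_yaml(outdir / "config.yaml")
    log.info("simulate outputs written to %s (seed=%d)", outdir, gen.seed)
    return outdir


def _require(path: Path, what: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"{what} not found at {path}")
    return path


def run_all(cfg: RunConfig) -> Path:
    """Run the full analysis sequence over a simulated input directory."""
    indir = Path(cfg.input_dir) if cfg.input_dir else Path(cfg.outdir)
    outdir = Path(cfg.outdir) / "results"
    outdir.mkdir(parents=True, exist_ok=True)
    run_log: list[str] = []

    def note(msg: str) -> None:
        log.info(msg)
        run_log.append(f"{pd.Timestamp.now().isoformat()} {msg}")

    panel = prs.load_variant_weights(_require(indir / "variant_panel.tsv", "variant panel"))
    dosages = prs.load_dosages_tsv(_require(indir / "dosages.tsv", "dosage table"))
    covs = pd.read_csv(
        _require(indir / "covariates.csv", "covariate table"),
        index_col="participant_id",
        parse_dates=["enrollment_date"],
    )
    survey = pd.read_csv(_require(indir / "survey.csv", "lifestyle survey"), index_col="participant_id")
    events = pd.read_csv(_require(indir / "icd_events.csv", "ICD event table"), parse_dates=["date"])
    pmap = default_phecode_map()

    analytic = covs.index[covs["subset"] == "analytic"]
    weighting = covs.index[covs["subset"] == "weighting"]
    data = covs.loc[analytic].copy()
    n = len(data)
    note(f"analytic cohort n={n}; weighting subset n={len(weighting)}")

    # --- PRS ---
    scores = prs.compute_scores(dosages.loc[analytic], panel)
    scores.to_csv(outdir / "prs_scores.csv")
    data["z_prs"] = scores.z
    med = scores.allele_scaled.median()
    note(
        f"PRS built from {panel.n_variants} variants; median (range) allele-scaled score "
        f"{med:.1f} ({scores.allele_scaled.min():.1f}, {scores.allele_scaled.max():.1f})"
    )

    # --- per-variant scan + sign concordance ---
    scan = models.per_variant_scan(dosages.loc[analytic], data, "bmi", PRS_COVARIATES)
    scan.to_csv(outdir / "variant_scan.csv", index=False)
    conc = models.sign_concordance_test(
        scan.set_index("variant_id").loc[panel.variant_ids, "beta"], panel.weights
    )
    note(
        f"sign concordance: {conc.n_concordant}/{conc.n_total} variants match the discovery "
        f"direction, exact one-sided binomial P={conc.p:.3g}"
    )

    summary_rows = []

    def keep(quantity, res: models.AssocResult) -> None:
        summary_rows.append(
            {
                "quantity": quantity,
                "effect": res.effect,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p": res.p,
                "n": res.n,
                "scale": res.scale,
            }
        )

    # --- PRS main effect, variance explained, decile contrast ---
    prs_fit = models.fit_linear(data, "bmi", "z_prs", PRS_COVARIATES)
    keep("BMI per SD of PRS", prs_fit)
    r2 = models.incremental_r2(data, "bmi", "z_prs", PRS_COVARIATES)
    note(f"PRS incremental R2 for BMI: {100 * r2:.1f}%")
    keep("BMI contrast, PRS decile 10 vs 1", models.decile_contrast(data, "bmi", "z_prs", PRS_COVARIATES))
    for stratum, res in models.stratified_effects(
        data, "bmi", "z_prs", PRS_COVARIATES, "morbidity"
    ).items():
        keep(f"BMI per SD of PRS, morbidity {stratum}", res)

    # --- lifestyle index ---
    interaction = None
    if len(weighting) == 0:
        note("no weighting subset: lifestyle-index stages skipped")
    else:
        survey_cc = ls.complete_cases(survey)
        prof_w = ls.classify_risk_factors(survey_cc.loc[survey_cc.index.intersection(weighting)])
        weights = ls.derive_factor_weights(
            prof_w, covs.loc[prof_w.index, "bmi"], covs.loc[prof_w.index, "age"], covs.loc[prof_w.index, "sex"]
        )
        weights.weights.rename_axis("factor").to_csv(outdir / "factor_weights.csv")
        note(f"factor weights fit in weighting subset n={weights.n}")
        prof_a = ls.classify_risk_factors(survey_cc.loc[survey_cc.index.intersection(analytic)])
        index = ls.compute_index(prof_a, weights)
        index.to_csv(outdir / "lifestyle_index.csv")
        data["l_index"] = index.z
        keep("BMI per SD of lifestyle index", models.fit_linear(data, "bmi", "l_index", INDEX_COVARIATES))
        r2_idx = models.incremental_r2(data, "bmi", "l_index", INDEX_COVARIATES)
        note(f"lifestyle-index incremental R2 for BMI: {100 * r2_idx:.1f}%")

        interaction = models.fit_interaction(data, "bmi", "z_prs", "l_index", PRS_COVARIATES)
        note(
            f"PRS x index interaction on BMI: beta_int={interaction.beta_interaction:.3f}, "
            f"P_int={interaction.p_interaction:.3g}"
        )
        for stratum, res in interaction.stratified.items():
            keep(f"BMI per SD of PRS, {stratum} index stratum", res)

    # --- phecode engine + PheWAS ---
    if events.empty:
        note("no ICD events: PheWAS stages skipped")
    else:
        if cfg.post_enrollment_days:
            events = restrict_post_enrollment(
                events, covs["enrollment_date"], min_days=cfg.post_enrollment_days
            )
            note(f"post-enrollment filter (>= {cfg.post_enrollment_days} d) left {len(events)} events")
        deduped = dedupe_events(events)
        instances = map_events(deduped, pmap)
        present = sorted(set(instances["phecode"]) & set(pmap.phecodes))
        ccsets = build_all_case_controls(instances, pmap, analytic, phecodes=present)
        min_cases = phewas.min_case_threshold(n, cfg.min_case_prevalence)
        n_testable = sum(cc.n_cases >= min_cases for cc in ccsets.values())
        note(
            f"PheWAS thresholds: min cases {min_cases} ({100 * cfg.min_case_prevalence:.0f}% of {n}); "
            f"alpha/m_tested = {cfg.alpha}/{max(n_testable, 1)} = "
            f"{cfg.alpha / max(n_testable, 1):.3g}; alpha/min_cases = "
            f"{cfg.alpha / max(min_cases, 1):.3g} (both reported; the scan uses alpha/m_tested)"
        )
        table = phewas.run_phewas(
            ccsets,
            data,
            "z_prs",
            PRS_COVARIATES,
            min_cases=min_cases,
            adjust_bmi="bmi" if cfg.adjust_bmi else None,
            alpha=cfg.alpha,
            pmap=pmap,
        )
        table.to_csv(outdir / "phewas.csv", index=False)
        if len(table):
            phewas.manhattan_export(table).to_csv(outdir / "phewas_manhattan.csv", index=False)
            sig = table.loc[table["significant"], "phecode"].tolist()
            note(f"PheWAS: {len(table)} phecodes tested, {len(sig)} significant: {sig}")
            q_rows = []
            for pc in sig:
                q = phewas.extreme_decile_or(ccsets[pc], data, "z_prs", PRS_COVARIATES)
                q_rows.append(
                    {"phecode": pc, "or_q10_vs_q1": q.effect, "ci_low": q.ci_low,
                     "ci_high": q.ci_high, "p": q.p}
                )
            pd.DataFrame(q_rows).to_csv(outdir / "phewas_decile_or.csv", index=False)
            if "l_index" in data.columns and sig:
                itab = phewas.run_interaction_phewas(
                    {pc: ccsets[pc] for pc in sig}, data.dropna(subset=["l_index"]),
                    "z_prs", "l_index", PRS_COVARIATES, alpha=cfg.alpha, pmap=pmap,
                )
                itab.to_csv(outdir / "phewas_interaction.csv", index=False)
                note(
                    f"interaction PheWAS over {len(itab)} outcomes at threshold "
                    f"{itab.attrs.get('bonferroni_threshold', float('nan')):.3g}: "
                    f"{int(itab['significant'].sum())} significant"
                )
        obesity_or = table.loc[table["phecode"] == simulate.OBESITY_PHECODE]
        if len(obesity_or):
            row = obesity_or.iloc[0]
            summary_rows.append(
                {"quantity": "obesity phecode OR per SD of PRS", "effect": row["or_per_sd"],
                 "ci_low": row["ci_low"], "ci_high": row["ci_high"], "p": row["p"],
                 "n": int(row["n_cases"] + row["n_controls"]), "scale": "or"}
            )

    summary = pd.DataFrame(summary_rows)
    summary.to_csv(outdir / "summary.csv", index=False)
    (outdir / "run.log").write_text("\n".join(run_log) + "\n")
    report = ["prslife analysis report", "=" * 24, ""]
    for row in summary_rows:
        report.append(
            f"{row['quantity']}: {row['effect']:.3f} "
            f"(95% CI {row['ci_low']:.3f}, {row['ci_high']:.3f}; P={row['p']:.3g}; n={row['n']})"
        )
    if interaction is not None:
        report.append(
            f"PRS x index interaction: beta_int={interaction.beta_interaction:.4f} "
            f"(P_int={interaction.p_interaction:.3g}; n={interaction.n})"
        )
    (outdir / "report.txt").write_text("\n".join(report) + "\n")
    note(f"report written to {outdir}")
    return outdir
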