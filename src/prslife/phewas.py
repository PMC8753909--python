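"""Phenome-wide association scan of the PRS across phecode outcomes.

For every phecode with enough cases, the scan fits a covariate-adjusted
logistic regression of case status on the standardized PRS using that
phecode's own case/control set (excluded participants dropped).  Significance
uses a Bonferroni threshold over the number of phecodes actually tested.
Follow-ups: a BMI-adjusted refit, top-vs-bottom score-decile ORs, and an
interaction scan (PRS x lifestyle index) over scan-significant outcomes.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .models import AssocResult, ModelError, assign_deciles, fit_logistic
from .phecode import CaseControlSet

log = logging.getLogger(__name__)


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / m for m tests."""
    if m < 1:
        raise ValueError(f"need at least one test (m={m})")
    return alpha / m


def min_case_threshold(n_cohort: int, prevalence: float = 0.01) -> int:
    """Minimum case count for a 1% (by default) case-prevalence filter.

    floor(prevalence * n): at n=33,511 this gives 335, matching the published
    convention of requiring n_cases >= 335.
    """
    if n_cohort < 1:
        raise ValueError("empty cohort")
    return int(math.floor(prevalence * n_cohort))


def _scan_frame(ccset: CaseControlSet, data: pd.DataFrame) -> pd.DataFrame:
    status = ccset.status()
    sub = data.loc[data.index.intersection(status.index)].copy()
    sub["__case"] = status.reindex(sub.index)
    return sub


def run_phewas(
    case_control_sets: dict[str, CaseControlSet],
    data: pd.DataFrame,
    score: str,
    covariates=(),
    min_cases: int = 335,
    adjust_bmi: str | None = None,
    alpha: float = 0.05,
    pmap=None,
) -> pd.DataFrame:
    """Scan the score over all qualifying phecodes.

    ``data`` is indexed by participant id and carries the score, covariates,
    and (optionally) the BMI column named by ``adjust_bmi`` for the
    BMI-adjusted sensitivity refit.  Phecodes with fewer than ``min_cases``
    cases are filtered out before testing; the Bonferroni threshold uses the
    number of phecodes actually tested.  Non-convergent fits are flagged per
    row and the scan continues.
    """
    covariates = tuple(covariates)
    rows = []
    tested = [pc for pc, cc in case_control_sets.items() if cc.n_cases >= min_cases]
    skipped = len(case_control_sets) - len(tested)
    if skipped:
        log.info("minimum-case filter (>= %d) removed %d phecode(s)", min_cases, skipped)
    for pc in tested:
        cc = case_control_sets[pc]
        sub = _scan_frame(cc, data)
        try:
            res = fit_logistic(sub, "__case", score, covariates)
        except ModelError as exc:
            res = AssocResult(
                effect=float("nan"), se=float("nan"), ci_low=float("nan"),
                ci_high=float("nan"), p=float("nan"), n=len(sub), outcome=pc,
                exposure=score, scale="or", converged=False, note=str(exc),
            )
        row = {
            "phecode": pc,
            "label": pmap.label(pc) if pmap is not None else "",
            "group": pmap.group(pc) if pmap is not None else "",
            "n_cases": cc.n_cases,
            "n_controls": cc.n_controls,
            "or_per_sd": res.effect,
            "ci_low": res.ci_low,
            "ci_high": res.ci_high,
            "p": res.p,
            "converged": res.converged,
        }
        if adjust_bmi is not None:
            adj = fit_logistic(sub, "__case", score, (*covariates, adjust_bmi))
            row["or_bmi_adjusted"] = adj.effect
            row["p_bmi_adjusted"] = adj.p
        rows.append(row)
    table = pd.DataFrame(rows)
    if len(table):
        threshold = bonferroni_threshold(len(tested), alpha)
        table["significant"] = table["p"] < threshold
        table.attrs["bonferroni_threshold"] = threshold
        table.attrs["n_tested"] = len(tested)
        table = table.sort_values("phecode", kind="stable").reset_index(drop=True)
    return table


def extreme_decile_or(
    ccset: CaseControlSet, data: pd.DataFrame, score: str, covariates=()
) -> AssocResult:
    """Adjusted OR comparing the top (Q10) to bottom (Q1) score decile.

    Deciles are formed on the score over the phecode's analytic set
    (cases + controls); the logistic fit is restricted to the two extreme
    deciles with a Q10-vs-Q1 indicator exposure.
    """
    sub = _scan_frame(ccset, data)
    dec = assign_deciles(sub[score].to_numpy())
    extreme = sub.loc[(dec == 1) | (dec == 10)].copy()
    extreme["__q10"] = (dec[(dec == 1) | (dec == 10)] == 10).astype(float)
    res = fit_logistic(extreme, "__case", "__q10", tuple(covariates))
    if not (extreme.groupby("__q10")["__case"].nunique() == 2).all():
        res = AssocResult(**{**res.__dict__, "converged": False, "note": "empty case/control cell"})
    return AssocResult(**{**res.__dict__, "exposure": f"{score} Q10 vs Q1"})


def run_interaction_phewas(
    significant_sets: dict[str, CaseControlSet],
    data: pd.DataFrame,
    score: str,
    index: str,
    covariates=(),
    alpha: float = 0.05,
    pmap=None,
) -> pd.DataFrame:
    """Interaction scan (score x index) over scan-significant outcomes.

    Logistic model per outcome with score, index and their product; the
    Bonferroni threshold divides alpha by the number of outcomes tested here.
    Restricted upstream to the survey subset (participants with an index).
    """
    covariates = tuple(covariates)
    rows = []
    work = data.copy()
    prod = f"{score}_x_{index}"
    work[prod] = work[score] * work[index]
    for pc, cc in significant_sets.items():
        sub = _scan_frame(cc, work)
        res = fit_logistic(sub, "__case", prod, (score, index, *covariates))
        rows.append(
            {
                "phecode": pc,
                "label": pmap.label(pc) if pmap is not None else "",
                "n_cases": int(sub["__case"].sum()),
                "or_interaction": res.effect,
                "p_int": res.p,
                "converged": res.converged,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        threshold = bonferroni_threshold(len(table), alpha)
        table["significant"] = table["p_int"] < threshold
        table.attrs["bonferroni_threshold"] = threshold
        table = table.sort_values("phecode", kind="stable").reset_index(drop=True)
    return table


def manhattan_export(table: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready export: phecode, group, -log10 P and effect direction."""
    out = table[["phecode", "group"]].copy() if "group" in table.columns else table[["phecode"]].copy()
    out["neglog10_p"] = -np.log10(table["p"])
    out["direction"] = np.where(table["or_per_sd"] >= 1.0, "+", "-")
    return out
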