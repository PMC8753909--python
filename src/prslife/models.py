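"""Covariate-adjusted association models.

Thin, opinionated wrappers over statsmodels OLS/Logit that return tidy
results (effect, Wald SE/CI/P, n, descriptors) for the exposure of interest,
plus the composite analyses built on them: PRS x lifestyle interaction with
median-split stratified fits, rank-based decile contrasts, per-variant
additive scans, the exact sign-concordance replication test, and incremental
variance explained.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .lifestyle import dichotomize_index

log = logging.getLogger(__name__)


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class AssocResult:
    """One fitted contrast: effect, Wald SE, 95% CI, P, n, descriptors.

    ``scale`` is 'linear' (effect in outcome units) or 'or' (effect is an
    odds ratio; se is on the log-odds scale).
    """

    effect: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    outcome: str = ""
    exposure: str = ""
    covariates: tuple = ()
    scale: str = "linear"
    converged: bool = True
    note: str = ""


def _design(data: pd.DataFrame, outcome: str, exposure: str, covariates) -> tuple:
    cols = [outcome, exposure, *covariates]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ModelError(f"column(s) missing from data: {missing}")
    sub = data[cols].dropna()
    n_dropped = len(data) - len(sub)
    if n_dropped:
        log.info("listwise deletion dropped %d of %d rows", n_dropped, len(data))
    X = sub[[exposure, *covariates]].astype(float)
    if X[exposure].nunique() < 2:
        raise ModelError(f"exposure {exposure!r} is constant after listwise deletion")
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax() if len(X.columns) > 1 else (exposure,)
        raise ModelError(f"collinear design; check columns {tuple(worst)}")
    y = sub[outcome].astype(float)
    return y, design, sub


def fit_linear(data: pd.DataFrame, outcome: str, exposure: str, covariates=()) -> AssocResult:
    """OLS of ``outcome`` on ``exposure`` + ``covariates``; Wald inference for
    the exposure coefficient.  Rows with any missing value are dropped."""
    covariates = tuple(covariates)
    y, design, sub = _design(data, outcome, exposure, covariates)
    if len(sub) <= design.shape[1] + 2:
        raise ModelError(f"too few rows (n={len(sub)}) for {design.shape[1]} parameters")
    fit = sm.OLS(y, design).fit()
    ci = fit.conf_int().loc[exposure]
    return AssocResult(
        effect=float(fit.params[exposure]),
        se=float(fit.bse[exposure]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p=float(fit.pvalues[exposure]),
        n=int(fit.nobs),
        outcome=outcome,
        exposure=exposure,
        covariates=covariates,
    )


def fit_logistic(
    data: pd.DataFrame, outcome: str, exposure: str, covariates=(), min_cases: int = 10
) -> AssocResult:
    """ML logistic regression; effect reported as OR per exposure unit.

    Non-convergence and (quasi-)separation are flagged on the result
    (``converged=False`` with a note) rather than raised, so scans over many
    outcomes can continue.
    """
    covariates = tuple(covariates)
    y, design, sub = _design(data, outcome, exposure, covariates)
    yv = y.to_numpy(float)
    if not set(np.unique(yv)) <= {0.0, 1.0}:
        raise ModelError(f"outcome {outcome!r} must be binary 0/1")
    n_cases = int(yv.sum())
    if n_cases == 0 or n_cases == len(yv):
        raise ModelError(f"outcome {outcome!r} has a single class")
    if n_cases < min_cases:
        raise ModelError(f"too few cases (n={n_cases} < {min_cases}) for {outcome!r}")

    def _flagged(note: str) -> AssocResult:
        return AssocResult(
            effect=float("nan"), se=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
            p=float("nan"), n=len(yv), outcome=outcome, exposure=exposure,
            covariates=covariates, scale="or", converged=False, note=note,
        )

    try:
        fit = sm.Logit(yv, design).fit(disp=0, maxiter=100)
    except Exception as exc:  # PerfectSeparationError and friends
        return _flagged(f"separation or fit failure: {type(exc).__name__}")
    if not fit.mle_retvals.get("converged", True):
        return _flagged("did not converge")
    beta = float(fit.params[exposure])
    se = float(fit.bse[exposure])
    if not math.isfinite(se) or se > 50:
        return _flagged("quasi-separation (unstable SE)")
    ci = fit.conf_int().loc[exposure]
    return AssocResult(
        effect=math.exp(beta),
        se=se,
        ci_low=math.exp(float(ci[0])),
        ci_high=math.exp(float(ci[1])),
        p=float(fit.pvalues[exposure]),
        n=int(fit.nobs),
        outcome=outcome,
        exposure=exposure,
        covariates=covariates,
        scale="or",
    )


def stratified_effects(
    data: pd.DataFrame, outcome: str, exposure: str, covariates, strata: str
) -> dict[str, AssocResult]:
    """Independent covariate-adjusted fits within each stratum.

    Strata too small to fit (n <= p + 2) are skipped with a log entry.
    """
    out: dict[str, AssocResult] = {}
    for label, sub in data.groupby(strata, observed=True):
        try:
            out[str(label)] = fit_linear(sub, outcome, exposure, covariates)
        except ModelError as exc:
            log.info("stratum %r skipped: %s", label, exc)
    return out


@dataclass(frozen=True)
class InteractionResult:
    """Product-term model plus median-split stratified main effects."""

    beta_interaction: float
    se_interaction: float
    p_interaction: float
    beta_score: float
    beta_index: float
    n: int
    stratified: dict[str, AssocResult] = field(default_factory=dict)


def fit_interaction(
    data: pd.DataFrame, outcome: str, score: str, index: str, covariates=()
) -> InteractionResult:
    """BMI ~ score + index + score:index + covariates, plus stratified fits.

    The stratified fits regress the outcome on the score (with the same
    covariates) separately in the low/high groups from the median split of
    the index column.
    """
    covariates = tuple(covariates)
    work = data.copy()
    prod = f"{score}_x_{index}"
    work[prod] = work[score] * work[index]
    res = fit_linear(work, outcome, prod, (score, index, *covariates))
    full = work[[outcome, score, index, prod, *covariates]].dropna()
    full["__group"] = dichotomize_index(full[index].to_numpy())
    strat = stratified_effects(full, outcome, score, covariates, "__group")

    # main-effect coefficients from the same product-term model
    y, design, _ = _design(work, outcome, prod, (score, index, *covariates))
    fit = sm.OLS(y, design).fit()
    return InteractionResult(
        beta_interaction=res.effect,
        se_interaction=res.se,
        p_interaction=res.p,
        beta_score=float(fit.params[score]),
        beta_index=float(fit.params[index]),
        n=res.n,
        stratified=strat,
    )


def assign_deciles(values) -> np.ndarray:
    """Rank-based decile labels 1..10; ties broken to the lower decile.

    Ties are resolved by ordinal ranking in order of appearance, which sends
    earlier tied rows to the lower decile — deterministic for a fixed row
    order.
    """
    x = np.asarray(values, dtype=float)
    if np.unique(x).size < 10:
        raise ModelError("need at least 10 distinct values to form deciles")
    ranks = stats.rankdata(x, method="ordinal")
    return np.minimum(9, ((ranks - 1) * 10) // len(x)).astype(int) + 1


def decile_contrast(data: pd.DataFrame, outcome: str, score: str, covariates=()) -> AssocResult:
    """Covariate-adjusted mean outcome difference, top vs bottom score decile."""
    covariates = tuple(covariates)
    sub = data[[outcome, score, *covariates]].dropna()
    if len(sub) < 20:
        raise ModelError(f"n={len(sub)} too small to form deciles")
    dec = assign_deciles(sub[score].to_numpy())
    extreme = sub.loc[(dec == 1) | (dec == 10)].copy()
    extreme["__top_decile"] = (dec[(dec == 1) | (dec == 10)] == 10).astype(float)
    res = fit_linear(extreme, outcome, "__top_decile", covariates)
    return AssocResult(
        **{**res.__dict__, "exposure": f"{score} decile 10 vs 1"}
    )


def per_variant_scan(
    dosages: pd.DataFrame, data: pd.DataFrame, outcome: str, covariates=()
) -> pd.DataFrame:
    """Per-variant additive scan: one OLS per dosage column.

    Returns a tidy table (variant_id, beta, se, ci, p, n); monomorphic
    variants are skipped with a log entry.
    """
    covariates = tuple(covariates)
    rows = []
    for vid in dosages.columns:
        work = data.copy()
        work["__dosage"] = dosages[vid].reindex(work.index).to_numpy(float)
        try:
            res = fit_linear(work, outcome, "__dosage", covariates)
        except ModelError as exc:
            log.info("variant %s skipped: %s", vid, exc)
            continue
        rows.append(
            {
                "variant_id": vid,
                "beta": res.effect,
                "se": res.se,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p": res.p,
                "n": res.n,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ConcordanceResult:
    """Exact one-sided binomial test of effect-direction replication."""

    n_total: int
    n_concordant: int
    p: float


def exact_binomial_tail(k: int, n: int) -> float:
    """P(X >= k) for X ~ Binomial(n, 1/2), by exact integer summation."""
    if not 0 <= k <= n:
        raise ModelError(f"k={k} outside [0, {n}]")
    total = sum(math.comb(n, i) for i in range(k, n + 1))
    return float(Fraction(total, 2**n))


def sign_concordance_test(betas_observed, betas_reference) -> ConcordanceResult:
    """Count sign agreements against a reference (discovery) effect vector.

    A zero observed effect counts as discordant.  The P value is the exact
    one-sided upper binomial tail at p0 = 1/2 (the replication hypothesis is
    more agreement than chance).
    """
    obs = np.asarray(betas_observed, dtype=float)
    ref = np.asarray(betas_reference, dtype=float)
    if obs.shape != ref.shape:
        raise ModelError("observed and reference effect vectors differ in length")
    if np.any(ref == 0):
        raise ModelError("reference effects must be nonzero")
    concordant = int(np.sum(np.sign(obs) * np.sign(ref) > 0))
    return ConcordanceResult(
        n_total=obs.size, n_concordant=concordant, p=exact_binomial_tail(concordant, obs.size)
    )


def incremental_r2(data: pd.DataFrame, outcome: str, exposure: str, covariates=()) -> float:
    """R2(covariates + exposure) - R2(covariates only)."""
    covariates = tuple(covariates)
    sub = data[[outcome, exposure, *covariates]].dropna()
    y = sub[outcome].astype(float)
    full = sm.add_constant(sub[[exposure, *covariates]].astype(float), has_constant="add")
    r2_full = sm.OLS(y, full).fit().rsquared
    if covariates:
        base = sm.add_constant(sub[list(covariates)].astype(float), has_constant="add")
        r2_base = sm.OLS(y, base).fit().rsquared
    else:
        r2_base = 0.0
    return float(r2_full - r2_base)
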