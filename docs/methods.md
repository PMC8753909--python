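# Methods

`prslife` re-creates, on fully synthetic data, a biobank-style analysis of
obesity genetics and lifestyle: a 97-variant polygenic risk score (PRS) for
BMI, a weighted index of six obesogenic lifestyle behaviours, their
interaction on clinically measured BMI, and a phenome-wide association scan
(PheWAS) of the PRS across phecode-defined diseases.  This note documents
the models, the generator the analyses run on, the numerical choices, and
what the passing checks do and do not show.

## The polygenic risk score

For dosages `d_ij ∈ [0, 2]` of the effect allele of variant `j` in
participant `i` and per-allele weights `β_j > 0` (all oriented to the
BMI-increasing allele at load time; negative input weights are flipped to
the other allele and logged):

    raw_i    = Σ_j β_j d_ij
    scaled_i = raw_i / (2 Σ_j β_j) · 2N          (allele scale, range [0, 2N])
    Z_i      = (scaled_i − mean) / SD            (sample SD, n−1)

The allele scale divides by twice the weight sum and multiplies by twice the
variant count, so `scaled` reads as an equivalent count of risk alleles: an
all-heterozygote scores exactly `N`, a participant homozygous for every risk
allele exactly `2N = 194`.  A published description of this rescaling reads
"twice the square of the SNP count", which conflicts with its own gloss that
the factor represents the maximum number of risk alleles (2N² = 18,818 is
not an allele count; 2N = 194 is); we implement `×2N`, matching the gloss
and standard practice, and record the literal alternative here.  Because the
three scales are affine images of one another, every downstream regression
on `Z` is invariant to this choice.

Missing dosages are a hard error by default (`mean_impute=True` opts into
column-mean imputation); panel variants absent from the dosage table are
never silently skipped.  Allele harmonization treats strand-ambiguous (A/T,
C/G) variants as unresolvable and passes them through with a warning.

## The obesogenic lifestyle risk index

Six binary indicators are classified from raw survey answers:

| factor | risk (=1) rule | reference (=0) |
|---|---|---|
| alcohol | any category other than "1-2 per day" (more *or* less) | 1-2 drinks/day |
| education | below masters/doctoral/professional degree | masters+ |
| inactivity | < 2.5 h/week moderate-to-high-intensity exercise | ≥ 2.5 h/week |
| sleep | weighted duration < 8 h or ≥ 10 h per night | 8-10 h |
| smoking | former smoker (quit) | never or current |
| shift work | night shift | any other schedule |

Sleep duration is computed per day as `(wake − bed) mod 24` from half-hour
clock times and combined as `5/7 × weekday + 2/7 × weekend`; equal bed and
wake times are rejected as ambiguous (0 vs 24 h).  The exercise sum counts
bicycling, higher-intensity exercise, jogging, lap swimming, running and
racquet sports; walking/hiking is excluded by definition of the factor, and
we also exclude the explicitly lower-intensity activity since it is not
moderate-to-high intensity.  Current smokers fold into the reference because
the named risk factor is *former* smoking; whether the original analysis
used one or two smoking dummies is not recoverable, so one binary is used.

Index weights `w_k` are the six indicator coefficients from a single OLS fit
of BMI on all six indicators plus age and sex, estimated in a weighting
subset disjoint from the analytic subset (rank-deficiency from a constant
indicator is an error naming the factor; n ≤ 50 is refused).  The index is
`raw = Σ_k w_k X_k`, standardized to mean 0 / SD 1, and dichotomized at the
population median with ties going to "low" (deterministic; with discrete
mass at the median the groups can be unequal but always partition the
cohort).  Missing survey items drop the participant (complete-case), with
counts logged.

## Phecode case/control algorithm

Billing events `(participant, date, vocabulary, code)` are reduced per
phecode:

1. exact same-day duplicates collapse to one; non-ICD-9/-10 vocabularies are
   dropped with a count;
2. events map to phecodes by exact string match (no hierarchy rollup), and
   unmapped codes are counted, not fatal;
3. a participant with ≥ 2 surviving instances of the phecode is a case (two
   *different* ICD codes mapping to the phecode on the same day count as
   two); exactly 1 instance excludes the participant (`one_code`); a
   non-case with any instance inside the phecode's exclusion ranges is
   excluded (`exclusion_range`); everyone else is a control.

Exclusion ranges exist to keep related diseases out of the control pool, so
a participant meeting the case rule stays a case even when carrying
exclusion-range codes; when both exclusion reasons apply, `one_code` is
recorded.  The post-enrollment sensitivity filter keeps events dated
`≥ enrollment + 365 days` (inclusive boundary).  The shipped 40-phecode map
is synthetic except that the obesity phecode 278.1 carries a realistic
ICD-9/ICD-10 code list; its exclusion range is 278-279.99.

## Association models and scans

All fits go through statsmodels (OLS; maximum-likelihood logistic) with Wald
SEs, 95% CIs and P values for the exposure coefficient, listwise deletion
(counts logged) and hard errors for collinear or constant designs.
Logistic non-convergence and (quasi-)separation are flagged on the result
row rather than raised, so phenome-wide scans continue past bad outcomes.

* **Interaction model**: BMI ~ Z + L + Z·L + age + sex + array + 5 PCs,
  with stratified per-SD PRS fits in the median-split low/high index groups
  (the caption-level covariate set, which includes age and sex, is used).
* **Decile contrast**: rank-based deciles (ordinal ranks; ties to the lower
  decile, deterministic for a fixed row order; < 10 distinct values is an
  error), then a covariate-adjusted fit of the outcome on a Q10-vs-Q1
  indicator restricted to the extreme deciles.  For a standard-normal score
  with per-SD effect `b`, the expected contrast is
  `b · 2φ(z_0.9)/0.1 ≈ 3.510 b`.
* **Sign concordance**: the count of variants whose scan effect sign matches
  the discovery weight sign (zero effects count as discordant) is tested
  against Binomial(n, ½) with an exact one-sided upper tail computed by
  integer arithmetic (`math.comb` summation over `2^n`); one-sided because
  the hypothesis is replication.  For 91/97 the exact tail is 6.665×10⁻²¹.
* **Variance explained**: incremental R², `R²(covariates + exposure) −
  R²(covariates)`.
* **PheWAS**: per qualifying phecode, a logistic fit of its own case/control
  set on the standardized PRS.  The minimum-case filter is
  `floor(0.01 · N)` (= 335 at N = 33,511).  The Bonferroni threshold divides
  α by the number of phecodes actually tested after filtering; the run log
  also prints α/min-cases, because the two conventions disagree in published
  practice and we do not silently pick one.  Follow-ups: BMI-adjusted refit,
  Q10-vs-Q1 ORs for significant rows, and an interaction scan
  (score × index product term) over scan-significant outcomes with α divided
  by the number of those outcomes (0.00125 for 40).

## The synthetic cohort generator

The generator emulates the analytic cohorts: BMI is

    BMI_i = μ + 0.02·age_i − 0.5·sex_i + b_PRS·Z_i + b_L·L_i + b_int·Z_i·L_i + ε_i

with `Z` the standardized PRS computed from binomial dosages
(`d_ij ~ Bin(2, f_j)`, linkage equilibrium — real LD structure is irrelevant
to the estimands tested) *through the actual scoring code*, and `L` the
standardized latent index `Σ a_k X_k` over six correlated binaries from a
Gaussian copula with exchangeable correlation 0.1.  The residual variance is
set to `bmi_sd² − Var(systematic)` using the realized systematic component,
so the marginal mean/SD match the configured 28.3/6.3 kg/m² by
construction; infeasible coefficient combinations raise.  Age is
N(60, 17) truncated to [18, 100], sex Bernoulli(0.53), genotyping array
Bernoulli(0.5), five PCs standard-normal nuisance columns with zero true
effect, and a morbidity stratum (low/mid/high, 25/50/25%) is carried as an
input column with no generated effect.

Survey answers are emitted on the correct side of each classifier threshold
(category strings from the legal lists; exercise totals drawn off the 2.5 h
boundary; sleep durations on the half-hour grid with equal weekday/weekend
duration so the 5/7–2/7 weighting is exact), which makes the
classifier round trip exact by design — a deliberately noiseless channel.
Default factor risk prevalences (alcohol 0.85, education 0.80, inactivity
0.50, sleep 0.35, former smoking 0.30, night shift 0.05) and relative
generating weights (0.5, 0.9, 1.2, 0.8, 0.6, 0.7 kg/m²) are choices
documented here, not inferred values: no per-factor prevalences were
available to anchor them.

Disease status for a modeled phecode follows
`case ~ Bernoulli(logistic(α + logOR·Z))` with `α` solved by root-finding so
the realized prevalence matches the target (obesity: 8,349/33,511 ≈ 24.9%,
logOR = ln 1.26).  Cases receive `2 + Poisson(1)` mapped billing events on
distinct dates uniform in a 10-year window centred on enrollment (so the
one-year post-enrollment filter has bite); small configurable fractions of
non-cases receive exactly one event (exercising the one-code exclusion) or
one exclusion-range event; null phecodes use logOR = 0.  Disease risk is
generated *directly* from `Z`, not mediated through BMI, so BMI adjustment
barely moves the obesity OR in this cohort — mediated outcomes exist only in
targeted tests.

### Interaction calibration

Because `Z ⊥ L`, the stratified per-SD PRS effect in a median-split group is
`b_PRS + b_int·E[L | group]`.  `calibrate_preset` measures the conditional
means `cH, cL` of the standardized index above/below the median on a pilot
simulation of the discrete factor index (pilot n = 200,000, fixed seed) and
solves

    b_int = (target_high − target_low) / (cH − cL),
    b_PRS = target_high − b_int·cH .

For an exactly normal index `cH − cL = 2√(2/π) ≈ 1.5958`, giving
`b_int ≈ 0.2444`, `b_PRS ≈ 0.785` for targets (0.98, 0.59); the discrete
six-factor index gives `cH − cL ≈ 1.653` and `b_int ≈ 0.236`.  Downstream
stratification uses the index re-derived from estimated weights, so the
closure check (simulate, re-estimate, compare to targets) is part of the
test suite.

## What passing checks show — and what they do not

The replication checks (per-SD PRS effect 0.83, index effect 1.49,
stratified 0.98/0.59, obesity OR 1.26, decile contrast vs 2.87) are
parameter-recovery exercises on cohorts *calibrated to those values* at the
published sample sizes.  They validate the full computational chain — survey
classification, weight derivation, standardization, the phecode engine, the
adjusted fits — not the epidemiology: real cohorts have LD, survey
measurement error and misclassification, informative missingness,
BMI-mediated disease risk, confounded lifestyle–genetics relationships and
population structure, none of which the generator emulates (by design; PCs
and the morbidity stratum are pure nuisance columns here).  Where a fixed
published CI is used as the per-seed acceptance band, an estimator with the
same sampling variance lands inside it ~93–96% of the time, so seed-level
results near the 19/20 boundary are expected behaviour, not instability.

Problem sizes: replication batteries run 20 seeds at n = 33,511 (genetic
cohort) and 17,040 + 30,045 (survey + weighting subsets), ~3 s per seed;
null-calibration checks (interaction type-I error, familywise error of the
null scan, P-uniformity) run at reduced n (120–400) over 200–1000
replicates, sizes chosen to make the Monte-Carlo error small relative to the
asserted bands.

## Known limitations

* The generator's survey channel is noiseless; classifier robustness to
  malformed answers is tested separately with hand-built fixtures.
* The exact-tail concordance P for 91/97 (6.665×10⁻²¹) is computed and
  documented; published accounts of the same count have printed slightly
  different values, and the implementation stands by its own exact
  computation.
* Incremental R² of the PRS implied by an 0.83 per-SD effect at SD 6.3 is
  (0.83/6.3)² ≈ 1.7%; published variance-explained figures for comparable
  scores (2.9%) cannot be reconciled with those marginals under this
  definition, so variance explained is reported as computed, not calibrated.
* The phecode map is a 40-code toy; scan behaviour on a 1,800-code phenome
  (runtime, multiplicity) is extrapolated, not tested.
* No mixed models, robust SEs, survival outcomes, ICD GEM translation or
  phecode version migration.
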