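"""Association models: OLS/logistic wrappers against independent references,
decile contrasts, interaction + stratified fits, the per-variant scan, the
exact concordance test and incremental variance explained."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prslife import models
from prslife.models import ModelError

from conftest import rng


def linear_data(n=200, beta=2.0, noise=1.0, seed_offset=20):
    r = rng(seed_offset)
    df = pd.DataFrame(
        {
            "x": r.normal(size=n),
            "age": r.normal(60, 10, n),
            "sex": r.integers(0, 2, n).astype(float),
        }
    )
    df["y"] = beta * df["x"] + 0.1 * df["age"] - 0.4 * df["sex"] + r.normal(0, noise, n)
    return df


class TestFitLinear:
    def test_noise_free_exact(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]})
        df["y"] = 2 * df["x"]
        res = models.fit_linear(df, "y", "x")
        assert res.effect == pytest.approx(2.0, abs=1e-10)
        assert res.se == pytest.approx(0.0, abs=1e-8)

    def test_irrelevant_covariates_leave_estimate_unbiased(self):
        ests = []
        for s in range(100):
            r = np.random.default_rng(5000 + s)
            n = 60
            df = pd.DataFrame({"x": r.normal(size=n), "junk": r.normal(size=n)})
            df["y"] = 1.5 * df["x"] + r.normal(size=n)
            ests.append(models.fit_linear(df, "y", "x", ("junk",)).effect)
        mc_se = np.std(ests, ddof=1) / 10
        assert abs(np.mean(ests) - 1.5) < 3 * mc_se

    def test_collinearity_error_names_columns(self):
        df = linear_data()
        df["x2"] = 2 * df["x"]
        with pytest.raises(ModelError, match="collinear"):
            models.fit_linear(df, "y", "x", ("x2",))

    def test_constant_exposure_rejected(self):
        df = linear_data()
        df["x"] = 1.0
        with pytest.raises(ModelError, match="constant"):
            models.fit_linear(df, "y", "x")

    def test_listwise_deletion_reflected_in_n(self):
        df = linear_data(n=100)
        df.loc[:9, "age"] = np.nan
        res = models.fit_linear(df, "y", "x", ("age",))
        assert res.n == 90

    def test_ci_brackets_point_estimate(self):
        res = models.fit_linear(linear_data(), "y", "x", ("age", "sex"))
        assert res.ci_low < res.effect < res.ci_high
        assert res.p < 1e-10

    def test_wald_ci_coverage_near_nominal(self):
        covered = 0
        n_sims = 500
        for s in range(n_sims):
            r = np.random.default_rng(7000 + s)
            df = pd.DataFrame({"x": r.normal(size=80)})
            df["y"] = 0.5 * df["x"] + r.normal(size=80)
            res = models.fit_linear(df, "y", "x")
            covered += res.ci_low < 0.5 < res.ci_high
        assert 0.92 <= covered / n_sims <= 0.98


class TestAgainstRReference:
    """statsmodels-backed fits must agree with R's lm/glm to 1e-8."""

    def test_lm_and_glm_coefficients(self, tmp_path):
        df = linear_data(n=150, seed_offset=21)
        df["case"] = (df["y"] + rng(22).normal(0, 2, 150) > df["y"].median()).astype(int)
        csv = tmp_path / "fixture.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "ref.R"
        script.write_text(
            textwrap.dedent(
                """
                d <- read.csv(commandArgs(trailingOnly=TRUE)[1])
                lin <- lm(y ~ x + age + sex, data=d)
                log <- glm(case ~ x + age + sex, data=d, family=binomial())
                cat(sprintf("%.12f %.12f %.12f %.12f\\n",
                    coef(lin)[["x"]], summary(lin)$coefficients["x", 2],
                    coef(log)[["x"]], summary(log)$coefficients["x", 2]))
                """
            )
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script), str(csv)],
            capture_output=True, text=True, check=True,
        )
        r_lin_b, r_lin_se, r_log_b, r_log_se = map(float, out.stdout.split())
        lin = models.fit_linear(df, "y", "x", ("age", "sex"))
        log = models.fit_logistic(df, "case", "x", ("age", "sex"))
        assert lin.effect == pytest.approx(r_lin_b, abs=1e-8)
        assert lin.se == pytest.approx(r_lin_se, abs=1e-8)
        assert np.log(log.effect) == pytest.approx(r_log_b, abs=1e-6)
        assert log.se == pytest.approx(r_log_se, abs=1e-6)


class TestFitLogistic:
    def test_two_by_two_table_matches_cross_product_or(self):
        # (cases, controls) = (20, 80) exposed; (10, 90) unexposed
        y = [1] * 20 + [0] * 80 + [1] * 10 + [0] * 90
        x = [1.0] * 100 + [0.0] * 100
        df = pd.DataFrame({"y": y, "x": x})
        res = models.fit_logistic(df, "y", "x")
        assert res.effect == pytest.approx((20 * 90) / (80 * 10), rel=1e-6)

    def test_null_association_or_near_one(self):
        r = rng(23)
        df = pd.DataFrame({"x": r.normal(size=2000), "y": r.integers(0, 2, 2000)})
        res = models.fit_logistic(df, "y", "x")
        assert res.ci_low < 1.0 < res.ci_high

    def test_separation_flagged_not_raised(self):
        df = pd.DataFrame({"x": np.r_[np.ones(30), -np.ones(30)], "y": np.r_[np.ones(30), np.zeros(30)]})
        res = models.fit_logistic(df, "y", "x")
        assert not res.converged
        assert res.note != ""

    def test_single_class_rejected(self):
        df = pd.DataFrame({"x": rng(24).normal(size=50), "y": np.ones(50)})
        with pytest.raises(ModelError, match="single class"):
            models.fit_logistic(df, "y", "x")


class TestDecileContrast:
    def test_null_score_contrast_near_zero(self):
        r = rng(25)
        df = pd.DataFrame({"s": r.normal(size=3000), "y": r.normal(28, 6, 3000)})
        res = models.decile_contrast(df, "y", "s")
        assert res.ci_low < 0 < res.ci_high

    def test_truncated_normal_expectation(self):
        """For a standard-normal score with per-SD effect b, the expected
        Q10-Q1 contrast is b * 2 * phi(z_0.9)/0.1 ~ 3.510 b."""
        r = rng(26)
        n, b = 40000, 1.0
        df = pd.DataFrame({"s": r.normal(size=n)})
        df["y"] = b * df["s"] + r.normal(0, 0.5, n)
        res = models.decile_contrast(df, "y", "s")
        expected = b * 2 * stats.norm.pdf(stats.norm.ppf(0.9)) / 0.1
        assert res.effect == pytest.approx(expected, abs=0.06)

    def test_too_few_distinct_values_rejected(self):
        df = pd.DataFrame({"s": [1.0, 2.0] * 20, "y": rng(27).normal(size=40)})
        with pytest.raises(ModelError, match="distinct"):
            models.decile_contrast(df, "y", "s")

    def test_decile_assignment_ties_to_lower(self):
        d = models.assign_deciles(np.arange(100) // 5)  # 20 distinct values
        assert d.min() == 1 and d.max() == 10
        counts = np.bincount(d)[1:]
        assert (counts == 10).all()


class TestStratifiedEffects:
    def test_identical_strata_identical_estimates(self):
        df = linear_data(n=200, seed_offset=28)
        both = pd.concat([df.assign(g="a"), df.assign(g="b")], ignore_index=True)
        res = models.stratified_effects(both, "y", "x", ("age",), "g")
        assert res["a"].effect == pytest.approx(res["b"].effect)

    def test_small_stratum_skipped(self, caplog):
        import logging

        df = linear_data(n=100, seed_offset=29)
        df["g"] = ["big"] * 97 + ["small"] * 3
        with caplog.at_level(logging.INFO, logger="prslife.models"):
            res = models.stratified_effects(df, "y", "x", ("age",), "g")
        assert set(res) == {"big"}
        assert "skipped" in caplog.text

    def test_equal_true_effects_give_overlapping_cis(self):
        overlaps = 0
        for s in range(40):
            r = np.random.default_rng(8000 + s)
            n = 400
            df = pd.DataFrame({"x": r.normal(size=n), "g": np.repeat(["a", "b"], n // 2)})
            df["y"] = 0.8 * df["x"] + r.normal(size=n)
            res = models.stratified_effects(df, "y", "x", (), "g")
            overlaps += res["a"].ci_low <= res["b"].ci_high and res["b"].ci_low <= res["a"].ci_high
        assert overlaps / 40 >= 0.95


class TestInteraction:
    def test_recovers_injected_interaction(self):
        r = rng(30)
        n = 4000
        df = pd.DataFrame({"z": r.normal(size=n), "l": r.normal(size=n)})
        df["y"] = 0.8 * df["z"] + 1.5 * df["l"] + 0.25 * df["z"] * df["l"] + r.normal(0, 6, n)
        res = models.fit_interaction(df, "y", "z", "l")
        assert abs(res.beta_interaction - 0.25) < 1.96 * res.se_interaction
        assert set(res.stratified) == {"low", "high"}
        # stratified effects bracket the main effect: b + b_int*E[l|group]
        assert res.stratified["high"].effect > res.stratified["low"].effect

    def test_null_interaction_p_uniform(self):
        """Under the null the interaction P value is Uniform(0,1) (KS test
        over 200 reduced-n simulations at alpha=0.01)."""
        pvals = []
        for s in range(200):
            r = np.random.default_rng(9000 + s)
            n = 120
            df = pd.DataFrame({"z": r.normal(size=n), "l": r.normal(size=n)})
            df["y"] = 0.5 * df["z"] + 0.5 * df["l"] + r.normal(size=n)
            pvals.append(models.fit_interaction(df, "y", "z", "l").p_interaction)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestPerVariantScan:
    def test_scan_equals_looped_single_fits(self, small_panel):
        r = rng(31)
        n = 300
        dosages = pd.DataFrame(
            r.integers(0, 3, size=(n, 5)).astype(float), columns=small_panel.variant_ids
        )
        data = pd.DataFrame({"age": r.normal(60, 10, n)})
        data["bmi"] = 28 + 0.5 * dosages["v2"] + r.normal(0, 3, n)
        scan = models.per_variant_scan(dosages, data, "bmi", ("age",))
        assert len(scan) == 5
        for _, row in scan.iterrows():
            work = data.copy()
            work["__dosage"] = dosages[row.variant_id]
            single = models.fit_linear(work, "bmi", "__dosage", ("age",))
            assert row.beta == pytest.approx(single.effect)
            assert row.p == pytest.approx(single.p)

    def test_single_causal_variant_recovered(self, small_panel):
        r = rng(32)
        n = 5000
        dosages = pd.DataFrame(
            r.binomial(2, 0.4, size=(n, 5)).astype(float), columns=small_panel.variant_ids
        )
        data = pd.DataFrame({"age": r.normal(60, 10, n)})
        data["bmi"] = 28 + 0.58 * dosages["v1"] + r.normal(0, 6, n)
        scan = models.per_variant_scan(dosages, data, "bmi", ("age",)).set_index("variant_id")
        assert scan.loc["v1", "ci_low"] < 0.58 < scan.loc["v1", "ci_high"]

    def test_monomorphic_variant_skipped(self, small_panel, caplog):
        import logging

        r = rng(33)
        dosages = pd.DataFrame(
            r.integers(0, 3, size=(50, 5)).astype(float), columns=small_panel.variant_ids
        )
        dosages["v3"] = 2.0
        data = pd.DataFrame({"bmi": r.normal(28, 6, 50)})
        with caplog.at_level(logging.INFO, logger="prslife.models"):
            scan = models.per_variant_scan(dosages, data, "bmi")
        assert "v3" not in set(scan["variant_id"])
        assert len(scan) == 4


class TestSignConcordance:
    def test_all_agree_closed_form(self):
        res = models.sign_concordance_test(np.ones(10), np.ones(10))
        assert res.n_concordant == 10
        assert res.p == pytest.approx(0.5**10)

    @pytest.mark.parametrize("n", [5, 23, 97])
    def test_exact_tail_matches_scipy_for_all_k(self, n):
        for k in range(n + 1):
            ours = models.exact_binomial_tail(k, n)
            reference = stats.binomtest(k, n, 0.5, alternative="greater").pvalue
            assert ours == pytest.approx(reference, rel=1e-12)

    def test_91_of_97_value(self):
        # the exact one-sided tail for the published concordance count
        res = models.sign_concordance_test(np.ones(97), np.ones(97))
        p_91 = models.exact_binomial_tail(91, 97)
        assert p_91 == pytest.approx(6.665e-21, rel=1e-3)
        assert res.p < p_91

    def test_zero_observed_effect_counts_discordant(self):
        res = models.sign_concordance_test([1.0, 0.0, -1.0], [1.0, 1.0, 1.0])
        assert res.n_concordant == 1

    def test_zero_reference_rejected(self):
        with pytest.raises(ModelError, match="nonzero"):
            models.sign_concordance_test([1.0], [0.0])


class TestIncrementalR2:
    def test_noise_free_single_predictor_is_one(self):
        df = pd.DataFrame({"x": np.arange(20.0)})
        df["y"] = df["x"]
        assert models.incremental_r2(df, "y", "x") == pytest.approx(1.0)

    def test_independent_exposure_adds_nothing(self):
        r = rng(34)
        df = pd.DataFrame({"x": r.normal(size=3000), "c": r.normal(size=3000)})
        df["y"] = df["c"] + r.normal(size=3000)
        assert models.incremental_r2(df, "y", "x", ("c",)) < 0.01

    def test_known_signal_fraction_recovered(self):
        r = rng(35)
        n = 20000
        df = pd.DataFrame({"x": r.normal(size=n), "c": r.normal(size=n)})
        # x contributes 0.5^2 of total variance 0.25 + 1 + 1
        df["y"] = 0.5 * df["x"] + df["c"] + r.normal(size=n)
        truth = 0.25 / 2.25
        assert models.incremental_r2(df, "y", "x", ("c",)) == pytest.approx(truth, abs=0.01)
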