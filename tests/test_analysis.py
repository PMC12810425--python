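import itertools

import numpy as np
import pytest
from scipy import stats

from telosim import (
    CollinearityError,
    GroupingError,
    StateError,
    UndefinedStatisticError,
)
from telosim.analysis import (
    ancova,
    build_report,
    diagnostics,
    fit_linear_model,
    interaction_model,
    pearson_r,
)


class TestPearson:
    def test_exact_linearity(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        r, p = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_p_against_exhaustive_permutation_oracle(self):
        """t-transform p vs the exact permutation distribution on 6 points."""
        x = np.array([0.2, 1.1, 1.9, 3.2, 3.8, 5.1])
        y = np.array([1.0, 0.4, 2.6, 2.2, 4.4, 3.9])
        r, p = pearson_r(x, y)
        perm_r = [np.corrcoef(x, np.array(perm))[0, 1]
                  for perm in itertools.permutations(y)]
        p_exact = np.mean(np.abs(perm_r) >= abs(r) - 1e-12)
        assert p == pytest.approx(p_exact, abs=0.05)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            pearson_r(np.ones(5), np.arange(5.0))


class TestLinearModel:
    def test_exact_fit_r2_one(self, rng):
        x1 = rng.normal(size=30)
        x2 = rng.normal(size=30)
        y = 2.0 + 1.5 * x1 - 0.7 * x2
        tab = fit_linear_model(y, {"x1": x1, "x2": x2})
        assert tab.r2 == pytest.approx(1.0, abs=1e-12)
        assert np.max(np.abs(tab.resid)) < 1e-10

    def test_matches_normal_equations_oracle(self, rng):
        x1 = rng.normal(size=10)
        x2 = rng.normal(size=10)
        y = 1.0 + 0.5 * x1 - 0.3 * x2 + rng.normal(size=10)
        tab = fit_linear_model(y, {"x1": x1, "x2": x2})
        X = np.column_stack([np.ones(10), x1, x2])
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(tab.B, oracle, atol=1e-10)

    def test_standardized_beta_equals_pearson_for_single_predictor(self, rng):
        x = rng.normal(size=200)
        y = 0.4 * x + rng.normal(size=200)
        tab = fit_linear_model(y, {"x": x})
        r, _ = pearson_r(x, y)
        assert tab.beta_std[1] == pytest.approx(r, abs=1e-12)

    def test_ci_contains_point_estimate_and_p_in_unit_interval(self, rng):
        x = rng.normal(size=50)
        y = 0.3 * x + rng.normal(size=50)
        tab = fit_linear_model(y, {"x": x})
        assert np.all(tab.ci_low <= tab.B) and np.all(tab.B <= tab.ci_high)
        assert np.all((tab.p >= 0) & (tab.p <= 1))
        assert tab.adj_r2 <= tab.r2

    def test_collinear_design_rejected_with_names(self, rng):
        x = rng.normal(size=20)
        with pytest.raises(CollinearityError, match="x2"):
            fit_linear_model(rng.normal(size=20), {"x1": x, "x2": 2 * x})


class TestAncova:
    @staticmethod
    def _toy(rng, n=12):
        factor = np.array(["a", "b", "c"] * (n // 3))
        cov = rng.normal(size=n)
        y = 1.0 + 0.5 * cov + (factor == "b") * 0.8 + rng.normal(size=n)
        return y, factor, {"cov": cov}

    def test_f_matches_nested_rss_oracle(self, rng):
        y, factor, covs = self._toy(rng)
        tab = ancova(y, factor, covs)
        X_full = np.column_stack([np.ones_like(y), covs["cov"],
                                  factor == "b", factor == "c"]).astype(float)
        X_red = X_full[:, :2]
        rss = lambda X: np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2)
        df1, df2 = 2, len(y) - 4
        F = ((rss(X_red) - rss(X_full)) / df1) / (rss(X_full) / df2)
        assert tab.factor_F == pytest.approx(F, abs=1e-10)
        assert (tab.df1, tab.df2) == (df1, df2)

    def test_no_covariates_degenerates_to_oneway_anova(self, rng):
        y, factor, _ = self._toy(rng, n=30)
        tab = ancova(y, factor, {})
        groups = [y[factor == g] for g in ("a", "b", "c")]
        F, p = stats.f_oneway(*groups)
        assert tab.factor_F == pytest.approx(F, abs=1e-10)
        assert tab.p == pytest.approx(p, abs=1e-12)

    def test_null_factor_F_near_one_on_average(self):
        Fs, ps = [], []
        for seed in range(200):
            g = np.random.default_rng(seed)
            y = g.normal(size=120)
            factor = np.repeat(["a", "b", "c", "d"], 30)
            cov = g.normal(size=120)
            tab = ancova(y, factor, {"cov": cov})
            Fs.append(tab.factor_F)
            ps.append(tab.p)
        assert np.mean(Fs) == pytest.approx(1.0, abs=0.15)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_empty_group_rejected(self, rng):
        y = rng.normal(size=10)
        factor = np.array(["a"] * 10)
        with pytest.raises(GroupingError):
            ancova(y, factor, {})

    def test_adjusted_means_and_bonferroni(self, rng):
        y, factor, covs = self._toy(rng, n=300)
        tab = ancova(y, factor, covs)
        assert set(tab.adjusted_means) == {"a", "b", "c"}
        for row in tab.posthoc:
            assert row["p_bonferroni"] >= row["p_raw"]
            assert row["p_bonferroni"] <= 1.0
        # built-in group effect: b sits ~0.8 above a after adjustment
        assert tab.adjusted_means["b"] - tab.adjusted_means["a"] == pytest.approx(
            0.8, abs=0.4)


class TestInteraction:
    def test_constant_sex_is_rank_deficient(self, rng):
        x = rng.normal(size=40)
        with pytest.raises(CollinearityError):
            interaction_model(rng.normal(size=40), x, np.ones(40), {})

    def test_recovers_known_interaction(self, rng):
        n = 100_000
        x = rng.gamma(3.0, 0.4, size=n)
        sex = (rng.random(n) < 0.5).astype(float)
        true_b = -0.25
        y = 1.0 - 0.3 * x + 0.2 * sex + true_b * (x - x.mean()) * sex + rng.normal(size=n)
        tab = interaction_model(y, x, sex, {})
        i = tab.predictors.index("exposure_x_sex")
        se = (tab.ci_high[i] - tab.ci_low[i]) / (2 * 1.96)
        assert abs(tab.B[i] - true_b) < 3 * se

    def test_female_density_slope_steeper_in_majority_of_replicates(
            self, replicate_cohorts):
        neg = 0
        for df in replicate_cohorts[:100]:
            tab = interaction_model(
                df["density_week24"].to_numpy(),
                df["exposure"].to_numpy(),
                df["sex"].to_numpy(float),
                {"age": df["age"].to_numpy(float),
                 "diet": df["diet"].to_numpy(float)},
            )
            i = tab.predictors.index("exposure_x_sex")
            neg += tab.B[i] < 0
        assert neg > 50


class TestDiagnostics:
    def test_normal_reference_shape(self, rng):
        r = rng.standard_normal(100_000)
        factor = np.repeat(["a", "b"], 50_000)
        rep = diagnostics(r, factor)
        assert abs(rep.resid_skewness) < 0.03
        assert abs(rep.resid_excess_kurtosis) < 0.06
        theo = np.array([q[0] for q in rep.qq])
        emp = np.array([q[1] for q in rep.qq])
        assert np.all(np.diff(theo) > 0)
        assert np.max(np.abs(theo - emp)) < 0.1

    def test_levene_null_p_uniform_across_seeds(self):
        ps = []
        for seed in range(200):
            g = np.random.default_rng(seed)
            r = g.normal(size=2000)
            factor = np.repeat(["a", "b"], 1000)
            ps.append(diagnostics(r, factor).levene_p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_levene_detects_variance_ratio(self):
        hits = 0
        for seed in range(100):
            g = np.random.default_rng(seed)
            r = np.concatenate([g.normal(0, 2.0, 500), g.normal(0, 1.0, 500)])
            factor = np.repeat(["a", "b"], 500)
            hits += diagnostics(r, factor).levene_p < 0.01
        assert hits >= 99

    def test_too_few_residuals_rejected(self):
        with pytest.raises(StateError):
            diagnostics(np.array([1.0, 2.0]), np.array(["a", "b"]))


class TestReport:
    def test_all_sections_present(self, paper_config):
        from telosim.pipeline import simulate_cohort
        from telosim.analysis import REPORT_SECTIONS

        df = simulate_cohort(paper_config, seed=12)
        report = build_report(df, paper_config.likert)
        for sec in REPORT_SECTIONS:
            assert sec in report
            assert "skipped" not in report[sec]

    def test_degenerate_exposure_yields_error_markers_not_crash(self, paper_config):
        from telosim.pipeline import simulate_cohort

        df = simulate_cohort(paper_config, seed=12)
        df["exposure"] = 1.0
        df["exposure_category"] = "moderate"
        report = build_report(df, paper_config.likert)
        assert "error" in report["correlations"]["exposure__sahl_total_week24"]

    def test_baseline_only_table_marks_sections_skipped(self, paper_config):
        from telosim.cohort import init_cohort
        from telosim.rng import RNGPolicy

        df = init_cohort(paper_config, RNGPolicy(1))
        report = build_report(df, paper_config.likert)
        assert report["ancova"] == {"skipped": "Week-24 columns absent"}
        assert "exposure__sahl_total_baseline" in report["correlations"]
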