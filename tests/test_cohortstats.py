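"""OLS, interaction models, influence diagnostics and exact tests."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qqoef.cohortstats import (
    analyze_cohort,
    bh_adjust,
    fisher_exact,
    fit_interaction_model,
    influence_measures,
    influence_screen,
    ols_fit,
    residual_diagnostics,
    wilcoxon_ranksum,
)
from qqoef.phantom import DEFAULT_ROIS, CohortSpec, RoiEffect, simulate_cohort


class TestOls:
    def test_exact_line(self):
        x = np.column_stack([np.ones(5), np.arange(5.0)])
        y = 2.0 * np.arange(5.0) + 1.0
        beta, cov, resid = ols_fit(x, y)
        assert beta == pytest.approx([1.0, 2.0])
        assert np.allclose(resid, 0.0, atol=1e-12)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(0)
        x = np.column_stack([np.ones(20), rng.standard_normal((20, 3))])
        y = rng.standard_normal(20)
        perm = rng.permutation(20)
        b1, _, _ = ols_fit(x, y)
        b2, _, _ = ols_fit(x[perm], y[perm])
        assert np.allclose(b1, b2)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(1)
        x = np.column_stack([np.ones(20), rng.standard_normal((20, 4))])
        y = rng.standard_normal(20)
        beta, cov, _ = ols_fit(x, y)
        oracle = np.linalg.inv(x.T @ x) @ x.T @ y
        assert np.abs(beta - oracle).max() / np.abs(oracle).max() < 1e-8

    def test_rank_deficiency_names_columns(self):
        x = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError, match="collinear"):
            ols_fit(x, np.zeros(10))


class TestInteractionModel:
    def test_noiseless_interaction_recovery(self):
        eff = {r: RoiEffect(20.0, -1.0, 0.2, 0.5, 0.01, 1e-7) for r in DEFAULT_ROIS}
        t = simulate_cohort(CohortSpec(effects=eff, seed=1))
        fit = fit_interaction_model(t, "oef_pallidum", "log_wmh")
        assert fit.coef["beta_interaction"] == pytest.approx(0.5, rel=1e-6)

    def test_group_swap_reparameterization(self):
        t = simulate_cohort(CohortSpec(seed=4))
        fit = fit_interaction_model(t, "oef_thalamus", "log_wmh")
        swapped = t.copy()
        swapped["group"] = np.where(swapped["group"] == "AD", "nonAD", "AD")
        fit_sw = fit_interaction_model(swapped, "oef_thalamus", "log_wmh")
        # simple slopes are invariant to which group carries the indicator
        assert fit_sw.simple_slopes["AD"]["slope"] == pytest.approx(
            fit.simple_slopes["nonAD"]["slope"])
        assert fit_sw.simple_slopes["nonAD"]["slope"] == pytest.approx(
            fit.simple_slopes["AD"]["slope"])
        assert fit_sw.coef["beta_interaction"] == pytest.approx(
            -fit.coef["beta_interaction"])
        assert fit_sw.coef["beta_group"] == pytest.approx(-fit.coef["beta_group"])

    def test_ad_moca_slope_power(self):
        pos = sum(
            fit_interaction_model(
                simulate_cohort(CohortSpec(predictor="moca", seed=s)),
                "oef_thalamus", "moca",
            ).simple_slopes["AD"]["slope"] > 0
            for s in range(200)
        )
        assert pos / 200 >= 0.95

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        t = simulate_cohort(CohortSpec(seed=9))
        fit = fit_interaction_model(t, "oef_putamen", "log_wmh")
        g = (t["group"] == "AD").astype(float).to_numpy()
        x = np.log(t["wmh_fraction"].to_numpy())
        design = np.column_stack([np.ones(len(t)), x, g, x * g, t["age"]])
        res = sm.OLS(t["oef_putamen"].to_numpy(), design).fit()
        for i, name in enumerate(fit.coef_names):
            assert fit.coef[name] == pytest.approx(res.params[i], rel=1e-10)
            assert fit.p[name] == pytest.approx(res.pvalues[i], rel=1e-8)

    def test_zero_wmh_with_log_raises_with_advice(self):
        t = simulate_cohort(CohortSpec(seed=0))
        t.loc[0, "wmh_fraction"] = 0.0
        with pytest.raises(ValueError, match="offset"):
            fit_interaction_model(t, "oef_thalamus", "log_wmh")

    def test_mch_covariate_accepted(self):
        t = simulate_cohort(CohortSpec(seed=2))
        fit = fit_interaction_model(t, "oef_thalamus", "log_wmh",
                                    covariates=("age", "mch"))
        assert "beta_mch" in fit.coef
        assert fit.dof == len(t) - 6


class TestInfluence:
    def test_thresholds_at_cohort_size(self):
        t = simulate_cohort(CohortSpec(n_ad=16, n_nonad=15, seed=0))
        fit = fit_interaction_model(t, "oef_thalamus", "log_wmh")
        report, _ = influence_screen(fit)
        assert report.cook_threshold == pytest.approx(4 / 31)
        assert report.dfbeta_threshold == pytest.approx(2 / math.sqrt(31))
        assert report.leverage_threshold == pytest.approx(2 * 5 / 31)

    def test_leverage_sums_to_coefficient_count(self):
        t = simulate_cohort(CohortSpec(seed=3))
        fit = fit_interaction_model(t, "oef_putamen", "log_wmh")
        report, _ = influence_screen(fit)
        assert report.leverage.sum() == pytest.approx(fit.design.shape[1])
        assert np.all((report.leverage >= 0) & (report.leverage <= 1))

    def test_loo_identities_match_literal_refits(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = np.column_stack([np.ones(25), rng.standard_normal((25, 4))])
            y = x @ rng.standard_normal(5) + rng.standard_normal(25)
            hat, cooks, dfbetas = influence_measures(x, y)
            b_full, _, _ = ols_fit(x, y)
            xtx_inv = np.linalg.inv(x.T @ x)
            i = int(rng.integers(25))
            keep = [j for j in range(25) if j != i]
            b_del, _, r_del = ols_fit(x[keep], y[keep])
            s_i2 = (r_del @ r_del) / (24 - 5)
            literal = (b_full - b_del) / np.sqrt(s_i2 * np.diag(xtx_inv))
            assert np.abs(dfbetas[i] - literal).max() < 1e-8

    def test_matches_statsmodels_influence(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(0)
        x = np.column_stack([np.ones(30), rng.standard_normal((30, 3))])
        y = rng.standard_normal(30)
        hat, cooks, dfbetas = influence_measures(x, y)
        infl = sm.OLS(y, x).fit().get_influence()
        assert np.allclose(cooks, infl.cooks_distance[0])
        assert np.allclose(dfbetas, infl.dfbetas)
        assert np.allclose(hat, infl.hat_matrix_diag)

    def test_balanced_exact_fit_has_no_cook_flags(self):
        x_half = np.column_stack([np.ones(8), np.arange(8.0)])
        x = np.vstack([x_half, x_half])  # duplicated balanced design
        y = x @ np.array([1.0, 0.5])
        y = y + np.tile([0.01, -0.01], 8)  # symmetric tiny residuals
        hat, cooks, _ = influence_measures(x, y)
        assert np.all(cooks <= 4 / len(y))

    def test_planted_outlier_flagged_by_cooks(self):
        hits = 0
        for seed in range(200):
            t = simulate_cohort(CohortSpec(seed=2000 + seed))
            t.loc[5, "oef_thalamus"] += 15.0  # 10 sd gross outlier
            fit = fit_interaction_model(t, "oef_thalamus", "log_wmh")
            report, _ = influence_screen(fit)
            hits += bool(report.flagged_cook[5])
        assert hits / 200 >= 0.99

    def test_refit_excludes_flagged(self):
        t = simulate_cohort(CohortSpec(seed=0))
        t.loc[3, "oef_thalamus"] += 20.0
        fit = fit_interaction_model(t, "oef_thalamus", "log_wmh")
        report, refit = influence_screen(fit)
        assert refit is not None
        assert refit.n == fit.n - report.flagged.sum()


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_ties_stay_equal(self):
        out = bh_adjust([0.2, 0.2, 0.2])
        assert np.allclose(out, 0.2)

    def test_adjusted_at_least_raw_and_capped(self):
        rng = np.random.default_rng(0)
        p = rng.random(20)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)

    def test_matches_statsmodels(self):
        mt = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(1)
        p = rng.random(11)
        assert np.allclose(bh_adjust(p), mt.multipletests(p, method="fdr_bh")[1])

    def test_null_family_rejection_rate_controlled(self):
        null_eff = {r: RoiEffect(intercept=25.0, noise_sd=1.5) for r in DEFAULT_ROIS}
        any_rej = 0
        for seed in range(1000):
            t = simulate_cohort(CohortSpec(effects=null_eff, seed=seed))
            ps = [
                fit_interaction_model(t, f"oef_{r}", "log_wmh").p["beta_interaction"]
                for r in DEFAULT_ROIS
            ]
            any_rej += bool((bh_adjust(ps) < 0.05).any())
        assert any_rej / 1000 <= 0.05


class TestWilcoxon:
    def test_identical_multisets(self):
        assert wilcoxon_ranksum([1, 2, 2, 3], [2, 1, 3, 2])[1] == pytest.approx(1.0)

    def test_exact_matches_exhaustive_enumeration(self):
        a, b = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]
        stat, p = wilcoxon_ranksum(a, b)
        pooled = np.array(a + b)
        ranks = stats.rankdata(pooled)
        w_obs = ranks[:3].sum()
        sums = [sum(ranks[list(c)]) for c in combinations(range(6), 3)]
        mu = np.mean(sums)
        p_oracle = np.mean(np.abs(np.array(sums) - mu) >= abs(w_obs - mu) - 1e-12)
        assert p == pytest.approx(p_oracle)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 9)
        assert wilcoxon_ranksum(a, b)[1] == pytest.approx(
            wilcoxon_ranksum(7.3 * a, 7.3 * b)[1])

    def test_large_sample_matches_scipy(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 20), rng.normal(0.8, 1, 18)
        _, p = wilcoxon_ranksum(a, b)
        p_sp = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        assert p == pytest.approx(p_sp, rel=0.05)

    def test_all_identical_values(self):
        assert wilcoxon_ranksum([5, 5, 5], [5, 5])[1] == 1.0


class TestFisherExact:
    def test_balanced_sex_table_is_one(self):
        assert fisher_exact([[7, 9], [7, 8]]) == 1.0

    def test_diagonal_table_matches_hypergeom_sum(self):
        p = fisher_exact([[5, 0], [0, 5]])
        oracle = stats.hypergeom.pmf(5, 10, 5, 5) + stats.hypergeom.pmf(0, 10, 5, 5)
        assert p == pytest.approx(oracle)
        assert p == pytest.approx(stats.fisher_exact([[5, 0], [0, 5]])[1])

    def test_transpose_symmetry(self):
        t = [[3, 7], [5, 2]]
        assert fisher_exact(t) == pytest.approx(fisher_exact(np.transpose(t)))

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            t = rng.integers(0, 12, (2, 2))
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            assert fisher_exact(t) == pytest.approx(
                stats.fisher_exact(t)[1], rel=1e-9)

    def test_empty_margin_warns_one(self):
        with pytest.warns(UserWarning):
            assert fisher_exact([[0, 0], [3, 4]]) == 1.0


class TestResidualDiagnostics:
    def test_exact_fit_zero_slope(self):
        t = simulate_cohort(CohortSpec(
            effects={r: RoiEffect(noise_sd=1e-9) for r in DEFAULT_ROIS}, seed=0))
        fit = fit_interaction_model(t, "oef_thalamus", "log_wmh")
        d = residual_diagnostics(fit)
        assert abs(d["trend_slope"]) < 1e-6

    def test_homoskedastic_spread_ratio_calibrated(self):
        # n = 100 so the half-sample variance ratio concentrates near 1
        ok = 0
        for seed in range(200):
            t = simulate_cohort(CohortSpec(n_ad=50, n_nonad=50, seed=seed))
            d = residual_diagnostics(
                fit_interaction_model(t, "oef_thalamus", "log_wmh"))
            ok += 0.5 <= d["spread_ratio"] <= 2.0
        assert ok / 200 >= 0.90

    def test_heteroskedastic_detected(self):
        # variance growing with the mean inflates the spread ratio
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            n = 100
            x = rng.uniform(1, 9, n)
            g = rng.integers(0, 2, n).astype(float)
            age = rng.normal(70, 8, n)
            mu = 5.0 * x
            y = mu + rng.standard_normal(n) * (0.2 * mu)
            t = pd.DataFrame({
                "group": np.where(g == 1, "AD", "nonAD"), "age": age,
                "moca": x, "mch": 0, "wmh_fraction": np.exp(x),
                "pwmh_fraction": np.exp(x) / 2, "dwmh_fraction": np.exp(x) / 2,
                "oef_thalamus": y,
            })
            d = residual_diagnostics(
                fit_interaction_model(t, "oef_thalamus", "moca"))
            hits += d["spread_ratio"] > 2.0
        assert hits / 200 >= 0.90


class TestAnalyzeCohort:
    def test_tidy_output_columns(self):
        t = simulate_cohort(CohortSpec(seed=0))
        out = analyze_cohort(t, "log_wmh")
        assert set(out["roi"]) == set(DEFAULT_ROIS)
        for col in ("beta_interaction", "p_beta_interaction",
                    "p_beta_interaction_bh", "slope_AD", "p_slope_nonAD"):
            assert col in out.columns
        assert np.all(out["p_beta_interaction_bh"] >= out["p_beta_interaction"] - 1e-15)

    def test_sensitivity_pattern_pwmh_drives_associations(self):
        # when the generator ties OEF to PWMH only, significance persists
        # for log-WMH and log-PWMH predictors and vanishes for log-DWMH
        eff = {r: (RoiEffect(22.0, -2.5, 0.0, 0.0, 0.0, 0.8)
                   if r in ("thalamus", "putamen", "pallidum")
                   else RoiEffect(noise_sd=0.8)) for r in DEFAULT_ROIS}
        rates = {"log_pwmh": 0, "log_wmh": 0, "log_dwmh": 0}
        n_seeds = 30
        for seed in range(n_seeds):
            t = simulate_cohort(CohortSpec(effects=eff, tie_to_pwmh=True, seed=seed))
            for pred in rates:
                ps = [
                    fit_interaction_model(t, f"oef_{r}", pred).simple_slopes["nonAD"]["p"]
                    for r in ("thalamus", "putamen", "pallidum")
                ]
                rates[pred] += bool((bh_adjust(ps) < 0.05).all())
        assert rates["log_pwmh"] / n_seeds >= 0.8
        assert rates["log_wmh"] / n_seeds >= 0.8
        assert rates["log_dwmh"] / n_seeds <= 0.2

    def test_exclude_influential_runs(self):
        t = simulate_cohort(CohortSpec(seed=1))
        t.loc[4, "oef_thalamus"] += 20.0
        out = analyze_cohort(t, "log_wmh", exclude_influential=True)
        row = out[out["roi"] == "thalamus"].iloc[0]
        assert row["n_excluded"] >= 1
        assert row["n"] < len(t)


def test_interaction_ci_coverage_nominal():
    """t-based CIs on simulate_cohort output cover truth at ~95%."""
    truth = {"intercept": 22.0, "beta_pred": -1.2, "beta_group": 0.0,
             "beta_interaction": 0.3, "beta_age": 0.0}
    cover = {k: 0 for k in truth}
    n = 500
    for seed in range(n):
        t = simulate_cohort(CohortSpec(seed=seed))
        fit = fit_interaction_model(t, "oef_thalamus", "log_wmh")
        tc = stats.t.ppf(0.975, fit.dof)
        for k, v in truth.items():
            cover[k] += fit.coef[k] - tc * fit.se[k] <= v <= fit.coef[k] + tc * fit.se[k]
    for k, c in cover.items():
        assert 0.92 <= c / n <= 0.98, k
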