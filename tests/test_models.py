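"""NB-GLM engine, size factors, LRT differential binding, Wald DE."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clipm6a import (
    differential_binding_lrt,
    differential_expression_wald,
    expression_covariate,
    fit_nb_glm,
    size_factors,
    simulate_binding_experiment,
)
from clipm6a.models import LN2, bh_adjust, low_count_filter, mom_dispersion, nb_loglik


def _nb(rng, mu, alpha):
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mu))


class TestSizeFactors:
    def test_identical_columns_are_unit(self):
        counts = pd.DataFrame({"a": [5, 80, 13], "b": [5, 80, 13]})
        assert np.allclose(size_factors(counts), 1.0)

    def test_doubled_column(self):
        counts = pd.DataFrame({"a": [10, 100, 7], "b": [20, 200, 14]})
        sf = size_factors(counts)
        assert sf["a"] == pytest.approx(1 / np.sqrt(2), abs=1e-4)
        assert sf["b"] == pytest.approx(np.sqrt(2), abs=1e-4)

    def test_two_feature_example(self):
        sf = size_factors(pd.DataFrame({"a": [10, 100], "b": [20, 200]}))
        assert sf.tolist() == pytest.approx([0.7071, 1.4142], abs=1e-4)

    def test_no_common_nonzero_feature_errors(self):
        counts = pd.DataFrame({"a": [5, 0], "b": [0, 9]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(counts)


class TestNBGLMEngine:
    def test_intercept_only_mean_mle(self):
        for alpha in (0.0, 0.1, 1.0):
            fit = fit_nb_glm(np.array([4.0, 6.0]), np.ones((2, 1)), alpha=alpha)
            assert fit.beta[0] == pytest.approx(np.log(5.0), abs=1e-8)
            assert fit.converged

    def test_poisson_limit_two_group_closed_form(self):
        y = np.array([10.0, 12.0, 8.0, 40.0, 44.0, 36.0])
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        fit = fit_nb_glm(y, X, alpha=0.0)
        assert fit.beta[1] / LN2 == pytest.approx(np.log2(4.0), abs=1e-6)
        assert fit.beta[0] == pytest.approx(np.log(10.0), abs=1e-6)

    def test_matches_statsmodels_nb_glm(self):
        """Independent cross-check of the IRLS fit against statsmodels."""
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(30), rng.normal(size=30)])
        y = _nb(rng, np.exp(1.0 + 0.5 * X[:, 1]), 0.2).astype(float)
        alpha = 0.2
        ours = fit_nb_glm(y, X, alpha=alpha)
        theirs = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha)).fit()
        assert ours.beta == pytest.approx(theirs.params, abs=1e-6)
        assert ours.loglik == pytest.approx(theirs.llf, abs=1e-6)

    def test_all_zero_row_flagged(self):
        fit = fit_nb_glm(np.zeros(4), np.ones((4, 1)))
        assert fit.status == "all_zero"

    def test_log2fc_recovery_monte_carlo(self):
        """Mean estimated log2FC within 0.1 of truth (n=3 vs 3, mean 100, a=0.1)."""
        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        groups = X[:, 1]
        estimates = []
        for _ in range(500):
            y = np.concatenate(
                [_nb(rng, np.full(3, 100.0), 0.1), _nb(rng, np.full(3, 400.0), 0.1)]
            ).astype(float)
            alpha = mom_dispersion(y, groups)
            fit = fit_nb_glm(y, X, alpha=alpha)
            if fit.status == "fitted":
                estimates.append(fit.beta[1] / LN2)
        assert abs(np.mean(estimates) - 2.0) < 0.1

    def test_loglik_poisson_limit_continuity(self):
        y = np.array([3.0, 7.0, 5.0])
        mu = np.array([4.0, 6.0, 5.0])
        assert nb_loglik(y, mu, 1e-10) == pytest.approx(nb_loglik(y, mu, 0.0), abs=1e-4)


class TestBHAndFilters:
    def test_padj_at_least_p_and_monotone(self):
        rng = np.random.default_rng(2)
        p = pd.Series(rng.uniform(size=200))
        padj = bh_adjust(p)
        assert (padj >= p - 1e-12).all()
        order = np.argsort(p.to_numpy())
        assert (np.diff(padj.to_numpy()[order]) >= -1e-12).all()

    def test_low_count_filter_modes(self):
        counts = pd.DataFrame([[5, 5, 5, 5, 5, 20]], index=["f1"],
                              columns=list("abcdef"))
        assert low_count_filter(counts, 10, 5, "per_sample")["f1"]
        assert not low_count_filter(counts, 10, 6, "per_sample")["f1"]
        assert not low_count_filter(counts, 10, 5, "rowsum")["f1"]
        assert low_count_filter(counts, 100, 5, "rowsum")["f1"]


class TestDifferentialBinding:
    def test_null_rejection_rate_calibrated(self, null_lrt_results):
        tested = null_lrt_results[null_lrt_results["status"] == "tested"]
        rate = (tested["p"] < 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_null_p_values_uniform(self, null_lrt_results):
        tested = null_lrt_results[null_lrt_results["status"] == "tested"]
        assert stats.kstest(tested["p"], "uniform").pvalue > 0.01

    def test_lrt_statistic_nonnegative(self, null_lrt_results):
        tested = null_lrt_results[null_lrt_results["status"] == "tested"]
        assert (tested["stat"] >= 0).all()

    def test_covariate_absorbs_expression_confound(self, confounded_lrt_results):
        res = confounded_lrt_results
        conf = res["confounded"]
        with_cov = res["with_cov"].loc[conf, "log2fc"].mean()
        without_cov = res["without_cov"].loc[conf, "log2fc"].mean()
        assert abs(with_cov) < 0.15
        assert 0.7 <= without_cov <= 1.3

    def test_low_count_feature_status(self):
        exp = simulate_binding_experiment(n_peaks=50, seed=9)
        counts = exp["peak_counts"]
        counts.iloc[0] = [5, 3, 4, 2, 5, 4]
        res = differential_binding_lrt(counts, exp["peak_genes"], exp["conditions"], None)
        assert res.iloc[0]["status"] == "low_count_filtered"
        assert np.isnan(res.iloc[0]["padj"])

    def test_constant_covariate_dropped_with_warning(self, caplog):
        exp = simulate_binding_experiment(n_peaks=30, seed=10)
        cov = pd.DataFrame(
            0.0, index=exp["peak_counts"].index, columns=exp["peak_counts"].columns
        )
        with caplog.at_level("WARNING"):
            res = differential_binding_lrt(
                exp["peak_counts"], exp["peak_genes"], exp["conditions"], cov
            )
        assert "constant expression covariate" in caplog.text
        assert (res["status"] == "tested").any()

    def test_doubling_a_sample_is_absorbed_by_size_factors(self):
        exp = simulate_binding_experiment(n_peaks=60, seed=12)
        counts = exp["peak_counts"]
        res1 = differential_binding_lrt(counts, exp["peak_genes"], exp["conditions"], None)
        doubled = counts.copy()
        doubled.iloc[:, 0] = doubled.iloc[:, 0] * 2
        res2 = differential_binding_lrt(doubled, exp["peak_genes"], exp["conditions"], None)
        both = (res1["status"] == "tested") & (res2["status"] == "tested")
        assert both.sum() > 50
        assert np.allclose(res1.loc[both, "log2fc"], res2.loc[both, "log2fc"], atol=1e-6)


class TestDifferentialExpression:
    CONDS6 = pd.Series(["A"] * 6 + ["B"] * 6, index=[f"s{i}" for i in range(12)])

    def test_identical_groups_small_lfc(self):
        rng = np.random.default_rng(31)
        counts = pd.DataFrame(
            _nb(rng, np.full((500, 12), 100.0), 0.001), columns=self.CONDS6.index
        )
        res = differential_expression_wald(counts, self.CONDS6)
        assert (res["log2fc"].abs() < 0.2).mean() >= 0.95

    def test_three_fold_change_recovered(self):
        """Spiked subset recovers log2(3); the stable majority anchors size factors."""
        rng = np.random.default_rng(32)
        mu = np.full((500, 12), 100.0)
        mu[:50, 6:] = 300.0  # 3-fold up in condition B for the first 50 genes
        counts = pd.DataFrame(_nb(rng, mu, 0.02), columns=self.CONDS6.index)
        res = differential_expression_wald(counts, self.CONDS6)
        spiked = res.iloc[:50]["log2fc"].mean()
        stable = res.iloc[50:]["log2fc"].mean()
        # spiked-vs-stable contrast removes the small size-factor compromise
        # that median-of-ratios makes when 10% of features are truly DE
        assert spiked - stable == pytest.approx(np.log2(3.0), abs=0.05)
        assert abs(stable) < 0.1

    def test_all_zero_gene_excluded(self):
        rng = np.random.default_rng(33)
        conds = pd.Series(["A", "A", "B", "B"], index=list("wxyz"))
        counts = pd.DataFrame(_nb(rng, np.full((10, 4), 50.0), 0.05),
                              index=[f"g{i}" for i in range(10)], columns=conds.index)
        counts.loc["g3"] = 0
        res = differential_expression_wald(counts, conds)
        assert "g3" not in res.index

    def test_single_replicate_errors(self):
        conds = pd.Series(["A", "B", "B"], index=list("xyz"))
        counts = pd.DataFrame([[5, 6, 7]], columns=conds.index)
        with pytest.raises(ValueError, match="replicates"):
            differential_expression_wald(counts, conds)


class TestExpressionCovariate:
    def test_tracks_true_log_expression(self):
        exp = simulate_binding_experiment(n_peaks=300, seed=44)
        cov = expression_covariate(
            exp["rna_counts"], exp["rna_conditions"],
            list(exp["peak_counts"].columns), exp["conditions"],
        )
        assert cov.shape == (300, 6)
        # standardized overall
        assert cov.values.mean() == pytest.approx(0.0, abs=1e-9)
        assert cov.values.std() == pytest.approx(1.0, abs=1e-6)
        # correlates with the log RNA counts it derives from, per column
        logged = np.log2(exp["rna_counts"] + 0.001)
        for clip_col, rna_col in zip(cov.columns, logged.columns):
            r = np.corrcoef(cov[clip_col], logged[rna_col])[0, 1]
            assert r > 0.95
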