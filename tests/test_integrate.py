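"""Proteomics differential, peak/m6A intersection, stratified KS, MW, percentages."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clipm6a import (
    peak_class,
    proteomics_differential,
    intersect_peaks_m6a,
    build_integration,
    stratify_and_test,
    category_peak_comparison,
    nested_filter_percentages,
    windowed_overlap_fraction,
)
from clipm6a.integrate import ecdf_table, ks_two_sample


class TestPeakClass:
    @pytest.mark.parametrize(
        "n,label",
        [(0, "0"), (1, "1-2"), (2, "1-2"), (3, "3-5"), (4, "3-5"), (5, "3-5"),
         (6, "6+"), (7, "6+"), (40, "6+")],
    )
    def test_bounds(self, n, label):
        assert peak_class(n) == label

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            peak_class(-1)


class TestProteomicsDifferential:
    def test_t_statistic_worked_example(self):
        """ratios {-2.0, -2.1, -1.9}: t = mean/(sd/sqrt(n)) = -34.64, p ~ 8.3e-4."""
        vals = np.array([-2.0, -2.1, -1.9])
        t = vals.mean() / (vals.std(ddof=1) / np.sqrt(3))
        p = 2 * stats.t.sf(abs(t), df=2)
        assert t == pytest.approx(-34.64, abs=0.01)
        assert p == pytest.approx(8.3e-4, rel=0.01)
        # the implementation reproduces them on raw ratios
        ratios = pd.DataFrame({"r1": [-2.0], "r2": [-2.1], "r3": [-1.9]}, index=["down"])
        res = proteomics_differential(ratios, z_transform=False)
        assert res.loc["down", "t"] == pytest.approx(t, abs=1e-9)
        assert res.loc["down", "p"] == pytest.approx(p, rel=1e-9)

    def test_zero_variance_flagged_never_significant(self):
        ratios = pd.DataFrame({"r1": [0.0, -3.0], "r2": [0.0, -3.1], "r3": [0.0, -2.9]},
                              index=["flat", "down"])
        res = proteomics_differential(ratios)
        assert res.loc["flat", "zero_variance"]
        assert np.isnan(res.loc["flat", "p"])
        assert not res.loc["flat", "significant"]

    def test_columns_standardized(self):
        rng = np.random.default_rng(3)
        ratios = pd.DataFrame(rng.normal(-0.5, 2.0, size=(200, 3)),
                              columns=["r1", "r2", "r3"])
        res = proteomics_differential(ratios)
        for col in ["r1_z", "r2_z", "r3_z"]:
            assert res[col].mean() == pytest.approx(0.0, abs=1e-9)
            assert res[col].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            proteomics_differential(pd.DataFrame({"r1": [1.0]}))


class TestIntersect:
    def _peaks(self, intervals, gene="gA"):
        return pd.DataFrame([
            {"chrom": "chr1", "strand": "+", "start": s, "end": e, "gene_id": gene}
            for s, e in intervals
        ])

    def _sites(self, positions):
        return pd.DataFrame({"chrom": "chr1", "strand": "+", "pos": positions})

    def test_overlap_and_halfopen_boundary(self):
        peaks, per_gene = intersect_peaks_m6a(self._peaks([(100, 150)]), self._sites([120]))
        assert peaks["has_m6a"].iloc[0]
        assert per_gene["gA"] == 1
        peaks, per_gene = intersect_peaks_m6a(self._peaks([(100, 150)]), self._sites([150]))
        assert not peaks["has_m6a"].iloc[0]
        assert per_gene["gA"] == 0

    def test_window_extension(self):
        peaks, _ = intersect_peaks_m6a(self._peaks([(100, 150)]), self._sites([153]), window=5)
        assert peaks["has_m6a"].iloc[0]

    def test_per_gene_counts_distinct_sites(self):
        peaks = self._peaks([(100, 150), (300, 360)])
        _, per_gene = intersect_peaks_m6a(peaks, self._sites([110, 120, 310, 500]))
        assert per_gene["gA"] == 3

    def test_strand_mismatch_no_overlap(self):
        sites = pd.DataFrame({"chrom": ["chr1"], "strand": ["-"], "pos": [120]})
        peaks, _ = intersect_peaks_m6a(self._peaks([(100, 150)]), sites)
        assert not peaks["has_m6a"].iloc[0]


class TestStratifyAndTest:
    def test_ks_worked_example(self):
        d, p = ks_two_sample(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert d == 1.0
        assert p == pytest.approx(0.1)

    def test_identical_samples(self):
        d, p = ks_two_sample(np.arange(10.0), np.arange(10.0))
        assert d == 0.0
        assert p == 1.0

    def test_ks_exact_matches_enumeration_oracle(self):
        """All n, m <= 5: exact p equals full permutation enumeration."""

        def ks_stat(a, b):
            allv = np.sort(np.concatenate([a, b]))
            fa = np.searchsorted(np.sort(a), allv, side="right") / len(a)
            fb = np.searchsorted(np.sort(b), allv, side="right") / len(b)
            return np.max(np.abs(fa - fb))

        rng = np.random.default_rng(0)
        for n in range(2, 6):
            for m in range(2, 6):
                vals = rng.permutation(np.arange(n + m, dtype=float))
                a, b = vals[:n], vals[n:]
                d_obs = ks_stat(a, b)
                pool = np.concatenate([a, b])
                count = total = 0
                for idx in combinations(range(n + m), n):
                    mask = np.zeros(n + m, bool)
                    mask[list(idx)] = True
                    if ks_stat(pool[mask], pool[~mask]) >= d_obs - 1e-12:
                        count += 1
                    total += 1
                _, p_impl = ks_two_sample(a, b)
                assert p_impl == pytest.approx(count / total, abs=1e-9), (n, m)

    def test_ecdf_monotone_reaching_one(self):
        table = ecdf_table(np.array([3.0, -1.0, 2.0, 2.0]))
        assert (np.diff(table["x"]) >= 0).all()
        assert (np.diff(table["ecdf"]) >= 0).all()
        assert table["ecdf"].iloc[-1] == 1.0

    def test_class_stratification_and_reference(self):
        integ = pd.DataFrame({
            "n_m6a_peaks": [0] * 10 + [1, 2] * 5 + [4] * 10 + [7] * 10,
            "protein_log2fc": np.concatenate([
                np.linspace(-0.1, 0.1, 10), np.linspace(-0.5, 0.0, 10),
                np.linspace(-1.2, -0.6, 10), np.linspace(-2.0, -1.2, 10),
            ]),
        })
        ecdfs, results = stratify_and_test(integ)
        assert {r.class_label for r in results} == {"1-2", "3-5", "6+"}
        by_label = {r.class_label: r for r in results}
        assert by_label["6+"].statistic == 1.0
        assert by_label["6+"].p < 0.01

    def test_empty_reference_class_errors(self):
        integ = pd.DataFrame({"n_m6a_peaks": [1, 2], "protein_log2fc": [0.1, 0.2]})
        with pytest.raises(ValueError, match="reference"):
            stratify_and_test(integ)


class TestCategoryComparison:
    def test_mw_worked_example(self):
        counts = pd.Series([1, 2, 3, 4, 5, 6], index=list("abcdef"), dtype=float)
        cats = {"low": ["a", "b", "c"], "high": ["d", "e", "f"]}
        summaries, tests = category_peak_comparison(counts, cats)
        row = tests.iloc[0]
        assert row["U"] == 0.0
        assert row["p"] == pytest.approx(0.1)
        assert row["method"] == "exact"
        assert summaries.loc["low", "median"] == 2.0

    def test_mw_exact_matches_enumeration_oracle(self):
        def ustat(x, y):
            return sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)

        rng = np.random.default_rng(1)
        for n in range(2, 6):
            for m in range(2, 6):
                vals = rng.permutation(np.arange(n + m, dtype=float))
                a, b = vals[:n], vals[n:]
                res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
                dev_obs = abs(ustat(a, b) - n * m / 2)
                pool = np.concatenate([a, b])
                count = total = 0
                for idx in combinations(range(n + m), n):
                    mask = np.zeros(n + m, bool)
                    mask[list(idx)] = True
                    if abs(ustat(pool[mask], pool[~mask]) - n * m / 2) >= dev_obs - 1e-12:
                        count += 1
                    total += 1
                assert res.pvalue == pytest.approx(count / total, abs=1e-9), (n, m)

    def test_identical_distributions_not_significant(self):
        vals = np.tile(np.arange(50.0), 2)
        counts = pd.Series(vals, index=[f"g{i}" for i in range(100)])
        cats = {"a": [f"g{i}" for i in range(50)], "b": [f"g{i}" for i in range(50, 100)]}
        _, tests = category_peak_comparison(counts, cats)
        assert tests.iloc[0]["p"] >= 0.99

    def test_large_shift_highly_significant(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate([rng.normal(0, 1, 30), rng.normal(10, 1, 30)])
        counts = pd.Series(vals, index=[f"g{i}" for i in range(60)])
        cats = {"a": [f"g{i}" for i in range(30)], "b": [f"g{i}" for i in range(30, 60)]}
        _, tests = category_peak_comparison(counts, cats)
        assert tests.iloc[0]["p"] < 0.001

    def test_missing_category_raises(self):
        counts = pd.Series([1.0], index=["a"])
        with pytest.raises(KeyError, match="ghost"):
            category_peak_comparison(counts, {"ok": ["a"], "ghost": ["zz"]})


class TestNestedPercentages:
    def test_simple_fraction(self):
        sets = {"down": {f"p{i}" for i in range(10)}}
        term = {f"p{i}" for i in range(4)}
        out = nested_filter_percentages(sets, term)
        assert out.loc[0, "pct"] == pytest.approx(40.0)

    def test_empty_set_flagged(self):
        out = nested_filter_percentages({"empty": set()}, {"x"})
        assert out.loc[0, "undefined"]
        assert np.isnan(out.loc[0, "pct"])

    def test_identical_site_sets_full_overlap(self):
        sites = pd.DataFrame({"chrom": "chr1", "strand": "+", "pos": [5, 9, 100]})
        assert windowed_overlap_fraction(sites, sites, window=0) == 100.0

    def test_windowed_overlap_partial(self):
        sites = pd.DataFrame({"chrom": "chr1", "strand": "+", "pos": [100, 200]})
        ref = pd.DataFrame({"chrom": "chr1", "strand": "+", "pos": [102]})
        assert windowed_overlap_fraction(sites, ref, window=5) == 50.0


class TestBuildIntegration:
    def test_proteomics_only_genes_get_class_zero(self):
        peaks = pd.Series({"gA": 3})
        m6a = pd.Series({"gA": 1})
        prot = pd.Series({"gA": -0.5, "gB": 0.2})
        integ = build_integration(peaks, m6a, prot)
        assert integ.loc["gB", "n_peaks"] == 0
        assert integ.loc["gB", "class_peaks"] == "0"
        assert integ.loc["gA", "class_peaks"] == "3-5"

    def test_genes_without_protein_dropped(self):
        peaks = pd.Series({"gA": 3, "gC": 8})
        prot = pd.Series({"gA": -0.5, "gC": np.nan})
        integ = build_integration(peaks, pd.Series(dtype=int), prot)
        assert "gC" not in integ.index
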