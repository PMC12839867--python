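import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cpdiet.dataio import AnalyteClass
from cpdiet import reference
from cpdiet.occurrence import (
    RegionSummary,
    bh_adjust,
    correlation_with_ci,
    kruskal_wallis,
    kruskal_wallis_exact_p,
    pairwise_wilcoxon_bh,
    pooled_mean,
    summarize_regions,
)

from conftest import make_record

SCCP = AnalyteClass.SCCP
MCCP = AnalyteClass.MCCP


def reference_summaries(analyte_class, regions=None):
    """RegionSummary rows built from the published regional table."""
    regions = regions or reference.REGION_ORDER
    out = []
    for name in regions:
        rs = reference.REGION_STATS[name]
        lo, hi = rs.range[analyte_class]
        out.append(RegionSummary(
            region=name, analyte_class=analyte_class, n=rs.n, n_detected=rs.n,
            detection_rate=1.0, mean=rs.mean[analyte_class], sd=0.0,
            min=lo, max=hi,
        ))
    return out


class TestSummarizeRegions:
    def test_all_above_mdl_full_detection(self):
        records = [make_record(f"s{i}", "Jilin", c10cl6=50.0 + i,
                               c14cl6=80.0 + i) for i in range(5)]
        summaries = summarize_regions(records)
        for s in summaries:
            assert s.detection_rate == 1.0
            assert s.n == 5

    def test_mean_min_max(self):
        records = [make_record("a", "R", c10cl6=10.0),
                   make_record("b", "R", c10cl6=30.0)]
        (sccp,) = [s for s in summarize_regions(records)
                   if s.analyte_class is SCCP]
        assert (sccp.mean, sccp.min, sccp.max) == (20.0, 10.0, 30.0)
        assert sccp.sd == pytest.approx(math.sqrt(200.0))

    def test_single_sample_sd_flagged_zero(self):
        records = [make_record("a", "R", c10cl6=10.0)]
        (sccp,) = [s for s in summarize_regions(records)
                   if s.analyte_class is SCCP]
        assert sccp.mean == sccp.min == sccp.max == 10.0
        assert sccp.sd == 0.0 and sccp.sd_undefined

    def test_below_mdl_totals_not_detected(self):
        # SCCP MDL is 3 ng/g: a 2 ng/g class total is a non-detect
        records = [make_record("a", "R", c10cl6=2.0),
                   make_record("b", "R", c10cl6=50.0)]
        (sccp,) = [s for s in summarize_regions(records)
                   if s.analyte_class is SCCP]
        assert sccp.n_detected == 1
        assert sccp.detection_rate == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_regions([])

    def test_synthetic_jilin_mean(self):
        # generator calibration oracle at n=10,000
        import dataclasses
        from cpdiet.synthetic import default_study_specs, gen_concentrations
        specs, _ = default_study_specs()
        jilin = dataclasses.replace(
            next(s for s in specs if s.region == "Jilin"), n_samples=10_000
        )
        summaries = summarize_regions(gen_concentrations(jilin, seed=5))
        (sccp,) = [s for s in summaries if s.analyte_class is SCCP]
        assert sccp.mean == pytest.approx(99.7, rel=0.05)


class TestPooledMean:
    def test_total_sccp(self):
        assert round(pooled_mean(reference_summaries(SCCP)), 1) == 95.8

    def test_total_mccp(self):
        assert round(pooled_mean(reference_summaries(MCCP)), 1) == 156.6

    def test_east_china_sccp(self):
        east = reference.REGION_BLOCKS["East China"]
        assert round(pooled_mean(reference_summaries(SCCP, east)), 1) == 156.2

    def test_northeast_mccp(self):
        ne = reference.REGION_BLOCKS["Northeast China"]
        assert round(pooled_mean(reference_summaries(MCCP, ne)), 1) == 182.0

    def test_north_china_sccp_known_rounding_gap(self):
        # pooling the rounded regional means gives 73.5; the published 73.4
        # presumably pooled unrounded sample values
        north = reference.REGION_BLOCKS["North China"]
        assert round(pooled_mean(reference_summaries(SCCP, north)), 1) == 73.5

    def test_single_summary_is_identity(self):
        (only,) = reference_summaries(SCCP, ["Tianjin"])
        assert pooled_mean([only]) == only.mean

    def test_mixed_classes_rejected(self):
        with pytest.raises(ValueError):
            pooled_mean(reference_summaries(SCCP, ["Jilin"])
                        + reference_summaries(MCCP, ["Jilin"]))

    def test_matches_concatenated_sample_mean(self):
        rng = np.random.default_rng(0)
        groups = [rng.lognormal(3, 1, size=n) for n in (5, 9, 14)]
        summaries = [
            RegionSummary(f"r{i}", SCCP, len(g), len(g), 1.0,
                          float(g.mean()), float(g.std(ddof=1)),
                          float(g.min()), float(g.max()))
            for i, g in enumerate(groups)
        ]
        pooled = pooled_mean(summaries)
        assert pooled == pytest.approx(np.concatenate(groups).mean(), rel=1e-12)


class TestKruskalWallis:
    def test_hand_computed_h(self):
        res = kruskal_wallis([[1, 2], [3, 4]])
        assert res.statistic == pytest.approx(2.4)

    def test_identical_groups(self):
        res = kruskal_wallis([[5, 5, 5], [5, 5]])
        assert res.statistic == 0.0
        assert res.raw_p == 1.0

    def test_matches_scipy(self):
        from scipy import stats
        rng = np.random.default_rng(1)
        groups = [rng.normal(loc, 1, size=12) for loc in (0, 0.5, 1)]
        res = kruskal_wallis(groups)
        expected = stats.kruskal(*groups)
        assert res.statistic == pytest.approx(expected.statistic)
        assert res.raw_p == pytest.approx(expected.pvalue)

    def test_exact_permutation_close_to_chisquare_at_n8(self):
        groups = [[1.0, 2.0, 3.0, 5.0], [4.0, 6.0, 7.0, 8.0]]
        approx = kruskal_wallis(groups).raw_p
        exact = kruskal_wallis_exact_p(groups)
        assert abs(approx - exact) < 0.05

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        groups = [list(rng.lognormal(0, 1, size=8)) for _ in range(3)]
        h1 = kruskal_wallis(groups).statistic
        h2 = kruskal_wallis([[math.log(v) for v in g] for g in groups]).statistic
        h3 = kruskal_wallis([[v ** 3 for v in g] for g in groups]).statistic
        assert h1 == pytest.approx(h2) == pytest.approx(h3)

    def test_needs_two_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


class TestBHAdjust:
    def test_hand_computed_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.04]) == [0.04]

    def test_all_equal_ps_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2, 0.2]) == pytest.approx([0.2] * 4)

    def test_textbook_stepup(self):
        # p*m/i with step-up running-minimum monotonicity, computed by hand:
        # sorted p*m/i = (.015, .045, .04); the .045 is capped at .04
        adjusted = bh_adjust([0.005, 0.04, 0.03])
        assert adjusted == pytest.approx([0.015, 0.04, 0.04])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=30))
    def test_properties(self, pvals):
        adjusted = bh_adjust(pvals)
        assert all(0 <= a <= 1 for a in adjusted)
        assert all(a >= p - 1e-12 for a, p in zip(adjusted, pvals))
        # order preserving
        order = np.argsort(pvals, kind="stable")
        assert all(
            adjusted[order[i]] <= adjusted[order[i + 1]] + 1e-12
            for i in range(len(order) - 1)
        )
        # re-application can only inflate (BH is not idempotent: the
        # step-up quotients q*m/i of already-adjusted values grow)
        assert all(a2 >= a1 - 1e-12
                   for a1, a2 in zip(adjusted, bh_adjust(adjusted)))

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2,
                    max_size=20))
    @settings(max_examples=30, deadline=None)
    def test_matches_statsmodels(self, pvals):
        from statsmodels.stats.multitest import multipletests
        expected = multipletests(pvals, method="fdr_bh")[1]
        assert bh_adjust(pvals) == pytest.approx(list(expected))


class TestPairwiseWilcoxon:
    def test_pair_count_and_adjustment(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(loc, 1, size=10) for loc in (0, 1, 2, 3)]
        results = pairwise_wilcoxon_bh(groups, labels=list("abcd"))
        assert len(results) == 6
        assert bh_adjust([r.raw_p for r in results]) == pytest.approx(
            [r.adjusted_p for r in results]
        )

    def test_single_comparison_adjusted_equals_raw(self):
        results = pairwise_wilcoxon_bh([[1.0, 2.0, 5.0], [3.0, 4.0, 6.0]])
        (res,) = results
        assert res.adjusted_p == pytest.approx(res.raw_p)

    def test_exact_used_for_small_tie_free_groups(self):
        results = pairwise_wilcoxon_bh([[1.0, 2.0], [3.0, 4.0]])
        assert "exact" in results[0].method

    def test_asymptotic_used_with_ties(self):
        results = pairwise_wilcoxon_bh([[1.0, 2.0, 2.0], [2.0, 3.0, 4.0]])
        assert "asymptotic" in results[0].method

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            pairwise_wilcoxon_bh([[1.0], []])

    def test_detects_shifted_region(self):
        rng = np.random.default_rng(4)
        groups = [rng.lognormal(0, 0.3, 40), rng.lognormal(0, 0.3, 40),
                  rng.lognormal(2.0, 0.3, 40)]
        results = pairwise_wilcoxon_bh(groups, labels=["a", "b", "jiangsu"])
        significant = {r.groups for r in results if r.adjusted_p < 0.001}
        assert ("a", "jiangsu") in significant
        assert ("b", "jiangsu") in significant
        insig = next(r for r in results if r.groups == ("a", "b"))
        assert insig.adjusted_p > 0.05


def exact_r_pair(r=0.5, n=30):
    """x, y with sample Pearson correlation exactly r (up to fp)."""
    x = np.arange(n, dtype=float)
    x = (x - x.mean()) / x.std()
    z = np.arange(n, dtype=float) ** 2
    z -= z.mean()
    z -= (z @ x) / (x @ x) * x  # orthogonalize
    z /= z.std()
    return x, r * x + math.sqrt(1 - r * r) * z


class TestCorrelation:
    def test_fisher_ci_hand_arithmetic(self):
        # z = atanh(0.5), se = 1/sqrt(27): CI = tanh(z -+ 1.96 se)
        x, y = exact_r_pair(0.5, 30)
        res = correlation_with_ci(x, y, method="pearson")
        assert res.r == pytest.approx(0.5, abs=1e-12)
        assert res.ci_low == pytest.approx(0.17043, abs=1e-3)
        assert res.ci_high == pytest.approx(0.72907, abs=1e-3)

    def test_spearman_monotone_cubic_is_one(self):
        x = np.linspace(-2, 2, 20)
        res = correlation_with_ci(x, x ** 3, method="spearman")
        assert res.r == 1.0
        assert res.degenerate_ci
        assert (res.ci_low, res.ci_high) == (1.0, 1.0)

    def test_spearman_ci_wider_than_pearson_z(self):
        x, y = exact_r_pair(0.6, 40)
        p = correlation_with_ci(x, y, method="pearson")
        s = correlation_with_ci(x, y, method="spearman")
        z_width_p = math.atanh(p.ci_high) - math.atanh(p.ci_low)
        z_width_s = math.atanh(s.ci_high) - math.atanh(s.ci_low)
        assert z_width_s == pytest.approx(z_width_p * math.sqrt(1.06), rel=1e-9)

    def test_independent_draws_near_zero(self):
        rng = np.random.default_rng(5)
        x, y = rng.standard_normal((2, 10_000))
        res = correlation_with_ci(x, y, method="pearson")
        assert abs(res.r) < 0.05
        assert res.ci_low < 0 < res.ci_high

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlation_with_ci([1, 1, 1, 1], [1, 2, 3, 4])

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            correlation_with_ci([1, 2, 3], [1, 2, 3])

    def test_pearson_on_standardized_equals_covariance(self):
        rng = np.random.default_rng(6)
        x, y = rng.standard_normal((2, 50))
        x = (x - x.mean()) / x.std()
        y = (y - y.mean()) / y.std()
        res = correlation_with_ci(x, y, method="pearson")
        assert res.r == pytest.approx(float(np.mean(x * y)), rel=1e-9)
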