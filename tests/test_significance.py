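"""Percentile p-values, product combination, and false-positive calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from bsakit.significance import (
    SignificanceConfig,
    classify_candidates,
    combine_pvalues,
    fdr_threshold_analytic,
    fdr_threshold_empirical,
    maf_bins,
    percentile_pvalues,
    product_uniform_cdf,
    score_snps,
)


class TestPercentilePvalues:
    def test_rank_counting(self):
        p = percentile_pvalues(np.array([0.9, 0.7, 0.5, 0.3, 0.1]))
        assert p.tolist() == pytest.approx([0.2, 0.4, 0.6, 0.8, 1.0])

    def test_minimum_gets_one(self):
        p = percentile_pvalues(np.array([0.9, 0.7, 0.5, 0.3, 0.1]))
        assert p[-1] == 1.0

    def test_inclusive_ties(self):
        p = percentile_pvalues(np.array([0.5, 0.5, 0.1]))
        assert p.tolist() == pytest.approx([2 / 3, 2 / 3, 1.0])

    def test_stratified_groups_are_independent(self):
        values = np.array([0.9, 0.1, 0.8, 0.2])
        groups = np.array([0, 0, 1, 1])
        p = percentile_pvalues(values, groups)
        assert p.tolist() == pytest.approx([0.5, 1.0, 0.5, 1.0])

    def test_empty_stratum_errors(self):
        with pytest.raises(ValueError):
            percentile_pvalues(np.array([]))

    def test_pvalues_are_tie_adjusted_ranks_over_n(self):
        """The p-value multiset is exactly {#{>= v_i}/n}."""
        rng = np.random.default_rng(0)
        v = rng.choice([0.1, 0.2, 0.3, 0.7], size=57)  # heavy ties
        p = percentile_pvalues(v)
        brute = np.array([(v >= x).sum() / len(v) for x in v])
        np.testing.assert_allclose(p, brute)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.floats(0.0, 1.0, allow_nan=False, width=32), min_size=1, max_size=60
        )
    )
    def test_properties_hold_for_arbitrary_strata(self, values):
        """p in (0,1]; max value gets the smallest p; anti-monotone in value."""
        v = np.asarray(values)
        p = percentile_pvalues(v)
        assert np.all((p > 0) & (p <= 1))
        assert p[np.argmax(v)] == p.min()
        order = np.argsort(v)
        assert np.all(np.diff(p[order]) <= 1e-12)

    def test_uniform_under_exchangeable_null(self):
        """KS test does not reject uniformity at n=10,000, alpha=0.01."""
        rng = np.random.default_rng(1)
        p = percentile_pvalues(rng.normal(size=10_000) ** 2)
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestCombine:
    def test_product(self):
        assert combine_pvalues(0.2, 0.5, 0.1) == pytest.approx(0.01)

    def test_identity_elements(self):
        assert combine_pvalues(1.0, 1.0, 1.0) == 1.0
        assert combine_pvalues(0.37, 1.0, 1.0) == pytest.approx(0.37)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            combine_pvalues(bad, 0.5, 0.5)


class TestMafBins:
    def test_fixed_width_assignment(self):
        maf = np.repeat([0.02, 0.07, 0.50], 5)
        idx, edges = maf_bins(maf, min_bin=1)
        assert edges[0] == (0.0, 0.05)
        assert idx[0] == 0 and idx[5] == 1
        # 0.50 belongs to the right-closed last stratum
        last = idx[-1]
        assert last == max(idx)
        assert edges[last][1] == 0.5

    def test_small_input_merges_to_single_stratum(self):
        idx, edges = maf_bins(np.linspace(0, 0.5, 10), min_bin=200)
        assert set(idx.tolist()) == {0}
        assert len(edges) == 1

    def test_merged_bins_reach_minimum(self):
        rng = np.random.default_rng(2)
        maf = rng.beta(0.5, 3, size=2_000) / 2
        idx, edges = maf_bins(maf, min_bin=200)
        counts = np.bincount(idx)
        assert (counts >= 200).all()
        assert len(edges) == len(counts)


class TestProductUniformCdf:
    def test_k1_is_identity(self):
        t = np.array([0.0, 0.05, 1.0])
        np.testing.assert_allclose(product_uniform_cdf(t, 1), t)

    def test_matches_gamma_tail_closed_form(self):
        """P(U1*U2*U3 < t) = P(Gamma(3,1) > -ln t): independent oracle."""
        for t in (1e-6, 1e-4, 1e-2, 0.1, 0.9):
            assert product_uniform_cdf(t, 3) == pytest.approx(
                stats.gamma.sf(-np.log(t), 3), rel=1e-12
            )

    def test_matches_monte_carlo(self):
        rng = np.random.default_rng(3)
        n = 2_000_000
        prod = rng.random((n, 3)).prod(axis=1)
        for t in (1e-4, 1e-3, 1e-2, 1e-1):
            f = product_uniform_cdf(t, 3)
            se = np.sqrt(f * (1 - f) / n)
            assert abs((prod < t).mean() - f) < 3 * se + 2 / n


class TestAnalyticThreshold:
    def test_k1_closed_form(self):
        assert fdr_threshold_analytic(5, 100, k=1) == pytest.approx(0.05)

    def test_k3_solves_defining_equation(self):
        t = fdr_threshold_analytic(1, 1000, k=3)
        u = -np.log(t)
        assert t * (1 + u + u**2 / 2) == pytest.approx(1e-3, rel=1e-9)

    def test_monotone_in_m(self):
        ts = [fdr_threshold_analytic(m, 46_736) for m in (0.05, 1, 5)]
        assert ts[0] < ts[1] < ts[2]

    def test_m_at_least_n_saturates(self):
        assert fdr_threshold_analytic(10, 10) == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fdr_threshold_analytic(0, 100)
        with pytest.raises(ValueError):
            fdr_threshold_analytic(1, 0)


class TestEmpiricalThreshold:
    @staticmethod
    def _uniform_null(rng, n):
        return rng.random((n, 3)).prod(axis=1)

    def test_agrees_with_analytic_for_exact_uniforms(self):
        rng = np.random.default_rng(4)
        n = 5_000
        t_emp = fdr_threshold_empirical(self._uniform_null, 5, n, 400, rng)
        t_ana = fdr_threshold_analytic(5, n)
        # compare on the implied expected count scale (stable across t scales)
        assert n * product_uniform_cdf(t_emp, 3) == pytest.approx(5, abs=1.0)
        assert t_emp == pytest.approx(t_ana, rel=0.5)

    def test_doubling_m_doubles_the_passing_count(self):
        rng = np.random.default_rng(5)
        n = 5_000
        t1 = fdr_threshold_empirical(self._uniform_null, 2, n, 300, rng)
        t2 = fdr_threshold_empirical(self._uniform_null, 4, n, 300, rng)
        c1 = n * product_uniform_cdf(t1, 3)
        c2 = n * product_uniform_cdf(t2, 3)
        assert c2 == pytest.approx(2 * c1, rel=0.35)

    def test_degenerate_null_saturates(self):
        t = fdr_threshold_empirical(lambda r, n: np.ones(n), 1, 100, 100, np.random.default_rng(0))
        assert t == 1.0

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            fdr_threshold_empirical(self._uniform_null, 1, 100, 50, np.random.default_rng(0))


class TestClassify:
    def _thresholds(self):
        return {0.05: 1e-7, 1.0: 1e-5, 5.0: 1e-4}

    def test_rule_application(self):
        p = np.array([5e-8, 5e-8, 5e-5, 1e-3])
        seg = np.array([True, False, True, True])
        tier = classify_candidates(p, self._thresholds(), seg)
        assert tier.tolist() == ["fp0.05", "none", "fp5", "none"]

    def test_tiers_nested_for_random_inputs(self):
        rng = np.random.default_rng(6)
        p = 10.0 ** rng.uniform(-9, 0, size=2_000)
        seg = rng.random(2_000) < 0.5
        tier = classify_candidates(p, self._thresholds(), seg)
        sets = {
            name: set(np.nonzero(tier == name)[0])
            for name in ("fp0.05", "fp1", "fp5")
        }
        strict = sets["fp0.05"]
        mid = strict | sets["fp1"]
        wide = mid | sets["fp5"]
        assert strict <= mid <= wide
        assert not (wide & set(np.nonzero(~seg)[0]))


class TestScoreSnps:
    def _records(self):
        rng = np.random.default_rng(7)
        n = 300
        df = pd.DataFrame(
            {
                "chrom": "1",
                "pos": np.arange(n) + 1,
                "afd_pop": rng.uniform(0.05, 1.0, n),
                "afd_line1": rng.uniform(0.05, 1.0, n),
                "afd_line2": rng.uniform(0.05, 1.0, n),
                "maf": rng.uniform(0, 0.5, n),
                "parental_config": rng.choice(["0/2", "1/1", "1/2"], n),
                "same_sign": True,
            }
        )
        df.loc[0, "parental_config"] = None
        df.loc[1, "parental_config"] = "2/2"  # monomorphic in the cross
        return df

    def test_monomorphic_sites_get_line_p_one(self):
        res = score_snps(self._records(), SignificanceConfig(min_bin=50))
        row = res.table.iloc[1]
        assert row["p_line1"] == 1.0 and row["p_line2"] == 1.0
        assert np.isnan(res.table.iloc[0]["p_pop"])  # unknown parents: unscored

    def test_combined_is_product(self):
        res = score_snps(self._records(), SignificanceConfig(min_bin=50))
        t = res.table.dropna(subset=["p_pop"])
        np.testing.assert_allclose(
            t["p_combined"], t["p_pop"] * t["p_line1"] * t["p_line2"]
        )

    def test_thresholds_computed_on_scored_set(self):
        res = score_snps(self._records(), SignificanceConfig(min_bin=50))
        assert res.n_scored == 299
        assert res.thresholds[5.0] == pytest.approx(
            fdr_threshold_analytic(5.0, 299)
        )
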