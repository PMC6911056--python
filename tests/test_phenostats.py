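import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from famseg.phenostats import (GroupSummary, anova_from_summary,
                               anova_oneway, bdr_percent, bonferroni,
                               bonferroni_adjust, covariate_adjust,
                               kruskal_wallis, odor_group_comparison,
                               shapiro_wilk, two_group_test)

AGE_SUMMARIES = [GroupSummary("GG", 57, 106.88, 42.09),
              GroupSummary("GC", 58, 101.36, 38.20),
              GroupSummary("CC", 26, 106.50, 38.36)]


def moment_matched(n, mean, sd, rng):
    """Raw sample with exactly the requested n, mean and SD (ddof=1)."""
    z = rng.normal(size=n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z


class TestShapiroWilk:
    def test_perfect_normal_order_statistics(self):
        x = sps.norm.ppf((np.arange(1, 11) - 0.375) / (10 + 0.25))
        r = shapiro_wilk(x)
        assert r.statistic >= 0.99

    def test_gross_outlier_rejected(self):
        r = shapiro_wilk([1, 1, 1, 1, 1, 1, 1, 1, 1, 100])
        assert r.p < 0.05

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            shapiro_wilk([5, 5, 5])

    def test_size_limits(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])


class TestAnova:
    def test_equal_means_null(self):
        groups = [[1, 2, 3], [1, 2, 3], [1, 2, 3]]
        r = anova_oneway(groups)
        assert r.statistic == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)
        assert r.df == (2, 6)

    def test_single_point_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([[1.0], [2.0]])

    def test_summary_equals_raw_on_moment_matched_data(self):
        """anova_from_summary and anova_oneway coincide to 1e-9 on data
        constructed to match given (n, mean, sd)."""
        rng = np.random.default_rng(12)
        for _ in range(5):
            ns = rng.integers(5, 40, size=3)
            means = rng.normal(50, 10, size=3)
            sds = rng.uniform(1, 15, size=3)
            groups = [moment_matched(n, m, s, rng)
                      for n, m, s in zip(ns, means, sds)]
            raw = anova_oneway(groups)
            summ = anova_from_summary([
                GroupSummary(f"g{i}", int(n), float(g.mean()),
                             float(g.std(ddof=1)))
                for i, (n, g) in enumerate(zip(ns, groups))])
            assert summ.statistic == pytest.approx(raw.statistic, abs=1e-9)
            assert summ.p == pytest.approx(raw.p, abs=1e-9)

    def test_age_row_from_printed_summaries(self):
        """The cohort's age row (n 57/58/26) is a null finding: p ~ 0.73."""
        r = anova_from_summary(AGE_SUMMARIES)
        assert r.p == pytest.approx(0.73, abs=0.005)

    def test_identical_means_summary(self):
        r = anova_from_summary([GroupSummary("a", 10, 5.0, 1.0),
                                GroupSummary("b", 12, 5.0, 2.0)])
        assert r.statistic == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_zero_within_variance_degenerate(self):
        r = anova_from_summary([GroupSummary("a", 5, 1.0, 0.0),
                                GroupSummary("b", 5, 2.0, 0.0)])
        assert r.degenerate and r.p == 0.0

    def test_group_order_invariance(self):
        r1 = anova_from_summary(AGE_SUMMARIES)
        r2 = anova_from_summary(AGE_SUMMARIES[::-1])
        assert r1.statistic == pytest.approx(r2.statistic)


class TestKruskalWallis:
    def test_hand_ranked_value(self):
        # groups {1,2} vs {3,4}: ranks 1,2 vs 3,4
        # H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2 = 2.4
        r = kruskal_wallis([[1, 2], [3, 4]])
        assert r.statistic == pytest.approx(2.4)
        assert r.p == pytest.approx(sps.chi2.sf(2.4, 1), abs=1e-9)

    def test_identical_groups_zero(self):
        r = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert r.statistic == pytest.approx(0.0)

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 1], [1, 1]])

    def test_asymptotic_vs_exact_permutation_small_n(self):
        """For tiny samples the chi-square approximation must make the
        same accept/reject call at alpha=0.2 as the exact permutation
        null of the H statistic."""
        def h_stat(a, b):
            return sps.kruskal(a, b).statistic

        rng = np.random.default_rng(3)
        for _ in range(6):
            pooled = rng.normal(size=7)
            a, b = pooled[:3], pooled[3:]
            h_obs = h_stat(a, b)
            perm_ps = []
            for idx in itertools.combinations(range(7), 3):
                mask = np.zeros(7, bool)
                mask[list(idx)] = True
                perm_ps.append(h_stat(pooled[mask], pooled[~mask]))
            p_exact = np.mean(np.array(perm_ps) >= h_obs - 1e-12)
            p_asym = kruskal_wallis([a, b]).p
            assert (p_exact <= 0.2) == (p_asym <= 0.2)


class TestTwoGroupTest:
    def test_identical_groups(self):
        r = two_group_test([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        headline = r if r.test_name == "t_test" else r.companion
        assert headline.statistic == pytest.approx(0.0)
        assert headline.p == pytest.approx(1.0)

    def test_large_effect_detected(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 20)
        b = rng.normal(2, 1, 20)
        r = two_group_test(a, b)
        assert r.p < 0.01

    def test_heavy_tails_route_nonparametric(self):
        rng = np.random.default_rng(19)
        a = sps.cauchy.rvs(size=30, random_state=rng)
        b = sps.cauchy.rvs(size=30, random_state=rng) + 1
        r = two_group_test(a, b)
        assert r.normality_route == "nonparametric"
        assert r.test_name == "wilcoxon"
        assert r.companion.test_name == "t_test"

    def test_normal_data_routes_parametric(self):
        rng = np.random.default_rng(21)
        r = two_group_test(rng.normal(size=25), rng.normal(size=25))
        assert r.normality_route == "parametric"


class TestBonferroni:
    def test_ten_comparisons(self):
        assert bonferroni(0.05, 10) == pytest.approx(0.005)

    def test_identity_single(self):
        assert bonferroni(0.05, 1) == pytest.approx(0.05)

    def test_adjust_caps_at_one(self):
        adj = bonferroni_adjust([0.3, 0.001, 0.05, 0.5, 0.2])
        assert adj[0] == 1.0
        assert adj[1] == pytest.approx(0.005)

    def test_adjust_monotone_and_idempotent_after_cap(self):
        p = np.array([0.001, 0.01, 0.04, 0.3])
        adj = bonferroni_adjust(p)
        assert np.all(np.diff(adj) >= 0)
        assert np.all(np.minimum(1.0, adj) == adj)

    def test_zero_comparisons_rejected(self):
        with pytest.raises(ValueError):
            bonferroni(0.05, 0)


class TestCovariateAdjust:
    def make_table(self, n, rng, linear=True):
        age = rng.uniform(5, 15, n)
        sex = rng.choice(["male", "female"], n)
        height = rng.uniform(100, 170, n)
        if linear:
            val = 3.0 + 2.0 * age + 5.0 * (sex == "female") + 0.1 * height
        else:
            val = rng.normal(20, 5, n)
        return pd.DataFrame({"feno_ppb": val, "age": age, "sex": sex,
                             "height": height})

    def test_exact_linear_gives_unit_ratios(self):
        rng = np.random.default_rng(2)
        t = self.make_table(50, rng, linear=True)
        ratio = covariate_adjust(t, "feno_ppb")
        assert np.allclose(ratio, 1.0, atol=1e-8)

    def test_independent_covariates_mean_ratio_one(self):
        rng = np.random.default_rng(7)
        t = self.make_table(100, rng, linear=False)
        ratio = covariate_adjust(t, "feno_ppb")
        assert abs(ratio.mean() - 1.0) < 0.05

    def test_insufficient_rows(self):
        rng = np.random.default_rng(0)
        t = self.make_table(3, rng)
        with pytest.raises(ValueError, match="complete rows"):
            covariate_adjust(t, "feno_ppb")

    def test_constant_covariate_named(self):
        rng = np.random.default_rng(1)
        t = self.make_table(30, rng)
        t["height"] = 150.0
        with pytest.raises(ValueError, match="height"):
            covariate_adjust(t, "feno_ppb")

    def test_missing_rows_get_nan(self):
        rng = np.random.default_rng(3)
        t = self.make_table(30, rng)
        t.loc[5, "age"] = np.nan
        ratio = covariate_adjust(t, "feno_ppb")
        assert np.isnan(ratio.loc[5])
        assert ratio.drop(5).notna().all()


class TestBdr:
    def test_direct_formula(self):
        assert bdr_percent(2.0, 2.2) == pytest.approx(10.0)

    def test_no_response(self):
        assert bdr_percent(1.8, 1.8) == pytest.approx(0.0)

    def test_zero_pre_rejected(self):
        with pytest.raises(ValueError):
            bdr_percent(0.0, 1.0)


class TestOdorComparison:
    def make_two_group_table(self, shift, rng, n_ctrl=6, n_asthma=9):
        rows = []
        for _ in range(n_ctrl):
            rows.append({"group": "control",
                         "odor_score_pea": rng.normal(9.0, 1.0)})
        for _ in range(n_asthma):
            rows.append({"group": "asthma",
                         "odor_score_pea": rng.normal(9.0 - shift, 1.0)})
        return pd.DataFrame(rows)

    def test_large_shift_significant(self):
        """A 3-tube drop in odor threshold (6 controls vs 9 asthmatics,
        SD 1) is detected."""
        rng = np.random.default_rng(11)
        t = self.make_two_group_table(3.0, rng)
        res, summary = odor_group_comparison(t, "group")
        assert res.p < 0.01
        assert set(summary["group"]) == {"control", "asthma"}
        assert (summary["sem"] > 0).all()

    def test_null_type_one_error(self):
        """With identical distributions the test rejects at roughly the
        nominal 5% rate."""
        rng = np.random.default_rng(13)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            t = self.make_two_group_table(0.0, rng)
            res, _ = odor_group_comparison(t, "group")
            rejections += res.p < 0.05
        assert 0.02 <= rejections / n_rep <= 0.09

    def test_three_genotype_groups_summary_path(self):
        """The genotyped-cohort odor-score comparison (means 8.4, 7.04,
        6.48 across GG/GC/CC) runs through the summary-statistics ANOVA
        and returns a valid result."""
        r = anova_from_summary([GroupSummary("GG", 57, 8.4, 3.09),
                                GroupSummary("GC", 58, 7.04, 3.39),
                                GroupSummary("CC", 26, 6.48, 3.63)])
        assert r.test_name == "anova"
        assert 0.0 <= r.p <= 1.0
        assert r.df == (2, 138)

    def test_three_group_raw_path(self):
        rng = np.random.default_rng(17)
        rows = []
        for grp, mean in (("GG", 8.4), ("GC", 7.0), ("CC", 6.5)):
            for _ in range(20):
                rows.append({"genotype_group": grp,
                             "odor_score_pea": rng.normal(mean, 3.0)})
        res, summary = odor_group_comparison(pd.DataFrame(rows),
                                             "genotype_group")
        assert res.test_name in ("anova", "kruskal_wallis")
        assert len(summary) == 3


class TestTypeOneError:
    def test_anova_null_calibration(self):
        """Under a 3-group normal null the ANOVA rejects at ~5%."""
        rng = np.random.default_rng(29)
        n_rep = 2000
        a = rng.normal(size=(n_rep, 20))
        b = rng.normal(size=(n_rep, 20))
        c = rng.normal(size=(n_rep, 20))
        _, p = sps.f_oneway(a, b, c, axis=1)
        # spot-check the vectorised nulls against our implementation
        r0 = anova_oneway([a[0], b[0], c[0]])
        assert r0.p == pytest.approx(p[0], abs=1e-12)
        rate = (p < 0.05).mean()
        assert 0.035 <= rate <= 0.065
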