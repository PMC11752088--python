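import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sandicortex.stats import (StatResult, adjusted_regression, bh_fdr,
                               cognition_scores, hedges_g_from_summary,
                               independent_t, paired_t, rm_anova_gg,
                               zscore_vs_hc)


# ---------------------------------------------------------------------------
# independent from-scratch oracles
# ---------------------------------------------------------------------------

def oracle_pooled_t(a, b):
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = (np.sum((a - np.mean(a)) ** 2) + np.sum((b - np.mean(b)) ** 2)) / df
    t = (np.mean(b) - np.mean(a)) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * (1 - sps.t.cdf(abs(t), df))
    return t, p


def oracle_gg_rm_anova(x):
    """Sums-of-squares + covariance-matrix repeated-measures oracle."""
    n, k = x.shape
    grand = x.mean()
    subj_means = x.mean(axis=1, keepdims=True)
    cond_means = x.mean(axis=0, keepdims=True)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    resid = x - subj_means - cond_means + grand
    ss_err = np.sum(resid ** 2)
    f = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
    s = np.cov(x, rowvar=False, ddof=1)
    centered = s - s.mean(axis=0, keepdims=True) - s.mean(axis=1, keepdims=True) + s.mean()
    eps = (np.trace(centered) ** 2) / ((k - 1) * np.sum(centered ** 2))
    p = 1 - sps.f.cdf(f, eps * (k - 1), eps * (k - 1) * (n - 1))
    return f, eps, p


def oracle_bh(p):
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


class TestIndependentT:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        r = independent_t(a, a.copy())
        assert r.mean_diff == 0.0
        assert r.hedges_g == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_hand_computed_g(self):
        # means 1 vs 0, unit variance, n = 10 each: J = 1 - 3/71
        rng = np.random.default_rng(0)
        a = rng.normal(size=10)
        a = (a - a.mean()) / a.std(ddof=1) + 1.0
        b = rng.normal(size=10)
        b = (b - b.mean()) / b.std(ddof=1)
        r = independent_t(a, b)
        assert r.hedges_g == pytest.approx((1 - 3 / 71) * 1.0, abs=1e-9)
        assert r.hedges_g == pytest.approx(0.958, abs=1e-3)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, rng.integers(4, 20))
        b = rng.normal(0.3, 1.4, rng.integers(4, 20))
        r = independent_t(a, b)
        t_o, p_o = oracle_pooled_t(a, b)
        assert r.statistic == pytest.approx(t_o, abs=1e-10)
        assert r.p == pytest.approx(p_o, abs=1e-10)
        ci_contains = r.ci_low <= r.mean_diff <= r.ci_high
        assert ci_contains

    def test_matches_scipy(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        r = independent_t(a, b)
        t_sp, p_sp = sps.ttest_ind(b, a, equal_var=True)
        assert r.statistic == pytest.approx(t_sp, abs=1e-12)
        assert r.p == pytest.approx(p_sp, abs=1e-12)

    def test_degenerate_zero_variance(self):
        r = independent_t([1.0, 1.0], [2.0, 2.0])
        assert r.degenerate and r.p == 0.0


class TestHedgesGFromSummary:
    def test_equal_means(self):
        assert hedges_g_from_summary(1.0, 1.0, 10, 1.0, 1.0, 10) == 0.0

    def test_hand_computed(self):
        assert hedges_g_from_summary(1, 1, 10, 0, 1, 10) == pytest.approx(
            1 - 3 / 71, abs=1e-12)

    def test_antisymmetry(self):
        g1 = hedges_g_from_summary(0.58, 0.028, 34, 0.49, 0.089, 41)
        g2 = hedges_g_from_summary(0.49, 0.089, 41, 0.58, 0.028, 34)
        assert g1 == pytest.approx(-g2)

    def test_matches_full_data_version(self, rng):
        a = rng.normal(0, 1, 14)
        b = rng.normal(1, 2, 9)
        g_summary = hedges_g_from_summary(a.mean(), a.std(ddof=1), a.size,
                                          b.mean(), b.std(ddof=1), b.size)
        assert independent_t(a, b).hedges_g == pytest.approx(g_summary, abs=1e-12)


class TestPairedT:
    def test_identical(self):
        a = np.array([1.0, 2.0, 3.0])
        r = paired_t(a, a.copy())
        assert r.statistic == 0.0 and r.p == pytest.approx(1.0)

    def test_hand_computed(self):
        # differences (1, 2, 3): t = 2 / (1/sqrt(3)) = 3.464
        r = paired_t([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])
        assert r.statistic == pytest.approx(np.sqrt(3) * 2, abs=1e-9)
        assert r.p == pytest.approx(2 * sps.t.sf(np.sqrt(12), 2), abs=1e-12)

    def test_antisymmetric_in_order(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0.4, 1, 10)
        assert paired_t(a, b).statistic == pytest.approx(
            -paired_t(b, a).statistic)

    def test_matches_scipy(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.4, 1, 12)
        r = paired_t(a, b)
        t_sp, p_sp = sps.ttest_rel(b, a)
        assert r.statistic == pytest.approx(t_sp, abs=1e-12)
        assert r.p == pytest.approx(p_sp, abs=1e-12)


class TestRMAnovaGG:
    def test_zero_effect(self):
        x = np.tile(np.array([[1.0], [2.0], [3.0], [2.5]]), (1, 4))
        r = rm_anova_gg(x)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sums_of_squares_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, (6, 4)) + rng.normal(0, 0.5, (6, 1))
        r = rm_anova_gg(x)
        f_o, eps_o, p_o = oracle_gg_rm_anova(x)
        assert r.statistic == pytest.approx(f_o, abs=1e-10)
        assert r.extra["eps"] == pytest.approx(eps_o, abs=1e-10)
        assert r.p == pytest.approx(p_o, abs=1e-10)

    def test_two_conditions_equals_paired_t_squared(self, rng):
        x = rng.normal(0, 1, (8, 2))
        r = rm_anova_gg(x)
        t = paired_t(x[:, 0], x[:, 1])
        assert r.extra["eps"] == pytest.approx(1.0, abs=1e-10)
        assert r.statistic == pytest.approx(t.statistic ** 2, abs=1e-9)

    def test_incomplete_matrix_rejected(self):
        x = np.ones((5, 3))
        x[0, 0] = np.nan
        with pytest.raises(ValueError):
            rm_anova_gg(x)


class TestZScore:
    def test_at_reference_mean(self):
        assert zscore_vs_hc(0.58, 0.58, 0.028) == 0.0

    def test_hand_computed(self):
        assert zscore_vs_hc(0.55, 0.58, 0.028) == pytest.approx(-1.071, abs=1e-3)

    def test_linearity(self):
        z1 = zscore_vs_hc(1.0, 0.0, 2.0)
        z2 = zscore_vs_hc(3.0, 0.0, 2.0)
        assert zscore_vs_hc(2.0, 0.0, 2.0) == pytest.approx((z1 + z2) / 2)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            zscore_vs_hc(1.0, 0.0, 0.0)


class TestAdjustedRegression:
    def test_perfect_fit(self, rng):
        x = rng.normal(0, 1, 30)
        age = rng.normal(45, 10, 30)
        sex = rng.integers(0, 2, 30)
        r = adjusted_regression(x, x, age, sex)
        assert r.mean_diff == pytest.approx(1.0, abs=1e-8)
        assert r.ci_low <= 1.0 <= r.ci_high

    def test_recovers_known_coefficient(self, rng):
        n = 200
        x = rng.normal(0, 1, n)
        age = rng.normal(45, 12, n)
        sex = rng.integers(0, 2, n)
        y = 0.5 * x + 0.1 * age + rng.normal(0, 0.3, n)
        r = adjusted_regression(y, x, age, sex)
        assert r.ci_low <= 0.5 <= r.ci_high
        assert r.mean_diff == pytest.approx(0.5, abs=0.1)

    def test_constant_predictor_rejected(self, rng):
        with pytest.raises(ValueError):
            adjusted_regression(rng.normal(0, 1, 20), np.ones(20),
                                rng.normal(45, 5, 20), rng.integers(0, 2, 20))

    def test_sex_strings_accepted(self, rng):
        x = rng.normal(0, 1, 25)
        y = x + rng.normal(0, 0.1, 25)
        sex = np.array(["M", "F"] * 12 + ["M"])
        r = adjusted_regression(y, x, rng.normal(40, 5, 25), sex)
        assert np.isfinite(r.p)


class TestBHFDR:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.03]), [0.03])

    def test_hand_applied_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_step_up_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, rng.integers(1, 25))
        np.testing.assert_allclose(bh_fdr(p), oracle_bh(p), atol=1e-12)

    def test_monotone_in_raw_ranks(self, rng):
        p = np.sort(rng.uniform(0, 1, 15))
        adj = bh_fdr(p)
        assert np.all(np.diff(adj) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestCognition:
    def test_all_zero(self):
        out = cognition_scores(pd.DataFrame({"a": [0.0], "b": [0.0]}))
        assert out["average_z"].iloc[0] == 0.0
        assert not out["impaired"].iloc[0]

    def test_hand_computed_average_and_flag(self):
        out = cognition_scores(pd.DataFrame({"a": [-1.6], "b": [0.0],
                                             "c": [0.0]}))
        assert out["average_z"].iloc[0] == pytest.approx(-0.5333, abs=1e-4)
        assert out["impaired"].iloc[0]

    def test_threshold_is_inclusive(self):
        out = cognition_scores(pd.DataFrame({"a": [-1.5]}))
        assert out["impaired"].iloc[0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cognition_scores(pd.DataFrame())
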