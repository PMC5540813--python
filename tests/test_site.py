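"""Within-site stage: AI arithmetic, adaptive exclusion, residualization
and the per-site test statistics."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from subasym import (
    CovariateResidualizer,
    ancova_age,
    compute_ai,
    exclude_outliers,
    one_sample_lateralization,
    residualize,
    sd_threshold,
    se_from_ci,
    summarize_site,
    welch_test,
)


class TestComputeAI:
    @pytest.mark.parametrize("left,right,expected", [
        (110.0, 90.0, 0.1),
        (100.0, 100.0, 0.0),
        (0.0, 50.0, -1.0),
        (50.0, 0.0, 1.0),
    ])
    def test_examples(self, left, right, expected):
        assert compute_ai(left, right) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize("left,right", [(0.0, 0.0), (-1.0, 5.0), (5.0, -1.0)])
    def test_domain_errors(self, left, right):
        with pytest.raises(ValueError):
            compute_ai(left, right)

    @given(st.floats(0.0, 1e6), st.floats(0.0, 1e6))
    def test_antisymmetric_and_bounded(self, left, right):
        if left + right <= 0:
            return
        ai = compute_ai(left, right)
        assert -1.0 <= ai <= 1.0
        assert compute_ai(right, left) == pytest.approx(-ai, abs=1e-15)


class TestSdThreshold:
    @pytest.mark.parametrize("n,expected", [
        (1, 2.5), (100, 2.5), (149, 2.5),
        (150, 3.0), (500, 3.0), (1000, 3.0),
        (1001, 3.5), (1500, 3.5),
    ])
    def test_tiers(self, n, expected):
        assert sd_threshold(n) == expected

    def test_domain_error(self):
        with pytest.raises(ValueError):
            sd_threshold(0)


def _brute_force_mask(x, thresh):
    x = np.asarray(x, float)
    z = (x - x.mean()) / x.std(ddof=1)
    return np.abs(z) <= thresh


class TestExcludeOutliers:
    def test_matches_brute_force_zscores(self, rng):
        for _ in range(20):
            x = rng.standard_t(df=3, size=50)
            for thresh in (2.5, 3.0, 3.5):
                np.testing.assert_array_equal(
                    exclude_outliers(x, thresh), _brute_force_mask(x, thresh))

    def test_single_large_value(self):
        # mean 20, SD ~44.7: z(100) ~ 1.79, inside a 2.5-SD fence; the mask
        # must agree with the brute-force z-scores, not intuition
        x = [0.0, 0.0, 0.0, 0.0, 100.0]
        np.testing.assert_array_equal(
            exclude_outliers(x, 2.5), _brute_force_mask(x, 2.5))

    def test_constant_vector_all_included(self):
        assert exclude_outliers([3.0] * 10, 2.5).all()

    def test_nonfinite_excluded(self):
        mask = exclude_outliers([1.0, np.nan, 2.0, np.inf, 3.0], 3.0)
        np.testing.assert_array_equal(mask, [True, False, True, False, True])

    def test_normal_tail_fraction(self, rng):
        # exclusion fraction at 3.5 SD ~ 2*Phi(-3.5) ~ 4.7e-4
        x = rng.standard_normal(200_000)
        frac = 1.0 - exclude_outliers(x, 3.5).mean()
        expected = 2 * stats.norm.cdf(-3.5)
        assert frac == pytest.approx(expected, abs=3 * math.sqrt(expected / 200_000))


class TestResidualize:
    def test_orthogonal_covariate_removes_only_mean(self, rng):
        y = rng.standard_normal(64)
        yc = y - y.mean()
        c = rng.standard_normal(64)
        c -= c.mean()
        c -= (c @ yc) / (yc @ yc) * yc  # orthogonal to both 1 and y
        res = residualize(y, [c])
        np.testing.assert_allclose(res, y - y.mean(), atol=1e-10)

    def test_exact_linear_signal_gives_zero_residuals(self, rng):
        x = rng.uniform(0, 10, 50)
        res = residualize(2.0 + 3.0 * x, [x])
        np.testing.assert_allclose(res, 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_covariates(self, rng):
        n = 200
        C = rng.standard_normal((n, 3))
        y = rng.standard_normal(n)
        res = residualize(y, list(C.T))
        assert abs(res.mean()) < 1e-12
        for j in range(3):
            assert abs(res @ C[:, j]) < 1e-8 * n

    def test_collinear_design_names_columns(self, rng):
        x = rng.standard_normal(30)
        with pytest.raises(ValueError, match="age|dup"):
            residualize(rng.standard_normal(30), [x, 2 * x], names=["age", "dup"])

    def test_transformer_matches_function(self, rng):
        n = 80
        C = rng.standard_normal((n, 2))
        Y = rng.standard_normal((n, 3))
        tr = CovariateResidualizer().fit(Y, covariates=list(C.T))
        out = tr.transform(Y, covariates=list(C.T))
        for j in range(3):
            np.testing.assert_allclose(
                out[:, j], residualize(Y[:, j], list(C.T)), atol=1e-10)


class TestWelch:
    def test_identical_groups(self):
        w = welch_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert w.t == 0.0 and w.p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # var=1 in both groups of 3: se = sqrt(2/3), df = 4 by Satterthwaite
        w = welch_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert w.mean_diff == pytest.approx(-1.0)
        assert w.se == pytest.approx(math.sqrt(2.0 / 3.0), rel=1e-12)
        assert w.t == pytest.approx(-1.0 / math.sqrt(2.0 / 3.0), rel=1e-12)
        assert w.df == pytest.approx(4.0, rel=1e-12)

    def test_balanced_equal_variance_matches_student(self, rng):
        a, b = rng.standard_normal(30), rng.standard_normal(30) + 0.5
        w = welch_test(a, b)
        t_student = stats.ttest_ind(a, b, equal_var=True).statistic
        assert w.t == pytest.approx(t_student, rel=1e-12)

    def test_degenerate_error(self):
        with pytest.raises(ValueError):
            welch_test([1.0, 1.0], [2.0, 2.0])

    def test_ci_roundtrips_through_se_from_ci(self, rng):
        a, b = rng.standard_normal(20), rng.standard_normal(35)
        w = welch_test(a, b)
        assert se_from_ci(w.ci_low, w.ci_high, w.df) == pytest.approx(w.se, abs=1e-12)


class TestAncova:
    def test_constant_ai_gives_zero_coefficient(self, rng):
        n = 50
        coef, _, _ = ancova_age(np.full(n, 0.02), rng.uniform(20, 60, n),
                                rng.integers(0, 2, n), rng.normal(1.5e6, 1e5, n))
        assert coef == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_signal(self, rng):
        n = 50
        age = rng.uniform(20, 60, n)
        coef, se, _ = ancova_age(0.001 * age, age, rng.integers(0, 2, n),
                                 rng.normal(1.5e6, 1e5, n))
        assert coef == pytest.approx(0.001, rel=1e-9)
        assert se == pytest.approx(0.0, abs=1e-9)

    def test_recovers_simulated_slope_within_3se(self, rng):
        n = 10_000
        kappa = 1.5e-4
        age = rng.uniform(18, 80, n)
        sex = rng.integers(0, 2, n).astype(float)
        icv = rng.normal(1.5e6, 1.2e5, n)
        ai = 0.02 + kappa * age - 0.002 * sex + rng.normal(0, 0.028, n)
        coef, se, _ = ancova_age(ai, age, sex, icv)
        assert abs(coef - kappa) < 3 * se

    def test_constant_age_errors(self, rng):
        n = 30
        with pytest.raises(ValueError):
            ancova_age(rng.standard_normal(n), np.full(n, 40.0),
                       rng.integers(0, 2, n), rng.normal(1.5e6, 1e5, n))


class TestOneSampleLateralization:
    def test_symmetric_sample_t_zero(self):
        mean, t, _ = one_sample_lateralization([-0.3, 0.3, -0.1, 0.1])
        assert mean == pytest.approx(0.0) and t == pytest.approx(0.0)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            one_sample_lateralization([0.1, 0.1, 0.1])

    def test_power_matches_noncentral_t(self, rng):
        # n=100 draws from N(0.02, 0.03^2) tested at alpha=0.007
        n, mu, sd, alpha = 100, 0.02, 0.03, 0.007
        delta = mu / (sd / math.sqrt(n))
        tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
        power = stats.nct.sf(tcrit, n - 1, delta) + stats.nct.cdf(-tcrit, n - 1, delta)
        reps = 800
        hits = sum(
            one_sample_lateralization(rng.normal(mu, sd, n))[2] < alpha
            for _ in range(reps)
        )
        se_mc = math.sqrt(power * (1 - power) / reps)
        assert hits / reps == pytest.approx(power, abs=4 * se_mc)


class TestSeFromCI:
    def test_normal_quantile_limit(self):
        assert se_from_ci(-0.1, 0.3, 10**6) == pytest.approx(0.4 / (2 * 1.959964), rel=1e-4)

    def test_t_quantile_small_df(self):
        assert se_from_ci(0.0, 0.2, 4) == pytest.approx(0.2 / (2 * 2.776445), rel=1e-5)

    @pytest.mark.parametrize("lo,hi,df", [(0.3, -0.1, 10), (0.0, 0.2, 0.5)])
    def test_domain_errors(self, lo, hi, df):
        with pytest.raises(ValueError):
            se_from_ci(lo, hi, df)


class TestSummarizeSite:
    def test_idempotent_and_complete(self, small_sites):
        s1 = summarize_site(small_sites[0])
        s2 = summarize_site(small_sites[0])
        assert s1.equals(s2)
        assert set(s1["contrast"]) >= {"sex", "age", "lateralization_M",
                                       "lateralization_F"}
        assert (s1["n_total"] <= len(small_sites[0])).all()
        assert (s1.loc[s1["se"].notna(), "se"] > 0).all()

    def test_pvalues_uniform_under_null(self, rng):
        # residualize-then-Welch on zero-effect data: p-values uniform
        pvals = []
        for _ in range(1000):
            n = 100
            age = rng.uniform(20, 60, n)
            icv = rng.normal(1.5e6, 1e5, n)
            ai = rng.normal(0, 0.03, n)
            male = np.zeros(n, bool)
            male[: n // 2] = True
            resid = residualize(ai, [age, icv])
            pvals.append(welch_test(resid[male], resid[~male]).p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
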