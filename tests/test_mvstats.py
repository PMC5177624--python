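"""Multivariate statistics against hand computations, Monte Carlo and an
independent implementation (pingouin)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from stepthrow.mvstats import (bonferroni, hotelling_one_sample, mardia_tests,
                               mean_confidence_ellipse, pair_within_subject,
                               rm_anova_one_way)


class TestHotelling:
    def test_four_point_hand_example(self):
        # mean (0,0), S = (2/3) I: T2 = 4 * 2 * (3/2) = 12, F(2,2) = 4,
        # and the F(2,2) survival function is 1/(1+x) -> p = 0.2
        x = np.array([[1, 0], [0, 1], [-1, 0], [0, -1]], dtype=float)
        gs = hotelling_one_sample(x, mu0=[1, 1])
        assert gs.t2 == pytest.approx(12.0)
        assert gs.f_value == pytest.approx(4.0)
        assert gs.df == (2, 2)
        assert gs.p_value == pytest.approx(0.2)

    def test_true_mean_gives_zero_statistic(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(10, 2))
        gs = hotelling_one_sample(x, mu0=x.mean(axis=0))
        assert gs.t2 == pytest.approx(0.0, abs=1e-12)
        assert gs.p_value == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(12, 2))
        mu0 = np.array([0.3, -0.1])
        a = np.array([[2.0, 0.7], [-0.3, 1.4]])
        b = np.array([5.0, -2.0])
        g1 = hotelling_one_sample(x, mu0)
        g2 = hotelling_one_sample(x @ a.T + b, a @ mu0 + b)
        assert g2.t2 == pytest.approx(g1.t2, rel=1e-9)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        x = rng.normal([0.2, -0.4], [1.0, 2.0], size=(15, 2))
        gs = hotelling_one_sample(x)
        ref = pingouin.multivariate_ttest(x)
        assert gs.t2 == pytest.approx(float(ref["T2"].iloc[0]), rel=1e-9)
        assert gs.f_value == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert gs.p_value == pytest.approx(float(ref["pval"].iloc[0]), rel=1e-9)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="n > p"):
            hotelling_one_sample(np.zeros((2, 2)))


class TestMeanConfidenceEllipse:
    def test_identity_covariance_semi_axes(self):
        # n=10, S=I: boundary c = (2*9/8) F_.95(2,8) ~ 10.033, semi-axis
        # sqrt(c/n) ~ 1.0016
        rng = np.random.default_rng(6)
        x = rng.normal(size=(10, 2))
        x = (x - x.mean(0)) @ np.linalg.inv(np.linalg.cholesky(np.cov(x.T))).T
        center, semi, axes, c = mean_confidence_ellipse(x, level=0.95)
        assert c == pytest.approx(10.0327, abs=2e-3)
        np.testing.assert_allclose(semi, 1.00163, rtol=1e-3)

    def test_ellipse_contains_sample_mean(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(9, 2))
        center, semi, axes, c = mean_confidence_ellipse(x)
        np.testing.assert_allclose(center, x.mean(axis=0))
        assert np.all(semi > 0)

    def test_coverage_of_true_mean(self):
        # the 95% group-mean ellipse covers the true mean in ~95% of draws
        rng = np.random.default_rng(8)
        n, reps, hits = 10, 2000, 0
        from scipy import stats
        crit = 2 * (n - 1) / (n - 2) * stats.f.ppf(0.95, 2, n - 2)
        for _ in range(reps):
            x = rng.normal(size=(n, 2))
            gs = hotelling_one_sample(x, mu0=[0, 0])
            hits += gs.t2 <= crit
        se = np.sqrt(0.95 * 0.05 / reps)
        assert hits / reps == pytest.approx(0.95, abs=4 * se)


class TestMardia:
    def test_symmetric_point_set_has_zero_skewness(self):
        x = np.array([[2, 0], [-2, 0], [0, 1], [0, -1],
                      [1, 1], [-1, -1], [1, -1], [-1, 1]], dtype=float)
        res = mardia_tests(x)
        assert res.b1p == pytest.approx(0.0, abs=1e-12)
        assert res.skew_df == 4  # p(p+1)(p+2)/6 for p = 2

    def test_gaussian_kurtosis_approaches_p_times_p_plus_2(self):
        rng = np.random.default_rng(9)
        res = mardia_tests(rng.normal(size=(40000, 2)))
        assert res.b2p == pytest.approx(8.0, abs=0.15)
        assert res.kurt_p > 0.01

    def test_null_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(10)
        reps, rej_s, rej_k = 400, 0, 0
        for _ in range(reps):
            res = mardia_tests(rng.normal(size=(80, 2)))
            rej_s += res.skew_p < 0.05
            rej_k += res.kurt_p < 0.05
        # asymptotic tests at n=80: near-nominal within a generous MC band
        assert 0.01 <= rej_s / reps <= 0.12
        assert 0.01 <= rej_k / reps <= 0.12


class TestBonferroni:
    def test_adjustment_examples(self):
        adj, rej = bonferroni([0.01], m=6)
        assert adj[0] == pytest.approx(0.06) and not rej[0]
        adj, rej = bonferroni([0.01], m=1)
        assert adj[0] == pytest.approx(0.01) and rej[0]
        adj, rej = bonferroni([0.0], m=100)
        assert rej[0]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st_.floats(0, 1), st_.integers(1, 50), st_.integers(1, 50))
    def test_adjusted_p_monotone_in_m(self, p, m1, m2):
        lo, hi = sorted((m1, m2))
        a_lo, _ = bonferroni([p], m=lo)
        a_hi, _ = bonferroni([p], m=hi)
        assert a_hi[0] >= a_lo[0] >= p


class TestRmAnova:
    def test_two_conditions_have_unit_epsilon(self):
        rng = np.random.default_rng(11)
        res = rm_anova_one_way(rng.normal(size=(8, 2)))
        assert res.epsilon == pytest.approx(1.0)

    def test_no_condition_effect_gives_zero_f(self):
        y = np.tile(np.arange(6.0)[:, None], (1, 4))  # subject offsets only
        res = rm_anova_one_way(y)
        assert res.f_value == pytest.approx(0.0, abs=1e-20)

    def test_matches_pingouin_with_gg_correction(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(12)
        y = rng.normal(size=(12, 4)) + rng.normal(size=(12, 1))
        res = rm_anova_one_way(y)
        long = pd.DataFrame({
            "y": y.ravel(),
            "subject": np.repeat(np.arange(12), 4),
            "cond": np.tile(np.arange(4), 12),
        })
        ref = pingouin.rm_anova(data=long, dv="y", within="cond",
                                subject="subject", correction=True)
        assert res.f_value == pytest.approx(float(ref["F"].iloc[0]), rel=1e-6)
        assert res.epsilon == pytest.approx(float(ref["eps"].iloc[0]), rel=1e-6)
        assert res.p_corrected == pytest.approx(float(ref["p_GG_corr"].iloc[0]),
                                                rel=1e-6)

    def test_null_type_i_error_near_alpha(self):
        rng = np.random.default_rng(13)
        reps, rej = 500, 0
        for _ in range(reps):
            y = rng.normal(size=(10, 4))
            rej += rm_anova_one_way(y).p_value < 0.05
        se = np.sqrt(0.05 * 0.95 / reps)
        assert rej / reps == pytest.approx(0.05, abs=3.5 * se)

    def test_incomplete_table_rejected(self):
        y = np.ones((4, 3))
        y[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            rm_anova_one_way(y)


class TestPairing:
    def test_reference_maps_to_zero_and_difference_example(self):
        values = {"central": np.array([[0.1, 0.2]]),
                  "medial": np.array([[0.15, 0.1]])}
        out = pair_within_subject(values, "central")
        np.testing.assert_allclose(out["central"], 0.0)
        np.testing.assert_allclose(out["medial"], [[0.05, -0.1]])

    def test_translation_invariance(self):
        rng = np.random.default_rng(14)
        a, b = rng.normal(size=(6, 2)), rng.normal(size=(6, 2))
        shift = rng.normal(size=(6, 2))
        d1 = pair_within_subject({"r": a, "c": b}, "r")
        d2 = pair_within_subject({"r": a + shift, "c": b + shift}, "r")
        np.testing.assert_allclose(d1["c"], d2["c"], atol=1e-12)

    def test_missing_reference_rejected(self):
        with pytest.raises(KeyError, match="reference"):
            pair_within_subject({"a": np.zeros((3, 2))}, "zzz")
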