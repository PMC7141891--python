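"""Correlations, the Hittner dependent-correlation test, Breusch-Pagan, t tests."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.diagnostic import het_breuschpagan

import microquant as mq


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p = mq.pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, -1.0, -1.0, 1.0])  # orthogonal to centred x
        r, _ = mq.pearson(x, y)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        r, _ = mq.pearson([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            mq.pearson([1, 1, 1], [1, 2, 3])

    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=20, unique=True))
    def test_symmetry_and_affine_invariance(self, xs):
        x = np.asarray(xs)
        rng = np.random.default_rng(0)
        y = x + rng.normal(0, 1, len(x))
        if np.ptp(y) == 0:
            return
        r_xy, _ = mq.pearson(x, y)
        r_yx, _ = mq.pearson(y, x)
        assert r_xy == pytest.approx(r_yx, abs=1e-12)
        r_aff, _ = mq.pearson(3 * x + 7, y)
        assert r_aff == pytest.approx(r_xy, abs=1e-9)


def _hittner_oracle(r12, r13, r23, n):
    """Step-by-step reference: Dunn & Clark z with the back-transformed
    average Fisher z plugged into the dependent-correlation covariance."""
    import math
    z12 = 0.5 * math.log((1 + r12) / (1 - r12))
    z13 = 0.5 * math.log((1 + r13) / (1 - r13))
    zm = (z12 + z13) / 2.0
    rm = (math.exp(2 * zm) - 1) / (math.exp(2 * zm) + 1)
    cov = (r23 * (1 - 2 * rm ** 2) - 0.5 * rm ** 2 * (1 - 2 * rm ** 2 - r23 ** 2))
    c = cov / ((1 - rm ** 2) ** 2)
    z = (z12 - z13) * math.sqrt((n - 3) / (2 - 2 * c))
    p = 2 * (1 - sps.norm.cdf(abs(z)))
    return z, p


class TestHittner:
    def test_equal_correlations_give_null(self):
        res = mq.compare_overlapping_correlations(0.8, 0.8, 0.5, 100)
        assert res.z == 0.0
        assert res.p == pytest.approx(1.0)

    def test_matches_independent_reference(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            r12, r13 = rng.uniform(-0.9, 0.9, 2)
            r23 = rng.uniform(-0.5, 0.9)
            n = int(rng.integers(10, 500))
            res = mq.compare_overlapping_correlations(r12, r13, r23, n)
            z_ref, p_ref = _hittner_oracle(r12, r13, r23, n)
            assert res.z == pytest.approx(z_ref, abs=1e-10)
            assert res.p == pytest.approx(p_ref, abs=1e-10)

    def test_sign_follows_correlation_difference(self):
        hi = mq.compare_overlapping_correlations(0.9, 0.5, 0.4, 50)
        lo = mq.compare_overlapping_correlations(0.5, 0.9, 0.4, 50)
        assert hi.z > 0 > lo.z
        assert hi.p == pytest.approx(lo.p, abs=1e-12)

    def test_degenerate_correlation_rejected(self):
        with pytest.raises(ValueError):
            mq.compare_overlapping_correlations(1.0, 0.5, 0.3, 50)
        with pytest.raises(ValueError):
            mq.compare_overlapping_correlations(0.5, 0.2, 1.5, 50)


class TestBreuschPagan:
    def test_matches_hand_computed_n_r_squared(self):
        # fixed 6-point dataset with variance growing in x
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([1.1, 1.9, 3.4, 3.1, 6.8, 3.0])
        lm, p = mq.breusch_pagan(y, x)
        design = np.column_stack([np.ones(6), x])
        beta = np.linalg.lstsq(design, y, rcond=None)[0]
        u2 = (y - design @ beta) ** 2
        g = np.linalg.lstsq(design, u2, rcond=None)[0]
        r2 = 1 - np.sum((u2 - design @ g) ** 2) / np.sum((u2 - u2.mean()) ** 2)
        assert lm == pytest.approx(6 * r2, abs=1e-10)
        assert p == pytest.approx(float(sps.chi2.sf(6 * r2, 1)), abs=1e-12)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=80)
        y = 2 + x + rng.normal(size=80) * (1 + 0.5 * np.abs(x))
        lm, p = mq.breusch_pagan(y, x)
        design = np.column_stack([np.ones(80), x])
        resid = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
        lm_sm, p_sm, _, _ = het_breuschpagan(resid, design, robust=True)
        assert lm == pytest.approx(lm_sm, abs=1e-8)
        assert p == pytest.approx(p_sm, abs=1e-10)

    def test_uncorrelated_squared_residuals_give_zero_lm(self):
        # residuals e*[1,-3,3,-1] are orthogonal to [1, x]; their squares
        # are symmetric in x so the auxiliary regression has R^2 = 0
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = x + 0.1 * np.array([1.0, -3.0, 3.0, -1.0])
        lm, p = mq.breusch_pagan(y, x)
        assert lm == pytest.approx(0.0, abs=1e-10)

    def test_singular_design_rejected(self):
        x = np.column_stack([np.arange(10.0), np.arange(10.0)])
        with pytest.raises(ValueError):
            mq.breusch_pagan(np.arange(10.0), x)

    def test_original_variant_differs_but_agrees_in_direction(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=60)
        y = x + rng.normal(size=60) * (1 + np.abs(x))
        lm_k, _ = mq.breusch_pagan(y, x, studentized=True)
        lm_o, _ = mq.breusch_pagan(y, x, studentized=False)
        assert lm_k > 0 and lm_o > 0


class TestMeanTests:
    def test_identical_paired_samples(self):
        a = np.array([1.0, 2.0, 3.0])
        t, p = mq.mean_tests(a, a.copy(), mode="paired")
        assert t == 0.0 or np.isnan(t)
        # identical pairs carry no evidence against the null
        assert np.isnan(p) or p == pytest.approx(1.0)

    def test_constant_shift_paired(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        t, p = mq.mean_tests(a + 1.0, a, mode="paired")
        assert p < 1e-10 or np.isinf(t)

    def test_welch_matches_formula(self):
        a = np.array([3.1, 2.8, 3.4, 3.0, 2.9])
        b = np.array([2.1, 2.4, 1.9, 2.2, 2.5])
        t, p = mq.mean_tests(a, b, mode="welch")
        va, vb = a.var(ddof=1) / 5, b.var(ddof=1) / 5
        t_ref = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / 4 + vb ** 2 / 4)
        p_ref = 2 * sps.t.sf(abs(t_ref), df)
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_one_sided_direction(self):
        rng = np.random.default_rng(1)
        a = rng.normal(1.0, 1.0, 50)
        t, p = mq.mean_tests(a, mode="one_sided")
        assert t > 0 and p < 0.01

    def test_too_small_samples_rejected(self):
        with pytest.raises(ValueError):
            mq.mean_tests([1.0], [1.0, 2.0])


class TestRegressionAndFormatting:
    def test_linear_fit_recovers_coefficients(self):
        x = np.arange(20.0)
        fit = mq.linear_fit(x, 0.6 + 0.9 * x)
        assert fit.intercept == pytest.approx(0.6)
        assert fit.slope == pytest.approx(0.9)

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError):
            mq.linear_fit(np.ones(5), np.arange(5.0))

    def test_p_value_formatting(self):
        assert mq.format_p(1e-20) == "< 2.2e-16"
        assert mq.format_p(0.034) == "0.034"
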