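"""Distribution-level checks: closed forms against independent numerical
oracles (finite differences, brute-force quadrature, Monte Carlo), the
reliability-function identities, and the shape summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, special

import mktl
from mktl import MKTLParams
from mktl.distribution import _quad_density_functional

from conftest import PARAM_GRID


class TestPointwiseForms:
    def test_cdf_matches_midpoint_rule_integration(self):
        """CDF at 0.3 equals brute-force midpoint integration of the density."""
        p = MKTLParams(1.0, 1.0)
        k = 10**6
        x = (np.arange(k) + 0.5) * (0.3 / k)
        brute = np.sum(mktl.pdf(x, p)) * (0.3 / k)
        assert mktl.cdf(0.3, p) == pytest.approx(brute, abs=1e-7)

    def test_pdf_matches_finite_difference_of_cdf(self):
        p = MKTLParams(2.0, 3.0)
        h = 1e-6
        fd = (mktl.cdf(0.5 + h, p) - mktl.cdf(0.5 - h, p)) / (2 * h)
        assert mktl.pdf(0.5, p) == pytest.approx(fd, rel=1e-6)

    @pytest.mark.parametrize("p", PARAM_GRID, ids=str)
    def test_density_normalizes(self, p):
        total = _quad_density_functional(lambda x: np.ones_like(x), p)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_domain_errors(self):
        p = MKTLParams(1.0, 1.0)
        for bad in (0.0, 1.0, -0.5, 1.5, np.nan):
            with pytest.raises(ValueError):
                mktl.cdf(bad, p)
            with pytest.raises(ValueError):
                mktl.pdf(bad, p)
        with pytest.raises(ValueError):
            mktl.quantile(1.0, p)
        with pytest.raises(ValueError):
            MKTLParams(-1.0, 1.0)
        with pytest.raises(ValueError):
            MKTLParams(1.0, 0.0)


class TestReliabilityIdentities:
    """Every derived reliability quantity must agree with its defining
    identity built from pdf/cdf to 1e-10 relative error."""

    def test_identity_suite(self, rng):
        x = rng.uniform(0.05, 0.9, size=100)
        for p in (MKTLParams(0.9, 1.4), MKTLParams(1.9, 0.6), MKTLParams(0.4, 0.4)):
            f, F, R = mktl.pdf(x, p), mktl.cdf(x, p), mktl.survival(x, p)
            np.testing.assert_allclose(F + R, 1.0, rtol=1e-12)
            np.testing.assert_allclose(mktl.hazard(x, p), f / R, rtol=1e-10)
            np.testing.assert_allclose(mktl.reversed_hazard(x, p), f / F, rtol=1e-10)
            np.testing.assert_allclose(mktl.cumulative_hazard(x, p), -np.log(R), rtol=1e-10)
            np.testing.assert_allclose(mktl.odds_ratio(x, p), F / R, rtol=1e-10)
            np.testing.assert_allclose(mktl.mills_ratio(x, p), R / f, rtol=1e-10)

    def test_failure_rate_average_is_scaled_cumulative_hazard(self):
        p = MKTLParams(0.9, 1.4)
        assert mktl.failure_rate_average(0.4, p) == pytest.approx(
            mktl.cumulative_hazard(0.4, p) / 0.4, rel=1e-12
        )

    def test_cumulative_hazard_non_negative(self, rng):
        x = rng.uniform(0.01, 0.99, 200)
        for p in PARAM_GRID:
            assert np.all(mktl.cumulative_hazard(x, p) >= 0.0)


class TestQuantile:
    @pytest.mark.parametrize("p", PARAM_GRID, ids=str)
    def test_cdf_quantile_round_trip(self, p):
        u = np.concatenate([
            np.logspace(-8, -0.31, 40),
            1.0 - np.logspace(-8, -0.31, 40),
        ])
        np.testing.assert_allclose(mktl.cdf(mktl.quantile(u, p), p), u, atol=1e-10)

    def test_quantile_strictly_increasing(self):
        u = np.linspace(1e-6, 1 - 1e-6, 500)
        for p in (MKTLParams(0.3, 0.3), MKTLParams(4.0, 4.0)):
            assert np.all(np.diff(mktl.quantile(u, p)) > 0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        u=st.floats(1e-6, 1 - 1e-6),
        eta=st.floats(0.25, 8.0),
        beta=st.floats(0.25, 8.0),
    )
    def test_round_trip_property(self, u, eta, beta):
        p = MKTLParams(eta, beta)
        assert mktl.cdf(mktl.quantile(u, p), p) == pytest.approx(u, abs=1e-10)


class TestSampling:
    def test_same_seed_same_sample(self):
        p = MKTLParams(0.9, 0.9)
        np.testing.assert_array_equal(mktl.rvs(100, p, seed=7), mktl.rvs(100, p, seed=7))

    def test_ks_self_consistency(self):
        """Inverse-transform draws pass a KS test against the model CDF."""
        p = MKTLParams(0.9, 0.9)
        n = 10**5
        s = np.sort(mktl.rvs(n, p, seed=5))
        f = mktl.cdf(s, p)
        i = np.arange(1, n + 1)
        d = max(np.max(i / n - f), np.max(f - (i - 1) / n))
        assert d < 1.63 / np.sqrt(n)  # 1% critical value

    def test_empirical_mean_matches_first_moment(self):
        p = MKTLParams(0.3, 0.2)
        s = mktl.rvs(10**6, p, seed=3)
        mu = mktl.raw_moment(1, p)
        se = s.std(ddof=1) / np.sqrt(s.size)
        assert abs(s.mean() - mu) < 3 * se


class TestQuantileSummary:
    def test_bowley_formula_and_symmetry(self):
        qs = mktl.quantile_summary(MKTLParams(1.5, 2.0))
        assert qs.q1 < qs.q2 < qs.q3
        assert qs.bsk == pytest.approx(
            (qs.q3 + qs.q1 - 2 * qs.q2) / (qs.q3 - qs.q1), abs=1e-12
        )
        # symmetric quartiles give zero Bowley skewness
        q1, q2, q3 = 0.2, 0.5, 0.8
        assert (q3 + q1 - 2 * q2) / (q3 - q1) == 0.0


class TestMoments:
    def test_first_moment_vs_monte_carlo(self):
        p = MKTLParams(1.7, 0.9)
        s = mktl.rvs(10**6, p, seed=11)
        se = s.std(ddof=1) / np.sqrt(s.size)
        assert mktl.raw_moment(1, p) == pytest.approx(s.mean(), abs=3 * se)

    def test_moment_summary_identities(self):
        for p in (MKTLParams(0.3, 0.2), MKTLParams(1.7, 0.9), MKTLParams(4.0, 4.0)):
            ms = mktl.moment_summary(p)
            assert ms.var == pytest.approx(ms.mu2 - ms.mu1**2, abs=1e-9)
            assert ms.var > 0
            assert ms.sd == pytest.approx(np.sqrt(ms.var), rel=1e-12)
            assert ms.cv == pytest.approx(ms.sd / ms.mu1, rel=1e-12)

    def test_incomplete_moment_brute_force(self):
        """Partial first moment on (0, 0.5] against midpoint-rule integration."""
        p = MKTLParams(1.0, 1.0)
        k = 10**6
        x = (np.arange(k) + 0.5) * (0.5 / k)
        brute = np.sum(x * mktl.pdf(x, p)) * (0.5 / k)
        assert mktl.incomplete_moment(1, 0.5, p) == pytest.approx(brute, abs=1e-7)

    def test_incomplete_moment_limits_and_bounds(self):
        p = MKTLParams(0.9, 1.4)
        assert mktl.incomplete_moment(1, 1 - 1e-9, p) == pytest.approx(
            mktl.raw_moment(1, p), abs=1e-8
        )
        assert mktl.incomplete_moment(2, 0.3, p) <= 0.3 * mktl.incomplete_moment(1, 0.3, p)
        # monotone non-decreasing in t (increments in the far tail can be
        # below float resolution), strictly increasing over the bulk
        t = np.linspace(0.05, 0.95, 10)
        vals = [mktl.incomplete_moment(1, ti, p) for ti in t]
        assert np.all(np.diff(vals) >= 0)
        assert np.all(np.diff(vals[:6]) > 0)
        with pytest.raises(ValueError):
            mktl.incomplete_moment(1, 1.2, p)
        with pytest.raises(ValueError):
            mktl.raw_moment(0, p)


class TestOrderStatistics:
    def test_single_observation_reduces_to_pdf(self, rng):
        p = MKTLParams(2.0, 1.0)
        x = rng.uniform(0.05, 0.95, 20)
        np.testing.assert_allclose(
            mktl.order_statistic_pdf(x, 1, 1, p), mktl.pdf(x, p), rtol=1e-12
        )

    def test_normalization(self):
        p = MKTLParams(2.0, 1.0)
        val, _ = integrate.quad(
            lambda x: mktl.order_statistic_pdf(x, 2, 5, p), 0, 1, limit=200
        )
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_extreme_order_statistics_match_closed_forms(self, rng):
        """m=1 and m=s reduce to s*f*(1-F)^(s-1) and s*f*F^(s-1)."""
        p = MKTLParams(1.5, 2.0)
        x = rng.uniform(0.1, 0.9, 30)
        f, F, R = mktl.pdf(x, p), mktl.cdf(x, p), mktl.survival(x, p)
        np.testing.assert_allclose(
            mktl.order_statistic_pdf(x, 1, 6, p), 6 * f * R**5, rtol=1e-10
        )
        np.testing.assert_allclose(
            mktl.order_statistic_pdf(x, 6, 6, p), 6 * f * F**5, rtol=1e-10
        )

    def test_density_of_third_smallest_vs_simulation(self):
        """Simulated third order statistic of samples of size 7 agrees with
        the closed-form density at x=0.4 within 3%."""
        p = MKTLParams(2.0, 1.0)
        rng = np.random.default_rng(17)
        sims = mktl.quantile(rng.uniform(size=(200_000, 7)), p)
        third = np.sort(sims, axis=1)[:, 2]
        h = 0.01
        emp = np.mean(np.abs(third - 0.4) < h) / (2 * h)
        assert emp == pytest.approx(mktl.order_statistic_pdf(0.4, 3, 7, p), rel=0.03)

    def test_invalid_orders(self):
        p = MKTLParams(1.0, 1.0)
        with pytest.raises(ValueError):
            mktl.order_statistic_pdf(0.5, 0, 5, p)
        with pytest.raises(ValueError):
            mktl.order_statistic_pdf(0.5, 6, 5, p)
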