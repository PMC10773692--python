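"""Distributional functions: closed forms against independent oracles.

The independent oracles are (a) numerical quadrature of the mixed-Poisson
integrand Poisson(x | lam) * EBWE(lam; beta) over lam, and (b) brute-force
series summation over a truncated support carrying essentially all mass.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import chisquare

from pebwe import BETA_MAX, EBWE, PEBWE, validate_beta

from conftest import VALID_BETAS


def pmf_quadrature(x: int, beta: float) -> float:
    """Mixed-Poisson oracle: integrate Poisson(x|lam) * EBWE(lam) dlam."""
    lb = math.log(beta)

    def integrand(lam):
        pois = math.exp(-lam + x * math.log(lam) - math.lgamma(x + 1)) if lam > 0 else (x == 0) * 1.0
        return pois * beta * (beta * lam - lb) * math.exp(-beta * lam) / (1 - lb)

    val, _ = quad(integrand, 0, np.inf, limit=200)
    return val


def truncated_support(dist: PEBWE, tol: float = 1e-12) -> np.ndarray:
    x = np.arange(len(dist.support_table(tail_mass=tol)))
    return x


class TestParameterDomain:
    def test_domain_bound_is_root_of_validity_equation(self):
        b = BETA_MAX
        assert (1 + b) * math.log(b) == pytest.approx(b, abs=1e-10)
        assert 1.92 < b < 1.94

    @pytest.mark.parametrize("bad", [-1.0, 0.0, math.e, 2.0, np.inf, np.nan])
    def test_invalid_beta_rejected(self, bad):
        with pytest.raises(ValueError):
            validate_beta(bad)

    def test_unsafe_flag_allows_formal_evaluation(self):
        dist = PEBWE(2.0, unsafe=True)
        assert dist.pmf(0) < 0  # pmf not a probability outside the domain


class TestPmf:
    def test_pmf_matches_quadrature_oracle_frozen_values(self):
        # frozen from the quadrature oracle at beta = 0.5
        assert PEBWE(0.5).pmf(0) == pytest.approx(0.20208530907785, abs=1e-10)
        assert PEBWE(0.5).pmf(1) == pytest.approx(0.17847288080373, abs=1e-10)

    @pytest.mark.parametrize("beta", [0.1, 0.5, 0.9, 1.5, 1.8])
    def test_pmf_matches_quadrature_oracle_grid(self, beta):
        dist = PEBWE(beta)
        for x in range(0, 21, 4):
            assert dist.pmf(x) == pytest.approx(pmf_quadrature(x, beta), abs=1e-8)

    @pytest.mark.parametrize("beta", VALID_BETAS)
    def test_normalization(self, beta):
        dist = PEBWE(beta)
        x = truncated_support(dist, tol=1e-13)
        assert dist.pmf(x).sum() == pytest.approx(1.0, abs=1e-10)

    def test_domain_errors(self):
        dist = PEBWE(0.5)
        with pytest.raises(ValueError):
            dist.pmf(-1)
        with pytest.raises(ValueError):
            dist.pmf(1.5)


class TestCdf:
    def test_cdf_at_zero_equals_pmf(self):
        assert PEBWE(0.5).cdf(0) == pytest.approx(PEBWE(0.5).pmf(0), rel=1e-12)

    @pytest.mark.parametrize("beta", VALID_BETAS)
    def test_telescoping_identity(self, beta):
        dist = PEBWE(beta)
        x = np.arange(1, 60)
        np.testing.assert_allclose(dist.cdf(x) - dist.cdf(x - 1), dist.pmf(x), atol=1e-12)

    def test_partial_sum_oracle(self):
        dist = PEBWE(0.5)
        assert dist.cdf(5) == pytest.approx(sum(dist.pmf(k) for k in range(6)), abs=1e-12)

    def test_minus_one_convention(self):
        assert PEBWE(0.5).cdf(-1) == pytest.approx(0.0, abs=1e-15)

    @given(st.sampled_from(VALID_BETAS), st.integers(0, 200))
    @settings(max_examples=50, deadline=None)
    def test_cdf_nondecreasing(self, beta, x):
        dist = PEBWE(beta)
        assert dist.cdf(x + 1) >= dist.cdf(x) - 1e-15


class TestHazard:
    def test_hazard_zero_equals_pmf_over_survival(self):
        # pmf(0)/sf(0) oracle, frozen
        assert PEBWE(0.5).hazard(0) == pytest.approx(0.25326681082198, abs=1e-10)

    @pytest.mark.parametrize("beta", VALID_BETAS)
    def test_hazard_strictly_increasing(self, beta):
        h = PEBWE(beta).hazard(np.arange(0, 501))
        assert np.all(np.diff(h) > 0)

    @pytest.mark.parametrize("beta", VALID_BETAS)
    def test_hazard_tail_limit_is_beta(self, beta):
        # convergence is O(1/(beta*x)), so go deep enough into the tail
        dist = PEBWE(beta)
        assert abs(dist.hazard(5000) - beta) < abs(dist.hazard(500) - beta) + 1e-12
        assert dist.hazard(5000) == pytest.approx(beta, rel=1e-2)


class TestMoments:
    # printed reference table: beta -> (mean, var, skew, kurt, DI, CV)
    TABLE = {
        0.1: (13.028, 164.42, 1.7974, 7.6916, 12.620, 0.9842),
        0.5: (3.1812, 10.511, 1.6455, 6.8850, 3.3040, 1.0191),
        0.8: (2.2720, 5.3450, 1.5602, 6.4932, 2.3526, 1.0176),
        0.9: (2.1163, 4.5742, 1.5307, 6.3703, 2.1614, 1.0106),
        1.2: (1.8525, 3.2068, 1.4354, 6.0221, 1.7311, 0.9667),
        1.5: (1.7880, 2.4702, 1.3414, 5.7724, 1.3815, 0.8790),
        1.8: (1.9033, 1.8930, 1.3640, 5.9838, 0.9946, 0.7229),
    }

    @pytest.mark.parametrize("beta", sorted(TABLE))
    def test_reference_table_regression(self, beta):
        mean, var, skew, kurt, di, cv = self.TABLE[beta]
        ms = PEBWE(beta).moment_summary()
        # agreement to the printed precision: +-1 in the last printed digit
        for got, want in [
            (ms.mean, mean), (ms.variance, var), (ms.skewness, skew),
            (ms.kurtosis, kurt), (ms.dispersion_index, di), (ms.cv, cv),
        ]:
            decimals = len(str(want).split(".")[1])
            assert got == pytest.approx(want, abs=1.01 * 10**-decimals)

    @pytest.mark.parametrize("beta", VALID_BETAS)
    def test_closed_forms_match_series_summation(self, beta):
        dist = PEBWE(beta)
        x = truncated_support(dist, tol=1e-13).astype(float)
        p = dist.pmf(x)
        mean = float(np.sum(x * p))
        var = float(np.sum((x - mean) ** 2 * p))
        ms = dist.moment_summary()
        assert ms.mean == pytest.approx(mean, abs=1e-6)
        assert ms.variance == pytest.approx(var, abs=1e-6)
        assert ms.skewness == pytest.approx(np.sum((x - mean) ** 3 * p) / var**1.5, abs=1e-6)
        assert ms.kurtosis == pytest.approx(np.sum((x - mean) ** 4 * p) / var**2, abs=1e-6)

    def test_moment_summary_internal_identities(self):
        ms = PEBWE(0.8).moment_summary()
        assert ms.dispersion_index == pytest.approx(ms.variance / ms.mean, rel=1e-12)
        assert ms.cv == pytest.approx(math.sqrt(ms.variance) / ms.mean, rel=1e-12)


class TestFactorialMoments:
    def test_r0_is_one(self):
        assert PEBWE(0.7).factorial_moment(0) == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("beta", VALID_BETAS)
    def test_r1_equals_mean(self, beta):
        dist = PEBWE(beta)
        assert dist.factorial_moment(1) == pytest.approx(dist.mean, rel=1e-12)

    def test_r2_brute_force(self):
        dist = PEBWE(0.5)
        x = truncated_support(dist, tol=1e-13).astype(float)
        oracle = float(np.sum(x * (x - 1) * dist.pmf(x)))
        assert dist.factorial_moment(2) == pytest.approx(oracle, rel=1e-9)
        assert dist.factorial_moment(2) == pytest.approx(17.449857746394, abs=1e-6)

    def test_negative_r_rejected(self):
        with pytest.raises(ValueError):
            PEBWE(0.5).factorial_moment(-1)


class TestGeneratingFunctions:
    @pytest.mark.parametrize("beta", VALID_BETAS)
    def test_pgf_at_one_is_one(self, beta):
        assert PEBWE(beta).pgf(1.0) == pytest.approx(1.0, rel=1e-12)

    def test_pgf_at_zero_is_pmf_zero(self):
        dist = PEBWE(0.8)
        assert dist.pgf(0.0) == pytest.approx(dist.pmf(0), rel=1e-12)

    def test_pgf_matches_truncated_series(self):
        dist = PEBWE(0.8)
        x = truncated_support(dist, tol=1e-13).astype(float)
        oracle = float(np.sum(0.5**x * dist.pmf(x)))
        assert dist.pgf(0.5) == pytest.approx(oracle, rel=1e-10)

    def test_mgf_at_zero_is_one_and_domain(self):
        dist = PEBWE(1.2)
        assert dist.mgf(0.0) == pytest.approx(1.0, rel=1e-12)
        # convergence strip extends to ln(1+beta), wider than t <= 0
        assert dist.mgf(0.5 * math.log1p(1.2)) > 1.0
        with pytest.raises(ValueError):
            dist.mgf(math.log1p(1.2))

    def test_pgf_derivative_at_one_is_mean(self):
        dist = PEBWE(0.9)
        h = 1e-6
        deriv = (dist.pgf(1.0) - dist.pgf(1.0 - h)) / h
        assert deriv == pytest.approx(dist.mean, rel=1e-4)

    def test_cf_modulus_bounded(self):
        dist = PEBWE(0.5)
        t = np.linspace(-10, 10, 41)
        assert np.all(np.abs(dist.cf(t)) <= 1.0 + 1e-12)

    def test_dispatch(self):
        dist = PEBWE(0.5)
        assert dist.generating_function("pgf", 1.0) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            dist.generating_function("laplace", 1.0)


class TestMode:
    def test_small_beta_mode_zero(self):
        res = PEBWE(0.5).mode()
        assert res.integer_mode == 0
        assert res.critical_point == 0.0

    def test_critical_point_closed_form(self):
        assert PEBWE(1.5).mode().critical_point == pytest.approx(0.76713184812, abs=1e-8)

    @pytest.mark.parametrize("beta", VALID_BETAS)
    def test_integer_mode_is_brute_force_argmax(self, beta):
        dist = PEBWE(beta)
        brute = int(np.argmax(dist.pmf(np.arange(201))))
        assert dist.mode().integer_mode == brute


class TestQuantile:
    def test_q_zero(self):
        assert PEBWE(0.5).quantile(0.0) == 0

    def test_median_beta_half(self):
        # cdf(1) ~ 0.3806 < 0.5 <= cdf(2) ~ 0.5287
        assert PEBWE(0.5).quantile(0.5) == 2

    @given(st.sampled_from(VALID_BETAS), st.integers(0, 100))
    @settings(max_examples=50, deadline=None)
    def test_right_continuity_contract(self, beta, x):
        dist = PEBWE(beta)
        assert dist.quantile(dist.cdf(x) - 1e-12) <= x

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            PEBWE(0.5).quantile(1.0)


class TestSampling:
    def test_same_seed_identical(self):
        a = PEBWE(0.8).rvs(1000, seed=42)
        b = PEBWE(0.8).rvs(1000, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_sample_mean_close_to_theory(self):
        dist = PEBWE(0.5)
        draws = dist.rvs(100_000, seed=7)
        se = math.sqrt(dist.var / len(draws))
        assert abs(draws.mean() - 3.1812) < 3 * se

    def test_kolmogorov_distance_small(self):
        dist = PEBWE(0.9)
        draws = dist.rvs(100_000, seed=11)
        xs = np.arange(draws.max() + 1)
        ecdf = np.searchsorted(np.sort(draws), xs, side="right") / len(draws)
        assert np.max(np.abs(ecdf - dist.cdf(xs))) < 0.01

    def test_chisquare_gof_not_rejected(self):
        dist = PEBWE(0.8)
        draws = dist.rvs(100_000, seed=3)
        kmax = 15
        obs = np.bincount(np.minimum(draws, kmax), minlength=kmax + 1)
        p = dist.pmf(np.arange(kmax))
        expected = np.append(p, dist.sf(kmax - 1)) * len(draws)
        stat, pval = chisquare(obs, expected * obs.sum() / expected.sum())
        assert pval > 0.01


class TestEBWE:
    def test_pdf_normalizes(self):
        val, _ = quad(EBWE(0.5).pdf, 0, np.inf)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_sf_at_zero(self):
        assert EBWE(0.5).sf(0) == pytest.approx(1.0, rel=1e-12)

    def test_mixing_mean_identity(self):
        # E(lam) under the mixing law equals the count-model mean
        val, _ = quad(lambda t: t * EBWE(0.5).pdf(t), 0, np.inf)
        assert val == pytest.approx(3.1812, abs=5e-4)
        assert EBWE(0.5).mean == pytest.approx(PEBWE(0.5).mean, rel=1e-12)

    def test_negative_density_region_flagged_for_beta_above_one(self):
        # the printed density is negative on [0, ln(b)/b) when b > 1
        dist = EBWE(1.5, unsafe=False)
        assert dist.pdf(0.01) < 0
        with pytest.raises(ValueError):
            dist.rvs(5, seed=0)

    def test_ppf_roundtrip(self):
        dist = EBWE(0.3)
        for q in (0.1, 0.5, 0.9):
            assert dist.cdf(dist.ppf(q)) == pytest.approx(q, abs=1e-9)

    def test_rvs_seeded_and_matches_cdf(self):
        dist = EBWE(0.05)
        a = dist.rvs(2000, seed=5)
        b = dist.rvs(2000, seed=5)
        np.testing.assert_array_equal(a, b)
        xs = np.sort(a)
        ecdf = np.arange(1, len(xs) + 1) / len(xs)
        assert np.max(np.abs(ecdf - dist.cdf(xs))) < 0.04
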