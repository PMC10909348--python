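"""Posterior sampler (ratio-of-uniforms + conjugate shape) and credible intervals."""

import numpy as np
import pytest
from scipy import stats as sps
from scipy.integrate import cumulative_trapezoid

from bsperc import BSParams, bs_rvs
from bsperc.bayes import (
    Hyperparams,
    bayes_interval,
    credible_interval,
    hpd_interval,
    log_marginal_beta,
    posterior_sample,
    posterior_theta,
    rou_bounds,
    rou_sample_beta,
    sample_alpha_given_beta,
)

HYPER = Hyperparams()


class TestMarginalKernel:
    def test_log_matches_direct_evaluation(self):
        # at n=5 and moderate β the raw kernel is representable: compare ratios
        x = np.array([0.8, 1.1, 1.4, 2.0, 0.6])
        n = x.size
        h = HYPER

        def direct(beta):
            prod = np.prod((beta / x) ** 0.5 + (beta / x) ** 1.5)
            quad = np.sum(x / beta + beta / x - 2.0) / 2.0 + h.b2
            return (
                beta ** -(n + h.a1 + 1)
                * np.exp(-h.b1 / beta)
                * prod
                * quad ** -((n + 1) / 2 + h.a2)
            )

        b1, b2 = 0.9, 1.7
        log_ratio = log_marginal_beta(b1, x, h) - log_marginal_beta(b2, x, h)
        assert np.exp(log_ratio) == pytest.approx(direct(b1) / direct(b2), rel=1e-10)

    def test_tails_diverge_to_minus_infinity(self, toy_sample):
        mid = log_marginal_beta(float(np.median(toy_sample)), toy_sample, HYPER)
        assert log_marginal_beta(1e-8, toy_sample, HYPER) < mid - 50
        assert log_marginal_beta(1e8, toy_sample, HYPER) < mid - 50

    def test_continuity_on_grid(self, toy_sample):
        med = float(np.median(toy_sample))
        grid = np.geomspace(0.1 * med, 100 * med, 20000)
        vals = log_marginal_beta(grid, toy_sample, HYPER)
        jumps = np.abs(np.diff(vals)) / np.maximum(np.abs(vals[:-1]), 1.0)
        assert jumps.max() < 1e-2  # smooth kernel on a fine grid


class TestRoUBounds:
    def test_grid_never_exceeds_suprema(self, toy_sample):
        b = rou_bounds(toy_sample, HYPER)
        grid = np.geomspace(1e-3, 1e3, 5000) * float(np.median(toy_sample))
        logq = log_marginal_beta(grid, toy_sample, HYPER) - b.log_shift
        a_vals = np.exp(logq / (HYPER.r + 1))
        bp_vals = grid * np.exp(logq * HYPER.r / (HYPER.r + 1))
        assert a_vals.max() <= b.a_r * (1 + 1e-6)
        assert bp_vals.max() <= b.b_plus * (1 + 1e-6)

    def test_b_minus_is_zero(self, toy_sample):
        assert rou_bounds(toy_sample, HYPER).b_minus == 0.0

    def test_kernel_rescaling_scales_bounds(self, toy_sample):
        base = rou_bounds(toy_sample, HYPER)
        shifted = rou_bounds(toy_sample, HYPER, log_shift=base.log_shift - np.log(8.0))
        r = HYPER.r
        assert shifted.a_r == pytest.approx(base.a_r * 8 ** (1 / (r + 1)), rel=1e-8)
        assert shifted.b_plus == pytest.approx(base.b_plus * 8 ** (r / (r + 1)), rel=1e-8)

    def test_rescaling_leaves_draws_unchanged(self, toy_sample):
        base = rou_bounds(toy_sample, HYPER)
        shifted = rou_bounds(toy_sample, HYPER, log_shift=base.log_shift - np.log(8.0))
        d1, _ = rou_sample_beta(toy_sample, HYPER, 500, rng=9, bounds=base)
        d2, _ = rou_sample_beta(toy_sample, HYPER, 2000, rng=10, bounds=shifted)
        assert sps.ks_2samp(d1, d2).pvalue > 0.01


class TestRoUSampler:
    def test_ks_against_quadrature_normalized_density(self, toy_sample):
        draws, rate = rou_sample_beta(toy_sample, HYPER, 20_000, rng=1)
        assert 0 < rate <= 1
        b = rou_bounds(toy_sample, HYPER)
        grid = np.geomspace(b.beta_mode / 50, b.beta_mode * 50, 40_000)
        dens = np.exp(log_marginal_beta(grid, toy_sample, HYPER) - b.log_shift)
        cdf = cumulative_trapezoid(dens, grid, initial=0.0)
        cdf /= cdf[-1]
        stat = sps.kstest(draws, lambda v: np.interp(v, grid, cdf)).statistic
        critical_1pct = 1.6276 / np.sqrt(draws.size)
        assert stat < critical_1pct

    def test_deterministic_under_seed(self, toy_sample):
        a, _ = rou_sample_beta(toy_sample, HYPER, 300, rng=6)
        b, _ = rou_sample_beta(toy_sample, HYPER, 300, rng=6)
        np.testing.assert_array_equal(a, b)


class TestConditionalShape:
    def test_inverse_gamma_moment(self, toy_sample):
        beta = float(np.median(toy_sample))
        rng = np.random.default_rng(2)
        draws = np.array(
            [sample_alpha_given_beta(beta, toy_sample, HYPER, rng) for _ in range(1)]
        )
        big = sample_alpha_given_beta(np.full(100_000, beta), toy_sample, HYPER, rng)
        a2 = np.asarray(big) ** 2
        n = len(toy_sample)
        x = np.asarray(toy_sample)
        shape = n / 2 + HYPER.a2
        scale = np.sum(x / beta + beta / x - 2) / 2 + HYPER.b2
        expected = scale / (shape - 1)
        se = np.std(a2) / np.sqrt(a2.size)
        assert abs(a2.mean() - expected) < 3 * se
        assert np.all(np.asarray(big) > 0) and draws[0] > 0

    def test_constant_sample_collapses_to_prior_scale(self):
        x = np.full(6, 3.0)
        rng = np.random.default_rng(3)
        draws = np.asarray(sample_alpha_given_beta(np.full(50_000, 3.0), x, HYPER, rng))
        # data term vanishes at β = c, so α² ~ IG(n/2 + a2, b2): tiny b2 ⇒ tiny α
        assert np.median(draws**2) < 1e-3


class TestThetaAndIntervals:
    def test_median_theta_equals_beta_draws(self, toy_sample):
        post = posterior_sample(toy_sample, HYPER, 500, rng=4)
        np.testing.assert_array_equal(posterior_theta(post, 0.5), post.beta)

    def test_theta_monotone_in_p(self, toy_sample):
        post = posterior_sample(toy_sample, HYPER, 500, rng=4)
        assert np.all(posterior_theta(post, 0.6) > posterior_theta(post, 0.4))

    def test_equal_tailed_quantile_convention(self):
        iv = credible_interval(np.arange(1.0, 101.0), 0.90)
        assert iv.lower == pytest.approx(5.95)
        assert iv.upper == pytest.approx(95.05)

    def test_constant_draws(self):
        iv = credible_interval(np.full(200, 3.0), 0.95)
        assert iv.lower == iv.upper == 3.0

    def test_nested_levels(self, rng):
        draws = rng.gamma(3.0, size=5000)
        narrow = credible_interval(draws, 0.95)
        wide = credible_interval(draws, 0.99)
        assert wide.lower <= narrow.lower and narrow.upper <= wide.upper

    def test_hpd_never_longer_than_equal_tailed(self, rng):
        for dist in (rng.standard_normal(4000), rng.gamma(2.0, size=4000),
                     np.exp(rng.standard_normal(4000))):
            assert hpd_interval(dist, 0.95).length <= credible_interval(dist, 0.95).length

    def test_hpd_matches_equal_tailed_for_symmetric_draws(self, rng):
        draws = rng.standard_normal(200_000)
        h = hpd_interval(draws, 0.95)
        e = credible_interval(draws, 0.95)
        assert h.lower == pytest.approx(e.lower, abs=0.05)
        assert h.upper == pytest.approx(e.upper, abs=0.05)

    def test_hpd_against_arviz(self, rng):
        # arviz's window holds ⌊level·M⌋+1 draws vs our ⌈level·M⌉, so the
        # endpoints may differ by about one order-statistic spacing in the tail
        az = pytest.importorskip("arviz")
        draws = rng.gamma(2.0, size=5000)
        ours = hpd_interval(draws, 0.95)
        lo, hi = az.hdi(draws, hdi_prob=0.95)
        assert ours.lower == pytest.approx(lo, abs=0.05)
        assert ours.upper == pytest.approx(hi, abs=0.05)
        assert ours.length <= hi - lo + 1e-12


class TestFullPipeline:
    def test_fixture_equal_tailed_interval(self, maehongson):
        iv = bayes_interval(maehongson, 0.5, 0.95, 5000, rng=0)
        # reference realization: [27.9843, 37.7447]
        assert iv.lower == pytest.approx(27.98, abs=0.5)
        assert iv.upper == pytest.approx(37.74, abs=0.5)

    def test_fixture_hpd_length(self, maehongson):
        iv = bayes_interval(maehongson, 0.5, 0.95, 5000, rng=0, hpd=True)
        assert iv.length == pytest.approx(9.7428, abs=0.5)

    def test_posterior_concentration(self):
        x = bs_rvs(BSParams(0.5, 1.0), 500, np.random.default_rng(8))
        post = posterior_sample(x, HYPER, 2000, rng=8)
        assert np.mean(post.beta) == pytest.approx(1.0, abs=0.05)

    def test_scale_equivariance_at_flat_priors(self):
        x = bs_rvs(BSParams(0.5, 1.0), 100, np.random.default_rng(12))
        a = bayes_interval(x, 0.5, 0.95, 4000, rng=13)
        b = bayes_interval(25.0 * x, 0.5, 0.95, 4000, rng=13)
        assert b.lower / 25.0 == pytest.approx(a.lower, rel=1e-2)
        assert b.upper / 25.0 == pytest.approx(a.upper, rel=1e-2)
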