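import numpy as np
import pytest
from scipy import stats

from dtpln import (NI2Config, draw_posterior_ni1, draw_posterior_ni2,
                   equal_tailed, hpd, metropolis_threshold,
                   threshold_log_kernel)


def brute_force_hpd(draws, level):
    """O(m^2)-style all-windows oracle for the shortest-window interval."""
    s = np.sort(draws)
    m = s.size
    k = int(np.ceil(level * m))
    best = None
    for i in range(m - k + 1):
        w = s[i + k - 1] - s[i]
        if best is None or w < best[0]:  # strict: ties keep smallest lower
            best = (w, s[i], s[i + k - 1])
    return best[1], best[2]


class TestKernel:
    def test_log_ratio(self):
        pos = np.array([10.0, 20.0, 40.0])
        got = threshold_log_kernel(5.0, pos) - threshold_log_kernel(0.0, pos)
        assert got == pytest.approx(np.log((10 * 20 * 40) / (5 * 15 * 35)),
                                    rel=1e-12)
        assert got == pytest.approx(np.log(3.0476), abs=1e-4)

    def test_at_zero(self):
        pos = np.array([3.0, 7.0, 11.0])
        assert threshold_log_kernel(0.0, pos) == pytest.approx(
            -np.sum(np.log(pos)), rel=1e-14)

    def test_monotone(self, rng):
        pos = np.sort(rng.lognormal(2, 1, 30)) + 1.0
        grid = np.linspace(0, pos.min() * 0.999, 300)
        vals = [threshold_log_kernel(a, pos) for a in grid]
        assert np.all(np.diff(vals) >= 0)

    def test_outside_support(self):
        pos = np.array([3.0, 7.0, 11.0])
        assert threshold_log_kernel(-0.5, pos) == -np.inf
        assert threshold_log_kernel(3.0, pos) == -np.inf


class TestMetropolis:
    def test_support_and_determinism(self):
        pos = np.array([4.0, 9.0, 12.0, 30.0])
        d1, acc = metropolis_threshold(pos, 2000, seed=5)
        d2, _ = metropolis_threshold(pos, 2000, seed=5)
        assert np.all((d1 >= 0) & (d1 < 4.0))
        np.testing.assert_array_equal(d1, d2)
        assert 0.0 < acc <= 1.0

    def test_matches_quadrature_normalized_kernel(self):
        """Long-run draw distribution matches the target density
        normalized by quadrature (Kolmogorov-Smirnov distance)."""
        # compare on [0, 9.99], away from the integrable-only-by-
        # truncation spike at x_(1) = 10 where a linear quadrature grid
        # cannot resolve the log-divergent mass
        pos = np.array([10.0, 100.0, 100.0, 100.0])
        grid = np.linspace(0.0, 9.99, 40001)
        dens = 1.0 / ((10.0 - grid) * (100.0 - grid) ** 3)
        cdf = np.concatenate([[0.0], np.cumsum(
            (dens[1:] + dens[:-1]) / 2 * np.diff(grid))])
        cdf /= cdf[-1]
        draws, _ = metropolis_threshold(pos, 50000, seed=17)
        sel = np.sort(draws[draws <= 9.99])
        assert sel.size > 10000
        ecdf = np.arange(1, sel.size + 1) / sel.size
        model = np.interp(sel, grid, cdf)
        ks = np.max(np.abs(ecdf - model))
        assert ks < 0.05


class TestPosteriorMoments:
    M = 10**5

    def test_ni1_component_moments(self, rainfall, rainfall_est):
        """NI1 blocks match Beta / Student-t / inverse-gamma moments."""
        est = rainfall_est
        n0, n1, s2 = est.n0, est.n1, est.s2_unbiased
        post = draw_posterior_ni1(rainfall, est, m=self.M, seed=3)
        # delta ~ Beta(n0 + 1/2, n1 + 3/2)
        bmean = (n0 + 0.5) / (n0 + n1 + 2.0)
        se = post.delta_draws.std() / np.sqrt(self.M)
        assert abs(post.delta_draws.mean() - bmean) < 3 * se
        assert bmean == pytest.approx(7.5 / 64, rel=1e-12)
        # sigma2 ~ IG(n1/2, (n1-1) s2 / 2): mean beta/(alpha-1)
        igmean = ((n1 - 1) * s2 / 2) / (n1 / 2 - 1)
        se = post.sigma2_draws.std() / np.sqrt(self.M)
        assert abs(post.sigma2_draws.mean() - igmean) < 3 * se
        # mu ~ t_{n1-1}(mu_hat, s2/n1)
        se = post.mu_draws.std() / np.sqrt(self.M)
        assert abs(post.mu_draws.mean() - est.mu_hat) < 3 * se
        df = n1 - 1
        tvar = df / (df - 2) * s2 / n1
        assert post.mu_draws.var() == pytest.approx(tvar, rel=0.05)
        # theta assembled elementwise
        np.testing.assert_allclose(
            post.theta_draws,
            np.log1p(-post.delta_draws)
            + np.log(post.a_draws + np.exp(post.mu_draws
                                           + post.sigma2_draws / 2)),
            rtol=1e-12)

    def test_ni2_component_moments(self, rainfall, rainfall_est):
        est = rainfall_est
        n0, n1, s2 = est.n0, est.n1, est.s2_unbiased
        cfg = NI2Config()
        assert cfg.c == pytest.approx(0.9736, abs=5e-5)
        post = draw_posterior_ni2(rainfall, est, cfg, m=self.M, seed=4)
        bmean = (n0 + cfg.c) / (n0 + n1 + 2 * cfg.c)
        se = post.delta_draws.std() / np.sqrt(self.M)
        assert abs(post.delta_draws.mean() - bmean) < 3 * se
        assert bmean == pytest.approx(7.9736 / 63.9472, abs=1e-4)
        igmean = ((n1 - 1) * s2 / 2) / ((n1 - 1) / 2 - 1)
        se = post.sigma2_draws.std() / np.sqrt(self.M)
        assert abs(post.sigma2_draws.mean() - igmean) < 3 * se

    def test_ni2_mu_scale_modes(self, rainfall, rainfall_est):
        """The literal derivation halves the squared location scale."""
        est = rainfall_est
        n1, s2 = est.n1, est.s2_unbiased
        df = n1 - 1
        for mode, sq in (("standard", s2 / n1), ("as-printed", s2 / (2 * n1))):
            post = draw_posterior_ni2(rainfall, est, NI2Config(mu_scale=mode),
                                      m=self.M, seed=5)
            assert post.mu_draws.var() == pytest.approx(
                df / (df - 2) * sq, rel=0.05)

    def test_block_independence(self, rainfall, rainfall_est):
        post = draw_posterior_ni1(rainfall, rainfall_est, m=self.M, seed=6)
        r = np.corrcoef(post.delta_draws, post.sigma2_draws)[0, 1]
        assert abs(r) < 0.02

    def test_plugin_threshold_draws(self, rainfall, rainfall_est):
        post = draw_posterior_ni1(rainfall, rainfall_est, m=500, seed=1)
        assert np.all(post.a_draws == rainfall_est.a_hat)

    def test_metropolis_threshold_draws(self, rainfall, rainfall_est):
        post = draw_posterior_ni1(rainfall, rainfall_est, m=500, seed=1,
                                  a_posterior="metropolis")
        assert np.all((post.a_draws >= 0) & (post.a_draws < rainfall.min_pos))
        assert 0 < post.acceptance_rate <= 1


class TestIntervals:
    def test_equal_tailed_interpolation(self):
        iv = equal_tailed(np.arange(1.0, 101.0), level=0.90)
        assert iv.lower == pytest.approx(5.95, rel=1e-12)
        assert iv.upper == pytest.approx(95.05, rel=1e-12)

    def test_equal_tailed_symmetry(self, rng):
        x = rng.standard_normal(4001)
        draws = np.concatenate([x, -x])
        iv = equal_tailed(draws, 0.9)
        assert iv.lower == pytest.approx(-iv.upper, abs=1e-10)

    def test_nested_in_level(self, rng):
        draws = rng.gamma(2, size=2000)
        widths = [equal_tailed(draws, lv).width for lv in (0.5, 0.8, 0.9, 0.99)]
        assert np.all(np.diff(widths) > 0)

    def test_hpd_equally_spaced(self):
        iv = hpd(np.arange(0, 1.05, 0.1), level=0.8)
        assert (iv.lower, iv.upper) == (0.0, pytest.approx(0.8))

    def test_hpd_excludes_outlier(self):
        draws = np.array([0, .1, .2, .3, .4, .5, .6, .7, .8, 5.0])
        iv = hpd(draws, level=0.9)
        assert (iv.lower, iv.upper) == (0.0, pytest.approx(0.8))

    @pytest.mark.parametrize("m, sampler", [
        (100, "normal"), (500, "lognormal"), (2000, "gamma"),
        (997, "uniform")])
    def test_hpd_matches_brute_force(self, rng, m, sampler):
        draws = {"normal": rng.standard_normal,
                 "lognormal": lambda size: rng.lognormal(0, 1, size),
                 "gamma": lambda size: rng.gamma(1.5, size=size),
                 "uniform": rng.random}[sampler](m)
        iv = hpd(draws, 0.95)
        lo, hi = brute_force_hpd(draws, 0.95)
        assert iv.lower == lo and iv.upper == hi

    def test_hpd_never_wider_than_equal_tailed(self, rng):
        # draw counts where ceil(level*m)-1 gaps fit inside the
        # equal-tailed span (m-1)*level; for other m the two quantile
        # granularities can disagree by a fraction of one gap
        for m in (100, 500, 1000, 2000, 5000):
            for _ in range(10):
                draws = rng.lognormal(rng.normal(), rng.random() + 0.2,
                                      size=m)
                assert (hpd(draws, 0.95).width
                        <= equal_tailed(draws, 0.95).width)

    def test_hpd_flat_density(self, rng):
        draws = rng.random(200000)
        assert hpd(draws, 0.9).width == pytest.approx(
            equal_tailed(draws, 0.9).width, abs=0.01)
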