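import numpy as np
import pytest

from neratio.ratio import (
    PriorSpec,
    analytic_mean_ratio,
    analytic_ratio_moments,
    effective_size,
    sample_ratio_posterior,
    summarize,
)

PUBLISHED = PriorSpec()  # theta_n U[10,16.5], theta_m U[0.01,0.05], mu priors


def degenerate_ideal(c=1.0, mu=1e-4):
    # theta_n = 4*c, theta_m = c, mu_n = mu_m: ratio is exactly 2
    return PriorSpec(
        theta_n=(4 * c, 4 * c), theta_m=(c, c), mu_n=(mu, mu), mu_m=(mu, mu)
    )


class TestPriorSpec:
    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            PriorSpec(theta_n=(5.0, 2.0))
        with pytest.raises(ValueError):
            PriorSpec(mu_n=(0.0, 1e-3))

    def test_degenerate_allowed(self):
        degenerate_ideal()


class TestEffectiveSize:
    def test_published_style_arithmetic(self):
        assert effective_size(13.23, 1e-4, 4) == pytest.approx(33075.0)
        assert effective_size(0.0238, 1e-7, 2) == pytest.approx(119000.0)

    def test_identity(self):
        mu = 2.5e-4
        assert effective_size(4 * mu, mu, 4) == pytest.approx(1.0)

    def test_invalid(self):
        with pytest.raises(ValueError):
            effective_size(1.0, 0.0, 4)
        with pytest.raises(ValueError):
            effective_size(1.0, 1e-4, 3)


class TestSampling:
    def test_degenerate_priors_give_exact_ratio_two(self):
        post = sample_ratio_posterior(degenerate_ideal(), n_samples=10_000, seed=0)
        assert np.all(post.ratio == 2.0)
        assert np.all(post.reduction_pct == 0.0)
        s = summarize(post)
        assert s.mean == 2.0 and s.sd == 0.0
        assert s.reduction_mean_pct == 0
        assert s.reduction_range_pct == (0, 0)

    def test_row_wise_identities(self):
        post = sample_ratio_posterior(PUBLISHED, n_samples=20_000, seed=1)
        assert np.allclose(post.ne, post.theta_n / (4 * post.mu_n))
        assert np.allclose(post.nef, post.theta_m / (2 * post.mu_m))
        assert np.allclose(post.ratio, post.ne / post.nef)
        assert np.allclose(post.reduction_pct, 100 * (1 - post.ratio / 2))
        assert np.all(post.ratio > 0)

    def test_mc_mean_converges_to_analytic(self):
        post = sample_ratio_posterior(PUBLISHED, n_samples=200_000, seed=2)
        target = analytic_mean_ratio(PUBLISHED)
        tol = 4 * post.ratio.std() / np.sqrt(post.n_samples)
        assert abs(post.ratio.mean() - target) < tol

    def test_analytic_oracle_value(self):
        # closed form: 13.25 * 5.5e-8 * ln(5)/0.04 * ln(100)/9.9e-4 / 2
        expected = 13.25 * 5.5e-8 * (np.log(5) / 0.04) * (np.log(100) / 9.9e-4) / 2
        assert analytic_mean_ratio(PUBLISHED) == pytest.approx(expected)
        assert analytic_mean_ratio(PUBLISHED) == pytest.approx(0.0682, abs=2e-4)

    def test_analytic_mean_degenerate(self):
        assert analytic_mean_ratio(degenerate_ideal()) == pytest.approx(2.0)

    def test_doubling_mu_m_doubles_mean(self):
        doubled = PriorSpec(mu_m=(2e-8, 2e-7))
        assert analytic_mean_ratio(doubled) == pytest.approx(
            2 * analytic_mean_ratio(PUBLISHED)
        )

    def test_analytic_sd_matches_mc(self):
        mean, sd = analytic_ratio_moments(PUBLISHED)
        post = sample_ratio_posterior(PUBLISHED, n_samples=400_000, seed=3)
        assert post.ratio.std() == pytest.approx(sd, rel=0.02)

    def test_adjusted_mode_scales_by_generation_time(self):
        pub = analytic_mean_ratio(PUBLISHED, mode="published")
        adj = analytic_mean_ratio(PUBLISHED, mode="adjusted")
        assert adj == pytest.approx(3.0 * pub)
        post = sample_ratio_posterior(PUBLISHED, n_samples=50_000, seed=4, mode="adjusted")
        assert post.ratio.mean() == pytest.approx(adj, rel=0.05)

    def test_monotonicity_in_priors(self):
        base = sample_ratio_posterior(PUBLISHED, n_samples=100_000, seed=5)
        higher_tn = sample_ratio_posterior(
            PriorSpec(theta_n=(20.0, 33.0)), n_samples=100_000, seed=5
        )
        higher_mn = sample_ratio_posterior(
            PriorSpec(mu_n=(2e-5, 2e-3)), n_samples=100_000, seed=5
        )
        assert higher_tn.ratio.mean() > base.ratio.mean()
        assert higher_mn.ratio.mean() < base.ratio.mean()

    def test_seed_determinism(self):
        a = summarize(sample_ratio_posterior(PUBLISHED, n_samples=50_000, seed=7))
        b = summarize(sample_ratio_posterior(PUBLISHED, n_samples=50_000, seed=7))
        assert a == b

    def test_invalid_mode(self):
        with pytest.raises(ValueError):
            sample_ratio_posterior(PUBLISHED, n_samples=100, seed=0, mode="bogus")


class TestSummarize:
    def test_brute_force_on_explicit_draws(self):
        # hand-listed 5-draw posterior, padded to the minimum size by
        # repetition so quantiles stay those of the explicit list
        base = np.array([0.02, 0.05, 0.1, 0.4, 2.0])
        draws = np.tile(base, 2000)
        post = sample_ratio_posterior(PUBLISHED, n_samples=10_000, seed=8)
        post.ratio = draws
        post.n_samples = draws.size
        s = summarize(post)
        assert s.mean == pytest.approx(draws.mean())
        assert s.sd == pytest.approx(draws.std())
        assert s.ci95 == (
            pytest.approx(np.quantile(draws, 0.025)),
            pytest.approx(np.quantile(draws, 0.975)),
        )
        assert s.reduction_mean_pct == round(100 * (1 - draws.mean() / 2))

    def test_reduction_transform_commutes_for_mean(self):
        post = sample_ratio_posterior(PUBLISHED, n_samples=50_000, seed=9)
        s = summarize(post)
        assert post.reduction_pct.mean() == pytest.approx(
            100 * (1 - post.ratio.mean() / 2)
        )
        assert s.reduction_mean_pct == round(post.reduction_pct.mean())

    def test_needs_enough_draws(self):
        post = sample_ratio_posterior(PUBLISHED, n_samples=100, seed=10)
        with pytest.raises(ValueError):
            summarize(post)
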