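import numpy as np
import pytest

from neratio.datatypes import GenotypeMatrix
from neratio.genealogy import coalescent_log_density, simulate_genealogy
from neratio.mcmc import (
    McmcOptions,
    MicrosatelliteModel,
    SequenceModel,
    propose_node_time,
    propose_tree_scale,
    propose_wilson_balding,
    reflect,
    upgma_genealogy,
)
from neratio.simulate import evolve_sequences
from neratio.theta import (
    bayes_theta_microsatellites,
    bayes_theta_sequences,
    watterson_theta,
)


def _fast_opts(**kw):
    defaults = dict(burn_in=200, n_samples=600, seed=1)
    defaults.update(kw)
    return McmcOptions(**defaults)


def test_reflect_stays_in_bounds_and_is_idempotent_inside():
    assert reflect(0.5, 0.0, 1.0) == 0.5
    assert reflect(1.2, 0.0, 1.0) == pytest.approx(0.8)
    assert reflect(-0.3, 0.0, 1.0) == pytest.approx(0.3)
    assert reflect(2.4, 0.0, 1.0) == pytest.approx(0.4)
    xs = np.linspace(-5, 5, 101)
    assert all(0.0 <= reflect(x, 0.0, 1.0) <= 1.0 for x in xs)


class TestProposals:
    def test_node_time_move_preserves_validity(self):
        rng = np.random.default_rng(0)
        tree = simulate_genealogy(12, rng)
        for _ in range(200):
            prop = propose_node_time(tree, rng, 0.4)
            if prop is None:
                continue
            tree, _ = prop
            tree.validate()

    def test_tree_scale_move_preserves_validity(self):
        rng = np.random.default_rng(1)
        tree = simulate_genealogy(9, rng)
        for _ in range(100):
            tree, log_h = propose_tree_scale(tree, rng, 0.4)
            tree.validate()

    def test_wilson_balding_preserves_validity(self):
        rng = np.random.default_rng(2)
        tree = simulate_genealogy(10, rng)
        n_ok = 0
        for _ in range(300):
            prop = propose_wilson_balding(tree, rng)
            if prop is None:
                continue
            tree, _ = prop
            tree.validate()
            n_ok += 1
        assert n_ok > 100

    def test_wilson_balding_keeps_root_time(self):
        rng = np.random.default_rng(3)
        tree = simulate_genealogy(8, rng)
        root_time = tree.tmrca
        for _ in range(100):
            prop = propose_wilson_balding(tree, rng)
            if prop is not None:
                tree = prop[0]
        assert tree.tmrca == pytest.approx(root_time)

    def test_detailed_balance_node_time_move(self):
        # the unclipped MH ratios of a move and its exact reverse multiply
        # to one: r(A->B) * r(B->A) = 1
        rng = np.random.default_rng(4)
        tree = simulate_genealogy(6, rng)
        u = tree.n_tips  # first internal node
        a, b = tree.children[u]
        lo = max(tree.times[a], tree.times[b])
        hi = tree.times[tree.parent[u]]
        fwd = tree.copy()
        fwd.times[u] = 0.5 * (lo + hi)
        # symmetric within a fixed interval: Hastings terms are zero, so
        # the ratio is the prior ratio and reverses exactly
        lp_a = coalescent_log_density(tree.times, tree.n_tips)
        lp_b = coalescent_log_density(fwd.times, fwd.n_tips)
        r_ab = lp_b - lp_a
        r_ba = lp_a - lp_b
        assert r_ab + r_ba == pytest.approx(0.0, abs=1e-12)

    def test_detailed_balance_tree_scale_move(self):
        # scaling by c then by 1/c returns the state; the log Hastings
        # terms (n-1)log(c) and (n-1)log(1/c) cancel exactly
        tree = simulate_genealogy(7, 5)
        n = tree.n_tips
        c = 1.37
        log_h_fwd = (n - 1) * np.log(c)
        log_h_rev = (n - 1) * np.log(1 / c)
        assert log_h_fwd + log_h_rev == pytest.approx(0.0, abs=1e-12)


class TestPriorSampling:
    def test_tree_moves_sample_the_coalescent_prior(self):
        # with the likelihood disabled the chain must reproduce coalescent
        # expectations, e.g. E[TMRCA] = 2(1 - 1/n); exercises the
        # Wilson-Balding Hastings ratio and the time moves jointly
        rng = np.random.default_rng(0)
        g = simulate_genealogy(8, rng)
        aln = evolve_sequences(g, 60, 0.05, 33.0, rng)
        post = bayes_theta_sequences(
            aln,
            prior_bounds=(0.0, 0.1),
            options=_fast_opts(burn_in=500, n_samples=4000, seed=11),
            prior_only=True,
        )
        roots = post.extras["root_time_trace"]
        expected = 2 * (1 - 1 / 8)
        se = np.std(roots) / np.sqrt(200)  # generous, accounts for autocorr
        assert abs(np.mean(roots) - expected) < 4 * se

    def test_sequence_sampler_recovers_prior(self):
        rng = np.random.default_rng(1)
        g = simulate_genealogy(6, rng)
        aln = evolve_sequences(g, 40, 0.02, 33.0, rng)
        post = bayes_theta_sequences(
            aln,
            prior_bounds=(0.0, 0.1),
            options=_fast_opts(burn_in=500, n_samples=8000, seed=2),
            prior_only=True,
        )
        assert post.mean == pytest.approx(0.05, abs=0.006)
        assert np.quantile(post.samples, 0.25) == pytest.approx(0.025, abs=0.008)

    def test_microsat_sampler_recovers_prior(self):
        alleles = np.array([[[20, 21], [19, 22]], [[20, 20], [21, 21]]])
        geno = GenotypeMatrix(["a", "b"], ["L1", "L2"], alleles)
        post = bayes_theta_microsatellites(
            geno,
            prior_bounds=(0.0, 100.0),
            options=_fast_opts(burn_in=500, n_samples=8000, seed=3),
            prior_only=True,
        )
        assert post.mean == pytest.approx(50.0, abs=6.0)


class TestSequenceSampler:
    def test_determinism(self):
        rng = np.random.default_rng(2)
        g = simulate_genealogy(8, rng)
        aln = evolve_sequences(g, 120, 0.03, 33.0, rng)
        p1 = bayes_theta_sequences(aln, options=_fast_opts())
        p2 = bayes_theta_sequences(aln, options=_fast_opts())
        assert np.array_equal(p1.samples, p2.samples)

    def test_monomorphic_alignment_posterior_near_zero(self):
        rng = np.random.default_rng(3)
        g = simulate_genealogy(10, rng)
        aln = evolve_sequences(g, 512, 0.0, 33.0, rng)
        post = bayes_theta_sequences(
            aln, options=_fast_opts(burn_in=400, n_samples=1500, seed=5)
        )
        # posterior must sit below the Watterson estimate for S=1
        assert np.median(post.samples) < watterson_theta(1, 10, 512)
        assert "piled_at_lower_bound" in post.flags

    def test_needs_three_sequences(self):
        rng = np.random.default_rng(4)
        g = simulate_genealogy(2, rng)
        aln = evolve_sequences(g, 50, 0.01, 33.0, rng)
        with pytest.raises(ValueError):
            bayes_theta_sequences(aln)

    def test_agrees_with_watterson_across_thetas(self):
        # moment-estimator agreement: r > 0.8 across replicates
        rng = np.random.default_rng(5)
        post_means, watt = [], []
        thetas = np.linspace(0.005, 0.05, 30)
        for k, theta in enumerate(thetas):
            g = simulate_genealogy(10, rng)
            aln = evolve_sequences(g, 300, theta, 33.0, rng)
            post = bayes_theta_sequences(
                aln, options=_fast_opts(burn_in=250, n_samples=600, seed=50 + k)
            )
            arr = aln.to_array()
            S = sum(len(set(col)) > 1 for col in arr.T)
            post_means.append(post.mean)
            watt.append(watterson_theta(S, 10, 300))
        r = np.corrcoef(post_means, watt)[0, 1]
        assert r > 0.8


class TestMicrosatModel:
    def test_two_tips_equal_values_likelihood_increases_towards_zero_theta(self):
        tree = simulate_genealogy(2, 1)
        model = MicrosatelliteModel([np.array([20.0, 20.0])])
        stats = model.stats(0, tree)
        lls = [model.loglik(0, stats, th) for th in (0.01, 0.1, 1.0, 10.0)]
        assert all(a > b for a, b in zip(lls, lls[1:]))

    def test_likelihood_finite_and_decreasing_far_from_data_scale(self):
        tree = simulate_genealogy(6, 2)
        vals = np.array([20.0, 21.0, 19.0, 22.0, 20.0, 18.0])
        model = MicrosatelliteModel([vals])
        stats = model.stats(0, tree)
        assert np.isfinite(model.loglik(0, stats, 5.0))
        assert model.loglik(0, stats, 5.0) > model.loglik(0, stats, 5000.0)

    def test_determinism(self, small_dataset):
        _, geno = small_dataset
        p1 = bayes_theta_microsatellites(geno, options=_fast_opts())
        p2 = bayes_theta_microsatellites(geno, options=_fast_opts())
        assert np.array_equal(p1.samples, p2.samples)

    def test_upgma_tree_is_valid(self):
        rng = np.random.default_rng(6)
        values = rng.integers(15, 25, size=30).astype(float)
        tree = upgma_genealogy(values)
        tree.validate()
        assert tree.n_tips == 30


def test_sequence_model_pattern_compression_matches_alignment():
    rng = np.random.default_rng(7)
    g = simulate_genealogy(6, rng)
    aln = evolve_sequences(g, 100, 0.05, 33.0, rng)
    model = SequenceModel(aln, 33.0)
    assert model.counts.sum() == aln.length
    assert model.tip_codes.shape[0] == aln.n_sequences


def test_sequence_likelihood_prefers_generating_theta_scale():
    rng = np.random.default_rng(8)
    g = simulate_genealogy(12, rng)
    aln = evolve_sequences(g, 800, 0.02, 33.0, rng)
    model = SequenceModel(aln, 33.0)
    stats = model.stats(0, g)  # true genealogy
    ll = {th: model.loglik(0, stats, th) for th in (0.0005, 0.02, 0.5)}
    assert ll[0.02] > ll[0.0005]
    assert ll[0.02] > ll[0.5]
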