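"""Metropolis-Hastings machinery: pCN proposals, acceptance rules, chains."""

import numpy as np
import pytest
from scipy.stats import kstest

import idealobs as io
from idealobs.errors import ChainInitError, ConfigurationError, StateError
from idealobs.mcmc import batch_means_se, pcn_log_proposal_ratio


class TestPcnPropose:
    def test_small_beta_freezes_chain(self):
        rng = np.random.default_rng(0)
        z = np.array([1.0, -2.0])
        out = io.pcn_propose(z, 1e-9, rng)
        np.testing.assert_allclose(out, z, atol=1e-6)

    def test_beta_one_is_independence_proposal(self):
        z = np.array([5.0, 5.0, 5.0])
        out = io.pcn_propose(z, 1.0, np.random.default_rng(1))
        expected = np.random.default_rng(1).standard_normal(3)
        np.testing.assert_allclose(out, expected)

    def test_invalid_beta(self):
        with pytest.raises(ConfigurationError):
            io.pcn_propose(np.zeros(2), 0.0, np.random.default_rng(0))
        with pytest.raises(ConfigurationError):
            io.pcn_propose(np.zeros(2), 1.5, np.random.default_rng(0))

    def test_prior_reversibility_identity(self):
        # p(z*) q(z|z*) = p(z) q(z*|z): prior log-ratio cancels proposal log-ratio
        rng = np.random.default_rng(2)
        for _ in range(20):
            z = rng.standard_normal(4)
            zc = io.pcn_propose(z, 0.3, rng)
            prior_ratio = 0.5 * np.sum(z**2) - 0.5 * np.sum(zc**2)
            assert prior_ratio + pcn_log_proposal_ratio(z, zc, 0.3) == pytest.approx(
                0.0, abs=1e-9
            )


class TestAcceptLatent:
    @pytest.fixture()
    def two_pixel_setup(self):
        # generator producing a fixed 2-pixel "signal" per latent value
        def gen_image(z):
            return np.array([[float(z[0]), 0.0]])

        return io.LatentGenerator(latent_dim=1, generate=gen_image, kind="signal")

    def test_identical_states_always_accepted(self, two_pixel_setup):
        g = np.array([[1.0, 2.0]])
        z = np.array([0.5])
        acc, log_pa = io.accept_latent(
            g, z, z, two_pixel_setup, 1.0, np.random.default_rng(0)
        )
        assert acc and log_pa == 0.0

    def test_hand_computed_two_pixel_ratio(self):
        # residual norms 8 vs 4 at sigma_n = 1: uphill log ratio 2 -> accept;
        # reversed move has log p_a = -2.
        def gen(z):
            return np.array([[float(z[0]), 0.0]])

        generator = io.LatentGenerator(latent_dim=1, generate=gen, kind="signal")
        g = np.array([[2.0, 2.0]])
        z_far = np.array([0.0])  # residual^2 = 4 + 4 = 8
        z_near = np.array([2.0])  # residual^2 = 0 + 4 = 4
        acc, log_pa = io.accept_latent(
            g, z_far, z_near, generator, 1.0, np.random.default_rng(0)
        )
        assert acc and log_pa == 0.0
        _, log_pa_rev = io.accept_latent(
            g, z_near, z_far, generator, 1.0, np.random.default_rng(0)
        )
        assert log_pa_rev == pytest.approx(-2.0)


class TestAcceptJoint:
    @pytest.fixture()
    def joint_setup(self, bks_cfg):
        gen = io.lumpy_background_generator(side=8, n_lumps=3, lump_width=2.0)
        unit = np.zeros((8, 8))
        unit[4, 4] = 1.0
        prior = io.AmplitudePrior.uniform(0.05, 0.15)
        return gen, unit, prior

    def test_identical_states_accepted(self, joint_setup):
        gen, unit, prior = joint_setup
        rng = np.random.default_rng(0)
        z = rng.standard_normal(gen.latent_dim)
        g = 0.1 * unit + gen.generate(z)
        acc, log_pa = io.accept_joint(
            g, (0.1, z), (0.1, z), unit, gen, 0.01, prior, rng
        )
        assert acc and log_pa == 0.0

    def test_out_of_support_theta_rejected_before_likelihood(self, joint_setup):
        gen, unit, prior = joint_setup
        rng = np.random.default_rng(1)
        z = rng.standard_normal(gen.latent_dim)
        g = gen.generate(z)
        acc, log_pa = io.accept_joint(
            g, (0.1, z), (0.2, z), unit, gen, 0.01, prior, rng
        )
        assert not acc and log_pa == -np.inf

    def test_general_ratio_equals_simplified_when_conditions_hold(self, joint_setup):
        # uniform prior inside support + symmetric theta proposal + pCN latent:
        # the explicit prior/proposal terms cancel and both paths agree.
        gen, unit, prior = joint_setup
        beta = 0.1
        width = prior.hi - prior.lo

        def log_theta_prior(th):
            return -np.log(width) if prior.contains(th) else -np.inf

        def log_latent_prior(z):
            return -0.5 * float(np.sum(z**2))

        rng = np.random.default_rng(2)
        for _ in range(100):
            z = rng.standard_normal(gen.latent_dim)
            zc = io.pcn_propose(z, beta, rng)
            th = rng.uniform(prior.lo, prior.hi)
            thc = rng.uniform(prior.lo, prior.hi)
            g = thc * unit + gen.generate(zc) + 0.01 * rng.standard_normal((8, 8))
            _, simple = io.accept_joint(
                g, (th, z), (thc, zc), unit, gen, 0.01, prior,
                np.random.default_rng(3),
            )
            _, general = io.accept_joint(
                g, (th, z), (thc, zc), unit, gen, 0.01, prior,
                np.random.default_rng(3),
                log_theta_prior=log_theta_prior,
                log_latent_prior=log_latent_prior,
                log_proposal_ratio=pcn_log_proposal_ratio(z, zc, beta),
            )
            assert general == pytest.approx(simple, abs=1e-7)


class TestRunChain:
    def test_flat_likelihood_pcn_accepts_everything(self):
        settings = io.ChainSettings(n_samples=500, burn_in=50, pcn_beta=0.5, seed=3)
        chain = io.run_chain(
            g=None,
            initial_state=np.zeros(2),
            settings=settings,
            propose=lambda s, rng: io.pcn_propose(s, 0.5, rng),
            accept=lambda g, s, c, rng: (True, 0.0),
        )
        assert chain.acceptance_rate == 1.0
        assert len(chain) == 500

    def test_flat_likelihood_samples_are_prior_distributed(self):
        # likelihood == 1: pCN leaves N(0, I_k) invariant; thin the chain to
        # break autocorrelation before the distributional test.
        settings = io.ChainSettings(
            n_samples=10_000, burn_in=200, pcn_beta=0.5, seed=4
        )
        chain = io.run_chain(
            None,
            np.zeros(2),
            settings,
            propose=lambda s, rng: io.pcn_propose(s, 0.5, rng),
            accept=lambda g, s, c, rng: (True, 0.0),
        )
        thinned = chain.samples[::20]
        for dim in range(2):
            assert kstest(thinned[:, dim], "norm").pvalue > 0.01

    def test_same_seed_identical_chains(self, bke_cfg, bke_model):
        gen = io.exact_signal_generator(bke_cfg)
        g = io.simulate_batch(bke_cfg, 1, 0, seed=9).images[0]
        settings = io.ChainSettings(n_samples=50, burn_in=10, seed=5)

        def run():
            return io.run_chain(
                g,
                np.zeros(1),
                settings,
                propose=lambda s, rng: io.pcn_propose(s, 0.2, rng),
                accept=lambda gg, s, c, rng: io.accept_latent(
                    gg, s, c, gen, bke_cfg.noise_sd, rng
                ),
                loglik=lambda gg, s: io.gaussian_loglik(
                    gg, gen.generate(s), bke_cfg.noise_sd
                ),
            )

        a, b = run(), run()
        np.testing.assert_array_equal(a.samples, b.samples)
        assert a.acceptance_rate == b.acceptance_rate
        np.testing.assert_array_equal(a.log_liks, b.log_liks)

    def test_nonfinite_initial_loglik_raises(self):
        settings = io.ChainSettings(n_samples=10, burn_in=0, seed=0)
        with pytest.raises(ChainInitError):
            io.run_chain(
                np.zeros(2),
                np.zeros(1),
                settings,
                propose=lambda s, rng: s,
                accept=lambda g, s, c, rng: (True, 0.0),
                loglik=lambda g, s: -np.inf,
            )

    def test_generic_chain_matches_conjugate_oracle(self, bke_cfg, bke_model):
        # image-space generic path (through the generator contract) agrees
        # with the closed-form posterior within Monte Carlo error
        gen = io.exact_signal_generator(bke_cfg)
        batch = io.simulate_batch(bke_cfg, 2, 0, seed=10)
        settings = io.ChainSettings(n_samples=2000, burn_in=500, seed=6)
        for g in batch.images:
            chain = io.run_chain(
                g,
                np.zeros(1),
                settings,
                propose=lambda s, rng: io.pcn_propose(s, 0.2, rng),
                accept=lambda gg, s, c, rng: io.accept_latent(
                    gg, s, c, gen, bke_cfg.noise_sd, rng
                ),
            )
            theta = 9.0 + 4.0 * chain.samples[:, 0]
            mean_true, var_true = io.conjugate_posterior(bke_model, g)
            se = batch_means_se(theta)
            assert abs(theta.mean() - mean_true) < 4 * se


class TestEstimators:
    def test_utility_mean_trivial_cases(self):
        samples = np.full(100, 7.0)
        assert io.estimate_utility_weighted_mean(samples, 7.0, 3.0) == 1.0
        half = 3.0 * np.sqrt(2 * np.log(2))
        two = np.array([7.0 + half, 7.0 - half])
        assert io.estimate_utility_weighted_mean(two, 7.0, 3.0) == pytest.approx(0.5)

    def test_empty_chain_raises(self):
        with pytest.raises(StateError):
            io.estimate_utility_weighted_mean(np.array([]), 0.0, 1.0)
        with pytest.raises(StateError):
            io.sample_based_estimator(np.array([]), 1.0, np.array([0.0]))

    def test_sample_estimator_degenerate_posterior(self):
        samples = np.full(50, 0.4)
        grid = np.linspace(0.0, 1.0, 11)
        assert io.sample_based_estimator(samples, 0.1, grid) == pytest.approx(0.4)

    def test_sample_estimator_gaussian_cloud_near_mean(self):
        rng = np.random.default_rng(11)
        samples = rng.normal(2.0, 0.5, 4000)
        grid = np.linspace(0.0, 4.0, 81)  # step 0.05
        est = io.sample_based_estimator(samples, 0.5, grid)
        assert abs(est - samples.mean()) <= 0.05 + 1e-12

    def test_sample_estimator_matches_finer_grid_bruteforce(self):
        rng = np.random.default_rng(12)
        samples = rng.normal(0.1, 0.02, 1000)
        coarse = np.linspace(0.05, 0.15, 21)
        fine = np.linspace(0.05, 0.15, 201)
        est_c = io.sample_based_estimator(samples, 0.05, coarse)
        est_f = io.sample_based_estimator(samples, 0.05, fine)
        assert abs(est_c - est_f) <= (coarse[1] - coarse[0]) + 1e-12


class TestVectorizedBkeChains:
    def test_reproducible_and_prior_initialized(self, bke_cfg, bke_model):
        batch = io.simulate_batch(bke_cfg, 5, 5, seed=20)
        st = io.ChainSettings(n_samples=200, burn_in=50, seed=21)
        a = io.run_sks_bke_chains(
            batch.images, bke_model.s_ref, 40.0, 9.0, 4.0, st
        )
        b = io.run_sks_bke_chains(
            batch.images, bke_model.s_ref, 40.0, 9.0, 4.0, st
        )
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_matches_conjugate_posterior(self, bke_cfg, bke_model):
        batch = io.simulate_batch(bke_cfg, 10, 0, seed=22)
        st = io.ChainSettings(n_samples=2000, burn_in=500, seed=23)
        with pytest.warns(RuntimeWarning):
            theta, rates = io.run_sks_bke_chains(
                batch.images, bke_model.s_ref, 40.0, 9.0, 4.0, st
            )
        mean_true, var_true = io.conjugate_posterior(bke_model, batch.images)
        for i in range(10):
            se = batch_means_se(theta[i])
            assert abs(theta[i].mean() - mean_true[i]) < 4 * se
        assert np.all(rates > 0.0) and np.all(rates <= 1.0)
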