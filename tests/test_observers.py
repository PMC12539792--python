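"""Observer composition, likelihood-ratio mapping, and learned networks."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import idealobs as io
from idealobs.analytic import quadrature_log_marginal_ratio
from idealobs.errors import DataError, DimensionError, TrainingDataError
from idealobs.nets import NetHyperparams


def _auc(stats, labels):
    s0 = np.sort(np.asarray(stats)[labels == 0])
    s1 = np.asarray(stats)[labels == 1]
    below = np.searchsorted(s0, s1, "left")
    ties = np.searchsorted(s0, s1, "right") - below
    return float((below + 0.5 * ties).sum() / (len(s0) * len(s1)))


class TestLikelihoodRatioFromPosterior:
    def test_indifference_and_odds_identity(self):
        assert io.likelihood_ratio_from_posterior(0.5) == pytest.approx(1.0)
        assert io.likelihood_ratio_from_posterior(0.9) == pytest.approx(9.0)
        assert io.likelihood_ratio_from_posterior(0.9, prior_odds=3.0) == pytest.approx(3.0)

    def test_boundary_probabilities_clamped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            lr = io.likelihood_ratio_from_posterior(np.array([0.0, 1.0]))
        assert np.all(np.isfinite(lr)) and lr[0] > 0

    def test_bayes_rule_roundtrip_recovers_quadrature_ratio(self, bke_cfg, bke_model):
        # true posterior p = Lambda/(1+Lambda) (equal priors); mapping back
        # must recover the quadrature likelihood ratio
        images = io.simulate_batch(bke_cfg, 3, 3, seed=30).images
        for g in images:
            log_lr = quadrature_log_marginal_ratio(bke_model, g)
            lr = np.exp(log_lr)
            p = lr / (1.0 + lr)
            assert io.likelihood_ratio_from_posterior(p) == pytest.approx(
                lr, rel=1e-6
            )


class TestHybridStatistic:
    def test_reduces_to_lambda_when_u_is_one(self):
        lr = np.array([0.5, 2.0, 9.0])
        np.testing.assert_allclose(io.hybrid_statistic(lr, np.ones(3)), lr)

    def test_product(self):
        assert io.hybrid_statistic(np.array([9.0]), np.array([0.5]))[0] == pytest.approx(4.5)

    def test_monotone_in_each_argument(self):
        t1 = io.hybrid_statistic(np.array([2.0]), np.array([0.5]))
        assert io.hybrid_statistic(np.array([3.0]), np.array([0.5])) > t1
        assert io.hybrid_statistic(np.array([2.0]), np.array([0.7])) > t1

    def test_validation(self):
        with pytest.raises(DimensionError):
            io.hybrid_statistic(np.ones(2), np.ones(3))
        with pytest.raises(DataError):
            io.hybrid_statistic(np.array([1.0]), np.array([1.5]))
        with pytest.raises(DataError):
            io.hybrid_statistic(np.array([-1.0]), np.array([0.5]))


class TestSubIdealObserver:
    def test_statistics_independent_of_estimator_source(self, bke_batch_small, bke_model):
        lr = lambda b: io.analytic_statistic(bke_model, b.images)
        res1 = io.sub_ideal_observer(bke_batch_small, lr, lambda b: io.analytic_estimate(bke_model, b.images))
        res2 = io.sub_ideal_observer(bke_batch_small, lr, lambda b: np.zeros(len(b.images)))
        np.testing.assert_array_equal(res1.statistics, res2.statistics)
        assert not np.array_equal(res1.estimates, res2.estimates)

    def test_detection_auc_equals_hybrid_with_constant_u(self, bke_batch_small, bke_model):
        log_lr = io.analytic_statistic(bke_model, bke_batch_small.images)
        hybrid = np.log(io.hybrid_statistic(np.exp(log_lr - log_lr.max()), np.full(log_lr.size, 0.25)))
        assert _auc(log_lr, bke_batch_small.labels) == _auc(hybrid, bke_batch_small.labels)


class TestHybridObserverBke:
    def test_hybrid_aeroc_not_below_pure_detection(self, bke_cfg, bke_model):
        # multiplying by the MCMC U(g) must not degrade AEROC beyond MC noise
        batch = io.simulate_batch(bke_cfg, 150, 150, seed=31)
        res_h, _ = io.hybrid_mcmc_observer_bke(
            batch, io.ChainSettings(n_samples=1000, burn_in=300, seed=32)
        )
        model = bke_model
        res_sub = io.sub_ideal_observer(
            batch,
            lambda b: io.analytic_statistic(model, b.images),
            lambda b: io.analytic_estimate(model, b.images),
        )
        from idealobs.studies import split_results
        from idealobs.eroc import paired_aeroc_delta_uncertainty

        hp, ha, truths = split_results(batch, res_h)
        sp, sa, _ = split_results(batch, res_sub)
        delta, hw = paired_aeroc_delta_uncertainty(
            hp, ha, sp, sa, truths, bke_cfg.utility_width, n_boot=500, seed=33
        )
        assert delta >= -hw


@pytest.fixture(scope="module")
def trained(bke_cfg):
    """Detection and estimation nets trained on 10^4 images of the BKE task."""
    train = io.simulate_batch(bke_cfg, 5000, 5000, seed=40)
    test = io.simulate_batch(bke_cfg, 1000, 1000, seed=41)
    hp = NetHyperparams(seed=0)
    det = io.train_detection(train, hp)
    est = io.train_estimation(train, bke_cfg.utility_width, hp)
    return det, est, test


class TestLearnedNetworks:
    def test_detection_requires_both_classes(self, bke_cfg):
        single = io.simulate_batch(bke_cfg, 50, 0, seed=42)
        with pytest.raises(TrainingDataError):
            io.train_detection(single, NetHyperparams(epochs=1))

    def test_estimation_requires_amplitudes(self, bke_cfg):
        absent = io.simulate_batch(bke_cfg, 0, 50, seed=43)
        with pytest.raises(TrainingDataError):
            io.train_estimation(absent, 3.0, NetHyperparams(epochs=1))

    def test_detection_outputs_strictly_inside_unit_interval(self, trained):
        det, _, test = trained
        p = det.predict(test.images)
        assert np.all((p > 0) & (p < 1))

    def test_detection_auc_close_to_analytic(self, trained, bke_model):
        det, _, test = trained
        learned_auc = _auc(det.predict_logit(test.images), test.labels)
        analytic_auc = _auc(
            io.analytic_statistic(bke_model, test.images), test.labels
        )
        assert analytic_auc - learned_auc < 0.02

    def test_detection_rank_correlation_with_log_lambda(self, trained, bke_model):
        det, _, test = trained
        rc = spearmanr(
            det.predict_logit(test.images),
            io.analytic_statistic(bke_model, test.images),
        ).statistic
        assert rc > 0.95

    def test_estimation_utility_close_to_analytic(self, trained, bke_cfg, bke_model):
        _, est, test = trained
        pres = test.present()
        u_learned = io.gaussian_utility(
            est.predict(pres.images), pres.amplitudes, bke_cfg.utility_width
        ).mean()
        u_analytic = io.gaussian_utility(
            io.analytic_estimate(bke_model, pres.images),
            pres.amplitudes,
            bke_cfg.utility_width,
        ).mean()
        assert u_analytic - u_learned < 0.02

    def test_estimation_beats_constant_prior_mean_predictor(self, trained, bke_cfg):
        _, est, test = trained
        pres = test.present()
        u_learned = io.gaussian_utility(
            est.predict(pres.images), pres.amplitudes, bke_cfg.utility_width
        ).mean()
        u_const = io.gaussian_utility(
            np.full(pres.n_present, 9.0), pres.amplitudes, bke_cfg.utility_width
        ).mean()
        assert u_learned > u_const

    def test_training_reproducible(self, bke_cfg):
        train = io.simulate_batch(bke_cfg, 300, 300, seed=44)
        hp = NetHyperparams(epochs=5, seed=1)
        a = io.train_detection(train, hp).predict(train.images[:10])
        b = io.train_detection(train, hp).predict(train.images[:10])
        np.testing.assert_array_equal(a, b)
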