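"""Closed-form Bayesian decoders vs direct evaluation and grid oracles."""

import numpy as np
import pytest

from priorpop.encoder import EncoderSpec, TaskSpec, sample_trials, tuning_rate
from priorpop.gridref import (
    default_grid,
    grid_class_posterior,
    grid_map_estimate,
    log_population_likelihood,
)
from priorpop.ideal_observer import (
    class_log_odds,
    decode_likelihood,
    decode_likelihood_batch,
    ideal_accuracy,
    map_estimate,
    posterior_class1,
)


@pytest.fixture
def cls_task():
    return TaskSpec.classification(prior=0.5)


class TestDecode:
    def test_single_spike_reads_out_the_center(self):
        centers = np.linspace(-20, 20, 11)  # includes 4.0
        spec = EncoderSpec(n_neurons=11, centers=centers)
        r = np.zeros(11, dtype=int)
        r[centers == 4.0] = 1
        dec = decode_likelihood(r, spec)
        assert dec.mu_r == pytest.approx(4.0)
        assert dec.sigma_r2 == pytest.approx(10.0)

    def test_two_symmetric_spikes_average(self):
        centers = np.linspace(-20, 20, 9)  # contains -5 and 5
        spec = EncoderSpec(n_neurons=9, centers=centers)
        r = np.zeros(9, dtype=int)
        r[centers == -5.0] = 1
        r[centers == 5.0] = 1
        dec = decode_likelihood(r, spec)
        assert dec.mu_r == pytest.approx(0.0)
        assert dec.sigma_r2 == pytest.approx(5.0)

    def test_zero_spikes_flagged_uninformative(self, spec_cls):
        dec = decode_likelihood(np.zeros(50, dtype=int), spec_cls)
        assert not dec.informative and dec.total_count == 0

    def test_decoded_moments_match_likelihood_grid(self, spec_cls):
        """The Gaussian summary equals the mean/variance of the brute-force
        normalized likelihood over a fine grid, for a dense spike vector."""
        rng = np.random.default_rng(0)
        r = rng.poisson(tuning_rate(2.5, 3.3, spec_cls))
        grid = default_grid(step=0.005)
        ll = log_population_likelihood(r, spec_cls, grid)
        w = np.exp(ll - ll.max())
        w /= w.sum()
        mean = float(w @ grid)
        var = float(w @ (grid - mean) ** 2)
        dec = decode_likelihood(r, spec_cls)
        assert dec.mu_r == pytest.approx(mean, abs=0.01)
        assert dec.sigma_r2 == pytest.approx(var, rel=0.02)


class TestLogOdds:
    def test_midpoint_with_flat_prior_is_ambiguous(self, spec_cls, cls_task):
        from priorpop.ideal_observer import DecodedLikelihood

        dec = DecodedLikelihood(mu_r=0.0, sigma_r2=1.0, total_count=10, informative=True)
        assert class_log_odds(dec, cls_task) == pytest.approx(0.0)

    def test_prior_counts_shift_by_log_ratio(self, spec_cls):
        from priorpop.ideal_observer import DecodedLikelihood

        dec = DecodedLikelihood(mu_r=0.0, sigma_r2=1.0, total_count=10, informative=True)
        task = TaskSpec.classification(prior=0.5)
        d = class_log_odds(dec, task, prior_counts=(300, 100))
        assert d == pytest.approx(np.log(3.0))

    def test_plug_in_arithmetic(self, cls_task):
        from priorpop.ideal_observer import DecodedLikelihood

        dec = DecodedLikelihood(mu_r=-5.0, sigma_r2=5.0, total_count=2, informative=True)
        # [2*(-5)*(-10) + 25 - 25] / [2*(5+25)] = 100/60
        assert class_log_odds(dec, cls_task) == pytest.approx(100.0 / 60.0)

    def test_monotone_decreasing_in_decoded_mean(self, cls_task):
        from priorpop.ideal_observer import DecodedLikelihood

        mus = np.linspace(-10, 10, 21)
        dec = DecodedLikelihood(
            mu_r=mus, sigma_r2=np.full_like(mus, 2.0),
            total_count=np.full(21, 5), informative=np.ones(21, bool),
        )
        d = class_log_odds(dec, cls_task)
        assert np.all(np.diff(d) < 0)

    def test_posterior_logistic_identities(self):
        assert posterior_class1(0.0) == 0.5
        assert posterior_class1(np.log(3.0)) == pytest.approx(0.75)
        assert posterior_class1(-2.3) == pytest.approx(1 - posterior_class1(2.3))
        assert posterior_class1(50.0) == pytest.approx(1.0)


class TestMAP:
    def test_equal_precision_averages_means(self):
        from priorpop.ideal_observer import DecodedLikelihood

        task = TaskSpec.estimation(prior_variance=10.0)
        dec = DecodedLikelihood(mu_r=10.0, sigma_r2=10.0, total_count=1, informative=True)
        assert map_estimate(dec, task) == pytest.approx(5.0)

    def test_flat_prior_limit_returns_decoded_mean(self):
        from priorpop.ideal_observer import DecodedLikelihood

        task = TaskSpec.estimation(prior_variance=1e12)
        dec = DecodedLikelihood(mu_r=7.3, sigma_r2=2.0, total_count=5, informative=True)
        assert map_estimate(dec, task) == pytest.approx(7.3, abs=1e-6)

    def test_agreeing_means_are_fixed_point(self):
        from priorpop.ideal_observer import DecodedLikelihood

        task = TaskSpec.estimation(prior_variance=3.0, prior_mean=2.0)
        dec = DecodedLikelihood(mu_r=2.0, sigma_r2=17.0, total_count=4, informative=True)
        assert map_estimate(dec, task) == pytest.approx(2.0)

    def test_zero_contrast_trials_fall_back_to_prior(self, spec_cls):
        task_e = TaskSpec.estimation(prior_variance=5.0, prior_mean=1.0)
        task_c = TaskSpec.classification(prior=0.67)
        r = np.zeros(50, dtype=int)
        dec = decode_likelihood(r, spec_cls)
        assert map_estimate(dec, task_e) == 1.0
        assert posterior_class1(class_log_odds(dec, task_c)) == pytest.approx(0.67)


class TestOracleEquivalence:
    """Closed forms vs brute-force grid integration (validates the log-odds
    algebra independently of any printed sign convention)."""

    def test_posterior_matches_grid_integration(self, spec_cls):
        rng = np.random.default_rng(1)
        task = TaskSpec.classification(prior=0.67)
        batch = sample_trials(task, spec_cls, 30, rng)
        dec = decode_likelihood_batch(batch.spikes, spec_cls)
        closed = np.asarray(posterior_class1(class_log_odds(dec, task)))
        for i in range(len(batch)):
            brute = grid_class_posterior(batch.spikes[i], task, spec_cls)
            assert abs(closed[i] - brute) < 1e-3

    def test_map_matches_grid_argmax(self, spec_est):
        rng = np.random.default_rng(2)
        task = TaskSpec.estimation(prior_variance=10.0)
        batch = sample_trials(task, spec_est, 30, rng, contrast=2.26)
        dec = decode_likelihood_batch(batch.spikes, spec_est)
        closed = np.asarray(map_estimate(dec, task))
        grid = default_grid(step=0.01)
        for i in range(len(batch)):
            brute = grid_map_estimate(batch.spikes[i], task, spec_est, grid)
            assert abs(closed[i] - brute) <= 0.011


class TestIdealAccuracy:
    def test_symmetric_prior_gives_equal_class_accuracy(self, spec_cls):
        task = TaskSpec.classification(prior=0.5)
        acc = ideal_accuracy(task, spec_cls, 2.6, 20_000, np.random.default_rng(3))
        se = 2 * np.sqrt(0.2 * 0.8 / 10_000)
        assert abs(acc[1] - acc[2]) < 2 * se

    def test_prior_shifts_accuracy_toward_likely_class(self, spec_cls):
        task = TaskSpec.classification(prior=0.75)
        acc = ideal_accuracy(task, spec_cls, 2.6, 20_000, np.random.default_rng(4))
        assert acc[1] > acc[2]

    def test_contrast_improves_overall_accuracy(self, spec_cls):
        task = TaskSpec.classification(prior=0.5)
        rng = np.random.default_rng(5)
        overall = []
        for c in (0.5, 4.0):
            acc = ideal_accuracy(task, spec_cls, c, 20_000, rng)
            overall.append(0.5 * (acc[1] + acc[2]))
        assert overall[1] > overall[0]
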