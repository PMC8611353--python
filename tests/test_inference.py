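"""Metropolis-Hastings machinery: priors, steps, tuning, chains."""

import numpy as np
import pytest

from spheroidfit.inference import (
    Chain,
    LogPosterior,
    PriorSpec,
    SolverSettings,
    autocorrelation,
    log_prior,
    map_estimate,
    metropolis_step,
    run_chain,
    tune_step_size,
)
from spheroidfit.kernels import ModelParams


@pytest.fixture(scope="module")
def std_normal_2d():
    """Toy target: correlated 2D Gaussian with known moments."""
    cov = np.array([[1.0, 0.6], [0.6, 1.0]])
    prec = np.linalg.inv(cov)

    def logp(x):
        return float(-0.5 * x @ prec @ x)

    return logp, cov


class TestLogPrior:
    priors = PriorSpec(medians=(1.04, 0.06, 0.1, 0.403))

    def test_value_at_medians(self):
        got = log_prior(self.priors.log_medians, self.priors)
        expect = -np.sum(np.log(np.sqrt(2 * np.pi) * np.array(self.priors.log_sds)))
        assert got == pytest.approx(expect, rel=1e-12)

    def test_one_sd_move_costs_half(self):
        theta = self.priors.log_medians.copy()
        base = log_prior(theta, self.priors)
        theta[0] += self.priors.log_sds[0]
        assert log_prior(theta, self.priors) == pytest.approx(base - 0.5, rel=1e-12)

    def test_alpha_coordinate_peaks_at_its_median(self):
        # V-79 prior proliferation rate 1.04: varying only log alpha, the
        # prior is maximal at log 1.04
        theta = self.priors.log_medians.copy()
        base = log_prior(theta, self.priors)
        for delta in (-0.3, 0.3):
            theta2 = theta.copy()
            theta2[0] = np.log(1.04) + delta
            assert log_prior(theta2, self.priors) < base


class TestMetropolisStep:
    def test_uphill_always_accepted(self):
        # any proposal with a higher posterior is accepted (ratio > 1)
        rng = np.random.default_rng(0)
        lp = -3.0
        for _ in range(50):
            new, new_lp, ok = metropolis_step(lambda x: lp + 1.0, np.zeros(2), lp, 0.5, rng)
            assert ok and new_lp == lp + 1.0

    def test_log_half_ratio_accepts_half_the_time(self):
        # fixed delta log-posterior of -log 2 -> acceptance probability 1/2
        rng = np.random.default_rng(42)
        n_acc = 0
        n = 4000
        for _ in range(n):
            _, _, ok = metropolis_step(lambda x: -np.log(2.0), np.zeros(1), 0.0, 1.0, rng)
            n_acc += ok
        assert n_acc / n == pytest.approx(0.5, abs=0.03)

    def test_1d_standard_normal_moments(self):
        logp = lambda x: float(-0.5 * x @ x)
        rng = np.random.default_rng(3)
        theta, lp = np.array([0.0]), 0.0
        draws = np.empty(100_000)
        for j in range(draws.size):
            theta, lp, _ = metropolis_step(logp, theta, lp, 2.0, rng)
            draws[j] = theta[0]
        assert draws.mean() == pytest.approx(0.0, abs=0.05)
        assert draws.var() == pytest.approx(1.0, abs=0.08)

    def test_nonpositive_step_rejected(self):
        with pytest.raises(ValueError):
            metropolis_step(lambda x: 0.0, np.zeros(1), 0.0, 0.0, np.random.default_rng())


class TestTuning:
    def test_toy_target_acceptance_in_band(self, std_normal_2d):
        logp, _ = std_normal_2d
        res = tune_step_size(logp, np.zeros(2), pilot_length=2000, seed=1)
        assert 0.18 <= res.acceptance <= 0.30

    def test_reproducible_under_seed(self, std_normal_2d):
        logp, _ = std_normal_2d
        a = tune_step_size(logp, np.zeros(2), pilot_length=1000, seed=9)
        b = tune_step_size(logp, np.zeros(2), pilot_length=1000, seed=9)
        assert a.step_size == b.step_size

    def test_larger_step_lowers_acceptance(self, std_normal_2d):
        logp, _ = std_normal_2d

        def rate(s, seed=4):
            rng = np.random.default_rng(seed)
            theta, lp = np.zeros(2), logp(np.zeros(2))
            acc = 0
            for _ in range(3000):
                theta, lp, ok = metropolis_step(logp, theta, lp, s, rng)
                acc += ok
            return acc / 3000

        assert rate(0.5) > rate(8.0) + 0.1

    def test_short_pilot_rejected(self, std_normal_2d):
        logp, _ = std_normal_2d
        with pytest.raises(ValueError):
            tune_step_size(logp, np.zeros(2), pilot_length=100)


class TestRunChain:
    def test_seed_determinism(self, std_normal_2d):
        logp, _ = std_normal_2d
        a = run_chain(logp, np.zeros(2), n_iter=1500, burn_in=100, seed=5, s=1.0)
        b = run_chain(logp, np.zeros(2), n_iter=1500, burn_in=100, seed=5, s=1.0)
        assert np.array_equal(a.draws, b.draws)
        assert np.array_equal(a.accepted, b.accepted)

    def test_burn_in_must_be_smaller(self, std_normal_2d):
        logp, _ = std_normal_2d
        with pytest.raises(ValueError):
            run_chain(logp, np.zeros(2), n_iter=100, burn_in=100, s=1.0)

    def test_acceptance_flags_match_distinct_draws(self, std_normal_2d):
        logp, _ = std_normal_2d
        ch = run_chain(logp, np.zeros(2), n_iter=2000, burn_in=100, seed=2, s=1.0)
        moved = np.any(ch.draws[1:] != ch.draws[:-1], axis=1)
        assert np.array_equal(moved, ch.accepted)

    def test_2d_gaussian_moments(self, std_normal_2d):
        logp, cov = std_normal_2d
        ch = run_chain(logp, np.zeros(2), n_iter=40_000, burn_in=2000, seed=11)
        post = ch.posterior_draws()
        assert np.abs(post.mean(axis=0)).max() < 0.06
        emp = np.cov(post.T)
        np.testing.assert_allclose(emp, cov, atol=0.12)
        assert 0.15 <= ch.acceptance_rate <= 0.35

    def test_checkpoint_resume_reproduces_chain(self, std_normal_2d, tmp_path):
        from spheroidfit.inference import resume_chain

        logp, _ = std_normal_2d
        full = run_chain(logp, np.zeros(2), n_iter=400, burn_in=50, seed=8, s=1.0)
        ck = tmp_path / "chain.npz"
        run_chain(
            logp, np.zeros(2), n_iter=200, burn_in=50, seed=8, s=1.0,
            checkpoint_path=ck, checkpoint_every=200,
        )
        resumed = resume_chain(ck, logp, n_iter=400)
        assert np.array_equal(resumed.draws, full.draws)

    def test_reparameterization_coherence(self, std_normal_2d):
        # sampling theta vs u = 2 theta with step variance x4 and
        # rescaled target gives exactly doubled draws under one seed
        logp, _ = std_normal_2d
        logp_u = lambda u: logp(u / 2.0)
        a = run_chain(logp, np.zeros(2), n_iter=500, burn_in=50, seed=13, s=0.8)
        b = run_chain(logp_u, np.zeros(2), n_iter=500, burn_in=50, seed=13, s=3.2)
        np.testing.assert_allclose(b.draws, 2.0 * a.draws, rtol=0, atol=1e-12)


class TestMapEstimate:
    def _chain(self, draws, lps):
        draws = np.asarray(draws, float)
        n = draws.shape[0] - 1
        return Chain(
            draws=draws,
            log_posteriors=np.asarray(lps, float),
            accepted=np.zeros(n, bool),
            step_size=1.0,
            seed=0,
            burn_in=0,
        )

    def test_single_repeated_draw(self):
        th = np.log([1.0, 0.06, 0.1, 0.4])
        ch = self._chain([th, th, th], [1.0, 1.0, 1.0])
        est = map_estimate(ch)
        np.testing.assert_allclose(est.as_log_array(), th)

    def test_picks_highest_posterior(self):
        a = np.log([1.0, 0.06, 0.1, 0.4])
        b = np.log([2.0, 0.05, 0.2, 0.3])
        ch = self._chain([a, b, a], [0.0, 5.0, 0.0])
        assert map_estimate(ch).alpha == pytest.approx(2.0)

    def test_polish_never_decreases_log_posterior(self):
        logp = lambda x: float(-np.sum((x - 1.0) ** 2))
        draws = np.array([[0.0, 0.0], [0.5, 0.5], [0.2, 0.9]])
        ch = self._chain(draws, [logp(d) for d in draws])
        raw = map_estimate(ch)
        polished = map_estimate(ch, log_post=logp, polish=True)
        assert logp(polished) >= logp(raw)

    def test_empty_post_burn_in_rejected(self):
        th = np.zeros((2, 4))
        ch = Chain(th, np.zeros(2), np.zeros(1, bool), 1.0, 0, 1)
        with pytest.raises(ValueError):
            map_estimate(ch)


class TestDiagnostics:
    def test_lag_zero_is_one(self, std_normal_2d):
        logp, _ = std_normal_2d
        ch = run_chain(logp, np.zeros(2), n_iter=2000, burn_in=100, seed=1, s=1.0)
        acf = autocorrelation(ch, max_lag=50)
        np.testing.assert_allclose(acf[0], 1.0)

    def test_white_noise_within_bands(self):
        rng = np.random.default_rng(21)
        n = 5000
        draws = rng.standard_normal((n + 1, 3))
        ch = Chain(draws, np.zeros(n + 1), np.ones(n, bool), 1.0, 0, 0)
        acf = autocorrelation(ch, max_lag=40)
        assert np.abs(acf[1:]).max() < 3.5 / np.sqrt(n)


class TestLogPosteriorSolverFailure:
    def test_absurd_parameters_give_minus_inf(self, v79_dataset, v79):
        ds, truth, solver = v79_dataset
        _, priors = v79
        post = LogPosterior(ds, priors, solver)
        # kernel radius beyond the domain -> rejected as -inf, not raised
        theta = np.log([1.0, 10.0, 0.1, 0.4])
        assert post(theta) == -np.inf
        assert post.n_failures >= 1

    def test_flat_prior_mode_equals_likelihood(self, v79_dataset, v79):
        ds, truth, solver = v79_dataset
        _, priors = v79
        from spheroidfit.observation import log_likelihood

        post = LogPosterior(ds, priors, solver, flat_prior=True)
        theta = truth.as_log_array()
        radii = post.model_radii(truth)
        assert post(theta) == pytest.approx(
            log_likelihood(ds, radii, truth.sigma_o), rel=1e-12
        )

    def test_deterministic_evaluations(self, v79_dataset, v79):
        ds, truth, solver = v79_dataset
        _, priors = v79
        post = LogPosterior(ds, priors, solver)
        theta = truth.as_log_array()
        assert post(theta) == post(theta)
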