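import numpy as np
import pytest
from scipy.stats import beta as beta_dist
from scipy.stats import kstest, logistic, norm

from occuprior import (
    CovariateMatrix,
    DetectionHistory,
    McmcConfig,
    PriorSpec,
    fit_bayes,
    gelman_rubin,
    posterior_mode,
    summarize,
    update_detection,
    update_latent_z,
    update_regression,
)

from oracles import quadrature_posterior

FAST = McmcConfig(n_iter=3000, burn_in=1000, n_chains=2, seed=5)


class TestUpdateLatentZ:
    def test_detected_sites_always_occupied(self):
        data = DetectionHistory([3, 1, 2], [5, 5, 5])
        rng = np.random.default_rng(0)
        for _ in range(20):
            z = update_latent_z(data, 0.5, 0.4, rng)
            assert np.all(z.z == 1)

    def test_p_zero_gives_prior_probability(self):
        # no information in non-detection when detection is impossible
        m = 40_000
        data = DetectionHistory(np.zeros(m, int), np.full(m, 10))
        rng = np.random.default_rng(1)
        z = update_latent_z(data, 0.37, 0.0, rng)
        se = np.sqrt(0.37 * 0.63 / m)
        assert abs(z.z.mean() - 0.37) < 3 * se

    def test_bayes_rule_oracle(self):
        # P(z=1 | y=0) = psi (1-p)^n / (psi (1-p)^n + 1 - psi)
        m = 40_000
        data = DetectionHistory(np.zeros(m, int), np.full(m, 10))
        rng = np.random.default_rng(2)
        z = update_latent_z(data, 0.9, 0.2, rng)
        want = 0.9 * 0.8**10 / (0.9 * 0.8**10 + 0.1)
        se = np.sqrt(want * (1 - want) / m)
        assert abs(z.z.mean() - want) < 3 * se


class TestUpdateDetection:
    def test_conjugate_beta_law(self):
        data = DetectionHistory([2], [10])
        rng = np.random.default_rng(3)
        draws = np.array(
            [update_detection(data, np.array([1]), rng) for _ in range(4000)]
        )
        # Beta(1+2, 1+8): mean 0.25
        assert abs(draws.mean() - 0.25) < 3 * draws.std(ddof=1) / np.sqrt(4000)
        assert kstest(draws, beta_dist(3, 9).cdf).pvalue > 0.01

    def test_no_occupied_sites_falls_back_to_prior(self):
        data = DetectionHistory([0, 0], [5, 5])
        rng = np.random.default_rng(4)
        draws = np.array(
            [update_detection(data, np.array([0, 0]), rng) for _ in range(4000)]
        )
        assert kstest(draws, "uniform").pvalue > 0.01


class TestUpdateRegression:
    def test_tiny_sigma_pins_intercept(self):
        data = DetectionHistory([0, 2, 1, 0], [5, 5, 5, 5])
        draws = fit_bayes(data, priors=PriorSpec("normal", 0, 1e-4), config=FAST)
        alpha = draws.pooled("alpha")
        assert abs(alpha.mean()) < 1e-3
        assert abs(draws.pooled("psi").mean() - 0.5) < 1e-3

    def test_prior_recovery_on_empty_data(self):
        # flat likelihood: the chain must sample the prior itself
        data = DetectionHistory([], [])
        cfg = McmcConfig(n_iter=24_000, burn_in=4_000, n_chains=2, seed=11)
        draws = fit_bayes(data, priors=PriorSpec("logistic", 0, 1), config=cfg)
        alpha = draws.pooled("alpha")[::20]  # thin to tame autocorrelation
        assert kstest(alpha, logistic(0, 1).cdf).pvalue > 0.01

    def test_acceptance_flags_shape(self):
        rng = np.random.default_rng(6)
        x = CovariateMatrix(rng.normal(size=(30, 2)))
        z = rng.integers(0, 2, 30)
        priors = [PriorSpec("normal", 0, 2)] * 3
        a, b, acc = update_regression(
            0.0, np.zeros(2), z, x, priors, rng, [0.5, 0.5, 0.5]
        )
        assert acc.shape == (3,)
        assert b.shape == (2,)

    def test_adapted_acceptance_rates_in_band(self):
        data = DetectionHistory(
            [0, 1, 2, 0, 3, 1, 0, 2, 1, 4], np.full(10, 10)
        )
        cfg = McmcConfig(n_iter=4000, burn_in=2000, n_chains=2, seed=9)
        draws = fit_bayes(data, priors=PriorSpec("normal", 0, 2), config=cfg)
        assert np.all(draws.acceptance_rates > 0.2)
        assert np.all(draws.acceptance_rates < 0.6)


class TestFitBayes:
    def test_quadrature_oracle_normal_prior(self, toy10):
        psi_mean, psi_med, p_mean, p_med = quadrature_posterior(
            toy10.y, toy10.n, lambda a: norm.logpdf(a, 0, 2)
        )
        draws = fit_bayes(
            toy10,
            priors=PriorSpec("normal", 0, 2),
            config=McmcConfig(n_iter=10_000, burn_in=5_000, n_chains=3, seed=3),
        )
        s, sp = draws.pooled("psi"), draws.pooled("p")
        assert abs(s.mean() - psi_mean) < 0.01
        assert abs(np.median(s) - psi_med) < 0.01
        assert abs(sp.mean() - p_mean) < 0.01
        assert abs(np.median(sp) - p_med) < 0.01

    def test_seeded_determinism(self, toy10):
        a = fit_bayes(toy10, priors=PriorSpec("logistic"), config=FAST)
        b = fit_bayes(toy10, priors=PriorSpec("logistic"), config=FAST)
        assert np.array_equal(a.draws, b.draws)

    def test_z_trace_respects_detections(self, toy10):
        cfg = McmcConfig(n_iter=600, burn_in=200, n_chains=2, seed=2, trace_z=True)
        draws = fit_bayes(toy10, priors=PriorSpec("logistic"), config=cfg)
        detected = toy10.y > 0
        assert draws.z_trace is not None
        assert np.all(draws.z_trace[:, :, detected] == 1)

    def test_probability_draws_bounded(self, toy10):
        draws = fit_bayes(toy10, priors=PriorSpec("cauchy", 0, 2.5), config=FAST)
        for name in ("p", "psi"):
            s = draws.pooled(name)
            assert np.all((s >= 0) & (s <= 1))

    def test_retained_length(self, toy10):
        draws = fit_bayes(toy10, config=FAST)
        assert draws.n_retained == FAST.n_iter - FAST.burn_in

    def test_jeffreys_with_covariates_rejected(self, toy10):
        x = CovariateMatrix(np.random.default_rng(0).normal(size=(10, 1)))
        with pytest.raises(ValueError, match="intercept-only"):
            fit_bayes(toy10, x, PriorSpec("jeffreys"), FAST)

    def test_covariate_model_runs_and_summarizes(self):
        from occuprior import OccupancyParams, SimulationConfig, simulate_dataset

        truth = OccupancyParams(0.8, 0.35, [1.0, -0.5])
        data, x, _ = simulate_dataset(
            SimulationConfig(200, 6, truth, n_covariates=2, seed=14)
        )
        draws = fit_bayes(data, x, PriorSpec("normal", 0, 2), FAST)
        summ = summarize(draws)
        names = set(summ.frame["parameter"])
        assert {"alpha", "beta_x1", "beta_x2", "p", "psi"} == names
        # coefficients should land in a broad band around the truth
        assert abs(summ["beta_x1"]["median"] - 1.0) < 0.8
        assert abs(summ["beta_x2"]["median"] + 0.5) < 0.8


class TestConfigValidation:
    def test_burn_in_bounds(self):
        with pytest.raises(ValueError):
            McmcConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            McmcConfig(n_iter=0, burn_in=0)


class TestGelmanRubin:
    def test_identical_chains_give_exactly_one(self):
        x = np.random.default_rng(0).normal(size=1000)
        stacked = np.vstack([x, x, x])
        assert gelman_rubin(stacked) == pytest.approx(1.0, abs=1e-12)

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = np.vstack([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        assert gelman_rubin(chains) > 1.5

    def test_well_mixed_sampler_converges(self, toy10):
        draws = fit_bayes(
            toy10,
            priors=PriorSpec("logistic"),
            config=McmcConfig(n_iter=4000, burn_in=2000, n_chains=3, seed=17),
        )
        rhat = gelman_rubin(draws)
        assert all(v < 1.1 for v in rhat.values())

    def test_single_chain_is_usage_error(self, toy10):
        draws = fit_bayes(
            toy10, config=McmcConfig(n_iter=300, burn_in=100, n_chains=1, seed=0)
        )
        with pytest.raises(ValueError, match="2 chains"):
            gelman_rubin(draws)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((2, 5)))


class TestPosteriorMode:
    def test_constant_sample(self):
        assert posterior_mode(np.full(500, 0.42)) == pytest.approx(0.42)

    def test_beta_closed_form(self):
        draws = beta_dist(20, 2).rvs(50_000, random_state=np.random.default_rng(8))
        assert abs(posterior_mode(draws, 0, 1) - 19 / 20) < 0.02

    def test_bimodal_returns_higher_density_mode(self):
        rng = np.random.default_rng(9)
        low = beta_dist(120, 80).rvs(12_000, random_state=rng)  # mode ~0.6
        high = beta_dist(600, 7).rvs(8_000, random_state=rng)  # mode ~0.99
        mode = posterior_mode(np.concatenate([low, high]), 0, 1)
        assert abs(mode - 0.99) < 0.03

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="run longer"):
            posterior_mode(np.linspace(0, 1, 50))


class TestSummarize:
    def test_symmetric_draws_median_matches_mode(self, toy10):
        rng = np.random.default_rng(10)
        draws = fit_bayes(toy10, priors=PriorSpec("normal", 0, 1), config=FAST)
        summ = summarize(draws)
        alpha = summ["alpha"]
        assert abs(alpha["median"] - alpha["mode"]) < 0.15

    def test_interval_is_quantile_pair(self, toy10):
        draws = fit_bayes(toy10, config=FAST)
        summ = summarize(draws)
        s = draws.pooled("psi")
        row = summ["psi"]
        assert row["ci_lo"] == pytest.approx(np.quantile(s, 0.025))
        assert row["ci_hi"] == pytest.approx(np.quantile(s, 0.975))
        assert row["ci_lo"] <= row["median"] <= row["ci_hi"]

    def test_unknown_parameter_raises(self, toy10):
        summ = summarize(fit_bayes(toy10, config=FAST))
        with pytest.raises(KeyError):
            summ["nope"]
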