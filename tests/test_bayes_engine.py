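import math

import numpy as np
import pytest
from scipy.integrate import quad, trapezoid
from scipy.special import logit

from discoverym import (
    DiscoveryMatrix,
    HeterogeneityParams,
    PriorSpec,
    SimulationSetting,
    estimate_m_matrix,
    heterogeneous_loglik,
    log_marginal_lik,
    posterior_mu_sigma,
    posterior_over_m,
    simulate_observed,
    truncate_zero_columns,
)


class TestPriors:
    def test_log_sigma_prior_is_a_density(self):
        prior = PriorSpec(nu=1.0)
        val, _ = quad(lambda x: math.exp(prior.log_prior_log_sigma(x)), -12, 25, limit=300)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_mu_prior_is_flat_at_scale(self):
        prior = PriorSpec()
        assert prior.log_prior_mu(0.0) == pytest.approx(prior.log_prior_mu(10.0), abs=1e-5)

    def test_resolve_m_default(self):
        assert PriorSpec().resolve_M(10) == 200
        assert PriorSpec().resolve_M(100) == 500
        assert PriorSpec(M=50).resolve_M(10) == 50
        with pytest.raises(ValueError):
            PriorSpec(M=5).resolve_M(10)


class TestMarginalLikelihood:
    def test_tiny_instance_matches_dense_brute_force(self, two_by_two):
        # independent oracle: plain trapezoid product rule over a wide
        # fixed (mu, log sigma) box, using the enumeration-validated
        # likelihood; no Laplace guidance, no adaptivity
        prior = PriorSpec()
        m = 3
        mus = np.linspace(-25.0, 12.0, 400)
        xs = np.linspace(-7.0, 6.0, 260)
        vals = np.empty((mus.size, xs.size))
        for a, mu in enumerate(mus):
            for b, x in enumerate(xs):
                vals[a, b] = math.exp(
                    heterogeneous_loglik(two_by_two, HeterogeneityParams(mu, math.exp(x)), m)
                    + float(prior.log_prior_mu(mu))
                    + float(prior.log_prior_log_sigma(x))
                )
        brute = math.log(trapezoid(trapezoid(vals, xs, axis=1), mus))
        assert log_marginal_lik(two_by_two, m, prior, backend="grid") == pytest.approx(
            brute, abs=0.02
        )

    def test_backends_agree_on_simulated_matrix(self):
        setting = SimulationSetting(m=12, mu=float(logit(0.2)), sigma=0.5, n=15, seed=7)
        d = simulate_observed(setting, 0)
        m = d.j + 3
        g = log_marginal_lik(d, m, backend="grid")
        mc = log_marginal_lik(d, m, backend="mc", seed=3)
        assert abs(g - mc) < 0.1

    def test_m_below_j_rejected(self, two_by_two):
        with pytest.raises(ValueError):
            log_marginal_lik(two_by_two, 1)


class TestPosterior:
    def test_hand_computed_homogeneous_diagnostic(self):
        # single participant, single detection, fixed p = 1/2:
        # P(d|m) = m * 0.5 * 0.5^(m-1), equal for m = 1 and m = 2
        d = DiscoveryMatrix([[1]])
        with pytest.warns(RuntimeWarning):
            post = posterior_over_m(d, prior=PriorSpec(M=2), fixed_p=0.5)
        assert post.probs == pytest.approx([0.5, 0.5])

    def test_normalization_and_support(self):
        setting = SimulationSetting(m=10, mu=float(logit(0.2)), sigma=0.5, n=12, seed=1)
        d = simulate_observed(setting, 0)
        post = posterior_over_m(d, prior=PriorSpec(M=60))
        assert post.probs.sum() == pytest.approx(1.0, abs=1e-10)
        assert (post.probs[: d.j - 1] == 0).all()
        assert d.j <= post.ci_low <= post.m_point <= post.ci_high <= post.M

    def test_invariant_under_row_and_column_permutations(self):
        rng = np.random.default_rng(5)
        setting = SimulationSetting(m=10, mu=float(logit(0.2)), sigma=0.5, n=12, seed=2)
        d = simulate_observed(setting, 0)
        post = posterior_over_m(d, prior=PriorSpec(M=50))
        d2 = truncate_zero_columns(
            d.cells[rng.permutation(d.n)][:, rng.permutation(d.j)]
        )
        post2 = posterior_over_m(d2, prior=PriorSpec(M=50))
        np.testing.assert_allclose(post.probs, post2.probs, atol=1e-9)

    def test_stable_when_m_upper_bound_grows(self):
        # n large enough that the posterior tail has died out well below
        # the first bound, so extending it is a no-op
        setting = SimulationSetting(m=10, mu=float(logit(0.2)), sigma=0.5, n=30, seed=3)
        d = simulate_observed(setting, 0)
        a = posterior_over_m(d, prior=PriorSpec(M=60))
        b = posterior_over_m(d, prior=PriorSpec(M=110))
        assert abs(a.m_point - b.m_point) <= 1
        assert abs(a.ci_low - b.ci_low) <= 1
        assert abs(a.ci_high - b.ci_high) <= 1

    def test_warns_when_m_too_small(self, worked_matrix):
        with pytest.warns(RuntimeWarning, match="too small"):
            post = posterior_over_m(worked_matrix, prior=PriorSpec(M=12))
        assert post.warnings

    def test_grid_backend_is_reproducible(self):
        setting = SimulationSetting(m=10, mu=float(logit(0.2)), sigma=0.5, n=30, seed=4)
        d = simulate_observed(setting, 0)
        a = posterior_over_m(d, prior=PriorSpec(M=50))
        b = posterior_over_m(d, prior=PriorSpec(M=50))
        assert (a.probs == b.probs).all()

    def test_estimate_result_wrapper(self, worked_matrix):
        res = estimate_m_matrix(worked_matrix, prior=PriorSpec(M=100))
        assert res.method == "matrix"
        assert worked_matrix.j <= res.ci_low <= res.m_hat <= res.ci_high


class TestMuSigmaPosterior:
    def test_recovery_at_moderate_size(self):
        setting = SimulationSetting(m=30, mu=float(logit(0.2)), sigma=0.5, n=50, seed=6)
        d = simulate_observed(setting, 0)
        ms = posterior_mu_sigma(d, prior=PriorSpec(M=150))
        assert ms["mu"]["q2.5"] <= setting.mu <= ms["mu"]["q97.5"]
        assert ms["sigma"]["q2.5"] <= 1.5  # truth 0.5 well inside the mass

    def test_homogeneous_truth_concentrates_sigma_near_zero(self):
        setting = SimulationSetting(m=25, mu=float(logit(0.3)), sigma=0.0, n=40, seed=7)
        d = simulate_observed(setting, 0)
        ms = posterior_mu_sigma(d, prior=PriorSpec(M=120))
        assert ms["sigma"]["median"] < 0.5

    def test_prior_dominates_with_minimal_data(self):
        # one participant, one detection: a tight prior on mu survives
        d = DiscoveryMatrix([[1]])
        ms = posterior_mu_sigma(d, prior=PriorSpec(A=0.01, M=5))
        assert abs(ms["mu"]["mean"]) < 0.2
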