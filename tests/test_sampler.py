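"""Reversible-jump sampler: closed forms, jump updates, chains."""

import numpy as np
import pytest

from bagol.data import LocalizationSet
from bagol.model import (ModelState, SamplerConfig, allocate_update,
                         birth_update, count_logpmf, death_update,
                         log_likelihood, move_conditional, move_update,
                         xi_update)
from bagol.sampler import run_chain

BOX = (-20.0, 20.0, -20.0, 20.0)


def single_emitter_locs(n, sigma, rng, center=(0.0, 0.0)):
    return LocalizationSet(rng.normal(center[0], sigma, n),
                           rng.normal(center[1], sigma, n),
                           np.full(n, sigma), np.full(n, sigma))


class TestLogLikelihood:
    def test_point_on_emitter_closed_form(self):
        locs = LocalizationSet([0.0], [0.0], [1.0], [1.0])
        state = ModelState(mu=[[0.0, 0.0]], a=[[0.0, 0.0]], Z=[0], xi=5.0)
        assert log_likelihood(state, locs) == pytest.approx(
            2 * np.log(1.0 / np.sqrt(2 * np.pi)))

    def test_doubling_sigma_shifts_by_gaussian_identity(self):
        locs1 = LocalizationSet([1.0], [2.0], [1.0], [1.0])
        locs2 = LocalizationSet([1.0], [2.0], [2.0], [2.0])
        state = ModelState(mu=[[0.0, 0.0]], a=[[0.0, 0.0]], Z=[0], xi=5.0)
        l1 = log_likelihood(state, locs1)
        l2 = log_likelihood(state, locs2)
        # residuals r: logL = -2 log(sigma) - |r|^2/(2 sigma^2) + const
        r2 = 1.0 + 4.0
        assert l2 - l1 == pytest.approx(-2 * np.log(2.0) + r2 / 2 - r2 / 8)

    def test_matches_independent_density_sum(self, tiny_locs):
        state = ModelState(mu=[[0.0, 0.0], [8.0, 0.0]], a=[[0.1, 0.0], [0.0, -0.2]],
                           Z=[0, 0, 1], xi=5.0)
        t = tiny_locs.t_normalized()
        expected = 0.0
        for i in range(3):
            k = state.Z[i]
            for v, mu, aa, s in ((tiny_locs.x[i], state.mu[k, 0], state.a[k, 0],
                                  tiny_locs.sigma_x[i]),
                                 (tiny_locs.y[i], state.mu[k, 1], state.a[k, 1],
                                  tiny_locs.sigma_y[i])):
                m = mu + aa * t[i]
                expected += (-0.5 * np.log(2 * np.pi * s ** 2)
                             - (v - m) ** 2 / (2 * s ** 2))
        assert log_likelihood(state, tiny_locs) == pytest.approx(expected)

    def test_invalid_allocation_raises(self, tiny_locs):
        state = ModelState(mu=[[0.0, 0.0]], a=[[0.0, 0.0]], Z=[0, 0, 5], xi=5.0)
        with pytest.raises(ValueError, match="nonexistent"):
            log_likelihood(state, tiny_locs)


class TestMoveConditional:
    def test_inverse_variance_formula(self):
        # two allocations at +-1 nm with sigma = 2 nm
        mean, cov = move_conditional([-1.0, 1.0], [0.25, 0.25], [0.0, 0.0],
                                     False, 10.0)
        assert mean[0] == pytest.approx(0.0, abs=1e-12)
        assert np.sqrt(cov[0, 0]) == pytest.approx(2.0 / np.sqrt(2), abs=1e-12)

    @pytest.mark.parametrize("n", [2, 5, 20, 100])
    def test_posterior_sd_scales_inverse_sqrt_n(self, n):
        sigma = 3.0
        mean, cov = move_conditional(np.zeros(n), np.full(n, sigma ** -2),
                                     np.zeros(n), False, 10.0)
        assert np.sqrt(cov[0, 0]) == pytest.approx(sigma / np.sqrt(n), abs=1e-12)

    def test_drift_posterior_equals_weighted_least_squares(self, rng):
        n = 60
        t = rng.uniform(0, 1, n)
        w = rng.uniform(0.2, 2.0, n)
        v = 3.0 + 2.5 * t  # exact line
        tau = 1e8  # effectively flat drift prior
        mean, cov = move_conditional(v, w, t, True, tau)
        X = np.column_stack([np.ones(n), t])
        beta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * v))
        np.testing.assert_allclose(mean, beta, atol=1e-8)
        assert mean[1] == pytest.approx(2.5, abs=1e-6)

    def test_kernel_and_reference_agree_to_1e10(self, rng):
        """Production move kernel must reproduce the closed-form conditional."""
        from bagol._kernels import run_chain_kernel  # compiled path exercised via chain

        n = 12
        sigma = 1.5
        locs = single_emitter_locs(n, sigma, rng)
        cfg = SamplerConfig(xi=n, xi_mode="fixed", n_samples=4000, n_burnin=100,
                            p_move=1.0, p_allocate=0.0, p_birth=0.0, p_death=0.0,
                            rng_seed=5)
        chain = run_chain(locs, cfg, box=BOX, init_positions=np.zeros((1, 2)))
        mean, cov = move_conditional(locs.x, 1.0 / locs.sigma_x ** 2,
                                     locs.t_normalized(), False, 10.0)
        mu_draws = chain.mu_x[:, 0]
        assert mu_draws.mean() == pytest.approx(mean[0], abs=4 * np.sqrt(cov[0, 0] / len(chain)))
        assert mu_draws.std(ddof=1) == pytest.approx(np.sqrt(cov[0, 0]), rel=0.1)


class TestJumpUpdates:
    def test_move_is_always_accepted_and_exact(self, rng):
        locs = single_emitter_locs(40, 2.0, rng)
        cfg = SamplerConfig(xi=40, xi_mode="fixed")
        state = ModelState(mu=[[5.0, -5.0]], a=[[0.0, 0.0]],
                           Z=np.zeros(40, dtype=int), xi=40.0)
        draws = np.array([move_update(state, locs, cfg, BOX,
                                      np.random.default_rng(s)).mu[0]
                          for s in range(300)])
        mean, cov = move_conditional(locs.x, 1.0 / locs.sigma_x ** 2,
                                     locs.t_normalized(), False, 10.0)
        assert draws[:, 0].mean() == pytest.approx(
            mean[0], abs=4 * np.sqrt(cov[0, 0] / 300))

    def test_single_component_allocation_trivially_accepted(self, rng, tiny_locs):
        cfg = SamplerConfig(xi=3, xi_mode="fixed")
        state = ModelState(mu=[[2.0, 0.0]], a=[[0.0, 0.0]], Z=[0, 0, 0], xi=3.0)
        new, accepted = allocate_update(state, tiny_locs, cfg,
                                        np.random.default_rng(0))
        assert accepted
        assert np.all(new.Z == 0)

    def test_well_separated_clusters_get_obvious_partition(self, cluster_factory):
        locs = cluster_factory([[0.0, 0.0], [200.0, 0.0]], 20, 1.0)
        cfg = SamplerConfig(xi=20, xi_mode="fixed")
        state = ModelState(mu=[[0.0, 0.0], [200.0, 0.0]],
                           a=np.zeros((2, 2)),
                           Z=np.zeros(40, dtype=int), xi=20.0)
        new, _ = allocate_update(state, locs, cfg, np.random.default_rng(1))
        assert np.all(new.Z[:20] == 0) and np.all(new.Z[20:] == 1)

    def test_coincident_emitters_allocation_follows_count_prior(self, rng):
        # With both emitters at the same position the likelihood is
        # allocation-independent, so long-run count fractions must follow
        # the exchangeable count prior; compare against enumeration of all
        # 2^N allocations.
        n = 6
        locs = single_emitter_locs(n, 1.0, rng)
        cfg = SamplerConfig(xi=3.0, xi_mode="fixed")
        state = ModelState(mu=[[0.0, 0.0], [0.0, 0.0]], a=np.zeros((2, 2)),
                           Z=np.zeros(n, dtype=int), xi=3.0)
        g = np.random.default_rng(2)
        counts = np.zeros(n + 1)
        for _ in range(4000):
            state, _ = allocate_update(state, locs, cfg, g)
            counts[int(np.sum(state.Z == 0))] += 1
        counts /= counts.sum()
        from scipy.special import comb, gammaln

        # P(n1) ~ C(n, n1) P(n1|lam) n1! P(n-n1|lam) (n-n1)! proportional
        lam = 3.0
        logw = [np.log(comb(n, k)) + k * np.log(lam) + (n - k) * np.log(lam)
                for k in range(n + 1)]
        w = np.exp(logw - np.max(logw))
        w /= w.sum()  # binomial(n, 1/2) after simplification
        np.testing.assert_allclose(counts, w, atol=0.05)

    def test_birth_of_far_emitter_rejected_under_poisson50(self, rng):
        locs = single_emitter_locs(50, 1.0, rng)
        cfg = SamplerConfig(xi=50.0, xi_mode="fixed", k_max=10)
        state = ModelState(mu=[[0.0, 0.0]], a=[[0.0, 0.0]],
                           Z=np.zeros(50, dtype=int), xi=50.0)
        g = np.random.default_rng(3)
        accepted = sum(birth_update(state, locs, cfg, BOX, g)[1]
                       for _ in range(200))
        assert accepted <= 4  # an empty far emitter costs e^-50 in the prior

    def test_death_from_k1_auto_rejected(self, rng, tiny_locs):
        cfg = SamplerConfig(xi=3, xi_mode="fixed")
        state = ModelState(mu=[[2.0, 0.0]], a=[[0.0, 0.0]], Z=[0, 0, 0], xi=3.0)
        new, accepted = death_update(state, tiny_locs, cfg, BOX,
                                     np.random.default_rng(4))
        assert not accepted and new.K == 1


class TestXiUpdate:
    def test_posterior_concentrates_at_conjugate_mean(self):
        cfg = SamplerConfig(xi_mode="hierarchical", xi_prior_eta=1.0,
                            xi_prior_gamma=50.0, xi_proposal_sd=0.05)
        counts = np.array([50, 48, 52, 50])
        state = ModelState(mu=np.zeros((4, 2)), a=np.zeros((4, 2)),
                           Z=np.repeat(np.arange(4), counts), xi=30.0)
        g = np.random.default_rng(5)
        lams = []
        for _ in range(4000):
            state, _ = xi_update(state, cfg, g)
            lams.append(state.xi)
        lams = np.array(lams[1000:])
        # conjugate Gamma(eta + sum n, rate eta/gamma + K)
        post_mean = (1.0 + counts.sum()) / (1.0 / 50.0 + 4)
        post_sd = np.sqrt(1.0 + counts.sum()) / (1.0 / 50.0 + 4)
        assert lams.mean() == pytest.approx(post_mean, abs=3 * post_sd / 10)

    def test_fixed_mode_never_changes_lambda(self, rng, tiny_locs):
        cfg = SamplerConfig(xi=7.0, xi_mode="fixed")
        chain = run_chain(tiny_locs, cfg, box=BOX)
        assert np.all(chain.xi == 7.0)

    def test_eta1_prior_is_exponential_with_mean_gamma(self):
        cfg = SamplerConfig(xi_mode="hierarchical", xi_prior_eta=1.0,
                            xi_prior_gamma=5.0)
        n = np.arange(0, 500)
        # marginal NB with eta=1 is geometric with mean gamma
        cfg2 = SamplerConfig(count_model="gamma_poisson", xi_mode="fixed",
                             xi_prior_eta=1.0, xi_prior_gamma=5.0)
        pmf = np.exp(count_logpmf(n, cfg2))
        assert pmf.sum() == pytest.approx(1.0, abs=1e-4)
        assert (n * pmf).sum() == pytest.approx(5.0, abs=0.05)


class TestRunChain:
    def test_single_tight_cluster_modal_k_one(self, rng):
        locs = single_emitter_locs(50, 1.0, rng)
        cfg = SamplerConfig(xi=50.0, xi_mode="fixed", n_samples=800, rng_seed=9)
        chain = run_chain(locs, cfg, box=BOX)
        assert chain.modal_K() == 1

    def test_two_separated_clusters_modal_k_two(self, cluster_factory):
        locs = cluster_factory([[0.0, 0.0], [30.0, 0.0]], 50, 1.5)
        cfg = SamplerConfig(xi=50.0, xi_mode="fixed", n_samples=800, rng_seed=9)
        chain = run_chain(locs, cfg, box=(-20, 50, -20, 20))
        assert chain.modal_K() == 2

    def test_same_seed_bit_identical(self, cluster_factory):
        locs = cluster_factory([[0.0, 0.0], [25.0, 5.0]], 30, 1.5)
        cfg = SamplerConfig(xi=30.0, xi_mode="fixed", n_samples=400, rng_seed=3)
        c1 = run_chain(locs, cfg, box=(-20, 45, -20, 25))
        c2 = run_chain(locs, cfg, box=(-20, 45, -20, 25))
        np.testing.assert_array_equal(c1.K, c2.K)
        np.testing.assert_array_equal(c1.mu_x, c2.mu_x)
        np.testing.assert_array_equal(c1.z_last, c2.z_last)

    def test_move_acceptance_rate_exactly_one(self, rng):
        locs = single_emitter_locs(30, 1.0, rng)
        cfg = SamplerConfig(xi=30.0, xi_mode="fixed", n_samples=500, rng_seed=2)
        chain = run_chain(locs, cfg, box=BOX)
        assert chain.acceptance_rate("move") == 1.0

    def test_translation_equivariance(self, cluster_factory):
        locs = cluster_factory([[0.0, 0.0], [20.0, 0.0]], 40, 1.5)
        shift = np.array([500.0, -300.0])
        shifted = LocalizationSet(locs.x + shift[0], locs.y + shift[1],
                                  locs.sigma_x, locs.sigma_y, locs.frame)
        cfg = SamplerConfig(xi=40.0, xi_mode="fixed", n_samples=400, rng_seed=8)
        box = (-15.0, 35.0, -15.0, 15.0)
        box_shifted = (box[0] + shift[0], box[1] + shift[0],
                       box[2] + shift[1], box[3] + shift[1])
        c1 = run_chain(locs, cfg, box=box)
        c2 = run_chain(shifted, cfg, box=box_shifted)
        np.testing.assert_array_equal(c1.K, c2.K)
        sel = c1.K == c1.modal_K()
        np.testing.assert_allclose(c2.mu_x[sel] - c1.mu_x[sel],
                                   np.where(c1.mu_x[sel] != 0, shift[0], 0),
                                   atol=1e-7)

    def test_empty_input_returns_k0_chain(self):
        locs = LocalizationSet(np.empty(0), np.empty(0), np.empty(0),
                               np.empty(0))
        cfg = SamplerConfig(xi=5.0, xi_mode="fixed", n_samples=100)
        chain = run_chain(locs, cfg)
        assert chain.modal_K() == 0 and len(chain) == 100

    def test_chain_hdf5_round_trip(self, cluster_factory, tmp_path):
        locs = cluster_factory([[0.0, 0.0]], 25, 1.0)
        cfg = SamplerConfig(xi=25.0, xi_mode="fixed", n_samples=200, rng_seed=1)
        chain = run_chain(locs, cfg, box=BOX)
        path = tmp_path / "chain.h5"
        chain.to_hdf5(path)
        from bagol.sampler import Chain

        back = Chain.from_hdf5(path)
        np.testing.assert_array_equal(back.K, chain.K)
        np.testing.assert_array_equal(back.counts, chain.counts)
        assert back.proposed == chain.proposed

    def test_engines_agree_on_toy_posterior(self, rng):
        locs = LocalizationSet([0.0, 1.5, 8.0], [0.0, 0.5, 0.2],
                               [1.0, 1.2, 0.9], [1.1, 1.0, 0.8])
        box = (-10.0, 18.0, -10.0, 10.0)
        freqs = {}
        for engine in ("numba", "python"):
            cfg = SamplerConfig(xi=2.0, xi_mode="fixed", n_samples=20000,
                                n_burnin=2000, rng_seed=11, k_max=6)
            ch = run_chain(locs, cfg, box=box, engine=engine,
                           init_positions=np.array([[2.0, 0.0]]))
            freqs[engine] = np.array([np.mean(ch.K == k) for k in (1, 2, 3)])
        np.testing.assert_allclose(freqs["numba"], freqs["python"], atol=0.05)
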