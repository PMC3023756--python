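import math

import numpy as np
import pytest
from scipy import stats

from cnvmix._kernels import pairwise_sq_diff, total_log_mixture
from cnvmix.gmrf import build_neighbor_graph, weights_from_field
from cnvmix.rjmcmc import (
    MixtureState,
    MoveStats,
    PriorConfig,
    allocation_log_probs,
    birth_log_acceptance,
    birth_log_acceptance_prior,
    birth_probability,
    death_log_acceptance,
    death_log_acceptance_prior,
    h_log_acceptance,
    interval_masses,
    log_prior_k,
    merge_components,
    run_chain,
    sample_truncated_normal,
    select_interval,
    tune_sigma_h,
    update_allocations,
    update_field,
    update_means_variances,
    _init_state,
    _iterate,
)
from cnvmix.simulator import ScenarioSpec, simulate

from conftest import dense_precision


def direct_log_mixture(state, y, cfg, act):
    """Dense oracle for the allocation-free mixture log-likelihood."""
    w = weights_from_field(state.x[:, act], cfg.phi)
    dens = stats.norm.pdf(y[:, None], loc=state.mu[act],
                          scale=np.sqrt(state.sigma2[act]))
    return float(np.sum(np.log(np.sum(w * dens, axis=1))))


class TestPriorOnK:
    def test_normalizes(self, prior_cfg):
        total = sum(math.exp(log_prior_k(k, prior_cfg)) for k in range(1, 8))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_poisson_pmf_ratio(self, prior_cfg):
        assert math.exp(log_prior_k(3, prior_cfg) - log_prior_k(2, prior_cfg)) \
            == pytest.approx(2.0 / 3.0)

    def test_direct_summation_oracle(self, prior_cfg):
        lam = prior_cfg.poisson_mean
        norm = sum(lam ** j / math.factorial(j) for j in range(1, 8))
        assert math.exp(log_prior_k(1, prior_cfg)) == pytest.approx(lam / norm)

    def test_out_of_range_rejected(self, prior_cfg):
        for k in (0, 8):
            with pytest.raises(ValueError):
                log_prior_k(k, prior_cfg)


class TestMoveProbabilities:
    def test_birth_probability_schedule(self, prior_cfg):
        assert birth_probability(1, prior_cfg) == 1.0
        assert birth_probability(7, prior_cfg) == 0.0
        assert birth_probability(4, prior_cfg) == 0.5

    @pytest.mark.parametrize("k", range(1, 7))
    def test_death_factor_is_reverse_of_birth_factor(self, prior_cfg, k):
        # Detailed balance of the dimension moves at the prior level.
        assert death_log_acceptance_prior(k + 1, prior_cfg) == pytest.approx(
            -birth_log_acceptance_prior(k, prior_cfg), abs=1e-12)


class TestKernels:
    def test_total_log_mixture_matches_dense_oracle(self, small_state):
        state, y, cfg = small_state
        act = state.active_indices()
        got = total_log_mixture(state.x, act, y, state.mu[act].copy(),
                                state.sigma2[act].copy(), cfg.phi)
        assert got == pytest.approx(direct_log_mixture(state, y, cfg, act),
                                    abs=1e-9)

    @pytest.mark.parametrize("n,nb", [(5, 1), (8, 3), (10, 4)])
    def test_pairwise_sq_diff_is_laplacian_quadratic_form(self, rng, n, nb):
        g = build_neighbor_graph(n, nb)
        x = np.zeros((n, 7))
        act = np.array([1, 4], dtype=np.int64)
        x[:, act] = rng.normal(size=(n, 2))
        q = g.laplacian()
        expected = sum(x[:, c] @ q @ x[:, c] for c in act)
        assert pairwise_sq_diff(x, act, nb) == pytest.approx(expected, abs=1e-9)


class TestDimensionMoves:
    def test_birth_log_acceptance_matches_direct_ratio(self, small_state, rng):
        state, y, cfg = small_state
        j, mu_new, s2_new = 1, -0.4, 0.05
        xcol = rng.normal(size=state.n)
        act_old = state.active_indices()
        ll_old = direct_log_mixture(state, y, cfg, act_old)
        ref = state.copy()
        ref.x[:, j] = xcol
        ref.mu[j] = mu_new
        ref.sigma2[j] = s2_new
        ll_new = direct_log_mixture(ref, y, cfg, np.sort(np.append(act_old, j)))
        expected = birth_log_acceptance_prior(state.k, cfg) + ll_new - ll_old
        got = birth_log_acceptance(state, y, cfg, j, mu_new, s2_new, xcol)
        assert got == pytest.approx(expected, abs=1e-9)
        # the helper must leave the field column untouched when not committing
        assert np.all(state.x[:, j] == 0.0)

    def test_death_is_exact_reverse_of_birth(self, small_state, rng):
        state, y, cfg = small_state
        j, mu_new, s2_new = 5, 0.8, 0.03
        xcol = rng.normal(size=state.n)
        forward = birth_log_acceptance(state, y, cfg, j, mu_new, s2_new, xcol)
        grown = state.copy()
        grown.active[j] = True
        grown.mu[j] = mu_new
        grown.sigma2[j] = s2_new
        grown.x[:, j] = xcol
        backward = death_log_acceptance(grown, y, cfg, j)
        assert backward == pytest.approx(-forward, abs=1e-9)

    def test_zero_weight_component_leaves_likelihood_unchanged(self, small_state):
        state, y, cfg = small_state
        # A field column far below the active ones gets softmax weight ~0,
        # so only the prior/proposal factor remains.
        xcol = np.full(state.n, -30.0)
        got = birth_log_acceptance(state, y, cfg, 4, 0.55, 0.02, xcol)
        assert got == pytest.approx(birth_log_acceptance_prior(state.k, cfg),
                                    abs=1e-6)


class TestFieldUpdate:
    def test_prior_sweeps_reproduce_gmrf_moments(self):
        # With the data term off the sweep is a sequential Gibbs sampler of
        # the field prior N(0, (I + hQ)^-1).
        n, nb, h = 6, 1, 2.0
        cfg = PriorConfig(nb=nb)
        g = build_neighbor_graph(n, nb)
        rng = np.random.default_rng(99)
        state = _init_state(np.zeros(n), cfg, rng, init_h=h, data_on=False)
        stats_ = MoveStats()
        draws = []
        for it in range(9000):
            update_field(state, np.zeros(n), cfg, g, rng, stats_, data_on=False)
            if it >= 500:
                draws.append(state.x[:, 2].copy())
        assert stats_.rate("field") == 1.0
        cov = np.cov(np.array(draws).T)
        assert np.allclose(cov, np.linalg.inv(dense_precision(g, h)), atol=0.08)

    def test_data_sweep_is_deterministic_given_rng(self, small_state):
        state, y, cfg = small_state
        g = build_neighbor_graph(state.n, cfg.nb)
        a = state.copy()
        b = state.copy()
        update_field(a, y, cfg, g, np.random.default_rng(7), MoveStats())
        update_field(b, y, cfg, g, np.random.default_rng(7), MoveStats())
        assert np.array_equal(a.x, b.x)


class TestHUpdate:
    def test_acceptance_matches_dense_determinant_oracle(self, prior_cfg):
        # With flat fields the roughness term vanishes and the ratio is the
        # k-th power of the normalizing constants plus truncation correction.
        n, nb = 6, 2
        cfg = PriorConfig(nb=nb, h_max=100.0)
        g = build_neighbor_graph(n, nb)
        h_old, h_new, k, sigma_h = 3.0, 7.5, 3, 2.0
        got = h_log_acceptance(h_old, h_new, k, 0.0, sigma_h, cfg, g)

        def log_c(h):
            sign, logdet = np.linalg.slogdet(
                2 * np.pi * np.linalg.inv(dense_precision(g, h)))
            return -0.5 * logdet

        num = stats.norm.cdf((cfg.h_max - h_old) / sigma_h) \
            - stats.norm.cdf(-h_old / sigma_h)
        den = stats.norm.cdf((cfg.h_max - h_new) / sigma_h) \
            - stats.norm.cdf(-h_new / sigma_h)
        expected = k * (log_c(h_new) - log_c(h_old)) + np.log(num / den)
        assert got == pytest.approx(expected, abs=1e-8)

    def test_truncation_correction_vanishes_far_from_bounds(self):
        cfg = PriorConfig(h_max=1e9)
        g = build_neighbor_graph(5, 1)
        sym = h_log_acceptance(5000.0, 5001.0, 2, 0.0, 1.0, cfg, g)
        ref = 2 * 0.5 * np.sum(np.log1p(5001.0 * g.laplacian_eigenvalues)
                               - np.log1p(5000.0 * g.laplacian_eigenvalues))
        assert sym == pytest.approx(ref, abs=1e-9)

    def test_sigma_h_adaptation_rules(self):
        for acc, factor in ((9, 1.25), (5, 1.0), (1, 0.8)):
            st_ = MoveStats(sigma_h=2.0, h_window_proposed=10,
                            h_window_accepted=acc)
            assert tune_sigma_h(st_) == pytest.approx(2.0 * factor)
            assert st_.h_window_proposed == 0


class TestAllocations:
    def test_log_probs_match_direct_normalization(self, small_state):
        state, y, cfg = small_state
        act, logits = allocation_log_probs(state, y, cfg)
        probs = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs /= probs.sum(axis=1, keepdims=True)
        w = weights_from_field(state.x[:, act], cfg.phi)
        dens = stats.norm.pdf(y[:, None], loc=state.mu[act],
                              scale=np.sqrt(state.sigma2[act]))
        direct = w * dens
        direct /= direct.sum(axis=1, keepdims=True)
        assert np.allclose(probs, direct, atol=1e-12)

    def test_indicator_weights_force_allocation(self, small_state):
        state, y, cfg = small_state
        state.x[:, 2] = 50.0  # overwhelming weight on the diploid class
        state.x[:, 3] = -50.0
        update_allocations(state, y, cfg, np.random.default_rng(0))
        assert np.all(state.z == 2)

    def test_symmetric_case_is_uniform(self):
        cfg = PriorConfig()
        n = 2000
        state = MixtureState(
            active=np.array([False, True, False, True, False, False, False]),
            mu=np.array([0, -1.0, 0, 1.0, 0, 0, 0.0]),
            sigma2=np.full(7, 0.5), x=np.zeros((n, 7)),
            z=np.full(n, 1, dtype=np.int64), h=0.0)
        update_allocations(state, np.zeros(n), cfg, np.random.default_rng(3))
        frac = np.mean(state.z == 1)
        assert frac == pytest.approx(0.5, abs=0.03)


class TestMeansVariances:
    def test_interval_masses_are_cdf_differences(self, classes):
        mean, sd = 0.21, 0.12
        masses = interval_masses(mean, sd, classes)
        expected = [stats.norm.cdf(c.upper, mean, sd)
                    - stats.norm.cdf(c.lower, mean, sd) for c in classes]
        assert np.allclose(masses, expected, atol=1e-12)
        assert select_interval(mean, sd, classes) == int(np.argmax(expected))

    def test_select_interval_survives_extreme_tail(self, classes):
        # posterior mass underflows everywhere; nearest interval wins
        assert select_interval(0.425, 1e-9, classes) in (3, 4)

    def test_truncated_normal_sampler_against_scipy(self, rng):
        mean, sd, lo, hi = 0.3, 0.15, 0.15, 0.4
        draws = np.array([sample_truncated_normal(mean, sd, lo, hi, rng)
                          for _ in range(2000)])
        assert np.all((draws > lo) & (draws < hi))
        a, b = (lo - mean) / sd, (hi - mean) / sd
        ks = stats.kstest(draws, stats.truncnorm(a, b, loc=mean, scale=sd).cdf)
        assert ks.pvalue > 1e-3

    def test_concentrated_data_pins_mean_in_its_interval(self, small_state):
        state, _, cfg = small_state
        y = np.full(state.n, 0.3)
        state.z[:] = 3
        state.sigma2[3] = 1e-6
        update_means_variances(state, y, cfg, np.random.default_rng(1),
                               MoveStats())
        assert 3 in state.active_indices()
        assert state.mu[3] == pytest.approx(0.3, abs=0.02)

    def test_empty_component_draws_from_prior(self, small_state):
        state, _, cfg = small_state
        # null data keep the diploid component in place; class 3 is empty
        y = np.zeros(state.n)
        state.z[:] = 2
        mus, s2s = [], []
        for seed in range(200):
            s = state.copy()
            update_means_variances(s, y, cfg, np.random.default_rng(seed),
                                   MoveStats())
            mus.append(s.mu[3])
            s2s.append(s.sigma2[3])
        cls = cfg.classes[3]
        assert np.all((np.array(mus) > cls.lower) & (np.array(mus) < cls.upper))
        # prior uniform has mean at the interval midpoint
        assert np.mean(mus) == pytest.approx(cls.midpoint, abs=0.02)
        assert np.all(np.array(s2s) > 0)


class TestMerge:
    def _two_in_one_interval(self, cfg, n=40):
        state = MixtureState(
            active=np.array([False, False, True, True, True, False, False]),
            mu=np.array([0, 0, 0.0, 0.3, 0.4, 0, 0.0]),
            sigma2=np.array([1, 1, 0.02, 0.02, 0.08, 1, 1.0]),
            x=np.zeros((n, 7)), z=np.zeros(n, dtype=np.int64), h=1.0)
        # mu of the class-4 component has wandered into the CN=3 interval
        state.x[:, 3] = 1.0
        state.x[:, 4] = -1.0
        state.z[:10] = 3
        state.z[10:] = 4
        state.z[10:] = np.where(np.arange(30) < 30, 4, 4)
        return state

    def test_sample_size_weighted_average(self, prior_cfg):
        state = self._two_in_one_interval(prior_cfg)
        n_total = len(state.z)
        merged = merge_components(state, prior_cfg)
        assert merged == 1
        act = state.active_indices()
        assert 4 not in act and 3 in act
        # (10*0.3 + 30*0.4) / 40
        assert state.mu[3] == pytest.approx(0.375)
        sigma = (10 * np.sqrt(0.02) + 30 * np.sqrt(0.08)) / 40
        assert state.sigma2[3] == pytest.approx(sigma ** 2)
        assert np.allclose(state.x[:, 3], (10 * 1.0 + 30 * -1.0) / 40)
        # allocations redirected, none orphaned
        assert np.sum(state.z == 3) == 30 + 10 - np.sum(state.z == 0)
        assert len(state.z) == n_total
        assert np.all(np.isin(state.z, act))

    def test_empty_components_merge_with_equal_weights(self, prior_cfg):
        state = self._two_in_one_interval(prior_cfg)
        state.z[:] = 2  # both merging components empty
        merge_components(state, prior_cfg)
        assert state.mu[3] == pytest.approx(0.35)  # (0.3 + 0.4) / 2

    def test_distinct_intervals_are_untouched(self, small_state, prior_cfg):
        state, _, _ = small_state
        before = state.copy()
        assert merge_components(state, prior_cfg) == 0
        assert np.array_equal(before.mu, state.mu)
        assert np.array_equal(before.active, state.active)


class TestChain:
    def test_identical_seeds_are_bit_identical(self):
        spec = ScenarioSpec(segments=((2, 20), (3, 15), (2, 25)), sd=0.1)
        track, _ = simulate(spec, 42)
        a = run_chain(track, None, 300, 300, seed=9)
        b = run_chain(track, None, 300, 300, seed=9)
        assert np.array_equal(a.omega_bar, b.omega_bar)
        assert np.array_equal(a.calls, b.calls)
        assert np.array_equal(a.h_trace, b.h_trace)

    def test_invariants_hold_through_iterations(self, prior_cfg):
        spec = ScenarioSpec(segments=((2, 15), (1, 10), (2, 15), (3, 10)), sd=0.15)
        track, _ = simulate(spec, 7)
        y = track.y
        g = build_neighbor_graph(len(y), prior_cfg.nb)
        rng = np.random.default_rng(11)
        state = _init_state(y, prior_cfg, rng, init_h=10.0, data_on=True)
        stats_ = MoveStats()
        for _ in range(150):
            _iterate(state, y, prior_cfg, g, rng, stats_, data_on=True)
            state.check_invariants(prior_cfg)
            assert len(state.z) == len(y)  # allocation conservation

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            run_chain(np.array([0.1, np.nan, 0.2]), None, 10, 10, seed=0)
        with pytest.raises(ValueError):
            run_chain(np.array([0.1]), None, 10, 10, seed=0)
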