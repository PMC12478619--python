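"""PL-MoMS sampler: proposals, adaptation, invariants, directional checks."""

import numpy as np
import pytest

from ordmrf.model import ModelParams, OrdinalData, gibbs_simulate
from ordmrf.priors import PriorSpec
from ordmrf.sampler import (
    ChainState,
    adapt_proposal_sd,
    run_pl_moms,
    threshold_proposal_params,
    update_active_interactions,
)


@pytest.fixture()
def chain_state(small_data):
    return ChainState(small_data, PriorSpec())


class TestThresholdProposal:
    def test_tail_slopes_sum_to_n_plus_alpha_beta(self, small_data):
        prior = PriorSpec(threshold_alpha=1.5, threshold_beta=0.8)
        state = ChainState(small_data, prior)
        for i in range(small_data.p):
            for h in range(1, small_data.n_categories[i]):
                p_t, q_t, c = threshold_proposal_params(i, h, state)
                assert p_t + q_t == pytest.approx(
                    small_data.n + prior.threshold_alpha + prior.threshold_beta
                )
                assert c > 0

    def test_c_matches_numerical_derivative(self, small_data):
        """The analytic derivative behind c agrees with a finite difference."""
        prior = PriorSpec()
        state = ChainState(small_data, prior)
        i, h = 0, 1
        p_t, q_t, c = threshold_proposal_params(i, h, state)

        def log_target(value):
            from ordmrf.priors import log_threshold_prior

            mu = state.mu[i].copy()
            mu[h] = value
            lse = state._lse(state._logits(i, state.rest[i], mu))
            n_ih = float(state.counts[i][h])
            return value * n_ih - float(lse.sum()) + log_threshold_prior(
                value, prior
            )

        mu0 = state.mu[i][h]
        eps = 1e-6
        deriv_fd = (log_target(mu0 + eps) - log_target(mu0 - eps)) / (2 * eps)
        # invert the c formula to the derivative it encodes
        u = c * np.exp(mu0) / (1.0 + c * np.exp(mu0))
        deriv_from_c = p_t - (p_t + q_t) * u
        assert deriv_from_c == pytest.approx(deriv_fd, abs=1e-4)

    def test_mode_matching_for_symmetric_target(self):
        """Symmetric counts at the target mode give a proposal with mode there."""
        values = np.repeat([[0], [1]], 25, axis=0)
        data = OrdinalData(values, np.array([2]))
        state = ChainState(data, PriorSpec())
        state.mu[0][1] = 0.0  # target mode: n_1 = n/2, alpha = beta
        p_t, q_t, c = threshold_proposal_params(0, 1, state)
        # proposal mode: log(p_t / q_t) - log c = 0
        assert np.log(p_t / q_t) - np.log(c) == pytest.approx(0.0, abs=1e-10)

    def test_sampled_thresholds_match_quadrature_posterior(self):
        """Long-run Block I histogram vs the 1-D normalized target (p=1)."""
        rng = np.random.default_rng(0)
        values = (rng.random(50) < 0.6).astype(int)[:, None]
        data = OrdinalData(values, np.array([2]))
        samples = run_pl_moms(
            data, PriorSpec(), n_iter=22_000, burnin=2_000, seed=1
        )
        draws = np.sort(samples.thresholds[:, 0])
        n1, n = int(values.sum()), values.size
        grid = np.linspace(-4, 4, 4001)
        logf = grid * (n1 + 1) - (n + 2) * np.logaddexp(0, grid)
        f = np.exp(logf - logf.max())
        f /= np.trapezoid(f, grid)
        cdf = np.cumsum(f) * (grid[1] - grid[0])
        emp = np.searchsorted(draws, grid) / draws.size
        assert np.abs(emp - cdf).max() < 0.02


class TestAdaptation:
    def test_all_rejections_shrink_sd_monotonically(self, chain_state):
        chain_state.adapting = True
        last = chain_state.prop_sd[0]
        for _ in range(50):
            new = adapt_proposal_sd(chain_state, 0, accepted=False)
            assert new < last or new == pytest.approx(1e-3)
            last = new

    def test_acceptances_grow_sd(self, chain_state):
        chain_state.adapting = True
        before = chain_state.prop_sd[1]
        adapt_proposal_sd(chain_state, 1, accepted=True)
        assert chain_state.prop_sd[1] > before

    def test_frozen_outside_adaptation_phase(self, chain_state):
        chain_state.adapting = False
        before = chain_state.prop_sd[2]
        adapt_proposal_sd(chain_state, 2, accepted=False)
        assert chain_state.prop_sd[2] == before

    def test_calibrates_to_target_rate_on_normal_target(self, small_data):
        """Self-contained RW-Metropolis on N(0,1) reaches 0.44 ± 0.05."""
        state = ChainState(small_data, PriorSpec())
        state.adapting = True
        rng = np.random.default_rng(99)
        x = 0.0
        accepted = []
        for t in range(5000):
            prop = x + rng.normal(0.0, state.prop_sd[0])
            acc = np.log(rng.random()) < 0.5 * (x**2 - prop**2)
            if acc:
                x = prop
            adapt_proposal_sd(state, 0, bool(acc))
            accepted.append(acc)
        assert np.mean(accepted[-2000:]) == pytest.approx(0.44, abs=0.05)


class TestRunPlMoms:
    def test_identical_seed_identical_traces(self, small_data):
        a = run_pl_moms(small_data, PriorSpec(), n_iter=300, burnin=100, seed=5)
        b = run_pl_moms(small_data, PriorSpec(), n_iter=300, burnin=100, seed=5)
        np.testing.assert_array_equal(a.gamma, b.gamma)
        np.testing.assert_array_equal(a.interactions, b.interactions)
        np.testing.assert_array_equal(a.thresholds, b.thresholds)

    def test_moms_coupling_invariant(self, small_data):
        s = run_pl_moms(small_data, PriorSpec(), n_iter=500, burnin=100, seed=6)
        np.testing.assert_array_equal(
            s.interactions != 0.0, s.gamma.astype(bool)
        )

    def test_zero_variance_column_is_hard_error(self):
        values = np.array([[0, 1], [0, 0], [0, 1], [0, 1]])
        data = OrdinalData(values, np.array([2, 2]))
        with pytest.raises(ValueError, match="zero variance"):
            run_pl_moms(data, PriorSpec(), n_iter=10, burnin=1)

    def test_trace_shapes_and_thinning(self, small_data):
        s = run_pl_moms(
            small_data, PriorSpec(), n_iter=450, burnin=150, thin=3, seed=2
        )
        assert s.n_draws == 100
        assert s.interactions.shape == (100, 3)
        assert s.thresholds.shape == (100, sum(small_data.n_categories - 1))
        assert sum(s.visited_structures.values()) == 100

    def test_random_scan_order_also_valid(self, small_data):
        s = run_pl_moms(
            small_data, PriorSpec(), n_iter=300, burnin=100, seed=3,
            scan_order="random",
        )
        np.testing.assert_array_equal(
            s.interactions != 0.0, s.gamma.astype(bool)
        )

    def test_strong_edge_detected_absent_edges_not(self):
        """3-variable toy: the generating edge wins, the null edges lose."""
        params = ModelParams(
            [np.array([0.0, 0.0])] * 3,
            np.array([[0.0, 2.0, 0.0], [2.0, 0.0, 0.0], [0.0, 0.0, 0.0]]),
        )
        data = gibbs_simulate(params, 500, sweeps=100, seed=21)
        s = run_pl_moms(data, PriorSpec(), n_iter=20_000, burnin=1_000, seed=22)
        incl = s.gamma.mean(axis=0)  # pairs (0,1), (0,2), (1,2)
        assert incl[0] > 0.95
        assert incl[1] < 0.5
        assert incl[2] < 0.5

    def test_prior_sampling_with_likelihood_off(self, small_data):
        """With the likelihood term switched off, γ marginals hit the prior."""
        s = run_pl_moms(
            small_data,
            PriorSpec(),
            n_iter=32_000,
            burnin=2_000,
            seed=8,
            likelihood_scale=0.0,
            update_thresholds=False,
        )
        incl = s.gamma.mean(axis=0)
        np.testing.assert_allclose(incl, 0.5, atol=0.01)


def test_active_interaction_update_noop_without_edges(small_data):
    state = ChainState(small_data, PriorSpec())
    rng = np.random.default_rng(0)
    sigma_before = state.sigma.copy()
    n_acc = update_active_interactions(state, rng)
    assert n_acc == 0
    np.testing.assert_array_equal(state.sigma, sigma_before)
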