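"""Core ordinal-MRF model: joint, conditionals, pseudolikelihood, simulator."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chisquare

from ordmrf.model import (
    ModelParams,
    OrdinalData,
    enumerate_joint,
    full_conditional,
    gibbs_simulate,
    log_pseudolikelihood,
    log_unnormalized_joint,
    mu_from_marginals,
    normalizing_constant,
    pair_prob_table,
    sigma_from_pair_probs,
    sufficient_stats,
)

from conftest import random_params


def brute_force_log_joint(x, params):
    """Independently coded double-loop oracle for the unnormalized log joint."""
    total = 0.0
    for i, xi in enumerate(x):
        total += params.thresholds[i][xi]
    p = len(x)
    for i in range(p):
        for j in range(i + 1, p):
            total += params.interactions[i, j] * x[i] * x[j]
    return total


class TestLogUnnormalizedJoint:
    def test_all_zero_pattern_is_zero(self, rng):
        params = random_params(rng, [3, 4, 2])
        assert log_unnormalized_joint([0, 0, 0], params) == 0.0

    def test_two_variable_hand_sum(self):
        params = ModelParams(
            [np.array([0.0, 0.5]), np.array([0.0, -0.5])],
            np.array([[0.0, 1.0], [1.0, 0.0]]),
        )
        assert log_unnormalized_joint([1, 1], params) == pytest.approx(1.0)

    def test_matches_double_loop_oracle(self, rng):
        params = random_params(rng, [3, 3, 3])
        for _ in range(20):
            x = rng.integers(0, 3, size=3)
            assert log_unnormalized_joint(x, params) == pytest.approx(
                brute_force_log_joint(x, params), abs=1e-12
            )

    def test_out_of_range_category_rejected(self, rng):
        params = random_params(rng, [3, 3])
        with pytest.raises(ValueError):
            log_unnormalized_joint([3, 0], params)


class TestNormalizingConstant:
    def test_null_model_counts_patterns(self):
        params = ModelParams.zeros([5] * 10)
        assert normalizing_constant(params) == pytest.approx(5**10)

    def test_single_variable_closed_form(self):
        a, b = 0.7, -1.1
        params = ModelParams([np.array([0.0, a, b])], np.zeros((1, 1)))
        assert normalizing_constant(params) == pytest.approx(
            1 + np.exp(a) + np.exp(b)
        )

    def test_probabilities_normalize(self, rng):
        params = random_params(rng, [3, 3, 3])
        z = normalizing_constant(params)
        total = 0.0
        for x in itertools.product(range(3), repeat=3):
            total += np.exp(log_unnormalized_joint(list(x), params) - np.log(z))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_state_space_guard(self):
        params = ModelParams.zeros([5] * 10)
        with pytest.raises(ValueError, match="9765625"):
            normalizing_constant(params, state_limit=1000)


class TestFullConditional:
    def test_null_model_is_uniform(self):
        params = ModelParams.zeros([4, 4])
        probs = full_conditional(0, [0, 2], params)
        np.testing.assert_allclose(probs, 0.25)

    def test_matches_enumerated_conditional(self, rng):
        params = random_params(rng, [3, 3])
        states, probs = enumerate_joint(params)
        for x1 in range(3):
            cond = full_conditional(0, [0, x1], params)
            mask = states[:, 1] == x1
            expected = probs[mask] / probs[mask].sum()
            order = np.argsort(states[mask][:, 0])
            np.testing.assert_allclose(cond, expected[order], atol=1e-12)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 10**6))
    def test_sums_to_one(self, seed):
        rng = np.random.default_rng(seed)
        params = random_params(rng, rng.integers(2, 5, size=3))
        x = [int(rng.integers(0, mi)) for mi in params.n_categories]
        probs = full_conditional(1, x, params)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert (probs >= 0).all()

    def test_markov_property_drops_disconnected_variable(self, rng):
        # sigma_{02} = 0: the conditional of variable 0 ignores x_2 exactly
        thresholds = [np.array([0.0, 0.4, -0.3])] * 3
        sigma = np.zeros((3, 3))
        sigma[0, 1] = sigma[1, 0] = 0.8
        params = ModelParams(thresholds, sigma)
        for x2 in range(3):
            np.testing.assert_array_equal(
                full_conditional(0, [0, 1, x2], params),
                full_conditional(0, [0, 1, 0], params),
            )


class TestIsingReduction:
    def test_binary_model_equals_ising_energy(self, rng):
        """With m_i = 2 and 0/1 scores the joint is the Ising energy."""

        def ising_energy(s, fields, couplings):
            e = float(fields @ s)
            p = s.size
            for i in range(p):
                for j in range(i + 1, p):
                    e += couplings[i, j] * s[i] * s[j]
            return e

        params = random_params(rng, [2, 2, 2, 2])
        fields = np.array([t[1] for t in params.thresholds])
        for _ in range(20):
            s = rng.integers(0, 2, size=4)
            assert log_unnormalized_joint(s, params) == pytest.approx(
                ising_energy(s, fields, params.interactions), abs=1e-12
            )


class TestPseudolikelihood:
    def test_independence_factorizes(self, rng):
        m = [3, 4]
        params = random_params(rng, m)
        params.interactions[:] = 0.0
        data = gibbs_simulate(params, 50, sweeps=5, seed=3)
        # categorical log-likelihood per variable
        expected = 0.0
        for i in range(2):
            logits = params.thresholds[i]
            logp = logits - np.log(np.exp(logits).sum())
            counts = np.bincount(data.values[:, i], minlength=m[i])
            expected += float(counts @ logp)
        assert log_pseudolikelihood(data, params) == pytest.approx(expected)

    def test_single_variable_equals_exact_loglik(self, rng):
        params = random_params(rng, [4])
        data = gibbs_simulate(params, 30, sweeps=5, seed=4)
        z = normalizing_constant(params)
        exact = sum(
            log_unnormalized_joint([v], params) - np.log(z)
            for v in data.values[:, 0]
        )
        assert log_pseudolikelihood(data, params) == pytest.approx(exact)

    def test_matches_naive_triple_loop(self, rng):
        params = random_params(rng, [3, 3, 3])
        data = gibbs_simulate(params, 20, sweeps=10, seed=5)
        total = 0.0
        for v in range(data.n):
            for i in range(3):
                probs = full_conditional(i, data.values[v], params)
                total += np.log(probs[data.values[v, i]])
        assert log_pseudolikelihood(data, params) == pytest.approx(total)


def test_conditionals_agree_with_enumeration_on_small_graphs(rng):
    """Oracle agreement on assorted category shapes with <= 10^4 states."""
    for m in ([2, 2, 2], [2, 3, 4], [5, 5], [3, 3, 3, 3]):
        params = random_params(rng, m)
        states, probs = enumerate_joint(params, state_limit=10_000)
        for _ in range(5):
            x = np.array([rng.integers(0, mi) for mi in m])
            for i in range(len(m)):
                mask = np.ones(states.shape[0], dtype=bool)
                for j in range(len(m)):
                    if j != i:
                        mask &= states[:, j] == x[j]
                expected = probs[mask] / probs[mask].sum()
                order = np.argsort(states[mask][:, i])
                np.testing.assert_allclose(
                    full_conditional(i, x, params), expected[order], atol=1e-10
                )


class TestGibbsSimulate:
    def test_seed_reproducibility(self, rng):
        params = random_params(rng, [3, 3])
        a = gibbs_simulate(params, 100, sweeps=20, seed=9)
        b = gibbs_simulate(params, 100, sweeps=20, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_independent_model_marginals(self):
        mu = np.array([0.0, 0.7, -0.4])
        params = ModelParams([mu, mu.copy()], np.zeros((2, 2)))
        data = gibbs_simulate(params, 10_000, sweeps=3, seed=12)
        expected = np.exp(mu) / np.exp(mu).sum()
        for i in range(2):
            counts = np.bincount(data.values[:, i], minlength=3)
            stat = chisquare(counts, expected * data.n)
            assert stat.pvalue > 1e-4

    def test_pairwise_log_odds_recover_sigma(self):
        params = ModelParams(
            [np.array([0.0, 0.2, -0.1])] * 2,
            np.array([[0.0, 0.8], [0.8, 0.0]]),
        )
        data = gibbs_simulate(params, 50_000, sweeps=40, seed=13)
        table = np.zeros((3, 3))
        np.add.at(table, (data.values[:, 0], data.values[:, 1]), 1.0)
        table /= table.sum()
        for h in range(2):
            for q in range(2):
                assert sigma_from_pair_probs(table, h, q) == pytest.approx(
                    0.8, abs=0.12
                )

    def test_zero_variance_warning_not_error(self):
        # extreme thresholds pin every draw to the top category
        params = ModelParams(
            [np.array([0.0, 30.0]), np.array([0.0, 30.0])], np.zeros((2, 2))
        )
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            gibbs_simulate(params, 50, sweeps=2, seed=1)


class TestIdentificationIdentities:
    def test_independence_table_gives_zero(self):
        marg_a = np.array([0.2, 0.5, 0.3])
        marg_b = np.array([0.6, 0.4])
        table = np.outer(marg_a, marg_b)
        for h in range(2):
            for q in range(1):
                assert sigma_from_pair_probs(table, h, q) == pytest.approx(0.0)

    def test_model_implied_table_identifies_sigma_everywhere(self):
        params = ModelParams(
            [np.array([0.0, 0.4, -0.2]), np.array([0.0, -0.3, 0.1])],
            np.array([[0.0, 1.3], [1.3, 0.0]]),
        )
        table = pair_prob_table(params, 0, 1)
        for h in range(2):
            for q in range(2):
                assert sigma_from_pair_probs(table, h, q) == pytest.approx(
                    1.3, abs=1e-10
                )
        # swapping variable roles transposes the table, same value
        assert sigma_from_pair_probs(table.T, 1, 0) == pytest.approx(
            sigma_from_pair_probs(table, 0, 1), abs=1e-10
        )

    def test_zero_cell_reported(self):
        table = np.array([[0.5, 0.0], [0.25, 0.25]])
        with pytest.raises(ValueError, match="zero cell"):
            sigma_from_pair_probs(table, 0, 0)

    def test_mu_from_uniform_marginal_is_zero(self):
        assert mu_from_marginals(np.full(4, 0.25), 2) == pytest.approx(0.0)

    def test_mu_softmax_inversion(self):
        mu = np.array([0.0, 1.0, -1.0])
        marg = np.exp(mu) / np.exp(mu).sum()
        assert mu_from_marginals(marg, 1) == pytest.approx(1.0)
        assert mu_from_marginals(marg, 2) == pytest.approx(-1.0)

    def test_mu_recovered_from_enumeration(self, rng):
        mu = np.concatenate([[0.0], rng.normal(size=3)])
        params = ModelParams([mu], np.zeros((1, 1)))
        _, probs = enumerate_joint(params)
        for h in range(1, 4):
            assert mu_from_marginals(probs, h) == pytest.approx(
                mu[h], abs=1e-12
            )


def test_sufficient_stats_counts_and_products(rng):
    values = np.array([[0, 1], [2, 1], [1, 0], [2, 1]])
    data = OrdinalData(values, np.array([3, 2]))
    stats = sufficient_stats(data)
    np.testing.assert_array_equal(stats.category_counts[0], [1, 1, 2])
    np.testing.assert_array_equal(stats.category_counts[1], [1, 3])
    assert stats.pair_products[0, 1] == pytest.approx(
        float((values[:, 0] * values[:, 1]).sum())
    )
    assert stats.pair_products[0, 0] == 0.0
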