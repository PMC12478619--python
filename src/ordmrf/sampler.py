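"""PL-MoMS: pseudolikelihood Metropolis-within-Gibbs edge selection.

Each iteration has two blocks:

* **Block I** updates every free category threshold μ_{ih} one at a time by
  an independence-chain Metropolis step. The proposal is a generalized
  beta-prime density g(μ) ∝ e^{p̃μ} / (1 + c e^μ)^{p̃+q̃} whose linear log
  tails are matched to those of the pseudolikelihood-times-prior full
  conditional (left slope n_{ih} + α, right slope −(n − n_{ih}) − β) and
  whose remaining constant c equates the log-derivative of proposal and
  target at the current state.
* **Block II** visits every pair i < j and proposes to flip the edge
  indicator together with its weight (a Metropolis move over a mixture of
  mutually singular distributions): a birth draws σ′ ~ N(0, ς²_{ij}) out of
  the point mass at zero, a death proposes σ′ = 0. It then refreshes all
  active interactions (γ = 1) with a random-walk Metropolis step. The
  pseudolikelihood ratio of a pair move involves only the full conditionals
  of variables i and j.

Proposal standard deviations ς_{ij} adapt during burn-in by a Robbins–Monro
recursion on log ς toward the univariate random-walk target acceptance rate
(0.44), driven by the active-interaction refresh acceptances (between-model
flips reuse the same ς but cannot attain that rate and so do not drive the
adaptation); the decaying gain gives diminishing adaptation, and ς is
frozen after burn-in.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from ._kernels import threshold_lse_pair, threshold_prob_sum, var_loglik
from .model import ModelParams, OrdinalData, sufficient_stats
from .priors import (
    PriorSpec,
    log_slab_density,
    log_threshold_prior,
    unit_information_precision,
)

__all__ = [
    "ChainState",
    "PosteriorSamples",
    "threshold_proposal_params",
    "update_threshold",
    "update_edge_pair",
    "update_active_interactions",
    "adapt_proposal_sd",
    "run_pl_moms",
]

TARGET_ACCEPT = 0.44
GAIN_EXPONENT = 0.75
PROP_SD_INIT = 1.0
PROP_SD_MIN = 1e-3
PROP_SD_MAX = 50.0


def _mple_thresholds(data: OrdinalData) -> list:
    """Independence-model MPLE log(n_ih / n_i0), count-smoothed by +1/2."""
    stats = sufficient_stats(data)
    out = []
    for counts in stats.category_counts:
        c = counts.astype(float) + 0.5
        mu = np.log(c) - np.log(c[0])
        mu[0] = 0.0
        out.append(mu)
    return out


class ChainState:
    """Mutable sampler state: parameters, indicators, caches, adaptation.

    Maintains the MoMS coupling γ_{ij} = 0 ⇔ σ_{ij} = 0, the rest-score
    matrix R = X σ, and per-variable cached conditional log-likelihood sums.
    """

    def __init__(
        self,
        data: OrdinalData,
        prior: PriorSpec,
        initial_params: ModelParams | None = None,
        likelihood_scale: float = 1.0,
    ):
        self.data = data
        self.prior = prior
        self.lscale = float(likelihood_scale)
        self.x = data.values
        self.n, self.p = self.x.shape
        self.m = data.n_categories
        iu, ju = np.triu_indices(self.p, 1)
        self.pairs = np.column_stack([iu, ju])
        self.n_pairs = self.pairs.shape[0]
        stats = sufficient_stats(data)
        self.counts = stats.category_counts

        if initial_params is None:
            self.mu = _mple_thresholds(data)
            self.sigma = np.zeros((self.p, self.p))
        else:
            if initial_params.p != self.p:
                raise ValueError("initial_params dimension mismatch")
            self.mu = [t.copy() for t in initial_params.thresholds]
            self.sigma = initial_params.interactions.copy()
        self.gamma = (self.sigma != 0).astype(np.int8)
        np.fill_diagonal(self.gamma, 0)

        # rest-scores stored (p, n) so each variable's row is contiguous
        self.xcols = [np.ascontiguousarray(self.x[:, i]) for i in range(self.p)]
        self.rest = np.ascontiguousarray((self.x @ self.sigma).T)
        self.cond_ll = np.array([self._var_ll(i) for i in range(self.p)])

        if prior.slab_family == "unit_information":
            self.ui_precision = unit_information_precision(data)
        else:
            self.ui_precision = None

        self.prop_sd = np.full(self.n_pairs, PROP_SD_INIT)
        self.adapt_t = np.zeros(self.n_pairs)
        self.adapting = True
        self.iteration = 0
        self.tally = {
            "threshold": [0, 0],
            "pair": [0, 0],
            "rw": [0, 0],
        }

    # -- likelihood pieces -------------------------------------------------

    def _logits(self, i: int, rest_i: np.ndarray, mu_i=None) -> np.ndarray:
        mu_i = self.mu[i] if mu_i is None else mu_i
        h = np.arange(self.m[i])
        return mu_i[None, :] + rest_i[:, None] * h[None, :]

    @staticmethod
    def _lse(logits: np.ndarray) -> np.ndarray:
        mx = logits.max(axis=1)
        return mx + np.log(np.exp(logits - mx[:, None]).sum(axis=1))

    def _var_ll(self, i: int, rest_i=None, mu_i=None) -> float:
        """Σ_v log P(x_{vi} | rest); the pseudolikelihood share of variable i."""
        rest_i = self.rest[i] if rest_i is None else rest_i
        mu_i = self.mu[i] if mu_i is None else mu_i
        return float(var_loglik(self.xcols[i], rest_i, mu_i))

    def slab_logpdf(self, k: int, value: float) -> float:
        prec = None if self.ui_precision is None else self.ui_precision[k]
        return log_slab_density(value, self.prior, precision=prec)

    def inclusion_log_odds(self, k: int) -> float:
        spec = self.prior
        if spec.edge_prior == "bernoulli":
            return float(np.log(spec.edge_theta) - np.log1p(-spec.edge_theta))
        i, j = self.pairs[k]
        kk = self.n_pairs
        iu, ju = np.triu_indices(self.p, 1)
        e_minus = int(self.gamma[iu, ju].sum()) - int(self.gamma[i, j])
        return float(
            np.log(spec.edge_a + e_minus)
            - np.log(spec.edge_b + kk - 1 - e_minus)
        )

    def params(self) -> ModelParams:
        return ModelParams([t.copy() for t in self.mu], self.sigma.copy())


# -- Block I ---------------------------------------------------------------


def threshold_proposal_params(i: int, h: int, state: ChainState):
    """Tail-matched generalized beta-prime proposal parameters (p̃, q̃, c).

    p̃ = n_{ih} + α and q̃ = n − n_{ih} + β match the linear log-tails of the
    full conditional of μ_{ih}; c solves d/dμ log g(μ) = d/dμ log f(μ) at
    the current state. Non-finite or out-of-range derivatives fall back to
    c = 1 with a warning.
    """
    spec = state.prior
    a, b = spec.threshold_alpha, spec.threshold_beta
    lsc = state.lscale
    n_ih = float(state.counts[i][h])
    n = float(state.n)
    p_t = lsc * n_ih + a
    q_t = lsc * (n - n_ih) + b
    mu0 = state.mu[i][h]

    prob_sum = threshold_prob_sum(state.rest[i], state.mu[i], h)
    deriv = (
        lsc * (n_ih - float(prob_sum))
        + a
        - (a + b) / (1.0 + np.exp(-mu0))
    )
    u = (p_t - deriv) / (p_t + q_t)
    if not np.isfinite(u) or not (1e-12 < u < 1 - 1e-12):
        warnings.warn(
            "non-finite derivative in threshold proposal; falling back to c=1",
            RuntimeWarning,
            stacklevel=2,
        )
        log_c = 0.0
    else:
        log_c = float(np.log(u) - np.log1p(-u) - mu0)
    return p_t, q_t, float(np.exp(log_c))


def update_threshold(i: int, h: int, state: ChainState, rng) -> bool:
    """One independence-chain Metropolis update of μ_{ih}; returns accept flag."""
    p_t, q_t, c = threshold_proposal_params(i, h, state)
    log_c = np.log(c)
    y = rng.beta(p_t, q_t)
    y = min(max(y, 1e-300), 1 - 1e-16)
    prop = float(np.log(y) - np.log1p(-y) - log_c)
    cur = float(state.mu[i][h])

    def log_g(mu):
        return p_t * mu - (p_t + q_t) * np.logaddexp(0.0, mu + log_c)

    sum_lse_cur, sum_lse_prop = threshold_lse_pair(
        state.rest[i], state.mu[i], h, cur, prop
    )
    n_ih = float(state.counts[i][h])
    logf_cur = (
        state.lscale * (cur * n_ih - sum_lse_cur)
        + log_threshold_prior(cur, state.prior)
    )
    logf_prop = (
        state.lscale * (prop * n_ih - sum_lse_prop)
        + log_threshold_prior(prop, state.prior)
    )
    log_ratio = (logf_prop - logf_cur) + (log_g(cur) - log_g(prop))
    accept = np.log(rng.random()) < log_ratio
    if accept:
        state.cond_ll[i] += n_ih * (prop - cur) - (sum_lse_prop - sum_lse_cur)
        state.mu[i][h] = prop
    state.tally["threshold"][0] += int(accept)
    state.tally["threshold"][1] += 1
    return bool(accept)


# -- Block II --------------------------------------------------------------


def _pair_delta_pl(state: ChainState, i: int, j: int, new_sigma: float):
    """Pseudolikelihood change from setting σ_{ij} to ``new_sigma``.

    Only the conditionals of variables i and j move.
    """
    d = new_sigma - state.sigma[i, j]
    rest_i = state.rest[i] + d * state.xcols[j]
    rest_j = state.rest[j] + d * state.xcols[i]
    ll_i = state._var_ll(i, rest_i)
    ll_j = state._var_ll(j, rest_j)
    delta = (ll_i + ll_j) - (state.cond_ll[i] + state.cond_ll[j])
    return delta, ll_i, ll_j, rest_i, rest_j


def _apply_pair(state, i, j, new_sigma, new_gamma, ll_i, ll_j, rest_i, rest_j):
    state.sigma[i, j] = state.sigma[j, i] = new_sigma
    state.gamma[i, j] = state.gamma[j, i] = new_gamma
    state.rest[i] = rest_i
    state.rest[j] = rest_j
    state.cond_ll[i] = ll_i
    state.cond_ll[j] = ll_j


def _normal_logpdf(x: float, sd: float) -> float:
    return float(-0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * (x / sd) ** 2)


def update_edge_pair(i: int, j: int, state: ChainState, rng) -> bool:
    """Between-model MoMS move for the pair (γ_{ij}, σ_{ij})."""
    k = _pair_index(state.p, i, j)
    sd = state.prop_sd[k]
    odds = state.inclusion_log_odds(k)
    if state.gamma[i, j] == 0:
        # birth: 0 -> sigma' ~ N(0, sd^2)
        s_new = float(rng.normal(0.0, sd))
        delta, ll_i, ll_j, r_i, r_j = _pair_delta_pl(state, i, j, s_new)
        log_ratio = (
            state.lscale * delta
            + state.slab_logpdf(k, s_new)
            + odds
            - _normal_logpdf(s_new, sd)
        )
        accept = np.log(rng.random()) < log_ratio
        if accept:
            _apply_pair(state, i, j, s_new, 1, ll_i, ll_j, r_i, r_j)
    else:
        # death: sigma -> 0
        s_cur = float(state.sigma[i, j])
        delta, ll_i, ll_j, r_i, r_j = _pair_delta_pl(state, i, j, 0.0)
        log_ratio = (
            state.lscale * delta
            + _normal_logpdf(s_cur, sd)
            - state.slab_logpdf(k, s_cur)
            - odds
        )
        accept = np.log(rng.random()) < log_ratio
        if accept:
            _apply_pair(state, i, j, 0.0, 0, ll_i, ll_j, r_i, r_j)
    state.tally["pair"][0] += int(accept)
    state.tally["pair"][1] += 1
    return bool(accept)


def update_active_interactions(state: ChainState, rng) -> int:
    """Random-walk Metropolis refresh of every active (γ = 1) interaction."""
    n_accepted = 0
    iu, ju = np.triu_indices(state.p, 1)
    active = np.flatnonzero(state.gamma[iu, ju])
    for k in active:
        i, j = int(iu[k]), int(ju[k])
        sd = state.prop_sd[k]
        s_cur = float(state.sigma[i, j])
        s_new = s_cur + float(rng.normal(0.0, sd))
        delta, ll_i, ll_j, r_i, r_j = _pair_delta_pl(state, i, j, s_new)
        log_ratio = (
            state.lscale * delta
            + state.slab_logpdf(k, s_new)
            - state.slab_logpdf(k, s_cur)
        )
        accept = np.log(rng.random()) < log_ratio
        if accept:
            _apply_pair(state, i, j, s_new, 1, ll_i, ll_j, r_i, r_j)
            n_accepted += 1
        state.tally["rw"][0] += int(accept)
        state.tally["rw"][1] += 1
        adapt_proposal_sd(state, k, bool(accept))
    return n_accepted


def adapt_proposal_sd(state: ChainState, k: int, accepted: bool) -> float:
    """Robbins–Monro step on log ς_{ij} toward the target acceptance rate.

    Frozen outside the burn-in/adaptation phase; the t^{-0.75} gain gives
    diminishing adaptation.
    """
    if not state.adapting:
        return state.prop_sd[k]
    state.adapt_t[k] += 1
    gain = state.adapt_t[k] ** (-GAIN_EXPONENT)
    log_sd = np.log(state.prop_sd[k]) + gain * (float(accepted) - TARGET_ACCEPT)
    state.prop_sd[k] = float(
        np.clip(np.exp(log_sd), PROP_SD_MIN, PROP_SD_MAX)
    )
    return state.prop_sd[k]


def _pair_index(p: int, i: int, j: int) -> int:
    """Index of (i, j), i < j, in upper-triangle row-major order."""
    if not 0 <= i < j < p:
        raise ValueError("need 0 <= i < j < p")
    return i * p - i * (i + 1) // 2 + (j - i - 1)


# -- Output container ------------------------------------------------------


@dataclass
class PosteriorSamples:
    """Retained MCMC draws plus tallies and structure-visit counts.

    ``thresholds`` holds the free thresholds (h ≥ 1) flattened per
    ``threshold_labels``; ``interactions``/``gamma`` hold the K upper-triangle
    pairs in ``pairs`` order. The MoMS coupling guarantees the interaction
    trace is exactly zero wherever the indicator trace is zero.
    """

    thresholds: np.ndarray
    threshold_labels: list
    interactions: np.ndarray
    gamma: np.ndarray
    pairs: np.ndarray
    n_categories: np.ndarray
    prior: PriorSpec
    acceptance: dict = field(default_factory=dict)
    visited_structures: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.gamma.shape[0]

    @property
    def p(self) -> int:
        return self.n_categories.size

    def sigma_matrix(self, values: np.ndarray) -> np.ndarray:
        """Expand a length-K upper-triangle vector to a symmetric p × p matrix."""
        out = np.zeros((self.p, self.p))
        iu, ju = self.pairs[:, 0], self.pairs[:, 1]
        out[iu, ju] = values
        out[ju, iu] = values
        return out


def _free_threshold_labels(m: np.ndarray) -> list:
    return [(i, h) for i in range(m.size) for h in range(1, int(m[i]))]


def run_pl_moms(
    data: OrdinalData,
    prior: PriorSpec | None = None,
    n_iter: int = 10_000,
    burnin: int = 1_000,
    seed=None,
    thin: int = 1,
    scan_order: str = "sequential",
    update_thresholds: bool = True,
    initial_params: ModelParams | None = None,
    likelihood_scale: float = 1.0,
    progress_callback=None,
) -> PosteriorSamples:
    """Run the PL-MoMS Gibbs sampler and return post-burn-in draws.

    ``n_iter`` counts total iterations; the ``n_iter - burnin`` post-burn-in
    states are retained (every ``thin``-th). Columns with zero variance are a
    hard error: such variables carry no information about their interactions
    and should be excluded before fitting.
    """
    if prior is None:
        prior = PriorSpec()
    if not n_iter > burnin >= 0:
        raise ValueError("need n_iter > burnin >= 0")
    zv = data.zero_variance_columns()
    if zv.size:
        raise ValueError(
            f"column(s) {zv.tolist()} have zero variance; exclude them "
            "before fitting"
        )
    rng = np.random.default_rng(seed)
    state = ChainState(
        data, prior, initial_params=initial_params,
        likelihood_scale=likelihood_scale,
    )
    m = state.m
    labels = _free_threshold_labels(m)
    n_keep = (n_iter - burnin + thin - 1) // thin
    thr_trace = np.empty((n_keep, len(labels)))
    sig_trace = np.empty((n_keep, state.n_pairs))
    gam_trace = np.empty((n_keep, state.n_pairs), dtype=np.int8)
    visits: Counter = Counter()
    iu, ju = np.triu_indices(state.p, 1)

    kept = 0
    for it in range(n_iter):
        state.iteration = it
        state.adapting = it < burnin
        if update_thresholds:
            for (i, h) in labels:
                update_threshold(i, h, state, rng)
        pair_order = np.arange(state.n_pairs)
        if scan_order == "random":
            pair_order = rng.permutation(pair_order)
        elif scan_order != "sequential":
            raise ValueError("scan_order must be 'sequential' or 'random'")
        for k in pair_order:
            i, j = state.pairs[k]
            update_edge_pair(int(i), int(j), state, rng)
        update_active_interactions(state, rng)
        if it >= burnin and (it - burnin) % thin == 0:
            thr_trace[kept] = [state.mu[i][h] for (i, h) in labels]
            gvec = state.gamma[iu, ju]
            sig_trace[kept] = state.sigma[iu, ju]
            gam_trace[kept] = gvec
            visits[np.packbits(gvec).tobytes()] += 1
            kept += 1
        if progress_callback is not None and (it + 1) % 1000 == 0:
            progress_callback(it + 1, state)

    acceptance = {
        name: (cnt / tot if tot else float("nan"))
        for name, (cnt, tot) in state.tally.items()
    }
    return PosteriorSamples(
        thresholds=thr_trace[:kept],
        threshold_labels=labels,
        interactions=sig_trace[:kept],
        gamma=gam_trace[:kept],
        pairs=state.pairs,
        n_categories=m,
        prior=prior,
        acceptance=acceptance,
        visited_structures=dict(visits),
        config={
            "sampler": "pl_moms",
            "n_iter": n_iter,
            "burnin": burnin,
            "thin": thin,
            "seed": seed,
            "scan_order": scan_order,
            "update_thresholds": update_thresholds,
            "likelihood_scale": likelihood_scale,
            "target_accept": TARGET_ACCEPT,
        },
    )
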