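"""DMH-MoMS: double Metropolis–Hastings edge selection.

The exchange-style acceptance replaces every pseudolikelihood ratio of the
PL-MoMS sampler with an exact-likelihood construction: a fresh auxiliary
dataset is drawn (approximately) from the model at the *proposed*
parameters by a short inner Gibbs run started at the observed data, and the
acceptance probability

    min(1, exp[ ℓ*(x; θ′) − ℓ*(x; θ) + ℓ*(y; θ) − ℓ*(y; θ′) + log prior ratio ])

uses only the *unnormalized* log joint ℓ* summed over rows — the
intractable normalizing constant cancels exactly. Because ℓ* is linear in
the sufficient statistics, the data-vs-auxiliary difference reduces to
(statistic(x) − statistic(y)) times the parameter change.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from ._kernels import run_gibbs_sweeps
from .model import ModelParams, OrdinalData, log_unnormalized_joint
from .priors import PriorSpec, log_threshold_prior
from .sampler import (
    ChainState,
    PosteriorSamples,
    _free_threshold_labels,
    _normal_logpdf,
    _pair_index,
    adapt_proposal_sd,
    threshold_proposal_params,
)

__all__ = ["DmhConfig", "auxiliary_draw", "dmh_accept", "run_dmh_moms"]


@dataclass
class DmhConfig:
    """DMH sampler settings; ``inner_sweeps`` controls the auxiliary draws."""

    inner_sweeps: int = 10
    n_iter: int = 10_000
    burnin: int = 1_000
    thin: int = 1
    seed: int | None = None
    update_thresholds: bool = True

    def __post_init__(self) -> None:
        if self.inner_sweeps < 1:
            raise ValueError("inner_sweeps must be >= 1")


def auxiliary_draw(
    params: ModelParams,
    data: OrdinalData,
    inner_sweeps: int,
    rng,
) -> OrdinalData:
    """Auxiliary dataset from ``inner_sweeps`` Gibbs sweeps at ``params``.

    Initialized at the observed data, same shape; ``inner_sweeps = 0`` (for
    testing only) returns a copy of the observations.
    """
    y = np.array(data.values, copy=True)
    if inner_sweeps > 0:
        run_gibbs_sweeps(y, params, inner_sweeps, rng)
    return OrdinalData(y, data.n_categories)


def dmh_accept(
    params_cur: ModelParams,
    params_prop: ModelParams,
    prior_ratio_log: float,
    data: OrdinalData,
    aux: OrdinalData,
    rng,
) -> bool:
    """Exchange acceptance; ``aux`` must have been drawn at ``params_prop``."""

    def ell(d: OrdinalData, p: ModelParams) -> float:
        return float(np.sum(log_unnormalized_joint(d.values, p)))

    log_ratio = (
        ell(data, params_prop)
        - ell(data, params_cur)
        + ell(aux, params_cur)
        - ell(aux, params_prop)
        + prior_ratio_log
    )
    return bool(np.log(rng.random()) < log_ratio)


# -- fast sufficient-statistic shortcuts (linear-in-parameter moves) -------


def _aux_values(state: ChainState, sigma, mu_i_index=None, mu_i=None,
                inner_sweeps: int = 10, rng=None) -> np.ndarray:
    """Raw auxiliary matrix at the proposed parameters (hot path)."""
    from ._kernels import _PAD, sweep_kernel_seeded

    m = state.m
    mu_pad = np.full((state.p, int(m.max())), _PAD)
    for i, t in enumerate(state.mu):
        mu_pad[i, : t.size] = t
    if mu_i_index is not None:
        mu_pad[mu_i_index, : mu_i.size] = mu_i
    y = np.array(state.x, copy=True)
    seed = int(rng.integers(0, 2**31 - 1))
    sweep_kernel_seeded(
        y, mu_pad, m.astype(np.int64), np.ascontiguousarray(sigma),
        inner_sweeps, seed,
    )
    return y


def _dmh_update_threshold(state: ChainState, i: int, h: int,
                          inner_sweeps: int, rng) -> bool:
    p_t, q_t, c = threshold_proposal_params(i, h, state)
    log_c = np.log(c)
    y = rng.beta(p_t, q_t)
    y = min(max(y, 1e-300), 1 - 1e-16)
    prop = float(np.log(y) - np.log1p(-y) - log_c)
    cur = float(state.mu[i][h])

    mu_prop = state.mu[i].copy()
    mu_prop[h] = prop
    aux = _aux_values(state, state.sigma, mu_i_index=i, mu_i=mu_prop,
                      inner_sweeps=inner_sweeps, rng=rng)
    # ell* is linear in mu_ih with coefficient #(column i == h)
    n_ih_data = float(state.counts[i][h])
    n_ih_aux = float(np.count_nonzero(aux[:, i] == h))

    def log_g(mu):
        return p_t * mu - (p_t + q_t) * np.logaddexp(0.0, mu + log_c)

    log_ratio = (
        (n_ih_data - n_ih_aux) * (prop - cur)
        + log_threshold_prior(prop, state.prior)
        - log_threshold_prior(cur, state.prior)
        + log_g(cur)
        - log_g(prop)
    )
    accept = np.log(rng.random()) < log_ratio
    if accept:
        state.mu[i][h] = prop
    state.tally["threshold"][0] += int(accept)
    state.tally["threshold"][1] += 1
    return bool(accept)


def _pair_stat(values: np.ndarray, i: int, j: int) -> float:
    return float(values[:, i] @ values[:, j])


def _dmh_pair_log_ratio(state: ChainState, i: int, j: int, s_new: float,
                        inner_sweeps: int, rng) -> float:
    """Exchange log-ratio of the likelihood part for σ_{ij} -> s_new."""
    s_cur = float(state.sigma[i, j])
    sigma_prop = state.sigma.copy()
    sigma_prop[i, j] = sigma_prop[j, i] = s_new
    aux = _aux_values(state, sigma_prop, inner_sweeps=inner_sweeps, rng=rng)
    # ell* is linear in sigma_ij with coefficient s_ij = sum_v x_vi x_vj
    return (s_new - s_cur) * (
        _pair_stat(state.x, i, j) - _pair_stat(aux, i, j)
    )


def _dmh_update_edge_pair(state: ChainState, i: int, j: int,
                          inner_sweeps: int, rng) -> bool:
    k = _pair_index(state.p, i, j)
    sd = state.prop_sd[k]
    odds = state.inclusion_log_odds(k)
    if state.gamma[i, j] == 0:
        s_new = float(rng.normal(0.0, sd))
        log_ratio = (
            _dmh_pair_log_ratio(state, i, j, s_new, inner_sweeps, rng)
            + state.slab_logpdf(k, s_new)
            + odds
            - _normal_logpdf(s_new, sd)
        )
        accept = np.log(rng.random()) < log_ratio
        if accept:
            _set_pair(state, i, j, s_new, 1)
    else:
        s_cur = float(state.sigma[i, j])
        log_ratio = (
            _dmh_pair_log_ratio(state, i, j, 0.0, inner_sweeps, rng)
            + _normal_logpdf(s_cur, sd)
            - state.slab_logpdf(k, s_cur)
            - odds
        )
        accept = np.log(rng.random()) < log_ratio
        if accept:
            _set_pair(state, i, j, 0.0, 0)
    state.tally["pair"][0] += int(accept)
    state.tally["pair"][1] += 1
    return bool(accept)


def _set_pair(state: ChainState, i: int, j: int, value: float, gamma: int):
    # keep the rest-score cache valid: Block I proposals read it
    d = value - float(state.sigma[i, j])
    state.rest[i] += d * state.xcols[j]
    state.rest[j] += d * state.xcols[i]
    state.sigma[i, j] = state.sigma[j, i] = value
    state.gamma[i, j] = state.gamma[j, i] = gamma


def _dmh_update_active(state: ChainState, inner_sweeps: int, rng) -> None:
    iu, ju = np.triu_indices(state.p, 1)
    active = np.flatnonzero(state.gamma[iu, ju])
    for k in active:
        i, j = int(iu[k]), int(ju[k])
        sd = state.prop_sd[k]
        s_cur = float(state.sigma[i, j])
        s_new = s_cur + float(rng.normal(0.0, sd))
        log_ratio = (
            _dmh_pair_log_ratio(state, i, j, s_new, inner_sweeps, rng)
            + state.slab_logpdf(k, s_new)
            - state.slab_logpdf(k, s_cur)
        )
        accept = np.log(rng.random()) < log_ratio
        if accept:
            _set_pair(state, i, j, s_new, 1)
        state.tally["rw"][0] += int(accept)
        state.tally["rw"][1] += 1
        adapt_proposal_sd(state, k, bool(accept))


def run_dmh_moms(
    data: OrdinalData,
    prior: PriorSpec | None = None,
    config: DmhConfig | None = None,
    initial_params: ModelParams | None = None,
    **overrides,
) -> PosteriorSamples:
    """Run the DMH-MoMS sampler; interface mirrors :func:`run_pl_moms`.

    Every proposal (threshold, pair birth/death, active random walk) draws a
    fresh auxiliary dataset at the proposed parameters via the inner Gibbs
    sampler (default 10 sweeps) initialized at the observed data.
    """
    if prior is None:
        prior = PriorSpec()
    if config is None:
        config = DmhConfig(**overrides)
    elif overrides:
        raise ValueError("pass either a DmhConfig or keyword overrides")
    if not config.n_iter > config.burnin >= 0:
        raise ValueError("need n_iter > burnin >= 0")
    zv = data.zero_variance_columns()
    if zv.size:
        raise ValueError(
            f"column(s) {zv.tolist()} have zero variance; exclude them "
            "before fitting"
        )
    rng = np.random.default_rng(config.seed)
    state = ChainState(data, prior, initial_params=initial_params)
    labels = _free_threshold_labels(state.m)
    n_keep = (config.n_iter - config.burnin + config.thin - 1) // config.thin
    thr_trace = np.empty((n_keep, len(labels)))
    sig_trace = np.empty((n_keep, state.n_pairs))
    gam_trace = np.empty((n_keep, state.n_pairs), dtype=np.int8)
    visits: Counter = Counter()
    iu, ju = np.triu_indices(state.p, 1)

    kept = 0
    for it in range(config.n_iter):
        state.iteration = it
        state.adapting = it < config.burnin
        if config.update_thresholds:
            for (i, h) in labels:
                _dmh_update_threshold(state, i, h, config.inner_sweeps, rng)
        for k in range(state.n_pairs):
            i, j = state.pairs[k]
            _dmh_update_edge_pair(state, int(i), int(j),
                                  config.inner_sweeps, rng)
        _dmh_update_active(state, config.inner_sweeps, rng)
        if it >= config.burnin and (it - config.burnin) % config.thin == 0:
            thr_trace[kept] = [state.mu[i][h] for (i, h) in labels]
            gvec = state.gamma[iu, ju]
            sig_trace[kept] = state.sigma[iu, ju]
            gam_trace[kept] = gvec
            visits[np.packbits(gvec).tobytes()] += 1
            kept += 1

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
        n_categories=state.m,
        prior=prior,
        acceptance=acceptance,
        visited_structures=dict(visits),
        config={
            "sampler": "dmh_moms",
            "n_iter": config.n_iter,
            "burnin": config.burnin,
            "thin": config.thin,
            "seed": config.seed,
            "inner_sweeps": config.inner_sweeps,
            "update_thresholds": config.update_thresholds,
        },
    )
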