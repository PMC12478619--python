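"""Posterior summaries for Bayesian edge selection.

From the retained draws of (μ, σ, γ) this module computes posterior
inclusion probabilities, inclusion Bayes factors (the ratio of posterior to
prior inclusion odds), the median probability model, model-averaged EAP
estimates, visited-structure summaries, and Bayes factors for sub-structure
(e.g. clique) configurations.

Estimated Bayes factors from a finite chain are truncated: an inclusion
frequency of exactly 0 or 1 over T draws is moved into
[1/(2T), 1 − 1/(2T)] before forming the odds, and the result is flagged as
a bound rather than a point estimate. Evidence categories follow the
conventional 1/10 and 10 cutoffs: BF < 1/10 is evidence of absence,
BF > 10 evidence of presence, anything else inconclusive (strict at the
boundaries).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .model import ModelParams
from .priors import EdgeIndicators, PriorSpec, prior_inclusion_probability
from .sampler import PosteriorSamples

__all__ = [
    "BF_PRESENCE_THRESHOLD",
    "BF_ABSENCE_THRESHOLD",
    "BayesFactor",
    "inclusion_probability",
    "inclusion_bayes_factor",
    "median_probability_model",
    "structure_summary",
    "substructure_bayes_factor",
    "eap_estimates",
    "evidence_plot_data",
    "edge_evidence_table",
]

BF_PRESENCE_THRESHOLD = 10.0
BF_ABSENCE_THRESHOLD = 1.0 / 10.0


class BayesFactor(NamedTuple):
    """A Bayes factor estimate; ``is_bound`` marks a truncated (one-sided) value."""

    value: float
    is_bound: bool


def inclusion_probability(samples: PosteriorSamples) -> np.ndarray:
    """Symmetric p × p matrix of per-edge posterior inclusion frequencies."""
    if samples.n_draws < 1:
        raise ValueError("need at least one retained draw")
    mean_gamma = samples.gamma.mean(axis=0)
    return samples.sigma_matrix(mean_gamma)


def _truncate_probability(post: float, n_draws: int) -> tuple[float, bool]:
    eps = 1.0 / (2.0 * n_draws)
    clipped = min(max(post, eps), 1.0 - eps)
    return clipped, clipped != post


def inclusion_bayes_factor(
    post_incl: float, prior_incl: float, n_draws: int
) -> BayesFactor:
    """Posterior-to-prior inclusion odds ratio, truncation-flagged.

    post = 0.75 against prior = 0.5 gives BF = 3; post = prior gives 1.
    """
    if not 0 < prior_incl < 1:
        raise ValueError("prior inclusion probability must lie in (0, 1)")
    post, bounded = _truncate_probability(float(post_incl), n_draws)
    post_odds = post / (1.0 - post)
    prior_odds = prior_incl / (1.0 - prior_incl)
    return BayesFactor(post_odds / prior_odds, bounded)


def median_probability_model(incl: np.ndarray) -> EdgeIndicators:
    """Edges with posterior inclusion probability strictly above 1/2."""
    incl = np.asarray(incl, dtype=float)
    if incl.min() < 0 or incl.max() > 1:
        raise ValueError("inclusion probabilities must lie in [0, 1]")
    gamma = (incl > 0.5).astype(np.int8)
    np.fill_diagonal(gamma, 0)
    return EdgeIndicators(np.maximum(gamma, gamma.T))


@dataclass
class StructureSummary:
    """Visited-structure bookkeeping over the retained draws."""

    n_distinct: int
    top_structures: list  # [(upper-triangle 0/1 tuple, visit fraction), ...]
    max_probability: float


def _unpack_key(key: bytes, k: int) -> tuple:
    bits = np.unpackbits(np.frombuffer(key, dtype=np.uint8))[:k]
    return tuple(int(b) for b in bits)


def structure_summary(samples: PosteriorSamples, top: int = 10) -> StructureSummary:
    """Distinct structures visited and the best-supported few."""
    if samples.n_draws < 1:
        raise ValueError("need at least one retained draw")
    total = sum(samples.visited_structures.values())
    k = samples.pairs.shape[0]
    ranked = sorted(
        samples.visited_structures.items(), key=lambda kv: -kv[1]
    )[:top]
    tops = [(_unpack_key(key, k), cnt / total) for key, cnt in ranked]
    return StructureSummary(
        n_distinct=len(samples.visited_structures),
        top_structures=tops,
        max_probability=tops[0][1] if tops else 0.0,
    )


def substructure_bayes_factor(
    samples: PosteriorSamples,
    edges: list,
    configuration,
    prior_spec: PriorSpec | None = None,
) -> BayesFactor:
    """Bayes factor for a specific on/off configuration of a set of edges.

    ``edges`` is a list of (i, j) pairs and ``configuration`` the 0/1 vector
    they must match (e.g. all ones for a clique). Under the uniform
    structure prior a k-edge configuration has prior probability 2^{-k}, so
    a 3-clique has prior odds 1/7. The posterior probability is the visit
    frequency of the configuration, truncated as for the inclusion BF.
    """
    edges = [tuple(e) for e in edges]
    k = len(edges)
    if not 1 <= k <= 20:
        raise ValueError("need between 1 and 20 edges")
    configuration = np.asarray(configuration, dtype=np.int8)
    if configuration.shape != (k,):
        raise ValueError("configuration must have one 0/1 entry per edge")
    pair_lookup = {
        (int(i), int(j)): idx for idx, (i, j) in enumerate(samples.pairs)
    }
    cols = []
    for (i, j) in edges:
        key = (min(i, j), max(i, j))
        if key not in pair_lookup:
            raise ValueError(f"unknown edge {key}")
        cols.append(pair_lookup[key])
    match = (samples.gamma[:, cols] == configuration[None, :]).all(axis=1)
    post = float(match.mean())
    post, bounded = _truncate_probability(post, samples.n_draws)
    if prior_spec is None:
        prior_spec = samples.prior
    theta = prior_inclusion_probability(prior_spec)
    prior_config = float(
        np.prod(np.where(configuration == 1, theta, 1.0 - theta))
    )
    post_odds = post / (1.0 - post)
    prior_odds = prior_config / (1.0 - prior_config)
    return BayesFactor(post_odds / prior_odds, bounded)


def eap_estimates(samples: PosteriorSamples) -> ModelParams:
    """Model-averaged posterior means (zeros of excluded-edge draws included)."""
    if samples.n_draws < 1:
        raise ValueError("need at least one retained draw")
    m = samples.n_categories
    thresholds = [np.zeros(int(mi)) for mi in m]
    mean_thr = samples.thresholds.mean(axis=0)
    for val, (i, h) in zip(mean_thr, samples.threshold_labels):
        thresholds[i][h] = val
    sigma = samples.sigma_matrix(samples.interactions.mean(axis=0))
    return ModelParams(thresholds, sigma)


def _categorize(bf: float) -> str:
    if bf > BF_PRESENCE_THRESHOLD:
        return "presence"
    if bf < BF_ABSENCE_THRESHOLD:
        return "absence"
    return "inconclusive"


def evidence_plot_data(
    samples: PosteriorSamples, prior_incl: float | None = None
) -> pd.DataFrame:
    """Per-edge (EAP σ, log inclusion BF, evidence category) table.

    The rows are the K = p(p−1)/2 edges; suitable for the EAP-versus-log-BF
    scatter display. Categories use the strict 1/10–10 rule.
    """
    if prior_incl is None:
        prior_incl = prior_inclusion_probability(samples.prior)
    incl = samples.gamma.mean(axis=0)
    eap = samples.interactions.mean(axis=0)
    rows = []
    for k, (i, j) in enumerate(samples.pairs):
        bf = inclusion_bayes_factor(incl[k], prior_incl, samples.n_draws)
        rows.append(
            {
                "edge_i": int(i),
                "edge_j": int(j),
                "incl_prob": float(incl[k]),
                "incl_bf": bf.value,
                "bf_is_bound": bf.is_bound,
                "log_incl_bf": float(np.log(bf.value)),
                "eap_sigma": float(eap[k]),
                "category": _categorize(bf.value),
            }
        )
    return pd.DataFrame(rows)


def edge_evidence_table(
    samples: PosteriorSamples, prior_incl: float | None = None
) -> pd.DataFrame:
    """CSV-ready edge evidence table (edge, incl_prob, incl_bf, bound, EAP, category)."""
    df = evidence_plot_data(samples, prior_incl)
    df = df.copy()
    df.insert(
        0, "edge", [f"{i}-{j}" for i, j in zip(df["edge_i"], df["edge_j"])]
    )
    return df[
        ["edge", "incl_prob", "incl_bf", "bf_is_bound", "eap_sigma", "category"]
    ]
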