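"""Prior distributions for Bayesian edge selection on the ordinal MRF.

Three ingredients:

* a discrete spike-and-slab prior on each interaction σ_{ij}: a point mass
  at zero when the edge indicator γ_{ij} = 0, and a diffuse slab density
  when γ_{ij} = 1. The slab is either a Cauchy(0, s) (default s = 2.5) or a
  zero-mean normal "unit-information" prior whose precision is the
  per-observation pseudolikelihood information about σ_{ij};
* a structure prior on the indicators: independent Bernoulli(θ = 1/2)
  (all structures equally likely) or the hierarchical Beta-Bernoulli(a, b)
  that puts a uniform density on the common inclusion probability;
* independent beta-prime(α, β) priors on e^{μ_{ih}} for the free category
  thresholds, a proper prior on the whole real μ line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln

from .model import OrdinalData, sufficient_stats

__all__ = [
    "PriorSpec",
    "EdgeIndicators",
    "log_slab_density",
    "unit_information_precision",
    "log_structure_prior",
    "log_threshold_prior",
    "prior_inclusion_probability",
    "prior_inclusion_log_odds",
]


@dataclass
class PriorSpec:
    """Configuration of the spike-and-slab, structure, and threshold priors."""

    slab_family: str = "cauchy"  # "cauchy" | "unit_information"
    slab_scale: float = 2.5
    edge_prior: str = "bernoulli"  # "bernoulli" | "beta_bernoulli"
    edge_theta: float = 0.5
    edge_a: float = 1.0
    edge_b: float = 1.0
    threshold_alpha: float = 1.0
    threshold_beta: float = 1.0

    def __post_init__(self) -> None:
        if self.slab_family not in ("cauchy", "unit_information"):
            raise ValueError(f"unknown slab family {self.slab_family!r}")
        if self.edge_prior not in ("bernoulli", "beta_bernoulli"):
            raise ValueError(f"unknown edge prior {self.edge_prior!r}")
        if self.slab_scale <= 0:
            raise ValueError("slab_scale must be positive")
        if not 0 < self.edge_theta < 1:
            raise ValueError("edge_theta must lie in (0, 1)")
        for name in ("edge_a", "edge_b", "threshold_alpha", "threshold_beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return {
            "slab_family": self.slab_family,
            "slab_scale": self.slab_scale,
            "edge_prior": self.edge_prior,
            "edge_theta": self.edge_theta,
            "edge_prior_a": self.edge_a,
            "edge_prior_b": self.edge_b,
            "threshold_alpha": self.threshold_alpha,
            "threshold_beta": self.threshold_beta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        return cls(
            slab_family=d.get("slab_family", "cauchy"),
            slab_scale=d.get("slab_scale", 2.5),
            edge_prior=d.get("edge_prior", "bernoulli"),
            edge_theta=d.get("edge_theta", 0.5),
            edge_a=d.get("edge_prior_a", 1.0),
            edge_b=d.get("edge_prior_b", 1.0),
            threshold_alpha=d.get("threshold_alpha", 1.0),
            threshold_beta=d.get("threshold_beta", 1.0),
        )


@dataclass
class EdgeIndicators:
    """Symmetric binary p × p edge-inclusion matrix with zero diagonal."""

    gamma: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.gamma, dtype=np.int8)
        if g.ndim != 2 or g.shape[0] != g.shape[1]:
            raise ValueError("gamma must be square")
        if not np.array_equal(g, g.T):
            raise ValueError("gamma must be symmetric")
        if np.any(np.diag(g) != 0):
            raise ValueError("gamma must have zero diagonal")
        if not np.isin(g, (0, 1)).all():
            raise ValueError("gamma entries must be 0/1")
        self.gamma = g

    @property
    def p(self) -> int:
        return self.gamma.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.gamma[np.triu_indices(self.p, 1)].sum())


def log_slab_density(
    sigma_value: float, spec: PriorSpec, precision: float | None = None
) -> float:
    """Log slab density at ``sigma_value``.

    Cauchy: −log(π s) − log(1 + (σ/s)²). Unit-information: Normal(0, 1/τ)
    with τ the per-edge precision (required, see
    :func:`unit_information_precision`).
    """
    if spec.slab_family == "cauchy":
        s = spec.slab_scale
        return float(-np.log(np.pi * s) - np.log1p((sigma_value / s) ** 2))
    if precision is None:
        raise ValueError(
            "unit_information slab requires a per-edge precision value"
        )
    tau = float(precision)
    return float(0.5 * np.log(tau / (2 * np.pi)) - 0.5 * tau * sigma_value**2)


def unit_information_precision(data: OrdinalData) -> np.ndarray:
    """Per-edge, per-observation pseudolikelihood information about σ_{ij}.

    Evaluated at the null reference point (all σ = 0, thresholds at the
    independence pseudolikelihood maximum). There the conditional of
    variable ``i`` is the categorical softmax(μ̂_i), so the observed
    information about σ_{ij} in one observation is

        E[x_j²] Var_i(H) + E[x_i²] Var_j(H)

    with Var_i(H) the category variance under softmax(μ̂_i). Returned as a
    length K = p(p−1)/2 vector in upper-triangle (i < j) order; strictly
    positive unless a column is degenerate, which raises.
    """
    if data.n < 2:
        raise ValueError("need at least two observations")
    zv = data.zero_variance_columns()
    if zv.size:
        raise ValueError(
            f"column(s) {zv.tolist()} have a single observed category; "
            "the information about their interactions is zero"
        )
    stats = sufficient_stats(data)
    p = data.p
    var_h = np.empty(p)
    for i in range(p):
        # independence MPLE: category probabilities = empirical frequencies
        w = stats.category_counts[i] / data.n
        h = np.arange(w.size)
        mean = float(w @ h)
        var_h[i] = float(w @ (h - mean) ** 2)
    msq = (data.values.astype(float) ** 2).mean(axis=0)
    iu, ju = np.triu_indices(p, 1)
    prec = msq[ju] * var_h[iu] + msq[iu] * var_h[ju]
    if np.any(prec <= 0):
        bad = int(np.flatnonzero(prec <= 0)[0])
        raise ValueError(f"non-positive information for edge index {bad}")
    return prec


def log_structure_prior(gamma: EdgeIndicators, spec: PriorSpec) -> float:
    """Log prior probability of the structure ``gamma``.

    Bernoulli(θ): e log θ + (K − e) log(1 − θ), which is −K log 2 at θ = 1/2.
    Beta-Bernoulli(a, b): log B(a + e, b + K − e) − log B(a, b).
    """
    k = gamma.p * (gamma.p - 1) // 2
    e = gamma.n_edges
    if spec.edge_prior == "bernoulli":
        th = spec.edge_theta
        return float(e * np.log(th) + (k - e) * np.log1p(-th))
    return float(
        betaln(spec.edge_a + e, spec.edge_b + k - e)
        - betaln(spec.edge_a, spec.edge_b)
    )


def log_threshold_prior(mu_value: float, spec: PriorSpec) -> float:
    """Log beta-prime(α, β) prior on e^μ, as a density in μ.

    Change of variables gives α μ − (α + β) log(1 + e^μ) − log B(α, β),
    proper for all real μ (the logistic density when α = β = 1).
    """
    a, b = spec.threshold_alpha, spec.threshold_beta
    return float(
        a * mu_value - (a + b) * np.logaddexp(0.0, mu_value) - betaln(a, b)
    )


def prior_inclusion_probability(spec: PriorSpec) -> float:
    """Marginal prior probability that any single edge is included."""
    if spec.edge_prior == "bernoulli":
        return spec.edge_theta
    return spec.edge_a / (spec.edge_a + spec.edge_b)


def prior_inclusion_log_odds(
    spec: PriorSpec, gamma: EdgeIndicators | None = None, pair=None
) -> float:
    """Log prior odds of including one edge, given the rest of the structure.

    Bernoulli edges are independent; under the Beta-Bernoulli prior the odds
    condition on the number of other included edges e₋:
    (a + e₋) / (b + K − 1 − e₋).
    """
    if spec.edge_prior == "bernoulli":
        return float(np.log(spec.edge_theta) - np.log1p(-spec.edge_theta))
    if gamma is None or pair is None:
        raise ValueError("beta_bernoulli odds need the current structure and pair")
    i, j = pair
    k = gamma.p * (gamma.p - 1) // 2
    e_minus = gamma.n_edges - int(gamma.gamma[i, j])
    return float(
        np.log(spec.edge_a + e_minus) - np.log(spec.edge_b + k - 1 - e_minus)
    )
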