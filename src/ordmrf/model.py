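"""Ordinal Markov random field: joint density, conditionals, pseudolikelihood.

The model places ``p`` ordinal variables, variable ``i`` taking integer
category scores ``0, ..., m_i - 1``, on the nodes of an undirected graph.
The joint probability of a response pattern ``x`` is

    P(x) ∝ exp( Σ_i μ_{i, x_i} + Σ_{i<j} σ_{ij} x_i x_j )

with category thresholds ``μ_{ih}`` (``μ_{i0} = 0`` for identification) and
a symmetric, zero-diagonal interaction matrix ``σ``. A zero interaction
``σ_{ij} = 0`` encodes conditional independence of ``i`` and ``j`` given the
rest — the missing edges of the graph. For all-binary variables with 0/1
scores the model is exactly the Ising model with external fields ``μ_{i1}``.

The full conditional of one variable given the rest is an adjacent-category
logit, which makes the pseudolikelihood (the product of full conditionals
over variables and observations) a tractable surrogate for the likelihood,
whose normalizing constant sums over ``Π_i m_i`` patterns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OrdinalData",
    "ModelParams",
    "SufficientStats",
    "log_unnormalized_joint",
    "normalizing_constant",
    "log_normalizing_constant",
    "enumerate_joint",
    "full_conditional",
    "log_pseudolikelihood",
    "gibbs_simulate",
    "pair_prob_table",
    "sigma_from_pair_probs",
    "mu_from_marginals",
    "sufficient_stats",
]


@dataclass
class OrdinalData:
    """n × p matrix of integer category codes plus per-variable category counts.

    ``values[v, i]`` lies in ``{0, ..., n_categories[i] - 1}``. Missing values
    are not representable; listwise deletion happens at ingestion
    (:func:`ordmrf.io.read_ordinal_csv`).
    """

    values: np.ndarray
    n_categories: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array of category codes")
        self.n_categories = np.asarray(self.n_categories, dtype=np.int64)
        if self.n_categories.shape != (self.values.shape[1],):
            raise ValueError("n_categories must have one entry per column")
        if np.any(self.n_categories < 2):
            raise ValueError("every variable needs at least two categories")
        if self.values.size:
            if self.values.min() < 0 or np.any(
                self.values.max(axis=0) >= self.n_categories
            ):
                raise ValueError("category codes out of range for n_categories")

    @classmethod
    def from_values(cls, values, n_categories=None) -> "OrdinalData":
        """Build from a raw integer matrix, inferring ``m_i = max + 1`` if needed."""
        values = np.asarray(values, dtype=np.int64)
        if n_categories is None:
            n_categories = values.max(axis=0) + 1
            n_categories = np.maximum(n_categories, 2)
        return cls(values, np.asarray(n_categories, dtype=np.int64))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def zero_variance_columns(self) -> np.ndarray:
        """Indices of columns where every observation falls in one category."""
        if self.n == 0:
            return np.arange(self.p)
        return np.flatnonzero(
            self.values.max(axis=0) == self.values.min(axis=0)
        )


@dataclass
class ModelParams:
    """Thresholds (ragged, ``μ_{i0} = 0``) and symmetric interactions.

    ``thresholds[i]`` is the length-``m_i`` vector ``(0, μ_{i1}, ..., μ_{i,m_i-1})``
    in log-odds units; ``interactions`` is the symmetric p × p matrix of log
    adjacent-category odds ratios with zero diagonal.
    """

    thresholds: list
    interactions: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = [np.asarray(t, dtype=float) for t in self.thresholds]
        self.interactions = np.asarray(self.interactions, dtype=float)
        p = len(self.thresholds)
        if self.interactions.shape != (p, p):
            raise ValueError("interaction matrix must be p × p")
        if not np.allclose(self.interactions, self.interactions.T):
            raise ValueError("interaction matrix must be symmetric")
        if not np.allclose(np.diag(self.interactions), 0.0):
            raise ValueError("interaction matrix must have zero diagonal")
        for i, t in enumerate(self.thresholds):
            if t.ndim != 1 or t.size < 2:
                raise ValueError(f"thresholds[{i}] must be a vector of length >= 2")
            if t[0] != 0.0:
                raise ValueError(
                    f"thresholds[{i}][0] must be 0 (lowest-category identification)"
                )

    @property
    def p(self) -> int:
        return len(self.thresholds)

    @property
    def n_categories(self) -> np.ndarray:
        return np.array([t.size for t in self.thresholds], dtype=np.int64)

    def copy(self) -> "ModelParams":
        return ModelParams(
            [t.copy() for t in self.thresholds], self.interactions.copy()
        )

    @classmethod
    def zeros(cls, n_categories) -> "ModelParams":
        m = np.asarray(n_categories, dtype=np.int64)
        return cls([np.zeros(mi) for mi in m], np.zeros((m.size, m.size)))


@dataclass
class SufficientStats:
    """Per-category counts ``n_{ih}`` and pairwise score products ``s_{ij}``."""

    category_counts: list = field(default_factory=list)
    pair_products: np.ndarray = None


def sufficient_stats(data: OrdinalData) -> SufficientStats:
    counts = [
        np.bincount(data.values[:, i], minlength=data.n_categories[i])
        for i in range(data.p)
    ]
    x = data.values.astype(float)
    s = x.T @ x
    np.fill_diagonal(s, 0.0)
    return SufficientStats(category_counts=counts, pair_products=s)


def _check_pattern(x: np.ndarray, params: ModelParams) -> np.ndarray:
    x = np.asarray(x, dtype=np.int64)
    if x.shape[-1] != params.p:
        raise ValueError("pattern length does not match number of variables")
    m = params.n_categories
    if x.min() < 0 or np.any(x.max(axis=0) >= m):
        raise ValueError("category code out of range for the model")
    return x


def log_unnormalized_joint(x, params: ModelParams) -> float:
    """Log of the unnormalized joint, Σ_i μ_{i,x_i} + Σ_{i<j} σ_{ij} x_i x_j.

    ``x`` may be a single pattern (1-D) or a matrix of patterns (rows), in
    which case a vector of values is returned.
    """
    x = _check_pattern(np.atleast_2d(x), params)
    thr = np.zeros(x.shape[0])
    for i in range(params.p):
        thr += params.thresholds[i][x[:, i]]
    xf = x.astype(float)
    quad = 0.5 * np.einsum("vi,ij,vj->v", xf, params.interactions, xf)
    out = thr + quad
    return float(out[0]) if out.size == 1 and np.asarray(x).ndim else out


def _iter_state_chunks(m: np.ndarray, chunk: int = 200_000):
    """Yield chunks of the full pattern space as integer matrices (mixed radix)."""
    total = int(np.prod(m))
    for start in range(0, total, chunk):
        idx = np.arange(start, min(start + chunk, total))
        yield np.array(np.unravel_index(idx, m)).T


def log_normalizing_constant(
    params: ModelParams, state_limit: int = 10_000_000
) -> float:
    """log Z by chunked enumeration on the log scale (overflow-safe)."""
    m = params.n_categories
    total = int(np.prod(m))
    if total > state_limit:
        raise ValueError(
            f"pattern space has {total} states, exceeding state_limit={state_limit}"
        )
    running = -np.inf
    for states in _iter_state_chunks(m):
        logw = log_unnormalized_joint(states, params)
        mx = max(running, float(logw.max()))
        running = mx + np.log(
            np.exp(running - mx) + np.exp(logw - mx).sum()
        )
    return float(running)


def normalizing_constant(params: ModelParams, state_limit: int = 10_000_000) -> float:
    """Z = Σ over all response patterns of exp(log unnormalized joint).

    Refuses when the pattern space ``Π_i m_i`` exceeds ``state_limit``.
    """
    return float(np.exp(log_normalizing_constant(params, state_limit)))


def enumerate_joint(params: ModelParams, state_limit: int = 100_000):
    """All response patterns with their exact probabilities (enumeration oracle)."""
    m = params.n_categories
    total = int(np.prod(m))
    if total > state_limit:
        raise ValueError(
            f"pattern space has {total} states, exceeding state_limit={state_limit}"
        )
    states = np.array(np.unravel_index(np.arange(total), m)).T
    logw = log_unnormalized_joint(states, params)
    logw = logw - logw.max()
    w = np.exp(logw)
    return states, w / w.sum()


def _conditional_logits(i: int, rest: np.ndarray, params: ModelParams) -> np.ndarray:
    """Logits μ_{ih} + h · rest for rest-scores ``rest`` (any shape)."""
    h = np.arange(params.n_categories[i])
    return params.thresholds[i][..., :] + np.multiply.outer(rest, h)


def full_conditional(i: int, x, params: ModelParams) -> np.ndarray:
    """P(X_i = h | x_{-i}) for h = 0..m_i-1; entry ``x[i]`` is ignored.

    This is the adjacent-category logit: component ``h`` is proportional to
    exp(μ_{ih} + h Σ_{j≠i} σ_{ij} x_j).
    """
    x = np.asarray(x, dtype=np.int64)
    sig = params.interactions[i].copy()
    sig[i] = 0.0
    rest = float(x @ sig)
    logits = _conditional_logits(i, rest, params)
    logits -= logits.max()
    w = np.exp(logits)
    return w / w.sum()


def log_pseudolikelihood(data: OrdinalData, params: ModelParams) -> float:
    """Σ_v Σ_i log P(x_{vi} | x_{v,-i}); the log joint pseudolikelihood."""
    if not np.array_equal(data.n_categories, params.n_categories):
        # allow data categories to be a subset of the model's range
        if np.any(data.n_categories > params.n_categories):
            raise ValueError("data has more categories than the model allows")
    x = data.values
    rest = x @ params.interactions  # zero diagonal makes Σ_{j≠i} automatic
    total = 0.0
    for i in range(params.p):
        logits = _conditional_logits(i, rest[:, i], params)  # n × m_i
        mx = logits.max(axis=1)
        lse = mx + np.log(np.exp(logits - mx[:, None]).sum(axis=1))
        obs = x[:, i]
        total += float(
            (params.thresholds[i][obs] + rest[:, i] * obs - lse).sum()
        )
    return total


def gibbs_simulate(
    params: ModelParams,
    n: int,
    sweeps: int = 1000,
    seed=None,
    rng: np.random.Generator | None = None,
    init: np.ndarray | None = None,
) -> OrdinalData:
    """Draw ``n`` approximately independent patterns by parallel Gibbs chains.

    Each of ``n`` chains starts from an independent draw of the σ ≡ 0 model
    (categorical with probabilities softmax(μ_i·)) unless ``init`` is given,
    and is advanced by ``sweeps`` sequential scans of full-conditional draws.
    Deterministic given ``seed``. Zero-variance output columns trigger a
    warning (near-degenerate parameter regimes), never an error.
    """
    from ._kernels import run_gibbs_sweeps

    if sweeps < 1 and init is None:
        raise ValueError("sweeps must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    m = params.n_categories
    p = params.p
    if init is None:
        x = np.empty((n, p), dtype=np.int64)
        for i in range(p):
            logits = params.thresholds[i] - params.thresholds[i].max()
            probs = np.exp(logits)
            probs /= probs.sum()
            x[:, i] = rng.choice(m[i], size=n, p=probs)
    else:
        x = np.array(init, dtype=np.int64, copy=True)
    run_gibbs_sweeps(x, params, sweeps, rng)
    out = OrdinalData(x, m)
    zv = out.zero_variance_columns()
    if zv.size:
        warnings.warn(
            f"simulated data has zero-variance columns {zv.tolist()} "
            "(parameters may be past a phase transition)",
            RuntimeWarning,
            stacklevel=2,
        )
    return out


def pair_prob_table(
    params: ModelParams, i: int, j: int, state_limit: int = 100_000
) -> np.ndarray:
    """Model-implied joint category table π^{(ij)}(h, q) by enumeration."""
    states, probs = enumerate_joint(params, state_limit)
    m = params.n_categories
    table = np.zeros((m[i], m[j]))
    np.add.at(table, (states[:, i], states[:, j]), probs)
    return table


def sigma_from_pair_probs(table: np.ndarray, h: int, q: int) -> float:
    """Log cross-ratio of the adjacent 2×2 block at (h, q).

    For a model-implied two-variable table this identifies σ_{ij} at every
    (h, q): σ = log[π(h+1, q+1) π(h, q) / (π(h+1, q) π(h, q+1))].
    """
    table = np.asarray(table, dtype=float)
    mi, mj = table.shape
    if not (0 <= h < mi - 1 and 0 <= q < mj - 1):
        raise ValueError("adjacent block (h, q) out of range")
    cells = table[h : h + 2, q : q + 2]
    if np.any(cells <= 0):
        raise ValueError(
            "zero cell in the adjacent 2x2 block; the log odds ratio is undefined"
        )
    return float(
        np.log(cells[1, 1]) + np.log(cells[0, 0])
        - np.log(cells[1, 0]) - np.log(cells[0, 1])
    )


def mu_from_marginals(marginal: np.ndarray, h: int) -> float:
    """Recover μ_{ih} from marginal category probabilities when σ ≡ 0.

    Under independence π_{ih} ∝ exp(μ_{ih}) with μ_{i0} = 0, so
    μ_{ih} = log(π_{ih} / π_{i0}).
    """
    marginal = np.asarray(marginal, dtype=float)
    if not (0 <= h < marginal.size):
        raise ValueError("category index out of range")
    if marginal[h] <= 0 or marginal[0] <= 0:
        raise ValueError("zero marginal probability; threshold undefined")
    return float(np.log(marginal[h]) - np.log(marginal[0]))
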