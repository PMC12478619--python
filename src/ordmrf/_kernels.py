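"""Compiled inner loops for Gibbs sweeps over the ordinal MRF.

The sequential-scan Gibbs sweep is the hot path of both the data simulator
and the double-MH auxiliary draws (which need a fresh sweep per proposal),
so it is JIT-compiled. Randomness enters only through a pre-generated array
of uniforms from the caller's ``numpy.random.Generator``, keeping results
bit-reproducible and independent of the compiler's own RNG.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_PAD = -1e305  # effectively -inf logit for padded categories


@njit(cache=True)
def var_loglik(obs, rest, mu):  # pragma: no cover - compiled
    """Σ_v log P(x_v = obs_v | rest_v) for one variable's conditional."""
    m = mu.size
    total = 0.0
    for v in range(obs.size):
        r = rest[v]
        mx = -1e308
        for h in range(m):
            val = mu[h] + h * r
            if val > mx:
                mx = val
        tot = 0.0
        for h in range(m):
            tot += np.exp(mu[h] + h * r - mx)
        total += mu[obs[v]] + obs[v] * r - mx - np.log(tot)
    return total


@njit(cache=True)
def threshold_prob_sum(rest, mu, h):  # pragma: no cover - compiled
    """Σ_v P(X = h | rest_v) under the current thresholds."""
    m = mu.size
    total = 0.0
    for v in range(rest.size):
        r = rest[v]
        mx = -1e308
        for k in range(m):
            val = mu[k] + k * r
            if val > mx:
                mx = val
        tot = 0.0
        for k in range(m):
            tot += np.exp(mu[k] + k * r - mx)
        total += np.exp(mu[h] + h * r - mx) / tot
    return total


@njit(cache=True)
def threshold_lse_pair(rest, mu, h, cur, prop):  # pragma: no cover - compiled
    """(Σ_v lse with μ_h = cur, Σ_v lse with μ_h = prop) in one pass."""
    m = mu.size
    s_cur = 0.0
    s_prop = 0.0
    for v in range(rest.size):
        r = rest[v]
        mx1 = -1e308
        mx2 = -1e308
        for k in range(m):
            base = k * r + (mu[k] if k != h else 0.0)
            v1 = base + (cur if k == h else 0.0)
            v2 = base + (prop if k == h else 0.0)
            if v1 > mx1:
                mx1 = v1
            if v2 > mx2:
                mx2 = v2
        t1 = 0.0
        t2 = 0.0
        for k in range(m):
            base = k * r + (mu[k] if k != h else 0.0)
            t1 += np.exp(base + (cur if k == h else 0.0) - mx1)
            t2 += np.exp(base + (prop if k == h else 0.0) - mx2)
        s_cur += mx1 + np.log(t1)
        s_prop += mx2 + np.log(t2)
    return s_cur, s_prop


@njit(cache=True)
def _sweep_kernel(x, mu, m, sigma, u):  # pragma: no cover - compiled
    sweeps = u.shape[0]
    n, p = x.shape
    for s in range(sweeps):
        for i in range(p):
            mi = m[i]
            for v in range(n):
                rest = 0.0
                for j in range(p):
                    rest += sigma[i, j] * x[v, j]
                mx = -1e308
                for h in range(mi):
                    val = mu[i, h] + h * rest
                    if val > mx:
                        mx = val
                tot = 0.0
                for h in range(mi):
                    tot += np.exp(mu[i, h] + h * rest - mx)
                target = u[s, i, v] * tot
                acc = 0.0
                newh = mi - 1
                for h in range(mi):
                    acc += np.exp(mu[i, h] + h * rest - mx)
                    if target <= acc:
                        newh = h
                        break
                x[v, i] = newh


@njit(cache=True)
def sweep_kernel_seeded(x, mu, m, sigma, sweeps, seed):  # pragma: no cover
    """As :func:`_sweep_kernel` but with in-kernel uniforms from ``seed``.

    Used on the double-MH auxiliary-draw hot path, where generating and
    passing a uniform buffer per proposal would dominate the cost. The seed
    comes from the caller's Generator, so runs stay reproducible.
    """
    np.random.seed(seed)
    n, p = x.shape
    for _ in range(sweeps):
        for i in range(p):
            mi = m[i]
            for v in range(n):
                rest = 0.0
                for j in range(p):
                    rest += sigma[i, j] * x[v, j]
                mx = -1e308
                for h in range(mi):
                    val = mu[i, h] + h * rest
                    if val > mx:
                        mx = val
                tot = 0.0
                for h in range(mi):
                    tot += np.exp(mu[i, h] + h * rest - mx)
                target = np.random.random() * tot
                acc = 0.0
                newh = mi - 1
                for h in range(mi):
                    acc += np.exp(mu[i, h] + h * rest - mx)
                    if target <= acc:
                        newh = h
                        break
                x[v, i] = newh


def pad_thresholds(params) -> tuple[np.ndarray, np.ndarray]:
    """Pack ragged thresholds into a padded (p, m_max) array for the kernel."""
    m = params.n_categories
    mu = np.full((params.p, int(m.max())), _PAD)
    for i, t in enumerate(params.thresholds):
        mu[i, : t.size] = t
    return mu, m.astype(np.int64)


def run_gibbs_sweeps(x: np.ndarray, params, sweeps: int, rng) -> None:
    """Advance chains ``x`` (n × p, in place) by ``sweeps`` sequential scans."""
    if sweeps <= 0:
        return
    mu, m = pad_thresholds(params)
    sigma = np.ascontiguousarray(params.interactions)
    n, p = x.shape
    # bound the uniform buffer to ~8e6 doubles per kernel call
    chunk = max(1, int(8_000_000 // max(1, n * p)))
    done = 0
    while done < sweeps:
        step = min(chunk, sweeps - done)
        u = rng.random((step, p, n))
        _sweep_kernel(x, mu, m, sigma, u)
        done += step
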