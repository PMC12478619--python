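"""Simulation designs and selection metrics for edge-selection studies.

Three study designs are registered, mirroring a binary (Ising)
edge-selection benchmark and its ordinal counterparts:

* ``ordinal_evidence`` — p = 24 ordinal variables with five categories,
  n = 300; four free thresholds per variable drawn U(−2, 0) and sorted in
  decreasing order; dense pairwise interactions drawn N(0, 0.1). Used for
  evidence-accumulation (EAP versus inclusion probability) comparisons.
* ``binary_park`` — p = 24 binary variables, n = 300; thresholds U(−1, 1);
  69 of the K = 276 edges present, 41 of them with weights U(0.5, 1) and 28
  with weights U(−1, −0.5).
* ``ordinal_selection`` — the binary design moved to five categories:
  thresholds U(−2, 0) sorted decreasing; the same 41/28 uniform interaction
  split multiplied by 1/16, because the score products x_i x_j grow from
  {0, 1} to the range 0..16. ``ordinal_selection_rescaled_prior`` is the
  same design tagged with a slab scale shrunk by the same factor
  (Cauchy 2.5/16) for the analysis stage.
* ``symptom_emulation`` — a 17-variable, five-category stand-in for a PTSD
  symptom checklist: sparse mixed-sign interactions, decreasing thresholds.

Selected graphs are scored against the generating graph by specificity
TN/(TN+FP), sensitivity TP/(TP+FN), and the Rand index (TN+TP)/K over the
K unordered pairs. Datasets with zero-variance columns are flagged (and
excluded by the study harness, never silently dropped).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ModelParams, OrdinalData, gibbs_simulate
from .priors import EdgeIndicators, PriorSpec
from .inference import inclusion_probability, median_probability_model
from .sampler import run_pl_moms

__all__ = [
    "SimulationDesign",
    "SelectionMetrics",
    "GeneratedDataset",
    "make_design",
    "generate_dataset",
    "selection_metrics",
    "run_study",
    "evidence_threshold_lines",
]

#: inclusion probabilities at which the inclusion BF equals 10, 1, 1/10
#: under the uniform (theta = 1/2) structure prior
EVIDENCE_THRESHOLD_INCLUSION_PROBS = {
    "bf_10": 10.0 / 11.0,
    "bf_1": 1.0 / 2.0,
    "bf_0.1": 1.0 / 11.0,
}


def evidence_threshold_lines() -> dict:
    """Inclusion-probability levels equivalent to BF ∈ {10, 1, 1/10}."""
    return dict(EVIDENCE_THRESHOLD_INCLUSION_PROBS)


@dataclass
class SimulationDesign:
    """A fully specified data-generating recipe for one study arm."""

    kind: str
    p: int
    n: int
    m: int
    n_edges_present: int | None  # None: dense (all pairs carry a weight)
    threshold_low: float
    threshold_high: float
    thresholds_sorted_decreasing: bool
    interaction_sampler: str  # "normal" | "uniform_split"
    interaction_sd: float = 0.0
    n_positive: int = 0
    positive_range: tuple = (0.5, 1.0)
    negative_range: tuple = (-1.0, -0.5)
    rescale_factor: float = 1.0
    slab_scale: float = 2.5
    gibbs_sweeps: int = 1000
    fixed_pattern: bool = False

    @property
    def n_pairs(self) -> int:
        return self.p * (self.p - 1) // 2


@dataclass
class SelectionMetrics:
    """Confusion counts over the K unordered pairs and the derived rates."""

    tn: int
    fp: int
    tp: int
    fn: int

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def rand_index(self) -> float:
        k = self.tn + self.fp + self.tp + self.fn
        return (self.tn + self.tp) / k if k else float("nan")


@dataclass
class GeneratedDataset:
    """One simulated dataset with its generating truth and degeneracy flags."""

    data: OrdinalData
    params: ModelParams
    truth: EdgeIndicators
    zero_variance_columns: np.ndarray = field(
        default_factory=lambda: np.array([], dtype=int)
    )

    @property
    def excluded(self) -> bool:
        return self.zero_variance_columns.size > 0


_BASE_DESIGNS = {
    "ordinal_evidence": dict(
        p=24, n=300, m=5, n_edges_present=None,
        threshold_low=-2.0, threshold_high=0.0,
        thresholds_sorted_decreasing=True,
        interaction_sampler="normal", interaction_sd=0.1,
        slab_scale=2.5,
    ),
    "binary_park": dict(
        p=24, n=300, m=2, n_edges_present=69,
        threshold_low=-1.0, threshold_high=1.0,
        thresholds_sorted_decreasing=False,
        interaction_sampler="uniform_split", n_positive=41,
        positive_range=(0.5, 1.0), negative_range=(-1.0, -0.5),
        slab_scale=2.5,
    ),
    "ordinal_selection": dict(
        p=24, n=300, m=5, n_edges_present=69,
        threshold_low=-2.0, threshold_high=0.0,
        thresholds_sorted_decreasing=True,
        interaction_sampler="uniform_split", n_positive=41,
        positive_range=(0.5, 1.0), negative_range=(-1.0, -0.5),
        rescale_factor=1.0 / 16.0, slab_scale=2.5,
    ),
    "symptom_emulation": dict(
        p=17, n=300, m=5, n_edges_present=34,
        threshold_low=-2.0, threshold_high=0.0,
        thresholds_sorted_decreasing=True,
        interaction_sampler="uniform_split", n_positive=26,
        positive_range=(0.05, 0.3), negative_range=(-0.2, -0.05),
        slab_scale=2.5,
    ),
}
_BASE_DESIGNS["ordinal_selection_rescaled_prior"] = dict(
    _BASE_DESIGNS["ordinal_selection"], slab_scale=2.5 / 16.0
)


def make_design(kind: str, **overrides) -> SimulationDesign:
    """Instantiate a registered design, optionally overriding its fields.

    Overriding ``p`` rescales the number of present edges (and the
    positive/negative split) proportionally to K = p(p−1)/2, rounding half
    up, unless explicit counts are also supplied.
    """
    if kind not in _BASE_DESIGNS:
        raise ValueError(
            f"unknown design {kind!r}; options: {sorted(_BASE_DESIGNS)}"
        )
    spec = dict(_BASE_DESIGNS[kind])
    base_p = spec["p"]
    p = overrides.get("p", base_p)
    if p != base_p and spec["n_edges_present"] is not None:
        base_k = base_p * (base_p - 1) // 2
        new_k = p * (p - 1) // 2
        if "n_edges_present" not in overrides:
            scaled = _round_half_up(spec["n_edges_present"] * new_k / base_k)
            spec["n_edges_present"] = max(1, scaled)
            if spec["interaction_sampler"] == "uniform_split":
                pos = _round_half_up(
                    spec["n_positive"] * new_k / base_k
                )
                spec["n_positive"] = min(spec["n_edges_present"], max(0, pos))
    spec.update(overrides)
    design = SimulationDesign(kind=kind, **spec)
    if design.n_edges_present is not None:
        if design.n_edges_present > design.n_pairs:
            raise ValueError("more present edges than pairs")
        if design.interaction_sampler == "uniform_split" and (
            design.n_positive > design.n_edges_present
        ):
            raise ValueError("positive count exceeds present-edge count")
    return design


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _draw_params(design: SimulationDesign, rng) -> tuple[ModelParams, EdgeIndicators]:
    p, m = design.p, design.m
    thresholds = []
    for _ in range(p):
        mu = rng.uniform(design.threshold_low, design.threshold_high, size=m - 1)
        if design.thresholds_sorted_decreasing:
            mu = np.sort(mu)[::-1]
        thresholds.append(np.concatenate([[0.0], mu]))
    sigma = np.zeros((p, p))
    iu, ju = np.triu_indices(p, 1)
    k = iu.size
    if design.n_edges_present is None:
        weights = rng.normal(0.0, design.interaction_sd, size=k)
        present = np.ones(k, dtype=bool)
        sigma[iu, ju] = weights
    else:
        chosen = rng.choice(k, size=design.n_edges_present, replace=False)
        weights = np.zeros(k)
        pos = chosen[: design.n_positive]
        neg = chosen[design.n_positive:]
        weights[pos] = rng.uniform(*design.positive_range, size=pos.size)
        weights[neg] = rng.uniform(*design.negative_range, size=neg.size)
        present = weights != 0
        sigma[iu, ju] = weights
    sigma[iu, ju] *= design.rescale_factor
    sigma = sigma + sigma.T
    gamma = np.zeros((p, p), dtype=np.int8)
    gamma[iu, ju] = present.astype(np.int8)
    gamma = gamma + gamma.T
    params = ModelParams(thresholds, sigma)
    return params, EdgeIndicators(gamma)


def generate_dataset(
    design: SimulationDesign, replicate_index: int, seed: int = 0
) -> GeneratedDataset:
    """Draw generating parameters and a dataset; deterministic in (seed, index)."""
    param_rng = np.random.default_rng([seed, replicate_index, 1])
    data_rng = np.random.default_rng([seed, replicate_index, 2])
    if design.fixed_pattern:
        # redraw weights per replicate but keep the edge pattern of replicate 0
        pattern_rng = np.random.default_rng([seed, 0, 1])
        params0, truth = _draw_params(design, pattern_rng)
        params, _ = _draw_params(design, param_rng)
        sigma = params.interactions * truth.gamma
        params = ModelParams(params.thresholds, sigma)
    else:
        params, truth = _draw_params(design, param_rng)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        data = gibbs_simulate(
            params, n=design.n, sweeps=design.gibbs_sweeps, rng=data_rng
        )
    return GeneratedDataset(
        data=data,
        params=params,
        truth=truth,
        zero_variance_columns=data.zero_variance_columns(),
    )


def selection_metrics(
    truth: EdgeIndicators, selected: EdgeIndicators
) -> SelectionMetrics:
    """Confusion counts of a selected graph against the generating graph."""
    if truth.p != selected.p:
        raise ValueError("graphs must have the same number of nodes")
    iu, ju = np.triu_indices(truth.p, 1)
    t = truth.gamma[iu, ju].astype(bool)
    s = selected.gamma[iu, ju].astype(bool)
    return SelectionMetrics(
        tn=int(np.sum(~t & ~s)),
        fp=int(np.sum(~t & s)),
        tp=int(np.sum(t & s)),
        fn=int(np.sum(t & ~s)),
    )


@dataclass
class StudyResult:
    """Per-dataset metrics plus averaged evidence-scatter data."""

    metrics: pd.DataFrame
    scatter: pd.DataFrame
    n_excluded: int
    threshold_lines: dict = field(default_factory=evidence_threshold_lines)

    def summary(self) -> pd.DataFrame:
        cols = ["specificity", "sensitivity", "rand_index"]
        mean = self.metrics[cols].mean()
        se = self.metrics[cols].std(ddof=1) / np.sqrt(len(self.metrics))
        return pd.DataFrame({"mean": mean, "mc_se": se})


def run_study(
    design: SimulationDesign,
    sampler: str = "pl",
    n_datasets: int = 25,
    n_iter: int = 10_000,
    burnin: int = 1_000,
    seed: int = 0,
    prior: PriorSpec | None = None,
    inner_sweeps: int = 10,
) -> StudyResult:
    """Generate datasets, fit the chosen sampler, and score graph recovery.

    Datasets with zero-variance columns are excluded (and counted), matching
    the screening rule of the binary benchmark. The scatter table holds the
    per-edge EAP interaction and inclusion probability averaged over the
    analyzed datasets.
    """
    if sampler not in ("pl", "dmh"):
        raise ValueError("sampler must be 'pl' or 'dmh'")
    if prior is None:
        prior = PriorSpec(slab_scale=design.slab_scale)
    rows = []
    k = design.n_pairs
    eap_sum = np.zeros(k)
    incl_sum = np.zeros(k)
    truth_sum = np.zeros(k)
    n_excluded = 0
    n_used = 0
    iu, ju = np.triu_indices(design.p, 1)
    for r in range(n_datasets):
        gen = generate_dataset(design, r, seed=seed)
        if gen.excluded:
            n_excluded += 1
            continue
        fit_seed = int(
            np.random.default_rng([seed, r, 3]).integers(0, 2**31 - 1)
        )
        if sampler == "pl":
            samples = run_pl_moms(
                gen.data, prior, n_iter=n_iter, burnin=burnin, seed=fit_seed
            )
        else:
            from .dmh import DmhConfig, run_dmh_moms

            samples = run_dmh_moms(
                gen.data,
                prior,
                DmhConfig(
                    inner_sweeps=inner_sweeps,
                    n_iter=n_iter,
                    burnin=burnin,
                    seed=fit_seed,
                ),
            )
        incl = inclusion_probability(samples)
        mpm = median_probability_model(incl)
        met = selection_metrics(gen.truth, mpm)
        rows.append(
            {
                "replicate": r,
                "seed": fit_seed,
                "tn": met.tn,
                "fp": met.fp,
                "tp": met.tp,
                "fn": met.fn,
                "specificity": met.specificity,
                "sensitivity": met.sensitivity,
                "rand_index": met.rand_index,
            }
        )
        eap_sum += samples.interactions.mean(axis=0)
        incl_sum += incl[iu, ju]
        truth_sum += gen.truth.gamma[iu, ju]
        n_used += 1
    metrics = pd.DataFrame(rows)
    if n_used:
        scatter = pd.DataFrame(
            {
                "edge_i": iu,
                "edge_j": ju,
                "mean_eap_sigma": eap_sum / n_used,
                "mean_incl_prob": incl_sum / n_used,
                "fraction_present_in_truth": truth_sum / n_used,
            }
        )
    else:
        scatter = pd.DataFrame(
            columns=[
                "edge_i",
                "edge_j",
                "mean_eap_sigma",
                "mean_incl_prob",
                "fraction_present_in_truth",
            ]
        )
    return StudyResult(metrics=metrics, scatter=scatter, n_excluded=n_excluded)
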