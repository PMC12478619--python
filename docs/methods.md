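# Methods

## Model

`ordmrf` implements a pairwise Markov random field for ordinal variables.
Variable `i` takes integer category scores `h = 0, …, m_i − 1` and the joint
probability of a response pattern is

```
P(x) = exp( Σ_i μ_{i,x_i} + Σ_{i<j} σ_{ij} x_i x_j ) / Z
```

The category score itself multiplies the interaction, so `σ_{ij}` is the log
adjacent-category odds ratio between variables `i` and `j`: for the
model-implied pair table, `log[π(h+1,q+1)π(h,q) / (π(h+1,q)π(h,q+1))] =
σ_{ij}` at every adjacent 2×2 block. The lowest threshold `μ_{i0}` is fixed
at zero; under independence (`σ ≡ 0`) the remaining thresholds satisfy
`μ_{ih} = log(π_{ih}/π_{i0})`. Both identities are exercised as tests
against enumerated joints. With binary variables and 0/1 scores the model
reduces exactly to the Ising model, which fixes the category coding
convention: scores are 0-based (a 1-based Likert input is recoded at
ingestion).

The full conditional of one variable is an adjacent-category logit in the
rest-score `r_i = Σ_{j≠i} σ_{ij} x_j`:

```
P(X_i = h | x_{-i}) ∝ exp(μ_{ih} + h · r_i)
```

Missing edges (`σ_{ij} = 0`) drop variable `j` from this conditional — the
global Markov property at the conditional level, tested exactly.

`Z` sums over `Π_i m_i` patterns and is intractable beyond toy sizes; an
enumeration routine (with an explicit state-space guard) exists for oracles
and toys only. Inference uses either the joint pseudolikelihood
`Σ_v Σ_i log P(x_{vi} | x_{v,−i})` or the exchange (double-MH) construction.

## Priors

* Interactions: discrete spike-and-slab. Given `γ_{ij} = 0`, `σ_{ij}` is a
  point mass at zero; given `γ_{ij} = 1` it follows the slab. Slabs:
  Cauchy(0, s) with default scale `s = 2.5` (the scale used throughout the
  simulation studies; `s = 1` exposed for robustness sweeps), or a
  zero-mean normal whose precision is the per-observation pseudolikelihood
  information about `σ_{ij}`. That information is evaluated at the null
  reference point — all interactions zero, thresholds at the independence
  maximum-pseudolikelihood point, where the conditional of `i` is the
  empirical category distribution — giving the closed form
  `E[x_j²]·Var_i(H) + E[x_i²]·Var_j(H)`. The null point is deterministic and
  cheap; it is verified against a finite-difference Hessian in tests.
* Structures: independent Bernoulli(θ = ½) indicators (all structures
  equally likely) by default, or Beta-Bernoulli(a, b) whose conditional
  inclusion odds given the other edges are `(a + e₋)/(b + K − 1 − e₋)`.
* Thresholds: independent beta-prime(α, β) on `e^{μ_{ih}}`, i.e. density
  `∝ e^{αμ}/(1+e^{μ})^{α+β}` in μ. Default `α = β = 1` (standard logistic):
  symmetric, heavy enough tails, and exactly conjugate in form to the
  generalized beta-prime proposal family below. The published default
  hyperparameters are not printed in the source material; α, β are
  configurable.

## PL-MoMS sampler

One iteration:

**Block I.** Every free threshold `μ_{ih}` in turn, by independence-chain
Metropolis. The log full conditional is concave with linear tails of slope
`n_{ih} + α` (left) and `−(n − n_{ih}) − β` (right), where `n_{ih}` is the
category count. The generalized beta-prime proposal
`g(μ) ∝ e^{p̃μ}/(1 + c e^{μ})^{p̃+q̃}` matches those tails exactly with
`p̃ = n_{ih} + α`, `q̃ = n − n_{ih} + β` (so `p̃ + q̃ = n + α + β` always),
and `c` solves `d/dμ log g = d/dμ log f` at the current state — the
derivative is available in closed form through the conditional category
probabilities. A draw is `μ′ = logit(Y) − log c` with `Y ~ Beta(p̃, q̃)`.
Degenerate derivative solutions fall back to `c = 1` with a warning. On a
single-variable binary problem the proposal *is* the target and acceptance
is exactly 1; in general the long-run draws match a 1-D quadrature
normalization of the target (KS < 0.02 in the acceptance suite).

**Block II.** A sequential scan of all pairs `i < j` (random scan
available). Each visit proposes to flip the edge: a *birth* (`γ: 0 → 1`)
draws `σ′ ~ N(0, ς²_{ij})` and accepts with
`min(1, PL-ratio · slab(σ′) · prior-odds / q(σ′))`; a *death* proposes
`σ′ = 0` with the reciprocal form. This is the Metropolis move over a
mixture of mutually singular distributions — no reversible-jump dimension
matching is needed, and the coupling `γ_{ij} = 0 ⇔ σ_{ij} = 0` holds at
every iteration (asserted per retained draw in tests). The
pseudolikelihood ratio involves only the conditionals of variables `i` and
`j`, evaluated over all observations via cached rest-scores. The scan is
followed by one random-walk Metropolis refresh of every active interaction.

**Adaptation.** Each pair has its own proposal SD `ς_{ij}`, updated during
burn-in by a Robbins–Monro recursion on `log ς` with gain `t^{−0.75}`
toward the univariate random-walk target acceptance rate 0.44, clamped to
`[10⁻³, 50]`, and frozen afterwards (diminishing adaptation). Only the
random-walk refresh acceptances drive the recursion: the 0.44 target is a
random-walk optimum, and letting the birth/death acceptances (which sit far
below it in sparse regimes) steer the shared `ς` was observed to collapse
transdimensional mixing in early testing. Between-model moves reuse the
adapted `ς` for their birth proposals.

All Metropolis ratios are computed in log space with max-subtracted
normalizations; acceptance compares against a log-uniform.

**Initialization.** `σ = 0`, `γ = 0`, thresholds at the independence MPLE
`log(n_{ih}/n_{i0})` with +½ count smoothing so empty cells stay finite —
deterministic and in the high-mass region of sparse posteriors. Defaults:
10 000 iterations, 1 000 burn-in, no thinning, all post-burn-in states
retained. Zero-variance data columns are a hard error at fit time (they
carry no information about their interactions); the data simulator only
warns, and the study harness excludes such datasets while counting them.

## DMH-MoMS sampler

Identical scan structure; every pseudolikelihood ratio is replaced by the
exchange acceptance. For a proposal `θ → θ′`, an auxiliary dataset `y` of
the observed shape is generated by `inner_sweeps` (default 10) full
sequential-scan Gibbs sweeps at `θ′`, initialized at the observed data —
one fresh auxiliary dataset per proposal, for threshold, birth/death, and
random-walk moves alike. The acceptance uses only the unnormalized log
joint, `ℓ*(x; θ′) − ℓ*(x; θ) + ℓ*(y; θ) − ℓ*(y; θ′)`, so `Z` cancels
exactly; because `ℓ*` is linear in the sufficient statistics, the
difference reduces to `(statistic(x) − statistic(y)) · Δθ` (category count
for a threshold, score product `Σ_v x_{vi} x_{vj}` for an interaction) —
the generic and reduced forms are asserted equal in tests. Threshold moves
reuse the Block I proposal with the DMH acceptance. The inner sweep is the
same compiled kernel as the data simulator; with 50 inner sweeps on a
two-variable toy the sampler reproduces the exact-likelihood posterior
inclusion probability within Monte-Carlo error, and the within-model bias
decreases monotonically over 1 → 5 → 50 sweeps.

## Inference summaries

Inclusion probabilities are per-edge means of `γ`; the median probability
model keeps edges with probability strictly above ½ (exact ties excluded).
The inclusion Bayes factor is the posterior-to-prior inclusion odds ratio;
estimated probabilities are truncated into `[1/(2T), 1 − 1/(2T)]` for `T`
retained draws before forming odds, and truncated values are flagged as
bounds rather than point estimates. Evidence categories use the
conventional strict thresholds: BF < 1/10 absence, BF > 10 presence, else
inconclusive. Sub-structure (e.g. clique) Bayes factors compare the visit
frequency of an edge configuration with its structure-prior probability
(`2^{−k}` for `k` edges under the uniform prior, so a 3-clique has prior
odds 1/7). Structure uncertainty is tracked by hashing the upper-triangle
indicator pattern of every retained draw. Under the uniform prior,
inclusion probabilities 10/11, 1/2 and 1/11 correspond exactly to inclusion
Bayes factors 10, 1 and 1/10; these constants are emitted with study
scatter data.

## Synthetic-data generator and study designs

`gibbs_simulate` draws `n` independent parallel chains, each initialized
from the σ ≡ 0 model (categorical softmax of the thresholds) and advanced
by sequential-scan Gibbs sweeps (default 1 000) in a compiled kernel;
randomness enters only as pre-generated uniforms from a seeded Generator,
so output is bit-reproducible. Correctness checks: χ² goodness-of-fit of
marginals under independence, recovery of `σ` from empirical adjacent-
category log odds-ratios at n = 50 000, and exact stratified conditional-
independence structure.

Registered designs (constants are the package's study conditions):

* `binary_park` — p = 24 binary variables, n = 300, thresholds U(−1, 1),
  69 of 276 edges present: 41 weights U(0.5, 1), 28 weights U(−1, −0.5).
* `ordinal_selection` — the same edge pattern and weight draw moved to five
  categories: thresholds U(−2, 0) sorted decreasing, weights multiplied by
  1/16 because the score products grow from {0, 1} to 0–16.
  `ordinal_selection_rescaled_prior` tags the same data recipe with a slab
  scale shrunk by the same factor (Cauchy 2.5/16) for the analysis stage.
* `ordinal_evidence` — p = 24, m = 5, n = 300, thresholds U(−2, 0) sorted
  decreasing, dense interactions N(0, 0.1). The SD is chosen so that
  effective effects (σ times products up to 16) span the evidence bands
  from clear exclusion to clear inclusion at n = 300.
* `symptom_emulation` — a 17-variable, 5-category stand-in for a PTSD-style
  symptom checklist (synthetic; no empirical data are bundled): 34 of 136
  edges, mostly positive with a minority of negative weights of magnitude
  0.05–0.3, decreasing thresholds.

The present-edge pattern is redrawn per replicate (configurable to fixed);
`p` overrides rescale the edge counts proportionally to `K = p(p−1)/2` with
round-half-up. Zero-variance columns are flagged, and the study harness
excludes affected datasets while reporting the count.

What the generator does *not* emulate: real questionnaire data have
item-specific missingness, potential latent multidimensionality beyond the
pairwise MRF, and response styles; passing tests demonstrate correctness of
the machinery under the model, not robustness to misspecification.

## Problem sizes and numerical choices

The published benchmark protocol (500 datasets × 50 000-iteration chains;
PL ≈ 5 min and DMH ≈ 11 h per dataset) is exposed behind an explicit
`--full` flag; defaults, the test suite and the acceptance script run
scaled-down versions chosen as desk-scale study sizes: oracle toys at p = 2
with 50 000–100 000 draws; parameter recovery at p = 6, m = 3, n = 2 000
with 20 (tests) or 10 (acceptance script) replicates of 2 500-iteration
chains; PL selection studies at the full p = 24, n = 300 with 4–5 datasets
and 1 500–2 000-iteration chains; PL-vs-DMH ordering checks at p = 10.
Means are reported with Monte-Carlo standard errors so scaled-down runs can
be compared to full-scale values with honest uncertainty.

Known limitations. The pseudolikelihood underestimates posterior spread:
relative to the exact-likelihood (DMH) posterior it leaves interaction
EAPs further from zero, which raises sensitivity and lowers specificity —
the trade-off the selection studies quantify. A concrete consequence,
visible in the recovery study, is that the sampling variability of
joint-MPLE estimates on null edges that share neighbors exceeds the
pseudolikelihood curvature, so occasional data-level false inclusions
survive arbitrarily long chains (~1–2% per null edge at n = 2 000 under
the Cauchy(2.5) slab). DMH accuracy is limited by the 10-sweep inner
sampler at benchmark scale; its exactness improves monotonically with
inner sweeps. Bayes factors at the truncation bound are reported as
one-sided bounds, not estimates.
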