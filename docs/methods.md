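# Methods

This note documents the models, conventions, and numerical choices behind
`netcontrol`, and what the synthetic benchmarks do and do not show about
real connectivity data.

## Linear control framework

Dynamics are the discrete-time LTI system `x(t+1) = A x(t) + B u(t)` on a
symmetric, non-negative weight matrix `A` with zero diagonal.  Before any
control metric is computed, `A` is divided by its largest eigenvalue
(Perron root), so the slowest-decaying mode has unit rate in every network
and horizons are comparable across networks.  Division by the Perron root
(rather than, say, `1 + λ_max`) is chosen because it fixes `λ_max = 1`
exactly, which is what "comparable time scales" requires here.

* **Control horizon** `T` (integer, default 4).  Small horizons probe
  transient controllability; the Gramian power series `I + A² + ⋯ +
  A^{2(T-1)}` gains one term per step.  Gramian monotonicity in `T`
  (PSD increments) and the resulting monotone decrease of energies are
  covered by tests for `T = 1..10`.
* **Minimum control energy** is computed by Cholesky-solving the SPD system
  `W x = e_i` instead of forming `W⁻¹`; with the full control set `W ⪰ I`,
  so the solve cannot be singular.  Inputs with asymmetry below 1e−10 are
  symmetrized as `(A + A')/2`; anything larger is rejected.
* **Modal controllability** uses a symmetric eigensolver with eigenvalues
  sorted descending.  For repeated eigenvalues the per-eigenvector terms
  depend on the returned basis, but their sum within a degenerate eigenspace
  (a projector diagonal) does not, so `φ` is well defined.
* **Weighted subgraph centrality** is evaluated on the *raw* weighted
  matrix by default (a `normalized=True` switch exists), since it is a
  descriptive centrality of the network itself rather than of the
  normalized dynamical system.  All correlation analyses use one convention
  for all metrics being compared.

## Synthetic network generator

Networks have a 2 × 2 block structure over two equal planted communities
(`n/2` each; equal halves make the modularity extremes land exactly at
−0.5 and 0).  A continuum position `f ∈ [0, 1]` fixes the fraction of the
`M = round(density · n(n−1)/2)` edges placed in the block(s) of interest:

* *disassortative → assortative*: `f` split evenly between the two
  on-diagonal blocks, `1 − f` between communities;
* *disassortative → core*: `f` in the `[1,1]` (core) block, `1 − f`
  between communities, `[2,2]` empty.

Fractional block counts are rounded by largest-remainder allocation (ties
toward the off-diagonal block, then `[1,1]`), so the total `M` — and hence
the binary density — is preserved exactly at every grid point.  Edges are
then placed uniformly at random without replacement inside each block.
Defaults are brain-scale: `n = 234`, density `0.1485`, ensembles of 100
networks per grid point, 21-point fraction grids.

Weight families:

* **normal(μ = 0.5, σ = 0.12)** — non-positive draws are redrawn
  (probability ≈ 1.5e−5 per draw at the defaults) so the weight matrix
  stays non-negative, as the control framework requires.
* **geometric** — support {1, 2, …} with `P(k) = p^{k−1}(1−p)` (an edge
  that exists keeps weight ≥ 1; weight 0 would delete the edge and change
  the binary density).  Per block, `p` is the block's binary density
  (edges present / possible pairs); a `p_mode="edge_fraction"` switch uses
  the block's share of total edges instead, and a fixed scalar `p` is also
  accepted.  Larger `p` means heavier weights (mean `1/(1−p)`).
* **lognormal(0, 1)** — used by the fat-tailed surrogate networks.

Analytic planted-partition modularity for balanced blocks with uniform
weights: `Q = f − 1/2` on the assortative continuum and
`Q = f − 1/2 − f²/2` on the core continuum (0 at `f = 1`); the empirical
weighted Q tracks these closely for the narrow normal weights.

### Surrogate "empirical-like" networks

`surrogate_empirical_network` draws a uniformly random topology at the
given density with `qa_like` (normal, approximately symmetric) or
`streamline_like` (log-normal, fat-tailed) weights.
`surrogate_empirical_ensemble` emulates repeated scans of one anatomy: a
single template is re-instantiated with 10% of its edges rewired to random
empty pairs (fresh weights) and the surviving weights jittered by
log-normal noise (s.d. 0.1 on the log scale).  Node identity therefore
persists across instantiations — the property that makes region-level
averaging meaningful.  Averaging metrics over fully *independent* random
networks instead leaves no persistent regional profile and the region-level
correlations collapse to noise.

What these surrogates do not capture: spatial embedding, true modular and
rich-club organization, and degree–weight correlations of real
connectomes.  One consequence, documented here deliberately: with
homogeneous qa-like weights on unstructured topology, `(A²)_ii` is nearly
a deterministic function of node strength, so after rank-controlling
strength the residuals of energy and modal controllability are noise and
their partial correlations with WSC are near zero.  The sign-structure
check (WSC partials negative with E and φ, positive with a) is therefore
asserted on the fat-tailed ensemble, whose weight heterogeneity creates
the higher-order walk structure the check needs.  Passing it shows the
pipeline recovers the sign structure when the signal exists in the data —
not that every random network carries that signal.

## Weighted stochastic block model

The model: labels `z_i ∈ {1..K}`; for an unordered pair, an edge exists
with probability `p_{z_i z_j}` and, if present, carries a weight from
`N(μ_{z_i z_j}, σ²_{z_i z_j})` (the log-normal family applies the normal
model to log-weights).  The two likelihood parts are mixed with weight
`α` (default 0.5, equal weighting; exposed as a parameter): `α` times the
Bernoulli term over all pairs plus `1 − α` times the weight term over
present edges.

Inference is conjugate mean-field variational Bayes:

* `q(z_i)` categorical; updated **one node at a time** (each update an
  exact coordinate maximization), so the evidence lower bound is
  non-decreasing along every trajectory — an asserted invariant.
* `q(p_rs)` Beta and `q(μ_rs, σ²_rs)` normal-inverse-gamma, updated in
  closed form from α-tempered expected sufficient statistics.
* Priors: Beta(1, 1); NIG with unit pseudo-counts (`κ₀ = 1`, shape
  `a₀ = 1`) centered empirically on the mean and variance of the observed
  (transformed) edge weights.  These are weakly informative; the empirical
  centering mainly guards against degenerate variance in near-empty blocks.
* Convergence: bound improvement < 1e−6 or 200 iterations.  Restarts
  (default 10) keep the fit with the highest final bound.  The first
  restart is seeded from k-means on the leading `K` eigenvectors of the
  weight matrix; the rest from peaked symmetric Dirichlet draws.  The
  spectral restart matters: coordinate ascent has a large basin of
  attraction around the label-symmetric fixed point, and purely random
  near-uniform initializations frequently stall there.
* Degree correction is deliberately not implemented; the likelihood above
  is the uncorrected block model.

Model order `K` is chosen by maximizing the final variational bound over a
grid (`select_k`); the KL terms of the bound penalize superfluous blocks.
Consensus across restarts uses variation of information
`VI = H(p₁) + H(p₂) − 2 I(p₁; p₂)` (nats): the partition minimizing the
summed VI distance to the others is the *central partition* (ties broken
by lowest index).

## Region-level statistics

Per-node metric tables from repeated network instantiations are averaged
region-wise, then every {PC, Z, WSC} × {E, a, φ} pair is correlated with
plain Spearman and with partial Spearman controlling node strength.
Partial Spearman is the Pearson partial correlation on midranks with a
t-approximate p-value on `n − 3` degrees of freedom (the standard toolkit
definition; cross-checked against pingouin in the tests).  A covariate
that is constant after ranking falls back to plain Spearman with a
degeneracy flag; raw p-values are reported without multiplicity
correction.

Continuum sweeps summarize each ensemble by the mean over the per-node
values ("mean of the 234 obtained values"; a median option exists), report
mean ± s.d. across the 100 networks, and Z-score the means across the grid
(sample s.d. convention).  Curve extrema are read off after a 3-point
moving-average smoothing (truncated windows at the ends) — a deterministic
replacement for reading extrema off a plot; ties return the midpoint of
the tied Q values.

## Known numerical behavior of the energy curve

On the disassortative-to-assortative continuum the node-mean energy and
node-mean average controllability are exact spectral traces of the
normalized matrix: `mean(E) = (1/n) Σ_j 1/g(λ_j)` and
`mean(a) = (1/n) Σ_j g(λ_j)` with `g(λ) = 1 + λ² + λ⁴ + λ⁶`.  Because the
two are anti-monotone in the spread of the spectral bulk, they cannot both
attain an extremum of the same sign at the random point.  In practice
(normal weights, defaults): mean average controllability has a clean
minimum at Q ≈ 0, while the mean-energy curve is a shallow U whose trough
is flat to ~5e−5 across |Q| < 0.3, with its smoothed argmin landing near
|Q| ≈ 0.2–0.3 rather than at 0.  Without spectral normalization the
energy curve instead shows a sharp minimum exactly at Q ≈ 0; the
`ExperimentConfig.normalize` flag exposes both conventions (default on).
With geometric weights the (normalized) energy curve inverts and peaks at
Q ≈ 0 robustly.  The acceptance script and tests report the normalized
readouts.

## Problem sizes

Defaults reproduce the brain-scale design (n = 234, ensembles of 100,
21-point grids) in the acceptance script.  The test suite exercises the
same pipelines at reduced sizes chosen for quick iteration — n = 120 with
ensembles of 30 for the sweep readouts, n = 100 and 20 seeds for block
recovery, 12 instantiations of a 234-node template for the region-level
sign checks — sizes at which every asserted property is already stable.
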