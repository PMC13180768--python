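# Methods

`ergmflow` implements simulation-based Bayesian inference for exponential
random graph models (ERGMs) over the statistic triple
(edges, GWESP, GWNSP), with three inference routes — the approximate
exchange algorithm, amortised/sequential neural posterior estimation, and
neural likelihood/ratio surrogates — plus the evaluation machinery needed
to decide whether a neural fit can be trusted.

## Model

An ERGM puts mass `p(y | θ) = exp(θᵀh(y)) / c(θ)` on every simple
undirected graph `y` on `n` labelled vertices, where `h(y)` is the
statistic vector and `c(θ) = Σ_{y'} exp(θᵀh(y'))` sums over all
`2^{n(n−1)/2}` graphs.  The statistics are

* edges — `|E(y)|`;
* GWESP — `e^τ Σ_{i≥1} (1 − (1 − e^{−τ})^i) p_i`, with `p_i` the number of
  *connected* vertex pairs sharing exactly `i` neighbours;
* GWNSP — the same weighting over `np_i`, the *non-connected* pairs.

The decay `τ` (default 0.75) down-weights high shared-partner counts;
`w_1 = 1` exactly for every `τ`, and at `τ = 0` the statistics reduce to
unweighted counts of pairs with at least one shared partner.  These two
closed forms, plus hand enumerations of the triangle, 3-path and 4-cycle,
anchor the statistic implementation in the tests.

Dyad toggles have O(n) change statistics (the pair itself moves between
the `p`/`np` histograms, and only pairs through the two endpoints shift by
one shared partner), which is what makes single-dyad Metropolis chains
affordable.  Adjacency is stored dense (uint8) — intended network sizes
are n ≈ 30–100, at most a few thousand dyads.

## Simulation

`simulate_network` runs a single-dyad Metropolis chain: propose a uniform
random dyad, accept the toggle with probability `min(1, exp(θᵀΔh))`.  The
chain length per simulated network (`aux_iterations`) and the initial
graph (`empty` / `full` / `observed` / `provided`) are always explicit:
in multi-modal or near-degenerate regimes the realised network genuinely
depends on both, so they are part of the study conditions, not nuisance
settings.  A tie/no-tie (TNT) kernel — half the proposals drawn from the
current edge list, with the proposal-ratio correction in the acceptance —
is available behind `kernel="tnt"` for very sparse graphs; the plain
kernel is the default.  The inner loop is numba-compiled; the first call
in a session pays a one-time JIT cost.

For `n ≤ 7` vertices, `enumerate_exact` computes the full outcome
distribution (statistics of all graphs, aggregated by statistic value),
exact moments and `log c(θ)`.  It is the oracle against which both the
simulator and the samplers are checked, and it also supports a grid
posterior `π(θ|x) ∝ π(θ) exp(θᵀx) / c(θ)` used as the reference for the
exchange chain on toy graphs.

## Exchange algorithm

The posterior is doubly intractable.  The exchange algorithm proposes
`θ' ~ N(θ, Σ)`, simulates one auxiliary network `y' ~ ERGM(θ')`, and
accepts with log-ratio
`log π(θ') − log π(θ) + (θ'−θ)ᵀh(y_obs) + (θ−θ')ᵀh(y')`, in which the
normalising constants cancel.  The proposal covariance is not dictated by
the method; the default is `0.1·I` with optional burn-in scale adaptation
towards 20–40% acceptance.  The auxiliary chain is re-initialised per
proposal from the simulator config.

The algorithm is *approximate*: it is exact only when the auxiliary
simulation delivers a perfect draw.  We observed (and the oracle
comparison documents) that for boundary observations — near-empty or
near-complete graphs — posterior mass extends into regions where
auxiliary chains mix poorly and the exchange posterior becomes visibly
over-dispersed even on 5-vertex toys.  The oracle comparison therefore
conditions on an interior observation and uses auxiliary chains of
~200 sweeps; both choices are part of the documented protocol.

## Neural posterior estimation

Because `h(y)` is sufficient, inference conditions on the statistics
`x = h(y)` rather than the graph.  Amortised NPE simulates pairs
`θ_b ~ π(θ), x_b ~ p(x|θ_b)` and fits a conditional masked autoregressive
flow `q_φ(θ|x)` by maximum likelihood; with the prior as proposal, the
trained density estimates the posterior directly, and a single trained
flow serves any observation of matching dimension by forward passes.

The flow is L stacked affine autoregressive transforms (default L = 5)
with MADE-masked single-hidden-layer tanh conditioners of width H
(default 50), conditioned on `x` unmasked, with order-reversing
permutations between transforms and a standard-normal base.  The log-scale
outputs pass through a smooth clamp `c·tanh(a/c)` (c = 5) for numerical
stability, output layers are zero-initialised so the flow starts at the
identity, and both `θ` and `x` are z-scored from the training set (ERGM
statistics span orders of magnitude).  Training uses Adam
(lr 5e−4, batch 200), a 10% validation split, early stopping with
patience 20 and restoration of the best-validation parameters.  The whole
flow — forward pass, reverse-mode gradients, optimiser — is implemented
directly in NumPy; the gradient is verified against finite differences in
the test suite, and the trained conditional density is checked to
integrate to 1 by importance sampling.

Sequential NPE targets one observation: round 1 is amortised NPE; round
r ≥ 2 draws its budget from the current flow posterior at `x_obs`,
accumulates pairs across rounds, warm-starts from the previous
parameters, and minimises the *atomic* loss: per pair, a softmax
cross-entropy over an atom set (the true `θ_b` plus `n_atoms − 1`
contrasting parameters resampled from the batch, default 10 atoms) with
logits `log q_φ(θ|x_b) − log π(θ)`.  This absorbs the proposal-correction
constant `Z_φ(x)`, which has no closed form for a MAF; it is never
evaluated explicitly.  Two exact identities pin the implementation down:
the loss is 0 with a single atom and `log(n_atoms)` when the `q/π` ratio
is constant across atoms, and one round of SNPE is bit-identical to
amortised NPE under shared seeds.  Proposal sampling from the flow is
direct (no rejection): all priors here are Gaussian with unbounded
support.

## Surrogate comparators

NLE fits the same flow with roles swapped — a density over `x` given `θ`
— giving a likelihood surrogate; NRE trains an MLP classifier (50 units,
2 layers, scikit-learn) separating joint pairs from within-batch
θ-permuted pairs, whose logit estimates `log p(x|θ)/p(x)`.  Both then
need MCMC at inference time: an adaptive random-walk Metropolis updates 8
chains in one batched operation on `log π(θ) + log surrogate`.  An
`OracleRatio` hook accepts an analytically supplied ratio so MCMC
correctness can be tested in isolation from classifier calibration.

## Evaluation designs

**Bias.** K truths are rejection-sampled from the prior into edge-count
strata by the mean edge count of pilot simulations (25 by default),
rejecting anything at or above the cap where the geometrically weighted
statistics become collinear.  The reference design is K = 40 truths, 10
per stratum over [0, 275), [275, 550), [550, 825), [825, 1100) on
90-vertex networks, M = 1,000 replicate observations per truth, 100,000
posterior draws per fit, prior N(0, 10I), B = 500,000 training pairs.
Point estimates average the per-replicate posterior means; ME / MAE /
RMSE are computed componentwise.  Whether the original stratum
assignment used mean or single-realisation edge counts is not
determinable; this implementation uses the pilot mean.

**Magnitude.** Parameter-space errors are mapped to the statistic space:
simulate a large reference sample at the truth and a predictive sample at
the replicate posterior means (default 100 networks per mean); a
component is small-bias when the predictive mean lies inside the
reference 5th–95th percentile band, and coverage is reported as the
percentage of reference draws inside the predictive min–max range.  The
overlap notion admits several renderings; the min–max containment rate
was chosen as the most conservative and is isolated behind one function
so a histogram-overlap coefficient can replace it.

**Coverage diagnostics.** `coverage_diagnostic` reports (a) a leakage
proxy — the fraction of posterior draws whose prior log-density falls
below the prior's 0.1% quantile (computed exactly via the chi-squared
radial quantile), (b) per-statistic standardised posterior-predictive
discrepancy, and (c) a truncation flag raised when the posterior mean
sits within 2 posterior sds of the proposal's effective support edge
(0.5%/99.5% quantiles).  The 0.1% threshold is a design choice of this
package; leakage is otherwise only a qualitative notion.

**Cost.** Exchange fitting costs ≈ `c·S·C1(I_aux)` per network (C1 = one
auxiliary simulation, S = posterior draws, c = dimensionless overhead);
amortised estimation costs `B·C1 + C2(B,H,L) + J·S·C3(H,L)` over J
networks.  Equating them gives the break-even
`J = (B·C1 + C2) / (S·(c·C1 − C3))`.  On the reference timing inputs
(C1 = 0.05163 s at I_aux = 10,000, C2 = 1311.3 s, C3 = 1.83 µs,
c = 0.48, B = 50,000, S = 100,000) this gives J ≈ 1.57: amortisation pays
off from the second network on.  Only the arithmetic and monotonic ranks
are tested; wall-clock values are hardware-dependent and the timing
harness records them without targets.

## Problem sizes in the default runs

The default test suite and the acceptance script run every study at
reduced scale, chosen so a single CPU completes them in minutes while
preserving the studied phenomena:

* oracle checks on 5-vertex graphs (exact enumeration, 400 replicates,
  exchange chains of 8,000 samples with 2,000 auxiliary iterations);
* conjugate checks on the linear-Gaussian toy
  (`θ ~ N(0, I)`, `x|θ ~ N(θ, 0.01·I)`, B = 20,000), whose posterior mean
  `x/(1+σ²)` is analytic;
* the stratified bias study on 30-vertex networks (435 dyads) with
  B = 10,000 prior pairs, K = 4 truths (one per stratum, boundaries
  0/30/60/90/120 — the same ~27% density cap as the 90-vertex design),
  M = 50 replicates, 2,000 posterior draws per fit, and the sanity floor
  that MAE stays below the prior standard deviation per component;
* SNPE round studies on 30-vertex networks with 500 pairs per round
  (within-coverage truth (−1.05, −0.86, 0.63); far-outside truth
  (−4.61, −4.45, 8.46) under an N(0, I) prior).

Paper-scale protocols (n = 90, B = 500,000, M = 1,000, K = 40, 100,000
draws) are reachable through the same APIs and CLI by passing those
arguments.

## What the synthetic data does and does not show

All training and evaluation data come from the package's own simulator,
so the studies validate internal consistency of the estimation stack:
correct statistics, a correctly targeted chain, a flow that actually
estimates the posterior it is trained for.  They do not exercise features
of real networks the model omits — nodal covariates, degree
heterogeneity beyond what (edges, GWESP, GWNSP) induce, directed or
valued ties — and a reduced-scale pass does not bound the bias of a
90-vertex, half-million-pair study.  The 30-vertex runs do reproduce the
qualitative pathologies that matter in practice: boundary effects (wide
parameter regions mapping to near-empty/near-complete graphs), SNPE
variance contraction under small budgets, and the coverage-masking
failure where a proposal-truncated posterior still produces
plausible-looking predictive checks — the diagnostic the package exists
to expose.

## Known limitations

* The exchange sampler's proposal covariance and adaptation are this
  package's choices; reference implementations may tune differently.
* Affine (not spline) autoregressive transforms; strongly multi-modal
  posteriors may need more expressive flows than the default.
* The flow trainer is single-threaded NumPy; paper-scale budgets
  (B ≥ 10⁵) train in hours, not minutes.
* Exact enumeration is capped at 7 vertices (2²¹ graphs) and is only
  fast below that cap.
* The undirected-from-nominations construction is implemented and tested
  on synthetic nomination lists; real nomination datasets are supplied by
  the user as edge lists.
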