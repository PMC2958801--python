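# Methods

## Model

A dyad is one investor–trustee pair playing ten rounds; round `t` produces
an investment ratio `i_t` (fraction of the fresh 20-MU endowment sent) and
a repayment ratio `r_t` (fraction of the tripled transfer returned).  Only
investor behavior is modeled.  The response vector of dyad `n` is
`y_n = (i_3, …, i_10)` — always eight entries, regardless of the look-back
window, so models with different windows remain comparable on identical
data.  The model matrix `X_n` holds, for each response round, every
monomial of total degree ≤ P in the 2D lagged variables
`i_{t−1}, r_{t−1}, …, i_{t−D}, r_{t−D}`; there are `M = C(2D+P, P)`
columns, ordered constant first, then degree-1 terms in recency order
(investment before repayment within a lag), then each higher degree
lexicographically.  The population model is a K-component mixture of
Gaussian regressions,

    y_n | z_n = k ~ N(X_n β_k, σ²_k I₈),   P(z_n = k) = λ_k,

with priors λ ~ Dirichlet(α), β_k ~ N(b₀, B₀), σ²_k ~ InvGamma(a, b).

### Prior defaults and why

The sources for the prior structure leave the hyperparameter values
unstated, so the package sets weakly informative defaults, all
configurable: α = 1 (uniform on the simplex), b₀ = 0, B₀ = I (unit prior
variance per coefficient — the regressors all live on [0, 1], so
coefficients of magnitude ≫ 1 are implausible), a = 3, b = 0.5 (prior mean
σ² = 0.25, i.e. residual sd ≈ 0.5, half the response range).  No test or
result depends on these exact values.

## Sampler

Two-stage data augmentation.  Step 1 draws each dyad's allocation from
`P(z_n = k) ∝ λ_k N(y_n; X_n β_k, σ²_k I)`, computed in log space with
log-sum-exp normalization.  Step 2, per cluster on the pooled member data:
σ²_k from its inverse-gamma full conditional given β_k, then β_k from its
multivariate-normal full conditional given σ²_k (precision
`B₀⁻¹ + X'X/σ²_k`), then λ from Dirichlet(α + counts).  Empty clusters
fall back to prior draws.  Chains are bit-reproducible from their seed.

**Initialization.**  The first planned scheme — allocations from the prior
weights, parameters from the priors — proved unreliable: prior β draws are
far from any data-supported region, the first allocation sweep is
effectively arbitrary, and chains frequently locked into a local mode in
which two true clusters merge and one component sits empty (that mode
sits ~130 log-likelihood units below the dominant mode on default
synthetic data, yet plain Gibbs practically never escapes it at desk-scale
chain lengths).  The default initialization is therefore a short
random-restart MAP-EM fit of the same mixture (the inverse-gamma prior in
the variance M-step prevents the degenerate σ² → 0 likelihood spikes plain
EM is prone to), refined by a split pass: repeatedly sacrifice the
emptiest component, split the most overdispersed one by 2-means on its
members' responses, re-run EM, accept on likelihood improvement.  The
chain starts from allocations sampled from the EM responsibilities, with
parameters drawn from their full conditionals given those allocations
(the initial σ² draw conditions on the member least-squares fit so initial
variances have the data's scale).  `init="random"` and `init="prior"`
remain available.

**Label switching.**  No identifiability constraint is imposed during
sampling.  Within-chain summaries (membership frequencies, modal
partitions) are label-switching-robust only when switching is rare, so
chains count draws in which more than 30% of allocations change at once
and expose the count (`n_label_switches`); well-separated fits show 0.

**Diagnostics.**  Residual normality: residuals `y − Xβ̂_z` at the modal
allocation with posterior-mean coefficients, standardized within cluster,
pooled, Jarque–Bera tested; clusters with under 3 residuals or zero
variance are excluded, and an all-degenerate case is reported as
inapplicable rather than as a pass.  Convergence: a Raftery–Lewis
run-length diagnostic (binarize the scalar trace at the target quantile,
choose the smallest thinning at which a first-order two-state Markov chain
is BIC-preferred over second-order, then the standard burn-in and
run-length formulas) for every monitored scalar.

## Marginal likelihood and model search

Candidate models are the triples (K ≤ 10, P ≤ 3, D ≤ 2).  Each candidate
is scored by the Laplace–Metropolis estimator

    log m(y) ≈ (d/2) log 2π + ½ log |H*| + log p(y|θ*) + log p(θ*),

evaluated in unconstrained coordinates — additive-log-ratio for λ, log for
σ² — because the simplex and positivity constraints would otherwise
corrupt the Gaussian approximation; the prior density in those coordinates
includes the Jacobian.  `H*` is the sample covariance of the recorded
draws (ridge-regularized with a warning if singular).  θ* is found by
component-wise ascent (blocks: each β_k, the log-variances, the weight
log-ratios) from the best recorded draw, with analytic block gradients,
until the relative improvement falls below 1e−8 or 200 sweeps.

The harmonic-mean estimator (−log of the posterior average of inverse
likelihoods, computed via log-sum-exp) is implemented as a cross-check
only.  It is upward-biased in proportion to how much the posterior
concentrates relative to the prior; the package's validation compares it
with the exact (quadrature) evidence on a deliberately weakly informative
single-component problem and documents the looser 2-log-unit tolerance.
On informative problems only its model *ranking* is trusted.

Search protocol: several samplers per candidate (9 by default, 3 in the
desk-scale configuration) under the search schedule (8,000 cycles with
3,000 burn-in at full scale).  A sampler is *empty-typed* if some cluster
has no members in its modal partition over the recorded draws; a candidate
is discarded when at least a threshold number of samplers are empty-typed
(configurable: 6-of-9, or the 2-of-3 variant that matches 3-sampler runs).
Selection then orders the surviving candidates by free-parameter count
`K(M+1) + (K−1)`; candidate A *beats* a simpler candidate B if A's log-ML
sample has both the larger median and a Wilcoxon rank-sum rejection, and
the selected model is the candidate with the largest median log-ML among
those that beat every simpler surviving candidate.  With 3 samplers per
model an exact two-sided rank-sum test cannot reach the 5% level even
under complete separation (minimum two-sided p = 0.1), which would make
the parsimony rule select the simplest model unconditionally; the test is
therefore one-sided ("greater") with rejection at p ≤ 0.05, which complete
separation attains exactly.

## Synthetic populations

The generator is the package's stand-in for the undeposited 287-dyad
cohort and defines the study conditions used throughout the tests:

- **n = 287 dyads** (574 subjects), eight groups (Healthy 40%, ADHD 12%,
  ASD 10%, MDD 8%, BPD-M 7%, BPD-N 8%, and two healthy task variants Per
  8% / Imp 7%).
- **Four latent clusters** with base weights (0.54, 0.23, 0.15, 0.08) —
  the chance shares of the four behavioral styles — and first-order lag-2
  regressions (P=1, D=2, M=5) with residual sd 0.1 per cluster.
- **Generating coefficients** (columns 1, i₁, r₁, i₂, r₂):
  a mid-level reciprocating cluster (0.15, 0.30, 0.25, 0.15, 0.15), a
  strongly lag-sensitive cluster with negative lag-2 terms (0.40, 0.50,
  0.10, −0.35, −0.25), a low-investment cluster with negative repayment
  response (0.20, 0.20, −0.15, 0.15, −0.10), and a high-constant "trust"
  cluster (0.70, 0.10, 0.02, 0.03, 0.02).  They were chosen once so that
  every pair of clusters is separated by at least ~2 residual sd in mean
  trajectory or by clearly distinct lag signatures, with near-stationary
  trajectories inside (0, 1) — the "well-separated" regime the recovery
  experiments presuppose.  An earlier draft with a smaller second-cluster
  constant left two clusters under 1 sd apart and the mixture (correctly)
  refused to distinguish them.
- **Enrichment**: each clinical group's cluster draw multiplies the base
  weight of "its" cluster by 3 and renormalizes (ADHD→1, ASD and Imp→2,
  BPD-M/N→3, MDD and Per→4, zero-based internally); Healthy is untilted.
- **Repayments are exogenous** Beta draws (concentration 8) with
  group-specific means (0.35 for BPD partners, 0.6 for MDD/Per, 0.45–0.5
  otherwise): the analysis clusters only investor behavior, and a
  group-dependent repayment level suffices to entangle the regressors.
  The Beta family is a modeling convenience, not sourced.
- **Rounds 1..D** investments are Beta(mean 0.5, concentration 8) draws;
  later rounds follow the cluster regression plus Gaussian noise,
  **clipped to [0, 1]**.  The fitted likelihood is an unbounded Gaussian,
  so the generator reports the clip rate and warns above 5%; defaults
  produce ≈2%.
- **Severity scores** (ASD-labeled dyads: a repetitive-behavior scale,
  intercept 4, slope +3, noise sd 1; BPD-labeled: an interpersonal-trust
  scale, intercept 60, slope −15, noise sd 5) are linear in the dyad's
  membership probability of the linked cluster *under the generating
  model* — the smoothed version of the true-cluster indicator — so
  severity genuinely correlates with membership probability.
- **Zero-investment rounds** store repayment ratio 0 (the ratio is
  undefined when nothing is sent); records flag such rounds.  Carrying the
  previous repayment forward is available as a configurable alternative.
- **Seeding**: one master seed; each dyad uses a counter-derived
  substream, so population size changes never perturb earlier dyads.

What the generator does **not** emulate: behavioral coupling from partner
to investor *within* a dyad beyond the regression structure (cluster
membership is assigned per investor, independent of the realized
repayments).  Consequently the group-level agent experiment — healthy
investor agent vs clinical-group trustee agent, looking for group-specific
cluster placement — is null on synthetic data by construction, and the
agent validation is instead run cluster-conditioned (agents sampled from
one fitted cluster's members are classified back into that cluster).
Passing tests demonstrate the pipeline's statistical machinery, not the
psychological realism of the trajectories.

## k-NN agents

An agent replays a recorded population: at round `t` it forms the vector
of its most recent choices (up to the last 3 investments and 3
repayments, most recent first, investment before repayment within a slot;
the trustee's vector starts with the current round's investment), finds
the k = 6 nearest recorded situations *at the same round position* in
Euclidean distance (ties broken by database insertion order), and emits
one of their outcomes uniformly at random.  Early rounds use however many
lags exist; a round-1 investor has no history and draws uniformly from all
recorded round-1 investments.  Round-position conditioning keeps distances
comparable without imputation.

## Over-representation statistics

With `n_c` dyads in cluster c (modal assignment, ties to the lowest
index), `n_gc` of them from group g, and `p_g` the group's population
share, `z_gc = (n_gc − n_c p_g)/sqrt(n_c p_g (1−p_g))` is asymptotically
standard normal under random placement.  The per-group test statistic
Σ_c z²_gc is referred to chi-square with K degrees of freedom (the sum has
K terms; a K−1 variant is configurable).  Two calibrations are reported:
the smallest common |z| at which K equal terms reach 5% significance,
`sqrt(χ²_crit/K)` — 1.54 for K = 4 — and the single-term threshold
`sqrt(χ²_crit)` at which one cluster alone suffices.

Severity correlations are Pearson r between a cluster's membership
frequency and the score, by default restricted to dyads whose modal
cluster is the target (the unrestricted variant is available and is also
reported by the analysis driver; in the well-separated synthetic regime
the within-cluster membership frequencies are nearly constant, so the
restricted correlation is weak there by construction).

The healthy-only concordance workflow refits the mixture on
healthy-labeled dyads, classifies the disordered dyads against that fit,
and compares the healthy dyads' two modal partitions by the adjusted Rand
index (permutation-model, via scikit-learn, brute-force verified in
tests).

## Problem sizes and numerical choices

Desk-scale schedules used by the tests, the analysis drivers, and the
acceptance script (chosen as the package's standard configuration;
full-scale schedules remain the documented defaults of `run_chain`):

- single-model fits: 1,000–3,000 recorded draws after 350–1,000 burn-in;
- the model-search experiment: grid K∈{2..6}, P∈{1,2}, D∈{1,2}, 3 samplers
  per candidate, 1,000-cycle chains (350 burn-in), 10 replicate
  populations;
- agent batches: 1,000 games (60 in tests).

Other numerical choices: log-space allocation probabilities (mandatory);
Cholesky sampling of β full conditionals; posterior-mode convergence at
relative 1e−8 or 200 sweeps; ridge regularization of a singular draw
covariance with an explicit flag; CSV written at %.17g and parsed with
round-trip float precision so dyad tables and chain archives reproduce
bit-exactly.

## Known limitations

- The Gaussian likelihood ignores the [0, 1] bounds; heavy clipping in a
  generated population (reported by `clip_report`) would bias coefficient
  recovery near the boundaries.
- The harmonic-mean evidence estimator is only trusted for rankings, as
  documented above.
- Merged-cluster posterior modes remain reachable in principle; the EM
  initialization makes them rare but multiple seeds stay advisable for
  any new data configuration.
- The 2-of-3 / 6-of-9 empty-type discard thresholds are both implemented;
  neither is privileged, and the desk-scale experiments use 2-of-3 to
  match their 3-sampler design.
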