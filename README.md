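# trustmix

Bayesian behavioral phenotyping of multi-round trust-game play.

In the 10-round trust game an *investor* is endowed with 20 monetary units
(MU) each round and sends a fraction `i_t` to a *trustee*; the transfer is
tripled, and the trustee returns a fraction `r_t` of the tripled amount.
When a healthy investor plays a partner drawn from a clinical population
(autism spectrum disorder, borderline personality disorder, major
depression, ADHD, ...), the *investor's* elicited dynamics carry information
about the partner — the healthy player acts as a behavioral biosensor.
`trustmix` implements the full statistical pipeline for extracting that
signal, for researchers working on computational phenotyping of social
exchange:

1. **Mixture of lagged-polynomial regressions.** Each dyad's investments
   in rounds 3–10 form a response vector `y_n`; with probability `λ_k` it
   follows `y_n ~ N(X_n β_k, σ²_k I)`, where the rows of `X_n` hold all
   monomials of degree ≤ P in the previous D rounds' investment and
   repayment ratios. Priors: Dirichlet on `λ`, multivariate normal on each
   `β_k`, inverse-gamma on each `σ²_k`.
2. **Two-stage data-augmented Gibbs sampler** over latent cluster
   allocations and parameters, with residual-normality (Jarque–Bera) and
   Raftery–Lewis convergence diagnostics.
3. **Model selection** over (K clusters, order P, look-back D) by the
   Laplace–Metropolis estimator of the log marginal likelihood (posterior
   mode by step-wise ascent, draw covariance in an unconstrained
   parametrization), with an empty-cluster discard rule and a Wilcoxon
   rank-sum parsimony rule; a harmonic-mean estimator serves as a
   cross-check.
4. **Cluster analysis**: per-dyad membership probabilities over posterior
   draws, group over-/under-representation z-scores
   `z_gc = (n_gc − n_c p_g) / sqrt(n_c p_g (1−p_g))` with chi-square group
   tests, severity-score correlations, cluster coefficient/trajectory
   profiles, and adjusted-Rand partition concordance.
5. **k-nearest-neighbor sampling agents** for both roles, which replay a
   recorded population and validate the clustering in closed loop.

The original 287-dyad human dataset is not publicly deposited, so the
package ships a synthetic-data generator (`trustmix.synthetic_data`) that
emulates the study design — 10-round games, four latent behavioral
clusters, eight labeled groups with controllable group→cluster enrichment,
severity scores linked to cluster membership — and every stage is exercised
against it.

## Worked example

The numbered scripts under `analysis/` run the pipeline end to end on the
default synthetic population; each writes its tables under `results/`.

```bash
python analysis/01_simulate_population.py
python analysis/02_fit_mixture.py
python analysis/04_cluster_analysis.py
```

Output of `01` (287 dyads, 2.0% of generated investments clipped at the
[0,1] boundary — mild enough to keep the Gaussian model honest):

```
population: 287 dyads (574 subjects), 8 groups
true cluster sizes: {1: 62, 0: 153, 2: 45, 3: 27}
investment clipping rate: 2.0%
```

Output of `02` — the sampler's residuals are consistent with the Gaussian
assumption and the chain length comfortably exceeds the Raftery–Lewis
requirement per scalar:

```
residual normality: skew +0.041, kurtosis 2.853, JB 2.71, p 0.258 -> not rejected
Raftery-Lewis (q=0.025, r=0.005, s=0.95): worst scalar beta[3,0] needs 4312 draws
```

Output of `04` — each clinical group is over-represented in "its" cluster;
z values above the per-term calibration 1.54 (starred) are statistically
significant, and severity scores correlate with membership probability:

```
per-term significance threshold |z| = 1.54
  ADHD     cluster 3  z = +2.15 *
  ASD      cluster 1  z = +2.74 *
  BPD-M    cluster 2  z = +3.11 *
  BPD-N    cluster 2  z = +2.41 *
  MDD      cluster 2  z = +1.34
  ADI-R-repetitive     cluster 1 (all scored dyads): r = +0.86, p = 2.3e-10, n = 33
  interpersonal-trust  cluster 2 (all scored dyads): r = -0.82, p = 3.3e-11, n = 41
```

`03_select_model.py` reruns the grid search (it selects K=4, P=1, D=2 on
this population), `05_agents.py` plays 1,000 agent-vs-agent games per
pairing and classifies them (the cluster-conditioned closed loop returns
its source cluster at z = +31.4), and `06_concordance.py` refits on the
healthy-labeled dyads alone (concordance ARI = 0.962 with the all-dyad
partition).

A command-line front end wraps the same library calls:

```bash
trustmix synth --seed 7 --out pop.csv
trustmix fit --input pop.csv -K 4 --draws 3000 --burn-in 1000 --out chain.json
trustmix analyze --input pop.csv --chain chain.json --out tables/
```

## Layout

```
src/trustmix/        library: game_core, synthetic_data, design,
                     mixture_gibbs, model_selection, cluster_analysis,
                     knn_agents, io, cli
analysis/            numbered narrative drivers (write results/)
tests/               pytest suite incl. end-to-end acceptance tests
scripts/acceptance.py
docs/methods.md      modeling and design notes
```
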