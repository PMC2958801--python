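"""Marginal-likelihood estimation and model search over (K, P, D).

Each candidate model is scored by the Laplace-Metropolis estimator of the log
marginal likelihood: a Gaussian approximation around the posterior mode whose
covariance is estimated from the posterior draws themselves,

    log m(y) ~= (d/2) log(2 pi) + (1/2) log|H*| + log p(y | theta*) + log p(theta*),

evaluated in an unconstrained parametrization (additive-log-ratio weights,
log variances) so the simplex and positivity constraints cannot distort the
Gaussian approximation.  Candidate models are compared under a parsimony
rule: a model is preferred over a simpler one only when its log-ML sample is
significantly larger by Wilcoxon rank-sum and has the larger median;
otherwise the simpler model wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln, logsumexp

from .design import DesignPair, ModelSpec, stack_designs
from .mixture_gibbs import (
    GibbsChain,
    PriorSpec,
    default_priors,
    log_likelihood_matrix,
    modal_allocation,
    run_chain,
)

__all__ = [
    "ModelScore",
    "ModelSearchResult",
    "posterior_mode",
    "laplace_metropolis_logml",
    "harmonic_mean_logml",
    "empty_type_discard",
    "select_model",
    "search_models",
]


# ---------------------------------------------------------------------------
# Unconstrained parametrization
# ---------------------------------------------------------------------------

def _pack(lam, beta, sigma2):
    """(lam, beta, sigma2) -> unconstrained theta.

    Weights via additive log-ratio against the last component; variances on
    the log scale; coefficients unchanged.
    """
    K = lam.size
    parts = [beta.ravel(), np.log(sigma2)]
    if K > 1:
        parts.append(np.log(lam[:-1]) - np.log(lam[-1]))
    return np.concatenate(parts)


def _unpack(theta, K, M):
    beta = theta[: K * M].reshape(K, M)
    sigma2 = np.exp(theta[K * M : K * M + K])
    if K > 1:
        a = theta[K * M + K :]
        e = np.concatenate([np.exp(a - max(a.max(), 0.0)),
                            [np.exp(-max(a.max(), 0.0))]])
        lam = e / e.sum()
    else:
        lam = np.ones(1)
    return lam, beta, sigma2


def n_free_params(spec: ModelSpec) -> int:
    return spec.n_params


def mixture_log_likelihood(Y, X, lam, beta, sigma2) -> float:
    """Observed-data log likelihood with allocations marginalized out."""
    ll = log_likelihood_matrix(Y, X, beta, sigma2)
    with np.errstate(divide="ignore"):
        return float(logsumexp(np.log(lam)[None, :] + ll, axis=1).sum())


def _log_prior_transformed(theta, K, M, priors: PriorSpec) -> float:
    """Log prior density in the unconstrained coordinates (Jacobian included)."""
    lam, beta, sigma2 = _unpack(theta, K, M)
    B0inv = np.linalg.inv(priors.beta_cov)
    _, logdet = np.linalg.slogdet(priors.beta_cov)
    lp = 0.0
    for k in range(K):
        d = beta[k] - priors.beta_mean
        lp += -0.5 * (M * np.log(2 * np.pi) + logdet + d @ B0inv @ d)
    a, b = priors.ig_shape, priors.ig_scale
    # inverse-gamma on sigma2, plus d(sigma2)/d(log sigma2) = sigma2
    lp += float(np.sum(a * np.log(b) - gammaln(a)
                       - (a + 1) * np.log(sigma2) - b / sigma2
                       + np.log(sigma2)))
    if K > 1:
        alpha = priors.dirichlet_alpha
        lp += float(gammaln(alpha.sum()) - gammaln(alpha).sum()
                    + ((alpha - 1) * np.log(lam)).sum())
        # ALR Jacobian: |d lam / d a| = prod_k lam_k
        lp += float(np.log(lam).sum())
    return lp


def log_posterior_transformed(theta, Y, X, K, M, priors) -> float:
    lam, beta, sigma2 = _unpack(theta, K, M)
    return mixture_log_likelihood(Y, X, lam, beta, sigma2) + _log_prior_transformed(
        theta, K, M, priors
    )


def _log_posterior_and_grad(theta, Y, X, K, M, priors):
    """Log posterior and its gradient in the unconstrained coordinates."""
    lam, beta, sigma2 = _unpack(theta, K, M)
    T = Y.shape[1]
    N = Y.shape[0]
    mu = np.einsum("ntm,km->ntk", X, beta)            # (N, T, K)
    resid = Y[:, :, None] - mu                         # (N, T, K)
    rss = np.square(resid).sum(axis=1)                 # (N, K)
    ll_mat = -0.5 * (T * np.log(2 * np.pi * sigma2)[None, :]
                     + rss / sigma2[None, :])
    with np.errstate(divide="ignore"):
        logp = np.log(lam)[None, :] + ll_mat
    lse = logsumexp(logp, axis=1)
    loglik = float(lse.sum())
    W = np.exp(logp - lse[:, None])                    # responsibilities (N, K)

    B0inv = np.linalg.inv(priors.beta_cov)
    a, b = priors.ig_shape, priors.ig_scale

    g_beta = np.empty((K, M))
    for k in range(K):
        g_beta[k] = (np.einsum("n,ntm,nt->m", W[:, k], X, resid[:, :, k])
                     / sigma2[k]) - B0inv @ (beta[k] - priors.beta_mean)
    g_logs2 = (W * (rss / (2.0 * sigma2)[None, :] - 0.5 * T)).sum(axis=0) \
        - (a + 1.0) + b / sigma2 + 1.0
    parts = [g_beta.ravel(), g_logs2]
    if K > 1:
        # d/d a_j with lam = softmax(a_1..a_{K-1}, 0):
        # lam_k * (d log post / d lam_k) = S_k + alpha_k =: full_k, then
        # grad_j = full_j - lam_j * sum(full)
        alpha = priors.dirichlet_alpha
        full = W.sum(axis=0) + alpha
        parts.append(full[:-1] - lam[:-1] * full.sum())
    grad = np.concatenate(parts)
    lp = loglik + _log_prior_transformed(theta, K, M, priors)
    return lp, grad


# ---------------------------------------------------------------------------
# Posterior mode by component-wise (conditional) maximization
# ---------------------------------------------------------------------------

def posterior_mode(
    chain: GibbsChain,
    data: Sequence[DesignPair],
    tol: float = 1e-8,
    max_sweeps: int = 200,
):
    """Step-wise ascent of the log posterior from the best recorded draw.

    The parameter vector is split into blocks (each cluster's coefficients,
    each log variance, the weight log-ratios); each sweep maximizes every
    block in turn with the others held fixed.  Stops when a full sweep
    improves the log posterior by a relative amount below ``tol`` or after
    ``max_sweeps`` sweeps (the latter sets ``converged=False``).

    Returns ``(theta_mode, log_posterior_at_mode, converged)`` with
    ``theta_mode`` in the unconstrained parametrization.
    """
    if chain.n_draws == 0:
        raise ValueError("empty chain")
    K, M = chain.spec.K, chain.spec.n_coef
    Y, X = stack_designs(data)
    priors = chain.priors

    def f(theta):
        return log_posterior_transformed(theta, Y, X, K, M, priors)

    def fg(theta):
        return _log_posterior_and_grad(theta, Y, X, K, M, priors)

    # best recorded draw as the starting point (scan thinned for speed)
    step = max(1, chain.n_draws // 200)
    scan = range(0, chain.n_draws, step)
    lp = np.array([
        f(_pack(chain.lam[t], chain.beta[t], chain.sigma2[t])) for t in scan
    ])
    t0 = list(scan)[int(lp.argmax())]
    theta = _pack(chain.lam[t0], chain.beta[t0], chain.sigma2[t0])
    best = lp.max()

    blocks = []
    for k in range(K):
        blocks.append(np.arange(k * M, (k + 1) * M))       # beta_k
    blocks.append(np.arange(K * M, K * M + K))             # log sigma2 (joint)
    if K > 1:
        blocks.append(np.arange(K * M + K, K * M + K + K - 1))  # ALR weights

    converged = False
    for _ in range(max_sweeps):
        start = best
        for idx in blocks:
            def neg(sub, idx=idx):
                th = theta.copy()
                th[idx] = sub
                lp, g = fg(th)
                return -lp, -g[idx]

            res = optimize.minimize(neg, theta[idx], jac=True,
                                    method="L-BFGS-B")
            if -res.fun > best:
                theta = theta.copy()
                theta[idx] = res.x
                best = -res.fun
        if best - start <= tol * max(1.0, abs(best)):
            converged = True
            break
    return theta, float(best), converged


# ---------------------------------------------------------------------------
# Marginal-likelihood estimators
# ---------------------------------------------------------------------------

def laplace_metropolis_logml(
    chain: GibbsChain,
    data: Sequence[DesignPair],
    mode: Optional[np.ndarray] = None,
    ridge: float = 1e-10,
):
    """Laplace-Metropolis estimate of the log marginal likelihood.

    ``H*`` is the sample covariance of the recorded draws mapped to the
    unconstrained parametrization; the mode is found by
    :func:`posterior_mode` unless supplied.  A singular covariance is
    ridge-regularized (with a warning recorded in the result).
    """
    if chain.n_draws < 2:
        raise ValueError("need at least 2 recorded draws")
    K, M = chain.spec.K, chain.spec.n_coef
    Y, X = stack_designs(data)
    thetas = np.stack([
        _pack(chain.lam[t], chain.beta[t], chain.sigma2[t])
        for t in range(chain.n_draws)
    ])
    d = thetas.shape[1]
    H = np.cov(thetas, rowvar=False).reshape(d, d)
    sign, logdet = np.linalg.slogdet(H)
    ridged = False
    if sign <= 0 or not np.isfinite(logdet):
        scale = max(float(np.trace(H)) / d, 1.0)
        H = H + ridge * scale * np.eye(d)
        sign, logdet = np.linalg.slogdet(H)
        ridged = True
    if mode is None:
        mode, lp_mode, _ = posterior_mode(chain, data)
    else:
        lp_mode = log_posterior_transformed(mode, Y, X, K, M, chain.priors)
    logml = 0.5 * d * np.log(2 * np.pi) + 0.5 * logdet + lp_mode
    return float(logml), ridged


def harmonic_mean_logml(chain: GibbsChain, data: Sequence[DesignPair]) -> float:
    """Harmonic-mean estimator: -log of the mean inverse likelihood.

    Computed stably in log space.  Known to be noisy and dominated by
    low-likelihood draws; used only as a cross-check on the
    Laplace-Metropolis ranking.
    """
    if chain.n_draws < 2:
        raise ValueError("need at least 2 recorded draws")
    Y, X = stack_designs(data)
    ll = np.array([
        mixture_log_likelihood(Y, X, chain.lam[t], chain.beta[t], chain.sigma2[t])
        for t in range(chain.n_draws)
    ])
    return float(-(logsumexp(-ll) - np.log(ll.size)))


# ---------------------------------------------------------------------------
# Model search protocol
# ---------------------------------------------------------------------------

@dataclass
class ModelScore:
    """Scores for one candidate spec across replicate samplers."""

    spec: ModelSpec
    logml: list = field(default_factory=list)
    n_empty_typed: int = 0
    n_chains: int = 0
    discarded: bool = False
    reason: str = ""

    @property
    def n_params(self) -> int:
        return self.spec.n_params

    @property
    def median_logml(self) -> float:
        return float(np.median(self.logml))


@dataclass
class ModelSearchResult:
    scores: list
    selected: Optional[ModelSpec] = None


def empty_type_discard(
    chains: Sequence[GibbsChain],
    threshold: int = 6,
    last: Optional[int] = 5000,
) -> tuple[bool, str, int]:
    """Discard rule based on empty clusters in the modal partition.

    A chain is "empty-typed" when some cluster has zero members in the modal
    allocation computed over the last ``last`` recorded draws.  The model is
    discarded when at least ``threshold`` of the chains are empty-typed
    (default 6-of-9; the 2-of-3 variant is the same rule with
    ``threshold=2``).  Returns ``(discard, reason, n_empty_typed)``.
    """
    n_empty = 0
    for chain in chains:
        if chain.spec.K == 1:
            continue
        zmode = modal_allocation(chain, last=last)
        if np.bincount(zmode, minlength=chain.spec.K).min() == 0:
            n_empty += 1
    discard = n_empty >= threshold
    reason = (
        f"{n_empty}/{len(chains)} samplers empty-typed (threshold {threshold})"
        if discard else ""
    )
    return discard, reason, n_empty


def _beats(a: ModelScore, b: ModelScore, alpha: float = 0.05) -> bool:
    """True iff model a's log-ML sample significantly exceeds model b's.

    Requires a strictly larger median AND a Wilcoxon rank-sum rejection at
    the ``alpha`` level (exact test; one-sided alternative "greater").
    """
    if np.median(a.logml) <= np.median(b.logml):
        return False
    try:
        res = stats.mannwhitneyu(a.logml, b.logml, alternative="greater",
                                 method="exact")
        p = float(res.pvalue)
    except ValueError:
        return False
    return p <= alpha


def select_model(result: ModelSearchResult, alpha: float = 0.05) -> ModelSpec:
    """Parsimony selection over the scored grid.

    Models are ordered by free-parameter count.  A model is a *candidate*
    when it beats (see :func:`_beats`) every non-discarded model with
    strictly fewer parameters.  Among the candidates the one with the
    largest median log-ML is selected; ties break toward fewer parameters.
    Deterministic given the log-ML samples.
    """
    live = [s for s in result.scores if not s.discarded and s.logml]
    if not live:
        raise ValueError("all candidate models were discarded")
    live.sort(key=lambda s: (s.n_params, s.spec.K, s.spec.P, s.spec.D))
    candidates = []
    for s in live:
        simpler = [t for t in live if t.n_params < s.n_params]
        if all(_beats(s, t, alpha=alpha) for t in simpler):
            candidates.append(s)
    chosen = max(candidates, key=lambda s: (s.median_logml, -s.n_params))
    result.selected = chosen.spec
    return chosen.spec


def search_models(
    records,
    grid: Sequence[ModelSpec],
    n_samplers: int = 9,
    n_cycles: int = 8000,
    burn_in: int = 3000,
    seed: int = 0,
    discard_threshold: int = 6,
    priors_for: Optional[Callable[[ModelSpec], PriorSpec]] = None,
    alpha: float = 0.05,
    progress: Optional[Callable[[str], None]] = None,
) -> ModelSearchResult:
    """Run the full model-search protocol over a grid of specs.

    For every spec, ``n_samplers`` independent chains are run under the
    search schedule (``n_cycles`` total, ``burn_in`` discarded); the
    empty-type rule is applied, each surviving chain contributes one
    Laplace-Metropolis log-ML value, and :func:`select_model` applies the
    Wilcoxon parsimony rule.
    """
    from .design import build_designs

    scores = []
    for spec in grid:
        data = build_designs(records, spec)
        priors = priors_for(spec) if priors_for else default_priors(spec)
        chains = []
        child = np.random.SeedSequence(seed, spawn_key=(spec.K, spec.P, spec.D))
        chain_seeds = child.generate_state(n_samplers)
        for j in range(n_samplers):
            chains.append(run_chain(
                data, spec, priors,
                n_draws=n_cycles - burn_in, burn_in=burn_in,
                seed=int(chain_seeds[j] % (2**31)),
            ))
        score = ModelScore(spec=spec, n_chains=n_samplers)
        score.discarded, score.reason, score.n_empty_typed = empty_type_discard(
            chains, threshold=discard_threshold, last=None
        )
        if not score.discarded:
            for chain in chains:
                logml, _ = laplace_metropolis_logml(chain, data)
                score.logml.append(logml)
        if progress:
            progress(
                f"spec K={spec.K} P={spec.P} D={spec.D}: "
                + (f"discarded ({score.reason})" if score.discarded
                   else f"median logML {score.median_logml:.2f}")
            )
        scores.append(score)
    result = ModelSearchResult(scores=scores)
    if any(not s.discarded for s in scores):
        select_model(result, alpha=alpha)
    return result
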