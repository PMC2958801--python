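"""Data-augmented Gibbs sampler for the mixture of lagged-polynomial regressions.

Model: dyad n's response vector y_n (8 investments) follows, with probability
lambda_k, a Gaussian linear regression

    y_n | z_n = k  ~  N(X_n beta_k, sigma2_k I_8)

with a Dirichlet prior on the weights lambda, independent multivariate-normal
priors on each beta_k, and inverse-gamma priors on each sigma2_k.  Latent
allocations z_n make every full conditional standard, giving the classic
two-stage sampler: (1) draw each dyad's allocation from its posterior cluster
probabilities; (2) per cluster, draw sigma2_k given beta_k, beta_k given
sigma2_k on the pooled member data, then lambda from its Dirichlet full
conditional.  No identifiability constraint is imposed during sampling;
within-chain summaries are allocation-based and label switching is monitored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .design import DesignPair, ModelSpec, stack_designs

__all__ = [
    "PriorSpec",
    "PosteriorDraw",
    "GibbsChain",
    "default_priors",
    "allocation_probabilities",
    "sample_step",
    "run_chain",
    "modal_allocation",
    "residual_normality",
    "pooled_standardized_jb",
    "raftery_lewis",
    "chain_diagnostics",
    "log_likelihood_matrix",
]

# Observations per dyad (investments of rounds 3-10).
T_OBS = 8


@dataclass(frozen=True)
class PriorSpec:
    """Conditionally conjugate prior hyperparameters.

    dirichlet_alpha : (K,) Dirichlet concentration on weights.
    beta_mean, beta_cov : N(beta_mean, beta_cov) prior on each cluster's
        coefficients.  Because all regressors live on [0, 1], the default
        covariance is the identity - unit prior variance per coefficient.
    ig_shape, ig_scale : inverse-gamma prior on each residual variance.
    """

    dirichlet_alpha: np.ndarray
    beta_mean: np.ndarray
    beta_cov: np.ndarray
    ig_shape: float = 3.0
    ig_scale: float = 0.5

    def __post_init__(self) -> None:
        a = np.asarray(self.dirichlet_alpha, float)
        m = np.asarray(self.beta_mean, float)
        C = np.asarray(self.beta_cov, float)
        object.__setattr__(self, "dirichlet_alpha", a)
        object.__setattr__(self, "beta_mean", m)
        object.__setattr__(self, "beta_cov", C)
        if np.any(a <= 0):
            raise ValueError("dirichlet_alpha must be positive")
        if C.shape != (m.size, m.size):
            raise ValueError("beta_cov shape does not match beta_mean")
        if not np.allclose(C, C.T):
            raise ValueError("beta_cov must be symmetric")
        np.linalg.cholesky(C)  # positive-definiteness check
        if self.ig_shape <= 0 or self.ig_scale <= 0:
            raise ValueError("inverse-gamma hyperparameters must be positive")


def default_priors(spec: ModelSpec) -> PriorSpec:
    """Weakly informative defaults sized for a model spec."""
    M = spec.n_coef
    return PriorSpec(
        dirichlet_alpha=np.ones(spec.K),
        beta_mean=np.zeros(M),
        beta_cov=np.eye(M),
    )


@dataclass
class PosteriorDraw:
    """One posterior draw: weights, coefficients, variances, allocations."""

    lam: np.ndarray     # (K,)
    beta: np.ndarray    # (K, M)
    sigma2: np.ndarray  # (K,)
    z: np.ndarray       # (N,) cluster indices, 0-based

    def validate(self) -> None:
        if abs(self.lam.sum() - 1.0) > 1e-8:
            raise ValueError("weights do not sum to 1")
        if np.any(self.sigma2 <= 0):
            raise ValueError("variances must be positive")


@dataclass
class GibbsChain:
    """Recorded post-burn-in draws of one sampler run.

    Draw arrays are stacked: ``lam`` (T, K), ``beta`` (T, K, M), ``sigma2``
    (T, K), ``z`` (T, N).  ``thin`` records the thinning factor applied when
    storing (1 = every post-burn-in cycle kept).
    """

    spec: ModelSpec
    priors: PriorSpec
    seed: int
    burn_in: int
    lam: np.ndarray
    beta: np.ndarray
    sigma2: np.ndarray
    z: np.ndarray
    thin: int = 1
    n_label_switches: int = 0

    @property
    def n_draws(self) -> int:
        return self.lam.shape[0]

    @property
    def n_dyads(self) -> int:
        return self.z.shape[1]

    def draw(self, t: int) -> PosteriorDraw:
        return PosteriorDraw(self.lam[t], self.beta[t], self.sigma2[t], self.z[t])


def log_likelihood_matrix(
    Y: np.ndarray, X: np.ndarray, beta: np.ndarray, sigma2: np.ndarray
) -> np.ndarray:
    """Per-dyad, per-cluster Gaussian log densities.

    Y is (N, 8), X is (N, 8, M); returns (N, K) with entry (n, k) equal to
    log N(y_n; X_n beta_k, sigma2_k I).
    """
    mu = np.einsum("ntm,km->ntk", X, beta)          # (N, 8, K)
    rss = np.square(Y[:, :, None] - mu).sum(axis=1)  # (N, K)
    T = Y.shape[1]
    return -0.5 * (T * np.log(2.0 * np.pi * sigma2)[None, :] + rss / sigma2[None, :])


def allocation_probabilities(
    y: np.ndarray,
    X: np.ndarray,
    lam: np.ndarray,
    beta: np.ndarray,
    sigma2: np.ndarray,
) -> np.ndarray:
    """Posterior cluster probabilities for a single response vector.

    Proportional to lambda_k N(y; X beta_k, sigma2_k I), normalized in log
    space (log-sum-exp) so widely separated densities cannot underflow.
    """
    ll = log_likelihood_matrix(y[None, :], X[None, :, :], beta, sigma2)[0]
    with np.errstate(divide="ignore"):  # lambda_k == 0 is a legal degenerate weight
        logp = np.log(lam) + ll
    if np.all(np.isinf(logp)):
        raise FloatingPointError("all cluster log densities are -inf")
    logp -= logsumexp(logp)
    return np.exp(logp)


def _sample_allocations(
    Y: np.ndarray,
    X: np.ndarray,
    lam: np.ndarray,
    beta: np.ndarray,
    sigma2: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    ll = log_likelihood_matrix(Y, X, beta, sigma2)
    with np.errstate(divide="ignore"):
        logp = np.log(lam)[None, :] + ll
    logp -= logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(Y.shape[0])
    return (np.cumsum(p, axis=1) < u[:, None]).sum(axis=1)


def _draw_beta_sigma(
    Yk: np.ndarray,
    Xk: np.ndarray,
    beta_cur: np.ndarray,
    priors: PriorSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Cluster-level conjugate updates on pooled member data.

    sigma2 | beta ~ IG(a + n/2, b + SSR/2); beta | sigma2 multivariate normal
    with precision B0^-1 + X'X / sigma2.
    """
    n = Yk.size
    resid = Yk - Xk @ beta_cur
    shape = priors.ig_shape + 0.5 * n
    scale = priors.ig_scale + 0.5 * float(resid @ resid)
    sigma2 = scale / rng.gamma(shape)
    B0inv = np.linalg.inv(priors.beta_cov)
    prec = B0inv + (Xk.T @ Xk) / sigma2
    rhs = B0inv @ priors.beta_mean + (Xk.T @ Yk) / sigma2
    L = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, rhs)
    noise = np.linalg.solve(L.T, rng.standard_normal(mean.size))
    return mean + noise, float(sigma2)


def _draw_prior(priors: PriorSpec, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    L = np.linalg.cholesky(priors.beta_cov)
    beta = priors.beta_mean + L @ rng.standard_normal(priors.beta_mean.size)
    sigma2 = priors.ig_scale / rng.gamma(priors.ig_shape)
    return beta, float(sigma2)


def sample_step(
    Y: np.ndarray,
    X: np.ndarray,
    current: PosteriorDraw,
    priors: PriorSpec,
    rng: np.random.Generator,
) -> PosteriorDraw:
    """One full Gibbs cycle: allocations, then (sigma2_k, beta_k), then lambda.

    Empty clusters fall back to draws from the prior, the standard
    data-augmentation convention.
    """
    K = current.lam.size
    z = _sample_allocations(Y, X, current.lam, current.beta, current.sigma2, rng)
    beta = np.empty_like(current.beta)
    sigma2 = np.empty_like(current.sigma2)
    for k in range(K):
        members = np.nonzero(z == k)[0]
        if members.size == 0:
            beta[k], sigma2[k] = _draw_prior(priors, rng)
            continue
        Yk = Y[members].ravel()
        Xk = X[members].reshape(-1, X.shape[2])
        beta[k], sigma2[k] = _draw_beta_sigma(
            Yk, Xk, current.beta[k], priors, rng
        )
    counts = np.bincount(z, minlength=K)
    lam = rng.dirichlet(priors.dirichlet_alpha + counts)
    return PosteriorDraw(lam=lam, beta=beta, sigma2=sigma2, z=z)


def _em_fit(Y, X, R, priors, XtX, Xty, n_iter=60, ridge=1e-6):
    """MAP-EM for the mixture of regressions from initial responsibilities.

    The variance M-step includes the inverse-gamma prior, which keeps
    near-empty components away from the degenerate likelihood spikes
    (sigma2 -> 0) that plain EM can fall into.  Returns ``(R, loglik)`` at
    convergence (or after ``n_iter`` sweeps).
    """
    N, T, M = X.shape
    K = R.shape[1]
    beta = np.zeros((K, M))
    sigma2 = np.full(K, float(Y.var()) + 1e-8)
    a, b0 = priors.ig_shape, priors.ig_scale
    ll = -np.inf
    for _ in range(n_iter):
        w = R.sum(axis=0)
        for k in range(K):
            A = np.einsum("n,nmp->mp", R[:, k], XtX) + ridge * np.eye(M)
            b = np.einsum("n,nm->m", R[:, k], Xty)
            beta[k] = np.linalg.solve(A, b)
            resid = Y - np.einsum("ntm,m->nt", X, beta[k])
            rss = float(R[:, k] @ np.square(resid).sum(axis=1))
            sigma2[k] = (2.0 * b0 + rss) / (2.0 * (a + 1.0) + T * w[k])
        lam = np.maximum(w / N, 1e-10)
        lam = lam / lam.sum()
        logp = np.log(lam)[None, :] + log_likelihood_matrix(Y, X, beta, sigma2)
        ll_new = float(logsumexp(logp, axis=1).sum())
        R = np.exp(logp - logsumexp(logp, axis=1, keepdims=True))
        if abs(ll_new - ll) < 1e-6 * max(1.0, abs(ll_new)):
            return R, ll_new
        ll = ll_new
    return R, ll


def _em_responsibilities(
    Y: np.ndarray,
    X: np.ndarray,
    K: int,
    rng: np.random.Generator,
    *,
    priors: PriorSpec,
    n_starts: int = 3,
    n_iter: int = 60,
) -> np.ndarray:
    """Short random-restart EM with split refinement.

    Random partition starts, best likelihood kept.  Because EM (like the
    Gibbs sampler itself) is prone to merged-cluster local optima in which
    one component sits empty, a refinement pass repeatedly sacrifices the
    emptiest component, splits the members of the most overdispersed one by
    2-means on their responses, and re-runs EM, accepting on likelihood
    improvement.  The result only initializes the Gibbs sampler; the
    posterior is explored by the chain.
    """
    from sklearn.cluster import KMeans

    N, T, M = X.shape
    XtX = np.einsum("ntm,ntp->nmp", X, X)
    Xty = np.einsum("ntm,nt->nm", X, Y)
    best_R, best_ll = None, -np.inf
    for _ in range(n_starts):
        z = rng.integers(K, size=N)
        R0 = np.zeros((N, K))
        R0[np.arange(N), z] = 1.0
        R, ll = _em_fit(Y, X, R0, priors, XtX, Xty, n_iter=n_iter)
        if ll > best_ll:
            best_ll, best_R = ll, R
    for _ in range(2 * K):  # split-refinement rounds
        z = best_R.argmax(axis=1)
        counts = np.bincount(z, minlength=K).astype(float)
        j = int(counts.argmin())  # donor: emptiest component
        # candidates to split, most overdispersed members first
        disp = np.full(K, -np.inf)
        for k in range(K):
            if k == j or counts[k] < 4:
                continue
            members = z == k
            disp[k] = counts[k] * float(Y[members].var(axis=0).mean())
        improved = False
        for k in np.argsort(disp)[::-1]:
            if not np.isfinite(disp[k]):
                break
            members = np.nonzero(z == k)[0]
            halves = KMeans(n_clusters=2, n_init=2,
                            random_state=int(rng.integers(2**31))) \
                .fit_predict(Y[members])
            z_new = z.copy()
            z_new[members[halves == 1]] = j
            R0 = np.zeros((N, K))
            R0[np.arange(N), z_new] = 1.0
            R, ll = _em_fit(Y, X, R0, priors, XtX, Xty, n_iter=n_iter)
            if ll > best_ll + 1e-6:
                best_ll, best_R = ll, R
                improved = True
                break
        if not improved:
            break
    return best_R


def _initial_draw(
    Y: np.ndarray,
    X: np.ndarray,
    spec: ModelSpec,
    priors: PriorSpec,
    rng: np.random.Generator,
    init: str,
) -> PosteriorDraw:
    """Initial state for the sampler.

    ``init="em"`` (default) runs a short random-restart EM fit of the
    mixture of regressions, keeps the best-likelihood start, and samples
    the initial allocations from its responsibilities, so the chain starts
    inside a data-supported basin; mixture Gibbs samplers are otherwise
    prone to sticking in merged-cluster modes.  ``init="random"`` assigns
    allocations uniformly at random instead (parameters still from their
    full conditionals); ``init="prior"`` draws everything from the priors.
    """
    N, K = Y.shape[0], spec.K
    if init == "prior":
        lam0 = rng.dirichlet(priors.dirichlet_alpha)
        beta0 = np.empty((K, spec.n_coef))
        sigma20 = np.empty(K)
        for k in range(K):
            beta0[k], sigma20[k] = _draw_prior(priors, rng)
        z0 = rng.choice(K, size=N, p=lam0)
        return PosteriorDraw(lam=lam0, beta=beta0, sigma2=sigma20, z=z0)
    if init == "em" and K > 1 and N > K:
        R = _em_responsibilities(Y, X, K, rng, priors=priors)
        u = rng.random(N)
        z0 = (np.cumsum(R, axis=1) < u[:, None]).sum(axis=1)
    elif init in ("em", "random"):
        z0 = rng.integers(K, size=N)
    else:
        raise ValueError(f"unknown init {init!r}")
    beta0 = np.empty((K, spec.n_coef))
    sigma20 = np.empty(K)
    for k in range(K):
        members = np.nonzero(z0 == k)[0]
        if members.size == 0:
            beta0[k], sigma20[k] = _draw_prior(priors, rng)
            continue
        Yk = Y[members].ravel()
        Xk = X[members].reshape(-1, X.shape[2])
        # condition the first sigma2 draw on the member least-squares fit,
        # not on the prior mean, so initial variances have the data's scale
        M = X.shape[2]
        beta_ls = np.linalg.solve(Xk.T @ Xk + 1e-8 * np.eye(M), Xk.T @ Yk)
        beta0[k], sigma20[k] = _draw_beta_sigma(Yk, Xk, beta_ls, priors, rng)
    lam0 = rng.dirichlet(priors.dirichlet_alpha + np.bincount(z0, minlength=K))
    return PosteriorDraw(lam=lam0, beta=beta0, sigma2=sigma20, z=z0)


def run_chain(
    data: Sequence[DesignPair],
    spec: ModelSpec,
    priors: Optional[PriorSpec] = None,
    n_draws: int = 30_000,
    burn_in: int = 1_000,
    seed: int = 0,
    thin: int = 1,
    init: str = "em",
) -> GibbsChain:
    """Run one sampler: burn-in cycles discarded, ``n_draws`` recorded.

    The default schedule (1,000 burn-in + 30,000 recorded) is the main
    analysis schedule; model search uses 8,000 total cycles with 3,000
    burn-in.  Identical seeds give bit-identical chains.
    """
    if n_draws <= 0:
        raise ValueError("n_draws must be positive")
    if priors is None:
        priors = default_priors(spec)
    if priors.dirichlet_alpha.size != spec.K:
        raise ValueError("prior dimensions do not match spec")
    if priors.beta_mean.size != spec.n_coef:
        raise ValueError("beta prior dimension does not match spec")
    Y, X = stack_designs(data)
    N = Y.shape[0]
    rng = np.random.default_rng(seed)
    current = _initial_draw(Y, X, spec, priors, rng, init)

    n_keep = n_draws // thin
    lam = np.empty((n_keep, spec.K))
    beta = np.empty((n_keep, spec.K, spec.n_coef))
    sigma2 = np.empty((n_keep, spec.K))
    z = np.empty((n_keep, N), dtype=np.int16)

    n_switch = 0
    prev_ranks = None
    stored = 0
    for it in range(burn_in + n_draws):
        try:
            current = sample_step(Y, X, current, priors, rng)
        except np.linalg.LinAlgError as err:  # pragma: no cover - defensive
            raise RuntimeError(f"Gibbs cycle {it} failed: {err}") from err
        if it < burn_in:
            continue
        rec = it - burn_in
        if rec % thin:
            continue
        lam[stored] = current.lam
        beta[stored] = current.beta
        sigma2[stored] = current.sigma2
        z[stored] = current.z
        # label-switch monitor: a genuine label swap reallocates a large
        # block of dyads at once, unlike ordinary draw-to-draw jitter
        if prev_ranks is not None:
            if np.mean(current.z != prev_ranks) > 0.3:
                n_switch += 1
        prev_ranks = current.z.copy()
        stored += 1
    return GibbsChain(
        spec=spec, priors=priors, seed=seed, burn_in=burn_in,
        lam=lam[:stored], beta=beta[:stored], sigma2=sigma2[:stored],
        z=z[:stored], thin=thin, n_label_switches=n_switch,
    )


def modal_allocation(chain: GibbsChain, last: Optional[int] = None) -> np.ndarray:
    """Per-dyad modal cluster over recorded draws (ties -> lowest index).

    ``last`` restricts to the final ``last`` recorded draws.
    """
    zs = chain.z if last is None else chain.z[-last:]
    K = chain.spec.K
    counts = np.stack([(zs == k).sum(axis=0) for k in range(K)], axis=1)
    return counts.argmax(axis=1)


def pooled_standardized_jb(residual_groups: Sequence[np.ndarray]):
    """Jarque-Bera on per-group-standardized, pooled residuals.

    Each group's residuals are centered by the group sample mean and scaled
    by the group sample standard deviation before pooling.  Groups with
    fewer than 3 values or zero variance are dropped; returns ``None`` when
    nothing testable remains (the degenerate case is inapplicable, not a
    pass).
    """
    pooled = []
    for resid in residual_groups:
        resid = np.asarray(resid, float)
        if resid.size < 3:
            continue
        sd = resid.std(ddof=1)
        if sd < 1e-12:
            continue
        pooled.append((resid - resid.mean()) / sd)
    if not pooled:
        return None
    pooled = np.concatenate(pooled)
    skew = float(stats.skew(pooled))
    kurt = float(stats.kurtosis(pooled, fisher=False))
    jb, p = stats.jarque_bera(pooled)
    return skew, kurt, float(jb), float(p)


def residual_normality(chain: GibbsChain, data: Sequence[DesignPair]):
    """Jarque-Bera check of the Gaussian residual assumption.

    Residuals y - X beta_{z} are formed at the modal allocation with each
    cluster's posterior-mean coefficients, standardized within cluster
    (subtract the cluster's sample mean of residuals, divide by its sample
    standard deviation), pooled, and tested.  Returns
    ``(skewness, kurtosis, jb_statistic, p_value)``; normality is "not
    rejected" iff p >= 0.05.  Clusters with fewer than 3 residuals, or
    degenerate zero-variance residuals, are excluded; if nothing remains the
    test is inapplicable and ``None`` is returned.
    """
    if chain.n_draws == 0:
        raise ValueError("empty chain")
    Y, X = stack_designs(data)
    zmode = modal_allocation(chain)
    beta_mean = chain.beta.mean(axis=0)
    groups = []
    for k in range(chain.spec.K):
        members = np.nonzero(zmode == k)[0]
        if members.size == 0:
            continue
        groups.append(
            (Y[members] - np.einsum("ntm,m->nt", X[members], beta_mean[k])).ravel()
        )
    return pooled_standardized_jb(groups)


def raftery_lewis(
    trace: np.ndarray,
    quantile: float = 0.025,
    accuracy: float = 0.005,
    confidence: float = 0.95,
    epsilon: float = 0.001,
):
    """Raftery-Lewis run-length diagnostic for one scalar trace.

    Binarizes the trace at its empirical ``quantile``, finds the smallest
    thinning at which the binary chain looks first-order Markov (BIC
    comparison against a second-order chain), fits the two-state transition
    probabilities (alpha, beta), and returns a dict with the recommended
    burn-in ``M``, required post-burn-in draws ``N``, thinning ``k_thin``,
    and the independence-chain minimum ``N_min = q(1-q)(z/r)^2``.

    A constant trace (or one the binarization cannot split) is flagged
    ``applicable=False``.
    """
    trace = np.asarray(trace, float)
    if trace.size < 100:
        raise ValueError("trace too short for the diagnostic")
    if np.ptp(trace) == 0:
        return {"applicable": False, "reason": "constant trace"}
    cutoff = np.quantile(trace, quantile)
    d = (trace <= cutoff).astype(np.int8)
    if d.min() == d.max():
        return {"applicable": False, "reason": "degenerate binarization"}

    z = stats.norm.ppf(0.5 * (1 + confidence))
    q = quantile
    n_min = q * (1 - q) * (z / accuracy) ** 2

    def transition_counts(seq, order):
        # counts indexed by (history state(s), next state)
        shape = (2,) * (order + 1)
        c = np.zeros(shape, dtype=float)
        idx = tuple(seq[j : len(seq) - order + j] for j in range(order + 1))
        np.add.at(c, idx, 1.0)
        return c

    def loglik(counts):
        tot = counts.sum(axis=-1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(tot > 0, counts / tot, 0.0)
            ll = np.where(counts > 0, counts * np.log(p), 0.0)
        return ll.sum()

    # Smallest thinning at which a first-order chain is preferred by BIC.
    k_thin = 1
    while True:
        sub = d[::k_thin]
        if sub.size < 50:
            break
        n_eff = sub.size - 2
        g1 = loglik(transition_counts(sub, 1))
        g2 = loglik(transition_counts(sub, 2))
        bic = 2.0 * (g2 - g1) - 2.0 * np.log(n_eff)
        if bic <= 0:
            break
        k_thin += 1
    sub = d[::k_thin]

    c = transition_counts(sub, 1)
    # alpha: P(0 -> 1), beta_p: P(1 -> 0)
    alpha = c[0, 1] / max(c[0].sum(), 1.0)
    beta_p = c[1, 0] / max(c[1].sum(), 1.0)
    alpha = min(max(alpha, 1e-8), 1 - 1e-8)
    beta_p = min(max(beta_p, 1e-8), 1 - 1e-8)
    s = alpha + beta_p

    m_burn = int(np.ceil(
        np.log(epsilon * s / max(alpha, beta_p)) / np.log(abs(1.0 - s))
    )) if abs(1.0 - s) > 1e-12 else 1
    n_req = int(np.ceil(((2.0 - s) * alpha * beta_p / s**3) * (z / accuracy) ** 2))
    return {
        "applicable": True,
        "burn_in": max(m_burn, 0) * k_thin,
        "n_required": n_req * k_thin,
        "k_thin": k_thin,
        "n_min": float(n_min),
        "dependence_factor": (n_req * k_thin) / n_min,
    }


def chain_diagnostics(chain: GibbsChain, **kwargs) -> dict:
    """Raftery-Lewis results for every monitored scalar (betas, sigma2, lam)."""
    out = {}
    K, M = chain.spec.K, chain.spec.n_coef
    for k in range(K):
        for m in range(M):
            out[f"beta[{k},{m}]"] = raftery_lewis(chain.beta[:, k, m], **kwargs)
        out[f"sigma2[{k}]"] = raftery_lewis(chain.sigma2[:, k], **kwargs)
        out[f"lambda[{k}]"] = raftery_lewis(chain.lam[:, k], **kwargs)
    return out
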