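"""Independent single-component oracle: exact posterior via 1-D quadrature.

For the K=1 model y = X beta + eps with beta ~ N(b0, B0), sigma2 ~ IG(a, b),
beta integrates out analytically given sigma2:

    y | sigma2 ~ N(X b0, sigma2 I + X B0 X'),

leaving one-dimensional integrals over sigma2 for the evidence and the
posterior moments.  Everything here is dense, direct arithmetic independent
of the sampler's code paths.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import multivariate_normal


def _log_ig(s2, a, b):
    return a * np.log(b) - gammaln(a) - (a + 1) * np.log(s2) - b / s2


def exact_k1_posterior(y, X, b0, B0, ig_shape, ig_scale, n_grid=1500):
    """Exact K=1 posterior summaries by quadrature over log sigma2.

    Returns a dict with ``log_evidence``, ``beta_mean``, ``sigma2_mean``,
    ``beta_cov`` (posterior covariance of beta).
    """
    y = np.asarray(y, float).ravel()
    X = np.asarray(X, float).reshape(y.size, -1)
    M = X.shape[1]
    B0inv = np.linalg.inv(B0)
    XB0Xt = X @ B0 @ X.T
    mean_y = X @ b0

    # grid wide enough to cover prior and likelihood-supported sigma2
    s2_hat = max(float(np.var(y - X @ np.linalg.lstsq(X, y, rcond=None)[0])),
                 1e-8)
    lo = np.log(min(s2_hat / 300.0, ig_scale / (ig_shape + 1) / 300.0))
    hi = np.log(max(s2_hat * 300.0, ig_scale / (ig_shape + 1) * 300.0))
    logs2 = np.linspace(lo, hi, n_grid)
    s2 = np.exp(logs2)

    log_joint = np.empty(n_grid)
    betas = np.empty((n_grid, M))
    covs = np.empty((n_grid, M, M))
    for i, v in enumerate(s2):
        cov = v * np.eye(y.size) + XB0Xt
        log_py = multivariate_normal.logpdf(y, mean=mean_y, cov=cov)
        # + log prior(s2) + Jacobian d s2 / d log s2 = s2
        log_joint[i] = log_py + _log_ig(v, ig_shape, ig_scale) + logs2[i]
        prec = B0inv + (X.T @ X) / v
        post_cov = np.linalg.inv(prec)
        betas[i] = post_cov @ (B0inv @ b0 + (X.T @ y) / v)
        covs[i] = post_cov

    dx = logs2[1] - logs2[0]
    log_evidence = logsumexp(log_joint) + np.log(dx)
    w = np.exp(log_joint - logsumexp(log_joint))
    beta_mean = w @ betas
    sigma2_mean = float(w @ s2)
    # law of total covariance: E[cov|s2] + cov of conditional means
    beta_cov = np.einsum("i,imp->mp", w, covs) \
        + np.einsum("i,im,ip->mp", w, betas - beta_mean, betas - beta_mean)
    return {
        "log_evidence": float(log_evidence),
        "beta_mean": beta_mean,
        "sigma2_mean": sigma2_mean,
        "beta_cov": beta_cov,
    }


def batch_means_mcse(trace, n_batches=20):
    """Monte-Carlo standard error of a trace mean by batch means."""
    trace = np.asarray(trace, float)
    n = (trace.size // n_batches) * n_batches
    batches = trace[:n].reshape(n_batches, -1).mean(axis=1)
    return float(batches.std(ddof=1) / np.sqrt(n_batches))
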