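"""Posterior-based cluster assignment and population-level statistics.

A fitted chain induces, for every dyad, a *membership profile*: the fraction
of recorded posterior draws allocating it to each cluster.  The modal cluster
defines a hard partition used for over-/under-representation statistics:
with n_c dyads in cluster c, n_gc of them from group g, and p_g the group's
population share, the standardized over-representation is

    z_gc = (n_gc - n_c p_g) / sqrt(n_c p_g (1 - p_g)),

asymptotically standard normal under random assignment; the per-group test
statistic sums the squared z over clusters against a chi-square null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from .design import DesignPair
from .game_core import DyadRecord
from .mixture_gibbs import GibbsChain

__all__ = [
    "MembershipProfile",
    "OverrepTable",
    "ClusterProfile",
    "membership_profiles",
    "classify_new",
    "overrep_z",
    "overrep_test",
    "overrep_table",
    "severity_correlation",
    "cluster_profiles",
    "adjusted_rand",
]


@dataclass(frozen=True)
class MembershipProfile:
    """Per-dyad posterior membership frequencies and modal cluster."""

    dyad_id: str
    frequencies: np.ndarray  # (K,), sums to 1
    modal: int               # argmax, ties toward the lowest index


@dataclass
class OverrepTable:
    """Group x cluster representation statistics.

    ``cells`` has one row per (group, cluster) with the observed and expected
    shares and the z statistic; ``group_tests`` one row per group with the
    chi-square statistic, degrees of freedom, p-value, and the two
    significance calibrations (common per-term |z| threshold and the
    single-term threshold).
    """

    cells: pd.DataFrame
    group_tests: pd.DataFrame
    cluster_sizes: np.ndarray


def membership_profiles(chain: GibbsChain,
                        dyad_ids: Optional[Sequence[str]] = None) -> list:
    """Membership frequencies over recorded draws for every training dyad."""
    if chain.n_draws == 0:
        raise ValueError("empty chain")
    N, K = chain.z.shape[1], chain.spec.K
    if dyad_ids is None:
        dyad_ids = [f"dyad{n:04d}" for n in range(N)]
    counts = np.stack(
        [(chain.z == k).sum(axis=0) for k in range(K)], axis=1
    ).astype(float)
    freqs = counts / counts.sum(axis=1, keepdims=True)
    return [
        MembershipProfile(dyad_ids[n], freqs[n], int(freqs[n].argmax()))
        for n in range(N)
    ]


def classify_new(pair: DesignPair, chain: GibbsChain, seed: int = 0,
                 dyad_id: str = "new") -> MembershipProfile:
    """Classify an out-of-sample response vector against a fitted chain.

    For each recorded draw the cluster probabilities of the new vector are
    computed from that draw's (lambda, beta, sigma2) and a cluster is
    sampled; the profile collects the sampled frequencies and the final
    assignment is the most frequently sampled cluster.
    """
    K = chain.spec.K
    if pair.X.shape[1] != chain.spec.n_coef:
        raise ValueError(
            f"design has {pair.X.shape[1]} columns, chain expects "
            f"{chain.spec.n_coef}"
        )
    rng = np.random.default_rng(seed)
    # vectorized over draws: log p(draw d, cluster k) for the new vector
    mu = np.einsum("tm,dkm->dtk", pair.X, chain.beta)
    rss = np.square(pair.y[None, :, None] - mu).sum(axis=1)  # (draws, K)
    T = pair.y.size
    ll = -0.5 * (T * np.log(2 * np.pi * chain.sigma2) + rss / chain.sigma2)
    with np.errstate(divide="ignore"):
        logp = np.log(chain.lam) + ll
    logp -= logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(chain.n_draws)
    sampled = (np.cumsum(p, axis=1) < u[:, None]).sum(axis=1)
    counts = np.bincount(sampled, minlength=K).astype(float)
    freqs = counts / counts.sum()
    return MembershipProfile(dyad_id, freqs, int(freqs.argmax()))


def overrep_z(n_c: int, n_gc: int, p_g: float) -> float:
    """Standardized over-representation of a group in one cluster."""
    if n_c <= 0:
        raise ValueError("cluster must be non-empty")
    if not (0.0 < p_g < 1.0):
        raise ValueError("group share must lie strictly inside (0, 1)")
    if not (0 <= n_gc <= n_c):
        raise ValueError("group count outside [0, cluster size]")
    return float((n_gc - n_c * p_g) / np.sqrt(n_c * p_g * (1.0 - p_g)))


def overrep_test(z_values: Sequence[float], alpha: float = 0.05) -> dict:
    """Chi-square test that one group is randomly spread over the clusters.

    The statistic sums the K squared z terms; under the null it is
    chi-square with K degrees of freedom.  Also reports two calibrations:
    ``per_term_threshold``, the smallest common |z| at which K equal terms
    reach significance (sqrt(chi2_crit / K)); and ``single_term_threshold``,
    the |z| at which one cluster alone suffices (sqrt(chi2_crit)).
    """
    z = np.asarray(z_values, float)
    K = z.size
    chi2 = float(np.sum(z**2))
    crit = float(stats.chi2.ppf(1.0 - alpha, df=K))
    p = float(stats.chi2.sf(chi2, df=K))
    return {
        "chi2": chi2,
        "df": K,
        "p": p,
        "significant": p < alpha,
        "per_term_threshold": float(np.sqrt(crit / K)),
        "single_term_threshold": float(np.sqrt(crit)),
    }


def overrep_table(profiles: Sequence[MembershipProfile],
                  groups: dict, alpha: float = 0.05) -> OverrepTable:
    """Assemble the full group x cluster over-representation table.

    ``groups`` maps dyad_id -> group label.  Counts come from modal
    clusters.  Groups comprising the whole population (p_g = 1) cannot be
    tested; their rows carry NaN z values and a flag.
    """
    import warnings

    missing = [p.dyad_id for p in profiles if p.dyad_id not in groups]
    if missing:
        raise KeyError(f"dyads without group label: {missing[:5]}")
    K = profiles[0].frequencies.size
    N = len(profiles)
    modal = np.array([p.modal for p in profiles])
    labels = np.array([groups[p.dyad_id] for p in profiles])
    unique_groups = sorted(set(labels))

    n_c = np.array([(modal == c).sum() for c in range(K)])
    rows, tests = [], []
    for g in unique_groups:
        mask = labels == g
        p_g = mask.mean()
        zs = []
        for c in range(K):
            n_gc = int((mask & (modal == c)).sum())
            if n_c[c] == 0 or not (0 < p_g < 1):
                z = np.nan
            else:
                z = overrep_z(int(n_c[c]), n_gc, float(p_g))
            zs.append(z)
            rows.append({
                "group": g, "cluster": c + 1, "n_c": int(n_c[c]),
                "n_gc": n_gc, "p_g": p_g,
                "expected_share": p_g,
                "observed_share": n_gc / n_c[c] if n_c[c] else np.nan,
                "z": z,
            })
        zs = np.asarray(zs)
        if np.all(np.isfinite(zs)):
            t = overrep_test(zs, alpha=alpha)
            t["applicable"] = True
        else:
            warnings.warn(f"group {g!r} untestable (degenerate share or "
                          "empty cluster)")
            t = {"chi2": np.nan, "df": K, "p": np.nan, "significant": False,
                 "per_term_threshold": np.nan,
                 "single_term_threshold": np.nan, "applicable": False}
        t["group"] = g
        t["n_g"] = int(mask.sum())
        tests.append(t)
    return OverrepTable(
        cells=pd.DataFrame(rows),
        group_tests=pd.DataFrame(tests),
        cluster_sizes=n_c,
    )


def severity_correlation(profiles: Sequence[MembershipProfile],
                         scores: dict, cluster: int,
                         restrict_to_modal: bool = True):
    """Pearson correlation of cluster-membership probability with severity.

    By default only dyads whose modal cluster is the target contribute (the
    membership-severity relation is examined *within* the cluster where the
    group is over-represented).  Returns ``(r, p, n)``; the p-value comes
    from the t distribution with n - 2 degrees of freedom.
    """
    xs, ys = [], []
    for prof in profiles:
        if prof.dyad_id not in scores:
            continue
        if restrict_to_modal and prof.modal != cluster:
            continue
        xs.append(prof.frequencies[cluster])
        ys.append(scores[prof.dyad_id])
    if len(xs) < 3:
        raise ValueError(f"need >= 3 scored dyads, have {len(xs)}")
    xs, ys = np.asarray(xs), np.asarray(ys)
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("zero variance in membership or scores")
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p), len(xs)


@dataclass
class ClusterProfile:
    """Posterior-mean coefficients and mean member trajectories of a cluster."""

    cluster: int
    mean_beta: np.ndarray
    beta_labels: tuple
    mean_investments: np.ndarray
    mean_repayments: np.ndarray
    n_members: int


def cluster_profiles(chain: GibbsChain, records: Sequence[DyadRecord],
                     column_labels: Optional[tuple] = None) -> list:
    """Summarize each cluster: mean coefficients and member trajectories.

    Empty clusters are omitted (noted by their absence).  Coefficient means
    are within-chain posterior means; trajectory means average the modal
    members' raw 10-round investment and repayment vectors.
    """
    profiles = membership_profiles(chain, [r.dyad_id for r in records])
    modal = np.array([p.modal for p in profiles])
    beta_mean = chain.beta.mean(axis=0)
    out = []
    for k in range(chain.spec.K):
        members = np.nonzero(modal == k)[0]
        if members.size == 0:
            continue
        inv = np.stack([records[j].investments for j in members])
        rep = np.stack([records[j].repayments for j in members])
        out.append(ClusterProfile(
            cluster=k,
            mean_beta=beta_mean[k],
            beta_labels=column_labels or (),
            mean_investments=inv.mean(axis=0),
            mean_repayments=rep.mean(axis=0),
            n_members=int(members.size),
        ))
    return out


def adjusted_rand(partition_a: Sequence[int], partition_b: Sequence[int]) -> float:
    """Permutation-model adjusted Rand index between two partitions."""
    a, b = np.asarray(partition_a), np.asarray(partition_b)
    if a.size != b.size:
        raise ValueError("partitions cover different item sets")
    if a.size < 2:
        raise ValueError("need at least 2 items")
    return float(adjusted_rand_score(a, b))
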