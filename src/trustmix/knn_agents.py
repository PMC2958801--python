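"""k-nearest-neighbor sampling agents for the investor and trustee roles.

An agent replays a recorded population: at each decision it assembles the
vector of recent choices (up to the last 3 investments and last 3
repayments), finds the k recorded situations at the same round position with
the smallest Euclidean distance to that vector, and emits one of their
recorded outcomes uniformly at random.  Databases are conditioned on the
round position so that only like-with-like histories are ever compared:
early rounds carry shorter histories (round-1 investor decisions have none
and are uniform draws over recorded round-1 investments).

History vector convention, fixed and shared by both roles: most recent
first, the investment before the repayment within each slot.  The investor
deciding round t sees (i_{t-1}, r_{t-1}, i_{t-2}, r_{t-2}, i_{t-3}, r_{t-3});
the trustee deciding round t has additionally seen the current investment,
so its vector is (i_t, r_{t-1}, i_{t-1}, r_{t-2}, i_{t-2}, r_{t-3}).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .game_core import DyadRecord, N_ROUNDS

__all__ = [
    "AgentDatabase",
    "build_database",
    "agent_move",
    "simulate_game",
    "simulate_batch",
    "classify_batch",
    "investor_history",
    "trustee_history",
]

MAX_LAGS = 3
DEFAULT_K = 6


def investor_history(investments, repayments, round_t: int) -> np.ndarray:
    """History available to the investor deciding (1-based) round ``round_t``."""
    h = []
    for lag in range(1, MAX_LAGS + 1):
        j = round_t - 1 - lag  # 0-based index of round t-lag
        if j < 0:
            break
        h += [investments[j], repayments[j]]
    return np.asarray(h, dtype=float)


def trustee_history(investments, repayments, round_t: int) -> np.ndarray:
    """History available to the trustee deciding round ``round_t``.

    Includes the current round's investment (already on the table) plus up
    to the last 3 completed exchanges, truncated to 3 investments and 3
    repayments total.
    """
    h = [investments[round_t - 1]]
    for lag in range(1, MAX_LAGS + 1):
        j = round_t - 1 - lag
        if j < 0:
            break
        h.append(repayments[j])
        if lag < MAX_LAGS:  # cap at 3 investments including the current one
            h.append(investments[j])
    return np.asarray(h, dtype=float)


@dataclass
class AgentDatabase:
    """Recorded (history, outcome) situations for one role, by round position.

    ``histories[t]`` is an (n_t, L_t) array of history vectors for decisions
    at round t (1-based key), ``outcomes[t]`` the matching recorded ratios.
    Entries keep database insertion order, which breaks distance ties
    deterministically.
    """

    role: str
    population: tuple
    histories: dict = field(default_factory=dict)
    outcomes: dict = field(default_factory=dict)

    def n_entries(self, round_t: int) -> int:
        return len(self.outcomes.get(round_t, ()))


def build_database(records: Sequence[DyadRecord], role: str,
                   population: Optional[Sequence[str]] = None) -> AgentDatabase:
    """Build the situation database for one role from recorded games.

    ``population`` filters by group label (None keeps every record).  One
    entry is produced per (dyad, decision round): 10 entries per dyad.
    """
    if role not in ("investor", "trustee"):
        raise ValueError(f"unknown role {role!r}")
    if population is not None:
        population = tuple(population)
        records = [r for r in records if r.group in population]
    if not records:
        raise ValueError("empty population after filtering")
    hist_fn = investor_history if role == "investor" else trustee_history
    outcome = (lambda r, t: r.investments[t - 1]) if role == "investor" \
        else (lambda r, t: r.repayments[t - 1])
    histories = {t: [] for t in range(1, N_ROUNDS + 1)}
    outcomes = {t: [] for t in range(1, N_ROUNDS + 1)}
    for rec in records:
        for t in range(1, N_ROUNDS + 1):
            histories[t].append(hist_fn(rec.investments, rec.repayments, t))
            outcomes[t].append(float(outcome(rec, t)))
    return AgentDatabase(
        role=role,
        population=population or ("*",),
        histories={t: np.asarray(v) for t, v in histories.items()},
        outcomes={t: np.asarray(v) for t, v in outcomes.items()},
    )


def agent_move(db: AgentDatabase, history: np.ndarray, round_t: int,
               k: int = DEFAULT_K, rng: Optional[np.random.Generator] = None
               ) -> float:
    """Sample the agent's choice for one decision.

    Finds the k database entries at the same round position closest to
    ``history`` in Euclidean distance (ties by insertion order) and returns
    one of their outcomes uniformly at random.  With fewer than k entries
    all are used (with a warning).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if round_t not in db.histories:
        raise ValueError(f"database has no round-{round_t} entries")
    rng = rng or np.random.default_rng()
    H = db.histories[round_t]
    out = db.outcomes[round_t]
    history = np.asarray(history, dtype=float)
    if H.shape[1] != history.size:
        raise ValueError(
            f"history length {history.size} != database round-{round_t} "
            f"length {H.shape[1]}"
        )
    if out.size < k:
        import warnings
        warnings.warn(f"only {out.size} entries at round {round_t}; using all")
        k = out.size
    if H.shape[1] == 0:
        # no history (round-1 investor): uniform over all recorded outcomes
        return float(out[rng.integers(out.size)])
    d2 = np.square(H - history[None, :]).sum(axis=1)
    neighbors = np.argsort(d2, kind="stable")[:k]
    return float(out[neighbors[rng.integers(neighbors.size)]])


def simulate_game(investor_db: AgentDatabase, trustee_db: AgentDatabase,
                  seed: int = 0, group: str = "Sim-Healthy",
                  dyad_id: str = "sim0000", k: int = DEFAULT_K) -> DyadRecord:
    """Play one full 10-round agent-vs-agent game.

    The investor agent and trustee agent alternate, threading the growing
    shared history.  A zero investment forces the round's repayment ratio to
    0 (nothing to return).
    """
    rng = np.random.default_rng(seed)
    inv = np.zeros(N_ROUNDS)
    rep = np.zeros(N_ROUNDS)
    for t in range(1, N_ROUNDS + 1):
        hi = investor_history(inv, rep, t)
        inv[t - 1] = agent_move(investor_db, hi, t, k=k, rng=rng)
        if inv[t - 1] == 0.0:
            rep[t - 1] = 0.0
            continue
        ht = trustee_history(inv, rep, t)
        rep[t - 1] = agent_move(trustee_db, ht, t, k=k, rng=rng)
    return DyadRecord(dyad_id=dyad_id, group=group,
                      investments=inv, repayments=rep)


def simulate_batch(investor_db: AgentDatabase, trustee_db: AgentDatabase,
                   n_games: int = 1000, seed: int = 0,
                   group: str = "Sim-Healthy", k: int = DEFAULT_K) -> list:
    """Simulate ``n_games`` independent games with counter-derived seeds."""
    out = []
    for j in range(n_games):
        child = np.random.SeedSequence(seed, spawn_key=(j,))
        game_seed = int(child.generate_state(1)[0] % (2**31))
        out.append(simulate_game(
            investor_db, trustee_db, seed=game_seed, group=group,
            dyad_id=f"sim{j:04d}", k=k,
        ))
    return out


def classify_batch(batch: Sequence[DyadRecord], chain, groups: dict,
                   seed: int = 0):
    """Assign each simulated dyad to the fitted clusters; tabulate groups.

    Runs :func:`trustmix.cluster_analysis.classify_new` on every simulated
    record (classification by the recorded posterior draws) and assembles
    the over-representation table of the batch's group labels across the
    resulting modal clusters.
    """
    from .cluster_analysis import classify_new, overrep_table
    from .design import build_design

    if not batch:
        raise ValueError("empty batch")
    profiles = []
    for j, rec in enumerate(batch):
        pair = build_design(rec, chain.spec)
        child = np.random.SeedSequence(seed, spawn_key=(j,))
        profiles.append(classify_new(
            pair, chain, seed=int(child.generate_state(1)[0] % (2**31)),
            dyad_id=rec.dyad_id,
        ))
    return overrep_table(profiles, groups), profiles
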