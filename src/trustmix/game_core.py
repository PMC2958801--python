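"""Domain types and arithmetic for the 10-round trust game.

A *dyad* is one investor--trustee pair playing a single 10-round game.  Each
round the investor sends a fraction ``i_t`` of a fresh 20-monetary-unit (MU)
endowment; the amount is tripled on its way to the trustee, who returns a
fraction ``r_t`` of the tripled receipt.  Dyad trajectories are therefore a
pair of 10-vectors of ratios in [0, 1], which is all the downstream
clustering machinery ever sees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "ENDOWMENT_MU",
    "MULTIPLIER",
    "N_ROUNDS",
    "GROUPS",
    "DyadRecord",
    "RoundOutcome",
    "round_transfer",
    "payout_dollars",
    "validate_record",
]

#: Investor endowment per round, in monetary units.
ENDOWMENT_MU = 20.0

#: Multiplier applied to the amount sent on its way to the trustee.
MULTIPLIER = 3.0

#: Rounds per game.
N_ROUNDS = 10

#: Recognised population labels.  The ``Sim-*`` labels mark trajectories
#: produced by agent-vs-agent simulation rather than by (synthetic) humans.
GROUPS = (
    "Healthy",
    "ASD",
    "ADHD",
    "MDD",
    "BPD-M",
    "BPD-N",
    "Per",
    "Imp",
    "Sim-Healthy",
    "Sim-BPD",
)


@dataclass
class DyadRecord:
    """One complete 10-round game.

    Parameters
    ----------
    dyad_id
        Unique identifier.
    group
        Population label, one of :data:`GROUPS`.
    investments, repayments
        Length-10 arrays of ratios in [0, 1].  When the investment in a round
        is zero the repayment ratio is undefined (nothing was sent); it is
        stored as 0 and the round listed in ``zero_investment_rounds``.
    severity
        Optional map from severity-scale name to score.
    true_cluster
        Generating cluster index, present only for synthetic data.
    clipped_rounds
        Rounds (1-based) whose generated investment hit the [0, 1] boundary;
        synthetic data only.
    """

    dyad_id: str
    group: str
    investments: np.ndarray
    repayments: np.ndarray
    severity: Optional[dict] = None
    true_cluster: Optional[int] = None
    clipped_rounds: tuple = ()

    def __post_init__(self) -> None:
        self.investments = np.asarray(self.investments, dtype=float)
        self.repayments = np.asarray(self.repayments, dtype=float)

    @property
    def zero_investment_rounds(self) -> tuple:
        """1-based rounds in which nothing was invested."""
        return tuple(int(t) + 1 for t in np.nonzero(self.investments == 0.0)[0])


@dataclass(frozen=True)
class RoundOutcome:
    """Monetary flow of a single round, all quantities in MU."""

    sent_mu: float
    received_by_trustee_mu: float
    returned_mu: float
    investor_keep_mu: float


def round_transfer(
    endowment_mu: float, invest_ratio: float, repay_ratio: float
) -> RoundOutcome:
    """Monetary outcome of one round.

    The investor sends ``invest_ratio * endowment_mu``; the transfer is
    tripled for the trustee, who returns ``repay_ratio`` of the tripled
    amount.
    """
    if not (0.0 <= invest_ratio <= 1.0):
        raise ValueError(f"invest_ratio {invest_ratio} outside [0, 1]")
    if not (0.0 <= repay_ratio <= 1.0):
        raise ValueError(f"repay_ratio {repay_ratio} outside [0, 1]")
    if endowment_mu <= 0:
        raise ValueError("endowment must be positive")
    sent = invest_ratio * endowment_mu
    received = MULTIPLIER * sent
    returned = repay_ratio * received
    return RoundOutcome(
        sent_mu=sent,
        received_by_trustee_mu=received,
        returned_mu=returned,
        investor_keep_mu=endowment_mu - sent,
    )


# (upper MU bound inclusive, dollars); the final bracket is open-ended.
_PAYOUT_BRACKETS = ((68.0, 20), (134.0, 25), (201.0, 30), (301.0, 35))


def payout_dollars(total_mu: float) -> int:
    """Dollar compensation for a participant's accrued MU total.

    Piecewise-constant schedule: <68 MU -> $20, 68-133 MU -> $25,
    134-200 MU -> $30, 201-300 MU -> $35, >300 MU -> $40.
    """
    if total_mu < 0:
        raise ValueError("MU total cannot be negative")
    for upper, dollars in _PAYOUT_BRACKETS:
        if total_mu < upper:
            return dollars
    return 40


def validate_record(record: DyadRecord) -> list[str]:
    """Check all DyadRecord invariants; return human-readable violations.

    Returns an empty list for a well-formed record.  Never raises: callers
    decide how to treat malformed data.
    """
    violations: list[str] = []
    if record.group not in GROUPS:
        violations.append(f"unknown group label {record.group!r}")
    for name, arr in (("investments", record.investments),
                      ("repayments", record.repayments)):
        if arr.shape != (N_ROUNDS,):
            violations.append(
                f"{name} has length {arr.size}, expected {N_ROUNDS}"
            )
            continue
        for t, v in enumerate(arr, start=1):
            if not np.isfinite(v):
                violations.append(f"round {t} {name[:-1]} is not finite")
            elif not (0.0 <= v <= 1.0):
                violations.append(
                    f"round {t} {name[:-1]} ratio {v} outside [0, 1]"
                )
    if (record.investments.shape == (N_ROUNDS,)
            and record.repayments.shape == (N_ROUNDS,)):
        for t in record.zero_investment_rounds:
            if record.repayments[t - 1] != 0.0:
                violations.append(
                    f"round {t} repayment nonzero despite zero investment"
                )
    return violations
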