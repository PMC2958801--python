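"""Regression design construction for lagged-polynomial investment models.

The clustered model predicts the investment ratio in round t from all
monomials of total degree <= P in the 2D lagged ratios
{i_{t-1}, r_{t-1}, ..., i_{t-D}, r_{t-D}}.  To keep models with different
look-back windows comparable, the response is always the 8 investments of
rounds 3-10; a D=1 model simply never references lag-2 columns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np

from .game_core import DyadRecord, N_ROUNDS, validate_record

__all__ = ["ModelSpec", "DesignPair", "monomial_count", "monomial_exponents",
           "build_design", "RESPONSE_ROUNDS"]

#: 1-based rounds forming the response vector (shared by every model).
RESPONSE_ROUNDS = tuple(range(3, N_ROUNDS + 1))

MAX_K, MAX_P, MAX_D = 10, 3, 2


@dataclass(frozen=True)
class ModelSpec:
    """Model triple: K clusters, polynomial order P, look-back window D."""

    K: int
    P: int
    D: int

    def __post_init__(self) -> None:
        if not (1 <= self.K <= MAX_K):
            raise ValueError(f"K={self.K} outside 1..{MAX_K}")
        if not (1 <= self.P <= MAX_P):
            raise ValueError(f"P={self.P} outside 1..{MAX_P}")
        if not (1 <= self.D <= MAX_D):
            raise ValueError(f"D={self.D} outside 1..{MAX_D}")

    @property
    def n_coef(self) -> int:
        """Number of regression coefficients M = C(2D + P, P)."""
        return monomial_count(self.P, self.D)

    @property
    def n_params(self) -> int:
        """Free parameters: K coefficient vectors and variances, K-1 weights."""
        return self.K * (self.n_coef + 1) + (self.K - 1)


@dataclass(frozen=True)
class DesignPair:
    """Response/model-matrix pair for a single dyad.

    ``y`` holds the 8 investments of rounds 3-10; row j of ``X`` holds the
    monomials evaluated on the lags of round ``RESPONSE_ROUNDS[j]``.
    """

    y: np.ndarray
    X: np.ndarray
    column_labels: tuple

    def __post_init__(self) -> None:
        if self.y.shape[0] != self.X.shape[0]:
            raise ValueError("y and X row counts differ")


def monomial_count(P: int, D: int) -> int:
    """Number of monomials of total degree <= P in the 2D lagged variables."""
    if P < 1 or D < 1:
        raise ValueError("P and D must be >= 1")
    return comb(2 * D + P, P)


def monomial_exponents(P: int, D: int) -> list[tuple[int, ...]]:
    """Exponent vectors over (i_{t-1}, r_{t-1}, ..., i_{t-D}, r_{t-D}).

    Fixed ordering convention so serialized coefficient vectors are portable:
    the constant first, then the degree-1 terms in recency order (investment
    before repayment within each lag), then each higher degree
    lexicographically by variable index.
    """
    nvar = 2 * D
    out: list[tuple[int, ...]] = [(0,) * nvar]
    for degree in range(1, P + 1):
        for combo in itertools.combinations_with_replacement(range(nvar), degree):
            e = [0] * nvar
            for v in combo:
                e[v] += 1
            out.append(tuple(e))
    return out


def _variable_labels(D: int) -> list[str]:
    labels = []
    for lag in range(1, D + 1):
        labels += [f"i[t-{lag}]", f"r[t-{lag}]"]
    return labels


def monomial_labels(P: int, D: int) -> tuple:
    """Human-readable labels matching :func:`monomial_exponents` order."""
    var = _variable_labels(D)
    labels = []
    for exps in monomial_exponents(P, D):
        if sum(exps) == 0:
            labels.append("1")
            continue
        parts = []
        for v, e in zip(var, exps):
            if e == 1:
                parts.append(v)
            elif e > 1:
                parts.append(f"{v}^{e}")
        labels.append("*".join(parts))
    return tuple(labels)


def build_design(record: DyadRecord, spec: ModelSpec) -> DesignPair:
    """Build the (y, X) pair for one dyad under a model spec.

    Raises ``ValueError`` if the record fails validation.
    """
    violations = validate_record(record)
    if violations:
        raise ValueError(
            f"invalid record {record.dyad_id}: " + "; ".join(violations)
        )
    exps = monomial_exponents(spec.P, spec.D)
    i, r = record.investments, record.repayments
    rows = []
    for t in RESPONSE_ROUNDS:  # 1-based round of the response
        lags = []
        for lag in range(1, spec.D + 1):
            lags += [i[t - 1 - lag], r[t - 1 - lag]]
        lags = np.asarray(lags)
        rows.append([np.prod(lags ** np.asarray(e)) for e in exps])
    y = i[np.asarray(RESPONSE_ROUNDS) - 1].astype(float)
    X = np.asarray(rows, dtype=float)
    return DesignPair(y=y, X=X, column_labels=monomial_labels(spec.P, spec.D))


def build_designs(records, spec: ModelSpec):
    """Design pairs for a list of records, preserving order."""
    return [build_design(rec, spec) for rec in records]


def stack_designs(pairs):
    """Stack designs into dense arrays: Y (N, 8) and X (N, 8, M)."""
    Y = np.stack([p.y for p in pairs])
    X = np.stack([p.X for p in pairs])
    return Y, X
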