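"""Closed-form layer of the grooming-strategy model.

The amount of grooming an ego directs at a partner grows linearly with the
partner's grooming density ``w = d/t`` (tie strength per elapsed day):
``v(w) = alpha*w + 1``.  Summing ``v`` over an ego's ties and subtracting
the cost of having created them leaves the daily budget available for
*reinforcing* existing ties,

    G(a, alpha; C, m) = alpha * C * (m**(1-a) - m**(-a)) / T,

where ``C = N * m**a`` is the ego's total cost and ``T`` the observation
period in days.  Substituting ``N = C * m**(-a)`` gives the equivalent form
``G = alpha * N * (m - 1) / T``, which only depends on the strength vector
through its mean — the identity checked by the test suite.

G's shape in ``m`` is the heart of the model: for ``a <= 1`` it increases
without bound (egos with few, deep ties groom the most), while for
``a > 1`` it peaks at ``m* = a/(a-1)`` (egos with many, shallow ties groom
the most).  The flip happens exactly at ``a = 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GroomingParams",
    "grooming_amount",
    "grooming_budget",
    "optimal_m",
    "construction_amount",
]


@dataclass(frozen=True)
class GroomingParams:
    """Parameters of the grooming budget: slope ``alpha``, trade-off
    exponent ``a``, total cost ``C`` (in ``u**b`` units) and period ``T``
    (days)."""

    alpha: float
    a: float
    C: float
    T: float

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.T < 1:
            raise ValueError(f"T must be >= 1, got {self.T}")
        if self.C < 1:
            raise ValueError(f"C must be >= 1, got {self.C}")


def grooming_amount(w: float, alpha: float) -> float:
    """Amount of grooming per act at density ``w``: ``alpha*w + 1``.

    Strictly increasing in ``w``; one unit at ``w = 0`` (every act has a
    base cost even toward a brand-new tie).
    """
    if w < 0:
        raise ValueError(f"grooming density w must be >= 0, got {w}")
    return alpha * w + 1.0


def grooming_budget(params: GroomingParams, m: float) -> float:
    """Daily grooming budget ``G`` for an ego with mean tie strength ``m``.

    Zero exactly at ``m = 1`` (a tie at the one-day floor needs no
    reinforcement budget).  Values of ``m`` marginally below 1 from
    floating-point noise are clamped to 1; genuinely smaller ``m`` is
    undefined in-model and rejected.
    """
    if m < 1.0 - 1e-9:
        raise ValueError(f"mean strength m must be >= 1, got {m}")
    m = max(m, 1.0)
    g = params.alpha * params.C * (m ** (1.0 - params.a) - m ** (-params.a)) / params.T
    return max(g, 0.0)


def optimal_m(a: float) -> float:
    """Mean tie strength maximising G over ``m >= 1``.

    Returns ``math.inf`` for ``a <= 1`` (G is strictly increasing in ``m``,
    so the optimum is unbounded); for ``a > 1`` the unique interior
    maximiser ``m* = a/(a-1)``.
    """
    if a <= 0:
        raise ValueError(f"trade-off exponent a must be > 0, got {a}")
    if a <= 1.0:
        return math.inf
    return a / (a - 1.0)


def construction_amount(N: float, alpha: float, T: float) -> float:
    """Grooming spent creating ``N`` ties at the density floor ``1/T``.

    Each creation costs ``v(1/T) = alpha/T + 1``, so the total is
    ``N*(alpha/T + 1)``, which approaches ``N`` when ``T >> alpha`` — tie
    construction is essentially one act per tie, independent of ``a``.
    """
    if N < 0:
        raise ValueError(f"tie count N must be >= 0, got {N}")
    return N * (alpha / T + 1.0)
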