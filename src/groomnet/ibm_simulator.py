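"""Resource-constrained Yule-Simon individual-based simulator.

Groomers build and reinforce directed ties to passive groomees over ``T``
days.  Each groomer ``i`` carries a fixed cost budget: every morning its
reinforcement resource is reset to ``R_i = G(a, alpha; C_i, m_i)`` where
``m_i = (C_i/N_i)**(1/a)`` is the *target* mean strength implied by the
trade-off ``C = N*m**a``.  The day then runs two processes:

1. **Creation** — the groomer meets ``k ~ Poisson((N_i-1)/T)`` strangers and
   opens a tie of strength 1 to each.  Creation is free (it is accounted
   for separately in the model's construction term), and because every
   groomer starts with one tie, the expected final tie count is exactly
   ``N_i``.
2. **Reinforcement** — a Yule-Simon process: partners are drawn with
   probability proportional to current tie strength, each at most once per
   day.  Reinforcing partner ``j`` adds 1 to ``d_ij`` and costs
   ``v(d_ij/t) = alpha*d_ij/t + 1`` from ``R_i`` (strength and day index
   *before* the increment).  If the remaining resource cannot cover the
   cost, a fractional amount ``R_i/v`` is added instead and the resource
   hits zero.  Leftover resource when every partner has been seen is
   discarded.

Ties never decay; strengths are non-decreasing and each dyad gains at most
one unit per day.  Runs are bit-reproducible: one seed per run, with
deterministic per-groomer substreams so results do not depend on how many
groomers share the population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .grooming_model import GroomingParams, grooming_budget

__all__ = [
    "SimConfig",
    "SimState",
    "SimResult",
    "init_population",
    "create_ties",
    "reinforce",
    "run_simulation",
]


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one simulator run.

    ``egos`` is a sequence of ``(C_i, N_i)`` pairs: total cost and target
    tie count per groomer, with ``C_i >= N_i >= 1`` so the target mean
    strength ``(C_i/N_i)**(1/a)`` is at least 1.
    """

    T: int
    a: float
    alpha: float
    egos: tuple[tuple[float, float], ...]
    seed: int = 0
    record_daily: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "egos", tuple((float(c), float(n)) for c, n in self.egos))
        if self.T < 1:
            raise ValueError(f"T must be >= 1, got {self.T}")
        if self.a <= 0:
            raise ValueError(f"a must be > 0, got {self.a}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        for i, (C, N) in enumerate(self.egos):
            if not C >= N >= 1:
                raise ValueError(f"ego {i}: need C >= N >= 1, got C={C}, N={N}")

    @property
    def M(self) -> int:
        return len(self.egos)

    def m_target(self, i: int) -> float:
        C, N = self.egos[i]
        return max((C / N) ** (1.0 / self.a), 1.0)


@dataclass
class SimState:
    """Mutable ledger of a run: day index, per-groomer strength vectors,
    creation days, remaining resources and RNG substreams."""

    t: int
    d: list[list[float]]
    created: list[list[int]]
    R: np.ndarray
    G: np.ndarray
    rngs: list[np.random.Generator]
    daily_spend: list[list[float]] | None = None


@dataclass
class SimResult:
    """Outputs of one run: final strength vectors and realized summaries."""

    config: SimConfig
    d: list[np.ndarray]
    created: list[np.ndarray]
    G: np.ndarray
    daily_spend: np.ndarray | None = None

    @property
    def n_realized(self) -> np.ndarray:
        """Realized tie count N' per groomer (all ties with d > 0)."""
        return np.array([len(di) for di in self.d], dtype=float)

    @property
    def m_realized(self) -> np.ndarray:
        """Realized mean tie strength m' per groomer."""
        return np.array([di.mean() for di in self.d])

    def all_strengths(self) -> np.ndarray:
        """Pooled tie strengths across groomers (the d_ij distribution)."""
        return np.concatenate(self.d) if self.d else np.empty(0)

    def to_edge_dict(self) -> dict[str, dict[str, float]]:
        """Edge-list form with generated ids g<i> -> g<i>p<j>."""
        return {
            f"g{i}": {f"g{i}p{j}": float(s) for j, s in enumerate(di)}
            for i, di in enumerate(self.d)
        }


def init_population(config: SimConfig) -> SimState:
    """Day-0 state: each groomer holds one tie of strength 1 to a fresh
    groomee; budgets G computed from the fixed targets; substreams spawned
    deterministically per groomer index."""
    M = config.M
    ss = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(child) for child in ss.spawn(M)]
    G = np.empty(M)
    for i in range(M):
        C, _ = config.egos[i]
        params = GroomingParams(alpha=config.alpha, a=config.a, C=max(C, 1.0), T=config.T)
        G[i] = grooming_budget(params, config.m_target(i))
    return SimState(
        t=0,
        d=[[1.0] for _ in range(M)],
        created=[[0] for _ in range(M)],
        R=G.copy(),
        G=G,
        rngs=rngs,
        daily_spend=[[] for _ in range(M)] if config.record_daily else None,
    )


def create_ties(state: SimState, config: SimConfig) -> SimState:
    """Creation step of day ``state.t``: per groomer, open
    ``k ~ Poisson((N_i-1)/T)`` fresh ties of strength 1.  Spends no R."""
    for i in range(config.M):
        _, N = config.egos[i]
        p = (N - 1.0) / config.T
        if p <= 0:
            continue
        k = int(state.rngs[i].poisson(p))
        if k:
            state.d[i].extend([1.0] * k)
            state.created[i].extend([state.t] * k)
    return state


def _reinforce_one(
    d: list[float], R: float, t: int, alpha: float, rng: np.random.Generator
) -> tuple[float, float]:
    """Spend resource R on one groomer's partners; returns (R_left, spent)."""
    w = np.array(d)
    total = float(w.sum())
    spent = 0.0
    inv_t = 1.0 / t
    while R > 1e-12 and total > 1e-12:
        r = rng.random() * total
        idx = int(np.searchsorted(np.cumsum(w), r, side="right"))
        if idx >= len(d):  # guard against fp edge at r ~ total
            idx = len(d) - 1
            while idx >= 0 and w[idx] == 0.0:
                idx -= 1
        cost = alpha * d[idx] * inv_t + 1.0
        if R >= cost:
            d[idx] += 1.0
            spent += cost
            R -= cost
        else:
            d[idx] += R / cost
            spent += R
            R = 0.0
        total -= float(w[idx])
        w[idx] = 0.0
    return R, spent


def reinforce(state: SimState, config: SimConfig) -> SimState:
    """Reinforcement step of day ``state.t``: Yule-Simon partner selection
    without within-day repeats, until resource or partners run out."""
    if state.t < 1:
        raise ValueError("reinforce requires day t >= 1")
    for i in range(config.M):
        R0 = float(state.R[i])
        if R0 <= 0:
            if state.daily_spend is not None:
                state.daily_spend[i].append(0.0)
            continue
        R_left, spent = _reinforce_one(state.d[i], R0, state.t, config.alpha, state.rngs[i])
        state.R[i] = R_left
        if state.daily_spend is not None:
            state.daily_spend[i].append(spent)
    return state


def run_simulation(config: SimConfig) -> SimResult:
    """Run the full T-day simulation: per day, reset R to G, create, then
    reinforce (new ties are immediately eligible).  Deterministic given the
    config's seed."""
    state = init_population(config)
    for t in range(1, config.T + 1):
        state.t = t
        state.R[:] = state.G
        create_ties(state, config)
        reinforce(state, config)
    daily = (
        np.array([np.asarray(s) for s in state.daily_spend])
        if state.daily_spend is not None
        else None
    )
    return SimResult(
        config=config,
        d=[np.array(di) for di in state.d],
        created=[np.array(ci) for ci in state.created],
        G=state.G,
        daily_spend=daily,
    )
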