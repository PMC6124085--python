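"""Synthetic ego populations, event logs and simulator configurations.

Real grooming datasets (SNS logs, call records, baboon grooming bouts)
share a statistical signature: heavy-tailed total costs ``C``, participation
days ``u`` tied to cost by ``C = u**b``, ego summaries scattered around the
trade-off plane ``log N = -a*log m + b*log u``, and right-skewed
tie-strength distributions.  This module generates populations with that
signature *and* records the exact generating values, so every estimator in
the package can be tested as an inverse problem with known ground truth.

Defaults describe a year-long, moderately active messaging-style dataset:
365-day window, participation days log-uniform on [10, 365], cost exponent
b = 1.3 and trade-off exponent a = 1.2 (lightweight-method range, matching
the magnitudes reported for SNS data), log-noise 0.1.  Simulator costs are
drawn log-normally with median ~150 and log-sd 1 — a heavy right skew whose
upper quartile comfortably exceeds a 100-day window, so even the largest
target tie counts remain affordable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io_eventlog import ContactEvent, EgoSummary

__all__ = ["GeneratorSpec", "gen_ego_population", "gen_event_log", "gen_sim_configs"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic-population generator.

    ``u_law`` is log-uniform on ``[u_min, T]``; ``m`` is ``1 +`` a
    log-normal deviate (the floor ``m >= 1`` always holds); ``C_law`` for
    simulator configs is log-normal with parameters ``(C_log_mu,
    C_log_sigma)``.  Tie strengths, when materialised, are allocated by
    preferential (rich-get-richer) assignment, mirroring the Yule-Simon
    reinforcement the simulator implements.
    """

    M: int = 500
    T: int = 365
    a_true: float = 1.2
    b_true: float = 1.3
    sigma_log: float = 0.1
    u_min: float = 10.0
    m_log_mu: float = 0.5
    m_log_sigma: float = 0.8
    C_log_mu: float = 5.0
    C_log_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M < 1 or self.T < 1:
            raise ValueError("M and T must be >= 1")
        if not (1 <= self.u_min <= self.T):
            raise ValueError(f"need 1 <= u_min <= T, got u_min={self.u_min}, T={self.T}")
        if self.sigma_log < 0 or self.m_log_sigma <= 0 or self.C_log_sigma <= 0:
            raise ValueError("scale parameters must be positive")


def _allocate_strengths(
    N: int, m_target: float, u: int, rng: np.random.Generator
) -> np.ndarray:
    """Integer strengths for N partners, preferentially allocated.

    Everyone starts at 1; the remaining ``round(N*m_target) - N`` units are
    assigned one at a time with probability proportional to current
    strength, capped at ``u`` (a partner cannot be groomed on more days
    than the ego was active)."""
    d = np.ones(N, dtype=float)
    total_units = int(round(N * m_target))
    extra = min(total_units, N * u) - N
    for _ in range(max(extra, 0)):
        free = d < u
        if not free.any():
            break
        w = np.where(free, d, 0.0)
        idx = rng.choice(N, p=w / w.sum())
        d[idx] += 1.0
    return d


def gen_ego_population(
    spec: GeneratorSpec,
    discretize: bool = True,
    with_d: bool = False,
) -> tuple[list[EgoSummary], dict]:
    """Draw an ego population obeying ``log N = -a*log m + b*log u + eps``.

    With ``discretize=False`` (and ``sigma_log=0``) the population lies
    exactly on the trade-off plane and the regression recovers
    ``(a_true, b_true)`` to machine precision.  With ``with_d=True`` each
    ego also gets an integer strength map (preferentially allocated, each
    ``d_j <= u``) whose mean replaces the continuous ``m`` so that
    event-log round trips are exact; ``u`` is capped at the total strength
    (an ego cannot be active on more days than it has grooming-days to
    place).

    Returns the summaries and a ground-truth dict with the generating
    draws.
    """
    rng = np.random.default_rng(spec.seed)
    log_u = rng.uniform(math.log(spec.u_min), math.log(spec.T), size=spec.M)
    u = np.exp(log_u)
    m = 1.0 + rng.lognormal(spec.m_log_mu, spec.m_log_sigma, size=spec.M)
    if discretize:
        u = np.maximum(np.floor(u + 0.5), 1.0)
        m = np.minimum(m, u)
    eps = (
        rng.normal(0.0, spec.sigma_log, size=spec.M)
        if spec.sigma_log > 0
        else np.zeros(spec.M)
    )
    logN = -spec.a_true * np.log(m) + spec.b_true * np.log(u) + eps
    N = np.exp(logN)
    if discretize:
        # round half away from zero, floor at 1
        N = np.maximum(np.floor(N + 0.5), 1.0)
    truth = {
        "a_true": spec.a_true,
        "b_true": spec.b_true,
        "sigma_log": spec.sigma_log,
        "u": u.copy(),
        "m_drawn": m.copy(),
        "N": N.copy(),
        "eps": eps,
        "seed": spec.seed,
    }
    egos: list[EgoSummary] = []
    for i in range(spec.M):
        if with_d:
            if not discretize:
                raise ValueError("with_d requires discretize=True")
            ui = int(u[i])
            Ni = int(N[i])
            d_vec = _allocate_strengths(Ni, float(m[i]), ui, rng)
            u_eff = min(ui, int(d_vec.sum()))
            d_map = {f"e{i}p{j}": float(v) for j, v in enumerate(d_vec)}
            egos.append(
                EgoSummary.from_strengths(
                    f"e{i}", d_map, u=float(u_eff), C=compute_cost(u_eff, spec.b_true)
                )
            )
        else:
            egos.append(
                EgoSummary(
                    ego=f"e{i}",
                    N=float(N[i]),
                    m=float(m[i]),
                    u=float(u[i]),
                    C=compute_cost(float(u[i]), spec.b_true),
                )
            )
    truth["d"] = [dict(e.d) for e in egos] if with_d else None
    return egos, truth


def compute_cost(u: float, b: float) -> float:
    """C = u**b (local helper; the canonical API lives in
    tradeoff_regression.compute_C)."""
    return float(u) ** b


def gen_event_log(
    egos: Sequence[EgoSummary], spec: GeneratorSpec
) -> list[ContactEvent]:
    """Materialise an event log realising each ego's strength map exactly.

    Picks ``u`` active days uniformly without replacement from ``[1, T]``,
    then assigns each partner ``d_j`` distinct active days by round-robin
    over a shuffled day order — every active day is covered (aggregation
    recovers ``u`` exactly) and no partner repeats a day (aggregation
    recovers ``d`` exactly).  Requires integer ``d`` with ``d_j <= u`` and
    ``sum(d) >= u``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(1,)))
    events: list[ContactEvent] = []
    for e in egos:
        if e.d is None:
            raise ValueError(f"ego {e.ego!r} has no strength map")
        u = int(e.u)
        total = int(round(sum(e.d.values())))
        if total < u:
            raise ValueError(f"ego {e.ego!r}: sum(d)={total} < u={u}; days not coverable")
        for dj in e.d.values():
            if dj > u:
                raise ValueError(f"ego {e.ego!r}: d={dj} exceeds u={u}")
        days = rng.choice(spec.T, size=u, replace=False) + 1
        rng.shuffle(days)
        cursor = 0
        for alter, dj in e.d.items():
            dj = int(round(dj))
            for k in range(dj):
                events.append(ContactEvent(e.ego, alter, int(days[(cursor + k) % u])))
            cursor += dj
    return events


def gen_sim_configs(
    spec: GeneratorSpec, mode: str = "production", M: int | None = None
) -> list[tuple[float, float]]:
    """Draw a ``(C_i, N_i)`` ego table for the simulator.

    ``mode="experiment1"``: a single scalar cost — the 75th percentile of
    the drawn cost sample — paired with M target tie counts equally spaced
    in log scale on [1, T] (the calibration protocol).  ``mode=
    "production"``: per-ego heavy-tailed ``C_i`` with ``N_i`` log-uniform
    on [1, min(T, C_i)], so every ego satisfies ``C_i >= N_i``.
    """
    M = M if M is not None else spec.M
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(2,)))
    C = rng.lognormal(spec.C_log_mu, spec.C_log_sigma, size=M)
    if mode == "experiment1":
        C_scalar = max(float(np.percentile(C, 75)), float(spec.T))
        N_grid = np.exp(np.linspace(0.0, math.log(spec.T), M))
        return [(C_scalar, float(n)) for n in N_grid]
    if mode == "production":
        C = np.maximum(C, 1.0)
        upper = np.minimum(C, float(spec.T))
        N = np.exp(rng.uniform(0.0, np.log(upper)))
        return [(float(c), float(n)) for c, n in zip(C, N)]
    raise ValueError(f"unknown mode {mode!r}")
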