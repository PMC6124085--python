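"""Fitting the grooming slope alpha and sweeping the (a, alpha) grid.

Two experiments connect the simulator back to ego summaries.

*Consistency fit* — given a method's exponent ``a``, window ``T`` and a
scalar cost ``C`` (the 75th percentile of the cost distribution), simulate
``M`` groomers whose target tie counts are log-spaced on ``[1, T]`` and
find the slope ``alpha`` that minimises the mean squared log-distance

    e = sum_i [(log N_i - log N'_i)**2 + (log m_i - log m'_i)**2] / M

between targets ``(N_i, m_i = (C/N_i)**(1/a))`` and the realized
``(N'_i, m'_i)``.  The objective is simulation noise on top of a smooth
curve, so the search uses common random numbers (the same replicate seeds
at every alpha) and a deterministic golden-section bracket.

*Grid sweep* — evaluate the replicate error on a full (a, alpha) grid,
keep per ``a`` the entries ranked in the lowest ``n_select`` of ``e``, and
re-run those alphas on a production ego table (per-ego heavy-tailed costs)
to measure the resulting social-relationship forms.  A convenience driver,
:func:`run_threshold_study`, chains the sweep with the power-law and
hierarchy analyses and the breakpoint scan of the phi-vs-a relationship.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .ibm_simulator import SimConfig, run_simulation
from .network_analysis import (
    SegmentedFit,
    breakpoint_scan,
    fit_powerlaw,
    hierarchy_profile,
)
from .synthetic_data import GeneratorSpec, gen_sim_configs

__all__ = [
    "CalibrationSetup",
    "CalibrationResult",
    "GridResult",
    "ThresholdStudy",
    "error_e",
    "fit_alpha",
    "grid_experiment",
    "grid_jobs",
    "paper_grid_a",
    "paper_grid_alpha",
    "run_threshold_study",
    "log_spaced_targets",
]

_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


def paper_grid_a() -> np.ndarray:
    """The canonical sweep grid for a: 0.50 to 2.00 in steps of 0.05."""
    return np.round(0.50 + 0.05 * np.arange(31), 10)


def paper_grid_alpha() -> np.ndarray:
    """The canonical sweep grid for alpha: 1.00 to 3.00 in steps of 0.02."""
    return np.round(1.00 + 0.02 * np.arange(101), 10)


@dataclass(frozen=True)
class CalibrationSetup:
    """Consistency-fit configuration: exponent ``a``, window ``T``, scalar
    cost ``C`` (>= T so every log-spaced target is affordable), population
    size ``M``, replicate count and master seed."""

    a: float
    T: int
    C: float
    M: int = 30
    replicates: int = 3
    seed: int = 0
    alpha_bounds: tuple[float, float] = (0.5, 4.0)

    def __post_init__(self) -> None:
        if self.M < 2:
            raise ValueError(f"M must be >= 2, got {self.M}")
        if self.C < 1:
            raise ValueError(f"C must be >= 1, got {self.C}")
        lo, hi = self.alpha_bounds
        if not (0 < lo < hi):
            raise ValueError(f"invalid alpha bounds {self.alpha_bounds}")


@dataclass
class CalibrationResult:
    alpha_hat: float
    e: float
    replicate_errors: np.ndarray
    trace: list[tuple[float, float]]
    converged: bool = True


def log_spaced_targets(setup: CalibrationSetup) -> tuple[np.ndarray, np.ndarray]:
    """Target (N_i, m_i): N log-spaced on [1, T], m_i = (C/N_i)**(1/a),
    clamped at the strength floor 1."""
    N = np.minimum(np.exp(np.linspace(0.0, math.log(setup.T), setup.M)), float(setup.T))
    m = np.maximum((setup.C / N) ** (1.0 / setup.a), 1.0)
    return N, m


def error_e(
    targets: Sequence[tuple[float, float]],
    realized: Sequence[tuple[float, float]],
) -> float:
    """Mean squared log-distance between target and realized (N, m) pairs."""
    if len(targets) != len(realized):
        raise ValueError("targets and realized must have equal length")
    M = len(targets)
    if M == 0:
        raise ValueError("empty target list")
    total = 0.0
    for (N, m), (Np, mp) in zip(targets, realized):
        if min(N, m, Np, mp) < 1.0 - 1e-12:
            raise ValueError(f"all N, m values must be >= 1; got {(N, m, Np, mp)}")
        total += (math.log(N) - math.log(Np)) ** 2 + (math.log(m) - math.log(mp)) ** 2
    return total / M


def _replicate_seeds(seed: int, replicates: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(replicates, dtype=np.uint32)
    return [int(s >> 1) for s in state]  # keep seeds below 2**31


def _simulate_error(setup: CalibrationSetup, alpha: float, sim_seed: int,
                    targets: Sequence[tuple[float, float]] | None = None) -> float:
    N_grid, m_grid = log_spaced_targets(setup)
    cfg = SimConfig(
        T=setup.T,
        a=setup.a,
        alpha=alpha,
        egos=tuple((setup.C, float(n)) for n in N_grid),
        seed=sim_seed,
    )
    res = run_simulation(cfg)
    realized = list(zip(res.n_realized, res.m_realized))
    tg = list(zip(N_grid, m_grid)) if targets is None else list(targets)
    return error_e(tg, realized)


def fit_alpha(
    setup: CalibrationSetup,
    targets: Sequence[tuple[float, float]] | None = None,
    tol: float = 0.02,
    max_evals: int = 80,
    n_scan: int = 21,
) -> CalibrationResult:
    """Bounded scalar search for the alpha minimising replicate-mean error.

    The simulation objective is jagged (different alphas produce different
    trajectories), so the search is a deterministic two-stage procedure: a
    coarse equally spaced scan of ``n_scan`` points over the bounds, then
    golden-section refinement inside the bracket around the scan minimum.
    Common random numbers: the same replicate seeds are reused at every
    alpha, making the whole fit deterministic given the setup.  If the
    bracket has not shrunk below ``tol`` within ``max_evals`` objective
    evaluations, the best point so far is returned with
    ``converged=False``.
    """
    seeds = _replicate_seeds(setup.seed, setup.replicates)
    cache: dict[float, tuple[float, np.ndarray]] = {}
    trace: list[tuple[float, float]] = []

    def objective(alpha: float) -> float:
        key = round(alpha, 12)
        if key not in cache:
            errs = np.array([_simulate_error(setup, alpha, s, targets) for s in seeds])
            cache[key] = (float(errs.mean()), errs)
            trace.append((alpha, float(errs.mean())))
        return cache[key][0]

    scan = np.linspace(*setup.alpha_bounds, n_scan)
    scan_vals = [objective(float(al)) for al in scan]
    j = int(np.argmin(scan_vals))
    lo = float(scan[max(j - 1, 0)])
    hi = float(scan[min(j + 1, n_scan - 1)])

    x1 = hi - _GOLDEN * (hi - lo)
    x2 = lo + _GOLDEN * (hi - lo)
    f1, f2 = objective(x1), objective(x2)
    converged = False
    while len(trace) < max_evals:
        if hi - lo < tol:
            converged = True
            break
        if f1 <= f2:
            hi, x2, f2 = x2, x1, f1
            x1 = hi - _GOLDEN * (hi - lo)
            f1 = objective(x1)
        else:
            lo, x1, f1 = x1, x2, f2
            x2 = lo + _GOLDEN * (hi - lo)
            f2 = objective(x2)
    best_alpha = min(cache, key=lambda k: cache[k][0])
    best_mean, best_errs = cache[best_alpha]
    return CalibrationResult(
        alpha_hat=float(best_alpha),
        e=best_mean,
        replicate_errors=best_errs,
        trace=trace,
        converged=converged,
    )


def grid_jobs(
    a_grid: Sequence[float], alpha_grid: Sequence[float], replicates: int
):
    """Enumerate every (a, alpha, replicate) evaluation of a sweep, in the
    deterministic order the sweep executes them."""
    for ia, a in enumerate(a_grid):
        for ja, alpha in enumerate(alpha_grid):
            for rep in range(replicates):
                yield (ia, float(a), ja, float(alpha), rep)


@dataclass
class GridResult:
    """Sweep bookkeeping: the full error table, the per-a lowest-``n``
    selection, and per-a summaries of the selected alphas."""

    errors: pd.DataFrame  # columns a, alpha, replicate, e
    selection: pd.DataFrame  # lowest-n rows per a, with rank
    alpha_stats: pd.DataFrame  # per a: alpha_mean, alpha_sd, e_mean
    n_select: int

    def results_per_a(self) -> pd.Series:
        return self.errors.groupby("a").size()


def grid_experiment(
    a_grid: Sequence[float],
    alpha_grid: Sequence[float],
    replicates: int,
    *,
    T: int,
    C: float,
    M: int = 30,
    seed: int = 0,
    n_select: int = 20,
) -> GridResult:
    """Evaluate the replicate error on every (a, alpha) cell.

    Replicate seeds are shared across alpha within each ``a`` (common
    random numbers), so neighbouring-alpha error vectors differ only
    through alpha.  Selection ranks the individual (alpha, replicate)
    results per ``a`` and keeps the lowest ``n_select``.
    """
    rows = []
    for ia, a in enumerate(a_grid):
        rep_seeds = [
            int(np.random.SeedSequence(entropy=seed, spawn_key=(ia, r)).generate_state(1)[0] >> 1)
            for r in range(replicates)
        ]
        setup = CalibrationSetup(a=float(a), T=T, C=C, M=M, replicates=replicates, seed=seed)
        for alpha in alpha_grid:
            for r in range(replicates):
                e = _simulate_error(setup, float(alpha), rep_seeds[r])
                rows.append({"a": float(a), "alpha": float(alpha), "replicate": r, "e": e})
    errors = pd.DataFrame(rows)
    sel_frames = []
    for a, grp in errors.groupby("a", sort=True):
        top = grp.nsmallest(n_select, "e").copy()
        top["rank"] = range(len(top))
        sel_frames.append(top)
    selection = pd.concat(sel_frames, ignore_index=True)
    alpha_stats = (
        selection.groupby("a")
        .agg(alpha_mean=("alpha", "mean"), alpha_sd=("alpha", "std"), e_mean=("e", "mean"))
        .reset_index()
    )
    return GridResult(errors=errors, selection=selection, alpha_stats=alpha_stats, n_select=n_select)


@dataclass
class ThresholdStudy:
    """Outputs of the full sweep-plus-forms pipeline."""

    grid: GridResult
    phi: pd.DataFrame  # per selected entry: a, alpha, replicate, rank, phi
    hierarchy: pd.DataFrame  # per entry and k: a, k, H, ratio (gt dialect)
    phi_by_a: pd.DataFrame  # per a: phi_mean, phi_sd
    breakpoint: float
    segmented: SegmentedFit
    no_clear_kink: bool
    production_egos: list[tuple[float, float]]
    C_scalar: float


def run_threshold_study(
    seed: int = 0,
    *,
    M: int = 30,
    T: int = 100,
    a_grid: Sequence[float] | None = None,
    alpha_grid: Sequence[float] | None = None,
    replicates: int = 10,
    n_select: int = 20,
    breakpoint_candidates: Sequence[float] | None = None,
    k_max: int = 10,
    generator: GeneratorSpec | None = None,
) -> ThresholdStudy:
    """Scaled sweep of the (a, alpha) grid plus social-form analysis.

    Defaults run a grid of a in 0.5..2.0 (step 0.1) by alpha in 1.0..3.0
    (step 0.1) with 10 replicates on a 100-day window and 30 groomers —
    small enough for a workstation, large enough for the threshold in the
    phi-vs-a relationship to be resolvable.  Costs are heavy-tailed
    log-normal; the calibration cost is their 75th percentile.
    """
    if a_grid is None:
        a_grid = np.round(0.5 + 0.1 * np.arange(16), 10)
    if alpha_grid is None:
        alpha_grid = np.round(1.0 + 0.1 * np.arange(21), 10)
    if breakpoint_candidates is None:
        breakpoint_candidates = np.round(0.6 + 0.1 * np.arange(7), 10)
    gen = generator if generator is not None else GeneratorSpec(M=M, T=T, seed=seed)
    production = gen_sim_configs(gen, mode="production", M=M)
    C_scalar = max(float(np.percentile([c for c, _ in production], 75)), float(T))

    grid = grid_experiment(
        a_grid, alpha_grid, replicates, T=T, C=C_scalar, M=M, seed=seed, n_select=n_select
    )

    phi_rows = []
    hier_rows = []
    for ia, a in enumerate(a_grid):
        sel = grid.selection[np.isclose(grid.selection["a"], a)]
        for _, row in sel.iterrows():
            run_seed = int(
                np.random.SeedSequence(entropy=seed, spawn_key=(1000 + ia, int(row["rank"])))
                .generate_state(1)[0]
                >> 1
            )
            cfg = SimConfig(T=T, a=float(a), alpha=float(row["alpha"]), egos=production, seed=run_seed)
            res = run_simulation(cfg)
            strengths = res.all_strengths()
            phi = fit_powerlaw(strengths).phi
            phi_rows.append(
                {
                    "a": float(a),
                    "alpha": float(row["alpha"]),
                    "replicate": int(row["replicate"]),
                    "rank": int(row["rank"]),
                    "phi": phi,
                }
            )
            prof = hierarchy_profile(strengths, mode="gt", k_max=k_max)
            for k in range(1, k_max + 1):
                hier_rows.append(
                    {
                        "a": float(a),
                        "rank": int(row["rank"]),
                        "k": k,
                        "H": prof.H[k],
                        "ratio": prof.ratios.get(k, np.nan),
                    }
                )
    phi_df = pd.DataFrame(phi_rows)
    hier_df = pd.DataFrame(hier_rows)
    phi_by_a = (
        phi_df.groupby("a").agg(phi_mean=("phi", "mean"), phi_sd=("phi", "std")).reset_index()
    )
    best_bp, seg, flat = breakpoint_scan(
        phi_df["a"].to_numpy(), phi_df["phi"].to_numpy(), breakpoint_candidates
    )
    return ThresholdStudy(
        grid=grid,
        phi=phi_df,
        hierarchy=hier_df,
        phi_by_a=phi_by_a,
        breakpoint=best_bp,
        segmented=seg,
        no_clear_kink=flat,
        production_egos=list(production),
        C_scalar=C_scalar,
    )
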