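"""Social-relationship-form statistics.

Three summaries of a tie-strength distribution and the regressions that
relate them to the trade-off exponent ``a``:

* the power-law exponent ``phi`` of the strength distribution (continuous
  maximum likelihood, density-exponent convention, fixed ``xmin = 1`` —
  the model's natural strength floor);
* hierarchy sizes ``H_k`` (number of ties above strength ``k``) and the
  ratios ``H_k/H_{k+1}`` that index the layering of social circles.  Two
  dialects exist because observed strengths are integer day counts while
  simulated strengths are real: ``"ge"`` counts ``d >= k``, ``"gt"``
  counts ``d > k``;
* a two-segment linear model of ``phi`` versus ``a`` with a breakpoint,
  compared against a plain line by AIC, plus a scan over candidate
  breakpoints.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "PowerLawFit",
    "HierarchyProfile",
    "SegmentedFit",
    "fit_powerlaw",
    "hierarchy_profile",
    "ratio_vs_a_regression",
    "segmented_phi_regression",
    "breakpoint_scan",
]


@dataclass(frozen=True)
class PowerLawFit:
    phi: float
    xmin: float
    n_tail: int
    method: str = "continuous-mle-density"


@dataclass(frozen=True)
class HierarchyProfile:
    mode: str  # "ge" (day-count data) or "gt" (real-valued simulation)
    H: dict[int, int]
    ratios: dict[int, float]


@dataclass(frozen=True)
class SegmentedFit:
    """Four-term threshold model phi ~ b1*a*f + b2*a*(1-f) + b3*f + b0
    (f = 1 iff a >= breakpoint) versus the plain line phi ~ b1*a + b0."""

    beta0: float
    beta1: float
    beta2: float
    beta3: float
    sigma: float
    aic_segmented: float
    aic_linear: float
    breakpoint: float
    linear_beta0: float = math.nan
    linear_beta1: float = math.nan

    @property
    def prefers_threshold(self) -> bool:
        return self.aic_segmented < self.aic_linear


def _aic(rss: float, n: int, k_mean: int) -> float:
    """AIC under the normal likelihood with ML variance; k counts mean
    parameters plus the variance."""
    sigma2 = rss / n
    return n * math.log(2.0 * math.pi * sigma2) + n + 2.0 * (k_mean + 1)


def fit_powerlaw(
    strengths: Sequence[float], xmin: float = 1.0, min_tail: int = 10
) -> PowerLawFit:
    """Continuous MLE of the density exponent: phi = 1 + n / sum(ln(x/xmin)).

    Only values >= xmin enter; a fit is reported only when the tail holds at
    least ``min_tail`` observations (default 10).  The estimate is invariant
    to rescaling x and xmin together.
    """
    x = np.asarray(strengths, dtype=float)
    if np.any(x <= 0):
        raise ValueError("strengths must be positive")
    tail = x[x >= xmin]
    n = tail.size
    if n < max(min_tail, 2):
        raise ValueError(f"need >= {max(min_tail, 2)} values >= xmin={xmin}, have {n}")
    s = float(np.log(tail / xmin).sum())
    if s <= 0.0:
        raise ValueError("all tail values equal xmin; exponent undefined")
    return PowerLawFit(phi=1.0 + n / s, xmin=xmin, n_tail=n)


def hierarchy_profile(
    strengths: Sequence[float], mode: str = "ge", k_max: int = 10
) -> HierarchyProfile:
    """Hierarchy sizes H_k for k = 1..k_max and neighbour ratios.

    ``mode="ge"`` counts ties with d >= k (integer day-count data, so H_1 is
    all ties); ``mode="gt"`` counts d > k (real-valued simulated strengths,
    so H_1 already excludes one-shot ties).  Ratios are reported only where
    H_{k+1} > 0.
    """
    if mode not in ("ge", "gt"):
        raise ValueError(f"mode must be 'ge' or 'gt', got {mode!r}")
    x = np.asarray(strengths, dtype=float)
    if x.size == 0:
        raise ValueError("empty strength vector")
    H = {}
    for k in range(1, k_max + 1):
        H[k] = int((x >= k).sum()) if mode == "ge" else int((x > k).sum())
    ratios = {}
    for k in range(1, k_max):
        if H[k + 1] > 0:
            ratios[k] = H[k] / H[k + 1]
        else:
            logger.info("H_%d = 0; ratio H_%d/H_%d undefined, omitted", k + 1, k, k + 1)
    return HierarchyProfile(mode=mode, H=H, ratios=ratios)


def ratio_vs_a_regression(points: pd.DataFrame) -> pd.DataFrame:
    """Per-k OLS of hierarchy ratio on a (with intercept).

    ``points`` needs columns ``k``, ``a``, ``ratio``.  Returns one row per
    k with beta1 (slope on a), beta0, standard errors and p-values.
    """
    out = []
    for k, grp in points.groupby("k"):
        a = grp["a"].to_numpy(dtype=float)
        y = grp["ratio"].to_numpy(dtype=float)
        if a.size < 3:
            raise ValueError(f"k={k}: need >= 3 points, have {a.size}")
        if np.unique(a).size < 2:
            raise ValueError(f"k={k}: degenerate a values")
        X = sm.add_constant(a)
        res = sm.OLS(y, X).fit()
        out.append(
            {
                "k": int(k),
                "beta1": float(res.params[1]),
                "beta0": float(res.params[0]),
                "se_beta1": float(res.bse[1]),
                "se_beta0": float(res.bse[0]),
                "p_beta1": float(res.pvalues[1]),
                "n": int(a.size),
            }
        )
    return pd.DataFrame(out).sort_values("k").reset_index(drop=True)


def segmented_phi_regression(
    a: Sequence[float], phi: Sequence[float], breakpoint: float = 0.8
) -> SegmentedFit:
    """Fit the threshold model and the plain line; compare by AIC.

    The threshold model allows separate slopes above (beta1) and below
    (beta2) the breakpoint and a level shift (beta3); with no noise and a
    genuine kink it interpolates the two segments exactly.
    """
    a = np.asarray(a, dtype=float)
    y = np.asarray(phi, dtype=float)
    if a.size != y.size:
        raise ValueError("a and phi must have equal length")
    f = (a >= breakpoint).astype(float)
    if f.min() == f.max():
        raise ValueError(f"all points on one side of breakpoint {breakpoint}")
    n = a.size
    X_seg = np.column_stack([a * f, a * (1.0 - f), f, np.ones(n)])
    res_seg = sm.OLS(y, X_seg).fit()
    X_lin = np.column_stack([a, np.ones(n)])
    res_lin = sm.OLS(y, X_lin).fit()
    return SegmentedFit(
        beta1=float(res_seg.params[0]),
        beta2=float(res_seg.params[1]),
        beta3=float(res_seg.params[2]),
        beta0=float(res_seg.params[3]),
        sigma=float(np.sqrt(res_seg.ssr / n)),
        aic_segmented=_aic(float(res_seg.ssr), n, 4),
        aic_linear=_aic(float(res_lin.ssr), n, 2),
        breakpoint=breakpoint,
        linear_beta1=float(res_lin.params[0]),
        linear_beta0=float(res_lin.params[1]),
    )


def breakpoint_scan(
    a: Sequence[float],
    phi: Sequence[float],
    candidates: Sequence[float],
) -> tuple[float, SegmentedFit, bool]:
    """Fit the threshold model at each candidate breakpoint; return the
    AIC-minimising one (ties toward the smaller candidate), its fit, and a
    flag that is True when the AIC profile is flat (range < 2 — no clear
    kink in the data)."""
    candidates = list(candidates)
    if len(candidates) < 1:
        raise ValueError("need at least one candidate breakpoint")
    fits = []
    for c in candidates:
        try:
            fits.append((c, segmented_phi_regression(a, phi, breakpoint=c)))
        except ValueError as exc:
            logger.warning("breakpoint candidate %s skipped: %s", c, exc)
    if not fits:
        raise ValueError("no candidate breakpoint splits the data")
    aics = [f.aic_segmented for _, f in fits]
    best_idx = min(range(len(fits)), key=lambda i: (aics[i], fits[i][0]))
    flat = (max(aics) - min(aics)) < 2.0
    if flat:
        logger.warning("breakpoint scan: AIC range %.3f < 2 — no clear kink", max(aics) - min(aics))
    best_c, best_fit = fits[best_idx]
    return best_c, best_fit, flat
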