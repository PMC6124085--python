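"""Number-vs-strength trade-off regression and grooming-method classification.

An ego investing total cost ``C`` in social relationships faces the
trade-off ``C = N * m**a`` between the number ``N`` and the mean strength
``m`` of its ties.  With the cost proxied by participation days,
``C = u**b``, taking logs gives the regression model

    log N ~ Normal(-a*log m + b*log u, sigma)

with no intercept.  The exponent ``a`` measures the steepness of the
trade-off and separates grooming methods: ``a < 1`` marks *elaborate*
methods (costly, face-to-face-like, favouring few strong ties) and
``a > 1`` marks *lightweight* methods (cheap, SNS-like, favouring many
weak ties).  Because the dichotomy pivots at 1, the headline test on
``a`` is H0: a = 1; the test on ``b`` is the usual H0: b = 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .io_eventlog import EgoSummary

logger = logging.getLogger(__name__)

__all__ = ["TradeoffFit", "fit_tradeoff", "classify", "compute_C", "IdentifiabilityError"]


class IdentifiabilityError(ValueError):
    """The design matrix cannot identify (a, b)."""


@dataclass(frozen=True)
class TradeoffFit:
    """Result of the no-intercept log-log trade-off regression.

    ``t_a``/``p_a`` test the trade-off exponent against the neutral value 1;
    ``t_b``/``p_b`` test the cost exponent against 0.  Both are two-sided.
    """

    a: float
    b: float
    sigma: float
    se_a: float
    se_b: float
    t_a: float
    t_b: float
    p_a: float
    p_b: float
    adj_r2: float
    n_egos: int

    @property
    def label(self) -> str:
        return classify(self.a)

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "sigma": self.sigma,
            "se_a": self.se_a,
            "se_b": self.se_b,
            "t_a": self.t_a,
            "t_b": self.t_b,
            "p_a": self.p_a,
            "p_b": self.p_b,
            "adj_r2": self.adj_r2,
            "n_egos": self.n_egos,
            "label": self.label,
        }


def classify(a: float) -> str:
    """Label a grooming method by its trade-off exponent.

    ``a < 1`` -> ``"elaborate"``; ``a > 1`` -> ``"lightweight"``; exactly 1
    -> ``"neutral"`` (the dichotomy is defined by strict inequalities, so
    the boundary gets its own label rather than a forced class).
    """
    if not math.isfinite(a):
        raise ValueError(f"non-finite trade-off exponent: {a!r}")
    if a < 1.0:
        return "elaborate"
    if a > 1.0:
        return "lightweight"
    return "neutral"


def compute_C(u: float, b: float) -> float:
    """Total grooming cost ``C = u**b`` from participation days ``u``."""
    if u < 1:
        raise ValueError(f"participation days u must be >= 1, got {u}")
    if not math.isfinite(b):
        raise ValueError(f"cost exponent b must be finite, got {b!r}")
    return float(u) ** b


def fit_tradeoff(egos: Sequence[EgoSummary]) -> TradeoffFit:
    """Fit ``log N = -a*log m + b*log u`` by least squares without intercept.

    Equivalent to maximum likelihood under the stated normal model.  Egos
    whose predictors are both exactly zero (m = 1 and u = 1) carry no
    information and are dropped with a warning.  Natural logs throughout;
    (a, b) are log-base invariant, sigma is reported in natural-log units.

    Raises
    ------
    IdentifiabilityError
        Fewer than 3 informative egos, fewer than two distinct m or u
        values, or collinear predictors (log m proportional to log u).
    """
    rows = [(e.N, e.m, e.u) for e in egos]
    for N, m, u in rows:
        if N <= 0 or m < 1 or u < 1:
            raise ValueError(f"ego with N={N}, m={m}, u={u}: need N > 0 and m, u >= 1")
    n_small = sum(1 for N, _, _ in rows if N < 1)
    if n_small:
        # inclusion rule: the regression's unit of observation needs at
        # least one relationship
        logger.warning("excluding %d ego(s) with N < 1 from the fit", n_small)
        rows = [r for r in rows if r[0] >= 1]
    arr = np.asarray(rows, dtype=float)
    logN = np.log(arr[:, 0])
    logm = np.log(arr[:, 1])
    logu = np.log(arr[:, 2])
    keep = ~((logm == 0.0) & (logu == 0.0))
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d ego(s) with m = u = 1 (all-zero predictors)", n_dropped)
    logN, logm, logu = logN[keep], logm[keep], logu[keep]
    n = logN.size
    if n < 3:
        raise IdentifiabilityError(f"need >= 3 informative egos, have {n}")
    if np.unique(logm).size < 2 or np.unique(logu).size < 2:
        raise IdentifiabilityError("need >= 2 distinct m values and >= 2 distinct u values")
    X = np.column_stack([logm, logu])
    if np.linalg.matrix_rank(X, tol=1e-10 * np.abs(X).max()) < 2:
        raise IdentifiabilityError("log m and log u are collinear; (a, b) not identifiable")

    res = sm.OLS(logN, X).fit()
    a_hat = -float(res.params[0])
    b_hat = float(res.params[1])
    se_a = float(res.bse[0])
    se_b = float(res.bse[1])
    df_resid = n - 2
    sigma = float(np.sqrt(res.ssr / df_resid)) if df_resid > 0 else 0.0
    t_a = (a_hat - 1.0) / se_a if se_a > 0 else math.inf * np.sign(a_hat - 1.0 or 1.0)
    t_b = b_hat / se_b if se_b > 0 else math.inf * np.sign(b_hat or 1.0)
    p_a = 2.0 * stats.t.sf(abs(t_a), df_resid)
    p_b = 2.0 * stats.t.sf(abs(t_b), df_resid)
    return TradeoffFit(
        a=a_hat,
        b=b_hat,
        sigma=sigma,
        se_a=se_a,
        se_b=se_b,
        t_a=float(t_a),
        t_b=float(t_b),
        p_a=float(p_a),
        p_b=float(p_b),
        adj_r2=float(res.rsquared_adj),
        n_egos=n,
    )


def format_fit_table(fit: TradeoffFit, name: str = "dataset") -> str:
    """Flat text table of a fit (one row per coefficient)."""
    lines = [
        f"method\tadj_R2\tcoef\testimate\ts.e.\tt\tp\tlabel",
        f"{name}\t{fit.adj_r2:.3f}\ta\t{fit.a:.5f}\t{fit.se_a:.5f}\t{fit.t_a:.3f}\t{fit.p_a:.3g}\t{fit.label}",
        f"{name}\t{fit.adj_r2:.3f}\tb\t{fit.b:.5f}\t{fit.se_b:.5f}\t{fit.t_b:.3f}\t{fit.p_b:.3g}\t",
    ]
    return "\n".join(lines) + "\n"
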