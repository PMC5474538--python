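"""Publication-bias diagnostics: Egger regression, Begg rank correlation, funnel data.

Small-study (publication) bias makes a funnel plot of effects against their
standard errors asymmetric.  Two classical tests are implemented:

* **Egger's regression** — ordinary least squares of the standardized effect
  ``z_i = logOR_i / se_i`` on the precision ``1 / se_i``.  Under no bias the
  intercept is zero; it is tested with a two-sided t-test on k - 2 df.
* **Begg-Mazumdar rank correlation** — Kendall's tau between the
  standardized deviations ``(logOR_i - logOR_FE) / sqrt(se_i**2 - se_FE**2)``
  and the variances ``se_i**2``, with the tie-corrected normal approximation
  and an optional continuity correction (on by default, appropriate for the
  small k typical of meta-analyses).

Both tests are descriptive screens with low power at small k; they are
reported alongside funnel-plot coordinates, never as proof of bias.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .effects import EffectEstimate, critical_value
from .pooling import PooledEffect, fixed_effect_pool

__all__ = ["BiasTestResult", "FunnelPoint", "egger_test", "begg_test", "funnel_data"]

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass(frozen=True)
class BiasTestResult:
    test: str  # "egger" | "begg"
    statistic: float  # Egger: intercept; Begg: Kendall tau-b
    p: float
    k: int
    detail: dict


@dataclass(frozen=True)
class FunnelPoint:
    x: float  # logOR
    y: float  # se of logOR
    label: str


def egger_test(effects: Sequence[EffectEstimate]) -> BiasTestResult:
    """Egger's linear regression test for funnel-plot asymmetry.

    Requires k >= 3 (two regression parameters) and non-identical
    precisions (otherwise the regressor is degenerate).
    """
    k = len(effects)
    if k < 3:
        raise ValueError("insufficient studies: Egger's test needs k >= 3")
    se = np.array([e.se_log_or for e in effects], dtype=float)
    y = np.array([e.log_or for e in effects], dtype=float) / se
    x = 1.0 / se
    if np.ptp(x) < _EPS:
        raise ValueError("degenerate regressor: all precisions identical")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = fit.params
    se_int = fit.bse[0]
    df = k - 2
    if se_int < _EPS:
        # perfect fit (zero residual variance): no evidence against a zero
        # intercept unless the intercept itself is nonzero
        t = 0.0 if abs(intercept) < 1e-10 else math.inf
        p = 1.0 if abs(intercept) < 1e-10 else 0.0
    else:
        t = intercept / se_int
        p = float(2.0 * stats.t.sf(abs(t), df))
    return BiasTestResult(
        test="egger", statistic=float(intercept), p=p, k=k,
        detail={"intercept_se": float(se_int), "t": float(t), "df": df,
                "slope": float(slope)},
    )


def _kendall_s(u: np.ndarray, v: np.ndarray) -> tuple[int, int, int]:
    """Concordant/discordant pair counts and the score S = C - D."""
    c = d = 0
    n = len(u)
    for i in range(n):
        for j in range(i + 1, n):
            s = np.sign(u[j] - u[i]) * np.sign(v[j] - v[i])
            if s > 0:
                c += 1
            elif s < 0:
                d += 1
    return c, d, c - d


def _tie_sizes(x: np.ndarray) -> np.ndarray:
    _, counts = np.unique(x, return_counts=True)
    return counts[counts > 1]


def begg_test(effects: Sequence[EffectEstimate], continuity: bool = True) -> BiasTestResult:
    """Begg-Mazumdar rank-correlation test for funnel-plot asymmetry.

    A study whose variance does not exceed the pooled variance (possible in
    degenerate inputs) has its deviation standardized with a floored
    denominator and a logged warning.  Complete ties are reported as
    tau = 0, p = 1 (no evidence of asymmetry).
    """
    k = len(effects)
    if k < 2:
        raise ValueError("Begg's test needs k >= 2")
    fe = fixed_effect_pool(effects)
    y = np.array([e.log_or for e in effects], dtype=float)
    v = np.array([e.se_log_or for e in effects], dtype=float) ** 2
    var_dev = v - fe.se**2
    if np.any(var_dev <= _EPS):
        logger.warning("Begg test: %d studies with variance <= pooled variance; "
                       "denominator floored", int(np.sum(var_dev <= _EPS)))
        var_dev = np.maximum(var_dev, _EPS)
    dev = y - fe.log_or
    dev[np.abs(dev) < 1e-12 * max(1.0, abs(fe.log_or))] = 0.0  # exact ties, not float noise
    t_star = dev / np.sqrt(var_dev)

    c, d, s = _kendall_s(t_star, v)
    n0 = k * (k - 1) // 2
    tt = _tie_sizes(t_star)
    uu = _tie_sizes(v)
    tie_t = float(np.sum(tt * (tt - 1) // 2))
    tie_u = float(np.sum(uu * (uu - 1) // 2))
    denom = math.sqrt((n0 - tie_t) * (n0 - tie_u))
    tau = s / denom if denom > 0 else 0.0

    # tie-corrected variance of S (normal approximation)
    var_s = k * (k - 1) * (2 * k + 5) / 18.0
    var_s -= float(np.sum(tt * (tt - 1) * (2 * tt + 5))) / 18.0
    var_s -= float(np.sum(uu * (uu - 1) * (2 * uu + 5))) / 18.0
    if k > 2:
        var_s += (float(np.sum(tt * (tt - 1) * (tt - 2))) *
                  float(np.sum(uu * (uu - 1) * (uu - 2)))) / (9.0 * k * (k - 1) * (k - 2))
    var_s += (2.0 * tie_t * 2.0 * tie_u) / (2.0 * k * (k - 1))

    if var_s <= 0 or s == 0:
        z = 0.0
        p = 1.0
    else:
        num = abs(s) - 1 if continuity else abs(s)
        z = max(0.0, num) / math.sqrt(var_s)
        p = float(2.0 * stats.norm.sf(z))
    return BiasTestResult(
        test="begg", statistic=float(tau), p=min(1.0, p), k=k,
        detail={"concordant": c, "discordant": d, "score": s, "var_score": var_s,
                "z": z, "continuity": continuity},
    )


def funnel_data(effects: Sequence[EffectEstimate], pooled: PooledEffect,
                n_grid: int = 50, confidence_level: float = 0.95
                ) -> tuple[list[FunnelPoint], dict[str, np.ndarray]]:
    """Funnel-plot coordinates: one point per study plus pseudo-CI guide lines.

    Guides run from se = 0 (apex at the pooled effect) to the largest study
    se: ``pooled.log_or +/- z_crit * se``.
    """
    if not effects:
        raise ValueError("no effects")
    points = [FunnelPoint(x=e.log_or, y=e.se_log_or, label=e.label) for e in effects]
    zc = critical_value(confidence_level)
    se_grid = np.linspace(0.0, max(e.se_log_or for e in effects), n_grid)
    guides = {
        "se": se_grid,
        "center": np.full_like(se_grid, pooled.log_or),
        "lower": pooled.log_or - zc * se_grid,
        "upper": pooled.log_or + zc * se_grid,
    }
    return points, guides
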