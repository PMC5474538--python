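"""Fixed- and random-effects pooling with heterogeneity statistics.

The fixed-effect (common-effect) pooled log odds ratio is the
inverse-variance-weighted mean of the study logORs; the random-effects model
uses the DerSimonian-Laird moment estimator of the between-study variance
tau-squared and re-weights by ``1 / (se_i**2 + tau**2)``.  Heterogeneity is
quantified by Cochran's Q (chi-square with k - 1 df under homogeneity) and
Higgins' I-squared = max(0, (Q - df) / Q) * 100.

Model selection follows the conventional screening rule used in
genetic-association meta-analyses: the fixed-effect model is retained when
the Q test p-value is at least 0.1 and I-squared is at most 50%, otherwise
the random-effects model is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .effects import EffectEstimate, critical_value

__all__ = [
    "HeterogeneityStats",
    "PooledEffect",
    "heterogeneity",
    "fixed_effect_pool",
    "dersimonian_laird_pool",
    "pool",
    "select_model",
    "association_pvalue",
]

Model = Literal["fixed", "random"]


@dataclass(frozen=True)
class HeterogeneityStats:
    q: float
    df: int
    p_q: float
    i_squared: float  # percent, truncated at 0
    tau_squared: float


@dataclass(frozen=True)
class PooledEffect:
    """A pooled log odds ratio with its Wald confidence interval and test."""

    log_or: float
    se: float
    or_value: float
    ci_lower: float
    ci_upper: float
    z: float
    p: float
    method: Model
    k: int
    heterogeneity: HeterogeneityStats


def _weights(effects: Sequence[EffectEstimate]) -> tuple[np.ndarray, np.ndarray]:
    y = np.array([e.log_or for e in effects], dtype=float)
    w = np.array([e.weight for e in effects], dtype=float)
    return y, w


def heterogeneity(effects: Sequence[EffectEstimate]) -> HeterogeneityStats:
    """Cochran's Q, its p-value, I-squared and the DL tau-squared estimate.

    For a single effect the statistics are defined as their homogeneous
    limits (Q = 0, df = 0, p = 1, I² = 0, tau² = 0).
    """
    if not effects:
        raise ValueError("no effects to assess")
    if len(effects) == 1:
        return HeterogeneityStats(q=0.0, df=0, p_q=1.0, i_squared=0.0, tau_squared=0.0)
    y, w = _weights(effects)
    mean = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - mean) ** 2))
    df = len(effects) - 1
    p_q = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    return HeterogeneityStats(q=q, df=df, p_q=p_q, i_squared=i2, tau_squared=tau2)


def _build(log_or: float, se: float, method: Model, k: int, het: HeterogeneityStats,
           confidence_level: float, z_crit: float | None) -> PooledEffect:
    zc = critical_value(confidence_level) if z_crit is None else z_crit
    z = log_or / se
    return PooledEffect(
        log_or=log_or,
        se=se,
        or_value=math.exp(log_or),
        ci_lower=math.exp(log_or - zc * se),
        ci_upper=math.exp(log_or + zc * se),
        z=z,
        p=float(2.0 * stats.norm.sf(abs(z))),
        method=method,
        k=k,
        heterogeneity=het,
    )


def fixed_effect_pool(effects: Sequence[EffectEstimate], confidence_level: float = 0.95,
                      z_crit: float | None = None) -> PooledEffect:
    """Inverse-variance fixed-effect pool of log odds ratios."""
    if not effects:
        raise ValueError("no effects to pool")
    y, w = _weights(effects)
    log_or = float(np.sum(w * y) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    return _build(log_or, se, "fixed", len(effects), heterogeneity(effects),
                  confidence_level, z_crit)


def dersimonian_laird_pool(effects: Sequence[EffectEstimate], confidence_level: float = 0.95,
                           z_crit: float | None = None) -> PooledEffect:
    """DerSimonian-Laird random-effects pool.

    With tau² truncated at zero (Q <= df) the result coincides with the
    fixed-effect pool apart from its ``method`` tag.  The interval is the
    normal (Wald) interval, without a Knapp-Hartung adjustment.
    """
    if not effects:
        raise ValueError("no effects to pool")
    het = heterogeneity(effects)
    y, _ = _weights(effects)
    se_i = np.array([e.se_log_or for e in effects], dtype=float)
    w_star = 1.0 / (se_i**2 + het.tau_squared)
    log_or = float(np.sum(w_star * y) / np.sum(w_star))
    se = float(np.sum(w_star) ** -0.5)
    return _build(log_or, se, "random", len(effects), het, confidence_level, z_crit)


def select_model(het: HeterogeneityStats, p_threshold: float = 0.1,
                 i2_threshold: float = 50.0) -> Model:
    """Fixed-effect model iff Q-test p >= 0.1 and I² <= 50%, else random."""
    return "fixed" if het.p_q >= p_threshold and het.i_squared <= i2_threshold else "random"


def pool(effects: Sequence[EffectEstimate], model: Literal["auto", "fixed", "random"] = "auto",
         confidence_level: float = 0.95, z_crit: float | None = None) -> PooledEffect:
    """Pool effects under an explicit model or the heterogeneity-screening rule."""
    if model == "auto":
        model = select_model(heterogeneity(effects)) if effects else "fixed"
    if model == "fixed":
        return fixed_effect_pool(effects, confidence_level, z_crit)
    if model == "random":
        return dersimonian_laird_pool(effects, confidence_level, z_crit)
    raise ValueError(f"unknown model {model!r}")


def association_pvalue(pooled: PooledEffect) -> float:
    """Two-sided normal p-value of the pooled association (z = logOR / se)."""
    if not (math.isfinite(pooled.se) and pooled.se > 0):
        raise ValueError("pooled effect must have a finite positive se")
    return float(2.0 * stats.norm.sf(abs(pooled.log_or / pooled.se)))
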