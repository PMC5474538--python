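"""Stratified pooling and between-stratum effect comparison.

Subgroup analysis pools the studies of each stratum (here: ethnicity)
separately and asks whether two strata's pooled log odds ratios differ more
than their sampling error allows:

    z = (logOR_a - logOR_b) / sqrt(se_a**2 + se_b**2)

referred to the standard normal (two-sided).  For more than two strata a
between-subgroup Q statistic is also provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

from scipy import stats

from .effects import effects_from_table
from .pooling import PooledEffect, pool
from .studies import StudyTable

__all__ = [
    "SubgroupResult",
    "SubgroupComparison",
    "stratified_pool",
    "subgroup_difference_test",
    "between_subgroup_q",
]


@dataclass(frozen=True)
class SubgroupResult:
    stratum: str
    pool: PooledEffect
    n_records: int
    n_sample_sets: int


@dataclass(frozen=True)
class SubgroupComparison:
    stratum_a: str
    stratum_b: str
    z: float
    p: float


def stratified_pool(table: StudyTable, model: Literal["auto", "fixed", "random"] = "auto",
                    confidence_level: float = 0.95,
                    z_crit: float | None = None) -> list[SubgroupResult]:
    """One pooled result per distinct stratum, in order of first appearance.

    ``model="auto"`` applies the heterogeneity screening rule within each
    stratum.  A single-record stratum is legal and pools to itself.
    """
    results = []
    for stratum in table.strata:
        sub = table.restrict(stratum)
        effects = effects_from_table(sub, confidence_level, z_crit)
        results.append(
            SubgroupResult(
                stratum=stratum,
                pool=pool(effects, model, confidence_level, z_crit),
                n_records=len(sub),
                n_sample_sets=sum(r.n_sample_sets for r in sub.records),
            )
        )
    return results


def subgroup_difference_test(a: PooledEffect, b: PooledEffect,
                             stratum_a: str = "a", stratum_b: str = "b") -> SubgroupComparison:
    """Two-sided Z-test for a difference between two pooled log odds ratios."""
    for p_ in (a, b):
        if not (math.isfinite(p_.se) and p_.se > 0):
            raise ValueError("both pools must have finite positive se")
    z = (a.log_or - b.log_or) / math.hypot(a.se, b.se)
    return SubgroupComparison(stratum_a=stratum_a, stratum_b=stratum_b, z=z,
                              p=float(2.0 * stats.norm.sf(abs(z))))


def between_subgroup_q(subgroups: Sequence[SubgroupResult]) -> tuple[float, int, float]:
    """Between-subgroup heterogeneity Q over any number of strata.

    Q = sum_s w_s (logOR_s - logOR_.)², with w_s the inverse squared pooled
    standard errors and logOR_. their weighted mean; chi-square with
    (number of strata - 1) df.  For two strata Q equals z² of
    :func:`subgroup_difference_test`.
    """
    if len(subgroups) < 2:
        raise ValueError("need at least two subgroups")
    w = [1.0 / s.pool.se**2 for s in subgroups]
    y = [s.pool.log_or for s in subgroups]
    mean = sum(wi * yi for wi, yi in zip(w, y)) / sum(w)
    q = sum(wi * (yi - mean) ** 2 for wi, yi in zip(w, y))
    df = len(subgroups) - 1
    return q, df, float(stats.chi2.sf(q, df))
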