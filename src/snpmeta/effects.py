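"""Log-scale effect estimates from published odds ratios and confidence limits.

Published association studies report an allelic odds ratio with a 95%
confidence interval.  Inverse-variance meta-analysis works on the natural-log
scale, so each study is converted to ``logOR`` with a standard error
back-transformed from the interval width:

    se(logOR) = [ln(UL) - ln(LL)] / (2 * z_crit)

where ``z_crit`` is the two-sided standard-normal critical value of the
interval's confidence level (1.959964 at 95%).  The inverse-variance weight
is ``w = 1 / se**2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .studies import StudyRecord, StudyTable

__all__ = ["EffectEstimate", "se_from_ci", "effect_from_record", "effects_from_table", "critical_value"]


def critical_value(confidence_level: float = 0.95) -> float:
    """Two-sided standard-normal critical value for a confidence level."""
    if not 0.0 < confidence_level < 1.0:
        raise ValueError("confidence_level must lie in (0, 1)")
    return float(stats.norm.ppf(0.5 + confidence_level / 2.0))


@dataclass(frozen=True)
class EffectEstimate:
    """A study's effect on the log-odds-ratio scale.

    ``weight`` is the inverse variance ``1 / se_log_or**2`` and is validated
    against ``se_log_or`` on construction.
    """

    log_or: float
    se_log_or: float
    weight: float
    label: str = ""
    stratum: str = ""

    def __post_init__(self) -> None:
        if self.se_log_or <= 0:
            raise ValueError("se_log_or must be positive")
        if not math.isclose(self.weight, 1.0 / self.se_log_or**2, rel_tol=1e-12):
            raise ValueError("weight must equal 1/se_log_or**2")

    @classmethod
    def from_log_or_se(cls, log_or: float, se: float, label: str = "", stratum: str = "") -> "EffectEstimate":
        return cls(log_or=log_or, se_log_or=se, weight=1.0 / se**2, label=label, stratum=stratum)


def se_from_ci(ci_lower: float, ci_upper: float, confidence_level: float = 0.95,
               z_crit: float | None = None) -> float:
    """Standard error of logOR back-transformed from a confidence interval.

    ``z_crit`` overrides the exact normal quantile (pass 1.96 to reproduce
    analyses that used the rounded constant; the difference is below
    reporting precision).
    """
    if ci_lower <= 0 or ci_upper <= 0:
        raise ValueError("confidence limits must be positive")
    if ci_lower >= ci_upper:
        raise ValueError("degenerate interval: ci_lower must be < ci_upper")
    z = critical_value(confidence_level) if z_crit is None else z_crit
    return (math.log(ci_upper) - math.log(ci_lower)) / (2.0 * z)


def effect_from_record(record: StudyRecord, confidence_level: float = 0.95,
                       z_crit: float | None = None) -> EffectEstimate:
    """Convert a study record's published OR and CI to a log-scale effect."""
    se = se_from_ci(record.ci_lower, record.ci_upper, confidence_level, z_crit)
    return EffectEstimate.from_log_or_se(
        math.log(record.or_allelic), se, label=record.label, stratum=record.stratum
    )


def effects_from_table(table: StudyTable, confidence_level: float = 0.95,
                       z_crit: float | None = None) -> list[EffectEstimate]:
    """Effects for every record of a table, preserving row order.

    Labels are taken from :attr:`StudyTable.labels` so duplicated
    author/year rows stay distinguishable downstream.
    """
    effects = []
    for label, record in zip(table.labels, table.records):
        eff = effect_from_record(record, confidence_level, z_crit)
        effects.append(EffectEstimate.from_log_or_se(eff.log_or, eff.se_log_or,
                                                     label=label, stratum=record.stratum))
    return effects
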