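"""Pooled risk-allele frequency and population attributable risk.

The exposure frequency entering Levin's attributable-risk formula is the
risk-allele frequency among controls, pooled across studies as the mean
weighted by control sample size:

    pooled RAF = sum(RAF_i * n_i) / sum(n_i)

and the population attributable risk percentage uses the pooled allelic
odds ratio as the relative-risk approximation:

    PAR% = f / (f + 1) * 100,   f = RAF * (OR - 1)

Two computation modes exist.  ``full`` feeds the unrounded pooled RAF and
OR into the formula; ``table`` first rounds every input to two decimals
(the precision at which meta-analyses conventionally print these
quantities), which is the mode that matches published summary tables
computed from rounded intermediates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

from .pooling import PooledEffect
from .studies import StudyRecord

__all__ = ["PARResult", "pooled_raf", "par_percent", "par_result"]

logger = logging.getLogger(__name__)

ParMode = Literal["full", "table"]


@dataclass(frozen=True)
class PARResult:
    stratum: str
    n_controls_total: int
    pooled_raf: float
    pooled_or: float
    par_percent: float


def pooled_raf(records: Sequence[StudyRecord], raf_decimals: int | None = None) -> float:
    """Control-sample-size-weighted mean risk-allele frequency.

    ``raf_decimals`` rounds each study's frequency before weighting
    (table-mode uses 2; the default keeps frequencies as stored).
    """
    if not records:
        raise ValueError("no records")
    num = den = 0.0
    for r in records:
        raf = round(r.raf_controls, raf_decimals) if raf_decimals is not None else r.raf_controls
        num += raf * r.n_controls
        den += r.n_controls
    return num / den


def par_percent(pooled_raf_value: float, pooled_or: float) -> float:
    """Levin-type population attributable risk, in percent.

    Negative for a protective allele (OR < 1); returned as-is with a note.
    """
    if not 0.0 < pooled_raf_value < 1.0:
        raise ValueError("pooled RAF must lie in (0, 1)")
    if pooled_or <= 0:
        raise ValueError("pooled OR must be positive")
    f = pooled_raf_value * (pooled_or - 1.0)
    out = f / (f + 1.0) * 100.0
    if pooled_or < 1.0:
        logger.info("protective allele (OR < 1): PAR%% is negative (%.3f)", out)
    return out


def par_result(stratum: str, records: Sequence[StudyRecord], pooled: PooledEffect,
               mode: ParMode = "full") -> PARResult:
    """PAR summary for one stratum from its records and pooled effect."""
    if mode == "table":
        raf = round(pooled_raf(records, raf_decimals=2), 2)
        or_value = round(pooled.or_value, 2)
    elif mode == "full":
        raf = pooled_raf(records)
        or_value = pooled.or_value
    else:
        raise ValueError(f"unknown PAR mode {mode!r}")
    return PARResult(
        stratum=stratum,
        n_controls_total=sum(r.n_controls for r in records),
        pooled_raf=raf,
        pooled_or=or_value,
        par_percent=par_percent(raf, or_value),
    )
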