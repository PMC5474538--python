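"""Synthetic biallelic case-control studies with known truth.

The generator emulates the study design the meta-analysis pools: for each
study, risk-allele counts are drawn binomially at the chromosome level
(two alleles per diploid subject, Hardy-Weinberg equilibrium and allelic
independence assumed), with the case-group allele frequency implied by the
true allelic odds ratio:

    p_case = OR * q / (1 - q + OR * q),   q = control RAF

The realized 2x2 allele-count table yields the study's odds ratio and a
Woolf (log-scale) 95% confidence interval; when any cell is zero the
Haldane-Anscombe correction adds 0.5 to all four cells.  Records store the
realized control allele frequency, mimicking how real studies report
observed frequencies, and flow through the identical pipeline entry points
as published tables.

An optional selection rule suppresses non-significant studies to create
publication bias on demand for power experiments on the bias tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .effects import critical_value
from .studies import StudyRecord, StudyTable

__all__ = ["SelectionRule", "SimulationConfig", "SimulatedStudySet",
           "simulate_study", "simulate_study_set"]

_MAX_ATTEMPTS_PER_STUDY = 10_000


@dataclass(frozen=True)
class SelectionRule:
    """Suppress studies whose two-sided association p exceeds ``max_p``."""

    max_p: float = 0.05


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth and design of a simulated set of case-control studies.

    ``case_control_jitter`` is the half-width of a log-uniform multiplier on
    each study's sample sizes (0 keeps all studies at the nominal size).
    ``tau`` is the between-study standard deviation of the true log odds
    ratio: each study's own true OR is drawn log-normally around
    ``true_or`` (0 means a common true effect).
    """

    true_or: float
    raf_controls: float
    n_cases: int
    n_controls: int
    k_studies: int = 1
    case_control_jitter: float = 0.0
    tau: float = 0.0
    selection_bias: SelectionRule | None = None
    seed: int = 0
    stratum: str = "Simulated"

    def __post_init__(self) -> None:
        if self.true_or <= 0:
            raise ValueError("true_or must be positive")
        if not 0.0 < self.raf_controls < 1.0:
            raise ValueError("raf_controls must lie in (0, 1)")
        if min(self.n_cases, self.n_controls, self.k_studies) < 1:
            raise ValueError("n_cases, n_controls and k_studies must be >= 1")
        if self.case_control_jitter < 0:
            raise ValueError("case_control_jitter must be >= 0")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        p = self.p_case
        if not 0.0 < p < 1.0:
            raise ValueError(f"implied case RAF {p} outside (0, 1)")

    @property
    def p_case(self) -> float:
        """Case-group risk-allele frequency implied by (true_or, raf_controls)."""
        q = self.raf_controls
        return self.true_or * q / (1.0 - q + self.true_or * q)


@dataclass(frozen=True)
class SimulatedStudySet:
    table: StudyTable
    truth: SimulationConfig
    allele_counts: tuple[np.ndarray, ...] = field(repr=False)  # 2x2 per study


def _or_ci_from_counts(counts: np.ndarray, z: float) -> tuple[float, float, float]:
    """Odds ratio and Woolf 95% CI from a 2x2 allele table.

    ``counts`` rows are (risk, non-risk) alleles; columns (cases, controls).
    Haldane-Anscombe: add 0.5 to every cell if any cell is zero.
    """
    c = counts.astype(float)
    if np.any(c == 0):
        c = c + 0.5
    a, b = c[0, 0], c[1, 0]
    cc, d = c[0, 1], c[1, 1]
    log_or = math.log(a * d / (b * cc))
    se = math.sqrt(1 / a + 1 / b + 1 / cc + 1 / d)
    return math.exp(log_or), math.exp(log_or - z * se), math.exp(log_or + z * se)


def simulate_study(config: SimulationConfig, rng: np.random.Generator,
                   index: int = 1) -> tuple[StudyRecord, np.ndarray]:
    """Draw one study: binomial allele counts, OR and Woolf CI, study record."""
    jitter = config.case_control_jitter
    if jitter > 0:
        n_cases = max(1, round(config.n_cases * math.exp(rng.uniform(-jitter, jitter))))
        n_controls = max(1, round(config.n_controls * math.exp(rng.uniform(-jitter, jitter))))
    else:
        n_cases, n_controls = config.n_cases, config.n_controls
    if config.tau > 0:
        q = config.raf_controls
        or_i = math.exp(rng.normal(math.log(config.true_or), config.tau))
        p_case = or_i * q / (1.0 - q + or_i * q)
    else:
        p_case = config.p_case
    case_risk = int(rng.binomial(2 * n_cases, p_case))
    ctrl_risk = int(rng.binomial(2 * n_controls, config.raf_controls))
    counts = np.array([[case_risk, ctrl_risk],
                       [2 * n_cases - case_risk, 2 * n_controls - ctrl_risk]])
    z = critical_value(0.95)
    or_value, lo, hi = _or_ci_from_counts(counts, z)
    # realized control frequency; corrected at the boundary so it stays in (0,1)
    if 0 < ctrl_risk < 2 * n_controls:
        raf = ctrl_risk / (2 * n_controls)
    else:
        raf = (ctrl_risk + 0.5) / (2 * n_controls + 1.0)
    record = StudyRecord(
        study_label=f"sim{index:03d}", year=2000 + index, design="simulated case-control",
        genotyping_method="simulation", n_cases=n_cases, n_controls=n_controls,
        raf_controls=raf, hwe_status="in_hwe", or_allelic=or_value,
        ci_lower=min(lo, or_value), ci_upper=max(hi, or_value),
        stratum=config.stratum, n_sample_sets=1,
    )
    return record, counts


def _study_pvalue(counts: np.ndarray) -> float:
    """Two-sided Wald p-value of the study's log odds ratio."""
    c = counts.astype(float)
    if np.any(c == 0):
        c = c + 0.5
    log_or = math.log(c[0, 0] * c[1, 1] / (c[1, 0] * c[0, 1]))
    se = math.sqrt(np.sum(1.0 / c))
    return float(2.0 * stats.norm.sf(abs(log_or / se)))


def simulate_study_set(config: SimulationConfig) -> SimulatedStudySet:
    """Draw ``k_studies`` independent studies, reproducible from ``config.seed``.

    With a selection rule, non-surviving draws are discarded and redrawn
    until ``k_studies`` remain; an error is raised if the acceptance
    probability appears to be below 1e-4.
    """
    rng = np.random.default_rng(config.seed)
    records: list[StudyRecord] = []
    tables: list[np.ndarray] = []
    attempts = 0
    while len(records) < config.k_studies:
        attempts += 1
        if attempts > _MAX_ATTEMPTS_PER_STUDY * config.k_studies:
            raise RuntimeError("selection rule too strict: acceptance probability < 1e-4")
        record, counts = simulate_study(config, rng, index=len(records) + 1)
        if config.selection_bias is not None and _study_pvalue(counts) > config.selection_bias.max_p:
            continue
        records.append(record)
        tables.append(counts)
    return SimulatedStudySet(
        table=StudyTable(tuple(records), source=f"simulated(seed={config.seed})"),
        truth=config,
        allele_counts=tuple(tables),
    )
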