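"""End-to-end analysis: pooling, subgroups, bias tests, attributable risk, reports.

`run_full_analysis` reproduces the complete synthesis from a study table in
the conventional order — heterogeneity assessment, model selection, overall
pooling, subgroup pooling and comparison, publication-bias testing, pooled
risk-allele frequency and PAR — and packages the result for serialization
(canonical JSON plus text and TSV renderings of the forest, funnel and PAR
tables).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Literal

import pandas as pd

from . import __version__
from .bias import BiasTestResult, begg_test, egger_test, funnel_data
from .effects import effects_from_table
from .par import PARResult, ParMode, par_result
from .pooling import PooledEffect, pool
from .studies import StudyTable, summarize_counts
from .subgroup import SubgroupComparison, SubgroupResult, stratified_pool, subgroup_difference_test

__all__ = ["AnalysisReport", "run_full_analysis", "forest_data", "report_to_dict",
           "write_report", "funnel_frame"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisReport:
    overall: PooledEffect
    subgroups: list[SubgroupResult]
    comparison: SubgroupComparison | None
    bias: list[BiasTestResult]
    par: list[PARResult]
    provenance: dict


def run_full_analysis(table: StudyTable,
                      model: Literal["auto", "fixed", "random"] = "auto",
                      confidence_level: float = 0.95,
                      z_crit: float | None = None,
                      par_mode: ParMode = "full",
                      begg_continuity: bool = True,
                      seed: int | None = None) -> AnalysisReport:
    """Run the full meta-analytic synthesis on a validated study table.

    Deterministic given the table and options.  Bias tests are skipped with
    a logged reason when too few studies are available (Egger needs k >= 3,
    Begg k >= 2); the subgroup comparison is produced only for exactly two
    strata.
    """
    effects = effects_from_table(table, confidence_level, z_crit)
    overall = pool(effects, model, confidence_level, z_crit)
    subgroups = stratified_pool(table, model, confidence_level, z_crit)

    comparison = None
    if len(subgroups) == 2:
        a, b = subgroups
        comparison = subgroup_difference_test(a.pool, b.pool, a.stratum, b.stratum)
    elif len(subgroups) > 2:
        logger.info("more than two strata: pairwise comparison left to subgroup module")

    bias: list[BiasTestResult] = []
    if len(effects) >= 3:
        bias.append(egger_test(effects))
    else:
        logger.info("skipping Egger test: k=%d < 3", len(effects))
    if len(effects) >= 2:
        bias.append(begg_test(effects, continuity=begg_continuity))
    else:
        logger.info("skipping Begg test: k=%d < 2", len(effects))

    par = [par_result(s.stratum, list(table.restrict(s.stratum).records), s.pool, par_mode)
           for s in subgroups]
    par.append(par_result("Overall", list(table.records), overall, par_mode))

    counts = summarize_counts(table)
    provenance = {
        "source": table.source,
        "package": f"snpmeta {__version__}",
        "n_studies": counts.n_studies,
        "n_sample_sets": counts.n_sample_sets,
        "n_cases": counts.n_cases,
        "n_controls": counts.n_controls,
        "model": model,
        "par_mode": par_mode,
        "confidence_level": confidence_level,
        "z_crit": z_crit,
        "seed": seed,
    }
    return AnalysisReport(overall=overall, subgroups=subgroups, comparison=comparison,
                          bias=bias, par=par, provenance=provenance)


def forest_data(table: StudyTable, report: AnalysisReport,
                confidence_level: float = 0.95, z_crit: float | None = None) -> pd.DataFrame:
    """Forest-plot rows: studies grouped by stratum, subgroup and overall diamonds.

    ``weight_pct`` is the study's inverse-variance weight as a percentage of
    its stratum block; ``weight_pct_overall`` is relative to all studies.
    Diamond rows carry the pooled OR/CI and 100% block weight.
    """
    effects = effects_from_table(table, confidence_level, z_crit)
    total_w = sum(e.weight for e in effects)
    rows = []
    for sub in report.subgroups:
        block = [e for e in effects if e.stratum == sub.stratum]
        block_w = sum(e.weight for e in block)
        for e in block:
            rec = table.records[[x.label for x in effects].index(e.label)]
            rows.append({
                "label": e.label, "stratum": e.stratum, "row_type": "study",
                "or": rec.or_allelic, "ci_lower": rec.ci_lower, "ci_upper": rec.ci_upper,
                "weight_pct": 100.0 * e.weight / block_w,
                "weight_pct_overall": 100.0 * e.weight / total_w,
            })
        rows.append({
            "label": f"{sub.stratum} subtotal", "stratum": sub.stratum, "row_type": "subgroup",
            "or": sub.pool.or_value, "ci_lower": sub.pool.ci_lower, "ci_upper": sub.pool.ci_upper,
            "weight_pct": 100.0, "weight_pct_overall": 100.0 * block_w / total_w,
        })
    rows.append({
        "label": "Overall", "stratum": "", "row_type": "overall",
        "or": report.overall.or_value, "ci_lower": report.overall.ci_lower,
        "ci_upper": report.overall.ci_upper,
        "weight_pct": 100.0, "weight_pct_overall": 100.0,
    })
    return pd.DataFrame(rows)


def funnel_frame(table: StudyTable, report: AnalysisReport,
                 confidence_level: float = 0.95, z_crit: float | None = None) -> pd.DataFrame:
    """Funnel-plot points as a tidy frame (label, log_or, se)."""
    effects = effects_from_table(table, confidence_level, z_crit)
    points, _ = funnel_data(effects, report.overall)
    return pd.DataFrame([{"label": p.label, "log_or": p.x, "se": p.y} for p in points])


def _round_sig(x: float, sig: int = 3) -> float:
    if x == 0:
        return 0.0
    from math import floor, log10
    return round(x, -int(floor(log10(abs(x)))) + sig - 1)


def _pool_dict(p: PooledEffect) -> dict:
    d = dataclasses.asdict(p)
    d["heterogeneity"] = dataclasses.asdict(p.heterogeneity)
    return d


def report_to_dict(report: AnalysisReport, deterministic: bool = False) -> dict:
    """JSON-ready dictionary; timestamps omitted under ``deterministic``."""
    out = {
        "provenance": dict(report.provenance),
        "overall": _pool_dict(report.overall),
        "subgroups": [{
            "stratum": s.stratum, "n_records": s.n_records,
            "n_sample_sets": s.n_sample_sets, "pool": _pool_dict(s.pool),
        } for s in report.subgroups],
        "comparison": dataclasses.asdict(report.comparison) if report.comparison else None,
        "bias": [dataclasses.asdict(b) for b in report.bias],
        "par": [dataclasses.asdict(p) for p in report.par],
    }
    if not deterministic:
        out["provenance"]["timestamp"] = datetime.now(timezone.utc).isoformat()
    return out


def _format_text(report: AnalysisReport) -> str:
    """Human-readable summary (ORs/CIs/RAF/PAR at 2 dp, p at 3 significant digits)."""
    lines = []
    prov = report.provenance
    lines.append(f"Meta-analysis of {prov['n_studies']} studies "
                 f"({prov['n_sample_sets']} sample sets, "
                 f"{prov['n_cases']} cases / {prov['n_controls']} controls)")
    def porow(name, p: PooledEffect):
        het = p.heterogeneity
        return (f"  {name:<12} OR {p.or_value:.2f} (95% CI {p.ci_lower:.2f}-{p.ci_upper:.2f}) "
                f"[{p.method}, k={p.k}]  p={_round_sig(p.p):.3g}  "
                f"I2={het.i_squared:.0f}% Q={het.q:.2f} (p={_round_sig(het.p_q):.3g})")
    lines.append(porow("Overall", report.overall))
    for s in report.subgroups:
        lines.append(porow(s.stratum, s.pool))
    if report.comparison:
        c = report.comparison
        lines.append(f"  {c.stratum_a} vs {c.stratum_b}: z={c.z:.2f}, p={_round_sig(c.p):.3g}")
    for b in report.bias:
        lines.append(f"  {b.test.capitalize()} test: statistic={b.statistic:.3f}, "
                     f"p={_round_sig(b.p):.3g} (k={b.k})")
    for p in report.par:
        lines.append(f"  PAR {p.stratum:<10} controls={p.n_controls_total}  "
                     f"RAF={p.pooled_raf:.2f}  OR={p.pooled_or:.2f}  PAR%={p.par_percent:.2f}")
    return "\n".join(lines) + "\n"


def write_report(report: AnalysisReport, table: StudyTable, out_dir: str | Path,
                 deterministic: bool = False) -> dict[str, Path]:
    """Write report.json, report.txt, forest.tsv, funnel.tsv and par.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["json"] = out / "report.json"
    paths["json"].write_text(json.dumps(report_to_dict(report, deterministic), indent=2) + "\n")
    paths["text"] = out / "report.txt"
    paths["text"].write_text(_format_text(report))
    paths["forest"] = out / "forest.tsv"
    forest_data(table, report).to_csv(paths["forest"], sep="\t", index=False)
    paths["funnel"] = out / "funnel.tsv"
    funnel_frame(table, report).to_csv(paths["funnel"], sep="\t", index=False)
    paths["par"] = out / "par.tsv"
    pd.DataFrame([dataclasses.asdict(p) for p in report.par]).to_csv(
        paths["par"], sep="\t", index=False)
    return paths
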