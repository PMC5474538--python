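"""Per-study input table: reading, validation, and the built-in study set.

A meta-analysis of published SNP association studies starts from a small
hand-built table with one row per case-control sample set: the study label,
sample sizes, the risk-allele frequency observed among controls, and the
published allelic odds ratio with its 95% confidence limits.  This module
defines the validated record type, CSV/TSV round-tripping, and the built-in
table of six bladder-cancer case-control studies of the rs798766 (TACC3)
C/T polymorphism (8194 cases, 50,165 controls, 16 independent sample sets;
the largest row aggregates 11 sets).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Literal

import pandas as pd

__all__ = [
    "StudyRecord",
    "StudyTable",
    "StudyTableError",
    "SchemaError",
    "COLUMNS",
    "read_study_table",
    "write_study_table",
    "builtin_fixture",
    "summarize_counts",
    "CountsSummary",
]

logger = logging.getLogger(__name__)

#: Canonical column order for study-table CSV/TSV files.
COLUMNS = [
    "study_label",
    "year",
    "design",
    "genotyping_method",
    "n_cases",
    "n_controls",
    "raf_controls",
    "hwe_status",
    "or_allelic",
    "ci_lower",
    "ci_upper",
    "stratum",
    "n_sample_sets",
]

HweStatus = Literal["in_hwe", "deviating", "unknown"]
_HWE_VALUES = {"in_hwe", "deviating", "unknown"}


class StudyTableError(ValueError):
    """Invalid study-table content (bad values, inverted CIs, empty table)."""


class SchemaError(StudyTableError):
    """Study-table file does not match the expected column schema."""


@dataclass(frozen=True)
class StudyRecord:
    """One published case-control sample set.

    ``raf_controls`` is the risk-allele frequency among control subjects
    (proportion of control chromosomes carrying the risk allele).
    ``or_allelic`` is the published allelic odds ratio with 95% confidence
    limits ``(ci_lower, ci_upper)``.  ``n_sample_sets`` is the number of
    independent case-control sets the row aggregates (1 unless the source
    publication pooled several sets into one reported estimate).
    ``hwe_status`` is carried as metadata only; no Hardy-Weinberg test is
    recomputed here.
    """

    study_label: str
    year: int
    design: str
    genotyping_method: str
    n_cases: int
    n_controls: int
    raf_controls: float
    hwe_status: HweStatus
    or_allelic: float
    ci_lower: float
    ci_upper: float
    stratum: str
    n_sample_sets: int = 1

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise StudyTableError(
                f"{self.study_label}: case/control counts must be >= 1 "
                f"(got {self.n_cases}/{self.n_controls})"
            )
        if not 0.0 < self.raf_controls < 1.0:
            raise StudyTableError(
                f"{self.study_label}: raf_controls must lie in (0, 1), "
                f"got {self.raf_controls}"
            )
        if self.hwe_status not in _HWE_VALUES:
            raise StudyTableError(
                f"{self.study_label}: hwe_status must be one of {sorted(_HWE_VALUES)}, "
                f"got {self.hwe_status!r}"
            )
        if not (0.0 < self.ci_lower <= self.or_allelic <= self.ci_upper):
            raise StudyTableError(
                f"{self.study_label}: require 0 < ci_lower <= or_allelic <= ci_upper, "
                f"got {self.ci_lower} / {self.or_allelic} / {self.ci_upper}"
            )
        if self.n_sample_sets < 1:
            raise StudyTableError(
                f"{self.study_label}: n_sample_sets must be >= 1, got {self.n_sample_sets}"
            )
        if not self.stratum:
            raise StudyTableError(f"{self.study_label}: stratum must be non-empty")

    @property
    def label(self) -> str:
        """Display label combining first author and publication year."""
        return f"{self.study_label} {self.year}"


@dataclass(frozen=True)
class StudyTable:
    """Ordered, validated collection of :class:`StudyRecord` rows."""

    records: tuple[StudyRecord, ...]
    source: str = "memory"

    def __post_init__(self) -> None:
        if not self.records:
            raise StudyTableError("empty study table")
        labels = [r.label for r in self.records]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            # Multi-set studies may legitimately be split over rows; keep the
            # rows but disambiguate display labels with an occurrence index.
            logger.warning("duplicate study labels (suffixing): %s", sorted(dupes))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[StudyRecord]:
        return iter(self.records)

    @property
    def labels(self) -> list[str]:
        """Unique display labels (duplicates suffixed with /2, /3, ...)."""
        seen: dict[str, int] = {}
        out = []
        for r in self.records:
            seen[r.label] = seen.get(r.label, 0) + 1
            out.append(r.label if seen[r.label] == 1 else f"{r.label}/{seen[r.label]}")
        return out

    @property
    def strata(self) -> list[str]:
        """Distinct strata in order of first appearance."""
        out: list[str] = []
        for r in self.records:
            if r.stratum not in out:
                out.append(r.stratum)
        return out

    def restrict(self, stratum: str) -> "StudyTable":
        """Sub-table of the records belonging to one stratum."""
        recs = tuple(r for r in self.records if r.stratum == stratum)
        if not recs:
            raise StudyTableError(f"no records in stratum {stratum!r}")
        return StudyTable(recs, source=f"{self.source}[{stratum}]")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records], columns=COLUMNS)


_NUMERIC = {
    "year": int,
    "n_cases": int,
    "n_controls": int,
    "n_sample_sets": int,
    "raf_controls": float,
    "or_allelic": float,
    "ci_lower": float,
    "ci_upper": float,
}


def read_study_table(path: str | Path, dialect: Literal["csv", "tsv"] | None = None) -> StudyTable:
    """Read and validate a study table from a CSV or TSV file.

    The header must contain the canonical columns (:data:`COLUMNS`); extra
    columns are ignored with a logged warning.  ``dialect`` defaults to the
    file extension (``.tsv`` -> tab, anything else -> comma).
    """
    path = Path(path)
    if dialect is None:
        dialect = "tsv" if path.suffix.lower() in {".tsv", ".tab"} else "csv"
    sep = "\t" if dialect == "tsv" else ","
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    extra = [c for c in frame.columns if c not in COLUMNS]
    if extra:
        logger.warning("ignoring unknown column(s): %s", ", ".join(extra))
    if len(frame) == 0:
        raise StudyTableError("empty study table")

    records = []
    for i, row in frame.iterrows():
        kwargs: dict = {}
        for col in COLUMNS:
            raw = row[col]
            caster = _NUMERIC.get(col)
            if caster is None:
                kwargs[col] = raw
                continue
            try:
                kwargs[col] = caster(raw)
            except (TypeError, ValueError) as exc:
                raise StudyTableError(
                    f"row {i}: non-numeric value {raw!r} in column {col!r}"
                ) from exc
        try:
            records.append(StudyRecord(**kwargs))
        except StudyTableError as exc:
            raise StudyTableError(f"row {i}: {exc}") from exc
    return StudyTable(tuple(records), source=str(path))


def write_study_table(table: StudyTable, path: str | Path, dialect: Literal["csv", "tsv"] | None = None) -> None:
    """Write a study table in the canonical CSV/TSV schema."""
    path = Path(path)
    if dialect is None:
        dialect = "tsv" if path.suffix.lower() in {".tsv", ".tab"} else "csv"
    table.to_dataframe().to_csv(path, sep="\t" if dialect == "tsv" else ",", index=False)


def builtin_fixture() -> StudyTable:
    """The built-in rs798766/bladder-cancer study table (six rows).

    Values are stored exactly as published (frequencies at 2-3 decimals, ORs
    and confidence limits at 2).  The Wu 2010 row is a synthesis of 11
    case-control sets of European ancestry; the remaining five rows are
    single East-Asian sample sets, giving 16 independent sets in total.
    """
    rows = [
        ("Wu", 2010, "synthesis of 11 case-control sets", "SNP array, PCR",
         4580, 45269, 0.19, 1.24, 1.17, 1.32, "Caucasian", 11),
        ("Figueroa", 2011, "case-control", "TaqMan",
         815, 1141, 0.118, 1.32, 1.09, 1.59, "Asian", 1),
        ("Ma", 2012, "case-control", "iPLEX",
         176, 959, 0.11, 1.64, 1.19, 2.27, "Asian", 1),
        ("Wang", 2013, "case-control", "TaqMan",
         1210, 1008, 0.11, 1.31, 1.09, 1.57, "Asian", 1),
        ("Wang", 2014, "case-control", "TaqMan",
         1050, 1404, 0.12, 1.24, 1.05, 1.46, "Asian", 1),
        ("Wang", 2015, "case-control", "TaqMan",
         363, 384, 0.11, 1.53, 1.13, 2.08, "Asian", 1),
    ]
    records = tuple(
        StudyRecord(
            study_label=label, year=year, design=design, genotyping_method=geno,
            n_cases=ncas, n_controls=nctl, raf_controls=raf, hwe_status="in_hwe",
            or_allelic=orv, ci_lower=lo, ci_upper=hi, stratum=stratum,
            n_sample_sets=nsets,
        )
        for (label, year, design, geno, ncas, nctl, raf, orv, lo, hi, stratum, nsets) in rows
    )
    return StudyTable(records, source="fixture")


@dataclass(frozen=True)
class CountsSummary:
    """Exact integer totals over a study table."""

    n_studies: int
    n_sample_sets: int
    n_cases: int
    n_controls: int
    per_stratum: dict[str, dict[str, int]] = field(default_factory=dict)


def summarize_counts(table: StudyTable) -> CountsSummary:
    """Total studies, sample sets, cases and controls, overall and per stratum."""
    per: dict[str, dict[str, int]] = {}
    for s in table.strata:
        recs = [r for r in table.records if r.stratum == s]
        per[s] = {
            "n_studies": len(recs),
            "n_sample_sets": sum(r.n_sample_sets for r in recs),
            "n_cases": sum(r.n_cases for r in recs),
            "n_controls": sum(r.n_controls for r in recs),
        }
    return CountsSummary(
        n_studies=len(table),
        n_sample_sets=sum(r.n_sample_sets for r in table.records),
        n_cases=sum(r.n_cases for r in table.records),
        n_controls=sum(r.n_controls for r in table.records),
        per_stratum=per,
    )
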