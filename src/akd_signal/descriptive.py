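"""Descriptive frequency tables over a case report set.

These operations recompute the standard pharmacovigilance summary tables
for a case series: preferred-term frequencies (main case-defining terms and
co-reported terms), ATC first-level class frequencies, top active
ingredients, demographics, seriousness criteria, and the fatal-outcome
subset broken down by class and ingredient.

Percentage convention: counts are reported against an explicit, stated
denominator and rounded half-away-from-zero to one decimal (or to the
nearest integer where integer display is requested).  Multi-membership
tables (a report can carry several ATC classes, terms or seriousness
criteria) legitimately sum to more than 100%; single-membership tables
(sex, age group) sum to 100 up to rounding.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

import pandas as pd

from .case_definition import CaseDefinition, is_case
from .report_model import DrugRole, ReportSet

__all__ = [
    "pct",
    "DenominatorKind",
    "FreqTable",
    "term_freq",
    "atc_freq",
    "ingredient_freq",
    "demographics",
    "seriousness_table",
    "fatal_breakdowns",
    "FatalSummary",
]


def pct(count: int, denom: int, decimals: int = 1) -> float:
    """Percentage of `count` in `denom`, rounded half-away-from-zero.

    >>> pct(155606, 435677)
    35.7
    >>> pct(435677, 33932051, decimals=3)
    1.284
    """
    if denom <= 0:
        raise ZeroDivisionError("percentage denominator must be positive")
    if not 0 <= count <= denom:
        raise ValueError(f"count {count} outside [0, {denom}]")
    q = Decimal(1).scaleb(-decimals)
    value = (Decimal(int(count)) * 100 / Decimal(int(denom))).quantize(
        q, rounding=ROUND_HALF_UP
    )
    return float(value)


class DenominatorKind(str, enum.Enum):
    ALL_CASES = "all_cases"
    FATAL_CASES = "fatal_cases"
    ALL_REPORTS = "all_reports"


@dataclass
class FreqTable:
    """Rows of (label, count, pct) against one stated denominator.

    Rows are sorted by count descending, ties broken lexicographically by
    label, and optionally truncated to the top `top_n`.
    """

    rows: list[tuple[str, int, float]]
    denominator: int
    denominator_kind: DenominatorKind

    @classmethod
    def from_counts(
        cls,
        counts: dict[str, int] | Counter,
        denominator: int,
        kind: DenominatorKind,
        top_n: int | None = None,
        decimals: int = 1,
    ) -> "FreqTable":
        if denominator < 0:
            raise ValueError("denominator must be nonnegative")
        if denominator == 0:
            # an empty case series yields an empty table, not a crash
            return cls([], 0, kind)
        ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if top_n is not None:
            ordered = ordered[:top_n]
        rows = [(label, n, pct(n, denominator, decimals)) for label, n in ordered]
        return cls(rows, denominator, kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["label", "count", "pct"])

    def __len__(self) -> int:
        return len(self.rows)


def _empty(kind: DenominatorKind) -> FreqTable:
    return FreqTable([], 0, kind)


def term_freq(
    cases: ReportSet, cd: CaseDefinition
) -> tuple[FreqTable, FreqTable]:
    """Frequencies of case-defining ("main") and co-reported terms.

    Both tables count whole reports; a report naming several terms counts
    toward each of them, so columns may sum past the denominator.
    """
    if len(cases) == 0:
        return _empty(DenominatorKind.ALL_CASES), _empty(DenominatorKind.ALL_CASES)
    main: Counter = Counter()
    other: Counter = Counter()
    for r in cases:
        for term in r.reactions:
            (main if term in cd.terms else other)[term] += 1
    denom = len(cases)
    return (
        FreqTable.from_counts(main, denom, DenominatorKind.ALL_CASES),
        FreqTable.from_counts(other, denom, DenominatorKind.ALL_CASES),
    )


def _role_ok(entry, role: DrugRole | None) -> bool:
    return role is None or entry.role == role


def atc_freq(
    rs: ReportSet,
    role_filter: DrugRole | None = DrugRole.SUSPECTED,
    kind: DenominatorKind = DenominatorKind.ALL_CASES,
    decimals: int = 1,
) -> FreqTable:
    """Report counts per ATC first-level letter.

    A report counts once per *distinct* letter among its role-filtered
    drugs; reports spanning several classes contribute to each, so
    percentages may sum to more than 100.
    """
    if len(rs) == 0:
        return _empty(kind)
    counts: Counter = Counter()
    for r in rs:
        letters: set[str] = set()
        for e in r.drugs:
            if _role_ok(e, role_filter):
                letters |= e.atc_letters
        for letter in letters:
            counts[letter] += 1
    return FreqTable.from_counts(counts, len(rs), kind, decimals=decimals)


def ingredient_freq(
    rs: ReportSet,
    top_n: int | None = None,
    role_filter: DrugRole | None = DrugRole.SUSPECTED,
    kind: DenominatorKind = DenominatorKind.ALL_CASES,
) -> FreqTable:
    """Report counts per active ingredient (report-level, role-filtered)."""
    if len(rs) == 0:
        return _empty(kind)
    counts: Counter = Counter()
    for r in rs:
        for ing in {e.ingredient for e in r.drugs if _role_ok(e, role_filter)}:
            counts[ing] += 1
    return FreqTable.from_counts(counts, len(rs), kind, top_n=top_n)


def demographics(rs: ReportSet) -> tuple[FreqTable, FreqTable]:
    """Sex and age-group distributions (single membership, sum to ~100%)."""
    if len(rs) == 0:
        return _empty(DenominatorKind.ALL_CASES), _empty(DenominatorKind.ALL_CASES)
    sex = Counter(r.sex.value for r in rs)
    age = Counter(r.age_group.value for r in rs)
    denom = len(rs)
    return (
        FreqTable.from_counts(sex, denom, DenominatorKind.ALL_CASES),
        FreqTable.from_counts(age, denom, DenominatorKind.ALL_CASES),
    )


def seriousness_table(rs: ReportSet) -> tuple[FreqTable, int, float]:
    """Per-criterion counts plus the serious share.

    Returns ``(table, n_serious, serious_pct)`` where a report is serious
    when it carries at least one criterion; multi-criteria reports count
    once per criterion in the table but once in the serious share.
    """
    if len(rs) == 0:
        return _empty(DenominatorKind.ALL_CASES), 0, 0.0
    counts: Counter = Counter()
    n_serious = 0
    for r in rs:
        if r.seriousness:
            n_serious += 1
        for s in r.seriousness:
            counts[s.value] += 1
    denom = len(rs)
    table = FreqTable.from_counts(counts, denom, DenominatorKind.ALL_CASES)
    return table, n_serious, pct(n_serious, denom)


@dataclass
class FatalSummary:
    """Fatal-outcome share and breakdowns restricted to fatal reports."""

    n_fatal: int
    fatal_pct: float
    atc: FreqTable
    ingredients: FreqTable


def fatal_breakdowns(
    rs: ReportSet,
    top_n: int | None = 10,
    role_filter: DrugRole | None = DrugRole.SUSPECTED,
) -> FatalSummary:
    """Fatal share of the case series plus ATC/ingredient tables whose
    denominator is the fatal-report count."""
    if len(rs) == 0:
        return FatalSummary(0, 0.0, _empty(DenominatorKind.FATAL_CASES),
                            _empty(DenominatorKind.FATAL_CASES))
    fatal_records = [r for r in rs if r.fatal]
    fatal = ReportSet(fatal_records, provenance=f"{rs.provenance}|fatal",
                      deduplicated=rs.deduplicated)
    share = pct(len(fatal), len(rs))
    return FatalSummary(
        n_fatal=len(fatal),
        fatal_pct=share,
        atc=atc_freq(fatal, role_filter, kind=DenominatorKind.FATAL_CASES),
        ingredients=ingredient_freq(
            fatal, top_n=top_n, role_filter=role_filter,
            kind=DenominatorKind.FATAL_CASES,
        ),
    )
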