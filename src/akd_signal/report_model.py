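"""Notification data model and delimited-text I/O for spontaneous ADR reports.

A *notification* (individual case safety report) is the unit of analysis in
spontaneous-report pharmacovigilance: one anonymized report carrying one or
more suspected or concomitant drugs, one or more reaction terms coded with
MedDRA-like preferred terms, demographics, regulatory seriousness criteria,
and a fatal-outcome flag.

On disk a report set is a long-format delimited table with one row per
report x drug x reaction combination; report-level fields repeat across the
rows of a report and multi-valued cells (ATC letters, seriousness) use ";"
as an internal separator.  This representation is lossless and trivially
diffable, and it round-trips exactly through :func:`write_reports` /
:func:`read_reports`.
"""

from __future__ import annotations

import csv
import enum
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "Sex",
    "AgeGroup",
    "Seriousness",
    "DrugRole",
    "ATC_LETTERS",
    "DrugEntry",
    "NotificationRecord",
    "ReportSet",
    "SchemaError",
    "normalize_ingredient",
    "normalize_term",
    "read_reports",
    "write_reports",
    "deduplicate",
]

#: First-level (anatomical main group) letters of the WHO ATC classification.
ATC_LETTERS = frozenset("ABCDGHJLMNPRSV")


class SchemaError(ValueError):
    """A mandatory column is missing from an input table or mapping."""


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class AgeGroup(str, enum.Enum):
    """Ordered age bins as commonly used in VigiBase-style extracts."""

    A0_1 = "0-1"
    A2_11 = "2-11"
    A12_17 = "12-17"
    A18_44 = "18-44"
    A45_64 = "45-64"
    A65_74 = "65-74"
    A75_PLUS = "75+"
    UNKNOWN = "unknown"


class Seriousness(str, enum.Enum):
    """Regulatory seriousness criteria attached to a notification."""

    OTHER_MEDICALLY_IMPORTANT = "other_medically_important"
    HOSPITALIZATION = "hospitalization"
    DEATH = "death"
    LIFE_THREATENING = "life_threatening"
    DISABLING = "disabling"
    CONGENITAL_ANOMALY = "congenital_anomaly"


class DrugRole(str, enum.Enum):
    SUSPECTED = "suspected"
    CONCOMITANT = "concomitant"


_WS = re.compile(r"\s+")


def normalize_term(raw: str) -> str:
    """Normalize a preferred-term string: trim, lower-case, collapse whitespace."""
    return _WS.sub(" ", raw.strip()).lower()


def normalize_ingredient(raw: str) -> str:
    """Canonicalize an active-ingredient name.

    Single ingredients are trimmed, case-folded and whitespace-collapsed.
    Combination products (components joined with "+") are normalized
    component-wise, sorted lexicographically and re-joined with ``" + "`` so
    that a combination has exactly one canonical spelling regardless of the
    order in which its components were reported.

    Raises
    ------
    ValueError
        If the input is empty or whitespace-only (or any combination
        component is).
    """
    if not isinstance(raw, str) or not raw.strip():
        raise ValueError("ingredient name must be a nonempty string")
    parts = [normalize_term(p) for p in raw.split("+")]
    if any(not p for p in parts):
        raise ValueError(f"empty component in ingredient name: {raw!r}")
    return " + ".join(sorted(parts))


def _parse_atc(cell: object) -> frozenset[str]:
    """Parse an ATC-letter cell like ``"A;J"`` (or ``"AJ"``) to a letter set."""
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return frozenset()
    letters = frozenset(ch.upper() for ch in str(cell) if ch.isalpha())
    bad = letters - ATC_LETTERS
    if bad:
        raise ValueError(f"unknown ATC first-level letters: {sorted(bad)}")
    return letters


@dataclass(frozen=True)
class DrugEntry:
    """One drug on a notification, at active-ingredient granularity.

    Combination products are single analytic entities (e.g.
    ``"emtricitabine + tenofovir disoproxil"``), never decomposed into
    components.
    """

    ingredient: str
    atc_letters: frozenset[str] = frozenset()
    role: DrugRole = DrugRole.SUSPECTED

    def __post_init__(self) -> None:
        if not self.ingredient or not self.ingredient.strip():
            raise ValueError("DrugEntry.ingredient must be nonempty")
        object.__setattr__(self, "atc_letters", frozenset(self.atc_letters))
        bad = self.atc_letters - ATC_LETTERS
        if bad:
            raise ValueError(f"invalid ATC letters {sorted(bad)}")
        if not isinstance(self.role, DrugRole):
            object.__setattr__(self, "role", DrugRole(self.role))


@dataclass(frozen=True)
class NotificationRecord:
    """One deduplicated spontaneous report."""

    report_id: str
    drugs: tuple[DrugEntry, ...]
    reactions: frozenset[str]
    year: int | None = None
    sex: Sex = Sex.UNKNOWN
    age_group: AgeGroup = AgeGroup.UNKNOWN
    seriousness: frozenset[Seriousness] = frozenset()
    fatal: bool = False

    def __post_init__(self) -> None:
        if not self.report_id:
            raise ValueError("report_id must be nonempty")
        object.__setattr__(self, "drugs", tuple(self.drugs))
        if not self.drugs:
            raise ValueError(f"report {self.report_id}: needs at least one drug")
        object.__setattr__(
            self, "reactions", frozenset(normalize_term(t) for t in self.reactions)
        )
        if not self.reactions:
            raise ValueError(f"report {self.report_id}: needs at least one reaction")
        object.__setattr__(self, "seriousness", frozenset(self.seriousness))

    @property
    def serious(self) -> bool:
        """True if at least one regulatory seriousness criterion applies."""
        return bool(self.seriousness)

    def validate_fatal(self, strict: bool = False) -> None:
        """Check the fatal flag against seriousness.

        In strict mode ``fatal=True`` requires the report to be serious.  The
        lenient default reflects the fact that the fatal outcome and the
        "death" seriousness criterion are distinct fields in real extracts.
        """
        if strict and self.fatal and not self.serious:
            raise ValueError(
                f"report {self.report_id}: fatal outcome on a non-serious report"
            )

    def content_key(
        self, fields: Sequence[str] | None = None
    ) -> tuple:
        """Hashable key over the named fields (default: all but report_id)."""
        names = fields or (
            "year",
            "sex",
            "age_group",
            "drugs",
            "reactions",
            "seriousness",
            "fatal",
        )
        out = []
        for name in names:
            v = getattr(self, name)
            if isinstance(v, frozenset):
                v = tuple(sorted(v))
            out.append(v)
        return tuple(out)


@dataclass
class ReportSet:
    """An ordered collection of notifications with unique report ids."""

    records: list[NotificationRecord] = field(default_factory=list)
    provenance: str = ""
    deduplicated: bool = False

    def __post_init__(self) -> None:
        self.records = list(self.records)
        ids = [r.report_id for r in self.records]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate report_id in ReportSet: {dup!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[NotificationRecord]:
        return iter(self.records)

    @property
    def report_ids(self) -> list[str]:
        return [r.report_id for r in self.records]


# ---------------------------------------------------------------------------
# delimited-text I/O

#: canonical column names of the long format
CANONICAL_COLUMNS = (
    "report_id",
    "year",
    "sex",
    "age_group",
    "drug",
    "atc",
    "role",
    "reaction",
    "seriousness",
    "fatal",
)
_MANDATORY = ("report_id", "drug", "reaction")

_TRUTHY = {"1", "true", "yes", "y", "fatal", "death"}

_SERIOUSNESS_ALIASES = {
    "other medically important condition": Seriousness.OTHER_MEDICALLY_IMPORTANT,
    "caused/prolonged hospitalization": Seriousness.HOSPITALIZATION,
    "caused/prolonged hospitalisation": Seriousness.HOSPITALIZATION,
    "disabling/incapacitating": Seriousness.DISABLING,
    "congenital anomaly/birth defect": Seriousness.CONGENITAL_ANOMALY,
    "life threatening": Seriousness.LIFE_THREATENING,
}


def _parse_enum(cls, raw: object, default):
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return default
    token = normalize_term(str(raw))
    if not token:
        return default
    try:
        return cls(token)
    except ValueError:
        return default


def _parse_seriousness(cell: object) -> frozenset[Seriousness]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return frozenset()
    out = set()
    for tok in str(cell).split(";"):
        tok_n = normalize_term(tok)
        if not tok_n:
            continue
        try:
            out.add(Seriousness(tok_n.replace(" ", "_")))
        except ValueError:
            if tok_n in _SERIOUSNESS_ALIASES:
                out.add(_SERIOUSNESS_ALIASES[tok_n])
            else:
                raise ValueError(f"unknown seriousness criterion: {tok!r}")
    return frozenset(out)


def _parse_fatal(cell: object) -> bool:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return False
    return normalize_term(str(cell)) in _TRUTHY


def read_reports(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    sep: str | None = None,
    provenance: str | None = None,
) -> ReportSet:
    """Read a long-format delimited report table into a :class:`ReportSet`.

    Parameters
    ----------
    path
        Delimited text file (UTF-8, header row).  The delimiter is
        auto-detected unless `sep` is given.
    schema
        Optional mapping from canonical column names (:data:`CANONICAL_COLUMNS`)
        to the file's column names.  Unmapped canonical columns default to
        their own name; missing optional columns are tolerated.
    sep
        Explicit field delimiter (e.g. ``"\\t"`` or ``","``).

    Returns
    -------
    ReportSet
        One record per distinct report id, with drugs, reactions and
        seriousness aggregated across the id's rows and unknown enum tokens
        mapped to the ``unknown`` member.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    colmap = {c: c for c in CANONICAL_COLUMNS}
    if schema:
        colmap.update(schema)
    try:
        if sep is None:
            df = pd.read_csv(path, sep=None, engine="python", dtype=str)
        else:
            df = pd.read_csv(path, sep=sep, dtype=str)
    except (pd.errors.EmptyDataError, csv.Error):
        # a zero-byte file defeats both the parser and delimiter sniffing
        warnings.warn(f"{path}: empty report file", stacklevel=2)
        return ReportSet([], provenance=provenance or str(path))

    missing = [c for c in _MANDATORY if colmap[c] not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: mandatory column(s) not found: "
            + ", ".join(colmap[c] for c in missing)
        )
    if df.empty:
        warnings.warn(f"{path}: header-only report file", stacklevel=2)
        return ReportSet([], provenance=provenance or str(path))

    def col(name: str, row) -> object:
        c = colmap[name]
        return row.get(c) if c in df.columns else None

    records: list[NotificationRecord] = []
    for rid, group in df.groupby(colmap["report_id"], sort=False):
        first = group.iloc[0]
        year_raw = col("year", first)
        year = None
        if year_raw is not None and not pd.isna(year_raw) and str(year_raw).strip():
            year = int(float(year_raw))
        drugs: list[DrugEntry] = []
        seen_drugs: set[tuple] = set()
        reactions: set[str] = set()
        seriousness: set[Seriousness] = set()
        fatal = False
        for _, row in group.iterrows():
            entry = DrugEntry(
                ingredient=normalize_ingredient(str(row[colmap["drug"]])),
                atc_letters=_parse_atc(col("atc", row)),
                role=_parse_enum(DrugRole, col("role", row), DrugRole.SUSPECTED),
            )
            k = (entry.ingredient, entry.atc_letters, entry.role)
            if k not in seen_drugs:
                seen_drugs.add(k)
                drugs.append(entry)
            reactions.add(normalize_term(str(row[colmap["reaction"]])))
            seriousness |= _parse_seriousness(col("seriousness", row))
            fatal = fatal or _parse_fatal(col("fatal", row))
        records.append(
            NotificationRecord(
                report_id=str(rid),
                year=year,
                sex=_parse_enum(Sex, col("sex", first), Sex.UNKNOWN),
                age_group=_parse_enum(AgeGroup, col("age_group", first), AgeGroup.UNKNOWN),
                drugs=tuple(drugs),
                reactions=frozenset(reactions),
                seriousness=frozenset(seriousness),
                fatal=fatal,
            )
        )
    return ReportSet(records, provenance=provenance or str(path))


def to_frame(rs: ReportSet) -> pd.DataFrame:
    """Long-format DataFrame view (one row per report x drug x reaction)."""
    rows = []
    for r in rs:
        for d in r.drugs:
            for term in sorted(r.reactions):
                rows.append(
                    {
                        "report_id": r.report_id,
                        "year": "" if r.year is None else r.year,
                        "sex": r.sex.value,
                        "age_group": r.age_group.value,
                        "drug": d.ingredient,
                        "atc": ";".join(sorted(d.atc_letters)),
                        "role": d.role.value,
                        "reaction": term,
                        "seriousness": ";".join(sorted(s.value for s in r.seriousness)),
                        "fatal": str(r.fatal).lower(),
                    }
                )
    return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


def write_reports(rs: ReportSet, path: str | Path, sep: str = "\t") -> Path:
    """Write a :class:`ReportSet` as a long-format delimited table.

    The output is readable by :func:`read_reports` with identical logical
    content; an empty set produces a header-only file.
    """
    path = Path(path)
    to_frame(rs).to_csv(path, sep=sep, index=False)
    return path


def deduplicate(
    rs: ReportSet, key: Sequence[str] | None = None
) -> tuple[ReportSet, int]:
    """Drop duplicate notifications, keeping the first occurrence (stable).

    Parameters
    ----------
    key
        Field names that define equality.  The default is exact equality on
        every field except ``report_id`` — without probabilistic record
        linkage this is the only defensible rule, and the real criteria used
        by database curators are not public.

    Returns
    -------
    (deduplicated ReportSet, number of records removed)
    """
    if key is not None and len(key) == 0:
        raise ValueError("deduplication key must be nonempty")
    seen: set[tuple] = set()
    kept: list[NotificationRecord] = []
    for r in rs:
        k = r.content_key(key)
        if k not in seen:
            seen.add(k)
            kept.append(r)
    out = ReportSet(kept, provenance=rs.provenance, deduplicated=True)
    return out, len(rs) - len(out)
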