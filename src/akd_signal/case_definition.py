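"""Case definitions over MedDRA-like preferred terms.

A case definition is simply a named set of preferred terms; a notification
is a *case* when at least one of its reported reactions matches a term of
the definition (string equality after normalization — no dictionary
hierarchy or SMQ logic, which would require the licensed MedDRA files).

The default acute-kidney-disease (AKD) definition ships with the package:
the ten renal preferred terms that dominate AKD reporting (acute kidney
injury, renal failure, renal impairment, blood creatinine increased, renal
injury, blood urea increased, tubulointerstitial nephritis, glomerular
filtration rate decreased, oliguria, anuria).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

from .report_model import NotificationRecord, ReportSet, normalize_term

__all__ = ["CaseDefinition", "akd_definition", "is_case", "split_cases"]


@dataclass(frozen=True)
class CaseDefinition:
    """A named, normalized set of preferred terms defining a case phenotype."""

    name: str
    terms: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "terms", frozenset(normalize_term(t) for t in self.terms)
        )
        if not self.terms:
            raise ValueError("a case definition needs at least one term")

    @classmethod
    def from_terms(cls, name: str, terms: Iterable[str]) -> "CaseDefinition":
        return cls(name=name, terms=frozenset(terms))

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "CaseDefinition":
        """Load a definition from a plain-text file, one term per line.

        Blank lines and lines starting with ``#`` are ignored.
        """
        path = Path(path)
        terms = [
            line.strip()
            for line in path.read_text(encoding="utf-8").splitlines()
            if line.strip() and not line.lstrip().startswith("#")
        ]
        return cls.from_terms(name or path.stem, terms)


def akd_definition() -> CaseDefinition:
    """The packaged default AKD case definition (10 renal preferred terms)."""
    ref = resources.files("akd_signal.data").joinpath("akd_case_terms.txt")
    with resources.as_file(ref) as path:
        return CaseDefinition.from_file(path, name="AKD")


def is_case(record: NotificationRecord, cd: CaseDefinition) -> bool:
    """True iff the record reports at least one term of the definition."""
    return not record.reactions.isdisjoint(cd.terms)


def split_cases(rs: ReportSet, cd: CaseDefinition) -> tuple[ReportSet, ReportSet]:
    """Partition a report set into (cases, non-cases).

    The two outputs are disjoint, preserve input order, and their union is
    the input.
    """
    cases, noncases = [], []
    for r in rs:
        (cases if is_case(r, cd) else noncases).append(r)
    return (
        ReportSet(cases, provenance=f"{rs.provenance}|cases:{cd.name}",
                  deduplicated=rs.deduplicated),
        ReportSet(noncases, provenance=f"{rs.provenance}|noncases:{cd.name}",
                  deduplicated=rs.deduplicated),
    )
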