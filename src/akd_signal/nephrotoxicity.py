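"""Bibliographic nephrotoxicity score (BS) and its three-level class.

The BS quantifies how well a drug's nephrotoxic potential is documented in
the literature: five predetermined bibliographic sources (two drug-safety
databases, one reference website and two reference books) are each checked
for evidence of nephrotoxicity, and the score is the count of sources with
evidence, from 0 (no documented nephrotoxicity) to 5 (consistently
documented).  Drugs are then classed as

* ``non_nephrotoxic``          — BS 0
* ``potentially_nephrotoxic``  — BS 1-2
* ``nephrotoxic``              — BS >= 3 (established nephrotoxin)

The indicators are user-supplied booleans (or precomputed scores); the
package does not scrape the sources.  A reference table of scores for 24
ingredients strongly associated with acute kidney disease in world-scale
pharmacovigilance data ships with the package
(:func:`reference_scores`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .report_model import normalize_ingredient
from .descriptive import pct

__all__ = [
    "NephroClass",
    "BiblioEvidence",
    "BiblioScore",
    "score",
    "classify_score",
    "class_proportions",
    "load_scores",
    "reference_scores",
]

N_SOURCES = 5


class NephroClass(str, enum.Enum):
    NON_NEPHROTOXIC = "non_nephrotoxic"
    POTENTIALLY_NEPHROTOXIC = "potentially_nephrotoxic"
    NEPHROTOXIC = "nephrotoxic"


@dataclass(frozen=True)
class BiblioEvidence:
    """Per-source nephrotoxicity evidence indicators for one ingredient."""

    ingredient: str
    sources: tuple[bool, bool, bool, bool, bool]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sources", tuple(bool(s) for s in self.sources))
        if len(self.sources) != N_SOURCES:
            raise ValueError(f"exactly {N_SOURCES} evidence indicators required")


@dataclass(frozen=True)
class BiblioScore:
    ingredient: str
    score: int
    category: NephroClass

    def __post_init__(self) -> None:
        if not 0 <= self.score <= N_SOURCES:
            raise ValueError(f"score must be in 0..{N_SOURCES}, got {self.score}")
        if self.category != classify_score(self.score):
            raise ValueError(
                f"category {self.category} inconsistent with score {self.score}"
            )


def classify_score(s: int) -> NephroClass:
    """Map a 0-5 score to its nephrotoxicity class (0 / 1-2 / >=3)."""
    if not 0 <= int(s) <= N_SOURCES:
        raise ValueError(f"score must be in 0..{N_SOURCES}, got {s}")
    if s == 0:
        return NephroClass.NON_NEPHROTOXIC
    if s <= 2:
        return NephroClass.POTENTIALLY_NEPHROTOXIC
    return NephroClass.NEPHROTOXIC


def score(e: BiblioEvidence) -> BiblioScore:
    """Sum the five evidence indicators and classify."""
    s = sum(e.sources)
    return BiblioScore(ingredient=e.ingredient, score=s, category=classify_score(s))


def from_value(ingredient: str, value: int) -> BiblioScore:
    """Build a :class:`BiblioScore` from a precomputed 0-5 score."""
    return BiblioScore(ingredient=ingredient, score=int(value),
                       category=classify_score(int(value)))


def class_proportions(scores: Iterable[BiblioScore]) -> dict[NephroClass, float]:
    """Percentage of drugs per nephrotoxicity class, to one decimal.

    Percentages use round-half-away-from-zero and sum to 100 up to
    rounding.  Raises on empty input.
    """
    scores = list(scores)
    if not scores:
        raise ValueError("class_proportions requires at least one score")
    total = len(scores)
    return {
        cls: pct(sum(1 for s in scores if s.category == cls), total)
        for cls in NephroClass
    }


def load_scores(path: str | Path, sep: str = "\t") -> list[BiblioScore]:
    """Read scores from a delimited file.

    Accepts either an ``ingredient`` column plus five boolean indicator
    columns (``source1``..``source5``), or ``ingredient`` plus a precomputed
    ``score`` column.  Ingredients are normalized on load.
    """
    df = pd.read_csv(path, sep=sep)
    if "ingredient" not in df.columns:
        raise ValueError(f"{path}: missing 'ingredient' column")
    indicator_cols = [f"source{i}" for i in range(1, N_SOURCES + 1)]
    out: list[BiblioScore] = []
    if all(c in df.columns for c in indicator_cols):
        for _, row in df.iterrows():
            ev = BiblioEvidence(
                ingredient=normalize_ingredient(row["ingredient"]),
                sources=tuple(_as_bool(row[c]) for c in indicator_cols),
            )
            out.append(score(ev))
    elif "score" in df.columns:
        for _, row in df.iterrows():
            out.append(from_value(normalize_ingredient(row["ingredient"]),
                                  int(row["score"])))
    else:
        raise ValueError(
            f"{path}: need either columns {indicator_cols} or a 'score' column"
        )
    return out


def _as_bool(v: object) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in {"1", "true", "yes", "y"}
    return bool(v)


def reference_scores(with_metadata: bool = False):
    """The packaged reference BS table (24 AKD-associated ingredients).

    Returns a list of :class:`BiblioScore`; with ``with_metadata=True``
    returns the raw DataFrame as shipped (ATC class, report counts and
    published disproportionality estimates included for context).
    """
    ref = resources.files("akd_signal.data").joinpath(
        "reference_bibliographic_scores.tsv"
    )
    with resources.as_file(ref) as path:
        if with_metadata:
            return pd.read_csv(path, sep="\t")
        return load_scores(path)
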