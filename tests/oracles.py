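"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive — double loops over records and
direct transcriptions of the textbook formulas — and shares no code with
the package implementation it checks.
"""

from __future__ import annotations

import math
import random

from scipy import stats

from akd_signal.report_model import (
    AgeGroup,
    DrugEntry,
    DrugRole,
    NotificationRecord,
    ReportSet,
    Seriousness,
    Sex,
)

AKD_TERMS = [
    "acute kidney injury", "renal failure", "renal impairment",
    "blood creatinine increased", "renal injury", "blood urea increased",
    "tubulointerstitial nephritis", "glomerular filtration rate decreased",
    "oliguria", "anuria",
]
OTHER_TERMS = ["nausea", "diarrhoea", "headache", "rash", "pyrexia", "fatigue"]
DRUG_VOCAB = [
    ("omeprazole", "A"), ("vancomycin", "J"), ("furosemide", "C"),
    ("ibuprofen", "M"), ("tacrolimus", "L"), ("inotersen", "N"),
    ("tenofovir disoproxil", "J"), ("paracetamol", "N"),
]


def random_reportset(rng: random.Random, n: int, prefix: str = "R") -> ReportSet:
    """A messy but valid random ReportSet for oracle comparisons."""
    records = []
    for i in range(n):
        k_drugs = rng.randint(1, 3)
        drugs = tuple(
            DrugEntry(
                ingredient=name,
                atc_letters=frozenset(atc),
                role=rng.choice([DrugRole.SUSPECTED, DrugRole.SUSPECTED,
                                 DrugRole.CONCOMITANT]),
            )
            for name, atc in rng.sample(DRUG_VOCAB, k_drugs)
        )
        k_terms = rng.randint(1, 3)
        reactions = frozenset(rng.sample(AKD_TERMS + OTHER_TERMS, k_terms))
        seriousness = frozenset(
            s for s in Seriousness if rng.random() < 0.15
        )
        records.append(
            NotificationRecord(
                report_id=f"{prefix}{i:05d}",
                year=rng.choice([2018, 2019, 2020, None]),
                sex=rng.choice(list(Sex)),
                age_group=rng.choice(list(AgeGroup)),
                drugs=drugs,
                reactions=reactions,
                seriousness=seriousness,
                fatal=rng.random() < 0.12,
            )
        )
    return ReportSet(records, provenance="random-test-set")


# -- brute-force counting ----------------------------------------------------


def bf_is_case(record: NotificationRecord, terms: set[str]) -> bool:
    return any(t in terms for t in record.reactions)


def bf_table(rs: ReportSet, ingredient: str, terms: set[str], role) -> tuple:
    """Exhaustive double loop over (reports x {drug, event} predicates)."""
    a = b = c = d = 0
    for r in rs:
        has_drug = False
        for e in r.drugs:
            if e.ingredient == ingredient and (role is None or e.role == role):
                has_drug = True
        has_event = bf_is_case(r, terms)
        if has_drug and has_event:
            a += 1
        elif has_drug:
            b += 1
        elif has_event:
            c += 1
        else:
            d += 1
    return a, b, c, d


def bf_term_counts(cases: ReportSet) -> dict[str, int]:
    out: dict[str, int] = {}
    for r in cases:
        for t in r.reactions:
            out[t] = out.get(t, 0) + 1
    return out


def bf_atc_counts(rs: ReportSet, role) -> dict[str, int]:
    out: dict[str, int] = {}
    for r in rs:
        letters = set()
        for e in r.drugs:
            if role is None or e.role == role:
                letters |= e.atc_letters
        for letter in letters:
            out[letter] = out.get(letter, 0) + 1
    return out


def bf_ingredient_counts(rs: ReportSet, role) -> dict[str, int]:
    out: dict[str, int] = {}
    for r in rs:
        for ing in {e.ingredient for e in r.drugs if role is None or e.role == role}:
            out[ing] = out.get(ing, 0) + 1
    return out


def bf_seriousness_counts(rs: ReportSet) -> tuple[dict[str, int], int]:
    out: dict[str, int] = {}
    n_serious = 0
    for r in rs:
        if r.seriousness:
            n_serious += 1
        for s in r.seriousness:
            out[s.value] = out.get(s.value, 0) + 1
    return out, n_serious


# -- hand formulas -----------------------------------------------------------


def hand_ror(a, b, c, d, alpha=0.05):
    """Woolf logit CI, written out directly from the formulas."""
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    est = (a * d) / (b * c)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return est, math.exp(math.log(est) - half), math.exp(math.log(est) + half)


def hand_ic(a, b, c, d):
    n = a + b + c + d
    e = (a + b) * (a + c) / n
    ic = math.log2((a + 0.5) / (e + 0.5))
    ic025 = ic - 3.3 * (a + 0.5) ** -0.5 - 2.0 * (a + 0.5) ** -1.5
    return ic, ic025
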