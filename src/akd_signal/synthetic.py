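"""Synthetic spontaneous-report generator with planted drug-event signals.

Real pharmacovigilance databases are proprietary, so every downstream stage
of this package is exercised against generated report sets that mimic their
structure: multi-drug multi-reaction notifications, sex/age/year marginals,
seriousness criteria and fatal outcomes, and a configurable set of planted
drug-event associations against an independent background.

Generative model
----------------
For each report, every catalog drug is included independently with its
configured marginal probability, and every catalog term likewise; a report
is redrawn until it has at least one drug and at least one reaction, so
report sizes follow zero-truncated Poisson-binomial distributions implied
by the marginals.  A planted signal ``(drug D, event terms T, strength λ)``
multiplies the *odds* of including each term of T by λ on reports that
contain D.  This mechanism was chosen because its report-level 2x2 odds
ratio is analytically available: for a single-term signal the conditional
odds of the event given D are exactly λ times the baseline odds, and the
nonemptiness conditioning cancels from the ratio, so the true odds ratio
equals λ exactly.  :func:`true_tables` returns the implied cell
probabilities in closed form for use as simulation oracles.

Randomness is a single integer seed; independent substreams (drugs, terms,
demographics, outcomes) are split off it with ``numpy``'s ``SeedSequence``
spawning, so output is bit-reproducible for a fixed configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .report_model import (
    ATC_LETTERS,
    AgeGroup,
    DrugEntry,
    DrugRole,
    NotificationRecord,
    ReportSet,
    Seriousness,
    Sex,
    normalize_ingredient,
    normalize_term,
)

__all__ = [
    "DrugSpec",
    "TermSpec",
    "PlantedSignal",
    "SyntheticConfig",
    "TrueCellProbs",
    "generate",
    "true_tables",
    "conditional_drug_marginals",
    "conditional_term_marginals",
    "default_config",
]


@dataclass(frozen=True)
class DrugSpec:
    """One catalog drug: normalized ingredient, ATC letters, inclusion prob."""

    ingredient: str
    atc_letters: frozenset[str]
    prob: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "ingredient", normalize_ingredient(self.ingredient))
        object.__setattr__(self, "atc_letters", frozenset(self.atc_letters))
        if self.atc_letters - ATC_LETTERS:
            raise ValueError(f"invalid ATC letters for {self.ingredient}")
        if not 0.0 < self.prob < 1.0:
            raise ValueError(f"drug prob must be in (0,1), got {self.prob}")


@dataclass(frozen=True)
class TermSpec:
    """One catalog preferred term and its inclusion probability."""

    term: str
    prob: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "term", normalize_term(self.term))
        if not self.term:
            raise ValueError("term must be nonempty")
        if not 0.0 < self.prob < 1.0:
            raise ValueError(f"term prob must be in (0,1), got {self.prob}")


@dataclass(frozen=True)
class PlantedSignal:
    """A drug-event association to inject at odds multiplier ``strength``."""

    ingredient: str
    event_terms: tuple[str, ...]
    strength: float
    expect_detect: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "ingredient", normalize_ingredient(self.ingredient))
        object.__setattr__(
            self, "event_terms", tuple(normalize_term(t) for t in self.event_terms)
        )
        if not self.event_terms:
            raise ValueError("signal needs at least one event term")
        if self.strength < 1.0:
            raise ValueError(f"signal strength must be >= 1, got {self.strength}")


def _check_dist(name: str, probs: Mapping, tol: float = 1e-8) -> None:
    vals = list(probs.values())
    if any(p < 0 or p > 1 for p in vals):
        raise ValueError(f"{name}: probabilities must lie in [0,1]")
    if abs(sum(vals) - 1.0) > tol:
        raise ValueError(f"{name}: probabilities must sum to 1 (got {sum(vals)})")


@dataclass
class SyntheticConfig:
    """Full description of one synthetic study population."""

    n_reports: int
    drug_catalog: tuple[DrugSpec, ...]
    term_catalog: tuple[TermSpec, ...]
    signals: tuple[PlantedSignal, ...] = ()
    sex_probs: dict[Sex, float] = field(
        default_factory=lambda: {Sex.MALE: 0.495, Sex.FEMALE: 0.46, Sex.UNKNOWN: 0.045}
    )
    age_probs: dict[AgeGroup, float] = field(
        default_factory=lambda: {
            AgeGroup.A0_1: 0.02, AgeGroup.A2_11: 0.03, AgeGroup.A12_17: 0.03,
            AgeGroup.A18_44: 0.22, AgeGroup.A45_64: 0.26, AgeGroup.A65_74: 0.16,
            AgeGroup.A75_PLUS: 0.14, AgeGroup.UNKNOWN: 0.14,
        }
    )
    year_probs: dict[int, float] = field(
        default_factory=lambda: {
            2016: 0.10, 2017: 0.11, 2018: 0.13, 2019: 0.16, 2020: 0.15,
            2021: 0.18, 2022: 0.17,
        }
    )
    seriousness_probs: dict[Seriousness, float] = field(
        default_factory=lambda: {
            Seriousness.OTHER_MEDICALLY_IMPORTANT: 0.44,
            Seriousness.HOSPITALIZATION: 0.40,
            Seriousness.DEATH: 0.115,
            Seriousness.LIFE_THREATENING: 0.066,
            Seriousness.DISABLING: 0.026,
            Seriousness.CONGENITAL_ANOMALY: 0.001,
        }
    )
    fatal_prob: float = 0.137
    seed: int = 0

    def __post_init__(self) -> None:
        self.drug_catalog = tuple(self.drug_catalog)
        self.term_catalog = tuple(self.term_catalog)
        self.signals = tuple(self.signals)
        self.validate()

    def validate(self) -> None:
        if self.n_reports < 0:
            raise ValueError("n_reports must be nonnegative")
        if not self.drug_catalog or not self.term_catalog:
            raise ValueError("drug and term catalogs must be nonempty")
        if len({d.ingredient for d in self.drug_catalog}) != len(self.drug_catalog):
            raise ValueError("duplicate ingredient in drug catalog")
        if len({t.term for t in self.term_catalog}) != len(self.term_catalog):
            raise ValueError("duplicate term in term catalog")
        _check_dist("sex_probs", self.sex_probs)
        _check_dist("age_probs", self.age_probs)
        _check_dist("year_probs", self.year_probs)
        for crit, p in self.seriousness_probs.items():
            if not 0.0 <= p < 1.0:
                raise ValueError(f"seriousness prob for {crit} must be in [0,1)")
        if not 0.0 <= self.fatal_prob < 1.0:
            raise ValueError("fatal_prob must be in [0,1)")
        drug_names = {d.ingredient for d in self.drug_catalog}
        term_names = {t.term for t in self.term_catalog}
        for s in self.signals:
            if s.ingredient not in drug_names:
                raise ValueError(f"signal drug {s.ingredient!r} not in catalog")
            missing = set(s.event_terms) - term_names
            if missing:
                raise ValueError(f"signal terms not in catalog: {sorted(missing)}")

    # -- convenience serialization (generator configs are plain YAML) -------

    def to_yaml(self, path: str | Path) -> Path:
        doc = {
            "n_reports": self.n_reports,
            "seed": self.seed,
            "fatal_prob": self.fatal_prob,
            "drug_catalog": [
                {"ingredient": d.ingredient, "atc": sorted(d.atc_letters),
                 "prob": d.prob}
                for d in self.drug_catalog
            ],
            "term_catalog": [
                {"term": t.term, "prob": t.prob} for t in self.term_catalog
            ],
            "signals": [
                {"ingredient": s.ingredient, "event_terms": list(s.event_terms),
                 "strength": s.strength, "expect_detect": s.expect_detect}
                for s in self.signals
            ],
            "sex_probs": {k.value: v for k, v in self.sex_probs.items()},
            "age_probs": {k.value: v for k, v in self.age_probs.items()},
            "year_probs": dict(self.year_probs),
            "seriousness_probs": {k.value: v for k, v in self.seriousness_probs.items()},
        }
        path = Path(path)
        path.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        kwargs = dict(
            n_reports=int(doc["n_reports"]),
            seed=int(doc.get("seed", 0)),
            drug_catalog=tuple(
                DrugSpec(d["ingredient"], frozenset(d.get("atc", [])), float(d["prob"]))
                for d in doc["drug_catalog"]
            ),
            term_catalog=tuple(
                TermSpec(t["term"], float(t["prob"])) for t in doc["term_catalog"]
            ),
            signals=tuple(
                PlantedSignal(s["ingredient"], tuple(s["event_terms"]),
                              float(s["strength"]), bool(s.get("expect_detect", True)))
                for s in doc.get("signals", [])
            ),
        )
        if "fatal_prob" in doc:
            kwargs["fatal_prob"] = float(doc["fatal_prob"])
        if "sex_probs" in doc:
            kwargs["sex_probs"] = {Sex(k): float(v) for k, v in doc["sex_probs"].items()}
        if "age_probs" in doc:
            kwargs["age_probs"] = {
                AgeGroup(k): float(v) for k, v in doc["age_probs"].items()
            }
        if "year_probs" in doc:
            kwargs["year_probs"] = {int(k): float(v) for k, v in doc["year_probs"].items()}
        if "seriousness_probs" in doc:
            kwargs["seriousness_probs"] = {
                Seriousness(k): float(v) for k, v in doc["seriousness_probs"].items()
            }
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# generation


def _fill_nonempty(rng: np.random.Generator, probs_rows: np.ndarray) -> np.ndarray:
    """Draw a Bernoulli matrix row-wise, redrawing rows until each has >= 1
    inclusion.  `probs_rows` is (n, k) (may be a broadcast view)."""
    n, k = probs_rows.shape
    out = rng.random((n, k)) < probs_rows
    empty = ~out.any(axis=1)
    while empty.any():
        idx = np.flatnonzero(empty)
        out[idx] = rng.random((idx.size, k)) < probs_rows[idx]
        empty[idx] = ~out[idx].any(axis=1)
    return out


def _membership_matrices(
    cfg: SyntheticConfig,
    rng_drugs: np.random.Generator,
    rng_terms: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    n = cfg.n_reports
    p_drug = np.array([d.prob for d in cfg.drug_catalog])
    drug_m = _fill_nonempty(rng_drugs, np.broadcast_to(p_drug, (n, p_drug.size)))

    p_term = np.array([t.prob for t in cfg.term_catalog])
    term_probs = np.tile(p_term, (n, 1))
    drug_index = {d.ingredient: i for i, d in enumerate(cfg.drug_catalog)}
    term_index = {t.term: j for j, t in enumerate(cfg.term_catalog)}
    for sig in cfg.signals:
        rows = drug_m[:, drug_index[sig.ingredient]]
        for term in sig.event_terms:
            j = term_index[term]
            p = term_probs[rows, j]
            odds = sig.strength * p / (1.0 - p)
            term_probs[rows, j] = odds / (1.0 + odds)
    term_m = _fill_nonempty(rng_terms, term_probs)
    return drug_m, term_m


def generate(cfg: SyntheticConfig) -> ReportSet:
    """Draw a :class:`ReportSet` of exactly ``cfg.n_reports`` notifications.

    Bit-reproducible for a fixed config (including seed).
    """
    cfg.validate()
    provenance = f"synthetic(seed={cfg.seed}, n={cfg.n_reports})"
    if cfg.n_reports == 0:
        return ReportSet([], provenance=provenance, deduplicated=True)

    streams = np.random.SeedSequence(cfg.seed).spawn(4)
    rng_drugs = np.random.default_rng(streams[0])
    rng_terms = np.random.default_rng(streams[1])
    rng_demo = np.random.default_rng(streams[2])
    rng_outcome = np.random.default_rng(streams[3])

    drug_m, term_m = _membership_matrices(cfg, rng_drugs, rng_terms)
    n = cfg.n_reports

    entries = tuple(
        DrugEntry(d.ingredient, d.atc_letters, DrugRole.SUSPECTED)
        for d in cfg.drug_catalog
    )
    term_names = tuple(t.term for t in cfg.term_catalog)

    sex_items, sex_p = zip(*cfg.sex_probs.items())
    age_items, age_p = zip(*cfg.age_probs.items())
    year_items, year_p = zip(*cfg.year_probs.items())
    sex_idx = rng_demo.choice(len(sex_items), size=n, p=np.array(sex_p) / sum(sex_p))
    age_idx = rng_demo.choice(len(age_items), size=n, p=np.array(age_p) / sum(age_p))
    year_idx = rng_demo.choice(len(year_items), size=n, p=np.array(year_p) / sum(year_p))

    crit_items = tuple(cfg.seriousness_probs)
    crit_p = np.array([cfg.seriousness_probs[c] for c in crit_items])
    crit_m = rng_outcome.random((n, len(crit_items))) < crit_p
    fatal = rng_outcome.random(n) < cfg.fatal_prob

    def per_row(mask: np.ndarray) -> list[np.ndarray]:
        rows, cols = np.nonzero(mask)
        return np.split(cols, np.searchsorted(rows, np.arange(1, n)))

    drug_rows = per_row(drug_m)
    term_rows = per_row(term_m)
    crit_rows = per_row(crit_m)

    width = max(6, len(str(n - 1)))
    records = []
    for i in range(n):
        records.append(
            NotificationRecord(
                report_id=f"SYN-{i:0{width}d}",
                year=int(year_items[year_idx[i]]),
                sex=sex_items[sex_idx[i]],
                age_group=age_items[age_idx[i]],
                drugs=tuple(entries[j] for j in drug_rows[i]),
                reactions=frozenset(term_names[j] for j in term_rows[i]),
                seriousness=frozenset(crit_items[j] for j in crit_rows[i]),
                fatal=bool(fatal[i]),
            )
        )
    return ReportSet(records, provenance=provenance, deduplicated=True)


# ---------------------------------------------------------------------------
# closed-form oracles


@dataclass(frozen=True)
class TrueCellProbs:
    """Exact cell probabilities implied by the generative model for one
    signal (single-signal configurations; see module docstring)."""

    pa: float
    pb: float
    pc: float
    pd: float

    @property
    def odds_ratio(self) -> float:
        return (self.pa * self.pd) / (self.pb * self.pc)

    @property
    def p_drug(self) -> float:
        return self.pa + self.pb

    @property
    def p_event(self) -> float:
        return self.pa + self.pc


def _boosted(p: float, lam: float) -> float:
    odds = lam * p / (1.0 - p)
    return odds / (1.0 + odds)


def true_tables(cfg: SyntheticConfig) -> dict[str, TrueCellProbs]:
    """Closed-form 2x2 cell probabilities for each planted signal.

    The event is "any of the signal's terms present".  Probabilities are
    conditional on the nonemptiness constraints the generator enforces.
    Exact for single-signal configurations; with several signals the
    residual coupling through the at-least-one-term condition is ignored
    (other signals' drugs are taken as absent).
    """
    cfg.validate()
    p_drug_all = np.array([d.prob for d in cfg.drug_catalog])
    q_drugs = float(np.prod(1.0 - p_drug_all))
    drug_prob = {d.ingredient: d.prob for d in cfg.drug_catalog}
    term_prob = {t.term: t.prob for t in cfg.term_catalog}

    out: dict[str, TrueCellProbs] = {}
    for sig in cfg.signals:
        t_set = set(sig.event_terms)
        r = math.prod(1.0 - p for t, p in term_prob.items() if t not in t_set)
        a0 = math.prod(1.0 - term_prob[t] for t in t_set)
        a1 = math.prod(1.0 - _boosted(term_prob[t], sig.strength) for t in t_set)
        p_event_given_drug = (1.0 - a1) / (1.0 - a1 * r)
        p_event_no_drug = (1.0 - a0) / (1.0 - a0 * r)
        p_d = drug_prob[sig.ingredient] / (1.0 - q_drugs)
        pa = p_d * p_event_given_drug
        pb = p_d * (1.0 - p_event_given_drug)
        pc = (1.0 - p_d) * p_event_no_drug
        pd = (1.0 - p_d) * (1.0 - p_event_no_drug)
        out[sig.ingredient] = TrueCellProbs(pa, pb, pc, pd)
    return out


def conditional_drug_marginals(cfg: SyntheticConfig) -> dict[str, float]:
    """P(drug present | >= 1 drug on the report), in closed form."""
    p = np.array([d.prob for d in cfg.drug_catalog])
    q = float(np.prod(1.0 - p))
    return {d.ingredient: d.prob / (1.0 - q) for d in cfg.drug_catalog}


def conditional_term_marginals(cfg: SyntheticConfig) -> dict[str, float]:
    """P(term present | >= 1 term), exact for signal-free configurations."""
    if any(s.strength != 1.0 for s in cfg.signals):
        raise ValueError(
            "closed-form term marginals require a null configuration "
            "(no signals with strength > 1)"
        )
    p = np.array([t.prob for t in cfg.term_catalog])
    q = float(np.prod(1.0 - p))
    return {t.term: t.prob / (1.0 - q) for t in cfg.term_catalog}


# ---------------------------------------------------------------------------
# a realistic default population


_DEFAULT_DRUGS: tuple[tuple[str, str, float], ...] = (
    ("omeprazole", "A", 0.060),
    ("esomeprazole", "A", 0.055),
    ("lansoprazole", "A", 0.050),
    ("pantoprazole", "A", 0.045),
    ("emtricitabine + tenofovir disoproxil", "J", 0.030),
    ("tenofovir disoproxil", "J", 0.028),
    ("dexlansoprazole", "A", 0.025),
    ("vancomycin", "J", 0.022),
    ("covid-19 vaccine", "J", 0.022),
    ("furosemide", "C", 0.020),
    ("metformine", "A", 0.020),
    ("ibuprofen", "M", 0.030),
    ("paracetamol", "N", 0.040),
    ("amoxicillin", "J", 0.030),
    ("lisinopril", "C", 0.020),
    ("spironolactone", "C", 0.012),
    ("rivaroxaban", "B", 0.015),
    ("lenalidomide", "L", 0.014),
    ("methotrexate", "L", 0.015),
    ("tacrolimus", "L", 0.010),
    ("ciclosporine", "L", 0.008),
    ("acyclovir", "J", 0.009),
    ("colistin", "J", 0.004),
    ("inotersen", "N", 0.002),
    ("atorvastatin", "C", 0.035),
    ("sertraline", "N", 0.025),
)

_DEFAULT_TERMS: tuple[tuple[str, float], ...] = (
    # renal (case-defining) terms
    ("acute kidney injury", 0.055),
    ("renal failure", 0.040),
    ("renal impairment", 0.028),
    ("blood creatinine increased", 0.022),
    ("renal injury", 0.009),
    ("blood urea increased", 0.008),
    ("tubulointerstitial nephritis", 0.006),
    ("glomerular filtration rate decreased", 0.004),
    ("oliguria", 0.003),
    ("anuria", 0.003),
    # common co-reported / background terms
    ("chronic kidney disease", 0.015),
    ("diarrhoea", 0.050),
    ("hypotension", 0.030),
    ("nausea", 0.060),
    ("vomiting", 0.045),
    ("dehydration", 0.025),
    ("dyspnoea", 0.035),
    ("pyrexia", 0.035),
    ("fatigue", 0.045),
    ("pain", 0.040),
    ("headache", 0.050),
    ("rash", 0.040),
    ("dizziness", 0.040),
    ("pruritus", 0.025),
    ("insomnia", 0.020),
    ("arthralgia", 0.020),
    ("cough", 0.020),
    ("constipation", 0.020),
    ("anaemia", 0.015),
    ("hyperkalaemia", 0.010),
)


def default_config(
    n_reports: int = 20_000,
    seed: int = 0,
    signals: Sequence[PlantedSignal] = (),
) -> SyntheticConfig:
    """A VigiBase-flavoured default population.

    Roughly 1.5 drugs and 1.5 reaction terms per report; the ten renal
    case-defining terms carry ~17% of reports between them, so a case
    series of useful size exists at moderate ``n_reports``.  Demographics,
    seriousness and fatal-outcome rates follow the field's typical
    case-series profile.
    """
    return SyntheticConfig(
        n_reports=n_reports,
        seed=seed,
        drug_catalog=tuple(
            DrugSpec(name, frozenset(atc), p) for name, atc, p in _DEFAULT_DRUGS
        ),
        term_catalog=tuple(TermSpec(t, p) for t, p in _DEFAULT_TERMS),
        signals=tuple(signals),
    )


#: the (drug, term) pair used by the signal-recovery benchmark population
RECOVERY_DRUG = "inotersen"
RECOVERY_TERM = "glomerular filtration rate decreased"


def signal_recovery_config(
    strength: float,
    n_reports: int = 20_000,
    seed: int = 0,
    drug_marginal: float = 0.01,
    event_marginal: float = 0.02,
) -> SyntheticConfig:
    """Benchmark population for signal-recovery studies.

    The default population with one planted single-term signal
    (:data:`RECOVERY_DRUG` -> :data:`RECOVERY_TERM`) whose drug and event
    marginals are pinned to 1% and 2%; because the signal has a single
    event term, the true report-level odds ratio equals ``strength``
    exactly.  Estimation against it should use a case definition containing
    only :data:`RECOVERY_TERM`.
    """
    drugs = tuple(
        DrugSpec(d.ingredient, d.atc_letters,
                 drug_marginal if d.ingredient == RECOVERY_DRUG else d.prob)
        for d in default_config().drug_catalog
    )
    terms = tuple(
        TermSpec(t.term, event_marginal if t.term == RECOVERY_TERM else t.prob)
        for t in default_config().term_catalog
    )
    return SyntheticConfig(
        n_reports=n_reports,
        seed=seed,
        drug_catalog=drugs,
        term_catalog=terms,
        signals=(PlantedSignal(RECOVERY_DRUG, (RECOVERY_TERM,), strength),),
    )
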