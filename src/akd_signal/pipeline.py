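"""End-to-end run orchestration: ingest -> dedup -> case split ->
disproportionality -> bibliographic-score merge -> descriptive tables.

A run is described by a :class:`RunConfig` (loadable from YAML), executes
deterministically for fixed inputs, and leaves behind one TSV per output
table, a plain-text log with stage timings, and ``summary.json`` — a
machine-readable record of every count, denominator and decision flag
used.  The summary deliberately contains no wall-clock information so that
re-running an identical configuration reproduces it byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import descriptive, disproportionality, nephrotoxicity
from .case_definition import CaseDefinition, akd_definition, split_cases
from .report_model import ReportSet, deduplicate, read_reports

__all__ = ["RunConfig", "RunReport", "run"]

log = logging.getLogger("akd_signal")


@dataclass
class RunConfig:
    """Paths and analysis settings for one pipeline run."""

    reports: str
    out_dir: str
    case_definition: str | None = None  # None -> packaged AKD definition
    scores: str | None = None  # None -> packaged reference scores
    role_filter: str = "suspected"
    min_reports: int = 3
    continuity: bool = True
    ic_mode: str = "approx"
    top_n: int = 10
    seed: int = 0
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False), encoding="utf-8")
        return path


@dataclass
class RunReport:
    """What a run produced: file paths plus the in-memory summary."""

    out_dir: Path
    files: dict[str, Path]
    summary: dict[str, Any]


def _write_freq(table: descriptive.FreqTable, path: Path) -> Path:
    df = table.to_frame()
    df.to_csv(path, sep="\t", index=False)
    return path


def run(config: RunConfig) -> RunReport:
    """Execute the full pipeline described by `config`.

    Any stage failure raises with a stage-named message; outputs for a
    fixed configuration and inputs are deterministic.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    log_lines: list[str] = []
    files: dict[str, Path] = {}

    def stage(name: str):
        t0 = time.perf_counter()

        def done(msg: str) -> None:
            dt = time.perf_counter() - t0
            line = f"[{name}] {msg} ({dt:.2f}s)"
            log.info(line)
            log_lines.append(line)

        return done

    # -- ingest -------------------------------------------------------------
    done = stage("ingest")
    try:
        rs = read_reports(config.reports)
    except Exception as exc:  # re-raise with the stage name attached
        raise RuntimeError(f"ingest: {exc}") from exc
    done(f"read {len(rs)} notifications from {config.reports}")

    # -- deduplicate --------------------------------------------------------
    done = stage("dedup")
    rs, removed = deduplicate(rs)
    done(f"{removed} duplicates removed, {len(rs)} kept")

    # -- case definition & split -------------------------------------------
    done = stage("case_split")
    try:
        cd = (
            akd_definition()
            if config.case_definition is None
            else CaseDefinition.from_file(config.case_definition)
        )
        cases, noncases = split_cases(rs, cd)
    except Exception as exc:
        raise RuntimeError(f"case_split: {exc}") from exc
    done(f"definition {cd.name!r} ({len(cd.terms)} terms): "
         f"{len(cases)} cases / {len(noncases)} non-cases")

    # -- disproportionality -------------------------------------------------
    done = stage("disproportionality")
    try:
        results = disproportionality.run_all(
            rs, cd,
            min_reports=config.min_reports,
            role_filter=config.role_filter,
            continuity=config.continuity,
            ic_mode=config.ic_mode,
        )
    except Exception as exc:
        raise RuntimeError(f"disproportionality: {exc}") from exc
    flagged = disproportionality.screen(results)
    done(f"{len(results)} ingredients analysed, {len(flagged)} screened in")

    # -- bibliographic scores -----------------------------------------------
    done = stage("scores")
    try:
        scores = (
            nephrotoxicity.reference_scores()
            if config.scores is None
            else nephrotoxicity.load_scores(config.scores)
        )
    except Exception as exc:
        raise RuntimeError(f"scores: {exc}") from exc
    score_map = {s.ingredient: s for s in scores}
    matched = [score_map[r.ingredient] for r in results if r.ingredient in score_map]
    class_props = (
        {k.value: v for k, v in nephrotoxicity.class_proportions(matched).items()}
        if matched
        else {}
    )
    done(f"{len(scores)} scores loaded, {len(matched)} matched to analysed drugs")

    # -- signal table (disproportionality + BS merged) ----------------------
    done = stage("write_signals")
    rows = []
    for r in results:
        s = score_map.get(r.ingredient)
        rows.append(
            {
                "ingredient": r.ingredient,
                "atc": ";".join(sorted(r.atc_letters)),
                "n_reports": r.table.a,
                "expected": round(r.expected, 3),
                "ror": round(r.ror, 2),
                "ror_ci95_low": round(r.ror_ci95[0], 2),
                "ror_ci95_high": round(r.ror_ci95[1], 2),
                "ic": round(r.ic, 2),
                "ic025": round(r.ic025, 2),
                "bs": "" if s is None else s.score,
                "nephrotoxicity_class": "" if s is None else s.category.value,
                "screened_in": str(r.screened_in).lower(),
            }
        )
    sig_path = out_dir / "signals.tsv"
    pd.DataFrame(
        rows,
        columns=["ingredient", "atc", "n_reports", "expected", "ror",
                 "ror_ci95_low", "ror_ci95_high", "ic", "ic025", "bs",
                 "nephrotoxicity_class", "screened_in"],
    ).to_csv(sig_path, sep="\t", index=False)
    files["signals"] = sig_path
    done(f"wrote {sig_path}")

    # -- descriptive tables --------------------------------------------------
    done = stage("descriptive")
    main_t, conc_t = descriptive.term_freq(cases, cd)
    atc_t = descriptive.atc_freq(cases, role_filter=_role(config))
    ing_t = descriptive.ingredient_freq(cases, top_n=config.top_n,
                                        role_filter=_role(config))
    sex_t, age_t = descriptive.demographics(cases)
    ser_t, n_serious, serious_pct = descriptive.seriousness_table(cases)
    fatal = descriptive.fatal_breakdowns(cases, top_n=config.top_n,
                                         role_filter=_role(config))
    for name, tbl in [
        ("main_terms", main_t), ("concomitant_terms", conc_t),
        ("atc_classes", atc_t), ("top_ingredients", ing_t),
        ("sex", sex_t), ("age_groups", age_t), ("seriousness", ser_t),
        ("fatal_atc_classes", fatal.atc), ("fatal_top_ingredients", fatal.ingredients),
    ]:
        files[name] = _write_freq(tbl, out_dir / f"{name}.tsv")
    done(f"wrote {len(files) - 1} descriptive tables")

    # -- summary ------------------------------------------------------------
    summary = {
        "config": {
            "reports": str(config.reports),
            "case_definition": config.case_definition or "packaged:AKD",
            "scores": config.scores or "packaged:reference",
            "role_filter": config.role_filter,
            "min_reports": config.min_reports,
            "continuity": config.continuity,
            "ic_mode": config.ic_mode,
            "seed": config.seed,
        },
        "counts": {
            "n_input": len(rs) + removed,
            "n_duplicates_removed": removed,
            "n_reports": len(rs),
            "n_cases": len(cases),
            "n_noncases": len(noncases),
            "n_serious_cases": n_serious,
            "serious_pct": serious_pct,
            "n_fatal_cases": fatal.n_fatal,
            "fatal_pct": fatal.fatal_pct,
        },
        "denominators": {
            "all_cases": len(cases),
            "fatal_cases": fatal.n_fatal,
            "all_reports": len(rs),
        },
        "screen": {
            "n_analysed": len(results),
            "n_screened_in": len(flagged),
            "screened_ingredients": [r.ingredient for r in flagged],
        },
        "nephrotoxicity_class_pct": class_props,
    }
    sum_path = out_dir / "summary.json"
    sum_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n",
                        encoding="utf-8")
    files["summary"] = sum_path
    log_path = out_dir / "run.log"
    log_path.write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    files["log"] = log_path
    return RunReport(out_dir=out_dir, files=files, summary=summary)


def _role(config: RunConfig):
    from .disproportionality import _resolve_role

    return _resolve_role(config.role_filter)
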