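# Methods

## Data model

The unit of analysis is the notification (individual case safety report):
an opaque unique id, year of receipt, sex, an ordered age bin
(0–1, 2–11, 12–17, 18–44, 45–64, 65–74, 75+, unknown), one or more drug
entries (normalized active ingredient, first-level ATC letters, suspected
or concomitant role), one or more MedDRA-like preferred terms, a possibly
empty set of regulatory seriousness criteria, and a fatal-outcome flag.
The fatal flag and the "death" seriousness criterion are kept as distinct
fields — real case series show different counts for the two — and by
default a fatal flag is allowed on a non-serious report
(`validate_fatal(strict=True)` enforces the stricter rule).

Ingredient names are canonicalized by trimming, case-folding and
whitespace collapsing; combination products are split on `+`, normalized
component-wise, sorted and re-joined with `" + "`, so each combination is
a single analytic entity with one spelling. Combination products are never
decomposed into components: component-level attribution is a different
analysis with different assumptions.

On disk a report set is long-format delimited text, one row per
report × drug × reaction, aggregated by report id on read. Long format was
chosen over one-row-per-report because it is lossless for any number of
drugs and reactions without quoting tricks, and it round-trips exactly.
Deduplication keeps the first record of each equivalence class under exact
equality on all fields except the id. The duplicate-detection rules used
by database curators are not public, so the key is configurable; exact
content match is the only defensible default without record linkage.

## Disproportionality

For ingredient *D* and case definition *C*, cells count whole reports:
a = |D ∧ C|, b = |D ∧ ¬C|, c = |¬D ∧ C|, d = |¬D ∧ ¬C|, N = a+b+c+d.
The comparator is always the full supplied report set. Users of a
database-wide extract therefore get database-relative estimates; users who
can only supply the case series plus a sample get estimates relative to
that background. Published estimates computed against a full proprietary
database are not reproducible from a case-series extract alone.

* **ROR** = a·d/(b·c); 95% CI by the Woolf logit method,
  exp(ln ROR ± z₀.₉₇₅·√(1/a+1/b+1/c+1/d)). If any raw cell is zero and the
  continuity option is on (default), 0.5 is added to all four cells
  (Haldane–Anscombe); with continuity off, a zero cell raises.
* **IC** = log₂((a+0.5)/(E+0.5)), E = (a+b)(a+c)/N — the
  shrinkage-regularized observed/expected log-ratio used for first-pass
  screening. The default lower credibility bound is the closed form
  IC₀₂₅ = IC − 3.3(a+0.5)^−1/2 − 2(a+0.5)^−3/2.
  An alternative mode evaluates log₂ of the exact 2.5% quantile of
  Gamma(shape = a+0.5, rate = E+0.5). The two are *not* interchangeable:
  the closed form is wider because its constant absorbs uncertainty beyond
  the conditional-on-margins gamma posterior (leading terms 3.3/√a versus
  2.83/√a, a gap of ≈0.47/√a, i.e. ≈0.035 at a=5). The closed form is the
  default because it is the screen used in practice on the world database;
  the gamma mode is provided for sensitivity analyses and is always the
  less conservative of the two.
* **Screen**: flagged ⇔ IC₀₂₅ > 0 (strict) and ROR > 1. Results failing
  the gate are retained with `screened_in=false` — negative associations
  (e.g. a large, well-reported drug with IC₀₂₅ < 0) are themselves
  informative and must not silently disappear.
* `run_all` reports every ingredient with at least `min_reports` (default
  3) case co-reports, ranked by IC₀₂₅ descending, ties by ROR then name.
  The floor suppresses vacuous signals from 1–2 reports, where the IC
  shrinkage already dominates; it is configurable down to 1.
* The IC is crude (unstratified). Age/sex/year-stratified expected counts
  are a known refinement and are out of scope.

## Bibliographic score

Five predetermined sources (two drug-safety databases, one reference
website, two reference books) are each scored 0/1 for nephrotoxicity
evidence; the BS is their sum. Classes: 0 → non-nephrotoxic, 1–2 →
potentially nephrotoxic, ≥3 → nephrotoxic. Sources are equally weighted —
the score is a transparency device, not a meta-analysis. The packaged
reference table carries 24 AKD-associated ingredients with their scores
and, for context, their published report counts and disproportionality
estimates; those published estimates are metadata, not quantities this
package can recompute (see comparator note above).

## Descriptive tables

Every frequency table carries its denominator and denominator kind
(all cases, fatal cases, all reports) explicitly. Percentages are rounded
half-away-from-zero to one decimal (or to integers where integer display
is conventional). Multi-membership tables — terms, ATC classes,
seriousness criteria — may sum past 100% by construction; single-
membership tables (sex, age) sum to 100 within ±0.05 per row of rounding
drift. Fatal breakdowns use the fatal-outcome count as denominator, not
the "death" seriousness criterion, consistent with how fatal-subset tables
are conventionally reported.

## Synthetic report generator

The generator emulates the *structure* of a spontaneous-report database,
not its pharmacology:

* Every catalog drug enters a report independently with its configured
  marginal probability; likewise every catalog term. A report is redrawn
  until it has ≥1 drug and ≥1 term, so per-report counts follow
  zero-truncated Poisson–binomial distributions implied by the marginals
  (about 1.5 drugs and 1.5 terms per report at the defaults). An explicit
  count-then-sample mechanism was rejected because it destroys the
  analytic odds-ratio identity below.
* A planted signal (drug D, event terms T, strength λ ≥ 1) multiplies the
  inclusion *odds* of each term in T by λ on reports containing D. For a
  single-term signal the true report-level odds ratio of (D, term) is
  exactly λ: the nonemptiness conditioning contributes the same factor to
  the event odds with and without the drug, so it cancels.
  `true_tables` returns closed-form cell probabilities (exact for
  single-signal configurations; with several signals the residual
  coupling through the ≥1-term condition is ignored).
* Conditioning on nonemptiness inflates each empirical marginal from p to
  p/(1 − q), q being the probability of an all-empty draw;
  `conditional_drug_marginals` / `conditional_term_marginals` return these
  closed forms, and the law-of-large-numbers tests compare against them.
* Demographics, seriousness criteria (independent per-criterion
  Bernoulli), and the fatal flag are drawn independently of drugs and
  terms. Defaults follow a typical renal case series: male share ≈49.5%,
  45–64 the modal age bin, serious-criterion rates of roughly 44/40/11.5/
  6.6/2.6/0.1% and a 13.7% fatal rate.
* The default drug catalog (26 ingredients, inclusion probabilities
  0.002–0.06) and term catalog (10 renal + 20 background terms, the renal
  block carrying ≈17% of reports) give case series of useful size at
  n ≈ 20,000 without resembling any real co-prescription structure.
* One integer seed; independent substreams for drugs, terms, demographics
  and outcomes are split with `SeedSequence.spawn`, so output is
  bit-reproducible and insensitive to the order in which other streams
  are consumed.

What the generator does **not** emulate: co-prescription networks,
indication channeling, reporting-over-time trends beyond a year marginal,
term co-occurrence beyond shared marginals, and duplicate submission
processes (duplicates arise only by chance content collision). Passing
calibration tests on this background therefore demonstrates estimator
correctness under independence-plus-planted-signal, not robustness to
confounding by indication or to correlated reporting.

## Calibration and recovery studies

The statistical test suite runs, at fixed seeds:

* **Oracle equivalence** — on 100 random report sets (≤200 reports),
  tables and descriptive counts equal exhaustive brute-force scans
  exactly, and ROR/IC equal direct formula transcriptions to 1e−12
  relative.
* **Null calibration** — 200 replicates of the signal-free default
  population at n = 50,000: among drugs with expected count ≥5, the
  fraction with IC₀₂₅ > 0 must stay ≤5% (the gate is nominally a 2.5%
  one-sided test, so this budget is conservative).
* **Signal recovery** — the benchmark signal (drug marginal 1%, event
  marginal 2%, single event term) at λ=10, n = 20,000 must be screened in
  (IC₀₂₅ > 0 and ROR > 1) in ≥95 of 100 replicates; and at n = 50,000 the
  median estimated ROR over 30 replicates must fall within 10% of λ for
  λ ∈ {2, 5, 10}.
* **Determinism** — identical configurations produce byte-identical
  generator output and pipeline summaries. The machine-readable
  `summary.json` therefore contains no wall-clock information; stage
  timings go to the run log only.

## Known limitations

* Preferred-term matching is flat string equality after normalization; no
  MedDRA hierarchy, SMQ logic or versioning. Term-list granularity (e.g.
  "renal injury" vs "renal impairment") materially changes the case set.
* Crude (unstratified) disproportionality; no PRR, EBGM/MGPS, or
  time-to-onset methods.
* Exact-match deduplication cannot find near-duplicates (same case
  reported twice with differing detail).
* The comparator-population caveat above: estimates are relative to
  whatever background the user supplies.
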