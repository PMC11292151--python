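import math
import random

import pytest
from scipy import stats

from akd_signal.case_definition import CaseDefinition, akd_definition
from akd_signal.disproportionality import (
    ContingencyTable,
    build_table,
    ic,
    ror,
    run_all,
    screen,
)
from akd_signal.report_model import DrugEntry, DrugRole, NotificationRecord, ReportSet
from akd_signal.synthetic import signal_recovery_config, generate, RECOVERY_DRUG, RECOVERY_TERM
from oracles import AKD_TERMS, bf_table, hand_ic, hand_ror, random_reportset


def _rec(rid, drug, terms, role=DrugRole.SUSPECTED):
    return NotificationRecord(
        report_id=rid,
        drugs=(DrugEntry(drug, role=role),),
        reactions=frozenset(terms),
    )


class TestBuildTable:
    def test_four_reports_one_per_cell(self):
        rs = ReportSet(
            [
                _rec("a", "omeprazole", {"anuria"}),          # drug + event
                _rec("b", "omeprazole", {"nausea"}),          # drug only
                _rec("c", "ibuprofen", {"anuria"}),           # event only
                _rec("d", "ibuprofen", {"nausea"}),           # neither
            ]
        )
        t = build_table(rs, "omeprazole", akd_definition())
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_report_level_counting_drug_listed_twice(self):
        r = NotificationRecord(
            report_id="x",
            drugs=(DrugEntry("omeprazole"), DrugEntry("omeprazole", frozenset("A"))),
            reactions=frozenset({"anuria"}),
        )
        t = build_table(ReportSet([r]), "omeprazole", akd_definition())
        assert t.a == 1 and t.n == 1

    def test_role_filter_excludes_concomitant_by_default(self):
        rs = ReportSet([_rec("a", "omeprazole", {"anuria"}, role=DrugRole.CONCOMITANT)])
        t = build_table(rs, "omeprazole", akd_definition())
        assert t.a == 0 and t.c == 1
        t_any = build_table(rs, "omeprazole", akd_definition(), role_filter="any")
        assert t_any.a == 1

    def test_absent_ingredient_gives_empty_drug_margin(self):
        rs = ReportSet([_rec("a", "omeprazole", {"anuria"})])
        t = build_table(rs, "colistin", akd_definition())
        assert t.a == 0 and t.b == 0 and t.n == 1

    def test_matches_bruteforce_double_loop(self, rng):
        cd = akd_definition()
        for trial in range(20):
            rs = random_reportset(rng, 80, prefix=f"T{trial}-")
            for ingredient in ("omeprazole", "vancomycin", "inotersen"):
                t = build_table(rs, ingredient, cd)
                assert (t.a, t.b, t.c, t.d) == bf_table(
                    rs, ingredient, set(AKD_TERMS), DrugRole.SUSPECTED
                )


class TestRor:
    def test_symmetric_table_gives_unity(self):
        est = ror(ContingencyTable(10, 10, 10, 10))
        assert est.ror == pytest.approx(1.0)
        assert est.ci_low < 1.0 < est.ci_high

    def test_hand_computed_example(self):
        t = ContingencyTable(10, 90, 100, 9900)
        est = ror(t)
        assert est.ror == pytest.approx(11.0)
        # frozen from the Woolf formula: exp(ln 11 +/- 1.96 * sqrt(sum 1/cell))
        assert est.ci_low == pytest.approx(5.5594, abs=1e-3)
        assert est.ci_high == pytest.approx(21.7634, abs=1e-3)

    def test_zero_cell_requires_continuity(self):
        t = ContingencyTable(0, 10, 10, 100)
        with pytest.raises(ZeroDivisionError):
            ror(t, continuity=False)
        est = ror(t, continuity=True)  # Haldane-Anscombe on all four cells
        a, b, c, d = 0.5, 10.5, 10.5, 100.5
        assert est.ror == pytest.approx((a * d) / (b * c))

    def test_matches_statsmodels_woolf_interval(self):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        for cells in [(10, 90, 100, 9900), (40, 60, 160, 1740), (3, 7, 11, 179)]:
            t = ContingencyTable(*cells)
            est = ror(t)
            tab = sm.Table2x2([[t.a, t.b], [t.c, t.d]])
            assert est.ror == pytest.approx(tab.oddsratio, rel=1e-12)
            lo, hi = tab.oddsratio_confint(0.05)
            assert est.ci_low == pytest.approx(lo, rel=1e-9)
            assert est.ci_high == pytest.approx(hi, rel=1e-9)

    def test_ci_width_shrinks_with_scale(self):
        widths = []
        for k in (1, 2, 4, 8):
            est = ror(ContingencyTable(10 * k, 90 * k, 100 * k, 9900 * k))
            widths.append(math.log(est.ci_high) - math.log(est.ci_low))
        assert widths == sorted(widths, reverse=True)


class TestIc:
    def test_observed_equals_expected_gives_zero(self):
        # a=10 with margins making E exactly 10
        t = ContingencyTable(10, 90, 990, 8910)
        assert t.expected == pytest.approx(10.0)
        assert ic(t).ic == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # N=2000, n_drug=100, n_event=200, a=40 -> E=10
        t = ContingencyTable(40, 60, 160, 1740)
        assert t.expected == pytest.approx(10.0)
        est = ic(t)
        assert est.ic == pytest.approx(math.log2(40.5 / 10.5), rel=1e-12)
        assert est.ic == pytest.approx(1.9475, abs=1e-4)
        assert est.ic025 == pytest.approx(1.4212, abs=1e-4)

    def test_zero_observed_is_negative(self):
        t = ContingencyTable(0, 100, 500, 9400)
        assert ic(t).ic < 0

    def test_zero_margin_raises(self):
        with pytest.raises(ZeroDivisionError):
            ic(ContingencyTable(0, 0, 10, 90))

    def test_gamma_mode_is_tighter_and_converges_to_approximation(self):
        # the closed-form bound is deliberately wider than the gamma
        # quantile conditional on the margins (it absorbs expected-count
        # uncertainty); the gap decays like ~0.47/sqrt(a)
        for a in (5, 10, 50, 500, 5000):
            t = ContingencyTable(a, 1000, 2 * a, 200000)
            approx = ic(t, mode="approx").ic025
            exact = ic(t, mode="gamma").ic025
            assert approx <= exact <= ic(t).ic
            assert exact - approx < 0.7 / math.sqrt(a)

    def test_antisymmetric_in_observed_and_expected(self):
        # swapping the roles of observed and expected flips the sign
        t = ContingencyTable(40, 60, 160, 1740)  # a=40, E=10
        swapped = ContingencyTable(10, 90, 790, 1110)  # a=10, E=40
        assert swapped.expected == pytest.approx(40.0)
        assert ic(swapped).ic == pytest.approx(-ic(t).ic, rel=1e-12)

    def test_agrees_with_hand_formulas_on_random_tables(self, rng):
        for _ in range(200):
            a = rng.randint(1, 50)
            b = rng.randint(1, 200)
            c = rng.randint(1, 200)
            d = rng.randint(1, 5000)
            t = ContingencyTable(a, b, c, d)
            est_r, est_i = ror(t), ic(t)
            h_ror = hand_ror(a, b, c, d)
            h_ic = hand_ic(a, b, c, d)
            assert est_r.ror == pytest.approx(h_ror[0], rel=1e-12)
            assert est_r.ci_low == pytest.approx(h_ror[1], rel=1e-12)
            assert est_i.ic == pytest.approx(h_ic[0], rel=1e-12)
            assert est_i.ic025 == pytest.approx(h_ic[1], rel=1e-12)


class TestScreenAndRunAll:
    def test_strict_gate_boundary(self):
        rs = ReportSet(
            [_rec("a", "omeprazole", {"anuria"})]
            + [_rec(f"b{i}", "ibuprofen", {"nausea"}) for i in range(20)]
            + [_rec(f"c{i}", "ibuprofen", {"anuria"}) for i in range(4)]
        )
        results = run_all(rs, akd_definition(), min_reports=1)
        for r in results:
            assert r.screened_in == (r.ic025 > 0 and r.ror > 1)
        flagged = screen(results)
        assert all(r.ic025 > 0 and r.ror > 1 for r in flagged)
        # non-flagged results stay in the output, not hidden
        assert len(results) >= len(flagged)

    def test_single_drug_set_yields_one_result(self):
        rs = ReportSet(
            [_rec("a", "omeprazole", {"anuria"}),
             _rec("b", "omeprazole", {"anuria"}),
             _rec("c", "omeprazole", {"nausea"}),
             _rec("d", "omeprazole", {"anuria"})]
        )
        results = run_all(rs, akd_definition())
        assert [r.ingredient for r in results] == ["omeprazole"]

    def test_min_reports_floor(self, rng):
        rs = random_reportset(rng, 100)
        for r in run_all(rs, akd_definition(), min_reports=5):
            assert r.table.a >= 5

    def test_ranking_deterministic_and_ordered(self, rng):
        rs = random_reportset(rng, 150)
        res1 = run_all(rs, akd_definition(), min_reports=1)
        res2 = run_all(rs, akd_definition(), min_reports=1)
        assert [r.ingredient for r in res1] == [r.ingredient for r in res2]
        keys = [(-r.ic025, -r.ror, r.ingredient) for r in res1]
        assert keys == sorted(keys)

    def test_planted_signal_outranks_null_drugs(self):
        cfg = signal_recovery_config(strength=10.0, n_reports=20_000, seed=11)
        rs = generate(cfg)
        cd = CaseDefinition.from_terms("recovery", [RECOVERY_TERM])
        results = run_all(rs, cd)
        assert results[0].ingredient == RECOVERY_DRUG
        assert results[0].screened_in
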