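import random
import warnings

import pytest
from hypothesis import given, strategies as st

from akd_signal.report_model import (
    DrugEntry,
    DrugRole,
    NotificationRecord,
    ReportSet,
    SchemaError,
    Seriousness,
    deduplicate,
    normalize_ingredient,
    read_reports,
    write_reports,
)
from oracles import random_reportset


class TestNormalizeIngredient:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("  Omeprazole ", "omeprazole"),
            ("VANCOMYCIN", "vancomycin"),
            ("tenofovir   disoproxil", "tenofovir disoproxil"),
            # combinations get one canonical component order
            ("tenofovir disoproxil + emtricitabine",
             "emtricitabine + tenofovir disoproxil"),
            ("Emtricitabine+Tenofovir Disoproxil",
             "emtricitabine + tenofovir disoproxil"),
        ],
    )
    def test_canonical_form(self, raw, expected):
        assert normalize_ingredient(raw) == expected

    @pytest.mark.parametrize("bad", ["", "   ", "a + ", "+"])
    def test_rejects_empty(self, bad):
        with pytest.raises(ValueError):
            normalize_ingredient(bad)

    @given(st.text(alphabet="abc +XY ", min_size=1).filter(
        lambda s: all(p.strip() for p in s.split("+"))))
    def test_idempotent(self, raw):
        once = normalize_ingredient(raw)
        assert normalize_ingredient(once) == once

    def test_component_order_invariant(self):
        assert normalize_ingredient("b + a + c") == normalize_ingredient("c + a + b")


class TestReadWrite:
    def test_rows_aggregate_by_report_id(self, tmp_path):
        f = tmp_path / "r.csv"
        f.write_text(
            "report_id,drug,reaction\n"
            "1,omeprazole,Acute kidney injury\n"
            "1,furosemide,Oliguria\n"
            "2,vancomycin,Renal failure\n"
        )
        rs = read_reports(f)
        assert len(rs) == 2
        r1 = rs.records[0]
        assert {d.ingredient for d in r1.drugs} == {"omeprazole", "furosemide"}
        assert r1.reactions == {"acute kidney injury", "oliguria"}

    def test_single_record_fields_survive(self, tmp_path):
        f = tmp_path / "r.csv"
        f.write_text(
            "report_id,drug,reaction,sex,fatal\n"
            "7,tenofovir disoproxil,Acute kidney injury,male,true\n"
        )
        rs = read_reports(f)
        (r,) = rs.records
        assert r.drugs[0].ingredient == "tenofovir disoproxil"
        assert r.reactions == {"acute kidney injury"}
        assert r.sex.value == "male"
        assert r.fatal

    def test_missing_mandatory_column_raises(self, tmp_path):
        f = tmp_path / "r.csv"
        f.write_text("report_id,drug\n1,omeprazole\n")
        with pytest.raises(SchemaError):
            read_reports(f)

    def test_empty_file_warns_and_returns_empty(self, tmp_path):
        f = tmp_path / "empty.csv"
        f.write_text("")
        with pytest.warns(UserWarning):
            rs = read_reports(f)
        assert len(rs) == 0

    def test_empty_reportset_writes_header_only(self, tmp_path):
        out = tmp_path / "out.tsv"
        write_reports(ReportSet([]), out)
        lines = out.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("report_id")

    def test_unknown_enum_tokens_map_to_unknown(self, tmp_path):
        f = tmp_path / "r.csv"
        f.write_text("report_id,drug,reaction,sex,age_group\n"
                     "1,omeprazole,anuria,hermaphrodite,200-300\n")
        (r,) = read_reports(f).records
        assert r.sex.value == "unknown"
        assert r.age_group.value == "unknown"

    @pytest.mark.parametrize("n", [1, 17, 60])
    def test_roundtrip_is_identity_on_logical_content(self, n, tmp_path):
        rng = random.Random(42 + n)
        rs = random_reportset(rng, n)
        path = tmp_path / "rt.tsv"
        write_reports(rs, path)
        back = read_reports(path)
        assert len(back) == len(rs)
        for orig, re_read in zip(rs.records, back.records):
            assert orig == re_read


class TestDeduplicate:
    def _record(self, rid, fatal=False):
        return NotificationRecord(
            report_id=rid,
            drugs=(DrugEntry("omeprazole", frozenset("A")),),
            reactions=frozenset({"anuria"}),
            fatal=fatal,
        )

    def test_identical_content_collapses(self):
        rs = ReportSet([self._record("a"), self._record("b")])
        out, removed = deduplicate(rs)
        assert len(out) == 1 and removed == 1
        assert out.records[0].report_id == "a"  # first kept, stable

    def test_no_duplicates_is_identity(self):
        rs = ReportSet([self._record("a"), self._record("b", fatal=True)])
        out, removed = deduplicate(rs)
        assert removed == 0 and out.records == rs.records

    def test_planted_duplicate_count_matches_pairwise_oracle(self, rng):
        base = random_reportset(rng, 40)
        dupes = [
            NotificationRecord(
                report_id=f"DUP{i}", year=r.year, sex=r.sex, age_group=r.age_group,
                drugs=r.drugs, reactions=r.reactions, seriousness=r.seriousness,
                fatal=r.fatal,
            )
            for i, r in enumerate(rng.sample(base.records, 9))
        ]
        mixed = base.records + dupes
        rng.shuffle(mixed)
        for i, r in enumerate(mixed):  # re-key so ids stay unique
            mixed[i] = NotificationRecord(
                report_id=f"M{i}", year=r.year, sex=r.sex, age_group=r.age_group,
                drugs=r.drugs, reactions=r.reactions, seriousness=r.seriousness,
                fatal=r.fatal,
            )
        rs = ReportSet(mixed)
        # oracle: count records whose content matches an earlier record
        expected_removed = 0
        seen = []
        for r in rs:
            key = (r.year, r.sex, r.age_group, r.drugs,
                   tuple(sorted(r.reactions)), tuple(sorted(r.seriousness)), r.fatal)
            if key in seen:
                expected_removed += 1
            else:
                seen.append(key)
        out, removed = deduplicate(rs)
        assert removed == expected_removed
        assert len(out) + removed == len(rs)

    def test_idempotent(self, small_reportset):
        once, _ = deduplicate(small_reportset)
        twice, removed = deduplicate(once)
        assert removed == 0 and twice.records == once.records

    def test_custom_key_subset(self):
        a = self._record("a", fatal=False)
        b = self._record("b", fatal=True)
        out, removed = deduplicate(ReportSet([a, b]), key=["drugs", "reactions"])
        assert removed == 1

    def test_empty_key_rejected(self, small_reportset):
        with pytest.raises(ValueError):
            deduplicate(small_reportset, key=[])


class TestRecordInvariants:
    def test_drugs_and_reactions_required(self):
        with pytest.raises(ValueError):
            NotificationRecord(report_id="x", drugs=(), reactions=frozenset({"anuria"}))
        with pytest.raises(ValueError):
            NotificationRecord(
                report_id="x",
                drugs=(DrugEntry("omeprazole"),),
                reactions=frozenset(),
            )

    def test_duplicate_ids_rejected(self):
        r = NotificationRecord(
            report_id="x", drugs=(DrugEntry("omeprazole"),),
            reactions=frozenset({"anuria"}),
        )
        with pytest.raises(ValueError):
            ReportSet([r, r])

    def test_fatal_strictness_modes(self):
        r = NotificationRecord(
            report_id="x", drugs=(DrugEntry("omeprazole"),),
            reactions=frozenset({"anuria"}), fatal=True,
        )
        r.validate_fatal(strict=False)  # lenient default: fine
        with pytest.raises(ValueError):
            r.validate_fatal(strict=True)

    def test_invalid_atc_letter_rejected(self):
        with pytest.raises(ValueError):
            DrugEntry("omeprazole", atc_letters=frozenset("Q"))
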