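"""Validation engine: value checks, sheet checks, subsets, merging."""

import random

import pytest

from metasheet import validate as V
from metasheet.model import (
    Severity,
    VocabEntry,
    Vocabulary,
    VType,
)


def _vocab(**entries):
    out = {}
    for key, values in entries.items():
        key = key.replace("_", " ")
        if values is None:
            out[key] = VocabEntry(key=key, vtype=VType.freetext)
        elif values == "date":
            out[key] = VocabEntry(key=key, vtype=VType.date)
        elif isinstance(values, tuple):
            out[key] = VocabEntry(key=key, vtype=VType.dropdown, allowed_values=values)
        else:  # multi
            out[key] = VocabEntry(
                key=key, vtype=VType.dropdown_multi, allowed_values=tuple(values)
            )
    return Vocabulary(entries=out)


TISSUE = _vocab(tissue=("liver", "brain"))


class TestValidateValue:
    def test_on_vocabulary_value_passes(self):
        assert V.validate_value("tissue", "liver", TISSUE) == []

    def test_case_insensitive_match(self):
        assert V.validate_value("tissue", "Liver", TISSUE) == []

    def test_off_vocabulary_single_issue(self):
        issues = V.validate_value("tissue", "kidney", TISSUE)
        assert [i.rule for i in issues] == ["off-vocabulary"]
        assert issues[0].severity is Severity.error

    def test_multi_select_each_token_validated(self):
        vocab = _vocab(timepoints=["0 h", "24 h", "48 h"])
        assert V.validate_value("timepoints", "0 h;24 h", vocab) == []
        bad = V.validate_value("timepoints", "0 h;96 h", vocab)
        assert [i.rule for i in bad] == ["off-vocabulary"]

    def test_unknown_key_is_warning_not_exception(self):
        issues = V.validate_value("colour", "blue", TISSUE)
        assert [i.rule for i in issues] == ["unknown-key"]
        assert issues[0].severity is Severity.warning

    @pytest.mark.parametrize(
        "raw,iso",
        [
            ("2024-05-22", "2024-05-22"),
            ("22.05.2024", "2024-05-22"),
            ("22/05/2024", "2024-05-22"),
            ("45434", "2024-05-22"),  # spreadsheet serial
        ],
    )
    def test_dates_normalize(self, raw, iso):
        assert V.normalize_date(raw) == iso

    def test_bad_date_flagged(self):
        vocab = _vocab(date="date")
        assert [i.rule for i in V.validate_value("date", "yesterday-ish", vocab)] == [
            "bad-date"
        ]


class TestValidateSheet:
    def test_unmodified_fixture_is_ok(self, showcase):
        sheet, vocab, registry = showcase
        assert V.validate_sheet(sheet, vocab, registry).ok

    def test_undeclared_instance_in_final_groups(self, showcase):
        sheet, vocab, registry = showcase
        group = sheet.planning.comparison_groups[0]
        trimmed = group.model_copy(update={"instances": group.instances[:-1]})
        sheet.planning = sheet.planning.model_copy(
            update={"comparison_groups": (trimmed,)}
        )
        report = V.validate_sheet(sheet, vocab, registry)
        assert not report.ok
        assert any(i.rule == "undeclared-instance" for i in report.errors())

    def test_replicates_unset_is_error(self, showcase):
        sheet, vocab, registry = showcase
        fgs = list(sheet.conduction.final_groups)
        fgs[0] = fgs[0].model_copy(update={"n_replicates": None})
        sheet.conduction = sheet.conduction.model_copy(
            update={"final_groups": tuple(fgs)}
        )
        report = V.validate_sheet(sheet, vocab, registry)
        errors = [i.rule for i in report.errors()]
        assert errors == ["replicates-unset"]
        # downstream matching is suppressed behind a single marker, a warning
        assert sum(i.rule == "blocked-by-upstream" for i in report.issues) == 1

    def test_conduction_blocked_when_planning_invalid(self, showcase):
        sheet, vocab, registry = showcase
        es = sheet.planning.experimental_system
        dep = dict(es.dependent_values)
        dep["tissue"] = "not-a-tissue"
        dep["line"] = "not-a-line"
        sheet.planning = sheet.planning.model_copy(
            update={
                "experimental_system": es.model_copy(
                    update={"dependent_values": dep}
                )
            }
        )
        report = V.validate_sheet(sheet, vocab, registry)
        assert len(report.errors()) == 2
        assert all(i.rule == "off-vocabulary" for i in report.errors())
        assert sum(i.rule == "blocked-by-upstream" for i in report.issues) == 1

    def test_column_count_mismatch_detected(self, showcase):
        sheet, vocab, registry = showcase
        table = sheet.matching
        sheet.matching = table.model_copy(
            update={"columns": table.columns[:-1]}
        )
        report = V.validate_sheet(sheet, vocab, registry)
        assert any(i.rule == "column-count" for i in report.errors())

    def test_off_vocab_injection_counts_match(self, showcase_session):
        """k injected off-vocabulary values yield exactly k error issues."""
        rng = random.Random(20240522)
        slots = ["line", "genotype", "tissue", "sex"]
        for _ in range(10):
            sheet, vocab, registry = showcase_session
            sheet = sheet.model_copy(deep=True)
            k = rng.randint(1, len(slots))
            for key in rng.sample(slots, k):
                es = sheet.planning.experimental_system
                dep = dict(es.dependent_values)
                dep[key] = "zzz-not-a-term"
                sheet.planning = sheet.planning.model_copy(
                    update={
                        "experimental_system": es.model_copy(
                            update={"dependent_values": dep}
                        )
                    }
                )
            report = V.validate_sheet(sheet, vocab, registry)
            errors = report.errors()
            assert len(errors) == k
            assert all(i.rule == "off-vocabulary" for i in errors)


class TestSubset:
    def test_subset_ok(self):
        group = _vocab(tissue=("liver",))
        assert V.check_subset(group, TISSUE).ok

    def test_extra_value_violates(self):
        group = _vocab(tissue=("kidney",))
        report = V.check_subset(group, TISSUE)
        assert [i.rule for i in report.errors()] == ["subset-extra-values"]

    def test_key_absent_from_master_violates(self):
        group = _vocab(organ=("liver",))
        assert [i.rule for i in V.check_subset(group, TISSUE).errors()] == [
            "subset-unknown-key"
        ]

    def test_type_mismatch_violates(self):
        group = _vocab(tissue=None)  # freetext vs master dropdown
        assert [i.rule for i in V.check_subset(group, TISSUE).errors()] == [
            "subset-type-mismatch"
        ]

    def test_self_subset_always_ok(self, base_vocab):
        assert V.check_subset(base_vocab, base_vocab).ok


class TestMerge:
    def test_disjoint_union(self):
        a = _vocab(tissue=("liver",))
        b = _vocab(weight=None)
        merged, report = V.merge_vocabularies(a, b)
        assert report.ok
        assert set(merged.entries) == {"tissue", "weight"}

    def test_shared_key_unions_values_in_order(self):
        a = _vocab(tissue=("liver",))
        b = _vocab(tissue=("liver", "brain"))
        merged, report = V.merge_vocabularies(a, b)
        assert report.ok
        assert merged.get("tissue").allowed_values == ("liver", "brain")

    def test_type_clash_reported_and_omitted(self):
        a = _vocab(weight=None)
        b = _vocab(weight=("low", "high"))
        merged, report = V.merge_vocabularies(a, b)
        assert not report.ok
        assert "weight" not in merged.entries

    def test_commutative_up_to_value_order(self):
        a = _vocab(tissue=("liver", "heart"), weight=None)
        b = _vocab(tissue=("brain",), sex=("male", "female"))
        ab, _ = V.merge_vocabularies(a, b)
        ba, _ = V.merge_vocabularies(b, a)
        assert set(ab.entries) == set(ba.entries)
        for key in ab.entries:
            assert set(ab.get(key).allowed_values) == set(
                ba.get(key).allowed_values
            )

    def test_associative_on_conflict_free_inputs(self):
        a = _vocab(tissue=("liver",))
        b = _vocab(tissue=("brain",), weight=None)
        c = _vocab(sex=("male",))
        ab_c, _ = V.merge_vocabularies(V.merge_vocabularies(a, b)[0], c)
        a_bc, _ = V.merge_vocabularies(a, V.merge_vocabularies(b, c)[0])
        assert set(ab_c.entries) == set(a_bc.entries)
        for key in ab_c.entries:
            assert set(ab_c.get(key).allowed_values) == set(
                a_bc.get(key).allowed_values
            )
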