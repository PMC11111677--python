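"""Workbook layout reading/writing: resource grids, round-trips, totality."""

import zipfile

import pytest
from openpyxl import Workbook, load_workbook

from metasheet import fixtures
from metasheet.fixtures import DesignSpec
from metasheet.model import (
    LayoutError,
    Metadatasheet,
    RegistryCategory,
    VType,
)
from metasheet.sheet_io import (
    read_dependent_fields,
    read_metadatasheet,
    read_vocabulary,
    write_metadatasheet,
)


def _grid(*columns):
    """Build a row grid from column lists (the sheets are column-oriented)."""
    height = max(len(c) for c in columns)
    return [
        [c[i] if i < len(c) else "" for c in columns] for i in range(height)
    ]


class TestVocabularyGrid:
    def test_dropdown_column(self):
        vocab = read_vocabulary(
            _grid(["DropDown", "choose organ", "tissue", "liver", "brain"])
        )
        entry = vocab.get("tissue")
        assert entry.vtype is VType.dropdown
        assert entry.allowed_values == ("liver", "brain")
        assert entry.help == "choose organ"

    def test_freetext_column_has_no_values(self):
        vocab = read_vocabulary(_grid(["freetext", "", "weight"]))
        entry = vocab.get("weight")
        assert entry.vtype is VType.freetext
        assert entry.allowed_values == ()

    def test_multi_select_token(self):
        vocab = read_vocabulary(_grid(["DropDown_M", "", "timepoints", "0 h"]))
        assert vocab.get("timepoints").vtype is VType.dropdown_multi

    def test_unknown_token_is_layout_error(self):
        with pytest.raises(LayoutError, match="DropDown_X"):
            read_vocabulary(_grid(["DropDown_X", "", "tissue", "liver"]))


class TestDependentFieldsGrid:
    def test_mouse_column(self):
        reg = read_dependent_fields(
            _grid(["experimental system", "mouse", "line", "genotype"])
        )
        entry = reg.get(RegistryCategory.experimental_system, "mouse")
        assert entry.keys == ("line", "genotype")

    def test_empty_column_skipped(self):
        reg = read_dependent_fields(
            _grid(
                ["experimental system", "mouse", "line"],
                ["", "", ""],
                ["measurement type", "FACS", "used facility"],
            )
        )
        assert len(reg.entries) == 2

    def test_unknown_category_is_layout_error(self):
        with pytest.raises(LayoutError, match="category"):
            read_dependent_fields(_grid(["animal", "mouse", "line"]))

    def test_duplicate_header_pair_is_layout_error(self):
        with pytest.raises(LayoutError, match="duplicate"):
            read_dependent_fields(
                _grid(
                    ["experimental system", "mouse", "line"],
                    ["experimental system", "mouse", "genotype"],
                )
            )


class TestRoundTrip:
    def test_showcase_roundtrip_field_for_field(self, showcase, tmp_path):
        sheet, vocab, registry = showcase
        path = tmp_path / "sheet.xlsx"
        written = write_metadatasheet(sheet, vocab, registry, path)
        result = read_metadatasheet(path)
        assert result.issues == ()
        assert result.sheet == written
        assert result.vocabulary == vocab
        assert result.registry == registry

    def test_showcase_parses_one_diet_group_with_six_instances(
        self, showcase, tmp_path
    ):
        sheet, vocab, registry = showcase
        path = tmp_path / "sheet.xlsx"
        write_metadatasheet(sheet, vocab, registry, path)
        parsed = read_metadatasheet(path).sheet
        groups = parsed.planning.comparison_groups
        assert len(groups) == 1
        assert groups[0].category.value == "diet"
        assert len(groups[0].instances) == 6

    def test_blank_template_roundtrip(self, base_vocab, base_registry, tmp_path):
        path = tmp_path / "blank.xlsx"
        written = write_metadatasheet(
            Metadatasheet(), base_vocab, base_registry, path
        )
        result = read_metadatasheet(path)
        assert result.issues == ()
        assert result.sheet == written
        assert result.sheet.conduction.final_groups == ()
        assert result.sheet.matching is None

    def test_uid_assigned_on_export_and_stable_on_reexport(
        self, showcase, tmp_path
    ):
        sheet, vocab, registry = showcase
        bare = sheet.model_copy(update={"uid": None})
        written = write_metadatasheet(bare, vocab, registry, tmp_path / "a.xlsx")
        assert written.uid
        again = write_metadatasheet(written, vocab, registry, tmp_path / "b.xlsx")
        assert again.uid == written.uid

    def test_group_vocab_sheet_roundtrips(self, showcase, tmp_path):
        sheet, vocab, registry = showcase
        group = vocab.model_copy(update={"group_label": "Liver"})
        path = tmp_path / "g.xlsx"
        write_metadatasheet(sheet, vocab, registry, path, group_vocabs=(group,))
        result = read_metadatasheet(path)
        assert "Liver" in result.group_vocabularies
        assert result.group_vocabularies["Liver"].entries == vocab.entries


class TestTotality:
    def test_missing_input_sheet_is_fatal(self, tmp_path):
        wb = Workbook()
        wb.active.title = "Whatever"
        path = tmp_path / "bad.xlsx"
        wb.save(path)
        with pytest.raises(LayoutError, match="Input"):
            read_metadatasheet(path)

    def test_missing_resources_fatal_with_hint(self, tmp_path):
        wb = Workbook()
        wb.active.title = "Input"
        path = tmp_path / "noresources.xlsx"
        wb.save(path)
        with pytest.raises(LayoutError, match="resources"):
            read_metadatasheet(path)

    def test_third_division_level_becomes_issue_not_crash(
        self, showcase, tmp_path
    ):
        sheet, vocab, registry = showcase
        spec = DesignSpec(division_levels=2)
        sheet2, vocab, registry = fixtures.generate_sheet(5, spec)
        path = tmp_path / "div3.xlsx"
        write_metadatasheet(sheet2, vocab, registry, path)
        wb = load_workbook(path)
        ws = wb["Input"]
        # doctor a third division block into the Preparation segment
        target = None
        for row in ws.iter_rows():
            if row[0].value == "-- Measurement --":
                target = row[0].row
        ws.insert_rows(target, amount=5)
        for i, (label, value) in enumerate(
            [
                ("division", "3"),
                ("n per parent", "1"),
                ("division instance", "extra"),
                ("division protocol", "p.pdf"),
                ("division replicates", "1"),
            ]
        ):
            ws.cell(row=target + i, column=1, value=label)
            ws.cell(row=target + i, column=2, value=value)
        wb.save(path)
        result = read_metadatasheet(path)
        assert any(
            i.rule == "segment-unparseable" and "two levels" in i.message
            for i in result.issues
        )

    def test_writer_output_is_macro_free(self, showcase, tmp_path):
        sheet, vocab, registry = showcase
        path = tmp_path / "plain.xlsx"
        write_metadatasheet(sheet, vocab, registry, path)
        names = zipfile.ZipFile(path).namelist()
        assert not any("vbaProject" in n for n in names)
        assert "[Content_Types].xml" in names
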