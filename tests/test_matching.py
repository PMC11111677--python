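"""ID-table generation, CHANGES promotion and data-file resolution."""

import pytest

from metasheet.matching import (
    FILENAME_KEY,
    collect_promoted_keys,
    generate_id_table,
    resolve_datafiles,
)
from metasheet.model import (
    CHANGES,
    Availability,
    CovariateRole,
    CovariateSpec,
    DataFileLinkage,
    DivisionInstance,
    DivisionLevel,
    FinalGroup,
    IDColumn,
    IDTable,
    LinkageMode,
    PreparationSpec,
    ResolutionError,
    SequentialIntegrityError,
)


def _fgs(*replicates):
    return [
        FinalGroup(assignment={"diet": f"d{i + 1}"}, n_replicates=r)
        for i, r in enumerate(replicates)
    ]


class TestPromotion:
    def test_linkage_changes_promotes_filename(self, showcase):
        sheet, _, _ = showcase
        linkage = sheet.conduction.linkage.model_copy(
            update={"mode": LinkageMode.changes}
        )
        sheet.conduction = sheet.conduction.model_copy(
            update={"linkage": linkage}
        )
        assert collect_promoted_keys(sheet) == [FILENAME_KEY]

    def test_no_changes_tokens_means_no_promotion(self, showcase):
        sheet, _, _ = showcase
        assert collect_promoted_keys(sheet) == []

    def test_two_promoted_keys_in_document_order(self, showcase):
        sheet, _, _ = showcase
        cov = CovariateSpec(
            name="batch", role=CovariateRole.constant, constant_value=CHANGES
        )
        meas = sheet.conduction.measurement
        dep = dict(meas.dependent_values)
        dep["used facility"] = CHANGES
        sheet.conduction = sheet.conduction.model_copy(
            update={
                "covariates": sheet.conduction.covariates + (cov,),
                "measurement": meas.model_copy(update={"dependent_values": dep}),
            }
        )
        assert collect_promoted_keys(sheet) == ["batch", "used facility"]

    def test_lowercase_changes_is_not_promoted(self, showcase):
        sheet, _, _ = showcase
        cov = CovariateSpec(
            name="batch", role=CovariateRole.constant, constant_value="changes"
        )
        sheet.conduction = sheet.conduction.model_copy(
            update={"covariates": sheet.conduction.covariates + (cov,)}
        )
        assert collect_promoted_keys(sheet) == []


class TestGenerateIDTable:
    def test_showcase_shape_30_columns(self):
        table = generate_id_table(_fgs(5, 5, 5, 5, 5, 5))
        assert len(table.columns) == 30
        assert table.dynamic_keys == ()
        assert not table.subsamples_present

    def test_minimal_single_column(self):
        table = generate_id_table(_fgs(1))
        assert len(table.columns) == 1
        col = table.columns[0]
        assert col.personal_id == ""
        assert col.replicate == 1
        assert not table.subsamples_present and not table.subsubsamples_present

    def test_column_count_is_sum_of_replicates(self):
        assert len(generate_id_table(_fgs(2, 3, 4)).columns) == 9

    def test_replicate_indices_one_based_per_group(self):
        table = generate_id_table(_fgs(2, 3))
        assert [c.replicate for c in table.columns] == [1, 2, 1, 2, 3]

    def test_covariates_and_promoted_keys_become_rows(self):
        covs = [
            CovariateSpec(name="body weight", unit="g", role=CovariateRole.covariate),
            CovariateSpec(
                name="cell type", role=CovariateRole.constant, constant_value="KC"
            ),
        ]
        table = generate_id_table(_fgs(2), covs, [FILENAME_KEY])
        # constants stay key:value in conduction; covariates + promoted only
        assert table.dynamic_keys == ("body weight", FILENAME_KEY)

    def test_division_levels_expand_with_parent_references(self):
        prep = PreparationSpec(
            protocol="p.pdf",
            divisions=(
                DivisionLevel(
                    n_per_parent=2,
                    instances=(
                        DivisionInstance(label="a", n_replicates=1),
                        DivisionInstance(label="b", n_replicates=2),
                    ),
                ),
            ),
        )
        table = generate_id_table(_fgs(2), preparation=prep)
        assert len(table.columns) == 2
        assert len(table.subsample.columns) == 2 * 3  # (1 + 2) per parent
        assert {c.parent_index for c in table.subsample.columns} == {0, 1}

    def test_replicates_unset_blocks_generation(self):
        groups = _fgs(2)
        groups[0] = groups[0].model_copy(update={"n_replicates": None})
        with pytest.raises(SequentialIntegrityError, match="replicate"):
            generate_id_table(groups)

    def test_empty_conduction_blocks_generation(self):
        with pytest.raises(SequentialIntegrityError):
            generate_id_table([])


def _table(*ids):
    return IDTable(
        columns=tuple(
            IDColumn(personal_id=i, replicate=1, final_group="g") for i in ids
        )
    )


def _linkage(mode, comment="x"):
    return DataFileLinkage(availability=Availability.raw, mode=mode, comment=comment)


class TestResolveDatafiles:
    def test_single_file_for_all(self, tmp_path):
        (tmp_path / "counts.csv").write_text("f,a\n")
        ids = [f"M{i}" for i in range(1, 31)]
        mapping, warns = resolve_datafiles(
            _table(*ids),
            _linkage(LinkageMode.single_file_for_all, "counts.csv"),
            tmp_path,
        )
        assert len(mapping) == 30
        assert all(v == [(tmp_path / "counts.csv").relative_to(tmp_path)] for v in mapping.values())
        assert warns == []

    def test_single_file_missing_is_error(self, tmp_path):
        with pytest.raises(ResolutionError, match="missing file"):
            resolve_datafiles(
                _table("M1"),
                _linkage(LinkageMode.single_file_for_all, "counts.csv"),
                tmp_path,
            )

    def test_id_in_filename_paired_end(self, tmp_path):
        for name in ("A1_R1.fastq", "A1_R2.fastq", "A2_R1.fastq", "A2_R2.fastq"):
            (tmp_path / name).write_text("@")
        mapping, warns = resolve_datafiles(
            _table("A1", "A2"), _linkage(LinkageMode.id_in_filename), tmp_path
        )
        assert [str(p) for p in mapping["A1"]] == ["A1_R1.fastq", "A1_R2.fastq"]
        assert [str(p) for p in mapping["A2"]] == ["A2_R1.fastq", "A2_R2.fastq"]
        assert warns == []

    def test_unmatched_id_is_error(self, tmp_path):
        (tmp_path / "A1.fastq").write_text("@")
        with pytest.raises(ResolutionError, match="Z9"):
            resolve_datafiles(
                _table("A1", "Z9"), _linkage(LinkageMode.id_in_filename), tmp_path
            )

    def test_prefix_collision_raises_ambiguity_warning(self, tmp_path):
        (tmp_path / "S1.csv").write_text("x")
        (tmp_path / "S10.csv").write_text("x")
        mapping, warns = resolve_datafiles(
            _table("S1", "S10"), _linkage(LinkageMode.id_in_filename), tmp_path
        )
        assert any(w.rule == "ambiguous-id" for w in warns)
        # plain substring matching: S1 matches both files, as documented
        assert [str(p) for p in mapping["S1"]] == ["S1.csv", "S10.csv"]
        assert [str(p) for p in mapping["S10"]] == ["S10.csv"]

    def test_changes_mode_uses_promoted_filename_row(self, tmp_path):
        (tmp_path / "fileA.tsv").write_text("x")
        (tmp_path / "fileB.tsv").write_text("x")
        table = IDTable(
            columns=(
                IDColumn(
                    personal_id="M1",
                    replicate=1,
                    values={FILENAME_KEY: "fileA.tsv"},
                ),
                IDColumn(
                    personal_id="M2",
                    replicate=1,
                    values={FILENAME_KEY: "fileB.tsv"},
                ),
            ),
            dynamic_keys=(FILENAME_KEY,),
        )
        mapping, _ = resolve_datafiles(
            table, _linkage(LinkageMode.changes), tmp_path
        )
        assert [str(p) for p in mapping["M1"]] == ["fileA.tsv"]
        assert [str(p) for p in mapping["M2"]] == ["fileB.tsv"]

    def test_blank_ids_block_resolution(self, tmp_path):
        with pytest.raises(ResolutionError, match="blank"):
            resolve_datafiles(
                _table(""), _linkage(LinkageMode.id_in_filename), tmp_path
            )

    def test_resolution_is_order_stable(self, tmp_path):
        # files created in shuffled order still resolve sorted
        for name in ("M1_z.tsv", "M1_a.tsv", "M1_k.tsv"):
            (tmp_path / name).write_text("x")
        mapping, _ = resolve_datafiles(
            _table("M1"), _linkage(LinkageMode.id_in_filename), tmp_path
        )
        assert [str(p) for p in mapping["M1"]] == [
            "M1_a.tsv",
            "M1_k.tsv",
            "M1_z.tsv",
        ]
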