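"""GEO export, OWL/RDF individuals export and the experiment bundle."""

import subprocess

import pytest
from openpyxl import load_workbook
from rdflib import Graph, RDF

from metasheet import export as E
from metasheet import fixtures, matching
from metasheet.export import MS
from metasheet.fixtures import DesignSpec
from metasheet.model import ExportError, LinkageMode


@pytest.fixture()
def resolved_showcase(showcase, tmp_path):
    sheet, vocab, registry = showcase
    fixtures.generate_datafiles(sheet, tmp_path, seed=1)
    resolved, _ = matching.resolve_datafiles(
        sheet.matching, sheet.conduction.linkage, tmp_path
    )
    return sheet, resolved, tmp_path


class TestGeo:
    def test_sample_rows_equal_measured_units(self, resolved_showcase):
        sheet, resolved, _ = resolved_showcase
        geo = E.export_geo(sheet, resolved)
        assert len(geo.samples) == 30
        assert len(geo.samples) == len(sheet.matching.deepest_ids())

    def test_missing_contributor_name_names_the_field(self, resolved_showcase):
        sheet, resolved, _ = resolved_showcase
        sheet.planning = sheet.planning.model_copy(
            update={
                "general": sheet.planning.general.model_copy(
                    update={"name": ""}
                )
            }
        )
        with pytest.raises(ExportError, match="contributor name"):
            E.export_geo(sheet, resolved)

    def test_constant_becomes_characteristics_column_in_every_row(
        self, tmp_path
    ):
        sheet, vocab, registry = fixtures.generate_sheet(
            4, DesignSpec(n_constants=2)
        )
        fixtures.generate_datafiles(sheet, tmp_path, seed=4)
        resolved, _ = matching.resolve_datafiles(
            sheet.matching, sheet.conduction.linkage, tmp_path
        )
        geo = E.export_geo(sheet, resolved)
        col = "characteristics: cell type"
        assert all(row[col] == "Kupffer Cells" for row in geo.samples)

    def test_division_sheet_counts_deepest_level(self, tmp_path):
        spec = DesignSpec(
            instances_per_group=(2,),
            replicates=2,
            division_levels=1,
            linkage_mode=LinkageMode.id_in_filename,
        )
        sheet, vocab, registry = fixtures.generate_sheet(6, spec)
        fixtures.generate_datafiles(sheet, tmp_path, seed=6)
        resolved, _ = matching.resolve_datafiles(
            sheet.matching, sheet.conduction.linkage, tmp_path
        )
        geo = E.export_geo(sheet, resolved)
        assert len(geo.samples) == len(sheet.matching.subsample.columns)

    def test_written_workbook_has_sample_block(
        self, resolved_showcase, tmp_path
    ):
        sheet, resolved, _ = resolved_showcase
        geo = E.export_geo(sheet, resolved)
        out = tmp_path / "geo.xlsx"
        E.write_geo_xlsx(geo, out)
        cells = [
            row[0].value for row in load_workbook(out)["Metadata"].iter_rows()
        ]
        assert "STUDY" in cells and "SAMPLES" in cells and "PROTOCOLS" in cells


class TestRdf:
    def test_empty_sheet_list_yields_schema_only_document(self):
        graph = E.export_xml([])
        assert list(graph.subjects(RDF.type, MS["Metadatasheet"])) == []
        Graph().parse(data=graph.serialize(format="xml"), format="xml")

    def test_individual_count_sheet_plus_units(self, showcase):
        sheet, _, _ = showcase
        graph = E.export_xml([sheet])
        sheets = set(graph.subjects(RDF.type, MS["Metadatasheet"]))
        units = set(graph.subjects(RDF.type, MS["MeasuredUnit"]))
        assert len(sheets) == 1
        assert len(units) == 30
        assert len(sheets | units) >= 31

    def test_serialization_parses_back_without_loss(self, showcase):
        sheet, _, _ = showcase
        graph = E.export_xml([sheet])
        for fmt in ("xml", "pretty-xml"):
            reparsed = Graph().parse(data=graph.serialize(format=fmt), format="xml")
            assert len(
                set(reparsed.subjects(RDF.type, MS["MeasuredUnit"]))
            ) == 30

    def test_curie_values_link_ontology_terms(self, showcase):
        sheet, _, _ = showcase  # tissue is 'BTO:0000759 liver'
        graph = E.export_xml([sheet])
        terms = list(graph.objects(None, MS["ontologyTerm"]))
        assert any(str(t).endswith("BTO_0000759") for t in terms)

    def test_unmapped_key_falls_back_to_generic_attribute(self, showcase):
        sheet, _, _ = showcase
        es = sheet.planning.experimental_system
        dep = dict(es.dependent_values)
        dep["moon phase"] = "waxing"
        sheet.planning = sheet.planning.model_copy(
            update={
                "experimental_system": es.model_copy(
                    update={"dependent_values": dep}
                )
            }
        )
        with pytest.warns(UserWarning, match="moon phase"):
            graph = E.export_xml([sheet])
        assert list(graph.subject_objects(MS["attribute"]))


class TestBundle:
    def test_single_matrix_aligns_on_personal_ids(self, resolved_showcase):
        sheet, _, root = resolved_showcase
        bundle = E.to_experiment_bundle(sheet, root)
        ids = list(sheet.matching.deepest_ids())
        assert list(bundle.assay.columns) == ids
        assert list(bundle.coldata.index) == ids
        assert bundle.metadata["conduction"]["measurement type"] == "bulk_RNA_seq"

    def test_per_id_files_assemble_matrix(self, tmp_path):
        spec = DesignSpec(
            instances_per_group=(2,),
            replicates=3,
            linkage_mode=LinkageMode.id_in_filename,
        )
        sheet, _, _ = fixtures.generate_sheet(8, spec)
        fixtures.generate_datafiles(sheet, tmp_path, seed=8)
        bundle = E.to_experiment_bundle(sheet, tmp_path)
        assert list(bundle.assay.columns) == list(sheet.matching.deepest_ids())

    def test_facs_sheet_is_refused(self, tmp_path):
        sheet, _, _ = fixtures.generate_sheet(
            9, DesignSpec(measurement_type="FACS")
        )
        with pytest.raises(ExportError, match="bulk-transcriptomics"):
            E.to_experiment_bundle(sheet, tmp_path)

    def test_missing_named_file_lists_candidates(self, showcase, tmp_path):
        sheet, _, _ = showcase
        (tmp_path / "mystery_counts.tsv").write_text("feature\tM001\ng\t1\n")
        with pytest.raises(E.ClarificationError) as exc:
            E.to_experiment_bundle(sheet, tmp_path)
        assert [str(c) for c in exc.value.candidates] == ["mystery_counts.tsv"]

    def test_bundle_roundtrips_through_disk(self, resolved_showcase, tmp_path):
        sheet, _, root = resolved_showcase
        bundle = E.to_experiment_bundle(sheet, root)
        outdir = tmp_path / "bundle"
        files = E.write_bundle(bundle, outdir)
        assert sorted(f.name for f in files) == [
            "assay.tsv",
            "coldata.tsv",
            "metadata.json",
        ]
        again = E.read_bundle(outdir)
        assert again.assay.equals(bundle.assay)
        assert list(again.coldata.index) == list(bundle.coldata.index)
        assert again.metadata == bundle.metadata

    def test_zero_feature_bundle_is_valid(self, showcase, tmp_path):
        sheet, _, _ = showcase
        ids = sheet.matching.deepest_ids()
        (tmp_path / "counts.tsv").write_text("feature\t" + "\t".join(ids) + "\n")
        bundle = E.to_experiment_bundle(sheet, tmp_path)
        assert bundle.assay.shape == (0, 30)
        E.write_bundle(bundle, tmp_path / "b")
        assert E.read_bundle(tmp_path / "b").assay.shape == (0, 30)

    def test_r_session_loads_bundle_as_summarized_experiment(
        self, resolved_showcase, tmp_path
    ):
        """Cross-language check: the TSV/JSON bundle builds a
        SummarizedExperiment with matching dimensions in R."""
        sheet, _, root = resolved_showcase
        bundle = E.to_experiment_bundle(sheet, root)
        outdir = tmp_path / "bundle"
        E.write_bundle(bundle, outdir)
        script = f"""
        suppressMessages(library(SummarizedExperiment))
        assay <- as.matrix(read.delim("{outdir}/assay.tsv", row.names=1, check.names=FALSE))
        coldata <- read.delim("{outdir}/coldata.tsv", row.names=1, check.names=FALSE)
        se <- SummarizedExperiment(assays=list(counts=assay), colData=coldata)
        cat(dim(se)[1], dim(se)[2], sep=" ")
        """
        proc = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert proc.returncode == 0, proc.stderr
        assert proc.stdout.strip().split() == [
            str(bundle.assay.shape[0]),
            str(bundle.assay.shape[1]),
        ]
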