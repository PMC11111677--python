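"""Exporters: NCBI GEO metadata spreadsheet, OWL/RDF individuals, and the
language-neutral experiment bundle.

The bundle mirrors the SummarizedExperiment conversion: an assay matrix
(features x measured units), a column-metadata table (the measurement-
matching section, one row per measured unit) and the sheet-level metadata —
serialized as TSV/JSON so any downstream environment (e.g. an R session
building a SummarizedExperiment with the matching table in ``colData``) can
load it.  Conversion is restricted to the three bulk omics families
(transcriptomics, metabolomics, lipidomics), reached through an alias table
from vocabulary measurement types such as ``bulk_RNA_seq``.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources as _resources
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from openpyxl import Workbook
from rdflib import Graph, Literal, Namespace, RDF, RDFS, URIRef

from .model import (
    Availability,
    CovariateRole,
    ExportError,
    IDTable,
    LinkageMode,
    Metadatasheet,
    ResolutionError,
    canonical_key,
    canonicalize,
)
from .matching import _deepest_columns, resolve_datafiles
from .sheet_io import _save_deterministic

__all__ = [
    "GeoMetadata",
    "ExperimentBundle",
    "ClarificationError",
    "AlignmentError",
    "export_geo",
    "write_geo_xlsx",
    "export_xml",
    "default_ontology_path",
    "to_experiment_bundle",
    "write_bundle",
    "read_bundle",
    "BULK_ALIASES",
]

MS = Namespace("https://w3id.org/metasheet/onto#")
SHEETNS = Namespace("https://w3id.org/metasheet/id/")

_CURIE_RE = re.compile(r"\b([A-Za-z][A-Za-z0-9]{1,15}):(\d{2,})\b")

#: Vocabulary measurement types accepted by the bundle converter, mapped to
#: the three bulk omics families.
BULK_ALIASES = {
    "bulk_rna_seq": "bulk-transcriptomics",
    "bulk rna seq": "bulk-transcriptomics",
    "bulk-transcriptomics": "bulk-transcriptomics",
    "bulk_transcriptomics": "bulk-transcriptomics",
    "bulk_metabolomics": "bulk-metabolomics",
    "bulk-metabolomics": "bulk-metabolomics",
    "bulk_lipidomics": "bulk-lipidomics",
    "bulk-lipidomics": "bulk-lipidomics",
}


class ClarificationError(ExportError):
    """The named data file is absent; candidate files (matched by extension)
    are offered for clarification."""

    def __init__(self, message: str, candidates: Sequence[Path]):
        super().__init__(message)
        self.candidates = list(candidates)


class AlignmentError(ExportError):
    """Assay columns and personal_IDs cannot be aligned."""


def _geo_config() -> dict:
    with _resources.files("metasheet.data").joinpath("geo_template.json").open() as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# GEO export
# ---------------------------------------------------------------------------


@dataclass
class GeoMetadata:
    """A GEO-template-shaped metadata document: study block, one sample row
    per measured unit, and the protocols block."""

    study: dict[str, str]
    samples: list[dict[str, str]]
    protocols: dict[str, str]
    template_version: str = ""

    @property
    def sample_columns(self) -> list[str]:
        cols: list[str] = []
        for row in self.samples:
            for key in row:
                if key not in cols:
                    cols.append(key)
        return cols


def export_geo(
    sheet: Metadatasheet,
    resolved: Optional[dict[str, list[Path]]] = None,
) -> GeoMetadata:
    """Build the GEO submission metadata from a completed sheet.

    Characteristics columns come from the comparison-group assignments, the
    covariates (per-sample values from the ID table) and the constants (the
    same value in every row); protocols from the preparation and measurement
    segments.  Missing mandatory fields raise :class:`ExportError`
    enumerating every gap.
    """
    cfg = _geo_config()
    g = sheet.planning.general
    es = sheet.planning.experimental_system
    con = sheet.conduction

    gaps: list[str] = []
    if not canonicalize(g.name):
        gaps.append("contributor name (planning/General/name)")
    if not canonicalize(g.project_title):
        gaps.append("title (planning/General/project title)")
    if es is None:
        gaps.append("organism (planning/Experimental System)")
    if sheet.matching is None or not sheet.matching.columns:
        gaps.append("samples (measurement-matching table)")
    if con.preparation is None or not canonicalize(con.preparation.protocol):
        gaps.append("extract protocol (conduction/Preparation/protocol)")
    if gaps:
        raise ExportError(
            "cannot export to GEO; mandatory fields missing: " + "; ".join(gaps)
        )
    assert es is not None and sheet.matching is not None

    design_bits = [
        f"{grp.category.value}: {len(grp.instances)} instance(s) "
        f"({', '.join(i.label for i in grp.instances)})"
        for grp in sheet.planning.comparison_groups
    ]
    study = {
        "title": g.project_title,
        "summary": f"{g.project_title} — {es.system} study recorded as a "
        "Metadatasheet.",
        "overall design": "; ".join(design_bits) or "single condition",
        "contributor": g.name,
        "supplementary file": "",
    }

    organism = cfg["organism_map"].get(canonical_key(es.system), es.system)
    source = es.dependent_values.get("tissue", es.system)
    family = BULK_ALIASES.get(
        canonical_key(con.measurement.measurement_type)
        if con.measurement is not None
        else "",
        "",
    )
    molecule = cfg["molecule_map"].get(family, "not applicable")

    constants = [
        c for c in con.covariates if c.role is CovariateRole.constant
        and c.constant_value != "CHANGES"
    ]
    covariate_names = [
        c.name for c in con.covariates if c.role is CovariateRole.covariate
    ]

    samples: list[dict[str, str]] = []
    for unit, ancestor in _deepest_columns(sheet.matching):
        row: dict[str, str] = {
            "library name": unit.personal_id,
            "title": f"{unit.personal_id} ({ancestor.final_group}, "
            f"replicate {unit.replicate})",
            "organism": organism,
            "source name": source,
            "molecule": molecule,
            "description": "",
        }
        for cat, label in ancestor.assignment.items():
            row[f"characteristics: {cat}"] = label
        for c in constants:
            unitsfx = f" ({c.unit})" if c.unit else ""
            row[f"characteristics: {c.name}{unitsfx}"] = c.constant_value or ""
        for name in covariate_names:
            value = unit.values.get(name, "") or ancestor.values.get(name, "")
            row[f"characteristics: {name}"] = value
        if getattr(unit, "instance", None):
            row["characteristics: division instance"] = unit.instance
        if resolved is not None:
            files = resolved.get(unit.personal_id, [])
            key = (
                "processed data file"
                if con.linkage is not None
                and con.linkage.availability is Availability.processed
                else "raw file"
            )
            for k, f in enumerate(files, start=1):
                row[f"{key} {k}" if len(files) > 1 else key] = str(f)
        samples.append(row)

    protocols = {
        "growth protocol": "; ".join(design_bits),
        "treatment protocol": "",
        "extract protocol": con.preparation.protocol,
        "library construction protocol": (
            con.measurement.dependent_values.get("library prep kit", "")
            if con.measurement is not None
            else ""
        ),
        "library strategy": (
            con.measurement.measurement_type if con.measurement else ""
        ),
        "data processing": (
            (con.linkage.processing_procedure or "")
            if con.linkage is not None
            and con.linkage.availability is Availability.processed
            else "raw data as produced by the instrument"
        ),
    }
    return GeoMetadata(
        study=study,
        samples=samples,
        protocols=protocols,
        template_version=cfg["template_version"],
    )


def write_geo_xlsx(geo: GeoMetadata, path) -> None:
    """Render the GEO metadata as a submission-style workbook."""
    wb = Workbook()
    ws = wb.active
    ws.title = "Metadata"
    row = 1
    ws.cell(row=row, column=1, value="STUDY")
    row += 1
    for key, value in geo.study.items():
        ws.cell(row=row, column=1, value=key)
        ws.cell(row=row, column=2, value=value)
        row += 1
    row += 1
    ws.cell(row=row, column=1, value="SAMPLES")
    row += 1
    cols = geo.sample_columns
    for j, name in enumerate(cols, start=1):
        ws.cell(row=row, column=j, value=name)
    row += 1
    for sample in geo.samples:
        for j, name in enumerate(cols, start=1):
            ws.cell(row=row, column=j, value=sample.get(name, ""))
        row += 1
    row += 1
    ws.cell(row=row, column=1, value="PROTOCOLS")
    row += 1
    for key, value in geo.protocols.items():
        ws.cell(row=row, column=1, value=key)
        ws.cell(row=row, column=2, value=value)
        row += 1
    _save_deterministic(wb, Path(path))


# ---------------------------------------------------------------------------
# OWL / RDF export
# ---------------------------------------------------------------------------


def default_ontology_path() -> Path:
    """The synthetic Metadatasheet ontology shipped with the package."""
    return Path(
        str(
            _resources.files("metasheet.data").joinpath(
                "metasheet_ontology_synthetic.owl"
            )
        )
    )


def _property_index(ontology: Graph) -> dict[str, URIRef]:
    index: dict[str, URIRef] = {}
    for s, _, label in ontology.triples((None, RDFS.label, None)):
        index[canonical_key(str(label))] = s
    for s in set(ontology.subjects()):
        if isinstance(s, URIRef) and "#" in str(s):
            local = str(s).rsplit("#", 1)[1]
            index.setdefault(canonical_key(local.replace("_", " ")), s)
    return index


def _slug(text: str) -> str:
    return re.sub(r"[^A-Za-z0-9_-]+", "_", canonicalize(text)) or "x"


def export_xml(
    sheets: Sequence[Metadatasheet],
    ontology: Optional[Graph | str | Path] = None,
) -> Graph:
    """Export sheets as OWL individuals in an RDF graph.

    One individual per sheet (class ``Metadatasheet``) and one per measured
    unit (class ``MeasuredUnit``), with property assertions for every filled
    key.  Keys without an ontology property mapping are emitted under the
    generic ``attribute`` annotation property with a warning.  Values that
    embed a CURIE (``PREFIX:digits``) additionally assert an ``ontologyTerm``
    link to the term IRI.  Serialize with ``graph.serialize(format='xml')``
    (RDF/XML, an OWL 2 exchange syntax) or ``'pretty-xml'``.
    """
    if ontology is None:
        ontology = default_ontology_path()
    if not isinstance(ontology, Graph):
        path = Path(ontology)
        ontology = Graph().parse(path)
    props = _property_index(ontology)
    generic = MS["attribute"]

    g = Graph()
    g.bind("ms", MS)
    g.bind("msid", SHEETNS)
    g += ontology  # schema travels with the individuals

    def prop_for(key: str) -> URIRef:
        hit = props.get(canonical_key(key))
        if hit is not None:
            return hit
        warnings.warn(
            f"key {key!r} has no ontology property; emitted as generic "
            "attribute",
            stacklevel=3,
        )
        return generic

    def assert_value(subject: URIRef, key: str, value: str) -> None:
        value = canonicalize(value)
        if not value:
            return
        g.add((subject, prop_for(key), Literal(value)))
        m = _CURIE_RE.search(value)
        if m:
            prefix, digits = m.groups()
            g.add(
                (
                    subject,
                    MS["ontologyTerm"],
                    URIRef(
                        f"http://purl.obolibrary.org/obo/{prefix}_{digits}"
                    ),
                )
            )

    for idx, sheet in enumerate(sheets):
        sid = sheet.uid or f"sheet-{idx + 1}"
        subject = SHEETNS[_slug(sid)]
        g.add((subject, RDF.type, MS["Metadatasheet"]))
        gen = sheet.planning.general
        assert_value(subject, "project title", gen.project_title)
        assert_value(subject, "name", gen.name)
        assert_value(subject, "affiliation", gen.affiliation)
        assert_value(subject, "email", gen.email)
        es = sheet.planning.experimental_system
        if es is not None:
            assert_value(subject, "experimental system", es.system)
            for key, value in es.dependent_values.items():
                assert_value(subject, key, value)
        if sheet.conduction.measurement is not None:
            assert_value(
                subject,
                "measurement type",
                sheet.conduction.measurement.measurement_type,
            )
            for key, value in sheet.conduction.measurement.dependent_values.items():
                assert_value(subject, key, value)
        if sheet.matching is None:
            continue
        for unit, ancestor in _deepest_columns(sheet.matching):
            uid = unit.personal_id or f"{sid}-unit"
            usubj = SHEETNS[f"{_slug(sid)}/{_slug(uid)}"]
            g.add((usubj, RDF.type, MS["MeasuredUnit"]))
            g.add((subject, MS["hasMeasuredUnit"], usubj))
            g.add((usubj, MS["partOfSheet"], subject))
            assert_value(usubj, "personal_ID", unit.personal_id)
            assert_value(usubj, "final_group", ancestor.final_group)
            assert_value(usubj, "replicate", str(unit.replicate))
            for cat, label in ancestor.assignment.items():
                assert_value(usubj, cat, label)
            for key, value in unit.values.items():
                assert_value(usubj, key, value)
            if getattr(unit, "instance", None):
                assert_value(usubj, "instance", unit.instance)
    return g


# ---------------------------------------------------------------------------
# Experiment bundle (SummarizedExperiment-shaped)
# ---------------------------------------------------------------------------


@dataclass
class ExperimentBundle:
    """Assay matrix + column metadata + sheet metadata, aligned on the
    personal_ID order of the measurement-matching table."""

    assay: pd.DataFrame
    coldata: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if list(self.assay.columns) != list(self.coldata.index):
            raise AlignmentError(
                "assay column order does not match column-metadata row order"
            )


def coldata_frame(table: IDTable) -> pd.DataFrame:
    """The measurement-matching section as a per-measured-unit table
    (deepest-level columns, main-table metadata inherited)."""
    rows = []
    for unit, ancestor in _deepest_columns(table):
        row: dict[str, str] = {
            "personal_ID": unit.personal_id,
            "final_group": ancestor.final_group,
        }
        row.update(ancestor.assignment)
        row["replicate"] = str(unit.replicate)
        for key in table.dynamic_keys:
            row[key] = unit.values.get(key, "") or ancestor.values.get(key, "")
        if unit is not ancestor:
            row["division instance"] = unit.instance
            row["parent_ID"] = _parent_id(table, unit)
        rows.append(row)
    frame = pd.DataFrame(rows).astype(str)
    return frame.set_index("personal_ID")


def _parent_id(table: IDTable, unit) -> str:
    if table.subsubsample is not None and unit in table.subsubsample.columns:
        return table.subsample.columns[unit.parent_index].personal_id
    if table.subsample is not None and unit in table.subsample.columns:
        return table.columns[unit.parent_index].personal_id
    return ""


def _read_matrix(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else None
    frame = pd.read_csv(
        path, sep=sep, engine="python" if sep is None else "c", index_col=0
    )
    frame.columns = [str(c) for c in frame.columns]
    return frame


def _sheet_metadata(sheet: Metadatasheet) -> dict:
    con = sheet.conduction
    es = sheet.planning.experimental_system
    return {
        "uid": sheet.uid,
        "planning": {
            "name": sheet.planning.general.name,
            "affiliation": sheet.planning.general.affiliation,
            "email": sheet.planning.general.email,
            "project title": sheet.planning.general.project_title,
            "experimental system": es.system if es else "",
            **(dict(es.dependent_values) if es else {}),
            "comparison groups": {
                grp.category.value: [i.label for i in grp.instances]
                for grp in sheet.planning.comparison_groups
            },
        },
        "conduction": {
            "final groups": {
                fg.label: fg.n_replicates for fg in con.final_groups
            },
            "covariates": {
                c.name: {
                    "unit": c.unit,
                    "role": c.role.value,
                    "value": c.constant_value,
                }
                for c in con.covariates
            },
            "measurement type": (
                con.measurement.measurement_type if con.measurement else ""
            ),
            **(dict(con.measurement.dependent_values) if con.measurement else {}),
            "preparation protocol": (
                con.preparation.protocol if con.preparation else ""
            ),
            "availability": (
                con.linkage.availability.value if con.linkage else ""
            ),
            "linkage mode": con.linkage.mode.value if con.linkage else "",
        },
    }


def to_experiment_bundle(sheet: Metadatasheet, root) -> ExperimentBundle:
    """Assemble the experiment bundle from a completed bulk-omics sheet.

    The measurement type must resolve (via :data:`BULK_ALIASES`) to one of
    bulk-transcriptomics, bulk-metabolomics or bulk-lipidomics; anything else
    (e.g. FACS) is refused.  The assay matrix is located through the
    DataFiles-Linkage segment with the sheet's directory as root; when the
    named single file is absent, candidate files with the same extension are
    returned in a :class:`ClarificationError`.
    """
    root = Path(root)
    con = sheet.conduction
    if con.measurement is None:
        raise ExportError("sheet has no measurement segment")
    family = BULK_ALIASES.get(canonical_key(con.measurement.measurement_type))
    if family is None:
        allowed = sorted(set(BULK_ALIASES.values()))
        raise ExportError(
            f"measurement type {con.measurement.measurement_type!r} is not "
            f"convertible; supported families: {', '.join(allowed)}"
        )
    if sheet.matching is None or con.linkage is None:
        raise ExportError(
            "sheet needs a completed DataFiles-Linkage segment and "
            "measurement-matching table"
        )

    try:
        resolved, _ = resolve_datafiles(sheet.matching, con.linkage, root)
    except ResolutionError as exc:
        if con.linkage.mode is LinkageMode.single_file_for_all:
            ext = Path(con.linkage.comment).suffix or ".csv"
            candidates = sorted(
                p.relative_to(root)
                for p in root.rglob(f"*{ext}")
                if p.is_file()
            )
            raise ClarificationError(
                f"{exc}; candidate files by extension {ext!r}: "
                f"{', '.join(map(str, candidates)) or '(none)'}",
                candidates,
            ) from exc
        raise

    ids = [i for i in sheet.matching.deepest_ids()]
    if con.linkage.mode is LinkageMode.single_file_for_all:
        matrix = _read_matrix(root / resolved[ids[0]][0])
        missing = [i for i in ids if i not in matrix.columns]
        if missing:
            raise AlignmentError(
                f"matrix {con.linkage.comment!r} lacks columns for IDs: "
                f"{', '.join(missing)}"
            )
        assay = matrix.loc[:, ids]
    else:
        pieces = []
        for pid in ids:
            files = resolved[pid]
            frame = _read_matrix(root / files[0])
            col = frame.iloc[:, 0]
            col.name = pid
            pieces.append(col)
        assay = pd.concat(pieces, axis=1)
        if assay.isna().any().any():
            raise AlignmentError(
                "per-ID files do not share a common feature index"
            )

    coldata = coldata_frame(sheet.matching)
    return ExperimentBundle(
        assay=assay, coldata=coldata, metadata=_sheet_metadata(sheet)
    )


def write_bundle(bundle: ExperimentBundle, path) -> list[Path]:
    """Write the bundle as a directory of plain files: assay.tsv,
    coldata.tsv, metadata.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    assay_path = path / "assay.tsv"
    coldata_path = path / "coldata.tsv"
    meta_path = path / "metadata.json"
    bundle.assay.to_csv(assay_path, sep="\t", index_label="feature")
    bundle.coldata.to_csv(coldata_path, sep="\t", index_label="personal_ID")
    meta_path.write_text(json.dumps(bundle.metadata, indent=2))
    return [assay_path, coldata_path, meta_path]


def read_bundle(path) -> ExperimentBundle:
    path = Path(path)
    assay = pd.read_csv(path / "assay.tsv", sep="\t", index_col=0)
    assay.columns = [str(c) for c in assay.columns]
    coldata = pd.read_csv(
        path / "coldata.tsv", sep="\t", index_col=0, dtype=str, keep_default_na=False
    )
    metadata = json.loads((path / "metadata.json").read_text())
    return ExperimentBundle(assay=assay, coldata=coldata, metadata=metadata)
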