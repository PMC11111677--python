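"""Read and write the Metadatasheet workbook layout (XLSX).

A workbook carries the sheets ``Input`` (the Metadatasheet itself),
``Validation`` (controlled vocabulary, three header rows: validation type,
help text, key), optional ``Validation_[Group]`` subsets, and
``dependentFields`` (two header rows: category, instance; dependent keys
enumerated below).  The hidden ``ResetSheet`` of Workbook-produced files is
ignored on read and never written.

Grid dialect of the ``Input`` sheet: keys occupy column A, values start at
column B; tabular segments extend column-wise per instance/sample.  Section
headers are written as ``=== PLANNING ===`` and segment headers as
``-- General --`` (bold, for the human reader); the marker strings are the
canonical recognizer so that style-stripped files still parse.

The reader is total: a workbook yields either a fatal :class:`LayoutError`
(missing sheets, unknown validation type) or a possibly issue-laden partial
model — segment-level problems become :class:`ValidationIssue` entries, not
exceptions.
"""

from __future__ import annotations

import datetime as _dt
import io
import re
import uuid
import zipfile
from pathlib import Path
from typing import Optional, Sequence

from openpyxl import Workbook, load_workbook
from openpyxl.styles import Font
from pydantic import ValidationError

from .model import (
    Availability,
    ComparisonGroup,
    Conduction,
    CovariateRole,
    CovariateSpec,
    DataFileLinkage,
    DependentFieldRegistry,
    DivisionInstance,
    DivisionLevel,
    ExperimentalSystem,
    FinalGroup,
    GeneralInfo,
    GroupCategory,
    GroupInstance,
    IDColumn,
    IDTable,
    LayoutError,
    LinkageMode,
    MeasurementSpec,
    Metadatasheet,
    Planning,
    PreparationSpec,
    RegistryCategory,
    RegistryEntry,
    SubColumn,
    SubTable,
    TimelineKind,
    TimelineSpec,
    TimelineStep,
    ValidationIssue,
    VocabEntry,
    Vocabulary,
    VType,
    canonical_key,
    canonicalize,
    issue,
)

__all__ = [
    "ParseResult",
    "read_vocabulary",
    "read_dependent_fields",
    "read_metadatasheet",
    "write_metadatasheet",
    "write_vocabulary_workbook",
]

SHEET_INPUT = "Input"
SHEET_VALIDATION = "Validation"
SHEET_DEPENDENT = "dependentFields"
GROUP_SHEET_PREFIX = "Validation_"
RESET_SHEET = "ResetSheet"

_SECTION_RE = re.compile(r"^\s*=+\s*(.+?)\s*=+\s*$")
_SEGMENT_RE = re.compile(r"^\s*--\s*(.+?)\s*--\s*$")

_VTYPE_TOKENS = {
    "freetext": VType.freetext,
    "date": VType.date,
    "dropdown": VType.dropdown,
    "dropdown_m": VType.dropdown_multi,
}
_VTYPE_OUT = {
    VType.freetext: "freetext",
    VType.date: "date",
    VType.dropdown: "DropDown",
    VType.dropdown_multi: "DropDown_M",
}
_CATEGORY_TOKENS = {
    "experimental system": RegistryCategory.experimental_system,
    "measurement type": RegistryCategory.measurement_type,
}
_CATEGORY_OUT = {
    RegistryCategory.experimental_system: "experimental system",
    RegistryCategory.measurement_type: "measurement type",
}
_MODE_OUT = {
    LinkageMode.id_in_filename: "ID contained in filename",
    LinkageMode.single_file_for_all: "single file for all",
    LinkageMode.changes: "CHANGES",
}

#: Fixed timestamp used for byte-deterministic workbook output.
_FIXED_STAMP = _dt.datetime(2024, 1, 1, 0, 0, 0)


def _txt(value) -> str:
    """Normalize an openpyxl cell value to the string dialect of the model."""
    if value is None:
        return ""
    if isinstance(value, str):
        return value
    if isinstance(value, bool):
        return "yes" if value else "no"
    if isinstance(value, _dt.datetime):
        return value.date().isoformat() if not value.time() else value.isoformat()
    if isinstance(value, _dt.date):
        return value.isoformat()
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    return str(value)


def _yesno(flag: bool) -> str:
    return "yes" if flag else "no"


def _parse_yesno(text: str) -> bool:
    return canonical_key(text) in {"yes", "y", "true", "1"}


# ---------------------------------------------------------------------------
# Validation / dependentFields grids
# ---------------------------------------------------------------------------


def _columns(grid: Sequence[Sequence[str]]) -> list[list[str]]:
    """Transpose a row grid into trimmed columns."""
    width = max((len(r) for r in grid), default=0)
    cols = []
    for j in range(width):
        col = [canonicalize(r[j]) if j < len(r) else "" for r in grid]
        while col and not col[-1]:
            col.pop()
        cols.append(col)
    return cols


def read_vocabulary(
    grid: Sequence[Sequence[str]], group_label: Optional[str] = None
) -> Vocabulary:
    """Parse a ``Validation`` grid: per non-empty column the three header
    rows (validation type, help text, key) then the allowed values.

    Raises :class:`LayoutError` for an unknown validation-type token, naming
    the offending column.
    """
    entries: dict[str, VocabEntry] = {}
    for j, col in enumerate(_columns(grid)):
        if not any(col):
            continue
        vtoken = col[0] if len(col) > 0 else ""
        help_text = col[1] if len(col) > 1 else ""
        key = col[2] if len(col) > 2 else ""
        vtype = _VTYPE_TOKENS.get(canonical_key(vtoken))
        if vtype is None:
            raise LayoutError(
                f"Validation column {j + 1}: unknown validation type "
                f"{vtoken!r} (expected freetext, date, DropDown or DropDown_M)"
            )
        if not key:
            raise LayoutError(f"Validation column {j + 1}: missing key in row 3")
        values = tuple(v for v in col[3:] if v)
        if vtype in (VType.freetext, VType.date):
            values = ()  # trailing cells are ignored for unconstrained types
        try:
            entry = VocabEntry(
                key=key, vtype=vtype, help=help_text, allowed_values=values
            )
        except ValidationError as exc:
            raise LayoutError(f"Validation column {j + 1} ({key!r}): {exc}") from exc
        if key in {k for k in entries} or any(
            canonical_key(k) == canonical_key(key) for k in entries
        ):
            raise LayoutError(
                f"Validation column {j + 1}: duplicate key {key!r}"
            )
        entries[key] = entry
    return Vocabulary(entries=entries, group_label=group_label)


def read_dependent_fields(
    grid: Sequence[Sequence[str]]
) -> DependentFieldRegistry:
    """Parse a ``dependentFields`` grid: per column the two header rows
    (category, instance) then the ordered dependent keys."""
    entries: list[RegistryEntry] = []
    seen: set[tuple[RegistryCategory, str]] = set()
    for j, col in enumerate(_columns(grid)):
        if not any(col):
            continue
        ctoken = col[0] if len(col) > 0 else ""
        instance = col[1] if len(col) > 1 else ""
        category = _CATEGORY_TOKENS.get(canonical_key(ctoken))
        if category is None:
            raise LayoutError(
                f"dependentFields column {j + 1}: unknown category "
                f"{ctoken!r} (expected 'experimental system' or "
                "'measurement type')"
            )
        if not instance:
            raise LayoutError(
                f"dependentFields column {j + 1}: missing instance in row 2"
            )
        ident = (category, canonical_key(instance))
        if ident in seen:
            raise LayoutError(
                f"dependentFields column {j + 1}: duplicate entry for "
                f"({ctoken}, {instance})"
            )
        seen.add(ident)
        entries.append(
            RegistryEntry(
                category=category,
                instance=instance,
                keys=tuple(k for k in col[2:] if k),
            )
        )
    return DependentFieldRegistry(entries=tuple(entries))


# ---------------------------------------------------------------------------
# Input sheet: writing
# ---------------------------------------------------------------------------


class _SheetWriter:
    def __init__(self, ws):
        self.ws = ws
        self.row = 1

    def put(self, label: str, *values: str, bold: bool = False) -> None:
        cells = [label, *values]
        for j, v in enumerate(cells, start=1):
            if v == "" and j > 1:
                continue
            c = self.ws.cell(row=self.row, column=j, value=v)
            if bold and j == 1:
                c.font = Font(bold=True)
        self.row += 1

    def blank(self) -> None:
        self.row += 1

    def section(self, name: str) -> None:
        self.put(f"=== {name} ===", bold=True)

    def segment(self, name: str) -> None:
        self.put(f"-- {name} --", bold=True)


def _write_input(ws, sheet: Metadatasheet) -> None:
    w = _SheetWriter(ws)
    w.put("Metadatasheet UID", sheet.uid or "")
    w.blank()

    w.section("PLANNING")
    g = sheet.planning.general
    w.segment("General")
    w.put("name", g.name)
    w.put("affiliation", g.affiliation)
    w.put("email", g.email)
    w.put("project title", g.project_title)
    w.put("part of collection?", _yesno(g.in_collection))
    w.put("linked sheet IDs", ";".join(g.linked_sheet_ids))

    es = sheet.planning.experimental_system
    if es is not None:
        w.segment("Experimental System")
        w.put("experimental system", es.system)
        for key, value in es.dependent_values.items():
            w.put(key, value)

    if sheet.planning.comparison_groups:
        w.segment("Comparison Groups")
        for group in sheet.planning.comparison_groups:
            w.put("comparison group", group.category.value)
            w.put("instance", *[i.label for i in group.instances])
            detail_keys: list[str] = []
            for inst in group.instances:
                for k in inst.details:
                    if k not in detail_keys:
                        detail_keys.append(k)
            for k in detail_keys:
                w.put(k, *[i.details.get(k, "") for i in group.instances])

    w.blank()
    w.section("CONDUCTION")
    con = sheet.conduction
    if con.final_groups:
        w.segment("Final Groups")
        w.put("final group", *[fg.label for fg in con.final_groups])
        categories = list(con.final_groups[0].assignment)
        for cat in categories:
            w.put(cat, *[fg.assignment.get(cat, "") for fg in con.final_groups])
        w.put(
            "replicates",
            *[
                "" if fg.n_replicates is None else str(fg.n_replicates)
                for fg in con.final_groups
            ],
        )
    if con.covariates:
        w.segment("Covariates/Constants")
        w.put("name", *[c.name for c in con.covariates])
        w.put("unit", *[c.unit for c in con.covariates])
        w.put("role", *[c.role.value for c in con.covariates])
        w.put("value", *[c.constant_value or "" for c in con.covariates])
    if con.timeline is not None:
        t = con.timeline
        w.segment("Time-Dependence-Timeline")
        w.put("interrupted?", _yesno(t.interrupted))
        if t.interrupted:
            w.put("type", t.kind.value)
            w.put("enriched group", t.enriched_group.value)
            w.put("time unit", t.time_unit)
            w.put("time", *[s.time for s in t.steps])
            w.put("event", *[s.event for s in t.steps])
    if con.preparation is not None:
        p = con.preparation
        w.segment("Preparation")
        w.put("protocol", p.protocol)
        for i, level in enumerate(p.divisions, start=1):
            w.put("division", str(i))
            w.put("n per parent", str(level.n_per_parent))
            w.put("division instance", *[d.label for d in level.instances])
            w.put("division protocol", *[d.protocol for d in level.instances])
            w.put(
                "division replicates",
                *[str(d.n_replicates) for d in level.instances],
            )
    if con.measurement is not None:
        w.segment("Measurement")
        w.put("measurement type", con.measurement.measurement_type)
        for key, value in con.measurement.dependent_values.items():
            w.put(key, value)
    if con.linkage is not None:
        lk = con.linkage
        w.segment("DataFiles-Linkage")
        w.put("availability", lk.availability.value)
        w.put("linkage mode", _MODE_OUT[lk.mode])
        w.put("comment", lk.comment)
        w.put("processing procedure", lk.processing_procedure or "")

    if sheet.matching is not None:
        table = sheet.matching
        w.blank()
        w.section("MEASUREMENT-MATCHING")
        w.segment("ID Table")
        cols = table.columns
        w.put("personal_ID", *[c.personal_id for c in cols])
        w.put("final_group", *[c.final_group for c in cols])
        categories = list(cols[0].assignment) if cols else []
        for cat in categories:
            w.put(cat, *[c.assignment.get(cat, "") for c in cols])
        w.put("replicate", *[str(c.replicate) for c in cols])
        for key in table.dynamic_keys:
            w.put(key, *[c.values.get(key, "") for c in cols])
        w.put("subsamples?", *[_yesno(table.subsamples_present)] * len(cols))
        w.put(
            "subsubsamples?", *[_yesno(table.subsubsamples_present)] * len(cols)
        )
        for name, sub, parents in (
            ("Subsamples", table.subsample, table.columns),
            (
                "Subsubsamples",
                table.subsubsample,
                table.subsample.columns if table.subsample else (),
            ),
        ):
            if sub is None:
                continue
            w.segment(name)
            w.put(
                "parent_column",
                *[f"#{c.parent_index + 1}" for c in sub.columns],
            )
            w.put(
                "parent_ID",
                *[parents[c.parent_index].personal_id for c in sub.columns],
            )
            w.put("instance", *[c.instance for c in sub.columns])
            w.put("replicate", *[str(c.replicate) for c in sub.columns])
            w.put("personal_ID", *[c.personal_id for c in sub.columns])
            value_keys: list[str] = []
            for c in sub.columns:
                for k in c.values:
                    if k not in value_keys:
                        value_keys.append(k)
            for k in value_keys:
                w.put(k, *[c.values.get(k, "") for c in sub.columns])


def _write_vocab_sheet(ws, vocab: Vocabulary) -> None:
    for j, entry in enumerate(vocab.entries.values(), start=1):
        ws.cell(row=1, column=j, value=_VTYPE_OUT[entry.vtype])
        ws.cell(row=2, column=j, value=entry.help)
        ws.cell(row=3, column=j, value=entry.key)
        for i, value in enumerate(entry.allowed_values, start=4):
            ws.cell(row=i, column=j, value=value)


def _write_registry_sheet(ws, registry: DependentFieldRegistry) -> None:
    for j, entry in enumerate(registry.entries, start=1):
        ws.cell(row=1, column=j, value=_CATEGORY_OUT[entry.category])
        ws.cell(row=2, column=j, value=entry.instance)
        for i, key in enumerate(entry.keys, start=3):
            ws.cell(row=i, column=j, value=key)


_STAMP_RE = re.compile(
    rb"(<dcterms:(?:created|modified)[^>]*>)[^<]*(</dcterms:)"
)


def _save_deterministic(wb: Workbook, path: Path) -> None:
    """Save a workbook with fixed document properties and zip timestamps so
    identical content yields identical bytes."""
    wb.properties.created = _FIXED_STAMP
    buf = io.BytesIO()
    wb.save(buf)
    buf.seek(0)
    stamp = _FIXED_STAMP.strftime("%Y-%m-%dT%H:%M:%SZ").encode()
    out = io.BytesIO()
    with zipfile.ZipFile(buf) as src, zipfile.ZipFile(
        out, "w", zipfile.ZIP_DEFLATED
    ) as dst:
        for name in src.namelist():
            data = src.read(name)
            if name == "docProps/core.xml":
                # openpyxl stamps dcterms:modified with the wall clock on save
                data = _STAMP_RE.sub(rb"\g<1>" + stamp + rb"\g<2>", data)
            info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            dst.writestr(info, data)
    Path(path).write_bytes(out.getvalue())


def write_metadatasheet(
    sheet: Metadatasheet,
    vocab: Vocabulary,
    registry: DependentFieldRegistry,
    path,
    group_vocabs: Sequence[Vocabulary] = (),
) -> Metadatasheet:
    """Write a macro-free XLSX workbook; returns the sheet actually written.

    A unique identifier (UUID4) is assigned automatically on export when the
    sheet carries none; re-exporting a sheet keeps its UID.  Round-trip
    guarantee: ``read_metadatasheet(write_metadatasheet(s)).sheet == s``
    (with the UID filled in).
    """
    if sheet.uid is None:
        sheet = sheet.model_copy(update={"uid": str(uuid.uuid4())})
    wb = Workbook()
    ws = wb.active
    ws.title = SHEET_INPUT
    _write_input(ws, sheet)
    _write_vocab_sheet(wb.create_sheet(SHEET_VALIDATION), vocab)
    for gv in group_vocabs:
        label = gv.group_label or "Group"
        _write_vocab_sheet(wb.create_sheet(f"{GROUP_SHEET_PREFIX}{label}"), gv)
    _write_registry_sheet(wb.create_sheet(SHEET_DEPENDENT), registry)
    _save_deterministic(wb, Path(path))
    return sheet


def write_vocabulary_workbook(vocab: Vocabulary, path) -> None:
    """Write a workbook holding only a ``Validation`` sheet (merge output)."""
    wb = Workbook()
    ws = wb.active
    ws.title = SHEET_VALIDATION
    _write_vocab_sheet(ws, vocab)
    _save_deterministic(wb, Path(path))


# ---------------------------------------------------------------------------
# Input sheet: reading
# ---------------------------------------------------------------------------


class ParseResult:
    """Outcome of :func:`read_metadatasheet`: a (possibly partial) model plus
    the workbook's resources and any parse issues."""

    def __init__(
        self,
        sheet: Metadatasheet,
        vocabulary: Vocabulary,
        registry: DependentFieldRegistry,
        issues: Sequence[ValidationIssue] = (),
        group_vocabularies: Optional[dict[str, Vocabulary]] = None,
    ):
        self.sheet = sheet
        self.vocabulary = vocabulary
        self.registry = registry
        self.issues = tuple(issues)
        self.group_vocabularies = dict(group_vocabularies or {})

    def __iter__(self):
        return iter((self.sheet, self.vocabulary, self.registry))


def _grid_of(ws) -> list[list[str]]:
    return [[_txt(v) for v in row] for row in ws.iter_rows(values_only=True)]


class _Block:
    """Rows of one segment, with key:value and table helpers."""

    def __init__(self, rows: list[list[str]]):
        self.rows = rows

    def value(self, key: str) -> str:
        for row in self.rows:
            if row and canonical_key(row[0]) == canonical_key(key):
                return canonicalize(row[1]) if len(row) > 1 else ""
        return ""

    def row_cells(self, key: str) -> Optional[list[str]]:
        for row in self.rows:
            if row and canonical_key(row[0]) == canonical_key(key):
                cells = [canonicalize(c) for c in row[1:]]
                while cells and not cells[-1]:
                    cells.pop()
                return cells
        return None

    def kv_pairs(self, skip: set[str]) -> list[tuple[str, str]]:
        out = []
        for row in self.rows:
            if not row or not canonicalize(row[0]):
                continue
            key = canonicalize(row[0])
            if canonical_key(key) in skip:
                continue
            out.append((key, canonicalize(row[1]) if len(row) > 1 else ""))
        return out

    def labelled_rows(self) -> list[tuple[str, list[str]]]:
        out = []
        for row in self.rows:
            if not row or not canonicalize(row[0]):
                continue
            cells = [canonicalize(c) for c in row[1:]]
            out.append((canonicalize(row[0]), cells))
        return out


def _split_segments(
    grid: list[list[str]]
) -> tuple[dict[str, _Block], str]:
    """Map canonical segment name -> block of rows; also return the UID."""
    uid = ""
    segments: dict[str, _Block] = {}
    current: Optional[str] = None
    rows: list[list[str]] = []

    def _flush():
        nonlocal rows
        if current is not None:
            segments[current] = _Block(rows)
        rows = []

    for row in grid:
        head = canonicalize(row[0]) if row else ""
        if canonical_key(head) == "metadatasheet uid":
            uid = canonicalize(row[1]) if len(row) > 1 else ""
            continue
        m = _SECTION_RE.match(head)
        if m:
            _flush()
            current = None
            continue
        m = _SEGMENT_RE.match(head)
        if m:
            _flush()
            current = canonical_key(m.group(1))
            continue
        if current is not None:
            rows.append(list(row))
    _flush()
    return segments, uid


def _parse_general(block: _Block) -> GeneralInfo:
    linked = tuple(
        t for t in (canonicalize(x) for x in block.value("linked sheet IDs").split(";")) if t
    )
    in_collection = _parse_yesno(block.value("part of collection?"))
    return GeneralInfo(
        name=block.value("name"),
        affiliation=block.value("affiliation"),
        email=block.value("email"),
        project_title=block.value("project title"),
        in_collection=in_collection or bool(linked),
        linked_sheet_ids=linked,
    )


def _parse_experimental_system(block: _Block) -> Optional[ExperimentalSystem]:
    system = block.value("experimental system")
    if not system:
        return None
    dep = dict(block.kv_pairs(skip={"experimental system"}))
    return ExperimentalSystem(system=system, dependent_values=dep)


def _parse_comparison_groups(block: _Block) -> tuple[ComparisonGroup, ...]:
    groups: list[ComparisonGroup] = []
    chunks: list[list[tuple[str, list[str]]]] = []
    for label, cells in block.labelled_rows():
        if canonical_key(label) == "comparison group":
            chunks.append([(label, cells)])
        elif chunks:
            chunks[-1].append((label, cells))
    for chunk in chunks:
        category = GroupCategory(canonical_key(chunk[0][1][0]))
        labels: list[str] = []
        detail_rows: list[tuple[str, list[str]]] = []
        for label, cells in chunk[1:]:
            if canonical_key(label) == "instance":
                labels = [c for c in cells if c]
            else:
                detail_rows.append((label, cells))
        instances = []
        for j, lab in enumerate(labels):
            details = {}
            for key, cells in detail_rows:
                val = cells[j] if j < len(cells) else ""
                if val:
                    details[key] = val
            instances.append(GroupInstance(label=lab, details=details))
        groups.append(
            ComparisonGroup(category=category, instances=tuple(instances))
        )
    return tuple(groups)


def _parse_final_groups(block: _Block) -> tuple[FinalGroup, ...]:
    rows = block.labelled_rows()
    labels = block.row_cells("final group") or []
    reps = block.row_cells("replicates") or []
    cat_rows = [
        (label, cells)
        for label, cells in rows
        if canonical_key(label) not in {"final group", "replicates"}
    ]
    out = []
    for j in range(len(labels)):
        assignment = {}
        for cat, cells in cat_rows:
            assignment[canonical_key(cat)] = cells[j] if j < len(cells) else ""
        rep = reps[j] if j < len(reps) else ""
        out.append(
            FinalGroup(
                assignment=assignment,
                n_replicates=int(rep) if rep else None,
            )
        )
    return tuple(out)


def _parse_covariates(block: _Block) -> tuple[CovariateSpec, ...]:
    names = block.row_cells("name") or []
    units = block.row_cells("unit") or []
    roles = block.row_cells("role") or []
    values = block.row_cells("value") or []

    def cell(cells, j):
        return cells[j] if j < len(cells) else ""

    out = []
    for j, name in enumerate(names):
        role = CovariateRole(canonical_key(cell(roles, j)) or "covariate")
        out.append(
            CovariateSpec(
                name=name,
                unit=cell(units, j),
                role=role,
                constant_value=(
                    cell(values, j) if role is CovariateRole.constant else None
                ),
            )
        )
    return tuple(out)


def _parse_timeline(block: _Block) -> Optional[TimelineSpec]:
    interrupted = _parse_yesno(block.value("interrupted?"))
    if not interrupted:
        return TimelineSpec(interrupted=False)
    times = block.row_cells("time") or []
    events = block.row_cells("event") or []
    steps = tuple(
        TimelineStep(time=t, event=events[j] if j < len(events) else "")
        for j, t in enumerate(times)
    )
    return TimelineSpec(
        interrupted=True,
        kind=TimelineKind(canonical_key(block.value("type"))),
        enriched_group=GroupCategory(canonical_key(block.value("enriched group"))),
        time_unit=block.value("time unit"),
        steps=steps,
    )


def _parse_preparation(block: _Block) -> PreparationSpec:
    rows = block.labelled_rows()
    levels: list[DivisionLevel] = []
    current: Optional[dict] = None
    for label, cells in rows:
        ck = canonical_key(label)
        if ck == "division":
            if current:
                levels.append(_division_from(current))
            current = {}
        elif current is not None and ck in {
            "n per parent",
            "division instance",
            "division protocol",
            "division replicates",
        }:
            current[ck] = cells
    if current:
        levels.append(_division_from(current))
    return PreparationSpec(
        protocol=block.value("protocol"), divisions=tuple(levels)
    )


def _division_from(data: dict) -> DivisionLevel:
    labels = [c for c in data.get("division instance", []) if c]
    protos = data.get("division protocol", [])
    reps = data.get("division replicates", [])
    instances = tuple(
        DivisionInstance(
            label=lab,
            protocol=protos[j] if j < len(protos) else "",
            n_replicates=int(reps[j]) if j < len(reps) and reps[j] else 1,
        )
        for j, lab in enumerate(labels)
    )
    npp_cells = [c for c in data.get("n per parent", []) if c]
    n_per_parent = int(npp_cells[0]) if npp_cells else len(instances)
    return DivisionLevel(n_per_parent=n_per_parent, instances=instances)


def _parse_measurement(block: _Block) -> Optional[MeasurementSpec]:
    mtype = block.value("measurement type")
    if not mtype:
        return None
    dep = dict(block.kv_pairs(skip={"measurement type"}))
    return MeasurementSpec(measurement_type=mtype, dependent_values=dep)


def _parse_linkage(block: _Block) -> Optional[DataFileLinkage]:
    avail = block.value("availability")
    mode_token = block.value("linkage mode")
    if not avail and not mode_token:
        return None
    mode: Optional[LinkageMode] = None
    if mode_token == "CHANGES":
        mode = LinkageMode.changes
    else:
        for m, token in _MODE_OUT.items():
            if canonical_key(mode_token) == canonical_key(token):
                mode = m
                break
    if mode is None:
        raise ValueError(f"unknown linkage mode {mode_token!r}")
    return DataFileLinkage(
        availability=Availability(canonical_key(avail)),
        mode=mode,
        comment=block.value("comment"),
        processing_procedure=block.value("processing procedure") or None,
    )


def _parse_id_table(
    block: _Block,
    sub_block: Optional[_Block],
    subsub_block: Optional[_Block],
) -> IDTable:
    rows = block.labelled_rows()
    labels = [canonical_key(l) for l, _ in rows]

    def cells_of(name: str) -> list[str]:
        return block.row_cells(name) or []

    pid = cells_of("personal_ID")
    fgroup = cells_of("final_group")
    reps = cells_of("replicate")
    ncols = max(
        [len(c) for _, c in rows if c] + [0]
    )
    # trim trailing empties consistently: use widest trimmed row
    widths = []
    for _, cells in rows:
        trimmed = list(cells)
        while trimmed and not trimmed[-1]:
            trimmed.pop()
        widths.append(len(trimmed))
    ncols = max(widths + [0])

    try:
        i_rep = labels.index("replicate")
        i_fg = labels.index("final_group")
        i_sub = labels.index("subsamples?")
    except ValueError as exc:
        raise ValueError(f"ID table misses a fixed row: {exc}") from exc
    cat_rows = [(rows[i][0], rows[i][1]) for i in range(i_fg + 1, i_rep)]
    dyn_rows = [(rows[i][0], rows[i][1]) for i in range(i_rep + 1, i_sub)]

    def at(cells, j):
        return canonicalize(cells[j]) if j < len(cells) else ""

    columns = []
    for j in range(ncols):
        columns.append(
            IDColumn(
                personal_id=at(pid, j),
                final_group=at(fgroup, j),
                assignment={
                    canonical_key(cat): at(cells, j) for cat, cells in cat_rows
                },
                replicate=int(at(reps, j)) if at(reps, j) else 1,
                values={key: at(cells, j) for key, cells in dyn_rows},
            )
        )

    def parse_sub(b: Optional[_Block]) -> Optional[SubTable]:
        if b is None:
            return None
        srows = b.labelled_rows()
        parents = b.row_cells("parent_column") or []
        insts = b.row_cells("instance") or []
        sreps = b.row_cells("replicate") or []
        spids = b.row_cells("personal_ID") or []
        fixed = {"parent_column", "parent_id", "instance", "replicate", "personal_id"}
        value_rows = [
            (label, cells)
            for label, cells in srows
            if canonical_key(label) not in fixed
        ]
        n = len(parents)
        cols = []
        for j in range(n):
            ref = at(parents, j)
            if not ref.startswith("#"):
                raise ValueError(
                    f"subtable parent_column {ref!r} is not a #n reference"
                )
            cols.append(
                SubColumn(
                    parent_index=int(ref[1:]) - 1,
                    instance=at(insts, j),
                    replicate=int(at(sreps, j)) if at(sreps, j) else 1,
                    personal_id=at(spids, j),
                    values={k: at(cells, j) for k, cells in value_rows},
                )
            )
        return SubTable(columns=tuple(cols))

    return IDTable(
        columns=tuple(columns),
        dynamic_keys=tuple(key for key, _ in dyn_rows),
        subsample=parse_sub(sub_block),
        subsubsample=parse_sub(subsub_block),
    )


def read_metadatasheet(path) -> ParseResult:
    """Read a Metadatasheet workbook into the typed model.

    Missing ``Input`` sheet is fatal; missing ``Validation`` or
    ``dependentFields`` is fatal with a hint to supply external resources.
    Unparseable segments become issues on a partial parse, never silent
    drops or exception escapes.
    """
    path = Path(path)
    try:
        wb = load_workbook(path, data_only=True)
    except Exception as exc:
        raise LayoutError(f"cannot open workbook {path}: {exc}") from exc
    names = wb.sheetnames
    if SHEET_INPUT not in names:
        raise LayoutError(f"workbook {path.name} has no {SHEET_INPUT!r} sheet")
    for required in (SHEET_VALIDATION, SHEET_DEPENDENT):
        if required not in names:
            raise LayoutError(
                f"workbook {path.name} has no {required!r} sheet; supply the "
                "validation/dependent-field resources alongside the Input "
                "sheet"
            )
    vocab = read_vocabulary(_grid_of(wb[SHEET_VALIDATION]))
    registry = read_dependent_fields(_grid_of(wb[SHEET_DEPENDENT]))
    group_vocabs: dict[str, Vocabulary] = {}
    for name in names:
        if name.startswith(GROUP_SHEET_PREFIX) and name != SHEET_VALIDATION:
            label = name[len(GROUP_SHEET_PREFIX):]
            group_vocabs[label] = read_vocabulary(
                _grid_of(wb[name]), group_label=label
            )

    grid = _grid_of(wb[SHEET_INPUT])
    segments, uid = _split_segments(grid)
    issues: list[ValidationIssue] = []

    def attempt(name: str, fn, default):
        block = segments.get(canonical_key(name))
        if block is None:
            return default
        try:
            return fn(block)
        except (ValueError, ValidationError) as exc:
            issues.append(
                issue(
                    "segment-unparseable",
                    f"segment {name!r} could not be parsed: {exc}",
                    segment=name,
                )
            )
            return default

    general = attempt("General", _parse_general, GeneralInfo())
    es = attempt("Experimental System", _parse_experimental_system, None)
    groups = attempt("Comparison Groups", _parse_comparison_groups, ())
    final_groups = attempt("Final Groups", _parse_final_groups, ())
    covariates = attempt("Covariates/Constants", _parse_covariates, ())
    timeline = attempt("Time-Dependence-Timeline", _parse_timeline, None)
    preparation = attempt("Preparation", _parse_preparation, None)
    measurement = attempt("Measurement", _parse_measurement, None)
    linkage = attempt("DataFiles-Linkage", _parse_linkage, None)

    matching: Optional[IDTable] = None
    if canonical_key("ID Table") in segments:
        try:
            matching = _parse_id_table(
                segments[canonical_key("ID Table")],
                segments.get(canonical_key("Subsamples")),
                segments.get(canonical_key("Subsubsamples")),
            )
        except (ValueError, ValidationError) as exc:
            issues.append(
                issue(
                    "segment-unparseable",
                    f"segment 'ID Table' could not be parsed: {exc}",
                    section="matching",
                    segment="ID Table",
                )
            )

    try:
        sheet = Metadatasheet(
            planning=Planning(
                general=general,
                experimental_system=es,
                comparison_groups=groups,
            ),
            conduction=Conduction(
                final_groups=final_groups,
                covariates=covariates,
                timeline=timeline,
                preparation=preparation,
                measurement=measurement,
                linkage=linkage,
            ),
            matching=matching,
            uid=uid or None,
        )
    except ValidationError as exc:
        issues.append(
            issue("sheet-invalid", f"sheet-level invariant violated: {exc}")
        )
        sheet = Metadatasheet(uid=uid or None)
    return ParseResult(sheet, vocab, registry, issues, group_vocabs)
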