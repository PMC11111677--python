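"""Measurement-Matching machinery: ID-table generation (the Workbook's
second 'generate' button), CHANGES promotion and data-file resolution.

The ID table holds one column per measured unit.  Its column count equals
the sum of replicate counts over the final groups; covariates and any
CHANGES-promoted keys appear as additional per-sample rows.  Sample
divisions declared in the preparation segment expand into subsample and
subsubsample tables whose columns reference their parent one level up; the
measurement IDs belong to the deepest table.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

from .model import (
    CHANGES,
    CovariateRole,
    CovariateSpec,
    DataFileLinkage,
    FinalGroup,
    IDColumn,
    IDTable,
    LinkageMode,
    Metadatasheet,
    PreparationSpec,
    ResolutionError,
    SequentialIntegrityError,
    Severity,
    SubColumn,
    SubTable,
    ValidationIssue,
    issue,
)

__all__ = [
    "collect_promoted_keys",
    "generate_id_table",
    "resolve_datafiles",
    "FILENAME_KEY",
]

#: Name of the dynamic ID-table row created when the DataFiles-Linkage
#: filename is promoted with CHANGES (or mode 'changes' is selected).
FILENAME_KEY = "filename"


def collect_promoted_keys(sheet: Metadatasheet) -> list[str]:
    """Keys of the conduction section whose value is the literal ``CHANGES``
    token, in document order.

    The token is matched case-sensitively (uppercase only) so ordinary
    values are never promoted by accident.  Linkage mode 'changes' promotes
    the filename row by definition.
    """
    promoted: list[str] = []

    def _add(key: str) -> None:
        if key not in promoted:
            promoted.append(key)

    con = sheet.conduction
    for cov in con.covariates:
        if cov.constant_value == CHANGES:
            _add(cov.name)
    if con.preparation is not None and con.preparation.protocol == CHANGES:
        _add("protocol")
    if con.measurement is not None:
        for key, value in con.measurement.dependent_values.items():
            if value == CHANGES:
                _add(key)
    if con.linkage is not None:
        if con.linkage.mode is LinkageMode.changes or con.linkage.comment == CHANGES:
            _add(FILENAME_KEY)
        if con.linkage.processing_procedure == CHANGES:
            _add("processing procedure")
    return promoted


def _expand_subtable(
    n_parents: int, level, promoted: Sequence[str]
) -> SubTable:
    cols = []
    for parent in range(n_parents):
        for inst in level.instances:
            for rep in range(1, inst.n_replicates + 1):
                cols.append(
                    SubColumn(
                        parent_index=parent,
                        instance=inst.label,
                        replicate=rep,
                        values={k: "" for k in promoted},
                    )
                )
    return SubTable(columns=tuple(cols))


def generate_id_table(
    final_groups: Sequence[FinalGroup],
    covariates: Sequence[CovariateSpec] = (),
    promoted_keys: Sequence[str] = (),
    preparation: Optional[PreparationSpec] = None,
) -> IDTable:
    """Generate the measurement-matching table from the conduction section.

    Requires a valid conduction section: final groups must exist and every
    replicate count must be set (sequential integrity).  personal_ID cells
    are left blank for the user; dynamic rows are one per covariate (role
    ``covariate``) plus one per promoted key, also blank.
    """
    if not final_groups:
        raise SequentialIntegrityError(
            "cannot generate the ID table: the conduction section declares "
            "no final groups"
        )
    unset = [fg.label for fg in final_groups if fg.n_replicates is None]
    if unset:
        raise SequentialIntegrityError(
            "cannot generate the ID table: replicate counts unset for final "
            f"group(s) {', '.join(unset)}"
        )

    dynamic: list[str] = [
        c.name for c in covariates if c.role is CovariateRole.covariate
    ]
    for key in promoted_keys:
        if key not in dynamic:
            dynamic.append(key)

    columns = []
    for fg in final_groups:
        for rep in range(1, fg.n_replicates + 1):  # type: ignore[operator]
            columns.append(
                IDColumn(
                    final_group=fg.label,
                    assignment=dict(fg.assignment),
                    replicate=rep,
                    values={k: "" for k in dynamic},
                )
            )

    subsample = subsubsample = None
    divisions = preparation.divisions if preparation is not None else ()
    if len(divisions) >= 1:
        # Promoted per-sample rows follow the measurement to the deepest
        # table, so subtable columns carry them too.
        subsample = _expand_subtable(len(columns), divisions[0], promoted_keys)
    if len(divisions) >= 2:
        subsubsample = _expand_subtable(
            len(subsample.columns), divisions[1], promoted_keys
        )

    return IDTable(
        columns=tuple(columns),
        dynamic_keys=tuple(dynamic),
        subsample=subsample,
        subsubsample=subsubsample,
    )


def _deepest_columns(table: IDTable):
    """(column, main-ancestor IDColumn) pairs of the deepest table."""
    level = table.deepest_level()
    if level == 0:
        return [(c, c) for c in table.columns]
    if level == 1:
        return [
            (c, table.columns[c.parent_index]) for c in table.subsample.columns  # type: ignore[union-attr]
        ]
    out = []
    for c in table.subsubsample.columns:  # type: ignore[union-attr]
        sub = table.subsample.columns[c.parent_index]  # type: ignore[union-attr]
        out.append((c, table.columns[sub.parent_index]))
    return out


def resolve_datafiles(
    table: IDTable,
    linkage: DataFileLinkage,
    root: Path,
) -> tuple[dict[str, list[Path]], list[ValidationIssue]]:
    """Map every measurement personal_ID to its data file path(s).

    The directory holding the Metadatasheet is the root; returned paths are
    relative to it and sorted lexicographically.  Matching for
    ``id_in_filename`` is substring containment against file *basenames*;
    because plain substring matching cannot distinguish IDs where one is a
    prefix of another (S1 vs S10), such collisions are reported as warnings.

    Raises :class:`ResolutionError` for an ID with zero matches or a missing
    single-file/per-sample file.
    """
    root = Path(root)
    pairs = _deepest_columns(table)
    ids = [c.personal_id for c, _ in pairs]
    if any(not i for i in ids):
        raise ResolutionError(
            "cannot resolve data files: the deepest ID table carries blank "
            "personal_ID values"
        )

    warnings_: list[ValidationIssue] = []
    mapping: dict[str, list[Path]] = {}

    if linkage.mode is LinkageMode.single_file_for_all:
        target = root / linkage.comment
        if not target.is_file():
            raise ResolutionError(
                f"missing file: {linkage.comment!r} not found under {root}"
            )
        rel = target.relative_to(root)
        for pid in ids:
            mapping[pid] = [rel]
        return mapping, warnings_

    if linkage.mode is LinkageMode.changes:
        for col, ancestor in pairs:
            fname = col.values.get(FILENAME_KEY, "") or ancestor.values.get(
                FILENAME_KEY, ""
            )
            if not fname.strip():
                raise ResolutionError(
                    f"unresolved ID {col.personal_id!r}: blank filename row "
                    "(mode 'changes')"
                )
            target = root / fname
            if not target.is_file():
                raise ResolutionError(
                    f"missing file: {fname!r} for ID {col.personal_id!r} "
                    f"not found under {root}"
                )
            mapping[col.personal_id] = [target.relative_to(root)]
        return mapping, warnings_

    # id_in_filename: substring scan over basenames below root.
    for a in ids:
        for b in ids:
            if a != b and a in b:
                warnings_.append(
                    issue(
                        "ambiguous-id",
                        f"personal_ID {a!r} is a substring of {b!r}; "
                        "filename matching by substring cannot distinguish "
                        "them",
                        severity=Severity.warning,
                        section="matching",
                        segment="DataFiles-Linkage",
                        key="personal_ID",
                        observed=a,
                    )
                )
    files = sorted(
        (p for p in root.rglob("*") if p.is_file()),
        key=lambda p: str(p.relative_to(root)),
    )
    for pid in ids:
        hits = [p.relative_to(root) for p in files if pid in p.name]
        if not hits:
            raise ResolutionError(
                f"unresolved ID {pid!r}: no file under {root} contains it "
                "in its name"
            )
        mapping[pid] = hits
    return mapping, warnings_
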