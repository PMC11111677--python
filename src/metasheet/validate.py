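"""Validation engine: value-level, segment-level and cross-section checks.

Mirrors the Workbook's highlight-not-fix behaviour: the engine never mutates
or corrects values, it only reports located issues.  Vocabulary and
structural violations are errors; unknown-but-well-formed extra keys and
incomplete (empty) values are warnings, because the standard is explicitly
extensible and sheets are live documents that grow along the data-lifecycle.

Sequential integrity: the conduction section is only checked against a valid
planning section and measurement-matching only against a valid conduction
section; everything downstream of an invalid section is suppressed behind a
single 'blocked by upstream' issue.
"""

from __future__ import annotations

import datetime as _dt
import re
from typing import Optional

from dateutil import parser as _dateparser

from .model import (
    CHANGES,
    CovariateRole,
    DependentFieldRegistry,
    LinkageMode,
    Metadatasheet,
    RegistryCategory,
    Severity,
    ValidationIssue,
    ValidationReport,
    VocabEntry,
    Vocabulary,
    VType,
    canonical_key,
    canonicalize,
    issue,
)
from . import design as _design
from .matching import FILENAME_KEY, collect_promoted_keys

__all__ = [
    "normalize_date",
    "validate_value",
    "validate_sheet",
    "check_subset",
    "merge_vocabularies",
]

#: Excel serial day 1 is 1900-01-01 with the epoch at 1899-12-30 (the
#: classic off-by-two including the phantom 1900 leap day).
_EXCEL_EPOCH = _dt.date(1899, 12, 30)
_SERIAL_RE = re.compile(r"^\d{1,7}(\.0+)?$")


def normalize_date(value: str) -> str:
    """Normalize a date written in any accepted form to ISO 8601.

    Accepted: ISO (2024-05-22), dotted/slashed European forms (22.05.2024,
    22/05/2024), month-name forms, and spreadsheet serial numbers.  Raises
    ``ValueError`` if unparseable.
    """
    text = canonicalize(value)
    if not text:
        raise ValueError("empty date")
    if _SERIAL_RE.match(text):
        serial = int(float(text))
        if not 1 <= serial <= 2958465:  # 9999-12-31
            raise ValueError(f"serial date {serial} out of range")
        return (_EXCEL_EPOCH + _dt.timedelta(days=serial)).isoformat()
    dayfirst = "." in text or ("/" in text and not text.split("/")[0].isalpha())
    parsed = _dateparser.parse(text, dayfirst=dayfirst)
    return parsed.date().isoformat()


def _issues_for(
    entry: VocabEntry,
    value: str,
    *,
    section: str = "",
    segment: str = "",
    column: Optional[int] = None,
) -> list[ValidationIssue]:
    """Core value check against one vocabulary entry."""
    loc = dict(section=section, segment=segment, key=entry.key, column=column)
    text = canonicalize(value)
    if not text:
        return [
            issue(
                "empty-value",
                f"key {entry.key!r} has no value yet",
                severity=Severity.warning,
                observed=value,
                **loc,
            )
        ]
    if entry.vtype is VType.freetext:
        return []
    if entry.vtype is VType.date:
        try:
            normalize_date(text)
            return []
        except ValueError:
            return [
                issue(
                    "bad-date",
                    f"{text!r} is not a recognizable date",
                    observed=value,
                    **loc,
                )
            ]
    if entry.vtype is VType.dropdown:
        if entry.match(text) is None:
            return [
                issue(
                    "off-vocabulary",
                    f"{text!r} is not in the controlled vocabulary for "
                    f"{entry.key!r}",
                    observed=value,
                    **loc,
                )
            ]
        return []
    # dropdown_multi: semicolon-delimited, every token must validate.
    out = []
    for token in text.split(";"):
        token = canonicalize(token)
        if not token:
            continue
        if entry.match(token) is None:
            out.append(
                issue(
                    "off-vocabulary",
                    f"token {token!r} is not in the controlled vocabulary "
                    f"for {entry.key!r}",
                    observed=value,
                    **loc,
                )
            )
    return out


def validate_value(
    key: str, value: str, vocab: Vocabulary
) -> list[ValidationIssue]:
    """Check a single key:value pair against the controlled vocabulary.

    Returns an empty list iff the value satisfies the key's validation type.
    An unknown key yields an ``unknown-key`` warning issue, never an
    exception.
    """
    entry = vocab.get(key)
    if entry is None:
        return [
            issue(
                "unknown-key",
                f"key {key!r} is not in the controlled vocabulary (the "
                "standard is extensible: add it to the validation resources)",
                severity=Severity.warning,
                key=key,
                observed=value,
            )
        ]
    return _issues_for(entry, value)


class _Engine:
    def __init__(
        self,
        sheet: Metadatasheet,
        vocab: Vocabulary,
        registry: DependentFieldRegistry,
        group_vocab: Optional[Vocabulary],
    ):
        self.sheet = sheet
        self.vocab = vocab
        self.registry = registry
        self.group_vocab = group_vocab
        self.issues: list[ValidationIssue] = []

    # -- helpers ----------------------------------------------------------

    def _entry(self, key: str) -> Optional[VocabEntry]:
        if self.group_vocab is not None:
            entry = self.group_vocab.get(key)
            if entry is not None:
                return entry
        return self.vocab.get(key)

    def _check_value(
        self,
        key: str,
        value: str,
        *,
        section: str,
        segment: str,
        column: Optional[int] = None,
        unknown_ok: bool = True,
    ) -> None:
        if value == CHANGES:
            return  # structural promotion token, not a vocabulary value
        entry = self._entry(key)
        if entry is None:
            if unknown_ok:
                self.issues.append(
                    issue(
                        "unknown-key",
                        f"key {key!r} is not in the controlled vocabulary",
                        severity=Severity.warning,
                        section=section,
                        segment=segment,
                        key=key,
                        column=column,
                        observed=value,
                    )
                )
            return
        self.issues.extend(
            _issues_for(
                entry, value, section=section, segment=segment, column=column
            )
        )

    def _check_dependent(
        self,
        category: RegistryCategory,
        instance: str,
        values: dict[str, str],
        *,
        section: str,
        segment: str,
    ) -> None:
        reg = self.registry.get(category, instance)
        if reg is None:
            self.issues.append(
                issue(
                    "unknown-instance",
                    f"{instance!r} has no dependent-key registration for "
                    f"{category.value}; extend the registry to add it",
                    severity=Severity.warning,
                    section=section,
                    segment=segment,
                    key=instance,
                    observed=instance,
                )
            )
        else:
            have = {canonical_key(k) for k in values}
            for key in reg.keys:
                if canonical_key(key) not in have:
                    self.issues.append(
                        issue(
                            "dependent-key-missing",
                            f"dependent key {key!r} (required once "
                            f"{instance!r} is chosen) is absent",
                            section=section,
                            segment=segment,
                            key=key,
                        )
                    )
        for key, value in values.items():
            self._check_value(key, value, section=section, segment=segment)

    # -- sections ---------------------------------------------------------

    def planning(self) -> None:
        p = self.sheet.planning
        for field, label in (
            (p.general.name, "name"),
            (p.general.project_title, "project title"),
        ):
            if not canonicalize(field):
                self.issues.append(
                    issue(
                        "empty-value",
                        f"general key {label!r} has no value yet",
                        severity=Severity.warning,
                        section="planning",
                        segment="General",
                        key=label,
                    )
                )
        if p.experimental_system is not None:
            self._check_value(
                "experimental system",
                p.experimental_system.system,
                section="planning",
                segment="Experimental System",
                unknown_ok=False,
            )
            self._check_dependent(
                RegistryCategory.experimental_system,
                p.experimental_system.system,
                p.experimental_system.dependent_values,
                section="planning",
                segment="Experimental System",
            )
        for group in p.comparison_groups:
            entry = self._entry(group.category.value)
            for col, inst in enumerate(group.instances):
                if entry is not None and entry.vtype in (
                    VType.dropdown,
                    VType.dropdown_multi,
                ):
                    self.issues.extend(
                        _issues_for(
                            entry,
                            inst.label,
                            section="planning",
                            segment="Comparison Groups",
                            column=col,
                        )
                    )
                for key, value in inst.details.items():
                    self._check_value(
                        key,
                        value,
                        section="planning",
                        segment="Comparison Groups",
                        column=col,
                    )

    def planning_valid(self) -> bool:
        return not any(
            i.severity is Severity.error and i.location.section == "planning"
            for i in self.issues
        )

    def planning_complete(self) -> bool:
        p = self.sheet.planning
        return p.experimental_system is not None and bool(p.comparison_groups)

    def conduction(self) -> None:
        con = self.sheet.conduction
        declared = {
            g.category.value: {canonical_key(i.label) for i in g.instances}
            for g in self.sheet.planning.comparison_groups
        }
        for col, fg in enumerate(con.final_groups):
            if set(fg.assignment) != set(declared):
                self.issues.append(
                    issue(
                        "assignment-categories",
                        f"final group {fg.label!r} assigns categories "
                        f"{sorted(fg.assignment)} but the planning section "
                        f"declares {sorted(declared)}",
                        section="conduction",
                        segment="Final Groups",
                        column=col,
                    )
                )
            for cat, label in fg.assignment.items():
                if canonical_key(label) not in declared.get(cat, set()):
                    self.issues.append(
                        issue(
                            "undeclared-instance",
                            f"final group assignment references instance "
                            f"{label!r} which is not declared for "
                            f"comparison group {cat!r}",
                            section="conduction",
                            segment="Final Groups",
                            key=cat,
                            column=col,
                            observed=label,
                        )
                    )
            if fg.n_replicates is None:
                self.issues.append(
                    issue(
                        "replicates-unset",
                        f"final group {fg.label!r} has no replicate count; "
                        "counts are never defaulted",
                        section="conduction",
                        segment="Final Groups",
                        key="replicates",
                        column=col,
                    )
                )
        if con.final_groups and declared:
            expected = 1
            for g in self.sheet.planning.comparison_groups:
                expected *= len(g.instances)
            if len(con.final_groups) != expected:
                self.issues.append(
                    issue(
                        "final-groups-incomplete",
                        f"{len(con.final_groups)} final groups present but "
                        f"the design implies {expected} combinations",
                        severity=Severity.warning,
                        section="conduction",
                        segment="Final Groups",
                    )
                )
        names = [canonical_key(c.name) for c in con.covariates]
        if len(set(names)) != len(names):
            self.issues.append(
                issue(
                    "duplicate-covariate",
                    "covariate/constant names are not unique",
                    section="conduction",
                    segment="Covariates/Constants",
                )
            )
        for col, cov in enumerate(con.covariates):
            if cov.role is CovariateRole.constant and cov.constant_value:
                self._check_value(
                    cov.name,
                    cov.constant_value,
                    section="conduction",
                    segment="Covariates/Constants",
                    column=col,
                )
        self.issues.extend(
            _design.check_timeline(
                con.timeline, self.sheet.planning.comparison_groups
            )
        )
        if con.measurement is not None:
            self._check_value(
                "measurement type",
                con.measurement.measurement_type,
                section="conduction",
                segment="Measurement",
                unknown_ok=False,
            )
            self._check_dependent(
                RegistryCategory.measurement_type,
                con.measurement.measurement_type,
                con.measurement.dependent_values,
                section="conduction",
                segment="Measurement",
            )

    def conduction_valid(self) -> bool:
        return not any(
            i.severity is Severity.error and i.location.section == "conduction"
            for i in self.issues
        )

    def conduction_complete(self) -> bool:
        con = self.sheet.conduction
        return bool(con.final_groups) and all(
            fg.n_replicates is not None for fg in con.final_groups
        )

    def matching(self) -> None:
        table = self.sheet.matching
        con = self.sheet.conduction
        assert table is not None
        expected_cols = sum(fg.n_replicates or 0 for fg in con.final_groups)
        if len(table.columns) != expected_cols:
            self.issues.append(
                issue(
                    "column-count",
                    f"ID table has {len(table.columns)} columns but the "
                    f"final groups imply {expected_cols} (sum of replicates)",
                    section="matching",
                    segment="ID Table",
                )
            )
        declared = {
            g.category.value: {canonical_key(i.label) for i in g.instances}
            for g in self.sheet.planning.comparison_groups
        }
        for colidx, col in enumerate(table.columns):
            for cat, label in col.assignment.items():
                if canonical_key(label) not in declared.get(cat, set()):
                    self.issues.append(
                        issue(
                            "undeclared-instance",
                            f"ID-table column assigns {label!r} to "
                            f"{cat!r}, which is not declared",
                            section="matching",
                            segment="ID Table",
                            key=cat,
                            column=colidx,
                            observed=label,
                        )
                    )
        expected_dynamic = [
            c.name for c in con.covariates if c.role is CovariateRole.covariate
        ]
        for key in collect_promoted_keys(self.sheet):
            if key not in expected_dynamic:
                expected_dynamic.append(key)
        if list(table.dynamic_keys) != expected_dynamic:
            self.issues.append(
                issue(
                    "dynamic-rows-mismatch",
                    f"ID-table dynamic rows {list(table.dynamic_keys)} do not "
                    f"match covariates + promoted keys {expected_dynamic}",
                    section="matching",
                    segment="ID Table",
                )
            )
        n_divisions = (
            len(con.preparation.divisions) if con.preparation is not None else 0
        )
        have_divisions = table.deepest_level()
        if n_divisions != have_divisions:
            self.issues.append(
                issue(
                    "division-tables-mismatch",
                    f"preparation declares {n_divisions} division level(s) "
                    f"but the matching section has {have_divisions} "
                    "subtable level(s)",
                    section="matching",
                    segment="ID Table",
                )
            )
        if (
            con.linkage is not None
            and con.linkage.mode is LinkageMode.changes
            and FILENAME_KEY not in table.dynamic_keys
        ):
            self.issues.append(
                issue(
                    "filename-row-missing",
                    "linkage mode 'changes' requires a promoted filename "
                    "row in the ID table",
                    section="matching",
                    segment="ID Table",
                    key=FILENAME_KEY,
                )
            )
        blank = [i for i in table.deepest_ids() if not i]
        if blank:
            self.issues.append(
                issue(
                    "ids-incomplete",
                    f"{len(blank)} measurement personal_ID value(s) are "
                    "still blank in the deepest table",
                    severity=Severity.warning,
                    section="matching",
                    segment="ID Table",
                    key="personal_ID",
                )
            )


def validate_sheet(
    sheet: Metadatasheet,
    vocab: Vocabulary,
    registry: DependentFieldRegistry,
    group_vocab: Optional[Vocabulary] = None,
) -> ValidationReport:
    """Full-sheet validation: values, dependent-key completeness, model
    invariants and sequential integrity.  All findings are issues; nothing
    raises."""
    eng = _Engine(sheet, vocab, registry, group_vocab)
    if group_vocab is not None:
        eng.issues.extend(check_subset(group_vocab, vocab).issues)
    eng.planning()

    con = sheet.conduction
    conduction_has_content = any(
        (
            con.final_groups,
            con.covariates,
            con.timeline is not None and con.timeline.interrupted,
            con.preparation is not None,
            con.measurement is not None,
            con.linkage is not None,
        )
    )
    if conduction_has_content and not (
        eng.planning_valid() and eng.planning_complete()
    ):
        eng.issues.append(
            issue(
                "blocked-by-upstream",
                "the conduction section cannot be checked: the planning "
                "section is incomplete or invalid",
                severity=Severity.warning,
                section="conduction",
            )
        )
        return ValidationReport(issues=tuple(eng.issues))

    if conduction_has_content:
        eng.conduction()

    if sheet.matching is not None:
        if not (eng.conduction_valid() and eng.conduction_complete()):
            eng.issues.append(
                issue(
                    "blocked-by-upstream",
                    "the measurement-matching section cannot be checked: "
                    "the conduction section is incomplete or invalid",
                    severity=Severity.warning,
                    section="matching",
                )
            )
        else:
            eng.matching()
    return ValidationReport(issues=tuple(eng.issues))


def check_subset(
    group_vocab: Vocabulary, master_vocab: Vocabulary
) -> ValidationReport:
    """Check that a group-specific vocabulary restricts the master one.

    Every group entry must exist in the master with the same validation type
    and (for dropdown types) allowed values contained in the master's.
    """
    issues: list[ValidationIssue] = []
    label = group_vocab.group_label or "group"
    for key, entry in group_vocab.entries.items():
        master = master_vocab.get(key)
        if master is None:
            issues.append(
                issue(
                    "subset-unknown-key",
                    f"group vocabulary {label!r} defines key {key!r} which "
                    "is absent from the master vocabulary",
                    segment="Validation",
                    key=key,
                )
            )
            continue
        if master.vtype is not entry.vtype:
            issues.append(
                issue(
                    "subset-type-mismatch",
                    f"key {key!r}: group type {entry.vtype.value} differs "
                    f"from master type {master.vtype.value}",
                    segment="Validation",
                    key=key,
                )
            )
            continue
        allowed = {canonical_key(v) for v in master.allowed_values}
        extra = [
            v for v in entry.allowed_values if canonical_key(v) not in allowed
        ]
        if extra:
            issues.append(
                issue(
                    "subset-extra-values",
                    f"key {key!r}: group values {extra} are not in the "
                    "master vocabulary (the group-specific validation must "
                    "be a subset of the overall validation)",
                    segment="Validation",
                    key=key,
                    observed=";".join(extra),
                )
            )
    return ValidationReport(issues=tuple(issues))


def merge_vocabularies(
    a: Vocabulary, b: Vocabulary
) -> tuple[Vocabulary, ValidationReport]:
    """Unite two differently extended controlled vocabularies.

    Shared keys with identical validation type union their allowed values
    (``a``'s order first, then ``b``'s novel values); shared keys whose types
    clash are omitted from the merge and reported as conflicts.
    """
    issues: list[ValidationIssue] = []
    merged: dict[str, VocabEntry] = {}
    b_by_canon = {canonical_key(k): e for k, e in b.entries.items()}
    consumed: set[str] = set()
    for key, ea in a.entries.items():
        eb = b_by_canon.get(canonical_key(key))
        if eb is None:
            merged[key] = ea
            continue
        consumed.add(canonical_key(key))
        if ea.vtype is not eb.vtype:
            issues.append(
                issue(
                    "merge-type-conflict",
                    f"key {key!r} is {ea.vtype.value} in one vocabulary and "
                    f"{eb.vtype.value} in the other; omitted from the merge",
                    segment="Validation",
                    key=key,
                )
            )
            continue
        values = list(ea.allowed_values)
        have = {canonical_key(v) for v in values}
        for v in eb.allowed_values:
            if canonical_key(v) not in have:
                values.append(v)
                have.add(canonical_key(v))
        merged[key] = VocabEntry(
            key=ea.key,
            vtype=ea.vtype,
            help=ea.help or eb.help,
            allowed_values=tuple(values),
        )
    for key, eb in b.entries.items():
        if canonical_key(key) not in consumed and canonical_key(key) not in {
            canonical_key(k) for k in merged
        }:
            merged[key] = eb
    return Vocabulary(entries=merged), ValidationReport(issues=tuple(issues))
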