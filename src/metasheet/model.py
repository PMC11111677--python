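"""Typed domain model for the Metadatasheet standard.

A Metadatasheet records the metadata of one experimental design combined
with one measurement type, organised into three sections that mirror the
research data-lifecycle:

* **Planning** — contact/project information, the experimental system with
  its dependent keys, and the comparison groups (the contrasted settings of
  the design, e.g. six diets).
* **Conduction** — the final groups (Cartesian combinations of comparison
  group instances) with replicate counts, covariates/constants, an optional
  interrupted timeline, sample preparation (with up to two levels of sample
  partitioning), the measurement segment, and the data-file linkage.
* **Measurement-Matching** — the ID-specific metadata table that ties every
  measured unit (column) to its measurement data via a unique personal ID.

Everything here is pure data with invariants enforced at construction;
reading/writing the workbook layout lives in :mod:`metasheet.sheet_io` and
all cross-structure checking in :mod:`metasheet.validate`.
"""

from __future__ import annotations

import enum
import re
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "canonicalize",
    "canonical_key",
    "CHANGES",
    "VType",
    "VocabEntry",
    "Vocabulary",
    "RegistryCategory",
    "RegistryEntry",
    "DependentFieldRegistry",
    "GeneralInfo",
    "ExperimentalSystem",
    "GroupCategory",
    "GroupInstance",
    "ComparisonGroup",
    "FinalGroup",
    "CovariateRole",
    "CovariateSpec",
    "TimelineKind",
    "TimelineStep",
    "TimelineSpec",
    "DivisionInstance",
    "DivisionLevel",
    "PreparationSpec",
    "MeasurementSpec",
    "Availability",
    "LinkageMode",
    "DataFileLinkage",
    "IDColumn",
    "SubColumn",
    "SubTable",
    "IDTable",
    "Planning",
    "Conduction",
    "Metadatasheet",
    "Severity",
    "Location",
    "ValidationIssue",
    "ValidationReport",
    "MetasheetError",
    "LayoutError",
    "SequentialIntegrityError",
    "RegistryError",
    "ResolutionError",
    "ExportError",
]

#: Reserved keyword that promotes a key:value pair into a per-sample row of
#: the measurement-matching table.  Matched case-sensitively, uppercase only,
#: so that ordinary values like "changes" are never promoted by accident.
CHANGES = "CHANGES"

_WS = re.compile(r"\s+")


def canonicalize(value: str) -> str:
    """Return the canonical form of a cell value.

    Leading/trailing whitespace is trimmed and internal whitespace runs are
    collapsed to a single space; case is preserved.  Vocabulary comparison is
    case-insensitive *on canonical forms* (see :func:`canonical_key`), but the
    stored spelling is always the vocabulary's canonical one.
    """
    return _WS.sub(" ", str(value).strip())


def canonical_key(value: str) -> str:
    """Case-folded canonical form, the unit of vocabulary comparison."""
    return canonicalize(value).casefold()


class _Base(BaseModel):
    model_config = ConfigDict(extra="forbid")


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class MetasheetError(Exception):
    """Base class for all errors raised by this package."""


class LayoutError(MetasheetError):
    """A workbook grid does not follow the Metadatasheet layout."""


class SequentialIntegrityError(MetasheetError):
    """A generate step was invoked while the preceding section is invalid."""


class RegistryError(MetasheetError):
    """Dependent-field registry lookup or extension failure."""


class ResolutionError(MetasheetError):
    """Data-file linkage could not be resolved (unresolved ID/missing file)."""


class ExportError(MetasheetError):
    """An exporter refused the sheet (e.g. mandatory GEO fields missing)."""


# ---------------------------------------------------------------------------
# Controlled vocabulary
# ---------------------------------------------------------------------------


class VType(str, enum.Enum):
    """Validation type of a key: the form its values must take."""

    freetext = "freetext"
    date = "date"
    dropdown = "dropdown"
    dropdown_multi = "dropdown_multi"


class VocabEntry(_Base):
    """One key of the controlled vocabulary with its input constraint.

    ``allowed_values`` is required exactly for the two dropdown types; for
    multi-select keys a value is a semicolon-delimited list whose every token
    must be an allowed value.
    """

    key: str
    vtype: VType
    help: str = ""
    allowed_values: tuple[str, ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "VocabEntry":
        if not canonicalize(self.key):
            raise ValueError("vocabulary key must be non-empty")
        if self.vtype in (VType.dropdown, VType.dropdown_multi):
            if not self.allowed_values:
                raise ValueError(
                    f"key {self.key!r}: dropdown types require allowed_values"
                )
            canon = [canonical_key(v) for v in self.allowed_values]
            if len(set(canon)) != len(canon):
                raise ValueError(
                    f"key {self.key!r}: allowed_values not unique after "
                    "canonicalization"
                )
        elif self.allowed_values:
            raise ValueError(
                f"key {self.key!r}: allowed_values only permitted for "
                "dropdown types"
            )
        return self

    def match(self, value: str) -> Optional[str]:
        """Canonical stored spelling for ``value``, or None if off-vocabulary."""
        want = canonical_key(value)
        for allowed in self.allowed_values:
            if canonical_key(allowed) == want:
                return allowed
        return None


class Vocabulary(_Base):
    """A controlled vocabulary: mapping key -> :class:`VocabEntry`.

    ``group_label`` names a group-specific subset (the ``Validation_[Group]``
    sheet); such a subset must be a restriction of the master vocabulary,
    which is checked relationally by :func:`metasheet.validate.check_subset`.
    """

    entries: dict[str, VocabEntry] = Field(default_factory=dict)
    group_label: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "Vocabulary":
        canon = [canonical_key(k) for k in self.entries]
        if len(set(canon)) != len(canon):
            raise ValueError("vocabulary keys not unique after canonicalization")
        for key, entry in self.entries.items():
            if canonical_key(key) != canonical_key(entry.key):
                raise ValueError(
                    f"vocabulary mapping key {key!r} != entry key {entry.key!r}"
                )
        return self

    def get(self, key: str) -> Optional[VocabEntry]:
        """Case-insensitive canonical lookup."""
        want = canonical_key(key)
        for k, entry in self.entries.items():
            if canonical_key(k) == want:
                return entry
        return None

    def __contains__(self, key: object) -> bool:
        return isinstance(key, str) and self.get(key) is not None

    def with_entry(self, entry: VocabEntry) -> "Vocabulary":
        """Copy of this vocabulary with ``entry`` added/replaced."""
        entries = dict(self.entries)
        entries[entry.key] = entry
        return Vocabulary(entries=entries, group_label=self.group_label)


# ---------------------------------------------------------------------------
# Dependent-field registry
# ---------------------------------------------------------------------------


class RegistryCategory(str, enum.Enum):
    experimental_system = "experimental_system"
    measurement_type = "measurement_type"


class RegistryEntry(_Base):
    """Ordered dependent keys for one (category, instance), e.g. the keys
    'line' and 'genotype' requested once 'mouse' is chosen."""

    category: RegistryCategory
    instance: str
    keys: tuple[str, ...] = ()


class DependentFieldRegistry(_Base):
    entries: tuple[RegistryEntry, ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "DependentFieldRegistry":
        seen = set()
        for e in self.entries:
            ident = (e.category, canonical_key(e.instance))
            if ident in seen:
                raise ValueError(
                    f"duplicate registry entry for ({e.category.value}, "
                    f"{e.instance!r})"
                )
            seen.add(ident)
        return self

    def get(
        self, category: RegistryCategory, instance: str
    ) -> Optional[RegistryEntry]:
        want = (category, canonical_key(instance))
        for e in self.entries:
            if (e.category, canonical_key(e.instance)) == want:
                return e
        return None


# ---------------------------------------------------------------------------
# Planning section
# ---------------------------------------------------------------------------


class GeneralInfo(_Base):
    """Contact and project information; linked sheet UIDs mark membership in
    a collection of related Metadatasheets."""

    name: str = ""
    affiliation: str = ""
    email: str = ""
    project_title: str = ""
    in_collection: bool = False
    linked_sheet_ids: tuple[str, ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "GeneralInfo":
        if self.linked_sheet_ids and not self.in_collection:
            raise ValueError(
                "linked_sheet_ids require in_collection=True"
            )
        return self


class ExperimentalSystem(_Base):
    """The system under study (mouse, rat, cell-line, ...) plus the values of
    its registry-dependent keys."""

    system: str
    dependent_values: dict[str, str] = Field(default_factory=dict)


class GroupCategory(str, enum.Enum):
    """The contrasting settings a design can compare."""

    diet = "diet"
    treatment = "treatment"
    genotype = "genotype"
    age = "age"
    temperature = "temperature"
    other = "other"


class GroupInstance(_Base):
    label: str
    details: dict[str, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "GroupInstance":
        if not canonicalize(self.label):
            raise ValueError("group instance label must be non-empty")
        return self


class ComparisonGroup(_Base):
    category: GroupCategory
    instances: tuple[GroupInstance, ...]

    @model_validator(mode="after")
    def _check(self) -> "ComparisonGroup":
        if not self.instances:
            raise ValueError(
                f"comparison group {self.category.value!r} needs >=1 instance"
            )
        canon = [canonical_key(i.label) for i in self.instances]
        if len(set(canon)) != len(canon):
            raise ValueError(
                f"comparison group {self.category.value!r}: duplicate "
                "instance labels"
            )
        return self


# ---------------------------------------------------------------------------
# Conduction section
# ---------------------------------------------------------------------------


class FinalGroup(_Base):
    """One element of the Cartesian product of the comparison groups.

    ``assignment`` maps category name -> instance label, one entry per
    declared comparison group, in declaration order.  Replicate counts have
    no default: an unset count is a validation error, never a silent n=1.
    """

    assignment: dict[str, str]
    n_replicates: Optional[int] = Field(default=None, ge=1)

    @property
    def label(self) -> str:
        """Display label: instance labels joined with ' × '."""
        return " × ".join(self.assignment.values())


class CovariateRole(str, enum.Enum):
    constant = "constant"
    covariate = "covariate"


class CovariateSpec(_Base):
    """A constant (value in place) or covariate (per-measurement values live
    in the ID table)."""

    name: str
    unit: str = ""
    role: CovariateRole
    constant_value: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "CovariateSpec":
        if self.role is CovariateRole.constant and self.constant_value is None:
            raise ValueError(f"constant {self.name!r} requires constant_value")
        if self.role is CovariateRole.covariate and self.constant_value is not None:
            raise ValueError(
                f"covariate {self.name!r} must not carry a constant_value; "
                "its values belong in the ID table"
            )
        return self


class TimelineKind(str, enum.Enum):
    continued = "continued"
    discontinued = "discontinued"


class TimelineStep(_Base):
    time: str
    event: str = ""


class TimelineSpec(_Base):
    """Interrupted-timeline enrichment of one comparison group.

    'continued' annotates temporal details (e.g. repeated glucose-tolerance
    tests during a diet setting); 'discontinued' records a mid-course change
    (agent A for 24 h, then agent B).  All sub-fields exist iff interrupted.
    """

    interrupted: bool = False
    kind: Optional[TimelineKind] = None
    enriched_group: Optional[GroupCategory] = None
    time_unit: Optional[str] = None
    steps: tuple[TimelineStep, ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "TimelineSpec":
        if self.interrupted:
            missing = [
                f
                for f in ("kind", "enriched_group", "time_unit")
                if getattr(self, f) is None
            ]
            if missing:
                raise ValueError(
                    f"interrupted timeline requires {', '.join(missing)}"
                )
            if not self.steps:
                raise ValueError("interrupted timeline requires >=1 step")
        else:
            if (
                self.kind is not None
                or self.enriched_group is not None
                or self.time_unit is not None
                or self.steps
            ):
                raise ValueError(
                    "timeline sub-fields only permitted when interrupted"
                )
        return self


class DivisionInstance(_Base):
    label: str
    protocol: str = ""
    n_replicates: int = Field(ge=1)


class DivisionLevel(_Base):
    """One level of sample partitioning (e.g. two cell types isolated from
    each liver); instance count must equal ``n_per_parent``."""

    n_per_parent: int = Field(ge=1)
    instances: tuple[DivisionInstance, ...]

    @model_validator(mode="after")
    def _check(self) -> "DivisionLevel":
        if len(self.instances) != self.n_per_parent:
            raise ValueError(
                f"division declares n_per_parent={self.n_per_parent} but "
                f"lists {len(self.instances)} instances"
            )
        canon = [canonical_key(i.label) for i in self.instances]
        if len(set(canon)) != len(canon):
            raise ValueError("division instance labels not unique")
        return self


class PreparationSpec(_Base):
    """Sample preparation: protocol term or filename, plus up to two levels
    of sample partitioning (subsamples / subsubsamples)."""

    protocol: str = ""
    divisions: tuple[DivisionLevel, ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "PreparationSpec":
        if len(self.divisions) > 2:
            raise ValueError(
                "at most two levels of sample partitioning are supported"
            )
        return self


class MeasurementSpec(_Base):
    measurement_type: str
    dependent_values: dict[str, str] = Field(default_factory=dict)


class Availability(str, enum.Enum):
    raw = "raw"
    processed = "processed"


class LinkageMode(str, enum.Enum):
    id_in_filename = "id_in_filename"
    single_file_for_all = "single_file_for_all"
    changes = "changes"


class DataFileLinkage(_Base):
    """How measurement files are found from a personal ID.

    * ``id_in_filename`` — the ID is a substring of the data file name(s);
    * ``single_file_for_all`` — one file (named in ``comment``) holds all
      measurements;
    * ``changes`` — a per-sample filename row is promoted into the ID table.

    For processed data a processing procedure (term or filename) is required.
    """

    availability: Availability
    mode: LinkageMode
    comment: str = ""
    processing_procedure: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "DataFileLinkage":
        if (
            self.availability is Availability.processed
            and not (self.processing_procedure or "").strip()
        ):
            raise ValueError(
                "processed data requires a processing_procedure"
            )
        if self.mode is LinkageMode.single_file_for_all and not canonicalize(
            self.comment
        ):
            raise ValueError(
                "mode single_file_for_all requires the filename in comment"
            )
        return self


# ---------------------------------------------------------------------------
# Measurement-Matching section
# ---------------------------------------------------------------------------


class IDColumn(_Base):
    """One measured unit (column) of the main ID table."""

    personal_id: str = ""
    final_group: str = ""
    assignment: dict[str, str] = Field(default_factory=dict)
    replicate: int = Field(ge=1)
    values: dict[str, str] = Field(default_factory=dict)


class SubColumn(_Base):
    """One column of a subsample/subsubsample table.

    ``parent_index`` is the structural, 0-based reference to a column one
    level up; the rendered ``parent_ID`` row mirrors that column's personal
    ID once assigned.
    """

    parent_index: int = Field(ge=0)
    instance: str
    replicate: int = Field(ge=1)
    personal_id: str = ""
    values: dict[str, str] = Field(default_factory=dict)


class SubTable(_Base):
    columns: tuple[SubColumn, ...] = ()


class IDTable(_Base):
    """The ID-specific metadata table plus optional division subtables.

    Fixed rows per column: personal_ID, final group label, per-category
    assignment, replicate index, and the yes/no subsample flags; dynamic rows
    (``dynamic_keys``) carry covariates and CHANGES-promoted keys.  The
    measurement IDs belong to the deepest populated table.
    """

    columns: tuple[IDColumn, ...] = ()
    dynamic_keys: tuple[str, ...] = ()
    subsample: Optional[SubTable] = None
    subsubsample: Optional[SubTable] = None

    @model_validator(mode="after")
    def _check(self) -> "IDTable":
        if self.subsubsample is not None and self.subsample is None:
            raise ValueError("subsubsample table requires a subsample table")
        ids = [c.personal_id for c in self.columns if c.personal_id]
        for tbl in (self.subsample, self.subsubsample):
            if tbl is not None:
                ids += [c.personal_id for c in tbl.columns if c.personal_id]
        if len(set(ids)) != len(ids):
            raise ValueError("personal_ID values must be unique across the sheet")
        if self.subsample is not None:
            for c in self.subsample.columns:
                if c.parent_index >= len(self.columns):
                    raise ValueError(
                        f"subsample parent_index {c.parent_index} out of range"
                    )
        if self.subsubsample is not None:
            n_sub = len(self.subsample.columns)  # type: ignore[union-attr]
            for c in self.subsubsample.columns:
                if c.parent_index >= n_sub:
                    raise ValueError(
                        f"subsubsample parent_index {c.parent_index} out of range"
                    )
        return self

    @property
    def subsamples_present(self) -> bool:
        return self.subsample is not None

    @property
    def subsubsamples_present(self) -> bool:
        return self.subsubsample is not None

    def deepest_level(self) -> int:
        """0 = main table, 1 = subsample, 2 = subsubsample."""
        if self.subsubsample is not None:
            return 2
        if self.subsample is not None:
            return 1
        return 0

    def deepest_ids(self) -> tuple[str, ...]:
        """personal_IDs of the deepest populated table (measurement IDs)."""
        level = self.deepest_level()
        if level == 2:
            return tuple(c.personal_id for c in self.subsubsample.columns)  # type: ignore[union-attr]
        if level == 1:
            return tuple(c.personal_id for c in self.subsample.columns)  # type: ignore[union-attr]
        return tuple(c.personal_id for c in self.columns)


# ---------------------------------------------------------------------------
# The sheet
# ---------------------------------------------------------------------------


class Planning(_Base):
    general: GeneralInfo = Field(default_factory=GeneralInfo)
    experimental_system: Optional[ExperimentalSystem] = None
    comparison_groups: tuple[ComparisonGroup, ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "Planning":
        cats = [g.category for g in self.comparison_groups]
        if len(set(cats)) != len(cats):
            raise ValueError("comparison group categories must be unique")
        return self


class Conduction(_Base):
    final_groups: tuple[FinalGroup, ...] = ()
    covariates: tuple[CovariateSpec, ...] = ()
    timeline: Optional[TimelineSpec] = None
    preparation: Optional[PreparationSpec] = None
    measurement: Optional[MeasurementSpec] = None
    linkage: Optional[DataFileLinkage] = None


class Metadatasheet(_Base):
    """One complete (or in-progress) Metadatasheet document."""

    planning: Planning = Field(default_factory=Planning)
    conduction: Conduction = Field(default_factory=Conduction)
    matching: Optional[IDTable] = None
    uid: Optional[str] = None

    def is_blank(self) -> bool:
        return self == Metadatasheet()


# ---------------------------------------------------------------------------
# Validation report plumbing
# ---------------------------------------------------------------------------


class Severity(str, enum.Enum):
    error = "error"
    warning = "warning"


class Location(_Base):
    section: str = ""
    segment: str = ""
    key: str = ""
    column: Optional[int] = None

    def __str__(self) -> str:
        parts = [p for p in (self.section, self.segment, self.key) if p]
        if self.column is not None:
            parts.append(f"col {self.column + 1}")
        return "/".join(parts) if parts else "(sheet)"


class ValidationIssue(_Base):
    location: Location = Field(default_factory=Location)
    observed: str = ""
    rule: str = ""
    severity: Severity = Severity.error
    message: str = ""

    def __str__(self) -> str:
        return f"[{self.severity.value}] {self.rule} @ {self.location}: {self.message}"


class ValidationReport(_Base):
    issues: tuple[ValidationIssue, ...] = ()

    @property
    def ok(self) -> bool:
        """True iff the report contains no error-severity issues."""
        return not any(i.severity is Severity.error for i in self.issues)

    def errors(self) -> tuple[ValidationIssue, ...]:
        return tuple(i for i in self.issues if i.severity is Severity.error)

    def warnings(self) -> tuple[ValidationIssue, ...]:
        return tuple(i for i in self.issues if i.severity is Severity.warning)

    def extend(self, issues) -> "ValidationReport":
        return ValidationReport(issues=self.issues + tuple(issues))

    def to_dict(self) -> dict:
        return {
            "ok": self.ok,
            "n_errors": len(self.errors()),
            "n_warnings": len(self.warnings()),
            "issues": [
                {
                    "location": str(i.location),
                    "observed": i.observed,
                    "rule": i.rule,
                    "severity": i.severity.value,
                    "message": i.message,
                }
                for i in self.issues
            ],
        }


def issue(
    rule: str,
    message: str,
    *,
    severity: Severity = Severity.error,
    section: str = "",
    segment: str = "",
    key: str = "",
    column: Optional[int] = None,
    observed: str = "",
) -> ValidationIssue:
    """Convenience constructor used throughout the engine."""
    return ValidationIssue(
        location=Location(section=section, segment=segment, key=key, column=column),
        observed=observed,
        rule=rule,
        severity=severity,
        message=message,
    )
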