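"""Planning/Conduction machinery: dependent-key insertion, final-group
generation (the Workbook's first 'generate' button) and timeline checks.

Final groups are the Cartesian product of the declared comparison groups'
instances: a design with six diets and two genotypes yields 12 final groups.
Generation enforces sequential integrity — it refuses to run when the
planning section it depends on is invalid.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Optional, Sequence

from .model import (
    ComparisonGroup,
    DependentFieldRegistry,
    FinalGroup,
    RegistryCategory,
    RegistryEntry,
    RegistryError,
    SequentialIntegrityError,
    Severity,
    TimelineSpec,
    ValidationIssue,
    VocabEntry,
    Vocabulary,
    VType,
    canonical_key,
    issue,
)

__all__ = [
    "insert_dependent_keys",
    "extend_registry",
    "generate_final_groups",
    "check_timeline",
]


def insert_dependent_keys(
    category: RegistryCategory,
    instance: str,
    registry: DependentFieldRegistry,
) -> list[str]:
    """Ordered dependent keys to materialize once ``instance`` is chosen.

    E.g. choosing experimental system 'mouse' requests 'line' and 'genotype'.
    Raises :class:`RegistryError` for an unknown instance, pointing the user
    at registry extension.
    """
    entry = registry.get(category, instance)
    if entry is None:
        known = sorted(
            e.instance for e in registry.entries if e.category is category
        )
        raise RegistryError(
            f"no dependent keys registered for ({category.value}, {instance!r}); "
            f"known instances: {', '.join(known) or '(none)'} — extend the "
            "registry with extend_registry() to add it"
        )
    return list(entry.keys)


def extend_registry(
    registry: DependentFieldRegistry,
    vocab: Vocabulary,
    category: RegistryCategory,
    instance: str,
    new_key: str,
    vtype: VType,
    allowed_values: Optional[Sequence[str]] = None,
) -> tuple[DependentFieldRegistry, Vocabulary]:
    """Add a dependent key plus its vocabulary constraint in one step.

    Existing keys can be extended, never changed: re-adding an already listed
    key is a no-op with a warning, and redefining an existing key's
    validation type is refused.  Returns new (registry, vocabulary) objects;
    the inputs are never mutated.
    """
    existing_vocab = vocab.get(new_key)
    if existing_vocab is not None and existing_vocab.vtype is not vtype:
        raise RegistryError(
            f"key {new_key!r} already exists with type "
            f"{existing_vocab.vtype.value}; existing keys can be extended, "
            "not changed"
        )
    if vtype in (VType.dropdown, VType.dropdown_multi) and not allowed_values:
        if existing_vocab is None:
            raise RegistryError(
                f"key {new_key!r}: dropdown types require allowed_values"
            )

    entry = registry.get(category, instance)
    if entry is not None and any(
        canonical_key(k) == canonical_key(new_key) for k in entry.keys
    ):
        warnings.warn(
            f"key {new_key!r} already registered for ({category.value}, "
            f"{instance!r}); nothing to do",
            stacklevel=2,
        )
        return registry, vocab

    if entry is None:
        new_entries = registry.entries + (
            RegistryEntry(category=category, instance=instance, keys=(new_key,)),
        )
    else:
        new_entries = tuple(
            e.model_copy(update={"keys": e.keys + (new_key,)}) if e is entry else e
            for e in registry.entries
        )
    new_registry = DependentFieldRegistry(entries=new_entries)

    if existing_vocab is None:
        vocab = vocab.with_entry(
            VocabEntry(
                key=new_key,
                vtype=vtype,
                allowed_values=tuple(allowed_values or ()),
            )
        )
    return new_registry, vocab


def generate_final_groups(
    comparison_groups: Sequence[ComparisonGroup],
) -> list[FinalGroup]:
    """All combinations of comparison-group instances, replicates unset.

    Groups iterate in declaration order with the last-declared group varying
    fastest (row-major), so output order is deterministic.  An empty design
    is a sequential-integrity error: the planning section must be completed
    first.
    """
    if not comparison_groups:
        raise SequentialIntegrityError(
            "cannot generate final groups: no comparison groups declared in "
            "the planning section"
        )
    for g in comparison_groups:
        if not g.instances:  # unreachable through the model, defensive
            raise SequentialIntegrityError(
                f"comparison group {g.category.value!r} has no instances"
            )
    categories = [g.category.value for g in comparison_groups]
    label_lists = [[i.label for i in g.instances] for g in comparison_groups]
    return [
        FinalGroup(assignment=dict(zip(categories, combo)))
        for combo in itertools.product(*label_lists)
    ]


def check_timeline(
    spec: Optional[TimelineSpec],
    groups: Sequence[ComparisonGroup],
) -> list[ValidationIssue]:
    """Consistency of the interrupted-timeline segment with the design.

    An uninterrupted (or absent) timeline carries no sub-fields — the segment
    collapses.  When interrupted, the enriched group must be one of the
    declared comparison groups and at least one time step must be given (the
    model already guarantees kind/time_unit/steps presence).
    """
    if spec is None or not spec.interrupted:
        return []
    issues: list[ValidationIssue] = []
    declared = {g.category for g in groups}
    if spec.enriched_group not in declared:
        issues.append(
            issue(
                "timeline-unknown-group",
                f"timeline enriches comparison group "
                f"{spec.enriched_group.value!r} which is not declared in the "
                "planning section",
                section="conduction",
                segment="Time-Dependence-Timeline",
                key="enriched group",
                observed=spec.enriched_group.value,
            )
        )
    for idx, step in enumerate(spec.steps):
        if not step.time.strip():
            issues.append(
                issue(
                    "timeline-empty-step",
                    f"time step {idx + 1} has no time value",
                    section="conduction",
                    segment="Time-Dependence-Timeline",
                    key="time",
                    column=idx,
                    severity=Severity.warning,
                )
            )
    return issues
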