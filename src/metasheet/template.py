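"""Reset/template machinery: blank sheets and template import.

Template import copies the planning and conduction sections verbatim and
regenerates the measurement-matching structure with every personal_ID (and
per-sample covariate value) cleared — the one thing a new experiment must
never inherit is the old IDs.  The UID is cleared too; a fresh one is
assigned on export.
"""

from __future__ import annotations

import warnings

from .model import (
    DependentFieldRegistry,
    Metadatasheet,
    SequentialIntegrityError,
    Vocabulary,
)
from .matching import collect_promoted_keys, generate_id_table

__all__ = ["new_blank", "from_template"]


def new_blank(
    vocab: Vocabulary, registry: DependentFieldRegistry
) -> Metadatasheet:
    """A blank Metadatasheet: all segments present in the document layout but
    no values, no final groups, no ID table."""
    return Metadatasheet()


def from_template(template: Metadatasheet) -> Metadatasheet:
    """Derive a fresh sheet from an existing one.

    Planning and conduction are copied verbatim; the matching structure is
    regenerated from the conduction section, so personal_IDs and per-sample
    values come out blank; the UID is cleared.  A template whose conduction
    cannot regenerate the table (e.g. replicate counts unset) degrades to a
    planning-only copy with a warning.
    """
    fresh = Metadatasheet(
        planning=template.planning.model_copy(deep=True),
        conduction=template.conduction.model_copy(deep=True),
        matching=None,
        uid=None,
    )
    if template.matching is None:
        return fresh
    try:
        fresh = fresh.model_copy(
            update={
                "matching": generate_id_table(
                    fresh.conduction.final_groups,
                    fresh.conduction.covariates,
                    collect_promoted_keys(fresh),
                    fresh.conduction.preparation,
                )
            }
        )
    except SequentialIntegrityError as exc:
        warnings.warn(
            f"template conduction section is invalid ({exc}); copying the "
            "planning section only",
            stacklevel=2,
        )
        fresh = Metadatasheet(planning=template.planning.model_copy(deep=True))
    return fresh
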