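"""Deterministic synthetic Metadatasheet generator plus dummy data files.

Emulates completed sheets of the kind produced in practice — the default
parameters are the showcase shape: a mouse study contrasting six diets with
five replicates each, measured by bulk RNA-seq, i.e. a 30-column
measurement-matching table.  Everything is seeded: the same seed and design
always yield an identical sheet, and (through the deterministic writer)
byte-identical workbooks.

Counts in the dummy bulk matrices are drawn from a seeded negative-binomial
distribution purely so the numbers look like bulk omics; they carry no
biological claim.
"""

from __future__ import annotations

import random
import uuid
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

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
    GeneralInfo,
    GroupCategory,
    GroupInstance,
    IDTable,
    LinkageMode,
    MeasurementSpec,
    Metadatasheet,
    MetasheetError,
    Planning,
    PreparationSpec,
    RegistryCategory,
    RegistryEntry as _RE,
    TimelineSpec,
    VocabEntry,
    Vocabulary,
    VType,
)
from .design import generate_final_groups
from .matching import FILENAME_KEY, collect_promoted_keys, generate_id_table

__all__ = [
    "DesignSpec",
    "base_vocabulary",
    "base_registry",
    "generate_sheet",
    "generate_datafiles",
]

DIETS = (
    "control diet",
    "high fat diet",
    "western diet",
    "low protein diet",
    "high sugar diet",
    "ketogenic diet",
)
GENOTYPES = ("wild type", "knockout")

#: Category order used when a design asks for several comparison groups.
#: diet and genotype draw their labels from the controlled vocabulary; the
#: free-text categories accept any number of synthetic instance labels.
_CATEGORY_ORDER = (
    GroupCategory.diet,
    GroupCategory.treatment,
    GroupCategory.age,
    GroupCategory.temperature,
    GroupCategory.other,
    GroupCategory.genotype,
)

_COVARIATE_POOL = (
    ("body weight", "g"),
    ("blood glucose", "mg/dl"),
    ("age at sacrifice", "weeks"),
    ("RIN score", ""),
    ("serum colour", ""),
)


def base_vocabulary() -> Vocabulary:
    """The controlled vocabulary the synthetic sheets draw from, seeded with
    the field's showcase terms (mouse systems, diets, a BTO tissue CURIE)."""
    entries = [
        VocabEntry(
            key="experimental system",
            vtype=VType.dropdown,
            help="system under study",
            allowed_values=("mouse", "rat", "human-derived", "cell-line", "patient"),
        ),
        VocabEntry(
            key="line",
            vtype=VType.dropdown,
            allowed_values=("C57BL/6J", "BALB/c"),
        ),
        VocabEntry(
            key="genotype",
            vtype=VType.dropdown,
            allowed_values=GENOTYPES,
        ),
        VocabEntry(
            key="tissue",
            vtype=VType.dropdown,
            help="BRENDA Tissue Ontology terms",
            allowed_values=(
                "BTO:0000759 liver",
                "BTO:0000142 brain",
                "BTO:0001239 adipose tissue",
            ),
        ),
        VocabEntry(key="sex", vtype=VType.dropdown, allowed_values=("male", "female")),
        VocabEntry(key="diet", vtype=VType.dropdown, allowed_values=DIETS),
        VocabEntry(key="treatment", vtype=VType.freetext),
        VocabEntry(key="age", vtype=VType.freetext),
        VocabEntry(key="temperature", vtype=VType.freetext),
        VocabEntry(key="other", vtype=VType.freetext),
        VocabEntry(
            key="measurement type",
            vtype=VType.dropdown,
            allowed_values=(
                "bulk_RNA_seq",
                "bulk_metabolomics",
                "bulk_lipidomics",
                "FACS",
            ),
        ),
        VocabEntry(
            key="sequencing platform",
            vtype=VType.dropdown,
            allowed_values=("Illumina NovaSeq 6000", "Illumina NextSeq 500"),
        ),
        VocabEntry(key="library prep kit", vtype=VType.freetext),
        VocabEntry(key="used facility", vtype=VType.freetext),
        VocabEntry(key="cell type", vtype=VType.freetext),
        VocabEntry(key="date of measurement", vtype=VType.date),
        VocabEntry(
            key="timepoints",
            vtype=VType.dropdown_multi,
            allowed_values=("0 h", "24 h", "48 h"),
        ),
    ]
    return Vocabulary(entries={e.key: e for e in entries})


def base_registry() -> DependentFieldRegistry:
    entries = (
        _RE(
            category=RegistryCategory.experimental_system,
            instance="mouse",
            keys=("line", "genotype", "tissue", "sex"),
        ),
        _RE(
            category=RegistryCategory.experimental_system,
            instance="rat",
            keys=("genotype", "tissue", "sex"),
        ),
        _RE(
            category=RegistryCategory.experimental_system,
            instance="cell-line",
            keys=("cell type",),
        ),
        _RE(
            category=RegistryCategory.experimental_system,
            instance="human-derived",
            keys=("tissue", "sex"),
        ),
        _RE(
            category=RegistryCategory.measurement_type,
            instance="bulk_RNA_seq",
            keys=("sequencing platform", "library prep kit", "used facility"),
        ),
        _RE(
            category=RegistryCategory.measurement_type,
            instance="bulk_metabolomics",
            keys=("used facility",),
        ),
        _RE(
            category=RegistryCategory.measurement_type,
            instance="bulk_lipidomics",
            keys=("used facility",),
        ),
        _RE(
            category=RegistryCategory.measurement_type,
            instance="FACS",
            keys=("used facility",),
        ),
    )
    return DependentFieldRegistry(entries=entries)


@dataclass(frozen=True)
class DesignSpec:
    """Design parameters of a synthetic sheet.

    Defaults reproduce the showcase shape: one comparison group (diet) with
    six instances, five replicates per final group, no covariates, no sample
    divisions, bulk RNA-seq, a single count matrix for all samples.
    """

    instances_per_group: tuple[int, ...] = (6,)
    replicates: int | tuple[int, ...] = 5
    n_covariates: int = 0
    n_constants: int = 0
    division_levels: int = 0
    subdivision_replicates: int = 1
    measurement_type: str = "bulk_RNA_seq"
    linkage_mode: LinkageMode = LinkageMode.single_file_for_all

    @property
    def n_groups(self) -> int:
        return len(self.instances_per_group)


_NAMES = ("Ada Gray", "Chen Wu", "Iris Novak", "Lars Berg", "Mina Patel")
_AFFILIATIONS = (
    "Institute of Metabolism Research",
    "Center for Systems Biomedicine",
    "Department of Molecular Nutrition",
)


def _instances_for(
    category: GroupCategory, n: int, gi: int
) -> tuple[GroupInstance, ...]:
    if category is GroupCategory.diet:
        if n > len(DIETS):
            raise MetasheetError(f"at most {len(DIETS)} diet instances available")
        labels = DIETS[:n]
    elif category is GroupCategory.genotype:
        if n > len(GENOTYPES):
            raise MetasheetError("at most 2 genotype instances available")
        labels = GENOTYPES[:n]
    else:
        labels = tuple(f"{category.value} setting {j + 1}" for j in range(n))
    return tuple(GroupInstance(label=lab) for lab in labels)


def generate_sheet(
    seed: int, spec: DesignSpec = DesignSpec()
) -> tuple[Metadatasheet, Vocabulary, DependentFieldRegistry]:
    """A complete, validation-clean synthetic Metadatasheet.

    Same seed and spec yield an identical sheet.  Raises
    :class:`MetasheetError` when the spec violates model bounds (e.g. more
    than two division levels).
    """
    if spec.division_levels not in (0, 1, 2):
        raise MetasheetError(
            f"division_levels must be 0, 1 or 2, got {spec.division_levels}"
        )
    if not spec.instances_per_group:
        raise MetasheetError("at least one comparison group is required")
    if spec.n_groups > len(_CATEGORY_ORDER):
        raise MetasheetError(
            f"at most {len(_CATEGORY_ORDER)} comparison groups supported"
        )
    rng = random.Random(seed)
    vocab = base_vocabulary()
    registry = base_registry()

    # -- planning ----------------------------------------------------------
    general = GeneralInfo(
        name=rng.choice(_NAMES),
        affiliation=rng.choice(_AFFILIATIONS),
        email="metadata@example.org",
        project_title=f"Synthetic showcase study (seed {seed})",
    )
    system = ExperimentalSystem(
        system="mouse",
        dependent_values={
            "line": rng.choice(("C57BL/6J", "BALB/c")),
            "genotype": "wild type",
            "tissue": "BTO:0000759 liver",
            "sex": rng.choice(("male", "female")),
        },
    )
    categories = list(_CATEGORY_ORDER[: spec.n_groups])
    # genotype supports only two instances; swap it in when it fits so small
    # two-level designs look like the field's 6 diets x 2 genotypes example
    if spec.n_groups >= 2 and spec.instances_per_group[1] <= 2:
        categories[1] = GroupCategory.genotype
    groups = tuple(
        ComparisonGroup(
            category=cat, instances=_instances_for(cat, n, gi)
        )
        for gi, (cat, n) in enumerate(zip(categories, spec.instances_per_group))
    )
    planning = Planning(
        general=general, experimental_system=system, comparison_groups=groups
    )

    # -- conduction --------------------------------------------------------
    final_groups = generate_final_groups(groups)
    reps = (
        [spec.replicates] * len(final_groups)
        if isinstance(spec.replicates, int)
        else list(spec.replicates)
    )
    if len(reps) != len(final_groups):
        raise MetasheetError(
            f"replicates vector length {len(reps)} != {len(final_groups)} "
            "final groups"
        )
    final_groups = [
        fg.model_copy(update={"n_replicates": r})
        for fg, r in zip(final_groups, reps)
    ]

    covariates = [
        CovariateSpec(
            name=_COVARIATE_POOL[i % len(_COVARIATE_POOL)][0],
            unit=_COVARIATE_POOL[i % len(_COVARIATE_POOL)][1],
            role=CovariateRole.covariate,
        )
        for i in range(spec.n_covariates)
    ]
    covariates += [
        CovariateSpec(
            name=("cell type", "genotype")[i % 2],
            unit="",
            role=CovariateRole.constant,
            constant_value=("Kupffer Cells", "wild type")[i % 2],
        )
        for i in range(spec.n_constants)
    ]

    division_names = (
        ("Kupffer cells", "hepatocytes"),
        ("technical replicate A", "technical replicate B"),
    )
    divisions = tuple(
        DivisionLevel(
            n_per_parent=2,
            instances=tuple(
                DivisionInstance(
                    label=lab,
                    protocol=f"protocol_isolation_{lab.replace(' ', '_')}.pdf",
                    n_replicates=spec.subdivision_replicates,
                )
                for lab in division_names[level]
            ),
        )
        for level in range(spec.division_levels)
    )
    preparation = PreparationSpec(
        protocol="protocol_liver_homogenization.pdf", divisions=divisions
    )

    mkeys = registry.get(RegistryCategory.measurement_type, spec.measurement_type)
    dep_values: dict[str, str] = {}
    for key in mkeys.keys if mkeys else ():
        if key == "sequencing platform":
            dep_values[key] = rng.choice(
                ("Illumina NovaSeq 6000", "Illumina NextSeq 500")
            )
        elif key == "library prep kit":
            dep_values[key] = "TruSeq stranded mRNA"
        else:
            dep_values[key] = "Core Facility Genomics"
    measurement = MeasurementSpec(
        measurement_type=spec.measurement_type, dependent_values=dep_values
    )

    if spec.linkage_mode is LinkageMode.single_file_for_all:
        linkage = DataFileLinkage(
            availability=Availability.raw,
            mode=spec.linkage_mode,
            comment="counts.tsv",
        )
    elif spec.linkage_mode is LinkageMode.id_in_filename:
        linkage = DataFileLinkage(
            availability=Availability.raw,
            mode=spec.linkage_mode,
            comment="one count file per personal ID",
        )
    else:
        linkage = DataFileLinkage(
            availability=Availability.raw,
            mode=LinkageMode.changes,
            comment="per-sample filenames in the matching table",
        )

    conduction = Conduction(
        final_groups=tuple(final_groups),
        covariates=tuple(covariates),
        timeline=TimelineSpec(interrupted=False),
        preparation=preparation,
        measurement=measurement,
        linkage=linkage,
    )

    sheet = Metadatasheet(planning=planning, conduction=conduction)
    table = generate_id_table(
        conduction.final_groups,
        conduction.covariates,
        collect_promoted_keys(sheet),
        preparation,
    )
    table = _fill_table(table, rng, spec)
    uid = str(uuid.UUID(int=rng.getrandbits(128), version=4))
    sheet = sheet.model_copy(update={"matching": table, "uid": uid})
    return sheet, vocab, registry


def _fill_table(table: IDTable, rng: random.Random, spec: DesignSpec) -> IDTable:
    """Assign personal IDs at every level and values for the dynamic rows."""

    def dyn_values(keys, pid):
        out = {}
        for key in keys:
            if key == FILENAME_KEY:
                out[key] = f"data_{pid}.tsv"
            else:
                out[key] = f"{rng.uniform(1, 100):.1f}"
        return out

    columns = tuple(
        c.model_copy(
            update={
                "personal_id": f"M{i + 1:03d}",
                "values": dyn_values(table.dynamic_keys, f"M{i + 1:03d}"),
            }
        )
        for i, c in enumerate(table.columns)
    )

    def fill_sub(sub, prefix):
        if sub is None:
            return None
        return sub.model_copy(
            update={
                "columns": tuple(
                    c.model_copy(
                        update={
                            "personal_id": f"{prefix}{i + 1:03d}",
                            "values": dyn_values(c.values, f"{prefix}{i + 1:03d}"),
                        }
                    )
                    for i, c in enumerate(sub.columns)
                )
            }
        )

    return table.model_copy(
        update={
            "columns": columns,
            "subsample": fill_sub(table.subsample, "S"),
            "subsubsample": fill_sub(table.subsubsample, "T"),
        }
    )


def generate_datafiles(
    sheet: Metadatasheet,
    root,
    mode: Optional[LinkageMode] = None,
    seed: int = 0,
    n_features: int = 120,
) -> list[Path]:
    """Write dummy measurement files matching the sheet's linkage mode.

    single_file_for_all: one TSV count matrix with a column per measurement
    ID; id_in_filename: one small TSV per ID with the ID in the file name;
    changes: one file per promoted filename-row value.  Counts come from a
    seeded negative-binomial draw.  Raises :class:`MetasheetError` when the
    sheet has blank measurement IDs.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    if sheet.matching is None:
        raise MetasheetError("sheet has no measurement-matching section")
    ids = list(sheet.matching.deepest_ids())
    if not ids or any(not i for i in ids):
        raise MetasheetError("sheet has blank personal_ID values")
    if mode is None:
        if sheet.conduction.linkage is None:
            raise MetasheetError("sheet has no DataFiles-Linkage segment")
        mode = sheet.conduction.linkage.mode

    rng = np.random.default_rng(seed)
    features = [f"gene_{i + 1:05d}" for i in range(n_features)]
    counts = rng.negative_binomial(5, 0.02, size=(n_features, len(ids)))

    written: list[Path] = []
    if mode is LinkageMode.single_file_for_all:
        name = (
            sheet.conduction.linkage.comment
            if sheet.conduction.linkage is not None
            and sheet.conduction.linkage.mode is mode
            else "counts.tsv"
        )
        path = root / name
        with open(path, "w") as fh:
            fh.write("feature\t" + "\t".join(ids) + "\n")
            for i, feat in enumerate(features):
                fh.write(feat + "\t" + "\t".join(map(str, counts[i])) + "\n")
        written.append(path)
    elif mode is LinkageMode.id_in_filename:
        for j, pid in enumerate(ids):
            path = root / f"{pid}_counts.tsv"
            with open(path, "w") as fh:
                fh.write(f"feature\t{pid}\n")
                for i, feat in enumerate(features):
                    fh.write(f"{feat}\t{counts[i, j]}\n")
            written.append(path)
    else:  # changes: use the promoted filename row of the deepest table
        from .matching import _deepest_columns

        for j, (col, ancestor) in enumerate(_deepest_columns(sheet.matching)):
            fname = col.values.get(FILENAME_KEY, "") or ancestor.values.get(
                FILENAME_KEY, ""
            )
            if not fname:
                raise MetasheetError(
                    f"no filename row value for ID {col.personal_id!r}"
                )
            path = root / fname
            with open(path, "w") as fh:
                fh.write(f"feature\t{col.personal_id}\n")
                for i, feat in enumerate(features):
                    fh.write(f"{feat}\t{counts[i, j]}\n")
            written.append(path)
    return written
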