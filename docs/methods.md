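# Methods

## The document model

A Metadatasheet records one experimental design combined with one
measurement type. The model (`metasheet.model`) is the single source of
truth for the standard's invariants; everything that can be decided from a
single object is enforced at construction (pydantic validators), while
cross-structure consistency (values vs. vocabulary, registry completeness,
section-to-section references) is the validation engine's job.

Structural rules enforced at construction:

- dropdown-type vocabulary entries require allowed values, unique after
  canonicalization; unconstrained types must not carry any;
- comparison groups need at least one instance and unique labels; a design
  declares each category (`diet`, `treatment`, `genotype`, `age`,
  `temperature`, `other`) at most once, because final-group assignments are
  keyed by category;
- constants carry their value in place, covariates never do (their values
  live in the ID table);
- an interrupted timeline requires kind (`continued`/`discontinued`),
  enriched group, time unit and at least one step — and forbids them
  otherwise, so the segment genuinely collapses;
- sample partitioning is limited to two division levels, with instance
  counts equal to the declared number per parent;
- personal IDs are unique across the whole sheet and subtable columns must
  reference a column one level up;
- processed data requires a processing procedure; single-file linkage
  requires the filename.

Canonicalization trims and collapses whitespace, preserving case; vocabulary
comparison is case-insensitive on canonical forms and matched values keep
the vocabulary's canonical spelling. The `CHANGES` promotion keyword is
matched case-sensitively (uppercase only) so an ordinary value like
"changes" is never promoted by accident.

## Validation semantics

The engine reports and never mutates. Severities follow one principle: a
violation of the standard is an **error**; incompleteness of a live document
is a **warning**. Concretely, off-vocabulary values, bad dates, missing
dependent keys, undeclared instance references, unset replicate counts and
wrong column counts are errors; empty values, unknown-but-well-formed extra
keys (the standard is explicitly extensible) and blank personal IDs are
warnings. Replicate counts are never defaulted — a silent n = 1 hides
design mistakes.

Sequential integrity: the conduction section is checked only against a
valid and complete planning section, measurement-matching only against a
valid and complete conduction section. Downstream checking is suppressed
behind a single `blocked-by-upstream` marker. The marker is a *warning*:
the actual defect is the upstream error, and counting it as a second error
would double-report a single mistake. The generate operations themselves
raise `SequentialIntegrityError` when their preceding section is invalid,
mirroring the generate-button behaviour.

Empty required values are warnings during recording and become hard errors
only at export time (the GEO exporter refuses on missing mandatory fields).

## The generators

`generate_final_groups` returns the Cartesian product of the declared
comparison groups' instances, iterating groups in declaration order with the
last-declared group varying fastest. The ordering is not prescribed by the
standard; a fixed row-major order makes output deterministic and testable.
Display labels join instance labels with " × "; the structured assignment
mapping remains authoritative. Regeneration replaces the segment (the CLI
warns when replicate counts were already set).

`generate_id_table` expands final groups into Σ replicates columns with
1-based replicate indices, blank personal IDs, and one dynamic row per
covariate (role `covariate`) plus one per CHANGES-promoted key. Constants
are deliberately **not** expanded into rows: their single in-place value is
already recorded in the conduction section and would only be duplicated
across every column; exporters (GEO characteristics) re-attach them per
sample. Promoted keys follow the measurement to the deepest table, so
subtable columns carry them too. Division levels expand multiplicatively:
each parent column spawns one subcolumn per instance replicate. Subtable
columns hold a structural `parent_column` reference (`#n`, 1-based) plus a
derived `parent_ID` row that mirrors the parent's personal ID once assigned —
the structural reference keeps freshly generated (ID-less) tables
round-trippable. The subsample/subsubsample flags render as literal
"yes"/"no" rows.

## Data-file resolution

The directory holding the sheet is the root; stored filenames are kept
exactly as typed and resolved relative to it. `id_in_filename` matches the
personal ID as a substring of file *basenames* (full relative paths would
make matches depend on directory naming); multiple hits per ID are
legitimate (paired-end reads) and returned sorted lexicographically.
Substring matching is the standard's contract, but it cannot distinguish
IDs where one is contained in another (S1 vs S10), so resolution emits an
`ambiguous-id` warning whenever one ID is a substring of another. A single
missing file or an ID with zero matches is a hard `ResolutionError`.

## Workbook layout

The `Input` sheet uses keys in column A with values from column B; tabular
segments extend column-wise. Section headers are written `=== PLANNING ===`
and segment headers `-- General --`, in bold. Bold/grey styling is the
human cue; the marker strings are the canonical recognizer, so files whose
styling has been stripped still parse. The `Validation` sheet carries three
header rows per column (validation type, help text, key; values below), the
`dependentFields` sheet two (category, instance; dependent keys below) —
group subsets live in `Validation_[Group]` sheets. The hidden `ResetSheet`
of macro-workbook files is ignored on read and never written. The writer
emits plain macro-free XLSX with fixed document properties and zip
timestamps, so identical content yields byte-identical files. UIDs are
UUID4, assigned on export when absent and preserved on re-export.

The reader is total: missing `Input`/`Validation`/`dependentFields` sheets
are fatal layout errors; anything else yields a (possibly partial) model
with segment-level problems attached as issues. Dates are normalized to ISO
8601 on read, accepting spreadsheet serial numbers (epoch 1899-12-30) and
dotted/slashed forms (day-first for dotted/slashed numeric dates).

## Exporters

**GEO** — the exporter targets a bulk-sequencing submission spreadsheet
shape; the column map and mandatory-field lists live in a versioned config
(`data/geo_template.json`) since submission templates evolve. One sample
row per deepest-level ID-table column; characteristics columns come from
comparison-group assignments, constants (same value in every row) and
covariates (per-sample values); organism is mapped from the experimental
system. Missing mandatory fields raise an error enumerating every gap.

**OWL/RDF** — sheets and measured units become individuals typed by the
classes of a shipped ontology (`data/metasheet_ontology_synthetic.owl`, a
small synthetic stand-in schema constructed for this package). Keys map to
properties by label; unmapped keys fall back to a generic `attribute`
annotation property with a warning. Values embedding a CURIE
(`PREFIX:digits`, e.g. `BTO:0000759 liver`) additionally assert an
`ontologyTerm` link to the OBO-style IRI. Serialization is RDF/XML (an
OWL 2 exchange syntax) via rdflib; a dedicated OWL/XML serializer is not
provided.

**Experiment bundle** — the conversion accepts the three bulk omics
families (`bulk-transcriptomics`, `bulk-metabolomics`, `bulk-lipidomics`),
reached via an alias table from vocabulary measurement types
(`bulk_RNA_seq` → `bulk-transcriptomics`); anything else is refused. The
assay matrix is located through the linkage segment; if the named single
file is absent, candidate files with the same extension are returned in a
clarification error. Output is TSV/JSON (assay, column metadata, sheet
metadata) rather than a binary object, so a downstream R session owns the
`SummarizedExperiment` construction — the matching table lands in
`colData`. Assay column order, column-metadata row order and personal_ID
order are kept identical by construction.

## Template machinery

Template import copies planning and conduction verbatim, clears the UID and
regenerates the matching structure, so every personal ID — and every
per-sample covariate value, which describes the old samples — comes out
blank; covariate *declarations* are kept. A template whose conduction
cannot regenerate the table (replicate counts unset) degrades to a
planning-only copy with a warning. A template without a matching section
keeps its (possibly partial) conduction and stays matching-less. The
operation is idempotent.

## The synthetic generator

`fixtures.generate_sheet(seed, DesignSpec(...))` produces complete,
validation-clean sheets. The defaults are the showcase shape: a mouse study
with one comparison group (diet, six instances from the built-in
vocabulary), five replicates per final group, bulk RNA-seq with a single
count matrix — i.e. a 30-column matching table. Designs with several groups
use distinct categories (diet, then genotype when the second group has ≤ 2
instances, otherwise free-text categories), up to two division levels, and
any mix of covariates/constants and linkage modes. Everything derives from
one seeded RNG; dummy count matrices use a seeded negative-binomial draw
(r = 5, p = 0.02) purely so the numbers look like bulk counts.

What the generator does **not** emulate: real ontology coverage beyond a
few BTO-style CURIEs, messy hand-typed spreadsheets (merged cells, stray
formatting, partially deleted segments), non-Latin text, or meaningful
biological signal in the matrices. Passing tests therefore demonstrate the
mechanics of the standard — expansion counts, referential integrity,
round-tripping, export alignment — not robustness to arbitrary real-world
workbooks beyond the dialect documented above.

## Problem sizes used in the test suite

Property corpora are seeded and sized for a laptop-class run: 500 random
designs for the Cartesian and column-count oracles (≤ 4 groups × ≤ 5
instances, replicates ≤ 6), 50 workbooks for round-trip identity, 50
templates for ID-clearing, 15 + 15 fuzz trials for off-vocabulary and
structural injection, and one fixture per division depth (0/1/2) for export
integrity. These sizes exercise every code path several times over while
the full suite stays under a minute.

## Known limitations

- Exactly one sheet per workbook; collections are linked by UID only.
- The GEO layout is one plausible rendering of the submission spreadsheet,
  not a pixel-faithful copy of any specific template revision.
- Group-specific vocabularies restrict value checking and subset checking;
  group-specific *dependent-field* subsets are not modelled.
- `id_in_filename` matching is substring-based by contract; the ambiguity
  warning flags, but does not resolve, ID prefix collisions.
- Reading legacy `.xls`, cell colours, collapsed-row state and other
  presentation aspects are out of scope.
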