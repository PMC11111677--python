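# metasheet

A scriptable Python implementation of the **Metadatasheet** standard for
biomedical experiment metadata: parse, validate, generate and export
structured metadata that is recorded *along* the research data-lifecycle —
Planning → Conduction → Measurement-Matching — instead of being
reconstructed at publication time.

The Metadatasheet captures one experimental design combined with one
measurement type in a single structured document:

- **Planning** — contact/project information; the experimental system
  (mouse, rat, cell-line, …) with its *dependent keys* (e.g. choosing
  `mouse` requests `line` and `genotype`); and the *comparison groups*, the
  contrasted settings of the design (`diet`, `treatment`, `genotype`, `age`,
  `temperature`, `other`), each with named instances.
- **Conduction** — the *final groups* (the Cartesian product of the
  comparison-group instances: six diets × two genotypes ⇒ 6 × 2 = 12
  final groups) with replicate counts; covariates/constants; an optional
  interrupted timeline; sample preparation with up to two levels of sample
  partitioning; the measurement segment; and the data-file linkage.
- **Measurement-Matching** — the ID-specific metadata table with one column
  per measured unit (Σ replicates columns in total), a unique `personal_ID`
  per unit, dynamic rows for covariates and any key promoted with the
  reserved `CHANGES` token, and subsample/subsubsample tables for nested
  designs.

Every value is checked against a controlled vocabulary (`freetext`, `date`,
`DropDown`, `DropDown_M` multi-select), which is extensible and can be
restricted per group; the library validates, never silently corrects.
Completed sheets export to plain XLSX, the NCBI GEO submission spreadsheet
layout, OWL individuals (RDF/XML, against a shipped ontology), and a
TSV/JSON *experiment bundle* that an R session can load straight into a
`SummarizedExperiment` (assay matrix + the matching table as `colData`).

## Worked example

The package ships a deterministic generator of complete synthetic sheets
(the default is a mouse study contrasting six diets with five replicates
each, measured by bulk RNA-seq):

```bash
$ metasheet demo --seed 1 --out demo
wrote demo/metadatasheet.xlsx and 1 data file(s)

$ metasheet validate demo/metadatasheet.xlsx
OK: 0 error(s), 0 warning(s)

$ metasheet link demo/metadatasheet.xlsx | head -3
M001	counts.tsv
M002	counts.tsv
M003	counts.tsv

$ metasheet export bundle demo/metadatasheet.xlsx --out demo/bundle
wrote bundle (120 features x 30 units) to demo/bundle
```

The sheet declares one comparison group (`diet`, six instances), so six
final groups are generated; with five replicates each the matching table
carries 6 × 5 = 30 ID columns, and the bundle's assay matrix has 30
columns aligned with the 30 `personal_ID`s. From Python:

```python
from metasheet import read_metadatasheet, generate_final_groups

result = read_metadatasheet("demo/metadatasheet.xlsx")
sheet = result.sheet
len(sheet.conduction.final_groups)   # 6
len(sheet.matching.columns)          # 30
```

Other commands: `metasheet generate groups|matching` (the two generate
steps, with sequential-integrity checks), `metasheet export geo|xml`,
`metasheet merge-vocab`, `metasheet new --template` (template import with
personal IDs cleared), `metasheet convert --to xlsx`.

## Layout

- `src/metasheet/model.py` — typed domain model, every invariant enforced
  at construction
- `src/metasheet/sheet_io.py` — XLSX workbook reader/writer (`Input`,
  `Validation`, `Validation_[Group]`, `dependentFields` sheets)
- `src/metasheet/validate.py` — validation engine, subset checking,
  vocabulary merging
- `src/metasheet/design.py` / `matching.py` — the two generate steps,
  CHANGES promotion, data-file resolution
- `src/metasheet/export.py` — GEO, OWL/RDF and experiment-bundle exporters
- `src/metasheet/template.py`, `fixtures.py`, `cli.py`

See `docs/methods.md` for design decisions and known limitations.
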