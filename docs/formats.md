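# Table formats

All tabular inputs are TSV: UTF-8, tab-separated, one header row,
columns by name (order free). GFF3 and GMT follow their standards.
Unparseable data rows are skipped with a logged warning; if more than
half of a file's rows fail, loading aborts.

## Escape calls

Carrel dialect (hybrid-line counts):

| column | type | notes |
|---|---|---|
| `gene` | string | raw identifier, normalized later |
| `n_expressing` | int | lines expressing the gene, 0..n_lines |
| `n_lines` | int, optional | default 9 |

Cotton dialect (allelic ratios):

| column | type | notes |
|---|---|---|
| `gene` | string | raw identifier |
| `xi_xa_ratio` | float ≥ 0 | inactive-X / active-X expression |

## Symbol map

| column | type | notes |
|---|---|---|
| `input_id` | string | raw spelling |
| `status` | enum | `approved`, `alias`, `previous`, `withdrawn` |
| `approved_symbol` | string | empty for `withdrawn` |

Identifiers absent from the map are `unmatched`.

## Annotations (GFF3)

Standard GFF3, 1-based inclusive. Recognized types: `gene`
(`protein_coding_gene`) and `miRNA` (`pre_miRNA`,
`miRNA_primary_transcript`). The feature identifier is the `ID`
attribute (fallback `Name`). Strand `.` becomes unknown; unknown-strand
features never satisfy the same-strand hosting policy.

## Tissue escape table

| column | type | notes |
|---|---|---|
| `gene` | string | approved symbol |
| `tissue` | string | |
| `expressed` | bool | `true`/`false` (also `1`/`0`, `yes`/`no`) |
| `logfc` | float | sex-bias log fold change; may be empty when not expressed |

## Target interactions

| column | type | notes |
|---|---|---|
| `mir_id` | string | mature or precursor ID, matched exactly |
| `gene` | string | approved symbol |
| `evidence` | string, optional | provenance tag |

Repeated (mir_id, gene) pairs collapse to the first occurrence.

## Pathway sets (GMT)

`name <tab> description <tab> member1 <tab> member2 ...` — at least one
member; duplicate set names are an error.

## qPCR Ct table

| column | type | notes |
|---|---|---|
| `sample_id` | string | |
| `group` | string | e.g. `XX` / `XY` |
| `assay` | string | target or reference assay name |
| `replicate` | int | well index within (sample, assay) |
| `ct` | float > 0 | threshold cycle |

Duplicate (sample_id, assay, replicate) triples are an error.

## Reports

JSON (sorted keys, 2-space indent, byte-stable for fixed input) or TSV
for flat record lists. `run-all` additionally writes the fully resolved
configuration as YAML next to the report.
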