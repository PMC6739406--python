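# Methods

## Escape calling

Two dialects of per-gene XCI evidence are supported, mirroring the two
classic dataset styles.

**Hybrid-line counts** (`classify_carrel`). Each X-linked gene is scored
by the number of human/rodent somatic-cell hybrid lines (out of
`n_lines`, default 9) in which it is expressed from the inactive human X.
Thresholds, both inclusive and both configurable: `escape_min = 7`
(escape), `inactive_max = 2` (inactivated), anything between is a
*variable* escaper. The classifier partitions {0..n_lines} and is
monotone in the count under inactivated < variable < escape.

**Xi/Xa ratios** (`classify_cotton`). Escape when the inactive-X
expression is at least `escape_ratio_min` of the active-X expression.
The source material for this dialect states no numeric cut-off, so the
package defaults to 0.10 — the conventional Xi/Xa escape threshold in the
XCI literature — inclusive at the boundary and exposed as a parameter.
This dialect has no variable tier.

Only full escapers enter the downstream candidate sets; variable genes
are excluded (the hybrid-line definition of an escaper is "expressed in
at least 7 of 9", which variable genes fail).

## Symbol normalization and reconciliation

Raw identifiers are resolved against an HGNC-style map with four entry
statuses. Approved, alias and previous identifiers resolve to the
approved symbol; withdrawn and unmatched identifiers are dropped; two raw
identifiers collapsing onto one approved symbol keep a single entry
(logged). Every input identifier receives exactly one mapping-log record,
so the raw→valid compression (e.g. 99 → 64 on the packaged bundle) is
fully auditable. Normalization is idempotent. Reconciliation is plain set
algebra over normalized symbols — the reconciled sets therefore reflect
post-normalization identity, the only reconstruction that is well defined
when the raw lists mix identifier vintages.

## Host-gene mapping

A gene hosts a miRNA when the precursor (stem-loop) interval lies fully
inside the gene body on the same chromosome — containment, not overlap,
since an intragenic miR transcribed with its host must sit within the
locus. Boundaries are inclusive under half-open arithmetic (a miR equal
to the gene interval is hosted). Mature arms (-5p/-3p) are name suffixes
of the precursor, not separate intervals. Default `strand_policy="same"`
(intragenic miRs are typically co-oriented with their hosts); `"ignore"`
is available and can only add pairs. Internally the mapper queries an
interval tree per chromosome; the test suite checks it against a
brute-force all-pairs oracle on random annotations.

Coordinates are 0-based half-open in memory and 1-based inclusive in all
GFF3 I/O.

## Tissue filter

A host gene counts as escaping in a given tissue iff it has a record for
that tissue, is expressed there, and has a strictly positive sex-bias log
fold change (female-biased expression being the observable consequence of
escape). Zero or negative logFC excludes — a host can carry escape
evidence in hybrid-line or allelic data yet be silenced or male-biased in
the tissue of interest. Each excluded gene gets exactly one reason
(`not_in_table`, `not_expressed`, `nonpositive_logfc`), and the filter
partitions its input.

## Negative-control selection

Controls are miRs contained in loci classified as inactivated (subject to
XCI), disjoint from the hosted escaper miRs. Same-numeric-family members
of a candidate miR are preferred — a family control shares seed sequence
biology, making "expressed equally in both sexes" maximally informative —
then lexicographic ID order.

## Over-representation test

One-sided upper-tail hypergeometric (equivalent to one-sided Fisher):
`p = P(X ≥ k)` for `X ~ Hypergeom(N, K, n)` with background size N, set
size K (after intersecting the set with the background), query size n and
overlap k; `k = 0` gives p = 1. The default background is the union of
all loaded gene-set members — a declared, reproducible convention, chosen
because an over-representation background must be stated to be
meaningful; it is overridable. Multiplicity across sets is handled by
Benjamini–Hochberg adjustment (step-up, monotone, capped at 1). In the
pipeline, a candidate's query is its validated-target set intersected
with the background.

The ranking key, in order: tissue support; pathway-of-interest enriched
at adjusted p ≤ alpha (default 0.05); target count ≥ `min_targets`
(default 10); raw target count; miR ID as the final deterministic
tie-break. Candidate mature-arm IDs are derived from hosted precursor IDs
by exact lookup of `<id>`, `<id>-5p` and `<id>-3p` in the interaction
table; only arms with at least one validated target are ranked.

## Relative quantification

2^−ΔΔCt with dual reference normalization: per sample, the target Ct
(mean of replicates) minus the arithmetic mean of the reference-assay Cts
— equivalent to geometric-mean normalization of reference quantities, the
standard multi-reference convention. ΔCt is averaged within each group;
ΔΔCt is the test-minus-calibrator difference of group means and
fold = 2^−ΔΔCt. This group-vs-group contrast is the primary view; a
per-sample view (each test sample against the calibrator-group mean) is
available via `per_sample=True`, since per-sample folds against either
sex's mean are both defensible readings of common practice. The 1.5-fold
significance rule is two-sided (fold ≥ 1.5 or ≤ 1/1.5) and
boundary-inclusive up to float round-off; down-regulation is as
meaningful as up-regulation. Fold changes are invariant to any global Ct
shift and invert exactly under group swap. Amplification-efficiency
correction (Pfaffl) is out of scope.

The MFI ratio (e.g. Bax/Bcl-2) is an exact quotient of two positive
median fluorescence intensities; statistics on MFI distributions are out
of scope.

## Synthetic data

The generators emulate the *shapes* of the source databases, not their
content: escape tables in both dialects with alias/previous/withdrawn
spellings and duplicate raw IDs so normalization does real work; a toy
chromosome (sequential 20-kb gene bodies, 10-kb gaps) whose hosting
topology — which miR sits in which gene — is exact while coordinates are
synthetic; a tissue table with per-gene expressed/logFC values; a target
table giving each miR a specified target count; GMT sets with an
analytically planted overlap; and replicate-level Ct tables with a
planted fold change, per-sample input-amount offsets (N(0, 0.5) cycles,
cancelling in ΔCt) and N(0, σ) well noise around reference/target base
levels of 20/25 cycles.

The frozen bundle (`paper_fixture`) pins the published relations: 99→64
and 68→65 identifier compressions, 23-gene intersection, 106-gene union;
six host genes carrying twelve miRs (CSF2RA: miR-3690; CTPS2: miR-548am;
GABRE: miR-224, miR-452; HTR2C: miR-1264, -1298, -1911, -1912, -448,
-764; PUDP: miR-4767; VGLL1: miR-934) among ≥ 50 intergenic decoys; the
fibroblast filter outcome (CSF2RA/HTR2C/VGLL1 unexpressed, GABRE
female-depleted, CTPS2 and PUDP retained); 332 targets for
hsa-miR-548am-5p including the eight apoptosis genes (APAF1, ATM, BAX,
CAPN2, PIK3R1, PRKAR2B, TNFRSF10B, XIAP) and 3 for hsa-miR-4767; controls
hsa-miR-23c and hsa-miR-548ax inside inactivated loci; and a qPCR cohort
of 8 samples per sex, triplicate wells, planted five-fold XX/XY target
difference at σ = 0.2 cycles. The 332-target list is the eight named
genes plus deterministic synthetic symbols — only the count and the
eight-gene overlap are pinned. Topology and counts are fixed by
construction; the seed moves only row order, strands and noise.

What passing on this bundle shows: the *procedure* — classification
rules, normalization semantics, containment geometry, filter logic, the
test statistic, the ranking key and the quantification arithmetic — is
implemented as specified. What it does not show: agreement with live
database versions (identifier maps, target catalogues and pathway
memberships drift), transcript-isoform effects (hosting is computed at
gene level; the gene-body interval stands in for the union of
transcripts), or anything about wet-lab measurements, which enter only as
arithmetic inputs.

## Numerical and testing choices

* Hypergeometric tails come from `scipy.stats.hypergeom.sf`; the suite
  checks them against a combination-counting oracle exhaustively for all
  N ≤ 25 and against full subset enumeration on a 20-choose-5 example.
* The null-calibration test draws queries uniformly from the background.
  Hypergeometric p-values are discrete, so attained levels approximate
  the nominal 0.05 only for large-enough sizes; the test uses
  N = 2000, K = 200, n = 150, where the attained level is 0.038, well
  inside the asserted 0.05 ± 0.02 band at 2000 replicates.
* Parameter-recovery runs use 200 synthetic cohorts (true fold 5,
  σ = 0.3, 8 samples per group) — large enough that the mean estimate's
  sampling error is a few percent, small enough for a desk-scale suite.
* Ct tables are written at 1e-6-cycle precision, so the noiseless (σ = 0)
  generator round-trips the planted fold to ~1e-6 relative accuracy.
* Tolerant loading: unparseable rows are logged and skipped; a file with
  more than half its rows failing aborts (wrong-file guard).
* Duplicate (sample, assay, replicate) Ct rows and duplicate GMT set
  names are hard errors, not warnings — both indicate corrupted input.

## Known limitations

* Gene-level hosting only; no intron/exon placement, no expression-based
  host–miR co-regulation test.
* The enrichment p-value of any specific live-database run is not a
  reproduction target: it depends on the interaction-catalogue version
  and an unstated background. The package's own background convention is
  declared instead.
* Escape thresholds are dataset conventions, not biological constants;
  they are parameters precisely so sensitivity analyses are possible.
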