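"""miRNA host-gene mapping, tissue-level escape filtering, control selection.

A gene *hosts* a miRNA when the precursor locus lies fully inside the gene
body on the same chromosome (interval containment, not mere overlap);
intragenic miRNAs typically share their host's promoter and hence its XCI
status, which is why escape of the host is evidence for escape of the miR.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from typing import Iterable, Literal

from intervaltree import IntervalTree

from .models import (
    ConfigError,
    GenomicFeature,
    HostingPair,
    Kind,
    TissueEscapeRecord,
)

log = logging.getLogger("xcimir")

StrandPolicy = Literal["same", "ignore"]

#: excluded-gene reasons emitted by the tissue filter
EXCLUSION_REASONS = ("not_in_table", "not_expressed", "nonpositive_logfc")


def map_hosted_mirs(
    genes: Iterable[GenomicFeature],
    mirs: Iterable[GenomicFeature],
    strand_policy: StrandPolicy = "same",
) -> list[HostingPair]:
    """Find every (gene, miRNA) pair with full interval containment.

    With ``strand_policy="same"`` the pair must also be co-oriented
    (features of unknown strand never satisfy the same-strand test). A miR
    contained in several genes yields one pair per containing gene. Output
    is sorted by (gene start, mir start, mir id).
    """
    if strand_policy not in ("same", "ignore"):
        raise ValueError(f"unknown strand_policy {strand_policy!r}")
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        if g.kind is not Kind.GENE:
            raise ValueError(f"{g.feature_id}: expected a gene feature")
        trees[g.chrom].addi(g.start, g.end, g)
    pairs: list[HostingPair] = []
    for m in mirs:
        if m.kind is not Kind.MIRNA:
            raise ValueError(f"{m.feature_id}: expected a mirna feature")
        for iv in trees[m.chrom].overlap(m.start, m.end):
            g = iv.data
            if not g.contains(m):
                continue
            same = g.strand == m.strand and g.strand.value in "+-"
            if strand_policy == "same" and not same:
                continue
            pairs.append(HostingPair(gene=g, mir=m, same_strand=same))
    pairs.sort(key=lambda p: (p.gene.start, p.mir.start, p.mir.feature_id))
    return pairs


def filter_tissue_escape(
    genes: set[str],
    tissue_table: list[TissueEscapeRecord],
    tissue: str,
) -> tuple[set[str], dict[str, str]]:
    """Keep genes with tissue-level evidence of escape.

    A gene is retained iff the table has a record for it in ``tissue`` with
    ``expressed`` true and a strictly positive sex-bias log fold change
    (female-biased expression). Every excluded gene gets exactly one reason:
    ``not_in_table``, ``not_expressed`` or ``nonpositive_logfc``.
    """
    in_tissue = {r.gene: r for r in tissue_table if r.tissue == tissue}
    if not in_tissue:
        raise ConfigError(f"tissue {tissue!r} absent from the tissue table")
    retained: set[str] = set()
    exclusion_log: dict[str, str] = {}
    for gene in genes:
        rec = in_tissue.get(gene)
        if rec is None:
            exclusion_log[gene] = "not_in_table"
        elif not rec.expressed:
            exclusion_log[gene] = "not_expressed"
        elif rec.logfc is None or rec.logfc <= 0:
            exclusion_log[gene] = "nonpositive_logfc"
        else:
            retained.add(gene)
    return retained, exclusion_log


_FAMILY_RE = re.compile(r"(?:hsa-)?(?:miR|mir|let)-(\d+)", re.IGNORECASE)


def mir_family(mir_id: str) -> str | None:
    """Numeric miRNA family of an ID (``hsa-miR-548am`` → ``548``)."""
    m = _FAMILY_RE.search(mir_id)
    return m.group(1) if m else None


def select_control_mirs(
    all_mirs: Iterable[GenomicFeature],
    hosted_mirs: Iterable[GenomicFeature],
    inactivated_gene_loci: Iterable[GenomicFeature],
    k: int = 2,
) -> list[str]:
    """Pick up to ``k`` negative-control miRs from XCI-subject loci.

    Controls are miRs fully contained in genes classified as inactivated,
    disjoint from the hosted escaper miRs. Same-family members of a
    candidate miR are preferred (a family control shares seed biology),
    then lexicographic ID order.
    """
    hosted_ids = {m.feature_id for m in hosted_mirs}
    candidate_families = {mir_family(i) for i in hosted_ids} - {None}
    loci = list(inactivated_gene_loci)
    eligible: list[str] = []
    for m in all_mirs:
        if m.feature_id in hosted_ids:
            continue
        if any(g.contains(m) for g in loci):
            eligible.append(m.feature_id)
    eligible = sorted(set(eligible))
    if not eligible:
        if k > 0:
            log.warning("no eligible control miR in inactivated loci")
        return []
    eligible.sort(key=lambda i: (mir_family(i) not in candidate_families, i))
    return eligible[:k]
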