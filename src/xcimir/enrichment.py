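"""Target extraction, hypergeometric over-representation, candidate ranking.

The over-representation statistic is the one-sided upper-tail
hypergeometric probability (equivalently a one-sided Fisher exact test):
with a background of N genes of which K belong to the set, and a query of
n genes of which k fall in the set,

    p = P(X >= k),   X ~ Hypergeometric(N, K, n).

Multiplicity across gene sets is handled by Benjamini–Hochberg FDR
adjustment.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .models import (
    CandidateRecord,
    DataError,
    EnrichmentResult,
    GeneSet,
    HostingPair,
    TargetInteraction,
)


def get_targets(mir_id: str, interactions: Iterable[TargetInteraction]) -> set[str]:
    """Experimentally validated target genes of one miRNA.

    Arm-specific identifiers match exactly: ``miR-548am-5p`` and
    ``miR-548am-3p`` are distinct. An unknown miR yields the empty set.
    """
    return {t.gene for t in interactions if t.mir_id == mir_id}


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k)."""
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrich(
    query: set[str], sets: Sequence[GeneSet], background: set[str]
) -> list[EnrichmentResult]:
    """Test each gene set for over-representation in the query.

    Every set is intersected with the background before testing; the query
    must already be a subset of the background. Results are BH-adjusted and
    sorted by p-value ascending, ties broken by set name.
    """
    if not background:
        raise DataError("empty background")
    stray = query - background
    if stray:
        raise DataError(f"query genes outside background: {sorted(stray)}")
    N, n = len(background), len(query)
    results = []
    for s in sets:
        inset = s.members & background
        K = len(inset)
        k = len(query & inset)
        results.append(
            EnrichmentResult(
                set_name=s.name, k=k, K=K, n=n, N=N,
                p_value=hypergeom_pvalue(k, K, n, N),
            )
        )
    adjusted = bh_adjust([r.p_value for r in results]) if results else []
    for r, p_adj in zip(results, adjusted):
        r.p_adjusted = p_adj
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjustment, order-preserving, capped at 1."""
    for p in p_values:
        if not 0 < p <= 1:
            raise ValueError(f"p-value {p!r} outside (0, 1]")
    if not p_values:
        return []
    return list(multipletests(list(p_values), method="fdr_bh")[1])


def prioritize(
    candidates: Sequence[
        tuple[str, HostingPair, bool, set[str], Sequence[EnrichmentResult]]
    ],
    pathway_of_interest: str,
    alpha: float = 0.05,
    min_targets: int = 10,
) -> list[CandidateRecord]:
    """Rank candidate miRs by the documented key.

    Sort key, in order: tissue support (desc); pathway of interest enriched
    at adjusted p <= alpha (desc); target count >= min_targets (desc);
    target count (desc); miR ID (asc). Ranks are 1..m.
    """
    records = []
    for mir_id, pair, tissue_supported, targets, enrichments in candidates:
        enriched = sorted(
            e.set_name
            for e in enrichments
            if e.p_adjusted is not None and e.p_adjusted <= alpha
        )
        records.append(
            CandidateRecord(
                mir_id=mir_id,
                host_gene=pair.gene.feature_id,
                tissue_supported=tissue_supported,
                n_targets=len(targets),
                enriched_sets=enriched,
            )
        )
    records.sort(
        key=lambda r: (
            not r.tissue_supported,
            pathway_of_interest not in r.enriched_sets,
            r.n_targets < min_targets,
            -r.n_targets,
            r.mir_id,
        )
    )
    for i, r in enumerate(records, start=1):
        r.rank = i
    return records
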