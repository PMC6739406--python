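"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the code paths they check: the hypergeometric
tail is computed by counting combinations, and host mapping by an
all-pairs coordinate comparison.
"""

import itertools
import math


def hypergeom_tail_by_counting(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by summing combination counts."""
    denom = math.comb(N, n)
    return (
        sum(math.comb(K, j) * math.comb(N - K, n - j) for j in range(k, min(K, n) + 1))
        / denom
    )


def hypergeom_tail_by_enumeration(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by enumerating every n-subset of an N-element universe."""
    universe = range(N)
    inset = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if sum(1 for g in draw if g in inset) >= k:
            hits += 1
    return hits / total


def hosted_pairs_brute_force(genes, mirs, strand_policy="same"):
    """All (gene id, mir id) containment pairs by an all-pairs double loop."""
    out = set()
    for g in genes:
        for m in mirs:
            if g.chrom != m.chrom:
                continue
            if not (g.start <= m.start and m.end <= g.end):
                continue
            if strand_policy == "same" and not (
                g.strand == m.strand and g.strand.value in "+-"
            ):
                continue
            out.add((g.feature_id, m.feature_id))
    return out
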