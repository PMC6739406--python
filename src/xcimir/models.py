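"""Domain types shared by every stage of the XCI-escape miRNA pipeline.

The pipeline reasons about five kinds of evidence:

* per-gene X-chromosome inactivation (XCI) escape calls, in either of two
  dialects — hybrid-line expression counts ("carrel") or inactive-X /
  active-X expression ratios ("cotton");
* genomic intervals for genes and miRNA precursor loci;
* gene-symbol normalization outcomes against an HGNC-style map;
* validated miRNA→target interactions and pathway gene sets;
* qPCR cycle-threshold (Ct) replicates for the validation arm.

All types are plain dataclasses with eager validation: constructing an
inconsistent object raises immediately, so downstream stages can assume
their invariants.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field


class XcimirError(Exception):
    """Base class for all package errors."""


class FormatError(XcimirError):
    """A file does not conform to its documented schema."""


class DialectError(XcimirError):
    """An escape call was passed to the wrong dataset's classifier."""


class DataError(XcimirError):
    """Input data violates a content-level contract (duplicates, missing assays...)."""


class ConfigError(XcimirError):
    """A run configuration or lookup table is unusable."""


class GenerationError(XcimirError):
    """A synthetic-data spec is unsatisfiable."""


class Dataset(str, enum.Enum):
    """Escape-call dialect: hybrid-line counts vs Xi/Xa ratios."""

    CARREL = "carrel"
    COTTON = "cotton"


class Category(str, enum.Enum):
    """XCI status of a gene. Ordered: inactivated < variable < escape."""

    ESCAPE = "escape"
    VARIABLE = "variable"
    INACTIVATED = "inactivated"
    UNKNOWN = "unknown"


#: ordering used by monotonicity checks (unknown deliberately excluded)
CATEGORY_ORDER = {Category.INACTIVATED: 0, Category.VARIABLE: 1, Category.ESCAPE: 2}


class Kind(str, enum.Enum):
    GENE = "gene"
    MIRNA = "mirna"


class Strand(str, enum.Enum):
    PLUS = "+"
    MINUS = "-"
    UNKNOWN = "unknown"


@dataclass
class EscapeCall:
    """One gene's XCI evidence from one source dataset.

    Exactly the fields of the declared dialect are populated: ``n_expressing``
    (out of ``n_lines`` somatic-cell hybrid lines) for carrel-style calls,
    ``xi_xa_ratio`` (inactive-X expression as a fraction of active-X
    expression) for cotton-style calls.
    """

    gene_id: str
    dataset: Dataset
    n_expressing: int | None = None
    n_lines: int | None = None
    xi_xa_ratio: float | None = None
    category: Category = Category.UNKNOWN

    def __post_init__(self) -> None:
        self.dataset = Dataset(self.dataset)
        self.category = Category(self.category)
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.dataset is Dataset.CARREL:
            if self.n_expressing is None:
                raise ValueError(f"{self.gene_id}: carrel call needs n_expressing")
            if self.n_lines is None:
                self.n_lines = 9
            if self.xi_xa_ratio is not None:
                raise ValueError(f"{self.gene_id}: xi_xa_ratio is a cotton field")
            if not 0 <= self.n_expressing <= self.n_lines:
                raise ValueError(
                    f"{self.gene_id}: n_expressing={self.n_expressing} "
                    f"outside 0..{self.n_lines}"
                )
        else:
            if self.xi_xa_ratio is None:
                raise ValueError(f"{self.gene_id}: cotton call needs xi_xa_ratio")
            if self.n_expressing is not None or self.n_lines is not None:
                raise ValueError(f"{self.gene_id}: hybrid-line counts are carrel fields")
            if self.xi_xa_ratio < 0:
                raise ValueError(f"{self.gene_id}: xi_xa_ratio must be >= 0")


@dataclass(frozen=True)
class GenomicFeature:
    """A gene or miRNA precursor locus.

    Coordinates are 0-based half-open internally; GFF3 I/O converts to and
    from the standard 1-based inclusive convention.
    """

    feature_id: str
    kind: Kind
    chrom: str
    start: int
    end: int
    strand: Strand = Strand.UNKNOWN

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", Kind(self.kind))
        object.__setattr__(self, "strand", Strand(self.strand))
        if not self.chrom:
            raise ValueError(f"{self.feature_id}: chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"{self.feature_id}: start must be < end")

    def contains(self, other: "GenomicFeature") -> bool:
        """Full interval inclusion on the same chromosome (boundaries inclusive)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


class MappingStatus(str, enum.Enum):
    APPROVED = "approved"
    ALIAS = "alias"
    PREVIOUS = "previous"
    WITHDRAWN = "withdrawn"
    UNMATCHED = "unmatched"


#: statuses that resolve to an approved symbol
RESOLVABLE = frozenset(
    {MappingStatus.APPROVED, MappingStatus.ALIAS, MappingStatus.PREVIOUS}
)


@dataclass(frozen=True)
class SymbolMapping:
    """Outcome of normalizing one raw gene identifier."""

    input_id: str
    status: MappingStatus
    approved_symbol: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "status", MappingStatus(self.status))
        if (self.approved_symbol is not None) != (self.status in RESOLVABLE):
            raise ValueError(
                f"{self.input_id}: approved_symbol must be present iff "
                f"status is approved/alias/previous (got {self.status.value})"
            )


@dataclass(frozen=True)
class TissueEscapeRecord:
    """Per-(gene, tissue) expression flag and sex-bias log fold change.

    A positive ``logfc`` (female-biased expression) evidences escape from
    XCI in that tissue.
    """

    gene: str
    tissue: str
    expressed: bool
    logfc: float | None = None

    def __post_init__(self) -> None:
        if self.expressed and (self.logfc is None or not math.isfinite(self.logfc)):
            raise ValueError(f"{self.gene}/{self.tissue}: expressed record needs finite logfc")


@dataclass(frozen=True)
class TargetInteraction:
    """One experimentally validated miRNA→gene interaction."""

    mir_id: str
    gene: str
    evidence: str = ""


@dataclass(frozen=True)
class GeneSet:
    """A named pathway gene set (GMT record)."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")


@dataclass
class QpcrSample:
    """Replicate Ct values for one (sample, assay) pair."""

    sample_id: str
    group: str
    assay: str
    ct_replicates: list[float]

    def __post_init__(self) -> None:
        if not self.ct_replicates:
            raise ValueError(f"{self.sample_id}/{self.assay}: needs >=1 replicate")
        for ct in self.ct_replicates:
            if not (math.isfinite(ct) and ct > 0):
                raise ValueError(f"{self.sample_id}/{self.assay}: Ct {ct!r} not finite and > 0")

    @property
    def mean_ct(self) -> float:
        return sum(self.ct_replicates) / len(self.ct_replicates)


@dataclass(frozen=True)
class HostingPair:
    """An escaper gene whose locus fully contains a miRNA locus."""

    gene: GenomicFeature
    mir: GenomicFeature
    containment: str = "full"
    same_strand: bool = True

    def __post_init__(self) -> None:
        if self.gene.kind is not Kind.GENE or self.mir.kind is not Kind.MIRNA:
            raise ValueError("HostingPair requires a gene and a mirna feature")
        if not self.gene.contains(self.mir):
            raise ValueError(
                f"{self.mir.feature_id} not contained in {self.gene.feature_id}"
            )


@dataclass
class ReconcileReport:
    """Set algebra of two normalized escaper lists plus the mapping audit log."""

    set_a: set[str]
    set_b: set[str]
    intersection: set[str]
    union: set[str]
    only_a: set[str]
    only_b: set[str]
    mapping_log: list[SymbolMapping] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.intersection == self.set_a & self.set_b
        assert self.union == self.set_a | self.set_b
        assert self.only_a == self.set_a - self.set_b
        assert self.only_b == self.set_b - self.set_a


@dataclass
class EnrichmentResult:
    """One gene-set over-representation test.

    ``p_value`` is the upper-tail hypergeometric probability of drawing at
    least ``k`` members of a ``K``-gene set when sampling ``n`` genes from a
    background of ``N``.
    """

    set_name: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if not (max(0, self.n + self.K - self.N) <= self.k <= min(self.K, self.n)):
            raise ValueError(f"{self.set_name}: overlap k={self.k} infeasible")
        if not 0 < self.p_value <= 1:
            raise ValueError(f"{self.set_name}: p_value out of (0, 1]")


@dataclass
class CandidateRecord:
    """One prioritized miRNA candidate with its audit trail."""

    mir_id: str
    host_gene: str
    tissue_supported: bool
    n_targets: int
    enriched_sets: list[str]
    rank: int = 0


@dataclass
class FoldChangeResult:
    """Group-vs-group relative quantification by the 2^-ddCt method."""

    assay: str
    group_test: str
    group_calibrator: str
    delta_ct_test: float
    delta_ct_cal: float
    ddct: float
    fold: float
    significant: bool
    per_sample_folds: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("fold must be positive")


@dataclass(frozen=True)
class MfiRatio:
    """Ratio of two median fluorescence intensities (e.g. Bax/Bcl-2)."""

    numerator_label: str
    denominator_label: str
    numerator: float
    denominator: float
    ratio: float

    def __post_init__(self) -> None:
        if self.numerator <= 0 or self.denominator <= 0:
            raise ValueError("MFI values must be > 0")
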