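"""End-to-end driver: escape calling → host mapping → enrichment → ranking.

``run_all`` chains every stage on one ``RunConfig`` and returns a single
consolidated report (also written as JSON when an output directory is
configured) carrying all intermediate counts, the per-gene exclusion logs
and the candidate ranking, so a run is auditable from one file.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import io as xio
from .escape import SymbolMap, classify_calls, normalize_symbols, reconcile
from .enrichment import get_targets, hypergeom_enrich, prioritize
from .hosting import filter_tissue_escape, map_hosted_mirs, select_control_mirs
from .models import Category, ConfigError, Dataset, Kind
from .qpcr import delta_delta_ct

log = logging.getLogger("xcimir")

REPORT_VERSION = "1.0"


@dataclass
class RunConfig:
    """Fully resolved configuration of one pipeline run."""

    carrel_table: str
    cotton_table: str
    symbol_map: str
    genes_gff3: str
    mirs_gff3: str
    tissue_table: str
    targets_table: str
    pathways_gmt: str
    qpcr_table: str | None = None
    out_dir: str | None = None
    escape_min: int = 7
    inactive_max: int = 2
    ratio_min: float = 0.10
    strand_policy: str = "same"
    tissue: str = "fibroblast"
    pathway_of_interest: str = "APOPTOSIS"
    alpha: float = 0.05
    min_targets: int = 10
    n_controls: int = 2
    qpcr_target: str = "hsa-miR-548am-5p"
    qpcr_references: list[str] = field(default_factory=lambda: ["RNU6B", "RNU44"])
    group_test: str = "XX"
    group_calibrator: str = "XY"
    fold_threshold: float = 1.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def for_fixture(cls, fixture_dir: str | Path, **overrides) -> "RunConfig":
        """Config pointing at a directory written by synth.paper_fixture."""
        d = Path(fixture_dir)
        return cls(
            carrel_table=str(d / "carrel.tsv"),
            cotton_table=str(d / "cotton.tsv"),
            symbol_map=str(d / "symbol_map.tsv"),
            genes_gff3=str(d / "genes.gff3"),
            mirs_gff3=str(d / "mirs.gff3"),
            tissue_table=str(d / "tissue.tsv"),
            targets_table=str(d / "targets.tsv"),
            pathways_gmt=str(d / "pathways.gmt"),
            qpcr_table=str(d / "qpcr.tsv"),
            **overrides,
        )

    def validate(self) -> None:
        for name in (
            "carrel_table", "cotton_table", "symbol_map", "genes_gff3",
            "mirs_gff3", "tissue_table", "targets_table", "pathways_gmt",
        ):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ConfigError(f"{name}: no such file {p!r}")
        if self.qpcr_table is not None and not Path(self.qpcr_table).exists():
            raise ConfigError(f"qpcr_table: no such file {self.qpcr_table!r}")
        if not 0 <= self.inactive_max < self.escape_min:
            raise ConfigError("need 0 <= inactive_max < escape_min")
        if not self.ratio_min > 0:
            raise ConfigError("ratio_min must be > 0")
        if self.strand_policy not in ("same", "ignore"):
            raise ConfigError(f"unknown strand_policy {self.strand_policy!r}")
        if not 0 < self.alpha <= 1:
            raise ConfigError("alpha must be in (0, 1]")
        if self.fold_threshold < 1:
            raise ConfigError("fold_threshold must be >= 1")


def _escaper_and_inactivated_ids(calls) -> tuple[list[str], list[str]]:
    esc = [c.gene_id for c in calls if c.category is Category.ESCAPE]
    ina = [c.gene_id for c in calls if c.category is Category.INACTIVATED]
    return esc, ina


def run_all(config: RunConfig) -> dict:
    """Execute every stage and return the consolidated report."""
    config.validate()

    # 1. escape calling + symbol normalization + reconciliation
    carrel = classify_calls(
        xio.read_escape_table(config.carrel_table, Dataset.CARREL),
        escape_min=config.escape_min, inactive_max=config.inactive_max,
    )
    cotton = classify_calls(
        xio.read_escape_table(config.cotton_table, Dataset.COTTON),
        escape_ratio_min=config.ratio_min,
    )
    raw_a, inact_a = _escaper_and_inactivated_ids(carrel)
    raw_b, inact_b = _escaper_and_inactivated_ids(cotton)
    smap = SymbolMap.from_tsv(config.symbol_map)
    valid_a, log_a = normalize_symbols(raw_a, smap)
    valid_b, log_b = normalize_symbols(raw_b, smap)
    recon = reconcile(set(valid_a), set(valid_b))
    inactivated_syms = set(normalize_symbols(inact_a, smap)[0]) | set(
        normalize_symbols(inact_b, smap)[0]
    )

    # 2. host-gene mapping restricted to the union escaper set
    genes = xio.read_gff3(config.genes_gff3, Kind.GENE)
    mirs = xio.read_gff3(config.mirs_gff3, Kind.MIRNA)
    escaper_feats = [g for g in genes if g.feature_id in recon.union]
    pairs = map_hosted_mirs(escaper_feats, mirs, strand_policy=config.strand_policy)
    host_genes = sorted({p.gene.feature_id for p in pairs})

    # 3. tissue-level escape filter on the host genes
    tissue_table = xio.read_tissue_table(config.tissue_table)
    retained, exclusions = filter_tissue_escape(set(host_genes), tissue_table, config.tissue)

    # 4. negative-control miRs from XCI-subject loci
    inact_feats = [g for g in genes if g.feature_id in inactivated_syms]
    controls = select_control_mirs(
        mirs, [p.mir for p in pairs], inact_feats, k=config.n_controls
    )

    # 5. validated targets per hosted miR arm, enrichment, ranking
    interactions = xio.read_targets(config.targets_table)
    known_mirs = {t.mir_id for t in interactions}
    gene_sets = xio.read_gmt(config.pathways_gmt)
    background = set().union(*(s.members for s in gene_sets))
    candidates = []
    seen_arms: set[str] = set()
    for pair in pairs:
        precursor = pair.mir.feature_id
        for arm in (precursor, f"{precursor}-5p", f"{precursor}-3p"):
            if arm not in known_mirs or arm in seen_arms:
                continue
            seen_arms.add(arm)
            targets = get_targets(arm, interactions)
            enrich = hypergeom_enrich(targets & background, gene_sets, background)
            candidates.append(
                (arm, pair, pair.gene.feature_id in retained, targets, enrich)
            )
    ranking = prioritize(
        candidates, config.pathway_of_interest,
        alpha=config.alpha, min_targets=config.min_targets,
    )
    enrichments = {
        arm: [
            {"set_name": e.set_name, "k": e.k, "K": e.K, "n": e.n, "N": e.N,
             "p_value": e.p_value, "p_adjusted": e.p_adjusted}
            for e in enrich
        ]
        for arm, _, _, _, enrich in candidates
    }

    # 6. optional validation-arm quantification
    qpcr_results = []
    if config.qpcr_table is not None:
        samples = xio.read_qpcr(config.qpcr_table)
        assays = sorted({s.assay for s in samples} - set(config.qpcr_references))
        for assay in assays:
            r = delta_delta_ct(
                samples, assay,
                reference_assays=config.qpcr_references,
                group_test=config.group_test,
                group_calibrator=config.group_calibrator,
                fold_threshold=config.fold_threshold,
            )
            qpcr_results.append(
                {"assay": assay, "ddct": r.ddct, "fold": r.fold,
                 "significant": r.significant}
            )

    report = {
        "version": REPORT_VERSION,
        "escape": {
            "carrel_raw_escapers": len(raw_a),
            "carrel_valid": len(valid_a),
            "cotton_raw_escapers": len(raw_b),
            "cotton_valid": len(valid_b),
            "intersection": len(recon.intersection),
            "union": len(recon.union),
            "intersection_genes": sorted(recon.intersection),
            "n_unmatched_or_withdrawn": sum(
                1 for m in log_a + log_b if m.approved_symbol is None
            ),
        },
        "hosting": {
            "n_pairs": len(pairs),
            "n_host_genes": len(host_genes),
            "host_genes": host_genes,
            "pairs": [
                {"gene": p.gene.feature_id, "mir": p.mir.feature_id}
                for p in pairs
            ],
        },
        "tissue_filter": {
            "tissue": config.tissue,
            "retained": sorted(retained),
            "exclusions": dict(sorted(exclusions.items())),
        },
        "controls": controls,
        "ranking": [
            {"rank": r.rank, "mir_id": r.mir_id, "host_gene": r.host_gene,
             "tissue_supported": r.tissue_supported, "n_targets": r.n_targets,
             "enriched_sets": r.enriched_sets}
            for r in ranking
        ],
        "enrichment": enrichments,
        "qpcr": qpcr_results,
        "config": asdict(config),
    }
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        xio.write_report(report, out / "report.json")
        (out / "resolved_config.yaml").write_text(
            yaml.safe_dump(asdict(config), sort_keys=True)
        )
    return report
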