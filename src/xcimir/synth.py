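"""Seeded generators for every input table the pipeline consumes.

All outputs are *synthetic*: they emulate the shapes of the source
databases (hybrid-line escape tables, Xi/Xa ratio tables, an HGNC-style
symbol map, GFF3 annotations on a toy X chromosome, a Tukiainen-style
tissue table, a Tarbase-style target table, KEGG-style GMT gene sets, and
TaqMan-style Ct tables) without downloading anything.

``paper_fixture`` writes a frozen bundle whose downstream counts encode
the published relations this pipeline is designed to reproduce offline:
99 raw / 64 valid hybrid-line escapers, 68 raw / 65 valid ratio escapers,
a 23-gene intersection and 106-gene union; six escaper host genes
containing twelve miRNA loci; a fibroblast filter retaining CTPS2 and
PUDP; 332 validated targets for hsa-miR-548am-5p (including eight
apoptosis-pathway genes) and 3 for hsa-miR-4767; negative-control miRs
hsa-miR-23c and hsa-miR-548ax in XCI-subject loci. Coordinates are a toy
chromosome, not GRCh positions: only the containment topology is real.

Every generator draws all randomness from one explicit seed and validates
its own output (generate → run the corresponding stage → counts equal the
spec) before writing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as xio
from .models import GenerationError, GenomicFeature, Kind, Strand

# ---------------------------------------------------------------------------
# published relations encoded by the frozen fixture bundle

TABLE1_HOSTING: dict[str, list[str]] = {
    "CSF2RA": ["hsa-miR-3690"],
    "CTPS2": ["hsa-miR-548am"],
    "GABRE": ["hsa-miR-224", "hsa-miR-452"],
    "HTR2C": [
        "hsa-miR-1264",
        "hsa-miR-1298",
        "hsa-miR-1911",
        "hsa-miR-1912",
        "hsa-miR-448",
        "hsa-miR-764",
    ],
    "PUDP": ["hsa-miR-4767"],
    "VGLL1": ["hsa-miR-934"],
}

APOPTOSIS_GENES = [
    "APAF1", "ATM", "BAX", "CAPN2", "PIK3R1", "PRKAR2B", "TNFRSF10B", "XIAP",
]

#: fibroblast rows for the six host genes: (expressed, sex-bias logFC)
FIBROBLAST_TISSUE_SPEC: dict[str, tuple[bool, float | None]] = {
    "CSF2RA": (False, None),
    "HTR2C": (False, None),
    "VGLL1": (False, None),
    "GABRE": (True, -0.82),
    "CTPS2": (True, 0.45),
    "PUDP": (True, 0.61),
}

#: XCI-subject loci hosting the negative-control miRs
CONTROL_HOSTING: dict[str, list[str]] = {
    "INAC01": ["hsa-miR-23c"],
    "INAC02": ["hsa-miR-548ax"],
}


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset bundle.

    ``overlap_spec`` is (|A|, |B|, |A∩B|) of the two post-normalization
    escaper sets; ``raw_totals`` the raw identifier counts before
    normalization (None → sizes plus a small excess of duplicates,
    withdrawn and junk identifiers); ``hosting_spec`` maps host genes to
    the miR loci placed inside them; ``qpcr_spec`` is
    (true_fold, sigma, n_per_group, n_replicates).
    """

    seed: int = 17
    overlap_spec: tuple[int, int, int] = (64, 65, 23)
    raw_totals: tuple[int, int] | None = None
    pinned_a_only: tuple[str, ...] = ()
    pinned_b_only: tuple[str, ...] = ()
    pinned_both: tuple[str, ...] = ()
    #: approved symbol -> (raw spelling, map status) used in the raw A list
    raw_overrides_a: dict[str, tuple[str, str]] = field(default_factory=dict)
    n_inactivated: int = 10
    n_variable: int = 6
    hosting_spec: dict[str, list[str]] = field(default_factory=dict)
    inactivated_hosting: dict[str, list[str]] = field(default_factory=dict)
    n_decoy_mirs: int = 50
    tissue: str = "fibroblast"
    tissue_spec: dict[str, tuple[bool, float | None]] = field(default_factory=dict)
    #: mir id -> (total target count, named members to include)
    target_spec: dict[str, tuple[int, list[str]]] = field(default_factory=dict)
    qpcr_spec: tuple[float, float, int, int] = (5.0, 0.2, 8, 3)

    def __post_init__(self) -> None:
        a, b, i = self.overlap_spec
        if min(a, b, i) < 0 or i > min(a, b):
            raise GenerationError(f"inconsistent overlap spec {self.overlap_spec}")
        if len(self.pinned_a_only) > a - i or len(self.pinned_b_only) > b - i:
            raise GenerationError("pinned genes exceed the requested set sizes")
        if len(self.pinned_both) > i:
            raise GenerationError("pinned shared genes exceed the intersection size")
        if self.raw_totals is not None and (
            self.raw_totals[0] < a or self.raw_totals[1] < b
        ):
            raise GenerationError("raw totals cannot be below the valid set sizes")
        fold, sigma, n, reps = self.qpcr_spec
        if fold <= 0 or sigma < 0 or n < 1 or reps < 1:
            raise GenerationError(f"invalid qpcr spec {self.qpcr_spec}")
        for mir, (count, named) in self.target_spec.items():
            if count < len(named):
                raise GenerationError(f"{mir}: target count below named members")


# ---------------------------------------------------------------------------
# escape tables + symbol map


def _raw_form(sym: str, idx: int, overrides: dict[str, tuple[str, str]]):
    """Deterministic raw spelling for an approved symbol: (raw, status)."""
    if sym in overrides:
        return overrides[sym]
    if idx % 5 == 2:
        return f"ALI{sym}", "alias"
    if idx % 5 == 4:
        return f"PRV{sym}", "previous"
    return sym, "approved"


def gen_escape_tables(spec: FixtureSpec, seed: int, out_dir: str | Path) -> dict:
    """Write carrel.tsv, cotton.tsv and symbol_map.tsv for a FixtureSpec.

    The raw identifier lists resolve, after symbol normalization, to sets
    of exactly the requested sizes and overlap; raw lists are padded with
    duplicates, withdrawn and unmatched identifiers so normalization is
    exercised. Returns the expected post-normalization sets.
    """
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    a, b, i = spec.overlap_spec

    pool = iter(f"ESC{j:03d}" for j in range(1, 1000))
    both = list(spec.pinned_both) + [next(pool) for _ in range(i - len(spec.pinned_both))]
    only_a = list(spec.pinned_a_only) + [
        next(pool) for _ in range(a - i - len(spec.pinned_a_only))
    ]
    only_b = list(spec.pinned_b_only) + [
        next(pool) for _ in range(b - i - len(spec.pinned_b_only))
    ]
    set_a, set_b = only_a + both, only_b + both
    inact = list(spec.inactivated_hosting) + [
        f"INA{j:02d}" for j in range(1, spec.n_inactivated - len(spec.inactivated_hosting) + 1)
    ]
    variable = [f"VAR{j:02d}" for j in range(1, spec.n_variable + 1)]

    # symbol map: approved self-rows for every real symbol, plus the alias /
    # previous raw spellings and some withdrawn identifiers
    map_rows: list[tuple[str, str, str]] = []
    for sym in sorted(set(set_a) | set(set_b) | set(inact) | set(variable)):
        map_rows.append((sym, "approved", sym))

    def raw_list(symbols: list[str], overrides: dict[str, tuple[str, str]]) -> list[str]:
        raws = []
        for idx, sym in enumerate(symbols):
            raw, status = _raw_form(sym, idx, overrides)
            raws.append(raw)
            if status != "approved":
                map_rows.append((raw, status, sym))
        return raws

    raw_a = raw_list(set_a, spec.raw_overrides_a)
    raw_b = raw_list(set_b, {})

    totals = spec.raw_totals or (a + max(3, a // 10) if a else 0,
                                 b + max(3, b // 10) if b else 0)

    def pad(raws: list[str], total: int, tag: str) -> list[str]:
        extra = total - len(raws)
        if extra <= 0:
            return raws
        n_dup = min(extra * 60 // 100, len(raws))
        n_wdn = (extra - n_dup) * 60 // 100
        n_junk = extra - n_dup - n_wdn
        padded = list(raws) + raws[:n_dup]
        for j in range(1, n_wdn + 1):
            wid = f"WDN{tag}{j:02d}"
            map_rows.append((wid, "withdrawn", ""))
            padded.append(wid)
        padded += [f"JUNK{tag}{j:02d}" for j in range(1, n_junk + 1)]
        return padded

    raw_a = pad(raw_a, totals[0], "A")
    raw_b = pad(raw_b, totals[1], "B")

    carrel_rows = [(g, int(rng.integers(7, 10)), 9) for g in raw_a]
    carrel_rows += [(g, int(rng.integers(3, 7)), 9) for g in variable]
    carrel_rows += [(g, int(rng.integers(0, 3)), 9) for g in inact]
    cotton_rows = [(g, round(float(rng.uniform(0.12, 0.95)), 3)) for g in raw_b]
    cotton_rows += [(g, round(float(rng.uniform(0.0, 0.09)), 3)) for g in inact]
    rng.shuffle(carrel_rows)
    rng.shuffle(cotton_rows)

    with open(out / "carrel.tsv", "w") as fh:
        fh.write("gene\tn_expressing\tn_lines\n")
        fh.writelines(f"{g}\t{n}\t{t}\n" for g, n, t in carrel_rows)
    with open(out / "cotton.tsv", "w") as fh:
        fh.write("gene\txi_xa_ratio\n")
        fh.writelines(f"{g}\t{r}\n" for g, r in cotton_rows)
    with open(out / "symbol_map.tsv", "w") as fh:
        fh.write("input_id\tstatus\tapproved_symbol\n")
        fh.writelines(f"{i_}\t{s}\t{ap}\n" for i_, s, ap in sorted(set(map_rows)))

    return {
        "set_a": sorted(set_a),
        "set_b": sorted(set_b),
        "inactivated": sorted(inact),
        "variable": sorted(variable),
        "raw_counts": (len(raw_a), len(raw_b)),
    }


# ---------------------------------------------------------------------------
# annotation


def gen_annotation(
    spec: FixtureSpec,
    seed: int,
    out_dir: str | Path,
    other_genes: list[str] | None = None,
    chrom: str = "chrX_syn",
    gene_length: int = 20_000,
    gap: int = 10_000,
) -> dict:
    """Write genes.gff3 and mirs.gff3 for a toy X chromosome.

    Host genes receive their specified miRs strictly inside the gene body
    on the same strand; decoy miRs land in intergenic gaps. A brute-force
    containment check guards against unintended hosting before writing.
    """
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    hosting = dict(spec.hosting_spec)
    hosting.update(spec.inactivated_hosting)
    names = sorted(set(hosting) | set(other_genes or []))
    genes: dict[str, GenomicFeature] = {}
    pos = 10_000
    for name in names:
        strand = Strand.PLUS if rng.random() < 0.5 else Strand.MINUS
        genes[name] = GenomicFeature(name, Kind.GENE, chrom, pos, pos + gene_length, strand)
        pos += gene_length + gap

    mirs: list[GenomicFeature] = []
    for host, mir_ids in sorted(hosting.items()):
        g = genes[host]
        if 500 + len(mir_ids) * 1500 + 100 > gene_length:
            raise GenerationError(f"{host}: too many miRs for the gene length")
        for j, mid in enumerate(mir_ids):
            s = g.start + 500 + j * 1500
            mirs.append(GenomicFeature(mid, Kind.MIRNA, chrom, s, s + 80, g.strand))

    # decoys: one per intergenic gap, the rest in the tail past the last gene
    gap_starts = [g.end + gap // 2 for g in genes.values()][: spec.n_decoy_mirs]
    tail = pos + gap
    while len(gap_starts) < spec.n_decoy_mirs:
        gap_starts.append(tail)
        tail += 500
    for j, s in enumerate(gap_starts, start=1):
        strand = Strand.PLUS if rng.random() < 0.5 else Strand.MINUS
        mirs.append(GenomicFeature(f"hsa-miR-9{j:03d}", Kind.MIRNA, chrom, s, s + 80, strand))

    hosted = {m for ids in hosting.values() for m in ids}
    for m in mirs:  # brute-force post-hoc check, independent of the mapper
        containers = [g.feature_id for g in genes.values() if g.contains(m)]
        want = [h for h, ids in hosting.items() if m.feature_id in ids]
        if sorted(containers) != sorted(want):
            raise GenerationError(
                f"{m.feature_id}: containment {containers} != intended {want}"
            )
        if m.feature_id not in hosted and containers:
            raise GenerationError(f"decoy {m.feature_id} landed inside {containers}")

    xio.write_gff3(genes.values(), out / "genes.gff3")
    xio.write_gff3(mirs, out / "mirs.gff3")
    return {"n_genes": len(genes), "n_mirs": len(mirs), "hosting": hosting}


# ---------------------------------------------------------------------------
# tissue, targets, pathways


def gen_tissue_table(spec: FixtureSpec, seed: int, out_dir: str | Path,
                     extra_genes: list[str] | None = None) -> Path:
    """Write tissue.tsv: per-(gene, tissue) expressed flag and sex-bias logFC."""
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [
        (g, spec.tissue, exp, "" if lfc is None else f"{lfc:.3f}")
        for g, (exp, lfc) in sorted(spec.tissue_spec.items())
    ]
    for g in sorted(extra_genes or []):
        if g in spec.tissue_spec:
            continue
        exp = bool(rng.random() < 0.8)
        lfc = f"{float(rng.normal(0.3, 0.4)):.3f}" if exp else ""
        rows.append((g, spec.tissue, exp, lfc))
    path = out / "tissue.tsv"
    with open(path, "w") as fh:
        fh.write("gene\ttissue\texpressed\tlogfc\n")
        fh.writelines(f"{g}\t{t}\t{str(e).lower()}\t{l}\n" for g, t, e, l in rows)
    return path


def gen_target_db(spec: FixtureSpec, seed: int, out_dir: str | Path) -> Path:
    """Write targets.tsv giving each miR exactly its specified target count."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows: list[tuple[str, str]] = []
    filler = 0
    for mir, (count, named) in sorted(spec.target_spec.items()):
        for g in named:
            rows.append((mir, g))
        for _ in range(count - len(named)):
            filler += 1
            rows.append((mir, f"TGT{filler:04d}"))
    path = out / "targets.tsv"
    with open(path, "w") as fh:
        fh.write("mir_id\tgene\tevidence\n")
        fh.writelines(f"{m}\t{g}\tsynthetic\n" for m, g in rows)
    return path


def gen_pathways(sets: dict[str, list[str]], out_dir: str | Path) -> Path:
    """Write pathways.gmt from an explicit name → members mapping."""
    from .models import GeneSet

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "pathways.gmt"
    xio.write_gmt(
        [GeneSet(name=n, members=frozenset(m)) for n, m in sets.items()], path
    )
    return path


def gen_planted_enrichment(
    N: int, K: int, n: int, k: int, seed: int
) -> tuple[set[str], "object", set[str]]:
    """Background, gene set and query with an exactly known overlap.

    The upper-tail hypergeometric p of the planted configuration is
    analytically determined by (N, K, n, k).
    """
    from .models import GeneSet

    if not (0 <= K <= N and 0 <= n <= N and max(0, n + K - N) <= k <= min(K, n)):
        raise GenerationError(f"infeasible enrichment spec N={N} K={K} n={n} k={k}")
    rng = np.random.default_rng(seed)
    names = [f"BG{j:04d}" for j in range(N)]
    rng.shuffle(names)
    background = set(names)
    members = names[:K]
    query = set(members[:k]) | set(names[K : K + (n - k)])
    return background, GeneSet(name="PLANTED", members=frozenset(members)), query


# ---------------------------------------------------------------------------
# qPCR


def gen_qpcr(
    true_fold: float,
    sigma: float,
    n_per_group: int,
    n_replicates: int,
    seed: int,
    out_dir: str | Path,
    target_assay: str = "hsa-miR-548am-5p",
    reference_assays: tuple[str, ...] = ("RNU6B", "RNU44"),
    null_assays: tuple[str, ...] = (),
    group_test: str = "XX",
    group_calibrator: str = "XY",
) -> Path:
    """Write a replicate-level Ct table with a planted group fold change.

    Reference Cts sit around a base level of 20 cycles, targets around 25;
    the test group's target Ct is shifted by −log2(true_fold). Each sample
    carries a shared input-amount offset (cancels in dCt) and each well
    Normal(0, sigma) replicate noise.
    """
    if true_fold <= 0 or sigma < 0 or n_per_group < 1 or n_replicates < 1:
        raise GenerationError("invalid qPCR generator parameters")
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "qpcr.tsv"
    rows = []
    for group in (group_test, group_calibrator):
        for s in range(1, n_per_group + 1):
            sample = f"{group}{s:02d}"
            input_offset = float(rng.normal(0.0, 0.5))
            assay_base = {a: 20.0 for a in reference_assays}
            assay_base[target_assay] = 25.0 - (
                np.log2(true_fold) if group == group_test else 0.0
            )
            for a in null_assays:
                assay_base[a] = 24.0
            for assay, base in assay_base.items():
                for rep in range(1, n_replicates + 1):
                    ct = base + input_offset + float(rng.normal(0.0, sigma))
                    rows.append((sample, group, assay, rep, f"{max(ct, 1.0):.6f}"))
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\tassay\treplicate\tct\n")
        fh.writelines(f"{s}\t{g}\t{a}\t{r}\t{c}\n" for s, g, a, r, c in rows)
    return path


# ---------------------------------------------------------------------------
# the frozen paper fixture


def paper_fixture_spec() -> FixtureSpec:
    """The FixtureSpec whose bundle encodes the published relations."""
    return FixtureSpec(
        overlap_spec=(64, 65, 23),
        raw_totals=(99, 68),
        pinned_a_only=("CTPS2",),
        pinned_b_only=("CSF2RA", "GABRE", "HTR2C", "VGLL1"),
        pinned_both=("PUDP",),
        raw_overrides_a={"PUDP": ("HDHD1", "previous")},
        hosting_spec=dict(TABLE1_HOSTING),
        inactivated_hosting=dict(CONTROL_HOSTING),
        tissue_spec=dict(FIBROBLAST_TISSUE_SPEC),
        target_spec={
            "hsa-miR-548am-5p": (332, list(APOPTOSIS_GENES)),
            "hsa-miR-4767": (3, []),
            "hsa-miR-23c": (15, []),
            "hsa-miR-548ax": (20, []),
        },
    )


def _paper_pathway_sets() -> dict[str, list[str]]:
    """Apoptosis (planted enrichment) plus six unenriched decoy pathways.

    Ten filler targets of hsa-miR-548am-5p are scattered over two decoy
    sets so the effective query exceeds the eight apoptosis genes without
    making any decoy significant.
    """
    sets = {"APOPTOSIS": APOPTOSIS_GENES + [f"APOG{j:02d}" for j in range(1, 33)]}
    decoys = [
        "P53_PATHWAY", "PROTEIN_UBIQUITINATION", "CELL_CYCLE",
        "FOCAL_ADHESION", "WNT_SIGNALING", "MAPK_SIGNALING",
    ]
    filler = 0
    for d, name in enumerate(decoys):
        members = [f"{name[:4]}{j:02d}" for j in range(1, 36)]
        if name in ("P53_PATHWAY", "PROTEIN_UBIQUITINATION"):
            members += [f"TGT{j:04d}" for j in range(filler + 1, filler + 6)]
            filler += 5
        sets[name] = members
    return sets


def paper_fixture(out_dir: str | Path, seed: int = 17) -> dict:
    """Write the complete fixture bundle plus a manifest of expected counts.

    The bundle's topology and counts are fixed by construction; the seed
    only moves row order, decoy strands and qPCR noise.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = paper_fixture_spec()
    esc = gen_escape_tables(spec, seed, out)
    union = sorted(set(esc["set_a"]) | set(esc["set_b"]))
    ann = gen_annotation(
        spec,
        seed + 1,
        out,
        other_genes=union + esc["inactivated"] + esc["variable"],
    )
    gen_tissue_table(spec, seed + 2, out, extra_genes=union[:20])
    gen_target_db(spec, seed + 3, out)
    gen_pathways(_paper_pathway_sets(), out)
    fold, sigma, n, reps = spec.qpcr_spec
    gen_qpcr(
        fold, sigma, n, reps, seed + 4, out,
        null_assays=("hsa-miR-23c", "hsa-miR-548ax"),
    )
    manifest = {
        "carrel_raw": esc["raw_counts"][0],
        "carrel_valid": len(esc["set_a"]),
        "cotton_raw": esc["raw_counts"][1],
        "cotton_valid": len(esc["set_b"]),
        "intersection": len(set(esc["set_a"]) & set(esc["set_b"])),
        "union": len(union),
        "host_genes": len(spec.hosting_spec),
        "hosting_pairs": sum(len(v) for v in spec.hosting_spec.values()),
        "tissue_retained": ["CTPS2", "PUDP"],
        "control_mirs": ["hsa-miR-548ax", "hsa-miR-23c"],
        "n_targets": {m: c for m, (c, _) in spec.target_spec.items()},
        "qpcr_true_fold": fold,
        "top_candidate": "hsa-miR-548am-5p",
        "files": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
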