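"""Host-gene mapping, tissue filtering and control-miR selection."""

import numpy as np
import pytest

from xcimir import io as xio
from xcimir.hosting import (
    filter_tissue_escape,
    map_hosted_mirs,
    mir_family,
    select_control_mirs,
)
from xcimir.models import (
    ConfigError,
    GenomicFeature,
    Kind,
    Strand,
    TissueEscapeRecord,
)
from xcimir.synth import FIBROBLAST_TISSUE_SPEC, TABLE1_HOSTING

from .oracles import hosted_pairs_brute_force


def gene(fid, start, end, chrom="chrX", strand=Strand.PLUS):
    return GenomicFeature(fid, Kind.GENE, chrom, start, end, strand)


def mir(fid, start, end, chrom="chrX", strand=Strand.PLUS):
    return GenomicFeature(fid, Kind.MIRNA, chrom, start, end, strand)


def random_annotation(rng, n_genes, n_mirs):
    chroms = ["chrX", "chr7"]
    genes, mirs = [], []
    for i in range(n_genes):
        s = int(rng.integers(0, 5000))
        genes.append(
            gene(f"G{i}", s, s + int(rng.integers(1, 800)),
                 chrom=chroms[int(rng.integers(2))],
                 strand=Strand.PLUS if rng.random() < 0.5 else Strand.MINUS)
        )
    for i in range(n_mirs):
        s = int(rng.integers(0, 5500))
        mirs.append(
            mir(f"M{i}", s, s + int(rng.integers(1, 120)),
                chrom=chroms[int(rng.integers(2))],
                strand=Strand.PLUS if rng.random() < 0.5 else Strand.MINUS)
        )
    return genes, mirs


class TestMapHostedMirs:
    def test_matches_brute_force_on_random_annotations(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            genes, mirs = random_annotation(
                rng, int(rng.integers(1, 100)), int(rng.integers(1, 100))
            )
            for policy in ("same", "ignore"):
                got = {
                    (p.gene.feature_id, p.mir.feature_id)
                    for p in map_hosted_mirs(genes, mirs, policy)
                }
                assert got == hosted_pairs_brute_force(genes, mirs, policy)

    def test_ignore_policy_never_returns_fewer_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            genes, mirs = random_annotation(rng, 40, 40)
            same = map_hosted_mirs(genes, mirs, "same")
            ignore = map_hosted_mirs(genes, mirs, "ignore")
            assert len(ignore) >= len(same)

    def test_outside_gene_is_not_hosted(self):
        assert map_hosted_mirs([gene("G", 100, 200)], [mir("M", 300, 350)]) == []

    def test_equal_intervals_count_as_hosted(self):
        pairs = map_hosted_mirs([gene("G", 100, 200)], [mir("M", 100, 200)])
        assert len(pairs) == 1

    def test_nested_genes_yield_two_pairs(self):
        genes = [gene("OUTER", 0, 1000), gene("INNER", 100, 500)]
        pairs = map_hosted_mirs(genes, [mir("M", 200, 300)])
        assert {p.gene.feature_id for p in pairs} == {"OUTER", "INNER"}

    def test_cross_chromosome_never_matches(self):
        assert map_hosted_mirs(
            [gene("G", 0, 1000, chrom="chrX")], [mir("M", 10, 50, chrom="chr7")]
        ) == []

    def test_output_sorted_by_gene_then_mir_start(self):
        genes = [gene("B", 500, 900), gene("A", 0, 400)]
        mirs = [mir("M2", 600, 650), mir("M1", 100, 150)]
        pairs = map_hosted_mirs(genes, mirs)
        assert [(p.gene.feature_id, p.mir.feature_id) for p in pairs] == [
            ("A", "M1"), ("B", "M2"),
        ]

    def test_fixture_reproduces_hosting_table(self, fixture_dir, fixture_manifest):
        genes = xio.read_gff3(fixture_dir / "genes.gff3", Kind.GENE)
        mirs_ = xio.read_gff3(fixture_dir / "mirs.gff3", Kind.MIRNA)
        # escaper genes only: drop the inactivated (INA*) and variable loci
        pairs = map_hosted_mirs(
            [g for g in genes if not g.feature_id.startswith(("INA", "VAR"))], mirs_
        )
        got = {}
        for p in pairs:
            got.setdefault(p.gene.feature_id, []).append(p.mir.feature_id)
        assert {g: sorted(m) for g, m in got.items()} == {
            g: sorted(m) for g, m in TABLE1_HOSTING.items()
        }
        assert len(pairs) == fixture_manifest["hosting_pairs"] == 12


FIB_TABLE = [
    TissueEscapeRecord(g, "fibroblast", exp, lfc)
    for g, (exp, lfc) in FIBROBLAST_TISSUE_SPEC.items()
]


class TestTissueFilter:
    def test_reproduces_published_exclusions(self):
        retained, reasons = filter_tissue_escape(
            set(TABLE1_HOSTING), FIB_TABLE, "fibroblast"
        )
        assert retained == {"CTPS2", "PUDP"}
        assert reasons == {
            "CSF2RA": "not_expressed",
            "HTR2C": "not_expressed",
            "VGLL1": "not_expressed",
            "GABRE": "nonpositive_logfc",
        }

    def test_gene_without_record_gets_not_in_table(self):
        retained, reasons = filter_tissue_escape({"NOVEL"}, FIB_TABLE, "fibroblast")
        assert retained == set() and reasons == {"NOVEL": "not_in_table"}

    def test_zero_logfc_excludes(self):
        table = [TissueEscapeRecord("G", "fibroblast", True, 0.0)]
        _, reasons = filter_tissue_escape({"G"}, table, "fibroblast")
        assert reasons == {"G": "nonpositive_logfc"}

    def test_partitions_input(self):
        genes = set(TABLE1_HOSTING) | {"NOVEL"}
        retained, reasons = filter_tissue_escape(genes, FIB_TABLE, "fibroblast")
        assert retained | set(reasons) == genes
        assert retained.isdisjoint(reasons)

    def test_unknown_tissue_is_config_error(self):
        with pytest.raises(ConfigError):
            filter_tissue_escape({"CTPS2"}, FIB_TABLE, "liver")


class TestControlSelection:
    def test_family_member_preferred_then_lexicographic(self):
        loci = [gene("INAC", 0, 1000)]
        pool = [mir("hsa-miR-23c", 10, 90), mir("hsa-miR-548ax", 200, 280),
                mir("hsa-miR-548am", 5000, 5080)]
        hosted = [mir("hsa-miR-548am", 5000, 5080)]
        assert select_control_mirs(pool, hosted, loci, k=2) == [
            "hsa-miR-548ax", "hsa-miR-23c",
        ]

    def test_k_zero_returns_empty(self):
        assert select_control_mirs([mir("M", 0, 10)], [], [gene("G", 0, 100)], k=0) == []

    def test_no_eligible_pool_warns(self, caplog):
        hosted = [mir("M", 10, 20)]
        out = select_control_mirs(hosted, hosted, [gene("G", 0, 100)], k=2)
        assert out == []
        assert any("control" in r.message for r in caplog.records)

    def test_fixture_controls(self, fixture_report, fixture_manifest):
        assert fixture_report["controls"] == fixture_manifest["control_mirs"]


@pytest.mark.parametrize(
    "mid,family",
    [("hsa-miR-548am", "548"), ("hsa-miR-548ax-5p", "548"),
     ("hsa-miR-23c", "23"), ("hsa-let-7a", "7"), ("SNORD1", None)],
)
def test_mir_family(mid, family):
    assert mir_family(mid) == family
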