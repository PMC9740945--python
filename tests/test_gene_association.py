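import numpy as np
import pytest

from regmap.gene_association import (
    associate,
    build_domains,
    classify_distance,
    partition_genes,
)
from regmap.genome_io import GeneModel, GenomeDescriptor, GenomicInterval
from regmap.region_calling import RegionMap

from oracles import associate_oracle, domain_oracle


def gene(gid, tss, strand="+", chrom="chr1"):
    tes = tss + 10_000 if strand == "+" else tss - 10_000
    return GeneModel(gid, chrom, strand, tss, tes)


class TestBuildDomains:
    def test_lone_gene_capped_by_max_extension(self):
        genome = GenomeDescriptor({"chr1": 2_000_000})
        (dom,) = build_domains([gene("g", 600_000)], genome)
        assert dom.basal == GenomicInterval("chr1", 598_000, 602_000, "+")
        assert dom.extended == GenomicInterval("chr1", 100_000, 1_100_000, "+")

    def test_neighbors_stop_at_each_others_basal(self):
        genome = GenomeDescriptor({"chr1": 2_000_000})
        doms = {
            d.gene.gene_id: d
            for d in build_domains([gene("A", 100_000), gene("B", 110_000)], genome)
        }
        assert doms["A"].extended.end == 108_000  # B's basal left edge
        assert doms["B"].extended.start == 102_000  # A's basal right edge
        # the midpoint of the shared gap lies in both extended domains
        for d in doms.values():
            assert d.extended.start <= 105_000 < d.extended.end

    def test_clipped_at_chromosome_start(self):
        genome = GenomeDescriptor({"chr1": 2_000_000})
        (dom,) = build_domains([gene("g", 1000)], genome)
        assert dom.extended.start == 0
        assert dom.basal.start == 0

    def test_basal_contains_tss_and_extended_contains_basal(self):
        rng = np.random.default_rng(8)
        genome = GenomeDescriptor({"chr1": 5_000_000})
        genes = [
            gene(f"g{i}", int(t), "+" if rng.random() < 0.5 else "-")
            for i, t in enumerate(np.sort(rng.integers(20_000, 4_900_000, 30)))
        ]
        genes = [g for i, g in enumerate(genes)
                 if i == 0 or abs(g.tss - genes[i - 1].tss) > 100]
        for dom in build_domains(genes, genome):
            assert dom.extended.start <= dom.basal.start
            assert dom.basal.end <= dom.extended.end
            assert dom.basal.start <= dom.gene.tss < dom.basal.end

    def test_extension_never_invades_foreign_basal(self):
        rng = np.random.default_rng(15)
        genome = GenomeDescriptor({"chr1": 3_000_000})
        genes = [gene(f"g{i}", int(t))
                 for i, t in enumerate(sorted(set(rng.integers(10_000, 2_900_000, 25))))]
        doms = build_domains(genes, genome)
        for d in doms:
            for other in doms:
                if other.gene.gene_id == d.gene.gene_id:
                    continue
                ob = other.basal
                # non-basal flanks of d.extended must not intrude into ob
                left = (d.extended.start, d.basal.start)
                right = (d.basal.end, d.extended.end)
                for lo, hi in (left, right):
                    if lo < hi:
                        assert ob.start >= hi or ob.end <= lo


class TestClassification:
    @pytest.mark.parametrize(
        "distance,klass",
        [
            (0, "proximal"),
            (2000, "proximal"),
            (-2000, "proximal"),
            (2001, "distal"),
            (-2001, "distal"),
            (500_000, "distal"),
            (500_001, None),
        ],
    )
    def test_boundaries(self, distance, klass):
        assert classify_distance(distance) == klass


class TestAssociate:
    def setup_map(self, spans):
        return RegionMap(regions=[GenomicInterval("chr1", s, e) for s, e in spans])

    def test_proximal_and_distal_examples(self):
        genome = GenomeDescriptor({"chr1": 2_000_000})
        domains = build_domains([gene("g", 600_000)], genome)
        region_map = self.setup_map([(601_400, 601_600), (649_900, 650_100)])
        assoc = associate(region_map, domains)
        klasses = {a.region_id: (a.klass, a.signed_distance) for a in assoc}
        assert klasses["region_00000"] == ("proximal", 1500)
        assert klasses["region_00001"] == ("distal", 50_000)

    def test_upstream_distance_is_negative_and_strand_aware(self):
        genome = GenomeDescriptor({"chr1": 2_000_000})
        minus = gene("m", 600_000, "-")
        domains = build_domains([minus], genome)
        # midpoint right of a minus-strand TSS is upstream -> negative
        region_map = self.setup_map([(604_900, 605_100)])
        (a,) = associate(region_map, domains)
        assert a.signed_distance == -5000

    def test_matches_exhaustive_pair_oracle(self):
        rng = np.random.default_rng(23)
        chrom_len = 3_000_000
        genome = GenomeDescriptor({"chr1": chrom_len})
        for _ in range(30):
            n_genes = int(rng.integers(2, 12))
            tss = sorted(set(int(t) for t in rng.integers(5000, chrom_len - 5000, n_genes)))
            strands = [("+", "-")[int(rng.integers(0, 2))] for _ in tss]
            genes = [gene(f"g{i}", t, s) for i, (t, s) in enumerate(zip(tss, strands))]
            regions = []
            for _ in range(int(rng.integers(1, 25))):
                s = int(rng.integers(0, chrom_len - 2000))
                regions.append((s, s + int(rng.integers(100, 2000))))
            region_map = self.setup_map(regions)
            got = {
                (a.region_id, a.gene_id, a.klass)
                for a in associate(region_map, build_domains(genes, genome))
            }
            expected = associate_oracle(
                [(rid, s, e) for rid, (s, e) in zip(region_map.region_ids(), regions)],
                [(g.gene_id, g.tss, g.strand) for g in genes],
                chrom_len,
            )
            assert got == expected

    def test_association_monotone_in_max_extension(self):
        rng = np.random.default_rng(31)
        chrom_len = 3_000_000
        genome = GenomeDescriptor({"chr1": chrom_len})
        tss = sorted(set(int(t) for t in rng.integers(5000, chrom_len - 5000, 8)))
        genes = [gene(f"g{i}", t) for i, t in enumerate(tss)]
        regions = []
        for _ in range(40):
            s = int(rng.integers(0, chrom_len - 1000))
            regions.append((s, s + 500))
        region_map = self.setup_map(regions)
        small = {
            (a.region_id, a.gene_id)
            for a in associate(region_map, build_domains(genes, genome, max_ext=100_000))
        }
        large = {
            (a.region_id, a.gene_id)
            for a in associate(region_map, build_domains(genes, genome, max_ext=500_000))
        }
        assert small <= large


class TestPartitionGenes:
    def make(self, triples):
        from regmap.gene_association import RegionGeneAssociation

        return [
            RegionGeneAssociation(region_id=r, gene_id=g, signed_distance=d, klass=k)
            for r, g, d, k in triples
        ]

    def test_group_membership(self):
        assoc = self.make(
            [
                ("r1", "gA", 10_000, "distal"),
                ("r2", "gA", -30_000, "distal"),
                ("r3", "gA", 40_000, "distal"),
                ("r4", "gA", 500, "proximal"),
                ("r5", "gB", 10_000, "distal"),
                ("r6", "gB", 20_000, "distal"),
                ("r4", "gC", 1000, "proximal"),
            ]
        )
        table = partition_genes(assoc)
        assert table.group("D2") == {"gA"}
        assert table.group("D1") == {"gB"}
        assert table.group("P") == {"gA", "gC"}
        # D1 and D2 partition the distal genes
        d_genes = set(table.genes.loc[table.genes["n_distal"] >= 1, "gene_id"])
        assert table.group("D1") | table.group("D2") == d_genes
        assert not (table.group("D1") & table.group("D2"))

    def test_region_level_counts(self):
        assoc = self.make(
            [
                ("r1", "gA", 10_000, "distal"),
                ("r1", "gB", -20_000, "distal"),
                ("r2", "gA", 500, "proximal"),
            ]
        )
        table = partition_genes(assoc)
        assert table.n_distal_regions == 1
        assert table.n_proximal_regions == 1
        row = table.regions.set_index("region_id").loc["r1"]
        assert row["n_distal_genes"] == 2 and row["n_genes"] == 2

    def test_duplicate_associations_count_once(self):
        assoc = self.make(
            [("r1", "gA", 5000, "distal"), ("r1", "gA", 5000, "distal")]
        )
        table = partition_genes(assoc)
        assert table.genes.set_index("gene_id").loc["gA", "n_distal"] == 1

    def test_no_associations_empty_table(self):
        table = partition_genes([])
        assert len(table.genes) == 0 and len(table.regions) == 0
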