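import io

import numpy as np
import pytest

from regmap.errors import AnnotationError, CoordinateError, FormatError
from regmap.genome_io import (
    FeatureTrack,
    GenomeDescriptor,
    GenomicInterval,
    intersect_any,
    parse_region_string,
    read_bed,
    read_gene_annotation,
    read_sam_records,
    write_bed,
)

from oracles import brute_overlap_flags


class TestParseRegionString:
    # printed 1-based fully-closed coordinates and their expected lengths
    @pytest.mark.parametrize(
        "text,chrom,length",
        [
            ("chr13:99,498,575- 99,499,229", "chr13", 655),
            ("chr4:41,934,622- 41,935,299", "chr4", 678),
            ("chr10:103,396,330- 103,396,860", "chr10", 531),
            ("chr6:26,171,938- 26,172,533", "chr6", 596),
            ("chr2:20,822,774- 20,823,142", "chr2", 369),
            ("chr3:9,791,789- 9,792,567", "chr3", 779),
            ("chr1:1-1", "chr1", 1),
        ],
    )
    def test_one_based_closed_lengths(self, text, chrom, length):
        iv = parse_region_string(text)
        assert iv.chrom == chrom
        assert iv.length == length

    def test_single_base_maps_to_zero_based(self):
        assert parse_region_string("chr1:1-1") == GenomicInterval("chr1", 0, 1)

    @pytest.mark.parametrize("bad", ["chr1", "chr1:10", "chr1:a-b", ""])
    def test_malformed_rejected(self, bad):
        with pytest.raises(FormatError):
            parse_region_string(bad)

    def test_inverted_coordinates_rejected(self):
        with pytest.raises(CoordinateError):
            parse_region_string("chr1:500-100")


class TestGenomicInterval:
    def test_invariants(self):
        with pytest.raises(CoordinateError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(CoordinateError):
            GenomicInterval("chr1", -1, 5)

    def test_bookended_intervals_do_not_overlap(self):
        a = GenomicInterval("chr1", 100, 200)
        assert not a.overlaps(GenomicInterval("chr1", 200, 300))
        assert a.overlaps(GenomicInterval("chr1", 199, 300))
        assert not a.overlaps(GenomicInterval("chr2", 100, 200))


class TestBed:
    def test_bed3_half_open(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\n")
        track = read_bed(p)
        assert track.intervals == [GenomicInterval("chr1", 100, 200)]
        assert track.intervals[0].length == 100

    def test_bed6_strand_and_score(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\tpeak1\t37.5\t-\n")
        track = read_bed(p)
        assert track.intervals[0].strand == "-"
        assert track.scores is not None and track.scores[0] == 37.5

    def test_round_trip_bit_exact(self, tmp_path):
        src = tmp_path / "src.bed"
        src.write_text(
            "chr1\t100\t200\tx_0\t5\t+\nchr1\t500\t900\tx_1\t7\t-\nchr2\t10\t40\tx_2\t1\t+\n"
        )
        track = read_bed(src, name="x")
        out = tmp_path / "out.bed"
        write_bed(track, out)
        again = read_bed(out, name="x")
        assert again.intervals == track.intervals
        assert np.array_equal(again.scores, track.scores)
        out2 = tmp_path / "out2.bed"
        write_bed(again, out2)
        assert out.read_text() == out2.read_text()

    def test_non_integer_coordinates_rejected(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t1.5\t200\n")
        with pytest.raises(FormatError):
            read_bed(p)


SAM_HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:chr1\tLN:100000\n"


class TestSam:
    def test_one_based_to_zero_based(self, tmp_path):
        p = tmp_path / "a.sam"
        p.write_text(
            SAM_HEADER + "q1\t99\tchr1\t1001\t42\t150M\t=\t1601\t750\t*\t*\n"
        )
        (rec,) = list(read_sam_records(p))
        assert rec.pos0 == 1000
        assert rec.end0 == 1150
        assert rec.tlen == 750
        assert rec.mate_pos0 == 1600
        assert not rec.is_unmapped

    def test_header_only_stream_is_empty(self, tmp_path):
        p = tmp_path / "empty.sam"
        p.write_text(SAM_HEADER)
        assert list(read_sam_records(p)) == []

    def test_unmapped_record_retained_and_flagged(self, tmp_path):
        p = tmp_path / "u.sam"
        p.write_text(SAM_HEADER + "q1\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n")
        (rec,) = list(read_sam_records(p))
        assert rec.is_unmapped

    def test_fields_agree_with_reference_split(self, tmp_path):
        """Cross-check the SAM reader against a naive column split."""
        lines = [
            "q1\t99\tchr1\t1001\t42\t150M\t=\t1601\t750\t*\t*",
            "q1\t147\tchr1\t1601\t42\t150M\t=\t1001\t-750\t*\t*",
            "q2\t83\tchr1\t5001\t7\t150M\t=\t4501\t-650\t*\t*",
        ]
        p = tmp_path / "x.sam"
        p.write_text(SAM_HEADER + "\n".join(lines) + "\n")
        records = list(read_sam_records(p))
        assert len(records) == len(lines)
        for rec, line in zip(records, lines):
            cols = line.split("\t")
            assert rec.qname == cols[0]
            assert rec.flag == int(cols[1])
            assert rec.chrom == cols[2]
            assert rec.pos0 == int(cols[3]) - 1
            assert rec.mapq == int(cols[4])
            assert rec.mate_pos0 == int(cols[7]) - 1
            assert rec.tlen == int(cols[8])


GFF = """##gff-version 3
chr1\tsrc\tgene\t5001\t8000\t.\t+\t.\tID=gplus
chr1\tsrc\tgene\t5001\t8000\t.\t-\t.\tID=gminus
chr2\tsrc\tgene\t100\t900\t.\t+\t.\tID=gother
"""


class TestGeneAnnotation:
    def test_strand_aware_five_prime_end(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(GFF)
        genes = {g.gene_id: g for g in read_gene_annotation(p)}
        assert len(genes) == 3
        assert genes["gplus"].tss == 5000
        assert genes["gminus"].tss == 7999  # 5'-end of a minus gene is its right edge
        assert genes["gminus"].tes == 5000

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "dup.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\ts\tgene\t1\t10\t.\t+\t.\tID=g1\n"
            "chr1\ts\tgene\t50\t90\t.\t+\t.\tID=g1\n"
        )
        with pytest.raises(Exception):
            read_gene_annotation(p)

    def test_missing_strand_rejected(self, tmp_path):
        p = tmp_path / "ns.bed"
        p.write_text("chr1\t100\t900\tg1\t0\t.\n")
        with pytest.raises(AnnotationError):
            read_gene_annotation(p)

    def test_bed6_genes(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t5000\t8000\tg1\t0\t-\n")
        (gene,) = read_gene_annotation(p)
        assert gene.tss == 7999 and gene.strand == "-"


class TestIntersectAny:
    def test_one_bp_overlap_counts(self):
        a = [GenomicInterval("chr1", 100, 200)]
        res = intersect_any(a, [GenomicInterval("chr1", 199, 300)])
        assert res.fraction == 1.0

    def test_half_open_bookends_do_not_count(self):
        a = [GenomicInterval("chr1", 100, 200)]
        res = intersect_any(a, [GenomicInterval("chr1", 200, 300)])
        assert res.fraction == 0.0 and res.flagged == []

    def test_fraction_of_ten(self):
        queries = [GenomicInterval("chr1", i * 1000, i * 1000 + 100) for i in range(10)]
        track = FeatureTrack("t", [GenomicInterval("chr1", i * 1000, i * 1000 + 50) for i in range(4)])
        assert intersect_any(queries, track).fraction == pytest.approx(0.4)

    def test_empty_inputs_zero_overlap(self):
        assert intersect_any([], FeatureTrack("t", [])).fraction == 0.0

    def test_agrees_with_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            def rand_ivs(n):
                out = []
                for _ in range(n):
                    chrom = f"chr{rng.integers(1, 3)}"
                    s = int(rng.integers(0, 5000))
                    out.append(GenomicInterval(chrom, s, s + int(rng.integers(1, 400))))
                return out

            a = rand_ivs(int(rng.integers(1, 50)))
            b = rand_ivs(int(rng.integers(1, 50)))
            res = intersect_any(a, b)
            flags, counts = brute_overlap_flags(
                [(x.chrom, x.start, x.end) for x in a],
                [(x.chrom, x.start, x.end) for x in b],
            )
            assert list(res.flags) == flags
            assert list(res.counts) == counts


def test_genome_descriptor_bounds(tmp_path):
    genome = GenomeDescriptor({"chr1": 1000})
    genome.validate([GenomicInterval("chr1", 0, 1000)])
    with pytest.raises(CoordinateError):
        genome.validate([GenomicInterval("chr1", 500, 1500)])
    with pytest.raises(CoordinateError):
        genome.validate([GenomicInterval("chrX", 0, 10)])
    p = tmp_path / "genome.tsv"
    genome.to_tsv(p)
    assert GenomeDescriptor.from_tsv(p).chrom_sizes == genome.chrom_sizes
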