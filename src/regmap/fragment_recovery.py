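"""Reconstruct cloned library fragments from paired-end alignments.

The selection assay recovers each cloned insert as a properly-paired read
pair.  Only primary, properly-paired, mapped records with MAPQ >= 10 are
used; the pair's strand is taken from the SAM flag combinations 99/147
(plus strand) and 83/163 (minus strand), and the fragment is the outer span
of the two mates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Sequence

from .genome_io import AlignmentRecord, GenomicInterval, read_sam_records

__all__ = [
    "AlignmentRecord",
    "FragmentSet",
    "filter_alignments",
    "assign_strand",
    "fragments_from_pairs",
    "recover_fragments",
]

PLUS_FLAGS = frozenset({99, 147})
MINUS_FLAGS = frozenset({83, 163})

_FLAG_PAIRED = 0x1
_FLAG_PROPER = 0x2
_FLAG_UNMAPPED = 0x4
_FLAG_SECONDARY = 0x100
_FLAG_SUPPLEMENTARY = 0x800


@dataclass
class FragmentSet:
    """Strand-assigned fragment intervals recovered from one library."""

    library_id: str
    fragments: list[GenomicInterval]
    discarded: int = 0  # pairs dropped for cross-chromosome or conflicting strands
    orphans: int = 0  # qnames with a single surviving record

    @property
    def total_count(self) -> int:
        return len(self.fragments)

    def by_strand(self, strand: str) -> list[GenomicInterval]:
        return [f for f in self.fragments if f.strand == strand]


def filter_alignments(
    records: Iterable[AlignmentRecord], mapq_min: int = 10
) -> list[AlignmentRecord]:
    """Keep properly-paired, mapped, primary alignments with MAPQ >= mapq_min.

    Input order is preserved; the operation is idempotent.
    """
    return [
        r
        for r in records
        if (r.flag & _FLAG_PROPER)
        and not (r.flag & _FLAG_UNMAPPED)
        and not (r.flag & _FLAG_SECONDARY)
        and not (r.flag & _FLAG_SUPPLEMENTARY)
        and r.mapq >= mapq_min
    ]


def assign_strand(record: AlignmentRecord) -> str | None:
    """Map the pair-orientation flag to the cloned fragment's strand.

    Flags 99/147 mean the insert came from the plus chain, 83/163 from the
    minus chain; any other flag value is excluded from fragment building.
    """
    if record.flag in PLUS_FLAGS:
        return "+"
    if record.flag in MINUS_FLAGS:
        return "-"
    return None


def fragments_from_pairs(
    records: Sequence[AlignmentRecord], library_id: str
) -> FragmentSet:
    """Build one fragment per read pair as the outer span of its two mates.

    Pairs with mates on different chromosomes, with conflicting strand
    assignments, or with a flag outside the four accepted combinations are
    discarded and counted; single-record qnames are counted as orphans.
    """
    by_qname: dict[str, list[AlignmentRecord]] = {}
    for rec in records:
        by_qname.setdefault(rec.qname, []).append(rec)

    fragments: list[GenomicInterval] = []
    discarded = 0
    orphans = 0
    for qname, recs in by_qname.items():
        if len(recs) == 1:
            orphans += 1
            continue
        if len(recs) != 2:
            discarded += 1
            continue
        a, b = recs
        sa, sb = assign_strand(a), assign_strand(b)
        if sa is None or sb is None or sa != sb or a.chrom != b.chrom:
            discarded += 1
            continue
        start = min(a.pos0, b.pos0)
        end = max(a.end0, b.end0)
        fragments.append(GenomicInterval(a.chrom, start, end, sa))
    return FragmentSet(library_id, fragments, discarded=discarded, orphans=orphans)


def recover_fragments(
    sam_path: str | PathLike, library_id: str, mapq_min: int = 10
) -> FragmentSet:
    """SAM file -> filtered, strand-assigned FragmentSet for one library."""
    records = filter_alignments(read_sam_records(sam_path), mapq_min=mapq_min)
    return fragments_from_pairs(records, library_id)


def write_bedpe(
    records: Sequence[AlignmentRecord], path: str | PathLike
) -> None:
    """Export mate pairs as minimal BEDPE (one line per qname)."""
    by_qname: dict[str, list[AlignmentRecord]] = {}
    for rec in records:
        by_qname.setdefault(rec.qname, []).append(rec)
    with open(path, "w") as fh:
        for qname, recs in by_qname.items():
            if len(recs) != 2:
                continue
            a, b = sorted(recs, key=lambda r: r.pos0)
            sa = assign_strand(a) or "."
            sb = assign_strand(b) or "."
            fh.write(
                f"{a.chrom}\t{a.pos0}\t{a.end0}\t{b.chrom}\t{b.pos0}\t{b.end0}"
                f"\t{qname}\t0\t{sa}\t{sb}\n"
            )
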