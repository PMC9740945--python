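"""Coordinate conventions, interval primitives and format readers/writers.

Internally every coordinate is 0-based half-open (the BED convention).
1-based fully-closed coordinates appear only at the parse/display boundary:
UCSC-style region strings (``chr13:99,498,575-99,499,229``) and SAM/GFF
positions are converted on the way in and out.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import AnnotationError, CoordinateError, FormatError

# strand symbols: '+' forward, '-' reverse, '.' unstranded
STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open span ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise CoordinateError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise CoordinateError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Strict half-open overlap: book-ended intervals do not overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:
        # display in the 1-based fully-closed convention
        return f"{self.chrom}:{self.start + 1:,}-{self.end:,}"


_REGION_RE = re.compile(r"^\s*([^\s:]+)\s*:\s*([\d,\s]+?)\s*-\s*([\d,\s]+?)\s*$")


def parse_region_string(text: str) -> GenomicInterval:
    """Parse a UCSC-style 1-based fully-closed region string.

    Commas and internal whitespace in the numbers are tolerated.  The
    returned half-open interval has ``length == printed_end - printed_start + 1``.
    """
    m = _REGION_RE.match(text)
    if m is None:
        raise FormatError(f"cannot parse region string {text!r}")
    chrom = m.group(1)
    start1 = int(re.sub(r"[,\s]", "", m.group(2)))
    end1 = int(re.sub(r"[,\s]", "", m.group(3)))
    if start1 < 1 or start1 > end1:
        raise CoordinateError(f"bad 1-based coordinates in {text!r}")
    return GenomicInterval(chrom, start1 - 1, end1)


@dataclass
class GenomeDescriptor:
    """Chromosome sizes plus optional assembly-gap intervals."""

    chrom_sizes: dict[str, int]
    gaps: "FeatureTrack | None" = None

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    @property
    def total_length(self) -> int:
        return sum(self.chrom_sizes.values())

    def contains(self, iv: GenomicInterval) -> bool:
        size = self.chrom_sizes.get(iv.chrom)
        return size is not None and 0 <= iv.start and iv.end <= size

    def validate(self, intervals: Iterable[GenomicInterval]) -> None:
        for iv in intervals:
            if not self.contains(iv):
                raise CoordinateError(f"interval {iv} outside genome bounds")

    @classmethod
    def from_tsv(cls, path: str | PathLike) -> "GenomeDescriptor":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
        return cls(dict(zip(df["chrom"].astype(str), df["size"].astype(int))))

    def to_tsv(self, path: str | PathLike) -> None:
        with open(path, "w") as fh:
            for chrom, size in self.chrom_sizes.items():
                fh.write(f"{chrom}\t{size}\n")


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to what the regulatory-domain rules need.

    ``tss`` is always the strand-aware 5'-end; for a minus-strand gene it is
    the rightmost base, hence ``tss > tes``.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.gene_id}: strand must be + or -")
        if self.strand == "+" and not self.tss < self.tes:
            raise AnnotationError(f"gene {self.gene_id}: + strand requires tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise AnnotationError(f"gene {self.gene_id}: - strand requires tss > tes")

    @property
    def span(self) -> GenomicInterval:
        lo, hi = min(self.tss, self.tes), max(self.tss, self.tes)
        return GenomicInterval(self.chrom, lo, hi + 1, self.strand)


class FeatureTrack:
    """A named set of intervals with optional per-interval scores.

    Intervals are kept sorted by (chrom, start); scores follow the sort.
    """

    def __init__(
        self,
        name: str,
        intervals: Sequence[GenomicInterval],
        scores: Sequence[float] | None = None,
    ) -> None:
        self.name = name
        intervals = list(intervals)
        if scores is not None:
            scores = np.asarray(scores, dtype=float)
            if len(scores) != len(intervals):
                raise FormatError("scores and intervals differ in length")
            if not np.all(np.isfinite(scores)):
                raise FormatError(f"track {name}: non-finite scores")
        order = sorted(range(len(intervals)), key=lambda i: (intervals[i].chrom, intervals[i].start, intervals[i].end))
        self.intervals: list[GenomicInterval] = [intervals[i] for i in order]
        self.scores: np.ndarray | None = scores[order] if scores is not None else None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "strand": [iv.strand for iv in self.intervals],
            }
        )
        if self.scores is not None:
            df["score"] = self.scores
        return df


# ---------------------------------------------------------------------------
# overlap machinery
# ---------------------------------------------------------------------------


class _ChromIndex:
    """Sorted start/end arrays per chromosome for counting overlap queries.

    For a query [qs, qe) the number of track intervals overlapping it is
    #{starts < qe} - #{ends <= qs}: every interval ending at or before qs
    also starts before qe, so the difference counts exactly the overlaps.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]) -> None:
        by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        for iv in intervals:
            starts, ends = by_chrom.setdefault(iv.chrom, ([], []))
            starts.append(iv.start)
            ends.append(iv.end)
        self._index = {
            chrom: (np.sort(np.array(s)), np.sort(np.array(e)))
            for chrom, (s, e) in by_chrom.items()
        }

    def count(self, iv: GenomicInterval) -> int:
        entry = self._index.get(iv.chrom)
        if entry is None:
            return 0
        starts, ends = entry
        n_started = int(np.searchsorted(starts, iv.end, side="left"))
        n_finished = int(np.searchsorted(ends, iv.start, side="right"))
        return n_started - n_finished


@dataclass
class OverlapResult:
    """Per-interval overlap flags of one interval set against a track."""

    flags: np.ndarray  # bool, aligned with the query order
    counts: np.ndarray  # number of track intervals overlapping each query
    flagged: list[GenomicInterval]  # queries with >=1 bp overlap

    @property
    def fraction(self) -> float:
        return float(self.flags.mean()) if len(self.flags) else 0.0


def intersect_any(
    intervals: Sequence[GenomicInterval], track: FeatureTrack | Sequence[GenomicInterval]
) -> OverlapResult:
    """Flag every query interval sharing >=1 bp with any track interval."""
    track_ivs = track.intervals if isinstance(track, FeatureTrack) else list(track)
    index = _ChromIndex(track_ivs)
    counts = np.array([index.count(iv) for iv in intervals], dtype=int)
    flags = counts > 0
    flagged = [iv for iv, f in zip(intervals, flags) if f]
    return OverlapResult(flags=flags, counts=counts, flagged=flagged)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(source: str | PathLike | io.TextIOBase, name: str | None = None) -> FeatureTrack:
    """Read a BED3/BED6 file (0-based half-open) into a FeatureTrack.

    Column 5, when present, is read as the score; column 6 as the strand.
    """
    if name is None:
        name = Path(source).stem if isinstance(source, (str, PathLike)) else "track"
    try:
        df = pd.read_csv(
            source, sep="\t", header=None, comment="#", dtype={0: str}
        )
    except pd.errors.EmptyDataError:
        return FeatureTrack(name, [])
    if df.shape[1] < 3:
        raise FormatError("BED requires at least 3 columns")
    try:
        raw_starts = pd.to_numeric(df[1], errors="raise")
        raw_ends = pd.to_numeric(df[2], errors="raise")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-integer BED coordinates: {exc}") from exc
    if (raw_starts % 1 != 0).any() or (raw_ends % 1 != 0).any():
        raise FormatError("non-integer BED coordinates")
    starts = raw_starts.astype(int)
    ends = raw_ends.astype(int)
    strands = df[5].astype(str) if df.shape[1] >= 6 else None
    intervals = []
    for i in range(len(df)):
        strand = strands.iloc[i] if strands is not None else "."
        if strand not in STRANDS:
            strand = "."
        intervals.append(
            GenomicInterval(str(df[0].iloc[i]), int(starts.iloc[i]), int(ends.iloc[i]), strand)
        )
    scores = None
    if df.shape[1] >= 5:
        raw = pd.to_numeric(df[4], errors="coerce")
        if raw.notna().all():
            scores = raw.to_numpy(dtype=float)
    return FeatureTrack(name, intervals, scores)


def write_bed(
    track: FeatureTrack,
    path: str | PathLike | io.TextIOBase,
    genome: GenomeDescriptor | None = None,
) -> None:
    """Write a FeatureTrack as BED3 or BED6 (with names/scores when scored).

    Ordering is deterministic: chromosomes in genome order when a descriptor
    is given (lexicographic otherwise), then by start.
    """
    ivs = list(track.intervals)
    scores = track.scores
    if genome is not None:
        rank = {c: i for i, c in enumerate(genome.chroms)}
        order = sorted(
            range(len(ivs)), key=lambda i: (rank.get(ivs[i].chrom, len(rank)), ivs[i].chrom, ivs[i].start)
        )
        ivs = [ivs[i] for i in order]
        scores = scores[order] if scores is not None else None
    stranded = any(iv.strand != "." for iv in ivs)
    own = isinstance(path, (str, PathLike))
    fh = open(path, "w") if own else path
    try:
        for i, iv in enumerate(ivs):
            if stranded or scores is not None:
                score = scores[i] if scores is not None else 0
                score_txt = f"{score:g}"
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{track.name}_{i}\t{score_txt}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    finally:
        if own:
            fh.close()


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentRecord:
    """One SAM alignment line, with coordinates converted to 0-based.

    ``pos0`` is -1 for unmapped records (SAM POS 0).  ``end0`` is the 0-based
    exclusive end of the aligned span (from the CIGAR reference length).
    """

    qname: str
    flag: int
    chrom: str
    pos0: int
    mapq: int
    tlen: int
    mate_chrom: str
    mate_pos0: int
    end0: int

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & 0x4) or self.pos0 < 0


def read_sam_records(path: str | PathLike) -> Iterator[AlignmentRecord]:
    """Yield AlignmentRecords from a text SAM file (mandatory columns only)."""
    try:
        sam = pysam.AlignmentFile(str(path), "r", check_sq=False)
    except ValueError as exc:
        raise FormatError(f"cannot open SAM {path}: {exc}") from exc
    with sam:
        try:
            for seg in sam.fetch(until_eof=True):
                pos0 = seg.reference_start if seg.reference_start is not None else -1
                end0 = seg.reference_end
                if end0 is None:
                    end0 = pos0 + (seg.query_length or 0) if pos0 >= 0 else -1
                yield AlignmentRecord(
                    qname=seg.query_name or "",
                    flag=seg.flag,
                    chrom=seg.reference_name or "*",
                    pos0=pos0,
                    mapq=seg.mapping_quality,
                    tlen=seg.template_length,
                    mate_chrom=seg.next_reference_name or "*",
                    mate_pos0=seg.next_reference_start
                    if seg.next_reference_start is not None
                    else -1,
                    end0=end0,
                )
        except ValueError as exc:
            raise FormatError(f"malformed SAM record in {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------


def _tss_tes(start0: int, end0: int, strand: str) -> tuple[int, int]:
    # 5'-end of a minus-strand gene is its rightmost base (end0 exclusive)
    if strand == "+":
        return start0, end0 - 1
    return end0 - 1, start0


def read_gene_annotation(path: str | PathLike) -> list[GeneModel]:
    """Read gene models from GFF3 or BED6/BED12 (one record per gene).

    ``tss`` is the strand-aware 5'-end.  Duplicate gene ids and missing
    strands are rejected.
    """
    suffix = Path(path).suffix.lower()
    genes: list[GeneModel] = []
    seen: set[str] = set()

    def add(gene_id: str, chrom: str, start0: int, end0: int, strand: str) -> None:
        if strand not in ("+", "-"):
            raise AnnotationError(f"gene {gene_id}: missing or invalid strand")
        if gene_id in seen:
            raise AnnotationError(f"duplicate gene id {gene_id}")
        seen.add(gene_id)
        tss, tes = _tss_tes(start0, end0, strand)
        genes.append(GeneModel(gene_id, chrom, strand, tss, tes))

    if suffix in (".gff", ".gff3", ".gtf"):
        import gffutils

        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="error",
        )
        for feat in db.all_features():
            if feat.featuretype not in ("gene", "pseudogene"):
                continue
            gene_id = feat.attributes.get("ID", [feat.id])[0]
            add(gene_id, feat.seqid, feat.start - 1, feat.end, feat.strand or ".")
    else:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
        if df.shape[1] < 6:
            raise AnnotationError("BED gene annotation requires >= 6 columns (strand)")
        for row in df.itertuples(index=False):
            add(str(row[3]), str(row[0]), int(row[1]), int(row[2]), str(row[5]))
    return genes
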