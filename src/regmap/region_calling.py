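"""Merge fragments into candidate regions, quantify RPM, threshold, union.

The caller is deliberately simple: same-orientation fragments that overlap
(or are book-ended) are merged, each merged region is quantified as
fragments-per-million of the library (RPM), regions with RPM strictly
greater than the threshold are retained, and the retained regions of all
libraries are merged strand-blind into the unique region map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .fragment_recovery import FragmentSet
from .genome_io import FeatureTrack, GenomeDescriptor, GenomicInterval, _ChromIndex


@dataclass
class RegionMap:
    """Candidate regulatory regions with per-region quantification.

    After any merge the regions are sorted and non-overlapping.  ``rpm`` is
    fragment_count * 1e6 / library total (per library, before union);
    after ``union_libraries`` rpm is dropped and ``sources`` records the
    contributing libraries per region.
    """

    regions: list[GenomicInterval]
    fragment_counts: list[int] | None = None
    rpm: list[float] | None = None
    sources: list[frozenset[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sources:
            self.sources = [frozenset()] * len(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def region_ids(self) -> list[str]:
        return [f"region_{i:05d}" for i in range(len(self.regions))]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "region_id": self.region_ids(),
                "chrom": [r.chrom for r in self.regions],
                "start": [r.start for r in self.regions],
                "end": [r.end for r in self.regions],
                "strand": [r.strand for r in self.regions],
            }
        )
        if self.fragment_counts is not None:
            df["fragment_count"] = self.fragment_counts
        if self.rpm is not None:
            df["rpm"] = self.rpm
        if any(self.sources):
            df["sources"] = [",".join(sorted(s)) for s in self.sources]
        return df

    def subset(self, keep: Sequence[int]) -> "RegionMap":
        keep = list(keep)
        return RegionMap(
            regions=[self.regions[i] for i in keep],
            fragment_counts=[self.fragment_counts[i] for i in keep]
            if self.fragment_counts is not None
            else None,
            rpm=[self.rpm[i] for i in keep] if self.rpm is not None else None,
            sources=[self.sources[i] for i in keep],
        )


def merge_intervals(
    intervals: Iterable[GenomicInterval], max_gap: int = 0, strand: str = "."
) -> list[GenomicInterval]:
    """Merge overlapping or <=max_gap-separated intervals into their union.

    Book-ended intervals (gap 0) merge at the default.  The result is
    sorted and non-overlapping; the operation is idempotent and independent
    of input order.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e + max_gap:
                cur_e = max(cur_e, e)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e, strand))
                cur_s, cur_e = s, e
        merged.append(GenomicInterval(chrom, cur_s, cur_e, strand))
    return merged


def merge_same_strand(
    fragments: FragmentSet, max_gap: int = 0
) -> dict[str, list[GenomicInterval]]:
    """Merge a library's fragments within each orientation separately."""
    out: dict[str, list[GenomicInterval]] = {}
    for strand in ("+", "-"):
        subset = fragments.by_strand(strand)
        out[strand] = merge_intervals(subset, max_gap=max_gap, strand=strand) if subset else []
    return out


def quantify_rpm(
    regions: Sequence[GenomicInterval], fragments: FragmentSet
) -> RegionMap:
    """Count same-strand fragments overlapping each region and normalize.

    rpm = count * 1e6 / total retained fragments of the library.  Regions
    with strand '.' count fragments of both orientations.
    """
    total = fragments.total_count
    if total == 0:
        raise DegenerateInputError(
            f"library {fragments.library_id}: no fragments, RPM undefined"
        )
    index_by_strand = {
        "+": _ChromIndex(fragments.by_strand("+")),
        "-": _ChromIndex(fragments.by_strand("-")),
    }
    counts = []
    for region in regions:
        if region.strand == ".":
            c = index_by_strand["+"].count(region) + index_by_strand["-"].count(region)
        else:
            c = index_by_strand[region.strand].count(region)
        counts.append(c)
    rpm = [c * 1e6 / total for c in counts]
    return RegionMap(
        regions=list(regions),
        fragment_counts=counts,
        rpm=rpm,
        sources=[frozenset({fragments.library_id})] * len(regions),
    )


def threshold_rpm(region_map: RegionMap, rpm_min: float = 10.0) -> RegionMap:
    """Retain regions with RPM strictly greater than rpm_min."""
    if region_map.rpm is None:
        raise DegenerateInputError("threshold_rpm requires quantified regions")
    keep = [i for i, v in enumerate(region_map.rpm) if v > rpm_min]
    return region_map.subset(keep)


def call_regions(
    fragments: FragmentSet, max_gap: int = 0, rpm_min: float = 10.0
) -> RegionMap:
    """One library's full calling pass: merge per strand, quantify, combine
    orientations, then apply the RPM threshold."""
    per_strand = merge_same_strand(fragments, max_gap=max_gap)
    combined = per_strand["+"] + per_strand["-"]
    combined.sort(key=lambda r: (r.chrom, r.start, r.end, r.strand))
    quantified = quantify_rpm(combined, fragments)
    return threshold_rpm(quantified, rpm_min=rpm_min)


def union_libraries(maps: Sequence[RegionMap], stranded: bool = False) -> RegionMap:
    """Merge thresholded maps from all libraries into the unique region map.

    The default union is strand-blind: overlapping regions merge regardless
    of orientation and the output regions are unstranded.  Each output
    region records which libraries contributed to it.
    """
    pooled: list[tuple[GenomicInterval, frozenset[str], int]] = []
    for m in maps:
        counts = m.fragment_counts or [0] * len(m)
        for region, src, cnt in zip(m.regions, m.sources, counts):
            pooled.append((region, src, cnt))
    if stranded:
        out_regions: list[GenomicInterval] = []
        for strand in ("+", "-", "."):
            sub = [p for p in pooled if p[0].strand == strand]
            out_regions.extend(
                merge_intervals([p[0] for p in sub], strand=strand)
            )
        out_regions.sort(key=lambda r: (r.chrom, r.start, r.strand))
    else:
        out_regions = merge_intervals([p[0] for p in pooled], strand=".")
    # attribute each pooled input to the output region that absorbed it;
    # merging guarantees every input lies inside exactly one output region
    # (of its strand, when the union is stranded)
    src_sets: list[set[str]] = [set() for _ in out_regions]
    counts_out = [0] * len(out_regions)
    grouped: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for idx, region in enumerate(out_regions):
        key = (region.chrom, region.strand if stranded else ".")
        grouped.setdefault(key, []).append((region.start, idx))
    lookup = {
        key: (np.array([s for s, _ in entries]), [i for _, i in entries])
        for key, entries in grouped.items()
    }
    for in_region, in_src, in_cnt in pooled:
        key = (in_region.chrom, in_region.strand if stranded else ".")
        starts, idxs = lookup[key]
        j = int(np.searchsorted(starts, in_region.start, side="right")) - 1
        out_idx = idxs[j]
        src_sets[out_idx] |= in_src
        counts_out[out_idx] += in_cnt
    sources = [frozenset(s) for s in src_sets]
    return RegionMap(
        regions=out_regions, fragment_counts=counts_out, rpm=None, sources=sources
    )


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def write_region_bed(
    region_map: RegionMap, path: str | PathLike, genome: GenomeDescriptor | None = None
) -> None:
    """BED export: per-library maps as BED6 (score = RPM*100 rounded),
    union maps (no rpm) as BED4."""
    ids = region_map.region_ids()
    lines = []
    for i, region in enumerate(region_map.regions):
        if region_map.rpm is not None:
            lib = ",".join(sorted(region_map.sources[i])) or "map"
            score = int(round(region_map.rpm[i] * 100))
            lines.append(
                (region, f"{region.chrom}\t{region.start}\t{region.end}"
                 f"\t{lib}:{i}\t{score}\t{region.strand}\n")
            )
        else:
            lines.append(
                (region, f"{region.chrom}\t{region.start}\t{region.end}\t{ids[i]}\n")
            )
    if genome is not None:
        rank = {c: j for j, c in enumerate(genome.chroms)}
        lines.sort(key=lambda t: (rank.get(t[0].chrom, len(rank)), t[0].start))
    with open(path, "w") as fh:
        for _, line in lines:
            fh.write(line)


def write_region_gff3(region_map: RegionMap, path: str | PathLike) -> None:
    """GFF3 export of a region map (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rid, region in zip(region_map.region_ids(), region_map.regions):
            strand = region.strand if region.strand != "." else "."
            fh.write(
                f"{region.chrom}\tregmap\tregion\t{region.start + 1}\t{region.end}"
                f"\t.\t{strand}\t.\tID={rid}\n"
            )


def region_map_from_bed(path: str | PathLike) -> RegionMap:
    """Load a region map previously written as BED."""
    from .genome_io import read_bed

    track = read_bed(path, name="regions")
    return RegionMap(regions=list(track.intervals))
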