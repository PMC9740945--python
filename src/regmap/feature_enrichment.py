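"""Overlap of the region map with feature tracks versus matched random regions.

The null model mirrors the mapped regions exactly: each random replicate
has the same number of regions, the same length multiset and the same
per-chromosome distribution, with every region placed uniformly at random
on its own chromosome (outside declared assembly gaps).  Enrichment is the
observed overlap fraction divided by the mean null fraction, with an
add-one upper-tail permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, PlacementError
from .genome_io import (
    FeatureTrack,
    GenomeDescriptor,
    GenomicInterval,
    OverlapResult,
    _ChromIndex,
    intersect_any,
)
from .group_stats import RankSumResult, rank_sum_test
from .region_calling import RegionMap

_MAX_PLACEMENT_TRIES = 1000


@dataclass
class MatchedRandomSet:
    """One replicate of size- and chromosome-matched random regions."""

    replicate_id: int
    regions: list[GenomicInterval]
    seed: int


@dataclass
class EnrichmentResult:
    """Observed overlap fraction against the matched-random null."""

    track_name: str
    observed_fraction: float
    null_fractions: np.ndarray
    flagged: list[GenomicInterval]

    @property
    def ratio(self) -> float:
        null_mean = float(self.null_fractions.mean())
        return float("inf") if null_mean == 0 else self.observed_fraction / null_mean

    @property
    def empirical_p(self) -> float:
        n = len(self.null_fractions)
        exceed = int(np.sum(self.null_fractions >= self.observed_fraction))
        return (1 + exceed) / (1 + n)


def shuffle_matched(
    template: RegionMap | list[GenomicInterval],
    genome: GenomeDescriptor,
    seed: int,
    replicate_id: int = 0,
) -> MatchedRandomSet:
    """Place a length- and chromosome-matched random copy of the template.

    Each template region is re-placed uniformly on its own chromosome;
    placements crossing a chromosome end are impossible by construction and
    placements overlapping a declared gap are rejected and resampled.
    """
    regions = template.regions if isinstance(template, RegionMap) else template
    rng = np.random.default_rng(seed)
    gap_index = _ChromIndex(genome.gaps.intervals) if genome.gaps is not None else None
    placed: list[GenomicInterval] = []
    for region in regions:
        chrom_len = genome.chrom_sizes[region.chrom]
        span = region.length
        if span > chrom_len:
            raise PlacementError(f"region {region} longer than its chromosome")
        for _ in range(_MAX_PLACEMENT_TRIES):
            start = int(rng.integers(0, chrom_len - span + 1))
            candidate = GenomicInterval(region.chrom, start, start + span)
            if gap_index is None or gap_index.count(candidate) == 0:
                placed.append(candidate)
                break
        else:
            raise PlacementError(
                f"could not place region {region} outside gaps on {region.chrom}"
            )
    return MatchedRandomSet(replicate_id=replicate_id, regions=placed, seed=seed)


def overlap_fraction(
    regions: RegionMap | list[GenomicInterval], track: FeatureTrack
) -> tuple[float, OverlapResult]:
    """Fraction of regions sharing >=1 bp with the track."""
    intervals = regions.regions if isinstance(regions, RegionMap) else regions
    if not intervals:
        raise DegenerateInputError("overlap fraction undefined for empty region set")
    result = intersect_any(intervals, track)
    return result.fraction, result


def enrichment_test(
    region_map: RegionMap,
    track: FeatureTrack,
    genome: GenomeDescriptor,
    n_replicates: int = 100,
    seed: int = 17,
) -> EnrichmentResult:
    """Compare observed track overlap with matched-random replicates.

    p = (1 + #{null >= observed}) / (1 + n_replicates): upper-tail with the
    add-one correction, so p is never zero.
    """
    if n_replicates < 1:
        raise DegenerateInputError("n_replicates must be >= 1")
    observed, result = overlap_fraction(region_map, track)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    null = np.empty(n_replicates)
    for i in range(n_replicates):
        replicate = shuffle_matched(
            region_map, genome, seed=int(child_seeds[i]), replicate_id=i
        )
        null[i], _ = overlap_fraction(replicate.regions, track)
    return EnrichmentResult(
        track_name=track.name,
        observed_fraction=observed,
        null_fractions=null,
        flagged=result.flagged,
    )


@dataclass
class ColocalizationResult:
    """Track-peak score distributions split by region-map overlap."""

    overlapped_scores: np.ndarray
    non_overlapped_scores: np.ndarray
    test: RankSumResult


def score_colocalization(
    region_map: RegionMap, scored_track: FeatureTrack
) -> ColocalizationResult:
    """Split scored peaks by whether any mapped region overlaps them and
    compare the two score samples with the rank-sum test."""
    if scored_track.scores is None:
        raise DegenerateInputError("score_colocalization requires a scored track")
    result = intersect_any(scored_track.intervals, region_map.regions)
    scores = scored_track.scores
    overlapped = scores[result.flags]
    non_overlapped = scores[~result.flags]
    if len(overlapped) == 0 or len(non_overlapped) == 0:
        raise DegenerateInputError(
            "degenerate split: every peak (or none) overlaps the region map"
        )
    test = rank_sum_test(overlapped, non_overlapped, fpkm_min=None)
    return ColocalizationResult(
        overlapped_scores=overlapped,
        non_overlapped_scores=non_overlapped,
        test=test,
    )
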