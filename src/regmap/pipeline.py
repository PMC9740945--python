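"""End-to-end orchestration: SAM alignments -> candidate regulatory map ->
gene groups -> expression statistics.

The full pass mirrors the published workflow: recover fragments per
library, merge same-orientation fragments, quantify RPM and keep regions
with RPM > 10, union the libraries strand-blind into the unique region
map, restrict the map to regions overlapping the acetylation-mark track
(only mark-supported regions enter the gene analysis), associate the
remaining regions with genes by the basal+extension rules, and partition
genes into P / D1 / D2 groups.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from os import PathLike
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import DegenerateInputError
from .fragment_recovery import FragmentSet, recover_fragments
from .gene_association import (
    GeneGroupTable,
    RegionGeneAssociation,
    associate,
    build_domains,
    partition_genes,
)
from .genome_io import (
    FeatureTrack,
    GeneModel,
    GenomeDescriptor,
    GenomicInterval,
    intersect_any,
)
from .group_stats import RankSumResult, rank_sum_test
from .region_calling import RegionMap, call_regions, union_libraries


def fragments_from_sam_text(sam_text: str, library_id: str, mapq_min: int = 10) -> FragmentSet:
    """Recover fragments from in-memory SAM text (written to a temp file
    for the SAM reader)."""
    with tempfile.NamedTemporaryFile("w", suffix=".sam", delete=False) as fh:
        fh.write(sam_text)
        tmp = fh.name
    try:
        return recover_fragments(tmp, library_id, mapq_min=mapq_min)
    finally:
        Path(tmp).unlink(missing_ok=True)


@dataclass
class PipelineResult:
    fragment_sets: dict[str, FragmentSet]
    library_maps: dict[str, RegionMap]
    union_map: RegionMap
    candidate_map: RegionMap  # union map restricted to track-supported regions
    track_overlap_fraction: float
    associations: list[RegionGeneAssociation]
    gene_table: GeneGroupTable


def run_pipeline(
    fragment_sets: Mapping[str, FragmentSet],
    genes: Sequence[GeneModel],
    genome: GenomeDescriptor,
    track: FeatureTrack | None = None,
    max_gap: int = 0,
    rpm_min: float = 10.0,
    basal_up: int = 2000,
    basal_down: int = 2000,
    max_ext: int = 500_000,
) -> PipelineResult:
    """Run the analysis from recovered fragments to gene groups.

    When a feature track is given, the unique region map is restricted to
    track-overlapping regions before gene association; without a track the
    full union map is associated.
    """
    library_maps = {
        lib: call_regions(fs, max_gap=max_gap, rpm_min=rpm_min)
        for lib, fs in fragment_sets.items()
    }
    union_map = union_libraries(list(library_maps.values()))
    if track is not None and len(union_map):
        result = intersect_any(union_map.regions, track)
        candidate_map = union_map.subset(list(map(int, result.flags.nonzero()[0])))
        track_overlap = result.fraction
    else:
        candidate_map = union_map
        track_overlap = float("nan")
    domains = build_domains(
        list(genes), genome, up=basal_up, down=basal_down, max_ext=max_ext
    )
    associations = associate(candidate_map, domains)
    gene_table = partition_genes(associations)
    return PipelineResult(
        fragment_sets=dict(fragment_sets),
        library_maps=library_maps,
        union_map=union_map,
        candidate_map=candidate_map,
        track_overlap_fraction=track_overlap,
        associations=associations,
        gene_table=gene_table,
    )


# ---------------------------------------------------------------------------
# recovery metrics against a known ground truth
# ---------------------------------------------------------------------------


def element_recall(
    region_map: RegionMap, elements: Sequence[GenomicInterval]
) -> float:
    """Fraction of planted elements overlapped (>=1 bp) by a called region."""
    if not elements:
        raise DegenerateInputError("recall undefined without elements")
    return intersect_any(list(elements), region_map.regions).fraction


def element_precision(
    region_map: RegionMap, elements: Sequence[GenomicInterval]
) -> float:
    """Fraction of called regions overlapping (>=1 bp) a planted element."""
    if not len(region_map):
        raise DegenerateInputError("precision undefined for an empty map")
    return intersect_any(region_map.regions, list(elements)).fraction


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    sa, sb = set(a), set(b)
    union = sa | sb
    if not union:
        raise DegenerateInputError("Jaccard undefined for two empty sets")
    return len(sa & sb) / len(union)


def expression_group_test(
    gene_table: GeneGroupTable,
    fpkm: Mapping[str, float],
    group_a: str = "D2",
    group_b: str = "D1",
    fpkm_min: float = 0.5,
) -> RankSumResult:
    """Rank-sum comparison of expression between two recovered gene groups."""
    a = [fpkm[g] for g in gene_table.group(group_a) if g in fpkm]
    b = [fpkm[g] for g in gene_table.group(group_b) if g in fpkm]
    return rank_sum_test(a, b, fpkm_min=fpkm_min)
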