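"""Basal+extension regulatory domains and region-to-gene association.

Each gene receives a basal domain around its TSS (default 2 kb upstream and
2 kb downstream, strand-aware) extended in both directions to the nearest
neighboring basal domain, at most 500 kb from the TSS, and never beyond the
chromosome.  A region associates with every gene whose extended domain
contains the region midpoint.  Associations within +/-2 kb of the TSS are
proximal, those 2-500 kb away distal; genes with >=1 proximal region form
the P group and genes with 1-2 / >=3 distal regions the D1 / D2 groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CoordinateError
from .genome_io import GeneModel, GenomeDescriptor, GenomicInterval
from .region_calling import RegionMap

PROXIMAL_MAX_BP = 2000
DISTAL_MAX_BP = 500_000


@dataclass(frozen=True)
class RegulatoryDomain:
    """Per-gene basal and extended association windows."""

    gene: GeneModel
    basal: GenomicInterval
    extended: GenomicInterval

    def __post_init__(self) -> None:
        if not (
            self.extended.start <= self.basal.start
            and self.basal.end <= self.extended.end
        ):
            raise CoordinateError(
                f"gene {self.gene.gene_id}: basal domain not contained in extended"
            )


@dataclass(frozen=True)
class RegionGeneAssociation:
    """One region-gene link with the strand-aware TSS distance.

    ``signed_distance`` is measured TSS -> region midpoint, negative when
    the midpoint lies upstream of the gene.
    """

    region_id: str
    gene_id: str
    signed_distance: int
    klass: str  # 'proximal' or 'distal'


def _basal_window(gene: GeneModel, up: int, down: int) -> tuple[int, int]:
    if gene.strand == "+":
        return gene.tss - up, gene.tss + down
    return gene.tss - down, gene.tss + up


def build_domains(
    genes: list[GeneModel],
    genome: GenomeDescriptor,
    up: int = 2000,
    down: int = 2000,
    max_ext: int = 500_000,
) -> list[RegulatoryDomain]:
    """Build basal+extension domains for every gene.

    Extension on each side stops at the nearest other basal-domain boundary,
    at ``max_ext`` bp from the TSS, or at the chromosome end, whichever is
    nearest; overlapping basal domains are never truncated.
    """
    if up < 0 or down < 0 or max_ext < max(up, down):
        raise CoordinateError("require up, down >= 0 and max_ext >= max(up, down)")
    by_chrom: dict[str, list[GeneModel]] = {}
    for gene in genes:
        by_chrom.setdefault(gene.chrom, []).append(gene)

    domains: list[RegulatoryDomain] = []
    for chrom, chrom_genes in by_chrom.items():
        chrom_len = genome.chrom_sizes[chrom]
        windows = [_basal_window(g, up, down) for g in chrom_genes]
        clipped = [(max(0, s), min(chrom_len, e)) for s, e in windows]
        for g, (bs, be) in zip(chrom_genes, clipped):
            if be <= 0 or bs >= chrom_len or bs >= be:
                raise CoordinateError(
                    f"gene {g.gene_id}: basal window outside chromosome"
                )
        for i, gene in enumerate(chrom_genes):
            bs, be = clipped[i]
            # nearest neighboring basal boundary on each side, capped so an
            # overlapping neighbor blocks extension without truncating basal
            left_bound = 0
            right_bound = chrom_len
            for j, (obs, obe) in enumerate(clipped):
                if j == i:
                    continue
                if obs < bs:
                    left_bound = max(left_bound, min(obe, bs))
                if obe > be:
                    right_bound = min(right_bound, max(obs, be))
            ext_start = min(bs, max(gene.tss - max_ext, 0, left_bound))
            ext_end = max(be, min(gene.tss + max_ext, chrom_len, right_bound))
            domains.append(
                RegulatoryDomain(
                    gene=gene,
                    basal=GenomicInterval(chrom, bs, be, gene.strand),
                    extended=GenomicInterval(chrom, ext_start, ext_end, gene.strand),
                )
            )
    return domains


def classify_distance(signed_distance: int) -> str | None:
    """Proximal within +/-2 kb (boundary inclusive), distal 2-500 kb."""
    d = abs(signed_distance)
    if d <= PROXIMAL_MAX_BP:
        return "proximal"
    if d <= DISTAL_MAX_BP:
        return "distal"
    return None


def associate(
    region_map: RegionMap, domains: list[RegulatoryDomain]
) -> list[RegionGeneAssociation]:
    """Associate every region with each gene whose extended domain contains
    the region midpoint; a region may associate with multiple genes."""
    by_chrom: dict[str, list[RegulatoryDomain]] = {}
    for dom in domains:
        by_chrom.setdefault(dom.gene.chrom, []).append(dom)
    # sort by extension start for a bounded scan window per chromosome
    sorted_doms = {
        chrom: sorted(doms, key=lambda d: d.extended.start)
        for chrom, doms in by_chrom.items()
    }
    starts = {
        chrom: np.array([d.extended.start for d in doms])
        for chrom, doms in sorted_doms.items()
    }
    associations: list[RegionGeneAssociation] = []
    for rid, region in zip(region_map.region_ids(), region_map.regions):
        doms = sorted_doms.get(region.chrom)
        if not doms:
            continue
        mid = region.midpoint
        # domains extend at most 2*max_ext; scan candidates starting at or
        # before mid and ending after it
        hi = int(np.searchsorted(starts[region.chrom], mid, side="right"))
        for dom in doms[:hi]:
            if not (dom.extended.start <= mid < dom.extended.end):
                continue
            gene = dom.gene
            signed = mid - gene.tss if gene.strand == "+" else gene.tss - mid
            klass = classify_distance(signed)
            if klass is None:
                continue
            associations.append(
                RegionGeneAssociation(
                    region_id=rid,
                    gene_id=gene.gene_id,
                    signed_distance=signed,
                    klass=klass,
                )
            )
    return associations


@dataclass
class GeneGroupTable:
    """Per-gene region counts and P/D1/D2 membership, plus region-level
    proximal/distal tallies."""

    genes: pd.DataFrame  # gene_id, n_proximal, n_distal, P, D1, D2
    regions: pd.DataFrame  # region_id, n_proximal_genes, n_distal_genes, n_genes

    def group(self, name: str) -> set[str]:
        return set(self.genes.loc[self.genes[name], "gene_id"])

    @property
    def n_proximal_regions(self) -> int:
        return int((self.regions["n_proximal_genes"] > 0).sum())

    @property
    def n_distal_regions(self) -> int:
        return int((self.regions["n_distal_genes"] > 0).sum())


def partition_genes(associations: list[RegionGeneAssociation]) -> GeneGroupTable:
    """Count distinct proximal/distal regions per gene and label groups.

    P: >=1 proximal region.  D1: 1-2 distal regions.  D2: >=3 distal
    regions.  P and D membership are independent; D1 and D2 are disjoint.
    Genes with no associations do not appear.
    """
    if not associations:
        empty_genes = pd.DataFrame(
            columns=["gene_id", "n_proximal", "n_distal", "P", "D1", "D2"]
        )
        empty_regions = pd.DataFrame(
            columns=["region_id", "n_proximal_genes", "n_distal_genes", "n_genes"]
        )
        return GeneGroupTable(genes=empty_genes, regions=empty_regions)
    df = pd.DataFrame(
        {
            "region_id": [a.region_id for a in associations],
            "gene_id": [a.gene_id for a in associations],
            "klass": [a.klass for a in associations],
        }
    ).drop_duplicates()

    per_gene = (
        df.pivot_table(
            index="gene_id",
            columns="klass",
            values="region_id",
            aggfunc="nunique",
            fill_value=0,
        )
        .reindex(columns=["proximal", "distal"], fill_value=0)
        .reset_index()
        .rename(columns={"proximal": "n_proximal", "distal": "n_distal"})
    )
    per_gene["P"] = per_gene["n_proximal"] >= 1
    per_gene["D1"] = (per_gene["n_distal"] >= 1) & (per_gene["n_distal"] <= 2)
    per_gene["D2"] = per_gene["n_distal"] >= 3

    per_region = (
        df.pivot_table(
            index="region_id",
            columns="klass",
            values="gene_id",
            aggfunc="nunique",
            fill_value=0,
        )
        .reindex(columns=["proximal", "distal"], fill_value=0)
        .reset_index()
        .rename(
            columns={"proximal": "n_proximal_genes", "distal": "n_distal_genes"}
        )
    )
    per_region["n_genes"] = (
        per_region["n_proximal_genes"] + per_region["n_distal_genes"]
    )
    return GeneGroupTable(genes=per_gene, regions=per_region)
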