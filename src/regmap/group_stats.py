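"""Group-level statistics: rank-sum expression tests, category composition,
hypergeometric fold enrichment with BH correction, and TSS distance profiles.

Expression values are FPKM (fragments per kilobase of transcript per
million mapped reads); by convention genes below 0.5 FPKM are removed
before ranking.  Fold enrichment of a category C within a gene set S over
a universe U is (|S∩C|/|S|) / (|C∩U|/|U|), with an upper-tail
hypergeometric p-value and Benjamini-Hochberg adjustment across the
categories tested together.
"""

from __future__ import annotations

from dataclasses import dataclass
from os import PathLike
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, FormatError
from .genome_io import GeneModel
from .region_calling import RegionMap


# ---------------------------------------------------------------------------
# expression / category tables
# ---------------------------------------------------------------------------


def read_expression_table(path: str | PathLike) -> dict[str, float]:
    """TSV gene_id -> FPKM.  Values must be finite and non-negative."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "fpkm"], comment="#")
    if df["gene_id"].astype(str).iloc[0] in ("gene_id", "gene"):
        df = df.iloc[1:]
    fpkm = pd.to_numeric(df["fpkm"], errors="raise").astype(float)
    if (fpkm < 0).any() or not np.isfinite(fpkm).all():
        raise FormatError("FPKM values must be finite and >= 0")
    return dict(zip(df["gene_id"].astype(str), fpkm))


def read_category_annotation(path: str | PathLike) -> dict[str, set[str]]:
    """TSV gene_id -> category label (one pair per line; sets may overlap)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["gene_id", "category"], comment="#"
    )
    out: dict[str, set[str]] = {}
    for gene_id, category in zip(df["gene_id"].astype(str), df["category"].astype(str)):
        out.setdefault(category, set()).add(gene_id)
    return out


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------


@dataclass
class RankSumResult:
    u_statistic: float  # U of the first group
    n1: int
    n2: int
    p_two_sided: float
    method: str  # 'exact' or 'normal_approx'


def rank_sum_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    fpkm_min: float | None = 0.5,
) -> RankSumResult:
    """Two-sided Mann-Whitney U with the expression cutoff applied first.

    Values below ``fpkm_min`` are removed before ranking (pass None to
    disable the cutoff).  The exact null distribution is enumerated when
    both groups have at most 8 values and there are no ties; otherwise the
    normal approximation with midrank tie correction and continuity
    correction is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if fpkm_min is not None:
        a = a[a >= fpkm_min]
        b = b[b >= fpkm_min]
    if len(a) == 0 or len(b) == 0:
        raise DegenerateInputError("a group is empty after the expression cutoff")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = len(a) <= 8 and len(b) <= 8 and not has_ties
    res = stats.mannwhitneyu(
        a,
        b,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return RankSumResult(
        u_statistic=float(res.statistic),
        n1=len(a),
        n2=len(b),
        p_two_sided=float(res.pvalue),
        method="exact" if exact else "normal_approx",
    )


@dataclass
class BoxStats:
    """Box-and-whisker descriptors mirroring min-max / 1.5 IQR plots."""

    n: int
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def whisker_low(self) -> float:
        return max(self.minimum, self.q1 - 1.5 * self.iqr)

    @property
    def whisker_high(self) -> float:
        return min(self.maximum, self.q3 + 1.5 * self.iqr)


def box_stats(values: Sequence[float]) -> BoxStats:
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        raise DegenerateInputError("box statistics of an empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return BoxStats(
        n=len(v),
        minimum=float(v.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        maximum=float(v.max()),
    )


# ---------------------------------------------------------------------------
# composition and enrichment
# ---------------------------------------------------------------------------


def group_composition(
    groups: Mapping[str, Iterable[str]], categories: Mapping[str, Iterable[str]]
) -> pd.DataFrame:
    """Percentage of each gene group falling in each category.

    Categories may overlap, so a group's percentages may sum past 100.
    """
    rows = []
    for group_name, group_genes in groups.items():
        gset = set(group_genes)
        if not gset:
            raise DegenerateInputError(f"group {group_name!r} is empty")
        for cat_name, cat_genes in categories.items():
            cset = set(cat_genes)
            rows.append(
                {
                    "group": group_name,
                    "category": cat_name,
                    "n_group": len(gset),
                    "n_overlap": len(gset & cset),
                    "percentage": 100.0 * len(gset & cset) / len(gset),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class FoldEnrichmentResult:
    category: str
    k: int  # category hits in the gene set
    n: int  # gene-set size
    K: int  # category size within the universe
    N: int  # universe size
    fold: float
    p: float
    p_adj: float


def fold_enrichment(
    gene_set: Iterable[str],
    categories: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    ease: bool = False,
) -> list[FoldEnrichmentResult]:
    """Hypergeometric fold enrichment of each category in a gene set.

    fold = (k/n) / (K/N); p is the upper-tail hypergeometric probability of
    >= k hits, and the EASE variant scores k-1 hits instead.  BH adjustment
    is applied across all categories of the call.
    """
    uni = set(universe)
    genes = set(gene_set) & uni
    N, n = len(uni), len(genes)
    if n == 0 or N == 0:
        raise DegenerateInputError("empty gene set or universe")
    raw: list[tuple[str, int, int, float, float]] = []
    for cat_name, cat_genes in categories.items():
        K = len(set(cat_genes) & uni)
        if K == 0:
            raise DegenerateInputError(f"category {cat_name!r} empty in the universe")
        k = len(genes & set(cat_genes) & uni)
        fold = (k / n) / (K / N)
        k_score = max(k - 1, 0) if ease else k
        p = float(stats.hypergeom.sf(k_score - 1, N, K, n))
        raw.append((cat_name, k, K, fold, p))
    p_adj = multipletests([r[4] for r in raw], method="fdr_bh")[1]
    return [
        FoldEnrichmentResult(
            category=name, k=k, n=n, K=K, N=N, fold=fold, p=p, p_adj=float(adj)
        )
        for (name, k, K, fold, p), adj in zip(raw, p_adj)
    ]


# ---------------------------------------------------------------------------
# TSS distance profile
# ---------------------------------------------------------------------------


def tss_distance_profile(
    region_map: RegionMap,
    genes: Sequence[GeneModel],
    window: int = 50_000,
    bin_size: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of region midpoints by signed TSS distance over all genes.

    Returns (bin_edges, counts): edges are signed distances from -window to
    +window in ``bin_size`` steps; a midpoint exactly at the TSS falls in
    the [0, bin_size) bin.  Distances are strand-aware (upstream negative).
    """
    if window % bin_size != 0:
        raise DegenerateInputError("window must be a multiple of bin_size")
    edges = np.arange(-window, window + bin_size, bin_size)
    counts = np.zeros(len(edges) - 1, dtype=int)
    mids_by_chrom: dict[str, np.ndarray] = {}
    for region in region_map.regions:
        mids_by_chrom.setdefault(region.chrom, [])
    tmp: dict[str, list[int]] = {c: [] for c in mids_by_chrom}
    for region in region_map.regions:
        tmp[region.chrom].append(region.midpoint)
    mids_by_chrom = {c: np.sort(np.array(v)) for c, v in tmp.items()}
    for gene in genes:
        mids = mids_by_chrom.get(gene.chrom)
        if mids is None or len(mids) == 0:
            continue
        lo = int(np.searchsorted(mids, gene.tss - window, side="left"))
        hi = int(np.searchsorted(mids, gene.tss + window, side="right"))
        for mid in mids[lo:hi]:
            signed = mid - gene.tss if gene.strand == "+" else gene.tss - mid
            if -window <= signed < window:
                counts[(signed + window) // bin_size] += 1
    return edges, counts
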