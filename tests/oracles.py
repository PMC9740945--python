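"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: all-pairs scans, union-find,
explicit enumeration, direct combinatorial sums.  None of it shares code
with the package.
"""

from __future__ import annotations

import itertools
from math import comb


def intervals_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def brute_overlap_flags(queries, targets):
    """queries/targets: sequences of (chrom, start, end). All-pairs scan."""
    flags = []
    counts = []
    for qc, qs, qe in queries:
        c = sum(
            1 for tc, ts, te in targets if tc == qc and intervals_overlap((qs, qe), (ts, te))
        )
        counts.append(c)
        flags.append(c > 0)
    return flags, counts


def sam_keep_oracle(flag: int, mapq: int, mapq_min: int = 10) -> bool:
    """Bit-decomposition of the alignment filter over all 12 SAM flag bits."""
    bits = [bool(flag & (1 << i)) for i in range(12)]
    proper = bits[1]
    unmapped = bits[2]
    secondary = bits[8]
    supplementary = bits[11]
    return proper and not unmapped and not secondary and not supplementary and mapq >= mapq_min


def strand_oracle(flag: int) -> str | None:
    return {99: "+", 147: "+", 83: "-", 163: "-"}.get(flag)


def merge_oracle(spans, max_gap: int = 0):
    """Union-find merge of (start, end) spans on one chromosome/strand."""
    n = len(spans)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            si, sj = spans[i], spans[j]
            gap = max(si[0], sj[0]) - min(si[1], sj[1])
            if gap <= max_gap:
                parent[find(i)] = find(j)
    groups: dict[int, list[tuple[int, int]]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(spans[i])
    merged = sorted(
        (min(s for s, _ in g), max(e for _, e in g)) for g in groups.values()
    )
    return merged


def count_overlaps_oracle(region, spans):
    """Number of spans sharing >=1 bp with region (same chromosome assumed)."""
    return sum(1 for s in spans if intervals_overlap(region, s))


def domain_oracle(genes, chrom_len: int, up: int, down: int, max_ext: int):
    """genes: list of (gene_id, tss, strand) on one chromosome.

    Returns gene_id -> (basal_start, basal_end, ext_start, ext_end),
    transcribing the basal+extension rule pair-by-pair.
    """
    basal = {}
    for gid, tss, strand in genes:
        if strand == "+":
            b = (tss - up, tss + down)
        else:
            b = (tss - down, tss + up)
        basal[gid] = (max(0, b[0]), min(chrom_len, b[1]))
    out = {}
    for gid, tss, strand in genes:
        bs, be = basal[gid]
        left = max(0, tss - max_ext)
        right = min(chrom_len, tss + max_ext)
        for other_id, _, _ in genes:
            if other_id == gid:
                continue
            obs, obe = basal[other_id]
            if obs < bs:  # neighbor domain begins to our left: blocks left extension
                left = max(left, min(obe, bs))
            if obe > be:  # neighbor domain ends to our right: blocks right extension
                right = min(right, max(obs, be))
        out[gid] = (bs, be, min(bs, left), max(be, right))
    return out


def associate_oracle(regions, genes, chrom_len, up=2000, down=2000, max_ext=500_000):
    """regions: (region_id, start, end); genes: (gene_id, tss, strand).

    Tests every (region, gene) pair against the domain definition; returns
    a set of (region_id, gene_id, klass) triples.
    """
    domains = domain_oracle(genes, chrom_len, up, down, max_ext)
    triples = set()
    for rid, start, end in regions:
        mid = (start + end) // 2
        for gid, tss, strand in genes:
            _, _, es, ee = domains[gid]
            if not (es <= mid < ee):
                continue
            signed = mid - tss if strand == "+" else tss - mid
            if abs(signed) <= 2000:
                triples.add((rid, gid, "proximal"))
            elif abs(signed) <= max_ext:
                triples.add((rid, gid, "distal"))
    return triples


def ranksum_exact_oracle(a, b) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney p by full enumeration of rank subsets.

    Assumes no ties.  Returns (U_a, p)."""
    n1, n2 = len(a), len(b)
    # observed U: pairs where a-value beats b-value
    u_obs = sum(1 for x in a for y in b if x > y)
    center = n1 * n2 / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        chosen = set(combo)
        u = 0
        for i in chosen:
            for j in range(n1 + n2):
                if j not in chosen and i > j:
                    u += 1
        total += 1
        if abs(u - center) >= abs(u_obs - center):
            count += 1
    return float(u_obs), count / total


def hypergeom_upper_tail_oracle(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] by direct summation of the hypergeometric pmf."""
    denom = comb(N, n)
    total = 0
    for i in range(k, min(n, K) + 1):
        total += comb(K, i) * comb(N - K, n - i)
    return total / denom


def bh_oracle(pvals):
    """Benjamini-Hochberg adjusted p-values by the textbook recursion."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj
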