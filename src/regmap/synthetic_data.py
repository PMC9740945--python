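"""Seeded synthetic dataset with the structure the analysis assumes.

The generator emulates a ChIP-selected reporter-library experiment:
regulatory elements planted on a toy genome, an acetylation-mark peak
track surrounding them (plus score-poor decoy peaks), two libraries of
paired-end fragments sampled preferentially from the elements with mean
insert length 750 bp, and an expression table in which genes wired to
three or more distal elements are expressed higher.

Element-to-gene wiring works on the ordered gene lattice of each
chromosome.  Every element placed in the gap between two consecutive
genes is, by the domain rules, distal to both flanking genes and to no
other gene; elements placed inside a gene's basal window are proximal to
that gene alone.  Planting therefore allocates elements to gaps in
isolated blocks (one unused buffer gene between blocks) so the implied
per-gene distal counts are exact by construction:

* a "D2 block" (buffer, a, b, c) puts 2 elements in gap(a,b) and 1 in
  gap(b,c): gene b collects 3 distal regions, its flanks a and c collect
  2 and 1;
* a "D1 block" (buffer, x, y) puts 1 element in gap(x,y): both x and y
  collect one distal region;
* proximal elements sit within +/-1 kb of an otherwise unused gene's TSS.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from os import PathLike
from pathlib import Path

import numpy as np

from .errors import ConfigError, PlacementError
from .genome_io import FeatureTrack, GeneModel, GenomeDescriptor, GenomicInterval

READ_LENGTH = 150


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; the dataset is a pure function of it."""

    seed: int = 17
    n_chroms: int = 3
    chrom_length: int = 10_000_000
    n_genes: int = 300
    n_planted_elements: int = 200
    element_length_min: int = 300
    element_length_max: int = 900
    fragment_length_mean: float = 750.0
    fragment_length_sd: float = 100.0
    fragment_length_min: int = 200
    n_fragments: int = 100_000
    background_fraction: float = 0.10
    n_libraries: int = 2
    d2_fraction: float = 0.10
    expression_log_mu: float = 1.0
    expression_log_sigma: float = 1.0
    d2_expression_multiplier: float = 4.0
    decoy_peak_fraction: float = 0.20
    corrupt_fraction: float = 0.0

    def __post_init__(self) -> None:
        positive = (
            self.n_chroms,
            self.chrom_length,
            self.n_genes,
            self.n_planted_elements,
            self.n_fragments,
            self.n_libraries,
            self.element_length_min,
            self.fragment_length_min,
        )
        if any(v <= 0 for v in positive):
            raise ConfigError("all counts and lengths must be positive")
        fractions = (
            self.background_fraction,
            self.d2_fraction,
            self.decoy_peak_fraction,
            self.corrupt_fraction,
        )
        if any(not 0.0 <= f <= 1.0 for f in fractions):
            raise ConfigError("fractions must lie in [0, 1]")
        if self.element_length_max < self.element_length_min:
            raise ConfigError("element length range inverted")


@dataclass
class PlantedElement:
    element_id: str
    interval: GenomicInterval
    weight: float


@dataclass
class GroundTruth:
    """Planted elements, their intended gene assignments, and the per-gene
    groups those assignments imply."""

    elements: list[PlantedElement]
    # (element_id, gene_id, 'proximal'|'distal')
    assignments: list[tuple[str, str, str]]

    def intended_groups(self) -> dict[str, set[str]]:
        n_prox: dict[str, int] = {}
        n_dist: dict[str, int] = {}
        for _, gene_id, klass in self.assignments:
            if klass == "proximal":
                n_prox[gene_id] = n_prox.get(gene_id, 0) + 1
            else:
                n_dist[gene_id] = n_dist.get(gene_id, 0) + 1
        return {
            "P": {g for g, c in n_prox.items() if c >= 1},
            "D1": {g for g, c in n_dist.items() if 1 <= c <= 2},
            "D2": {g for g, c in n_dist.items() if c >= 3},
        }

    def element_intervals(self) -> list[GenomicInterval]:
        return [e.interval for e in self.elements]

    def to_json(self) -> str:
        payload = {
            "elements": [
                {
                    "element_id": e.element_id,
                    "chrom": e.interval.chrom,
                    "start": e.interval.start,
                    "end": e.interval.end,
                    "weight": e.weight,
                }
                for e in self.elements
            ],
            "assignments": [
                {"element_id": ei, "gene_id": gi, "klass": k}
                for ei, gi, k in self.assignments
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        payload = json.loads(text)
        elements = [
            PlantedElement(
                element_id=e["element_id"],
                interval=GenomicInterval(e["chrom"], e["start"], e["end"]),
                weight=e["weight"],
            )
            for e in payload["elements"]
        ]
        assignments = [
            (a["element_id"], a["gene_id"], a["klass"])
            for a in payload["assignments"]
        ]
        return cls(elements=elements, assignments=assignments)


# ---------------------------------------------------------------------------
# genome and genes
# ---------------------------------------------------------------------------

_MIN_TSS_SPACING_FACTOR = 0.4  # jittered lattice guarantees this * mean spacing
_GAP_MARGIN = 3000  # element midpoints keep this distance from flanking TSSs
_SUBBAND_MARGIN = 2500  # keeps same-gap elements >= 5 kb apart


def make_genome_and_genes(
    config: SimulationConfig,
) -> tuple[GenomeDescriptor, list[GeneModel]]:
    """Place genes on a jittered lattice, one lattice per chromosome.

    The lattice guarantees a minimum TSS spacing of 0.4x the mean spacing,
    which the element-planting margins rely on.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    sizes = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    genome = GenomeDescriptor(chrom_sizes=sizes)
    base = config.n_genes // config.n_chroms
    extra = config.n_genes % config.n_chroms
    genes: list[GeneModel] = []
    idx = 0
    for c, chrom in enumerate(genome.chroms):
        n_here = base + (1 if c < extra else 0)
        if n_here == 0:
            continue
        spacing = config.chrom_length / n_here
        if spacing * _MIN_TSS_SPACING_FACTOR < 25_000:
            raise ConfigError(
                f"gene density too high: {n_here} genes on {config.chrom_length} bp "
                "leaves no room for regulatory-domain structure"
            )
        jitter = rng.uniform(-0.3, 0.3, n_here) * spacing
        tss_positions = np.round((np.arange(n_here) + 0.5) * spacing + jitter).astype(int)
        strands = rng.choice(["+", "-"], size=n_here)
        lengths = rng.integers(2000, 20_001, size=n_here)
        for tss, strand, length in zip(tss_positions, strands, lengths):
            tss = int(tss)
            if strand == "+":
                tes = min(config.chrom_length - 1, tss + int(length))
            else:
                tes = max(0, tss - int(length))
            genes.append(GeneModel(f"gene_{idx:04d}", chrom, str(strand), tss, tes))
            idx += 1
    return genome, genes


# ---------------------------------------------------------------------------
# element planting
# ---------------------------------------------------------------------------


def _place_in_gap(
    left_tss: int,
    right_tss: int,
    k: int,
    rng: np.random.Generator,
) -> list[int]:
    """k element midpoints in the gap between two consecutive TSSs.

    The band keeps a 3 kb margin from both TSSs (so the resulting regions
    stay unambiguously distal) and is split into k sub-bands with inner
    margins so midpoints stay >= 5 kb apart (fragment clouds of distinct
    elements never merge)."""
    lo, hi = left_tss + _GAP_MARGIN, right_tss - _GAP_MARGIN
    # keep every midpoint within distal range of both flanking genes
    hi = min(hi, left_tss + 480_000)
    lo = max(lo, right_tss - 480_000)
    if hi - lo < k * (2 * _SUBBAND_MARGIN + 1):
        raise PlacementError(
            f"gap {left_tss}-{right_tss} too narrow for {k} elements"
        )
    width = (hi - lo) / k
    mids = []
    for i in range(k):
        sub_lo = int(lo + i * width) + _SUBBAND_MARGIN
        sub_hi = int(lo + (i + 1) * width) - _SUBBAND_MARGIN
        mids.append(int(rng.integers(sub_lo, sub_hi + 1)))
    return mids


def plant_elements(
    genome: GenomeDescriptor,
    genes: list[GeneModel],
    config: SimulationConfig,
) -> tuple[GroundTruth, FeatureTrack]:
    """Allocate elements to gap blocks and basal windows; emit the scored
    peak track (planted peaks score with sampling weight, decoys score low)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n_d2 = int(round(config.d2_fraction * config.n_genes))
    e_d2 = 3 * n_d2
    if e_d2 > config.n_planted_elements:
        raise ConfigError("d2_fraction demands more elements than are planted")
    remainder = config.n_planted_elements - e_d2
    n_prox = (remainder + 1) // 2
    n_d1_elems = remainder - n_prox
    # one element per D1 block: apart from the unavoidable D2-block flanks
    # (which collect 2), intended-D1 genes sit at 1 distal element, well
    # away from the >=3 boundary that defines D2
    d1_blocks = [1] * n_d1_elems

    by_chrom: dict[str, list[GeneModel]] = {}
    for gene in genes:
        by_chrom.setdefault(gene.chrom, []).append(gene)
    for chrom_genes in by_chrom.values():
        chrom_genes.sort(key=lambda g: g.tss)

    # queue of blocks: ('D2',) needs 4 consecutive genes, ('D1', k) needs 3
    queue: list[tuple[str, int]] = [("D2", 3)] * n_d2 + [("D1", k) for k in d1_blocks]
    placements: list[tuple[str, list[GeneModel], int]] = []  # kind, genes, k
    used_genes: set[str] = set()
    qi = 0
    for chrom in genome.chroms:
        chrom_genes = by_chrom.get(chrom, [])
        pos = 0
        while qi < len(queue):
            kind, k = queue[qi]
            size = 4 if kind == "D2" else 3
            if pos + size > len(chrom_genes):
                break
            block = chrom_genes[pos : pos + size]
            placements.append((kind, block, k))
            used_genes.update(g.gene_id for g in block[1:])  # buffer stays free
            pos += size
            qi += 1
    if qi < len(queue):
        raise PlacementError("not enough genes to lay out the requested elements")

    elements: list[PlantedElement] = []
    assignments: list[tuple[str, str, str]] = []
    weights = rng.lognormal(0.0, 0.5, config.n_planted_elements)

    def add_element(chrom: str, mid: int) -> PlantedElement:
        eid = f"element_{len(elements):04d}"
        length = int(
            rng.integers(config.element_length_min, config.element_length_max + 1)
        )
        start = mid - length // 2
        el = PlantedElement(
            element_id=eid,
            interval=GenomicInterval(chrom, start, start + length),
            weight=float(weights[len(elements)]),
        )
        elements.append(el)
        return el

    def assign_gap_element(el: PlantedElement, flanks: list[GeneModel]) -> None:
        mid = el.interval.midpoint
        for gene in flanks:
            d = abs(mid - gene.tss)
            if 2000 < d <= 500_000:
                assignments.append((el.element_id, gene.gene_id, "distal"))

    for kind, block, k in placements:
        if kind == "D2":
            _, a, b, c = block
            for mid in _place_in_gap(a.tss, b.tss, 2, rng):
                assign_gap_element(add_element(a.chrom, mid), [a, b])
            for mid in _place_in_gap(b.tss, c.tss, 1, rng):
                assign_gap_element(add_element(b.chrom, mid), [b, c])
        else:
            _, x, y = block
            for mid in _place_in_gap(x.tss, y.tss, k, rng):
                assign_gap_element(add_element(x.chrom, mid), [x, y])

    free = sorted(set(g.gene_id for g in genes) - used_genes)
    if n_prox > len(free):
        raise PlacementError("not enough unused genes for proximal elements")
    gene_by_id = {g.gene_id: g for g in genes}
    prox_ids = rng.choice(free, size=n_prox, replace=False)
    for gid in prox_ids:
        gene = gene_by_id[str(gid)]
        mid = gene.tss + int(rng.integers(-1000, 1001))
        el = add_element(gene.chrom, mid)
        assignments.append((el.element_id, gene.gene_id, "proximal"))

    truth = GroundTruth(elements=elements, assignments=assignments)

    # peak track: one scored peak around each element, plus decoys
    peak_ivs: list[GenomicInterval] = []
    peak_scores: list[float] = []
    for el in elements:
        pad_l = int(rng.integers(200, 501))
        pad_r = int(rng.integers(200, 501))
        peak_ivs.append(
            GenomicInterval(
                el.interval.chrom,
                max(0, el.interval.start - pad_l),
                el.interval.end + pad_r,
            )
        )
        peak_scores.append(50.0 + 100.0 * el.weight)
    n_decoys = int(
        round(
            config.decoy_peak_fraction
            / (1.0 - config.decoy_peak_fraction)
            * len(elements)
        )
    )
    chrom_names = genome.chroms
    chrom_lens = np.array([genome.chrom_sizes[c] for c in chrom_names], dtype=float)
    chrom_p = chrom_lens / chrom_lens.sum()
    planted_sorted = sorted(peak_ivs, key=lambda p: (p.chrom, p.start))
    placed_decoys = 0
    tries = 0
    while placed_decoys < n_decoys:
        tries += 1
        if tries > 100 * n_decoys + 100:
            raise PlacementError("could not place decoy peaks clear of elements")
        chrom = str(rng.choice(chrom_names, p=chrom_p))
        length = int(rng.integers(700, 1901))
        start = int(rng.integers(0, genome.chrom_sizes[chrom] - length))
        candidate = GenomicInterval(chrom, start, start + length)
        if any(candidate.overlaps(p) for p in planted_sorted):
            continue
        peak_ivs.append(candidate)
        peak_scores.append(10.0 + 40.0 * float(rng.random()))
        placed_decoys += 1
    track = FeatureTrack("h3k27ac", peak_ivs, peak_scores)
    return truth, track


# ---------------------------------------------------------------------------
# read-pair simulation
# ---------------------------------------------------------------------------


def simulate_library(
    truth: GroundTruth,
    genome: GenomeDescriptor,
    config: SimulationConfig,
    library_id: str,
) -> str:
    """Emit one library as SAM text: weight-proportional element fragments
    plus uniform background, one proper pair per fragment.

    A ``corrupt_fraction`` of pairs is spoiled (low MAPQ, secondary flag,
    or orphaned mate) to exercise the alignment filters.
    """
    lib_index = sum(ord(ch) for ch in library_id) % 1000
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3, lib_index]))
    n = config.n_fragments
    n_bg = int(round(config.background_fraction * n))
    n_el = n - n_bg

    frag_lens = np.round(
        rng.normal(config.fragment_length_mean, config.fragment_length_sd, n)
    ).astype(int)
    frag_lens = np.maximum(frag_lens, config.fragment_length_min)
    strands = rng.choice(["+", "-"], size=n)

    chroms: list[str] = []
    starts = np.empty(n, dtype=int)

    weights = np.array([e.weight for e in truth.elements])
    p = weights / weights.sum()
    el_idx = rng.choice(len(truth.elements), size=n_el, p=p)
    el_starts = np.array([e.interval.start for e in truth.elements])
    el_ends = np.array([e.interval.end for e in truth.elements])
    el_chroms = [e.interval.chrom for e in truth.elements]
    for i in range(n_el):
        e = el_idx[i]
        lf = frag_lens[i]
        le = el_ends[e] - el_starts[e]
        if lf >= le:
            # fragment covers the element with a random overhang
            offset = int(rng.integers(0, lf - le + 1))
            start = el_starts[e] - offset
        else:
            start = el_starts[e] + int(rng.integers(0, le - lf + 1))
        starts[i] = start
        chroms.append(el_chroms[e])

    chrom_names = genome.chroms
    chrom_lens = np.array([genome.chrom_sizes[c] for c in chrom_names], dtype=float)
    chrom_p = chrom_lens / chrom_lens.sum()
    bg_chrom_idx = rng.choice(len(chrom_names), size=n_bg, p=chrom_p)
    for j in range(n_bg):
        i = n_el + j
        chrom = chrom_names[bg_chrom_idx[j]]
        starts[i] = int(rng.integers(0, genome.chrom_sizes[chrom] - frag_lens[i]))
        chroms.append(chrom)

    n_corrupt = int(round(config.corrupt_fraction * n))
    corrupt_idx = (
        set(rng.choice(n, size=n_corrupt, replace=False).tolist()) if n_corrupt else set()
    )

    lines = [f"@HD\tVN:1.6\tSO:unsorted"]
    for chrom in chrom_names:
        lines.append(f"@SQ\tSN:{chrom}\tLN:{genome.chrom_sizes[chrom]}")
    R = READ_LENGTH
    for i in range(n):
        qname = f"{library_id}_{i:06d}"
        chrom = chroms[i]
        start = int(starts[i])
        length = int(frag_lens[i])
        end = start + length
        left_pos1 = start + 1
        right_pos1 = end - R + 1
        if strands[i] == "+":
            left_flag, right_flag = 99, 147
        else:
            left_flag, right_flag = 163, 83
        mapq = 42
        corrupt_mode = -1
        if i in corrupt_idx:
            corrupt_mode = i % 3
        if corrupt_mode == 0:
            mapq = 2
        if corrupt_mode == 1:
            left_flag |= 0x100
            right_flag |= 0x100
        lines.append(
            f"{qname}\t{left_flag}\t{chrom}\t{left_pos1}\t{mapq}\t{R}M\t=\t"
            f"{right_pos1}\t{length}\t*\t*"
        )
        if corrupt_mode != 2:  # mode 2: orphan the right mate
            lines.append(
                f"{qname}\t{right_flag}\t{chrom}\t{right_pos1}\t{mapq}\t{R}M\t=\t"
                f"{left_pos1}\t{-length}\t*\t*"
            )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# expression and categories
# ---------------------------------------------------------------------------


def simulate_expression(
    truth: GroundTruth,
    genes: list[GeneModel],
    config: SimulationConfig,
) -> tuple[dict[str, float], dict[str, set[str]]]:
    """Log-normal baseline FPKM with a multiplicative boost for intended-D2
    genes, plus three gene categories reflecting the planted structure."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    groups = truth.intended_groups()
    fpkm: dict[str, float] = {}
    baseline = rng.lognormal(
        config.expression_log_mu, config.expression_log_sigma, len(genes)
    )
    for gene, value in zip(genes, baseline):
        if gene.gene_id in groups["D2"]:
            value *= config.d2_expression_multiplier
        fpkm[gene.gene_id] = float(value)

    categories: dict[str, set[str]] = {
        "cancer_like": set(),
        "housekeeping_like": set(),
        "neutral": set(),
    }
    for gene in genes:
        gid = gene.gene_id
        if gid in groups["D2"]:
            if rng.random() < 0.8:
                categories["cancer_like"].add(gid)
        elif rng.random() < 0.05:
            categories["cancer_like"].add(gid)
        if gid in groups["P"]:
            if rng.random() < 0.7:
                categories["housekeeping_like"].add(gid)
        elif rng.random() < 0.05:
            categories["housekeeping_like"].add(gid)
        if rng.random() < 0.2:
            categories["neutral"].add(gid)
    return fpkm, categories


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: GenomeDescriptor
    genes: list[GeneModel]
    truth: GroundTruth
    track: FeatureTrack
    sam_texts: dict[str, str]
    fpkm: dict[str, float]
    categories: dict[str, set[str]]


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Generate the complete dataset deterministically from the config."""
    genome, genes = make_genome_and_genes(config)
    truth, track = plant_elements(genome, genes, config)
    sam_texts = {
        f"L{i + 1}": simulate_library(truth, genome, config, f"L{i + 1}")
        for i in range(config.n_libraries)
    }
    fpkm, categories = simulate_expression(truth, genes, config)
    return SimulatedDataset(
        config=config,
        genome=genome,
        genes=genes,
        truth=truth,
        track=track,
        sam_texts=sam_texts,
        fpkm=fpkm,
        categories=categories,
    )


def write_genes_gff3(genes: list[GeneModel], path: str | PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            lo = min(gene.tss, gene.tes)
            hi = max(gene.tss, gene.tes)
            fh.write(
                f"{gene.chrom}\tregmap_sim\tgene\t{lo + 1}\t{hi + 1}\t.\t"
                f"{gene.strand}\t.\tID={gene.gene_id}\n"
            )


def write_dataset(dataset: SimulatedDataset, out_dir: str | PathLike) -> dict[str, Path]:
    """Write every artifact of the dataset; returns name -> path."""
    from .genome_io import write_bed

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genome"] = out / "genome.tsv"
    dataset.genome.to_tsv(paths["genome"])

    paths["genes"] = out / "genes.gff3"
    write_genes_gff3(dataset.genes, paths["genes"])

    paths["truth"] = out / "truth.json"
    paths["truth"].write_text(dataset.truth.to_json())

    paths["track"] = out / "h3k27ac.bed"
    write_bed(dataset.track, paths["track"], genome=dataset.genome)

    for lib_id, text in dataset.sam_texts.items():
        paths[lib_id] = out / f"{lib_id}.sam"
        paths[lib_id].write_text(text)

    paths["fpkm"] = out / "fpkm.tsv"
    with open(paths["fpkm"], "w") as fh:
        for gid in sorted(dataset.fpkm):
            fh.write(f"{gid}\t{dataset.fpkm[gid]:.6f}\n")

    paths["categories"] = out / "categories.tsv"
    with open(paths["categories"], "w") as fh:
        for cat in sorted(dataset.categories):
            for gid in sorted(dataset.categories[cat]):
                fh.write(f"{gid}\t{cat}\n")
    return paths
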