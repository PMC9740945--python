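# regmap

Downstream analysis for ChIP-selected reporter-assay (MPRA) fragment
libraries: from paired-end alignments of selected library fragments to a
unique map of candidate regulatory regions, their enrichment in chromatin
feature tracks versus matched random regions, their association with genes
by regulatory-domain rules, and the expression/category statistics of the
resulting gene groups.

## The problem

A lentiviral MPRA with H3K27ac chromatin-immunoprecipitation pre-enrichment
selects genomic fragments that can drive reporter expression. After
sequencing the selected libraries, the computational questions are:

1. **Which genomic regions were selected?**  Properly-paired, primary
   alignments with MAPQ ≥ 10 are kept; the SAM flag combinations 99/147
   (plus chain) and 83/163 (minus chain) assign each fragment its strand;
   same-orientation overlapping fragments are merged; each merged region is
   quantified as fragments per million (RPM = count × 10⁶ / library total)
   and regions with RPM > 10 are retained; the retained regions of all
   libraries are merged strand-blind into the *unique region map*.
2. **Are they biologically meaningful?**  The map is intersected with
   feature tracks (H3K27ac peaks, DHS clusters, super-enhancers, CAGE
   peaks) and compared with random regions matched in count, length
   multiset, and per-chromosome distribution.
3. **Which genes do they regulate?**  Each gene receives a basal domain
   (TSS ± 2 kb, strand-aware) extended toward its neighbours' basal domains
   up to 500 kb; a region associates with every gene whose extended domain
   contains its midpoint.  Regions within ±2 kb of a 5′-end are *proximal*
   (P), those 2–500 kb away *distal* (D).  Genes with ≥ 1 proximal region
   form the P group; genes with 1–2 / ≥ 3 distal regions form the D1 / D2
   groups.
4. **Do the groups differ?**  Mann–Whitney rank-sum tests on FPKM (0.5 FPKM
   cutoff), category composition percentages, and hypergeometric fold
   enrichment `(k/n)/(K/N)` with Benjamini–Hochberg correction.

A fully deterministic synthetic-data generator (`regmap.synthetic_data`)
produces a toy genome with planted regulatory elements, a scored peak
track, paired-end SAM libraries, and an expression table with the assumed
structure (genes wired to ≥ 3 distal elements expressed higher), so the
whole pipeline runs and is validated without any downloads.

## Worked example

```python
import regmap as rm

config = rm.SimulationConfig(seed=17)
dataset = rm.simulate(config)
fragments = {lib: rm.fragments_from_sam_text(text, lib)
             for lib, text in dataset.sam_texts.items()}
result = rm.run_pipeline(fragments, dataset.genes, dataset.genome,
                         track=dataset.track)

print("fragments per library:",
      {lib: fs.total_count for lib, fs in fragments.items()})
print("unique regions:", len(result.union_map))
print("mark-supported candidates:", len(result.candidate_map),
      f"({100 * result.track_overlap_fraction:.1f}% of the map)")
table = result.gene_table
print("P/D1/D2 genes:", len(table.group("P")), len(table.group("D1")),
      len(table.group("D2")))
test = rm.expression_group_test(table, dataset.fpkm)
print(f"D2 vs D1 expression: U={test.u_statistic:.0f}, "
      f"n={test.n1}/{test.n2}, p={test.p_two_sided:.2e}")
```

prints

```
fragments per library: {'L1': 100000, 'L2': 100000}
unique regions: 2088
mark-supported candidates: 203 (9.7% of the map)
P/D1/D2 genes: 55 171 31
D2 vs D1 expression: U=4105, n=31/164, p=5.89e-08
```

Reading: two libraries of 100,000 fragments each call 2,088 unique regions
after merging and RPM thresholding.  Restricting to regions supported by
the acetylation-mark track leaves 203 candidate regulatory regions (the
planted structure contains 200 elements).  Gene association recovers 55
promoter-proximal (P) genes, 171 genes with 1–2 distal regions (D1) and 31
genes with ≥ 3 distal regions (D2); the D2 group is expressed significantly
higher than D1 (two-sided rank-sum p ≈ 6×10⁻⁸), reproducing the structure
the generator planted.

The same steps are available from the shell:

```sh
regmap simulate --seed 17 --out-dir sim/
regmap fragments --sam sim/L1.sam --library L1 --out L1.fragments.bed
regmap call --fragments L1.fragments.bed --library L1 --out L1.regions.bed
regmap union L1.regions.bed L2.regions.bed --out map.bed
regmap enrich --map map.bed --track sim/h3k27ac.bed --genome sim/genome.tsv
regmap associate --map map.bed --genes sim/genes.gff3 \
    --genome sim/genome.tsv --out-prefix assoc
regmap stats --groups assoc.gene_groups.tsv --expression sim/fpkm.tsv \
    --categories sim/categories.tsv
```

## Documentation

`docs/methods.md` describes the model and its assumptions, the generator's
design and what it does and does not emulate, numerical conventions
(coordinates, tie-breaks, boundary cases), and known limitations.
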