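# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open (`[start, end)`), the BED
convention.  1-based fully-closed coordinates appear only at boundaries:
UCSC-style display strings (`chr13:99,498,575-99,499,229`), SAM `POS`, and
GFF3 positions are converted on input and output.  A printed 1-based
closed region of start *s* and end *e* has length *e − s + 1*; the parser
tolerates commas and internal whitespace.  Book-ended intervals
(`end == start`) never overlap; proximity-based merging is controlled
exclusively by the merge operation's `max_gap` parameter.  Chromosome
names are matched by exact string equality — no `chr` aliasing is
attempted, so mixed naming surfaces as zero overlap rather than as a
silent half-match.

## Fragment recovery

The selection assay clones genomic fragments whose sequencing yields one
properly-paired read pair per fragment.  Recovery keeps records with the
proper-pair bit (0x2) set and the unmapped (0x4), secondary (0x100) and
supplementary (0x800) bits clear, at MAPQ ≥ 10 (the `mapq_min` default).
The pair's chain of origin comes from the flag combinations 99/147 (plus)
and 83/163 (minus); any other flag value excludes the record from
fragment building.  A fragment is the outer span of its two mates —
leftmost aligned base to rightmost aligned base — which equals |TLEN| for
well-formed pairs but does not depend on the TLEN sign convention.
Mates on different chromosomes or with conflicting chain assignments are
discarded and counted rather than guessed; single-record query names are
counted as orphans.  Soft-clipping is ignored: spans use POS and the
CIGAR reference length only.

## Region calling

Within each library and orientation, fragments that overlap or are
book-ended (`max_gap = 0`, matching the default of the standard
interval-merge tools) collapse into regions.  Each region is quantified
as RPM = fragment_count × 10⁶ / total retained fragments of the library;
the denominator is the post-filter fragment total because raw read counts
are not available downstream of filtering.  Orientations are then
combined and regions with RPM **strictly greater** than 10 are retained —
RPM exactly 10 is dropped.  The retained maps of all libraries are merged
strand-blind into the unique region map (regions carry no strand in any
downstream analysis); each merged region records which libraries
contributed.  A `stranded` union that keeps per-orientation regions
separate is available as an option.  The caller is deliberately
merge-and-threshold only: no peak-shape model, local background, or
significance testing.

## Mark-supported candidate map

The end-to-end pipeline restricts the unique region map to regions
overlapping the acetylation-mark peak track (≥ 1 bp) before any gene
association.  Only mark-supported regions are candidate regulatory
elements; unsupported regions — at desk scale, mostly coincidental
overlaps of two background fragments that clear the RPM threshold — carry
no evidence of regulatory chromatin and would otherwise flood the distal
gene counts.  Running `run_pipeline` without a track skips the
restriction and associates the full map.

## Matched-random enrichment

The null model re-places every region of the template map uniformly at
random on its own chromosome, preserving the region count, the length
multiset, and the per-chromosome distribution exactly; placements
crossing a chromosome end are impossible by construction and placements
overlapping a declared assembly gap are rejected and resampled (up to
1000 attempts per region, then an error naming the region).  When no gap
track is supplied, placement is over the whole chromosome.  The overlap
criterion is ≥ 1 bp everywhere, with no reciprocal-fraction requirement.
Enrichment is reported as observed fraction / mean null fraction together
with an upper-tail permutation p-value with the add-one correction,
p = (1 + #{null ≥ observed}) / (1 + n); the add-one keeps p strictly
positive at any replicate count.  Default n = 100 replicates, seed 17.
GC- or mappability-matched nulls and locality-preserving shuffles are out
of scope.

## Regulatory domains and gene association

Each gene's basal domain is the strand-aware window `TSS − up` to
`TSS + down` (defaults 2 kb/2 kb, so effectively symmetric).  The
extended domain grows from the basal edges in each direction to the
nearest other gene's basal-domain boundary, to at most `max_ext`
(500 kb) from the TSS, and never beyond the chromosome; overlapping basal
domains are never truncated, so every extended domain contains its basal
domain and its own TSS.  Note the consequence: the gap between two
consecutive genes belongs to *both* flanking extended domains, so one
region can regulate several genes.

A region associates with a gene iff the region **midpoint** (integer
floor of (start+end)/2) lies inside the extended domain — midpoint
membership and TSS-to-midpoint distance are the conventions of the
association service this reimplements.  The signed distance is negative
upstream of the TSS (strand-aware).  Midpoints exactly 2000 bp from the
TSS classify as proximal (the ±2 kb boundary is inclusive); 2–500 kb is
distal; beyond 500 kb no association is recorded.

Per gene, distinct proximal and distal regions are counted:
P = {≥ 1 proximal}, D1 = {1–2 distal}, D2 = {≥ 3 distal}.  P and the
distal groups are *not* mutually exclusive; D1 and D2 partition the
distal genes.  A per-region gene count (`n_genes`) is reported alongside
for the complementary regions-per-gene view, but drives no grouping.
Curated regulatory domains are simply never loaded.

## Group statistics

* **Rank-sum**: two-sided Mann–Whitney U with midrank ties.  Values below
  the 0.5 FPKM cutoff are removed before ranking (the cutoff can be
  disabled).  The exact null is enumerated when both groups have ≤ 8
  values and no ties; otherwise the normal approximation with tie and
  continuity corrections is used.  Whisker trimming ("1.5 IQR") is plot
  cosmetics only — values are never trimmed before testing; box
  descriptors (median, quartiles, min–max, 1.5 IQR whiskers) are emitted
  separately.
* **Composition**: 100 × |group ∩ category| / |group|; categories may
  overlap, so a group's percentages may exceed 100 in total.
* **Fold enrichment**: fold = (k/n)/(K/N) with an upper-tail
  hypergeometric p; the EASE variant (scoring k − 1) is available behind
  a flag but plain hypergeometric is the default, as the EASE penalty is
  a tool-specific conservative convention.  The universe defaults to all
  annotated genes and is overridable.  Benjamini–Hochberg adjustment is
  applied across the categories of one call.
* **TSS distance profile**: strand-aware histogram of region midpoints by
  signed distance to gene 5′-ends, aggregated over genes (default ±50 kb
  in 1 kb bins; a midpoint exactly at the TSS falls in the [0, bin) bin).

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
at desk scale: 3 chromosomes × 10 Mb, 300 genes, 200 planted elements of
300–900 bp, two libraries of 100,000 fragments with insert length
N(750, 100²) truncated at 200 bp (the assay's observed mean insert is
~750 bp), 10% uniform background, and a log-normal(μ=1, σ=1) FPKM
baseline with a ×4 multiplier for genes wired to ≥ 3 distal elements.

Genes sit on a per-chromosome jittered lattice (uniform ±30% jitter
around even spacing), which guarantees a minimum TSS spacing of 0.4× the
mean spacing; layouts denser than 25 kb minimum spacing are rejected as
infeasible.  Elements are allocated on the ordered gene lattice in
isolated blocks separated by unused buffer genes, exploiting the domain
geometry (a gap element is distal to exactly its two flanking genes; a
basal element is proximal to exactly its own gene):

* **D2 block** (buffer, a, b, c): 2 elements in gap(a,b) and 1 in
  gap(b,c) give gene b exactly 3 distal regions and its flanks 2 and 1.
  A flank at 2 is unavoidable — 3 elements over 2 gaps always leave one
  gap with ≥ 2.
* **D1 block** (buffer, x, y): 1 element in the shared gap gives both
  genes 1 distal region.  One element per block keeps all other non-D2
  genes well away from the ≥ 3 boundary, so a few spurious regions cannot
  flip them into D2.
* **Proximal singles**: elements within ±1 kb of an otherwise unused
  gene's TSS (leak-free, since basal midpoints fall outside every other
  extended domain).

Gap elements keep 3 kb margins from flanking TSSs (regions stay
unambiguously distal after fragment-cloud widening) and ≥ 5 kb from each
other (fragment clouds of distinct elements never merge).  Element
sampling weights are log-normal(0, 0.5); fragment sampling is
weight-proportional, modelling reporter selection as enrichment of the
fragment pool rather than as cell-level dynamics.  Each element emits a
surrounding scored peak (score 50 + 100 × weight); decoy peaks with no
element (20% of the track, scores 10–50) are placed uniformly, clear of
planted peaks.  Libraries are emitted directly as SAM text (alignment
itself is out of scope): one proper pair per fragment with flags 99/147
or 83/163, MAPQ 42, 150M CIGAR, and TLEN equal to the fragment length.
An optional `corrupt_fraction` spoils pairs (low MAPQ, secondary flag,
or orphaned mate) to exercise the filters; its default is 0, which keeps
the retained-fragment total at exactly 100,000 so that a single
background fragment scores RPM = 10.0 — precisely at, and therefore
below, the strict > 10 threshold.

The whole dataset is a pure function of `SimulationConfig`; all
randomness derives from seeded child sequences of `config.seed`, and the
same seed reproduces every artifact byte-for-byte.

**What the generator does not emulate**: sequencing errors and base
qualities, PCR duplicates, soft-clipping, GC and mappability biases,
realistic gene-density variation, assembly gaps, and genuine
chromatin-state correlation structure.  Passing tests therefore show the
pipeline's logic is correct under the assumed model, not that the
biological conclusions transfer to any particular real dataset.

## Numerical choices and degenerate inputs

Strict inequality at the RPM threshold; inclusive ±2 kb proximal
boundary; integer-floor midpoints; deterministic writer ordering (genome
chromosome order, then start).  Operations whose result would be
undefined raise typed errors rather than returning sentinels: RPM with an
empty library, overlap fractions of an empty region set, rank-sum groups
emptied by the cutoff, empty enrichment universes or categories, and
score-colocalization splits in which every peak (or none) overlaps the
map.

## Limitations

The caller cannot separate two regulatory elements closer than a
fragment length; RPM normalization assumes comparable library
complexity; the association rule ignores chromatin contacts and TADs, so
distal assignments are proximity-based hypotheses; the matched-random
null preserves no sequence composition; and at desk scale the RPM
threshold is deliberately balanced so that singleton background
fragments are excluded while coincident background pairs are not — the
mark-support restriction is what removes those, as in the analysis this
package reimplements.
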