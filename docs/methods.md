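# Methods

This note documents the models, conventions and parameter choices behind
`accessprofiler`, in the order the pipeline runs them. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinates and containers

All in-memory coordinates are 0-based half-open. BED, narrowPeak and
bedGraph are native in that convention; GFF3 is converted on read/write
(via gffutils). Insertion tracks are stored as dense per-chromosome integer
arrays — the right trade-off at the megabase scale this package targets;
for a full 15 Gb genome a chunked or sparse store would be the natural
extension. Organellar contigs carry the reserved names `chrPt` and `chrMt`
and are excluded from all "nuclear" statistics (background rate, gene
placement).

## Insertion tracks

A fragment (chrom, s, e) represents one aligned read pair and contributes
exactly two Tn5 insertion events, at bases s and e−1. The conventional
+4/−5 dyad correction (`shift_mode="tn5_offset"`, counting s+4 and e−6,
clamped to the chromosome) is offered but **off by default**: the two raw
fragment ends are the primary definition here, and the shifted variant is
a display/convention option rather than a different statistic.

Density tracks are sliding histograms: windows of `bin_size` (default
150 bp) anchored at multiples of `slide` (default 20 bp) **from coordinate
0**, not from the first insertion, so tracks from different samples are
comparable bin for bin. Each bar spans the centre `slide` bp of its window
and its height is the exact insertion count in the full window; windows
overhanging the chromosome end are truncated for the sum.

SPOT (Signal Portion Of Tags) is computed over insertion events — not read
pairs — against the union of the supplied peak intervals, so overlapping
peaks never double-count. Which tag definition and which peak set a given
published SPOT value used is often ambiguous; computing it over the
sample's own merged peaks is this package's documented choice, and the
peak set is an explicit argument so any reference hotspot list can be
substituted.

## Peak operations

*Merging*: peaks whose gap (next start − previous end) is **strictly**
below `max_gap` (default 10 bp) are merged transitively; a merged peak
spans the union, keeps the first member's name and the maximum score.
Merging is idempotent and never reduces covered bases (both are asserted
in tests).

*Two-set comparison*: a query peak counts as shared when the union of the
other set's peaks covers at least `min_fraction` (default 10 %) of the
query's **own** length. Two deliberate readings are baked in here. First,
the fraction is query-relative and evaluated per direction, which is the
only reading that lets the two directions be computed independently and
reported as separate shared/unique counts per set (they need not be
symmetric: one long peak can share with several short ones). Second,
coverage is the union over subjects rather than the best single subject —
a query split across two subject peaks is biologically one overlap.

*Down-sampling* operates on fragments (read pairs), not individual reads
or insertions, since insertions come in pairs; it is a uniform sample
without replacement, deterministic under the supplied seed.

## Genomic categories

The genome is partitioned into five categories: exon, intron, up2k
(< `flank` bp upstream of the TSS, strand-aware; default 2000), down2k
(same downstream of the TTS), and intergenic. Where several genes claim a
base, precedence is exon > intron > up2k > down2k: transcribed state is
directly observed while flanks are inferred, and the upstream flank — the
regulatory region of interest — beats the downstream one. UTR bases count
as exon (they are part of the transcribed region in the gene models this
package consumes). A peak is assigned the category of its midpoint base
⌊(start+end)/2⌋, giving each peak exactly one category so distributions
sum to 100 %; a boundary-spanning peak could defensibly be fractionally
assigned, but the midpoint rule is simple, deterministic and matches how
such distributions are usually tabulated.

"Closest gene" means minimal interval-to-interval distance (0 when the
peak overlaps the gene body), ties broken by the lexicographically smaller
gene id. A TSS-distance metric is a plausible alternative; gene-body
distance is the simplest reading and the one implemented.

The exclusive gene classes are pure set algebra: map each peak class to
its closest genes, then discard genes claimed by both classes ("mixed"),
leaving two disjoint gene sets by construction.

## Accessibility vs expression

Genes with FPKM = 0 form group 0; genes with FPKM > 0 are split into ten
rank deciles (ties broken by gene id, so the partition is deterministic;
decile sizes differ by at most one), decile 10 highest.

Upstream offsets are counted with u = 1 the base immediately 5′ of the
TSS: position TSS − u on plus-strand genes and TSS + u on minus-strand
genes. The aggregate profile at offset u is the mean insertion count over
the group's genes, excluding genes whose offset base falls off the
chromosome. Fold accessibility over background divides each per-offset
mean by the genome-wide per-base insertion rate computed over **nuclear
chromosomes only**, so organellar contamination cannot deflate the fold
values.

The per-gene accessibility window of width w centred c bp upstream covers
offsets [c − w/2 + 1, c + w/2] — for the defaults (c = 225, w = 150),
offsets 151–300, i.e. genomic interval [TSS−300, TSS−150) on a plus-strand
gene. Genes whose window overlaps a neighbouring gene are not excluded.
The accessibility–expression correlation is Pearson's r on raw window
counts vs raw FPKM by default; a log10(x+1) transform of both sides is
available as an option (`log_transform=True`) since "total accessibility"
admits either reading.

LOESS smoothing is tricube-weighted local **linear** regression
(statsmodels lowess, no robustness iterations), evaluated at the input
offsets. The default span of 0.3 over a 1000-point profile (~300-point
windows) resolves a ~150 bp promoter hotspot while suppressing per-base
Poisson noise; degree-1 fitting makes the smoother exact on linear series,
which the tests assert. Fewer than 10 points, or a span whose windows hold
fewer than 2 points, is an error.

Heatmap matrices hold log10(count + 1) — the pseudocount makes the zero
cells well-defined — in 150/20 sliding windows over [TSS − 1 kb, TSS], a
gene body rescaled to a fixed number of equal slices (`body_bins`,
default 20), and [TTS, TTS + 1 kb], all oriented 5′→3′; rows are ordered
by descending expression. Rescaling the body (rather than cropping a fixed
width) keeps one column meaning "same relative position in the gene" for
genes of different lengths.

## Enrichment test

A gene is tissue-enriched when FPKM_target ≥ fold × FPKM_other **and**
FPKM_target > 0 (default fold 10). "At least tenfold" is read inclusively;
the zero-handling convention means a gene expressed only in the target
tissue is enriched and a gene silent in both is not. The class comparison
is Pearson's χ² on the 2 × 2 class-by-enrichment table, 1 df, **no
continuity correction** by default (the intended use is large classes
where the correction only biases the statistic); the corrected variant is
exposed as an option. A zero margin (e.g. no enriched gene anywhere) is an
error naming the degenerate margin rather than a silent χ² = 0.

## Synthetic data generator

The generator emulates exactly the structure the analyses assume — and
nothing more. What it does **not** model: sequence content (no FASTQ, no
mapping ambiguity), Tn5 sequence bias, duplicate reads, chromatin domains
or any spatial autocorrelation beyond the promoter hotspots, isoforms
(one transcript per gene), or peak-calling noise (peak pairs are placed
geometrically, not called from the fragments). Passing recovery tests
therefore validates the pipeline's arithmetic and geometry on data that
satisfies its assumptions; they say nothing about robustness to alignment
artifacts or biological confounders in real data.

*Genome/annotation*: genes are apportioned to nuclear chromosomes by
length and packed left to right with at least `flank_min` bp between
neighbours (and clear of chromosome ends), leftover space spread
multinomially over the gaps; strands uniform; 1–3 exons per gene with
≥ 30 bp segments. Infeasible packing raises an error naming the violated
capacity.

*Expression*: per-tissue zero-inflated log-normal FPKM
(P(zero) = 0.3, log-mean 1.0, log-sd 1.5 by default — a heavy-tailed
distribution with roughly a third of genes silent per tissue, the shape
bulk RNA-seq FPKM tables typically show). A fraction (default 0.15) of
genes expressed in the first tissue is forced to ≥ 10-fold enrichment over
the second, and those ids are returned as ground truth.

*Fragments*: per-base insertion events follow an inhomogeneous Poisson
law at `background_rate` (default 0.01 /bp, the order of magnitude of a
deeply sequenced ATAC library spread over its mappable genome), raised to
background × (1 + intensity_q) inside each gene's hotspot window (150 bp
centred 225 bp upstream of the TSS, strand-aware, truncated at chromosome
bounds and recorded as such). The intensity is indexed by the gene's
expression quantile with non-decreasing defaults (0, 0.5, 1, 1.5, 2.5,
3.5, 5, 6.5, 8, 10, 12): intensity is the *excess* fold over background,
so non-expressed genes (intensity 0) sit at fold ≈ 1, matching the
expectation that silent promoters are not depleted below genomic average.
The total event count per chromosome is Poisson with the rate-field mass;
each fragment contributes two ends — one anchor drawn from the rate field,
its mate at a uniform 50–300 bp distance in a random direction (fragment
length is otherwise immaterial downstream, only the ends matter). A
fraction (default 0.08, split by contig length between a 135 kb `chrPt`
and a 450 kb `chrMt`) of fragments is drawn uniformly on the organellar
contigs — combined plastid + mitochondrial contamination of a clean
nuclei prep is in the several-percent range.

*Peak pairs*: each B peak is independently labelled shared with
probability `shared_peak_fraction` (default 0.83). Peaks live in disjoint
3×max-length slots; a shared B peak overlaps a distinct A peak by at
least 20 % of **both** lengths (comfortably above the 10 % criterion, so
truth labels and the partition agree exactly), and unique peaks of either
set overlap the other set by exactly zero. Peak lengths are uniform
200–800 bp; the max/min ratio must stay ≤ 5 so the 20 % mutual-overlap
construction is always feasible.

*Default scale*: one 1 Mb chromosome with 500 genes. At that density the
2 kb flanking convention of real annotations cannot hold (501 × 2 kb
already exceeds 1 Mb), so the generator's default `flank_min` is 600 bp
with gene lengths 400–1200 bp — enough to keep each 300 bp hotspot span in
intergenic space. The 1,000-peak pair recovery uses a 10 Mb chromosome,
since 2,000-odd disjoint 2.4 kb slots do not fit in 1 Mb; genome size here
is layout plumbing, not a parameter of any statistic.

*Determinism*: a single global seed feeds fixed per-generator substreams
(annotation 0, expression 1, fragments 2, peaks 3 — each
`default_rng([seed, stream])`), so regenerating one output never perturbs
the others; identical configs give byte-identical files.

## Numerical and statistical checks

The interval/counting primitives (insertion extraction, density windows,
merging, fractional-overlap partition, category assignment, upstream
profiles) are each validated exactly against independent brute-force
oracles (per-base scans, fixed-point pairwise merging, set arithmetic) on
100+ random instances. Recovery tests on the default synthetic conditions
assert: LOESS-profile argmax within ±20 bp of the simulated 225 bp hotspot
centre (pooled over expressed genes), strictly increasing window
accessibility across deciles (Spearman ρ > 0.9), positive Pearson r with
p < 0.01, organellar and shared-peak fractions within 3 SD of their
binomial expectations, and SPOT's 0/1 normalisation bounds. The χ²
statistic matches its closed form exactly and its p-value is uniform under
label permutation (KS test at 1,000 permutations on a 2 × 2000-gene null
with enrichment rate 0.2 — large enough that the hypergeometric support
makes the p-value distribution effectively continuous).

## Known limitations

- Dense per-base arrays bound practical genome size to tens of megabases.
- The fragment model draws one end from the accessibility field and the
  mate at a uniform distance; real libraries have both ends in accessible
  chromatin and a non-uniform insert-size distribution, so simulated
  profiles are slightly wider than real ones.
- `exclusive_gene_classes` iterates peak-by-peak; for very large peak sets
  a vectorised nearest-gene join would be preferable.
- The heatmap renderer is a plain matrix image; no clustering or
  column-block annotations.
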