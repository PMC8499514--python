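# Methods

This note documents the models, parameter choices and numerical
conventions behind the package, and what the synthetic cohort does and
does not establish about real data.

## Junction calling

A junction read is modeled as `[U5 LTR anchor | 16-nt index | host DNA]`.
The biological LTR terminus *is* the index window — the WT barcode is the
unmodified U5 3' end and H1/H5 are barcoded variants — so the anchor
template is the U5 prefix followed by 16 wildcard positions. Anchor
location uses a Hamming scan (no indels inside the anchor, at most 2
mismatches): the LTR is a fixed synthetic construct, so indels there
indicate an artifact rather than variation, and the scan keeps calling
O(read length). Treating the index positions as wildcards matters:
otherwise a WT read would pay three mismatches against an H1-bearing
template and be lost.

Index classification demands a *unique* minimal Hamming distance at most
1. H1 and H5 differ at a single position, so a sequencing error at the
discriminating base makes a read equidistant from both; such ties are
demoted to `unclassified` rather than guessed.

Host placement is two-pass. Pass 1 finds candidate placements on both
strands via exact 20-mer seed lookup (a sorted-hash k-mer index over the
genome) with full-segment Hamming verification; when no seed hits (both
seed halves errored, or indels), an edlib infix alignment over the whole
genome is the fallback. Pass 2 re-aligns the segment against the ± 500 bp
window around the best candidate and accepts only if identity ≥ 0.95 over
≥ 25 aligned columns. Identity is the fraction of matching columns over
all alignment columns (mismatches and indels both count against it),
computed from the alignment path. Uniqueness is strict: a second
placement tying the best score rejects the read as `multimapped`; the
removal of "poorly mapped" reads is read conservatively. Coordinates are
0-based half-open internally; all emitted tables are 1-based inclusive.
The reported position is the first host base at the junction; on the
minus strand that is the 3' end of the segment's forward-strand match.
Only right-LTR junctions are modeled; left-LTR and paired-end support are
out of scope.

## Quantification and corrections

Accepted reads aggregate into sites per (chrom, position, strand, index
label). Positions within a 5 bp merge window (sequencing/trimming jitter)
collapse to the modal position, ties toward the smaller coordinate.

The two artifact corrections both use a 10:1 dominance ratio, exposed as
configuration: the upstream literature this assay family builds on does
not publish the exact thresholds, so they are explicit package defaults,
not inferred values.

* **Signal crossover** (index hopping): at one genomic coordinate, any
  barcode whose total count is below 0.1 × the dominant barcode's total
  is folded into the dominant barcode. Counts are preserved, only labels
  change.
* **Collisions**: a coordinate present in several animals is kept only in
  the animal whose count dominates every other animal by the same ratio;
  with no dominant animal the coordinate is dropped everywhere, since
  ownership cannot be established.

Afterwards the min-count filter removes sites whose total count is
strictly below the number of samples analyzed for that animal, and
frequencies are `p_i = s_i / S` per sample. Replicates are kept as raw
count columns; averaging happens at the statistic level (diversity,
concordance), not the count level.

## Clonal dynamics

Frequency bands use quartiles of the per-clone maximum frequency with
linear interpolation between order statistics (the common quantile
default). The published rule is strict ("below"/"above"), so values equal
to Q1 or Q3 are medium; with fewer than four clones quartiles are
meaningless and everything is medium (with a warning). Persistence is
frequency > 0 at every tracked timepoint. Top-k selection breaks exact
frequency ties by site-key order so output is deterministic.

Sharing percentages are **row-relative**: percent(i, j) = 100·|V_i ∩
V_j|/|V_i|. The source heatmaps do not state their denominator; this is a
documented convention, with the shared-count matrix (symmetric) alongside.

Replicate concordance reports Pearson's *r* and the single-rater
**absolute-agreement** ICC from the two-way ANOVA decomposition, i.e.
ICC(A,1). The literature label "ICC(3,1) … absolute agreement" mixes two
conventions (ICC(3,1) is normally the consistency form); the
absolute-agreement formula is implemented as stated, with
`form="consistency"` available. Absolute agreement penalizes systematic
shifts between replicates, which is the right property for reproducibility
of abundance profiles.

## Diversity

Rényi entropy uses natural log (the source's log is unannotated; `base`
is a parameter). The default grid is {0, 0.25, 0.5, 1, 2, 4, 8, 16, 32,
64, ∞}; α = 1 uses the Shannon limit and α = ∞ the analytic −ln p_max
rather than numerical limits. Zero-frequency clones are dropped from the
power sum, so at α = 0 only detected clones count toward richness.

The top-clone contribution is exposed as both p_max = exp(−H_∞) and its
reciprocal exp(H_∞): the source figure legend labels the plotted quantity
exp(H(∞)) while the plotted values (0.078 rising to 0.174) behave as
p_max. Both transforms are returned and the ambiguity is deliberately not
resolved.

## Genomic and epigenomic context

The random-IS null rejection-samples uniform genomic positions (chromosomes
weighted by length, strand uniform) until n = 1000 lie within ± 1500 bp of
a `GTAC` occurrence — the recoverability constraint the CviQI/RsaI digest
imposes on the real assay. GTAC is its own reverse complement; asymmetric
motifs are scanned on both strands. A genome without the motif raises
after a bounded attempt budget.

Gene distance is measured to gene-*body* boundaries (0 inside), because
the "± 1 kb of genes" phrasing is body-relative; a TSS-relative mode is a
flag. Calls farther than 1 kb from every gene are `distal`. Exact distance
ties break by biotype priority protein_coding > lncRNA > other, then
gene id. Biotypes collapse onto that three-way split, with `other`
absorbing pseudogenes and remaining classes. Activity is strictly
FPKM > 1; distal sites have no activity call. Peak distance is 0 inside a
peak, else base pairs to the nearest interval edge (a center-distance
mode exists behind a flag); chromosomes without peaks of a feature give
null. Distance histograms bin |d| into 100 bp bins over [0, 1000] (the
published figures do not state the width; 100 bp is a config default),
last bin right-inclusive.

Enrichment vs the null uses Pearson's chi-squared with Yates continuity
correction on the 2×2 near/far table, implemented directly as
N·(max(|ad − bc| − N/2, 0))²/((a+b)(c+d)(a+c)(b+d)) with 1 df; the test
suite checks it against an independent statistical library on random
tables. Coverage matrices support reference-point (± 1 kb around a site,
mean coverage per bin) and scale-regions (gene body rescaled, 2 kb
unscaled flanks) layouts; per-feature mean profiles feed an ordinary PCA
for feature separation.

## Synthetic cohort: what it emulates

The generator's defaults define the canonical study conditions: a 2 Mb
two-chromosome genome with `GTAC` placed as a 1/kb Poisson process
(natural occurrences scrubbed first so the rate is controlled), 150
non-overlapping genes (70/15/15% protein_coding/lncRNA/other, log-normal
FPKM with median e^0.5 ≈ 1.6 so roughly 60% of genes are active), 600 bp
peaks — H3K36me3/H3K79me2 inside active gene bodies, promoter marks at
active TSS, H3K4me1 upstream, H3K27me3 on inactive bodies, plus uniform
background peaks — and coverage tracks elevated 10× inside peaks.

One animal carries 300 clones with log-normal (σ = 1) base abundances
evolving across weeks 13/15/17/19 by a multiplicative log-normal step
(σ = 0.3), so a minority of clones expand — qualitatively reproducing
expansion-driven repopulation without claiming the real dynamics.
Integration sites follow bias weights (50% H3K36me3 peaks, 25% gene
bodies, 5% TSS-proximal, 20% intergenic), all within 1500 bp of a motif,
≥ 50 bp apart, with 12% of clones on the WT barcode and the rest H5.
Each of the 8 blood samples (4 weeks × MDA duplicates) draws ~18,750
reads (~150k total; ~62 reads per clone per sample), each read 31 bp of
anchor+index plus 40 bp of host with 0.2% per-base substitution error and
1% index hopping. A 40-clone second animal sampled at the final week
receives low-count (Poisson mean 3/sample) copies of the 5 most abundant
primary clones as collisions — dominance resolution presumes the true
owner dwarfs the bleed-over, which is exactly the situation real
collisions arise from.

Whole-genome-amplification noise is modeled as negative-binomial
overdispersion of per-sample clone counts (variance μ + φμ²). φ = 0.02
was calibrated once so that duplicate frequency profiles correlate at
r ≈ 0.95, the concordance regime reported for MDA duplicates of 25 µl
blood; it is fully configurable.

**What passing tests do not show about real data**: the genome is random
sequence without repeats, segmental duplications or GC structure, so
multimapping is far rarer than in a real genome; errors are substitutions
only (no indels, no quality-dependent error profile); amplification bias
is clone-independent, whereas real MDA bias correlates with locus
properties; and read counts scale linearly with clone abundance with no
PCR-competition saturation. Recovery and concordance figures on the
synthetic cohort are therefore best-case bounds, not expected field
performance.

## Problem sizes and determinism

The default test suite runs a 200 kb/40-clone cohort (~20k reads,
seconds) for module tests and the full 2 Mb/300-clone cohort once
(session fixture, ~25 s) for the end-to-end suite; the acceptance script
runs the full cohort in ~30 s. All randomness flows from a single integer
seed through `numpy.random.SeedSequence` spawns, so every run is
bit-reproducible; identical seeds give byte-identical genomes, truth
tables and reads.

## Known limitations

* No UMI deduplication or fragment-length abundance model: sequences are
  counted, matching the assay's counting scheme.
* The collision/crossover thresholds are configuration, not estimates;
  datasets with systematically unbalanced depths between animals may need
  a different dominance ratio.
* `aggregate_sites` chains positions by adjacent gaps within the merge
  window; a long chain of closely spaced distinct sites (< 5 bp apart)
  would merge. The simulator keeps true sites ≥ 50 bp apart, and real VIS
  are effectively never that close.
* The left LTR junction, peak calling, GO enrichment and plot rendering
  are out of scope; the package emits the tabular data behind such
  figures.
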