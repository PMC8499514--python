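# lovis

Quantitative, longitudinal clonal tracking of lentiviral **vector
integration sites (VIS)** from LTR-junction sequencing reads.

When hematopoietic stem and progenitor cells are gene-modified with a
lentiviral vector, each transduced clone is permanently marked by the
genomic coordinate where the vector integrated. Sequencing the junction
between the vector's 3' LTR and flanking host DNA — including a 16-nt
**LTR index** barcode (H1/H5/WT) that distinguishes vector populations —
turns a blood sample into a census of repopulating clones. This package
implements the downstream computational workflow for such assays, aimed
at gene-therapy and stem-cell researchers tracking clonal repopulation in
small-animal models:

* **Junction calling** — locate the U5 LTR anchor in each read, classify
  the barcode (unique minimal Hamming distance, ties rejected), and map
  the ≥ 25 bp host segment onto the genome. A read is a true VIS read-out
  only if it aligns with ≥ 95% identity at a unique best placement
  (two-pass: genome-wide search, then local re-alignment).
* **Quantification** — aggregate calls into a VIS × sample count matrix;
  fold **signal crossover** (index hopping) into the dominant barcode at
  each coordinate; resolve cross-animal **collisions** by count dominance;
  drop sites with total count below the number of samples analyzed; and
  compute clone frequencies `p_i = s_i / S`.
* **Clonal dynamics** — quartile frequency bands (low/medium/high by the
  per-clone maximum frequency vs Q1/Q3), **persistent clones** (frequency
  > 0 at every tracked week), top-10 clones per timepoint, sharing
  matrices between timepoints/tissues, and replicate concordance via
  Pearson's *r* and the single-rater absolute-agreement intraclass
  correlation

      ICC = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + (k/n)·(MS_C − MS_E))

  from a two-way ANOVA over n clones × k replicates.
* **Diversity** — Rényi entropy profiles

      H_α = 1/(1−α) · ln Σ p_i^α

  over α ∈ {0, …, 64, ∞}, with H_0 = ln richness, H_1 = Shannon,
  H_2 = ln(1/Simpson), H_∞ = −ln p_max, replicate-averaged per α.
* **Genomic context** — motif-constrained random-IS null (uniform genomic
  positions within ± 1500 bp of a CviQI/RsaI `GTAC` site, mirroring what
  the restriction-digest assay can recover), nearest-gene/biotype
  annotation with FPKM > 1 activity calls, distances to chromatin-feature
  peaks (0 inside a peak), distance histograms, Yates-corrected
  chi-squared enrichment against the null, and coverage matrices (± 1 kb
  reference-point or scaled gene-body) with PCA feature separation.
* **Synthetic data** — a generator producing genome, GTF, FPKM table,
  peak BEDs, bedGraph tracks and junction FASTQs from a clone population
  with known sites and abundances, including sequencing error, index
  hopping, collisions and amplification overdispersion, so the entire
  workflow is testable end to end with known truth.

## Worked example

```python
from lovis import (SimulationConfig, simulate, run_pipeline,
                   diversity_profile, icc_a1, pearson_r)
from lovis.clonal_dynamics import classify_clones

cfg = SimulationConfig(seed=11, genome_length=200_000, n_genes=30,
                       n_clones=40, depth=2500,
                       n_secondary_clones=10, secondary_depth=800)
ref, truth, reads = simulate(cfg)
result = run_pipeline(reads, ref.genome, truth.sample_sheet)

m = result["matrices"]["m1"]
f = result["frequencies"]["m1"].p
wk13 = [c for c in f.columns if "wk13" in c]
print(m.n_sites, "sites;",
      f"r={pearson_r(f[wk13[0]], f[wk13[1]]):.3f}",
      f"ICC={icc_a1(f[wk13].to_numpy()):.3f}")
```

prints

```
animal m1: 40 integration sites x 8 samples
replicate Pearson r = 0.960, ICC(A,1) = 0.952
Renyi H_alpha (mean of replicates):
  alpha= 0.0: 3.689
  alpha= 1.0: 3.203
  alpha= 2.0: 2.860
  alpha= inf: 1.864
{'medium': 20, 'low': 10, 'high': 10} persistent: 40
```

All 40 simulated clones are recovered at their exact coordinates
(H_0 = ln 40 ≈ 3.689); the MDA-replicate concordance (r ≈ 0.96,
ICC ≈ 0.95) sits in the regime expected for duplicate low-volume blood
measurements, and the decreasing profile H_0 > H_1 > H_2 > H_∞ reflects
unequal clone sizes, with the largest clone holding exp(−1.864) ≈ 15% of
the population.

The same workflow is available from the shell:

```bash
lovis simulate --seed 3 -o fixture/
lovis call --fastq fixture/reads/m1_wk13_blood_r1.fastq \
           --ref fixture/reference/genome.fa -o calls.tsv
lovis quantify --calls calls/ --samples fixture/samples.tsv -o quant/
lovis track --freq quant/vis_freq_m1.tsv --samples fixture/samples.tsv -o track/
lovis diversity --counts quant/vis_matrix_m1.tsv -o diversity.tsv
lovis context --vis quant/vis_matrix_m1.tsv --gtf fixture/reference/genes.gtf \
              --fpkm fixture/reference/fpkm.tsv --peaks-dir fixture/reference/peaks \
              --genome fixture/reference/genome.fa -o context/
```

## Layout

```
src/lovis/junction_caller.py   reads -> validated integration sites
src/lovis/vis_quantifier.py    calls -> corrected count matrices, frequencies
src/lovis/clonal_dynamics.py   bands, persistence, sharing, Pearson/ICC
src/lovis/diversity.py         Renyi diversity profiles
src/lovis/genomic_context.py   random-IS null, gene/peak annotation, enrichment
src/lovis/synthetic_data.py    fixture generator with known truth
src/lovis/pipeline.py          end-to-end orchestration
src/lovis/cli.py               `lovis` command-line interface
docs/methods.md                models, parameters, numerical choices
```
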