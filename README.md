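# editpeaks

Inosine peak calling and A-to-I editing analysis for modification-enrichment
RNA sequencing, with per-gene ADAR1-isoform dependency classification.

## The problem

Adenosine-to-inosine (A-to-I) editing by ADAR enzymes is the most abundant
modification of human mRNA; inosine base-pairs like guanosine, so edits
surface in sequencing data as A→G mismatches (T→C in reference-forward
coordinates on minus-strand transcripts). Bead-capture enrichment assays
pull down modification-bearing RNA fragments, encode the modification
identity in a read-embedded barcode (MBC) alongside a UMI, and sequence the
captured fraction next to a non-enriched *solution control* of the same
library. Comparing enrichment to control, with exogenous spike-ins to put
fold enrichment on an absolute scale, locates modification peaks; pileup
analysis inside inosine peaks then pinpoints edited bases. Profiling
wild-type cells against ADAR1 p150 and p150/p110 knockouts tells, gene by
gene, which isoform the editing requires.

`editpeaks` implements that computational pipeline end to end for anyone
analyzing this class of data or studying its statistical behavior:

- **simdata** — seeded synthetic genomes, gene models, spike-ins and paired
  enrichment/control read sets with planted peaks, editing rates and
  dependency categories, so every stage has ground truth;
- **readproc** — MBC/UMI extraction, quality/length filtering (inserts
  < 30 nt are dropped), duplicate collapse per modification class on the
  (UMI, contig, strand, 5′ start) key;
- **peaks** — per (contig, strand, modification class), the smoothed
  log2 ratio of enrichment over size-scaled control is segmented into
  peaks (`scipy.signal.find_peaks`); fold enrichment is summit-based and
  divided by the spike-in enrichment factor
  (Σmodified recovery ÷ Σunmodified recovery); confidence is a PHRED
  q-score, −10·log₁₀(1 − mean enriched-state posterior) from a two-state
  Gaussian HMM on the binned signal; high-confidence peaks need q ≥ 13 and
  ≥ 5 reads of enrichment depth;
- **sites** — strand-aware pileup calling of A→G / T→C sites restricted to
  inosine peaks, with depth > 5 and variant rate ≥ 10%, written as VCF;
- **annotate** — interval-tree assignment of peaks to genes and feature
  classes (exon / intron / 5′UTR / 3′UTR / lncRNA) from a GTF;
- **dependency** — per-gene scores (max spike-scaled fold, replicate means
  per condition), the dependency ratio WT/(p150KO+1) with categories
  strong (≥ 4), mild (1–4), independent (< 1), p150KO-specific
  (WT = 0, p150KO > 1) and double-KO-specific, knockout reduction
  percentages, and Ward clustering of z-scored gene profiles.

## Worked example

`examples/` contains one short script per capability. The full
multi-condition analysis (`examples/05_dependency_analysis.py`) simulates
nine genes — three per planted category — across WT, p150 KO and
p150/p110 KO with two replicates each, and prints:

```
inosine peak counts per condition: {'WT': [9, 9], 'p150KO': [6, 6], 'p150_p110KO': [0, 0]}
percent reduction vs WT: {'p150KO': 33.3, 'p150_p110KO': 100.0}

per-gene dependency calls (ratio = WT / (p150KO + 1)):
gene_id    wt  p150ko  dko  ratio    category
   g000  6.85    0.00  0.0   6.85      strong
   g001  6.26    3.63  0.0   1.35        mild
   g002  6.81    8.26  0.0   0.74 independent
   ...
planted categories recovered: 9/9
```

All nine peaks are found in each WT replicate; the three "strong" genes
lose their peaks in the p150 KO (ratio ≥ 4), the "mild" genes keep reduced
signal (ratio between 1 and 4), the "independent" genes are unchanged
(ratio < 1), and the double knockout abolishes every peak — the 33.3% and
100% reductions follow directly from the 3-of-9 and 9-of-9 peak losses.

A thin CLI wraps the same functions for shell use:

```bash
editpeaks simulate --seed 1 --outdir sim/
editpeaks run --seed 1 --outdir results/ --n-clusters 3
editpeaks callpeaks --enrich E.tsv --control C.tsv --spikes S.tsv --genome g.fa --out peaks.bed
```

## Scope

The pipeline consumes mapped reads (a documented TSV alignment table, or
SAM via `editpeaks.io.reads_from_sam`); alignment itself, motif discovery,
GO enrichment and differential-expression testing are upstream/downstream
of this package. See `docs/methods.md` for the model, parameter defaults
and known limitations.
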