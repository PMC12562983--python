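# Methods

## Signal model and peak calling

Peak calling treats the enrichment library as signal and the non-enriched
solution control as background, separately per (contig, strand,
modification class). With enrichment depth E(p), control depth C(p),
pseudocount c₀ and library-size factor s, the working signal is

    y(p) = log2( (E(p) + c₀) / (s·C(p) + c₀) )

smoothed by a centered moving average of width w. The library-size factor
is the ratio of total deduplicated enrichment to control reads of the
sample — computed over the whole library rather than per track, so sparse
tracks are not self-normalized against their own planted signal. A zero
control depth is handled by the pseudocount, never by excluding positions.

Candidate summits are local maxima of the smoothed signal found with
`scipy.signal.find_peaks`, required both to have topographic prominence
≥ `min_prominence` **and to reach** `min_prominence` in absolute value.
The second requirement is deliberate: on a mean-zero log-ratio, noise
valleys dip below zero, so bumps of height ~0.2 can acquire prominence 1
purely from the depth of neighboring dips; enrichment is a positive
excursion and must stand at least `min_prominence` above zero itself.
Boundaries descend from each summit until the signal falls below
(summit − prominence/2) or below zero, with the descent prominence capped
at the summit value — i.e. classic half-maximum boundaries floored at
zero. Overlapping candidates are merged; candidates narrower than
`min_width` are dropped. Fold enrichment is summit-based
(2^max smoothed signal) and afterwards divided by the spike-in enrichment
factor, the ratio-of-ratios

    (Σ enriched_modified / Σ control_modified) /
    (Σ enriched_unmodified / Σ control_unmodified).

Spike scaling applies to fold values only, never to coordinates.
Coordinates are 0-based half-open internally, BED on disk.

### Confidence scores

The upstream assay's published scorer is a proprietary HMM +
random-forest ensemble whose features and training data are unavailable;
this package replaces it with the reproducible HMM half of that contract.
A two-state (background/enriched) Gaussian HMM is fit on the w-binned
smoothed signal with deterministic initialization (low/high split of the
sorted bins, transition prior 0.95/0.05, ≤ 100 EM iterations, tolerance
1e−6), so scoring needs no random seed. A peak's q-score is

    q = −10·log10( max(1e−10, 1 − mean posterior of the enriched state) )

capped at 100, averaged over the bins whose centers lie inside the peak
(edge bins mostly outside the interval would otherwise dilute the
posterior). If the fitted enriched-state mean is below `min_prominence`,
the two states merely partition background noise — there is no credible
enriched regime — and the whole track is scored peak-free; without this
guard, signal-free tracks (e.g. a double knockout) hand q = 100 to
upper-tail noise bins. High confidence means q ≥ 13 (posterior ≈ 0.95, a
documented choice — no published cutoff exists) plus the assay's minimum
enrichment depth of 5 reads.

### Defaults

| parameter | default | meaning |
|---|---|---|
| smoothing window w | 25 nt | moving-average width and HMM bin size |
| pseudocount c₀ | 1 read | stabilizes the ratio at low depth |
| min prominence | 1 (log2) | 2-fold minimum excursion |
| min width | 30 nt | narrowest reportable peak |
| q_min / depth_min | 13 / 5 | high-confidence filter |

At control depth 20 the summit-based fold has ±8% per-peak scatter: the
maximum of a smoothed noisy plateau is biased up by roughly the same
amount as the pseudocount shrinks the ratio down, so fold estimates are
nearly unbiased on average but individual peaks can deviate by ~20%.

## Editing-site calling

Sites are called from plain per-column pileups of the deduplicated
enrichment library over inosine peak intervals, capped at 20 000 reads
per column (truncation in (start, read_id) order). A site is reported iff
(a) it lies inside a high-confidence inosine peak (start inclusive, end
exclusive); (b) the mismatch matches the peak's strand context — A→G for
'+', T→C in reference-forward coordinates for '−'; (c) column depth is
strictly greater than 5; (d) the variant rate, alt reads over total
column depth with both read strands counted jointly, is at least 10%.
Only the A→G/T→C component of a multi-allelic column is evaluated. No
base-quality recalibration or alignment-quality adjustment is applied —
those belong to the external caller this contract mirrors — and no
germline-variant database subtraction is performed; the peak-overlap
requirement is the specificity mechanism.

## Annotation

`gffutils` parses the GTF; intervals go into per-(contig, strand)
interval trees. Introns are the exact gaps between consecutive exons of a
transcript (overlapping exons are a hard error); UTRs are exon minus the
transcript's CDS span, oriented by strand, and take precedence over the
generic exon class on the stretches they cover; every exonic interval of
a gene with biotype `lncRNA` is classed `lncRNA`. A peak annotates to all
(gene, class) pairs overlapping it by ≥ 1 base on the same strand — no
fractional-overlap threshold, and the union over isoforms is reported
when transcripts disagree. Regional distributions count distinct genes
per class, so a gene edited in several regions contributes to each.

## Dependency classification

A gene's score in a sample is the **maximum** spike-scaled fold over its
peaks (robust to peak fragmentation; configurable); condition scores are
arithmetic means over replicates (the source material does not state how
replicates combine, so the mean is a documented choice). With ratio
r = WT/(p150KO+1), evaluated in order:

1. WT = 0, p150KO = 0, dKO > 1 → `dko_specific`
2. WT = 0, p150KO > 1 → `p150KO_specific`
3. r ≥ 4 → `strong`
4. 1 < r < 4 → `mild`
5. r < 1 → `independent`
6. otherwise → `unclassified` (the stated partition excludes r = 1
   exactly, so it is surfaced rather than silently binned)

Knockout reductions pair replicates by position (clone #i against WT
clone #i) and average the per-pair reductions — this is the arithmetic
that reproduces the published 73.4%/99.9% figures from the replicate peak
counts, where a ratio of condition means gives 73.3% — falling back to
the ratio of means when replicate counts differ. Clustering z-scores each
gene across condition means (zero-variance rows get z = 0) and applies
Ward-linkage agglomerative clustering with Euclidean affinity
(`sklearn.cluster.AgglomerativeClustering`).

## Synthetic data

The generator emulates the assay's study design: a random genome with
non-overlapping single-transcript gene models (exons 200–600 nt, introns
300–800 nt, UTRs carved from terminal exons, ~20% lncRNA), inosine peaks
of 150–300 nt planted inside genes with fold enrichment 8–12, per-site
editing rates ~ Beta(2, 5), flat Poisson background (default 20
reads/base per strand and class), and four synthetic spike-ins (modified
recovery 2×). Reads are fixed-length (100 nt) single-end fragments with a
modification-class label and a random 8-nt UMI; all randomness flows from
the config seed through fixed-offset substreams, so identical configs are
byte-identical. Conditions follow a WT / p150KO / p150-p110KO design in
which each peak-bearing gene belongs to a category scaling both its peak
intensity and its editing per condition (strong 1/0/0, mild 1/0.4/0,
independent 1/1/0 by default); m6A peaks, when planted, are constant
across conditions. Editing is applied to both the enrichment and the
solution-control library, since both derive from the same edited RNA.

Planted sites per peak default to 21–42 transcript-strand adenosines.
This was calibrated once so the **called** median editing density inside
peaks lands in the 7–8 sites per 100 nt range reported for
lymphoblastoid cells: called peak widths include ~130 nt of
fragment-length smear beyond the planted interval, and sites edited below
the 10% reporting floor are lost, so the called density is roughly half
the planted one.

What the generator does *not* model — and hence what passing tests do not
establish about real data: sequencing errors beyond an optional uniform
substitution rate (default 0), indels, paired-end structure, non-uniform
fragmentation or coverage along transcripts, Alu/repeat sequence context,
expression differences between genes, germline SNPs masquerading as
edits, or interferon-driven expression changes in the knockouts. Null
coverage tracks drawn base-by-base from Poisson lack the read-length
autocorrelation of real coverage; read-level simulations carry that
autocorrelation and are used wherever it matters.

## Problem sizes and numerics

Tests and the acceptance script use compact designs — genomes of
15–50 kb, 3–10 genes, background depth 20–100, two replicates — chosen so
planted effects are measurable with comfortable statistical margins while
whole-suite runs stay in the tens of seconds. Recovery claims verified on
simulated data: ≥ 95% of planted peaks (fold ≥ 8, depth ≥ 20,
width ≥ 100) recovered at Jaccard ≥ 0.5 across 20 seeds with ≤ 1 false
peak per 100 kb of null track; editing-rate MAE < 0.02 at ~1000× depth;
≥ 90% of planted dependency categories recovered across 10 seeds at
fold ≥ 8, depth 30. Degenerate inputs are defined, not special-cased:
empty read sets yield empty outputs, constant tracks yield no peaks and
q = 0 posteriors, zero-variance gene rows get z = 0, and ties in
deduplication and clustering break deterministically (lexicographic
read_id, lower gene index).

## Known limitations

- The HMM q-score reproduces the published scorer's contract, not its
  output byte-for-byte; the random-forest half of the original ensemble
  is unobservable and omitted.
- Summit-based fold estimates carry upward max-of-noise bias at low
  control depth (see above); mean-based folds would trade bias for
  sensitivity to boundary placement.
- UMI collapse is exact-match only; no 1-mismatch merging, so UMI
  sequencing errors slightly inflate unique-read counts.
- The spike-in set is synthetic: the commercial assay's spike sequences
  and composition are proprietary, so only the count-level contract
  (recovery ratio-of-ratios) is modeled.
- SAM input supports peak calling but not site calling (mismatch bases
  are not reconstructed from alignments); the TSV alignment table is the
  full-fidelity interchange format.
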