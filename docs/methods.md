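# Methods

## Scope and data model

The package operates downstream of read alignment, peak calling and
differential-expression testing: its inputs are per-replicate peak
calls (narrowPeak), open-chromatin intervals (BED), gene models
(GTF-lite or TSV), TADs (BED), per-base conservation scores (bedGraph),
genome sequence (FASTA), motif count matrices, and per-contrast DE
tables carrying a linear fold change, a raw p-value and per-sample
expression. All coordinates are held internally as 0-based half-open
intervals; 1-based GTF input is converted on read. Chromosome names
are matched by exact string equality (no `chr` aliasing), which keeps
every set operation deterministic.

## Replicate peak confirmation

Published replicate-combination tools implement a multi-stage decision
procedure (per-replicate confirmation counts, technical vs biological
modes, a multiple-testing stage). This package implements the core of
that procedure as documented by its thresholds: a candidate peak with
p ≤ *w* (weak threshold) is confirmed when candidates from at least
`min_supporting_replicates` other replicates overlap it by ≥ 1 bp and
Fisher's combined probability over the overlapping group is ≤ *s*
(stringent threshold). Fisher's statistic is X = −2 Σ ln pᵢ with
upper-tail χ² on 2k degrees of freedom (computed via
`scipy.stats.combine_pvalues`). Defaults are *s* = 1e−5, *w* = 1e−2 for
ChIP-style input and one supporting replicate ("biological" mode with
a single required confirmation); ATAC-style confirmation uses
*s* = 1e−10, *w* = 1e−6 through the same configuration object.

Confirmed candidates that overlap across replicates merge by
transitive closure of pairwise overlap: the merged peak spans the union
interval, carries the minimum p-value among members and the summit of
the minimum-p member (ties broken toward the smaller start
coordinate), and records the number of distinct contributing
replicates. Merging by transitive closure makes the result invariant
to replicate order, which is asserted by test.

## Peak annotation

The anchor for TSS distance is the peak summit (the single-base point
of maximal enrichment), configurable to the interval midpoint for
parity with annotators that use peak centers. Signed distance is
`summit − TSS` in genome orientation; gene strand affects only where
the TSS is (start on +, end−1 on −). Categories partition the peak
set: promoter when |distance| ≤ 2.5 kb, else intragenic when the peak
interval overlaps any gene body, else intergenic. The absolute-distance
histogram uses bins [0, 5 kb), [5, 50 kb), [50, 100 kb), [100 kb, ∞);
only the first and last bin boundaries are externally meaningful (the
promoter-proximal and TSS-distal fractions), and the edges are
configurable. Conservation profiles average the score track over the
2 × 150 bp window centered on summits, per offset, skipping missing
(NaN) bases and out-of-bounds positions.

## Motif scanning with exact p-values

A PWM is a count matrix; the score of base *j* at position *i* is
log2(((countᵢⱼ + ε) / (rowtotalᵢ + 4ε)) / bgⱼ) with pseudocount
ε = 0.1 and a 0-order background (uniform by default). Site p-values
are made exact by quantisation: per-position scores are shifted to
non-negative integers on a grid dividing the motif's total score range
into 10,000 bins; the null distribution of the window score under the
background is the convolution of per-position distributions, and the
p-value is the inclusive upper-tail mass. Scanning uses the same
quantised scores, so the reported p-value is exactly the null tail
probability of the observed (quantised) score — the construction used
by FIMO. This guarantees p monotone non-increasing in score and p = 1
at the minimum achievable score; agreement with exhaustive k-mer
enumeration is exact up to floating-point summation (tested at
k ≤ 8 to 1e−6). Both strands are scanned (the reverse strand by
scanning the reverse-complemented sequence); windows containing
non-ACGT symbols are skipped. A best-site p above the 1e−4 threshold
is reported as no hit, and the region × motif matrix stores
−log10(p) with 0 for no hit, so every positive entry is ≥ 4.

Row clustering is agglomerative complete linkage on Euclidean
distances, implemented in-package so that ties in the minimum linkage
distance break deterministically toward the smallest cluster-index
pair; scipy's `linkage` serves as an independent oracle in the tests.
Column clustering, when wanted, is the same operation on the
transpose.

## DEG filtering

The differential statistic itself is an upstream input. The package
applies, in order: the expression floor (≥ 1 fragment-per-million in
≥ 3 samples, counted jointly across all samples of both genotypes),
exclusion of chromosomes X, Y and M, Benjamini–Hochberg correction
computed on the filtered universe only (via
`statsmodels.stats.multitest`), and the direction call — up when
q ≤ 0.1 and linear fold change ≥ 1.2, down when q ≤ 0.1 and fold
change ≤ 1/1.2, otherwise unchanged. The symmetric reading of the
fold-change floor follows from the analysis reporting both up- and
downregulated genes under a single threshold.

## Target integration and TAD statistics

Confirmed peaks overlapping ≥ 1 bp of open chromatin are assigned to
the nearest DEG TSS by absolute summit–TSS distance, with a 1 Mb
bound (the average TAD size); assignment is to DEGs only, not to the
nearest gene overall, because the scientific question is which
expression change each binding event explains. A peak maps to at most
one gene; ties break toward the smallest gene identifier. Per-TAD
density is the count of peak summits in the TAD divided by the count
of gene TSSs in it; every gene inherits its TAD's density, and genes
outside all TADs are excluded and reported. Class comparisons
(up vs unchanged, down vs unchanged, up vs down) use the two-sided
Mann–Whitney test: the exact null distribution of U (computed by the
Gaussian-binomial recurrence, verified against full enumeration) when
the pooled sample is ≤ 25 and tie-free, with two-sided p as twice the
smaller tail capped at 1; otherwise the tie- and continuity-corrected
normal approximation (scipy). Scanning all U for the 9-vs-10 design
shows that exactly one exact two-sided p (U = 16, mirrored at 74)
rounds to 0.017212 at six decimals, so published values at that
precision derive from the exact convention implemented here.

## Pathway crosstalk

Shared DEGs are the gene-wise intersection of two direction-labelled
DEG sets (genes unchanged in either contrast are excluded).
Concordance compares direction labels, not fold-change magnitudes.
Each shared gene produces two edges — one per pathway — signed by the
loss-of-function logic: a pathway activates genes that drop when it is
removed, and inhibits genes that rise. Spatial-bias categories
(anterior, posterior, proximal, distal, core, AER) are a curated input
table; genes absent from it are labelled unannotated. The module is
pathway-agnostic: labels are free strings.

## Synthetic data generator

The generator emulates the study design, not sequencing: a small
multi-chromosome genome with non-overlapping genes, TADs tiling each
chromosome at 1 Mb, and per stage:

- **True peaks.** Each of `n_true_targets` genes receives 1–3 enhancer
  peaks present in every replicate with −log10 p ~ U(6, 12) (well past
  the stringent threshold after Fisher combination), summit jitter of
  ±25 bp between replicates, widths 200–400 bp. Summits are
  rejection-sampled so the realised nearest-TSS distance falls in a
  drawn bin — within 5 kb with probability 0.40, beyond 100 kb with
  probability 0.20, in between otherwise, echoing the observed
  cistrome geometry — and so the nearest planted DEG is the peak's own
  target gene (which makes the planted target set recoverable by the
  nearest-DEG rule, i.e. recovery failures indicate pipeline defects,
  not generator ambiguity). When a gene's neighbourhood leaves no
  position in the intended bin, the intent degrades distal → mid →
  promoter and the deficit is repaid by promoting a later mid intent,
  keeping realised fractions centred on the planted ones; realised
  bins are recorded in the truth manifest.
- **Noise peaks.** Replicate-private, uniformly placed, −log10 p ~
  U(2.5, 5); they fail confirmation for lack of cross-replicate
  overlap except for rare coincidences.
- **Open chromatin.** Each true peak's interval extended by 200 bp,
  plus uniform decoy open regions.
- **Conservation.** A constant baseline (0.08) with a triangular bump
  to 0.60 of half-width 75 bp at each true summit.
- **Sequence and motifs.** Uniform-background genome sequence; three
  sharp 8-mer PWMs (dominant count 85 vs 5); the consensus (or its
  reverse complement) is planted at 80 % of true summits.
- **DE tables.** Planted genes draw |log2 FC| ~ N(1.0, 0.3) with
  random sign and raw p log-uniform on [1e−8, 1e−3] (a sharply
  right-skewed small-p model standing in for the out-of-scope count
  test); nulls draw log2 FC ~ N(0, 0.1) and p ~ U(0, 1]. Two contrasts
  share 20 planted genes with exactly round(0.30 × 20) sign-concordant
  — the concordance fraction observed between the two pathways the
  design mirrors. Expression columns (3 + 4 samples, as in the
  profiled genotypes) place planted genes above the
  fragments-per-million floor and 10 % of null genes below it.
- Planted DEG TSSs are kept ≥ 10 kb apart so promoter-proximal peaks
  are always nearest their own gene.

Randomness flows from one seed through `numpy.random.SeedSequence`
spawning per-stage streams, so identical configurations produce
byte-identical emitted files (asserted by test). A `truth.json`
manifest (planted targets, peaks with realised distance bins, motif
sites, DEG signs, concordant genes, low-expressed genes) accompanies
every dataset.

What the generator does **not** model: read-level noise, fragment-size
effects, GC or mappability bias, realistic nucleotide composition,
correlated replicate structure beyond summit jitter, TAD-boundary
biology (TADs tile exactly), or the count-based DE statistic. Passing
recovery tests therefore demonstrates the correctness of the
integration logic under the stated statistical structure, not
performance on real sequencing data.

## Problem sizes and numerical choices

Default desk-scale conditions: 3 chromosomes × 8 Mb, 90 genes, 30
target genes, 2 replicates, 150 noise peaks per replicate, 60 planted
DEGs per contrast. The TSS-distance geometry check uses 5 × 50 Mb,
500 genes/targets (~1000 confirmed peaks) with a 12 kb minimum gene
gap so distal placements are geometrically feasible; its tolerance is
four binomial standard errors, since peaks cluster 1–3 per gene and
the effective sample is smaller than the peak count. The TAD density
comparison uses 400 genes with ~100 genes per DEG class. Recovery is
scored over 20 seeds: ≥ 90 % of planted targets recovered with ≤ 5 %
false calls. The full default pipeline runs in a few seconds; the
acceptance script in well under a minute.

Numerical details: narrowPeak −log10 p is serialized at 6 significant
digits, so p-values round-trip to ~1e−4 relative precision; a summit
offset of −1 falls back to the interval midpoint; BH q-values are
capped at 1; Mann–Whitney U is computed from midrank sums;
`nearest_point` breaks distance ties by lexicographically smallest
label; degenerate inputs (empty samples, < 2 replicates, < 2 cluster
rows, overlapping TADs, p-values outside (0, 1]) raise typed
validation errors naming the offending input.

## Known limitations

- The replicate-confirmation procedure is the documented-threshold
  core, not a re-implementation of any specific tool's full decision
  tree; confirmed peak counts can differ from such tools at the
  margin.
- Nearest-DEG assignment is point-based (summit to TSS); no
  enhancer–promoter contact model beyond the 1 Mb bound and the static
  TAD file.
- Motif p-values are exact for the quantised score matrix; extremely
  long motifs with extreme score ranges would need a finer grid.
- The distance-histogram bin edges between 5 kb and 100 kb are
  conventional, not externally constrained.
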