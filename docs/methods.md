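# Methods

This note documents the models and procedures znfpipe implements, the
parameters that matter, what the simulator does and does not emulate, and the
numerical choices made where the design was genuinely open.

## Coordinates and containers

All coordinates are 0-based half-open (BED-native) everywhere in memory and
on disk; 1-based coordinates appear only in log text. Peak sets are disjoint
per chromosome, sorted by (chrom, start), and carry ranks 1..N assigned by
descending height with ties broken by coordinate. Tag libraries store read 5′
positions with strand; gene models store exons in genomic order, with
transcription order derived from strand (the final exon of a `-` gene is the
genomically first).

## Tiling-array caller

Smoothing averages each probe with up to five probes on either side **in
probe-index space**, never crossing a chromosome; at array ends the window
simply holds fewer probes. Index-space windows mean a missing probe widens
the bp footprint of the window instead of shrinking the sample count, which
is the intended behavior on repetitive regions where probes are absent.

The height cutoff at level q is the smallest value v such that exactly
⌈qN⌉ probes satisfy value ≥ v (ties can enlarge the above-threshold set;
"above threshold" always means ≥ v). Levels in routine use: 0.05 for
spreading histone marks, 0.01 for site-specific factors, 0.005 for sparse
factors.

Peak construction walks each chromosome's probes: a run accumulates
consecutive above-threshold probes; an absent grid position (a multiple of
the 100 bp tile interval with no probe) may be bridged as long as the run's
total missing count stays ≤ 6; a *present* probe below threshold always
terminates the run — only absence is forgiven, not weak signal. Two open
readings were settled as follows: the missing-oligo budget counts **total**
missing positions per region (not consecutive), and the span is measured
from the first probe start to the last probe **end**. A run is emitted when
span ≥ 800 bp and the probe count is at least half of
⌊span/tile⌋ + 1 expected positions. Peak height is the maximum smoothed
value in the run. On gap-free tracks the procedure is provably identical to
brute-force maximal-run enumeration, and the test suite asserts exactly that.

## Broad ChIP-seq caller

Each tag is extended to the library fragment length (default 150 bp)
3′-ward from its 5′ start; per-bp fragment coverage is averaged into 30 bp
bins anchored at multiples of 30 from coordinate 0, and each bin is smoothed
as the mean of the raw bins whose start lies within ±600 bp. Smoothing
fragment *coverage* (rather than raw tag counts) is the package's choice; the
fragment length is configurable.

Input normalization is global depth scaling, s = depth(ChIP)/depth(input).
A CNV-aware correction of the input (detecting duplicated and deleted
segments first) would be more faithful for aneuploid cell lines but is a
deliberate simplification here — the simulator plants no CNVs, and the
scaling enters only through the FDR estimator.

The height cutoff h\* is the **lowest** observed ChIP bin value h with

    FDR(h) = s · #{input bins ≥ h} / #{ChIP bins ≥ h} ≤ 0.01,

found by an exhaustive scan over the observed values (which guarantees the
"lowest value" semantics; the suite checks it against an independent scan).
When no value qualifies — e.g. ChIP and input are statistically identical —
the caller reports no signal and emits zero peaks. Peaks are maximal runs of
bins ≥ h\* of length ≥ 150 bp (five bins), approximating the minimal
chromatin fragment size. A per-peak significance-over-background test is
intentionally absent: for broad domains the FDR height cutoff already
controls background, and small input fluctuations would only fragment real
domains.

Null calibration (measured, not assumed): with ChIP and input drawn iid
uniform at 100k tags over 5 Mb, on average well under 0.1% of the genome is
called. Recovery: 50 planted 2 kb domains at 5-fold enrichment with
500k/500k tags are recovered with recall and precision ≈ 1 at per-domain
Jaccard ≥ 0.5. Note that planted domains closer together than the ±600 bp
smoothing footprint merge into one called region; this is correct behavior
for spreading marks, and the truth-scoring of the default gene-cluster
simulation reflects it.

## Replicate QC and qPCR

Both ranked peak lists are truncated to the length of the shorter; the top
⌈0.4·n⌉ peaks of one list are intersected (≥ 1 bp) with the other truncated
list, in both directions. Overlap = any positive intersection, and ceiling
rounding for the top-fraction count, are the package's choices. qPCR fold
enrichment is 2^(cT_input − cT_ChIP).

## Peak-set operations

Overlap counting uses a per-chromosome sweep (sorted starts + prefix-max of
ends); the tests pin it against all-pairs brute force. Peak centers are
floor midpoints; distance profiles are signed query−subject center
differences, nearest by absolute distance with ties resolved toward the
smaller subject coordinate; query peaks on subject-free chromosomes are
reported as missing (NaN). Top-fraction selection takes the ⌈f·N⌉ highest
peaks with coordinate-order tie-breaks, so boundary ties are deterministic.

## Location analysis

Pass 1 assigns every peak overlapping a gene body ([tx start, tx end)) to
the gene with the greatest overlap (ties: smaller gene start, then gene id —
the tie rule is a package choice). Pass 2 assigns the remainder to the
same-chromosome gene with the nearest strand-aware TSS, measured from the
peak center. Context is classified against the assigned gene's exons with
priority final exon → internal exon → intron; for nearest-TSS assignments
the peak is upstream or downstream of the TSS in the gene's orientation.
Finger-count histograms count each C2H2 gene once (bound iff it has ≥ 1
assignment); expression quintiles are cut at the 20/40/60/80th percentiles
of the full expression table, with boundary values falling into the lower
quintile.

## Motif pipeline

Foreground sequences are the 100 nt windows centered on peak midpoints
(windows that would cross a contig edge are skipped with a warning). The
background is the set of final-exon sequences of C2H2 genes whose body
intersects no peak — the construction that cancels the finger/linker coding
signal shared by all ZNF 3′ exons.

Discovery is a k-mer-seeded iteration (k = 6..12): every k-mer is counted on
both strands in foreground and background; enrichment is a one-sided binomial
test of the foreground count against the background per-window rate,
Bonferroni-corrected over 4^k, with acceptance at adjusted p ≤ 1e-6. Two
numerical guards stabilize the rate estimate: a +0.5 pseudocount, and a
floor at the background base-composition rate of the k-mer — with ~10^5
background windows, the raw ratio estimate of a rare k-mer can be driven to
zero by sampling noise alone, fabricating enrichment where none exists. The
winning k-mer's foreground occurrences (±3 bp flanks, strand-aligned,
non-ACGT symbols excluded from counts) become a count matrix with
pseudocount 0.25 per cell; the occurrences are masked and the search
repeats, up to 30 rounds. Matrices whose best ungapped alignment (either
orientation) reaches mean per-column Pearson correlation ≥ 0.8 are merged
over the union of their columns; among qualifying alignments the **longest**
overlap wins, since a short chance overlap must not preempt the true
extended alignment of two fragments of one motif. This merging is what
reassembles a long motif from the fragments left by masking.

Scores follow the matrix-library convention: the summed log-probability of a
window, min–max normalized by the worst/best attainable window, over all
columns (PWM score) and over the 5 consecutive columns of maximal
information content (core score). Stringency cutoffs are fitted per motif:
foreground sequences whose best hit outscores every background sequence's
best hit are taken as motif-positive (the background set acting as the
negative control it was built to be), and the cutoff pair is the
bootstrap-averaged value calibrated so that 95% of positives pass **both**
cutoffs jointly — marginal 5th percentiles on the two scores would jointly
reject ~9% of true sites. The reported occurrence count is the number of
foreground sequences with ≥ 1 hit at the fitted stringency. Scanning allows
overlapping hits on both strands; hit counts are monotone non-increasing in
both cutoffs by construction.

Reverse-orientation merging slides the reverse-complement of one consensus
against the other over all ungapped offsets with overlap ≥ 4; the
largest-overlap offset with ≥ 90% column identity yields the union-span
consensus (length L_B + L_A − overlap for end-to-end arrangements). This is
the operation that reconstructs the 29 bp linker/H2-helix coding motif from
two shorter motifs discovered independently.

## Synthetic data

The simulator emulates the structure of a ZNF-cluster chromosome at desk
scale. Defaults: one 5 Mb chromosome; 120 genes in clusters of 10 (2 kb
intragenic, 20 kb intercluster spacing); 60% C2H2, of which half are
"bound"; finger counts uniform on 6..18; each gene has three 150 bp exons
and a final exon of finger_count tandem 84 bp finger/linker units (28
codons). Bound genes embed a fixed canonical 29mer in each unit, mutated per
position at rate 0.10 per copy; unbound C2H2 genes carry a fixed divergent
linker ≥ 8 mismatches away. Broad domains (2 kb, 5-fold) cover each bound
final exon with a sharp site (200 bp, 8-fold) at the domain center —
the co-localized geometry the analyses are designed to detect.

Arrays: probes every 100 bp (50 bp long), value = log2(fold) inside domains
plus Gaussian noise (σ = 0.25), each probe dropped independently with
probability 0.05. Tags: fragment centers are drawn from a
piecewise-constant intensity (uniform for input; multiplied by the planted
folds for ChIP); each fragment is read from a random end, so `+` tags fall
upstream and `-` tags downstream of site centers; exactly n tags are
emitted (multinomial over bp). Replicates are independent draws from one
intensity with spawned sub-seeds. Everything derives from one master seed
through named, hashed sub-streams, so all outputs are bit-reproducible.

The motif fixture plants copies at least 5 bp inside the 100 nt windows:
peak-sequence extraction is midpoint-centered precisely because sites are
interior to peaks, and an edge-clipped copy could never align a full-length
matrix.

What the simulator does **not** emulate: mappability holes and repeat
structure beyond missing probes, CNVs in the input, realistic read sequences
or qualities, fragment-length variation, inter-array normalization effects,
and correlated probe noise. Passing tests therefore demonstrate the
correctness and calibration of the algorithms under their stated models, not
performance on real libraries with those artifacts.

## Problem sizes

The test suite and the acceptance script use 5 Mb chromosomes with 100k–500k
tags, 200 random array tracks, 1000-peak interval sets, and 337-sequence
motif fixtures across 5–20 seeds per property — sizes chosen so the full
suite runs in a couple of minutes on one CPU while keeping every estimator
(FDR scan, binomial enrichment, bootstrap cutoffs) in its asymptotic regime.

## Known limitations

- The empirical FDR uses a global depth scale; locally elevated input
  (CNVs, blacklisted regions) is not modeled or corrected.
- The percentile cutoff's "above threshold" set can exceed ⌈qN⌉ under ties.
- Greedy run-building in the tiling caller is exact for gap-free tracks and
  conservative otherwise (a run is closed when the next bridge would exceed
  the missing budget); alternative segmentations of heavily gapped runs are
  not explored.
- Motif discovery assumes ungapped motifs and a fixed ±3 flank; gapped or
  variable-spacing motifs are out of scope.
- Nearest-TSS assignment is restricted to the peak's chromosome; peaks on
  chromosomes with no annotated gene are reported unassigned with a warning.
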