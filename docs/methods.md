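# Methods

`pyronome` re-implements, as a tested and reusable pipeline, a set of
analyses that in genome-project practice usually live in one-off scripts:
k-mer genome-size estimation, RIP-index genome scanning, splice-junction
based detection of natural antisense transcripts (NATs), a ratio-based
("classical") differential-expression classification with consensus
calling against an external Bayesian analysis, expression-level mixture
decomposition, and reciprocal-best-hit orthology with microsynteny
counting. Every stage is paired with a seeded synthetic-data generator so
the whole pipeline can be exercised against known ground truth without any
sequencing data. This note records the models, the defaults and why they
were chosen, the numerical choices, and what the synthetic benchmarks do
and do not demonstrate.

## Coordinates and alphabets

All internal coordinates are 0-based half-open. GFF3 (1-based inclusive)
is converted at the I/O boundary and converted back on write; the round
trip is exact and tested. DNA is normalised to {A,C,G,T,N}: U maps to T
and all other IUPAC ambiguity codes collapse to N (with a logged warning)
rather than erroring, because public assemblies contain them and every
downstream counter simply skips N. Genes with strand "." are excluded from
strand-dependent analyses rather than guessed.

## k-mer genome-size estimation

Reads are decomposed into canonical k-mers (lexicographic minimum of the
k-mer and its reverse complement; shotgun reads sample both strands, so
non-canonical counting would halve the apparent depth). K-mers containing
N are skipped. The occurrence histogram h(f) = number of distinct k-mers
seen exactly f times has, for a haploid genome sequenced to depth c with
reads of length R, a single main peak near λ = c·(R−k+1)/R, plus a
low-frequency error component: a k-mer hit by a sequencing error is almost
always unique. Frequencies below `error_cutoff` (default 10, the error
region of the histogram) are excluded, and

    genome size = Σ_{f ≥ cutoff} f·h(f) / (main-peak depth).

`find_main_peak` reports the occurrence-weighted mode (argmax of f·h(f),
ties to the smaller f), which is robust to long flat tails. For the size
estimate the peak depth is refined to the h-weighted centroid of
frequencies within ±25% of that mode: the integer mode alone quantises the
estimate in steps of 1/λ (≈3% at λ = 35), and when λ sits between two
integers the mode is a coin flip between them; the centroid of the
(near-symmetric) peak removes that granularity. For a histogram whose main
peak occupies a single bin the centroid equals the mode exactly. No
repeat-peak deconvolution is attempted (single-peak model): the estimator
targets haploid genomes whose histogram shows one clear peak, and a
strongly repetitive genome would be underestimated.

The packed-integer counter (2 bits/base, k ≤ 32) is validated against an
independent dict-of-strings counter by property test. Benchmarks use a
100 kb synthetic genome at 50× coverage: error-free reads reproduce the
size within 2%, reads with 1% substitution errors within 5% after the
cutoff. Real libraries add non-uniform coverage, GC bias and repeats,
which these benchmarks do not emulate.

## RIP scanning

Repeat-induced point mutation (RIP) converts C:G to T:A in duplicated
sequences (> 400 bp, ≥ 80% identity) during the fungal sexual cycle,
preferentially at CpA/TpG sites. Following the established dinucleotide
statistics, each window yields

* product index = TpA/ApT (RIP creates TpA),
* substrate index = (CpA+TpG)/(ApC+GpT) (RIP destroys its substrate),
* composite index = product − substrate.

Windows are 500 bp at 100 bp steps (`--window/--step`); the last partial
window is dropped so index variance is comparable across windows. A window
is `ripped` under the threshold rule — product ≥ 1.1 AND substrate < 0.9 —
or, in `composite` mode, when composite > 0; `non_ripped` when product
< 0.8 and substrate ≥ 1.1 (thresholds mode); otherwise `indeterminate`.
Zero denominators make an index, and the window, `undefined`; such windows
never contribute to regions (no division-by-zero semantics are defensible,
and exclusion is conservative). Indices are computed on the forward strand
only; the substrate index is strand-symmetric by construction (CpA+TpG and
ApC+GpT are each reverse-complement-closed), which is asserted in a test.
The default genome-fraction summary uses thresholds mode, the stricter and
better-specified of the two rules; composite mode is one flag away.

**Region consolidation.** Compositionally unbiased DNA has both indices
near 1.0 — right at the calling thresholds — so isolated `ripped` windows
are frequent by chance: on i.i.d. sequence at GC 47.8%, ~13% of single
windows exceed the threshold pair. Genuinely RIPped duplications instead
produce long runs of flagged windows (a 2 kb segment mutated at rate 0.5
yields ~25 consecutive flags). Reported regions therefore merge
overlapping/adjacent ripped windows and require a sustained run of at
least `min_windows` supporting windows (default 12, i.e. ~1.6 kb of
continuous evidence at the default window/step). The default was
calibrated on the null: in 5 Mb of i.i.d. sequence at genome GC, runs of
≥ 12 flagged windows cover ~0.3% of the sequence and the 99.9th percentile
run length is 14 windows, so chance regions are rare while the planted
positive control is recovered in full. `min_windows=1` restores plain
merging. Per-window calls are never altered by the consolidation and are
available via `--per-window`. The scanner does not attempt to identify the
duplication partner of a RIPped region or per-repeat-family statistics.

## NAT detection

Spliced reads reveal transcript orientation even in non-strand-specific
RNA-seq via the intron consensus (5' GT or GC ... AG 3'). For each
junction (intron interval with spliced-read support, read from Tophat-style
BED12 — the two blocks are the exonic anchors, the intron the gap between
them — or a 6-column intron BED), the boundary motifs are read from the
genome: forward-consistent iff the text starts GT/GC and ends AG,
reverse-consistent iff the reverse complement does (forward text CT...AC
or CT...GC). A junction consistent in exactly one direction gets that
strand; both or neither is `ambiguous` and assigns nothing. Junctions are
assigned sense/antisense to every gene whose span (UTRs included — the
annotation carries them, and antisense overlap of a UTR is still antisense
transcription; this is an interpretation, flagged as such) overlaps the
intron by ≥ 1 bp.

Antisense calls pass when spliced-read support is **at least 5 reads**
(inclusive) and **more than 10%** (strict) of the sense transcript's mean
exon-union depth, mirroring the wording of the two published thresholds;
the boundary semantics (support 5 vs depth 49 passes, vs depth 50 fails)
are pinned by tests. "Coverage of the antisense splice site" is its
spliced-read support; "average coverage of the sense transcript" is mean
per-base depth over the gene's exon union, supplied as a TSV — the only
unit-compatible reading of the comparison, documented here rather than
asserted as the original one. Genes with zero sense depth pass the
relative test whenever the absolute one holds. Manual curation is replaced
by non-destructive QC flags (`near_gap`: N-run ≥ 10 bases within 500 bp;
`in_repeat`: overlap with a repeat BED; `near_scaffold_end`: within 500 bp
of a boundary) that never change the verdict — curated removals are not
reproducible, flags are. Unspliced antisense transcripts are invisible to
this method by construction.

## Differential-expression classification

Counts are normalised to each sample's total (per million; the constant
cancels in every ratio). Per-replicate ratios pair replicate i of
condition A with replicate i of B (the replicate pairing is not dictated
by the design; index pairing is declared, all-pairs is available behind
`--pairing all`). Mean, sample SD (n−1) and CV = SD/mean are computed over
the replicate ratios; any zero paired denominator makes the gene's record
undefined and excludes it. Group classification follows the printed
cascade (4 > 3 > 2 > 1 > 0):

* group 4: every replicate ratio ≥ 4 or every ratio ≤ 0.25 (one side
  satisfied by all replicates — direction consistency),
* group 3: mean ≤ 0.25 or ≥ 4 and CV < 0.5,
* group 2: every ratio ≥ 2 or ≤ 0.5,
* group 1: mean ≤ 0.5 or ≥ 2 and CV < 0.5,
* group 0: everything else.

The cascade is verified against a literal transcription of the four rules
on 10^5 random ratio pairs. The consensus verdict (−1/0/+1) combines the
classical mean ratio with an external Bayesian table (ratio and posterior
probability per gene and comparison — consumed, never re-implemented):
a non-zero call needs both ratios beyond the mode's threshold (> 2 / < 0.5
normal, > 4 / < 0.25 stringent), external probability ≥ 1 − 10⁻⁶ (the
printed "probability = 1", loosened one ulp-scale epsilon because any
numerical Bayesian tool emits floats), and classical group ≥ 1. A gene is
development-specific (`up_in_sex`) iff called +1 in sex/DD and sex/vegmix
and 0 in DD/vegmix (down analogously). RPKM = reads · 10⁹ / (mRNA length
(nt) · library size); condition values are replicate means. No
multiple-testing correction is applied anywhere — the consensus scheme is
deliberately rule-based.

## Expression-level mixture and KS comparisons

Genome-wide log2 expression levels are decomposed into K univariate normal
components by expectation-maximisation. Initialisation is deterministic —
component means at the (i+0.5)/K data quantiles, equal weights, pooled
variance — so fits are reproducible (the alternative, random restarts,
reproduces nothing and the published fits involved manual adjustment
anyway). Convergence: log-likelihood improvement < 10⁻⁸ or 500 iterations;
variances are floored at 10⁻⁶ to avoid the classic single-point collapse.
The E-step works in log space (logsumexp). Monotone non-decreasing
log-likelihood is asserted on every fit, and recovered means agree with an
independent EM implementation (scikit-learn) in a cross-check test.
Callers exclude the zero-coverage sentinel (−11) before fitting.
Group-wise expression distributions are compared with the two-sample
two-sided Kolmogorov-Smirnov test (scipy, asymptotic p); a warning is
logged when min(n, m) < 25 where the asymptotic p-value is rough. Null
calibration (n = 200 per group, 1,000 resamples) keeps the rejection rate
at α = 0.05 within [0.03, 0.07].

## Orthology, lineage groups, microsynteny

RBH orthology runs on user-supplied 12-column similarity tables (running
the aligner is out of scope): hits are filtered at e-value ≤ 10⁻³, the
best hit per query is the highest bitscore (ties: lower e-value, then
lexicographic subject), and a pair is kept iff the two directions agree.
A gene whose top two bitscores tie exactly in either direction is
unresolvable paralogy and is excluded — multi-paralog families cannot give
"clear" orthologs. Lineage-specificity groups come from a nested clade
hierarchy supplied as configuration (orphan group outward); a gene is
assigned the innermost clade covering all species it has orthologs in, so
group composition is a data file, not code. Microsynteny: two ortholog
pairs are syntenic when the two A-genes share a scaffold within 20 kb
(start-coordinate distance — midpoints or gaps would change little and
starts are what position tables carry) and the two B-genes do likewise;
triplets use 40 kb for all pairwise distances in both species. Unordered
sets are counted once; no gene-order or strand conservation is required
(a minimal reading of "within a window"). The per-scaffold sliding-window
counter is validated against a dense all-subsets oracle on random
instances up to 200 genes.

## Synthetic data: what it emulates, and what not

All generators are pure functions of `SimConfig` (identical seed ⇒
byte-identical output; each stage draws from its own seed stream so adding
draws to one stage never perturbs another). Defaults describe the target
study design: GC 0.478; one 2 kb duplication (comfortably above the 400 bp
RIP substrate minimum) with CpA→TpA / TpG→TpA mutations at rate 0.5 in one
copy, decided on the pre-mutation sequence — exactly the contexts the
scanner's statistics assume, a clean positive control; 100 nt reads at
50× with i.i.d. substitution errors; three conditions (sex, DD, vegmix) ×
2 replicates of negative-binomial counts (variance μ + 0.05·μ², log-uniform
means 100–2000 — Poisson noise would make the CV criterion vacuous) with
5% of genes planted at 2³-fold in the sex condition only; gene models of
two exons around a canonical intron, an antisense intron planted in 30% of
genes with the first four planted junctions deterministically set to the
filter's boundary cases (support/depth 5/49, 5/50, 4/10, 30/100); ortholog
tables whose genome B preserves genome A's order except for a configurable
shuffled fraction relocated to random scaffolds. Every generator emits a
truth table, re-derivable by brute force from the generated files (tested).

What passing these benchmarks shows: the implementations compute the
stated statistics correctly, the filters implement the stated boundaries,
and the detectors recover structure planted under their own model
assumptions. What it does not show: behaviour under real-data pathologies —
non-uniform coverage, misannotated gene models, degraded RIP at low
mutation rates, overlapping genes, batch effects between replicates, or
paralogy structure more tangled than an exact bitscore tie.

## Problem sizes

The test suite and the acceptance script run desk-scale problems chosen to
make the statistical assertions stable: 500 kb genomes for RIP scanning,
100 kb genomes at 50× for k-mer estimation, 100 genes (30% antisense) for
NAT detection, 2,000 genes for the classifier benchmark, 10⁵ ratio pairs
for the group-rule cross-check, 100 random instances (≤ 200 genes) for the
synteny oracle, n = 4,000 for the mixture fit and 1,000 resamples for the
KS calibration.
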