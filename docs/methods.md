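# Methods

This note documents the models, defaults and numerical choices behind
`enhmotif`, and what the synthetic benchmarks do and do not demonstrate.

## PWM model and scanning

Count matrices are converted to log-odds in bits. The pseudocount
(default 1.0) is distributed across bases in proportion to the background,
so a column with equal counts under a uniform background scores exactly 0;
the background defaults to uniform (0.25 each) and can be set to an
observed composition. Scanning keeps only the maximally scoring placement
per sequence over both strands by default; minus-strand placements are
scored with the reverse-complemented matrix and reported at their + strand
offset. A placement overlapping any masked base (lowercase soft-masking or
N) is invalid rather than scored with a neutral column — this matches
scanning of a masked genome assembly, where repeat-derived matches are
unwanted. If every placement is masked the scan returns a "no valid
placement" sentinel rather than a score.

Ties are broken by the smallest offset, then the + strand. Scores within
1e-9 bits are treated as tied so that genuinely equal placements (e.g. a
palindromic word on both strands) resolve identically regardless of
floating-point summation order.

Presence/absence calls downstream use the relative score
`(score − min) / (max − min) ≥ 0.8`, the 80%-of-maximum convention of
common PWM scanners. One consequence matters at desk scale: for a 6-bp
matrix with roughly homogeneous columns, any single-mismatch word also
clears 0.8 (one mismatch costs at most 1/6 of the score range), so the
chance of at least one qualifying placement approaches 1 in sequences of
a few hundred bp. Presence-based statistics therefore saturate for short
words in long sequences. For this reason the enrichment functions also
offer a count statistic (qualifying hits per kb), which remains sensitive
when presence saturates; the end-to-end demo uses it for its 6-bp anchor.

## Bootstrap enrichment

The observed statistic is the difference in the per-sequence feature
(presence fraction by default, hits/kb optionally) between enhancers and
controls. Controls are the immediately adjacent flanks, one upstream and
one downstream, each length-matched to its enhancer; flanks that run off
the contig or overlap another enhancer are dropped and counted. The null
resamples `n_enhancer` sequences with replacement from the control pool
and recomputes the statistic against the full control pool; the p-value is
`(1 + #{null ≥ observed}) / (B + 1)`, which is never exactly zero and has
floor `1/(B+1)`. Resampling is seed-deterministic but order-sensitive; the
pipeline sorts sequences by id before testing so runs reproduce across
platforms.

This null captures only the sampling variability of the enhancer-set
fraction, not that of the control mean. Calibration therefore requires the
control pool to be several times the enhancer set; with a 4:1 pool the
measured type-I error at α = 0.05 is 5–6% (the calibration benchmark runs
500 null datasets of 100 sequences at B = 199), while a 2:1 pool is
measurably anticonservative (~8%). With two flanks per enhancer the
natural pool is 2:1, so for borderline p-values the count statistic and a
larger B are advisable; the benchmarks use a 4:1 pool.

Between-group comparisons (each ordered pair of Q, A, PAN) pool the two
groups and resample both group-sized sets from the pool, which matches the
observed statistic's variance and is calibrated at any base rate. Group
sizes below 20 trigger a power warning.

Positional bias uses the fraction of hit midpoints inside a central window
(default half the sequence) against an exact binomial upper tail with
success probability equal to the window fraction. This is a coarse,
deliberately simple analogue of CentriMo's local-enrichment question; it
ignores edge effects of the motif width (the midpoint correction removes
most of it) and is conservative for small hit counts.

## Word discovery in anchor flanks

Anchors are matched on the + strand only, as an exact IUPAC word; 15 bp
windows on each side of each occurrence (anchor excluded, truncated at
sequence ends) form the positive set. The "15 bp" is read as 15 bp per
side, not total — a window must be at least as long as the words sought.
The contrast set is either the corresponding windows from another enhancer
group or, by default, dinucleotide-shuffled copies of the positive windows
(Altschul–Erikson shuffling, seeded, preserving exact dinucleotide counts).

Candidates are all exact words of length 4–8 occurring in at least one
positive window, collapsed with their reverse complements; a word counts
once per window. Each candidate is tested with a one-sided Fisher exact
test (computed as the hypergeometric upper tail) on per-window presence,
and its E-value multiplies the p-value by the number of candidates
examined in the first round. The best word (smallest E, ties lexicographic)
is reported, windows containing it are removed from both sets, and the
search repeats until the E-value threshold (0.05) or the motif cap is hit.
This replaces DREME's generalized IUPAC search with an exhaustive exact-word
scan: deterministic, desk-scale, and adequate for planted-word benchmarks,
but unable to find degenerate motifs whose instances share no exact word.

A subtlety the benchmarks expose: a planted word and its one-letter-shorter
subwords discriminate almost equally when the contrast set is small, so
which ranks first can flip by sampling noise. Background word frequencies
separate them, and those are pinned down by the contrast set size; the
recovery benchmark therefore uses a contrast set five times the positive
set (shuffled controls are free), after which the full planted word wins
essentially always (100/100 held-out replicates).

Discovered words are mapped to a PWM library by converting each word to a
degenerate count matrix (matched bases share unit weight) and taking the
best mean per-column Pearson correlation over all ungapped offsets with at
least 4 aligned columns, in both orientations — a simplified TOMTOM without
its E-value machinery. A column with zero variance (e.g. from a uniform
matrix) contributes correlation 0.

## Expression linkage

Genes are linked to enhancers either through an association table or by
nearest-enhancer assignment (distance 0 inside an interval, else distance
to the nearer edge; ties go to the upstream enhancer, then the smaller
start). Both paths exist because association tables and proximity rules
are both common in practice. A gene's motif presence is the union over its
linked enhancers of the 0.8-relative-score call; genes with no linked
enhancer count as motif-absent (configurable) so the contingency margins
stay interpretable. The 3×2 table (up/down/ns × present/absent) is tested
with a plain Pearson χ² on 2 df, no continuity correction (undefined for
3×2); expected counts below 5 raise a warning flag. Exclusive gene sets
require presence in Q and absence in both A and PAN; the dual variant
additionally requires one Q enhancer carrying both the anchor and the
second motif.

Note that exclusive sets are not monotone in the score threshold in
general: raising the threshold can remove a disqualifying A-group hit and
admit a gene. What is monotone is the set of genes with any Q-group hit,
and the tests check exactly that.

## Quantitative assays

PSI defaults to the raw intensity ratio 100·I_FL/(I_FL+I_ΔE6); an optional
molar correction divides each band by its amplicon length first, for use
when staining scales with fragment mass. ΔΔCt assumes amplification
efficiency 2 (the Livak model); efficiency-corrected variants are out of
scope. Half-life fitting regresses ln(intensity) on time by ordinary least
squares — the standard first-order model for cycloheximide chases — and a
non-negative slope returns a flagged fit with an infinite half-life rather
than an error, since saturating chases are a real outcome. The log-linear
fit weights late (low-intensity) points more than a nonlinear exponential
fit would; at the 5% noise level of the benchmarks this is immaterial
(median recovery error ~2% for a 3.3 h half-life over 6 points spanning
8 h).

## Synthetic data

The generator emulates the statistical structure of a grouped enhancer
atlas at desk scale: by default 300 enhancers per group of 200 bp, each
placed mid-contig so both length-matched flanks exist. Real atlases are
one to two orders of magnitude larger with longer intervals; 200 bp
approximates an enhancer core around a peak summit and, importantly, keeps
the 0.8-relative-score presence call of a 6-bp word away from saturation
so both statistics remain exercised. The background is an order-1 Markov
chain, uniform by default (any 4×4 transition matrix can be supplied);
uniform background means the benchmarks say nothing about compositional
biases such as CpG depletion or repeat structure of a real genome — the
masked-base machinery is exercised by the masking stream instead, which
soft-masks geometric runs to a target fraction.

The anchor word is planted on the + strand at a uniform offset with
per-group probability (default 0.6 in all groups, loosely motivated by the
~60% motif incidence the quiescence-linked gene analysis reports); the
co-motif word (TTGGCA) is planted with conditional probability given an
anchor (default 0.6 in Q, 0.05 in A and PAN) at a uniform position inside
the 15-bp window beside the anchor, clipped at enhancer ends. The DE
generator draws classes at 20/20/60%, gives up-genes motif presence at the
odds ratio (default 3) against a 30% baseline, and independently draws
A/PAN presence and the dual flag, recording the realized exclusive and
dual gene sets as ground truth. Assay tables realise a 61% exon-retention
truth, an 8-fold expression truth and a 3.3 h half-life truth under
multiplicative lognormal (gel, decay) or additive Gaussian Ct noise.

All randomness derives from one seed through named substreams (sequences,
masking, planting, DE, assays), so changing one stage's parameters leaves
the other stages' draws untouched.

The demo PWM library is constructed programmatically from published
consensus words (LEF1 CTTTGT/CTTTGA, SOX2 CCWTTGTT, NFIX TTGGCA, ASCL1
GCAGCTG, ASCL2 CAGCTGC) with 80% of counts on the consensus base — a
synthetic stand-in with the right consensus structure, not curated
database matrices, and labelled accordingly.

## What the benchmarks show — and don't

Passing benchmarks demonstrate internal correctness and statistical
behaviour under the generator's assumptions: exact agreement of the
scanner with enumeration, bootstrap type-I error near nominal with an
adequate control pool, high power against planted spikes, reliable
recovery of a planted co-motif word, χ² calibration and power at known
odds ratios, and accurate assay-formula recovery under realistic noise.
They do not demonstrate performance on real genomic sequence (repeat
structure, compositional heterogeneity, correlated enhancers), nor do the
desk-scale gene counts correspond to any real atlas's figures — the
headline numbers of a genome-wide study require its external ChIP-seq/
RNA-seq data and are out of scope here.

## Problem sizes

Defaults were chosen so the full test suite runs in about a minute and the
acceptance script in under two on one CPU: 500 null datasets of 100+400
sequences for calibration, 20 replicates for power and recovery rates,
500/20 replicates for the χ² rates, 100 simulations for the assay
recoveries, and a 900-enhancer demo for the end-to-end run.
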