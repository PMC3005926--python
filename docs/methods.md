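# Methods

## Scope and model

`mirfish` implements a discovery pipeline for miRNA genes in a genome
without prior miRNA annotation.  Its statistical core is a binary
classifier over candidate hairpins: every perfect-match locus of a
filtered small-RNA read is treated as a candidate mature miRNA, its
±60 nt neighborhood as a candidate precursor, and a 10-dimensional
summary of the folded precursor is scored by an RBF-kernel SVM.  The
decision is reported as an empirical p-value — the probability that a
held-out background window scores at least as high — so "positive at
p < 0.05" literally means "fewer than 5% of background windows look
this hairpin-like".  Everything downstream (isomiR stacks, Mh/Mn
annotation, clusters, arm profiles, conservation quartiles) is
bookkeeping and classical statistics on those positive calls.

## Pipeline stages and their parameters

Stage order is fixed: collapse → copy-number filter → adapter trim →
length filter → perfect-match mapping → decoy-identity filter →
multi-locus filter → precursor extraction → folding → features → SVM →
assembly → annotation → characterization.  All thresholds live in
`PipelineConfig` with these defaults:

| parameter | default | meaning |
|---|---|---|
| `min_copies` | 3 | minimum copy number of a unique read |
| `min_len`, `max_len` | 18, 25 | mature read length window (nt, inclusive) |
| `min_adapter_overlap` | 6 | shortest adapter prefix trimmed from a read suffix |
| `refseq_min_identity` | 0.90 | reads above this ungapped identity to a decoy are dropped (strict >) |
| `max_loci` | 10 | reads mapping to more loci are dropped (exactly 10 survives) |
| `flank` | 60 | precursor extension each side of the mature (nt) |
| `alpha` | 0.05 | positive-call threshold on the empirical p-value |
| `max_variations` | 2 | edit distance for homolog (Mh) matching |
| `cluster_window` | 10,000 | max end-to-start gap (bp) inside a miRNA cluster |
| `dominance_ratio` | 2.0 | copy ratio separating "dominant" from "equal abundance" |
| `svm_C`, `svm_gamma` | 10, "scale" | SVM capacity; C chosen by held-out accuracy over {1, 10, 100} |

The dominance ratio deserves a note: the five arm categories require a
quantitative boundary between "dominant" and "equal abundance" that the
category names alone do not supply; 2.0 is our declared choice and is
exposed in the config.

## Folding

The folder is an in-package Nussinov-style dynamic program maximizing
weighted pairs (GC = 3, AU = 2, GU = 1; minimum loop 3), with a
deterministic traceback (prefer pairing, leftmost partner).  It
reports an integer `pairing_score`, deliberately not called an energy.
Numba compiles the O(n³) fill; sequences ≤ 25 nt are verified in the
tests against a memo-free exhaustive search over all nested structures.
Two caveats are intrinsic to pair maximization: random sequence pairs
extensively (so absolute scores are only meaningful relative to
background, which is exactly how the SVM consumes them), and the score
is **not** invariant under reverse complement when GU wobble is enabled
(a G·U pair maps to A·C, which cannot pair); `fold(..., gu_wobble=False)`
restores the strict symmetry and the test suite checks it there.

## Arm assignment

The natural rule — compare the mature midpoint with the terminal loop
of the folded precursor — fails systematically for matures lying near
the precursor edge: their partner arm can sit entirely outside the
±60 nt window, and no structure computed on that window can recover
the true stem.  We therefore assign arms by direct complementarity:
the mature (padded by 8 nt of arm context) is scanned against 150 nt
of genomic sequence on each side, scoring ungapped antiparallel
pairing with the same weight table; the side holding the
reverse-complement partner decides the arm (partner downstream in
sense orientation ⇒ 5p).  Near-equal evidence on both sides flags the
isomiR "loop-spanning", and such reads are excluded from arm
statistics.  The midpoint-versus-loop rule remains as a fallback when
no genome is available to scan.

## The synthetic-data generator

The generator emulates the conditions of a whole-body small-RNA
sequencing experiment against a draft genome: ~108–155 nt precursors
(50–65 nt arms, 8–15 nt loop) on both strands, the 3' arm a reverse
complement of the 5' arm with Binomial(n, 0.1) point mutations; read
stacks of 600 reads per gene split between arms by per-gene 5p:3p
weights drawn from the empirical vertebrate category frequencies
(43.3% 5p-only, 41.4% 3p-only, 6.7% 5p-dominant, 5.2% 3p-dominant,
3.4% equal); isomiR end-variation concentrated at the 3' end
(50% canonical, 43% 3'-shifted, 7% 5'-shifted); repeat units copied to
15 loci and deliberately left unmasked, mimicking high-frequency
elements that escape repeat annotation in draft assemblies; ≥200 nt
coding decoys feeding the identity filter; and noise reads verified
absent from the genome.  Clustered genes sit 0.5–2.5 kb apart while
everything else keeps ≥12 kb clearance, so planted clusters are
unambiguous.  Reads are emitted error-free by default: the mapper
demands perfect identity, so sequencing errors would only create
discarded reads.

What the generator does **not** emulate — and hence what passing tests
cannot show about real data: sequencing error and quality structure,
colorspace artifacts, tissue-dependent expression mixtures, genuine
thermodynamic folding of AT-rich genomes, mirtrons, RNA editing, and
catalog incompleteness beyond the planted `n_species` counts.

One consequence of the hairpin construction is worth naming: a hairpin
is approximately its own reverse complement, so when the mirrored
window of a mature happens to be mutation-free, its reads also map to
the opposite strand and yield a second, overlapping pre-miRNA call.
The evaluation therefore matches predictions to planted genes by
interval overlap ignoring strand: such a call is a duplicate detection
of a real gene, not a false discovery.

## Classification and calibration

Training data at desk scale comes from the planted truth: positives
are windows around every planted mature, jittered by a few nt (the
jitter range widens automatically so at least ~60 positive windows
exist even for small truth tables); negatives are random genomic
windows kept 200 bp clear of planted precursors.  Half of each class
is held out; the held-out negatives' decision scores form the
calibration table, and a candidate's p-value is the add-one-smoothed
fraction of calibration scores at or above its own (n = 999 calibration
negatives and a top score give p = 1/1000).  Held-out accuracy on the
default conditions is ~0.92–0.99.  With a real catalog, catalog
precursors can serve as positives through the same `train` interface.

## Conservation versus expression

Mh families are sorted by ascending conservation level (number of
catalog species encoding the family), ties broken by family name so
the split is reproducible, and divided into four contiguous quarters
with any remainder going to the earlier quarters.  The per-family
statistic is log10 of the top isomiR copy number (no pseudo-count:
expression is ≥ 3 by the copy filter).  Adjacent quarters are compared
with Welch's unequal-variance t-test — chosen over Student's because
quarter sizes and spreads differ by construction.  Simulations in the
acceptance script put the power to detect a 2-log-unit gradient
(n = 25/quarter, σ = 0.5) at ~100% and the null rejection rate near
the nominal 5%.

## Numerical and tie-breaking choices

Coordinates are 0-based half-open throughout; minus-strand precursors
are reverse-complemented so matures always appear in sense
orientation.  Collapsed reads order by descending copy then sequence;
assembly representatives by copy, then p-value, then position; homolog
ties by edit distance then catalog id; percentages round half-up to
one decimal, as summary tables print them.  Decoy identity uses the
read length as denominator (not alignment length) and ungapped
alignment — reads are ≤ 25 nt, where gaps are not meaningful.
"Two nucleotide variations" for Mh membership is edit distance, not
Hamming, because isomiRs differ in length.  Cluster membership is
strand-agnostic with per-member strand retained.

## Problem sizes

The test suite and acceptance script run on 2 × 300 kb genomes with 20
planted miRNAs at 600 reads per gene (three seeds), 100-replicate
quartile simulations, and ≤ 25 nt sequences for the exhaustive folding
oracle — sizes at which every brute-force oracle remains exact and the
whole suite completes in a few minutes on one CPU.

## Known limitations

Pair-maximization folding overestimates structure in random sequence;
candidate windows clipped at chromosome ends can lose their partner
arm; cross-strand duplicate calls of strong hairpins are reported, not
merged; the ten features are a classical reconstruction — a concrete,
self-contained choice, not a claim about any particular published
feature set; and the SVM is only as good as the training windows, so
runs on real data should train on catalog precursors of a related
species rather than synthetic truth.
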