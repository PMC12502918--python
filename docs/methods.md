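# Methods

## Overview

`synclass` classifies long (nanopore-style) DNA reads against a collection
of reference assemblies using short, subsampled k-mers. It has two parts:
a compressed reference index and a per-read binomial significance test.
The design goal is the regime of adaptive sampling ("read-until"), where a
classifier sees only the first few hundred bases of a molecule and must
decide quickly with a small memory footprint; short k-mers tolerate high
error rates but match by chance often, so raw match counts are replaced by
a significance test calibrated per assembly.

## k-mer encoding and subsampling

Each k-mer is packed into an integer with 2 bits per base, A=0, C=1, G=2,
T=3, first base most significant, so integer order equals lexicographic
order. The canonical form of a k-mer is the minimum of the k-mer and its
reverse complement, collapsing the two strands. `k` is capped at 31 so
codes fit one 64-bit word.

Windows are subsampled with **open syncmers**: a k-mer is kept iff its
minimal s-mer starts exactly at offset `t` (0-indexed), ties broken by the
leftmost occurrence of the minimum. Unlike minimizers, the rule depends
only on the k-mer itself, so a sequencing error perturbs the sample only
locally. Defaults: `k=15`, `s=9`, `t=2`.

Order of operations: each window is **canonicalized first**, and the
syncmer test is applied to the canonical form. Measured on uniform random
15-mers this emits ~11.8% of windows; applying the test to the as-read
orientation instead (available via the `canonical_before_syncmer=False`
switch) emits ~13.8%. The canonical-first order is the default because
the universe of storable k-mers is then exactly the set of canonical codes
passing the test, which is what the match-probability model assumes.
Lexicographic canonicalization biases the minimal s-mer toward early
offsets, which is why the emission density (11.8%) sits below the naive
1/(k−s+1) ≈ 14.3%.

Windows containing any non-ACGT character are skipped entirely; lowercase
input is accepted and uppercased.

The universe size |U| (distinct storable codes) is enumerated exactly for
k ≤ 10 and otherwise estimated by Monte-Carlo with 1e7 samples at a fixed
seed; the estimate enters only the match probabilities p_i = |K_i|/|U|,
which need ~3 significant digits at the default significance threshold,
far less than the Monte-Carlo precision (relative error ~1e-3).

## Matrix compression

The index is conceptually a |U| × |A| 0/1 matrix M: row = k-mer, column =
assembly. Rows are stored run-length encoded so that a query for k-mer j
can iterate the assemblies containing j in time proportional to the number
of hits. Two levers reduce the run count:

1. **Column ordering.** The total naive-RLE run count over all rows equals
   (number of rows) + Σ Hamming distances between consecutive columns, so
   minimizing runs is a traveling-salesperson problem over columns in
   Hamming space (NP-hard). We use the greedy nearest-neighbor heuristic:
   start from a column (default: column 0, for reproducibility; a seeded
   random start is a CLI flag) and repeatedly append the closest unvisited
   column, ties to the smallest index. Distances are computed on sorted
   sparse code sets as |K_i| + |K_j| − 2|K_i ∩ K_j|; a `distance_fn` hook
   allows plugging estimated (e.g. sketch-based) distances.

2. **Adaptive RLE.** Rows are encoded greedily left to right with w-bit
   words (default w=16). A run of ≥ w identical bits becomes one
   compressed word (1 flag bit, 1 bit value, w−2 length bits, so a run
   covers at most 2^(w−2)−1 bits); anything shorter is folded into a raw
   word storing the next min(w−1, remaining) bits verbatim. The adaptive
   word count never exceeds the naive run count when runs in both schemes
   are capped at 2^(w−2)−1 bits (at any fixed word width an over-long run
   must occupy several length fields; the property tests compare against
   that capped count). Decoding is exact; a trailing partial raw word is
   disambiguated by the decoder tracking the remaining row length.

Only rows with at least one set bit are stored (storing all 4^k rows is
infeasible at k=15); absent codes mean zero matches. The on-disk format is
a small versioned little-endian layout documented in
`synclass/database.py`, with a sorted (code → word offset) index for
binary-search lookup.

## Classification model

For a read, every emitted window is one **trial** (repeated syncmers count
separately — the model treats trials as i.i.d. draws, and dropping repeats
would bias n on repetitive reads); n is the trial count and x_i the number
of trials found in assembly i. Under the null hypothesis that the read is
random sequence, x_i ~ Bin(n, p_i) with p_i = |K_i|/|U|. The reported
statistic is the exact upper tail P(Bin ≥ x_i), computed through the
regularized incomplete beta function (scipy), stable to ~1e-300.

To make one cutoff comparable across read lengths, counts are rescaled to
a fixed trial budget `n_fixed` (default 100): x̄_i = ⌊x_i · n_fixed / n⌋
when n ≥ n_fixed, and x̄_i = x_i unscaled when n < n_fixed; the P-value is
always looked up in a per-assembly table of P(Bin(n_fixed, p_i) ≥ x) for
x ∈ [0, n_fixed], precomputed at startup. The read is assigned to the
assembly with the smallest P-value when it is below 10^(−e) (default
e=12), otherwise reported unclassified.

Numerical and tie-breaking choices:

- table entries that underflow are clamped to the smallest positive normal
  double (≈2.2e-308), still far below any sensible cutoff, so ordering
  among extreme winners stays defined;
- exact P-value ties are broken by larger scaled count, then smaller p_i,
  then smaller column index (deterministic);
- columns with x_i = 0 are skipped (their tail is 1, never below cutoff);
- reads shorter than k, or with no ACGT-only window, yield n = 0 and are
  unclassified;
- assemblies with zero usable k-mers keep their column but are excluded
  from classification with a warning (p_i is undefined).

Prefix truncation (`max_read_length` ℓ) keeps only the first ℓ bases of
each read before extraction, emulating the chunk visible to an
adaptive-sampling controller. No multiple-testing correction is applied
across assemblies: the single fixed cutoff is the model.

## Evaluation

Per read with ground truth: TP if the predicted label equals the truth;
FP if it differs (including any prediction when the true source is absent
from the database, sentinel `OUT_OF_DB`); FN if unclassified with in-database
truth; TN if unclassified with out-of-database truth. Recall = TP/(TP+FN),
precision = TP/(TP+FP), accuracy = (TP+TN)/total, F1 = harmonic mean of
precision and recall; metrics with zero denominators are reported as
undefined (NA), never as 0. An optional label→parent map re-scores at a
coarser rank (e.g. genus from species); unmapped labels pass through as
their own parent with a warning, and cyclic maps are rejected.

## Synthetic data

The generator stands in for real sequencing runs. Genomes are uniform
i.i.d. ACGT — either independent (negligible k-mer sharing at k=15) or
mutated copies of one ancestor at a chosen per-base divergence, which
reproduces the shared-k-mer structure of closely related strains that the
column-reordering step exploits. Reads are drawn from uniform positions
and strands (reverse-strand reads are reverse-complemented, exercising
canonicalization end to end) with independent per-base substitution,
insertion and deletion rates; a fixed fraction of reads comes from a
withheld genome labeled `OUT_OF_DB`. All outputs are byte-deterministic
per seed.

What it does **not** model: nanopore homopolymer-dependent and bursty
errors, quality-score structure, chimeras, abundance skew, real genomic
repeat content and inter-species homology. Passing the recovery tests
therefore demonstrates the statistical machinery (calibration of p_i,
scaling, cutoff behavior, strand handling) rather than field accuracy on
real metagenomes.

Study conditions used by the test suite's recovery check: 5 genomes of
100 kb, 2 000 reads of 1 kb at 5% substitution error, 10% out-of-database
reads, defaults k=15/s=9/t=2/n_fixed=100/e=12, plus a rerun truncated to
ℓ=360 bp. These sizes are scaled-down stand-ins chosen so the whole suite
runs on a laptop while keeping every per-read quantity (trials per read,
p_i magnitudes, tail depths) in the same regime as genome-scale use.

## Known limitations

- Database construction materializes all (code, column) pairs in memory;
  fine for thousands of bacterial-scale assemblies, not for full RefSeq.
- The nearest-neighbor ordering is O(|A|²) exact distances; for large |A|
  supply a sketch-based `distance_fn`.
- One FASTA file is one classification target; no taxonomy integration —
  rollup maps are the caller's responsibility.
- The binomial model assumes independent trials although overlapping
  windows share bases; this is the standard approximation and is what the
  fixed cutoff is calibrated against.
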