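# Methods

## Model and procedure

duquant treats metagenomic quantification as a coverage-uniformity problem.
Reads from genomic DNA land approximately uniformly along each source
genome, so the number of reads containing a given indexed substring of
length ℓ is, in expectation, (L − ℓ + 1)/L · p · (1 − êrr)^ℓ, where p is the
genome's mean coverage, L the read length and êrr the per-base substitution
rate ((1 − êrr)^ℓ is the probability the substring survives uncorrupted
inside a read). Identification and abundance estimation then amount to
choosing the genome set and coverages whose predicted substring counts best
match the observed counters, in total absolute deviation.

The pipeline has four stages:

1. **Index construction.** Every genome is canonicalized to a single string
   holding each contig forward and reverse-complemented with out-of-alphabet
   separators (no indexed substring may cross a contig or strand boundary;
   ambiguous IUPAC bases act as boundaries too). A generalized suffix array
   over the concatenation of all canonical texts, its Kasai LCP array, and
   two linear sweeps yield, per text position, the longest match into the
   nearest and second-nearest *other* genome. The minimal unique substring
   at position p is one base longer than the longest other-genome match; the
   minimal doubly-unique substring one base longer than the second-longest,
   valid only while exactly one other genome still matches. Candidates
   shorter than L_min are extended to L_min; candidates longer than L_max
   are dropped; a containment prune keeps only substrings containing no
   shorter kept substring of the same kind. The sweeps keep the top-3
   distinct genomes under a running LCP minimum, which is lossless for the
   top-2 values among non-self genomes (a dropped genome's running value can
   never again exceed the kept third's). A quadratic brute-force enumerator
   in the test suite provides the independent oracle.

2. **Sparsification.** Per genome and kind, a left-to-right sliding-window
   greedy retains the rightmost candidate occurrence inside each uncovered
   L-window whose window string is itself unique (doubly-unique), breaking
   ties toward shorter and then lexicographically smaller sequences for
   byte-stable indexes. The retained set covers every such L-mer that
   contains any candidate occurrence, and is of exhaustively minimal
   cardinality whenever each candidate occurs once on the genome (verified
   against subset enumeration in tests); with repeated candidates only the
   cover property is guaranteed. Windows whose only distinguishing
   substrings exceed L_max are uncoverable and skipped.

3. **Read scanning and counting.** Reads are scanned on both strands; each
   h-mer (h = L_min) is 2-bit-packed by a rolling update into an exact
   integer key — injective, so bucket hits need no verification — and bucket
   hits extend greedily through a suffix trie, reporting every accepting
   node passed. A read is conflict-free when the intersection of its matched
   substrings' genome sets is non-empty; conflict-free reads increment each
   matched substring's counter once and, for two-genome intersections, the
   genome-pair counter.

4. **Queries.** A1 ranks genomes with positive unique counters. A2 solves
   the minimum hitting set (unique-evidence genomes forced; every active
   pair covered) as a binary ILP with lexicographic tie-breaking (below).
   A3 solves the abundance MILP with per-substring auxiliary variables
   γ ≥ |c − e| linearizing the absolute deviations.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| L | 100 | nominal read length (bp); windows for L-mer statistics |
| L_min | 26 | shortest indexed substring; shorter markers differ from other genomes by one base and are too easily created by read errors |
| L_max | 50 | longest indexed substring, L/2: balances the chance a substring fits in a read (∝ L − ℓ + 1) against marker specificity |
| h | L_min | bucket prefix length; packed in 52 bits |
| α | 1e-4 | a genome is dropped from the A3 solution space only if its unique counter sum < α·nuᴸ **and** its doubly counter sum < α·ndᴸ; genomes with no unique L-mers are never dropped on the unique condition |
| ε | 0.3 | slack on the coverage lower bound L·Σc/nᴸ·(1−ε) of selected genomes. The printed bound overestimates coverage by the mean number of retained substrings per read window (≈1.1–1.4 at these L/L_max); ε must absorb that overlap factor plus error deflation of the raw counters, otherwise the true solution becomes infeasible and one member of a near-identical pair is dropped. 0.3 covers overlap factors up to ≈1.4 |
| p_max | 100 | abundance cap against contamination anomalies |
| êrr | 0 | substitution rate used in the expectation; set it to the known/estimated error rate of the reads |
| identification cutoff | 1e-4 | a genome counts as identified when its relative abundance ≥ 0.01% of the total |

Relative abundance is reported as pᵢ / Σⱼ pⱼ over selected genomes — the
coverage-proportional (cell-fraction) normalization. Base-proportional
shares can be derived as pᵢ|sᵢ| / Σ pⱼ|sⱼ|.

## Numerical choices

- Both ILPs run on HiGHS (`scipy.optimize.milp`) with a 1e-9 relative MIP
  gap; solutions are deterministic for identical inputs.
- A2 tie-breaking is lexicographic: (1) minimum cardinality, (2) maximum
  total aggregated counters, (3) minimum total unique-L-mer count (nuᴸ) of
  the chosen genomes. The third stage decides otherwise-symmetric pairs: a
  genome carrying many unique markers of which none was observed is a less
  plausible explanation than one that has no unique markers to show. This
  is what lets a genome with zero unique L-mers (fully contained in a
  relative) win the tie against its superset partner.
- In A3, δ is reported as 1 exactly when the fitted p exceeds solver
  tolerance (presence means positive abundance); objective terms of a
  genome with no retained substrings of a kind are dropped (empty-sum limit
  of the 1/nu normalization), and genomes with no retained substrings at
  all are pinned to zero. Counters stay unrounded; γ absorbs residuals.
- Because counts are integers and most retained substrings clip to exactly
  L_min on near-random sequence, the least-absolute-deviation optimum sits
  on a grid of spacing ≈ L/(L − L_min + 1) in coverage units; the relative
  quantization error therefore shrinks as 1/coverage. This drives the
  choice of ≥ 24× coverage in the end-to-end validation below.
- Suffix arrays are built by numpy prefix doubling; LCPs by Kasai's
  algorithm, clamped at boundary characters (exact, because equal-prefix
  suffixes reach their first boundary at the same offset).

## Sample-complexity bounds

For n error-free reads drawn from a genomes with abundances p (coverage
semantics: a read originates from genome i with probability
p′ᵢ ∝ pᵢ·nᵢᴸ), a read is attributable by unique evidence exactly when its
window is a unique L-mer, which happens with probability p′ᵢ·qᵢ. The module
implements the sufficient read counts for identification and for an L1
target ε on the estimator p̂ᵢ = (cᵢ/qᵢ)/n, and the achievable L1 bound at a
given n. Note the two printed statements carry different constants
(2(a+1) + ln(1/ζ) versus 2[ln(1/ζ) + (a+1)]), so plugging the sufficient n
for ε into the achievable-bound expression yields
ε·√((2B + 2A)/(B + 2A)) with B = ln(1/ζ), A = a + 1 — between ε and ε√2,
approaching ε as ζ → 1. The tests assert this exact algebraic relation.
The "unnormalized abundance" target is implemented as
p′ᵢ = pᵢ·nᵢᴸ / Σⱼ pⱼ·nⱼᴸ, the only normalizing reading consistent with the
estimator. The Monte-Carlo harness samples reads at the mandated n and
attributes them through the database's unique-L-mer masks — equivalent to
scanning error-free reads against the sparsified index, by the cover
property — and reports empirical success rates for both guarantees.

## What the synthetic data does and does not emulate

The generator produces: i.i.d. uniform-composition genomes; pairs sharing a
stated backbone fraction (the shared region yields doubly-unique, the
private regions unique substrings); near-clonal pairs differing at a fixed
number of SNPs; uniform or lognormal abundances on a coverage scale (a
read-share switch exists); uniform read positions with an optional linear
coverage ramp; and i.i.d. substitution errors. It does **not** emulate
repeat structure, skewed GC or k-mer composition, indels, quality-dependent
error profiles, chimeras, or genomes absent from the database. Passing tests
therefore demonstrate correctness of the algorithms and the behaviour of
the method under its own model assumptions — near-worst-case length
quantization, in fact, since random sequence makes almost every minimal
marker clip to L_min — but not performance on real instruments or real
pangenomes.

## Validation conditions

The end-to-end validation uses 20 genomes of 10 kb (five 90%-shared
backbone pairs, ten independent genomes), uniform abundances, 100 bp reads
at 32× coverage (24× in the faster test-suite variant), error-free and with
1% substitution errors (êrr set to match). These sizes keep a full run
around a minute on one CPU while leaving the pair-decoupling problem
genuinely hard: only ~10% of a pair genome's 100-mers are unique. The
sample-complexity harness uses 2 kb independent genomes, where q ≈ 1, a ∈
{2, 3, 5} and ζ ∈ {0.05, 0.2} with 200 replicates.

## Known limitations

- Almost-unique substrings for c ≥ 3 genomes are out of scope; so are
  GC-bias coverage corrections and paired-end mate rescue.
- The A3 coverage model assumes genomic DNA with roughly uniform coverage;
  it is not suitable for RNA-seq, where A1/A2 remain applicable.
- Index construction holds the suffix array and per-position match arrays
  in memory (~40 bytes/position including both strands), and the sweeps are
  pure Python: practical for databases up to a few tens of Mb, not for
  full RefSeq.
- Sparsification minimality is guaranteed only when each candidate occurs
  once on its genome; with repeats the retained set is still a valid cover.
- When genomes are exact duplicates, no query can distinguish the copies;
  A2 reports one representative of the duplicate group.
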