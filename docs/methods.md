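# Methods

## Model

`emrec` reconstructs near-full-length 16S rRNA genes from a sheared-amplicon
paired-end library by expectation-maximization over a finite mixture.

**Data.** Read pairs (r₁, r₂) with per-base Phred qualities, trimmed from
the 3′ end and length-filtered. **Parameters.** A set of candidate
sequences s₁…s_J (strings over {A,C,G,T}, fixed length each, no indels) and
mixture weights π₁…π_J summing to 1.

**Placement likelihood.** A pair is placed on a candidate gaplessly, both
mates in consistent orientation, implied insert inside an accepted window.
With ε_b = min(10^(−Q_b/10), 0.25) the error probability of read base b,

    log P(pair | candidate, placement) = Σ_matches log(1 − ε_b)
                                       + Σ_mismatches log(ε_b / 3).

The 0.25 cap keeps every base at worst uninformative rather than actively
negative. Within one candidate only the best-likelihood placement is kept
(one fragment has one origin); ties break to the leftmost fragment start,
then forward orientation. Placements are found by seed-and-extend: exact
15-mer seeds at three offsets per mate (start, middle, end), then full
gapless verification with per-mate mismatches ≤ 6% of mate length. The
model has no indel states anywhere; a true indel in a community member
appears as a run of substitutions.

**E-step.** P(j | i) = π_j P(rᵢ | s_j) / Σ_k π_k P(rᵢ | s_k), computed in
log space. **M-step.** π′_j = Σ_i P(j | i) / N over the N pairs with at
least one placement; per-position base weights
w_j[b, p] = Σ reads covering p with base b of P(j | i)·(1 − ε), and the new
consensus base at p is argmax_b w_j[b, p] (ties → current base, then
alphabetical; uncovered positions keep the current base). Abundances are
therefore fractions *of mapped pairs*, and the final report keeps
reconstructions with abundance ≥ 0.01% (not renormalized after the cut).

**Merging and pruning.** After each M-step, any group of candidates
connected pairwise by ≥ 97% consensus identity is merged transitively; the
highest-abundance member survives (ties → lexicographic id), receives the
summed abundance, and absorbs base weights after ungapped offset alignment.
Candidates expecting fewer than 0.05 reads of posterior mass are pruned —
the candidate set must be able to shrink from a database-scale seed; the
threshold is configurable and logged.

**Iteration schedule.** Priors start uniform over candidates that attract
at least one placement in the initial mapping. Placements are recomputed
from scratch (seed search) whenever the candidate set changed (merge or
prune) or any consensus base changed; otherwise the cached placements are
re-scored against the current consensuses — substitution-only consensus
updates cannot move a gapless placement, so this caching is exact. Hits
whose mismatch count exceeds the cap after a consensus update are dropped.
The classic EM guarantee (non-decreasing data log-likelihood) holds on
iterations where the candidate set and consensuses are unchanged, and is
asserted in the tests; merges, prunes and consensus flips may move the
likelihood discontinuously.

## Percent identity

Identity between two sequences is matched columns / aligned columns under a
banded global alignment with free (unpenalized, uncounted) terminal gaps.
The objective is lexicographic: maximize score (match +1, mismatch 0,
internal gap −1), then matches, then aligned columns — this makes the
reported value well-defined (independent of traceback order) and symmetric.
The band half-width is max(5% of the shorter length, length difference + 2,
10); for rRNA-scale sequences related by substitutions and short indels the
banded optimum equals the unbanded one, which the tests verify against a
full dynamic-programming oracle. Greedy centroid clustering (reference
database preparation, cross-sample OTU picking) processes records in a
stated order — input order for the database, decreasing abundance for OTU
picking — and opens a new centroid whenever no existing centroid reaches
the threshold.

## The simulator and what it emulates

The generator models the study conditions the reconstruction is designed
for: near-full-length amplicons excised between the 27F/1492R primer sites
(best-matching windows by Hamming distance, no mismatch cap; ties leftmost
for the forward primer, rightmost for the reverse), sheared to
truncated-normal inserts (default mean 275 bp, sd 15 bp, truncated to
[read length, amplicon length]), sequenced as 93 bp mates (read 1 the first
93 bases of the fragment, read 2 the reverse complement of the last 93),
with uniform per-base substitution errors (default 1%) and the matching
constant Phred quality. Fragment start positions carry weight
`end_bias_weight` (default 100) at the two terminal placements and 1
elsewhere — the observed ~100-fold preference of library fragments for
beginning exactly at an amplicon end. Every simulated pair is logged to a
truth table (source, start, insert, injected errors) for parameter-recovery
tests.

Not emulated: PCR chimeras, polymerase bias, indel errors, position-
dependent quality decay (available as an option only through the error-rate
argument, not enabled by default), multiple 16S copies per genome, and
barcode/index effects. Passing tests on simulated data therefore
demonstrate correctness of the estimation machinery under the declared
generative model, not robustness to every real-library artifact.

## Coverage model

For a member at relative abundance a of a library of n read pairs, total
sequenced bases are n·a·2·read_len, giving naive depth D = bases / amplicon
length. With N = amplicon − insert + 1 fragment placements of which the two
terminal ones carry weight w, interior positions receive fragment starts at
per-position rate 1/Z (Z = 2w + N − 2) versus N/Z·(1/N) for a uniform
library, so interior mean depth is D·N/Z — exactly D when w = 1. The
fraction of bases reaching a depth threshold t is P(X ≥ t) for
X ~ Poisson(interior mean depth). Whole-fold quotations ("11×") round the
interior depth to the nearest integer; the package evaluates the Poisson
tail either at the exact mean (default) or at that rounded depth
(`round_depth=True`), the convention used when quoting the pair of numbers
together. With the defaults (10⁶ reads = interpreting the library size as
pairs of 93 bp reads, 0.01% member, 1464 bp amplicon, 275 bp insert,
w = 100): interior depth 10.89 ≈ 11×, and 98.49% of bases at ≥ 5×. The
library-size-as-pairs interpretation is exposed as `reads_are_pairs`;
counting single reads instead would halve the depth and no longer match the
whole-fold expectation quoted above.

## Downstream procedures

- **Adjusted OTU table**: entry(o, s) = mapped pairs in sample s × summed
  abundance of sample-s reconstructions assigned to OTU o; column sums are
  conserved exactly.
- **High-specificity rule**: an OTU qualifies if present in ≥ 12 of the 16
  technical subsamples of at least one biological sample.
- **V3 excision**: minimal-Hamming windows for 341F and (downstream of it)
  the reverse complement of 518R, any number of mismatches, region
  inclusive of primer sites, rejected outside 100–225 bp.
- **Rarefaction**: expected counts are integerized per sample by
  largest-remainder rounding (column totals preserved), then each replicate
  draws the target depth *without replacement* (multivariate
  hypergeometric — a full-depth draw returns the sample unchanged), then
  all counts ≤ 20 are set to 0. Without-replacement sampling was chosen so
  rarefying at full depth is exactly the identity, which pins down the
  semantics of the clipping step.
- **End-bias diagnostics**: per fragment, distance to the nearest amplicon
  end is min(start, L − end). The enrichment factor divides the histogram
  mass at distance 0 by the mean *per-placement* mass over interior
  distances (each distance bin pools up to two start positions), which
  recovers the generative weight: a weight-100 library measures ≈ 100, an
  unbiased one ≈ 1.

## Numerical and design choices

- Coordinates 0-based half-open; all tie-breaks deterministic (documented
  at each site), so fixed-seed reruns are byte-identical.
- One seeded RNG per stage (database ambiguity resolution consumes a single
  generator in record order; the simulator derives everything from
  `SimConfig.seed`); the EM itself is deterministic and uses no RNG.
- Quality trimming: the cut lands on the first sub-threshold base inside
  the first 10-base window whose mean quality drops below the threshold
  (default Q20); pairs with either mate under 60 bp are rejected.
- The EM's insert window is estimate ± 5 sd (the estimate comes from
  unique-best concordant placements of an initial mapping). A ±3 sd window
  would silently drop ~0.3% of genuinely concordant pairs; the placement
  likelihood, not the window, does the discriminating.
- Per-base likelihood terms are accumulated in float32 (memory ~linear in
  library size); candidate ranking is unaffected because a single mismatch
  moves the log-likelihood by ~6 units.
- System tests run at desk scale: 20-species communities (abundances
  log-spaced 0.001–0.3, normalized), 10⁵ pairs, 1% error, 30 EM iterations
  (the reconstruction converges within ~5 iterations when seeded with exact
  references; the library default of 120 iterations matches the intended
  field use with database-scale seeds).

## Known limitations

- No indel handling: a candidate whose true sequence differs by indels is
  reconstructed as the substitution-nearest same-length sequence.
- No strain-level candidate splitting: co-occurring variants closer than
  the merge threshold collapse into one consensus.
- Greedy clustering is order-dependent (by design, with the order stated);
  it is a re-implemented analog of centroid clustering, not a claim of
  equivalence to any particular external tool.
- The mapper requires one exact 15-mer seed per mate; at error rates far
  above ~3% per base, seed misses begin to bias the mapped fraction.
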