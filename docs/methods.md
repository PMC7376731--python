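# Methods

## Seed model

A seed over a query `Q` and reference `R` is a triple `(q, r, l)` with
`Q[q, q+l) = R[r, r+l)`. Its δ-value `r − q` indexes the diagonal of the
reference × query plane on which the seed lies. Two seeds are *attached*
when they share a δ-value and their reference intervals overlap or touch;
attached seeds jointly describe one contiguous region of equivalence.
Conventions, used consistently across the API, TSV output and CLI:

* 0-based coordinates, half-open intervals;
* alphabet Σ = {A, C, G, T}; any other character (N, IUPAC codes) never
  matches any character, including itself, so ambiguity runs can never
  produce or extend seeds;
* seed length ≥ 1 — the definitions never produce empty seeds, and the
  types reject them;
* forward strand only: reverse-complement seeding is done by the caller on
  the reverse-complemented query;
* seeds are value objects; equality is componentwise on `(q, r, l)`.

## Indexes and sampling schemes

The reference index is a hash table from k-length words to ascending start
positions. Three schemes populate it: all k-mers (`full`), every k-mer
starting at a position divisible by `m` (`m-step`, fixed sampling), or
(w, k)-minimizers. Both sampled schemes bound the distance between adjacent
selected positions inside any matching stretch — by `m` trivially, by `w`
via the covering property (every window of `w` consecutive k-mer positions
contains a selected one). That bound is the *maximal sampling distance* the
MEM construction must bridge.

Minimizer order: the default ranks a k-mer by a splitmix64-style mixing of
its 2-bit packing with fixed, hard-coded constants, tie-broken by the word
itself — deterministic across runs and machines, and decorrelated from
base composition (plain lexicographic order over-selects A-rich words). A
`lex` order is available for hand-checkable examples. **All** positions
tying for the window minimum are selected: leftmost-only tie-breaking can
destroy the guarantee that two sequences sharing a substring of length
≥ w + k − 1 share a minimizer at the homologous offset, which the
completeness result below relies on. No end-minimizers or syncmer variants
are implemented.

The occurrence filter deletes buckets holding **strictly more** than the
threshold's number of reference positions, before any query is looked up,
and records the purged words. Lookup pairs *every* query k-mer with every
surviving reference position of the same word; the query side is never
sampled by default (sampling the query too — the practical sketching mode —
is available as an option on minimizer indexes, but weakens the
completeness guarantee to matches sharing a minimizer on both sides).

## Merge-extend MEM construction

Input: the fixed-size seed set of one read, the seed length `k`, and the
index's maximal sampling distance `m` (1 for full, `m` for m-step, `w` for
minimizers).

1. **Sort** by `(δ, q)`; attached seeds become consecutive. Distinct seeds
   cannot tie on both keys, so no further tie-break is needed. When a
   producer already delivers δ-sorted step-1 seeds, `merge_only` performs
   just the linear merge pass with no sorting and no character access.
2. **Merge pass.** Walk the sorted list keeping one growing seed per
   diagonal run. An attached successor is absorbed directly. A successor
   separated by a gap (possible only when `m > k`) is reached by comparing
   query/reference characters across the gap: if all match, merge; on the
   first mismatch the current seed is finalized *keeping the partial
   rightward extension* — those characters are part of the current MEM's
   true right end, and no later step could extend past the mismatch anyway.
   Keeping them means each gap character is compared exactly once.
3. **Final extension.** Each finalized seed is extended maximally left and
   right, stopping at the first mismatch or sequence boundary.

Output MEMs are filtered to a minimal length, by default `m + k − 1`: above
that length every MEM necessarily contains a sampled k-mer (an m-step
position, or a minimizer shared via the window inside the match), so the
output is complete and duplicate-free — two merged seeds on one diagonal
are always separated by a mismatch, hence extend to different MEMs. The
floor may be lowered to `k`, with the caveat that shorter MEMs appear only
if the sampled index happened to retain one of their k-mers. No gap-closing
or final extension walks more than `m − 1` nt before meeting a neighbour or
stopping; the `MergeStats` counters expose this bound, total character
comparisons, merges, and (always zero) duplicates, making the strategy
comparable against extend-purge by operation counts rather than wall
clock. A validation mode re-checks every input seed against the sequences;
tests run with it on, the CLI leaves it off.

## Seed filters

*SMEMs* (query interval enclosed by no other MEM's): sweep the MEMs sorted
by query start ascending and, within equal starts, length descending, so
any potential encloser precedes what it encloses. `qend` tracks the
rightmost query end visited; a seed ending beyond `qend` is a SMEM. A seed
spanning exactly the query interval of the last emitted SMEM (necessarily a
different reference interval) is also a SMEM — equal query intervals never
enclose one another.

*Maximal spanning seeds* (longest at ≥ 1 query position; "longer" is
strict, so equal-length mutual cover keeps both): an interval tree over
query intervals supports a sweep position `qpos`. At each `qpos` the
overlapping seeds are heapified by length and all seeds of maximal length
are emitted. `qpos` then advances to the nearest point where the covering
maximum can change: the smallest query end among the just-emitted seeds
**or the next seed start**, whichever is closer (a longer seed can begin
strictly inside the currently covered stretch; jumping only to the emitted
end would skip it). Seed-free stretches are crossed by jumping to the next
start. Each iteration either emits or crosses a start, bounding the loop at
2n iterations. Duplicate `(q, r, l)` input triples are rejected by both
filters rather than silently deduplicated — MEM sets are duplicate-free by
definition, so a duplicate signals an upstream bug.

Both filters are checked against literal definitional oracles (all-pairs
enclosure; per-position longest-cover scan) on a thousand randomized seed
sets, and for idempotence, order invariance, composability
(maxspan ∘ smem = maxspan) and the subset chain maxspan ⊆ smem ⊆ mem.

## Correctness rate

For a read originating from reference interval `I` and a seed set `S`,
`CR = n / |S|` where `n` counts nucleotides of `I` covered by at least one
seed's reference interval. Choices:

* a seed is *correct* when its reference interval intersects `I` —
  maximally extended seeds may legitimately overhang the origin's edges;
  coverage `n` is nevertheless clipped to `I`. Seeds on another contig are
  always incorrect;
* `|S| = 0` raises rather than returning 0 or ∞ — the rate is undefined
  and callers must branch;
* the metric cannot distinguish seeds inside `I` that belong to the true
  alignment from coincidental ones; it inherits that limitation from
  knowing only the origin interval.

Because merging only reduces `|S|` while preserving coverage, and final
extension only adds coverage, the merge-extend output's CR is ≥ the input
seed set's CR *per read*, not merely on average (with the length floor at
`k`; a higher floor can drop seeds and void the guarantee). The mean-CR
ordering maxspan ≥ SMEM ≥ MEM ≥ minimizer, by contrast, is an empirical
regularity checked stochastically. `hierarchy_counts` computes the
correct/incorrect counts of the five-set hierarchy (k-mers ⊇ minimizers;
MEMs → SMEMs → maximal spanning seeds at length ≥ w + k − 1) and asserts
both monotone chains per instance.

## Synthetic data

The generator emulates long-read seeding conditions without external data:
an i.i.d. uniform reference with optional planted dispersed repeats
(`repeat_spec`, needed to drive buckets over occurrence thresholds), and
reads of fixed consumed reference span with independent per-base errors.
Defaults: 100 kb reference, 1 kb reads, substitution/insertion/deletion
rates 2%/2%/1% — a mid-quality long read between error-free and raw
continuous-long-read quality; `SimConfig.scaled(f)` multiplies all three
rates jointly to sweep the error rate. Each read records the exact
reference interval it consumed as its origin. The RNG seed is part of the
config; reference and read streams draw from disjoint seeded generators so
outputs are bit-reproducible.

What the generator does **not** model: realistic error/length profiles
(homopolymer-biased indels, burst errors), genome-scale repeat structure,
reverse-strand reads, or quality values. Tests passing on this generator
therefore demonstrate algorithmic correctness and the direction of the
seeding trade-offs, not absolute correctness-rate magnitudes on real
genomes.

## Problem sizes and numerical choices

Randomized equivalence suites run on queries ≤ 100 nt and references
≤ 200 nt (with planted shared substrings so long MEMs occur) across
k ∈ {3, 5}, m ∈ {1, 2, 4} and both sampled schemes — over 1000 instances —
against brute-force MEM enumeration; filter oracles run on 1000 seed sets
of ≤ 50 seeds; correctness-rate statistics use 500 simulated 500-nt reads
on a 20 kb reference with an (5, 11)-minimizer index. These sizes make the
definitional oracles (quadratic or worse) exact companions of every run.
All computation is integer or exact string comparison; no floating-point
tolerances enter except in CR mean comparisons (5% relative slack on
stochastic orderings). Degenerate inputs: empty seed lists pass through
every algorithm as empty outputs; sequences shorter than `k` (or
`w + k − 1` for minimizers) yield empty k-mer (minimizer) sets by
definition rather than erroring.

## Known limitations

* The merge-extend completeness guarantee is conditional on the input seed
  set actually coming from an index with sampling distance ≤ m; occurrence
  filtering breaks the premise, producing the documented false-negative
  (a frequent k-mer hides a rare long MEM) and false-positive SMEM
  artefacts (a missing minimizer promotes an enclosed MEM).
* Suffix-array/FMD-index based seeding, seed chaining and alignment are out
  of scope; seeds are not alignments and no SAM/BAM is emitted.
* Single-threaded by design at these problem sizes.
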