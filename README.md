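# seedbridge

Algorithmic bridge between **fixed-size seeding** (k-mers, m-step k-mers,
(w, k)-minimizers) and **variable-size seeding** (MEMs, SMEMs, maximal
spanning seeds) for read alignment.

Sequence aligners start by *seeding*: finding exact matches between a query
(read) and a reference. Fixed-size seeds come cheaply from a hash table but
are many and ambiguous; variable-size seeds are fewer and more specific but
traditionally require heavyweight index structures (suffix arrays,
FMD-indexes). `seedbridge` computes the variable-size seed sets directly
from a hash-table index:

* **merge-extend MEM construction** — sort the fixed-size seeds by
  `(δ, q)` where `δ = r − q` is the diagonal of a seed `(q, r, l)` in the
  reference × query plane; merge *attached* seeds (same diagonal,
  overlapping or touching intervals) in one pass, close sampling gaps by
  character-verified extension, then extend each merged seed maximally
  once. For an index with maximal sampling distance `m` (step size of an
  m-step index, window size `w` of a minimizer index), this yields **every
  MEM of length ≥ m + k − 1 exactly once** — no duplicate purging, and no
  seed end walks more than `m − 1` nt. The competing *extend-purge*
  strategy (extend every seed, then deduplicate) is provided as a baseline
  with operation counters.
* **SMEM filter** — a sorted sweep keeps the MEMs whose query interval is
  not enclosed by another MEM's (super-maximal exact matches), in
  O(n log n).
* **maximal-spanning-seed filter** — an interval tree plus length heap
  keeps the MEMs that are, at some query position, the longest seed
  covering it; these are always a subset of the SMEMs.
* **occurrence filter** — hash-table buckets with more reference positions
  than a threshold are purged, the standard repeat-suppression heuristic;
  the package also demonstrates the false negatives and false-positive
  SMEMs this causes on the minimizer path.
* **correctness rate** — for a read with known origin interval `I` and
  seed set `S`, `CR = n / |S|` with `n` the number of nucleotides of `I`
  covered by seeds: the average number of correctly placed nucleotides a
  single seed contributes.

Every operation is validated against brute-force definitional oracles
(`seedbridge.reference`). Coordinates are 0-based, intervals half-open,
alphabet `{A, C, G, T}` (ambiguity characters never match, not even
themselves); only the forward strand is modelled — seed the reverse
complement of the query separately if needed.

## Worked example

Six 3-mer seeds between a 12-nt read and a 14-nt reference collapse into
three MEMs; two of those are SMEMs and maximal spanning seeds:

```python
from seedbridge import (Sequence, build_index, lookup_seeds, sort_for_merge,
                        merge_and_extend, MergeParams, filter_smems,
                        filter_max_spanning, correctness_rate, OriginInterval)

Q = Sequence("read", "CGGTGTCAAACT")
R = Sequence("ref",  "GCTTGTCAACCGTC")
seeds = sort_for_merge(lookup_seeds(Q, build_index(R, k=3, scheme="full")))
print("k-mer seeds:", [(s.q, s.r, s.l) for s in seeds])
mems = merge_and_extend(Q, R, seeds, MergeParams(k=3, m=1))
print("MEMs:", [(s.q, s.r, s.l) for s in mems])
print("SMEMs:", [(s.q, s.r, s.l) for s in filter_smems(mems)])
print("maxspan:", [(s.q, s.r, s.l) for s in filter_max_spanning(mems)])
print("CR:", correctness_rate(mems, OriginInterval("ref", 3, 11)))
```

prints

```
k-mer seeds: [(8, 7, 3), (3, 3, 3), (4, 4, 3), (5, 5, 3), (6, 6, 3), (4, 11, 3)]
MEMs: [(8, 7, 3), (3, 3, 6), (4, 11, 3)]
SMEMs: [(3, 3, 6), (8, 7, 3)]
maxspan: [(3, 3, 6), (8, 7, 3)]
CR: CrReport(n=7, set_size=3, cr=2.3333333333333335, n_correct=2, n_incorrect=1)
```

The four attached seeds on diagonal δ = 0 (query positions 3–6) merge into
the single 6-nt MEM `(3, 3, 6)`; the two isolated seeds stay as 3-nt MEMs.
The seed `(4, 11, 3)` is enclosed on the query by `(3, 3, 6)` and is
therefore not a SMEM. Against the origin interval `[3, 11)` the three MEMs
cover 7 of its nucleotides with one mis-placed seed, a correctness rate of
7/3 ≈ 2.33 nt per seed.

The same chain is available from the shell:

```bash
seedbridge simulate --config sim.yaml --out-ref ref.fa --out-reads reads.fa --out-origins origins.tsv
seedbridge pipeline --ref ref.fa --query reads.fa --k 19 --scheme minimizer --w 10 --occ 2000 --out-dir out/
seedbridge cr --seeds out/maxspan.tsv --origins origins.tsv --out cr.tsv
```

`pipeline` writes `mems.tsv`, `smems.tsv` and `maxspan.tsv` (TSV columns
`query_id ref_id q r l delta`, 0-based half-open); subset relationships
maxspan ⊆ smems ⊆ mems hold row-wise. See `seedbridge --help` for the
remaining subcommands (`index`, `seed`, `mems`, `smems`, `maxspan`).

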