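# karyocover

Recovering rearranged chromosome structure from weighted karyotype graphs
(interval adjacency graphs).

A karyotype graph places one *segment edge* per reference interval and
*adjacency edges* between segment extremities, each weighted by its copy
number. `karyocover` provides:

- **Eulerian decomposition** (`solve_edp`) and **minimal Eulerian
  decomposition** (`solve_min_edp`): collections of alternating walks —
  candidate linear/circular chromosomes — using every edge exactly its
  multiplicity. Closed-form identities for the path count and minimal size
  are asserted on every run.
- **Consistent contig covering** (`run_ccr`): since minimal decompositions
  are usually not unique, this recovers the unambiguous parts — a covering
  whose every contig occurs in *every* minimal decomposition, with the
  total unused adjacency multiplicity (the *contiguity discordance*)
  minimized. A naive single-option chaining baseline (`naive_covering`)
  and the trivial per-segment `primitive_covering` are included.
- **Brute-force oracles** (`karyocover.oracle`): exhaustive enumeration of
  all decompositions, forced junctions, and optimal coverings on small
  instances; used throughout the test-suite and by `--verify` to pin the
  polynomial algorithms to ground truth. Maximising the decomposition
  cardinality is NP-hard (via a triangle edge-partition reduction,
  `k3_reduction`), so it is *only* available through the oracle.
- **A rearrangement simulator** (`karyocover.simulator`): seeded deletions,
  tandem duplications, inversions, reciprocal translocations,
  circularizations and whole-genome duplications over a segmented
  reference, emitting the induced graph plus the true chromosomes.
- **Metrics** (`n50`, `covering_stats`, `contig_supported`) and
  tab-separated **I/O** (RCK-style segment/adjacency tables, contig-path
  tables, AGP v2.1 for linear contigs).

## CLI

```sh
# simulate a rearranged genome and its graph
karyocover simulate --seed 7 --out-dir sim/ --tandem-duplications 3 --inversions 2

# minimal Eulerian decomposition (exit 2 on non-decomposable input)
karyocover decompose --segments sim/segments.tsv --adjacencies sim/adjacencies.tsv --out decomp.tsv

# consistent contig covering + stats + AGP, with brute-force verification
karyocover ccr --segments sim/segments.tsv --adjacencies sim/adjacencies.tsv \
    --out-dir out/ --baseline --verify

# recompute stats for a contig table; run all oracle cross-checks
karyocover stats --contigs out/contigs.tsv --segments sim/segments.tsv --adjacencies sim/adjacencies.tsv
karyocover verify --segments sim/segments.tsv --adjacencies sim/adjacencies.tsv
```

Input dialect: `segments.tsv` (`chrom start end cn`, 1-based inclusive) and
`adjacencies.tsv` (`aid chrom1 coord1 strand1 chrom2 coord2 strand2 kind cn`
with `kind` R = reference / N = novel; a `+` breakend names the head of the
segment ending at that coordinate, a `-` breakend the tail of the segment
starting there). Tables are single-clone, single-haplotype; project
per-clone exports down to one column set before use.

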