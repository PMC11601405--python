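# Methods

## Model and procedure

The object of analysis is a dense trait × gene matrix M of association
p-values from a phenome-wide TWAS. The pipeline treats significance as a
binary property: E<sub>ij</sub> = 1 iff M<sub>ij</sub> < t, with strict
inequality, so a cell exactly at the threshold is *not* significant. A
bicluster is an all-ones submatrix of E — a trait subset 𝒯 and gene
subset 𝒢 with every pair significant. This is an exact, noise-free
bicluster definition: a single non-significant cell excludes a rectangle.
No approximate or probabilistic biclustering is attempted.

**Threshold.** The default t = 5.49 × 10⁻¹⁰ is the study-scale
Bonferroni-level constant used with phenome-wide matrices of roughly
4,000 traits × 22,500 genes. Note that 0.05 / (4,091 × 22,515) ≈
5.43 × 10⁻¹⁰: published cutoffs often reflect an effective test count
that cannot be recovered from the matrix shape alone. The package
therefore treats the threshold as an explicit configuration constant;
`bonferroni_threshold(alpha, n_tests)` is available when the user wants
the arithmetic cutoff, but it is never substituted silently.

**Missing values** binarize to 0. Absence of evidence cannot create a
bicluster cell, and any other choice would let missingness fabricate
structure.

**BiBit enumeration.** Rows are packed 8 columns per byte (little-endian
bit order within the byte), a layout that is identical on every platform
and lets pattern AND, containment (`row AND P == P`) and popcount run on
whole arrays. Every unordered pair of rows with at least mnc set bits
proposes the pattern P = row_a AND row_b; patterns are deduplicated on
their exact packed bytes; a novel pattern with popcount ≥ mnc is extended
to its full row support, and emitted when the support has ≥ mnr rows.
Consequences of this construction, all asserted by tests: every emitted
rectangle is all-ones; the row set is maximal (no left-out row contains
the pattern); results are invariant to row order; each gene pattern
appears once. Defaults are mnr = mnc = 2, the most permissive seeding —
size selection is deliberately deferred to the downstream ≥ 10-gene
filter so that filtering policy lives in one place. The enumeration is
restricted to patterns reachable from row pairs, which is the defining
scope of the algorithm, and `brute_force_biclusters` (plain nested loops,
no bit operations, guarded to 64 × 64) provides an independent oracle
with the same contract.

**Meta-clustering.** Filtered biclusters (≥ min_genes genes, default 10,
optionally required to contain a trait of interest given as explicit ids
and/or a regex on trait identifiers) are compared by the Jaccard
coefficient of their gene sets. Jaccard of two empty sets is defined as
0. Clustering is agglomerative average linkage (UPGMA) on the distance
d = 1 − J, the standard Jaccard metric; the tree is cut into exactly k
groups (default 10). The main path delegates to scipy's hierarchical
clustering; `reference_upgma_partitions` re-implements UPGMA with
explicit loops and a deterministic tie-break (merge the pair whose
smaller cluster-minimum index is lowest, then whose larger is lowest) and
the two are required to produce identical partitions at every cut level
on random distance matrices. On exactly tied merge distances the two
routes may legitimately differ; random real-valued Jaccard distances make
ties a measure-zero event, and within one route results are fully
deterministic either way. Group labels are C1..Ck in ascending order of
each group's smallest member index. No automatic selection of k is
provided, since the procedure being reproduced fixes k.

**Enrichment.** For query q (a meta-bicluster's gene union, or the union
of traits over its member biclusters), universe U, and term T: N = |U|,
K = |T ∩ U|, n = |q ∩ U|, k = |q ∩ T ∩ U|, and the p-value is the
upper-tail hypergeometric probability P(X ≥ k) (the observed overlap is
included — the standard over-representation convention). Query members
outside the universe are dropped with a logged count; terms empty after
universe intersection carry no test and are removed before adjustment.
Adjustment is Benjamini–Hochberg across the terms of one collection for
one query — the least surprising default where no procedure is mandated —
and the default universe is the corresponding axis of the association
matrix, the natural sampling frame; both are overridable. Collections are
flat GMT sets; no ontology download or graph propagation is performed.

**Reporting transform.** `p_to_z` maps a p-value to the absolute
two-sided normal quantile Φ⁻¹(1 − p/2), the scale on which association
heatmaps are conventionally drawn. Underflowed p-values (reported as 0)
map to a configurable cap, default 40 (the two-sided p at z = 40 is
≈ 7 × 10⁻³⁵⁰, already below double precision), with a warning.

## Synthetic data: what it emulates and what it does not

`generate_planted_dataset` draws background cells Uniform(0, 1), redraws
an independent Bernoulli(background_sig_rate) subset of them Uniform(0,
signal_p_max) to mimic isolated significant associations, and overwrites
planted rectangular blocks with Uniform(0, signal_p_max) draws. Blocks
are laid out disjointly in traits; consecutive blocks may share a chosen
number of gene columns, emulating pleiotropic genes spanning trait
groups. Annotation collections contain one term per block — exactly the
block's genes (or traits) — plus uniformly drawn noise terms.
Defaults (signal_p_max = 1e-12, background_sig_rate = 0.01, 50 noise
terms of 15 members) represent signal far below any plausible threshold
and a ~1% stray-significance rate, a regime in which planted structure is
clearly defined yet noise visibly perturbs the pattern space.

The generator is a pure function of (parameters, seed); matrix and
annotation draws come from sub-streams spawned deterministically from one
`SeedSequence`, so adding annotation terms never perturbs the matrix.

The null is deliberately minimal: independent per-cell uniformity, no
correlation between traits (comorbidity), no linkage disequilibrium
between genes, no tissue structure, no realistic effect-size
distribution. Real TWAS matrices violate independence pervasively —
correlated traits and LD-linked genes produce many more near-duplicate
biclusters than this null does. Passing the recovery benchmarks therefore
demonstrates correctness of the algorithmic chain on well-posed planted
structure, not performance on real phenome-wide data.

## Numerical and design choices

- Strict `<` at the binarization boundary; missing → 0 (above).
- Bit layout: byte-packed, little-endian within byte; digest of a binary
  matrix is the SHA-256 of dimensions plus packed bytes.
- Pattern dedup keys on the exact packed bytes of the pattern — collision-free
  by construction.
- Hypergeometric p-values come from the scipy survival function at k − 1;
  BH-adjusted values are floored at the raw p (the two can differ only by
  floating error). Results sort by (p, term id) so output order is total
  and reproducible.
- Similarity matrices must be symmetric to 1e-12 and carry a unit
  diagonal; distances are clamped to an exactly zero diagonal before
  linkage.
- `match_score` (planted-block recovery) is the mean over truth blocks of
  the best cell-set Jaccard over found biclusters; it is 0 for an empty
  found set and defined as 0 for an empty truth list.
- The analysis path consumes no randomness at all; the pipeline records
  the seed but uses it only when simulating input. Two runs of one config
  are byte-identical, which the manifest's per-file SHA-256 digests make
  checkable.
- Benchmark problem sizes: oracle comparisons use 100 random matrices up
  to 20 × 30 at densities 0.1–0.5 (where brute force is exact and cheap);
  recovery benchmarks plant five 8 × 15 blocks in 200 × 1000 — large
  enough that ~2,000 background-significant cells coexist with 600
  planted ones, small enough for interactive runs. UPGMA equivalence uses
  50 random matrices up to n = 15, where full partition comparison at
  every k is feasible.

## Limitations

- The all-ones bicluster definition is brittle to false-negative cells:
  one missing association splits or shrinks a rectangle. This mirrors the
  method being implemented; no rescue heuristic is added.
- BiBit's pair seeding cannot emit a pattern supported by rows whose
  pairwise ANDs never equal it; at mnr = 2 with exact planted blocks this
  does not arise, but it is a known property of the algorithm, not a bug.
- Pairwise similarity is O(B²) in the number of filtered biclusters and
  the reference UPGMA is O(B³); both are intended for the post-filter
  scale (tens to thousands), not for the raw enumeration output of a
  phenome-wide run.
- Cross-group "distinctness" of enrichment results is reported per group
  and left to the user's judgement; no formal criterion is imposed.
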