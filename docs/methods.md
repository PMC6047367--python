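# Methods

## The bit engine

A signature over a K-feature universe is stored as W = ⌈K/64⌉ unsigned
64-bit words, feature k at word ⌊k/64⌋, bit k mod 64, least-significant bit
first. The convention is arbitrary but fixed, so serialized containers are
bit-exact across platforms; any fixed order is observationally equivalent
for counts. Padding bits (indices ≥ K in the last word) are forced to zero
at pack time and re-validated whenever a container is loaded. Because AND,
OR and XOR all map zero pads to zero pads, every pairwise count is correct
without masking; a NOT/complement operator would break this property and is
deliberately not offered.

Pairwise counts are computed with `numpy.bitwise_count` over blocks of the
packed word arrays. Blocks are sized so the transient (W × n × m) word
tensor stays within a 2 MiB working set: on one CPU this cache-resident
batching is measurably faster (~40%) than larger batches. Counts are stored
as unsigned 32-bit integers (K < 2³² in every intended use; both reference
applications have K ≈ 20,000–22,688), so the output needs 4 bytes per cell.

Self-comparison returns a strictly upper triangular matrix with zero
diagonal: each unordered pair exactly once, the diagonal (a signature with
itself) carrying no information beyond the signature's own popcount. When a
self-comparison is computed blockwise, blocks straddling the diagonal zero
their lower parts, so the chunked path satisfies the same contract.

Chunking splits rows first (as many full-width rows per chunk as the byte
budget allows) and falls back to splitting single rows into column runs only
when one output row alone exceeds the budget. No particular tiling is
canonical — any tiling whose blocks each fit the budget and cover the output
exactly once yields cellwise-identical results, and the test suite asserts
that equivalence across several budgets. The default budget is 1 GiB.

There is no randomness anywhere in the engine; results are bit-identical
across runs.

## Binarization

Continuous expression-like matrices are split into paired *low*/*high*
signature matrices with strict inequalities: low bit iff value < low_cut,
high bit iff value > high_cut (defaults −0.6 / +0.6). Strictness means a
value exactly at a cut sets neither bit, and no value can set both. Under
the benchmark's data model — i.i.d. Gaussian with mean 0 and **standard
deviation** 0.5 (the generator exposes sigma explicitly, so a
variance-0.25 reading is one keyword away) — each tail captures
Φ(−0.6/0.5) = Φ(−1.2) ≈ 0.11507 of entries, which the calibration test
checks to within three binomial standard errors over ≥ 10⁶ draws.

Non-finite values default to "treat as zero" (the feature is simply not in
the signature, in either direction); an `error` policy is available. This is
the conservative reading for a filter: a missing measurement should not
create similarity.

## Filter-then-refine

The filter statistic for a pair is the *sum* of its low-shared and
high-shared AND counts — the same additive merge the network layer uses for
edge weights. Pairs reaching `min_shared` (default 20) get the exact cosine
or Euclidean value computed on the original continuous columns, with a fixed
sequential accumulation order so refined values are reproducible run to run.
Admissibility of the filter (whether the top full-precision pairs survive a
given cut) is an empirical property of the data, not a guarantee; the suite
*reports* the surviving fraction on synthetic data rather than asserting it.

## Network layer

Up-shared and down-shared self-comparison tables are merged by cellwise
addition. Discordant sharing (up in one experiment, down in the other) is
not scored or subtracted; that is a deliberate extension point, since the
merged scalar edge weight is the quantity of record. Graph construction
keeps pairs by weight threshold or the k heaviest pairs with a deterministic
tie-break (weight descending, then smaller first index, then smaller second
index) so regression tests are bit-exact. Sub-network extraction is the
minimal one-hop reading: seeds plus their neighbors, with all edges among
that node set, optionally trimmed to the heaviest edges.

Second-order similarity binarizes the adjacency at weight ≥ `edge_cut`
(default 20, the point below which pairs are indistinguishable from the
unrelated-pair background), packs the adjacency columns as signatures and
runs the AND self-comparison, answering "how many nodes are incident on both
i and j". It depends only on the binarized adjacency, which the suite checks
by rescaling weights above the cut.

Set-overlap enrichment is the one-sided (greater) hypergeometric tail
P(X ≥ observed overlap), the set-overlap half of a Fisher's exact test. The
observed overlap is computed with the packed AND count; the tail probability
comes from `scipy.stats.hypergeom.sf`, and the tests verify it against an
explicit combinatorial summation to 10⁻¹² absolute.

## Genome layer

Presence/absence matrices are already binary, so shared-gene content is a
direct AND self-comparison. Within-group means average a genome's shared
counts over the *other* members of its group; a singleton group has no such
pair and is flagged undefined rather than given a number. The group-pair
matrix's diagonal excludes self-pairs for the same reason: a genome's
similarity to itself is trivially its gene count and would inflate
within-group means. Minimalist-genome selection uses inclusive bounds
[200, 600]: where "fewer than 600" and "200–600" readings conflict, the
closed range was adopted.

## Synthetic data

All generators are pure functions of (config, seed), using numpy's
`default_rng` PRNG family.

* `gaussian_matrix` — i.i.d. N(0, 0.5² ) values. Default 20,000 × 500: the
  signature length of the reference benchmark with the column count scaled
  from 15,000 to 500 so a desk run finishes in seconds; the full size is one
  config away.
* `lincs_like` — 22,688-gene universe; 5 planted clusters of 10 signatures
  plus 50 background signatures; 150 up and 150 down genes per signature
  (a few hundred differential genes per experiment is typical of
  characteristic-direction-style calls); cluster members draw 60% of each
  direction from a shared disjoint template and fill the rest at random
  outside it. Expected within-cluster merged sharing is then
  2 × 0.6² × 150 ≈ 108 genes versus ≈ 2 for unrelated pairs
  (2 × 150²/22,688), a >5× separation that makes top-k components recover
  the planted clusters essentially always.
* `kegg_like` — the full reference composition by default: 20,624 orthologs
  across 4648 genomes (356 eukaryotes, 4049 bacteria, 243 archaea), groups
  of 8 genomes per genus, a core gene set comprising 70% of the group's
  genome size shared by all members, accessory genes drawn independently
  outside the core. Genome sizes are uniform per domain — eukaryotes
  2500–6000 annotated genes, bacteria 800–2500, archaea 600–1500 — matching
  the broad ordering of annotated gene counts across domains. Within-group
  mean sharing concentrates near the core size (≥ 0.7 × size), while
  cross-group overlap stays near the random-subset expectation
  size_a × size_b / K; the worst case (a small archaeal group against the
  largest eukaryotes, ≈ 175 expected shared genes versus ≈ 430 within) still
  separates cleanly, which is why the full-scale separation check passes for
  every genus. The full-scale self-comparison (4648 genomes, 323 words)
  runs in a few seconds on one CPU.

What the generators do *not* emulate: real expression signatures are not
exchangeable Bernoulli draws (gene–gene correlation, hub genes, cell-line
structure are absent); real genomes share genes through phylogeny, not a
flat core/accessory split, so between-group similarity here is flatter than
reality; and no metadata schemas (perturbation descriptions, assay
annotations) are modelled. Passing tests therefore demonstrate the
correctness and calibration of the machinery, not biological conclusions
about any particular compendium.

## Numerical and interface choices

* Counts: uint32 cells, 4 bytes per cell in chunk planning.
* TSV floats: 9 significant digits, enough for value-exact round-trips of
  the reference metrics at double precision.
* Binary container: little-endian, magic `BSG1`, header (version, K, N, W),
  column-major words, length-prefixed JSON id tables; the loader re-checks
  the padding invariant so corruption fails loudly.
* Self-comparison TSV tables store each unordered pair once; the reader
  re-normalizes to the strict upper triangle under its own id ordering, so
  a re-sorted id set cannot silently drop pairs.
* Logging goes to stderr; files and stdout carry only machine-readable
  results. Every CLI command writes a JSON manifest sufficient to re-run it.

## Problem sizes in the suite

The test suite and acceptance script run at desk scale by design: oracle
equivalence on instances up to K = 512 and 50 signatures a side; calibration
on 10⁶ Gaussian draws; the expression recovery at the generator default of
100 signatures; the genome separation at the full 4648-genome default; and
the informal benchmark at 20,000 × 500. The whole suite completes in well
under a minute of compute plus ~25 s for the full-scale genome check.

## Known limitations

* The engine is single-node, single-process; no GPU or SIMD intrinsics
  beyond what numpy's popcount ufunc uses internally.
* Wall-clock comparisons against the cosine baseline depend on the host
  BLAS; the acceptance script reports the observed ratio without asserting
  it.
* `min_shared` and `edge_cut` defaults (both 20) are sensible for
  expression-scale signatures but are data-dependent knobs, not constants.
* The hypergeometric enrichment assumes a well-defined finite universe;
  choosing U is the caller's modelling decision.
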