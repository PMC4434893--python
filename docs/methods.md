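# Methods

## Model and assumptions

The object of study is a directed regulatory graph over three node
classes. Transcription factors (TFs) regulate genes, other TFs and miRNA
loci; miRNAs repress gene and TF transcripts; target genes only receive
regulation. A miRNA regulating another miRNA is rejected as a data error
(curated interaction databases do not record direct miRNA→miRNA
regulation). The graph is *simple*: one edge per ordered pair, with the
contributing source databases kept as edge provenance, and no self-loops —
autoregulation is removed because the path machinery below treats a
self-loop as a trivial cycle. When sources disagree about a node's class,
TF wins over miRNA wins over gene: "gene" is the residual class for pure
targets, and a node that regulates anything as a TF is a TF even where it
is also a target. A node claimed both TF and miRNA is an input error.

The biological hypothesis behind the pipeline is that disease-active
regulation is concentrated around differentially expressed (DE) nodes, and
that causally meaningful cascades show up as *acyclic source-to-sink
paths* of the active sub-network that are unusually rich in already-known
disease genes and miRNAs.

## Active sub-network

Seeds are the DE disease-related identifiers that map into the network.
Neighbour discovery ignores direction (a seed's regulators are as relevant
as its targets); edge direction is preserved everywhere else. By default
the sub-network is the full induced subgraph over seeds plus neighbours —
edges between two non-seed neighbours are kept, since they are part of the
local regulatory context; `induced=False` (CLI `--seed-incident-only`)
restricts to seed-incident edges for the narrower reading. Seeds that do
not map are reported, not fatal: typically only a minority of DE entities
appear in curated regulation databases. Zero mapped seeds produces an
empty sub-network and a warning rather than an error, so screening runs
over many seed lists do not abort.

## Hypergeometric testing

All enrichment uses the inclusive upper tail P(X ≥ k) of
Hypergeometric(N, K, n) — the standard over-representation convention.
For N ≤ 10⁴ the tail is computed as a single ratio of big-integer sums,
exact to float rounding (the test suite checks 1e-12 relative agreement
with a rational-arithmetic oracle up to N = 200); larger universes fall
back to `scipy.stats.hypergeom.sf`. The point probability P(X = k) is
reported alongside the tail in `EnrichmentResult`: published enrichment
figures occasionally turn out to be point masses rather than tails, and
carrying both makes such discrepancies visible instead of mysterious. In
the shipped STS example the path-level probabilities (0.00053, 0.0007)
are inclusive upper tails, while the sub-network figure commonly quoted
for those counts (3.12 × 10⁻¹⁰ at N=3184, K=158, n=239, k=36) is the
point probability; the corresponding tail is 4.08 × 10⁻¹⁰.

Per-path p-values are *not* multiplicity-corrected by default — selection
applies a raw p < α cutoff with α = 0.001, strict inequality. A
Benjamini–Hochberg helper (`stats.bh_adjust`, CLI `--bh`) is available
but off by default.

## Path discovery and scoring

A path is an ordered, repeat-free walk along directed edges from a
zero-in-degree node to a zero-out-degree node *of the searched network* —
endpoints are relative to the sub-network the search runs on, not to any
parent network. Length is counted in nodes, admissible range 3–30
inclusive by default; the cap aborts a walk rather than truncating it, so
no emitted path is a prefix of a longer walk. Enumeration is an iterative
depth-first search from each source that never revisits a node already on
the current walk, so cyclic input is handled naturally; output is
deduplicated and lexicographically ordered, making runs reproducible
byte-for-byte.

Candidate paths are filtered to DE fraction ≥ 0.5 (inclusive; all node
classes count, TF genes being genes). The scoring population (N_pop,
K_pop) is the union of nodes over **all** enumerated candidate paths and
the known nodes within that union, computed *before* the DE filter: the
population describes what the path search could have returned, and the
DE filter is a relevance screen on the alternatives, not on the
population. The population can be overridden (`--pop-total/--pop-known`)
when scoring must be comparable across sub-networks or match an external
census. Each path of length L with k known nodes gets coverage ratio k/L
and p = P(X ≥ k) under Hypergeometric(N_pop, K_pop, L). Significant paths
(p < α) merge into a composite graph by set union of nodes and
consecutive-pair edges; merging is commutative and idempotent.

## Synthetic data generator

`SyntheticSpec`/`generate_network` emulate the structure of curated
TF–miRNA networks: three strata (TF, miRNA, gene) wired by independent
Bernoulli draws per ordered pair at per-regulation-type densities, plus
planted source-to-sink chains alternating TF/miRNA and ending in a gene,
whose nodes are annotated known/DE at controlled rates. Genes never
regulate, so sinks are plentiful; TFs receive edges only from miRNAs, so
sources exist with high probability — mirroring the skewed source/sink
structure of real curated networks. All randomness flows from a single
integer seed through one `numpy` generator; no global state.

Defaults (20 TF, 20 miRNA, 100 gene; densities 0.07 / 0.10 / 0.05 / 0.02
for TF→gene / TF→miRNA / miRNA→gene / miRNA→TF; half the background as
seeds; one planted 10-node chain) are calibrated so one draw resembles
the operating regime of a real STS-scale analysis scaled to desk size:
roughly 290 edges over 150 nodes, a candidate-path population of ~115
nodes with known fraction ~0.21 — the regime of the published 127-node /
27-known population. `background_known_fraction = 0.17` equals
(27−7)/(127−10): the background rate that reproduces a 27/127 census
once a planted chain contributes its own known nodes.

`planted_known_fraction` defaults to 0.8 (8 known of 10). This is a
power consideration, fixed a priori: a chain with exactly 7/10 known
scores ≈ 7 × 10⁻⁴ against a 127/27 population — so close to α = 0.001
that binomial fluctuation of K_pop pushes it over the cutoff in roughly a
third of draws, and no generator at that coverage can be recovered
reliably. At coverage 0.8 the analytic recovery probability exceeds 0.99,
so the ≥ 95% planted-path recovery check tests the pipeline rather than
the vagaries of the draw.

What the generator does **not** emulate: expression measurement and DE
calling (annotations are drawn, not derived from simulated expression);
degree heterogeneity within a stratum (real hubs are heavier-tailed than
Bernoulli wiring produces); correlated database provenance; and planted
chains are node-disjoint from the background, so recovery results say
nothing about planted signal entangled with background wiring. Passing
tests therefore demonstrate correctness of the machinery under a
realistic scale and annotation regime, not performance on real curated
networks.

## The STS example

`sts_example()` ships the twelve significant ten-node STS metastasis
chains and their 15-node/18-edge merged composite path (sources AP2 and
BMP-2, sink TYMS). The nine known-STS entities are AP2, BMP-2, MYC,
hsa-miR-26a, hsa-miR-221, PTEN, ESR1, TP53 and TYMS — the complement of
the six entities (FOS, hsa-miR-19a, hsa-miR-22, hsa-miR-24, hsa-miR-215,
hsa-miR-302c) related to STS only indirectly; this assignment gives every
ten-node chain exactly 7 known nodes and the merged set 9. The DE set of
the example is taken equal to the known set, a documented convention that
gives each chain DE fraction 0.7 (the true DE flags of the original
screen are not part of the example); every example p-value is invariant
to this choice because DE content only gates filtering, never scoring.
The population is fixed at (127, 27), the census of the candidate-path
union the chains were scored against. Note that enumerating paths on the
*merged* network yields 24 paths of 9–11 nodes, more than the original
twelve: merging creates routes (e.g. BMP-2's branch reaching FOS) that
did not exist in the sub-network the chains came from.

## Numerical and design choices

* Hub rule: inclusive (total degree ≥ 10), because reported hub tables
  include nodes at exactly 10; `strict=True` gives the greater-than
  reading.
* Boundary conventions: DE filter inclusive (≥ 0.5); significance strict
  (p < α); both chosen to match how the cutoffs are quoted.
* Ties everywhere break lexicographically; all writers sort, so identical
  inputs give byte-identical outputs (timestamps only in `run.log`).
* Degenerate inputs: empty path sets are contract errors for population
  building and merging (they indicate a wiring bug upstream), but an
  empty *significant* set is a normal outcome and produces empty tables.
* Problem sizes in the test suite: oracle comparisons run on 200 random
  DAGs of ≤ 12 nodes (exhaustive recursion stays trivial there), tail
  accuracy on universes ≤ 200 (rational arithmetic stays fast), and
  recovery on 100 draws at the default ~150-node scale — sizes at which
  every check is exact or well-powered while the whole suite runs in
  seconds.

## Known limitations

* miRNA identifier versions (e.g. -5p/-3p arms) are not reconciled; names
  are treated verbatim, as supplied.
* No motif analysis (e.g. feed-forward loops), centrality measures or
  community detection; degree is the only topology statistic.
* The per-path test treats path length as the draw size, ignoring that
  paths are constrained walks, not uniform node subsets; p-values are
  therefore calibrated only in the sense the coverage-ratio method
  defines, not as exact sampling probabilities of the path process.
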