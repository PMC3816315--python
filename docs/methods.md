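# Methods

## The model

`ovlcoarse` represents a sequencing read set as an *overlap graph*: one node
per read, one undirected edge per detected pairwise overlap, with the edge
weight set to the alignment overlap length in bp. Rather than committing to
a single graph (or a single flat clustering), the package produces a *series*
of graphs G_0, G_1, …, G_N by iterative coarsening, so the read set can be
inspected at any granularity: fine levels retain individual overlap
relationships, coarse levels expose cluster structure. Read clusters can be
extracted from any level, which matters for metagenomes, where reads must be
binned by source organism before assembly or analysis.

## Overlap detection

All reads are concatenated into one string with a `$` sentinel terminating
each read, and the concatenation is indexed by a suffix array (prefix
doubling over numpy argsorts, O(n log² n)). For each read in turn, its
l−k+1 component k-mers (default k = 16) are binary-searched in the suffix
array; every exact occurrence in a *different* read yields a seed hit with a
diagonal (ref offset − query offset). k-mers containing N never match.

Seed hits for a read pair are grouped into diagonal clusters (diagonals
within `band` of each other); each cluster is screened by a q-gram filter
and then extended by a banded overlap alignment:

* **q-gram filter** (default q = 8). For the overlap window of length w
  implied by the diagonal, two sequences within e edit operations share at
  least t = w + 1 − q·(e + 1) common q-grams; the error budget is
  e = ⌈(1 − min_identity/100)·w⌉. The filter counts multiset-common q-grams
  and rejects only below t, so it never discards a pair that could still
  meet the identity threshold (lemma soundness is oracle-tested against an
  edlib edit-distance check).
* **Banded overlap alignment.** Needleman–Wunsch restricted to diagonals
  within ±band (default 8) of the seed diagonal, with free end gaps (no
  penalty for the unaligned prefix of one read and suffix of the other, so
  dovetail and containment overlaps are both scored naturally) and unit
  scores (+1 match, −1 mismatch, −1 gap). The algorithm itself fixes no
  scoring scheme, so the unit scheme is this package's choice. Identity is
  100·matches/columns. With band ≥ max(|a|,|b|) the banded DP provably
  equals the unrestricted quadratic DP (tested on random pairs).

An overlap is accepted iff alignment length ≥ min_overlap_length (default
50 bp) and identity ≥ min_identity (default 90%). Each unordered pair is
evaluated once, from its lower-id member; if several diagonal clusters
align, the best (score, then length) is kept. Ties in the DP are resolved
deterministically (diagonal > up > left; first maximal end cell in scan
order), so the whole stage is reproducible bit-for-bit.

Defaults for k, q, band and the thresholds are engineering choices exposed
as flags; there is no canonical published value for them.

## The graph and its storage

Adjacency is CSR-style: flat destination and weight arrays plus a per-node
offset array, each undirected edge stored once per endpoint. Within a
node's edge set, edges are sorted by descending weight (ties: ascending
destination id). This makes "heaviest neighbor first" a linear scan and
gives O(1) edge-set lookup. Duplicate pair records are collapsed keeping
the longest alignment. Level-0 edges additionally carry percent identity;
coarse levels carry weights only.

## Coarsening by Heavy Edge Matching

Each iteration computes a matching and contracts it:

* **Visit order.** Nodes are keyed by their heaviest incident edge weight
  and visited in descending key order, shuffled within equal keys by a
  seeded RNG — reads with long overlaps are considered first, since a long
  overlap is the strongest evidence of adjacency in the underlying genome.
* **Matching.** Each still-unmatched node u scans its neighbors from
  heaviest: the scan *stops* at the weight floor `min_edge_weight` (weights
  are sorted, so nothing below can qualify), *skips* already-matched
  neighbors, and *skips* neighbors failing the density test (density is not
  monotone in weight, so a failure cannot justify stopping). The first
  surviving neighbor is matched and the scan ends. `passes` sweeps (default
  1) revisit unmatched nodes with a fresh shuffle.
* **Edge density.** With nw[u] the number of level-0 reads inside supernode
  u and ew[u] the total level-0 edge weight internal to u, the density of
  the prospective merge z = u∪v with s = nw[u]+nw[v] is

      edge_density(u, v) = 2·(ew[u] + ew[v] + w(u,v)) / (s·(s−1)),

  the supernode's internal weight normalized by its node-pair count. A
  match requires density strictly greater than `min_density` (default 50).
  For two singleton reads this reduces to the overlap length, so the default
  admits only >50 bp overlaps at level 0; at coarser levels the summed
  parallel-edge weights keep densely overlapping (well-covered) regions
  mergeable while preventing long, thin chains from collapsing into
  low-coherence supernodes.
* **Contraction.** Supernode ids are allocated scanning old ids ascending
  (first-seen member of each pair, then each unmatched node — an arbitrary
  but fixed convention for reproducibility). nw/ew accumulate as
  nw[z] = nw[u]+nw[v], ew[z] = ew[u]+ew[v]+w(u,v); node_map records each
  node's supernode; node_map_inverse[2z], [2z+1] record z's children (−1
  when z has one child). Edges are relabeled through node_map; self-mapped
  edges are dropped; parallel edges merge with summed weights; edge sets
  are re-sorted. Two conservation laws hold at every level and are tested:
  Σ nw = |V_0| and Σ_{E_0} w = Σ_{V_i} ew + Σ_{E_i} w.
* **Termination.** Coarsening stops when the matched fraction
  2·|M|/|V| drops strictly below `min_match_ratio` (default 0.01), or at
  `max_iterations` (default 50, comfortably above observed depths).

Both thresholds use strict comparisons ("greater than" for density, "falls
below" for termination). The density threshold 50 and match-ratio minimum
0.01 are the documented operating point of the method and are this
package's defaults.

## Cluster extraction and evaluation

A supernode expands to reads by nested descent through the node_map_inverse
arrays down to level 0, where node labels are read ids. The clusters of a
level form a partition whose sizes equal the node weights (cross-checked in
tests). Against ground-truth labels, each cluster is classified by majority
read vote (ties: lexicographically smallest label, a deterministic choice
the method itself leaves open) and the error rate is the percentage of
reads whose true genome differs from their cluster's majority label.

Edge relabeling renumbers level-0 nodes by a breadth-first traversal of a
reduced graph (components seeded at the heaviest-node-weight supernode,
neighbors in stored order; DFS of the expansion within each supernode), so
overlapping reads receive nearby ids. The tested contract is bijectivity
plus a non-increasing mean |src−dst| locality score; BFS vs DFS is an open
stylistic choice and only BFS is built in.

## The synthetic-data generator

`simdata` emulates a simulated-metagenome study design: several reference
genomes, i.i.d. uniform over A/C/G/T, optionally with homologous pairs
(a contiguous segment covering `shared_fraction` of the genome copied
between the pair, the copy mutated at `homology_divergence` — defaults
0.1/0.05, as inter-genome divergence within a taxonomic order is not
standardized); reads sampled per genome at count ⌊coverage·L/l̄⌋ with
uniform starts; fixed 100 bp lengths (Illumina-like) or truncated-Gaussian
~440±60 bp (454-like); substitution errors i.i.d. per base. Reads are
forward-strand by default (a `both_strands` flag enables reverse-complement
sampling; the overlapper's reverse-strand handling is intentionally out of
scope for the default pipeline). Byte-identical output given the same spec
and seed.

The generator deliberately omits quality-profile-dependent errors,
homopolymer indels, chimeras and real inter-species homology structure.
Passing tests therefore demonstrate correctness of the graph machinery and
recoverability of well-separated genomes under substitution noise — not
binning accuracy on real communities, where homologous regions will create
inter-genome edges and raise the error floor.

Default study conditions (four non-homologous 50 kb genomes, 100 bp reads,
15× coverage, 0.5% substitutions) are the package's standard test-bed;
coverage sweeps use 5×/15×/25× with the same genomes. Genome sizes are
scaled down from complete bacterial chromosomes so the whole pipeline runs
in minutes on one core; coverage, read length and error rate are kept
realistic, and the graph-level behaviour (fold reduction increasing with
coverage; near-zero majority-vote error for non-homologous genomes) matches
the full-scale qualitative picture.

## Numerical and degenerate-input choices

* Integer weights throughout the graph stack; density is the only float.
* Empty overlap windows and all-band-invalid alignments are rejected, not
  scored.
* An edgeless graph terminates coarsening immediately (match ratio 0).
* Reads with characters outside {A,C,G,T,N} have those characters collapsed
  to N on input; N never seeds and never matches in alignment.
* Identity is serialized at 2 decimal places; all integer arrays round-trip
  bit-exactly through the per-level TSV files.
* Every source of randomness flows from a single seed (the pipeline derives
  per-stage seeds by a fixed affine map), and all tie-breaks are
  deterministic, so every stage is byte-reproducible.

## Known limitations

Single-process only (the design admits block-parallel overlap detection and
a parallel merge sort, but those are out of scope here); forward-strand
overlap detection by default; no indel-aware seed chaining, so overlaps
whose true diagonal drifts more than `band` from the seed diagonal are
found only as their best-in-band alignment; no assembly or consensus stage.
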