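# Methods

## Model and procedure

focuslite treats assembly as graph construction plus graph mining rather
than contig maximisation. Reads become nodes of an undirected overlap graph
*G*₀ whose edges are pairwise dovetail/containment overlaps weighted by
overlap length; the graph is coarsened by heavy-edge matching into a
multilevel set *G*₀…*G*ₙ; best-representative read clusters (those whose
cleaned read-level subgraph is a single path) are drawn from the most
reduced level possible and integrated into a hybrid graph; and node-level
Shannon scores over incident edge weights expose repeated or
cross-species-shared sequence. The core assumptions are: single-end reads;
overlaps detectable by exact k-mer seeds plus banded alignment
(substitution-dominated error); and the identification of a node's
"diversity" with the richness and evenness of its incident edge weights.

### Orientation model

The preprocessor emits the reverse complement of every retained read (id
suffix `/rc`), and all subsequent alignment is same-orientation. As a
consequence each genomic region is represented twice, once per strand: the
overlap graph of a clean genome splits into two mirror components, every
contig appears with its reverse complement, and Shannon scores come in
mirror pairs. This keeps the alignment and coarsening machinery free of
per-edge orientation bookkeeping; consumers who want one record per locus
can dedupe by canonical (lexicographically smaller of contig/revcomp)
sequence.

### Overlap detection

Reference subsets are concatenated with `$` separators and indexed by a
true suffix array (prefix doubling). Repeated lookups at one k are served
by order-preserving integer codes of the k-prefixes in suffix-array order,
so a k-mer query is two binary searches on an int64 array. A seed fixes a
diagonal; each read pair is aligned at most once per diagonal (repeats
inside a pair can propose several; each is tried until one yields an
accepted edge — trying only the first diagonal can discard a true overlap
when a chance shared k-mer fires first). The implied overlap region is
compared exactly, then gaplessly (Hamming), and only if that fails is the
banded Needleman–Wunsch run (match +1, mismatch −1, gap −2; the gapless
shortcut is exact for the acceptance path because a gap pair costs more
than two mismatches, so when the diagonal already meets the identity
threshold the DP cannot select a gapped path with more matches per column).
Identity is matches/columns; acceptance needs overlap ≥ `min_overlap`
(default 40 bp) and identity ≥ `min_identity` (default 0.95). Defaults
k=16, step=4, band=10 suit reads of ≥ 75 bp.

### Coarsening and the density threshold

Heavy-edge matching visits nodes in `n_passes` (default 4) quantile buckets
of maximum incident edge weight, heaviest bucket first, ascending id inside
a bucket; a node scans its neighbors in decreasing edge weight, stops
(unmatched) at the first edge below `min_edge_weight` (default =
min_overlap), skips candidates whose merge density is not above
`min_density`, and contracts with the first qualifying partner. Matched
ratio below `stop_ratio` (default 0.1) ends coarsening. Two conservation
laws hold exactly at every level and are asserted in tests: Σ nw = |G₀|
and Σ ew + Σ level edge weights = Σ G₀ edge weights.

The density threshold is the granularity dial. For a path-like cluster of
n reads at local read coverage c (100 bp reads, ≥ 40 bp overlaps) the
merged-cluster density is ≈ 84·c/n, so a threshold τ caps cluster *span*
at about 8400/τ bp regardless of coverage. The default `min_density = 6`
keeps unique-region clusters near 1–1.4 kb of sequence at 20× — small
enough that the hybrid graph retains branch structure and 5-neighborhoods
are local — while multi-copy regions (higher c) still coalesce. Set
`min_density = 0` for pure assembly: coarsening then runs to one node per
component and a clean genome is reconstructed exactly (verified on
error-free 20× simulations).

### Cluster cleaning and contig construction

Before the single-path test, a cluster's read-level subgraph is cleaned:

- **Contained-read folding.** Reads wholly contained in another read (exact
  duplicates included; the smaller id survives) are dropped first. They
  carry no layout information, and their all-equal edge weights otherwise
  make tip/bubble tie-breaking ambiguous — in practice the ambiguity cost
  terminal bases of otherwise perfect contigs.
- **Tips**: dead-end chains of ≤ `max_tip_len` nodes (default 3) hanging
  off a branching node are removed only when a competing branch is longer
  or continues — a plain path never clips its own ends, and equal-length
  dead ends are both kept.
- **Bubbles**: pairs of short node-disjoint paths (≤ 5 nodes) with common
  endpoints; the lighter-total-weight arm is deleted. The rejoin node is
  the earliest common node along both arms (walks can wrap a cycle, so the
  min-max-position candidate is taken).
- **Transitive reduction**: an edge implied by a two-edge chain of
  heavier-or-equal overlaps is removed; edges are processed in increasing
  weight (id tie-break) against the current graph, which resolves
  equal-weight symmetric ties without disconnecting anything.

The three steps iterate to a fixed point because reduction can expose new
tips. A cluster passing the single-path test is laid out by the per-edge
offsets recorded at alignment time and consensus is majority-per-column
(ties: the first covering read in layout order).

### Hybrid graph and trimming

Representatives selected at any level block all their descendants, so the
member read sets of the selected nodes partition the retained reads. Hybrid
edges carry summed inter-cluster G₀ edge weight. The trimming pass visits
nodes in ascending contig length; a node whose contig is shorter than
`max_containment_len` (default 200 bp) and maps into a neighbor's contig at
≥ 0.95 identity (edlib infix alignment) is deleted, iterating to a fixed
point, after which transitive edges are removed.

### Mining

Shannon's index of a node is the entropy of its normalised incident-edge
weight distribution (0 for ≤ 1 edge; maximum ln n; invariant to weight
permutation and scale; a spurious low-weight edge barely moves it). The
high-score threshold is 1.0 ≈ ln 3: ln 2 would admit clean two-edge path
nodes pushed over by one spurious edge. Genus composition vectors are
length-weighted over distance-1 neighbors, excluding nodes with > 20 %
unknown-labeled neighborhood sequence; clustering is k-means
(k-means++ initialisation, 50 restarts, seeded) with within-cluster
sum-of-squares reported for the elbow choice of k. Enrichment uses, per
cluster, the deduplicated union of radius-5 neighborhoods of its members;
per gene class a 2×2 table (class vs other hits × inside vs all hybrid
contigs, one count per contig-class pair) is tested one-sided (greater)
with Fisher's exact test and corrected across all (cluster, class) pairs by
Benjamini–Hochberg. Genus and gene-class labels are inputs (TSV tables);
the simulator provides truth-derived tables, and real data would use
read-mapping majority votes and protein-database hits produced externally.

## The synthetic community generator

`simdata` emulates exactly the features the miner is meant to detect:
genomes are uniform-random ACGT backbones; one identical element per
carrier group (inverted repeat + core + reverse-complemented repeat,
default 1 kb with 30 bp IRs) is spliced into each carrier at a random
locus; an rRNA-like segment (default 600 bp) recurs in identical copies
within each genome (distinct between genomes, so genomes share only the
element); a resistance-class segment sits a fixed offset (default 1.5 kb)
downstream of element copies; and background gene segments of a neutral
class are scattered so enrichment tables have a non-degenerate outside
column. Reads are sampled uniformly from both strands (one read anchored at
each genome end so the configured fold covers the full sequence), with
i.i.d. substitutions at `error_rate` (default 0 — the headline study
condition; a separate test checks the realised rate binomially at 2 %) and
Normal(30, 5) Phred qualities clamped to [2, 40]. The generator does not
model indels (the aligner handles them, the generator doesn't emit them by
default), GC or abundance skew, chimeras, or platform-specific error
profiles — passing tests therefore speak to the graph algorithms, not to
robustness against real instrument noise.

Default study condition (`shared-transposon` preset): 3 genomes × 20 kb,
one element shared by all three, 2 rRNA copies per genome, 6 background
genes per genome, 20× coverage of 100 bp reads, error 0, seed 0.

## Observed behavior and known limitations

- On the default study condition the shared element is represented by a
  high-Shannon core node (H > 1, ≥ 3–4 incident edges once strand mirrors
  are counted separately) flanked by "straddle" nodes that extend from a
  carrier's unique flank into the element. A single node containing the
  *entire* element is not a stable outcome of heavy-edge matching: the
  density cap limits cluster span identically for repeated and unique
  sequence (span ≈ 8400/τ bp), so either flank clusters absorb the element
  ends or the element interior itself splits. The mining signal — element
  core above the ln 3 threshold, unique nodes concentrated in [0.6, 0.7],
  planted resistance class enriched at q < 0.05 — is robust to this.
- Scores, contigs and clusters all appear twice (strand mirrors); counts in
  reports should be read per orientation.
- The matched-ratio stop rule plus the density cap means deep levels can be
  nearly idempotent on sparse graphs; `max_levels` (64) is a safety bound.
- Quality trimming follows the strict reading of "average window quality
  greater than q": a window averaging exactly q trims.
- Connectivity of the overlap graph at low fold assumes gap-free sampling:
  Poisson start positions at ≤ 6× leave occasional inter-read gaps beyond
  read_len − min_overlap, which correctly fragments the graph.
- Serial execution only; the subset machinery exists for determinism (the
  edge set is provably independent of subset count), not for speed.
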