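# Methods

## The network model

An anatomical network is a simple, undirected, unweighted graph. Nodes are
anatomical units tagged with a tissue class (`bone`, `cartilage`, `muscle`)
and a body side (`left`, `right`, `median`); edges are physical contacts
tagged with a contact type (`suture`, `synchondrosis`, `synovial`,
`muscle_fusion`, `tendon`, `attachment`, or `unspecified` when a curated
table omits it). Geometry, contact area and edge direction are deliberately
out of the model: the analysis is purely topological, so two units either
touch or they do not. Self-loops are rejected; duplicate contacts in input
tables collapse to one edge with a warning, because hand-curated anatomical
tables commonly repeat contacts. Isolated nodes are legal and meaningful —
in the muscle-only subnetwork most muscles lose all their contacts, since
they attach to bone rather than to each other.

The packaged head registry transcribes the published 181-unit label list
verbatim, including its printed typos, with tissue class and side recorded
in the fixture file itself so the derivation is auditable rather than
recomputed at load time. Two printed quirks are preserved as-is: the
cervical-vertebra range supplies seven ids for six names (the fixture keeps
seven nodes, numbered 1–7, and notes the inconsistency in its header), and
the arytenoid transverse muscle appears as a left/right pair although the
muscle is classically unpaired. The packaged reference partition expands
each unsided entry of the published module table to both its left and right
nodes (modules printed without side qualifiers), keeps the printed
left/right split of the explicitly sided modules, and flags the hyoid —
printed under two different modules — as ambiguous instead of forcing an
assignment.

## Module detection

### Walk profiles

The detector characterizes each node by the exact distribution of a lazy
random walk of length `t` started there: one step from a node of degree *d*
stays put or moves to each neighbor with probability 1/(*d*+1), and the
profile is the *t*-th matrix power of that rule. The self-loop (laziness)
matters: without it the walk is periodic on bipartite regions, and on
near-bipartite subgraphs odd/even walk lengths alias, which measurably
misranks candidate merges — on seeded two-block benchmark graphs the
self-loop-free variant missed the exhaustive modularity optimum on 3 of 50
draws (by up to 0.22), while the lazy variant attained it on all 50. The
lazy formulation is also the one the field's standard walktrap
implementations use, and this package's merge sequences match the igraph
implementation merge for merge.

`t` is a tunable parameter (default 3, dimensionless walk steps). Short
walks see local structure; walks much longer than the graph's mixing time
blur all profiles toward the stationary distribution. For head-sized
networks (tens to a few hundred nodes) 3 is the conventional choice and the
package's default.

### Agglomeration

Nodes *i*, *j* are compared by the degree-weighted Euclidean distance
between their profiles, r_ij = sqrt( Σ_k (P^t_ik − P^t_jk)² / d_k ), with
d_k the lazy-walk degree (*d*+1); the weighting damps the dominance of hubs,
which every walk visits often. Communities start as singletons and the
edge-adjacent pair with the smallest Ward cost

    Δσ(C₁, C₂) = (1/n) · |C₁||C₂| / (|C₁|+|C₂|) · r²(C₁, C₂)

is merged repeatedly, where a community's profile is the mean of its
members' profiles and *n* is the connected component's walk-eligible node
count (the 1/n factor is constant within a component, so it cannot change
merge order; normalizing per component keeps detection on a disconnected
graph identical to detecting on each component separately). After a merge,
costs against bystander communities follow the Lance–Williams Ward update;
a pair that first becomes edge-adjacent after a merge gets its cost directly
from the stored mean profiles, which for Ward on Euclidean centroids is
algebraically the same number. Only edge-adjacent communities may merge, so
connected components never fuse and a component of *n* nodes contributes
exactly *n*−1 merges.

### Modularity and cut selection

Each dendrogram level is scored with Newman's modularity
Q = Σ_m (e_mm − a_m²): e_mm is the fraction of edges inside module *m*, a_m
the fraction of edge endpoints in *m*, and a_m² the expected within-module
edge fraction in a degree-matched random network. Q ∈ [−1, 1]; the
single-module partition scores exactly 0. The reported partition is the
level with maximal Q. Isolated nodes bypass the walk machinery entirely and
are appended as singleton modules flagged `isolate`; they contribute
e = a = 0 to Q and are excluded from the headline module count, so "the
muscular network divides into k modules" always refers to connected groups
of two or more units (or singletons that merely lost a tie, which do count —
only degree-zero units are flagged).

### Tie-breaks and tolerances

All detection is deterministic. Merge costs within 1e-12 of the minimum are
treated as tied and the lexicographically smallest (min id, max id)
community pair wins; equal-Q dendrogram levels resolve toward fewer modules
(parsimony); the exhaustive oracle breaks ties toward fewer modules, then
the lexicographically smallest canonical assignment. Walk-profile rows are
validated to sum to 1 within 1e-9 absolute, adequate for double-precision
matrix powers at the few-hundred-node scale this package targets. Edgeless
networks are rejected (modularity is undefined without edges); networks
whose chosen tissue subset has no edges raise the same error in the
pipeline.

### The exhaustive oracle

`brute_force_max_modularity` enumerates all set partitions of the
non-isolated nodes (restricted-growth-string order) and returns the global
Q optimum. It is a test oracle, capped at 12 active nodes (Bell(12) ≈ 4.2
million partitions); the test suite exercises it up to 10.

## Partition comparison

Detected and reference partitions are compared on their shared node set by
the adjusted Rand index (permutation-model chance correction; 0 expected for
unrelated labelings, 1 for identity up to relabeling) and normalized mutual
information with arithmetic-mean normalization — the common default, fixed
explicitly so scores are comparable across tools. Ambiguous reference nodes
and detected isolates are excluded from the scalar scores and listed in the
report, and each detected module is matched to the reference module with
maximal Jaccard overlap. Both metrics are delegated to scikit-learn.

## Synthetic data

The planted-partition generator draws each within-block node pair as an edge
with probability `p_in` and each between-block pair with `p_out`
(defaults 0.9 / 0.02: clearly modular yet noisy, comparable in density
contrast to the anatomical networks the detector targets). The bilateral
generator mirrors the blocks into left and right copies, samples each side
independently, and adds exactly `midline_edges` connectors drawn uniformly
from the cross-side pairs of the designated midline blocks (all blocks by
default; any left node of a block may connect to any right node of the same
block, the strict mirror pair included). Tissue labels are sampled
independently of topology at fraction `tissue_mix` muscle (default 0.75,
echoing the head's 136/181 muscle share) and exist only so tissue subsetting
can be exercised. All sampling flows from one `numpy` generator seeded per
call, so a spec plus seed reproduces the exact edge set.

What the generator does *not* emulate: degree heterogeneity within blocks
(no hubs like the sphenoid or the hyoid), block-size asymmetry of real
module decompositions, tissue-dependent wiring (real muscles attach mostly
to bone), and the bipartite-ish muscle–bone layering of the full
musculoskeletal network. Passing recovery tests therefore demonstrate
correctness of the machinery under clean modular structure, not performance
guarantees on real anatomical tables.

## Problem sizes in the shipped checks

The test suite and the acceptance script run entirely on generated or
packaged data: exhaustive-oracle comparisons use 50 two-block graphs of
6–10 nodes; recovery uses 20 replicates of four 10-node blocks; the
bilateral sweep uses a mirrored 8-block at five midline levels × 25
replicates. These sizes give stable medians and frequencies while keeping
the whole suite in the tens of seconds on one CPU.

## Known limitations

- Weighted or directed contacts, overlapping modules, and resolution-limit
  corrections to Q are out of scope; so is significance testing of Q against
  randomized networks.
- The walktrap dendrogram restricts the candidate partitions; the reported
  max-Q cut is optimal over dendrogram levels, not over all partitions
  (the exhaustive oracle exists precisely to quantify that gap on small
  graphs).
- Full reproduction of the published head decomposition needs the source
  article's supplementary contact list, which is not redistributable here;
  the loader accepts a user-supplied transcription
  (`anna/data/head_edges.csv` or an explicit path).
- Published modularity values for the head networks were produced by a
  particular software version; merge tie-breaking may shift the fourth
  decimal of Q even between faithful implementations, so small |ΔQ| with an
  identical module count should be read as agreement.
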