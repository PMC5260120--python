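# Methods

## Problem and model

A draft genome is a set of contigs whose order and orientation along the
chromosome are unknown. Given one or more complete genomes of related
organisms, each contig can be placed on each reference, and each reference
then proposes an ordering of the contigs. Any single reference can mislead:
rearrangements between target and reference, or a distant phylogenetic
relationship, produce wrong adjacencies. `multiscaf` merges the per-reference
proposals into one consensus set of scaffolds.

Write each contig c as an oriented segment with a tail extremity c_t and a
head extremity c_h; +c means the tail precedes the head in reading
direction. The merging model is a weighted *contig adjacency graph*
G = (V, E) with V = {c_t, c_h | c ∈ T}:

- every pair of extremities from *different* contigs carries exactly one
  edge; extremities of the same contig are never joined;
- when two contigs are consecutive in the scaffolding proposed by reference
  R_i (with weight W_i > 0), the extremity pair they realize gains W_i and
  R_i is recorded as a supporter; an edge's weight is the sum of its
  supporters' weights;
- unsupported pairs are zero-weight *dummy* edges, present only so that a
  perfect matching always exists. They are stored implicitly (absent pair =
  weight 0) and materialized on demand, keeping memory proportional to the
  supported edges.

A perfect matching M of G selects one partner per extremity — a globally
consistent set of adjacencies — and the maximum-weight M is the
best-supported one. With C = {(c_t, c_h) | c ∈ T}, every extremity has
degree 2 in C ∪ M, so C ∪ M is a disjoint union of even, alternating
cycles. Scaffolds are linear, so one matching edge per cycle must go; since
the cycles are vertex-disjoint, removing each cycle's minimum-weight
matching edge removes the minimum possible total weight. The residual M′
induces the final scaffolds: walk each path of C ∪ M′, emitting +c when a
contig is entered at its tail and −c at its head.

The per-reference weights W_i (default 1) encode the user's belief in each
reference's phylogenetic closeness; they only ever enter the method through
the edge-weight sums.

## The per-reference stage

The merging layer is backend-agnostic: it consumes, per reference
chromosome, an ordered and oriented set of scaffolds. Three backends are
provided.

1. **Built-in anchoring + position sorting.** Anchors are maximal exact
   matches seeded by k-mers unique in the contig and unique in the
   reference counting both strands (MUM-like; default k = 15), extended
   maximally, then filtered: drop anchors shorter than `min_len` (default
   2k) and resolve contig overlaps greedily by descending length (ties:
   ascending reference position, '+' first). Each contig's anchors are
   clustered along the reference (a gap of more than `cluster_radius`,
   default 10 kb, between successive anchor midpoints starts a new locus);
   the locus with the most anchored bases wins. The contig's orientation is
   the strand holding the majority of anchored bases there, and its
   position the support-weighted median of the cluster's anchor midpoints.
   Placed contigs, sorted by position (ties by contig id), form one
   scaffold per reference chromosome; unplaced contigs contribute no
   adjacencies.
2. **Imported alignments.** show-coords-style tables from NUCmer or PROmer
   (including the translated-amino-acid mode, which is deliberately not
   re-implemented) are converted row-for-row into anchors and fed into the
   same placement rule.
3. **Imported scaffoldings.** The output of any single-reference
   scaffolder, e.g. one that minimizes a genome rearrangement distance,
   can be loaded from the plain-text scaffold-list format and used as-is.

The built-in scaffolder is intentionally simple — position sorting after
best-locus placement — because the package's contribution is the merging
layer; rearrangement-distance-minimizing ordering belongs to external
tools and enters through backend 3.

## Determinism

The matching solver is networkx's blossom-based `max_weight_matching` on
the dummy-completed graph (maximum cardinality forces perfection);
exactness is enforced in the test suite by exhaustive enumeration on all
instances with ≤ 6 contigs. Three tie situations are resolved to fixed
canonical choices so identical inputs give byte-identical outputs:

- **Equal-weight optimal matchings.** The solver's matching is
  post-processed by weight-preserving two-edge rewirings toward the
  lexicographically smallest sorted pair list (extremities ordered by
  contig id, tail before head); each accepted swap strictly decreases that
  list, so the loop terminates.
- **Equal-weight cycle edges.** Within a cycle, among minimum-weight
  matching edges the one whose maximum incident contig id is largest is
  removed (numeric ids compare numerically).
- **Scaffold reading direction.** Of the two readings of an emitted
  scaffold, the one whose first signed contig is smaller under
  (contig id, '+' < '-') is kept; scaffolds are sorted by first contig.

Dummy edges that survive into M′ are cut before path extraction by
default: they carry no reference support, and emitting them would assert
adjacencies no reference witnessed. `use_dummy=True` restores the literal
"everything in M′ joins" behaviour.

Edge-weight comparisons use an absolute tolerance of 1e-9, ample for sums
of user weights of magnitude ~1.

## Evaluation metrics

The truth is a *reference order*: contigs placed on the finished target
genome by the same best-locus rule, sorted, signed by majority strand;
contigs with no anchors at all are excluded. A join (x, y) in a scaffold is
correct iff (x, y) or (−y, −x) is a consecutive pair of the reference
order; joins touching excluded contigs are false positives. With P = joins
in the reference order, sensitivity = TP/P and precision = TP/(TP+FP).
Genome coverage counts each contig's full length if both its ends have
correct adjacencies, half if one end does, nothing otherwise, over the
total contig length; a scaffold end is never granted a free "correct
adjacency", so a perfect linear scaffolding of n equal contigs scores
(n−1)/n. N50 is the largest scaffold size L such that scaffolds of size
≥ L contain at least half the assembly; sizes exclude gaps unless a gap
length is supplied. Degenerate cases are flagged explicitly: with no joins
at all precision is reported as 1.0 with `no_joins=True`, and with P = 0
sensitivity is reported as 1.0 with `no_true_joins=True`, rather than NaN.

## Synthetic data

`simulate_truth` draws a uniform-random genome and tiles it with contigs:
each contig gets `min_contig_len` bases plus a multinomial share of the
spare length, and consecutive contigs are separated by `inter_contig_gap`
unassembled bases. Half of the contigs are stored reverse-complemented and
signed '−' in the recorded truth. `simulate_reference` derives each
reference by the stated number of uniform random segment reversals and
block interchanges (two disjoint segments swapped; breakpoints drawn by
rejection until distinct) followed by independent point substitutions.

Defaults: 200 kb genome, 20 contigs, 5 references, 3 reversals + 1 block
interchange per reference, 0.5 % point mutations, `min_contig_len` 2 kb,
gap 100 bp. These sizes emulate a small prokaryotic draft (contig N50
around 10 kb) while letting the full simulate–scaffold–evaluate loop run
in a few seconds, so replicated studies stay desk-scale.

What the generator does **not** emulate: indels and duplications, repeat
content (contigs are unique by construction, so anchoring is nearly
noise-free), assembly chimerism, uneven reference divergence, and
phylogenetic correlation among references (each is an independent draw
from the truth). Passing the recovery and trend tests therefore shows the
combinatorial machinery is correct and that multiple references help under
the modelled rearrangement noise — not that the built-in anchorer matches
a production aligner on repeat-rich real genomes, which is what the coords
import path is for.

## Known limitations

- The built-in anchorer requires unique seeds on both sides; heavily
  repetitive targets should use imported NUCmer/PROmer alignments.
- The blossom matching is exact but O(n³)-ish in the number of extremities;
  hundreds of contigs are fine, tens of thousands are not the design point.
- Each reference chromosome is processed independently; multi-chromosome
  references are supported simply as multi-record FASTA files.
- `cluster_radius` is a genuinely free parameter of the placement rule;
  10 kb suits prokaryote-scale rearrangement spacing, and contigs anchored
  at several loci within one radius are placed at their dominant locus.
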