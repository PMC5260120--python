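# multiscaf

Multi-reference contig scaffolding: order and orient the contigs of a draft
genome using several complete genomes of related organisms at once, without
paired-end libraries or a phylogenetic tree.

A single reference genome can mislead a scaffolder whenever the target and
the reference differ by rearrangements or are phylogenetically distant.
`multiscaf` lets every reference vote. Each reference chromosome R_i (with a
user weight W_i > 0, default 1) proposes an ordering of the contigs; the
proposals are merged on a **contig adjacency graph** whose vertices are the
tail/head extremities c_t, c_h of every contig c, and whose edge between two
extremities of different contigs weighs the summed weights of the references
supporting that adjacency (zero-weight dummy edges complete the graph). A
**maximum-weight perfect matching** M picks one partner per extremity; with
C = {(c_t, c_h)}, the union C ∪ M decomposes into disjoint cycles, from
each of which the minimum-weight matching edge is removed; the acyclic
residual M′ spells out the final scaffolds, reading +c when a contig is
entered at its tail and −c at its head. Everything is polynomial and exact —
no NP-hard subproblem, no heuristic search.

The package also ships the standard scaffold-evaluation metrics
(sensitivity TP/P, precision TP/(TP+FP), half/whole-length genome coverage,
scaffold count, N50) and a synthetic-data simulator that fragments a random
genome into contigs and derives references from it by segment reversals and
block interchanges, so the whole pipeline can be scored against a known
truth.

It is aimed at people finishing small (prokaryote-scale) genomes who have
several related complete genomes at hand, and at anyone who wants a tested,
deterministic implementation of extremity-matching scaffold merging to
build on.

## Worked example

Four references, equal weight 1, each proposing a scaffolding of the four
contigs {1, 2, 3, 4} (scaffold-list files: one signed contig per line under
a `>scaffold_i` header):

    S1 = (+1,+2,+3)   S2 = (+2,+3,+4)   S3 = (−1,−4,−3,−2)   S4 = (+1,−4,+2,−3)

```bash
multiscaf scaffold -c contigs.fasta -r R1.txt -r R2.txt -r R3.txt -r R4.txt -o out
```

prints

```
adjacency graph: 4 contigs, 7 supported edges (total weight 10)
maximum matching weight: 7
cycles in C∪M: 1
edges removed: 1t-4h (w=1)
residual weight: 6
scaffolds: (+1,+2,+3,+4)
```

Reading the log: the four proposals realize seven distinct adjacencies
(e.g. 2h–3t is supported by three references, weight 3; 1t–4h only by S3,
weight 1). The maximum-weight perfect matching
{(1t,4h), (1h,2t), (2h,3t), (3h,4t)} has weight 7 but closes one cycle
through all eight extremities, so its cheapest edge (1t,4h) is dropped;
the residual joins spell the single scaffold (+1,+2,+3,+4). `out/` then
contains `scaffolds.txt` (scaffold list), `scaffolds.agp` (AGP v2.1),
`scaffolds.fasta` (contigs joined by N-gaps), `graph.tsv` and `run.log`.

References can also be given as FASTA (`-r ref.fasta[:weight]`, anchored
with the built-in unique-k-mer anchorer), as MUMmer `show-coords` tables
(`-r aln.coords`), or as scaffold lists from any external single-reference
scaffolder — mixed freely, or listed in a YAML config (`--config run.yaml`).

A full synthetic round trip:

```bash
multiscaf simulate -o ds --seed 7
multiscaf scaffold -c ds/contigs.fasta -r ds/ref_1.fasta -r ds/ref_2.fasta \
    -r ds/ref_3.fasta -r ds/ref_4.fasta -r ds/ref_5.fasta -o out
multiscaf evaluate -s out/scaffolds.txt -t ds/truth_order.txt -c ds/contigs.fasta -o eval
```

`eval/report.json` holds TP/FP/P, sensitivity, precision, genome coverage,
scaffold count and N50.

## Library layout

| module | contents |
| --- | --- |
| `multiscaf.formats` | FASTA, show-coords tables, scaffold lists, AGP v2.1 |
| `multiscaf.anchors` | built-in unique-k-mer anchorer, filtering, coords import |
| `multiscaf.single_ref` | per-reference placement, ordering, external scaffolding import |
| `multiscaf.adjacency_graph` | extremities, weighted adjacency edges, graph construction |
| `multiscaf.matcher` | maximum-weight perfect matching, cycle breaking, scaffold emission |
| `multiscaf.evaluation` | reference order, TP/FP, sensitivity, precision, coverage, N50 |
| `multiscaf.synthetic` | truth genomes, rearranged references, dataset writer |
| `multiscaf.pipeline`, `multiscaf.cli` | orchestration and the `multiscaf` command |

See `docs/methods.md` for the model, tie-breaking rules, simulator
assumptions and known limitations.
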