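"""Independent brute-force oracles for the matching/cycle-breaking stage.

These enumerate exhaustively and never call the code paths they check.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx

from multiscaf.adjacency_graph import (
    ContigAdjacencyGraph,
    Extremity,
    build_graph,
    make_pair,
)
from multiscaf.scaffolds import SignedContig
from multiscaf.single_ref import ReferenceScaffolding


def ext(token: str) -> Extremity:
    """'12h' -> Extremity('12', 'h')."""
    return Extremity(token[:-1], token[-1])


def all_perfect_matchings(vertices, same_contig):
    """Yield every perfect matching (as a frozenset of canonical pairs) of a
    complete graph on `vertices` minus intra-contig pairs."""
    vertices = sorted(vertices, key=Extremity.key)

    def rec(remaining):
        if not remaining:
            yield frozenset()
            return
        v = remaining[0]
        for u in remaining[1:]:
            if same_contig(v, u):
                continue
            rest = [x for x in remaining[1:] if x != u]
            for m in rec(rest):
                yield m | {make_pair(v, u)}

    yield from rec(vertices)


def brute_max_matching_weight(g: ContigAdjacencyGraph) -> float:
    best = None
    for m in all_perfect_matchings(g.vertices(), lambda a, b: a.contig_id == b.contig_id):
        w = sum(g.edge(u, v).weight for u, v in m)
        if best is None or w > best:
            best = w
    return best


def brute_min_removal_weight(matching_pairs, contigs, g: ContigAdjacencyGraph) -> float:
    """Minimum total weight of matching edges whose removal makes
    C ∪ (M - removed) acyclic, by exhausting all subsets of M."""
    pairs = sorted(matching_pairs, key=lambda p: (p[0].key(), p[1].key()))
    c_edges = [(Extremity(c, "t"), Extremity(c, "h")) for c in contigs]
    best = None
    for r in range(len(pairs) + 1):
        for removed in combinations(pairs, r):
            kept = [p for p in pairs if p not in removed]
            G = nx.Graph()
            G.add_nodes_from(Extremity(c, e) for c in contigs for e in "th")
            G.add_edges_from(c_edges)
            G.add_edges_from(kept)
            if nx.is_forest(G):
                w = sum(g.edge(u, v).weight for u, v in removed)
                if best is None or w < best:
                    best = w
    return best


def random_instance(rng, n_max: int = 6):
    """A random multi-reference scaffolding problem: n contigs, 1-4 weighted
    references, each splitting a random signed permutation into scaffolds."""
    n = int(rng.integers(2, n_max + 1))
    contigs = [str(i) for i in range(1, n + 1)]
    k = int(rng.integers(1, 5))
    scaffoldings = []
    for i in range(k):
        perm = list(rng.permutation(contigs))
        signs = rng.choice(["+", "-"], size=n)
        signed = [SignedContig(c, s) for c, s in zip(perm, signs)]
        # split into 1..n scaffolds at random cut points
        n_cuts = int(rng.integers(0, n))
        cuts = sorted(rng.choice(range(1, n), size=n_cuts, replace=False).tolist()) if n_cuts else []
        scaffolds, prev = [], 0
        for c in cuts + [n]:
            scaffolds.append(tuple(signed[prev:c]))
            prev = c
        weight = float(rng.integers(1, 4))
        scaffoldings.append(ReferenceScaffolding(f"R{i + 1}", weight, scaffolds))
    return set(contigs), scaffoldings, build_graph(scaffoldings, set(contigs))
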