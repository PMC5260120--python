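"""Maximum-weight perfect matching and cycle breaking.

The best-supported global set of contig adjacencies is a maximum-weight
perfect matching M of the contig adjacency graph (dummy edges make one
exist for n >= 2). Joining M with the intra-contig pairs
C = {(c_t, c_h)} gives every extremity degree 2, so C ∪ M decomposes into
vertex-disjoint alternating cycles; a scaffold must be linear, so from each
cycle the minimum-weight matching edge is removed, which is globally
optimal because the cycles are disjoint. The residual M' induces the final
scaffolds.

Any exact matching solver is acceptable; this module uses networkx's
blossom implementation and enforces correctness by brute-force enumeration
in the test suite. Ties between optimal matchings are resolved to a
canonical representative so results are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from ._util import contig_sort_key
from .adjacency_graph import (
    HEAD,
    TAIL,
    AdjacencyEdge,
    ContigAdjacencyGraph,
    Extremity,
    Pair,
    make_pair,
)
from .errors import UserInputError
from .scaffolds import Scaffold, SignedContig, canonical_direction

_EPS = 1e-9


@dataclass
class PerfectMatching:
    """A perfect matching M: every extremity incident to exactly one edge."""

    edges: list[AdjacencyEdge]
    total_weight: float

    def pairs(self) -> set[Pair]:
        return {e.pair for e in self.edges}

    def mate(self) -> dict[Extremity, Extremity]:
        out = {}
        for e in self.edges:
            out[e.u] = e.v
            out[e.v] = e.u
        return out


@dataclass
class CyclePartition:
    """The alternating cycles of C ∪ M, as extremity sequences.

    Each cycle lists its vertices in traversal order starting from its
    smallest extremity; consecutive vertices alternate C-edges (positions
    0-1, 2-3, ...) and M-edges (1-2, 3-4, ..., last-first)."""

    cycles: list[list[Extremity]]

    def matching_edges(self, cycle: list[Extremity]) -> list[Pair]:
        pairs = [make_pair(cycle[i], cycle[i + 1]) for i in range(1, len(cycle) - 1, 2)]
        pairs.append(make_pair(cycle[-1], cycle[0]))
        return pairs


def _swap_candidates(e1: Pair, e2: Pair):
    (a, b), (c, d) = e1, e2
    for p, q in (((a, c), (b, d)), ((a, d), (b, c))):
        if p[0].contig_id != p[1].contig_id and q[0].contig_id != q[1].contig_id:
            yield make_pair(*p), make_pair(*q)


def _canonicalize(pairs: set[Pair], g: ContigAdjacencyGraph) -> set[Pair]:
    """Among equal-weight matchings reachable by 2-edge rewirings, move to
    the one with the lexicographically smallest sorted pair list.

    A cheap local test: whenever rewiring two matching edges preserves total
    weight, prefer the smaller configuration. Terminates because each
    accepted swap strictly decreases the sorted pair list."""

    def w(p: Pair) -> float:
        return g.edge(*p).weight

    improved = True
    while improved:
        improved = False
        plist = sorted(pairs, key=lambda p: (p[0].key(), p[1].key()))
        for i in range(len(plist)):
            for j in range(i + 1, len(plist)):
                e1, e2 = plist[i], plist[j]
                cur_w = w(e1) + w(e2)
                for f1, f2 in _swap_candidates(e1, e2):
                    if abs(w(f1) + w(f2) - cur_w) > _EPS:
                        continue
                    candidate = (pairs - {e1, e2}) | {f1, f2}
                    if sorted(candidate, key=lambda p: (p[0].key(), p[1].key())) < plist:
                        pairs = candidate
                        improved = True
                        break
                if improved:
                    break
            if improved:
                break
    return pairs


def max_weight_perfect_matching(g: ContigAdjacencyGraph) -> PerfectMatching:
    """Exact maximum-weight perfect matching of the adjacency graph.

    Dummy edges participate with weight 0, so a perfect matching always
    exists for n >= 2. Among optimal matchings the canonical representative
    (smallest sorted extremity-pair list) is returned.
    """
    if g.n == 0:
        return PerfectMatching([], 0.0)
    if g.n == 1:
        raise UserInputError("matching needs n >= 2 contigs; handle singletons upstream")
    G = nx.Graph()
    for e in g.all_edges():
        G.add_edge(e.u, e.v, weight=e.weight)
    mate = nx.max_weight_matching(G, maxcardinality=True)
    pairs = {make_pair(u, v) for u, v in mate}
    if len(pairs) != g.n:
        raise AssertionError("solver returned a non-perfect matching")
    pairs = _canonicalize(pairs, g)
    edges = [g.edge(u, v) for u, v in sorted(pairs, key=lambda p: (p[0].key(), p[1].key()))]
    return PerfectMatching(edges, sum(e.weight for e in edges))


def decompose_cycles(m: PerfectMatching, contigs: set[str]) -> CyclePartition:
    """Split C ∪ M into its alternating cycles.

    Every extremity has exactly one C-edge (its partner on the same contig)
    and one M-edge, so the union is a disjoint cycle cover of all 2n
    extremities; cycles have even length.
    """
    mate = m.mate()
    vertices = sorted(
        (Extremity(c, e) for c in contigs for e in (TAIL, HEAD)), key=Extremity.key
    )
    missing = [v for v in vertices if v not in mate]
    if missing or len(mate) != 2 * len(contigs):
        raise UserInputError(f"matching is not perfect on the contig set (unmatched: {missing})")
    seen: set[Extremity] = set()
    cycles = []
    for start in vertices:
        if start in seen:
            continue
        cycle = []
        cur = start
        while True:
            cycle.append(cur)
            seen.add(cur)
            partner = cur.partner()  # C-edge
            cycle.append(partner)
            seen.add(partner)
            cur = mate[partner]  # M-edge
            if cur == start:
                break
        cycles.append(cycle)
    return CyclePartition(cycles)


def _removal_choice(pairs: list[Pair], g: ContigAdjacencyGraph) -> Pair:
    """Which matching edge of one cycle to remove: minimum weight; among
    ties, the edge whose maximum incident contig id is largest (numeric ids
    compare numerically)."""
    min_w = min(g.edge(*p).weight for p in pairs)
    ties = [p for p in pairs if g.edge(*p).weight <= min_w + _EPS]

    def tie_key(p: Pair):
        ck = sorted((contig_sort_key(p[0].contig_id), contig_sort_key(p[1].contig_id)), reverse=True)
        return (ck[0], ck[1], p[0].key(), p[1].key())

    return max(ties, key=tie_key)


@dataclass
class ResidualMatching:
    """M' = M minus one minimum-weight edge per cycle; C ∪ M' is acyclic."""

    edges: list[AdjacencyEdge]
    removed: list[AdjacencyEdge]
    removed_weight: float
    total_weight: float


def break_cycles(m: PerfectMatching, cp: CyclePartition, g: ContigAdjacencyGraph) -> ResidualMatching:
    """Remove, per cycle, the minimum-weight matching edge.

    Cycles are vertex-disjoint, so removing each cycle's cheapest edge
    removes the minimum total weight over all edge sets whose removal makes
    C ∪ M' acyclic.
    """
    to_remove: set[Pair] = set()
    for cycle in cp.cycles:
        to_remove.add(_removal_choice(cp.matching_edges(cycle), g))
    kept = [e for e in m.edges if e.pair not in to_remove]
    removed = [e for e in m.edges if e.pair in to_remove]
    return ResidualMatching(
        edges=kept,
        removed=removed,
        removed_weight=sum(e.weight for e in removed),
        total_weight=sum(e.weight for e in kept),
    )


def emit_scaffolds(
    m_prime: ResidualMatching | list[AdjacencyEdge],
    contigs: set[str],
    use_dummy: bool = False,
) -> list[Scaffold]:
    """Turn the acyclic residual C ∪ M' into signed-contig scaffolds.

    Each path becomes one scaffold: entering a contig at its tail reads +c,
    at its head -c. By default dummy edges are cut first, so only
    reference-supported joins appear; ``use_dummy=True`` keeps them. Every
    contig appears in exactly one scaffold; each scaffold is emitted in its
    canonical direction and scaffolds are sorted by their first contig.
    """
    edges = m_prime.edges if isinstance(m_prime, ResidualMatching) else list(m_prime)
    if not use_dummy:
        edges = [e for e in edges if not e.dummy]
    mate: dict[Extremity, Extremity] = {}
    for e in edges:
        mate[e.u] = e.v
        mate[e.v] = e.u

    visited: set[str] = set()
    scaffolds: list[Scaffold] = []
    for start in sorted(
        (Extremity(c, e) for c in contigs for e in (TAIL, HEAD)), key=Extremity.key
    ):
        if start.contig_id in visited or start in mate:
            continue  # interior extremity or contig already emitted
        chain: list[SignedContig] = []
        cur = start
        while True:
            visited.add(cur.contig_id)
            chain.append(SignedContig(cur.contig_id, "+" if cur.end == TAIL else "-"))
            exit_ext = cur.partner()
            nxt = mate.get(exit_ext)
            if nxt is None:
                break
            if nxt.contig_id in visited:
                raise AssertionError("cycle encountered; residual matching is not acyclic")
            cur = nxt
        scaffolds.append(canonical_direction(tuple(chain)))
    if visited != set(contigs):
        raise AssertionError("scaffolds do not partition the contig set")
    scaffolds.sort(key=lambda s: (contig_sort_key(s[0].contig_id), s[0].strand))
    return scaffolds
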