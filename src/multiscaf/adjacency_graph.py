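"""The contig adjacency graph.

Every contig contributes two vertices, its tail and head extremities. Each
per-reference scaffolding votes for the extremity pairs its consecutive
contigs realize; an edge's weight is the sum of the weights of the
references supporting it. Every remaining inter-contig extremity pair is a
zero-weight dummy edge, present so a perfect matching always exists; dummy
edges are stored implicitly (any absent pair is weight 0) but reported by
the accessors, keeping memory proportional to the real edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterator, NamedTuple

from ._util import contig_sort_key
from .errors import UserInputError
from .scaffolds import Scaffold
from .single_ref import ReferenceScaffolding

TAIL = "t"
HEAD = "h"


class Extremity(NamedTuple):
    """One end of a contig: its tail (t) or head (h)."""

    contig_id: str
    end: str

    def key(self):
        return (contig_sort_key(self.contig_id), 0 if self.end == TAIL else 1)

    def partner(self) -> "Extremity":
        """The other extremity of the same contig (the C-edge partner)."""
        return Extremity(self.contig_id, HEAD if self.end == TAIL else TAIL)

    def __str__(self) -> str:
        return f"{self.contig_id}{self.end}"


#: Unordered extremity pair, canonically ordered by Extremity.key.
Pair = tuple[Extremity, Extremity]


def make_pair(u: Extremity, v: Extremity) -> Pair:
    if u.contig_id == v.contig_id:
        raise UserInputError(f"no edge may join two extremities of contig {u.contig_id!r}")
    return (u, v) if u.key() <= v.key() else (v, u)


@dataclass(frozen=True)
class AdjacencyEdge:
    u: Extremity
    v: Extremity
    weight: float
    supports: frozenset[str]
    dummy: bool

    @property
    def pair(self) -> Pair:
        return make_pair(self.u, self.v)


def scaffold_adjacencies(s: Scaffold) -> list[Pair]:
    """Extremity pairs realized by consecutive contigs of one scaffold.

    Reading left to right, +c exposes its tail first and head last, -c the
    reverse; each join connects the right end of one contig to the left end
    of the next. A singleton scaffold yields no pairs.
    """
    ids = [sc.contig_id for sc in s]
    if len(set(ids)) != len(ids):
        raise UserInputError(f"scaffold repeats a contig: {ids}")
    pairs = []
    for a, b in zip(s, s[1:]):
        right = Extremity(a.contig_id, HEAD if a.strand == "+" else TAIL)
        left = Extremity(b.contig_id, TAIL if b.strand == "+" else HEAD)
        pairs.append(make_pair(right, left))
    return pairs


@dataclass
class ContigAdjacencyGraph:
    """Weighted graph on contig extremities; dummies implicit."""

    contigs: set[str]
    _edges: dict[Pair, tuple[float, set[str]]] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.contigs)

    def vertices(self) -> list[Extremity]:
        out = [Extremity(c, e) for c in self.contigs for e in (TAIL, HEAD)]
        return sorted(out, key=Extremity.key)

    def add_support(self, u: Extremity, v: Extremity, ref_id: str, weight: float) -> None:
        for x in (u, v):
            if x.contig_id not in self.contigs:
                raise UserInputError(f"scaffolding mentions unknown contig {x.contig_id!r}")
        pair = make_pair(u, v)
        w, supports = self._edges.setdefault(pair, (0.0, set()))
        if ref_id in supports:
            raise UserInputError(
                f"reference {ref_id!r} supports extremity pair {u}-{v} twice"
            )
        supports.add(ref_id)
        self._edges[pair] = (w + weight, supports)

    def edge(self, u: Extremity, v: Extremity) -> AdjacencyEdge:
        """The unique edge on this inter-contig pair; a dummy if unsupported."""
        pair = make_pair(u, v)
        w, supports = self._edges.get(pair, (0.0, set()))
        return AdjacencyEdge(pair[0], pair[1], w, frozenset(supports), not supports)

    def real_edges(self) -> list[AdjacencyEdge]:
        return [
            AdjacencyEdge(p[0], p[1], w, frozenset(s), False)
            for p, (w, s) in sorted(self._edges.items(), key=lambda kv: (kv[0][0].key(), kv[0][1].key()))
        ]

    def all_edges(self) -> Iterator[AdjacencyEdge]:
        """Every inter-contig extremity pair, dummies included."""
        for u, v in combinations(self.vertices(), 2):
            if u.contig_id != v.contig_id:
                yield self.edge(u, v)

    def edge_count(self) -> int:
        """|E| counting dummies: C(2n,2) minus the n intra-contig pairs."""
        return self.n * (2 * self.n - 1) - self.n

    def total_real_weight(self) -> float:
        return sum(w for w, _ in self._edges.values())

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("u\tv\tweight\tsupports\tdummy\n")
            for e in self.real_edges():
                fh.write(
                    f"{e.u}\t{e.v}\t{e.weight:g}\t{','.join(sorted(e.supports))}\t{e.dummy}\n"
                )


def build_graph(
    scaffoldings: list[ReferenceScaffolding], contigs: set[str]
) -> ContigAdjacencyGraph:
    """Accumulate the adjacency votes of all per-reference scaffoldings.

    Each adjacency supported by reference R_i adds W_i to its edge weight and
    R_i to its support set; the result is independent of the order of the
    scaffoldings.
    """
    if not scaffoldings:
        raise UserInputError("at least one reference scaffolding is required")
    g = ContigAdjacencyGraph(set(contigs))
    for rs in scaffoldings:
        unknown = sorted(rs.contig_ids() - g.contigs)
        if unknown:
            raise UserInputError(
                f"scaffolding of {rs.ref_id!r} mentions unknown contigs: {', '.join(unknown)}"
            )
        for s in rs.scaffolds:
            for u, v in scaffold_adjacencies(s):
                g.add_support(u, v, rs.ref_id, rs.weight)
    return g
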