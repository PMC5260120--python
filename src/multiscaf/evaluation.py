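"""Scoring scaffolds against a known truth.

The truth is a *reference order*: the contigs of the (actually finished)
target genome, ordered and signed by where they map on the complete
sequence; contigs that do not map at all are excluded. A contig join (x, y)
in a scaffold is correct iff (x, y) — or its reverse reading (-y, -x) —
appears consecutively in the reference order. From the correct/incorrect
joins follow sensitivity TP/P, precision TP/(TP+FP), the half/whole-length
genome coverage rule, scaffold count and N50.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._util import contig_sort_key
from .anchors import AnchorSet
from .errors import UserInputError
from .scaffolds import Scaffold, SignedContig, scaffold_joins
from .single_ref import DEFAULT_CLUSTER_RADIUS, place_contigs


@dataclass
class ReferenceOrder:
    """Ordered signed contigs of the true genome, plus the unmapped ones."""

    order: Scaffold
    excluded: set[str] = field(default_factory=set)

    def __post_init__(self):
        ids = [sc.contig_id for sc in self.order]
        if len(set(ids)) != len(ids):
            raise UserInputError("reference order repeats a contig")
        if set(ids) & self.excluded:
            raise UserInputError("a contig cannot be both ordered and excluded")

    @property
    def p(self) -> int:
        """Number of contig joins in the reference order."""
        return max(0, len(self.order) - 1)

    def correct_pairs(self) -> set[tuple[SignedContig, SignedContig]]:
        out = set()
        for x, y in scaffold_joins(self.order):
            out.add((x, y))
            out.add((y.negate(), x.negate()))
        return out


def derive_reference_order(
    aset: AnchorSet,
    contig_ids: set[str] | list[str],
    cluster_radius: float = DEFAULT_CLUSTER_RADIUS,
) -> ReferenceOrder:
    """Truth from anchors against the complete genome: contigs sorted by
    best-locus position with majority-strand signs; unanchored contigs are
    excluded from the order."""
    placements = place_contigs(aset, contig_ids, cluster_radius)
    placed = sorted(
        (p for p in placements if p.placed),
        key=lambda p: (p.position, contig_sort_key(p.contig_id)),
    )
    return ReferenceOrder(
        order=tuple(SignedContig(p.contig_id, p.orientation) for p in placed),
        excluded={p.contig_id for p in placements if not p.placed},
    )


def classify_joins(scaffolds: list[Scaffold], ro: ReferenceOrder) -> tuple[int, int, int]:
    """(TP, FP, P): correct joins, incorrect joins, joins in the truth.

    A join is correct iff its two signed contigs appear consecutively, in
    that orientation, in the reference order read in either direction. Joins
    involving excluded contigs are false positives.
    """
    correct = ro.correct_pairs()
    tp = fp = 0
    for s in scaffolds:
        for join in scaffold_joins(s):
            if join in correct:
                tp += 1
            else:
                fp += 1
    return tp, fp, ro.p


def genome_coverage(
    scaffolds: list[Scaffold], ro: ReferenceOrder, lengths: dict[str, int]
) -> float:
    """Length-weighted fraction of contigs held in place by correct joins.

    A contig with correct adjacencies at both ends contributes its whole
    length, with one correct end half its length, otherwise nothing; the
    denominator is the total length of all contigs in the scaffolds.
    """
    correct = ro.correct_pairs()
    credit: dict[str, int] = {}
    total = 0
    for s in scaffolds:
        for sc in s:
            if sc.contig_id not in lengths:
                raise UserInputError(f"no length known for contig {sc.contig_id!r}")
            total += lengths[sc.contig_id]
            credit.setdefault(sc.contig_id, 0)
        for x, y in scaffold_joins(s):
            if (x, y) in correct:
                credit[x.contig_id] += 1
                credit[y.contig_id] += 1
    if total == 0:
        raise UserInputError("empty scaffold set")
    covered = sum(
        lengths[cid] if ends >= 2 else (lengths[cid] / 2 if ends == 1 else 0)
        for cid, ends in credit.items()
    )
    return covered / total


def scaffold_sizes(
    scaffolds: list[Scaffold], lengths: dict[str, int], gap_len: int = 0
) -> list[int]:
    sizes = []
    for s in scaffolds:
        for sc in s:
            if sc.contig_id not in lengths:
                raise UserInputError(f"no length known for contig {sc.contig_id!r}")
        sizes.append(sum(lengths[sc.contig_id] for sc in s) + gap_len * (len(s) - 1))
    return sizes


def n50(scaffolds: list[Scaffold], lengths: dict[str, int], gap_len: int = 0) -> int:
    """Largest scaffold size L such that scaffolds of size >= L hold at
    least half the assembly. Gaps are excluded from sizes unless gap_len
    is set."""
    sizes = sorted(scaffold_sizes(scaffolds, lengths, gap_len), reverse=True)
    if not sizes:
        raise UserInputError("N50 of an empty scaffold set is undefined")
    half = sum(sizes) / 2
    acc = 0
    for size in sizes:
        acc += size
        if acc >= half:
            return size
    return sizes[-1]


@dataclass
class EvaluationReport:
    tp: int
    fp: int
    p: int
    sensitivity: float
    precision: float
    genome_coverage: float
    scaffold_count: int
    n50: int
    no_joins: bool = False  # TP+FP = 0: precision undefined, reported as 1
    no_true_joins: bool = False  # P = 0: sensitivity undefined, reported as 1

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "p": self.p,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "genome_coverage": self.genome_coverage,
            "scaffold_count": self.scaffold_count,
            "n50": self.n50,
            "no_joins": self.no_joins,
            "no_true_joins": self.no_true_joins,
        }

    def to_tsv(self, path) -> None:
        d = self.to_dict()
        with open(path, "w") as fh:
            fh.write("\t".join(d.keys()) + "\n")
            fh.write("\t".join(str(v) for v in d.values()) + "\n")


def evaluate(
    scaffolds: list[Scaffold],
    ro: ReferenceOrder,
    lengths: dict[str, int],
    gap_len: int = 0,
) -> EvaluationReport:
    """All metrics in one report."""
    tp, fp, p = classify_joins(scaffolds, ro)
    no_joins = (tp + fp) == 0
    no_true = p == 0
    return EvaluationReport(
        tp=tp,
        fp=fp,
        p=p,
        sensitivity=1.0 if no_true else tp / p,
        precision=1.0 if no_joins else tp / (tp + fp),
        genome_coverage=genome_coverage(scaffolds, ro, lengths),
        scaffold_count=len(scaffolds),
        n50=n50(scaffolds, lengths, gap_len),
        no_joins=no_joins,
        no_true_joins=no_true,
    )
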