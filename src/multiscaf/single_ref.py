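"""Per-reference ordering and orientation of contigs.

For each reference chromosome the contigs are placed at the locus where they
gain the most anchored bases, oriented by majority strand, and sorted by
position into one scaffold. This position-based scaffolder is the built-in
backend; :func:`load_external_scaffolding` plugs in the output of any other
single-reference scaffolder via the scaffold-list format, so the
multi-reference merging layer stays backend-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._util import contig_sort_key
from .anchors import Anchor, AnchorSet
from .errors import UserInputError
from .formats import read_scaffold_list
from .scaffolds import Scaffold, SignedContig

DEFAULT_CLUSTER_RADIUS = 10_000


@dataclass
class ContigPlacement:
    """Where (and whether) one contig lands on one reference."""

    contig_id: str
    ref_id: str
    placed: bool
    position: float = 0.0  # support-weighted median of anchor midpoints
    orientation: str = "+"
    support: int = 0  # total anchored bases at the winning locus

    def __post_init__(self):
        if self.placed and self.support <= 0:
            raise ValueError("a placed contig must have positive support")


@dataclass
class ReferenceScaffolding:
    """The scaffolds one reference chromosome induces, with its weight."""

    ref_id: str
    weight: float
    scaffolds: list[Scaffold] = field(default_factory=list)

    def __post_init__(self):
        if not self.weight > 0:
            raise UserInputError(
                f"reference weight must be a positive real, got {self.weight}"
            )
        seen: set[str] = set()
        for s in self.scaffolds:
            for sc in s:
                if sc.contig_id in seen:
                    raise UserInputError(
                        f"contig {sc.contig_id!r} appears twice in scaffolding of {self.ref_id!r}"
                    )
                seen.add(sc.contig_id)

    def contig_ids(self) -> set[str]:
        return {sc.contig_id for s in self.scaffolds for sc in s}


def _clusters(anchors: list[Anchor], radius: float) -> list[list[Anchor]]:
    """Group anchors by reference midpoint; a gap > radius starts a new locus."""
    ordered = sorted(anchors, key=lambda a: (a.ref_midpoint, a.contig_interval))
    out: list[list[Anchor]] = []
    prev_mid = None
    for a in ordered:
        if prev_mid is None or a.ref_midpoint - prev_mid > radius:
            out.append([])
        out[-1].append(a)
        prev_mid = a.ref_midpoint
    return out


def _weighted_median(values_weights: list[tuple[float, int]]) -> float:
    """Weighted median: smallest value whose cumulative weight reaches half."""
    ordered = sorted(values_weights)
    total = sum(w for _, w in ordered)
    acc = 0
    for v, w in ordered:
        acc += w
        if 2 * acc >= total:
            return v
    return ordered[-1][0]


def place_contigs(
    aset: AnchorSet,
    contig_ids: set[str] | list[str],
    cluster_radius: float = DEFAULT_CLUSTER_RADIUS,
) -> list[ContigPlacement]:
    """Place each contig on the reference at its best-supported locus.

    The anchor set must concern a single reference. A contig with no anchors
    is unplaced. Otherwise its anchors are clustered along the reference
    (``cluster_radius`` bp between midpoints); the cluster with the greatest
    total anchored length wins, the orientation is the strand carrying more
    anchored bases there, and the position is the support-weighted median of
    the cluster's anchor midpoints.
    """
    refs = aset.ref_ids()
    if len(refs) > 1:
        raise UserInputError(f"anchor set spans several references: {sorted(refs)}")
    ref_id = next(iter(refs)) if refs else ""
    by_contig = {cid: [] for cid in contig_ids}
    for a in aset:
        if a.contig_id not in by_contig:
            raise UserInputError(f"anchor names unknown contig {a.contig_id!r}")
        by_contig[a.contig_id].append(a)

    placements = []
    for cid in sorted(by_contig, key=contig_sort_key):
        group = by_contig[cid]
        if not group:
            placements.append(ContigPlacement(cid, ref_id, placed=False))
            continue
        clusters = _clusters(group, cluster_radius)
        best = max(clusters, key=lambda cl: (sum(a.length for a in cl), -cl[0].ref_midpoint))
        support = sum(a.length for a in best)
        fwd = sum(a.length for a in best if a.strand == "+")
        rev = support - fwd
        orientation = "-" if rev > fwd else "+"
        position = _weighted_median([(a.ref_midpoint, a.length) for a in best])
        placements.append(
            ContigPlacement(cid, ref_id, True, position, orientation, support)
        )
    return placements


def order_and_orient(
    placements: list[ContigPlacement], weight: float, ref_id: str | None = None
) -> ReferenceScaffolding:
    """Sort placed contigs by position into one signed scaffold.

    Unplaced contigs are omitted: they contribute no adjacencies. Position
    ties break by contig id.
    """
    if ref_id is None:
        ref_id = placements[0].ref_id if placements else ""
    placed = sorted(
        (p for p in placements if p.placed),
        key=lambda p: (p.position, contig_sort_key(p.contig_id)),
    )
    scaffold = tuple(SignedContig(p.contig_id, p.orientation) for p in placed)
    return ReferenceScaffolding(ref_id, weight, [scaffold] if scaffold else [])


def load_external_scaffolding(
    path,
    weight: float,
    ref_id: str | None = None,
    known_contigs: set[str] | None = None,
) -> ReferenceScaffolding:
    """Wrap a scaffold-list file (e.g. the output of an external
    single-reference scaffolder) as a weighted reference scaffolding."""
    scaffolds = read_scaffold_list(path)
    if known_contigs is not None:
        unknown = sorted(
            {sc.contig_id for s in scaffolds for sc in s} - set(known_contigs)
        )
        if unknown:
            raise UserInputError(
                f"scaffold list {path} references unknown contigs: {', '.join(unknown)}"
            )
    return ReferenceScaffolding(ref_id or str(path), weight, scaffolds)
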