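"""Conserved-marker (anchor) detection between contigs and references.

The built-in anchorer finds maximal exact matches seeded by k-mers that are
unique in the contig and unique in the reference (counting both strands),
in the spirit of MUM-based aligners. It is deterministic and dependency
free. Alignments produced externally (NUCmer/PROmer via show-coords tables,
including translated-protein anchoring) enter through
:func:`anchors_from_coords` instead.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from ._util import revcomp
from .errors import UserInputError
from .formats import CoordsRow, FastaRecord

DEFAULT_K = 15


@dataclass(frozen=True)
class Anchor:
    """One marker occurrence: a local match between a contig and a reference.

    Intervals are 0-based half-open in their own sequence's forward
    coordinates; ``strand`` says whether the contig segment matches the
    reference forward (+) or reverse complemented (-).
    """

    contig_id: str
    ref_id: str
    contig_interval: tuple[int, int]
    ref_interval: tuple[int, int]
    strand: str
    length: int
    identity: float = 1.0

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("anchor length must be >= 1")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be a fraction in [0,1]")

    @property
    def ref_midpoint(self) -> float:
        a, b = self.ref_interval
        return (a + b) / 2.0


@dataclass
class AnchorSet:
    """Anchors plus their provenance; grouped on demand by (contig, reference)."""

    anchors: list[Anchor] = field(default_factory=list)
    k: int = DEFAULT_K
    provenance: str = "builtin"  # or "coords"

    def __len__(self) -> int:
        return len(self.anchors)

    def __iter__(self):
        return iter(self.anchors)

    def groups(self) -> dict[tuple[str, str], list[Anchor]]:
        out: dict[tuple[str, str], list[Anchor]] = {}
        for a in self.anchors:
            out.setdefault((a.contig_id, a.ref_id), []).append(a)
        return out

    def for_reference(self, ref_id: str) -> "AnchorSet":
        return AnchorSet(
            [a for a in self.anchors if a.ref_id == ref_id], self.k, self.provenance
        )

    def ref_ids(self) -> set[str]:
        return {a.ref_id for a in self.anchors}


class ReferenceIndex:
    """Unique-k-mer index of one reference, reusable across many contigs.

    For each k-mer the index remembers its single forward position, or -1 if
    it occurs more than once. The reverse complement of the reference is kept
    for reverse-strand extension.
    """

    def __init__(self, reference: FastaRecord, k: int):
        if k < 8:
            raise UserInputError(f"seed length k must be >= 8, got {k}")
        self.ref = reference
        self.k = k
        self.rc_seq = revcomp(reference.sequence)
        self.pos: dict[str, int] = {}
        seq = reference.sequence
        for j in range(len(seq) - k + 1):
            kmer = seq[j : j + k]
            self.pos[kmer] = -1 if kmer in self.pos else j

    def occurrences(self, kmer: str) -> tuple[int | None, int | None]:
        """(forward position | None, reverse position | None); -1 means multiple."""
        return self.pos.get(kmer), self.pos.get(revcomp(kmer))


def _extend(c: str, r: str, ci: int, rj: int, k: int) -> tuple[int, int, int]:
    """Maximally extend an exact k-match left and right.

    Returns (contig_start, contig_end, r_start) of the maximal match, with
    the match in ``r``'s coordinates starting at r_start.
    """
    a, ja = ci, rj
    while a > 0 and ja > 0 and c[a - 1] == r[ja - 1]:
        a -= 1
        ja -= 1
    b, jb = ci + k, rj + k
    n_c, n_r = len(c), len(r)
    while b < n_c and jb < n_r and c[b] == r[jb]:
        b += 1
        jb += 1
    return a, b, ja


def find_anchors_indexed(contig: FastaRecord, index: ReferenceIndex) -> AnchorSet:
    """Anchor one contig against a prebuilt reference index."""
    k = index.k
    c = contig.sequence
    ref = index.ref
    n_r = len(ref.sequence)
    result = AnchorSet([], k, "builtin")
    if len(c) < k or n_r < k:
        return result

    counts = Counter(c[i : i + k] for i in range(len(c) - k + 1))
    seen: set[tuple] = set()
    # last contig end extended per (strand, diagonal): seeds inside an anchor
    # already found on the same diagonal cannot yield a new maximal match
    last_end: dict[tuple[str, int], int] = {}

    for i in range(len(c) - k + 1):
        kmer = c[i : i + k]
        if counts[kmer] != 1:
            continue
        fwd, rev = index.occurrences(kmer)
        if kmer == revcomp(kmer):
            continue  # palindromic seed is ambiguous by construction
        n_occ = (fwd is not None) + (rev is not None)
        if n_occ != 1 or fwd == -1 or rev == -1:
            continue
        if fwd is not None:
            diag = fwd - i
            if last_end.get(("+", diag), -1) > i:
                continue
            a, b, ja = _extend(c, ref.sequence, i, fwd, k)
            last_end[("+", diag)] = b
            key = (a, b, ja, "+")
            if key in seen:
                continue
            seen.add(key)
            result.anchors.append(
                Anchor(contig.id, ref.id, (a, b), (ja, ja + (b - a)), "+", b - a)
            )
        else:
            # reference holds revcomp(kmer) at position `rev`; in reverse
            # complement coordinates the contig k-mer sits at n_r - k - rev
            j2 = n_r - k - rev
            diag = j2 - i
            if last_end.get(("-", diag), -1) > i:
                continue
            a, b, ja = _extend(c, index.rc_seq, i, j2, k)
            last_end[("-", diag)] = b
            jb = ja + (b - a)
            ref_iv = (n_r - jb, n_r - ja)
            key = (a, b, ref_iv[0], "-")
            if key in seen:
                continue
            seen.add(key)
            result.anchors.append(
                Anchor(contig.id, ref.id, (a, b), ref_iv, "-", b - a)
            )
    result.anchors.sort(key=lambda x: (x.contig_interval, x.ref_interval, x.strand))
    return result


def find_anchors(contig: FastaRecord, reference: FastaRecord, k: int = DEFAULT_K) -> AnchorSet:
    """Maximal exact matches between one contig and one reference.

    Seeds are k-mers occurring exactly once in the contig and exactly once in
    the reference (either strand), extended maximally in both directions;
    identity is 1 by construction. A k longer than either sequence yields an
    empty set.
    """
    if k < 8:
        raise UserInputError(f"seed length k must be >= 8, got {k}")
    if len(contig.sequence) < k or len(reference.sequence) < k:
        return AnchorSet([], k, "builtin")
    return find_anchors_indexed(contig, ReferenceIndex(reference, k))


def find_anchors_many(
    contigs: list[FastaRecord], reference: FastaRecord, k: int = DEFAULT_K
) -> AnchorSet:
    """Anchor many contigs against one reference, indexing it once."""
    if k < 8:
        raise UserInputError(f"seed length k must be >= 8, got {k}")
    if len(reference.sequence) < k:
        return AnchorSet([], k, "builtin")
    index = ReferenceIndex(reference, k)
    merged = AnchorSet([], k, "builtin")
    for contig in contigs:
        merged.anchors.extend(find_anchors_indexed(contig, index).anchors)
    return merged


def filter_anchors(aset: AnchorSet, min_len: int) -> AnchorSet:
    """Drop anchors shorter than ``min_len``, then resolve contig-overlap
    within each (contig, reference) group greedily by descending length.

    Ties are broken by ascending reference position, '+' strand first.
    """
    kept: list[Anchor] = []
    for _, group in sorted(aset.groups().items()):
        order = sorted(
            (a for a in group if a.length >= min_len),
            key=lambda a: (-a.length, a.ref_interval[0], a.strand != "+", a.contig_interval[0]),
        )
        chosen: list[Anchor] = []
        for a in order:
            s, e = a.contig_interval
            if all(e <= c.contig_interval[0] or s >= c.contig_interval[1] for c in chosen):
                chosen.append(a)
        kept.extend(chosen)
    kept.sort(key=lambda x: (x.contig_id, x.ref_id, x.contig_interval))
    return AnchorSet(kept, aset.k, aset.provenance)


def anchors_from_coords(
    rows: list[CoordsRow], known_contigs: set[str] | None = None
) -> AnchorSet:
    """Convert externally computed alignment rows into anchors.

    Each row becomes one anchor; identity is the row's percent identity as a
    fraction, strand follows the query column order. If ``known_contigs`` is
    given, rows naming unknown contigs raise an error listing the offenders.
    """
    if known_contigs is not None:
        unknown = sorted({r.qry_id for r in rows} - known_contigs)
        if unknown:
            raise UserInputError(f"coords rows reference unknown contigs: {', '.join(unknown)}")
    anchors = []
    for r in rows:
        ci = r.qry_interval()
        anchors.append(
            Anchor(
                contig_id=r.qry_id,
                ref_id=r.ref_id,
                contig_interval=ci,
                ref_interval=r.ref_interval(),
                strand=r.strand,
                length=ci[1] - ci[0],
                identity=r.pct_identity / 100.0,
            )
        )
    return AnchorSet(anchors, k=0, provenance="coords")


def write_anchor_tsv(aset: AnchorSet, path) -> None:
    """Debug dump: one row per anchor."""
    with open(path, "w") as fh:
        fh.write("contig_id\tref_id\tc_start\tc_end\tr_start\tr_end\tstrand\tidentity\n")
        for a in aset:
            fh.write(
                f"{a.contig_id}\t{a.ref_id}\t{a.contig_interval[0]}\t{a.contig_interval[1]}"
                f"\t{a.ref_interval[0]}\t{a.ref_interval[1]}\t{a.strand}\t{a.identity:.4f}\n"
            )
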