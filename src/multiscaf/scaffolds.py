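"""Signed-contig scaffolds.

A scaffold is an ordered, oriented chain of contigs. Each element is a
``SignedContig``: the contig id plus a strand sign. Reading a scaffold in
the opposite direction negates every sign and reverses the order; the two
readings describe the same physical object, so a canonical direction is
chosen when scaffolds are emitted (see :func:`canonical_direction`).
"""

from __future__ import annotations

from typing import NamedTuple

from ._util import contig_sort_key
from .errors import FormatError

FORWARD = "+"
REVERSE = "-"


class SignedContig(NamedTuple):
    contig_id: str
    strand: str  # '+' or '-'

    def negate(self) -> "SignedContig":
        return SignedContig(self.contig_id, REVERSE if self.strand == FORWARD else FORWARD)

    def token(self) -> str:
        return f"{self.strand}{self.contig_id}"


#: A scaffold is an ordered tuple of signed contigs.
Scaffold = tuple[SignedContig, ...]


def parse_signed_token(token: str) -> SignedContig:
    """Parse a token like ``+ctg1`` or ``-7``. Unicode minus is accepted."""
    token = token.strip().replace("−", "-")
    if len(token) < 2 or token[0] not in "+-":
        raise FormatError(f"signed contig token must start with '+' or '-': {token!r}")
    return SignedContig(token[1:], token[0])


def make_scaffold(tokens) -> Scaffold:
    """Build a scaffold from ``SignedContig`` items or ``+id`` strings."""
    out = []
    for t in tokens:
        out.append(t if isinstance(t, SignedContig) else parse_signed_token(t))
    return tuple(out)


def reverse_scaffold(s: Scaffold) -> Scaffold:
    """The opposite reading direction: reversed order, all signs flipped."""
    return tuple(sc.negate() for sc in reversed(s))


def canonical_direction(s: Scaffold) -> Scaffold:
    """Of the two reading directions, keep the one whose first signed contig
    has the smaller (contig id, sign) with '+' < '-'."""
    if not s:
        return s
    rev = reverse_scaffold(s)
    key = lambda sc: (contig_sort_key(sc.contig_id), 0 if sc.strand == FORWARD else 1)
    return s if key(s[0]) <= key(rev[0]) else rev


def scaffold_joins(s: Scaffold) -> list[tuple[SignedContig, SignedContig]]:
    """Consecutive signed-contig pairs (the contig joins) of a scaffold."""
    return [(s[i], s[i + 1]) for i in range(len(s) - 1)]


def format_scaffold(s: Scaffold) -> str:
    return "(" + ",".join(sc.token() for sc in s) + ")"
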