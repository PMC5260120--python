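"""On-disk formats: FASTA, alignment coordinate tables, scaffold lists, AGP.

Coordinate conventions: every external format here is 1-based inclusive
(the MUMmer/AGP convention); everything handed to the rest of the package
is 0-based half-open. The conversion happens in this module only, so no
other module ever adds or subtracts 1.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, UserInputError
from .scaffolds import Scaffold, SignedContig, parse_signed_token


# ---------------------------------------------------------------------------
# FASTA


@dataclass
class FastaRecord:
    """One FASTA record; ``id`` is the first whitespace-delimited header token."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise FormatError("FASTA record with empty id")
        if not self.sequence:
            raise FormatError(f"FASTA record {self.id!r} has an empty sequence")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path) -> list[FastaRecord]:
    """Read a (multi-)FASTA file; sequences are uppercased.

    Raises on an empty file and on duplicate record ids.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(FastaRecord(id=rec.id, sequence=str(rec.seq), description=desc))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[FastaRecord], path, width: int = 70) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


# ---------------------------------------------------------------------------
# MUMmer-style coordinate tables (show-coords dialect)


@dataclass(frozen=True)
class CoordsRow:
    """One alignment row, 1-based inclusive as printed by ``show-coords``.

    ``qry_start > qry_end`` encodes a reverse-strand alignment.
    """

    ref_start: int
    ref_end: int
    qry_start: int
    qry_end: int
    ref_len_aln: int
    qry_len_aln: int
    pct_identity: float
    ref_id: str
    qry_id: str

    def __post_init__(self):
        if min(self.ref_start, self.ref_end, self.qry_start, self.qry_end) < 1:
            raise FormatError(f"coords positions must be >= 1: {self}")
        if self.ref_start > self.ref_end:
            raise FormatError(f"reference interval reversed (ref strand is fixed): {self}")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise FormatError(f"percent identity outside [0,100]: {self}")

    @property
    def strand(self) -> str:
        return "-" if self.qry_start > self.qry_end else "+"

    def ref_interval(self) -> tuple[int, int]:
        """0-based half-open interval on the reference."""
        return (self.ref_start - 1, self.ref_end)

    def qry_interval(self) -> tuple[int, int]:
        """0-based half-open interval on the contig (always start < end)."""
        lo, hi = sorted((self.qry_start, self.qry_end))
        return (lo - 1, hi)


def read_coords(path) -> list[CoordsRow]:
    """Parse a show-coords-like table.

    Header/banner lines (anything not starting with a digit) are skipped;
    '|' column separators are tolerated; columns beyond the seventh that are
    not the trailing ref/query ids are ignored, which accepts the common
    ``-rcl`` layout. A data line with a non-numeric coordinate raises with
    its line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or not stripped[0].isdigit():
                continue  # banner, column headers, '====' rulers, paths
            tokens = stripped.replace("|", " ").split()
            if len(tokens) < 9:
                raise FormatError(
                    f"{path}:{lineno}: expected at least 9 columns, got {len(tokens)}"
                )
            try:
                ints = [int(t) for t in tokens[:6]]
                pct = float(tokens[6])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric coordinate field ({exc})")
            rows.append(
                CoordsRow(*ints, pct, ref_id=tokens[-2], qry_id=tokens[-1])
            )
    return rows


def write_coords(rows: Iterable[CoordsRow], path) -> None:
    with open(path, "w") as fh:
        for r in rows:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.ref_start, r.ref_end, r.qry_start, r.qry_end,
                        r.ref_len_aln, r.qry_len_aln,
                        f"{r.pct_identity:.2f}", r.ref_id, r.qry_id,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Scaffold-list files: ">scaffold_i" headers, one signed contig per line


def read_scaffold_list(path) -> list[Scaffold]:
    """Read an ordered list of scaffolds of signed contig ids.

    Each contig id may appear at most once across the whole file; an empty
    scaffold block is an error.
    """
    scaffolds: list[Scaffold] = []
    current: list[SignedContig] | None = None
    seen: set[str] = set()

    def flush():
        nonlocal current
        if current is not None:
            if not current:
                raise FormatError(f"{path}: empty scaffold block")
            scaffolds.append(tuple(current))
        current = None

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                flush()
                current = []
                continue
            if current is None:
                raise FormatError(f"{path}:{lineno}: contig line before any scaffold header")
            sc = parse_signed_token(stripped)
            if sc.contig_id in seen:
                raise FormatError(f"{path}:{lineno}: contig {sc.contig_id!r} listed twice")
            seen.add(sc.contig_id)
            current.append(sc)
    flush()
    if not scaffolds:
        raise FormatError(f"{path}: no scaffolds found")
    return scaffolds


def write_scaffold_list(scaffolds: Iterable[Scaffold], path) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(scaffolds, start=1):
            fh.write(f">scaffold_{i}\n")
            for sc in s:
                fh.write(sc.token() + "\n")


# ---------------------------------------------------------------------------
# AGP v2.1


def write_agp(
    scaffolds: Iterable[Scaffold],
    contig_lengths: dict[str, int],
    path,
    gap_len: int = 100,
    gap_type: str = "scaffold",
    evidence: str = "align_genus",
) -> None:
    """Write scaffolds as AGP v2.1: W lines for contigs, N lines for the
    fixed-length gaps between consecutive contigs. Object coordinates are
    1-based, contiguous and strictly increasing."""
    if gap_len < 0:
        raise UserInputError("gap_len must be >= 0")
    with open(path, "w") as fh:
        fh.write("##agp-version 2.1\n")
        for i, s in enumerate(scaffolds, start=1):
            obj = f"scaffold_{i}"
            pos = 0  # bases emitted so far on the object
            part = 0
            for j, sc in enumerate(s):
                if sc.contig_id not in contig_lengths:
                    raise UserInputError(f"no length known for contig {sc.contig_id!r}")
                if j > 0 and gap_len > 0:
                    part += 1
                    fh.write(
                        f"{obj}\t{pos + 1}\t{pos + gap_len}\t{part}\tN\t{gap_len}"
                        f"\t{gap_type}\tyes\t{evidence}\n"
                    )
                    pos += gap_len
                clen = contig_lengths[sc.contig_id]
                part += 1
                fh.write(
                    f"{obj}\t{pos + 1}\t{pos + clen}\t{part}\tW\t{sc.contig_id}"
                    f"\t1\t{clen}\t{sc.strand}\n"
                )
                pos += clen


def read_agp(path) -> tuple[list[Scaffold], dict[str, int]]:
    """Parse an AGP file back into scaffolds plus component lengths.

    Used for consistency checks; only W/N component types are understood.
    """
    per_object: dict[str, list[SignedContig]] = {}
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 AGP columns")
            obj, _, _, _, ctype = cols[:5]
            if ctype == "N" or ctype == "U":
                continue
            if ctype != "W":
                raise FormatError(f"{path}:{lineno}: unsupported component type {ctype!r}")
            comp_id, beg, end, orient = cols[5], int(cols[6]), int(cols[7]), cols[8]
            per_object.setdefault(obj, []).append(SignedContig(comp_id, orient))
            lengths[comp_id] = end - beg + 1
    return [tuple(v) for v in per_object.values()], lengths
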