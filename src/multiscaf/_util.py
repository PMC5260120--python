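"""Small shared helpers: reverse complement and deterministic contig ordering."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def contig_sort_key(contig_id: str):
    """Total order on contig ids: numeric ids sort numerically, others
    lexicographically, numerics first. Used everywhere a deterministic
    tie-break on contigs is needed."""
    if contig_id.isdigit():
        return (0, int(contig_id), contig_id)
    return (1, 0, contig_id)
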