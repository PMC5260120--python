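"""Self-contained synthetic datasets for the scaffolding problem.

A linear truth genome is generated, partitioned into contigs separated by
short unassembled gaps, and k reference genomes are derived from the truth
by random segment reversals and block interchanges (the rearrangement
vocabulary the scaffolder is designed around) followed by uniform point
mutations. The true contig order and orientations are recorded, so the
whole pipeline can be scored against a known answer.

Defaults model a desk-scale prokaryotic draft: a 200 kb genome in 20
contigs, five references each 3 reversals + 1 block interchange away, 0.5 %
point divergence.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from ._util import revcomp
from .errors import UserInputError
from .evaluation import ReferenceOrder
from .formats import FastaRecord, write_fasta, write_scaffold_list
from .scaffolds import SignedContig

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimulationConfig:
    genome_len: int = 200_000
    n_contigs: int = 20
    k_refs: int = 5
    reversals_per_ref: int = 3
    block_interchanges_per_ref: int = 1
    min_contig_len: int = 2_000
    inter_contig_gap: int = 100
    point_mutation_rate: float = 0.005
    seed: int = 0

    def validate(self) -> None:
        if self.n_contigs < 1:
            raise UserInputError("n_contigs must be >= 1")
        if self.k_refs < 1:
            raise UserInputError("at least one reference is required")
        if not 0.0 <= self.point_mutation_rate < 1.0:
            raise UserInputError("point_mutation_rate must be in [0, 1)")
        if min(self.reversals_per_ref, self.block_interchanges_per_ref) < 0:
            raise UserInputError("rearrangement counts must be >= 0")
        needed = self.n_contigs * self.min_contig_len + (self.n_contigs - 1) * self.inter_contig_gap
        if self.genome_len < needed:
            raise UserInputError(
                f"genome_len {self.genome_len} cannot hold {self.n_contigs} contigs of "
                f">= {self.min_contig_len} bp with {self.inter_contig_gap} bp gaps "
                f"(needs >= {needed})"
            )


@dataclass
class TruthGenome:
    sequence: str
    contig_intervals: list[tuple[int, int]]  # 0-based half-open, ordered, disjoint
    true_order: ReferenceOrder
    contigs: list[FastaRecord] = field(default_factory=list)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def simulate_truth(cfg: SimulationConfig) -> TruthGenome:
    """Truth genome plus its contig fragmentation.

    Contig lengths are min_contig_len plus a multinomial split of the spare
    bases; contigs tile the genome left to right separated by
    inter_contig_gap unassembled bases. Half of the contigs (rounded down),
    chosen at random, are stored reverse-complemented, and the true order
    records their '-' signs.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_contigs
    sequence = _random_dna(rng, cfg.genome_len)

    spare = cfg.genome_len - n * cfg.min_contig_len - (n - 1) * cfg.inter_contig_gap
    extras = rng.multinomial(spare, [1.0 / n] * n)
    intervals = []
    pos = 0
    for i in range(n):
        length = cfg.min_contig_len + int(extras[i])
        intervals.append((pos, pos + length))
        pos += length + cfg.inter_contig_gap

    width = len(str(n))
    flipped = set(rng.choice(n, size=n // 2, replace=False).tolist())
    contigs, order = [], []
    for i, (s, e) in enumerate(intervals):
        cid = f"ctg{i + 1:0{width}d}"
        seq = sequence[s:e]
        sign = "+"
        if i in flipped:
            seq = revcomp(seq)
            sign = "-"
        contigs.append(FastaRecord(id=cid, sequence=seq))
        order.append(SignedContig(cid, sign))

    return TruthGenome(
        sequence=sequence,
        contig_intervals=intervals,
        true_order=ReferenceOrder(order=tuple(order)),
        contigs=contigs,
    )


def simulate_reference(
    truth: TruthGenome,
    reversals: int,
    block_interchanges: int,
    mutation_rate: float,
    seed,
    ref_id: str = "ref",
) -> tuple[FastaRecord, list[dict]]:
    """One rearranged relative of the truth genome, with its operation log.

    Reversals reverse-complement a random segment in place; block
    interchanges swap two disjoint random segments; both are
    length-preserving. Point mutations then substitute a different base at a
    binomial number of positions. Fully reproducible from the seed.
    """
    rng = np.random.default_rng(seed)
    seq = truth.sequence
    L = len(seq)
    log: list[dict] = []

    for _ in range(reversals):
        i, j = sorted(rng.choice(L + 1, size=2, replace=False).tolist())
        seq = seq[:i] + revcomp(seq[i:j]) + seq[j:]
        log.append({"op": "reversal", "start": i, "end": j})

    for _ in range(block_interchanges):
        a, b, c, d = sorted(rng.choice(L + 1, size=4, replace=False).tolist())
        seq = seq[:a] + seq[c:d] + seq[b:c] + seq[a:b] + seq[d:]
        log.append({"op": "block_interchange", "segments": [[a, b], [c, d]]})

    n_mut = int(rng.binomial(L, mutation_rate)) if mutation_rate > 0 else 0
    if n_mut:
        positions = rng.choice(L, size=n_mut, replace=False)
        chars = list(seq)
        for p in positions.tolist():
            alternatives = [x for x in "ACGT" if x != chars[p]]
            chars[p] = alternatives[int(rng.integers(3))]
        seq = "".join(chars)
    log.append({"op": "point_mutations", "count": n_mut})

    return FastaRecord(id=ref_id, sequence=seq), log


def make_dataset(cfg: SimulationConfig, outdir) -> dict[str, str]:
    """Write a complete dataset: contigs, k references, truth order, manifest.

    Returns the paths written, keyed by role ('contigs', 'ref_1', ...,
    'truth_order', 'manifest').
    """
    cfg.validate()
    os.makedirs(outdir, exist_ok=True)
    truth = simulate_truth(cfg)
    paths = {}

    contigs_path = os.path.join(outdir, "contigs.fasta")
    write_fasta(truth.contigs, contigs_path)
    paths["contigs"] = contigs_path

    op_logs = {}
    for i in range(1, cfg.k_refs + 1):
        ref, log = simulate_reference(
            truth,
            cfg.reversals_per_ref,
            cfg.block_interchanges_per_ref,
            cfg.point_mutation_rate,
            seed=[cfg.seed, i],
            ref_id=f"ref_{i}",
        )
        p = os.path.join(outdir, f"ref_{i}.fasta")
        write_fasta([ref], p)
        paths[f"ref_{i}"] = p
        op_logs[f"ref_{i}"] = log

    truth_path = os.path.join(outdir, "truth_order.txt")
    write_scaffold_list([truth.true_order.order], truth_path)
    paths["truth_order"] = truth_path

    manifest_path = os.path.join(outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(
            {
                "config": asdict(cfg),
                "contig_intervals": truth.contig_intervals,
                "operations": op_logs,
            },
            fh,
            indent=2,
        )
    paths["manifest"] = manifest_path
    return paths
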