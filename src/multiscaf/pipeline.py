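"""End-to-end scaffolding pipeline.

Per reference: anchor (built-in, or imported coords), place, order and
orient — or load an external scaffolder's output directly. Then merge: build
the contig adjacency graph, find the maximum-weight perfect matching, break
cycles, emit scaffolds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .adjacency_graph import ContigAdjacencyGraph, build_graph
from .anchors import (
    DEFAULT_K,
    anchors_from_coords,
    filter_anchors,
    find_anchors_many,
)
from .errors import UserInputError
from .formats import FastaRecord, read_coords, read_fasta
from .matcher import (
    CyclePartition,
    PerfectMatching,
    ResidualMatching,
    break_cycles,
    decompose_cycles,
    emit_scaffolds,
    max_weight_perfect_matching,
)
from .scaffolds import Scaffold, SignedContig, format_scaffold
from .single_ref import (
    DEFAULT_CLUSTER_RADIUS,
    ReferenceScaffolding,
    load_external_scaffolding,
    order_and_orient,
    place_contigs,
)

logger = logging.getLogger("multiscaf")


@dataclass
class AnchorParams:
    k: int = DEFAULT_K
    min_len: int | None = None  # default: 2k
    cluster_radius: float = DEFAULT_CLUSTER_RADIUS

    @property
    def effective_min_len(self) -> int:
        return self.min_len if self.min_len is not None else 2 * self.k


@dataclass
class ReferenceSpec:
    """One reference input: a FASTA, a coords table, or a scaffold list."""

    path: str
    kind: str  # 'fasta' | 'coords' | 'scaffolds'
    weight: float = 1.0
    ref_id: str | None = None

    def __post_init__(self):
        if self.kind not in ("fasta", "coords", "scaffolds"):
            raise UserInputError(f"unknown reference kind {self.kind!r}")
        if not self.weight > 0:
            raise UserInputError(f"reference weight must be positive, got {self.weight}")


def scaffolding_from_reference_fasta(
    contigs: list[FastaRecord],
    reference: FastaRecord,
    weight: float,
    params: AnchorParams | None = None,
) -> ReferenceScaffolding:
    """Built-in per-reference stage: anchor, filter, place, order, orient."""
    params = params or AnchorParams()
    aset = find_anchors_many(contigs, reference, params.k)
    aset = filter_anchors(aset, params.effective_min_len)
    placements = place_contigs(
        aset.for_reference(reference.id) if aset.ref_ids() else aset,
        {c.id for c in contigs},
        params.cluster_radius,
    )
    return order_and_orient(placements, weight, ref_id=reference.id)


def per_reference_scaffoldings(
    contigs: list[FastaRecord],
    specs: list[ReferenceSpec],
    params: AnchorParams | None = None,
) -> list[ReferenceScaffolding]:
    """Resolve every reference input into a weighted scaffolding.

    A multi-record reference FASTA yields one scaffolding per chromosome
    record, each with the spec's weight.
    """
    params = params or AnchorParams()
    contig_ids = {c.id for c in contigs}
    out: list[ReferenceScaffolding] = []
    for spec in specs:
        if spec.kind == "fasta":
            for rec in read_fasta(spec.path):
                out.append(scaffolding_from_reference_fasta(contigs, rec, spec.weight, params))
        elif spec.kind == "coords":
            rows = read_coords(spec.path)
            aset = anchors_from_coords(rows, known_contigs=contig_ids)
            for ref_id in sorted(aset.ref_ids()):
                placements = place_contigs(
                    aset.for_reference(ref_id), contig_ids, params.cluster_radius
                )
                out.append(order_and_orient(placements, spec.weight, ref_id=ref_id))
        else:
            out.append(
                load_external_scaffolding(
                    spec.path, spec.weight, ref_id=spec.ref_id or spec.path,
                    known_contigs=contig_ids,
                )
            )
    return out


@dataclass
class ScaffoldResult:
    scaffolds: list[Scaffold]
    graph: ContigAdjacencyGraph | None = None
    matching: PerfectMatching | None = None
    cycles: CyclePartition | None = None
    residual: ResidualMatching | None = None
    log_lines: list[str] = field(default_factory=list)


def merge_scaffoldings(
    scaffoldings: list[ReferenceScaffolding],
    contig_ids: set[str],
    use_dummy: bool = False,
) -> ScaffoldResult:
    """The multi-reference merging core: graph, matching, cycle breaking.

    A single contig short-circuits to one singleton scaffold (matching needs
    n >= 2).
    """
    if not contig_ids:
        raise UserInputError("no contigs to scaffold")
    if len(contig_ids) == 1:
        only = next(iter(contig_ids))
        return ScaffoldResult(
            scaffolds=[(SignedContig(only, "+"),)],
            log_lines=["single contig: emitted singleton scaffold"],
        )
    g = build_graph(scaffoldings, contig_ids)
    m = max_weight_perfect_matching(g)
    cp = decompose_cycles(m, g.contigs)
    residual = break_cycles(m, cp, g)
    scaffolds = emit_scaffolds(residual, g.contigs, use_dummy=use_dummy)
    lines = [
        f"adjacency graph: {g.n} contigs, {len(g.real_edges())} supported edges "
        f"(total weight {g.total_real_weight():g})",
        f"maximum matching weight: {m.total_weight:g}",
        f"cycles in C∪M: {len(cp.cycles)}",
        f"edges removed: {', '.join(f'{e.u}-{e.v} (w={e.weight:g})' for e in residual.removed)}"
        if residual.removed else "edges removed: none",
        f"residual weight: {residual.total_weight:g}",
        f"scaffolds: {'; '.join(format_scaffold(s) for s in scaffolds)}",
    ]
    for line in lines:
        logger.info(line)
    return ScaffoldResult(scaffolds, g, m, cp, residual, lines)


def scaffold_target(
    contigs: list[FastaRecord],
    specs: list[ReferenceSpec],
    params: AnchorParams | None = None,
    use_dummy: bool = False,
) -> ScaffoldResult:
    """Full pipeline from contig records and reference specs to scaffolds."""
    scaffoldings = per_reference_scaffoldings(contigs, specs, params)
    return merge_scaffoldings(scaffoldings, {c.id for c in contigs}, use_dummy=use_dummy)
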