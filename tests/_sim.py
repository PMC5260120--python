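"""Shared driver for simulation-based tests: simulate, scaffold, score."""

from __future__ import annotations

from multiscaf.evaluation import EvaluationReport, evaluate
from multiscaf.pipeline import merge_scaffoldings, scaffolding_from_reference_fasta
from multiscaf.synthetic import SimulationConfig, simulate_reference, simulate_truth


def simulated_reports(cfg: SimulationConfig, k_values: list[int]) -> dict[int, EvaluationReport]:
    """Run the full pipeline on one simulated dataset and score it at each
    requested number of references (reusing the per-reference stage)."""
    truth = simulate_truth(cfg)
    lengths = {c.id: len(c) for c in truth.contigs}
    contig_ids = set(lengths)
    scaffoldings = []
    for i in range(1, max(k_values) + 1):
        ref, _ = simulate_reference(
            truth,
            cfg.reversals_per_ref,
            cfg.block_interchanges_per_ref,
            cfg.point_mutation_rate,
            seed=[cfg.seed, i],
            ref_id=f"ref_{i}",
        )
        scaffoldings.append(scaffolding_from_reference_fasta(truth.contigs, ref, 1.0))
    out = {}
    for k in k_values:
        result = merge_scaffoldings(scaffoldings[:k], contig_ids)
        out[k] = evaluate(result.scaffolds, truth.true_order, lengths)
    return out
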