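"""Matching, cycle decomposition, cycle breaking and scaffold emission."""

import pytest

from _brute import (
    brute_max_matching_weight,
    brute_min_removal_weight,
    ext,
    random_instance,
)
from multiscaf.adjacency_graph import build_graph, make_pair
from multiscaf.matcher import (
    break_cycles,
    decompose_cycles,
    emit_scaffolds,
    max_weight_perfect_matching,
)
from multiscaf.scaffolds import make_scaffold, reverse_scaffold
from multiscaf.single_ref import ReferenceScaffolding


def _graph(worked_example):
    return build_graph(worked_example["scaffoldings"], worked_example["contigs"])


class TestMatching:
    def test_worked_example_matching(self, worked_example):
        m = max_weight_perfect_matching(_graph(worked_example))
        assert m.pairs() == {
            make_pair(ext(a), ext(b))
            for a, b in [("1t", "4h"), ("1h", "2t"), ("2h", "3t"), ("3h", "4t")]
        }

    def test_worked_example_weight_matches_enumeration(self, worked_example):
        g = _graph(worked_example)
        m = max_weight_perfect_matching(g)
        assert m.total_weight == pytest.approx(7.0)
        assert m.total_weight == pytest.approx(brute_max_matching_weight(g))

    def test_two_contigs_forced_completion(self):
        g = build_graph(
            [ReferenceScaffolding("R1", 1.0, [make_scaffold(["+1", "+2"])])], {"1", "2"}
        )
        m = max_weight_perfect_matching(g)
        assert m.total_weight == pytest.approx(1.0)
        assert make_pair(ext("1h"), ext("2t")) in m.pairs()
        # the two leftover extremities are forced onto a dummy edge
        assert make_pair(ext("1t"), ext("2h")) in m.pairs()

    def test_empty_graph(self):
        g = build_graph(
            [ReferenceScaffolding("R1", 1.0, [make_scaffold(["+1", "+2"])])], {"1", "2"}
        )
        g.contigs = set()
        g._edges = {}
        assert max_weight_perfect_matching(g).edges == []

    def test_deterministic_under_ties(self):
        # two references pulling equally in different directions: any optimum
        # is acceptable but repeated runs must agree
        scaffoldings = [
            ReferenceScaffolding("R1", 1.0, [make_scaffold(["+1", "+2", "+3", "+4"])]),
            ReferenceScaffolding("R2", 1.0, [make_scaffold(["+2", "+1", "+4", "+3"])]),
        ]
        contigs = {"1", "2", "3", "4"}
        first = max_weight_perfect_matching(build_graph(scaffoldings, contigs))
        for _ in range(5):
            again = max_weight_perfect_matching(build_graph(scaffoldings, contigs))
            assert again.pairs() == first.pairs()


class TestCycles:
    def test_worked_example_single_cycle(self, worked_example):
        g = _graph(worked_example)
        m = max_weight_perfect_matching(g)
        cp = decompose_cycles(m, g.contigs)
        assert len(cp.cycles) == 1
        assert len(cp.cycles[0]) == 8

    def test_smallest_cycles(self, worked_example):
        g = build_graph(
            [ReferenceScaffolding("R1", 1.0, [make_scaffold(["+1", "+2"])])], {"1", "2"}
        )
        m = max_weight_perfect_matching(g)
        cp = decompose_cycles(m, {"1", "2"})
        assert [len(c) for c in cp.cycles] == [4]

    def test_worked_example_break(self, worked_example):
        g = _graph(worked_example)
        m = max_weight_perfect_matching(g)
        res = break_cycles(m, decompose_cycles(m, g.contigs), g)
        assert {e.pair for e in res.removed} == {make_pair(ext("1t"), ext("4h"))}
        assert res.removed_weight == pytest.approx(1.0)
        assert res.total_weight == pytest.approx(6.0)
        assert {e.pair for e in res.edges} == {
            make_pair(ext(a), ext(b))
            for a, b in [("1h", "2t"), ("2h", "3t"), ("3h", "4t")]
        }


class TestEmitScaffolds:
    def test_worked_example_final_scaffold(self, worked_example):
        g = _graph(worked_example)
        m = max_weight_perfect_matching(g)
        res = break_cycles(m, decompose_cycles(m, g.contigs), g)
        assert emit_scaffolds(res, g.contigs) == [make_scaffold(["+1", "+2", "+3", "+4"])]

    def test_no_joins_gives_singletons(self):
        assert emit_scaffolds([], {"1", "2", "3"}) == [
            make_scaffold(["+1"]),
            make_scaffold(["+2"]),
            make_scaffold(["+3"]),
        ]

    def test_head_head_join_flips_sign(self, worked_example):
        g = build_graph(
            [ReferenceScaffolding("R1", 1.0, [make_scaffold(["+1", "-2"])])], {"1", "2"}
        )
        edge = g.edge(ext("1h"), ext("2h"))
        assert emit_scaffolds([edge], {"1", "2"}) == [make_scaffold(["+1", "-2"])]


class TestRandomInstanceOracles:
    def test_matching_weight_equals_brute_force(self, rng):
        for _ in range(30):
            _, _, g = random_instance(rng)
            m = max_weight_perfect_matching(g)
            assert m.total_weight == pytest.approx(brute_max_matching_weight(g))

    def test_cycle_breaking_is_minimal(self, rng):
        for _ in range(30):
            contigs, _, g = random_instance(rng)
            m = max_weight_perfect_matching(g)
            res = break_cycles(m, decompose_cycles(m, contigs), g)
            assert res.removed_weight == pytest.approx(
                brute_min_removal_weight(m.pairs(), contigs, g)
            )

    def test_outputs_partition_the_contig_set(self, rng):
        for _ in range(30):
            contigs, _, g = random_instance(rng)
            m = max_weight_perfect_matching(g)
            res = break_cycles(m, decompose_cycles(m, contigs), g)
            for use_dummy in (False, True):
                scaffolds = emit_scaffolds(res, contigs, use_dummy=use_dummy)
                seen = [sc.contig_id for s in scaffolds for sc in s]
                assert sorted(seen) == sorted(contigs)

    def test_global_orientation_symmetry(self, rng):
        # Negating every sign in every input scaffolding is a tail<->head
        # mirror of the adjacency graph, so the matching weight is unchanged
        # and, when the optimum is unique, the output scaffolds are the
        # elementwise negation of the originals (up to reading direction).
        from _brute import all_perfect_matchings

        def final(graph, contigs):
            m = max_weight_perfect_matching(graph)
            res = break_cycles(m, decompose_cycles(m, contigs), graph)
            return m, emit_scaffolds(res, contigs)

        checked_unique = 0
        for _ in range(20):
            contigs, scaffoldings, g = random_instance(rng, n_max=4)
            flipped = [
                ReferenceScaffolding(
                    rs.ref_id,
                    rs.weight,
                    [tuple(sc.negate() for sc in s) for s in rs.scaffolds],
                )
                for rs in scaffoldings
            ]
            g2 = build_graph(flipped, contigs)
            m1, out1 = final(g, contigs)
            m2, out2 = final(g2, contigs)
            assert m1.total_weight == pytest.approx(m2.total_weight)

            best = m1.total_weight
            n_optima = sum(
                1
                for pm in all_perfect_matchings(
                    g.vertices(), lambda a, b: a.contig_id == b.contig_id
                )
                if abs(sum(g.edge(u, v).weight for u, v in pm) - best) < 1e-9
            )
            if n_optima == 1:
                checked_unique += 1
                norm = lambda ss: sorted(min(s, reverse_scaffold(s)) for s in ss)
                negated = [tuple(sc.negate() for sc in s) for s in out1]
                assert norm(out2) == norm(negated)
        assert checked_unique >= 3  # the scaffold-level check actually ran
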