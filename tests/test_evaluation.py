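"""Scaffold scoring: join classification, coverage, N50, full report."""

import random

import pytest

from multiscaf._util import revcomp
from multiscaf.anchors import filter_anchors, find_anchors_many
from multiscaf.errors import UserInputError
from multiscaf.evaluation import (
    ReferenceOrder,
    classify_joins,
    derive_reference_order,
    evaluate,
    genome_coverage,
    n50,
)
from multiscaf.formats import FastaRecord
from multiscaf.scaffolds import make_scaffold, reverse_scaffold

RO_1234 = ReferenceOrder(order=make_scaffold(["+1", "+2", "+3", "+4"]))


class TestDeriveReferenceOrder:
    def _tiling(self, seed=21, flip=None):
        rnd = random.Random(seed)
        genome = "".join(rnd.choices("ACGT", k=16_000))
        contigs = []
        for i in range(4):
            seq = genome[i * 4000:(i + 1) * 4000]
            if flip == i:
                seq = revcomp(seq)
            contigs.append(FastaRecord(str(i + 1), seq))
        return genome, contigs

    def test_identity_layout(self):
        genome, contigs = self._tiling()
        aset = filter_anchors(find_anchors_many(contigs, FastaRecord("g", genome), 15), 30)
        ro = derive_reference_order(aset, {c.id for c in contigs})
        assert ro.order == make_scaffold(["+1", "+2", "+3", "+4"])
        assert ro.excluded == set()
        assert ro.p == 3

    def test_unanchored_contig_excluded(self):
        genome, contigs = self._tiling()
        rnd = random.Random(99)
        contigs[2] = FastaRecord("3", "".join(rnd.choices("ACGT", k=4000)))
        aset = filter_anchors(find_anchors_many(contigs, FastaRecord("g", genome), 15), 30)
        ro = derive_reference_order(aset, {c.id for c in contigs})
        assert ro.order == make_scaffold(["+1", "+2", "+4"])
        assert ro.excluded == {"3"}
        assert ro.p == 2

    def test_reverse_complemented_contig_gets_minus_sign(self):
        genome, contigs = self._tiling(flip=1)
        aset = filter_anchors(find_anchors_many(contigs, FastaRecord("g", genome), 15), 30)
        ro = derive_reference_order(aset, {c.id for c in contigs})
        assert ro.order == make_scaffold(["+1", "-2", "+3", "+4"])


class TestClassifyJoins:
    @pytest.mark.parametrize(
        "tokens,expected",
        [
            (["+1", "+2", "+3", "+4"], (3, 0, 3)),
            (["+2", "+3", "+4", "+1"], (2, 1, 3)),
            (["-4", "-3", "-2", "-1"], (3, 0, 3)),
        ],
    )
    def test_hand_checked_cases(self, tokens, expected):
        assert classify_joins([make_scaffold(tokens)], RO_1234) == expected

    def test_join_to_excluded_contig_is_fp(self):
        ro = ReferenceOrder(order=make_scaffold(["+1", "+2"]), excluded={"5"})
        assert classify_joins([make_scaffold(["+1", "+2", "+5"])], ro) == (1, 1, 1)

    def test_invariant_under_scaffold_reversal(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 8))
            perm = [str(i) for i in rng.permutation(range(1, n + 1))]
            signs = rng.choice(["+", "-"], size=n)
            s = make_scaffold([f"{sg}{c}" for sg, c in zip(signs, perm)])
            ro = ReferenceOrder(order=make_scaffold([f"+{i}" for i in range(1, n + 1)]))
            assert classify_joins([s], ro) == classify_joins([reverse_scaffold(s)], ro)

    def test_incorrect_join_never_helps(self):
        base = [make_scaffold(["+1", "+2"]), make_scaffold(["+4"])]
        with_bad = [make_scaffold(["+1", "+2"]), make_scaffold(["+4", "+3"])]
        tp0, fp0, p = classify_joins(base, RO_1234)
        tp1, fp1, _ = classify_joins(with_bad, RO_1234)
        assert tp1 == tp0  # sensitivity unchanged
        assert fp1 == fp0 + 1
        assert tp1 / (tp1 + fp1) <= tp0 / (tp0 + fp0) if tp0 + fp0 else True


class TestGenomeCoverage:
    def test_perfect_equal_length_case(self):
        s = [make_scaffold(["+1", "+2", "+3", "+4"])]
        lengths = {c: 100 for c in "1234"}
        assert genome_coverage(s, RO_1234, lengths) == pytest.approx(0.75)

    def test_no_correct_joins(self):
        s = [make_scaffold(["+3", "+1", "+4", "+2"])]
        lengths = {c: 100 for c in "1234"}
        assert genome_coverage(s, RO_1234, lengths) == 0.0

    def test_half_length_rule(self):
        ro = ReferenceOrder(order=make_scaffold(["+a", "+b"]))
        s = [make_scaffold(["+a", "+b"])]
        assert genome_coverage(s, ro, {"a": 100, "b": 300}) == pytest.approx(0.5)

    def test_missing_length_errors(self):
        with pytest.raises(UserInputError, match="b"):
            genome_coverage([make_scaffold(["+a", "+b"])], RO_1234, {"a": 1})


class TestN50:
    @pytest.mark.parametrize(
        "sizes,expected",
        [
            ([5, 4, 3, 2, 1], 4),
            ([42], 42),
            ([10, 10], 10),
        ],
    )
    def test_definition(self, sizes, expected):
        scaffolds = [make_scaffold([f"+s{i}"]) for i in range(len(sizes))]
        lengths = {f"s{i}": sz for i, sz in enumerate(sizes)}
        assert n50(scaffolds, lengths) == expected

    def test_gap_inclusion_flag(self):
        s = [make_scaffold(["+a", "+b"])]
        lengths = {"a": 100, "b": 100}
        assert n50(s, lengths) == 200
        assert n50(s, lengths, gap_len=50) == 250

    def test_empty_set_errors(self):
        with pytest.raises(UserInputError):
            n50([], {})


class TestEvaluate:
    def test_perfect_four_contig_case(self):
        s = [make_scaffold(["+1", "+2", "+3", "+4"])]
        r = evaluate(s, RO_1234, {c: 100 for c in "1234"})
        assert (r.sensitivity, r.precision) == (1.0, 1.0)
        assert r.genome_coverage == pytest.approx(0.75)
        assert r.scaffold_count == 1
        assert r.n50 == 400
        assert not r.no_joins

    def test_all_singletons(self):
        s = [make_scaffold([f"+{c}"]) for c in "1234"]
        r = evaluate(s, RO_1234, {c: 100 for c in "1234"})
        assert r.sensitivity == 0.0
        assert r.genome_coverage == 0.0
        assert r.scaffold_count == 4
        assert r.no_joins and r.precision == 1.0

    def test_report_matches_per_metric_recomputation(self, rng):
        for _ in range(15):
            n = int(rng.integers(2, 10))
            ids = [str(i) for i in range(1, n + 1)]
            lengths = {c: int(rng.integers(50, 5000)) for c in ids}
            ro = ReferenceOrder(order=make_scaffold([f"+{c}" for c in ids]))
            perm = [str(i) for i in rng.permutation(range(1, n + 1))]
            signs = rng.choice(["+", "-"], size=n)
            signed = [f"{sg}{c}" for sg, c in zip(signs, perm)]
            cuts = sorted(set(rng.integers(1, n, size=int(rng.integers(0, n))).tolist()))
            scaffolds, prev = [], 0
            for c in cuts + [n]:
                if c > prev:
                    scaffolds.append(make_scaffold(signed[prev:c]))
                    prev = c
            r = evaluate(scaffolds, ro, lengths)
            tp, fp, p = classify_joins(scaffolds, ro)
            assert (r.tp, r.fp, r.p) == (tp, fp, p)
            assert r.sensitivity == (tp / p if p else 1.0)
            assert r.precision == (tp / (tp + fp) if tp + fp else 1.0)
            assert r.genome_coverage == pytest.approx(genome_coverage(scaffolds, ro, lengths))
            assert r.n50 == n50(scaffolds, lengths)
            assert 0 <= r.tp <= r.p
            assert 0.0 <= r.sensitivity <= 1.0
            assert 0.0 <= r.precision <= 1.0
            assert 0.0 <= r.genome_coverage <= 1.0
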