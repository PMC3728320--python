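import itertools

import numpy as np
import pytest

from plastid_delim.alignment_stats import (
    collapse_haplotypes,
    detect_indels,
    diversity,
    gc_content,
    simple_indel_coding,
    site_classes,
)
from plastid_delim.errors import AlignmentError
from plastid_delim.io_formats import Alignment

from conftest import random_alignment


def brute_force_pi_theta(rows: list[str]):
    """Independent oracle: complete deletion, all-pairs all-sites loops."""
    n, L = len(rows), len(rows[0])
    keep = [c for c in range(L) if all(r[c] in "ACGT" for r in rows)]
    S = sum(1 for c in keep if len({r[c] for r in rows}) >= 2)
    total = 0
    for i, j in itertools.combinations(range(n), 2):
        total += sum(1 for c in keep if rows[i][c] != rows[j][c])
    npairs = n * (n - 1) / 2
    a_n = sum(1.0 / i for i in range(1, n))
    L_eff = len(keep)
    return S, S / (a_n * L_eff), total / npairs / L_eff


class TestSiteClasses:
    def test_hand_example(self, toy_alignment):
        sc = site_classes(toy_alignment, gap_policy="missing")
        assert (sc.constant, sc.variable_uninformative, sc.parsimony_informative) == (1, 1, 1)

    def test_identical_rows_all_constant(self):
        aln = Alignment([("a", "ACGT"), ("b", "ACGT")])
        sc = site_classes(aln)
        assert sc.constant == 4 and sc.variable == 0

    def test_exclude_site_policy_counts_gapped_columns(self):
        aln = Alignment([("a", "A-GT"), ("b", "ACGT"), ("c", "ACGA")])
        sc = site_classes(aln, gap_policy="exclude_site")
        assert sc.excluded == 1
        assert sc.total == 4

    def test_counts_sum_to_length(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            aln = random_alignment(rng, 6, 30, missing_frac=0.1)
            for policy in ("missing", "exclude_site"):
                assert site_classes(aln, gap_policy=policy).total == 30

    def test_informative_count_invariant_to_row_order_and_constant_columns(self):
        rng = np.random.default_rng(5)
        aln = random_alignment(rng, 8, 40, missing_frac=0.05)
        base = site_classes(aln).parsimony_informative
        perm = Alignment(list(reversed(aln.rows)))
        assert site_classes(perm).parsimony_informative == base
        padded = Alignment([(i, s + "AAAA") for i, s in aln.rows])
        assert site_classes(padded).parsimony_informative == base


class TestDiversity:
    def test_hand_example(self, toy_alignment):
        d = diversity(toy_alignment, deletion="complete")
        assert d.S == 2
        assert d.a_n == pytest.approx(11 / 6)
        assert d.theta_w_site == pytest.approx(2 / ((11 / 6) * 3))
        assert d.pi_site == pytest.approx((7 / 6) / 3)

    def test_identical_rows_zero(self):
        aln = Alignment([("a", "ACGT"), ("b", "ACGT")])
        d = diversity(aln)
        assert d.theta_w_site == 0 and d.pi_site == 0

    def test_no_analyzable_sites_is_an_error(self):
        aln = Alignment([("a", "-N"), ("b", "AN")])
        with pytest.raises(AlignmentError, match="no analyzable"):
            diversity(aln, deletion="complete")

    def test_matches_brute_force_oracle_on_random_alignments(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            n = int(rng.integers(3, 13))
            L = int(rng.integers(10, 51))
            aln = random_alignment(rng, n, L, missing_frac=0.05)
            rows = [s for _, s in aln.rows]
            try:
                S, theta, pi = brute_force_pi_theta(rows)
            except ZeroDivisionError:
                continue
            d = diversity(aln, deletion="complete")
            assert d.S == S
            assert d.theta_w_site == pytest.approx(theta)
            assert d.pi_site == pytest.approx(pi)

    def test_pairwise_deletion_normalises_per_pair(self):
        # pair (a,b): 1 diff over 3 shared; (a,c): 0/4... computed by hand
        aln = Alignment([("a", "ACGT"), ("b", "NCGA"), ("c", "ACGT")])
        d = diversity(aln, deletion="pairwise")
        # pairs: a-b diff 1/3, a-c 0/4, b-c 1/3
        assert d.pi_site == pytest.approx((1 / 3 + 0 + 1 / 3) / 3)


class TestGC:
    @pytest.mark.parametrize(
        "rows,expect",
        [([("a", "GGCC")], 1.0), ([("a", "AT")], 0.0),
         ([("a", "ACGT"), ("b", "ACGA")], 0.5)],
    )
    def test_examples(self, rows, expect):
        assert gc_content(Alignment(rows)) == pytest.approx(expect)

    def test_all_missing_is_an_error(self):
        with pytest.raises(AlignmentError):
            gc_content(Alignment([("a", "NN--")]))


class TestHaplotypes:
    def test_strict_vs_distance_zero(self):
        aln = Alignment([("a", "AAT"), ("b", "AAN")])
        assert collapse_haplotypes(aln, identity="strict").n_haplotypes == 2
        assert collapse_haplotypes(aln, identity="distance_zero").n_haplotypes == 1

    def test_strict_groups_identical_rows(self):
        aln = Alignment([("a", "AAT"), ("b", "AAT"), ("c", "AGT")])
        tab = collapse_haplotypes(aln, identity="strict")
        assert tab.n_haplotypes == 2
        assert tab.classes[0][1] == ["a", "b"]

    def test_single_linkage_closure_is_transitive(self):
        # a~b via missing, b~c via missing, but a and c differ: still one class
        aln = Alignment([("a", "AAT"), ("b", "ANT"), ("c", "ACT")])
        tab = collapse_haplotypes(aln, identity="distance_zero")
        assert tab.n_haplotypes == 1

    def test_strict_refines_distance_zero_on_random_inputs(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            aln = random_alignment(rng, int(rng.integers(2, 10)), 20,
                                   missing_frac=0.15)
            strict = collapse_haplotypes(aln, identity="strict")
            dz = collapse_haplotypes(aln, identity="distance_zero")
            dz_of = dz.class_of()
            for _, members in strict.classes:
                assert len({dz_of[m] for m in members}) == 1
            assert dz.n_haplotypes <= strict.n_haplotypes <= aln.n


class TestIndels:
    def test_shared_event(self):
        aln = Alignment([("a", "A--T"), ("b", "A--T"), ("c", "ACGT")])
        events = detect_indels(aln)
        assert len(events) == 1
        assert (events[0].start, events[0].end) == (2, 3)
        assert events[0].members == ("a", "b")

    def test_no_gaps_no_events(self, toy_alignment):
        assert detect_indels(toy_alignment) == []

    def test_terminal_run_is_missing_not_indel(self):
        aln = Alignment([("a", "A--T"), ("b", "A---"), ("c", "ACGT")])
        events = detect_indels(aln)
        assert [(e.start, e.end) for e in events] == [(2, 3)]
        assert events[0].members == ("a",)

    def test_leading_run_excluded(self):
        aln = Alignment([("a", "--GT"), ("b", "ACGT")])
        assert detect_indels(aln) == []


class TestSimpleIndelCoding:
    def test_states_for_shared_event(self):
        aln = Alignment([("a", "A--T"), ("b", "A--T"), ("c", "ACGT")])
        coding = simple_indel_coding(aln)
        assert len(coding.events) == 1
        assert (coding.matrix["a"], coding.matrix["b"], coding.matrix["c"]) == ("1", "1", "0")

    def test_nested_gap_coded_inapplicable(self):
        aln = Alignment(
            [("a", "A---TCCG"), ("b", "A-----TG"), ("c", "ACGATCCG")]
        )
        coding = simple_indel_coding(aln)
        spans = [(e.start, e.end) for e in coding.events]
        assert (2, 4) in spans and (2, 6) in spans
        col = spans.index((2, 4))
        assert coding.matrix["a"][col] == "1"
        assert coding.matrix["b"][col] == "-"  # longer gap strictly contains
        assert coding.matrix["c"][col] == "0"

    def test_gapless_alignment_adds_no_characters(self, toy_alignment):
        assert simple_indel_coding(toy_alignment).events == []

    def test_one_character_per_event_and_stability_under_row_removal(self):
        rng = np.random.default_rng(3)
        aln = Alignment(
            [("a", "AC--TGGA"), ("b", "AC--TGGA"), ("c", "ACGATG-A"),
             ("d", "ACGATGGA")]
        )
        coding = simple_indel_coding(aln)
        assert all(len(v) == len(coding.events) for v in coding.matrix.values())
        # drop d (member of no event): characters of untouched events identical
        smaller = Alignment([r for r in aln.rows if r[0] != "d"])
        coding2 = simple_indel_coding(smaller)
        assert [(e.start, e.end) for e in coding2.events] == [
            (e.start, e.end) for e in coding.events
        ]
        for rid in ("a", "b", "c"):
            assert coding2.matrix[rid] == coding.matrix[rid]
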