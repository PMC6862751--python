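"""Global aligner: oracle equivalence, tie rules, orientation choice,
window extraction."""

import numpy as np
import pytest

from oracle_align import dp_score, enum_score

from islandswap.align_core import (
    Reference,
    ScoringScheme,
    align_best,
    choose_orientation,
    extract_window,
    global_align,
)
from islandswap.reference_model import (
    derive_allele,
    invert_between_cuts,
    locus_with_insert,
    revcomp,
)


def random_dna(rng, n, with_n=False):
    alpha = list("ACGTN" if with_n else "ACGT")
    p = [0.23, 0.23, 0.23, 0.23, 0.08] if with_n else None
    return "".join(rng.choice(alpha, size=n, p=p))


def mutate(seq, rate, rng):
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([c for c in "ACGT" if c != out[i]])
    return "".join(out)


class TestOracle:
    def test_enumeration_validates_dp_oracle(self, rng):
        # the DP oracle itself is checked against exhaustive path
        # enumeration on very small pairs
        for _ in range(30):
            q = random_dna(rng, rng.integers(1, 6))
            r = random_dna(rng, rng.integers(1, 6))
            assert dp_score(q, r) == pytest.approx(enum_score(q, r))

    def test_kernel_matches_dp_oracle_small_pairs(self, rng):
        for _ in range(100):
            q = random_dna(rng, rng.integers(1, 9), with_n=True)
            r = random_dna(rng, rng.integers(1, 9))
            got = global_align(q, r, band=None).score
            assert got == pytest.approx(dp_score(q, r)), (q, r)

    def test_identity_alignment(self):
        a = global_align("ACGTACGT", "ACGTACGT")
        assert a.score == 40.0  # 8 matches at +5
        assert a.ops == [("=", 8)]
        assert a.indel_events() == []

    def test_single_base_deletion(self):
        a = global_align("ACGT", "ACGGT")
        assert a.score == pytest.approx(4 * 5 - 10.5)
        events = a.indel_events()
        assert len(events) == 1 and events[0].size == -1

    def test_empty_and_bad_alphabet(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT")
        with pytest.raises(ValueError):
            global_align("ACQT", "ACGT")


class TestTieRules:
    def test_mismatch_preferred_over_gap_pair(self):
        # with open=1, ext=1 a mismatch (-4) ties an I+D pair (-2-2)
        sc = ScoringScheme(5, -4, 1.0, 1.0)
        a = global_align("AT", "AA", sc, band=None)
        assert a.ops == [("=", 1), ("X", 1)]

    def test_deletion_before_insertion_on_tie(self):
        # mismatches priced out: the two optimal paths are D-then-I or
        # I-then-D around the shared middle base; deletion must lead
        sc = ScoringScheme(5, -100, 0.5, 0.5)
        a = global_align("CA", "AC", sc, band=None)
        assert a.score == pytest.approx(5 - 1 - 1)
        assert a.ops[0][0] == "D"

    def test_leftmost_indel_placement(self):
        a = global_align("AAAA", "AAAAA")
        assert a.ops == [("D", 1), ("=", 4)]
        b = global_align("AAAAA", "AAAA")
        assert b.ops == [("I", 1), ("=", 4)]

    def test_query_n_is_always_mismatch(self):
        a = global_align("ANGT", "ACGT")
        assert a.ops == [("=", 1), ("X", 1), ("=", 2)]
        _, exact, _ = extract_window(a, (0, 4))
        assert not exact

    def test_reference_n_is_wildcard(self):
        a = global_align("ACGT", "NNGT")
        assert a.ops == [("=", 4)]
        assert a.score == 20.0


class TestBandedEqualsFull:
    def test_on_indel_bearing_pairs(self, rng):
        for _ in range(15):
            ref = random_dna(rng, 400)
            q = list(mutate(ref, 0.01, rng))
            # plant a deletion and an insertion
            del_at = int(rng.integers(50, 150))
            del_len = int(rng.integers(1, 30))
            ins_at = int(rng.integers(200, 350))
            q[del_at : del_at + del_len] = []
            q[ins_at:ins_at] = list(random_dna(rng, int(rng.integers(1, 20))))
            q = "".join(q)
            full = global_align(q, ref, band=None)
            banded = global_align(q, ref, band=64)
            assert banded.score == full.score
            assert banded.cigar() == full.cigar()

    def test_score_monotone_under_substitution(self, rng):
        ref = random_dna(rng, 120)
        q = mutate(ref, 0.02, rng)
        base = global_align(q, ref).score
        for _ in range(10):
            i = int(rng.integers(len(q)))
            sub = q[:i] + rng.choice([c for c in "ACGT" if c != q[i]]) + q[i + 1 :]
            assert global_align(sub, ref).score <= base + 1e-9


class TestChooseOrientation:
    def test_exact_inverted_read(self, model, pb_refs):
        inv = invert_between_cuts(model, model.insert_seq)
        a = choose_orientation("A" * 12 + inv, pb_refs)
        assert a.orientation_class == "inverted"
        assert a.orientation == "as-is"

    def test_revcomp_of_forward_locus(self, model, pb_refs):
        rd = "A" * 12 + model.locus_seq
        a = choose_orientation(revcomp(rd), pb_refs)
        assert a.orientation_class == "forward"
        assert a.orientation == "revcomp"

    def test_symmetry_under_reverse_complement(self, model, pb_refs, rng):
        base = locus_with_insert(model, derive_allele(model, "allele2", True))
        for _ in range(5):
            rd = random_dna(rng, 12) + mutate(base, 0.006, rng)
            a = choose_orientation(rd, pb_refs)
            b = choose_orientation(revcomp(rd), pb_refs)
            assert a.orientation_class == b.orientation_class
            assert a.score == b.score
            assert {a.orientation, b.orientation} == {"as-is", "revcomp"}

    def test_wholesale_deletion_ties_across_classes(self, model, pb_refs):
        rd = "A" * 12 + model.flank_up_seq + model.flank_down_seq
        a = choose_orientation(rd, pb_refs)
        assert a.ambiguous  # flanks are shared by both references

    def test_simulated_inverted_reads_assigned(self, model, pb_refs, rng):
        inv = invert_between_cuts(model, derive_allele(model, "wildtype", False))
        hits = 0
        n = 60
        for _ in range(n):
            rd = random_dna(rng, 12) + mutate(inv, 0.006, rng)
            if rng.random() < 0.5:
                rd = revcomp(rd)
            a = choose_orientation(rd, pb_refs)
            hits += a.orientation_class == "inverted"
        assert hits / n >= 0.99

    def test_prescreen_equals_exact_mode(self, model, pb_refs, rng):
        base = locus_with_insert(model, derive_allele(model, "allele1", True))
        inv = invert_between_cuts(model, derive_allele(model, "allele1", True))
        for template in (base, inv):
            for _ in range(8):
                rd = random_dna(rng, 12) + mutate(template, 0.006, rng)
                fast = choose_orientation(rd, pb_refs, prescreen=True)
                slow = choose_orientation(rd, pb_refs, prescreen=False)
                assert (fast.score, fast.ref_id, fast.orientation, fast.cigar()) == (
                    slow.score, slow.ref_id, slow.orientation, slow.cigar()
                )

    def test_requires_both_orientation_classes(self, pb_refs):
        with pytest.raises(ValueError):
            choose_orientation("ACGT", [pb_refs[0]])


def test_sam_like_dump():
    from islandswap.align_core import to_sam_like

    a = global_align("ACGT", "ACGGT", query_id="r1", ref_id="ref")
    df = to_sam_like([a])
    assert list(df.cigar) == ["2=1D2="]  # leftmost placement in the GG run
    assert list(df.read_id) == ["r1"]


def test_normalize_deletions_to_cuts_moves_gap_flush():
    from islandswap.align_core import normalize_deletions_to_cuts

    # ref: flank "TTGC" + insert "GCAA..." — a deletion of the insert's
    # first two bases can sit two bases left (leftmost rule); the
    # normalizer must move it flush with the cut at position 4
    ref = "TTGC" + "GCAATT"
    q = "TTGC" + "AATT"
    a = global_align(q, ref, band=None)
    ev = a.indel_events()[0]
    assert (ev.ref_start, ev.ref_end) == (2, 4)  # leftmost placement
    b = normalize_deletions_to_cuts(a, ref, cuts=(4, 10))
    ev2 = b.indel_events()[0]
    assert (ev2.ref_start, ev2.ref_end) == (4, 6)
    assert b.score == a.score
    assert sum(n for op, n in b.ops if op != "D") == len(q)


class TestExtractWindow:
    def test_identity_window_exact(self):
        a = global_align("ACGTACGT", "ACGTACGT")
        bases, exact, overlap = extract_window(a, (2, 6))
        assert (bases, exact, overlap) == ("GTAC", True, False)

    def test_deletion_inside_window(self):
        a = global_align("ACGTGT", "ACGTACGT", band=None)
        bases, exact, overlap = extract_window(a, (2, 8))
        assert not exact and overlap

    def test_indel_abutting_window_is_exact(self):
        # 3-base deletion at reference positions 4..6, window starts at 7
        ref = "ACGTAAACGTACGT"
        q = ref[:4] + ref[7:]
        a = global_align(q, ref, band=None)
        assert any(e.size == -3 for e in a.indel_events())
        ev = next(e for e in a.indel_events() if e.size == -3)
        bases, exact, overlap = extract_window(a, (ev.ref_end, len(ref)))
        assert exact and not overlap

    def test_window_bounds_checked(self):
        a = global_align("ACGT", "ACGT")
        with pytest.raises(ValueError):
            extract_window(a, (0, 5))

    def test_excluded_positions_tolerate_mismatch(self):
        a = global_align("ACTT", "ACGT")
        _, exact, _ = extract_window(a, (0, 4))
        assert not exact
        _, exact_excl, _ = extract_window(a, (0, 4), exclude={2})
        assert exact_excl
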