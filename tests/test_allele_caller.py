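"""Allele x orientation calling under the perfect-match rules."""

import itertools

import numpy as np
import pytest

from islandswap.align_core import choose_orientation, global_align
from islandswap.allele_caller import (
    GROUPS,
    call_illumina,
    call_pacbio,
    calls_frame,
    tabulate,
)
from islandswap.reference_model import (
    derive_allele,
    invert_between_cuts,
    locus_with_insert,
    revcomp,
)
from islandswap.synthetic_reads import (
    IndelModel,
    SimConfig,
    emit_reads,
    simulate_cells,
    truth_group_orientation,
)

UMI = "ACGTACGTACGT"


def pb_call(read, pb_refs, pb_frames):
    a = choose_orientation(read, pb_refs)
    return call_pacbio(a, pb_frames)


class TestCallPacbio:
    @pytest.mark.parametrize(
        "allele,inverted,expected_group",
        [
            ("wildtype", False, "wildtype"),
            ("wildtype", True, "wildtype"),
            ("allele1", False, "allele1"),
            ("allele1", True, "allele1"),
            ("allele2", False, "allele2"),
            ("allele2", True, "allele2"),
        ],
    )
    def test_zero_error_classes(self, model, pb_refs, pb_frames, allele, inverted, expected_group):
        ins = derive_allele(model, allele, pam_mutated=(allele != "wildtype"))
        locus = invert_between_cuts(model, ins) if inverted else locus_with_insert(model, ins)
        call = pb_call(UMI + locus, pb_refs, pb_frames)
        assert call.group == expected_group
        assert call.orientation == ("inverted" if inverted else "forward")
        assert (call.left_indel, call.right_indel) == (0, 0)

    def test_strand_flipped_read_same_call(self, model, pb_refs, pb_frames):
        ins = derive_allele(model, "allele1", True)
        call = pb_call(revcomp(UMI + locus_with_insert(model, ins)), pb_refs, pb_frames)
        assert (call.group, call.orientation) == ("allele1", "forward")

    def test_wholesale_deletion(self, model, pb_refs, pb_frames):
        call = pb_call(UMI + model.flank_up_seq + model.flank_down_seq, pb_refs, pb_frames)
        assert call.group == "deletion"
        assert call.orientation == "n/a"

    def test_substitution_in_window_unassigned(self, model, pb_refs, pb_frames):
        locus = list(model.locus_seq)
        pos = model.flank_up + 400 - 1  # insert offset 400, inside the 250-bp window
        locus[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[locus[pos]]
        call = pb_call(UMI + "".join(locus), pb_refs, pb_frames)
        assert call.group == "unassigned" and call.reason == "window_mismatch"

    def test_all_16_snv_combinations(self, model, pb_refs, pb_frames):
        """Of the 2^4 SNV state combinations, exactly wild type, allele 1
        and allele 2 are callable; the 13 chimeric patterns are mixed."""
        offsets = sorted(s.offset for s in model.snvs)
        by_offset = {s.offset: s for s in model.snvs}
        valid = {
            (False, False, False, False): "wildtype",
            (True, False, False, True): "allele1",
            (False, True, True, False): "allele2",
        }
        n_assigned = 0
        for combo in itertools.product([False, True], repeat=4):
            expected = valid.get(combo)
            ins = list(model.insert_seq)
            for off, use_alt in zip(offsets, combo):
                if use_alt:
                    ins[off - 1] = by_offset[off].alt_base
            if expected in ("allele1", "allele2"):
                for pam in model.pams:
                    ins[pam.offset - 1] = pam.alt_base
            call = pb_call(UMI + locus_with_insert(model, "".join(ins)), pb_refs, pb_frames)
            if expected:
                assert call.group == expected
                n_assigned += 1
            else:
                assert call.group == "unassigned"
                assert call.reason == "snv_pattern_mixed"
        assert n_assigned == 3

    @pytest.mark.parametrize("side", ["left", "right"])
    @pytest.mark.parametrize("size", range(0, 11))
    def test_pam_window_theorem(self, model, pb_refs, pb_frames, side, size):
        """Junction deletions of up to 5 bases into the insert stay
        assignable; 6 or more remove the PAM base and do not."""
        ins = derive_allele(model, "allele1", True)
        chewed = ins[size:] if side == "left" else ins[: len(ins) - size]
        locus = model.flank_up_seq + chewed + model.flank_down_seq
        call = pb_call(UMI + locus, pb_refs, pb_frames)
        if size == 0:
            assert call.group == "allele1"
        elif size <= 5:
            assert call.group == "allele1"
            indel = call.left_indel if side == "left" else call.right_indel
            assert indel == -size
        else:
            assert call.group == "unassigned"
            assert call.reason == "pam_mismatch"

    def test_junction_insertion_recorded_and_assigned(self, model, pb_refs, pb_frames):
        ins = derive_allele(model, "allele2", True)
        locus = model.flank_up_seq + "TTTT" + ins + model.flank_down_seq
        call = pb_call(UMI + locus, pb_refs, pb_frames)
        assert call.group == "allele2"
        assert call.left_indel == 4

    def test_wrong_pam_state_unassigned(self, model, pb_refs, pb_frames):
        # transfected allele must carry PAM mutations; wild-type PAMs
        # with allele-1 SNVs is a PAM mismatch
        ins = derive_allele(model, "allele1", pam_mutated=False)
        call = pb_call(UMI + locus_with_insert(model, ins), pb_refs, pb_frames)
        assert call.group == "unassigned" and call.reason == "pam_mismatch"


class TestCallIllumina:
    def read_for(self, model, allele):
        lo, hi = model.illumina_window
        ins = derive_allele(model, allele, pam_mutated=(allele != "wildtype"))
        return UMI + ins[lo - 1 - 20 : hi + 20]

    def align(self, read, ill_frame):
        return global_align(read, ill_frame.ref.seq, ref_id=ill_frame.ref.ref_id)

    @pytest.mark.parametrize("allele", GROUPS)
    def test_zero_error_assignment(self, model, ill_frame, allele):
        a = self.align(self.read_for(model, allele), ill_frame)
        call = call_illumina(a, ill_frame)
        assert call.group == allele
        assert call.orientation == "forward"

    def test_substitution_in_window_unassigned(self, model, ill_frame):
        read = list(self.read_for(model, "wildtype"))
        i = 12 + 30  # inside the 44-bp window, not an SNV offset
        assert 502 <= (482 + 30) <= 545
        read[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[i]]
        call = call_illumina(self.align("".join(read), ill_frame), ill_frame)
        assert call.group == "unassigned" and call.reason == "window_mismatch"

    def test_chimeric_snv_pattern(self, model, ill_frame):
        by_offset = {s.offset: s for s in model.snvs}
        lo, hi = model.illumina_window
        ins = list(model.insert_seq)
        ins[532 - 1] = by_offset[532].alt_base  # allele1 state at 532 only
        read = UMI + "".join(ins)[lo - 1 - 20 : hi + 20]
        call = call_illumina(self.align(read, ill_frame), ill_frame)
        assert call.group == "unassigned" and call.reason == "snv_pattern_mixed"


class TestTabulate:
    def _df(self, rows):
        import pandas as pd

        return pd.DataFrame(
            rows,
            columns=["consensus_id", "branch", "group", "orientation",
                     "left_indel", "right_indel", "reason", "n_reads"],
        )

    def test_all_wildtype_is_100pct(self):
        df = self._df([(f"c{i}", "pacbio", "wildtype", "forward", 0, 0, "", 1)
                       for i in range(10)])
        t = tabulate(df, "strict_matched")
        assert t[t.group == "wildtype"].pct.iloc[0] == 100.0
        assert t["count"].sum() == 10

    def test_orientation_summary_50_50(self):
        rows = [(f"m{i}", "pacbio", "allele1", "forward", 0, 0, "", 1) for i in range(5)]
        rows += [(f"w{i}", "pacbio", "wildtype", "inverted", 0, 0, "", 1) for i in range(5)]
        t = tabulate(self._df(rows), "orientation")
        assert t[t.orientation == "forward"].pct.iloc[0] == 50.0

    def test_policy_sums_to_100(self):
        rows = [("a", "pacbio", "wildtype", "forward", 0, 0, "", 1),
                ("b", "pacbio", "allele1", "forward", 0, 0, "", 1),
                ("c", "pacbio", "allele2", "inverted", 0, 0, "", 1),
                ("d", "pacbio", "unassigned", "forward", 0, 0, "window_mismatch", 1),
                ("e", "pacbio", "deletion", "n/a", 0, 0, "", 1)]
        df = self._df(rows)
        strict = tabulate(df, "strict_matched")
        assert strict.pct.sum() == pytest.approx(100.0)
        assert strict.denominator.iloc[0] == 2  # forward assigned only
        full = tabulate(df, "all_aligned_minus_deletions")
        assert full.pct.sum() == pytest.approx(100.0)
        assert full.denominator.iloc[0] == 4  # deletion excluded, unassigned kept

    def test_empty_input_flagged(self):
        t = tabulate(self._df([]), "strict_matched")
        assert (t.denominator == 0).all()
        assert t.pct.isna().all()

    def test_unknown_policy(self):
        with pytest.raises(ValueError):
            tabulate(self._df([]), "bogus")


def test_zero_error_confusion_diagonal_small(model, pb_refs, pb_frames, rng):
    """At zero error and with junction indels off, every emitted long
    read is assigned and matches its truth class exactly."""
    cfg = SimConfig(
        n_cells=120,
        error_rates={"illumina": 0, "pacbio": 0, "bisulfite": 0},
        indel_model=IndelModel(prob_indel=0.0),
        methylated_allele="allele2",
    )
    cells = simulate_cells(model, cfg, rng)
    reads = emit_reads("pacbio", cells, model, cfg, rng)
    for r in reads:
        call = pb_call(r.seq, pb_refs, pb_frames)
        expected = truth_group_orientation(r.cell.outcome, cfg.methylated_allele)
        assert (call.group, call.orientation) == expected
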