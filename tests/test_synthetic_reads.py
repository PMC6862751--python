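"""Read simulator: outcome sampling, junction indels, selection,
branch emission rules, conversion and error models."""

import numpy as np
import pytest

from islandswap.reference_model import revcomp
from islandswap.synthetic_reads import (
    IndelModel,
    SimConfig,
    apply_selection,
    emit_reads,
    simulate_cell,
    simulate_cells,
    truth_table,
    truth_group_orientation,
    write_fastq,
)

NO_INDELS = IndelModel(prob_indel=0.0)


def cfg_with(**kw) -> SimConfig:
    kw.setdefault("indel_model", NO_INDELS)
    return SimConfig(**kw)


def pure(outcome: str, **kw) -> SimConfig:
    return cfg_with(class_proportions={outcome: 1.0}, **kw)


class TestSimulateCell:
    def test_wt_forward_identity(self, model, rng):
        cell = simulate_cell(model, pure("wt_fwd"), rng)
        assert cell.locus == model.locus_seq

    def test_clean_excision_length(self, model, rng):
        cell = simulate_cell(model, pure("deletion"), rng)
        assert len(cell.locus) == model.flank_up + model.flank_down
        assert cell.locus == model.flank_up_seq + model.flank_down_seq

    def test_inverted_insert(self, model, rng):
        cell = simulate_cell(model, pure("wt_inv"), rng)
        fu = model.flank_up
        assert cell.locus[fu : fu + model.insert_len] == revcomp(model.insert_seq)

    def test_class_counts_binomial(self, model):
        rng = np.random.default_rng(7)
        cfg = cfg_with(class_proportions={"meth_fwd": 0.3, "wt_inv": 0.7}, n_cells=10000)
        cells = simulate_cells(model, cfg, rng)
        k = sum(c.outcome == "meth_fwd" for c in cells)
        sigma = np.sqrt(10000 * 0.3 * 0.7)
        assert abs(k - 3000) <= 3 * sigma

    def test_junction_deletion_chews_symmetrically(self, model):
        rng = np.random.default_rng(0)
        im = IndelModel(prob_indel=1.0, p_insertion=0.0, mean_size=6.0, max_size=10)
        cfg = SimConfig(class_proportions={"wt_fwd": 1.0}, indel_model=im)
        cell = simulate_cell(model, cfg, rng)
        assert cell.left_indel < 0 and cell.right_indel < 0
        s = -cell.left_indel
        assert cell.left_del_into_insert == s - s // 2
        expected_len = len(model.locus_seq) + cell.left_indel + cell.right_indel
        assert len(cell.locus) == expected_len

    def test_junction_insertion_adds_bases(self, model):
        rng = np.random.default_rng(1)
        im = IndelModel(prob_indel=1.0, p_insertion=1.0, mean_size=4.0, max_size=10)
        cfg = SimConfig(class_proportions={"wt_fwd": 1.0}, indel_model=im)
        cell = simulate_cell(model, cfg, rng)
        assert cell.left_indel > 0 and cell.right_indel > 0
        assert len(cell.locus) == len(model.locus_seq) + cell.left_indel + cell.right_indel
        assert cell.left_del_into_insert == 0

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            SimConfig(class_proportions={"wt_fwd": 0.5})
        with pytest.raises(ValueError):
            SimConfig(maintenance_rate=1.5)


class TestSelection:
    def test_all_expressing_epsilon_zero_is_empty_pool(self, model, rng):
        cfg = pure("wt_fwd", epsilon=0.0)
        cells = simulate_cells(model, cfg, rng)
        with pytest.raises(ValueError):
            apply_selection(cells, cfg, "6tg", model, rng)

    def test_all_silenced_composition_unchanged(self, model, rng):
        cfg = pure("meth_fwd", epsilon=0.0)
        cells = simulate_cells(model, cfg, rng)
        out = apply_selection(cells, cfg, "6tg", model, rng)
        assert len(out) == len(cells)
        assert all(c.outcome == "meth_fwd" for c in out)

    def test_mixture_resolves_to_silenced_class(self, model, rng):
        cfg = cfg_with(
            class_proportions={"wt_fwd": 0.5, "wt_inv": 0.5}, epsilon=0.0, n_cells=400
        )
        cells = simulate_cells(model, cfg, rng)
        out = apply_selection(cells, cfg, "6tg", model, rng)
        assert all(c.outcome == "wt_inv" for c in out)

    def test_pre_is_identity_mock_resamples(self, model, rng):
        cfg = pure("wt_fwd")
        cells = simulate_cells(model, cfg, rng)
        assert apply_selection(cells, cfg, "pre", model, rng) == cells
        mock = apply_selection(cells, cfg, "mock", model, rng)
        assert len(mock) == len(cells)

    def test_functional_window_indel_rescues_expressing_cell(self, model, rng):
        # deletions long enough to reach the promoter/exon window make
        # an unmethylated forward insert selectable
        im = IndelModel(prob_indel=1.0, p_insertion=0.0, mean_size=500.0, max_size=1000)
        cfg = SimConfig(
            class_proportions={"unmeth_fwd": 1.0}, epsilon=0.0, n_cells=300,
            indel_model=im,
        )
        cells = simulate_cells(model, cfg, rng)
        out = apply_selection(cells, cfg, "6tg", model, rng)
        from islandswap.synthetic_reads import functional_window_hit

        assert out  # some deletions reach the window
        assert all(functional_window_hit(c, model) for c in out)

    def test_unknown_arm(self, model, rng):
        cfg = pure("wt_fwd")
        with pytest.raises(ValueError):
            apply_selection([], cfg, "weak", model, rng)


class TestEmission:
    def test_illumina_excludes_inversions_and_deletions(self, model, rng):
        cfg = cfg_with(
            class_proportions={
                "wt_fwd": 0.3, "wt_inv": 0.2, "deletion": 0.2,
                "meth_fwd": 0.15, "unmeth_inv": 0.15,
            },
            n_cells=300, error_rates={"illumina": 0.0, "pacbio": 0.0, "bisulfite": 0.0},
        )
        cells = simulate_cells(model, cfg, rng)
        reads = emit_reads("illumina", cells, model, cfg, rng)
        assert reads
        assert {r.cell.outcome for r in reads} <= {"wt_fwd", "meth_fwd", "unmeth_fwd"}

    def test_pacbio_deletion_exclusion_and_flag(self, model, rng):
        cfg = pure("deletion")
        cells = simulate_cells(model, cfg, rng)
        assert emit_reads("pacbio", cells, model, cfg, rng) == []
        cfg_keep = pure("deletion", keep_deletions=True)
        reads = emit_reads("pacbio", cells, model, cfg_keep, rng)
        assert len(reads) == len(cells)

    def test_zero_error_reads_are_exact_templates(self, model, rng):
        cfg = pure("wt_fwd", error_rates={"illumina": 0, "pacbio": 0, "bisulfite": 0},
                   n_cells=30)
        cells = simulate_cells(model, cfg, rng)
        for r in emit_reads("pacbio", cells, model, cfg, rng):
            seq = r.seq
            if r.cell.locus not in seq:
                seq = revcomp(seq)
            assert seq == r.umi + r.cell.locus

    def test_substitution_error_rate_poisson(self, model):
        rng = np.random.default_rng(3)
        cfg = pure("wt_fwd", n_cells=300)
        cells = simulate_cells(model, cfg, rng)
        reads = emit_reads("pacbio", cells, model, cfg, rng)
        L = len(reads[0].cell.locus) + cfg.umi_length
        subs = []
        for r in reads:
            seq = r.seq
            truth = r.umi + r.cell.locus
            if sum(a != b for a, b in zip(seq[:50], truth[:50])) > 10:
                seq = revcomp(seq)
            subs.append(sum(a != b for a, b in zip(seq, truth)))
        lam = 0.006 * L
        assert abs(np.mean(subs) - lam) <= 3 * np.sqrt(lam / len(reads))

    def test_bisulfite_perfect_conversion_methylated(self, model, rng):
        cfg = pure(
            "meth_fwd", maintenance_rate=1.0, conversion_failure_rate=0.0,
            background_methylation=0.0,
            error_rates={"illumina": 0, "pacbio": 0, "bisulfite": 0}, n_cells=5,
        )
        cells = simulate_cells(model, cfg, rng)
        reads = emit_reads("bisulfite", cells, model, cfg, rng)
        lo, hi = model.bisulfite_window
        start = lo - 20
        for r in reads:
            body = r.seq[cfg.umi_length :]
            # all 35 CpG cytosines retained
            for off in model.cpg_offsets:
                assert body[off - start] == "C"
            # every other C in the window reads T
            insert = model.insert_seq
            for off in range(lo, hi + 1):
                if insert[off - 1] == "C" and off not in model.cpg_offsets:
                    assert body[off - start] == "T"

    def test_bisulfite_unmethylated_keeps_no_cpg(self, model, rng):
        cfg = pure(
            "unmeth_fwd", conversion_failure_rate=0.0, background_methylation=0.0,
            error_rates={"illumina": 0, "pacbio": 0, "bisulfite": 0}, n_cells=5,
        )
        cells = simulate_cells(model, cfg, rng)
        for r in emit_reads("bisulfite", cells, model, cfg, rng):
            body = r.seq[cfg.umi_length :]
            start = model.bisulfite_window[0] - 20
            assert all(body[off - start] == "T" for off in model.cpg_offsets)

    def test_truth_class_conserved_and_counts(self, model, rng):
        cfg = cfg_with(
            class_proportions={"wt_fwd": 0.5, "meth_inv": 0.5},
            n_cells=50, reads_per_cell=3,
        )
        cells = simulate_cells(model, cfg, rng)
        reads = emit_reads("pacbio", cells, model, cfg, rng)
        assert len(reads) == 150
        by_cell = {}
        for r in reads:
            assert r.cell.outcome in ("wt_fwd", "meth_inv")
            by_cell.setdefault(r.cell.cell_id, set()).add(r.umi)
        assert all(len(u) == 1 for u in by_cell.values())  # one UMI per molecule

    def test_deterministic_fastq(self, model, tmp_path):
        cfg = SimConfig(n_cells=40)
        paths = []
        for i in (1, 2):
            rng = np.random.default_rng(99)
            cells = simulate_cells(model, cfg, rng)
            reads = emit_reads("pacbio", cells, model, cfg, rng)
            paths.append(write_fastq(reads, tmp_path / f"run{i}.fastq"))
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_truth_table_columns(self, model, rng):
        cfg = pure("meth_fwd", n_cells=5)
        cells = simulate_cells(model, cfg, rng)
        df = truth_table(emit_reads("pacbio", cells, model, cfg, rng))
        assert list(df.columns) == [
            "read_id", "cell_id", "class", "allele",
            "left_indel", "right_indel", "umi", "meth_vector",
        ]
        assert (df["class"] == "meth_fwd").all()
        assert df["meth_vector"].str.len().eq(35).all()


def test_truth_group_orientation_mapping():
    assert truth_group_orientation("deletion", "allele1") == ("deletion", "n/a")
    assert truth_group_orientation("wt_inv", "allele1") == ("wildtype", "inverted")
    assert truth_group_orientation("meth_fwd", "allele2") == ("allele2", "forward")
    assert truth_group_orientation("unmeth_inv", "allele2") == ("allele1", "inverted")
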