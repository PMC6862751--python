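"""Bisulfite read assignment and per-CpG methylation calling.

Bisulfite treatment deaminates unmethylated cytosine to uracil (read as
T) while methylated cytosine is protected, so a converted read can no
longer be compared against the plain reference.  Following the
experiment's strategy, each allele gets three reference variants: a
converted sequence assuming no CpG methylated (every C reads T), a
converted sequence assuming every CpG methylated (CpG cytosines keep
C), and the unconverted sequence.  A read is anchored on its
best-scoring variant; allele assignment then requires a perfect match
over the 283-bp analysis window at all conversion-invariant positions
(window bases that are not cytosines) and at the four SNV offsets under
their post-conversion expected bases.  The locus model guarantees no
SNV overlaps a CpG, so the C>T SNVs convert deterministically and the
three post-conversion SNV patterns remain mutually distinct (each
allele keeps one conversion-immune distinguishing base).

Methylation is then read per site, not inferred from the winning
variant: at each of the 35 window CpGs a C means methylated, a T
unmethylated, and a gap or other base is uncallable and excluded from
the count denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .align_core import (
    AlignmentResult,
    DEFAULT_SCORING,
    Reference,
    ScoringScheme,
    align_best,
    extract_window,
)
from .allele_caller import GROUPS, _group_patterns
from .reference_model import AmpliconModel, derive_allele

VARIANTS = ("converted_unmeth", "converted_meth", "unconverted")

#: margin of template kept on each side of the bisulfite window
BISULFITE_MARGIN = 20


def convert_sequence(seq: str, assume_methylated: bool) -> str:
    """Top-strand bisulfite conversion of a reference sequence.

    Every C becomes T; with ``assume_methylated`` the C of each CpG
    dinucleotide is retained instead.
    """
    out = list(seq)
    for i, b in enumerate(seq):
        if b != "C":
            continue
        if assume_methylated and i + 1 < len(seq) and seq[i + 1] == "G":
            continue
        out[i] = "T"
    return "".join(out)


@dataclass(frozen=True)
class BisulfiteReferenceSet:
    """Per-allele converted/unconverted references in one frame.

    All nine references share coordinates (conversion never changes
    length).  Positions are 0-based in the padded frame.
    """

    refs: dict[tuple[str, str], Reference]  # (group, variant) -> reference
    umi_window: tuple[int, int]
    window: tuple[int, int]
    snv_positions: tuple[int, ...]
    snv_expected: dict[str, tuple[str, ...]]  # post-conversion patterns
    cpg_positions: tuple[int, ...]
    invariant_exclude: frozenset[int]  # positions exempt from window exactness

    def all_refs(self) -> list[Reference]:
        return list(self.refs.values())


def build_bisulfite_refs(
    model: AmpliconModel, umi_length: int = 12, margin: int = BISULFITE_MARGIN
) -> BisulfiteReferenceSet:
    """Conversion-aware reference set over the bisulfite amplicon."""
    lo, hi = model.bisulfite_window
    start = lo - margin  # 1-based insert offset of template[0]
    pad = "N" * umi_length

    def pos(offset: int) -> int:
        return umi_length + offset - start

    refs: dict[tuple[str, str], Reference] = {}
    for group in GROUPS:
        insert = derive_allele(model, group, pam_mutated=(group != "wildtype"))
        template = insert[start - 1 : hi + margin]
        for variant, seq in (
            ("converted_unmeth", convert_sequence(template, False)),
            ("converted_meth", convert_sequence(template, True)),
            ("unconverted", template),
        ):
            refs[(group, variant)] = Reference(
                f"bis_{group}_{variant}", pad + seq, "forward"
            )

    snv_offsets = sorted(s.offset for s in model.snvs)
    fwd_patterns = _group_patterns(model)
    # post-conversion expectation: a C at an SNV offset is never in CpG
    # context (model constraint), so it always reads T after conversion
    snv_expected = {
        g: tuple(
            "T" if fwd_patterns[g][o] == "C" else fwd_patterns[g][o]
            for o in snv_offsets
        )
        for g in GROUPS
    }
    wt_insert = model.insert_seq
    invariant_exclude = frozenset(
        pos(o)
        for o in range(lo, hi + 1)
        if wt_insert[o - 1] == "C" or o in snv_offsets
    )
    return BisulfiteReferenceSet(
        refs=refs,
        umi_window=(0, umi_length),
        window=(pos(lo), pos(hi) + 1),
        snv_positions=tuple(pos(o) for o in snv_offsets),
        snv_expected=snv_expected,
        cpg_positions=tuple(pos(o) for o in model.cpg_offsets),
        invariant_exclude=invariant_exclude,
    )


@dataclass
class MethylationCall:
    """Per-consensus methylation summary over the 35 window CpGs."""

    consensus_id: str
    group: str  # wildtype / allele1 / allele2 / unassigned
    reason: str  # when unassigned
    states: str  # M/U/N per CpG site
    n_methylated: int
    n_callable: int
    n_reads: int = 1


def call_methylation(
    a: AlignmentResult,
    refset: BisulfiteReferenceSet,
    consensus_id: str = "",
    n_reads: int = 1,
) -> MethylationCall:
    """Assign a converted consensus to an allele and count methylated CpGs."""
    cid = consensus_id or a.query_id
    states = []
    for p in refset.cpg_positions:
        base = a.query_slice(p, p + 1)
        states.append("M" if base == "C" else "U" if base == "T" else "N")
    states_str = "".join(states)
    n_meth = states_str.count("M")
    n_call = len(states_str) - states_str.count("N")

    _, exact, _ = extract_window(a, refset.window, exclude=refset.invariant_exclude)
    if not exact:
        return MethylationCall(cid, "unassigned", "window_mismatch",
                               states_str, n_meth, n_call, n_reads)
    observed = tuple(a.query_slice(p, p + 1) for p in refset.snv_positions)
    hits = [g for g in GROUPS if refset.snv_expected[g] == observed]
    if len(hits) != 1:
        return MethylationCall(cid, "unassigned", "snv_pattern_mixed",
                               states_str, n_meth, n_call, n_reads)
    return MethylationCall(cid, hits[0], "", states_str, n_meth, n_call, n_reads)


def align_bisulfite(
    query: str,
    refset: BisulfiteReferenceSet,
    scoring: ScoringScheme = DEFAULT_SCORING,
    query_id: str = "",
    prescreen: bool = True,
) -> AlignmentResult:
    """Anchor a read on its best-scoring reference variant (directional
    amplicon: the reverse complement is not tried)."""
    return align_best(
        query, refset.all_refs(), scoring, query_id=query_id,
        prescreen=prescreen, try_revcomp=False,
    )


def methylation_frame(calls: list[MethylationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "consensus_id": [c.consensus_id for c in calls],
            "group": [c.group for c in calls],
            "reason": [c.reason for c in calls],
            "states": [c.states for c in calls],
            "n_methylated": [c.n_methylated for c in calls],
            "n_callable": [c.n_callable for c in calls],
            "n_reads": [c.n_reads for c in calls],
        }
    )


def methylation_histogram(
    calls: pd.DataFrame, n_sites: int = 35, by: list[str] | None = None
) -> pd.DataFrame:
    """Distribution of methylated-site counts 0..n per group (and any
    further grouping columns, e.g. arm); pass ``by=[]`` to sum across
    arms."""
    df = calls[calls.group != "unassigned"]
    keys = ["group"] + (by or [])
    rows = []
    for key, sub in df.groupby(keys):
        key = key if isinstance(key, tuple) else (key,)
        counts = sub["n_methylated"].value_counts()
        for k in range(n_sites + 1):
            rows.append((*key, k, int(counts.get(k, 0))))
    return pd.DataFrame(rows, columns=[*keys, "n_methylated", "count"])
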