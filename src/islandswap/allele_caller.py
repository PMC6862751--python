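"""Assignment of consensus sequences to allele x orientation groups.

A consensus is assigned to wild type, allele 1 or allele 2 only under
strict perfect-match rules mirroring the experiment's analysis:

* short-read branch: every base of the 44-bp exon window must match the
  reference (SNV offsets excepted) and the four SNV bases must equal
  exactly one allele's pattern; orientation is always forward because
  the nested amplicon cannot amplify inversions or deletions;
* long-read branch: wholesale deletions are recognised first (an
  alignment-level deletion of at least the insert length minus 50
  spanning the segment); otherwise the 250-bp promoter/exon/splice
  window, the four SNV bases and both PAM bases must match perfectly on
  whichever orientation's reference won the alignment.  Because the PAM
  mutations sit at the sixth base from each segment end, a junction
  deletion reaching six or more bases into the segment necessarily
  fails the PAM requirement and the read stays unassigned.

Unassigned is a value, never an error, and carries a reason code
(window_mismatch, snv_pattern_mixed, pam_mismatch,
ambiguous_orientation).  Junction indel sizes within +-5 bp of each cut
are recorded on every call where they can be determined.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .align_core import (
    AlignmentResult,
    DEFAULT_SCORING,
    Reference,
    ScoringScheme,
    extract_window,
    global_align,
    normalize_deletions_to_cuts,
)
from .reference_model import AmpliconModel, reference_loci

GROUPS = ("wildtype", "allele1", "allele2")
UNASSIGNED_REASONS = (
    "window_mismatch",
    "snv_pattern_mixed",
    "pam_mismatch",
    "ambiguous_orientation",
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: wholesale-deletion tolerance: alignment deletion of at least
#: insert_len - DELETION_TOLERANCE spanning the segment counts as a
#: wholesale deletion (replaces the amplicon-size criterion).
DELETION_TOLERANCE = 50

JUNCTION_WINDOW = 5  # bp on either side of a cut


@dataclass(frozen=True)
class CallingFrame:
    """Coordinate frame of one (padded) reference for calling.

    All positions are 0-based in the padded reference; ``cuts`` are
    inter-base positions of the two Cas9 cuts; expected SNV/PAM bases
    are given per group on this reference's strand.
    """

    ref: Reference
    umi_window: tuple[int, int]
    window: tuple[int, int]
    snv_positions: tuple[int, ...]
    snv_expected: dict[str, tuple[str, ...]]
    pam_positions: tuple[int, ...]
    pam_expected: dict[str, tuple[str, ...]]
    cuts: tuple[int, int] | None = None
    insert_span: tuple[int, int] | None = None
    #: allele-matched reference per group, same coordinates as ``ref``;
    #: used to re-anchor reads whose junction indel lets the optimal
    #: wild-type alignment swallow a mutated PAM/SNV base
    alt_refs: dict[str, Reference] | None = None


def _group_patterns(model: AmpliconModel) -> dict[str, dict[int, str]]:
    """Expected forward-strand base per SNV offset per group."""
    offsets = sorted(s.offset for s in model.snvs)
    by_offset = {s.offset: s for s in model.snvs}
    pats: dict[str, dict[int, str]] = {}
    for group in GROUPS:
        pats[group] = {
            o: (by_offset[o].alt_base if by_offset[o].allele_id == group else by_offset[o].ref_base)
            for o in offsets
        }
    return pats


def _pam_patterns(model: AmpliconModel) -> dict[str, dict[int, str]]:
    pats: dict[str, dict[int, str]] = {}
    for group in GROUPS:
        pats[group] = {
            p.offset: (p.ref_base if group == "wildtype" else p.alt_base)
            for p in model.pams
        }
    return pats


def pacbio_frames(model: AmpliconModel, umi_length: int = 12) -> dict[str, CallingFrame]:
    """Forward and inverted wild-type locus frames with UMI pads.

    Alignment always runs against the wild-type locus (SNVs/PAMs are
    point mismatches that barely perturb a global alignment); allele
    identity is then read off the aligned bases.  On the inverted
    reference, insert offsets map to mirrored positions and expected
    bases are complemented.
    """
    loci = reference_loci(model)
    pad = "N" * umi_length
    snv_offsets = sorted(s.offset for s in model.snvs)
    pam_offsets = sorted(p.offset for p in model.pams)
    snv_pats = _group_patterns(model)
    pam_pats = _pam_patterns(model)
    lo, hi = model.pacbio_window
    n = model.insert_len

    def fwd_pos(offset: int) -> int:
        return umi_length + model.flank_up + offset - 1

    def inv_pos(offset: int) -> int:
        return umi_length + model.flank_up + (n - offset)

    cuts = (umi_length + model.cut_left, umi_length + model.cut_right)
    alt_fwd = {
        g: Reference(
            f"locus_{'wt' if g == 'wildtype' else g}_fwd",
            pad + loci[f"locus_{'wt' if g == 'wildtype' else g}_fwd"],
            "forward",
        )
        for g in GROUPS
    }
    alt_inv = {
        g: Reference(
            f"locus_{'wt' if g == 'wildtype' else g}_inv",
            pad + loci[f"locus_{'wt' if g == 'wildtype' else g}_inv"],
            "inverted",
        )
        for g in GROUPS
    }
    frames = {}
    frames["locus_wt_fwd"] = CallingFrame(
        ref=Reference("locus_wt_fwd", pad + loci["locus_wt_fwd"], "forward"),
        umi_window=(0, umi_length),
        window=(fwd_pos(lo), fwd_pos(hi) + 1),
        snv_positions=tuple(fwd_pos(o) for o in snv_offsets),
        snv_expected={
            g: tuple(snv_pats[g][o] for o in snv_offsets) for g in GROUPS
        },
        pam_positions=tuple(fwd_pos(o) for o in pam_offsets),
        pam_expected={
            g: tuple(pam_pats[g][o] for o in pam_offsets) for g in GROUPS
        },
        cuts=cuts,
        insert_span=cuts,
        alt_refs=alt_fwd,
    )
    frames["locus_wt_inv"] = CallingFrame(
        ref=Reference("locus_wt_inv", pad + loci["locus_wt_inv"], "inverted"),
        umi_window=(0, umi_length),
        window=(inv_pos(hi), inv_pos(lo) + 1),
        snv_positions=tuple(inv_pos(o) for o in snv_offsets),
        snv_expected={
            g: tuple(_COMP[snv_pats[g][o]] for o in snv_offsets) for g in GROUPS
        },
        pam_positions=tuple(inv_pos(o) for o in pam_offsets),
        pam_expected={
            g: tuple(_COMP[pam_pats[g][o]] for o in pam_offsets) for g in GROUPS
        },
        cuts=cuts,
        insert_span=cuts,
        alt_refs=alt_inv,
    )
    return frames


def illumina_frame(
    model: AmpliconModel, umi_length: int = 12, margin: int = 20
) -> CallingFrame:
    """Short-amplicon wild-type frame (44-bp exon window plus margins)."""
    lo, hi = model.illumina_window
    start = lo - margin  # 1-based insert offset of the first template base
    template = model.insert_seq[start - 1 : hi + margin]
    pad = "N" * umi_length
    snv_offsets = sorted(s.offset for s in model.snvs)
    snv_pats = _group_patterns(model)

    def pos(offset: int) -> int:
        return umi_length + offset - start

    return CallingFrame(
        ref=Reference("illumina_wt", pad + template, "forward"),
        umi_window=(0, umi_length),
        window=(pos(lo), pos(hi) + 1),
        snv_positions=tuple(pos(o) for o in snv_offsets),
        snv_expected={g: tuple(snv_pats[g][o] for o in snv_offsets) for g in GROUPS},
        pam_positions=(),
        pam_expected={g: () for g in GROUPS},
    )


@dataclass
class AlleleCall:
    """Classification of one consensus sequence."""

    consensus_id: str
    branch: str
    group: str  # wildtype / allele1 / allele2 / deletion / unassigned
    orientation: str  # forward / inverted / n/a
    left_indel: int = 0
    right_indel: int = 0
    reason: str = ""  # populated when group == "unassigned"
    n_reads: int = 1


def junction_indels(
    a: AlignmentResult, cuts: tuple[int, int], window: int = JUNCTION_WINDOW
) -> tuple[int, int]:
    """Signed indel size at each cut (0 = none within the window).

    An event belongs to a junction when its junction-proximal edge lies
    within ``window`` bases of the cut; with several events the one
    whose edge is closest wins.
    """
    out = []
    for cut in cuts:
        best_size = 0
        best_dist = window + 1
        for ev in a.indel_events():
            dist = min(abs(ev.ref_start - cut), abs(ev.ref_end - cut))
            if dist <= window and dist < best_dist:
                best_dist = dist
                best_size = ev.size
        out.append(best_size)
    return out[0], out[1]


def _bases_at(a: AlignmentResult, positions: tuple[int, ...]) -> tuple[str, ...]:
    return tuple(a.query_slice(p, p + 1) for p in positions)


def _match_group(
    observed: tuple[str, ...], expected: dict[str, tuple[str, ...]]
) -> str | None:
    hits = [g for g in GROUPS if expected[g] == observed]
    return hits[0] if len(hits) == 1 else None


def call_illumina(
    a: AlignmentResult, frame: CallingFrame, consensus_id: str = "", n_reads: int = 1
) -> AlleleCall:
    """Short-read call: perfect 44-bp window + exact SNV pattern."""
    cid = consensus_id or a.query_id
    _, exact, _ = extract_window(a, frame.window, exclude=set(frame.snv_positions))
    if not exact:
        return AlleleCall(cid, "illumina", "unassigned", "n/a",
                          reason="window_mismatch", n_reads=n_reads)
    group = _match_group(_bases_at(a, frame.snv_positions), frame.snv_expected)
    if group is None:
        return AlleleCall(cid, "illumina", "unassigned", "n/a",
                          reason="snv_pattern_mixed", n_reads=n_reads)
    return AlleleCall(cid, "illumina", group, "forward", n_reads=n_reads)


def is_wholesale_deletion(a: AlignmentResult, frame: CallingFrame) -> bool:
    """Alignment-level wholesale loss of the cut-to-cut segment."""
    if frame.insert_span is None:
        return False
    lo, hi = frame.insert_span
    min_size = (hi - lo) - DELETION_TOLERANCE
    for ev in a.indel_events():
        if ev.size <= -min_size and ev.ref_start < hi and ev.ref_end > lo:
            return True
    return False


def call_pacbio(
    a: AlignmentResult,
    frames: dict[str, CallingFrame],
    consensus_id: str = "",
    n_reads: int = 1,
    refine: bool = True,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> AlleleCall:
    """Long-read call on the winning orientation's reference frame.

    With ``refine`` (default), a read that fails the perfect-match
    rules *and* carries a junction indel is re-anchored against each
    allele-matched reference before being declared unassigned: against
    the wild-type reference the optimal alignment of such a read can
    shift its junction deletion to swallow a mutated PAM base (hiding a
    mismatch inside the gap), whereas the allele-specific expectations
    of the matching rules are frame-stable.
    """
    cid = consensus_id or a.query_id
    frame = frames[a.ref_id]
    if frame.cuts is not None:
        a = normalize_deletions_to_cuts(a, frame.ref.seq, frame.cuts)
    call = _call_pacbio_once(a, frame, cid, n_reads)
    if (
        refine
        and call.group == "unassigned"
        and call.reason in ("window_mismatch", "snv_pattern_mixed", "pam_mismatch")
        and (call.left_indel != 0 or call.right_indel != 0)
        and frame.alt_refs
    ):
        for group in ("allele1", "allele2"):
            alt = frame.alt_refs[group]
            a2 = global_align(
                a.query, alt.seq, scoring, query_id=a.query_id,
                ref_id=a.ref_id, orientation=a.orientation,
                orientation_class=frame.ref.orientation_class,
            )
            if frame.cuts is not None:
                a2 = normalize_deletions_to_cuts(a2, alt.seq, frame.cuts)
            call2 = _call_pacbio_once(a2, frame, cid, n_reads)
            if call2.group in GROUPS:
                return call2
    return call


def _call_pacbio_once(
    a: AlignmentResult,
    frame: CallingFrame,
    cid: str,
    n_reads: int,
) -> AlleleCall:
    assert frame.cuts is not None
    li, ri = junction_indels(a, frame.cuts)

    # a wholesale deletion aligns identically to both orientation
    # references (the flanks are shared), so check it before the
    # orientation-ambiguity flag
    if is_wholesale_deletion(a, frame):
        return AlleleCall(cid, "pacbio", "deletion", "n/a",
                          left_indel=li, right_indel=ri, n_reads=n_reads)
    if a.ambiguous:
        return AlleleCall(cid, "pacbio", "unassigned", "n/a",
                          left_indel=li, right_indel=ri,
                          reason="ambiguous_orientation", n_reads=n_reads)
    orientation = "forward" if frame.ref.orientation_class == "forward" else "inverted"
    _, exact, _ = extract_window(a, frame.window, exclude=set(frame.snv_positions))
    if not exact:
        return AlleleCall(cid, "pacbio", "unassigned", orientation,
                          left_indel=li, right_indel=ri,
                          reason="window_mismatch", n_reads=n_reads)
    group = _match_group(_bases_at(a, frame.snv_positions), frame.snv_expected)
    if group is None:
        return AlleleCall(cid, "pacbio", "unassigned", orientation,
                          left_indel=li, right_indel=ri,
                          reason="snv_pattern_mixed", n_reads=n_reads)
    if _bases_at(a, frame.pam_positions) != frame.pam_expected[group]:
        return AlleleCall(cid, "pacbio", "unassigned", orientation,
                          left_indel=li, right_indel=ri,
                          reason="pam_mismatch", n_reads=n_reads)
    return AlleleCall(cid, "pacbio", group, orientation,
                      left_indel=li, right_indel=ri, n_reads=n_reads)


def calls_frame(calls: list[AlleleCall]) -> pd.DataFrame:
    """One row per call."""
    return pd.DataFrame(
        {
            "consensus_id": [c.consensus_id for c in calls],
            "branch": [c.branch for c in calls],
            "group": [c.group for c in calls],
            "orientation": [c.orientation for c in calls],
            "left_indel": [c.left_indel for c in calls],
            "right_indel": [c.right_indel for c in calls],
            "reason": [c.reason for c in calls],
            "n_reads": [c.n_reads for c in calls],
        }
    )


POLICIES = ("strict_matched", "all_aligned_minus_deletions", "orientation")


def tabulate(
    calls: pd.DataFrame | list[AlleleCall],
    policy: str = "strict_matched",
    sample_id: str = "",
    arm: str = "",
) -> pd.DataFrame:
    """Frequency table under one denominator policy.

    ``strict_matched``: percentages of assigned *forward* groups over
    assigned forward calls only (short-read / exact-match convention;
    wild type included in the denominator).
    ``all_aligned_minus_deletions``: percentages of each assigned
    (group, orientation) over every non-deletion consensus, assigned or
    not (insertion-rate convention; an ``unassigned`` row completes the
    table).
    ``orientation``: forward vs inverted percentages over assigned
    non-deletion calls, groups collapsed (deletions not counted).
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}")
    df = calls if isinstance(calls, pd.DataFrame) else calls_frame(calls)
    rows = []
    if policy == "strict_matched":
        sub = df[(df.group.isin(GROUPS)) & (df.orientation == "forward")]
        denom = len(sub)
        for g in GROUPS:
            n = int((sub.group == g).sum())
            rows.append((g, "forward", n))
    elif policy == "all_aligned_minus_deletions":
        sub = df[df.group != "deletion"]
        denom = len(sub)
        for g in GROUPS:
            for o in ("forward", "inverted"):
                n = int(((sub.group == g) & (sub.orientation == o)).sum())
                rows.append((g, o, n))
        rows.append(("unassigned", "n/a", int((sub.group == "unassigned").sum())))
    else:  # orientation
        sub = df[df.group.isin(GROUPS)]
        denom = len(sub)
        for o in ("forward", "inverted"):
            rows.append(("any", o, int((sub.orientation == o).sum())))
    out = pd.DataFrame(rows, columns=["group", "orientation", "count"])
    out.insert(0, "sample_id", sample_id)
    out.insert(1, "arm", arm)
    out["policy"] = policy
    out["denominator"] = denom
    out["pct"] = 100.0 * out["count"] / denom if denom else float("nan")
    return out
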