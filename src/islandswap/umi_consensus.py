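"""UMI extraction, exact clustering, and per-cluster majority consensus.

Reads that share a unique molecular identifier are PCR copies of one
original molecule; collapsing them to a single consensus suppresses
independent sequencing errors.  UMIs are taken from the read bases that
align to the reference's UMI slot (the leading N-wildcard pad), reads
are grouped by exact UMI string (no edit-distance merging: with a
4^12 tag space collisions are negligible and exact grouping is the
reproducible minimal rule), and the consensus is a simple per-column
majority in the shared reference frame, realigned afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter

import numpy as np

from .align_core import AlignmentResult, extract_window

_CODE_TO_CHAR = np.array(list("ACGTN-"), dtype="U1")


def extract_umi(a: AlignmentResult, umi_window: tuple[int, int]) -> str | None:
    """Read bases aligned to the UMI slot, or None if gapped/incomplete.

    ``umi_window`` is 0-based half-open in the reference frame.  A read
    whose alignment has any gap over the slot cannot yield a full-length
    tag and is dropped (the caller counts these).
    """
    bases, _exact, indel_overlap = extract_window(a, umi_window)
    if indel_overlap or len(bases) != umi_window[1] - umi_window[0]:
        return None
    return bases


@dataclass
class UmiCluster:
    """Reads sharing one UMI, aligned to a common reference frame."""

    umi: str
    members: list[AlignmentResult]
    n_frame_excluded: int = 0  # members dropped for disagreeing on the reference

    @property
    def size(self) -> int:
        return len(self.members)


def cluster_by_umi(
    alignments: list[AlignmentResult], umis: list[str]
) -> list[UmiCluster]:
    """Exact-string grouping; one cluster per distinct UMI.

    Within a cluster, members aligned to a different (reference,
    orientation-class) than the cluster majority are excluded from
    consensus building and counted.
    """
    if len(alignments) != len(umis):
        raise ValueError("alignments and umis must be parallel")
    groups: dict[str, list[AlignmentResult]] = {}
    for a, u in zip(alignments, umis):
        groups.setdefault(u, []).append(a)
    clusters = []
    for umi, members in groups.items():
        frames = Counter((m.ref_id, m.orientation_class) for m in members)
        modal = frames.most_common(1)[0][0]
        kept = [m for m in members if (m.ref_id, m.orientation_class) == modal]
        clusters.append(UmiCluster(umi, kept, n_frame_excluded=len(members) - len(kept)))
    return clusters


def consensus(cluster: UmiCluster) -> str:
    """Per-column plurality consensus over the cluster's reference frame.

    At each reference position the plurality symbol among
    {A, C, G, T, gap} wins (read Ns abstain); a tie yields N, except
    that a gap is emitted only when it is the unique plurality.
    Insertions are voted as whole strings per inter-base position, the
    plurality string winning and ties resolving to no insertion.  The
    consensus of a single-read cluster is that read (in its aligned
    orientation).
    """
    if not cluster.members:
        raise ValueError("empty cluster")
    ref_len = cluster.members[0].ref_len
    k = len(cluster.members)
    mat = np.empty((k, ref_len), dtype=np.uint8)
    all_ins: list[dict[int, str]] = []
    for row, m in enumerate(cluster.members):
        col, ins = m.aligned_to_ref()
        mat[row] = col
        all_ins.append(ins)

    # votes per symbol: bases 0..3 and gap (5); N (4) abstains
    counts = np.stack([(mat == s).sum(axis=0) for s in (0, 1, 2, 3, 5)])
    top = counts.max(axis=0)
    n_top = (counts == top).sum(axis=0)
    winner = counts.argmax(axis=0)  # 0..3 base, 4 -> gap
    codes = np.where(
        (n_top == 1) & (top > 0),
        np.where(winner == 4, 5, winner),
        np.where(top == 0, 4, np.uint8(4)),  # no votes or tie -> N
    ).astype(np.uint8)

    ins_votes: dict[int, str] = {}
    ins_positions = set()
    for ins in all_ins:
        ins_positions.update(ins)
    for pos in ins_positions:
        tally = Counter(ins.get(pos, "") for ins in all_ins)
        best, n_best = tally.most_common(1)[0]
        ties = [s for s, c in tally.items() if c == n_best]
        ins_votes[pos] = best if len(ties) == 1 else ""

    out: list[str] = []
    for pos in range(ref_len):
        if pos in ins_votes and ins_votes[pos]:
            out.append(ins_votes[pos])
        c = codes[pos]
        if c != 5:
            out.append(str(_CODE_TO_CHAR[c]))
    if ref_len in ins_votes and ins_votes[ref_len]:
        out.append(ins_votes[ref_len])
    return "".join(out)


def cluster_table(clusters: list[UmiCluster]) -> "pd.DataFrame":  # noqa: F821
    """Cluster summary (umi, size, frame-excluded members)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "umi": [c.umi for c in clusters],
            "size": [c.size for c in clusters],
            "n_frame_excluded": [c.n_frame_excluded for c in clusters],
            "consensus_id": [f"u{c.umi}" for c in clusters],
        }
    )
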