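"""Indel occupancy profiles and junction indel size distributions.

Repair junctions formed at the two Cas9 cuts carry NHEJ indels whose
positional distribution peaks at the cut sites.  This module computes

* the per-reference-position fraction of reads whose alignment has an
  indel covering that position (deletion runs cover their span; an
  insertion, having no reference span, covers only its flanking
  reference position),
* signed size distributions of junction indels — events whose
  junction-proximal edge lies within 5 bp of a cut — with the reads
  that carry no junction indel contributing a size-0 bin, and the
  max-1 scaling used for cross-group comparison (every distribution is
  divided by its largest bin),
* per-group junction indel rates as (numerator, denominator) pairs for
  contingency testing.

Events are counted per event in size distributions; a read counts once
in rates, whatever its number of events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align_core import AlignmentResult
from .allele_caller import JUNCTION_WINDOW


@dataclass
class IndelProfile:
    """Fraction of included reads with an indel at each position."""

    fractions: np.ndarray
    n_reads: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(len(self.fractions)),
                "fraction": self.fractions,
                "n": self.n_reads,
            }
        )


@dataclass
class SizeDistribution:
    """Signed indel-size histogram; size 0 holds indel-free reads."""

    counts: dict[int, int]

    def scaled(self) -> dict[int, float]:
        """Counts divided by the largest bin (max-1 scaling)."""
        if not self.counts:
            return {}
        peak = max(self.counts.values())
        return {s: c / peak for s, c in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        scaled = self.scaled()
        sizes = sorted(self.counts)
        return pd.DataFrame(
            {
                "size": sizes,
                "count": [self.counts[s] for s in sizes],
                "scaled": [scaled[s] for s in sizes],
            }
        )


def positional_profile(alignments: list[AlignmentResult]) -> IndelProfile:
    """Indel occupancy along the reference for an included read set."""
    if not alignments:
        raise ValueError("empty inclusion set")
    ref_len = alignments[0].ref_len
    hit = np.zeros(ref_len, dtype=np.int64)
    for a in alignments:
        covered = np.zeros(ref_len, dtype=bool)
        for ev in a.indel_events():
            if ev.size < 0:
                covered[ev.ref_start : ev.ref_end] = True
            else:
                pos = min(ev.ref_start, ref_len - 1)
                covered[pos] = True
        hit += covered
    return IndelProfile(hit / len(alignments), len(alignments))


def junction_size_distribution(
    alignments: list[AlignmentResult],
    cuts: tuple[int, int],
    window: int = JUNCTION_WINDOW,
) -> SizeDistribution:
    """Per-event junction indel sizes (deletions negative).

    An event is a junction event when its junction-proximal edge lies
    within ``window`` bases of either cut.  Reads without any junction
    event land in the size-0 bin.
    """
    counts: dict[int, int] = {}
    for a in alignments:
        any_event = False
        for ev in a.indel_events():
            dist = min(
                min(abs(ev.ref_start - c), abs(ev.ref_end - c)) for c in cuts
            )
            if dist <= window:
                counts[ev.size] = counts.get(ev.size, 0) + 1
                any_event = True
        if not any_event:
            counts[0] = counts.get(0, 0) + 1
    return SizeDistribution(counts)


def sizes_from_calls(calls: pd.DataFrame) -> SizeDistribution:
    """Junction size distribution from recorded per-call indel sizes."""
    counts: dict[int, int] = {}
    for li, ri in zip(calls["left_indel"], calls["right_indel"]):
        events = [s for s in (li, ri) if s != 0]
        if not events:
            counts[0] = counts.get(0, 0) + 1
        for s in events:
            counts[s] = counts.get(s, 0) + 1
    return SizeDistribution(counts)


def indel_rate(calls: pd.DataFrame) -> tuple[float, int, int]:
    """Fraction of reads with at least one junction indel.

    Returns ``(proportion, numerator, denominator)`` for contingency
    use.  Raises on an empty group.
    """
    n = len(calls)
    if n == 0:
        raise ValueError("empty group")
    k = int(((calls["left_indel"] != 0) | (calls["right_indel"] != 0)).sum())
    return k / n, k, n
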