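"""Global pairwise alignment against forward and inverted references.

Long-read classification of editing outcomes needs end-to-end (global)
alignment of each amplicon read against the forward-orientation and
inverted-segment reference loci, in both read orientations, followed by
indel-event extraction and exact-match window checks.  The aligner is a
banded affine-gap (Gotoh) dynamic program with EMBOSS-needle-style
default scoring (match +5, mismatch -4, gap open 10, gap extend 0.5; a
gap of length L costs ``open + L*extend``) and deterministic
tie-breaking:

* at equal score a diagonal step (match/mismatch) beats a gap, and a
  deletion (gap in the read) beats an insertion;
* within a gap, extension beats re-opening, which together with the
  diagonal preference places indels leftmost along the reference.

``N`` in a read scores as a mismatch against every base (including
``N``), so an ``N`` can never satisfy a perfect-match window.  ``N`` in
a *reference* is a wildcard that matches any read base: references use
it only for the UMI slot adjacent to the locus, so that the random
molecular tag aligns as a match run and can be extracted by reference
coordinates without distorting the alignment.  Banding is an
acceleration only: the band is re-widened and the cell recomputed
whenever the optimal path touches a band edge, so results are identical
to the unbanded program.  ``edlib`` edit distance is used as a
pre-screen to shortlist (reference, orientation) combinations before
exact scoring; an exact all-pairs mode is available for verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

import edlib

from .reference_model import revcomp

_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i
_VALID = np.zeros(256, dtype=bool)
for _b in "ACGTNacgtn":
    _VALID[ord(_b)] = True

NEG = np.int32(-(2**28))

OP_EQ, OP_X, OP_D, OP_I = 0, 1, 2, 3
_OP_CHARS = "=XDI"


def seq_to_codes(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes (A=0, C=1, G=2, T=3, anything else=4)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scoring; penalties are positive magnitudes."""

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if not self.gap_open >= self.gap_extend >= 0:
            raise ValueError("require gap_open >= gap_extend >= 0")
        for v in (self.match, self.mismatch, self.gap_open, self.gap_extend):
            if (2 * v) != int(2 * v):
                raise ValueError("scores must be multiples of 0.5")

    def doubled(self) -> tuple[int, int, int, int]:
        """Integer parameters at twice the nominal scale (exact arithmetic)."""
        return (
            int(2 * self.match),
            int(2 * self.mismatch),
            int(2 * self.gap_open),
            int(2 * self.gap_extend),
        )


DEFAULT_SCORING = ScoringScheme()


@njit(cache=True, nogil=True)
def _align_band(q, r, m2, x2, o2, e2, dlo, dhi):  # pragma: no cover - numba
    """Banded affine global alignment.

    Band: cells (i, j) with ``i + dlo <= j <= i + dhi``.  Returns
    ``(score2, ops, touched)`` where ``ops`` is the operation sequence
    (codes 0==,1=X,2=D,3=I) in alignment order and ``touched`` is True
    if the optimal path hit a band edge (the caller must then re-run
    with a wider band).
    """
    n = q.shape[0]
    m = r.shape[0]
    W = dhi - dlo + 1
    M = np.full((n + 1, W), NEG, dtype=np.int32)
    D = np.full((n + 1, W), NEG, dtype=np.int32)
    II = np.full((n + 1, W), NEG, dtype=np.int32)
    # packed predecessor states: bits 0-1 for M, 2-3 for D, 4-5 for I
    P = np.zeros((n + 1, W), dtype=np.uint8)

    for i in range(n + 1):
        jlo = i + dlo
        if jlo < 0:
            jlo = 0
        jhi = i + dhi
        if jhi > m:
            jhi = m
        if jlo > jhi:
            continue
        for j in range(jlo, jhi + 1):
            k = j - i - dlo  # band column
            if i == 0 and j == 0:
                M[0, k] = 0
                continue
            # deletion: gap in query, consumes reference (from (i, j-1))
            if j > 0 and j - 1 >= i + dlo:
                kk = k - 1
                ext = D[i, kk]
                if ext > NEG:
                    ext = ext - e2
                om = M[i, kk]
                if om > NEG:
                    om = om - o2 - e2
                oi = II[i, kk]
                if oi > NEG:
                    oi = oi - o2 - e2
                best = ext
                pred = 1
                if om > best:
                    best = om
                    pred = 0
                if oi > best:
                    best = oi
                    pred = 2
                if best > NEG:
                    D[i, k] = best
                    P[i, k] |= np.uint8(pred << 2)
            # insertion: gap in reference, consumes query (from (i-1, j))
            if i > 0 and j <= i - 1 + dhi:
                kk = k + 1
                ext = II[i - 1, kk]
                if ext > NEG:
                    ext = ext - e2
                om = M[i - 1, kk]
                if om > NEG:
                    om = om - o2 - e2
                od = D[i - 1, kk]
                if od > NEG:
                    od = od - o2 - e2
                best = ext
                pred = 2
                if om > best:
                    best = om
                    pred = 0
                if od > best:
                    best = od
                    pred = 1
                if best > NEG:
                    II[i, k] = best
                    P[i, k] |= np.uint8(pred << 4)
            # diagonal
            if i > 0 and j > 0 and j - 1 >= i - 1 + dlo and j - 1 <= i - 1 + dhi:
                qa = q[i - 1]
                rb = r[j - 1]
                s = m2 if qa < 4 and (qa == rb or rb == 4) else x2
                # tie order M > I > D: picked right-to-left during
                # traceback, this places a deletion before an adjacent
                # insertion in reading order
                dm = M[i - 1, k]
                dd = D[i - 1, k]
                di = II[i - 1, k]
                best = dm
                pred = 0
                if di > best:
                    best = di
                    pred = 2
                if dd > best:
                    best = dd
                    pred = 1
                if best > NEG:
                    M[i, k] = best + s
                    P[i, k] |= np.uint8(pred)

    # terminal state at equal score: M, then I, then D (right-to-left
    # traceback, so preferring I here puts the D earlier in the output)
    kend = m - n - dlo
    sM = M[n, kend]
    sD = D[n, kend]
    sI = II[n, kend]
    state = 0
    score = sM
    if sI > score:
        score = sI
        state = 2
    if sD > score:
        score = sD
        state = 1

    ops = np.empty(n + m, dtype=np.int8)
    pos = n + m
    i = n
    j = m
    touched = False
    while i > 0 or j > 0:
        k = j - i - dlo
        if 0 < i < n and (j == i + dlo or j == i + dhi) and 0 < j < m:
            touched = True
        p = P[i, k]
        pos -= 1
        if state == 0:
            qa = q[i - 1]
            rb = r[j - 1]
            ops[pos] = OP_EQ if qa < 4 and (qa == rb or rb == 4) else OP_X
            state = p & 3
            i -= 1
            j -= 1
        elif state == 1:
            ops[pos] = OP_D
            state = (p >> 2) & 3
            j -= 1
        else:
            ops[pos] = OP_I
            state = (p >> 4) & 3
            i -= 1
    return score, ops[pos:], touched


def _run_length(op_codes: np.ndarray) -> list[tuple[str, int]]:
    ops: list[tuple[str, int]] = []
    for code in op_codes:
        ch = _OP_CHARS[code]
        if ops and ops[-1][0] == ch:
            ops[-1] = (ch, ops[-1][1] + 1)
        else:
            ops.append((ch, 1))
    return ops


@dataclass(frozen=True)
class IndelEvent:
    """A gap run on the reference frame.

    ``size`` is signed: negative for deletions (reference bases missing
    from the read), positive for insertions (extra read bases).  For
    deletions ``ref_start:ref_end`` is the deleted reference span
    (0-based half-open); for insertions both equal the inter-base
    reference position of the insertion point.
    """

    size: int
    ref_start: int
    ref_end: int


@dataclass
class AlignmentResult:
    """Orientation-resolved global alignment of one read."""

    query_id: str
    ref_id: str
    orientation: str  # "as-is" | "revcomp": how the read was used
    orientation_class: str  # "forward" | "inverted": which reference won
    score: float
    ops: list[tuple[str, int]]
    query: str  # the (possibly reverse-complemented) read as aligned
    ref_len: int
    ambiguous: bool = False
    edit_distance: int | None = None

    def cigar(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.ops)

    def indel_events(self) -> list[IndelEvent]:
        events: list[IndelEvent] = []
        rpos = 0
        for op, n in self.ops:
            if op in "=X":
                rpos += n
            elif op == "D":
                events.append(IndelEvent(-n, rpos, rpos + n))
                rpos += n
            else:  # I
                events.append(IndelEvent(n, rpos, rpos))
        return events

    def aligned_to_ref(self) -> tuple[np.ndarray, dict[int, str]]:
        """Per-reference-position read bases plus insertions.

        Returns ``(col, ins)`` where ``col`` is a uint8 array of length
        ``ref_len`` holding the read base code at each reference
        position (4 meaning a gap/N) ... codes as in :func:`seq_to_codes`
        with gap encoded as 5, and ``ins`` maps an inter-base reference
        position to the inserted read substring.
        """
        col = np.full(self.ref_len, 5, dtype=np.uint8)
        ins: dict[int, str] = {}
        q = seq_to_codes(self.query)
        qpos = 0
        rpos = 0
        for op, n in self.ops:
            if op in "=X":
                col[rpos : rpos + n] = q[qpos : qpos + n]
                qpos += n
                rpos += n
            elif op == "D":
                rpos += n
            else:
                prev = ins.get(rpos, "")
                ins[rpos] = prev + self.query[qpos : qpos + n]
                qpos += n
        return col, ins

    def query_slice(self, ref_start: int, ref_end: int) -> str:
        """Read bases aligned within reference window (0-based half-open)."""
        out: list[str] = []
        qpos = 0
        rpos = 0
        for op, n in self.ops:
            if op in "=X":
                lo = max(rpos, ref_start)
                hi = min(rpos + n, ref_end)
                if hi > lo:
                    out.append(self.query[qpos + lo - rpos : qpos + hi - rpos])
                qpos += n
                rpos += n
            elif op == "D":
                rpos += n
            else:
                if ref_start < rpos < ref_end:
                    out.append(self.query[qpos : qpos + n])
                qpos += n
        return "".join(out)


def global_align(
    query: str,
    ref: str,
    scoring: ScoringScheme = DEFAULT_SCORING,
    band: int | None = 64,
    query_id: str = "",
    ref_id: str = "",
    orientation: str = "as-is",
    orientation_class: str = "forward",
) -> AlignmentResult:
    """Optimal global affine-gap alignment of ``query`` against ``ref``.

    ``band=None`` forces the full dynamic program; otherwise the band
    half-width starts at ``band`` plus the length difference and doubles
    until the optimal path clears the band edges, so the result equals
    the full program.
    """
    if not query or not ref:
        raise ValueError("empty sequence")
    for s, name in ((query, "query"), (ref, "ref")):
        arr = np.frombuffer(s.encode("ascii", errors="replace"), dtype=np.uint8)
        if not _VALID[arr].all():
            raise ValueError(f"non-DNA alphabet in {name}")
    q = seq_to_codes(query)
    r = seq_to_codes(ref)
    n, m = len(q), len(r)
    m2, x2, o2, e2 = scoring.doubled()
    w = max(n, m) if band is None else min(band, max(n, m))
    while True:
        dlo = min(0, m - n) - w
        dhi = max(0, m - n) + w
        score2, codes, touched = _align_band(q, r, m2, x2, o2, e2, dlo, dhi)
        if not touched or w >= max(n, m):
            break
        w = min(4 * w, max(n, m))
    return AlignmentResult(
        query_id=query_id,
        ref_id=ref_id,
        orientation=orientation,
        orientation_class=orientation_class,
        score=score2 / 2.0,
        ops=_run_length(codes),
        query=query,
        ref_len=m,
    )


@dataclass(frozen=True)
class Reference:
    """A named reference sequence with its orientation class."""

    ref_id: str
    seq: str
    orientation_class: str  # "forward" | "inverted"


# N in the reference pad should match anything during edlib pre-screening
# so that the UMI region does not contribute to the screening distance.
_EQUALITIES = [("N", b) for b in "ACGT"]


def _identity_result(
    query: str, ref: Reference, orientation: str, scoring: ScoringScheme, query_id: str
) -> AlignmentResult:
    """Gapless column-wise alignment; valid shortcut when the edlib
    distance (N-tolerant) is 0 and lengths match: no gapped alignment
    can beat the all-diagonal path then."""
    q = seq_to_codes(query)
    r = seq_to_codes(ref.seq)
    eq = (q < 4) & ((q == r) | (r == 4))
    m2, x2, _, _ = scoring.doubled()
    score2 = int(eq.sum()) * m2 + int((~eq).sum()) * x2
    codes = np.where(eq, OP_EQ, OP_X).astype(np.int8)
    return AlignmentResult(
        query_id=query_id,
        ref_id=ref.ref_id,
        orientation=orientation,
        orientation_class=ref.orientation_class,
        score=score2 / 2.0,
        ops=_run_length(codes),
        query=query,
        ref_len=len(ref.seq),
        edit_distance=0,
    )


def align_best(
    query: str,
    refs: list[Reference],
    scoring: ScoringScheme = DEFAULT_SCORING,
    query_id: str = "",
    prescreen: bool = True,
    prescreen_margin: int = 60,
    band: int | None = 64,
    try_revcomp: bool = True,
) -> AlignmentResult:
    """Highest-scoring (reference, read-orientation) combination.

    Aligns the read (and, with ``try_revcomp``, its reverse complement)
    against every reference and returns the single best combination.
    An exact score tie across orientation classes is flagged
    ``ambiguous`` rather than silently broken; ties within a class
    resolve to the first reference in input order.

    With ``prescreen=True`` (default) edlib edit distances shortlist
    combinations: only those within ``prescreen_margin`` edits of the
    minimum receive exact affine scoring.  Combinations outside the
    margin cannot be competitive for any sane scoring (each excess edit
    costs at least ``match - mismatch`` relative to the leader while a
    gap can regroup edits worth at most the open penalty), and the
    equivalence with the exact mode is covered by tests.
    """
    orientations = (("as-is", query), ("revcomp", revcomp(query))) if try_revcomp else (
        ("as-is", query),
    )
    combos = [(ref, ori, q) for ref in refs for ori, q in orientations]

    candidates: list[tuple[Reference, str, str, int | None]] = []
    if prescreen:
        dists: list[int] = []
        best_d = None
        for ref, ori, q in combos:
            k = -1 if best_d is None else best_d + prescreen_margin
            res = edlib.align(q, ref.seq, mode="NW", task="distance", k=k,
                              additionalEqualities=_EQUALITIES)
            d = res["editDistance"]
            if d < 0:
                d = len(q) + len(ref.seq)  # beyond k: not competitive
            dists.append(d)
            if best_d is None or d < best_d:
                best_d = d
        for (ref, ori, q), d in zip(combos, dists):
            if d <= best_d + prescreen_margin:
                candidates.append((ref, ori, q, d))
    else:
        candidates = [(ref, ori, q, None) for ref, ori, q in combos]

    best: AlignmentResult | None = None
    tie_classes: set[str] = set()
    for ref, ori, q, d in candidates:
        if d == 0 and len(q) == len(ref.seq):
            res = _identity_result(q, ref, ori, scoring, query_id)
        else:
            res = global_align(
                q, ref.seq, scoring, band=band, query_id=query_id,
                ref_id=ref.ref_id, orientation=ori,
                orientation_class=ref.orientation_class,
            )
            res.edit_distance = d
        if best is None or res.score > best.score:
            best = res
            tie_classes = {res.orientation_class}
        elif res.score == best.score:
            tie_classes.add(res.orientation_class)
    assert best is not None
    if len(tie_classes) > 1:
        best.ambiguous = True
    return best


def choose_orientation(
    query: str,
    refs: list[Reference],
    scoring: ScoringScheme = DEFAULT_SCORING,
    query_id: str = "",
    prescreen: bool = True,
    prescreen_margin: int = 60,
    band: int | None = 64,
) -> AlignmentResult:
    """Orientation-resolving alignment against forward and inverted
    reference sets; see :func:`align_best` for the search semantics."""
    if not any(r.orientation_class == "forward" for r in refs) or not any(
        r.orientation_class == "inverted" for r in refs
    ):
        raise ValueError("need at least one forward and one inverted reference")
    return align_best(
        query, refs, scoring, query_id=query_id, prescreen=prescreen,
        prescreen_margin=prescreen_margin, band=band, try_revcomp=True,
    )


def extract_window(
    a: AlignmentResult, window: tuple[int, int], exclude: frozenset[int] | set[int] = frozenset()
) -> tuple[str, bool, bool]:
    """Read bases over a reference window plus exact-match flags.

    ``window`` is 0-based half-open in the reference frame of ``a``.
    Returns ``(query_bases, exact_match, indel_overlap)``.
    ``exact_match`` is True iff every window position lies in a match
    run (no mismatch, no gap) — positions listed in ``exclude`` (e.g.
    SNV offsets checked separately) are exempt from the mismatch
    condition but must still be aligned without gaps.  Indels abutting
    the window boundary from outside do not violate exactness.
    """
    lo, hi = window
    if lo < 0 or hi > a.ref_len or lo >= hi:
        raise ValueError(f"window {window} outside reference 0..{a.ref_len}")
    exact = True
    indel_overlap = False
    rpos = 0
    for op, n in a.ops:
        if op in "=X":
            if op == "X":
                for p in range(max(rpos, lo), min(rpos + n, hi)):
                    if p not in exclude:
                        exact = False
                        break
            rpos += n
        elif op == "D":
            if rpos < hi and rpos + n > lo:
                exact = False
                indel_overlap = True
            rpos += n
        else:  # insertion at inter-base position rpos
            if lo < rpos < hi:
                exact = False
                indel_overlap = True
    return a.query_slice(lo, hi), exact, indel_overlap


def normalize_deletions_to_cuts(
    a: AlignmentResult, ref_seq: str, cuts: tuple[int, int], max_dist: int = 50
) -> AlignmentResult:
    """Canonicalize junction-proximal deletion placement.

    In repetitive context a junction deletion admits several
    score-equivalent placements (the aligner's leftmost rule picks one
    arbitrarily), and a placement shifted into the flank can let a
    flank base spuriously occupy a PAM/SNV slot inside the segment.
    This normalization shifts each deletion run near a cut — the score
    is unchanged because a shift is taken only across equal reference
    bases — so that it abuts the cut on the segment side: runs near the
    left cut are moved to start at the cut, runs near the right cut to
    end at it.  Deletions farther than ``max_dist`` from both cuts are
    untouched.
    """
    left_cut, right_cut = cuts
    runs = [list(r) for r in a.ops]
    changed = False
    rpos = 0
    spans = []  # (run index, ref_start) for every run
    for idx, (op, n) in enumerate(a.ops):
        spans.append((idx, rpos))
        if op in ("=", "X", "D"):
            rpos += n
    for idx, b in spans:
        op, n = runs[idx]
        if op != "D":
            continue
        e = b + n
        d_left = min(abs(b - left_cut), abs(e - left_cut))
        d_right = min(abs(b - right_cut), abs(e - right_cut))
        if min(d_left, d_right) > max_dist:
            continue
        shift = (left_cut - b) if d_left <= d_right else (right_cut - e)
        if shift > 0 and idx + 1 < len(runs):
            nop, nn = runs[idx + 1]
            if nop not in ("=", "X"):
                continue
            k = 0
            while k < shift and k < nn and ref_seq[b + k] == ref_seq[e + k]:
                k += 1
            if k:
                runs[idx + 1][1] -= k
                runs.insert(idx, [nop, k])
                changed = True
        elif shift < 0 and idx - 1 >= 0:
            pop, pn = runs[idx - 1]
            if pop not in ("=", "X"):
                continue
            k = 0
            while k < -shift and k < pn and ref_seq[e - 1 - k] == ref_seq[b - 1 - k]:
                k += 1
            if k:
                runs[idx - 1][1] -= k
                runs.insert(idx + 1, [pop, k])
                changed = True
        if changed:
            break  # re-derive spans after a structural change
    if not changed:
        return a
    merged: list[tuple[str, int]] = []
    for op, n in runs:
        if n <= 0:
            continue
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    out = AlignmentResult(
        query_id=a.query_id, ref_id=a.ref_id, orientation=a.orientation,
        orientation_class=a.orientation_class, score=a.score, ops=merged,
        query=a.query, ref_len=a.ref_len, ambiguous=a.ambiguous,
        edit_distance=a.edit_distance,
    )
    # a single pass moves one run; recurse until stable (runs are few)
    return normalize_deletions_to_cuts(out, ref_seq, cuts, max_dist)


def to_sam_like(results: list[AlignmentResult]) -> "pd.DataFrame":  # noqa: F821
    """Alignment dump (read_id, ref_id, orientation, score, CIGAR)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "read_id": [a.query_id for a in results],
            "ref_id": [a.ref_id for a in results],
            "orientation": [a.orientation for a in results],
            "orientation_class": [a.orientation_class for a in results],
            "score": [a.score for a in results],
            "cigar": [a.cigar() for a in results],
        }
    )
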