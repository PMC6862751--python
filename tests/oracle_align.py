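"""Independent alignment oracles for verifying the package aligner.

``dp_score`` is a plain, unbanded, float-arithmetic Gotoh dynamic
program written without reference to the package kernel; ``enum_score``
exhaustively recurses over every global alignment path (exponential,
for tiny sequences only) and is used to validate ``dp_score`` itself.
Both use the same conventions as the package contract: a gap of length
L costs open + L*extend, N in the query mismatches everything, N in the
reference matches any non-N query base.
"""

import math


def _sub(qc: str, rc: str, match: float, mismatch: float) -> float:
    if qc != "N" and (qc == rc or rc == "N"):
        return match
    return mismatch


def dp_score(q: str, r: str, match=5.0, mismatch=-4.0, open_=10.0, ext=0.5) -> float:
    n, m = len(q), len(r)
    NEG = -math.inf
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    D = [[NEG] * (m + 1) for _ in range(n + 1)]
    I = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(n + 1):
        for j in range(m + 1):
            if i == 0 and j == 0:
                continue
            if j > 0:
                cand = [D[i][j - 1] - ext]
                for src in (M[i][j - 1], I[i][j - 1]):
                    cand.append(src - open_ - ext)
                D[i][j] = max(cand)
            if i > 0:
                cand = [I[i - 1][j] - ext]
                for src in (M[i - 1][j], D[i - 1][j]):
                    cand.append(src - open_ - ext)
                I[i][j] = max(cand)
            if i > 0 and j > 0:
                best = max(M[i - 1][j - 1], D[i - 1][j - 1], I[i - 1][j - 1])
                if best > NEG:
                    M[i][j] = best + _sub(q[i - 1], r[j - 1], match, mismatch)
    return max(M[n][m], D[n][m], I[n][m])


def enum_score(q: str, r: str, match=5.0, mismatch=-4.0, open_=10.0, ext=0.5) -> float:
    """Exhaustive recursion over all global alignment paths."""
    best = [-math.inf]

    def rec(i: int, j: int, prev: str, score: float) -> None:
        if i == len(q) and j == len(r):
            if score > best[0]:
                best[0] = score
            return
        if i < len(q) and j < len(r):
            rec(i + 1, j + 1, "M", score + _sub(q[i], r[j], match, mismatch))
        if j < len(r):
            cost = ext if prev == "D" else open_ + ext
            rec(i, j + 1, "D", score - cost)
        if i < len(q):
            cost = ext if prev == "I" else open_ + ext
            rec(i + 1, j, "I", score - cost)

    rec(0, 0, "", 0.0)
    return best[0]
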