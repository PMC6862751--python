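"""Comparison statistics over frequency tables.

The experiment's inference layer is deliberately simple: per-replicate
fold changes of allele frequencies under selection vs mock, paired
t-tests after a variance-stabilising transform (natural log for fold
changes, arcsine square root for proportions), Fisher's exact test on
2x2 indel-rate tables, and exact (Clopper-Pearson) binomial confidence
intervals for recovery checks.  Pairing is within transfection
replicate (three replicates of each reciprocal design, six pairs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class PairedTResult:
    t: float
    p: float
    n: int
    transform: str
    degenerate: bool = False


def fold_change(freq_sel: float, freq_mock: float) -> float:
    """Selected-over-mock frequency ratio; NaN when the mock frequency
    is zero (no automatic pseudo-count)."""
    if freq_mock < 0 or freq_sel < 0:
        raise ValueError("frequencies must be non-negative")
    if freq_mock == 0:
        return float("nan")
    return freq_sel / freq_mock


def paired_t(
    a: np.ndarray | list[float],
    b: np.ndarray | list[float],
    transform: str = "none",
) -> PairedTResult:
    """Paired t-test on transformed values.

    ``log`` is the natural log (values must be positive);
    ``arcsine_sqrt`` expects proportions in [0, 1] (divide percentages
    by 100 first).  All-zero differences give t=0, p=1; a constant
    non-zero difference (zero variance) is flagged degenerate with p=0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length vectors of n >= 2 pairs")
    if transform == "log":
        if np.any(a <= 0) or np.any(b <= 0):
            raise ValueError("log transform requires positive values")
        a, b = np.log(a), np.log(b)
    elif transform == "arcsine_sqrt":
        if np.any((a < 0) | (a > 1) | (b < 0) | (b > 1)):
            raise ValueError("arcsine_sqrt requires proportions in [0, 1]")
        a, b = np.arcsin(np.sqrt(a)), np.arcsin(np.sqrt(b))
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    d = a - b
    n = d.size
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return PairedTResult(0.0, 1.0, n, transform, degenerate=False)
        return PairedTResult(math.inf if d[0] > 0 else -math.inf, 0.0, n,
                             transform, degenerate=True)
    t, p = sps.ttest_rel(a, b)
    return PairedTResult(float(t), float(p), n, transform)


def fisher_exact(table: list[list[int]] | np.ndarray) -> float:
    """Two-sided Fisher's exact p for a 2x2 table (hypergeometric
    summation of tables no more probable than the observed one)."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        return 1.0  # degenerate margin
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact Clopper-Pearson interval for a binomial proportion."""
    if not (0 <= k <= n) or n < 1:
        raise ValueError("need 0 <= k <= n, n >= 1")
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi
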