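"""Independent reference implementations used as test oracles.

These deliberately use naive exhaustive or closed-form routes so they
share no code with the package internals they check.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate
from scipy.stats import rankdata


def brute_force_align(a: str, b: str, match=5.0, mismatch=-4.0,
                      gap_open=10.0, gap_extend=0.5) -> float:
    """Exhaustive enumeration of all global alignments with affine gaps.

    A gap run of length L costs gap_open + (L-1)*gap_extend; end gaps
    are penalized. Exponential-time recursion, intended for len <= 6.
    """
    a = a.upper().replace("U", "T")
    b = b.upper().replace("U", "T")

    def rec(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = -np.inf
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1, "M"))
        if i < len(a):  # gap in b
            cost = gap_extend if prev == "D" else gap_open
            best = max(best, -cost + rec(i + 1, j, "D"))
        if j < len(b):  # gap in a
            cost = gap_extend if prev == "I" else gap_open
            best = max(best, -cost + rec(i, j + 1, "I"))
        return best

    return rec(0, 0, "start")


def naive_mbsi(sim: np.ndarray, incidence: np.ndarray,
               exclude: int | None = None) -> np.ndarray:
    """Double-loop evaluation of the similarity-weighted association mean."""
    n, d = incidence.shape
    a = incidence.copy().astype(float)
    if exclude is not None:
        a[exclude, :] = 0.0
    out = np.zeros((n, d))
    for i in range(n):
        for j in range(d):
            num = den = 0.0
            for l in range(n):
                if l == i:
                    continue
                num += sim[i, l] * a[l, j]
                den += sim[i, l]
            out[i, j] = num / den if den > 0 else 0.0
    return out


def mann_whitney_auc(scores, labels) -> float:
    """Tie-corrected pairwise concordance probability (rank form)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def t_tail_probability(t: float, df: int) -> float:
    """P(T >= t) for Student's t by direct numerical integration."""
    from math import gamma, sqrt, pi

    c = gamma((df + 1) / 2) / (gamma(df / 2) * sqrt(df * pi))
    pdf = lambda x: c * (1 + x * x / df) ** (-(df + 1) / 2)
    val, _ = integrate.quad(pdf, t, np.inf)
    return val
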