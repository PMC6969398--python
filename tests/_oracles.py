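"""Independent brute-force oracles used to check the implementation.

These deliberately share no code with the package: a quadratic-time
Gotoh dynamic program for affine-gap local alignment scores, and a
bisection solver for the ungapped Karlin-Altschul characteristic
equation.
"""

from __future__ import annotations

import math

NEG = float("-inf")


def sw_affine_score(q: str, s: str, match: int, mismatch: int,
                    gap_open: int, gap_extend: int) -> float:
    """Best local-alignment score; a gap of length k costs open + k*extend."""
    q, s = q.upper(), s.upper()
    n, m = len(q), len(s)
    best = 0.0
    h_prev = [0.0] * (m + 1)
    f_prev = [NEG] * (m + 1)
    for i in range(1, n + 1):
        h_cur = [0.0] * (m + 1)
        f_cur = [NEG] * (m + 1)
        e = NEG
        for j in range(1, m + 1):
            e = max(e - gap_extend, h_cur[j - 1] - gap_open - gap_extend)
            f_cur[j] = max(f_prev[j] - gap_extend, h_prev[j] - gap_open - gap_extend)
            sub = match if q[i - 1] == s[j - 1] else mismatch
            h = max(0.0, h_prev[j - 1] + sub, e, f_cur[j])
            h_cur[j] = h
            if h > best:
                best = h
        h_prev, f_prev = h_cur, f_cur
    return best


def lambda_bisection(match: int, mismatch: int, tol: float = 1e-12) -> float:
    """Positive root of (1/4)e^(lam*match) + (3/4)e^(lam*mismatch) = 1,
    i.e. the uniform-base ungapped characteristic equation, by bisection."""

    def f(lam: float) -> float:
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    lo, hi = 1e-12, 1.0
    while f(hi) < 0:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)
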