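"""Independent reference implementations used as test oracles.

These deliberately share no code with the package: brute-force transitive
closure for single-linkage components, a scalar Gotoh aligner with the
same lexicographic objective, exhaustive alignment enumeration for tiny
sequences, and high-precision distance formulas via the decimal module.
"""

from __future__ import annotations

import itertools
from decimal import Decimal, getcontext


def brute_force_components(matrix, threshold) -> set[frozenset[int]]:
    """Transitive closure of the relation d(i,j) < threshold."""
    n = len(matrix)
    linked = [[matrix[i][j] < threshold for j in range(n)] for i in range(n)]
    for i in range(n):
        linked[i][i] = True
    changed = True
    while changed:
        changed = False
        for i, j, k in itertools.product(range(n), repeat=3):
            if linked[i][k] and linked[k][j] and not linked[i][j]:
                linked[i][j] = True
                changed = True
    return {frozenset(j for j in range(n) if linked[i][j]) for i in range(n)}


_NEG3 = (-(10**9),) * 3


def gotoh_overlap_stats(a: str, b: str, match=1, mis=-1, gap_open=-5, gap_ext=-2):
    """Scalar affine-gap overlap alignment (terminal gaps free) maximising
    (score, matches, -columns) lexicographically; returns
    (score, matches, columns)."""

    def add(t, ds, dm):
        return (t[0] + ds, t[1] + dm, t[2] - 1)  # every column costs 1

    n, m = len(a), len(b)
    zero = (0, 0, 0)
    B = [zero] * (m + 1)  # row 0: free skip of b prefix
    X = [_NEG3] * (m + 1)
    best = zero  # the empty alignment is always admissible
    for i in range(1, n + 1):
        Bn = [zero] + [_NEG3] * m  # column 0: free skip of a prefix
        Xn = [_NEG3] * (m + 1)
        Y = [_NEG3] * (m + 1)
        prevM, prevX = _NEG3, _NEG3
        for j in range(1, m + 1):
            if a[i - 1] == b[j - 1]:
                M = add(B[j - 1], match, 1)
            else:
                M = add(B[j - 1], mis, 0)
            Xn[j] = max(add(B[j], gap_open, 0), add(X[j], gap_ext, 0))
            if j >= 2:
                Y[j] = max(add(max(prevM, prevX), gap_open, 0), add(Y[j - 1], gap_ext, 0))
            Bn[j] = max(M, Xn[j], Y[j])
            prevM, prevX = M, Xn[j]
        best = max(best, Bn[m])  # trailing a free after row i
        if i == n:
            best = max(best, max(Bn))  # trailing b free
        B, X = Bn, Xn
    score, matches, neg_cols = best
    return score, matches, -neg_cols


def enumerate_alignments(a: str, b: str, match=1, mis=-1, gap_open=-5, gap_ext=-2):
    """Exhaustive enumeration of all overlap alignments of tiny sequences;
    returns the lexicographically best (score, matches, columns)."""
    best = [(-(10**9), 0, 0)]

    def walk(i, j, score, matches, columns, state):
        if i == len(a) or j == len(b):  # remaining suffix of the other is free
            cand = (score, matches, -columns)
            if cand > best[0]:
                best[0] = cand
        if i < len(a) and j < len(b):
            hit = a[i] == b[j]
            walk(i + 1, j + 1, score + (match if hit else mis), matches + hit, columns + 1, "M")
        if i < len(a):
            walk(i + 1, j, score + (gap_ext if state == "X" else gap_open), matches, columns + 1, "X")
        if j < len(b):
            walk(i, j + 1, score + (gap_ext if state == "Y" else gap_open), matches, columns + 1, "Y")

    for i0 in range(len(a) + 1):
        walk(i0, 0, 0, 0, 0, "-")
    for j0 in range(1, len(b) + 1):
        walk(0, j0, 0, 0, 0, "-")
    score, matches, neg_cols = best[0]
    return score, matches, -neg_cols


def jc69_highprec(p) -> float:
    getcontext().prec = 50
    arg = 1 - Decimal(4) / Decimal(3) * Decimal(str(p))
    return float(Decimal("-0.75") * arg.ln())


def k2p_highprec(P, Q) -> float:
    getcontext().prec = 50
    Pd, Qd = Decimal(str(P)), Decimal(str(Q))
    return float(Decimal("-0.5") * (1 - 2 * Pd - Qd).ln() - Decimal("0.25") * (1 - 2 * Qd).ln())
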