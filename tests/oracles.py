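"""Independent reference implementations used only to check the package.

Each oracle re-derives a quantity with a naive method: a plain-Python
Gotoh dynamic program for local alignment, an exact-rational hypergeometric
enumeration for the two-sided Fisher p, and a permutation filter for the
greedy accumulation order.  They follow the same documented tie-break
conventions as the package (ties among co-optimal alignments change the
identical-column count, so the convention is part of the contract) but
share no code with it.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

NEG = float("-inf")


def naive_local_alignment(
    q: str, s: str, match: int = 2, mismatch: int = -3,
    gap_open: int = -5, gap_extend: int = -2,
) -> dict:
    """Plain-Python optimal local alignment with affine gaps.

    First gap base costs ``gap_open``, further bases ``gap_extend``.
    Returns score, identical, aligned_length, gaps and the aligned column
    list [(qi, sj)], gaps as None.
    """
    n, m = len(q), len(s)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in s (consume q)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in q (consume s)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            equal = q[i - 1] == s[j - 1] and q[i - 1] != "N"
            sub = match if equal else mismatch
            M[i][j] = max(
                0.0,
                max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + sub,
            )
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend)
    best, bi, bj = 0.0, 0, 0
    for i in range(n + 1):  # row-major: smallest (i, j) wins ties
        for j in range(m + 1):
            if M[i][j] > best:
                best, bi, bj = M[i][j], i, j
    if best == 0:
        return {"score": 0, "identical": 0, "aligned_length": 0, "gaps": 0,
                "columns": []}
    cols: list[tuple[int | None, int | None]] = []
    identical = 0
    i, j, state = bi, bj, "M"
    while True:
        if state == "M":
            equal = q[i - 1] == s[j - 1] and q[i - 1] != "N"
            cols.append((i - 1, j - 1))
            if equal:
                identical += 1
            prev = M[i][j] - (match if equal else mismatch)
            i, j = i - 1, j - 1
            if prev == 0:
                break
            if M[i][j] == prev:
                state = "M"
            elif X[i][j] == prev:
                state = "X"
            else:
                assert Y[i][j] == prev
                state = "Y"
        elif state == "X":
            cols.append((i - 1, None))
            state = "M" if M[i - 1][j] + gap_open == X[i][j] else "X"
            i -= 1
        else:
            cols.append((None, j - 1))
            state = "M" if M[i][j - 1] + gap_open == Y[i][j] else "Y"
            j -= 1
    cols.reverse()
    return {
        "score": int(best),
        "identical": identical,
        "aligned_length": len(cols),
        "gaps": sum(1 for a, b in cols if a is None or b is None),
        "columns": cols,
    }


def fisher_exact_enumeration(table) -> float:
    """Two-sided Fisher p by exact-rational hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    denom = math.comb(n, c1)
    p_obs = Fraction(math.comb(r1, a) * math.comb(r2, c1 - a), denom)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_k = Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)
        if p_k <= p_obs:
            total += p_k
    return float(total)


def minimal_addition_order(site_sets: dict[str, set]) -> tuple[list, list]:
    """Stepwise-minimal sample ordering by exhaustive permutation search.

    Among all permutations, keeps those whose first sample is a smallest
    set and whose every later step adds the minimum possible number of new
    sites; lexicographic order resolves ties.  Returns (order, cumulative).
    """
    names = sorted(site_sets)
    admissible = []
    for perm in itertools.permutations(names):
        if len(site_sets[perm[0]]) != min(len(site_sets[x]) for x in names):
            continue
        covered = set(site_sets[perm[0]])
        cum = [len(covered)]
        ok = True
        for k in range(1, len(perm)):
            remaining = perm[k:]
            added = len(site_sets[perm[k]] - covered)
            if added != min(len(site_sets[x] - covered) for x in remaining):
                ok = False
                break
            covered |= site_sets[perm[k]]
            cum.append(len(covered))
        if ok:
            admissible.append((list(perm), cum))
    admissible.sort(key=lambda t: t[0])
    return admissible[0]
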