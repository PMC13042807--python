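"""Independent brute-force oracles used by the test suite.

Each oracle implements the stated rule by direct enumeration, sharing no
code with the package implementation it checks.
"""

from __future__ import annotations

import re
from fractions import Fraction
from math import comb


def patch_fraction_bruteforce(seq: str, residue: str,
                              min_occ: int = 4, max_gap: int = 2) -> float:
    """Enumerate all candidate spans between occurrence pairs of
    ``residue``; a span qualifies when it holds >= min_occ occurrences
    and every pair of consecutive occurrences inside is separated by
    <= max_gap other residues.  Returns the covered fraction."""
    occ = [i for i, ch in enumerate(seq) if ch == residue]
    covered: set[int] = set()
    for ai in range(len(occ)):
        for bi in range(ai, len(occ)):
            inside = occ[ai:bi + 1]
            if len(inside) < min_occ:
                continue
            if any(q - p - 1 > max_gap for p, q in zip(inside, inside[1:])):
                continue
            covered.update(range(occ[ai], occ[bi] + 1))
    return len(covered) / len(seq)


def rg_fraction_bruteforce(seq: str, min_occ: int = 2, max_gap: int = 2) -> float:
    """Same enumeration over non-overlapping left-to-right RG dimers."""
    occ = [m.start() for m in re.finditer("RG", seq)]
    covered: set[int] = set()
    for ai in range(len(occ)):
        for bi in range(ai, len(occ)):
            inside = occ[ai:bi + 1]
            if len(inside) < min_occ:
                continue
            if any(q - (p + 2) > max_gap for p, q in zip(inside, inside[1:])):
                continue
            covered.update(range(occ[ai], occ[bi] + 2))
    return len(covered) / len(seq)


def fisher_two_sided_bruteforce(table) -> float:
    """Two-sided Fisher p-value by exact hypergeometric enumeration over
    all 2x2 tables with the observed margins, in rational arithmetic."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def pmf(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    p_obs = pmf(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        if pmf(x) <= p_obs:
            total += pmf(x)
    return float(total)


def merge_bruteforce(intervals, max_gap: int = 100):
    """Fuse intervals by repeated pairwise fusion until a fixed point.

    Two intervals on the same chromosome fuse when they overlap, touch,
    or are separated by <= max_gap bp.
    """
    items = [list(t) for t in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                ci, si, ei = items[i]
                cj, sj, ej = items[j]
                if ci != cj:
                    continue
                gap = max(si, sj) - min(ei, ej)
                if gap <= max_gap:
                    items[i] = [ci, min(si, sj), max(ei, ej)]
                    del items[j]
                    changed = True
                    break
            if changed:
                break
    return sorted(tuple(t) for t in items)


def idr_runs_bruteforce(scores, threshold: float = 0.5, min_len: int = 30):
    """Maximal runs of scores >= threshold, length strictly > min_len,
    found by scanning every start position."""
    n = len(scores)
    runs = []
    i = 0
    while i < n:
        if scores[i] >= threshold:
            j = i
            while j < n and scores[j] >= threshold:
                j += 1
            if j - i > min_len:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs
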