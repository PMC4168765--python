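"""Independent oracles used by the test suite.

These re-derive alignment scores by routes independent of the package's
alignment engine: a prefix-table formulation written from scratch for the
semi-global (free-end-gaps) and local affine-gap problems, and, for tiny
inputs, exhaustive enumeration of every monotone alignment path.
"""

from __future__ import annotations

from itertools import product

NEG = float("-inf")


def _pair(a: str, b: str, match: float, mismatch: float) -> float:
    return match if a == b else mismatch


def semi_global_score_oracle(a: str, b: str, match: float, mismatch: float,
                             go: float, ge: float) -> float:
    """Optimal global score with free end gaps; gap of L costs go+(L-1)*ge.

    Prefix-table formulation: best[i][j][s] = best score of aligning a[:i]
    with b[:j] ending in state s (0 diagonal, 1 gap-in-b, 2 gap-in-a),
    where leading gap runs are free; the answer allows free trailing gaps
    by maximising over the last row and column.
    """
    la, lb = len(a), len(b)
    best = [[[NEG] * 3 for _ in range(lb + 1)] for _ in range(la + 1)]
    best[0][0][0] = 0.0
    for i in range(1, la + 1):
        best[i][0][1] = 0.0  # leading gap in b is terminal -> free
    for j in range(1, lb + 1):
        best[0][j][2] = 0.0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = _pair(a[i - 1], b[j - 1], match, mismatch)
            best[i][j][0] = max(best[i - 1][j - 1]) + s
            best[i][j][1] = max(best[i - 1][j][0] - go,
                                best[i - 1][j][1] - ge,
                                best[i - 1][j][2] - go)
            best[i][j][2] = max(best[i][j - 1][0] - go,
                                best[i][j - 1][2] - ge,
                                best[i][j - 1][1] - go)
    out = NEG
    for j in range(lb + 1):
        out = max(out, max(best[la][j]))
    for i in range(la + 1):
        out = max(out, max(best[i][lb]))
    return out


def local_score_oracle(a: str, b: str, match: float, mismatch: float,
                       go: float, ge: float) -> float:
    """Optimal local (Smith-Waterman, affine) score; empty alignment = 0."""
    la, lb = len(a), len(b)
    H = [[0.0] * (lb + 1) for _ in range(la + 1)]
    E = [[NEG] * (lb + 1) for _ in range(la + 1)]
    F = [[NEG] * (lb + 1) for _ in range(la + 1)]
    out = 0.0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            E[i][j] = max(H[i - 1][j] - go, E[i - 1][j] - ge)
            F[i][j] = max(H[i][j - 1] - go, F[i][j - 1] - ge)
            s = _pair(a[i - 1], b[j - 1], match, mismatch)
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            out = max(out, H[i][j])
    return out


def _enumerate_paths(la: int, lb: int):
    """All monotone alignment paths as op strings over D/U/L."""
    def rec(i, j, acc):
        if i == la and j == lb:
            yield acc
            return
        if i < la and j < lb:
            yield from rec(i + 1, j + 1, acc + "D")
        if i < la:
            yield from rec(i + 1, j, acc + "U")
        if j < lb:
            yield from rec(i, j + 1, acc + "L")
    yield from rec(0, 0, "")


def _score_path(ops: str, a: str, b: str, match: float, mismatch: float,
                go: float, ge: float, free_ends: bool) -> float:
    # terminal gap runs: a maximal run of ONE gap type touching either end
    # (a mixed U/L stretch is not a single terminal run)
    n = len(ops)
    lead = 0
    if n and ops[0] in "UL":
        while lead < n and ops[lead] == ops[0]:
            lead += 1
    trail = 0
    if n and ops[-1] in "UL":
        while trail < n and ops[n - 1 - trail] == ops[-1]:
            trail += 1
    if lead + trail > n:  # the whole path is one gap run
        trail = n - lead
    score = 0.0
    i = j = 0
    run = None
    for k, op in enumerate(ops):
        terminal = free_ends and (k < lead or k >= n - trail)
        if op == "D":
            score += _pair(a[i], b[j], match, mismatch)
            i += 1
            j += 1
            run = None
        else:
            if not terminal:
                score -= ge if run == op else go
            run = op
            if op == "U":
                i += 1
            else:
                j += 1
    return score


def enumerate_semi_global_score(a: str, b: str, match: float, mismatch: float,
                                go: float, ge: float) -> float:
    """Brute-force free-end-gaps score by scoring every alignment path."""
    return max(_score_path(ops, a, b, match, mismatch, go, ge, True)
               for ops in _enumerate_paths(len(a), len(b)))


def enumerate_local_score(a: str, b: str, match: float, mismatch: float,
                          go: float, ge: float) -> float:
    """Brute-force local score: best sub-alignment over all substring pairs."""
    best = 0.0
    la, lb = len(a), len(b)
    for i1 in range(la):
        for i2 in range(i1 + 1, la + 1):
            for j1 in range(lb):
                for j2 in range(j1 + 1, lb + 1):
                    sub_a, sub_b = a[i1:i2], b[j1:j2]
                    s = max(_score_path(ops, sub_a, sub_b, match, mismatch,
                                        go, ge, False)
                            for ops in _enumerate_paths(len(sub_a), len(sub_b)))
                    best = max(best, s)
    return best
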