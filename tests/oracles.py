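"""Independent reference implementations used only to check the package.

These deliberately take a different algorithmic route from the library:
the local-alignment oracle enumerates every pair of substrings and
scores each pair with a GLOBAL affine-gap recursion over plain Python
lists (no numpy, no local-alignment logic, no shared code with the DP
kernel); the bias oracle scans all O(n^2) substrings directly.
"""

from __future__ import annotations

NEG = float("-inf")


def global_affine_score(profile_rows, subject, gap_open, gap_extend):
    """Optimal GLOBAL alignment score of a position-score profile vs a
    subject, gap of length k costing open + k*extend. profile_rows is a
    list of per-position lists indexed by subject residue code."""
    m = len(profile_rows)
    n = len(subject)
    go_ge = gap_open + gap_extend
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    X = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in subject (profile consumed)
    Y = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in profile (subject consumed)
    M[0][0] = 0.0
    for i in range(1, m + 1):
        X[i][0] = -gap_open - gap_extend * i
    for j in range(1, n + 1):
        Y[0][j] = -gap_open - gap_extend * j
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = profile_rows[i - 1][subject[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - go_ge, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - go_ge, Y[i][j - 1] - gap_extend)
    return max(M[m][n], X[m][n], Y[m][n])


def brute_local_score(profile_rows, subject, gap_open, gap_extend):
    """Best local affine-gap alignment score: exhaustive maximum of the
    global score over every (profile substring, subject substring) pair,
    floored at 0 (the empty alignment)."""
    m = len(profile_rows)
    n = len(subject)
    best = 0.0
    for i0 in range(m):
        for i1 in range(i0 + 1, m + 1):
            rows = profile_rows[i0:i1]
            for j0 in range(n):
                for j1 in range(j0 + 1, n + 1):
                    s = global_affine_score(rows, subject[j0:j1],
                                            gap_open, gap_extend)
                    if s > best:
                        best = s
    return best


def brute_homopolymer(seq, residue, matrix):
    """Quadratic scan: best-scoring substring of seq against an infinite
    homopolymer of `residue`, with the leftmost-end/leftmost-start
    tie-break. Returns (score, (start, end)) 1-based, or (0, None)."""
    scores = [matrix.score(residue, c) for c in seq]
    best = 0
    best_iv = None
    for j in range(len(seq)):  # end first: smallest end wins ties
        total = 0
        cand = None
        for i in range(j, -1, -1):  # then smallest start
            total += scores[i]
            if total >= (cand[0] if cand else -10**9):
                cand = (total, i)
        if cand and cand[0] > best:
            best = cand[0]
            best_iv = (cand[1] + 1, j + 1)
    return best, best_iv
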