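"""Affine-gap local alignment kernels (Gotoh dynamic programming).

One profile-vs-sequence formulation serves both pairwise alignment (a
sequence acts as a profile whose row i is the substitution-matrix row of
its residue i) and PSSM-vs-proteome searches. Gap cost follows the BLAST
convention: a gap of length k costs open + k*extend.

Determinism contract:
- the reported optimum is the first strictly-maximal cell in row-major
  order (smallest profile end, then smallest subject end);
- traceback ties prefer diagonal > up (gap in subject) > left (gap in
  profile).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10 ** 9)


@njit(cache=True)
def sw_score(profile, subject, gap_open, gap_extend):
    """Best local alignment score and end coordinates (score-only pass).

    profile: (L, 21) int32 position scores (column 20 = X);
    subject: (n,) int8 residue indices.
    Returns (score, qend, send) with 0-based inclusive ends; score 0 and
    ends -1 mean no positive-scoring alignment exists.
    """
    L = profile.shape[0]
    n = subject.shape[0]
    Hprev = np.zeros(n + 1, dtype=np.int64)
    Hcur = np.zeros(n + 1, dtype=np.int64)
    F = np.full(n + 1, NEG, dtype=np.int64)  # gap in subject (vertical)
    best = 0
    bi = -1
    bj = -1
    for i in range(1, L + 1):
        row = profile[i - 1]
        E = NEG  # gap in profile (horizontal), scalar within the row
        Hcur[0] = 0
        for j in range(1, n + 1):
            e_open = Hcur[j - 1] - gap_open - gap_extend
            E = E - gap_extend
            if e_open > E:
                E = e_open
            f_open = Hprev[j] - gap_open - gap_extend
            f = F[j] - gap_extend
            if f_open > f:
                f = f_open
            F[j] = f
            h = Hprev[j - 1] + row[subject[j - 1]]
            if f > h:
                h = f
            if E > h:
                h = E
            if h < 0:
                h = 0
            Hcur[j] = h
            if h > best:
                best = h
                bi = i - 1
                bj = j - 1
        Hprev, Hcur = Hcur, Hprev
    return best, bi, bj


@njit(cache=True)
def sw_traceback(profile, subject, gap_open, gap_extend):
    """Full DP with traceback.

    Returns (score, qstart, qend, sstart, send, qpath, spath) where qpath
    and spath are equal-length int32 arrays over the alignment columns,
    holding 0-based positions or -1 for a gap; coordinates are 0-based
    inclusive. score 0 means empty alignment (paths of length 0).
    """
    L = profile.shape[0]
    n = subject.shape[0]
    H = np.zeros((L + 1, n + 1), dtype=np.int64)
    E = np.full((L + 1, n + 1), NEG, dtype=np.int64)
    F = np.full((L + 1, n + 1), NEG, dtype=np.int64)
    # ptrH: 0 stop, 1 diag, 2 up (F), 3 left (E); ptrE/ptrF: 1 = extend
    ptrH = np.zeros((L + 1, n + 1), dtype=np.uint8)
    ptrE = np.zeros((L + 1, n + 1), dtype=np.uint8)
    ptrF = np.zeros((L + 1, n + 1), dtype=np.uint8)
    best = 0
    bi = -1
    bj = -1
    for i in range(1, L + 1):
        row = profile[i - 1]
        for j in range(1, n + 1):
            e_open = H[i, j - 1] - gap_open - gap_extend
            e_ext = E[i, j - 1] - gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
            else:
                E[i, j] = e_ext
                ptrE[i, j] = 1
            f_open = H[i - 1, j] - gap_open - gap_extend
            f_ext = F[i - 1, j] - gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
            else:
                F[i, j] = f_ext
                ptrF[i, j] = 1
            h = H[i - 1, j - 1] + row[subject[j - 1]]
            p = 1
            if F[i, j] > h:  # strict: diag preferred on ties
                h = F[i, j]
                p = 2
            if E[i, j] > h:  # up preferred over left on ties
                h = E[i, j]
                p = 3
            if h <= 0:
                h = 0
                p = 0
            H[i, j] = h
            ptrH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    if best == 0:
        empty = np.empty(0, dtype=np.int32)
        return 0, -1, -1, -1, -1, empty, empty

    qpath = np.empty(L + n, dtype=np.int32)
    spath = np.empty(L + n, dtype=np.int32)
    k = L + n
    i, j = bi, bj
    state = 0  # 0: in H, 1: in E, 2: in F
    while True:
        if state == 0:
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                k -= 1
                qpath[k] = i - 1
                spath[k] = j - 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 1
        elif state == 1:  # E: gap in profile, consume subject
            k -= 1
            qpath[k] = -1
            spath[k] = j - 1
            ext = ptrE[i, j]
            j -= 1
            if ext == 0:
                state = 0
        else:  # F: gap in subject, consume profile
            k -= 1
            qpath[k] = i - 1
            spath[k] = -1
            ext = ptrF[i, j]
            i -= 1
            if ext == 0:
                state = 0
    return best, i, bi - 1, j, bj - 1, qpath[k:].copy(), spath[k:].copy()
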