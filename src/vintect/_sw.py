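"""Affine-gap local alignment kernel (numba).

Scoring convention: a gap of length g scores gap_open + g * gap_extend,
i.e. the first gapped column costs gap_open + gap_extend. Base code 4 (N)
mismatches everything, including another N.
"""
from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10 ** 9)


@njit(cache=True)
def sw_align(q, s, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Best local alignment of encoded query q vs subject s.

    Returns (score, qstart, qend, sstart, send, n_match, n_cols) with
    half-open spans; all zeros when no positive-scoring alignment exists.
    """
    m = q.shape[0]
    n = s.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    tbH = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 0 stop,1 diag,2 E,3 F
    tbE = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 1 = extend
    tbF = np.zeros((m + 1, n + 1), dtype=np.uint8)

    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            e_open = H[i, j - 1] + gap_open + gap_extend
            e_ext = E[i, j - 1] + gap_extend
            if e_ext > e_open:
                E[i, j] = e_ext
                tbE[i, j] = 1
            else:
                E[i, j] = e_open

            f_open = H[i - 1, j] + gap_open + gap_extend
            f_ext = F[i - 1, j] + gap_extend
            if f_ext > f_open:
                F[i, j] = f_ext
                tbF[i, j] = 1
            else:
                F[i, j] = f_open

            if qi == s[j - 1] and qi != 4:
                sub = match
            else:
                sub = mismatch
            diag = H[i - 1, j - 1] + sub

            h = 0
            tb = 0
            if diag > h:
                h = diag
                tb = 1
            if E[i, j] > h:
                h = E[i, j]
                tb = 2
            if F[i, j] > h:
                h = F[i, j]
                tb = 3
            H[i, j] = h
            tbH[i, j] = tb
            if h > best:
                best = h
                bi = i
                bj = j

    if best <= 0:
        return 0, 0, 0, 0, 0, 0, 0

    i = bi
    j = bj
    n_match = 0
    n_cols = 0
    state = 0  # 0=H, 1=E, 2=F
    while True:
        if state == 0:
            tb = tbH[i, j]
            if tb == 0:
                break
            elif tb == 1:
                n_cols += 1
                if q[i - 1] == s[j - 1] and q[i - 1] != 4:
                    n_match += 1
                i -= 1
                j -= 1
            elif tb == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            n_cols += 1
            ext = tbE[i, j]
            j -= 1
            if ext == 0:
                state = 0
        else:
            n_cols += 1
            ext = tbF[i, j]
            i -= 1
            if ext == 0:
                state = 0

    return best, i, bi, j, bj, n_match, n_cols
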