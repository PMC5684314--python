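"""Numba Smith-Waterman kernel with affine gaps and traceback.

Scores are integers.  Gap of length k costs gap_open + k * gap_extend
(the NCBI convention for which the bundled Karlin-Altschul constants
are published).  Stop symbols are handled upstream by assigning them a
very large negative substitution score, so a local alignment never
crosses a stop.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int64(-(10**15))


@njit(cache=True)
def sw_score(q, s, sub, gap_open, gap_extend, stop_idx):  # pragma: no cover - jitted
    """Best local alignment score only (two-row DP, no traceback).

    A subject position equal to ``stop_idx`` can be consumed neither
    diagonally (its substitution scores are NEG) nor by a query gap, so no
    alignment crosses a stop; pass -1 to disable.
    """
    m = q.shape[0]
    n = s.shape[0]
    Hp = np.zeros(n + 1, np.int64)
    Hc = np.zeros(n + 1, np.int64)
    Ec = np.full(n + 1, NEG, np.int64)
    Fc = np.full(n + 1, NEG, np.int64)
    go = gap_open + gap_extend
    best = np.int64(0)
    for i in range(1, m + 1):
        qi = q[i - 1]
        Hc[0] = 0
        Ec[0] = NEG
        for j in range(1, n + 1):
            if s[j - 1] == stop_idx:
                e = NEG
            else:
                e = Hc[j - 1] - go
                ee = Ec[j - 1] - gap_extend
                if ee > e:
                    e = ee
            Ec[j] = e
            fo = Hp[j] - go
            fe = Fc[j] - gap_extend
            f = fe if fe > fo else fo
            Fc[j] = f
            h = Hp[j - 1] + sub[qi, s[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            Hc[j] = h
            if h > best:
                best = h
        Hp, Hc = Hc, Hp
    return int(best)


@njit(cache=True)
def sw_affine(q, s, sub, gap_open, gap_extend, stop_idx):  # pragma: no cover - jitted
    """Optimal local alignment of encoded sequences q and s.

    Returns (score, q_start, q_end, s_start, s_end, n_ident, n_aligned_cols)
    with half-open spans; n_aligned_cols counts residue-residue columns only
    (gap columns excluded), n_ident the identical ones among them.
    A zero score yields empty spans.
    """
    m = q.shape[0]
    n = s.shape[0]
    H = np.zeros((m + 1, n + 1), np.int64)
    E = np.full((m + 1, n + 1), NEG, np.int64)
    F = np.full((m + 1, n + 1), NEG, np.int64)
    # ptrH: 0 local start, 1 diagonal, 2 gap in query (E, left), 3 gap in subject (F, up)
    ptrH = np.zeros((m + 1, n + 1), np.uint8)
    ptrE = np.zeros((m + 1, n + 1), np.uint8)  # 1 = extend from E, 0 = open from H
    ptrF = np.zeros((m + 1, n + 1), np.uint8)
    go = gap_open + gap_extend  # cost of the first gap residue
    best = np.int64(0)
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            if s[j - 1] == stop_idx:
                E[i, j] = NEG
            else:
                e_open = H[i, j - 1] - go
                e_ext = E[i, j - 1] - gap_extend
                if e_ext > e_open:
                    E[i, j] = e_ext
                    ptrE[i, j] = 1
                else:
                    E[i, j] = e_open
            f_open = H[i - 1, j] - go
            f_ext = F[i - 1, j] - gap_extend
            if f_ext > f_open:
                F[i, j] = f_ext
                ptrF[i, j] = 1
            else:
                F[i, j] = f_open
            d = H[i - 1, j - 1] + sub[qi, s[j - 1]]
            h = np.int64(0)
            p = np.uint8(0)
            if d > h:
                h = d
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ptrH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    if best == 0:
        return 0, 0, 0, 0, 0, 0, 0
    # traceback
    i = bi
    j = bj
    n_ident = 0
    n_cols = 0
    state = 0  # 0 = H, 1 = E, 2 = F
    while True:
        if state == 0:
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                if q[i - 1] == s[j - 1]:
                    n_ident += 1
                n_cols += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            if ptrE[i, j] == 0:
                state = 0
            j -= 1
        else:
            if ptrF[i, j] == 0:
                state = 0
            i -= 1
    return int(best), i, bi, j, bj, n_ident, n_cols
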