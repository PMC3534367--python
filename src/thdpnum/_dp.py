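"""Numba kernels for the profile-HMM dynamic programming.

All arithmetic is in log2 space (bits).  The model is traversed glocally:
begin -> (M1|D1), ..., (MK|DK) -> end, with any number of query residues
absorbed before entry and after exit at zero log-odds (flank states scored
at background).

Array conventions (K match states, L query residues, indices 1-based in
the maths, 0-based in storage):

* ``mat_lo[k-1, a]``  match-state k log-odds for symbol a
* ``ins_lo[k, a]``    insert-state k log-odds (rows 0 and K are flanks and
                      are forced to zero by the caller)
* ``tmm[k]``          log2 P(M_k -> M_{k+1}); ``tmm[0]`` is begin -> M1
* ``tmd[k]``          log2 P(M_k -> D_{k+1}); ``tmd[0]`` is begin -> D1
* ``tmi/tim/tii/tdm/tdd[k]`` likewise, defined for k = 1..K-1

M_K -> end and D_K -> end carry probability 1 (zero bits).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -np.inf

# traceback codes
_FROM_M = 0
_FROM_I = 1
_FROM_D = 2
_FROM_BEGIN = 3


@njit(cache=True)
def _logaddexp2(a, b):
    if a == NEG_INF:
        return b
    if b == NEG_INF:
        return a
    if a < b:
        a, b = b, a
    return a + np.log2(1.0 + 2.0 ** (b - a))


@njit(cache=True)
def viterbi_fill(seq, mat_lo, ins_lo, tmm, tmi, tmd, tim, tii, tdm, tdd):
    """Fill Viterbi matrices with traceback pointers.

    Tie-breaking prefers match over delete over insert predecessors, which
    is encoded by the comparison order below (strict ``>`` keeps the
    earlier, preferred, option).
    """
    L = seq.shape[0]
    K = mat_lo.shape[0]
    M = np.full((L + 1, K + 1), NEG_INF)
    I = np.full((L + 1, K + 1), NEG_INF)
    D = np.full((L + 1, K + 1), NEG_INF)
    ptrM = np.zeros((L + 1, K + 1), dtype=np.int8)
    ptrI = np.zeros((L + 1, K + 1), dtype=np.int8)
    ptrD = np.zeros((L + 1, K + 1), dtype=np.int8)

    # node 1 entered from the free N-flank (any prefix, zero bits)
    for i in range(0, L + 1):
        D[i, 1] = tmd[0]
        ptrD[i, 1] = _FROM_BEGIN
    for i in range(1, L + 1):
        M[i, 1] = mat_lo[0, seq[i - 1]] + tmm[0]
        ptrM[i, 1] = _FROM_BEGIN

    for i in range(0, L + 1):
        for k in range(1, K + 1):
            if k >= 2 and i >= 1:
                best = M[i - 1, k - 1] + tmm[k - 1]
                ptr = _FROM_M
                alt = D[i - 1, k - 1] + tdm[k - 1]
                if alt > best:
                    best = alt
                    ptr = _FROM_D
                alt = I[i - 1, k - 1] + tim[k - 1]
                if alt > best:
                    best = alt
                    ptr = _FROM_I
                M[i, k] = mat_lo[k - 1, seq[i - 1]] + best
                ptrM[i, k] = ptr
            # interior insert states I_1..I_{K-1}
            if 1 <= k <= K - 1 and i >= 1:
                best = M[i - 1, k] + tmi[k]
                ptr = _FROM_M
                alt = I[i - 1, k] + tii[k]
                if alt > best:
                    best = alt
                    ptr = _FROM_I
                I[i, k] = ins_lo[k, seq[i - 1]] + best
                ptrI[i, k] = ptr
            if k >= 2:
                best = M[i, k - 1] + tmd[k - 1]
                ptr = _FROM_M
                alt = D[i, k - 1] + tdd[k - 1]
                if alt > best:
                    best = alt
                    ptr = _FROM_D
                D[i, k] = best
                ptrD[i, k] = ptr

    return M, I, D, ptrM, ptrI, ptrD


@njit(cache=True)
def viterbi_traceback(M, I, D, ptrM, ptrI, ptrD, L, K):
    """Pick the best exit and trace the core path back to the entry point.

    Returns (score, kinds, nodes, qidx, n_steps, entry_i, exit_i) where
    kinds is 0=M, 1=I, 2=D over the core path in forward order.
    """
    best = NEG_INF
    exit_i = 0
    exit_state = 0  # 0 = M, 2 = D
    for i in range(0, L + 1):
        if M[i, K] >= best:
            best = M[i, K]
            exit_i = i
            exit_state = 0
        if D[i, K] > best:
            best = D[i, K]
            exit_i = i
            exit_state = 2

    kinds = np.empty(L + K + 1, dtype=np.int8)
    nodes = np.empty(L + K + 1, dtype=np.int64)
    qidx = np.empty(L + K + 1, dtype=np.int64)
    n = 0
    state = exit_state
    i = exit_i
    k = K
    while True:
        kinds[n] = state
        nodes[n] = k
        qidx[n] = i if state != 2 else 0
        n += 1
        if state == 0:
            p = ptrM[i, k]
            i -= 1
            if p == _FROM_BEGIN:
                break
            k_next = k - 1
            if p == _FROM_M:
                state = 0
            elif p == _FROM_I:
                state = 1
            else:
                state = 2
            k = k_next
        elif state == 1:
            p = ptrI[i, k]
            i -= 1
            state = 0 if p == _FROM_M else 1
        else:
            p = ptrD[i, k]
            if p == _FROM_BEGIN:
                break
            k -= 1
            state = 0 if p == _FROM_M else 2

    # reverse into forward order
    kinds_f = kinds[:n][::-1].copy()
    nodes_f = nodes[:n][::-1].copy()
    qidx_f = qidx[:n][::-1].copy()
    entry_i = i
    return best, kinds_f, nodes_f, qidx_f, n, entry_i, exit_i


@njit(cache=True)
def forward_score(seq, mat_lo, ins_lo, tmm, tmi, tmd, tim, tii, tdm, tdd):
    """Log2-sum over all glocal paths (bits)."""
    L = seq.shape[0]
    K = mat_lo.shape[0]
    M = np.full((L + 1, K + 1), NEG_INF)
    I = np.full((L + 1, K + 1), NEG_INF)
    D = np.full((L + 1, K + 1), NEG_INF)

    for i in range(0, L + 1):
        D[i, 1] = tmd[0]
    for i in range(1, L + 1):
        M[i, 1] = mat_lo[0, seq[i - 1]] + tmm[0]

    for i in range(0, L + 1):
        for k in range(1, K + 1):
            if k >= 2 and i >= 1:
                s = _logaddexp2(M[i - 1, k - 1] + tmm[k - 1],
                                D[i - 1, k - 1] + tdm[k - 1])
                s = _logaddexp2(s, I[i - 1, k - 1] + tim[k - 1])
                M[i, k] = mat_lo[k - 1, seq[i - 1]] + s
            if 1 <= k <= K - 1 and i >= 1:
                s = _logaddexp2(M[i - 1, k] + tmi[k],
                                I[i - 1, k] + tii[k])
                I[i, k] = ins_lo[k, seq[i - 1]] + s
            if k >= 2:
                D[i, k] = _logaddexp2(M[i, k - 1] + tmd[k - 1],
                                      D[i, k - 1] + tdd[k - 1])

    total = NEG_INF
    for i in range(0, L + 1):
        total = _logaddexp2(total, M[i, K])
        total = _logaddexp2(total, D[i, K])
    return total
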