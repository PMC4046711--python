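"""Jit-compiled dynamic-programming kernels for the pair-HMM.

State order everywhere: 0 = M, 1 = I_x, 2 = I_y.  All arrays are log
probabilities (-inf for forbidden moves).  Cell (i, j) of a DP table means
"i symbols of x and j symbols of y emitted"; tables carry a leading 0
row/column for the empty prefix.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -np.inf


@njit(cache=True)
def _lse3(a: float, b: float, c: float) -> float:
    m = a
    if b > m:
        m = b
    if c > m:
        m = c
    if m == NEG_INF:
        return NEG_INF
    return m + np.log(np.exp(a - m) + np.exp(b - m) + np.exp(c - m))


@njit(cache=True)
def forward_full(lem_m, lem_x, lem_y, ltr, lstart, ltau):
    """Full forward table F[state, i, j]; returns (F, log total probability)."""
    L, M = lem_m.shape
    F = np.full((3, L + 1, M + 1), NEG_INF)
    for i in range(L + 1):
        for j in range(M + 1):
            if i == 0 and j == 0:
                continue
            if i >= 1 and j >= 1:
                acc = _lse3(
                    F[0, i - 1, j - 1] + ltr[0, 0],
                    F[1, i - 1, j - 1] + ltr[1, 0],
                    F[2, i - 1, j - 1] + ltr[2, 0],
                )
                if i == 1 and j == 1:
                    acc = np.logaddexp(acc, lstart[0])
                F[0, i, j] = lem_m[i - 1, j - 1] + acc
            if i >= 1:
                acc = _lse3(
                    F[0, i - 1, j] + ltr[0, 1],
                    F[1, i - 1, j] + ltr[1, 1],
                    F[2, i - 1, j] + ltr[2, 1],
                )
                if i == 1 and j == 0:
                    acc = np.logaddexp(acc, lstart[1])
                F[1, i, j] = lem_x[i - 1] + acc
            if j >= 1:
                acc = _lse3(
                    F[0, i, j - 1] + ltr[0, 2],
                    F[1, i, j - 1] + ltr[1, 2],
                    F[2, i, j - 1] + ltr[2, 2],
                )
                if i == 0 and j == 1:
                    acc = np.logaddexp(acc, lstart[2])
                F[2, i, j] = lem_y[j - 1] + acc
    total = _lse3(
        F[0, L, M] + ltau[0], F[1, L, M] + ltau[1], F[2, L, M] + ltau[2]
    )
    return F, total


@njit(cache=True)
def backward_full(lem_m, lem_x, lem_y, ltr, ltau):
    """Full backward table B[state, i, j]: log probability of emitting the
    remaining suffixes given the chain is at state after cell (i, j)."""
    L, M = lem_m.shape
    B = np.full((3, L + 1, M + 1), NEG_INF)
    for s in range(3):
        B[s, L, M] = ltau[s]
    for i in range(L, -1, -1):
        for j in range(M, -1, -1):
            if i == L and j == M:
                continue
            diag = NEG_INF
            up = NEG_INF
            left = NEG_INF
            if i < L and j < M:
                diag = lem_m[i, j] + B[0, i + 1, j + 1]
            if i < L:
                up = lem_x[i] + B[1, i + 1, j]
            if j < M:
                left = lem_y[j] + B[2, i, j + 1]
            for s in range(3):
                B[s, i, j] = _lse3(
                    ltr[s, 0] + diag, ltr[s, 1] + up, ltr[s, 2] + left
                )
    return B


@njit(cache=True)
def forward_rolling(XA, YW, lem_x, lem_y, ltr, lstart, ltau):
    """log total probability with O(M) memory; match emission computed on the
    fly as dot(XA[i], YW[j]).  For very long sequence pairs."""
    L = XA.shape[0]
    M = YW.shape[0]
    K = XA.shape[1]
    prev = np.full((3, M + 1), NEG_INF)
    cur = np.full((3, M + 1), NEG_INF)
    # row i = 0: only I_y emissions
    for j in range(1, M + 1):
        acc = _lse3(
            prev[0, j - 1] + ltr[0, 2],
            prev[1, j - 1] + ltr[1, 2],
            prev[2, j - 1] + ltr[2, 2],
        )
        if j == 1:
            acc = np.logaddexp(acc, lstart[2])
        prev[2, j] = lem_y[j - 1] + acc
    for i in range(1, L + 1):
        for s in range(3):
            for j in range(M + 1):
                cur[s, j] = NEG_INF
        for j in range(M + 1):
            if j >= 1:
                em = 0.0
                for k in range(K):
                    em += XA[i - 1, k] * YW[j - 1, k]
                acc = _lse3(
                    prev[0, j - 1] + ltr[0, 0],
                    prev[1, j - 1] + ltr[1, 0],
                    prev[2, j - 1] + ltr[2, 0],
                )
                if i == 1 and j == 1:
                    acc = np.logaddexp(acc, lstart[0])
                cur[0, j] = np.log(em) + acc
            acc = _lse3(
                prev[0, j] + ltr[0, 1],
                prev[1, j] + ltr[1, 1],
                prev[2, j] + ltr[2, 1],
            )
            if i == 1 and j == 0:
                acc = np.logaddexp(acc, lstart[1])
            cur[1, j] = lem_x[i - 1] + acc
            if j >= 1:
                acc = _lse3(
                    cur[0, j - 1] + ltr[0, 2],
                    cur[1, j - 1] + ltr[1, 2],
                    cur[2, j - 1] + ltr[2, 2],
                )
                cur[2, j] = lem_y[j - 1] + acc
        tmp = prev
        prev = cur
        cur = tmp
    return _lse3(
        prev[0, M] + ltau[0], prev[1, M] + ltau[1], prev[2, M] + ltau[2]
    )


@njit(cache=True)
def viterbi_full(lem_m, lem_x, lem_y, ltr, lstart, ltau):
    """Most probable state path.  Returns (states array, log path probability).

    Ties broken toward the lower state index: M, then I_x, then I_y.
    """
    L, M = lem_m.shape
    V = np.full((3, L + 1, M + 1), NEG_INF)
    ptr = np.full((3, L + 1, M + 1), -1, dtype=np.int8)
    for i in range(L + 1):
        for j in range(M + 1):
            if i == 0 and j == 0:
                continue
            if i >= 1 and j >= 1:
                best = NEG_INF
                arg = -1
                for s in range(3):
                    v = V[s, i - 1, j - 1] + ltr[s, 0]
                    if v > best:
                        best = v
                        arg = s
                if i == 1 and j == 1 and lstart[0] > best:
                    best = lstart[0]
                    arg = 3  # start
                V[0, i, j] = lem_m[i - 1, j - 1] + best
                ptr[0, i, j] = arg
            if i >= 1:
                best = NEG_INF
                arg = -1
                for s in range(3):
                    v = V[s, i - 1, j] + ltr[s, 1]
                    if v > best:
                        best = v
                        arg = s
                if i == 1 and j == 0 and lstart[1] > best:
                    best = lstart[1]
                    arg = 3
                V[1, i, j] = lem_x[i - 1] + best
                ptr[1, i, j] = arg
            if j >= 1:
                best = NEG_INF
                arg = -1
                for s in range(3):
                    v = V[s, i, j - 1] + ltr[s, 2]
                    if v > best:
                        best = v
                        arg = s
                if i == 0 and j == 1 and lstart[2] > best:
                    best = lstart[2]
                    arg = 3
                V[2, i, j] = lem_y[j - 1] + best
                ptr[2, i, j] = arg
    best = NEG_INF
    s_end = 0
    for s in range(3):
        v = V[s, L, M] + ltau[s]
        if v > best:
            best = v
            s_end = s
    # traceback
    states = np.empty(L + M, dtype=np.int8)
    n = 0
    s = s_end
    i, j = L, M
    while True:
        states[n] = s
        n += 1
        p = ptr[s, i, j]
        if s == 0:
            i -= 1
            j -= 1
        elif s == 1:
            i -= 1
        else:
            j -= 1
        if p == 3 or p == -1:
            break
        s = p
    out = states[:n][::-1].copy()
    return out, best
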