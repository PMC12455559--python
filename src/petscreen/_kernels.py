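"""Numba dynamic-programming kernels: affine-gap alignment, profile-HMM forward/Viterbi.

All kernels work in plain float64 arrays so they can be reused for
sequence-sequence and profile-profile alignment alike.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -np.inf


@njit(cache=True)
def nw_affine(S, gap_open, gap_extend):
    """Global affine-gap alignment (Gotoh) over a precomputed pair-score matrix.

    S[i, j] is the score of pairing item i of A with item j of B. A gap run of
    length k costs gap_open + (k - 1) * gap_extend (both arguments negative).

    Returns (score, ai, bj) where ai/bj are index arrays of the aligned path
    with -1 marking a gap. Tie-break: match > delete (gap in B) > insert.
    """
    n, m = S.shape
    H = np.full((n + 1, m + 1), NEG_INF)
    E = np.full((n + 1, m + 1), NEG_INF)  # gap in A (consumes B)
    F = np.full((n + 1, m + 1), NEG_INF)  # gap in B (consumes A)
    ptrH = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 from F, 2 from E
    ptrE = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 open, 1 extend
    ptrF = np.zeros((n + 1, m + 1), dtype=np.int8)

    H[0, 0] = 0.0
    for i in range(1, n + 1):
        F[i, 0] = gap_open + (i - 1) * gap_extend
        H[i, 0] = F[i, 0]
        ptrH[i, 0] = 1
        ptrF[i, 0] = 1
    for j in range(1, m + 1):
        E[0, j] = gap_open + (j - 1) * gap_extend
        H[0, j] = E[0, j]
        ptrH[0, j] = 2
        ptrE[0, j] = 1

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i, j - 1] + gap_open
            e_ext = E[i, j - 1] + gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                ptrE[i, j] = 0
            else:
                E[i, j] = e_ext
                ptrE[i, j] = 1
            f_open = H[i - 1, j] + gap_open
            f_ext = F[i - 1, j] + gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                ptrF[i, j] = 0
            else:
                F[i, j] = f_ext
                ptrF[i, j] = 1
            diag = H[i - 1, j - 1] + S[i - 1, j - 1]
            best = diag
            p = 0
            if F[i, j] > best:
                best = F[i, j]
                p = 1
            if E[i, j] > best:
                best = E[i, j]
                p = 2
            H[i, j] = best
            ptrH[i, j] = p

    # traceback
    ai = np.empty(n + m, dtype=np.int64)
    bj = np.empty(n + m, dtype=np.int64)
    k = 0
    i, j = n, m
    state = 0  # 0 = H, 1 = F, 2 = E
    while i > 0 or j > 0:
        if state == 0:
            p = ptrH[i, j]
            if p == 0:
                ai[k] = i - 1
                bj[k] = j - 1
                k += 1
                i -= 1
                j -= 1
            else:
                state = p
        elif state == 1:
            ai[k] = i - 1
            bj[k] = -1
            k += 1
            nxt = ptrF[i, j]
            i -= 1
            state = 0 if nxt == 0 else 1
        else:
            ai[k] = -1
            bj[k] = j - 1
            k += 1
            nxt = ptrE[i, j]
            j -= 1
            state = 0 if nxt == 0 else 2
    return H[n, m], ai[:k][::-1].copy(), bj[:k][::-1].copy()


@njit(cache=True)
def hmm_forward(x, lodds_m, lodds_i, ltr, local):
    """Log-odds forward score (natural log) of encoded sequence x.

    lodds_m/lodds_i: (L+1, 21) log-odds emissions for match/insert states
    (row 0 of lodds_m unused; insert row 0 is I0). ltr: (L+1, 3, 3) log
    transition probabilities, node k from-state {0:M,1:I,2:D} to-state
    {0:M(k+1), 1:I(k), 2:D(k+1)}; node 0 M is Begin, node L M->M is exit to End.

    local=True gives uni-local scoring: uniform entry over match states,
    free exit, flanking residues emitted at background odds (0 log-odds).
    """
    n = x.shape[0]
    L = lodds_m.shape[0] - 1
    fM = np.full((L + 1, n + 1), NEG_INF)
    fI = np.full((L + 1, n + 1), NEG_INF)
    fD = np.full((L + 1, n + 1), NEG_INF)

    log_entry = -np.log(L) if local else 0.0

    if not local:
        fM[0, 0] = 0.0  # Begin
        # delete chain from Begin along t = 0
        for k in range(1, L + 1):
            fD[k, 0] = np.logaddexp(
                fM[k - 1, 0] + ltr[k - 1, 0, 2], fD[k - 1, 0] + ltr[k - 1, 2, 2]
            )
    # fC[t]: local-mode suffix flank; fN = 0 for all t in local mode
    fC = np.full(n + 1, NEG_INF)

    for t in range(1, n + 1):
        c = x[t - 1]
        for k in range(1, L + 1):
            acc = fM[k - 1, t - 1] + ltr[k - 1, 0, 0]
            acc = np.logaddexp(acc, fI[k - 1, t - 1] + ltr[k - 1, 1, 0])
            acc = np.logaddexp(acc, fD[k - 1, t - 1] + ltr[k - 1, 2, 0])
            if local:
                acc = np.logaddexp(acc, log_entry)  # from N at t-1, fN = 0
            fM[k, t] = lodds_m[k, c] + acc
        for k in range(0, L + 1):
            acc = np.logaddexp(fM[k, t - 1] + ltr[k, 0, 1], fI[k, t - 1] + ltr[k, 1, 1])
            acc = np.logaddexp(acc, fD[k, t - 1] + ltr[k, 2, 1])
            fI[k, t] = lodds_i[k, c] + acc
        for k in range(1, L + 1):
            acc = np.logaddexp(fM[k - 1, t] + ltr[k - 1, 0, 2], fI[k - 1, t] + ltr[k - 1, 1, 2])
            acc = np.logaddexp(acc, fD[k - 1, t] + ltr[k - 1, 2, 2])
            fD[k, t] = acc
        if local:
            acc = fC[t - 1]
            for k in range(1, L + 1):
                acc = np.logaddexp(acc, fM[k, t])
            fC[t] = acc

    if local:
        total = 0.0 if n == 0 else NEG_INF  # all-flank path
        if n > 0:
            total = fC[n]
            total = np.logaddexp(total, 0.0)  # sequence fully emitted by N
        return total
    acc = np.logaddexp(fM[L, n] + ltr[L, 0, 0], fI[L, n] + ltr[L, 1, 0])
    acc = np.logaddexp(acc, fD[L, n] + ltr[L, 2, 0])
    return acc


@njit(cache=True)
def hmm_viterbi(x, lodds_m, lodds_i, ltr, local):
    """Viterbi path. Returns (score, col_assign).

    col_assign[t] for residue t (0-based): k > 0 residue emitted by match
    state k; -k residue emitted by insert state I(k); 0 flank (local mode).
    Tie-break on incoming state: M > D > I.
    """
    n = x.shape[0]
    L = lodds_m.shape[0] - 1
    vM = np.full((L + 1, n + 1), NEG_INF)
    vI = np.full((L + 1, n + 1), NEG_INF)
    vD = np.full((L + 1, n + 1), NEG_INF)
    pM = np.zeros((L + 1, n + 1), dtype=np.int8)  # 0 M, 1 I, 2 D, 3 flank/Begin
    pI = np.zeros((L + 1, n + 1), dtype=np.int8)
    pD = np.zeros((L + 1, n + 1), dtype=np.int8)

    log_entry = -np.log(L) if local else 0.0

    if not local:
        vM[0, 0] = 0.0
        for k in range(1, L + 1):
            a = vM[k - 1, 0] + ltr[k - 1, 0, 2]
            b = vD[k - 1, 0] + ltr[k - 1, 2, 2]
            if a >= b:
                vD[k, 0] = a
                pD[k, 0] = 0
            else:
                vD[k, 0] = b
                pD[k, 0] = 2

    for t in range(1, n + 1):
        c = x[t - 1]
        for k in range(1, L + 1):
            best = vM[k - 1, t - 1] + ltr[k - 1, 0, 0]
            p = 0
            cand = vD[k - 1, t - 1] + ltr[k - 1, 2, 0]
            if cand > best:
                best = cand
                p = 2
            cand = vI[k - 1, t - 1] + ltr[k - 1, 1, 0]
            if cand > best:
                best = cand
                p = 1
            if local and log_entry > best:
                best = log_entry
                p = 3
            vM[k, t] = lodds_m[k, c] + best
            pM[k, t] = p
        for k in range(0, L + 1):
            best = vM[k, t - 1] + ltr[k, 0, 1]
            p = 0
            cand = vD[k, t - 1] + ltr[k, 2, 1]
            if cand > best:
                best = cand
                p = 2
            cand = vI[k, t - 1] + ltr[k, 1, 1]
            if cand > best:
                best = cand
                p = 1
            vI[k, t] = lodds_i[k, c] + best
            pI[k, t] = p
        for k in range(1, L + 1):
            best = vM[k - 1, t] + ltr[k - 1, 0, 2]
            p = 0
            cand = vD[k - 1, t] + ltr[k - 1, 2, 2]
            if cand > best:
                best = cand
                p = 2
            cand = vI[k - 1, t] + ltr[k - 1, 1, 2]
            if cand > best:
                best = cand
                p = 1
            vD[k, t] = best
            pD[k, t] = p

    col_assign = np.zeros(n, dtype=np.int64)

    if local:
        # best exit: match state k at position t, suffix t+1..n is flank
        best = NEG_INF
        bk = 0
        bt = 0
        for t in range(1, n + 1):
            for k in range(1, L + 1):
                if vM[k, t] > best:
                    best = vM[k, t]
                    bk = k
                    bt = t
        if n == 0 or best < 0.0:
            # all-flank path (score 0) wins
            return 0.0, col_assign
        k, t = bk, bt
        state = 0
        while True:
            if state == 0:
                col_assign[t - 1] = k
                p = pM[k, t]
                if p == 3:
                    break
                k2 = k - 1
                t2 = t - 1
                k, t, state = k2, t2, int(p)
            elif state == 1:
                col_assign[t - 1] = -k
                p = pI[k, t]
                t -= 1
                state = int(p)
            else:
                p = pD[k, t]
                k -= 1
                state = int(p)
        return best, col_assign

    # global: end = M(L+1); choose best of M/D/I at node L, t = n
    best = vM[L, n] + ltr[L, 0, 0]
    state = 0
    cand = vD[L, n] + ltr[L, 2, 0]
    if cand > best:
        best = cand
        state = 2
    cand = vI[L, n] + ltr[L, 1, 0]
    if cand > best:
        best = cand
        state = 1
    k, t = L, n
    while k > 0 or t > 0:
        if state == 0:
            if k == 0:
                break
            col_assign[t - 1] = k
            p = pM[k, t]
            k -= 1
            t -= 1
            state = int(p)
        elif state == 1:
            col_assign[t - 1] = -k
            p = pI[k, t]
            t -= 1
            state = int(p)
        else:
            p = pD[k, t]
            k -= 1
            state = int(p)
    return best, col_assign
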