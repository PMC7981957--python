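"""Numba kernels for the diploid copying-HMM forward-backward recursion.

The hidden state is an ordered template pair (i, j); the transition kernel
factorizes per haplotype, so one step costs O(K^2):

    sum_{k,l} T(k->i) T(l->j) P(k,l)
        = sp^2 P(i,j) + sp*m (row_i + col_j) + m^2 S

with T(k->i) = m + sp * delta(k,i), sp = stay - move, row/col/S the partial
sums of P.  Emissions depend on the state only through the template allele
sum c = a_i + a_j, written branchlessly as the quadratic
e(c) = e0 + (e1-e0)(a_i+a_j) + (e2-2e1+e0) a_i a_j.

Loops are written scalar-style so numba can vectorize them; the forward
matrices are stored per site and consumed by the backward pass.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_JIT = dict(cache=True, fastmath=True, nogil=True)


@njit(**_JIT)
def forward_pass(af_t, evals, stays, moves, seg_start, F, err):
    """Scaled forward recursion; fills F (M, K, K) and returns log-likelihood.

    ``af_t`` is the (M, K) float allele matrix (site-major).  ``err`` is a
    one-element int64 buffer: -1 on success, else the site index where the
    forward probability vanished.
    """
    M, K = af_t.shape
    err[0] = -1
    u = 1.0 / (K * K)
    loglik = 0.0
    for m in range(M):
        e0, e1, e2 = evals[m, 0], evals[m, 1], evals[m, 2]
        d1 = e1 - e0
        d2 = e2 - 2.0 * e1 + e0
        a = af_t[m]
        c = 0.0
        if seg_start[m]:
            for i in range(K):
                ai = a[i]
                base = (e0 + d1 * ai) * u
                fac = (d1 + d2 * ai) * u
                for j in range(K):
                    v = base + fac * a[j]
                    F[m, i, j] = v
                    c += v
        else:
            P = F[m - 1]
            stay = stays[m]
            move = moves[m]
            sp = stay - move
            row = np.empty(K)
            col = np.zeros(K)
            for i in range(K):
                r = 0.0
                for j in range(K):
                    v = P[i, j]
                    r += v
                    col[j] += v
                row[i] = r
            S = 0.0
            for i in range(K):
                S += row[i]
            spsp = sp * sp
            spm = sp * move
            mm = move * move * S
            for i in range(K):
                ai = a[i]
                ri = spm * row[i] + mm
                base = e0 + d1 * ai
                fac = d1 + d2 * ai
                for j in range(K):
                    em = base + fac * a[j]
                    v = (spsp * P[i, j] + ri + spm * col[j]) * em
                    F[m, i, j] = v
                    c += v
        if not (c > 0.0):
            err[0] = m
            return 0.0
        inv = 1.0 / c
        for i in range(K):
            for j in range(K):
                F[m, i, j] *= inv
        loglik += np.log(c)
    return loglik


@njit(**_JIT)
def _class_masses_of(P, B, a, K):
    """Mass of P*B on template-allele-sum classes via moment accumulators."""
    tot = 0.0
    acc1 = 0.0
    acc2 = 0.0
    for i in range(K):
        ai = a[i]
        for j in range(K):
            v = P[i, j] * B[i, j]
            aj = a[j]
            tot += v
            acc1 += v * (ai + aj)
            acc2 += v * (ai * aj)
    m2 = acc2
    m1 = acc1 - 2.0 * acc2
    m0 = tot - m1 - m2
    return m0, m1, m2


@njit(**_JIT)
def backward_pass(gls, af_t, evals, stays, moves, seg_start, W, F, posts, loo,
                  compute_loo):
    """Backward recursion accumulating genotype posteriors (and LOO dosages).

    ``posts`` (M, 3) and ``loo`` (M,) are output buffers.  The backward
    message is rescaled by its own sum, so a site's emission never enters
    its own leave-one-out dosage.
    """
    M, K = af_t.shape
    u = 1.0 / (K * K)
    B = np.full((K, K), u)
    EB = np.empty((K, K))
    UNI = np.full((K, K), u)
    for m in range(M - 1, -1, -1):
        a = af_t[m]
        e0, e1, e2 = evals[m, 0], evals[m, 1], evals[m, 2]
        m0, m1, m2 = _class_masses_of(F[m], B, a, K)
        tot = m0 + m1 + m2
        m0 /= tot
        m1 /= tot
        m2 /= tot
        ps = 0.0
        for g in range(3):
            s = 0.0
            if e0 > 0.0:
                s += m0 / e0 * W[0, g] * gls[m, g]
            if e1 > 0.0:
                s += m1 / e1 * W[1, g] * gls[m, g]
            if e2 > 0.0:
                s += m2 / e2 * W[2, g] * gls[m, g]
            posts[m, g] = s
            ps += s
        for g in range(3):
            posts[m, g] /= ps

        if compute_loo:
            if seg_start[m]:
                q0, q1, q2 = _class_masses_of(UNI, B, a, K)
            else:
                P = F[m - 1]
                stay = stays[m]
                move = moves[m]
                sp = stay - move
                row = np.empty(K)
                col = np.zeros(K)
                for i in range(K):
                    r = 0.0
                    for j in range(K):
                        v = P[i, j]
                        r += v
                        col[j] += v
                    row[i] = r
                S = 0.0
                for i in range(K):
                    S += row[i]
                spsp = sp * sp
                spm = sp * move
                mm = move * move * S
                q0 = 0.0
                q1 = 0.0
                q2 = 0.0
                for i in range(K):
                    ai = a[i]
                    ri = spm * row[i] + mm
                    for j in range(K):
                        v = (spsp * P[i, j] + ri + spm * col[j]) * B[i, j]
                        aj = a[j]
                        q1 += v * (ai + aj)
                        q2 += v * (ai * aj)
                        q0 += v
                q0 = q0 - q1 + q2  # q0 accumulated tot; convert moments to classes
                q1 = q1 - 2.0 * q2
            qt = q0 + q1 + q2
            q0 /= qt
            q1 /= qt
            q2 /= qt
            g1 = q0 * W[0, 1] + q1 * W[1, 1] + q2 * W[2, 1]
            g2 = q0 * W[0, 2] + q1 * W[1, 2] + q2 * W[2, 2]
            loo[m] = g1 + 2.0 * g2

        if m > 0:
            if seg_start[m]:
                for i in range(K):
                    for j in range(K):
                        B[i, j] = u
            else:
                d1 = e1 - e0
                d2 = e2 - 2.0 * e1 + e0
                for i in range(K):
                    ai = a[i]
                    base = e0 + d1 * ai
                    fac = d1 + d2 * ai
                    for j in range(K):
                        EB[i, j] = (base + fac * a[j]) * B[i, j]
                stay = stays[m]
                move = moves[m]
                sp = stay - move
                row = np.empty(K)
                col = np.zeros(K)
                for i in range(K):
                    r = 0.0
                    for j in range(K):
                        v = EB[i, j]
                        r += v
                        col[j] += v
                    row[i] = r
                S = 0.0
                for i in range(K):
                    S += row[i]
                spsp = sp * sp
                spm = sp * move
                mm = move * move * S
                bs = 0.0
                for i in range(K):
                    ri = spm * row[i] + mm
                    for j in range(K):
                        v = spsp * EB[i, j] + ri + spm * col[j]
                        B[i, j] = v
                        bs += v
                inv = 1.0 / bs
                for i in range(K):
                    for j in range(K):
                        B[i, j] *= inv
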