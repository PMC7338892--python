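"""Compiled inner loops for the online trainers.

All kernels use explicit scalar loops with a fixed accumulation order.
This keeps the reductions exact: running the network kernel with d = 1,
or the multiview kernel with k = 2, performs bit-for-bit the same
floating-point operations as the single-neuron kernel.

Kernels advance the state in place over a chunk of presented samples;
the Python wrappers handle initialization, chunking, metric recording
and divergence checks.
"""

import numpy as np
from numba import njit

__all__ = [
    "single_chunk",
    "network_chunk",
    "nonlocal_chunk",
    "multiview_chunk",
]


@njit(cache=True)
def single_chunk(X, Y, idx, fac, ba, bb, balpha, bbeta, a, b, ab):
    """Single two-compartment neuron; ``ab = [alpha, beta]`` mutated in place."""
    n = a.shape[0]
    m = b.shape[0]
    for s in range(idx.shape[0]):
        t = idx[s]
        f = fac[s]
        ca = 0.0
        for i in range(n):
            ca += a[i] * X[t, i]
        cb = 0.0
        for i in range(m):
            cb += b[i] * Y[t, i]
        c = ca + cb
        ga = c - ab[0] * ca
        gb = c - ab[1] * cb
        ea = ba * f
        eb = bb * f
        for i in range(n):
            a[i] += ea * ga * X[t, i]
        for i in range(m):
            b[i] += eb * gb * Y[t, i]
        ab[0] += 0.5 * (balpha * f) * (ca * ca - 1.0)
        ab[1] += 0.5 * (bbeta * f) * (cb * cb - 1.0)


@njit(cache=True)
def network_chunk(
    X, Y, idx, fac, ba, bb, balpha, bbeta, bm,
    gate, A, B, M, alpha, beta, ca, cb, c, local_rule,
):
    """Asymmetric deflation network of d pyramidal neurons.

    ``A`` (d, n) and ``B`` (d, m) hold one neuron per row; ``M`` (d, d)
    is strictly lower triangular.  ``gate`` (d,) multiplies every rate of
    a neuron (0 freezes it; used by sequential training).  ``ca, cb, c``
    are scratch vectors of length d.  ``local_rule`` selects the lateral
    update: 1 uses the somatic output ``c_j c_l`` (local, default), 0
    uses ``(c^a_j + c^b_j) c_l`` (the form requiring compartment access).
    """
    d = A.shape[0]
    n = A.shape[1]
    m = B.shape[1]
    for s in range(idx.shape[0]):
        t = idx[s]
        f = fac[s]
        for j in range(d):
            acc = 0.0
            for i in range(n):
                acc += A[j, i] * X[t, i]
            ca[j] = acc
            acc = 0.0
            for i in range(m):
                acc += B[j, i] * Y[t, i]
            cb[j] = acc
        for j in range(d):
            cj = ca[j] + cb[j]
            for l in range(j):
                cj -= M[j, l] * c[l]
            c[j] = cj
        for j in range(d):
            ga = c[j] - alpha[j] * ca[j]
            gb = c[j] - beta[j] * cb[j]
            ea = ba * gate[j] * f
            eb = bb * gate[j] * f
            for i in range(n):
                A[j, i] += ea * ga * X[t, i]
            for i in range(m):
                B[j, i] += eb * gb * Y[t, i]
            alpha[j] += 0.5 * (balpha * gate[j] * f) * (ca[j] * ca[j] - 1.0)
            beta[j] += 0.5 * (bbeta * gate[j] * f) * (cb[j] * cb[j] - 1.0)
        for j in range(d):
            em = bm * gate[j] * f
            if local_rule == 1:
                for l in range(j):
                    M[j, l] += em * c[j] * c[l]
            else:
                for l in range(j):
                    M[j, l] += em * (ca[j] + cb[j]) * c[l]


@njit(cache=True)
def nonlocal_chunk(
    X, Y, idx, fac, ba, bb, balpha, bbeta, bm,
    A, B, Ga, Gb, alpha, beta, ca, cb,
):
    """Multi-channel baseline with compartment-level decorrelation multipliers.

    ``Ga``/``Gb`` (d, d, symmetric, zero diagonal) are the Lagrange
    multipliers of the within-view decorrelation constraints on distal
    and proximal currents; their updates need the individual dendritic
    currents of *other* neurons, which is what makes this baseline
    non-local.
    """
    d = A.shape[0]
    n = A.shape[1]
    m = B.shape[1]
    for s in range(idx.shape[0]):
        t = idx[s]
        f = fac[s]
        for j in range(d):
            acc = 0.0
            for i in range(n):
                acc += A[j, i] * X[t, i]
            ca[j] = acc
            acc = 0.0
            for i in range(m):
                acc += B[j, i] * Y[t, i]
            cb[j] = acc
        for j in range(d):
            ga = (ca[j] + cb[j]) - alpha[j] * ca[j]
            gb = (ca[j] + cb[j]) - beta[j] * cb[j]
            for l in range(d):
                if l != j:
                    ga -= Ga[j, l] * ca[l]
                    gb -= Gb[j, l] * cb[l]
            ea = ba * f
            eb = bb * f
            for i in range(n):
                A[j, i] += ea * ga * X[t, i]
            for i in range(m):
                B[j, i] += eb * gb * Y[t, i]
            alpha[j] += 0.5 * (balpha * f) * (ca[j] * ca[j] - 1.0)
            beta[j] += 0.5 * (bbeta * f) * (cb[j] * cb[j] - 1.0)
        em = bm * f
        for j in range(d):
            for l in range(j):
                g = em * ca[j] * ca[l]
                Ga[j, l] += g
                Ga[l, j] += g
                g = em * cb[j] * cb[l]
                Gb[j, l] += g
                Gb[l, j] += g


@njit(cache=True)
def multiview_chunk(Xc, offsets, idx, fac, ba, balpha, w, alpha, cview):
    """k-compartment multiview neuron on concatenated views.

    ``Xc`` (T, sum n_i) stores the views side by side with column ranges
    in ``offsets`` (k+1,); ``w`` is the concatenated weight vector,
    ``ba``/``balpha`` per-view base rates, ``cview`` scratch (k,).
    """
    k = offsets.shape[0] - 1
    for s in range(idx.shape[0]):
        t = idx[s]
        f = fac[s]
        c = 0.0
        for v in range(k):
            acc = 0.0
            for p in range(offsets[v], offsets[v + 1]):
                acc += w[p] * Xc[t, p]
            cview[v] = acc
            c = c + acc
        for v in range(k):
            g = c - alpha[v] * cview[v]
            ea = ba[v] * f
            for p in range(offsets[v], offsets[v + 1]):
                w[p] += ea * g * Xc[t, p]
            alpha[v] += 0.5 * (balpha[v] * f) * (cview[v] * cview[v] - 1.0)
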