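"""Numba kernels for the 2-D t-SNE optimizer (exact O(n^2) repulsion)."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(fastmath=True)
def repulsion_exact(Y):
    """Repulsive forces and partition sum Z for a 2-D layout.

    F[i] = sum_j w_ij^2 (y_i - y_j), Z = sum_{i != j} w_ij with
    w_ij = 1 / (1 + ||y_i - y_j||^2).
    """
    n = Y.shape[0]
    F = np.empty((n, 2))
    Z = 0.0
    for i in range(n):
        yi0 = Y[i, 0]
        yi1 = Y[i, 1]
        f0 = 0.0
        f1 = 0.0
        for j in range(n):
            d0 = yi0 - Y[j, 0]
            d1 = yi1 - Y[j, 1]
            q = 1.0 / (1.0 + d0 * d0 + d1 * d1)
            Z += q
            q2 = q * q
            f0 += q2 * d0
            f1 += q2 * d1
        F[i, 0] = f0
        F[i, 1] = f1
    return F, Z - n  # remove the n diagonal terms (w_ii = 1)


@njit(fastmath=True)
def attraction_csr(indptr, indices, data, Y):
    """Attractive forces F[i] = sum_j p_ij w_ij (y_i - y_j) over sparse P."""
    n = Y.shape[0]
    F = np.zeros((n, 2))
    for i in range(n):
        yi0 = Y[i, 0]
        yi1 = Y[i, 1]
        for ptr in range(indptr[i], indptr[i + 1]):
            j = indices[ptr]
            p = data[ptr]
            d0 = yi0 - Y[j, 0]
            d1 = yi1 - Y[j, 1]
            w = 1.0 / (1.0 + d0 * d0 + d1 * d1)
            F[i, 0] += p * w * d0
            F[i, 1] += p * w * d1
    return F


@njit(fastmath=True)
def kl_csr(indptr, indices, data, Y, Z):
    """KL(P || Q) summed over the nonzeros of P, with q_ij = w_ij / Z."""
    n = Y.shape[0]
    kl = 0.0
    logZ = np.log(Z)
    for i in range(n):
        yi0 = Y[i, 0]
        yi1 = Y[i, 1]
        for ptr in range(indptr[i], indptr[i + 1]):
            j = indices[ptr]
            p = data[ptr]
            if p <= 0.0:
                continue
            d0 = yi0 - Y[j, 0]
            d1 = yi1 - Y[j, 1]
            w = 1.0 / (1.0 + d0 * d0 + d1 * d1)
            kl += p * (np.log(p) - np.log(w) + logZ)
    return kl
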