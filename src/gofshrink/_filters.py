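"""Filter design for the dual-tree complex wavelet transform.

The dual tree needs two orthonormal conjugate-quadrature filter (CQF) pairs
whose lowpass filters differ by (approximately) half a sample of group delay,
so that the two trees' wavelets form an approximate Hilbert pair.  The pair
used for levels >= 2 is designed here by the common-factor construction:

    H_A(z) = Q(z) (1 + z^-1)^K D(z)
    H_B(z) = Q(z) (1 + z^-1)^K z^-L D(1/z)

where D is a Thiran-style maximally-flat fractional-delay factor of order L
(so H_B/H_A is an all-pass ratio approximating z^(-1/2)) and Q is obtained by
spectral factorization so that H_A (hence H_B) is an orthonormal CQF lowpass
with K vanishing moments.  All coefficients are computed at run time from the
closed-form construction; nothing is tabulated.

At the first level the half-sample condition degenerates to a one-sample
integer offset, which the transform realizes exactly by odd-phase
downsampling of tree B with a single shared orthonormal filter (db10).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pywt
from scipy.special import comb

__all__ = ["qmf", "dual_tree_filters", "first_stage_filter"]


def qmf(h: np.ndarray) -> np.ndarray:
    """Conjugate-quadrature highpass: h1[n] = (-1)^n h0[M-1-n]."""
    h = np.asarray(h, dtype=float)
    return ((-1.0) ** np.arange(h.size)) * h[::-1]


def _thiran_half_delay(order: int) -> np.ndarray:
    # Coefficients d(k) such that z^-L D(1/z)/D(z) is a maximally-flat
    # approximation of a half-sample delay (tau = 1/2).
    tau = 0.5
    d = np.empty(order + 1)
    for k in range(order + 1):
        prod = 1.0
        for n in range(order + 1):
            prod *= (tau - order + n) / (tau - order + k + n)
        d[k] = (-1.0) ** k * comb(order, k, exact=True) * prod
    return d


@lru_cache(maxsize=8)
def dual_tree_filters(vanishing_moments: int = 4, delay_order: int = 3):
    """Design the level>=2 lowpass pair (h_a, h_b).

    Returns two unit-norm lowpass filters of length
    ``2 * (vanishing_moments + delay_order)`` whose frequency responses have
    equal magnitude and differ in phase by approximately omega/2 over the
    passband.  Both satisfy the orthonormal CQF (double-shift orthogonality)
    conditions to machine precision.
    """
    K, L = vanishing_moments, delay_order
    d = _thiran_half_delay(L)
    b = np.array([1.0])
    for _ in range(K):
        b = np.convolve(b, [1.0, 1.0])

    # Symmetric known part G(z) = (1+z)^K (1+z^-1)^K D(z) D(1/z); the unknown
    # symmetric factor R(z) = Q(z)Q(1/z) of degree q is found from the
    # halfband conditions on P(z) = R(z) G(z):  P_0 = 1, P_{2m} = 0.
    g = np.convolve(np.convolve(d, d[::-1]), np.convolve(b, b[::-1]))
    center = K + L
    q = K + L - 1

    def gcoef(k: int) -> float:
        i = center + k
        return g[i] if 0 <= i < g.size else 0.0

    rows, rhs = [], []
    for e in range(0, center + q + 1, 2):
        row = np.zeros(q + 1)
        for m in range(-q, q + 1):
            row[abs(m)] += gcoef(e - m)
        rows.append(row)
        rhs.append(1.0 if e == 0 else 0.0)
    r = np.linalg.lstsq(np.asarray(rows), np.asarray(rhs), rcond=None)[0]

    full_r = np.zeros(2 * q + 1)
    for m in range(-q, q + 1):
        full_r[q + m] = r[abs(m)]
    # Spectral factorization: keep the roots inside the unit circle.
    roots = np.roots(full_r[::-1])
    q_poly = np.real(np.poly(roots[np.abs(roots) < 1.0]))

    h_a = np.convolve(np.convolve(b, q_poly), d)
    h_b = np.convolve(np.convolve(b, q_poly), d[::-1])
    h_a *= np.sqrt(2.0) / h_a.sum()
    h_b *= np.sqrt(2.0) / h_b.sum()
    return h_a, h_b


@lru_cache(maxsize=8)
def first_stage_filter(name: str = "db10") -> np.ndarray:
    """Orthonormal lowpass used by both trees at level 1 (tree B offset by one
    sample via odd-phase downsampling, giving the exact integer-delay
    condition the dual tree requires at the finest scale)."""
    w = pywt.Wavelet(name)
    h = np.asarray(w.dec_lo, dtype=float)[::-1]
    return h * (np.sqrt(2.0) / h.sum())
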