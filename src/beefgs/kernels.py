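"""Compiled pedigree kernels (numba).

Conventions: animals are 0..n-1 in topological order (parents before
offspring); parent codes < 0 mean "unknown" (possibly an unknown-parent
group or metafounder, which these standard-relationship kernels treat as
unrelated founders).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def inbreeding(sire, dam, f_prev):
    """Inbreeding coefficients by the Meuwissen & Luo recursion.

    ``f_prev`` holds already-known coefficients for a prefix of the
    pedigree (pass an empty array to compute from scratch); only the new
    animals are computed, so repeated calls over a growing pedigree cost no
    more than one full pass.
    """
    n = sire.shape[0]
    start = f_prev.shape[0]
    f = np.empty(n, dtype=np.float64)
    f[:start] = f_prev
    dvec = np.empty(n, dtype=np.float64)
    for j in range(n):
        if j < start:
            d = 1.0
            if sire[j] >= 0:
                d -= 0.25 * (1.0 + f[sire[j]])
            if dam[j] >= 0:
                d -= 0.25 * (1.0 + f[dam[j]])
            dvec[j] = d
    v = np.zeros(n, dtype=np.float64)
    for i in range(start, n):
        s, d0 = sire[i], dam[i]
        dd = 1.0
        if s >= 0:
            dd -= 0.25 * (1.0 + f[s])
        if d0 >= 0:
            dd -= 0.25 * (1.0 + f[d0])
        dvec[i] = dd
        if s < 0 or d0 < 0:
            f[i] = 0.0
            continue
        # a(s, d) via the L-row of a virtual progeny
        v[s] += 0.5
        v[d0] += 0.5
        a_sd2 = 0.0  # accumulates a_ii - d_i of the virtual progeny
        top = s if s > d0 else d0
        for j in range(top, -1, -1):
            vj = v[j]
            if vj != 0.0:
                a_sd2 += vj * vj * dvec[j]
                if sire[j] >= 0:
                    v[sire[j]] += 0.5 * vj
                if dam[j] >= 0:
                    v[dam[j]] += 0.5 * vj
                v[j] = 0.0
        # virtual progeny diagonal = 1 + f_i = a_sd2 + (1 - 0.25*(2 + f_s + f_d))
        f[i] = a_sd2 - 0.25 * (2.0 + f[s] + f[d0])
    return f


@njit(cache=True)
def mendelian_variance(sire, dam, f):
    """d_i = 1 - 0.25*(a_ss + a_dd), with unknown parents contributing 0."""
    n = sire.shape[0]
    d = np.empty(n, dtype=np.float64)
    for i in range(n):
        dd = 1.0
        if sire[i] >= 0:
            dd -= 0.25 * (1.0 + f[sire[i]])
        if dam[i] >= 0:
            dd -= 0.25 * (1.0 + f[dam[i]])
        d[i] = dd
    return d


@njit(cache=True)
def a_matvec(sire, dam, dvec, x):
    """y = A x by Colleau's indirect method (A = T D T')."""
    n = x.shape[0]
    u = x.copy()
    for i in range(n - 1, -1, -1):
        ui = u[i]
        if ui != 0.0:
            if sire[i] >= 0:
                u[sire[i]] += 0.5 * ui
            if dam[i] >= 0:
                u[dam[i]] += 0.5 * ui
    y = u * dvec
    for i in range(n):
        yi = y[i]
        if sire[i] >= 0:
            yi += 0.5 * y[sire[i]]
        if dam[i] >= 0:
            yi += 0.5 * y[dam[i]]
        y[i] = yi
    return y


@njit(cache=True)
def a_submatrix(sire, dam, dvec, idx):
    """Dense A[idx, idx] via one Colleau pass per column."""
    m = idx.shape[0]
    n = sire.shape[0]
    out = np.empty((m, m), dtype=np.float64)
    x = np.zeros(n, dtype=np.float64)
    for k in range(m):
        x[idx[k]] = 1.0
        y = a_matvec(sire, dam, dvec, x)
        for j in range(m):
            out[j, k] = y[idx[j]]
        x[idx[k]] = 0.0
    return 0.5 * (out + out.T)
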