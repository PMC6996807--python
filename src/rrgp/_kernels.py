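"""Numba kernels for the Gibbs location sweep.

The sweep samples, in place, the fixed regression coefficients and every
accession's genetic and permanent-environment coefficient vectors from their
multivariate-normal full conditionals. Records are grouped by (accession, day)
so that the day-level residual covariance between traits enters through the
2x2 inverse block; a day with a single observed trait uses the marginal
precision of that trait.

State carried across calls (all modified in place):
  e    — residual vector y - Xb - Zu - Qp per record
  b    — fixed coefficients (M,)
  U, P — accession-major coefficient matrices (n, M)
  S    — running product Ginv @ U, kept consistent as U changes within the
         sweep so that each accession's conditional uses the latest values

Randomness enters only through pre-generated standard-normal draws (z_u, z_p,
z_b), so the caller's numpy Generator remains the single source of
randomness.
"""

import numpy as np
from numba import njit

__all__ = ["gibbs_location_sweep"]


@njit(cache=True)
def _chol_lower(A, L):
    """In-place lower Cholesky of a small SPD matrix into L."""
    m = A.shape[0]
    for i in range(m):
        for j in range(i + 1):
            s = A[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]


@njit(cache=True)
def _forward_solve(L, rhs, out):
    m = L.shape[0]
    for i in range(m):
        s = rhs[i]
        for k in range(i):
            s -= L[i, k] * out[k]
        out[i] = s / L[i, i]


@njit(cache=True)
def _backward_solve_t(L, rhs, out):
    """Solve L' x = rhs for lower-triangular L."""
    m = L.shape[0]
    for i in range(m - 1, -1, -1):
        s = rhs[i]
        for k in range(i + 1, m):
            s -= L[k, i] * out[k]
        out[i] = s / L[i, i]


@njit(cache=True)
def _accumulate_normal_eq(g0, g1, grp_ptr, phi, recq, recday,
                          rinv_full, rinv_marg, radd, K, W, rhs):
    """Add data contributions A' Rinv A and A' Rinv r over groups [g0, g1)."""
    for g in range(g0, g1):
        i0 = grp_ptr[g]
        i1 = grp_ptr[g + 1]
        t = recday[i0]
        if i1 - i0 == 2:
            # both traits observed this day: full 2x2 residual precision
            for a in range(2):
                for bq in range(2):
                    w = rinv_full[t, a, bq]
                    if w != 0.0:
                        for k in range(K):
                            ph_k = phi[i0, k]
                            rhs[a * K + k] += w * radd[i0 + bq] * ph_k
                            for l in range(K):
                                W[a * K + k, bq * K + l] += w * ph_k * phi[i0, l]
        else:
            q = recq[i0]
            w = rinv_marg[t, q]
            for k in range(K):
                ph_k = phi[i0, k]
                rhs[q * K + k] += w * radd[i0] * ph_k
                for l in range(K):
                    W[q * K + k, q * K + l] += w * ph_k * phi[i0, l]


@njit(cache=True)
def gibbs_location_sweep(e, b, U, P, S, phi, recq, recday, rec_acc, grp_ptr,
                         acc_grp_ptr, Ginv, Cinv, Dinv, rinv_full, rinv_marg,
                         fixw, z_u, z_p, z_b, radd):
    """One Gibbs sweep over b, all (u_j, p_j) blocks (in place).

    ``fixw`` scales the fixed-effect design per accession: in the eigenbasis
    of G the random-effect designs are unchanged but the overall-mean
    covariates acquire the factor (V' 1)_k per eigen-accession; in the
    untransformed parameterization fixw is all ones. radd is an n_records
    scratch buffer.
    """
    n, M = U.shape
    K = phi.shape[1]
    n_rec = e.shape[0]
    M2 = 2 * M
    W = np.empty((M, M))
    L = np.empty((M, M))
    rhs = np.empty(M)
    tmp = np.empty(M)
    mu = np.empty(M)
    xz = np.empty(M)
    du = np.empty(M)
    # joint (u_j, p_j) workspaces: the two blocks share the same data design,
    # so their posterior is strongly coupled and must be sampled together
    WJ = np.empty((M2, M2))
    LJ = np.empty((M2, M2))
    rhsJ = np.empty(M2)
    tmpJ = np.empty(M2)
    muJ = np.empty(M2)
    xzJ = np.empty(M2)
    zJ = np.empty(M2)

    for j in range(n):
        g0 = acc_grp_ptr[j]
        g1 = acc_grp_ptr[j + 1]
        a0 = grp_ptr[g0]
        a1 = grp_ptr[g1]

        # residuals with accession j's total effect (u_j + p_j) added back
        for i in range(a0, a1):
            q = recq[i]
            s = e[i]
            for k in range(K):
                s += phi[i, k] * (U[j, q * K + k] + P[j, q * K + k])
            radd[i] = s
        for a in range(M):
            rhs[a] = 0.0
            for c in range(M):
                W[a, c] = 0.0
        _accumulate_normal_eq(g0, g1, grp_ptr, phi, recq, recday,
                              rinv_full, rinv_marg, radd, K, W, rhs)

        gjj = Ginv[j, j]
        for a in range(M):
            for c in range(M):
                WJ[a, c] = W[a, c] + gjj * Cinv[a, c]
                WJ[a, M + c] = W[a, c]
                WJ[M + a, c] = W[a, c]
                WJ[M + a, M + c] = W[a, c] + Dinv[a, c]
        for a in range(M):
            cross = 0.0
            for c in range(M):
                cross += Cinv[a, c] * (S[j, c] - gjj * U[j, c])
            rhsJ[a] = rhs[a] - cross
            rhsJ[M + a] = rhs[a]

        _chol_lower(WJ, LJ)
        _forward_solve(LJ, rhsJ, tmpJ)
        _backward_solve_t(LJ, tmpJ, muJ)
        for a in range(M):
            zJ[a] = z_u[j, a]
            zJ[M + a] = z_p[j, a]
        _backward_solve_t(LJ, zJ, xzJ)

        for a in range(M):
            du[a] = muJ[a] + xzJ[a] - U[j, a]
            U[j, a] += du[a]
            P[j, a] = muJ[M + a] + xzJ[M + a]
        for i in range(n):
            gij = Ginv[i, j]
            for a in range(M):
                S[i, a] += gij * du[a]
        for i in range(a0, a1):
            q = recq[i]
            s = radd[i]
            for k in range(K):
                s -= phi[i, k] * (U[j, q * K + k] + P[j, q * K + k])
            e[i] = s

    # ---- fixed coefficients b (flat prior); design row is fixw[acc] * phi
    for i in range(n_rec):
        q = recq[i]
        w = fixw[rec_acc[i]]
        s = e[i]
        for k in range(K):
            s += w * phi[i, k] * b[q * K + k]
        radd[i] = s
    for a in range(M):
        rhs[a] = 0.0
        for c in range(M):
            W[a, c] = 0.0
    n_groups = acc_grp_ptr[n]
    for g in range(n_groups):
        i0 = grp_ptr[g]
        i1 = grp_ptr[g + 1]
        t = recday[i0]
        w_acc = fixw[rec_acc[i0]]
        if i1 - i0 == 2:
            for a in range(2):
                for bq in range(2):
                    wgt = rinv_full[t, a, bq] * w_acc
                    if wgt != 0.0:
                        for k in range(K):
                            ph_k = phi[i0, k]
                            rhs[a * K + k] += wgt * radd[i0 + bq] * ph_k
                            for l in range(K):
                                W[a * K + k, bq * K + l] += wgt * w_acc * ph_k * phi[i0, l]
        else:
            q = recq[i0]
            wgt = rinv_marg[t, q] * w_acc
            for k in range(K):
                ph_k = phi[i0, k]
                rhs[q * K + k] += wgt * radd[i0] * ph_k
                for l in range(K):
                    W[q * K + k, q * K + l] += wgt * w_acc * ph_k * phi[i0, l]
    _chol_lower(W, L)
    _forward_solve(L, rhs, tmp)
    _backward_solve_t(L, tmp, mu)
    _backward_solve_t(L, z_b, xz)
    for a in range(M):
        b[a] = mu[a] + xz[a]
    for i in range(n_rec):
        q = recq[i]
        w = fixw[rec_acc[i]]
        s = radd[i]
        for k in range(K):
            s -= w * phi[i, k] * b[q * K + k]
        e[i] = s
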