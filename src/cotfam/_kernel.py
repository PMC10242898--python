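"""Compiled fast path for the grouped FIML objective.

The numpy implementation in :mod:`cotfam.fiml` defines the contract; this
kernel recomputes the same quantity with explicit loops under numba for
the optimizer's inner loop.  Tests pin the two paths together to ~1e-8.
Everything here is a function of plain float/int arrays so the kernel is
cacheable and has no Python-object traffic.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


_LOG2PI = float(np.log(2.0 * np.pi))


@njit(cache=True)
def _build_stack(
    alphas, mothers, fathers, is_father,
    a2, c2, e2, rA, rE,
    lam, th, mu_meas,           # (2 indicators, 2 sexes): [ind, is_father]
    p_m, p_f, g, a_c2, c_c2, e_c2, mu_o,
):
    """Implied 12x12 covariance and base mean per unique structure."""
    U = alphas.shape[0]
    cov = np.zeros((U, 12, 12))
    mu0 = np.zeros((U, 12))
    for u in range(U):
        al = alphas[u]
        K = np.empty((4, 4))
        for i in range(4):
            K[i, i] = 1.0
        K[0, 1] = K[1, 0] = rA
        K[2, 3] = K[3, 2] = rA
        K[0, 2] = K[2, 0] = al
        K[0, 3] = K[3, 0] = rA * al
        K[1, 2] = K[2, 1] = rA * al
        K[1, 3] = K[3, 1] = rA * rA * al

        Ncov = np.empty((4, 4))
        for i in range(4):
            for j in range(4):
                Ncov[i, j] = a2 * K[i, j]
        for i in range(4):
            Ncov[i, i] += e2 + c2
        Ncov[0, 1] += rE * e2
        Ncov[1, 0] += rE * e2
        Ncov[2, 3] += rE * e2
        Ncov[3, 2] += rE * e2
        Ncov[0, 2] += c2
        Ncov[2, 0] += c2

        m = mothers[u]
        f = fathers[u]
        NG = np.empty((4, 4))          # Cov(N_x, G_c)
        for x in range(4):
            for ch in range(4):
                NG[x, ch] = 0.5 * a2 * (K[x, m[ch]] + K[x, f[ch]])
        GG = np.empty((4, 4))
        for ci in range(4):
            for cj in range(4):
                GG[ci, cj] = 0.25 * a2 * (
                    K[m[ci], m[cj]] + K[m[ci], f[cj]]
                    + K[f[ci], m[cj]] + K[f[ci], f[cj]]
                )
            GG[ci, ci] += 0.5 * a2
        # child outcome loadings onto [N x4, G x4]
        L = np.zeros((4, 8))
        for ch in range(4):
            L[ch, m[ch]] += p_m
            L[ch, f[ch]] += p_f
            L[ch, 4 + ch] = g
        Z = np.empty((8, 8))
        for i in range(4):
            for j in range(4):
                Z[i, j] = Ncov[i, j]
                Z[i, 4 + j] = NG[i, j]
                Z[4 + j, i] = NG[i, j]
                Z[4 + i, 4 + j] = GG[i, j]
        NO = np.zeros((4, 4))          # Cov(N_x, O_c)
        for x in range(4):
            for ch in range(4):
                acc = 0.0
                for z in range(8):
                    acc += Z[x, z] * L[ch, z]
                NO[x, ch] = acc
        OO = np.zeros((4, 4))
        ZL = np.zeros((8, 4))
        for z in range(8):
            for ch in range(4):
                acc = 0.0
                for w in range(8):
                    acc += Z[z, w] * L[ch, w]
                ZL[z, ch] = acc
        for ci in range(4):
            for cj in range(4):
                acc = 0.0
                for z in range(8):
                    acc += L[ci, z] * ZL[z, cj]
                # child-specific additive kinship: 1 self, 0.5 full sibs,
                # alpha/4 cousins; nuclear C shared within family
                fam_i = ci // 2
                fam_j = cj // 2
                if ci == cj:
                    acc += a_c2 + c_c2 + e_c2
                elif fam_i == fam_j:
                    acc += 0.5 * a_c2 + c_c2
                else:
                    acc += 0.25 * al * a_c2
                OO[ci, cj] = acc

        lam_s = np.empty(8)
        th_s = np.empty(8)
        for s in range(8):
            adult = s // 2
            ind = s % 2
            sx = 1 if is_father[u, adult] else 0
            lam_s[s] = lam[ind, sx]
            th_s[s] = th[ind, sx]
            mu0[u, s] = mu_meas[ind, sx]
        for s in range(8):
            for t in range(8):
                cov[u, s, t] = lam_s[s] * lam_s[t] * Ncov[s // 2, t // 2]
            cov[u, s, s] += th_s[s]
            for ch in range(4):
                v = lam_s[s] * NO[s // 2, ch]
                cov[u, s, 8 + ch] = v
                cov[u, 8 + ch, s] = v
        for ci in range(4):
            for cj in range(4):
                cov[u, 8 + ci, 8 + cj] = OO[ci, cj]
            mu0[u, 8 + ci] = mu_o
    return cov, mu0


@njit(cache=True)
def _chol_inv12(P, Lw, Li):
    """Cholesky of a 12x12 SPD matrix, its log-determinant and inverse.

    Returns logdet, or NaN if the matrix is not positive definite.
    Workspaces ``Lw`` (lower factor) and ``Li`` (its inverse) are reused.
    """
    k = 12
    for i in range(k):
        for j in range(k):
            Lw[i, j] = 0.0
            Li[i, j] = 0.0
    logdet = 0.0
    for i in range(k):
        for j in range(i + 1):
            acc = P[i, j]
            for t in range(j):
                acc -= Lw[i, t] * Lw[j, t]
            if i == j:
                if acc <= 0.0:
                    return np.nan
                Lw[i, i] = np.sqrt(acc)
                logdet += 2.0 * np.log(Lw[i, i])
            else:
                Lw[i, j] = acc / Lw[j, j]
    # invert the lower-triangular factor by forward substitution
    for j in range(k):
        Li[j, j] = 1.0 / Lw[j, j]
        for i in range(j + 1, k):
            acc = 0.0
            for t in range(j, i):
                acc -= Lw[i, t] * Li[t, j]
            Li[i, j] = acc / Lw[i, i]
    return logdet


@njit(cache=True)
def fiml_objective(
    alphas, mothers, fathers, is_father,
    a2, c2, e2, rA, rE, lam, th, mu_meas,
    p_m, p_f, g, a_c2, c_c2, e_c2, mu_o, beta_sex, beta_parity,
    group_sid, group_mask,
    sid, gid, Y0, mask, sex, parity, k_obs,
    D,
):
    """Total −2LL with free means (columns of ``D``) profiled out by GLS.

    With ``D`` empty this is the plain objective at the supplied means.
    Returns ``(minus2ll, mean_hat)``; ``minus2ll`` is ``inf`` when a padded
    pattern covariance fails to factorize.
    """
    cov, mu0 = _build_stack(
        alphas, mothers, fathers, is_father,
        a2, c2, e2, rA, rE, lam, th, mu_meas,
        p_m, p_f, g, a_c2, c_c2, e_c2, mu_o,
    )
    G = group_sid.shape[0]
    Pinv = np.empty((G, 12, 12))
    logdet = np.empty(G)
    P = np.empty((12, 12))
    Lw = np.empty((12, 12))
    Li = np.empty((12, 12))
    for gi in range(G):
        su = group_sid[gi]
        for i in range(12):
            for j in range(12):
                if group_mask[gi, i] and group_mask[gi, j]:
                    P[i, j] = cov[su, i, j]
                elif i == j:
                    P[i, j] = 1.0
                else:
                    P[i, j] = 0.0
        ld = _chol_inv12(P, Lw, Li)
        if np.isnan(ld):
            return np.inf, np.zeros(D.shape[2])
        logdet[gi] = ld
        # Pinv = Li' Li
        for i in range(12):
            for j in range(i + 1):
                acc = 0.0
                for t in range(max(i, j), 12):
                    acc += Li[t, i] * Li[t, j]
                Pinv[gi, i, j] = acc
                Pinv[gi, j, i] = acc

    n = Y0.shape[0]
    q = D.shape[2]
    A = np.zeros((q, q))
    b = np.zeros(q)
    quad = 0.0
    ldsum = 0.0
    ksum = 0.0
    r0 = np.empty(12)
    u_vec = np.empty(12)
    PD = np.empty((12, q))
    for i in range(n):
        su = sid[i]
        gi = gid[i]
        for s in range(12):
            if mask[i, s]:
                m0 = mu0[su, s]
                if s >= 8:
                    m0 += beta_sex * sex[i, s - 8] + beta_parity * parity[i, s - 8]
                r0[s] = Y0[i, s] - m0
            else:
                r0[s] = 0.0
        for s in range(12):
            acc = 0.0
            for t in range(12):
                acc += Pinv[gi, s, t] * r0[t]
            u_vec[s] = acc
        for s in range(12):
            quad += r0[s] * u_vec[s]
        ldsum += logdet[gi]
        ksum += k_obs[i]
        if q:
            for s in range(12):
                for p in range(q):
                    acc = 0.0
                    for t in range(12):
                        acc += Pinv[gi, s, t] * D[i, t, p]
                    PD[s, p] = acc
            for p in range(q):
                for p2 in range(p + 1):
                    acc = 0.0
                    for s in range(12):
                        acc += D[i, s, p] * PD[s, p2]
                    A[p, p2] += acc
                acc = 0.0
                for s in range(12):
                    acc += D[i, s, p] * u_vec[s]
                b[p] += acc
    mean_hat = np.zeros(q)
    if q:
        for p in range(q):
            for p2 in range(p + 1, q):
                A[p, p2] = A[p2, p]
        mean_hat = np.linalg.solve(A, b)
        for p in range(q):
            quad -= mean_hat[p] * b[p]
    value = ksum * _LOG2PI + ldsum + quad
    return value, mean_hat
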