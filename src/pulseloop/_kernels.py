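"""Compiled element kernels for chamber assembly.

These numba kernels duplicate the material-point arithmetic of
:mod:`pulseloop.materials` in scalar form for speed; the equivalence of the
two implementations is asserted by the test suite on random states.  All
arrays are float64 and C-contiguous.

Parameter packing
-----------------
LV:    [C, b_ff, b_xx, b_fx, T_max, Ca0, Ca0_max, B, l_0, t_0, m, b, l_r]
aorta: [c1, c2, c3, c4, c5, phi_e, phi_m, S_m_eff, lam_M, lam_0,
        phik1, phik2, phik3, phik4]   (S_m_eff = 0 disables active tone)
"""

from __future__ import annotations

import numpy as np
from numba import njit

_F = dict(cache=True, fastmath=True)


@njit(**_F)
def _det3(F):
    return (
        F[0, 0] * (F[1, 1] * F[2, 2] - F[1, 2] * F[2, 1])
        - F[0, 1] * (F[1, 0] * F[2, 2] - F[1, 2] * F[2, 0])
        + F[0, 2] * (F[1, 0] * F[2, 1] - F[1, 1] * F[2, 0])
    )


@njit(**_F)
def _inv3(F, J, out):
    out[0, 0] = (F[1, 1] * F[2, 2] - F[1, 2] * F[2, 1]) / J
    out[0, 1] = (F[0, 2] * F[2, 1] - F[0, 1] * F[2, 2]) / J
    out[0, 2] = (F[0, 1] * F[1, 2] - F[0, 2] * F[1, 1]) / J
    out[1, 0] = (F[1, 2] * F[2, 0] - F[1, 0] * F[2, 2]) / J
    out[1, 1] = (F[0, 0] * F[2, 2] - F[0, 2] * F[2, 0]) / J
    out[1, 2] = (F[0, 2] * F[1, 0] - F[0, 0] * F[1, 2]) / J
    out[2, 0] = (F[1, 0] * F[2, 1] - F[1, 1] * F[2, 0]) / J
    out[2, 1] = (F[0, 1] * F[2, 0] - F[0, 0] * F[2, 1]) / J
    out[2, 2] = (F[0, 0] * F[1, 1] - F[0, 1] * F[1, 0]) / J


@njit(**_F)
def _active_tension(t, l, prm):
    """Scalar active twitch tension (kPa); prm is the LV packing."""
    Tmax, Ca0, Ca0max, B, l0 = prm[4], prm[5], prm[6], prm[7], prm[8]
    t0, m, b = prm[9], prm[10], prm[11]
    if l <= l0 + 1e-12:
        return 0.0
    eca2 = Ca0max * Ca0max / (np.expm1(B * (l - l0)))
    tr = m * l + b
    if t < t0:
        omega = np.pi * t / t0
    elif t < t0 + tr:
        omega = np.pi * (t - t0 + tr) / tr
    else:
        omega = 0.0
    ct = 0.5 * (1.0 - np.cos(omega))
    ca2 = Ca0 * Ca0
    return Tmax * ca2 / (ca2 + eca2) * ct


@njit(**_F)
def _rotate4(C4h, R, out):
    """out_abcd = R_ai R_bj R_ck R_dl C4h_ijkl (pairwise)."""
    t1 = np.zeros((3, 3, 3, 3))
    for a in range(3):
        for j in range(3):
            for k in range(3):
                for l in range(3):
                    s = 0.0
                    for i in range(3):
                        s += R[a, i] * C4h[i, j, k, l]
                    t1[a, j, k, l] = s
    t2 = np.zeros((3, 3, 3, 3))
    for a in range(3):
        for b in range(3):
            for k in range(3):
                for l in range(3):
                    s = 0.0
                    for j in range(3):
                        s += R[b, j] * t1[a, j, k, l]
                    t2[a, b, k, l] = s
    for a in range(3):
        for b in range(3):
            for c in range(3):
                for l in range(3):
                    s = 0.0
                    for k in range(3):
                        s += R[c, k] * t2[a, b, k, l]
                    t1[a, b, c, l] = s
    for a in range(3):
        for b in range(3):
            for c in range(3):
                for d in range(3):
                    s = 0.0
                    for l in range(3):
                        s += R[d, l] * t1[a, b, c, l]
                    out[a, b, c, d] = s


@njit(**_F)
def _lv_point(F, R, prm, t, act, S, C4, want_K):
    """Guccione passive + active fiber stress at one point.

    R has the frame vectors as *columns* (f, s, n)."""
    # E in the fiber frame: Eh = R^T E R
    C = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            s = 0.0
            for k in range(3):
                s += F[k, i] * F[k, j]
            C[i, j] = s
    Eg = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            Eg[i, j] = 0.5 * (C[i, j] - (1.0 if i == j else 0.0))
    Eh = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            s = 0.0
            for a in range(3):
                for b in range(3):
                    s += R[a, i] * Eg[a, b] * R[b, j]
            Eh[i, j] = s
    q = np.zeros((3, 3))
    q[0, 0] = prm[1]
    q[0, 1] = q[1, 0] = q[0, 2] = q[2, 0] = prm[3]
    q[1, 1] = q[2, 2] = q[1, 2] = q[2, 1] = prm[2]
    Q = 0.0
    for i in range(3):
        for j in range(3):
            Q += q[i, j] * Eh[i, j] * Eh[i, j]
    if Q > 60.0 or not np.isfinite(Q):
        return False
    eQ = np.exp(Q)
    Cc = prm[0]
    qE = q * Eh
    # S = R Sh R^T
    for a in range(3):
        for b in range(3):
            s = 0.0
            for i in range(3):
                for j in range(3):
                    s += R[a, i] * qE[i, j] * R[b, j]
            S[a, b] = Cc * eQ * s
    if want_K:
        C4h = np.zeros((3, 3, 3, 3))
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    for l in range(3):
                        v = 2.0 * qE[i, j] * qE[k, l]
                        if i == k and j == l:
                            v += 0.5 * q[i, j]
                        if i == l and j == k:
                            v += 0.5 * q[i, j]
                        C4h[i, j, k, l] = Cc * eQ * v
        _rotate4(C4h, R, C4)
    # active fiber tension (frame column 0 is e_f0)
    lam2 = 0.0
    for a in range(3):
        for b in range(3):
            lam2 += R[a, 0] * C[a, b] * R[b, 0]
    lam = np.sqrt(lam2)
    lr = prm[12]
    l = lam * lr
    T = act * _active_tension(t, l, prm)
    h = 1e-6
    dT = act * (
        _active_tension(t, l + h, prm) - _active_tension(t, l - h, prm)
    ) / (2 * h)
    if T != 0.0 or dT != 0.0:
        coefS = T / lam
        coefK = (dT * lr * lam - T) / (lam * lam2)
        for a in range(3):
            for b in range(3):
                S[a, b] += coefS * R[a, 0] * R[b, 0]
        if want_K:
            for a in range(3):
                for b in range(3):
                    for c in range(3):
                        for d in range(3):
                            C4[a, b, c, d] += (
                                coefK * R[a, 0] * R[b, 0] * R[c, 0] * R[d, 0]
                            )
    return True


@njit(**_F)
def _aorta_point(F, dirs, prm, S, C4, want_K):
    """Elastin + four collagen families + SMC (passive and tone)."""
    c1, c2, c3, c4, c5 = prm[0], prm[1], prm[2], prm[3], prm[4]
    phi_e, phi_m, Sm = prm[5], prm[6], prm[7]
    lamM, lam0 = prm[8], prm[9]
    C = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            s = 0.0
            for k in range(3):
                s += F[k, i] * F[k, j]
            C[i, j] = s
    for i in range(3):
        for j in range(3):
            S[i, j] = phi_e * c1 if i == j else 0.0
            if want_K:
                for k in range(3):
                    for l in range(3):
                        C4[i, j, k, l] = 0.0
    # five fiber-type contributions: 4 collagen families + SMC passive
    for k in range(5):
        if k < 4:
            phi = prm[10 + k]
            ca, cb = c2, c3
            e = dirs[k]
        else:
            phi = phi_m
            ca, cb = c4, c5
            e = dirs[1]
        lam2 = 0.0
        for a in range(3):
            for b in range(3):
                lam2 += e[a] * C[a, b] * e[b]
        y1 = lam2 - 1.0
        arg = cb * y1 * y1
        if arg > 60.0 or not np.isfinite(arg):
            return False
        ee = np.exp(arg)
        W1 = phi * 0.5 * ca * y1 * ee
        W2 = phi * 0.5 * ca * ee * (1.0 + 2.0 * cb * y1 * y1)
        for a in range(3):
            for b in range(3):
                S[a, b] += 2.0 * W1 * e[a] * e[b]
        if want_K:
            for a in range(3):
                for b in range(3):
                    for c in range(3):
                        for d in range(3):
                            C4[a, b, c, d] += 4.0 * W2 * e[a] * e[b] * e[c] * e[d]
    if Sm != 0.0:
        e = dirs[1]
        lam2 = 0.0
        for a in range(3):
            for b in range(3):
                lam2 += e[a] * C[a, b] * e[b]
        lam = np.sqrt(lam2)
        span = lamM - lam0
        g = phi_m * Sm * (1.0 - ((lamM - lam) / span) ** 2)
        gp = phi_m * Sm * 2.0 * (lamM - lam) / (span * span)
        for a in range(3):
            for b in range(3):
                S[a, b] += (g / lam) * e[a] * e[b]
        if want_K:
            coef = (gp * lam - g) / (lam * lam2)
            for a in range(3):
                for b in range(3):
                    for c in range(3):
                        for d in range(3):
                            C4[a, b, c, d] += coef * e[a] * e[b] * e[c] * e[d]
    return True


@njit(**_F)
def assemble_elements(
    u_e, p_e, dNdX, wdet, Np, dirs, prm, t, is_lv, act_scale, kappa, want_K,
    Ru, Rp, Jout, Kuu, Kup,
):
    """Element residual (and tangent) blocks for all elements.

    Returns False if the deformation is inverted or the material
    overflowed, in which case outputs are invalid.
    """
    E, Q = wdet.shape
    S = np.zeros((3, 3))
    C4 = np.zeros((3, 3, 3, 3))
    F = np.zeros((3, 3))
    Finv = np.zeros((3, 3))
    P = np.zeros((3, 3))
    A = np.zeros((3, 3, 3, 3))
    tmp = np.zeros((10, 3, 3, 3))
    R33 = np.zeros((3, 3))
    for e in range(E):
        for a in range(30):
            Ru[e, a] = 0.0
            if want_K:
                for b in range(30):
                    Kuu[e, a, b] = 0.0
                for c in range(4):
                    Kup[e, a, c] = 0.0
        for c in range(4):
            Rp[e, c] = 0.0
        for qq in range(Q):
            for i in range(3):
                for I in range(3):
                    s = 1.0 if i == I else 0.0
                    for a in range(10):
                        s += u_e[e, a, i] * dNdX[e, qq, a, I]
                    F[i, I] = s
            J = _det3(F)
            if not np.isfinite(J) or J <= 0.0:
                return False
            Jout[e, qq] = J
            _inv3(F, J, Finv)
            if is_lv:
                for i in range(3):
                    for j in range(3):
                        R33[i, j] = dirs[e, qq, j, i]  # columns f,s,n
                ok = _lv_point(F, R33, prm, t, act_scale[e, qq], S, C4, want_K)
            else:
                ok = _aorta_point(F, dirs[e, qq], prm, S, C4, want_K)
            if not ok:
                return False
            pq = 0.0
            for c in range(4):
                pq += Np[qq, c] * p_e[e, c]
            # augmented-Lagrangian volumetric term: effective pressure
            # p - kappa (J - 1); vanishes at the converged solution
            peff = pq - kappa * (J - 1.0)
            w = wdet[e, qq]
            # P = F S - p_eff J F^{-T};  note F^{-T}_{iI} = Finv_{I,i}
            for i in range(3):
                for I in range(3):
                    s = 0.0
                    for K in range(3):
                        s += F[i, K] * S[K, I]
                    P[i, I] = s - peff * J * Finv[I, i]
            for a in range(10):
                for i in range(3):
                    s = 0.0
                    for I in range(3):
                        s += P[i, I] * dNdX[e, qq, a, I]
                    Ru[e, 3 * a + i] += w * s
            for c in range(4):
                Rp[e, c] -= w * Np[qq, c] * (J - 1.0)
            if want_K:
                # A_iIjJ = d_ij S_IJ + F_iK C4_KIJN F_jN
                #          - p_eff J (Finv_Ii Finv_Jj - Finv_Ij Finv_Ji)
                #          + kappa J^2 Finv_Ii Finv_Jj
                for i in range(3):
                    for I in range(3):
                        for j in range(3):
                            for J2 in range(3):
                                s = S[I, J2] if i == j else 0.0
                                for K in range(3):
                                    acc = 0.0
                                    for N in range(3):
                                        acc += C4[K, I, J2, N] * F[j, N]
                                    s += F[i, K] * acc
                                s -= peff * J * (
                                    Finv[I, i] * Finv[J2, j]
                                    - Finv[I, j] * Finv[J2, i]
                                )
                                s += kappa * J * J * Finv[I, i] * Finv[J2, j]
                                A[i, I, j, J2] = s
                # tmp_aijJ = dNdX_aI A_iIjJ
                for a in range(10):
                    for i in range(3):
                        for j in range(3):
                            for J2 in range(3):
                                s = 0.0
                                for I in range(3):
                                    s += dNdX[e, qq, a, I] * A[i, I, j, J2]
                                tmp[a, i, j, J2] = s
                for a in range(10):
                    for i in range(3):
                        for b in range(10):
                            for j in range(3):
                                s = 0.0
                                for J2 in range(3):
                                    s += tmp[a, i, j, J2] * dNdX[e, qq, b, J2]
                                Kuu[e, 3 * a + i, 3 * b + j] += w * s
                for a in range(10):
                    for i in range(3):
                        s = 0.0
                        for I in range(3):
                            s += Finv[I, i] * dNdX[e, qq, a, I]
                        for c in range(4):
                            Kup[e, 3 * a + i, c] -= w * J * s * Np[qq, c]
    return True
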