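"""McMurchie-Davidson Gaussian integral kernels (numba).

All kernels work on flattened shell/primitive arrays in *Cartesian*
components; the :class:`~saptvqe.integrals.basis.BasisSet` wrapper applies the
spherical transform and normalization afterwards. The two-electron driver is
organised around precomputed shell-pair Hermite expansions so that every
integral class ((AA|AA), (AA|BB), (AB|AB), (AA|AB), (AB|BB)) is served by the
same kernel.
"""
from __future__ import annotations

import math

import numpy as np
from numba import njit

from .basis import CART_COMPONENTS

_SQRT_PI = math.sqrt(math.pi)
_TWO_PI_POW = 2.0 * math.pi ** 2.5

# ---------------------------------------------------------------------------
# Boys function
# ---------------------------------------------------------------------------


@njit(cache=True)
def boys(m_max, x, out):
    """F_m(x) for m = 0..m_max into ``out`` (downward recursion, series tail)."""
    if x < 1e-13:
        for m in range(m_max + 1):
            out[m] = 1.0 / (2 * m + 1)
        return
    if x > 30.0:
        out[0] = 0.5 * math.sqrt(math.pi / x)
        ex = math.exp(-x)
        for m in range(m_max):
            out[m + 1] = ((2 * m + 1) * out[m] - ex) / (2.0 * x)
        return
    ex = math.exp(-x)
    # series for the highest order, then downward recursion
    m = m_max
    denom = 2.0 * m + 1.0
    term = 1.0 / denom
    total = term
    for _ in range(250):
        denom += 2.0
        term *= 2.0 * x / denom
        total += term
        if term < 1e-17 * total:
            break
    out[m_max] = ex * total
    for mm in range(m_max - 1, -1, -1):
        out[mm] = (2.0 * x * out[mm + 1] + ex) / (2 * mm + 1)


# ---------------------------------------------------------------------------
# Hermite expansion coefficients
# ---------------------------------------------------------------------------


@njit(cache=True)
def _e_coeffs(imax, jmax, a, b, ab, E):
    """Fill E[i, j, t] for x_A^i x_B^j -> Hermite Lambda_t; ``ab`` = A_x - B_x.

    E must be zeroed, shape (imax+1, jmax+1, imax+jmax+1).
    """
    p = a + b
    mu = a * b / p
    E[0, 0, 0] = math.exp(-mu * ab * ab)
    pa = -b / p * ab  # P_x - A_x
    pb = a / p * ab  # P - B = (a/p)(A-B)
    for i in range(imax + 1):
        for j in range(jmax + 1):
            if i == 0 and j == 0:
                continue
            if j == 0:
                # build from (i-1, 0)
                for t in range(i + 1):
                    v = pa * E[i - 1, 0, t]
                    if t > 0:
                        v += E[i - 1, 0, t - 1] / (2.0 * p)
                    if t + 1 <= i - 1:
                        v += (t + 1) * E[i - 1, 0, t + 1]
                    E[i, 0, t] = v
            else:
                for t in range(i + j + 1):
                    v = pb * E[i, j - 1, t]
                    if t > 0:
                        v += E[i, j - 1, t - 1] / (2.0 * p)
                    if t + 1 <= i + j - 1:
                        v += (t + 1) * E[i, j - 1, t + 1]
                    E[i, j, t] = v


@njit(cache=True)
def _hermite_r(tmax, umax, vmax, alpha, x, y, z, R):
    """Hermite Coulomb integrals R^0_{tuv}; R shape (tmax+1, umax+1, vmax+1)."""
    nmax = tmax + umax + vmax
    f = np.empty(nmax + 1)
    boys(nmax, alpha * (x * x + y * y + z * z), f)
    # R^n_{000} = (-2 alpha)^n F_n
    rn = np.zeros((nmax + 1, tmax + 1, umax + 1, vmax + 1))
    fac = 1.0
    for n in range(nmax + 1):
        rn[n, 0, 0, 0] = fac * f[n]
        fac *= -2.0 * alpha
    for n in range(nmax - 1, -1, -1):
        for t in range(tmax + 1):
            for u in range(umax + 1):
                for v in range(vmax + 1):
                    if t + u + v == 0 or t + u + v > nmax - n:
                        continue
                    if t > 0:
                        val = x * rn[n + 1, t - 1, u, v]
                        if t > 1:
                            val += (t - 1) * rn[n + 1, t - 2, u, v]
                    elif u > 0:
                        val = y * rn[n + 1, t, u - 1, v]
                        if u > 1:
                            val += (u - 1) * rn[n + 1, t, u - 2, v]
                    else:
                        val = z * rn[n + 1, t, u, v - 1]
                        if v > 1:
                            val += (v - 1) * rn[n + 1, t, u, v - 2]
                    rn[n, t, u, v] = val
    R[:, :, :] = rn[0]


_CART_TABLE = np.zeros((3, 6, 3), dtype=np.int64)
for _l, _comps in CART_COMPONENTS.items():
    for _c, (_i, _j, _k) in enumerate(_comps):
        _CART_TABLE[_l, _c, 0] = _i
        _CART_TABLE[_l, _c, 1] = _j
        _CART_TABLE[_l, _c, 2] = _k
_NCART = np.array([1, 3, 6], dtype=np.int64)


# ---------------------------------------------------------------------------
# flat basis representation
# ---------------------------------------------------------------------------


def flatten_basis(bas) -> tuple:
    """Flat numba-friendly arrays for a BasisSet."""
    ns = len(bas.shells)
    l = np.empty(ns, dtype=np.int64)
    pptr = np.zeros(ns + 1, dtype=np.int64)
    centers = np.empty((ns, 3))
    for i, sh in enumerate(bas.shells):
        l[i] = sh.l
        pptr[i + 1] = pptr[i] + len(sh.exponents)
        centers[i] = sh.center
    pexp = np.concatenate([sh.exponents for sh in bas.shells])
    pcoef = np.concatenate([sh.coefficients for sh in bas.shells])
    cartoff = bas.cart_offsets.astype(np.int64)
    return l, pptr, centers, pexp, pcoef, cartoff


# ---------------------------------------------------------------------------
# one-electron integrals
# ---------------------------------------------------------------------------


@njit(cache=True)
def _overlap_kinetic_pair(l1, l2, c1, c2, e1, e2, x1, x2, s_blk, t_blk, do_kin):
    n1 = _NCART[l1]
    n2 = _NCART[l2]
    for c in range(n1):
        for d in range(n2):
            s_blk[c, d] = 0.0
            t_blk[c, d] = 0.0
    jext = l2 + 2
    E = np.zeros((3, l1 + 1, jext + 1, l1 + jext + 1))
    for ip in range(len(e1)):
        for jp in range(len(e2)):
            a = e1[ip]
            b = e2[jp]
            p = a + b
            coef = c1[ip] * c2[jp]
            for d in range(3):
                E[d, :, :, :] = 0.0
                _e_coeffs(l1, jext, a, b, x1[d] - x2[d], E[d])
            pref = coef * (math.pi / p) ** 1.5
            for c in range(n1):
                i1 = _CART_TABLE[l1, c]
                for dd in range(n2):
                    i2 = _CART_TABLE[l2, dd]
                    sx = E[0, i1[0], i2[0], 0]
                    sy = E[1, i1[1], i2[1], 0]
                    sz = E[2, i1[2], i2[2], 0]
                    s_blk[c, dd] += pref * sx * sy * sz
                    if do_kin:
                        kx = -2.0 * b * b * E[0, i1[0], i2[0] + 2, 0] \
                            + b * (2 * i2[0] + 1) * sx
                        if i2[0] >= 2:
                            kx -= 0.5 * i2[0] * (i2[0] - 1) * E[0, i1[0], i2[0] - 2, 0]
                        ky = -2.0 * b * b * E[1, i1[1], i2[1] + 2, 0] \
                            + b * (2 * i2[1] + 1) * sy
                        if i2[1] >= 2:
                            ky -= 0.5 * i2[1] * (i2[1] - 1) * E[1, i1[1], i2[1] - 2, 0]
                        kz = -2.0 * b * b * E[2, i1[2], i2[2] + 2, 0] \
                            + b * (2 * i2[2] + 1) * sz
                        if i2[2] >= 2:
                            kz -= 0.5 * i2[2] * (i2[2] - 1) * E[2, i1[2], i2[2] - 2, 0]
                        t_blk[c, dd] += pref * (kx * sy * sz + sx * ky * sz
                                                + sx * sy * kz)


@njit(cache=True)
def _nuclear_pair(l1, l2, c1, c2, e1, e2, x1, x2, charges, positions, v_blk):
    n1 = _NCART[l1]
    n2 = _NCART[l2]
    for c in range(n1):
        for d in range(n2):
            v_blk[c, d] = 0.0
    lsum = l1 + l2
    E = np.zeros((3, l1 + 1, l2 + 1, lsum + 1))
    R = np.empty((lsum + 1, lsum + 1, lsum + 1))
    for ip in range(len(e1)):
        for jp in range(len(e2)):
            a = e1[ip]
            b = e2[jp]
            p = a + b
            coef = c1[ip] * c2[jp]
            px = (a * x1[0] + b * x2[0]) / p
            py = (a * x1[1] + b * x2[1]) / p
            pz = (a * x1[2] + b * x2[2]) / p
            for d in range(3):
                E[d, :, :, :] = 0.0
                _e_coeffs(l1, l2, a, b, x1[d] - x2[d], E[d])
            pref = coef * 2.0 * math.pi / p
            for kq in range(len(charges)):
                _hermite_r(lsum, lsum, lsum, p,
                           px - positions[kq, 0], py - positions[kq, 1],
                           pz - positions[kq, 2], R)
                for c in range(n1):
                    i1 = _CART_TABLE[l1, c]
                    for dd in range(n2):
                        i2 = _CART_TABLE[l2, dd]
                        acc = 0.0
                        for t in range(i1[0] + i2[0] + 1):
                            ex = E[0, i1[0], i2[0], t]
                            for u in range(i1[1] + i2[1] + 1):
                                exy = ex * E[1, i1[1], i2[1], u]
                                for v in range(i1[2] + i2[2] + 1):
                                    acc += exy * E[2, i1[2], i2[2], v] * R[t, u, v]
                        v_blk[c, dd] += -charges[kq] * pref * acc


def _one_electron(b1, b2, kind, charges=None, positions=None):
    l1a, pptr1, cen1, pe1, pc1, coff1 = flatten_basis(b1)
    l2a, pptr2, cen2, pe2, pc2, coff2 = flatten_basis(b2)
    s = np.zeros((b1.n_cart, b2.n_cart))
    t = np.zeros((b1.n_cart, b2.n_cart)) if kind == "kinetic" else None
    blk_s = np.zeros((6, 6))
    blk_t = np.zeros((6, 6))
    for i in range(len(b1.shells)):
        for j in range(len(b2.shells)):
            e1 = pe1[pptr1[i]:pptr1[i + 1]]
            c1 = pc1[pptr1[i]:pptr1[i + 1]]
            e2 = pe2[pptr2[j]:pptr2[j + 1]]
            c2 = pc2[pptr2[j]:pptr2[j + 1]]
            n1 = _NCART[l1a[i]]
            n2 = _NCART[l2a[j]]
            if kind in ("overlap", "kinetic"):
                _overlap_kinetic_pair(l1a[i], l2a[j], c1, c2, e1, e2,
                                      cen1[i], cen2[j], blk_s, blk_t,
                                      kind == "kinetic")
                s[coff1[i]:coff1[i] + n1, coff2[j]:coff2[j] + n2] = blk_s[:n1, :n2]
                if kind == "kinetic":
                    t[coff1[i]:coff1[i] + n1, coff2[j]:coff2[j] + n2] = \
                        blk_t[:n1, :n2]
            else:
                _nuclear_pair(l1a[i], l2a[j], c1, c2, e1, e2, cen1[i], cen2[j],
                              charges, positions, blk_s)
                s[coff1[i]:coff1[i] + n1, coff2[j]:coff2[j] + n2] = blk_s[:n1, :n2]
    return (s, t) if kind == "kinetic" else s


def overlap_cart(b1, b2):
    return _one_electron(b1, b2, "overlap")


def overlap(b1, b2):
    return b2.finalize(b1.finalize(overlap_cart(b1, b2), (0,)), (1,)) \
        if b1 is not b2 else b1.finalize(overlap_cart(b1, b1), (0, 1))


def kinetic(b1):
    _, t = _one_electron(b1, b1, "kinetic")
    return b1.finalize(t, (0, 1))


def nuclear_attraction(b1, b2, charges, positions):
    """<mu|sum_c -Z_c/|r-R_c||nu> with mu from b1, nu from b2."""
    v = _one_electron(b1, b2, "nuclear",
                      np.asarray(charges, float),
                      np.ascontiguousarray(positions, float))
    if b1 is b2:
        return b1.finalize(v, (0, 1))
    return b2.finalize(b1.finalize(v, (0,)), (1,))


def overlap_cross(b1, b2):
    return b2.finalize(b1.finalize(overlap_cart(b1, b2), (0,)), (1,))


# ---------------------------------------------------------------------------
# shell-pair data and the ERI kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _build_pairdata(l1a, pptr1, cen1, pe1, pc1,
                    l2a, pptr2, cen2, pe2, pc2,
                    i_arr, j_arr):
    npairs = len(i_arr)
    # first pass: count primitive pairs and E3 storage
    pp_ptr = np.zeros(npairs + 1, dtype=np.int64)
    e3_ptr_pairs = np.zeros(npairs + 1, dtype=np.int64)
    for k in range(npairs):
        i = i_arr[k]
        j = j_arr[k]
        np1 = pptr1[i + 1] - pptr1[i]
        np2 = pptr2[j + 1] - pptr2[j]
        l1 = l1a[i]
        l2 = l2a[j]
        nc = _NCART[l1] * _NCART[l2]
        nherm = (l1 + l2 + 1) ** 3
        pp_ptr[k + 1] = pp_ptr[k] + np1 * np2
        e3_ptr_pairs[k + 1] = e3_ptr_pairs[k] + np1 * np2 * nc * nherm
    ntot = pp_ptr[npairs]
    pp_p = np.empty(ntot)
    pp_P = np.empty((ntot, 3))
    pp_coef = np.empty(ntot)
    e3 = np.zeros(e3_ptr_pairs[npairs])
    E = np.zeros((3, 3, 3, 5))  # scratch: (dim, i, j, t), l <= 2
    for k in range(npairs):
        i = i_arr[k]
        j = j_arr[k]
        l1 = l1a[i]
        l2 = l2a[j]
        n1 = _NCART[l1]
        n2 = _NCART[l2]
        lsum = l1 + l2
        nh1 = lsum + 1
        nherm = nh1 ** 3
        x1 = cen1[i]
        x2 = cen2[j]
        idx = pp_ptr[k]
        e3_base = e3_ptr_pairs[k]
        for ip in range(pptr1[i], pptr1[i + 1]):
            for jp in range(pptr2[j], pptr2[j + 1]):
                a = pe1[ip]
                b = pe2[jp]
                p = a + b
                pp_p[idx] = p
                for d in range(3):
                    pp_P[idx, d] = (a * x1[d] + b * x2[d]) / p
                pp_coef[idx] = pc1[ip] * pc2[jp]
                for d in range(3):
                    E[d, :, :, :] = 0.0
                    _e_coeffs(l1, l2, a, b, x1[d] - x2[d], E[d, :l1 + 1, :l2 + 1, :lsum + 1])
                base = e3_base + (idx - pp_ptr[k]) * n1 * n2 * nherm
                for c in range(n1):
                    i1 = _CART_TABLE[l1, c]
                    for dd in range(n2):
                        i2 = _CART_TABLE[l2, dd]
                        off = base + (c * n2 + dd) * nherm
                        for t in range(i1[0] + i2[0] + 1):
                            ex = E[0, i1[0], i2[0], t]
                            for u in range(i1[1] + i2[1] + 1):
                                exy = ex * E[1, i1[1], i2[1], u]
                                for v in range(i1[2] + i2[2] + 1):
                                    e3[off + (t * nh1 + u) * nh1 + v] = \
                                        exy * E[2, i1[2], i2[2], v]
                idx += 1
    return pp_ptr, pp_p, pp_P, pp_coef, e3, e3_ptr_pairs


class PairList:
    """Precomputed Hermite expansions for a list of shell pairs."""

    def __init__(self, bas1, bas2, symmetric: bool):
        self.bas1, self.bas2 = bas1, bas2
        self.symmetric = symmetric and (bas1 is bas2)
        f1 = flatten_basis(bas1)
        f2 = flatten_basis(bas2)
        ns1, ns2 = len(bas1.shells), len(bas2.shells)
        ii, jj = [], []
        for i in range(ns1):
            for j in range(ns2):
                if self.symmetric and j < i:
                    continue
                ii.append(i)
                jj.append(j)
        self.i_arr = np.array(ii, dtype=np.int64)
        self.j_arr = np.array(jj, dtype=np.int64)
        (self.pp_ptr, self.pp_p, self.pp_P, self.pp_coef, self.e3,
         self.e3_ptr) = _build_pairdata(f1[0], f1[1], f1[2], f1[3], f1[4],
                                        f2[0], f2[1], f2[2], f2[3], f2[4],
                                        self.i_arr, self.j_arr)
        self.l1 = f1[0][self.i_arr]
        self.l2 = f2[0][self.j_arr]
        self.off1 = f1[5][self.i_arr]
        self.off2 = f2[5][self.j_arr]
        self.schwarz = _schwarz_bounds(
            self.l1, self.l2, self.pp_ptr, self.pp_p, self.pp_P, self.pp_coef,
            self.e3, self.e3_ptr)


@njit(cache=True)
def _contract_quartet(lb, lk, pptr_b, p_b, P_b, coef_b, e3_b, e3b_base,
                      pptr_k, p_k, P_k, coef_k, e3_k, e3k_base,
                      kb, kk, out_block):
    l12 = lb
    l34 = lk
    nh_b = l12 + 1
    nh_k = l34 + 1
    nherm_b = nh_b ** 3
    nherm_k = nh_k ** 3
    nc_b = out_block.shape[0]
    nc_k = out_block.shape[1]
    ltot = l12 + l34
    R = np.empty((ltot + 1, ltot + 1, ltot + 1))
    X = np.empty((nc_k, nherm_b))
    for cb in range(nc_b):
        for ck in range(nc_k):
            out_block[cb, ck] = 0.0
    nb0 = pptr_b[kb]
    nb1 = pptr_b[kb + 1]
    nk0 = pptr_k[kk]
    nk1 = pptr_k[kk + 1]
    for ib in range(nb0, nb1):
        p = p_b[ib]
        cb_coef = coef_b[ib]
        baseb = e3b_base + (ib - nb0) * nc_b * nherm_b
        for ik in range(nk0, nk1):
            q = p_k[ik]
            alpha = p * q / (p + q)
            pref = cb_coef * coef_k[ik] * _TWO_PI_POW / (p * q * math.sqrt(p + q))
            _hermite_r(ltot, ltot, ltot, alpha,
                       P_b[ib, 0] - P_k[ik, 0],
                       P_b[ib, 1] - P_k[ik, 1],
                       P_b[ib, 2] - P_k[ik, 2], R)
            basek = e3k_base + (ik - nk0) * nc_k * nherm_k
            # X[ck, tuv_bra] = sum_ket (-1)^(tau+nu+phi) E3k R
            for ck in range(nc_k):
                offk = basek + ck * nherm_k
                for t in range(nh_b):
                    for u in range(nh_b):
                        for v in range(nh_b):
                            acc = 0.0
                            for tt in range(nh_k):
                                sgn_t = -1.0 if (tt % 2) else 1.0
                                for uu in range(nh_k):
                                    sgn_u = -sgn_t if (uu % 2) else sgn_t
                                    for vv in range(nh_k):
                                        sgn = -sgn_u if (vv % 2) else sgn_u
                                        e = e3_k[offk + (tt * nh_k + uu) * nh_k + vv]
                                        if e != 0.0:
                                            acc += sgn * e * R[t + tt, u + uu, v + vv]
                            X[ck, (t * nh_b + u) * nh_b + v] = acc
            for cb in range(nc_b):
                offb = baseb + cb * nherm_b
                for ck in range(nc_k):
                    acc = 0.0
                    for h in range(nherm_b):
                        e = e3_b[offb + h]
                        if e != 0.0:
                            acc += e * X[ck, h]
                    out_block[cb, ck] += pref * acc


@njit(cache=True)
def _schwarz_bounds(l1, l2, pp_ptr, pp_p, pp_P, pp_coef, e3, e3_ptr):
    npairs = len(l1)
    out = np.empty(npairs)
    blk = np.empty((36, 36))
    for k in range(npairs):
        n12 = _NCART[l1[k]] * _NCART[l2[k]]
        lb = l1[k] + l2[k]
        _contract_quartet(lb, lb, pp_ptr, pp_p, pp_P, pp_coef, e3, e3_ptr[k],
                          pp_ptr, pp_p, pp_P, pp_coef, e3, e3_ptr[k],
                          k, k, blk[:n12, :n12])
        m = 0.0
        for c in range(n12):
            if blk[c, c] > m:
                m = blk[c, c]
        out[k] = math.sqrt(abs(m))
    return out


@njit(cache=True)
def _eri_kernel(lb1, lb2, offb1, offb2, pptr_b, p_b, P_b, coef_b, e3_b, e3b_ptr,
                schwarz_b,
                lk1, lk2, offk1, offk2, pptr_k, p_k, P_k, coef_k, e3_k, e3k_ptr,
                schwarz_k,
                bra_sym, ket_sym, braket_sym, thresh, out):
    nbp = len(lb1)
    nkp = len(lk1)
    blk = np.empty((36, 36))
    for kb in range(nbp):
        n1 = _NCART[lb1[kb]]
        n2 = _NCART[lb2[kb]]
        for kk in range(nkp):
            if braket_sym and kk < kb:
                continue
            if schwarz_b[kb] * schwarz_k[kk] < thresh:
                continue
            n3 = _NCART[lk1[kk]]
            n4 = _NCART[lk2[kk]]
            _contract_quartet(lb1[kb] + lb2[kb], lk1[kk] + lk2[kk],
                              pptr_b, p_b, P_b, coef_b, e3_b, e3b_ptr[kb],
                              pptr_k, p_k, P_k, coef_k, e3_k, e3k_ptr[kk],
                              kb, kk, blk[:n1 * n2, :n3 * n4])
            o1 = offb1[kb]
            o2 = offb2[kb]
            o3 = offk1[kk]
            o4 = offk2[kk]
            for c1 in range(n1):
                for c2 in range(n2):
                    row = blk[c1 * n2 + c2]
                    for c3 in range(n3):
                        for c4 in range(n4):
                            v = row[c3 * n4 + c4]
                            out[o1 + c1, o2 + c2, o3 + c3, o4 + c4] = v
                            if bra_sym:
                                out[o2 + c2, o1 + c1, o3 + c3, o4 + c4] = v
                            if ket_sym:
                                out[o1 + c1, o2 + c2, o4 + c4, o3 + c3] = v
                            if bra_sym and ket_sym:
                                out[o2 + c2, o1 + c1, o4 + c4, o3 + c3] = v
                            if braket_sym:
                                out[o3 + c3, o4 + c4, o1 + c1, o2 + c2] = v
                                if bra_sym:
                                    out[o3 + c3, o4 + c4, o2 + c2, o1 + c1] = v
                                if ket_sym:
                                    out[o4 + c4, o3 + c3, o1 + c1, o2 + c2] = v
                                if bra_sym and ket_sym:
                                    out[o4 + c4, o3 + c3, o2 + c2, o1 + c1] = v


def eri_class(bra: PairList, ket: PairList, thresh: float = 1e-13) -> np.ndarray:
    """Contracted ERI tensor (b1 b2 | k1 k2) in chemists' notation, finalized
    (spherical + normalized). ``bra``/``ket`` may share pair lists for the
    bra-ket-symmetric classes."""
    out = np.zeros((bra.bas1.n_cart, bra.bas2.n_cart,
                    ket.bas1.n_cart, ket.bas2.n_cart))
    _eri_kernel(bra.l1, bra.l2, bra.off1, bra.off2, bra.pp_ptr, bra.pp_p,
                bra.pp_P, bra.pp_coef, bra.e3, bra.e3_ptr, bra.schwarz,
                ket.l1, ket.l2, ket.off1, ket.off2, ket.pp_ptr, ket.pp_p,
                ket.pp_P, ket.pp_coef, ket.e3, ket.e3_ptr, ket.schwarz,
                bra.symmetric, ket.symmetric, bra is ket, thresh, out)
    out = bra.bas1.finalize(out, (0,))
    out = bra.bas2.finalize(out, (1,))
    out = ket.bas1.finalize(out, (2,))
    out = ket.bas2.finalize(out, (3,))
    return out
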