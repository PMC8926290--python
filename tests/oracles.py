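"""Independent test oracles.

Everything here deliberately avoids the production code paths it is used to
check: an Obara-Saika integral recursion (vs the McMurchie-Davidson engine),
a first-quantized brute-force enumeration of the single-exchange expectation
values (vs the density-matrix exchange contractions), a non-orthogonal
determinant Heitler-London energy, and dense spin operators for symmetry
checks.
"""
from __future__ import annotations

import math
from itertools import permutations

import numpy as np

from saptvqe import qsim
from saptvqe.integrals import (compute_monomer_integrals, run_rhf,
                               _union_integrals)
from saptvqe.integrals import _engine as eng

# ---------------------------------------------------------------------------
# Obara-Saika electron-repulsion integrals (primitive Cartesian Gaussians)
# ---------------------------------------------------------------------------


def _boys_ref(m, x):
    from scipy.special import gammainc, gamma
    if x < 1e-13:
        return 1.0 / (2 * m + 1)
    return gamma(m + 0.5) * gammainc(m + 0.5, x) / (2 * x ** (m + 0.5))


def os_eri_primitive(la, a, A, lb, b, B, lc, c, C, ld, d, D):
    """(ab|cd) for primitive Cartesian Gaussians with angular tuples
    la..ld = (i,j,k), via Obara-Saika vertical + horizontal recursions."""
    A, B, C, D = map(np.asarray, (A, B, C, D))
    p = a + b
    q = c + d
    P = (a * A + b * B) / p
    Q = (c * C + d * D) / q
    W = (p * P + q * Q) / (p + q)
    rho = p * q / (p + q)
    kab = math.exp(-a * b / p * float((A - B) @ (A - B)))
    kcd = math.exp(-c * d / q * float((C - D) @ (C - D)))
    pref = 2 * math.pi ** 2.5 / (p * q * math.sqrt(p + q)) * kab * kcd
    memo = {}

    def vrr(at, ct, m):
        """(a 0 | c 0)^m with angular tuples at, ct."""
        key = (at, ct, m)
        if key in memo:
            return memo[key]
        if at == (0, 0, 0) and ct == (0, 0, 0):
            val = pref * _boys_ref(m, rho * float((P - Q) @ (P - Q)))
        elif at != (0, 0, 0):
            i = max(range(3), key=lambda k: at[k])
            am = tuple(at[k] - (k == i) for k in range(3))
            val = (P[i] - A[i]) * vrr(am, ct, m) \
                + (W[i] - P[i]) * vrr(am, ct, m + 1)
            if am[i] > 0:
                amm = tuple(am[k] - (k == i) for k in range(3))
                val += am[i] / (2 * p) * (vrr(amm, ct, m)
                                          - rho / p * vrr(amm, ct, m + 1))
            if ct[i] > 0:
                cm = tuple(ct[k] - (k == i) for k in range(3))
                val += ct[i] / (2 * (p + q)) * vrr(am, cm, m + 1)
        else:
            i = max(range(3), key=lambda k: ct[k])
            cm = tuple(ct[k] - (k == i) for k in range(3))
            val = (Q[i] - C[i]) * vrr(at, cm, m) \
                + (W[i] - Q[i]) * vrr(at, cm, m + 1)
            if cm[i] > 0:
                cmm = tuple(cm[k] - (k == i) for k in range(3))
                val += cm[i] / (2 * q) * (vrr(at, cmm, m)
                                          - rho / q * vrr(at, cmm, m + 1))
            if at[i] > 0:
                am = tuple(at[k] - (k == i) for k in range(3))
                val += at[i] / (2 * (p + q)) * vrr(am, cm, m + 1)
        memo[key] = val
        return val

    def hrr_bra(at, bt, ct, dt):
        if bt == (0, 0, 0):
            return hrr_ket(at, ct, dt)
        i = max(range(3), key=lambda k: bt[k])
        bm = tuple(bt[k] - (k == i) for k in range(3))
        ap = tuple(at[k] + (k == i) for k in range(3))
        return hrr_bra(ap, bm, ct, dt) + (A[i] - B[i]) * hrr_bra(at, bm, ct, dt)

    def hrr_ket(at, ct, dt):
        if dt == (0, 0, 0):
            return vrr(at, ct, 0)
        i = max(range(3), key=lambda k: dt[k])
        dm = tuple(dt[k] - (k == i) for k in range(3))
        cp = tuple(ct[k] + (k == i) for k in range(3))
        return hrr_ket(at, cp, dm) + (C[i] - D[i]) * hrr_ket(at, ct, dm)

    return hrr_bra(tuple(la), tuple(lb), tuple(lc), tuple(ld))


# ---------------------------------------------------------------------------
# brute-force first-quantized exchange enumeration (2-electron monomers)
# ---------------------------------------------------------------------------


class TwoElectronMonomerSystem:
    """A dimer of two 2-electron monomers with arbitrary (possibly
    correlated) singlet monomer wavefunctions given as CI expansions over
    their own spatial orbitals. Provides exact <v(i,j) P_{i'j'}> sums."""

    def __init__(self, dimer, orbs_a, ci_a, orbs_b, ci_b):
        """orbs_x: (n_ao_union, n_orb_x) orbital columns in the union AO
        basis; ci_x: dict {(occ_i, occ_j): coef} over closed-shell spatial
        configurations (i==j means doubly occupied orbital i)."""
        self.u = _union_integrals(dimer)
        za = dimer.monomer_a.atomic_numbers.astype(float)
        zb = dimer.monomer_b.atomic_numbers.astype(float)
        self.vA = eng.nuclear_attraction(self.u.basis, self.u.basis, za,
                                         dimer.monomer_a.coords)
        self.vB = eng.nuclear_attraction(self.u.basis, self.u.basis, zb,
                                         dimer.monomer_b.coords)
        self.v_nn = dimer.nuclear_repulsion_cross()
        self.orbs = {}
        for i in range(orbs_a.shape[1]):
            self.orbs[("a", i)] = orbs_a[:, i]
        for i in range(orbs_b.shape[1]):
            self.orbs[("b", i)] = orbs_b[:, i]
        self.ci_a, self.ci_b = ci_a, ci_b
        self.na = self.nb = 2

    def _ov(self, f, g):
        return self.orbs[f] @ self.u.overlap @ self.orbs[g]

    def _vmat(self, f, g, m):
        return self.orbs[f] @ m @ self.orbs[g]

    def _eri(self, f, g, h, k):
        return np.einsum("pqrs,p,q,r,s->", self.u.eri, self.orbs[f],
                         self.orbs[g], self.orbs[h], self.orbs[k])

    def _vgen(self, f, h, g, k):
        """<f(1) g(2)| v |h(1) k(2)> with the 1/N-distributed interaction."""
        return (self._eri(f, h, g, k)
                + self._vmat(f, h, self.vB) * self._ov(g, k) / self.nb
                + self._vmat(g, k, self.vA) * self._ov(f, h) / self.na
                + self.v_nn * self._ov(f, h) * self._ov(g, k)
                / (self.na * self.nb))

    def _monomer_products(self, which):
        """Expansion of the monomer wavefunction over spin-orbital product
        terms: yields (coef, (so1, so2)) for coordinates in order."""
        ci = self.ci_a if which == "a" else self.ci_b
        out = []
        for (i, j), coef in ci.items():
            oi, oj = (which, i), (which, j)
            if i == j:
                # |i ibar|: (1/sqrt2)[up(1)dn(2) - dn(1)up(2)] spatial i i
                out.append((coef / math.sqrt(2), ((oi, "u"), (oj, "d"))))
                out.append((-coef / math.sqrt(2), ((oi, "d"), (oj, "u"))))
            else:
                # closed-shell singlet open-pair CSF (i<j):
                # (1/2)[ij+ji](spatial) x (ud-du)(spin)
                for (f1, f2) in ((oi, oj), (oj, oi)):
                    out.append((coef / 2.0, ((f1, "u"), (f2, "d"))))
                    out.append((-coef / 2.0, ((f1, "d"), (f2, "u"))))
        return out

    def _all_products(self):
        pa = self._monomer_products("a")
        pb = self._monomer_products("b")
        for ca, fa in pa:
            for cb, fb in pb:
                yield ca * cb, {1: fa[0], 2: fa[1], 3: fb[0], 4: fb[1]}

    def braket_vp(self, i, j, i2, j2):
        """<Psi0| v(x_i, x_j) P_{i2 j2} |Psi0> (P = identity if i2 is None)."""
        tot = 0.0
        for cb_, bra in self._all_products():
            for ck, ket0 in self._all_products():
                ket = dict(ket0)
                if i2 is not None:
                    ket[i2], ket[j2] = ket[j2], ket[i2]
                val = cb_ * ck
                ok = True
                for coord in (1, 2, 3, 4):
                    (fb, sb) = bra[coord]
                    (fk, sk) = ket[coord]
                    if sb != sk:
                        ok = False
                        break
                    if coord not in (i, j):
                        val *= self._ov(fb, fk)
                if not ok or val == 0.0:
                    continue
                f1 = bra[i][0]
                h1 = ket[i][0]
                g2 = bra[j][0]
                k2 = ket[j][0]
                tot += val * self._vgen(f1, h1, g2, k2)
        return tot

    def braket_perm(self, i2, j2):
        """<Psi0| P_{i2 j2} |Psi0>."""
        tot = 0.0
        for cb_, bra in self._all_products():
            for ck, ket0 in self._all_products():
                ket = dict(ket0)
                ket[i2], ket[j2] = ket[j2], ket[i2]
                val = cb_ * ck
                for coord in (1, 2, 3, 4):
                    (fb, sb) = bra[coord]
                    (fk, sk) = ket[coord]
                    if sb != sk:
                        val = 0.0
                        break
                    val *= self._ov(fb, fk)
                tot += val
        return tot

    def exchange_s2(self):
        """-<V P> + E_pol <P> by explicit enumeration."""
        a_coords, b_coords = (1, 2), (3, 4)
        e_pol = sum(self.braket_vp(i, j, None, None)
                    for i in a_coords for j in b_coords)
        vp = sum(self.braket_vp(i, j, i2, j2)
                 for i in a_coords for j in b_coords
                 for i2 in a_coords for j2 in b_coords)
        perm = sum(self.braket_perm(i2, j2)
                   for i2 in a_coords for j2 in b_coords)
        return -vp + e_pol * perm, e_pol, perm


# ---------------------------------------------------------------------------
# Heitler-London (non-orthogonal determinant) interaction energy
# ---------------------------------------------------------------------------


def heitler_london_interaction(dimer) -> float:
    """<A Psi0|H|A Psi0>/<.|.> - E_A - E_B for RHF monomers, through the
    generalized (non-orthogonal) closed-shell density."""
    u = _union_integrals(dimer)
    ia = compute_monomer_integrals(dimer.monomer_a, dimer.basis_a)
    ib = compute_monomer_integrals(dimer.monomer_b, dimer.basis_b)
    sa, sb = run_rhf(ia), run_rhf(ib)
    na = ia.n_basis
    c = np.zeros((u.n_basis, sa.n_occ + sb.n_occ))
    c[:na, :sa.n_occ] = sa.mo_coeff[:, :sa.n_occ]
    c[na:, sa.n_occ:] = sb.mo_coeff[:, :sb.n_occ]
    m = c.T @ u.overlap @ c
    p = 2.0 * c @ np.linalg.solve(m, c.T)
    j = np.einsum("pqrs,rs->pq", u.eri, p, optimize=True)
    k = np.einsum("prqs,rs->pq", u.eri, p, optimize=True)
    e = (np.sum(p * u.core_h) + 0.5 * np.sum(p * j) - 0.25 * np.sum(p * k)
         + u.nuclear_repulsion)
    return float(e - sa.e_total - sb.e_total)


# ---------------------------------------------------------------------------
# overlap-scaled cross integrals (S^2 structure probe)
# ---------------------------------------------------------------------------


def scale_cross(cross, lam: float):
    """Scale every overlap-carrying cross block: one power of lambda per
    mixed (A,B) charge distribution."""
    from dataclasses import replace
    return replace(
        cross,
        s_ab=lam * cross.s_ab,
        v_a_ab=lam * cross.v_a_ab,
        v_b_ab=lam * cross.v_b_ab,
        eri_abab=lam ** 2 * cross.eri_abab,
        eri_aaab=lam * cross.eri_aaab,
        eri_abbb=lam * cross.eri_abbb,
    )


# ---------------------------------------------------------------------------
# dense spin operators on the statevector
# ---------------------------------------------------------------------------


def _create(sv: qsim.Statevector, p: int) -> np.ndarray:
    amps = sv.amplitudes
    idx = np.arange(len(amps))
    empty = ((idx >> p) & 1) == 0
    src = idx[empty]
    dst = src + (1 << p)
    below = src & ((1 << p) - 1)
    sign = np.array([(-1.0) ** bin(int(b)).count("1") for b in below])
    out = np.zeros_like(amps)
    out[dst] = sign * amps[src]
    return out


def s_squared(sv: qsim.Statevector) -> float:
    """<S^2> = <S_- S_+> + <S_z>(<S_z>+1) for an S_z eigenstate."""
    n = sv.n_orb
    splus = np.zeros_like(sv.amplitudes)
    for t in range(n):
        tmp = qsim.annihilate(sv, n + t)              # a_{t beta}
        splus += _create(qsim.Statevector(tmp, n), t)  # a+_{t alpha}
    na = sv.number_expectation("alpha")
    nb = sv.number_expectation("beta")
    sz = 0.5 * (na - nb)
    return float(splus @ splus) + sz * (sz + 1.0)
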