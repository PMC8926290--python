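"""Ideal statevector simulation of the active space under Jordan-Wigner.

Qubit layout: ``2 N_a`` qubits in blocked spin order — qubit ``t`` holds the
alpha spin-orbital of spatial orbital ``t`` and qubit ``N_a + t`` the beta
one. A full-register index ``n`` therefore decomposes as
``n = i_beta * 2**N_a + i_alpha``. Canonical occupation-number states carry a
+1 phase for the ordered product of creation operators (ascending qubit
index applied last), which fixes every fermionic sign below.

The circuit family is the k-muCJ ansatz: alternating spin-restricted
orbital-rotation fabrics exp(K) (identical Givens angles for both spins) and
layers of four-qubit pair-exchange gates P_X(theta) that rotate between the
doubly-occupied / doubly-empty configurations of two neighboring spatial
orbitals. Everything is real; no sampling noise is modelled anywhere.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

__all__ = [
    "Statevector",
    "AnsatzParams",
    "RDMPair",
    "prepare_reference",
    "apply_givens",
    "apply_orbital_rotation",
    "apply_orbital_transform",
    "apply_pair_exchange",
    "pair_pattern",
    "apply_mucj",
    "expectation",
    "compute_rdms",
    "annihilate",
    "spin_orbital_rdms",
]


@dataclass
class Statevector:
    """Real amplitudes over the 2**(2 n_orb) Jordan-Wigner basis."""

    amplitudes: np.ndarray
    n_orb: int

    def __post_init__(self):
        dim = 1 << (2 * self.n_orb)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.shape != (dim,):
            raise ValueError(f"amplitude vector must have length {dim}")

    def copy(self) -> "Statevector":
        return Statevector(self.amplitudes.copy(), self.n_orb)

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.amplitudes))

    def number_expectation(self, spin: str) -> float:
        """<N_alpha> or <N_beta>."""
        n = self.n_orb
        idx = np.arange(len(self.amplitudes))
        reg = idx & ((1 << n) - 1) if spin == "alpha" else idx >> n
        counts = np.array([bin(x).count("1") for x in range(1 << n)])
        return float(np.sum(self.amplitudes ** 2 * counts[reg]))


@dataclass
class AnsatzParams:
    """k-muCJ parameters: per layer an antisymmetric orbital-rotation
    generator kappa and pair-exchange angles tau over the alternating
    nearest-neighbor pattern, plus one trailing kappa."""

    layers: list  # [(kappa_i, tau_i), ...]
    kappa_final: np.ndarray

    @property
    def k(self) -> int:
        return len(self.layers)

    @staticmethod
    def zeros(n_orb: int, k: int) -> "AnsatzParams":
        n_tau = len(pair_pattern(n_orb))
        return AnsatzParams(
            [(np.zeros((n_orb, n_orb)), np.zeros(n_tau)) for _ in range(k)],
            np.zeros((n_orb, n_orb)),
        )

    def to_vector(self) -> np.ndarray:
        n = self.kappa_final.shape[0]
        iu = np.triu_indices(n, 1)
        parts = []
        for kappa, tau in self.layers:
            parts.append(kappa[iu])
            parts.append(tau)
        parts.append(self.kappa_final[iu])
        return np.concatenate(parts)

    @staticmethod
    def from_vector(x: np.ndarray, n_orb: int, k: int) -> "AnsatzParams":
        iu = np.triu_indices(n_orb, 1)
        n_kap = len(iu[0])
        n_tau = len(pair_pattern(n_orb))
        layers = []
        pos = 0
        for _ in range(k):
            kappa = np.zeros((n_orb, n_orb))
            kappa[iu] = x[pos:pos + n_kap]
            kappa -= kappa.T
            pos += n_kap
            tau = np.array(x[pos:pos + n_tau])
            pos += n_tau
            layers.append((kappa, tau))
        kf = np.zeros((n_orb, n_orb))
        kf[iu] = x[pos:pos + n_kap]
        kf -= kf.T
        return AnsatzParams(layers, kf)


@dataclass
class RDMPair:
    """Spin-summed one- and two-particle reduced density matrices.

    Conventions (matching the active-space Hamiltonian contraction):
    ``gamma[t, t'] = <E_tt'>`` and
    ``gamma2[t, t', u, u'] = sum_st < t+_s u+_t u'_t t'_s >`` so that
    ``E = e_core + sum h~ gamma + 1/2 sum (tt'|uu') gamma2``.
    """

    gamma: np.ndarray
    gamma2: np.ndarray
    n_elec: int


def prepare_reference(n_orb: int, n_alpha: int, n_beta: int) -> Statevector:
    """Aufbau reference determinant: lowest n_alpha alpha and n_beta beta
    spin-orbitals occupied."""
    if not (0 <= n_alpha <= n_orb and 0 <= n_beta <= n_orb):
        raise ValueError("occupation counts exceed orbital count")
    dim = 1 << (2 * n_orb)
    amps = np.zeros(dim)
    ia = (1 << n_alpha) - 1
    ib = (1 << n_beta) - 1
    amps[(ib << n_orb) | ia] = 1.0
    return Statevector(amps, n_orb)


def _bit(idx: np.ndarray, q: int) -> np.ndarray:
    return (idx >> q) & 1


_GIVENS_CACHE: dict = {}
_PAIRX_CACHE: dict = {}


def _givens_indices(n: int, q: int):
    """(src, dst) full-register indices of the |..1_q 0_{q+1}..> states and
    their |..0 1..> partners; cached per register size and qubit."""
    key = (n, q)
    if key not in _GIVENS_CACHE:
        idx = np.arange(1 << (2 * n))
        m10 = (_bit(idx, q) == 1) & (_bit(idx, q + 1) == 0)
        src = idx[m10]
        _GIVENS_CACHE[key] = (src, src - (1 << q) + (1 << (q + 1)))
    return _GIVENS_CACHE[key]


def apply_givens(sv: Statevector, orbital: int, theta: float) -> Statevector:
    """Spin-restricted fermionic Givens rotation between spatial orbitals
    (orbital, orbital+1), same angle for both spin registers.

    Single-particle convention: a+_p -> c a+_p + s a+_{p+1}.
    """
    n = sv.n_orb
    if not (0 <= orbital < n - 1):
        raise ValueError("orbital pair out of range")
    amps = sv.amplitudes.copy()
    c, s = np.cos(theta), np.sin(theta)
    for q in (orbital, n + orbital):  # alpha register, then beta register
        src, dst = _givens_indices(n, q)
        a10 = amps[src]
        a01 = amps[dst]
        amps[src] = c * a10 - s * a01
        amps[dst] = s * a10 + c * a01
    return Statevector(amps, n)


def _givens_decompose(q: np.ndarray):
    """Adjacent-row Givens decomposition of a special orthogonal matrix:
    q = G_1^T ... G_m^T R with R = diag(+-1). Returns ([(row, theta)...], R)."""
    n = q.shape[0]
    r = q.copy()
    gs = []
    for col in range(n):
        for row in range(n - 1, col, -1):
            if abs(r[row, col]) < 1e-15:
                continue
            theta = np.arctan2(r[row, col], r[row - 1, col])
            c, s = np.cos(theta), np.sin(theta)
            g = np.array([[c, s], [-s, c]])
            r[[row - 1, row], :] = g @ r[[row - 1, row], :]
            gs.append((row - 1, theta))
    return gs, np.diag(r).copy()


def apply_orbital_transform(sv: Statevector, q: np.ndarray) -> Statevector:
    """Apply the Fock-space image of the special orthogonal single-particle
    transform ``q`` (same transform for both spins), compiled into a fabric
    of adjacent Givens rotations."""
    n = sv.n_orb
    if q.shape != (n, n):
        raise ValueError("transform dimension mismatch")
    det = np.linalg.det(q)
    if not np.allclose(q @ q.T, np.eye(n), atol=1e-9) or det < 0:
        raise ValueError("transform must be special orthogonal")
    gs, diag = _givens_decompose(q)
    out = sv.copy()
    # q = G1^T ... Gm^T R  ->  apply U(R) first, then U(Gm^T) ... U(G1^T)
    if np.any(diag < 0):
        idx = np.arange(len(out.amplitudes))
        phase = np.ones(len(idx))
        for orb in np.where(diag < 0)[0]:
            for qq in (int(orb), n + int(orb)):
                phase *= np.where(_bit(idx, qq) == 1, -1.0, 1.0)
        out = Statevector(out.amplitudes * phase, n)
    for row, theta in reversed(gs):
        out = apply_givens(out, row, theta)
    return out


def apply_orbital_rotation(sv: Statevector, kappa: np.ndarray) -> Statevector:
    """exp(K) with K = sum kappa_pq (a+_p a_q - h.c. style one-body
    antihermitian generator), identical for both spins."""
    kappa = np.asarray(kappa, float)
    if np.max(np.abs(kappa + kappa.T)) > 1e-10:
        raise ValueError("kappa must be real antisymmetric")
    return apply_orbital_transform(sv, expm(kappa))


def pair_pattern(n_orb: int) -> list[tuple[int, int]]:
    """Alternating nearest-neighbor spatial-orbital pairs: even-start pairs
    (0,1),(2,3),... then odd-start pairs (1,2),(3,4),..."""
    evens = [(p, p + 1) for p in range(0, n_orb - 1, 2)]
    odds = [(p, p + 1) for p in range(1, n_orb - 1, 2)]
    return evens + odds


def apply_pair_exchange(sv: Statevector, pair: tuple[int, int],
                        theta: float) -> Statevector:
    """Four-qubit pair-exchange gate P_X(theta) on spatial orbitals
    (p, p+1): rotates between the |2,0> and |0,2> pair configurations
    (cos/sin amplitudes) and acts as the identity on every other four-qubit
    sector."""
    p, q = pair
    if q != p + 1 or not (0 <= p < sv.n_orb - 1):
        raise ValueError("pair must be nearest-neighbor (p, p+1) in range")
    n = sv.n_orb
    amps = sv.amplitudes.copy()
    key = (n, p)
    if key not in _PAIRX_CACHE:
        idx = np.arange(len(amps))
        pa, pb, qa, qb = p, n + p, p + 1, n + p + 1
        m20 = ((_bit(idx, pa) == 1) & (_bit(idx, pb) == 1)
               & (_bit(idx, qa) == 0) & (_bit(idx, qb) == 0))
        src = idx[m20]
        dst = src - (1 << pa) - (1 << pb) + (1 << qa) + (1 << qb)
        _PAIRX_CACHE[key] = (src, dst)
    src, dst = _PAIRX_CACHE[key]
    c, s = np.cos(theta), np.sin(theta)
    a20 = amps[src]
    a02 = amps[dst]
    amps[src] = c * a20 - s * a02
    amps[dst] = s * a20 + c * a02
    return Statevector(amps, n)


def apply_mucj(sv: Statevector, params: AnsatzParams) -> Statevector:
    """One full k-muCJ circuit: per layer an orbital rotation followed by the
    pair-exchange layer, closed by the trailing orbital rotation. All-zero
    parameters give the identity."""
    n = sv.n_orb
    pairs = pair_pattern(n)
    out = sv
    for kappa, tau in params.layers:
        if kappa.shape != (n, n) or len(tau) != len(pairs):
            raise ValueError("ansatz parameters dimensioned for a different "
                             "orbital count")
        out = apply_orbital_rotation(out, kappa)
        for (pq, t) in zip(pairs, tau):
            out = apply_pair_exchange(out, pq, t)
    out = apply_orbital_rotation(out, params.kappa_final)
    return out


# ---------------------------------------------------------------------------
# operators and reduced density matrices
# ---------------------------------------------------------------------------


def annihilate(sv: Statevector, spin_orbital: int) -> np.ndarray:
    """Amplitudes of a_P |psi> with the Jordan-Wigner sign convention;
    P < n_orb are alpha, P >= n_orb beta spin-orbitals."""
    n2 = 2 * sv.n_orb
    if not (0 <= spin_orbital < n2):
        raise ValueError("spin-orbital index out of range")
    amps = sv.amplitudes
    idx = np.arange(len(amps))
    occ = _bit(idx, spin_orbital) == 1
    src = idx[occ]
    dst = src - (1 << spin_orbital)
    below = src & ((1 << spin_orbital) - 1)
    cnt = np.array([bin(int(b)).count("1") for b in below])
    sign = np.where(cnt % 2, -1.0, 1.0)
    out = np.zeros_like(amps)
    out[dst] = sign * amps[src]
    return out


def spin_orbital_rdms(sv: Statevector):
    """Spin-orbital 1- and 2-RDMs by direct statevector contraction:
    D1[P,Q] = <a+_P a_Q>, D2[P,Q,R,S] = <a+_P a+_Q a_S a_R>."""
    n2 = 2 * sv.n_orb
    a = np.array([annihilate(sv, p) for p in range(n2)])
    d1 = a @ a.T
    b = np.zeros((n2, n2, len(sv.amplitudes)))
    for p in range(n2):
        svp = Statevector(a[p], sv.n_orb)
        for q in range(n2):
            b[p, q] = annihilate(svp, q)
    # D2[P,Q,R,S] = <a+_P a+_Q a_S a_R> = (a_Q a_P psi) . (a_S a_R psi)
    #             = b[P,Q] . b[R,S]
    flat = b.reshape(n2 * n2, -1)
    d2 = (flat @ flat.T).reshape(n2, n2, n2, n2)
    return d1, d2


def compute_rdms(sv: Statevector) -> RDMPair:
    """Spin-summed (gamma, Gamma) in the package convention."""
    n = sv.n_orb
    d1, d2 = spin_orbital_rdms(sv)
    gamma = d1[:n, :n] + d1[n:, n:]
    # Gamma_tt'uu' = sum_st <t_s+ u_t+ u'_t t'_s> = sum D2[(t,s),(u,t),(t',s),(u',t)]
    gamma2 = np.zeros((n, n, n, n))
    for s_off in (0, n):
        for t_off in (0, n):
            gamma2 += d2[s_off:s_off + n, t_off:t_off + n,
                         s_off:s_off + n, t_off:t_off + n].transpose(0, 2, 1, 3)
    n_elec = int(round(np.trace(gamma)))
    return RDMPair(gamma, gamma2, n_elec)


def expectation(sv: Statevector, ham) -> float:
    """<psi|H_active|psi> + e_core via the determinant-sector Hamiltonian
    (independent of the RDM contraction route)."""
    from .solvers import sector_hamiltonian, sector_indices

    n = sv.n_orb
    if ham.n_active_orb != n:
        raise ValueError("Hamiltonian dimensioned for a different active space")
    n_alpha = round(sv.number_expectation("alpha"))
    n_beta = round(sv.number_expectation("beta"))
    h, strings_a, strings_b = sector_hamiltonian(ham, int(n_alpha), int(n_beta))
    sel = sector_indices(n, strings_a, strings_b)
    psi = sv.amplitudes[sel]
    leak = sv.norm ** 2 - float(psi @ psi)
    if leak > 1e-9:
        raise ValueError("statevector is not particle-number definite")
    return float(psi @ (h @ psi)) + ham.e_core
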