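"""Ground-state solvers over an embedded active-space Hamiltonian.

CASCI: exact diagonalization in the fixed (n_alpha, n_beta) determinant
sector, used both as a production solver and as the reference against which
the VQE is benchmarked. The determinant basis uses the same occupation-number
phase convention as the Jordan-Wigner simulator, so sector amplitudes can be
exchanged between the two without sign bookkeeping.

VQE: L-BFGS-B minimization of the statevector expectation value of the
k-muCJ ansatz starting from the RHF reference (all parameters zero), with
central finite-difference gradients and optional seeded random restarts.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import scipy.optimize
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .active_space import ActiveHamiltonian
from . import qsim
from .qsim import AnsatzParams, RDMPair, Statevector

__all__ = [
    "CASCIResult",
    "VQEResult",
    "casci_solve",
    "vqe_objective",
    "vqe_optimize",
    "sector_hamiltonian",
    "sector_indices",
    "DeterminantSpaceError",
]

_DIM_CAP = 1_000_000


class DeterminantSpaceError(RuntimeError):
    pass


def _strings(n_orb: int, n_elec: int) -> np.ndarray:
    """All n_orb-bit strings with n_elec bits set, ascending."""
    out = []
    for occ in combinations(range(n_orb), n_elec):
        s = 0
        for o in occ:
            s |= 1 << o
        out.append(s)
    return np.array(sorted(out), dtype=np.int64)


def _excitation_matrix(strings: np.ndarray, n_orb: int, p: int, q: int):
    """Sparse matrix of a+_p a_q within one spin register's string list,
    Jordan-Wigner phase convention."""
    index = {int(s): i for i, s in enumerate(strings)}
    rows, cols, vals = [], [], []
    for j, s in enumerate(strings):
        s = int(s)
        if not (s >> q) & 1:
            continue
        s1 = s & ~(1 << q)
        sign = (-1) ** bin(s & ((1 << q) - 1)).count("1")
        if (s1 >> p) & 1:
            continue
        s2 = s1 | (1 << p)
        sign *= (-1) ** bin(s1 & ((1 << p) - 1)).count("1")
        rows.append(index[s2])
        cols.append(j)
        vals.append(float(sign))
    n = len(strings)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def _spin_summed_e(ham_orbs: int, strings_a, strings_b):
    """E_pq = e^alpha_pq x I + I x e^beta_pq over the sector basis
    (determinant index = ia * n_b + ib)."""
    na, nb = len(strings_a), len(strings_b)
    ia_id = sp.identity(na, format="csr")
    ib_id = sp.identity(nb, format="csr")
    e = {}
    for p in range(ham_orbs):
        for q in range(ham_orbs):
            ea = _excitation_matrix(strings_a, ham_orbs, p, q)
            eb = _excitation_matrix(strings_b, ham_orbs, p, q)
            e[p, q] = sp.kron(ea, ib_id, format="csr") \
                + sp.kron(ia_id, eb, format="csr")
    return e


def sector_hamiltonian(ham: ActiveHamiltonian, n_alpha: int, n_beta: int):
    """Dense active Hamiltonian (without e_core) in the determinant sector,
    plus the alpha/beta string lists defining the basis order."""
    n = ham.n_active_orb
    strings_a = _strings(n, n_alpha)
    strings_b = _strings(n, n_beta)
    dim = len(strings_a) * len(strings_b)
    if dim > _DIM_CAP:
        raise DeterminantSpaceError(
            f"determinant space of dimension {dim} exceeds the cap {_DIM_CAP}"
        )
    e = _spin_summed_e(n, strings_a, strings_b)
    h = sp.csr_matrix((dim, dim))
    for p in range(n):
        for q in range(n):
            if abs(ham.h_tilde[p, q]) > 1e-15:
                h = h + ham.h_tilde[p, q] * e[p, q]
    # 1/2 sum g_pqrs (E_pq E_rs - delta_qr E_ps)
    for p in range(n):
        for q in range(n):
            epq = e[p, q]
            for r in range(n):
                for s in range(n):
                    g = ham.eri_active[p, q, r, s]
                    if abs(g) < 1e-15:
                        continue
                    h = h + 0.5 * g * (epq @ e[r, s])
                    if q == r:
                        h = h - 0.5 * g * e[p, s]
    return h.toarray(), strings_a, strings_b


def sector_indices(n_orb: int, strings_a, strings_b) -> np.ndarray:
    """Full-register Jordan-Wigner indices of the sector determinants, in
    the (ia major, ib minor) basis order used by sector_hamiltonian."""
    ia = np.repeat(strings_a, len(strings_b))
    ib = np.tile(strings_b, len(strings_a))
    return (ib << n_orb) | ia


@dataclass
class CASCIResult:
    energy: float              # total: active eigenvalue + e_core
    ci_vector: np.ndarray      # sector amplitudes
    rdms: RDMPair
    strings_a: np.ndarray
    strings_b: np.ndarray


@dataclass
class VQEResult:
    params: AnsatzParams
    energy: float
    rdms: RDMPair
    n_iterations: int
    trace: np.ndarray          # best-so-far energy per evaluation
    converged: bool
    statevector: Statevector


def _sector_rdms(ci: np.ndarray, n_orb: int, strings_a, strings_b) -> RDMPair:
    e = _spin_summed_e(n_orb, strings_a, strings_b)
    gamma = np.zeros((n_orb, n_orb))
    vec = {}
    for p in range(n_orb):
        for q in range(n_orb):
            vec[p, q] = e[p, q] @ ci
            gamma[p, q] = float(ci @ vec[p, q])
    gamma2 = np.zeros((n_orb,) * 4)
    for p in range(n_orb):
        for q in range(n_orb):
            bra = vec[q, p]  # (E_pq)^T ci
            for r in range(n_orb):
                for s in range(n_orb):
                    val = float(bra @ vec[r, s])
                    if q == r:
                        val -= gamma[p, s]
                    gamma2[p, q, r, s] = val
    n_elec = int(round(np.trace(gamma)))
    return RDMPair(gamma, gamma2, n_elec)


def casci_solve(ham: ActiveHamiltonian, n_alpha: int | None = None,
                n_beta: int | None = None) -> CASCIResult:
    """Lowest eigenpair of the active Hamiltonian in the fixed spin sector,
    with RDMs from the CI vector."""
    if n_alpha is None:
        n_alpha = ham.n_active_elec // 2
    if n_beta is None:
        n_beta = ham.n_active_elec - n_alpha
    h, sa, sb = sector_hamiltonian(ham, n_alpha, n_beta)
    dim = h.shape[0]
    if dim <= 1500:
        w, v = np.linalg.eigh(h)
        e0, c0 = float(w[0]), v[:, 0]
    else:
        w, v = spla.eigsh(sp.csr_matrix(h), k=1, which="SA")
        e0, c0 = float(w[0]), v[:, 0]
    if c0[np.argmax(np.abs(c0))] < 0:
        c0 = -c0
    rdms = _sector_rdms(c0, ham.n_active_orb, sa, sb)
    return CASCIResult(e0 + ham.e_core, c0, rdms, sa, sb)


# ---------------------------------------------------------------------------
# VQE
# ---------------------------------------------------------------------------


def _prepare_state(x: np.ndarray, ham: ActiveHamiltonian, k: int) -> Statevector:
    n = ham.n_active_orb
    n_alpha = ham.n_active_elec // 2
    ref = qsim.prepare_reference(n, n_alpha, ham.n_active_elec - n_alpha)
    params = AnsatzParams.from_vector(x, n, k)
    return qsim.apply_mucj(ref, params)


def vqe_objective(params: AnsatzParams, ham: ActiveHamiltonian) -> float:
    """Total energy (incl. e_core) of the muCJ state for given parameters;
    deterministic statevector pipeline."""
    x = params.to_vector()
    return _vqe_objective_vec(x, ham, params.k, _sector_cache(ham))


def _sector_cache(ham: ActiveHamiltonian):
    n_alpha = ham.n_active_elec // 2
    h, sa, sb = sector_hamiltonian(ham, n_alpha, ham.n_active_elec - n_alpha)
    sel = sector_indices(ham.n_active_orb, sa, sb)
    return h, sel


def _vqe_objective_vec(x, ham, k, cache) -> float:
    h, sel = cache
    sv = _prepare_state(x, ham, k)
    psi = sv.amplitudes[sel]
    return float(psi @ (h @ psi)) + ham.e_core


def pad_params(params: AnsatzParams, k: int) -> AnsatzParams:
    """Zero-pad a shallower parameter set to depth ``k``: appended layers are
    identity circuits, so the represented state is unchanged."""
    if k < params.k:
        raise ValueError("cannot pad to a smaller depth")
    n = params.kappa_final.shape[0]
    n_tau = len(qsim.pair_pattern(n))
    extra = [(np.zeros((n, n)), np.zeros(n_tau)) for _ in range(k - params.k)]
    return AnsatzParams(list(params.layers) + extra, params.kappa_final.copy())


def vqe_optimize(ham: ActiveHamiltonian, k: int = 1, seed: int = 0,
                 n_restarts: int = 1, fd_step: float = 1e-5,
                 gtol: float = 1e-6, maxiter: int = 2000,
                 initial: AnsatzParams | None = None) -> VQEResult:
    """L-BFGS-B minimization of the k-muCJ energy.

    The first start is the deterministic zero-parameter point (the RHF
    reference) unless ``initial`` parameters are given (e.g. a shallower
    solution zero-padded to depth k); additional restarts perturb the start
    with seeded Gaussian noise of scale 1e-2 to escape local minima.
    Gradients are central finite differences with step ``fd_step``.
    """
    if k < 1:
        raise ValueError("ansatz depth k must be >= 1")
    n = ham.n_active_orb
    cache = _sector_cache(ham)
    if initial is not None:
        if initial.k != k:
            raise ValueError("initial parameters have the wrong depth")
        x0 = initial.to_vector()
    else:
        x0 = AnsatzParams.zeros(n, k).to_vector()
    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(max(1, n_restarts)):
        x_start = x0 if attempt == 0 else x0 + 0.01 * rng.standard_normal(len(x0))
        trace = []

        def fun(x):
            e = _vqe_objective_vec(x, ham, k, cache)
            trace.append(e)
            return e

        def grad(x):
            g = np.empty_like(x)
            for i in range(len(x)):
                xp = x.copy()
                xp[i] += fd_step
                xm = x.copy()
                xm[i] -= fd_step
                g[i] = (_vqe_objective_vec(xp, ham, k, cache)
                        - _vqe_objective_vec(xm, ham, k, cache)) / (2 * fd_step)
            return g

        res = scipy.optimize.minimize(
            fun, x_start, jac=grad, method="L-BFGS-B",
            options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-13},
        )
        if best is None or res.fun < best[0]:
            best = (res.fun, res.x, res, np.minimum.accumulate(np.array(trace)))
    e_best, x_best, res, trace = best
    sv = _prepare_state(x_best, ham, k)
    sv = Statevector(sv.amplitudes / sv.norm, n)
    rdms = qsim.compute_rdms(sv)
    return VQEResult(
        params=AnsatzParams.from_vector(x_best, n, k),
        energy=float(e_best),
        rdms=rdms,
        n_iterations=int(res.nit),
        trace=trace,
        converged=bool(res.success),
        statevector=sv,
    )
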