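"""Restricted Hartree-Fock with DIIS acceleration.

Deterministic by construction: symmetric orthogonalization, core-Hamiltonian
initial guess, fixed iteration schedule.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SCFState", "ScfConvergenceError", "rhf"]


class ScfConvergenceError(RuntimeError):
    def __init__(self, msg, last_energy):
        super().__init__(msg)
        self.last_energy = last_energy


@dataclass(frozen=True)
class SCFState:
    """Converged RHF solution: MO coefficients, energies, occupation."""

    mo_coeff: np.ndarray     # (n_ao, n_mo)
    mo_energy: np.ndarray    # (n_mo,)
    n_occ: int               # doubly occupied orbitals
    e_total: float           # hartree, includes nuclear repulsion
    converged: bool

    @property
    def density(self) -> np.ndarray:
        """AO density matrix D = 2 C_occ C_occ^T."""
        c = self.mo_coeff[:, : self.n_occ]
        return 2.0 * c @ c.T


def _orthogonalizer(s: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(s)
    if w.min() < 1e-10:
        raise np.linalg.LinAlgError(
            f"overlap matrix is (near-)singular: smallest eigenvalue {w.min():.3e}"
        )
    return v @ np.diag(w ** -0.5) @ v.T


def _fock(h, eri, d):
    j = np.einsum("pqrs,rs->pq", eri, d, optimize=True)
    k = np.einsum("prqs,rs->pq", eri, d, optimize=True)
    return h + j - 0.5 * k


def rhf(s, h, eri, n_elec: int, e_nuc: float,
        e_tol: float = 1e-11, grad_tol: float = 1e-8,
        max_iter: int = 200) -> SCFState:
    """Solve RHF for ``n_elec`` electrons (closed shell) over given AO integrals."""
    if n_elec % 2:
        raise ValueError("RHF requires an even electron count")
    n_occ = n_elec // 2
    n_ao = s.shape[0]
    if n_occ > n_ao:
        raise ValueError(
            f"{n_elec} electrons need {n_occ} orbitals but basis has only {n_ao}"
        )
    x = _orthogonalizer(s)
    # core guess
    f = h.copy()
    e_old = 0.0
    d = None
    diis_f: list[np.ndarray] = []
    diis_e: list[np.ndarray] = []
    e_elec = 0.0
    for it in range(max_iter):
        fp = x.T @ f @ x
        eps, cp = np.linalg.eigh(fp)
        c = x @ cp
        occ = c[:, :n_occ]
        d = 2.0 * occ @ occ.T
        f = _fock(h, eri, d)
        e_elec = 0.5 * np.sum(d * (h + f))
        grad = f @ d @ s - s @ d @ f
        gnorm = np.linalg.norm(grad) / max(n_ao, 1)
        if abs(e_elec - e_old) < e_tol and gnorm < grad_tol and it > 0:
            return SCFState(c, eps, n_occ, e_elec + e_nuc, True)
        e_old = e_elec
        # DIIS
        diis_f.append(f.copy())
        diis_e.append(x.T @ grad @ x)
        if len(diis_f) > 8:
            diis_f.pop(0)
            diis_e.pop(0)
        if len(diis_f) >= 2:
            m = len(diis_f)
            bmat = -np.ones((m + 1, m + 1))
            bmat[m, m] = 0.0
            for i in range(m):
                for j in range(m):
                    bmat[i, j] = np.sum(diis_e[i] * diis_e[j])
            rhs = np.zeros(m + 1)
            rhs[m] = -1.0
            try:
                coefs = np.linalg.solve(bmat, rhs)[:m]
                f = sum(ci * fi for ci, fi in zip(coefs, diis_f))
            except np.linalg.LinAlgError:
                pass
    raise ScfConvergenceError(
        f"RHF did not converge in {max_iter} iterations "
        f"(last E_elec = {e_elec:.10f})",
        e_elec + e_nuc,
    )
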