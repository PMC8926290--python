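"""Core/active/virtual partitioning and the embedded active-space Hamiltonian.

The monomer's canonical RHF orbitals are split into ``N_c`` doubly occupied
core orbitals, ``N_a`` active orbitals and the remaining virtuals. Core
electrons are folded into a one-electron potential (core Coulomb/exchange),
leaving an active-space Hamiltonian

    H_act = e_core + sum_tt' h~_tt' E_tt' + 1/2 sum (tt'|uu') e_tt'uu'

whose ground state is solved by CASCI or VQE. ``e_core`` is fixed by the
requirement that e_core plus the active-space expectation value reproduces
the total electronic + nuclear energy.

Spin-summed density-matrix conventions used throughout the package:

    gamma_pp'    = < p+_s p'_s >  summed over spin s
    Gamma_pp'qq' = < p+_s q+_t q'_t p'_s > summed over s,t

so that  E = e_core + sum h~ gamma + 1/2 sum (tt'|uu') Gamma_tt'uu'.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .integrals import MonomerIntegrals, SCFState

__all__ = [
    "OrbitalPartition",
    "CoreEnvironment",
    "ActiveHamiltonian",
    "select_window",
    "build_core_environment",
    "build_active_hamiltonian",
    "assemble_full_space_rdms",
    "ao_density",
    "pair_cumulant",
]


@dataclass(frozen=True)
class OrbitalPartition:
    """Ordered index lists of core/active/virtual canonical orbitals."""

    core: tuple[int, ...]
    active: tuple[int, ...]
    virtual: tuple[int, ...]
    n_active_elec: int

    def __post_init__(self):
        all_idx = sorted(self.core + self.active + self.virtual)
        if all_idx != list(range(len(all_idx))):
            raise ValueError("core/active/virtual lists must partition 0..n-1")
        if self.n_active_elec % 2:
            raise ValueError("active electron count must be even (singlet)")
        if not (0 < self.n_active_elec <= 2 * len(self.active)):
            raise ValueError("active electron count incompatible with space size")

    @property
    def n_core(self) -> int:
        return len(self.core)

    @property
    def n_active(self) -> int:
        return len(self.active)

    @property
    def n_orb(self) -> int:
        return len(self.core) + len(self.active) + len(self.virtual)


@dataclass(frozen=True)
class CoreEnvironment:
    """AO-basis core density and the core-folded one-electron operator."""

    d_core: np.ndarray      # occupation-2 core density
    j_core: np.ndarray      # Coulomb of d_core
    k_core: np.ndarray      # exchange of d_core
    h_tilde_ao: np.ndarray  # h + j_core - k_core/2
    e_core: float           # hartree, includes nuclear repulsion


@dataclass(frozen=True)
class ActiveHamiltonian:
    """Embedded Hamiltonian over the active MOs."""

    h_tilde: np.ndarray     # (N_a, N_a)
    eri_active: np.ndarray  # (tt'|uu')
    e_core: float
    n_active_elec: int
    n_active_orb: int


def select_window(scf: SCFState, n_elec: int, n_orb: int) -> OrbitalPartition:
    """(n_elec, n_orb) active window around the Fermi level of canonical RHF
    orbitals: HOMO-(n_elec/2-1) .. LUMO+(n_orb-n_elec/2-1) by energy order.

    Degenerate frontier orbitals are resolved deterministically by
    (energy, index) order, which is the order `mo_energy` already has.
    """
    if n_elec % 2:
        raise ValueError("active electron count must be even")
    n_mo = len(scf.mo_energy)
    first = scf.n_occ - n_elec // 2
    last = scf.n_occ + (n_orb - n_elec // 2)  # exclusive
    if first < 0 or last > n_mo:
        raise ValueError(
            f"({n_elec}e,{n_orb}o) window does not fit: occupied={scf.n_occ}, "
            f"n_mo={n_mo}"
        )
    return OrbitalPartition(
        core=tuple(range(first)),
        active=tuple(range(first, last)),
        virtual=tuple(range(last, n_mo)),
        n_active_elec=n_elec,
    )


def build_core_environment(ints: MonomerIntegrals, scf: SCFState,
                           part: OrbitalPartition) -> CoreEnvironment:
    """Fold the core orbitals into an effective one-electron operator."""
    c_core = scf.mo_coeff[:, list(part.core)]
    d_core = 2.0 * c_core @ c_core.T
    j_core = np.einsum("pqrs,rs->pq", ints.eri, d_core, optimize=True)
    k_core = np.einsum("prqs,rs->pq", ints.eri, d_core, optimize=True)
    h_tilde_ao = ints.core_h + j_core - 0.5 * k_core
    e_core = 0.5 * np.sum(d_core * (ints.core_h + h_tilde_ao)) \
        + ints.nuclear_repulsion
    return CoreEnvironment(d_core, j_core, k_core, h_tilde_ao, float(e_core))


def build_active_hamiltonian(ints: MonomerIntegrals, scf: SCFState,
                             part: OrbitalPartition) -> ActiveHamiltonian:
    """Active-MO one-electron matrix and ERIs plus the scalar core energy."""
    env = build_core_environment(ints, scf, part)
    c_act = scf.mo_coeff[:, list(part.active)]
    h_tilde = c_act.T @ env.h_tilde_ao @ c_act
    eri_act = np.einsum("pqrs,pt,qu,rv,sw->tuvw", ints.eri,
                        c_act, c_act, c_act, c_act, optimize=True)
    return ActiveHamiltonian(h_tilde, eri_act, env.e_core,
                             part.n_active_elec, part.n_active)


def pair_cumulant(gamma: np.ndarray, gamma2: np.ndarray) -> np.ndarray:
    """Lambda = Gamma - (gamma x gamma - 1/2 gamma ^ gamma): vanishes for a
    closed-shell determinant and, embedded over the active block, carries all
    correlation beyond the mean field."""
    return gamma2 - (np.einsum("pq,rs->pqrs", gamma, gamma)
                     - 0.5 * np.einsum("ps,rq->pqrs", gamma, gamma))


def assemble_full_space_rdms(gamma_act: np.ndarray, gamma2_act: np.ndarray,
                             part: OrbitalPartition):
    """Full-orbital-space spin-summed (gamma, Gamma) from active-space ones.

    Core block of gamma is 2*delta; the 2-RDM follows the closed-shell-core
    block structure, which is exactly gamma x gamma - 1/2 gamma ^ gamma plus
    the active-only pair cumulant.
    """
    n = part.n_orb
    n_a = part.n_active
    if gamma_act.shape != (n_a, n_a):
        raise ValueError("active 1-RDM dimension mismatch with partition")
    if gamma2_act.shape != (n_a, n_a, n_a, n_a):
        raise ValueError("active 2-RDM dimension mismatch with partition")
    gamma = np.zeros((n, n))
    for i in part.core:
        gamma[i, i] = 2.0
    act = list(part.active)
    gamma[np.ix_(act, act)] = gamma_act
    gamma2 = (np.einsum("pq,rs->pqrs", gamma, gamma)
              - 0.5 * np.einsum("ps,rq->pqrs", gamma, gamma))
    lam = pair_cumulant(gamma_act, gamma2_act)
    gamma2[np.ix_(act, act, act, act)] += lam
    return gamma, gamma2


def ao_density(scf: SCFState, part: OrbitalPartition,
               gamma_act: np.ndarray) -> np.ndarray:
    """Total AO one-particle density: doubly occupied core plus the active
    1-RDM mapped through the active MO coefficients."""
    c_core = scf.mo_coeff[:, list(part.core)]
    c_act = scf.mo_coeff[:, list(part.active)]
    return 2.0 * c_core @ c_core.T + c_act @ gamma_act @ c_act.T
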