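"""First-order symmetry-adapted perturbation theory from monomer RDMs.

Electrostatics (E1_pol) is the classical Coulomb interaction of the two
monomer charge distributions. The first-order exchange energy in the S^2
approximation (second order in the intermolecular overlap) is evaluated in
the density-matrix formulation: with the single-exchange operator
P = sum_{i in A, j in B} P_ij and the interaction operator V distributed as

    v(i,j) = 1/r_ij + v_B(r_i)/N_B + v_A(r_j)/N_A + V_nn/(N_A N_B),

one has  E1_exch(S^2) = -<V P> + E1_pol <P>.  Expanding <V P> by electron
coincidences gives five pieces that involve at most the spin-summed one- and
two-particle RDMs of each (singlet) monomer:

    T1: gamma_A x gamma_B      (single exchange through both densities)
    T2: Gamma_A x gamma_B
    T3: gamma_A x Gamma_B
    T4: Gamma_A x Gamma_B
    T5: +E1_pol <P>, with <P> = 1/2 Tr(gamma_A S gamma_B S^T)

The production path exploits the core/active block structure through the
pair-cumulant split Gamma = gamma x gamma - 1/2 gamma ^ gamma + Lambda
(Lambda supported on active^4 only) and contracts everything in the monomer
MO basis restricted to occupied+active ranges, so generalized two-electron
quantities are only ever formed with O(N_a^4) active storage. A naive dense
full-space contraction of the same five pieces in the AO basis serves as the
oracle for small systems.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .constants import HARTREE_TO_KCALMOL
from .active_space import (ActiveHamiltonian, OrbitalPartition, ao_density,
                           assemble_full_space_rdms, build_active_hamiltonian,
                           pair_cumulant, select_window)
from .integrals import (CrossIntegrals, MonomerIntegrals, SCFState,
                        compute_cross_integrals, compute_monomer_integrals,
                        run_rhf)
from .molsys import DimerSystem
from .qsim import RDMPair

__all__ = [
    "GeneralizedJK",
    "ExchangeBreakdown",
    "SAPTResult",
    "MonomerTreatment",
    "e1_pol",
    "build_generalized_jk",
    "e1_exch_s2",
    "e1_exch_s2_oracle",
    "rhf_rdms",
    "rhf_partition",
    "sapt_report",
]


def _check_trace(d: np.ndarray, s_own: np.ndarray, n_elec: int, label: str):
    tr = float(np.sum(d * s_own))
    if abs(tr - n_elec) > 1e-6:
        raise ValueError(
            f"AO density of monomer {label} integrates to {tr:.8f} electrons, "
            f"expected {n_elec}"
        )


def e1_pol(gamma_a_ao: np.ndarray, gamma_b_ao: np.ndarray,
           cross: CrossIntegrals,
           s_aa: Optional[np.ndarray] = None,
           s_bb: Optional[np.ndarray] = None) -> float:
    """Classical electrostatic energy of the two monomer charge clouds:
    electron-electron + electron-nucleus (both directions) + nucleus-nucleus.

    If the monomer AO overlap matrices are given, the densities' electron
    counts are validated against the declared ones.
    """
    if s_aa is not None:
        _check_trace(gamma_a_ao, s_aa, cross.n_a_elec, "A")
    if s_bb is not None:
        _check_trace(gamma_b_ao, s_bb, cross.n_b_elec, "B")
    e_ee = float(np.einsum("pqrs,pq,rs->", cross.eri_aabb,
                           gamma_a_ao, gamma_b_ao, optimize=True))
    e_en = float(np.sum(gamma_a_ao * cross.v_b_on_a))
    e_ne = float(np.sum(gamma_b_ao * cross.v_a_on_b))
    return e_ee + e_en + e_ne + cross.v_nn


@dataclass(frozen=True)
class GeneralizedJK:
    """Generalized Coulomb/exchange matrices built from the dressed
    intermolecular two-electron kernel (cross ERIs plus overlap- and
    nuclear-attraction dressing with the 1/N electron-count normalizations).
    """

    j_tilde: np.ndarray   # square matrix over the receiving monomer's AOs
    k_tilde: np.ndarray   # mixed (A x B) exchange matrix


def build_generalized_jk(cross: CrossIntegrals, gamma_other_ao: np.ndarray,
                         s_own: np.ndarray, side: str = "a") -> GeneralizedJK:
    """J~ and K~ for the monomer on ``side`` generated by the partner's
    density. With the overlap and nuclear dressings zeroed these reduce to
    the plain cross-ERI Coulomb/exchange builds."""
    na, nb = cross.n_a_elec, cross.n_b_elec
    if side == "a":
        d_b = gamma_other_ao
        j = np.einsum("pqrs,rs->pq", cross.eri_aabb, d_b, optimize=True)
        j += cross.v_b_on_a
        j += s_own * (float(np.sum(d_b * cross.v_a_on_b)) / na)
        j += s_own * (cross.v_nn / na)
        # mixed exchange matrix: dressed kernel contracted with P = D_A s D_B
        # is performed by the caller; here K~[mu,nu] = sum v~x[mu nu; m n] X[m,n]
        # with X = s_ab-projected partner density
        x = cross.s_ab @ d_b  # (A x B) -> used as the half-transformed density
        k = np.einsum("pqrs,rs->pq", _vx_kernel(cross), x, optimize=True)
        return GeneralizedJK(j, k)
    elif side == "b":
        d_a = gamma_other_ao
        j = np.einsum("pqrs,pq->rs", cross.eri_aabb, d_a, optimize=True)
        j += cross.v_a_on_b
        j += s_own * (float(np.sum(d_a * cross.v_b_on_a)) / nb)
        j += s_own * (cross.v_nn / nb)
        x = d_a @ cross.s_ab
        k = np.einsum("pqrs,pq->rs", _vx_kernel(cross), x, optimize=True)
        return GeneralizedJK(j, k)
    raise ValueError("side must be 'a' or 'b'")


def _vx_kernel(cross: CrossIntegrals) -> np.ndarray:
    """Dressed mixed-distribution kernel v~x[mu nu; mu' nu']: the (AB|AB)
    ERI class plus overlap/nuclear dressing with 1/N normalizations."""
    na, nb = cross.n_a_elec, cross.n_b_elec
    w = cross.eri_abab.copy()
    w += np.einsum("pq,rs->pqrs", cross.v_b_ab, cross.s_ab) / nb
    w += np.einsum("pq,rs->pqrs", cross.s_ab, cross.v_a_ab) / na
    w += np.einsum("pq,rs->pqrs", cross.s_ab, cross.s_ab) \
        * (cross.v_nn / (na * nb))
    return w


@dataclass(frozen=True)
class ExchangeBreakdown:
    """E1_exch(S^2) and its five-term decomposition (hartree)."""

    t1: float
    t2: float
    t3: float
    t4: float
    t5: float
    intermediates: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        return self.t1 + self.t2 + self.t3 + self.t4 + self.t5


def _restricted_mo(cross: CrossIntegrals, scf_a: SCFState, scf_b: SCFState,
                   part_a: OrbitalPartition, part_b: OrbitalPartition):
    """Transform every cross block to the monomer-MO ranges that can carry
    density (core+active); virtuals never enter the first-order expressions."""
    occ_a = list(part_a.core) + list(part_a.active)
    occ_b = list(part_b.core) + list(part_b.active)
    ca = scf_a.mo_coeff[:, occ_a]
    cb = scf_b.mo_coeff[:, occ_b]
    mo = {
        "S": ca.T @ cross.s_ab @ cb,
        "vB_aa": ca.T @ cross.v_b_on_a @ ca,
        "vA_bb": cb.T @ cross.v_a_on_b @ cb,
        "vA_ab": ca.T @ cross.v_a_ab @ cb,
        "vB_ab": ca.T @ cross.v_b_ab @ cb,
        "g_aabb": np.einsum("pqrs,pt,qu,rv,sw->tuvw", cross.eri_aabb,
                            ca, ca, cb, cb, optimize=True),
        "g_abab": np.einsum("pqrs,pt,qu,rv,sw->tuvw", cross.eri_abab,
                            ca, cb, ca, cb, optimize=True),
        "g_aaab": np.einsum("pqrs,pt,qu,rv,sw->tuvw", cross.eri_aaab,
                            ca, ca, ca, cb, optimize=True),
        "g_abbb": np.einsum("pqrs,pt,qu,rv,sw->tuvw", cross.eri_abbb,
                            ca, cb, cb, cb, optimize=True),
    }
    return mo, len(part_a.core), len(part_b.core)


def _occ_gamma(part: OrbitalPartition, gamma_act: np.ndarray) -> np.ndarray:
    """gamma over the core+active MO range: 2 on core, active 1-RDM block."""
    n = part.n_core + part.n_active
    g = np.zeros((n, n))
    for i in range(part.n_core):
        g[i, i] = 2.0
    g[part.n_core:, part.n_core:] = gamma_act
    return g


def e1_exch_s2(rdms_a: RDMPair, rdms_b: RDMPair,
               part_a: OrbitalPartition, part_b: OrbitalPartition,
               scf_a: SCFState, scf_b: SCFState,
               cross: CrossIntegrals) -> ExchangeBreakdown:
    """S^2-approximate first-order exchange energy with the active-space
    optimized contractions (cumulant split, restricted MO ranges, named
    overlap-dressed intermediates)."""
    na, nb = cross.n_a_elec, cross.n_b_elec
    mo, nca, ncb = _restricted_mo(cross, scf_a, scf_b, part_a, part_b)
    ga = _occ_gamma(part_a, rdms_a.gamma)
    gb = _occ_gamma(part_b, rdms_b.gamma)
    lam_a = pair_cumulant(rdms_a.gamma, rdms_a.gamma2)
    lam_b = pair_cumulant(rdms_b.gamma, rdms_b.gamma2)
    s = mo["S"]
    vnn = cross.v_nn
    act_a = slice(nca, nca + part_a.n_active)
    act_b = slice(ncb, ncb + part_b.n_active)

    # permutation expectation <P> = 1/2 Tr(gA S gB S^T)
    p_perm = 0.5 * float(np.trace(ga @ s @ gb @ s.T))
    e_pol = e1_pol(ao_density(scf_a, part_a, rdms_a.gamma),
                   ao_density(scf_b, part_b, rdms_b.gamma), cross)

    # ---- T1: gamma_A gamma_B through the dressed mixed kernel -------------
    ident_a = np.eye(ga.shape[0])
    ident_b = np.eye(gb.shape[0])
    w1 = (mo["g_abab"]
          + np.einsum("Pq,pQ->PqpQ", mo["vB_ab"], s) / nb
          + np.einsum("pQ,Pq->PqpQ", mo["vA_ab"], s) / na
          + np.einsum("Pq,pQ->PqpQ", s, s) * (vnn / (na * nb)))
    t1 = 0.5 * float(np.einsum("pP,qQ,PqpQ->", ga, gb, w1, optimize=True))

    # ---- T2: Gamma_A gamma_B ---------------------------------------------
    # overlap-dressed partner density SB[u, B] = (S gamma_B)[u, B]
    sb = s @ gb
    w2 = (mo["g_aaab"]
          + np.einsum("tT,UB->tTUB", mo["vB_aa"], s) / nb
          + np.einsum("tT,UB->tTUB", ident_a, mo["vA_ab"]) / na
          + np.einsum("tT,UB->tTUB", ident_a, s) * (vnn / (na * nb)))
    x2 = np.einsum("tTUB,uB->tTUu", w2, sb, optimize=True)
    t2 = 0.5 * float(np.einsum("tT,uU,tTUu->", ga, ga, x2, optimize=True))
    t2 += -0.25 * float(np.einsum("tU,uT,tTUu->", ga, ga, x2, optimize=True))
    t2 += 0.5 * float(np.einsum("tTuU,tTUu->", lam_a,
                                x2[act_a, act_a, act_a, act_a], optimize=True))

    # ---- T3: gamma_A Gamma_B (mirror of T2) -------------------------------
    gs = ga @ s  # GS[T, c]
    w3 = (mo["g_abbb"]
          + np.einsum("TC,bB->TCbB", mo["vB_ab"], ident_b) / nb
          + np.einsum("TC,bB->TCbB", s, mo["vA_bb"]) / na
          + np.einsum("TC,bB->TCbB", s, ident_b) * (vnn / (na * nb)))
    x3 = np.einsum("Tc,TCbB->cCbB", gs, w3, optimize=True)
    t3 = 0.5 * float(np.einsum("bB,cC,cCbB->", gb, gb, x3, optimize=True))
    t3 += -0.25 * float(np.einsum("bC,cB,cCbB->", gb, gb, x3, optimize=True))
    t3 += 0.5 * float(np.einsum("bBcC,cCbB->", lam_b,
                                x3[act_b, act_b, act_b, act_b], optimize=True))

    # ---- T4: Gamma_A Gamma_B ---------------------------------------------
    vt = (mo["g_aabb"]
          + np.einsum("tT,bB->tTbB", mo["vB_aa"], ident_b) / nb
          + np.einsum("tT,bB->tTbB", ident_a, mo["vA_bb"]) / na
          + np.einsum("tT,bB->tTbB", ident_a, ident_b) * (vnn / (na * nb)))
    a_parts = [  # (coefficient, subscripts, operands, active-only?)
        (1.0, "tT,uU", (ga, ga), False),
        (-0.5, "tU,uT", (ga, ga), False),
        (1.0, "tTuU", (lam_a,), True),
    ]
    b_parts = [
        (1.0, "bB,cC", (gb, gb), False),
        (-0.5, "bC,cB", (gb, gb), False),
        (1.0, "bBcC", (lam_b,), True),
    ]
    t4 = 0.0
    for ca_coef, sub_a, ops_a, act_only_a in a_parts:
        for cb_coef, sub_b, ops_b, act_only_b in b_parts:
            s_u = s[act_a] if act_only_a else s
            s_uu = s[act_a] if act_only_a else s
            v_slice = vt
            if act_only_a:
                v_slice = v_slice[act_a, act_a]
            if act_only_b:
                v_slice = v_slice[:, :, act_b, act_b]
                s_u = s_u[:, act_b]
                s_uu = s_uu[:, act_b]
            val = np.einsum(
                f"{sub_a},{sub_b},uC,Uc,tTbB->",
                *ops_a, *ops_b, s_u, s_uu, v_slice, optimize=True)
            t4 += 0.5 * ca_coef * cb_coef * float(val)

    t5 = e_pol * p_perm
    return ExchangeBreakdown(
        t1=-t1, t2=-t2, t3=-t3, t4=-t4, t5=t5,
        intermediates={"p_perm": p_perm, "e_pol": e_pol},
    )


def e1_exch_s2_oracle(gamma_a_ao: np.ndarray, gamma2_a_ao: np.ndarray,
                      gamma_b_ao: np.ndarray, gamma2_b_ao: np.ndarray,
                      cross: CrossIntegrals,
                      s_aa: np.ndarray, s_bb: np.ndarray,
                      size_cap: int = 40) -> float:
    """Dense full-space contraction of the S^2 exchange in the AO basis: no
    cumulant split, no block factorization, full 2-RDM tensors. Ground truth
    for the optimized path on systems small enough for O(N^4) tensors."""
    n_a = gamma_a_ao.shape[0]
    n_b = gamma_b_ao.shape[0]
    if max(n_a, n_b) > size_cap:
        raise MemoryError(
            f"oracle limited to {size_cap} AOs per monomer (got {n_a}, {n_b})"
        )
    na, nb = cross.n_a_elec, cross.n_b_elec
    s = cross.s_ab
    vnn = cross.v_nn
    e_pol = e1_pol(gamma_a_ao, gamma_b_ao, cross)
    p_perm = 0.5 * float(np.trace(gamma_a_ao @ s @ gamma_b_ao @ s.T))

    w1 = (cross.eri_abab
          + np.einsum("Pq,pQ->PqpQ", cross.v_b_ab, s) / nb
          + np.einsum("pQ,Pq->PqpQ", cross.v_a_ab, s) / na
          + np.einsum("Pq,pQ->PqpQ", s, s) * (vnn / (na * nb)))
    t1 = 0.5 * np.einsum("pP,qQ,PqpQ->", gamma_a_ao, gamma_b_ao, w1,
                         optimize=True)

    w2 = (cross.eri_aaab
          + np.einsum("tT,UB->tTUB", cross.v_b_on_a, s) / nb
          + np.einsum("tT,UB->tTUB", s_aa, cross.v_a_ab) / na
          + np.einsum("tT,UB->tTUB", s_aa, s) * (vnn / (na * nb)))
    t2 = 0.5 * np.einsum("tTuU,bB,ub,tTUB->", gamma2_a_ao, gamma_b_ao,
                         s, w2, optimize=True)

    w3 = (cross.eri_abbb
          + np.einsum("TC,bB->TCbB", cross.v_b_ab, s_bb) / nb
          + np.einsum("TC,bB->TCbB", s, cross.v_a_on_b) / na
          + np.einsum("TC,bB->TCbB", s, s_bb) * (vnn / (na * nb)))
    t3 = 0.5 * np.einsum("bBcC,tT,tc,TCbB->", gamma2_b_ao, gamma_a_ao,
                         s, w3, optimize=True)

    vt = (cross.eri_aabb
          + np.einsum("tT,bB->tTbB", cross.v_b_on_a, s_bb) / nb
          + np.einsum("tT,bB->tTbB", s_aa, cross.v_a_on_b) / na
          + np.einsum("tT,bB->tTbB", s_aa, s_bb) * (vnn / (na * nb)))
    t4 = 0.5 * np.einsum("tTuU,bBcC,uC,Uc,tTbB->", gamma2_a_ao, gamma2_b_ao,
                         s, s, vt, optimize=True)

    return float(-(t1 + t2 + t3 + t4) + e_pol * p_perm)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def rhf_rdms() -> RDMPair:
    """The trivial (2e,1o) active-space RDMs of a closed-shell determinant;
    treating a monomer this way reproduces its RHF density exactly."""
    return RDMPair(np.array([[2.0]]), np.full((1, 1, 1, 1), 2.0), 2)


def rhf_partition(scf: SCFState) -> OrbitalPartition:
    """Degenerate (2e,1o) window: HOMO active, everything below core."""
    return select_window(scf, 2, 1)


@dataclass
class MonomerTreatment:
    """How one monomer's ground state is obtained."""

    solver: str = "rhf"                 # rhf | casci | vqe
    n_active_elec: int = 0
    n_active_orb: int = 0
    k: int = 1
    seed: int = 0
    n_restarts: int = 1

    def validate(self):
        if self.solver not in ("rhf", "casci", "vqe"):
            raise ValueError(f"unknown solver {self.solver!r}")
        if self.solver != "rhf":
            if self.n_active_elec <= 0 or self.n_active_orb <= 0:
                raise ValueError("active-space solvers need (n_elec, n_orb)")


@dataclass
class SAPTResult:
    """First-order SAPT components plus solver metadata."""

    e1_pol: float
    e1_exch_s2: float
    breakdown: ExchangeBreakdown
    monomers: dict
    e_pol_kcal: float = 0.0
    e_exch_kcal: float = 0.0

    def __post_init__(self):
        self.e_pol_kcal = self.e1_pol * HARTREE_TO_KCALMOL
        self.e_exch_kcal = self.e1_exch_s2 * HARTREE_TO_KCALMOL

    def as_dict(self) -> dict:
        b = self.breakdown
        return {
            "e1_pol_hartree": self.e1_pol,
            "e1_exch_s2_hartree": self.e1_exch_s2,
            "e1_pol_kcal_mol": self.e_pol_kcal,
            "e1_exch_s2_kcal_mol": self.e_exch_kcal,
            "exchange_breakdown_hartree": {
                "t1": b.t1, "t2": b.t2, "t3": b.t3, "t4": b.t4, "t5": b.t5,
            },
            "monomers": self.monomers,
        }


def _solve_monomer(ints: MonomerIntegrals, scf: SCFState,
                   treatment: MonomerTreatment):
    from . import solvers

    treatment.validate()
    meta = {"solver": treatment.solver, "rhf_energy": scf.e_total}
    if treatment.solver == "rhf":
        return rhf_partition(scf), rhf_rdms(), meta
    part = select_window(scf, treatment.n_active_elec, treatment.n_active_orb)
    ham = build_active_hamiltonian(ints, scf, part)
    if treatment.solver == "casci":
        res = solvers.casci_solve(ham)
        meta.update(energy=res.energy)
        return part, res.rdms, meta
    res = solvers.vqe_optimize(ham, k=treatment.k, seed=treatment.seed,
                               n_restarts=treatment.n_restarts)
    meta.update(energy=res.energy, k=treatment.k,
                n_iterations=res.n_iterations, converged=res.converged)
    return part, res.rdms, meta


def sapt_report(dimer: DimerSystem,
                treatment_a: MonomerTreatment | None = None,
                treatment_b: MonomerTreatment | None = None,
                cross: CrossIntegrals | None = None) -> SAPTResult:
    """Full pipeline: integrals -> RHF -> active space -> solver -> RDMs ->
    E1_pol + E1_exch(S^2)."""
    treatment_a = treatment_a or MonomerTreatment()
    treatment_b = treatment_b or MonomerTreatment()
    stage = "integrals"
    try:
        ints_a = compute_monomer_integrals(dimer.monomer_a, dimer.basis_a)
        ints_b = compute_monomer_integrals(dimer.monomer_b, dimer.basis_b)
        if cross is None:
            cross = compute_cross_integrals(dimer)
        stage = "scf"
        scf_a = run_rhf(ints_a)
        scf_b = run_rhf(ints_b)
        stage = "solver"
        part_a, rdms_a, meta_a = _solve_monomer(ints_a, scf_a, treatment_a)
        part_b, rdms_b, meta_b = _solve_monomer(ints_b, scf_b, treatment_b)
        stage = "sapt"
        d_a = ao_density(scf_a, part_a, rdms_a.gamma)
        d_b = ao_density(scf_b, part_b, rdms_b.gamma)
        pol = e1_pol(d_a, d_b, cross, ints_a.overlap, ints_b.overlap)
        exch = e1_exch_s2(rdms_a, rdms_b, part_a, part_b, scf_a, scf_b, cross)
    except Exception as exc:
        raise RuntimeError(f"SAPT pipeline failed at stage '{stage}': {exc}") \
            from exc
    return SAPTResult(
        e1_pol=pol, e1_exch_s2=exch.total, breakdown=exch,
        monomers={"a": meta_a, "b": meta_b},
    )
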