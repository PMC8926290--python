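"""AO integrals and restricted Hartree-Fock for monomers and dimers.

This package is the only part of the code that touches the integrals engine;
everything downstream consumes plain numpy tensors. Monomer-centered bases
throughout: each monomer is described in its own AO basis and the
intermolecular operator is represented by rectangular cross blocks.

The two-electron cross integrals come in four distribution classes, written
in chemists' notation with ``a`` AOs on monomer A and ``b`` AOs on monomer B:

=============  ============================
``eri_aabb``   (a a' | b b')
``eri_abab``   (a b | a' b')
``eri_aaab``   (a a' | a'' b)
``eri_abbb``   (a b | b' b'')
=============  ============================

The (AA|BB) class carries the electrostatics; the mixed-distribution classes
appear only in the exchange energy, where orbitals of the two monomers
overlap.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..molsys import DimerSystem, Molecule
from . import _engine as eng
from .basis import BasisSet
from .scf import SCFState, ScfConvergenceError, rhf

__all__ = [
    "MonomerIntegrals",
    "CrossIntegrals",
    "SCFState",
    "ScfConvergenceError",
    "compute_monomer_integrals",
    "compute_cross_integrals",
    "run_rhf",
    "supermolecular_rhf_interaction",
]


@dataclass
class MonomerIntegrals:
    """All intra-monomer AO integrals plus bookkeeping."""

    overlap: np.ndarray
    core_h: np.ndarray             # kinetic + attraction to own nuclei
    eri: np.ndarray                # (pq|rs), chemists' notation, dense
    nuclear_repulsion: float
    n_basis: int
    mol: Molecule
    basis: BasisSet


@dataclass
class CrossIntegrals:
    """Every intermolecular AO-basis ingredient of the interaction operator."""

    s_ab: np.ndarray               # <a|b>
    v_a_on_b: np.ndarray           # <b|V_A|b'> : A's nuclei in B's basis
    v_b_on_a: np.ndarray           # <a|V_B|a'>
    v_a_ab: np.ndarray             # <a|V_A|b>  : mixed blocks for exchange
    v_b_ab: np.ndarray             # <a|V_B|b>
    eri_aabb: np.ndarray
    eri_abab: np.ndarray
    eri_aaab: np.ndarray
    eri_abbb: np.ndarray
    v_nn: float                    # intermolecular nuclear repulsion
    n_a_elec: int
    n_b_elec: int

    @property
    def eri_cross(self) -> np.ndarray:
        """Alias for the (a a'|b b') class."""
        return self.eri_aabb


def compute_monomer_integrals(mol: Molecule, basis: str) -> MonomerIntegrals:
    """Dense AO integrals for one monomer in its own basis."""
    bas = BasisSet(mol, basis)
    s = eng.overlap(bas, bas)
    w = np.linalg.eigvalsh(s)
    if w.min() < 1e-10:
        raise ValueError(
            f"basis {basis!r} is linearly dependent on this geometry: "
            f"smallest overlap eigenvalue {w.min():.3e}"
        )
    t = eng.kinetic(bas)
    v = eng.nuclear_attraction(bas, bas, mol.atomic_numbers.astype(float),
                               mol.coords)
    pl = eng.PairList(bas, bas, symmetric=True)
    eri = eng.eri_class(pl, pl)
    return MonomerIntegrals(s, t + v, eri, mol.nuclear_repulsion(),
                            bas.n_ao, mol, bas)


def compute_cross_integrals(dimer: DimerSystem,
                            eri_threshold: float = 1e-12) -> CrossIntegrals:
    """All intermolecular integral blocks in monomer-centered bases."""
    mol_a, mol_b = dimer.monomer_a, dimer.monomer_b
    try:
        bas_a = BasisSet(mol_a, dimer.basis_a)
        bas_b = BasisSet(mol_b, dimer.basis_b)
    except ValueError as exc:
        raise ValueError(
            f"basis resolution failed for dimer "
            f"({mol_a.label!r}, {mol_b.label!r}): {exc}"
        ) from exc
    za = mol_a.atomic_numbers.astype(float)
    zb = mol_b.atomic_numbers.astype(float)
    s_ab = eng.overlap_cross(bas_a, bas_b)
    v_b_on_a = eng.nuclear_attraction(bas_a, bas_a, zb, mol_b.coords)
    v_a_on_b = eng.nuclear_attraction(bas_b, bas_b, za, mol_a.coords)
    v_a_ab = eng.nuclear_attraction(bas_a, bas_b, za, mol_a.coords)
    v_b_ab = eng.nuclear_attraction(bas_a, bas_b, zb, mol_b.coords)
    pl_aa = eng.PairList(bas_a, bas_a, symmetric=True)
    pl_bb = eng.PairList(bas_b, bas_b, symmetric=True)
    pl_ab = eng.PairList(bas_a, bas_b, symmetric=False)
    eri_aabb = eng.eri_class(pl_aa, pl_bb, eri_threshold)
    eri_abab = eng.eri_class(pl_ab, pl_ab, eri_threshold)
    eri_aaab = eng.eri_class(pl_aa, pl_ab, eri_threshold)
    eri_abbb = eng.eri_class(pl_ab, pl_bb, eri_threshold)
    return CrossIntegrals(
        s_ab=s_ab, v_a_on_b=v_a_on_b, v_b_on_a=v_b_on_a,
        v_a_ab=v_a_ab, v_b_ab=v_b_ab,
        eri_aabb=eri_aabb, eri_abab=eri_abab,
        eri_aaab=eri_aaab, eri_abbb=eri_abbb,
        v_nn=dimer.nuclear_repulsion_cross(),
        n_a_elec=mol_a.n_electrons, n_b_elec=mol_b.n_electrons,
    )


def run_rhf(ints: MonomerIntegrals, n_elec: int | None = None) -> SCFState:
    """Converged restricted Hartree-Fock over precomputed monomer integrals."""
    if n_elec is None:
        n_elec = ints.mol.n_electrons
    return rhf(ints.overlap, ints.core_h, ints.eri, n_elec,
               ints.nuclear_repulsion)


def _union_integrals(dimer: DimerSystem) -> MonomerIntegrals:
    mol_a, mol_b = dimer.monomer_a, dimer.monomer_b
    combined = Molecule(
        mol_a.elements + mol_b.elements,
        np.vstack([mol_a.coords, mol_b.coords]),
        charge=mol_a.charge + mol_b.charge,
        multiplicity=1,
        label=f"{mol_a.label}+{mol_b.label}",
    )
    bas = BasisSet.merge(BasisSet(mol_a, dimer.basis_a),
                         BasisSet(mol_b, dimer.basis_b),
                         atom_offset=mol_a.n_atoms)
    s = eng.overlap(bas, bas)
    t = eng.kinetic(bas)
    v = eng.nuclear_attraction(bas, bas, combined.atomic_numbers.astype(float),
                               combined.coords)
    pl = eng.PairList(bas, bas, symmetric=True)
    eri = eng.eri_class(pl, pl)
    return MonomerIntegrals(s, t + v, eri, combined.nuclear_repulsion(),
                            bas.n_ao, combined, bas)


def supermolecular_rhf_interaction(dimer: DimerSystem) -> float:
    """E_int = E_AB - E_A - E_B at the frozen dimer geometry, RHF level,
    monomer-centered bases for the monomers (no counterpoise)."""
    ints_ab = _union_integrals(dimer)
    e_ab = run_rhf(ints_ab).e_total
    e_a = run_rhf(compute_monomer_integrals(dimer.monomer_a, dimer.basis_a)).e_total
    e_b = run_rhf(compute_monomer_integrals(dimer.monomer_b, dimer.basis_b)).e_total
    return e_ab - e_a - e_b
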