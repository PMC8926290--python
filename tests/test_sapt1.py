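import numpy as np
import pytest

from saptvqe.active_space import (ao_density, assemble_full_space_rdms,
                                  build_active_hamiltonian, select_window)
from saptvqe.integrals import compute_cross_integrals
from saptvqe.molsys import DimerSystem, make_toy_dimer, make_water_dimer
from saptvqe.qsim import RDMPair
from saptvqe.sapt1 import (MonomerTreatment, build_generalized_jk, e1_exch_s2,
                           e1_exch_s2_oracle, e1_pol, rhf_partition, rhf_rdms,
                           sapt_report)
from saptvqe.solvers import casci_solve

from .oracles import (TwoElectronMonomerSystem, heitler_london_interaction,
                      scale_cross)


def _full_ao_rdms(scf, part, rdms):
    gf, g2f = assemble_full_space_rdms(rdms.gamma, rdms.gamma2, part)
    c = scf.mo_coeff
    d = c @ gf @ c.T
    g2 = np.einsum("pqrs,ap,bq,cr,ds->abcd", g2f, c, c, c, c, optimize=True)
    return d, g2


def _rhf_setup(bundle):
    pa, pb = rhf_partition(bundle.scf_a), rhf_partition(bundle.scf_b)
    ra, rb = rhf_rdms(), rhf_rdms()
    da = ao_density(bundle.scf_a, pa, ra.gamma)
    db = ao_density(bundle.scf_b, pb, rb.gamma)
    return pa, pb, ra, rb, da, db


# ---------------------------------------------------------------------------
# electrostatics
# ---------------------------------------------------------------------------

def test_e1_pol_vanishes_for_far_neutral_atoms():
    far = make_toy_dimer("hehe", 50.0)
    rep = sapt_report(far)
    assert abs(rep.e1_pol) < 1e-8


def test_e1_pol_point_charge_limit(hehe):
    """With the electron clouds removed, only the analytic nuclear Coulomb
    term survives."""
    cross = hehe.cross
    na = hehe.ints_a.n_basis
    nb = hehe.ints_b.n_basis
    zero_a, zero_b = np.zeros((na, na)), np.zeros((nb, nb))
    from dataclasses import replace
    bare = replace(cross, n_a_elec=0, n_b_elec=0)
    assert e1_pol(zero_a, zero_b, bare) == pytest.approx(cross.v_nn, abs=1e-14)


def test_e1_pol_trace_guard(hehe):
    with pytest.raises(ValueError, match="electrons"):
        e1_pol(np.zeros_like(hehe.ints_a.overlap),
               np.zeros_like(hehe.ints_b.overlap), hehe.cross,
               hehe.ints_a.overlap, hehe.ints_b.overlap)


def test_generalized_jk(water_eq):
    b = water_eq
    pa, pb, ra, rb, da, db = _rhf_setup(b)
    pol = e1_pol(da, db, b.cross, b.ints_a.overlap, b.ints_b.overlap)
    jk_a = build_generalized_jk(b.cross, db, b.ints_a.overlap, side="a")
    assert np.sum(da * jk_a.j_tilde) == pytest.approx(pol, abs=1e-10)
    jk_b = build_generalized_jk(b.cross, da, b.ints_b.overlap, side="b")
    assert np.sum(db * jk_b.j_tilde) == pytest.approx(pol, abs=1e-10)
    # dressing off -> ordinary Coulomb matrix from the cross ERIs
    stripped = scale_cross(b.cross, 0.0)
    from dataclasses import replace
    stripped = replace(stripped, v_b_on_a=0 * b.cross.v_b_on_a,
                       v_a_on_b=0 * b.cross.v_a_on_b, v_nn=0.0)
    jk0 = build_generalized_jk(stripped, db, b.ints_a.overlap, side="a")
    j_plain = np.einsum("pqrs,rs->pq", b.cross.eri_aabb, db, optimize=True)
    assert np.allclose(jk0.j_tilde, j_plain, atol=1e-12)
    assert np.allclose(jk0.k_tilde, 0.0, atol=1e-12)


# ---------------------------------------------------------------------------
# exchange: brute-force first-quantized oracle (the decisive check)
# ---------------------------------------------------------------------------

def test_exchange_vs_brute_force_enumeration_rhf(hehe):
    """He-He at RHF: the full S^2 exchange against explicit enumeration of
    every <v(i,j) P_{i'j'}> term over electrons, permutations and spins."""
    b = hehe
    pa, pb, ra, rb, da, db = _rhf_setup(b)
    ex = e1_exch_s2(ra, rb, pa, pb, b.scf_a, b.scf_b, b.cross)
    orbs_a = np.zeros((2, 1))
    orbs_a[0, 0] = b.scf_a.mo_coeff[0, 0]
    orbs_b = np.zeros((2, 1))
    orbs_b[1, 0] = b.scf_b.mo_coeff[0, 0]
    sys4 = TwoElectronMonomerSystem(b.dimer, orbs_a, {(0, 0): 1.0},
                                    orbs_b, {(0, 0): 1.0})
    ref, e_pol_ref, perm_ref = sys4.exchange_s2()
    assert ex.total == pytest.approx(ref, abs=1e-12)
    pol = e1_pol(da, db, b.cross)
    assert pol == pytest.approx(e_pol_ref, abs=1e-12)
    assert ex.intermediates["p_perm"] == pytest.approx(perm_ref, abs=1e-12)


def test_exchange_vs_brute_force_enumeration_correlated(h2h2, h2h2_cas):
    """H2-H2 with FCI-correlated monomers: validates the two-particle-RDM
    (cumulant) pathway against the same first-principles enumeration."""
    b = h2h2
    (part_a, ham_a, cas_a), (part_b, ham_b, cas_b) = h2h2_cas
    ex = e1_exch_s2(cas_a.rdms, cas_b.rdms, part_a, part_b,
                    b.scf_a, b.scf_b, b.cross)
    na_ao = b.ints_a.n_basis
    orbs_a = np.zeros((na_ao + b.ints_b.n_basis, 2))
    orbs_a[:na_ao] = b.scf_a.mo_coeff
    orbs_b = np.zeros_like(orbs_a)
    orbs_b[na_ao:] = b.scf_b.mo_coeff
    # CI over closed-shell determinants |00bar> and |11bar>
    def ci_dict(cas):
        v = cas.ci_vector.reshape(2, 2)  # (alpha string, beta string)
        return {(0, 0): v[0, 0], (1, 1): v[1, 1]}
    sys4 = TwoElectronMonomerSystem(b.dimer, orbs_a, ci_dict(cas_a),
                                    orbs_b, ci_dict(cas_b))
    ref, e_pol_ref, perm_ref = sys4.exchange_s2()
    assert ex.total == pytest.approx(ref, abs=1e-11)
    da = ao_density(b.scf_a, part_a, cas_a.rdms.gamma)
    db = ao_density(b.scf_b, part_b, cas_b.rdms.gamma)
    assert e1_pol(da, db, b.cross) == pytest.approx(e_pol_ref, abs=1e-11)


# ---------------------------------------------------------------------------
# exchange: optimized path vs dense full-space oracle
# ---------------------------------------------------------------------------

def test_exchange_oracle_equivalence_h2h2(h2h2, h2h2_cas):
    b = h2h2
    (part_a, _, cas_a), (part_b, _, cas_b) = h2h2_cas
    ex = e1_exch_s2(cas_a.rdms, cas_b.rdms, part_a, part_b,
                    b.scf_a, b.scf_b, b.cross)
    da, g2a = _full_ao_rdms(b.scf_a, part_a, cas_a.rdms)
    db, g2b = _full_ao_rdms(b.scf_b, part_b, cas_b.rdms)
    ref = e1_exch_s2_oracle(da, g2a, db, g2b, b.cross,
                            b.ints_a.overlap, b.ints_b.overlap)
    assert ex.total == pytest.approx(ref, abs=1e-9)
    assert ex.total == pytest.approx(ex.t1 + ex.t2 + ex.t3 + ex.t4 + ex.t5,
                                     abs=1e-12)


def test_exchange_oracle_equivalence_water(water_stretched,
                                           water_stretched_cas):
    b = water_stretched
    part_a, _, cas = water_stretched_cas
    part_b, rb = rhf_partition(b.scf_b), rhf_rdms()
    ex = e1_exch_s2(cas.rdms, rb, part_a, part_b, b.scf_a, b.scf_b, b.cross)
    da, g2a = _full_ao_rdms(b.scf_a, part_a, cas.rdms)
    db, g2b = _full_ao_rdms(b.scf_b, part_b, rb)
    ref = e1_exch_s2_oracle(da, g2a, db, g2b, b.cross,
                            b.ints_a.overlap, b.ints_b.overlap)
    assert ex.total == pytest.approx(ref, abs=1e-9)


def test_exchange_s2_overlap_scaling(h2h2, h2h2_cas):
    """The exchange is second order in the intermolecular overlap: scaling
    every overlap-carrying block by lambda scales it by lambda^2."""
    b = h2h2
    (part_a, _, cas_a), (part_b, _, cas_b) = h2h2_cas
    lam = 1e-3
    ex1 = e1_exch_s2(cas_a.rdms, cas_b.rdms, part_a, part_b,
                     b.scf_a, b.scf_b, b.cross)
    ex_l = e1_exch_s2(cas_a.rdms, cas_b.rdms, part_a, part_b,
                      b.scf_a, b.scf_b, scale_cross(b.cross, lam))
    # remove the e_pol*<P> piece's own lambda-independent e_pol prefactor:
    # both T-sum and <P> scale as lambda^2, so the total does too
    assert ex_l.total == pytest.approx(lam ** 2 * ex1.total,
                                       rel=1e-4, abs=1e-18)
    ex_0 = e1_exch_s2(cas_a.rdms, cas_b.rdms, part_a, part_b,
                      b.scf_a, b.scf_b, scale_cross(b.cross, 0.0))
    assert ex_0.total == 0.0


def test_exchange_vanishes_at_long_range():
    rep = sapt_report(make_toy_dimer("h2h2", 50.0))
    assert abs(rep.e1_exch_s2) < 1e-10


def test_exchange_swap_symmetry(water_stretched, water_stretched_cas):
    b = water_stretched
    part_a, _, cas = water_stretched_cas
    part_b, rb = rhf_partition(b.scf_b), rhf_rdms()
    ex = e1_exch_s2(cas.rdms, rb, part_a, part_b, b.scf_a, b.scf_b, b.cross)
    swapped = DimerSystem(b.dimer.monomer_b, b.dimer.monomer_a,
                          b.dimer.basis_b, b.dimer.basis_a)
    cross_sw = compute_cross_integrals(swapped)
    ex_sw = e1_exch_s2(rb, cas.rdms, part_b, part_a, b.scf_b, b.scf_a,
                       cross_sw)
    assert ex.total == pytest.approx(ex_sw.total, abs=1e-9)


def test_exchange_heitler_london_consistency(water_eq):
    """For RHF monomers the first-order SAPT total must reproduce the sign
    and bulk of the non-orthogonal-determinant (Heitler-London) interaction;
    they differ by S^3+ terms and zeroth-order exchange-deformation."""
    b = water_eq
    pa, pb, ra, rb, da, db = _rhf_setup(b)
    pol = e1_pol(da, db, b.cross)
    ex = e1_exch_s2(ra, rb, pa, pb, b.scf_a, b.scf_b, b.cross)
    hl = heitler_london_interaction(b.dimer)
    assert hl < 0  # hydrogen-bonded minimum
    assert pol + ex.total < 0
    assert abs((pol + ex.total) - hl) < 0.5 * abs(hl)


def test_long_range_decay_rates():
    """E1_pol of neutral monomers decays polynomially; the exchange decays
    faster than any power (overlap-driven)."""
    pols, exs = [], []
    for r in (10.0, 15.0, 20.0):
        rep = sapt_report(make_toy_dimer("h2h2", r, basis="sto-3g"))
        pols.append(abs(rep.e1_pol))
        exs.append(abs(rep.e1_exch_s2) + 1e-300)
    # quadrupole-quadrupole electrostatics ~ R^-5: polynomially slow decay
    assert 0.02 < pols[1] / pols[0] < 0.5
    # exchange decays exponentially: many orders faster over the same step
    assert exs[1] < 1e-4 * exs[0] + 1e-25


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def test_sapt_report_rhf_schema(water_eq):
    rep = sapt_report(water_eq.dimer, cross=water_eq.cross)
    d = rep.as_dict()
    assert set(d["exchange_breakdown_hartree"]) == {"t1", "t2", "t3", "t4", "t5"}
    assert d["e1_pol_kcal_mol"] == pytest.approx(d["e1_pol_hartree"] * 627.5094740631)
    assert d["monomers"]["a"]["solver"] == "rhf"


def test_sapt_vqe_equals_sapt_casci_2e2o(h2h2, h2h2_cas):
    """With an exactly expressive ansatz the VQE and CASCI components must
    coincide."""
    t_cas = MonomerTreatment("casci", 2, 2)
    t_vqe = MonomerTreatment("vqe", 2, 2, k=1, seed=0)
    rep_cas = sapt_report(h2h2.dimer, t_cas, t_cas, cross=h2h2.cross)
    rep_vqe = sapt_report(h2h2.dimer, t_vqe, t_vqe, cross=h2h2.cross)
    assert rep_vqe.e1_pol == pytest.approx(rep_cas.e1_pol, abs=1e-6)
    assert rep_vqe.e1_exch_s2 == pytest.approx(rep_cas.e1_exch_s2, abs=1e-6)


def test_sapt_report_stage_error():
    bad = make_toy_dimer("hehe", 3.0)
    with pytest.raises(RuntimeError, match="stage"):
        sapt_report(bad, MonomerTreatment("casci", 2, 5))  # window too big


def test_translation_invariance_end_to_end():
    d = make_toy_dimer("h2h2", 3.0)
    r1 = sapt_report(d)
    r2 = sapt_report(d.translated([0.5, -1.0, 2.0]))
    assert r1.e1_pol == pytest.approx(r2.e1_pol, abs=1e-9)
    assert r1.e1_exch_s2 == pytest.approx(r2.e1_exch_s2, abs=1e-9)
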