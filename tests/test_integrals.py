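import math

import numpy as np
import pytest

from saptvqe.constants import ANGSTROM_TO_BOHR
from saptvqe.integrals import (ScfConvergenceError, compute_cross_integrals,
                               compute_monomer_integrals, run_rhf,
                               supermolecular_rhf_interaction)
from saptvqe.integrals import _engine as eng
from saptvqe.integrals.basis import BasisSet
from saptvqe.integrals.scf import rhf
from saptvqe.molsys import Molecule, make_toy_dimer, make_water_dimer

from .oracles import _boys_ref, os_eri_primitive


# ---------------------------------------------------------------------------
# engine primitives vs independent references
# ---------------------------------------------------------------------------

def test_boys_function_vs_scipy():
    xs = [0.0, 1e-8, 0.1, 1.0, 7.3, 25.0, 29.9, 30.1, 80.0, 400.0]
    out = np.empty(9)
    for x in xs:
        eng.boys(8, x, out)
        for m in range(9):
            assert out[m] == pytest.approx(_boys_ref(m, x), abs=1e-13, rel=1e-12)


@pytest.mark.parametrize("seed", [0, 1])
def test_eri_engine_vs_obara_saika(seed):
    """Raw primitive Cartesian ERIs from the McMurchie-Davidson kernel must
    match an independent Obara-Saika recursion, including d shells."""
    rng = np.random.default_rng(seed)
    shells = []  # (l, exponent, center)
    for l in (0, 1, 2):
        shells.append((l, 0.3 + 2.0 * rng.random(), rng.normal(size=3)))
    from saptvqe.integrals.basis import CART_COMPONENTS, Shell

    bas = BasisSet.__new__(BasisSet)
    raw = [Shell(l, c, np.array([a]), np.array([1.0]), i)
           for i, (l, a, c) in enumerate(shells)]
    bas._init_from_shells(raw, "testing")
    # raw Cartesian integrals (no spherical transform, no normalization)
    pl = eng.PairList(bas, bas, symmetric=False)
    got = np.zeros((bas.n_cart,) * 4)
    eng._eri_kernel(pl.l1, pl.l2, pl.off1, pl.off2, pl.pp_ptr, pl.pp_p,
                    pl.pp_P, pl.pp_coef, pl.e3, pl.e3_ptr, pl.schwarz,
                    pl.l1, pl.l2, pl.off1, pl.off2, pl.pp_ptr, pl.pp_p,
                    pl.pp_P, pl.pp_coef, pl.e3, pl.e3_ptr, pl.schwarz,
                    False, False, False, 0.0, got)
    offs = bas.cart_offsets
    checked = 0
    for i1, (l1, a1, c1) in enumerate(shells):
        for i2, (l2, a2, c2) in enumerate(shells):
            for i3, (l3, a3, c3) in enumerate(shells):
                for c_1, t1 in enumerate(CART_COMPONENTS[l1]):
                    for c_2, t2 in enumerate(CART_COMPONENTS[l2]):
                        t3 = CART_COMPONENTS[l3][0]
                        ref = os_eri_primitive(t1, a1, c1, t2, a2, c2,
                                               t3, a3, c3,
                                               (0, 0, 0), shells[0][1],
                                               shells[0][2])
                        val = got[offs[i1] + c_1, offs[i2] + c_2,
                                  offs[i3], offs[0]]
                        assert val == pytest.approx(ref, rel=1e-10, abs=1e-14)
                        checked += 1
    assert checked > 50


def test_h_atom_minimal_overlap_is_identity():
    h = Molecule(("H",), np.zeros((1, 3)), multiplicity=2)
    bas = BasisSet(h, "sto-3g")
    s = eng.overlap(bas, bas)
    assert s.shape == (1, 1)
    assert s[0, 0] == pytest.approx(1.0, abs=1e-12)


def test_single_gaussian_hydrogen_variational_closed_form():
    """For one s Gaussian with exponent alpha on a proton: <T> = 3a/2 and
    <V> = -sqrt(8a/pi); checks kinetic and nuclear-attraction kernels
    against analytic values."""
    from saptvqe.integrals.basis import Shell

    for alpha in (0.3, 8.0 / (9.0 * math.pi), 2.5):
        bas = BasisSet.__new__(BasisSet)
        from saptvqe.integrals.basis import primitive_norm
        bas._init_from_shells(
            [Shell(0, np.zeros(3), np.array([alpha]),
                   np.array([primitive_norm(alpha, 0)]), 0)], "single")
        t = eng.kinetic(bas)[0, 0]
        v = eng.nuclear_attraction(bas, bas, [1.0], np.zeros((1, 3)))[0, 0]
        assert t == pytest.approx(1.5 * alpha, rel=1e-12)
        assert v == pytest.approx(-math.sqrt(8.0 * alpha / math.pi), rel=1e-12)


def test_overlap_spectrum_invariant_under_atom_permutation():
    w = make_water_dimer().monomer_a
    perm = Molecule((w.elements[1], w.elements[2], w.elements[0]),
                    w.coords[[1, 2, 0]])
    s1 = compute_monomer_integrals(w, "6-31g").overlap
    s2 = compute_monomer_integrals(perm, "6-31g").overlap
    assert np.allclose(np.linalg.eigvalsh(s1), np.linalg.eigvalsh(s2),
                       atol=1e-10)


def test_monomer_integral_symmetries(water_eq):
    ints = water_eq.ints_a
    s, eri = ints.overlap, ints.eri
    assert np.allclose(s, s.T, atol=1e-12)
    assert np.linalg.eigvalsh(s).min() > 1e-10
    assert np.allclose(eri, eri.transpose(1, 0, 2, 3), atol=1e-10)
    assert np.allclose(eri, eri.transpose(0, 1, 3, 2), atol=1e-10)
    assert np.allclose(eri, eri.transpose(2, 3, 0, 1), atol=1e-10)


# ---------------------------------------------------------------------------
# cross integrals
# ---------------------------------------------------------------------------

def test_cross_nuclear_repulsion_point_charges():
    d = make_toy_dimer("h2h2", 10.0)
    cross = compute_cross_integrals(d)
    za = d.monomer_a.atomic_numbers
    ref = sum(za[i] * za[j]
              / np.linalg.norm(d.monomer_a.coords[i] - d.monomer_b.coords[j])
              for i in range(2) for j in range(2))
    assert cross.v_nn == pytest.approx(ref, rel=1e-14)


def test_cross_overlap_decays():
    far = compute_cross_integrals(make_toy_dimer("hehe", 50.0))
    assert np.max(np.abs(far.s_ab)) < 1e-8


def test_cross_eri_point_charge_limit():
    d = make_toy_dimer("h2h2", 20.0)
    cross = compute_cross_integrals(d)
    # centers of the leading s functions sit on the atoms; (11|11) across
    # 20 A approaches q^2/R for unit charge distributions
    r = np.linalg.norm(d.monomer_a.coords[0] - d.monomer_b.coords[0])
    assert cross.eri_aabb[0, 0, 0, 0] == pytest.approx(1.0 / r, rel=1e-2)


def test_cross_transpose_symmetry(h2h2):
    from saptvqe.molsys import DimerSystem
    d = h2h2.dimer
    swapped = DimerSystem(d.monomer_b, d.monomer_a, d.basis_b, d.basis_a)
    c1 = h2h2.cross
    c2 = compute_cross_integrals(swapped)
    assert np.allclose(c1.s_ab, c2.s_ab.T, atol=1e-12)
    assert np.allclose(c1.eri_aabb, c2.eri_aabb.transpose(2, 3, 0, 1),
                       atol=1e-12)
    assert np.allclose(c1.v_b_on_a, c2.v_a_on_b, atol=1e-12)


def test_integrals_translation_invariance():
    d = make_toy_dimer("h2h2", 3.0)
    shift = np.array([1.7, -0.4, 2.2])
    d2 = d.translated(shift)
    c1 = compute_cross_integrals(d)
    c2 = compute_cross_integrals(d2)
    assert np.allclose(c1.s_ab, c2.s_ab, atol=1e-10)
    assert np.allclose(c1.eri_abab, c2.eri_abab, atol=1e-10)
    assert c1.v_nn == pytest.approx(c2.v_nn, abs=1e-10)


# ---------------------------------------------------------------------------
# RHF
# ---------------------------------------------------------------------------

def test_rhf_two_electron_one_function_closed_form():
    he = Molecule(("He",), np.zeros((1, 3)))
    ints = compute_monomer_integrals(he, "sto-3g")
    scf = run_rhf(ints)
    closed = 2 * ints.core_h[0, 0] + ints.eri[0, 0, 0, 0]
    assert scf.e_total == pytest.approx(closed, abs=1e-12)
    assert scf.converged


def test_rhf_orthonormality_and_order(water_eq):
    scf, ints = water_eq.scf_a, water_eq.ints_a
    c = scf.mo_coeff
    assert np.allclose(c.T @ ints.overlap @ c, np.eye(c.shape[1]), atol=1e-8)
    assert np.all(np.diff(scf.mo_energy) >= -1e-10)


def test_rhf_too_many_electrons_rejected():
    he = Molecule(("He",), np.zeros((1, 3)))
    ints = compute_monomer_integrals(he, "sto-3g")
    with pytest.raises(ValueError):
        run_rhf(ints, n_elec=4)
    with pytest.raises(ValueError):
        run_rhf(ints, n_elec=3)


def test_supermolecular_limits():
    far = make_toy_dimer("hehe", 50.0)
    assert abs(supermolecular_rhf_interaction(far)) < 1e-6
    # translation invariance of E_int
    near = make_toy_dimer("h2h2", 3.0)
    e1 = supermolecular_rhf_interaction(near)
    e2 = supermolecular_rhf_interaction(near.translated([0.3, 1.1, -2.0]))
    assert e1 == pytest.approx(e2, abs=1e-9)


def test_supermolecular_water_dimer_bound(water_eq):
    e_int = supermolecular_rhf_interaction(water_eq.dimer)
    assert e_int < 0.0  # hydrogen bond


def test_rhf_energies_match_published_values(water_eq):
    """Two classic anchors for the whole integrals+SCF stack."""
    # H2 at 0.7414 A in STO-3G
    d = make_toy_dimer("h2h2", 10.0)
    scf = run_rhf(compute_monomer_integrals(d.monomer_a, "sto-3g"))
    assert scf.e_total == pytest.approx(-1.11668, abs=2e-5)
    # water 6-31G at the textbook geometry
    assert water_eq.scf_a.e_total == pytest.approx(-75.9840, abs=2e-3)


def test_optional_integral_cache_roundtrip(tmp_path):
    h5py = pytest.importorskip("h5py")
    from saptvqe.integrals.cache import cached_monomer_integrals
    from saptvqe.molsys import make_toy_dimer

    mol = make_toy_dimer("hehe", 3.0).monomer_a
    first = cached_monomer_integrals(mol, "sto-3g", str(tmp_path))
    second = cached_monomer_integrals(mol, "sto-3g", str(tmp_path))
    assert np.array_equal(first.eri, second.eri)  # bit-identical on hit
    assert np.array_equal(first.overlap, second.overlap)
    assert first.nuclear_repulsion == second.nuclear_repulsion
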