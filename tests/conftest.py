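"""Shared, session-cached heavy fixtures: integrals, SCF and CASCI bundles
for the benchmark systems. Everything is generated programmatically."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from saptvqe.active_space import (OrbitalPartition, ao_density,
                                  build_active_hamiltonian, select_window)
from saptvqe.integrals import (CrossIntegrals, MonomerIntegrals, SCFState,
                               compute_cross_integrals,
                               compute_monomer_integrals, run_rhf)
from saptvqe.molsys import DimerSystem, make_toy_dimer, make_water_dimer
from saptvqe.sapt1 import rhf_partition, rhf_rdms
from saptvqe.solvers import CASCIResult, casci_solve


@dataclass
class DimerBundle:
    dimer: DimerSystem
    ints_a: MonomerIntegrals
    ints_b: MonomerIntegrals
    scf_a: SCFState
    scf_b: SCFState
    cross: CrossIntegrals


def _bundle(dimer: DimerSystem) -> DimerBundle:
    ints_a = compute_monomer_integrals(dimer.monomer_a, dimer.basis_a)
    ints_b = compute_monomer_integrals(dimer.monomer_b, dimer.basis_b)
    return DimerBundle(dimer, ints_a, ints_b, run_rhf(ints_a), run_rhf(ints_b),
                       compute_cross_integrals(dimer))


@pytest.fixture(scope="session")
def hehe():
    return _bundle(make_toy_dimer("hehe", 3.0))


@pytest.fixture(scope="session")
def h2h2():
    return _bundle(make_toy_dimer("h2h2", 3.5))


@pytest.fixture(scope="session")
def water_eq():
    return _bundle(make_water_dimer(0.9572))


@pytest.fixture(scope="session")
def water_stretched():
    return _bundle(make_water_dimer(2.0))


@pytest.fixture(scope="session")
def water_stretched_cas(water_stretched):
    """(6e,6o) CASCI on the stretched water monomer A."""
    b = water_stretched
    part = select_window(b.scf_a, 6, 6)
    ham = build_active_hamiltonian(b.ints_a, b.scf_a, part)
    return part, ham, casci_solve(ham)


@pytest.fixture(scope="session")
def h2h2_cas(h2h2):
    """(2e,2o) CASCI (= FCI) for both H2 monomers."""
    out = []
    for ints, scf in ((h2h2.ints_a, h2h2.scf_a), (h2h2.ints_b, h2h2.scf_b)):
        part = select_window(scf, 2, 2)
        ham = build_active_hamiltonian(ints, scf, part)
        out.append((part, ham, casci_solve(ham)))
    return out
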