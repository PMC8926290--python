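# saptvqe

First-order symmetry-adapted perturbation theory (SAPT) for intermolecular
interaction energies, computed from the one- and two-particle reduced
density matrices of active-space monomer wavefunctions — solved by
restricted Hartree–Fock, exact active-space diagonalization (CASCI), or an
ideal-statevector VQE with a k-layer modified unitary cluster-Jastrow
(k-muCJ) circuit.

## Why

Computing a protein–ligand interaction energy as E_AB − E_A − E_B demands
resolving total energies of thousands of kcal/mol to sub-kcal/mol precision
— brutal for near-term quantum algorithms, whose total energies carry large
ansatz and optimization errors. SAPT instead evaluates the interaction
*directly* as expectation values of the intermolecular operator V̂ over the
monomer ground states:

    E_int = E1_pol + E1_exch + (higher orders)

    E1_pol        = <Ψ_A Ψ_B | V̂ | Ψ_A Ψ_B>
    E1_exch(S²)   = −<V̂ P̂> + E1_pol <P̂>,   P̂ = Σ_{i∈A, j∈B} P_ij

truncated at second order in the intermolecular overlap (S²). Both terms
need only the spin-summed monomer RDMs γ and Γ, which is all a quantum
solver has to deliver. Errors of an approximate monomer wavefunction largely
cancel in these components: a k=1 muCJ wavefunction whose total energy is
wrong by >10 kcal/mol still yields interaction components accurate to a few
hundredths of a kcal/mol. Monomer-centered bases are used throughout (no
counterpoise machinery), and core electrons are folded into an embedded
active-space Hamiltonian so the quantum resource is 2·N_a qubits — e.g. 12
qubits for a (6e,6o) monomer.

The package is self-contained: it carries its own Gaussian-integrals engine
(McMurchie–Davidson, numba), RHF, determinant CASCI, and Jordan–Wigner
statevector simulator, plus deterministic fixture generators for every
benchmark system (water dimer with a symmetrically stretched monomer,
T-shaped benzene–p-benzyne, H₂–H₂/He–He toys).

## Worked example

Stretched-water dimer (6-31G): the acceptor water's two O–H bonds are
stretched to 2.0 Å — a double bond-breaking that RHF cannot describe — and
solved in a (6e,6o) active space, with the donor water at RHF:

```python
from saptvqe.molsys import make_water_dimer
from saptvqe.sapt1 import MonomerTreatment, sapt_report

dimer = make_water_dimer(2.0)          # monomer A = stretched water
report = sapt_report(
    dimer,
    MonomerTreatment("vqe", n_active_elec=6, n_active_orb=6, k=1, seed=0),
    MonomerTreatment("rhf"),
)
print(f"E1_pol      = {report.e_pol_kcal:8.3f} kcal/mol")
print(f"E1_exch(S2) = {report.e_exch_kcal:8.3f} kcal/mol")
```

Output:

    E1_pol      =   -1.376 kcal/mol
    E1_exch(S2) =    3.137 kcal/mol

The same calculation with `MonomerTreatment("casci", 6, 6)` gives −1.226 and
3.127 kcal/mol: the k=1 components are within 0.15 kcal/mol of the exact
active-space answer, while the VQE *total* energy is off by ~4.7 kcal/mol —
the error contraction that motivates the method. (VQE numbers quoted for
seed 0.)

The same pipeline is available from the shell:

    saptvqe --config run.yaml --output report.json

with a YAML config selecting fixtures or XYZ files, per-monomer solvers and
active spaces (see `saptvqe/cli.py` docstring for the schema). Reports carry
both hartree and kcal/mol values, the T1..T5 exchange breakdown, and solver
metadata.

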